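gene	symbol	function	stress
b0605	ahpC	reduction of hydroperoxide substrate.	Oxidative
b0606	ahpF	reduction of hydroperoxide substrate.	Oxidative
b2962	yggX	protect iron-sulfur proteins	Oxidative
b4209	ytfE	Iron-sulfur cluster repair	Oxidative
b3662	nepI	purine ribonucleoside exporter	Oxidative
b0812	dps	DNA damage protection and iron sequestration	Oxidative
b3961	oxyR	Regulator for the expression of antioxidant genes	Oxidative
b4062	soxS	Transcriptional activator for the superoxide response regulon	Oxidative
b4063	soxR	Redox-sensitive transcriptional activator of soxS	Oxidative
b0439	lon	Degradation of abnormal proteins	Thermal
b3509	hdeB	Periplasmic chaperone for acid stress protection	Acid
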