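# stressme

Desk-scale, self-contained modeling of *E. coli*-style **metabolism and
expression (ME) under combined stress**: thermal (protein folding and
chaperone competition), acid (periplasmic stability, HdeB protection,
membrane response) and oxidative (ROS damage and repair of
metalloproteins), coupled through a shared proteome budget.

## Who this is for

Systems biologists who want the *mechanisms* of stress-coupled ME
modeling — growth-rate-coupled enzyme synthesis, stability-driven folding
workloads, damage/repair cycles, keff quality control, flux variability
analysis — in a package small enough to run on a laptop, inspect line by
line, and extend, rather than a genome-scale reconstruction that needs a
cluster and a quad-precision solver.

## The model

An ME model couples every catalysed flux to the synthesis cost of its
catalyst.  At growth rate μ (h⁻¹), sustaining a metabolic flux
v<sub>metabolic</sub> requires catalyst synthesis

> v<sub>translation</sub> ≥ (μ / k<sub>eff</sub>) · v<sub>metabolic</sub>

with k<sub>eff</sub> the enzyme's effective turnover rate (stored in s⁻¹,
converted to h⁻¹ internally).  μ/k<sub>eff</sub> is the small amount of
catalyst tied up per unit flux, so slow enzymes are expensive: dropping
k<sub>eff</sub> from 88.72 to 0.01 s⁻¹ raises the enzyme demand exactly
8872-fold.  All μ-dependent coefficients are linear at fixed μ, so the
model is solved as a family of LPs (HiGHS via `scipy.optimize.linprog`)
with the maximal growth rate located by bisection.

Stress enters through condition-dependent coefficients evaluated at LP
assembly:

* **Thermal** — each protein carries a Gibbs–Helmholtz stability curve
  ΔG(T); the unfolding equilibrium Keq(T) = exp(−ΔG/RT) pins a recycle
  flux through the unfolded state, and three competing folding routes
  (spontaneous, DnaK, GroEL/ES, plus Lon degradation) serve that
  workload at temperature- and aggregation-dependent turnover numbers.
  Metabolic keffs rise with temperature (Arrhenius), so growth versus
  temperature is unimodal: kinetics win below the optimum, folding
  workloads win above it.
* **Acid** — periplasmic proteins are destabilised by a linear ΔG shift
  per pH unit below 7 (HdeB opens a protected folding route below pH 6);
  membrane-enzyme keffs scale with a pH-dependent activity factor; the
  membrane lipid pseudo-reaction shifts toward unsaturated fatty acids.
* **Oxidative** — superoxide and peroxide (basal levels × a multiplier)
  drive demetallation of Fe(II) enzymes and Fe–S cluster oxidation in
  proportion to each target's turnover; repair runs through slow
  YtfE-coupled machinery, released Fe(II) is sequestered by Dps or feeds
  Fenton chemistry, and a mismetallated Mn(II) variant lets the LP trade
  activity for invulnerability.

A global proteome constraint ties it together: modeled translation mass
equals (1 − unmodeled fraction) · μ · total proteome mass, with the
unmodeled fraction (default 10%) carried by a dedicated sink.

The packaged **toy network** (deterministic from a seed; ~60 species,
~112 reactions, 23 proteins) expresses every mechanism: an acetate
overflow branch with alternative catalysts (acetate-kinase/GAR-
transformylase pair), Fe–S-dependent and Fe–S-free NADH dehydrogenases,
an essential melting-prone DXP-reductoisomerase analogue whose keff
differs 0.01 vs 88.72 s⁻¹ between the wild-type and heat-evolved
kinetomes, and a redundant homocysteine-lyase pathway pair.

## Worked example

```bash
$ stressme make-toy --seed 7 --out toy_model.json
wrote toy_model.json: 60 metabolites, 112 reactions, 23 proteins

$ stressme solve toy_model.json --temp 42 --ros 1 --tol 1e-5
T42C_pH7_ROS1x keff=wild_type: mu* = 1.243406 1/h
modeled protein fraction = 0.9000
  ndh1         0.4365
  tca          0.1745
  aasyn        0.1080
  dnaK         0.0601
  dxr          0.0505
```

At 42 °C the wild-type kinetome still grows (μ* ≈ 1.24 h⁻¹), but the
proteome is dominated by the respiratory complex-I analogue and the TCA
enzyme, the DnaK chaperone has entered the top five (6% of modeled
protein mass — folding workloads are ramping up), and the slow
(0.01 s⁻¹) reductoisomerase consumes 5% of the proteome on a tiny flux.
The modeled protein fraction sits at 90%, the structural complement of
the 10% unmodeled reserve.

```bash
$ stressme screen toy_model.json --tol 1e-4 --out screen.csv
wrote screen.csv (6 swapped reactions)
most sensitive: DXPRIi (mu 1.1412 -> 1.2047)
```

The single-effect sensitivity screen swaps one keff at a time from the
wild-type to the heat-evolved vector at 37 °C: only the
DXP-reductoisomerase swap moves growth materially (+0.064 h⁻¹); the
redundant lyase and the remaining drifts rank far below, which is the
basis for consolidating the two kinetomes with a single override
(`stressme.kinetome.consolidate`).

Condition grids (`stressme grid --temps 26,…,46 --phs 7,5 --ros 1,10`)
emit `phenotypes.csv`, `proteome.csv` and `fluxome.csv`;
`stressme fva` reports exchange-flux ranges at fixed growth fractions
(uptake negative, secretion positive).

## Layout

| module | contents |
| --- | --- |
| `stressme.core` | metabolites, μ-linear reactions, proteins, conditions, model JSON I/O |
| `stressme.solver` | LP assembly, growth bisection, fixed-growth optimisation, knockouts |
| `stressme.thermal` | stability curves, folding network, Lon degradation |
| `stressme.acid` | periplasmic Keq(pH, T), HdeB, lipid composition, membrane activity |
| `stressme.oxidative` | ROS environment, damage rules, Fe–S cycles, Fenton/Dps, mismetallation |
| `stressme.kinetome` | keff vectors (TSV I/O), sensitivity screen, consolidation, redundancy probe |
| `stressme.analysis` | FVA, proteome mass fractions, category totals, mass-balance QC, condition grids |
| `stressme.fixtures` | deterministic toy generator, packaged stress-gene registry |

See `docs/methods.md` for the modeling choices, parameter meanings and
known limitations.
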