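# Methods

This note records the model structure, the reasoning behind the open
design choices, the parameters that matter, and what the packaged toy
network can and cannot show.

## Growth-coupled LP and bisection

At fixed growth rate μ the model is a linear program over reaction
fluxes v (mmol gDW⁻¹ h⁻¹):

* **Mass balance** Σᵣ S(μ)ₘᵣ vᵣ = 0 for every species, including protein
  species (native, unfolded, damaged, apo forms).  Stoichiometric
  coefficients may be linear in μ (`{"const": c, "mu_coeff": m}` in the
  model JSON).
* **Enzyme coupling**, one row per catalyst form:
  Σᵣ (μ/k<sub>eff,r</sub>) vᵣ ≤ v<sub>dilution</sub>.  Enforced as an
  inequality — the demand is *at least* μ·v/k<sub>eff</sub>; surplus
  protein simply dilutes.  keffs are stored in s⁻¹ as conventionally
  printed and converted by ×3600, since μ and fluxes are per hour; any
  ratio of demands is unit-invariant.  Reactions with several admissible
  catalysts (a GPR OR rule) are split into one LP column per catalyst,
  each drawing on its own catalyst's capacity.
* **Proteome budget**: Σ mw·v<sub>translation</sub> over modeled proteins
  = (1 − f<sub>unmodeled</sub>)·μ·P<sub>tot</sub> (equality), and an
  unmodeled-protein sink pinned to the remaining f<sub>unmodeled</sub>
  share.  Defaults: f = 0.10, P<sub>tot</sub> = 0.55 g protein/gDW.  The
  equality makes the "modeled fraction = 90%" check a structural
  identity of any optimal solution, and it encodes the biological
  assumption that the cell maintains a full proteome whether or not all
  of it is catalytically employed.  Ballast synthesis is absorbed by a
  designated inert bulk protein whose translation costs marginally less
  ATP per residue (3.8 vs 4.0), which breaks vertex degeneracy and keeps
  solutions reproducible.

Feasibility of this LP is monotone in μ (every μ-dependent demand
relaxes as μ falls; the toy suite verifies this by grid scan), so the
maximal growth rate is found by bisection on [0, 3] h⁻¹ to a default
tolerance of 10⁻⁶ h⁻¹.  LPs are solved in double precision with HiGHS;
primal/dual feasibility tolerances are tightened to 10⁻¹⁰/10⁻⁹ because
coupling coefficients reach O(10⁻⁶) and looser tolerances let visible
flux leak through zero-capacity enzymes.  Whether the coupling should be
an equality or ≥ is genuinely open; ≥ was chosen as the weaker, safer
reading, and none of the packaged behaviors depend on the difference
(dilution of surplus is always available either way).

`fix_growth_and_optimize` re-solves the same LP at a fixed μ with an
arbitrary reaction objective; FVA is min/max of exchange targets at
growth fractions (default endpoints 0.95 and 1.0), reported
secretion-positive / uptake-negative.

## Thermal module

Unfolding free energy uses the Gibbs–Helmholtz form
ΔG(T) = ΔH<sub>m</sub>(1 − T/T<sub>m</sub>) − C<sub>p</sub>((T<sub>m</sub> − T) + T ln(T/T<sub>m</sub>)),
zero at the melting point by construction, with per-protein
(ΔH<sub>m</sub>, C<sub>p</sub>, T<sub>m</sub>).  The validity window is
293–323 K; outside it values are still returned with a warning.
Keq(T) = exp(−ΔG/RT) is clipped at 10³ inside LP rows: beyond that the
folding workload already exceeds turnover a thousandfold and growth has
collapsed, while the clip keeps the constraint matrix well scaled.

The steady-state unfolded share is imposed as a hard partition rather
than reversible mass action (which would be nonlinear at fixed μ): the
unfolding back-reaction is pinned to v<sub>unfold</sub> = Keq ·
v<sub>dilution</sub>, so the folding routes process
(1 + Keq) × turnover and the unfolded share of processed flux is
Keq/(1 + Keq).  Folding is competitive among three routes, and the LP
picks the cheapest mix:

* *spontaneous*: coupled to the client's own native pool with turnover
  kf(T)/(1 + agg), where kf(T) = kf_ref·exp(−0.45·(T − 310.15)) above
  the reference temperature (held at kf_ref below it; cold denaturation
  is out of scope).  Slow folders tie up their own copies.
* *DnaK* (5 ATP/event) and *GroEL/ES* (7 ATP/event): coupled to the
  chaperone's pool at base turnovers 0.004 and 0.002 s⁻¹ with
  aggregation boosts (1 + agg)¹ and (1 + agg)², reflecting that
  aggregation-prone clients are preferentially chaperone substrates.
  How the upstream models combine kf and agg into pathway propensities
  is not restated in this package's sources; this partition is a
  declared design choice.

Lon degrades unfolded protein at 0.05 s⁻¹ with full amino-acid recycle
(0.5 ATP/residue), so translation = dilution + degradation holds exactly
at optimum.  Metabolic keffs carry an Arrhenius factor
exp(E<sub>a</sub>/R·(1/T<sub>ref</sub> − 1/T)) with E<sub>a</sub> =
25 kJ/mol (Q₁₀ ≈ 1.4); chaperone and machinery turnovers are treated as
temperature-robust.  The rising Arrhenius branch and the exploding
folding branch together produce the unimodal growth–temperature curve;
the wild-type kinetome peaks earlier than the heat-evolved one because
its slow reductoisomerase keff forces a large pool of the least stable
protein, whose folding workload detonates first.

## Acid module

Three channels, mirroring the periplasm-focused mechanisms the framework
models; cytoplasmic pH homeostasis, decarboxylase systems and proton
bioenergetics are deliberately absent.

* Periplasmic stability: ΔG is reduced by `slope · max(0, 7 − pH)` with
  slope 12 kJ/mol per pH unit — one interpretable knob standing in for
  per-protein pH curves.  The slope was fixed once so that unprotected
  periplasmic folding becomes clearly uneconomical around pH 5–5.5 while
  remaining negligible at neutral pH.
* HdeB: a protected spontaneous-folding route coupled to HdeB capacity
  (0.05 s⁻¹ base), open only below the activation pH 6.0 (configurable;
  the sources speak only of "acidic conditions").  Because HdeB is
  periplasmic, its cost meets cytoplasmic chaperones only through the
  shared proteome budget — the structural basis for acid response not
  competing directly with cytoplasmic folding.
* Membrane: lipid composition interpolates linearly between anchor rows
  at pH 7 (65/35 saturated/unsaturated) and pH 5 (45/55), each summing
  to one so total lipid mass is conserved; membrane-located enzymes
  (PTS transporter and both NADH dehydrogenases in the toy) have their
  keffs multiplied by an activity factor interpolated from
  {7: 1.0, 6: 0.85, 5: 0.6, 4.5: 0.5}.

## Oxidative module

The ROS environment is (superoxide, peroxide) = (0.02, 50) nM × a
condition multiplier; 0.02 nM superoxide anchors the "1×" level to the
validation range of the source models, while the peroxide basal is a
fixture choice (the sources do not define the "× basal" → concentration
mapping for H₂O₂).  Damage rows are linear at fixed μ: each forces
v<sub>damage</sub> = rate · [ROS] · v<sub>dilution</sub> of the target's
native form — first-order in ROS and in enzyme turnover, exactly zero at
zero ROS, and μ-independent as a coefficient.  Metal-centre mechanisms
read the superoxide level; Fenton-type chemistry reads peroxide.

Costs are arranged so damage is genuinely expensive rather than a free
repair loop: Fe insertion and Fe–S repair run through slow YtfE-coupled
machinery (5×10⁻⁴ s⁻¹; 5×10⁻⁵ for the essential biosynthetic target,
which therefore prefers Lon degradation plus resynthesis, visibly
inflating its mass fraction under ROS).  Released Fe(II) lands in a free
pool with two exits — Dps sequestration (0.5 s⁻¹, recycling iron to the
supply pool) or Fenton reaction with peroxide, whose hydroxyl radical
carries a lumped 5-ATP DNA-repair cost.  The free-iron balance row makes
iron conservation (released = Dps + Fenton) structural.  Endogenous
peroxide is generated in proportion to respiratory flux times the ROS
multiplier (2×10⁻³ per unit NADH-dehydrogenase flux) and detoxified by
an AhpC-like NADH peroxidase; tying generation to respiration keeps
zero-metabolism states feasible (a closed-medium model still solves at
μ = 0).  Mismetallation adds a Mn(II) holo-form of the mononuclear
Fe(II) enzyme at a keff penalty of 0.5: the Fe form wins at low ROS
(higher keff, lower demand), the Mn form takes over when
re-metallation cycling grows too costly.

Amino-acid supplementation presets map the four validation media to
uptake caps on the single lumped amino-acid exchange (full: 2.0, each
group-dropout: 1.4 mmol gDW⁻¹ h⁻¹); the toy does not resolve individual
amino acids, so group identity is not chemically meaningful here.

## The toy network: what it shows and what it does not

The generator emits, deterministically from a seed, a ~112-reaction
network with: periplasmic + PTS glucose uptake, lumped glycolysis, PDH,
TCA (pinned to a minimum duty by a 2-oxoglutarate requirement of amino-
acid synthesis), Fe–S-dependent (3 ATP/NADH) and Fe–S-free (1.5
ATP/NADH) respiratory routes, an acetate-overflow branch whose reaction
accepts either of two catalysts, the DXP-reductoisomerase analogue
(wild-type/heat-evolved keffs 0.01/88.72 s⁻¹, T<sub>m</sub> 312 K,
agg 3 — the designed thermal bottleneck), the redundant
lyase/cystathionine-β-lyase pair for homocysteine (keffs 0.01/28.8),
fatty-acid and lipid synthesis, biomass assembly pinned to μ, and the
full stress machinery (DnaK, GroEL, Lon, HdeB, Dps, YtfE, AhpC).
A closed xylose pathway provides a structurally blocked catalysed
reaction for screen diagnostics.  Mechanism-critical constants (the two
keff pairs, the 10% unmodeled fraction, the NADH-route economics) are
fixed; the seed jitters only non-critical molecular weights and keffs by
~3%, so a spec+seed pair reproduces byte-identical files.

Fixture calibration (keffs of order 1–10 s⁻¹ for bulk metabolism,
stability midpoints between 312 and 333 K, damage rates 2–25 per nM·h)
was chosen once to place the reference growth rate near 1.1 h⁻¹ at
37 °C and to make each designed phenomenon — unimodal growth in
temperature with the heat-evolved optimum at or above the wild-type's,
monotone decline under acid and ROS, chaperone and HdeB induction,
the NADH-route switch, acetate overflow, screen ranking — an economic
consequence of the coupling law rather than a hard-coded output.

What passing tests on this network do **not** show: agreement with any
organism's measured growth rates, temperatures or mass fractions; the
behavior of a genome-scale reconstruction (thousands of coupled
constraints, transcription units, full translation machinery); or
pH/ROS chemistry beyond the three acid channels and two damage
mechanisms modeled.  The toy demonstrates mechanisms and their
interactions, at a scale where every result can be cross-checked by
brute force.

## Numerical choices and degenerate inputs

* Bisection bracket [0, 3] h⁻¹, tolerance 10⁻⁶ h⁻¹ (tests use 10⁻⁴–10⁻⁵
  for speed); problem sizes in the suite are the full toy (~130 LP
  columns) and a 7-reaction model for closed-form and vertex-enumeration
  oracles.
* μ = 0 is handled as pure feasibility: the growth reaction is pinned to
  [0, 0] and the all-zero flux vector is feasible whenever exchange
  bounds admit zero; proteome rows degrade to 0 = 0.
* Mass-balance QC passes at |residual| ≤ 10⁻⁶ mmol gDW⁻¹ h⁻¹; observed
  residuals are ~10⁻¹⁴.
* Ties among alternative catalysts are left to the solver (alternative
  optima are accepted and tested for phenotype invariance, not catalyst
  identity); screen ranking breaks ties by |Δμ| descending, then
  reaction id ascending.
* Grid CSVs are written at six significant digits and reproduce
  byte-identically because every step (assembly, HiGHS, serialisation)
  is deterministic.

## Known limitations

Transcription, ribosomes, tRNA charging and mRNA are lumped into one
translation reaction per protein; chaperone stoichiometry and ATP costs
per folding event are plausible placeholders, configurable in
`ThermalConfig`; acid stability uses a single linear slope rather than
per-protein titration curves; the OxyR/SoxRS regulators appear only as
registry entries, not as regulatory logic; and keff values are inputs,
not fitted quantities — the kinetome tools diagnose and reconcile them
but do not estimate them from data.
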