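"""Deterministic synthetic mini-network and packaged reference tables.

The toy model stands in for a genome-scale reconstruction at desk scale:
~20 small molecules, ~2 dozen proteins and ~100 LP columns, rich enough to
express every stress mechanism the framework models.  Its backbone is a
lumped central metabolism (PTS-style glucose uptake through a periplasmic
step, glycolysis, pyruvate dehydrogenase, TCA, two NADH-dehydrogenase
routes of different ATP yield, an acetate-overflow branch with two
alternative catalysts) plus amino-acid, terpenoid (DXP-pathway analogue),
homocysteine (S-ribosylhomocysteine lyase vs cystathionine beta-lyase) and
membrane-lipid biosynthesis, a biomass assembly pinned to the growth rate
and a proteome budget with a 10% unmodeled reserve.

Stress machinery: cytoplasmic folding clients with DnaK/GroEL/Lon service,
a periplasmic substrate-binding protein protected by HdeB under acid,
iron-sulfur enzymes with YtfE repair, a demetallation/mismetallation pair,
Dps iron sequestration and Fenton chemistry.  Mechanism-critical constants
(the 0.01 / 88.72 s^-1 keff pair of the DXP-reductoisomerase analogue, the
0.01 / 28.8 pair of the lyase, the 10% unmodeled fraction) are fixed;
the seed only perturbs non-critical parameters within a few percent, so
the same spec and seed always emit a byte-identical model file.
"""

from __future__ import annotations

import importlib.resources as _resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    MEModel,
    Metabolite,
    MuLinear,
    ProteinSpec,
    Reaction,
    Stability,
)
from .thermal import ThermalConfig, build_folding_network, lon_degradation
from .acid import AcidResponseSpec, add_periplasmic_folding, add_hdeb_protection
from .oxidative import (
    RosEnvironment,
    add_demetallation,
    add_fe_s_cycle,
    add_fenton_and_dps,
    add_metalloprotein,
    mismetallation_variant,
)

__all__ = [
    "ToyModelSpec",
    "build_toy_model",
    "load_stress_gene_registry",
    "REGISTRY_ROWS",
]

#: Number of rows the packaged stress-gene registry must contain.
REGISTRY_ROWS = 11

# Keff pairs carried over verbatim between the wild-type and heat-evolved
# kinetomes of the full-scale models this toy emulates.
DXR_KEFF_WT = 0.01
DXR_KEFF_HEAT = 88.72
RHCCE_KEFF_WT = 0.01
RHCCE_KEFF_HEAT = 28.8


@dataclass(frozen=True)
class ToyModelSpec:
    """Parameters of the deterministic toy generator."""

    seed: int = 7
    n_extra_enzymes: int = 0
    include_thermal: bool = True
    include_acid: bool = True
    include_oxidative: bool = True
    glucose_uptake_max: float = 10.0
    o2_uptake_max: float = 30.0
    total_proteome_mass: float = 0.55
    unmodeled_protein_fraction: float = 0.10
    jitter: float = 0.03  # relative sd of non-critical perturbations


def load_stress_gene_registry() -> pd.DataFrame:
    """Load the packaged 11-gene stress-response registry.

    Returns a frame with columns (gene, symbol, function, stress); raises
    a data-integrity error if the packaged table does not hold exactly 11
    rows or contains an unknown stress class.
    """
    ref = _resources.files("stressme.data") / "table1_registry.tsv"
    with _resources.as_file(ref) as path:
        frame = pd.read_csv(path, sep="\t")
    if list(frame.columns) != ["gene", "symbol", "function", "stress"]:
        raise ValueError("registry has unexpected columns")
    if len(frame) != REGISTRY_ROWS:
        raise ValueError(
            f"registry must contain exactly {REGISTRY_ROWS} genes, "
            f"found {len(frame)}")
    bad = set(frame.stress) - {"Oxidative", "Thermal", "Acid"}
    if bad:
        raise ValueError(f"unknown stress classes in registry: {bad}")
    return frame


def _jitter(rng: np.random.Generator, value: float, rel: float) -> float:
    """Deterministic multiplicative perturbation, clipped to +-3 sigma."""
    z = float(np.clip(rng.normal(0.0, 1.0), -3.0, 3.0))
    return value * (1.0 + rel * z)


def build_toy_model(spec: ToyModelSpec = ToyModelSpec()) -> MEModel:
    """Emit the toy ME model for a generator spec.

    Deterministic in (spec, seed): mechanism-critical constants are fixed
    and the RNG only jitters molecular weights and non-critical keffs by a
    few percent, so repeated builds are byte-identical.
    """
    rng = np.random.default_rng(spec.seed)
    j = lambda v: _jitter(rng, v, spec.jitter)  # noqa: E731

    model = MEModel(
        id=f"toy_stressme_seed{spec.seed}",
        total_proteome_mass=spec.total_proteome_mass,
        unmodeled_protein_fraction=spec.unmodeled_protein_fraction,
        growth_reaction="BIOMASS",
        aa_exchange="EX_aa",
    )
    model.thermal = ThermalConfig()
    model.acid = AcidResponseSpec()
    model.ros = RosEnvironment()

    # -- small molecules --------------------------------------------------
    for mid, comp in [
        ("glc_e", "extracellular"), ("glc_p", "periplasm"),
        ("g6p", "cytoplasm"), ("pyr", "cytoplasm"), ("accoa", "cytoplasm"),
        ("atp", "cytoplasm"), ("adp", "cytoplasm"),
        ("nad", "cytoplasm"), ("nadh", "cytoplasm"),
        ("o2", "cytoplasm"), ("co2", "cytoplasm"), ("ac", "cytoplasm"),
        ("aa", "cytoplasm"), ("hcys", "cytoplasm"), ("rhcys", "cytoplasm"),
        ("quinone", "cytoplasm"), ("xyl", "cytoplasm"),
        ("akg", "cytoplasm"),
        ("fa_sat", "cytoplasm"), ("fa_unsat", "cytoplasm"),
        ("lipid", "membrane"),
        ("fe2_supply", "cytoplasm"), ("mn2", "cytoplasm"),
    ]:
        model.add_metabolite(Metabolite(mid, comp))

    # -- proteins ----------------------------------------------------------
    # (id, gene, mw kDa, compartment, stability, kf_ref, agg, metal, fe_s,
    #  category).  Stability triples are (dH_m kJ/mol, Cp kJ/mol/K, Tm K);
    # the DXP-reductoisomerase analogue is the least stable client
    # (melts near 315 K) so its folding burden dominates at high T.
    stable = Stability(450.0, 6.0, 333.0)
    defs = [
        ("peri_bp", "glnH", 28.0, "periplasm", Stability(300.0, 5.0, 322.0),
         4.0, 1.5, "none", 0, "transport"),
        ("pts", "ptsG", 60.0, "membrane", stable, 8.0, 0.5, "none", 0,
         "transport"),
        ("glyc", "pfkA", 55.0, "cytoplasm", Stability(700.0, 6.0, 320.0),
         1.2, 1.0, "none", 0, "metabolism"),
        ("pdh", "aceE", 65.0, "cytoplasm", stable, 8.0, 0.5, "Fe2", 0,
         "metabolism"),
        ("tca", "gltA", 70.0, "cytoplasm", Stability(600.0, 6.5, 318.0),
         1.0, 2.0, "none", 0, "metabolism"),
        ("ndh1", "nuoB", 80.0, "membrane", stable, 6.0, 1.0, "Fe2", 2,
         "energy"),
        ("ndh2", "ndh", 45.0, "membrane", stable, 8.0, 0.5, "none", 0,
         "energy"),
        ("ack", "ackA", 43.0, "cytoplasm", stable, 8.0, 0.5, "none", 0,
         "metabolism"),
        ("purt", "purT", 42.0, "cytoplasm", stable, 8.0, 0.5, "none", 0,
         "metabolism"),
        ("dxr", "dxr", 43.0, "cytoplasm", Stability(900.0, 8.0, 312.0),
         0.8, 3.0, "Mg2", 0, "metabolism"),
        ("luxs", "luxS", 40.0, "cytoplasm", Stability(500.0, 5.0, 317.0),
         1.5, 2.0, "none", 0, "metabolism"),
        ("metc", "metC", 43.0, "cytoplasm", stable, 8.0, 0.5, "none", 0,
         "metabolism"),
        ("aasyn", "ilvD", 48.0, "cytoplasm", stable, 6.0, 1.0, "Fe2", 2,
         "metabolism"),
        ("fab", "fabB", 47.0, "cytoplasm", stable, 8.0, 0.5, "none", 0,
         "metabolism"),
        ("xylp", "xylA", 50.0, "cytoplasm", stable, 8.0, 0.5, "none", 0,
         "metabolism"),
        ("bulk", "ycgB", 45.0, "cytoplasm", stable, 8.0, 0.2, "none", 0,
         "other"),
        ("dnaK", "dnaK", 70.0, "cytoplasm", stable, 10.0, 0.0, "none", 0,
         "chaperone"),
        ("groEL", "groL", 800.0, "cytoplasm", stable, 10.0, 0.0, "none", 0,
         "chaperone"),
        ("lon", "lon", 87.0, "cytoplasm", stable, 10.0, 0.0, "none", 0,
         "chaperone"),
        ("hdeB", "hdeB", 12.0, "periplasm", stable, 10.0, 0.0, "none", 0,
         "chaperone"),
        ("dps", "dps", 19.0, "cytoplasm", stable, 10.0, 0.0, "none", 0,
         "stress_oxidative"),
        ("ytfE", "ytfE", 25.0, "cytoplasm", stable, 10.0, 0.0, "none", 0,
         "stress_oxidative"),
        ("ahpC", "ahpC", 21.0, "cytoplasm", stable, 10.0, 0.0, "none", 0,
         "stress_oxidative"),
    ]
    for pid, gene, mw, comp, stab, kf, agg, metal, fes, cat in defs:
        atp_cost = 3.8 if pid == "bulk" else 4.0  # bulk is the cheapest
        model.add_protein(ProteinSpec(
            id=pid, gene=gene, mw_kda=round(j(mw), 3), compartment=comp,
            stability=stab, kf_ref=kf, agg=agg, metal=metal,
            fe_s_clusters=fes, category=cat), atp_per_residue=atp_cost)

    for k in range(spec.n_extra_enzymes):
        model.add_protein(ProteinSpec(
            id=f"extra{k}", gene=f"yex{k}", mw_kda=round(j(45.0), 3),
            stability=stable, kf_ref=8.0, agg=0.5, category="other"))

    # unmodeled-protein sink: consumes amino acids and energy for the
    # reserved 10% of the proteome budget (flux pinned by the budget row)
    n_u = model.unmodeled_mw_kda / 0.11
    model.add_reaction(Reaction(
        id="translation__unmodeled", kind="translation",
        stoichiometry={"aa": -n_u, "atp": -4.0 * n_u, "adp": 4.0 * n_u},
    ))

    # -- exchanges (secretion-positive; uptake negative) -------------------
    ex = [
        ("EX_glc", "glc_e", -spec.glucose_uptake_max, 0.0),
        ("EX_o2", "o2", -spec.o2_uptake_max, 0.0),
        ("EX_ac", "ac", 0.0, 1000.0),
        ("EX_co2", "co2", 0.0, 1000.0),
        ("EX_aa", "aa", 0.0, 0.0),      # opened by the medium preset
        ("EX_xyl", "xyl", 0.0, 0.0),    # closed medium: xylose path blocked
        ("EX_fe", "fe2_supply", -1000.0, 0.0),
        ("EX_mn", "mn2", -1000.0, 0.0),
    ]
    for rid, met, lb, ub in ex:
        model.add_reaction(Reaction(
            id=rid, kind="exchange", stoichiometry={met: -1.0},
            lower_bound=lb, upper_bound=ub))

    # -- catalysed core metabolism ----------------------------------------
    def rxn(rid, stoich, cats, lb=0.0, ub=1000.0, kind="metabolic"):
        model.add_reaction(Reaction(
            id=rid, kind=kind, stoichiometry=stoich,
            lower_bound=lb, upper_bound=ub,
            catalysts=tuple(cats),
            coupling_source="kinetome" if cats else None))

    rxn("GLCperi", {"glc_e": -1, "glc_p": 1}, ["peri_bp"])
    rxn("GLCpts", {"glc_p": -1, "atp": -1, "adp": 1, "g6p": 1}, ["pts"])
    rxn("GLYC", {"g6p": -1, "adp": -2, "nad": -2,
                 "pyr": 2, "atp": 2, "nadh": 2}, ["glyc"])
    rxn("PDH", {"pyr": -1, "nad": -1, "accoa": 1, "co2": 1, "nadh": 1},
        ["pdh"])
    rxn("TCA", {"accoa": -1, "nad": -3, "adp": -1,
                "co2": 1.7, "nadh": 3, "atp": 1, "akg": 0.3}, ["tca"])
    rxn("NDH1", {"nadh": -1, "o2": -0.5, "adp": -3, "nad": 1, "atp": 3},
        ["ndh1"])
    rxn("NDH2", {"nadh": -1, "o2": -0.5, "adp": -1.5, "nad": 1, "atp": 1.5},
        ["ndh2"])
    rxn("ACKr", {"accoa": -1, "adp": -1, "ac": 1, "atp": 1},
        ["ack", "purt"])
    rxn("DXPRIi", {"g6p": -1, "atp": -1, "nadh": -1,
                   "quinone": 1, "adp": 1, "nad": 1}, ["dxr"])
    rxn("RHCCE", {"rhcys": -1, "hcys": 1}, ["luxs"])
    rxn("CYSTL", {"pyr": -1, "nadh": -1, "hcys": 1, "nad": 1}, ["metc"])
    rxn("AASYN", {"pyr": -1, "akg": -0.2, "atp": -2, "nadh": -1,
                  "hcys": -0.05, "aa": 1, "co2": 0.2, "adp": 2, "nad": 1,
                  "rhcys": 0.0007}, ["aasyn"])
    rxn("FASAT", {"accoa": -4, "atp": -2, "nadh": -2,
                  "fa_sat": 1, "adp": 2, "nad": 2}, ["fab"])
    rxn("FAUNSAT", {"accoa": -4, "atp": -2, "nadh": -2.5,
                    "fa_unsat": 1, "adp": 2, "nad": 2.5}, ["fab"])
    rxn("XYLU", {"xyl": -1, "g6p": 1}, ["xylp"])

    # membrane assembly: fatty-acid coefficients are re-derived from the
    # acid response's pH-dependent composition at LP assembly
    model.add_reaction(Reaction(
        id="LIPID", kind="metabolic",
        stoichiometry={"fa_sat": -0.65, "fa_unsat": -0.35, "lipid": 1.0},
        lipid_pseudo=True))

    model.add_reaction(Reaction(
        id="BIOMASS", kind="sink",
        stoichiometry={"g6p": -0.25, "pyr": -0.4, "hcys": -0.05,
                       "quinone": -0.02, "lipid": -0.08,
                       "atp": -35.0, "adp": 35.0},
        is_growth=True))

    # -- kinetomes ---------------------------------------------------------
    # Wild-type keffs follow the broad, lower-median distribution of the
    # oxidative/acid lineage; the heat-evolved vector differs materially
    # only for the DXP-reductoisomerase analogue (0.01 -> 88.72 s^-1) and
    # the lyase (0.01 -> 28.8), with small drifts elsewhere.
    wt = {
        "GLCperi": j(8.0), "GLCpts": j(4.0), "GLYC": j(6.0),
        "PDH": j(5.0), "TCA": j(0.8), "NDH1": 2.0, "NDH2": 2.5,
        "ACKr": j(8.0), "DXPRIi": DXR_KEFF_WT, "RHCCE": RHCCE_KEFF_WT,
        "CYSTL": j(1.2), "AASYN": j(1.6), "FASAT": j(2.4),
        "FAUNSAT": j(2.4), "XYLU": j(6.0),
    }
    wt = {k: round(v, 4) for k, v in wt.items()}
    heat = dict(wt)
    heat["DXPRIi"] = DXR_KEFF_HEAT
    heat["RHCCE"] = RHCCE_KEFF_HEAT
    for rid in ("GLYC", "TCA", "NDH1", "XYLU"):
        heat[rid] = round(wt[rid] * j(1.05), 4)
    model.keff_vectors = {"wild_type": wt, "heat_evolved": heat}
    model.active_keff = "wild_type"

    # -- stress decorations ------------------------------------------------
    if spec.include_thermal:
        for pid in ("glyc", "tca", "dxr", "luxs"):
            build_folding_network(model, model.proteins[pid])
            lon_degradation(model, model.proteins[pid])

    if spec.include_acid:
        add_periplasmic_folding(model, model.proteins["peri_bp"])
        add_hdeb_protection(model, model.proteins["peri_bp"])

    if spec.include_oxidative:
        # free-iron hazard pool exists only with the oxidative module
        model.add_metabolite(Metabolite("fe2_free", "cytoplasm"))
        # mononuclear Fe(II) enzyme with a Mn(II) escape variant; Fe
        # insertion runs through the slow YtfE-like machinery, so the
        # ROS-driven demetallation/re-metallation cycle has a real cost
        add_metalloprotein(model, model.proteins["pdh"], n_metal=1,
                           catalyst="ytfE", catalyst_keff=5e-4)
        add_demetallation(model, model.proteins["pdh"], rate_per_nm=25.0)
        mismetallation_variant(model, model.proteins["pdh"], "mn2",
                               keff_penalty=0.5)
        # iron-sulfur enzymes: respiratory complex I analogue (with the
        # Fe-S-free NDH2 bypass) and an essential biosynthetic target
        # whose slow repair favours degradation plus resynthesis
        add_metalloprotein(model, model.proteins["ndh1"],
                           n_metal=2, atp_cost=4.0)
        add_fe_s_cycle(model, model.proteins["ndh1"], rate_per_nm=8.0,
                       ytfe_keff=5e-4)
        add_metalloprotein(model, model.proteins["aasyn"], n_metal=2)
        add_fe_s_cycle(model, model.proteins["aasyn"], rate_per_nm=8.0,
                       ytfe_keff=5e-5)
        add_fenton_and_dps(model, respiration_refs={"NDH1": 1.0,
                                                    "NDH2": 1.0})
        # NADH-dependent hydroperoxide detoxification
        model.add_reaction(Reaction(
            id="AHPC", kind="repair",
            stoichiometry={"h2o2": -1.0, "nadh": -1.0, "nad": 1.0},
            catalysts=("ahpC",), coupling_source="fixed", fixed_keff=50.0))

    issues = model.check_consistency()
    if issues:
        raise AssertionError(
            "toy model failed its structural self-check: " + "; ".join(issues))
    return model
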