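"""Oxidative stress: ROS damage to metalloproteins, iron bookkeeping and
protective machinery.

Reactive oxygen species (superoxide and peroxide, at basal concentrations
times a condition multiplier) attack metalloproteins.  Two damage
mechanisms are modeled: demetallation of mononuclear Fe(II) enzymes and
oxidation of iron-sulfur clusters.  Damage fluxes are first-order in the
effective ROS level and in the target's turnover: each damage row forces a
consumption of native enzyme proportional to its dilution flux, which must
be compensated by extra synthesis or repair.

Released Fe(II) enters a free pool that is hazardous: it can react with
peroxide (Fenton) to yield hydroxyl radicals whose DNA damage carries a
lumped repair cost.  Dps sequesters free iron and recycles it into the
usable supply pool; YtfE repairs oxidised iron-sulfur clusters.
Mismetallation gives a mononuclear Fe(II) enzyme an alternative holo-form
using another metal at a keff penalty, letting the LP trade activity for
invulnerability.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

from .core import (
    MEModel,
    Metabolite,
    ProteinSpec,
    Reaction,
    CatalystForm,
    translation_id,
    dilution_id,
    native_species,
    damaged_species,
    apo_species,
)

__all__ = [
    "RosEnvironment",
    "DamageRule",
    "damage_flux",
    "add_metalloprotein",
    "add_demetallation",
    "add_fe_s_cycle",
    "add_fenton_and_dps",
    "add_ros_generation",
    "mismetallation_variant",
]


@dataclass(frozen=True)
class RosEnvironment:
    """Basal ROS concentrations (nM) and the condition multiplier."""

    basal_superoxide_nm: float = 0.02
    basal_h2o2_nm: float = 50.0
    multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.multiplier < 0:
            raise ValueError("ROS multiplier must be >= 0")

    @property
    def superoxide_nm(self) -> float:
        return self.basal_superoxide_nm * self.multiplier

    @property
    def h2o2_nm(self) -> float:
        return self.basal_h2o2_nm * self.multiplier

    def with_multiplier(self, multiplier: float) -> "RosEnvironment":
        return RosEnvironment(self.basal_superoxide_nm,
                              self.basal_h2o2_nm, multiplier)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class DamageRule:
    """One ROS damage mechanism acting on one target protein."""

    target: str
    mechanism: str  # demetallation | fe_s_oxidation | fenton_dna
    rate_per_nm: float
    repair_id: str | None = None
    alt_metal: str | None = None
    keff_penalty: float | None = None

    def __post_init__(self) -> None:
        if self.mechanism not in ("demetallation", "fe_s_oxidation",
                                  "fenton_dna"):
            raise ValueError(f"unknown damage mechanism {self.mechanism!r}")
        if self.rate_per_nm < 0:
            raise ValueError("damage rate constant must be >= 0")


def damage_flux(rule: DamageRule, dilution_flux: float,
                ros: RosEnvironment) -> float:
    """Damage flux for a rule, first-order in ROS and in target turnover.

    ``dilution_flux`` is the dilution (turnover) flux of the target's
    native form; the relevant ROS species is superoxide for metal-centre
    mechanisms and peroxide for Fenton-type chemistry.
    """
    if dilution_flux < 0:
        raise ValueError("dilution flux must be >= 0")
    conc = (ros.h2o2_nm if rule.mechanism == "fenton_dna"
            else ros.superoxide_nm)
    return rule.rate_per_nm * conc * dilution_flux


def add_metalloprotein(model: MEModel, protein: ProteinSpec,
                       metal_species: str = "fe2_supply",
                       n_metal: int = 1,
                       atp_cost: float = 2.0,
                       catalyst: str | None = None,
                       catalyst_keff: float | None = None) -> MEModel:
    """Split a protein into apo and holo forms, in place.

    Translation is rewired to produce the apo species; a metallation
    (complex-formation) reaction inserts the metal at an ATP cost to yield
    the catalytically active native form.  If a ``catalyst`` is given
    (e.g. an YtfE-like metal-insertion complex), the metallation flux is
    capacity-coupled to it at ``catalyst_keff`` (s^-1) — this makes
    ROS-driven demetallation/re-metallation cycling genuinely costly
    rather than a free loop.
    """
    pid = protein.id
    apo = apo_species(pid)
    nat = native_species(pid)
    model.add_metabolite(Metabolite(apo, protein.compartment,
                                    is_macromolecule=True))
    trans = model.reactions[translation_id(pid)]
    trans.stoichiometry.pop(nat)
    trans.stoichiometry[apo] = 1.0
    model.add_reaction(Reaction(
        id=f"metallation__{pid}",
        kind="complex_formation",
        stoichiometry={
            apo: -1.0,
            metal_species: -float(n_metal),
            model.atp_species: -atp_cost,
            model.adp_species: atp_cost,
            nat: 1.0,
        },
        catalysts=(catalyst,) if catalyst else (),
        coupling_source="fixed" if catalyst else None,
        fixed_keff=catalyst_keff,
    ))
    return model


def add_demetallation(model: MEModel, protein: ProteinSpec,
                      rate_per_nm: float,
                      free_metal_species: str = "fe2_free",
                      n_metal: int = 1) -> MEModel:
    """ROS-driven loss of the metal cofactor, in place.

    Native -> apo + free metal, forced proportional to the native form's
    dilution flux times the superoxide level.  The apo form can be
    re-metallated (or mismetallated, if a variant exists).
    """
    if protein.metal != "Fe2":
        raise ValueError(f"{protein.id}: demetallation targets Fe(II) "
                         f"proteins")
    pid = protein.id
    model.add_reaction(Reaction(
        id=f"demetallation__{pid}",
        kind="damage",
        stoichiometry={
            native_species(pid): -1.0,
            apo_species(pid): 1.0,
            free_metal_species: float(n_metal),
        },
        forced_ratio={"refs": {dilution_id(pid): rate_per_nm},
                      "scale": "superoxide_nm"},
    ))
    model.damage_rules.append(DamageRule(pid, "demetallation", rate_per_nm))
    return model


def add_fe_s_cycle(model: MEModel, protein: ProteinSpec,
                   rate_per_nm: float,
                   ytfe: str = "ytfE",
                   lon: str = "lon",
                   ytfe_keff: float = 5e-4,
                   free_metal_species: str = "fe2_free",
                   supply_metal_species: str = "fe2_supply",
                   repair_atp: float = 10.0) -> MEModel:
    """Iron-sulfur cluster oxidation and repair, in place.

    Native -> damaged (+ released Fe2+), forced proportional to the native
    dilution flux times the superoxide level; repair re-inserts iron from
    the supply pool at an ATP cost under YtfE catalysis.  Damaged protein
    may alternatively be degraded by Lon with full amino-acid recycle.
    """
    if protein.fe_s_clusters < 1:
        raise ValueError(f"{protein.id} has no iron-sulfur clusters")
    if ytfe not in model.catalyst_forms:
        raise KeyError(f"repair complex {ytfe!r} not in model")
    pid = protein.id
    dmg = damaged_species(pid)
    nat = native_species(pid)
    n_fe = float(protein.fe_s_clusters)
    model.add_metabolite(Metabolite(dmg, protein.compartment,
                                    is_macromolecule=True))
    model.add_reaction(Reaction(
        id=f"fe_s_damage__{pid}",
        kind="damage",
        stoichiometry={nat: -1.0, dmg: 1.0, free_metal_species: n_fe},
        forced_ratio={"refs": {dilution_id(pid): rate_per_nm},
                      "scale": "superoxide_nm"},
    ))
    model.add_reaction(Reaction(
        id=f"fe_s_repair__{pid}",
        kind="repair",
        stoichiometry={
            dmg: -1.0,
            supply_metal_species: -n_fe,
            model.atp_species: -repair_atp,
            model.adp_species: repair_atp,
            nat: 1.0,
        },
        catalysts=(ytfe,),
        coupling_source="fixed",
        fixed_keff=ytfe_keff,
    ))
    if lon in model.catalyst_forms:
        n = protein.n_residues
        model.add_reaction(Reaction(
            id=f"degrade_damaged__{pid}",
            kind="damage",
            stoichiometry={
                dmg: -1.0,
                model.atp_species: -0.5 * n,
                model.adp_species: 0.5 * n,
                model.aa_species: n,
            },
            catalysts=(lon,),
            coupling_source="fixed",
            fixed_keff=model.thermal.lon_keff if model.thermal else 0.05,
        ))
    model.damage_rules.append(
        DamageRule(pid, "fe_s_oxidation", rate_per_nm,
                   repair_id=f"fe_s_repair__{pid}"))
    return model


def add_fenton_and_dps(model: MEModel,
                       dps: str = "dps",
                       dps_keff: float = 0.5,
                       fenton_repair_atp: float = 5.0,
                       respiration_refs: dict | None = None,
                       h2o2_per_flux: float = 2.0e-3) -> MEModel:
    """Free-iron hazard chemistry and Dps protection, in place.

    Adds the peroxide pool with an endogenous generation row (proportional
    to respiratory flux times the ROS multiplier), the Fenton reaction
    (free Fe2+ + H2O2 -> hydroxyl radical) with a lumped DNA-repair cost,
    and Dps-mediated sequestration that returns free iron to the supply
    pool under capacity coupling.
    """
    if dps not in model.catalyst_forms:
        raise KeyError(f"Dps complex {dps!r} not in model")
    for sid, comp in (("h2o2", "cytoplasm"), ("oh_radical", "cytoplasm")):
        if sid not in model.metabolites:
            model.add_metabolite(Metabolite(sid, comp))
    if respiration_refs:
        model.add_reaction(Reaction(
            id="ros_generation",
            kind="damage",
            stoichiometry={"h2o2": 1.0},
            forced_ratio={
                "refs": {r: h2o2_per_flux * w
                         for r, w in respiration_refs.items()},
                "scale": "ros_multiplier"},
        ))
    model.add_reaction(Reaction(
        id="fenton",
        kind="damage",
        stoichiometry={"fe2_free": -1.0, "h2o2": -1.0, "oh_radical": 1.0},
    ))
    model.add_reaction(Reaction(
        id="dna_damage_repair",
        kind="repair",
        stoichiometry={
            "oh_radical": -1.0,
            model.atp_species: -fenton_repair_atp,
            model.adp_species: fenton_repair_atp,
        },
    ))
    model.add_reaction(Reaction(
        id="dps_sequestration",
        kind="repair",
        stoichiometry={"fe2_free": -1.0, "fe2_supply": 1.0},
        catalysts=(dps,),
        coupling_source="fixed",
        fixed_keff=dps_keff,
    ))
    return model


def add_ros_generation(model: MEModel, refs: dict,
                       h2o2_per_flux: float = 2.0e-3) -> MEModel:
    """Standalone endogenous peroxide generation row (if not added via
    :func:`add_fenton_and_dps`)."""
    model.add_reaction(Reaction(
        id="ros_generation",
        kind="damage",
        stoichiometry={"h2o2": 1.0},
        forced_ratio={"refs": {r: h2o2_per_flux * w for r, w in refs.items()},
                      "scale": "ros_multiplier"},
    ))
    return model


def mismetallation_variant(model: MEModel, protein: ProteinSpec,
                           alt_metal_species: str,
                           keff_penalty: float,
                           atp_cost: float = 2.0,
                           n_metal: int = 1) -> MEModel:
    """Add an alternative holo-form using another metal, in place.

    The variant shares the protein's apo pool, carries its own native
    species and dilution demand, and catalyses the same reactions at
    ``keff * keff_penalty``.  The LP chooses between forms; the Fe form is
    weakly preferred at zero ROS (higher keff means lower demand) while
    the variant escapes Fe-targeted damage.
    """
    if protein.metal != "Fe2":
        raise ValueError(f"{protein.id}: mismetallation applies to Fe(II) "
                         f"proteins")
    if not 0.0 < keff_penalty < 1.0:
        raise ValueError("keff penalty must lie in (0, 1)")
    pid = protein.id
    apo = apo_species(pid)
    if apo not in model.metabolites:
        raise ValueError(f"{pid}: add the metalloprotein split first")
    metal_tag = alt_metal_species.rstrip("2").split("_")[0]
    form_id = f"{pid}__{metal_tag}"
    nat = native_species(form_id)
    model.add_metabolite(Metabolite(nat, protein.compartment,
                                    is_macromolecule=True))
    model.add_catalyst_form(CatalystForm(form_id, pid,
                                         keff_scale=keff_penalty))
    model.add_reaction(Reaction(
        id=f"metallation__{form_id}",
        kind="complex_formation",
        stoichiometry={
            apo: -1.0,
            alt_metal_species: -float(n_metal),
            model.atp_species: -atp_cost,
            model.adp_species: atp_cost,
            nat: 1.0,
        },
    ))
    model.add_reaction(Reaction(
        id=dilution_id(form_id),
        kind="sink",
        stoichiometry={nat: -1.0},
    ))
    for rxn in model.reactions.values():
        if pid in rxn.catalysts and rxn.coupling_source == "kinetome":
            rxn.catalysts = tuple(rxn.catalysts) + (form_id,)
    model.damage_rules.append(
        DamageRule(pid, "demetallation", 0.0, alt_metal=alt_metal_species,
                   keff_penalty=keff_penalty))
    return model
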