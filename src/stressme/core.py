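"""Core data model for a growth-rate-parameterised ME (metabolism and
expression) model.

An ME model couples metabolic fluxes to the expression cost of the enzymes
that carry them: the synthesis rate of a catalyst must cover at least
``mu / keff`` times the catalysed flux, where ``mu`` is the specific growth
rate (h^-1) and ``keff`` the effective turnover rate of the catalyst.  All
stoichiometric coefficients and bounds may be linear functions of ``mu``,
so at a fixed growth rate the whole problem is a linear program; the
maximal growth rate is found by bisection over that feasibility family
(see :mod:`stressme.solver`).

This module holds the containers only: metabolites, reactions (with
mu-linear coefficients and coupling metadata), protein specifications with
thermodynamic stability parameters, catalyst forms (e.g. metallation
variants), stress conditions and solutions, plus JSON (de)serialisation of
the documented model schema.
"""

from __future__ import annotations

import copy as _copy
import json
from dataclasses import dataclass, field, asdict
from typing import Any, Iterable, Mapping

__all__ = [
    "GAS_CONSTANT_KJ",
    "AA_RESIDUE_MW_KDA",
    "COMPARTMENTS",
    "REACTION_KINDS",
    "AA_SUPPLEMENT_UPTAKE",
    "MuLinear",
    "Metabolite",
    "Stability",
    "ProteinSpec",
    "CatalystForm",
    "Reaction",
    "StressCondition",
    "Solution",
    "MEModel",
    "translation_id",
    "dilution_id",
    "native_species",
    "unfolded_species",
    "damaged_species",
    "apo_species",
]

#: Gas constant in kJ mol^-1 K^-1 (stability curves are in kJ/mol).
GAS_CONSTANT_KJ = 8.314e-3

#: Mass of one average amino-acid residue, kDa (g/mmol).  Used to convert a
#: protein's molecular weight into its residue count for translation
#: stoichiometry, so that amino-acid mass is conserved exactly.
AA_RESIDUE_MW_KDA = 0.11

COMPARTMENTS = ("cytoplasm", "periplasm", "membrane", "extracellular")

REACTION_KINDS = (
    "metabolic",
    "translation",
    "complex_formation",
    "folding",
    "damage",
    "repair",
    "exchange",
    "sink",
)

#: Medium presets for amino-acid supplementation: maximal uptake rate
#: (mmol gDW^-1 h^-1) applied to the model's amino-acid exchange.  The toy
#: network carries a single lumped amino-acid pool, so group-dropout media
#: are represented by a reduced cap rather than per-group chemistry.
AA_SUPPLEMENT_UPTAKE = {
    "none": 0.0,
    "full": 2.0,
    "no_ile_val": 1.4,
    "no_met_cys": 1.4,
    "no_phe_trp_tyr": 1.4,
}

COUPLING_SOURCES = (
    "kinetome",
    "fixed",
    "spontaneous_folding",
    "chaperone_folding",
)


@dataclass(frozen=True)
class MuLinear:
    """A coefficient of the form ``const + mu_coeff * mu``."""

    const: float = 0.0
    mu_coeff: float = 0.0

    def at(self, mu: float) -> float:
        return self.const + self.mu_coeff * mu

    def to_json(self) -> dict:
        return {"const": self.const, "mu_coeff": self.mu_coeff}

    @staticmethod
    def coerce(value: "float | MuLinear | Mapping") -> "float | MuLinear":
        if isinstance(value, MuLinear):
            return value
        if isinstance(value, Mapping):
            return MuLinear(float(value.get("const", 0.0)),
                            float(value.get("mu_coeff", 0.0)))
        return float(value)


def _eval(value: "float | MuLinear", mu: float) -> float:
    if isinstance(value, MuLinear):
        return value.at(mu)
    return float(value)


@dataclass
class Metabolite:
    id: str
    compartment: str = "cytoplasm"
    is_macromolecule: bool = False

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValueError(
                f"unknown compartment {self.compartment!r} for {self.id}")


@dataclass(frozen=True)
class Stability:
    """Gibbs-Helmholtz parameterisation of the unfolding free energy.

    ``dG_unfold(T) = dh_m * (1 - T/tm) - cp * ((tm - T) + T * ln(T/tm))``
    with ``dh_m`` the van't Hoff enthalpy at the melting point (kJ/mol),
    ``cp`` the unfolding heat-capacity change (kJ/mol/K) and ``tm`` the
    melting temperature (K).  By construction ``dG_unfold(tm) = 0``.
    """

    dh_m: float = 400.0
    cp: float = 6.0
    tm: float = 325.0

    def __post_init__(self) -> None:
        if self.tm <= 273.0:
            raise ValueError(f"melting temperature must exceed 273 K, got {self.tm}")


@dataclass
class ProteinSpec:
    """A modeled protein: mass, location, stability and damage annotations.

    ``kf_ref`` is the spontaneous folding rate constant (s^-1) at the
    reference temperature of the thermal configuration; the temperature
    dependence is an exponential decay with a shared slope.  ``agg`` is a
    dimensionless aggregation propensity shifting folding demand toward the
    chaperone pathways.  ``metal``/``fe_s_clusters`` mark targets of
    ROS-driven demetallation and iron-sulfur cluster damage.
    """

    id: str
    gene: str
    mw_kda: float
    compartment: str = "cytoplasm"
    stability: Stability = field(default_factory=Stability)
    kf_ref: float = 10.0
    agg: float = 0.0
    metal: str = "none"
    fe_s_clusters: int = 0
    category: str = "metabolism"

    def __post_init__(self) -> None:
        if self.mw_kda <= 0:
            raise ValueError(f"{self.id}: molecular weight must be positive")
        if self.agg < 0:
            raise ValueError(f"{self.id}: aggregation propensity must be >= 0")
        if self.metal not in ("Fe2", "Mn2", "Co2", "Mg2", "none"):
            raise ValueError(f"{self.id}: unknown metal {self.metal!r}")
        if self.fe_s_clusters < 0:
            raise ValueError(f"{self.id}: fe_s_clusters must be >= 0")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"{self.id}: unknown compartment")

    @property
    def n_residues(self) -> float:
        """Residue count implied by the molecular weight (mass-exact)."""
        return self.mw_kda / AA_RESIDUE_MW_KDA


@dataclass
class CatalystForm:
    """A catalytically competent form of a protein.

    The default form is the protein itself; metallation variants (e.g. a
    mismetallated Mn(II) holo-enzyme) are additional forms of the same
    protein sharing its translation reaction but carrying their own native
    species, dilution demand and keff scaling factor.
    """

    id: str
    protein: str
    keff_scale: float = 1.0


def translation_id(protein: str) -> str:
    return f"translation__{protein}"


def dilution_id(form: str) -> str:
    return f"dilution__{form}"


def native_species(form: str) -> str:
    return f"{form}__native"


def unfolded_species(protein: str) -> str:
    return f"{protein}__unfolded"


def damaged_species(protein: str) -> str:
    return f"{protein}__damaged"


def apo_species(protein: str) -> str:
    return f"{protein}__apo"


@dataclass
class Reaction:
    """A model reaction with mu-linear stoichiometry and coupling metadata.

    Coupling metadata drives LP assembly:

    * ``catalysts`` — catalyst-form ids that can carry this reaction
      (alternatives, i.e. a GPR OR rule).  Reactions with more than one
      catalyst are split into one LP column per catalyst.
    * ``coupling_source`` — where the keff comes from: ``"kinetome"`` (the
      active keff vector, Arrhenius- and membrane-scaled), ``"fixed"``
      (machinery with a fixed keff), ``"spontaneous_folding"`` /
      ``"chaperone_folding"`` (temperature/aggregation-scaled folding
      pathways).
    * ``partition`` — marks an unfolding back-reaction whose flux is pinned
      to ``Keq(T[, pH])`` times the client's dilution flux.
    * ``forced_ratio`` — pins this reaction's flux to a weighted sum of
      reference fluxes, optionally scaled by the ROS environment (damage
      and endogenous ROS generation rows).
    * ``ph_gate`` — the reaction is open only below this pH (HdeB route).
    * ``lipid_pseudo`` — stoichiometry is re-derived from the acid
      response's pH-dependent fatty-acid composition at assembly.
    """

    id: str
    kind: str
    stoichiometry: dict = field(default_factory=dict)
    lower_bound: Any = 0.0
    upper_bound: Any = 1000.0
    catalysts: tuple = ()
    coupling_source: str | None = None
    fixed_keff: float | None = None
    client_protein: str | None = None
    keff_scale: dict = field(default_factory=dict)
    partition: dict | None = None
    forced_ratio: dict | None = None
    ph_gate: float | None = None
    lipid_pseudo: bool = False
    is_growth: bool = False

    def __post_init__(self) -> None:
        if self.kind not in REACTION_KINDS:
            raise ValueError(f"{self.id}: unknown reaction kind {self.kind!r}")
        if self.coupling_source is not None \
                and self.coupling_source not in COUPLING_SOURCES:
            raise ValueError(
                f"{self.id}: unknown coupling source {self.coupling_source!r}")
        self.catalysts = tuple(self.catalysts)
        self.stoichiometry = {
            met: MuLinear.coerce(coef) for met, coef in self.stoichiometry.items()
        }
        self.lower_bound = MuLinear.coerce(self.lower_bound)
        self.upper_bound = MuLinear.coerce(self.upper_bound)

    def bounds_at(self, mu: float) -> tuple[float, float]:
        lb = _eval(self.lower_bound, mu)
        ub = _eval(self.upper_bound, mu)
        if lb > ub + 1e-12:
            raise ValueError(f"{self.id}: lower bound exceeds upper at mu={mu}")
        return lb, ub

    def stoich_at(self, mu: float) -> dict[str, float]:
        return {met: _eval(coef, mu) for met, coef in self.stoichiometry.items()}


@dataclass(frozen=True)
class StressCondition:
    """An environmental condition: temperature, acidity, oxidative load.

    ``ros_multiplier`` scales the basal superoxide and peroxide levels of
    the model's ROS environment (the "0.01x"-"10x" scale).  The
    ``aa_supplement`` preset opens the amino-acid exchange according to
    :data:`AA_SUPPLEMENT_UPTAKE`.
    """

    temperature_c: float = 37.0
    ph: float = 7.0
    ros_multiplier: float = 1.0
    aa_supplement: str = "none"

    def __post_init__(self) -> None:
        if self.ros_multiplier < 0:
            raise ValueError("ROS multiplier must be >= 0")
        if self.aa_supplement not in AA_SUPPLEMENT_UPTAKE:
            raise ValueError(
                f"unknown amino-acid supplementation preset "
                f"{self.aa_supplement!r}")

    @property
    def temperature_k(self) -> float:
        return self.temperature_c + 273.15

    def label(self) -> str:
        return (f"T{self.temperature_c:g}C_pH{self.ph:g}"
                f"_ROS{self.ros_multiplier:g}x")


@dataclass
class Solution:
    """Result of one ME-model optimisation.

    ``flux`` maps reaction ids to fluxes in mmol gDW^-1 h^-1; for reactions
    split over alternative catalysts, per-catalyst components are reported
    under ``"<reaction>@<form>"`` in addition to the aggregated entry.
    ``mass_balance_residuals`` holds the net production of every metabolite
    (zero up to solver tolerance at any optimal solution).
    """

    mu: float
    flux: dict = field(default_factory=dict)
    status: str = "optimal"
    mass_balance_residuals: dict = field(default_factory=dict)
    objective_value: float | None = None
    condition: StressCondition | None = None
    keff_label: str | None = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    @property
    def max_residual(self) -> float:
        if not self.mass_balance_residuals:
            return 0.0
        return max(abs(v) for v in self.mass_balance_residuals.values())


@dataclass
class MEModel:
    """A small ME model: species, reactions, proteins and global budgets.

    ``unmodeled_protein_fraction`` reserves a share of the total proteome
    mass (``total_proteome_mass``, g protein per gDW) for proteins outside
    the model's scope; the remaining fraction must be synthesised by the
    modeled translation reactions (an equality in the LP, making the
    modeled-fraction check structural).
    """

    id: str = "me_model"
    metabolites: dict = field(default_factory=dict)
    reactions: dict = field(default_factory=dict)
    proteins: dict = field(default_factory=dict)
    catalyst_forms: dict = field(default_factory=dict)
    keff_vectors: dict = field(default_factory=dict)
    active_keff: str = "wild_type"
    unmodeled_protein_fraction: float = 0.10
    total_proteome_mass: float = 0.55
    unmodeled_mw_kda: float = 40.0
    thermal: Any = None
    acid: Any = None
    ros: Any = None
    damage_rules: list = field(default_factory=list)
    growth_reaction: str = "BIOMASS"
    aa_exchange: str | None = None
    aa_species: str = "aa"
    atp_species: str = "atp"
    adp_species: str = "adp"

    def __post_init__(self) -> None:
        if not 0.0 <= self.unmodeled_protein_fraction < 1.0:
            raise ValueError("unmodeled_protein_fraction must be in [0, 1)")
        if self.total_proteome_mass <= 0:
            raise ValueError("total_proteome_mass must be positive")

    # -- construction -----------------------------------------------------

    def add_metabolite(self, met: Metabolite) -> Metabolite:
        if met.id in self.metabolites:
            raise ValueError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met
        return met

    def add_reaction(self, rxn: Reaction) -> Reaction:
        if rxn.id in self.reactions:
            raise ValueError(f"duplicate reaction id {rxn.id!r}")
        for met in rxn.stoichiometry:
            if met not in self.metabolites:
                raise ValueError(
                    f"reaction {rxn.id!r} references undeclared metabolite "
                    f"{met!r}")
        self.reactions[rxn.id] = rxn
        return rxn

    def add_protein(self, spec: ProteinSpec, *,
                    atp_per_residue: float = 4.0) -> ProteinSpec:
        """Register a protein with its translation and dilution plumbing.

        Adds the native species, a lumped translation reaction (amino acids
        + ATP -> one native protein) and a dilution sink, and registers the
        protein's default catalyst form.  Stress modules may later rewire
        the translation product (folding networks, metallation).
        """
        if spec.id in self.proteins:
            raise ValueError(f"duplicate protein id {spec.id!r}")
        self.proteins[spec.id] = spec
        nat = native_species(spec.id)
        self.add_metabolite(Metabolite(nat, spec.compartment,
                                       is_macromolecule=True))
        n = spec.n_residues
        self.add_reaction(Reaction(
            id=translation_id(spec.id),
            kind="translation",
            stoichiometry={
                self.aa_species: -n,
                self.atp_species: -atp_per_residue * n,
                self.adp_species: atp_per_residue * n,
                nat: 1.0,
            },
        ))
        self.add_reaction(Reaction(
            id=dilution_id(spec.id),
            kind="sink",
            stoichiometry={nat: -1.0},
        ))
        self.catalyst_forms[spec.id] = CatalystForm(spec.id, spec.id)
        return spec

    def add_catalyst_form(self, form: CatalystForm) -> CatalystForm:
        if form.id in self.catalyst_forms:
            raise ValueError(f"duplicate catalyst form {form.id!r}")
        if form.protein not in self.proteins:
            raise ValueError(f"catalyst form {form.id!r} references unknown "
                             f"protein {form.protein!r}")
        self.catalyst_forms[form.id] = form
        return form

    def copy(self) -> "MEModel":
        return _copy.deepcopy(self)

    # -- lookups ----------------------------------------------------------

    def protein_by_gene(self, gene: str) -> list[ProteinSpec]:
        hits = [p for p in self.proteins.values() if p.gene == gene]
        if not hits:
            raise KeyError(f"no protein with gene {gene!r}")
        return hits

    def translation_reactions(self) -> dict[str, Reaction]:
        """Modeled translation reactions keyed by protein id."""
        out = {}
        for pid in self.proteins:
            rid = translation_id(pid)
            if rid in self.reactions:
                out[pid] = self.reactions[rid]
        return out

    def kinetome_coupled_reactions(self) -> list[str]:
        return [r.id for r in self.reactions.values()
                if r.coupling_source == "kinetome"]

    def keffs(self, label: str | None = None) -> dict:
        label = label or self.active_keff
        try:
            return self.keff_vectors[label]
        except KeyError:
            raise KeyError(f"no keff vector labelled {label!r}") from None

    # -- validation -------------------------------------------------------

    def check_consistency(self) -> list[str]:
        """Structural checks; returns a list of human-readable issues.

        Verifies that stoichiometries reference declared metabolites, that
        every kinetome-coupled reaction has a keff in the active vector,
        and that every metabolite can be both produced and consumed by some
        reaction (exchange bounds count as structural production or
        consumption).
        """
        issues: list[str] = []
        producible: set[str] = set()
        consumable: set[str] = set()
        keffs = self.keffs()
        for rxn in self.reactions.values():
            lb, ub = rxn.bounds_at(0.0)
            lb1, ub1 = rxn.bounds_at(1.0)
            if lb > ub or lb1 > ub1:
                issues.append(f"{rxn.id}: inconsistent bounds")
            if rxn.coupling_source == "kinetome":
                for cat in rxn.catalysts:
                    if cat not in self.catalyst_forms:
                        issues.append(f"{rxn.id}: unknown catalyst {cat!r}")
                if rxn.id not in keffs:
                    issues.append(
                        f"{rxn.id}: catalysed reaction lacks a keff in the "
                        f"active vector {self.active_keff!r}")
            for met, coef in rxn.stoich_at(0.5).items():
                if met not in self.metabolites:
                    issues.append(f"{rxn.id}: undeclared metabolite {met!r}")
                    continue
                if rxn.kind == "exchange":
                    # boundary species: structurally open even if the
                    # current medium closes the exchange bounds
                    producible.add(met)
                    consumable.add(met)
                    continue
                fwd = ub1 > 1e-12 or ub > 1e-12
                rev = lb1 < -1e-12 or lb < -1e-12
                if (coef > 0 and fwd) or (coef < 0 and rev):
                    producible.add(met)
                if (coef < 0 and fwd) or (coef > 0 and rev):
                    consumable.add(met)
        for met in self.metabolites:
            if met not in producible:
                issues.append(f"metabolite {met} is never produced")
            if met not in consumable:
                issues.append(f"metabolite {met} is never consumed")
        return issues

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        def coef_json(value):
            return value.to_json() if isinstance(value, MuLinear) else value

        rxns = []
        for rxn in self.reactions.values():
            d = {
                "id": rxn.id,
                "kind": rxn.kind,
                "stoichiometry": {m: coef_json(c)
                                  for m, c in rxn.stoichiometry.items()},
                "lower_bound": coef_json(rxn.lower_bound),
                "upper_bound": coef_json(rxn.upper_bound),
            }
            for key in ("catalysts", "coupling_source", "fixed_keff",
                        "client_protein", "keff_scale", "partition",
                        "forced_ratio", "ph_gate", "lipid_pseudo",
                        "is_growth"):
                value = getattr(rxn, key)
                if value not in (None, (), {}, False):
                    d[key] = list(value) if key == "catalysts" else value
            rxns.append(d)

        prots = []
        for p in self.proteins.values():
            d = asdict(p)
            prots.append(d)

        return {
            "id": self.id,
            "parameters": {
                "unmodeled_protein_fraction": self.unmodeled_protein_fraction,
                "total_proteome_mass": self.total_proteome_mass,
                "unmodeled_mw_kda": self.unmodeled_mw_kda,
                "active_keff": self.active_keff,
                "growth_reaction": self.growth_reaction,
                "aa_exchange": self.aa_exchange,
                "aa_species": self.aa_species,
                "atp_species": self.atp_species,
                "adp_species": self.adp_species,
            },
            "metabolites": [asdict(m) for m in self.metabolites.values()],
            "reactions": rxns,
            "proteins": prots,
            "catalyst_forms": [asdict(f) for f in self.catalyst_forms.values()],
            "keff_vectors": self.keff_vectors,
            "damage_rules": [r if isinstance(r, dict) else asdict(r)
                             for r in self.damage_rules],
            "thermal": None if self.thermal is None else self.thermal.to_dict(),
            "acid": None if self.acid is None else self.acid.to_dict(),
            "ros": None if self.ros is None else self.ros.to_dict(),
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "MEModel":
        from .thermal import ThermalConfig
        from .acid import AcidResponseSpec
        from .oxidative import RosEnvironment, DamageRule

        params = data.get("parameters", {})
        model = cls(
            id=data.get("id", "me_model"),
            unmodeled_protein_fraction=params.get(
                "unmodeled_protein_fraction", 0.10),
            total_proteome_mass=params.get("total_proteome_mass", 0.55),
            unmodeled_mw_kda=params.get("unmodeled_mw_kda", 40.0),
            active_keff=params.get("active_keff", "wild_type"),
            growth_reaction=params.get("growth_reaction", "BIOMASS"),
            aa_exchange=params.get("aa_exchange"),
            aa_species=params.get("aa_species", "aa"),
            atp_species=params.get("atp_species", "atp"),
            adp_species=params.get("adp_species", "adp"),
        )
        for m in data.get("metabolites", []):
            model.add_metabolite(Metabolite(**m))
        for p in data.get("proteins", []):
            stab = p.pop("stability", None)
            spec = ProteinSpec(
                stability=Stability(**stab) if stab else Stability(), **p)
            model.proteins[spec.id] = spec
        for f in data.get("catalyst_forms", []):
            model.catalyst_forms[f["id"]] = CatalystForm(**f)
        for r in data.get("reactions", []):
            model.add_reaction(Reaction(**r))
        model.keff_vectors = {k: dict(v)
                              for k, v in data.get("keff_vectors", {}).items()}
        model.damage_rules = [DamageRule(**d)
                              for d in data.get("damage_rules", [])]
        if data.get("thermal"):
            model.thermal = ThermalConfig.from_dict(data["thermal"])
        if data.get("acid"):
            model.acid = AcidResponseSpec.from_dict(data["acid"])
        if data.get("ros"):
            model.ros = RosEnvironment(**data["ros"])
        return model

    def to_json(self, **kwargs: Any) -> str:
        kwargs.setdefault("indent", 1)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)

    def save_json(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())
            fh.write("\n")

    @classmethod
    def load_json(cls, path: str) -> "MEModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
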