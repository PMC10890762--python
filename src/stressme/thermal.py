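"""Thermal stress: protein stability curves and the cytoplasmic folding
network.

Protein unfolding is described by a Gibbs-Helmholtz free-energy curve
(:func:`delta_g_unfold`) whose parameters (van't Hoff enthalpy, heat
capacity change, melting temperature) live on each
:class:`~stressme.core.ProteinSpec`.  The unfolding equilibrium constant
``Keq(T) = exp(-dG/RT)`` sets, at steady state, the share of a protein's
turnover that cycles through the unfolded state: the LP carries an
unfolding back-reaction whose flux is pinned to ``Keq`` times the native
dilution flux, so hotter (or less stable) proteins impose a larger folding
workload.

Folding itself is competitive between three routes — spontaneous,
DnaK-assisted and GroEL/ES-mediated — modeled as parallel reactions whose
effective turnover numbers scale with the kinetic folding rate ``kf(T)``
and the aggregation propensity ``agg``.  The spontaneous route is coupled
to the client protein's own pool (slow folders tie up their own copies),
while chaperone routes draw on chaperone capacity via the usual mu/keff
coupling and burn ATP per folding event.  Lon provides an ATP-dependent
degradation route for unfolded protein, recycling its amino acids.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

from .core import (
    GAS_CONSTANT_KJ,
    MEModel,
    ProteinSpec,
    Metabolite,
    Reaction,
    translation_id,
    native_species,
    unfolded_species,
)

__all__ = [
    "KEQ_CAP",
    "TEMPERATURE_VALIDITY_K",
    "FoldingPathway",
    "ThermalConfig",
    "delta_g_unfold",
    "unfolding_keq",
    "folding_rate",
    "arrhenius_factor",
    "build_folding_network",
    "lon_degradation",
]

#: Numerical cap on unfolding Keq inside LP rows.  A bulk protein with
#: Keq >= 1000 already implies a folding workload three orders of magnitude
#: above its dilution turnover; growth has collapsed long before the cap
#: matters, and the cap keeps the constraint matrix well scaled.
KEQ_CAP = 1.0e3

#: Validity window of the stability parameterisation (K).  Values outside
#: are still returned, with a warning.
TEMPERATURE_VALIDITY_K = (293.0, 323.0)


@dataclass(frozen=True)
class FoldingPathway:
    """One route of the folding network.

    ``chaperone`` is None for spontaneous folding.  ``keff_base`` is the
    pathway turnover (s^-1) before aggregation scaling; ``atp_per_event``
    the ATP hydrolysed per folding event.
    """

    name: str
    chaperone: str | None
    keff_base: float
    atp_per_event: float = 0.0
    agg_exponent: float = 1.0


@dataclass
class ThermalConfig:
    """Global thermal parameters shared across proteins.

    ``kf_slope_per_k`` controls the exponential decay of the spontaneous
    folding rate above the reference temperature; ``arrhenius_ea_kj``
    is the activation energy applied to all kinetome keffs (metabolic
    enzymes speed up with temperature until stability takes over).
    """

    t_ref_k: float = 310.15
    kf_slope_per_k: float = 0.45
    arrhenius_ea_kj: float = 25.0
    lon_keff: float = 0.05
    pathways: list = field(default_factory=lambda: [
        FoldingPathway("spontaneous", None, 0.0, 0.0),
        FoldingPathway("dnaK", "dnaK", 0.004, 5.0, 1.0),
        FoldingPathway("groEL", "groEL", 0.002, 7.0, 2.0),
    ])

    def to_dict(self) -> dict:
        return {
            "t_ref_k": self.t_ref_k,
            "kf_slope_per_k": self.kf_slope_per_k,
            "arrhenius_ea_kj": self.arrhenius_ea_kj,
            "lon_keff": self.lon_keff,
            "pathways": [asdict(p) for p in self.pathways],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ThermalConfig":
        data = dict(data)
        pathways = [FoldingPathway(**p) for p in data.pop("pathways", [])]
        cfg = cls(**data)
        if pathways:
            cfg.pathways = pathways
        return cfg


def _check_validity(t_kelvin: float) -> None:
    lo, hi = TEMPERATURE_VALIDITY_K
    if not lo <= t_kelvin <= hi:
        warnings.warn(
            f"temperature {t_kelvin:.2f} K outside the stability validity "
            f"window [{lo:.0f}, {hi:.0f}] K; extrapolating",
            stacklevel=3)


def delta_g_unfold(protein: ProteinSpec, t_kelvin: float) -> float:
    """Unfolding free energy dG(T) in kJ/mol (Gibbs-Helmholtz form).

    Positive dG means the native state is favoured; dG(Tm) = 0 by
    construction.
    """
    _check_validity(t_kelvin)
    s = protein.stability
    return (s.dh_m * (1.0 - t_kelvin / s.tm)
            - s.cp * ((s.tm - t_kelvin)
                      + t_kelvin * math.log(t_kelvin / s.tm)))


def unfolding_keq(protein: ProteinSpec, t_kelvin: float) -> float:
    """Equilibrium constant of Native <=> Unfolded at temperature T."""
    dg = delta_g_unfold(protein, t_kelvin)
    return math.exp(-dg / (GAS_CONSTANT_KJ * t_kelvin))


def folding_rate(protein: ProteinSpec, t_kelvin: float,
                 config: ThermalConfig) -> float:
    """Kinetic folding rate kf(T), s^-1.

    An exponential decay above the reference temperature: folding slows as
    intermediates are destabilised.  Below the reference the rate is held
    at kf_ref (cold denaturation is out of scope).
    """
    excess = max(0.0, t_kelvin - config.t_ref_k)
    return protein.kf_ref * math.exp(-config.kf_slope_per_k * excess)


def arrhenius_factor(t_kelvin: float, config: ThermalConfig) -> float:
    """Arrhenius scaling of kinetome keffs relative to the reference T."""
    ea = config.arrhenius_ea_kj
    return math.exp(ea / GAS_CONSTANT_KJ
                    * (1.0 / config.t_ref_k - 1.0 / t_kelvin))


def build_folding_network(model: MEModel, protein: ProteinSpec) -> MEModel:
    """Attach the cytoplasmic folding network to a protein, in place.

    Rewires translation to produce the unfolded species and adds one
    folding reaction per configured pathway plus the unfolding
    back-reaction whose flux tracks ``Keq(T)`` times the native dilution
    (the steady-state unfolded share is then ``Keq/(1+Keq)`` of the
    processed flux).  Temperature enters at LP assembly, not here, so a
    single network serves a whole condition grid.
    """
    if protein.compartment != "cytoplasm":
        raise ValueError(
            f"{protein.id}: folding network applies to cytoplasmic proteins")
    if model.thermal is None:
        raise ValueError("model has no thermal configuration")
    pid = protein.id
    unf = unfolded_species(pid)
    nat = native_species(pid)
    model.add_metabolite(Metabolite(unf, "cytoplasm", is_macromolecule=True))
    trans = model.reactions[translation_id(pid)]
    trans.stoichiometry.pop(nat)
    trans.stoichiometry[unf] = 1.0

    atp, adp = model.atp_species, model.adp_species
    for path in model.thermal.pathways:
        stoich: dict = {unf: -1.0, nat: 1.0}
        if path.atp_per_event:
            stoich[atp] = -path.atp_per_event
            stoich[adp] = path.atp_per_event
        if path.chaperone is None:
            model.add_reaction(Reaction(
                id=f"fold_spontaneous__{pid}",
                kind="folding",
                stoichiometry=stoich,
                catalysts=(pid,),
                coupling_source="spontaneous_folding",
                client_protein=pid,
            ))
        else:
            if path.chaperone not in model.catalyst_forms:
                raise KeyError(
                    f"folding pathway {path.name!r} references missing "
                    f"chaperone complex {path.chaperone!r}")
            # aggregation-prone clients are better chaperone substrates:
            # the pathway keff carries an agg-weighted boost, precomputed
            # here so assembly stays condition-only
            boost = (1.0 + protein.agg) ** path.agg_exponent
            model.add_reaction(Reaction(
                id=f"fold_{path.name}__{pid}",
                kind="folding",
                stoichiometry=stoich,
                catalysts=(path.chaperone,),
                coupling_source="chaperone_folding",
                fixed_keff=path.keff_base * boost,
                client_protein=pid,
            ))
    model.add_reaction(Reaction(
        id=f"unfold__{pid}",
        kind="folding",
        stoichiometry={nat: -1.0, unf: 1.0},
        partition={"client_form": pid, "scope": "thermal"},
    ))
    return model


def lon_degradation(model: MEModel, protein: ProteinSpec,
                    lon: str = "lon",
                    atp_per_residue: float = 0.5) -> MEModel:
    """Add Lon-mediated degradation of the unfolded protein, in place.

    Unfolded protein + ATP -> amino-acid recycle, catalysed by the Lon
    protease.  Amino-acid mass is conserved exactly (the full residue
    count is returned to the pool).
    """
    pid = protein.id
    unf = unfolded_species(pid)
    if unf not in model.metabolites:
        raise ValueError(f"{pid}: no unfolded species; build the folding "
                         f"network first")
    if lon not in model.catalyst_forms:
        raise KeyError(f"Lon complex {lon!r} not in model")
    n = protein.n_residues
    model.add_reaction(Reaction(
        id=f"degrade_lon__{pid}",
        kind="damage",
        stoichiometry={
            unf: -1.0,
            model.atp_species: -atp_per_residue * n,
            model.adp_species: atp_per_residue * n,
            model.aa_species: n,
        },
        catalysts=(lon,),
        coupling_source="fixed",
        fixed_keff=model.thermal.lon_keff if model.thermal else 0.05,
    ))
    return model
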