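"""Acid stress: periplasmic protein stability, HdeB protection, membrane
lipid composition and membrane-enzyme activity.

Acidity acts through three channels.  (1) Periplasmic proteins, exposed to
external pH, are destabilised by a linear free-energy shift per pH unit
below 7, inflating their unfolding Keq and hence their folding workload;
the periplasmic chaperone HdeB offers a protected folding route that opens
below an activation pH.  (2) The membrane lipid pseudo-reaction shifts
toward unsaturated fatty acids as pH drops (compositions interpolate
between tabulated pH anchors at fixed total lipid mass).  (3) Membrane
enzymes lose activity: their keffs are multiplied by a pH-dependent factor
of at most 1.  Proton bioenergetics are deliberately not modeled.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .core import (
    GAS_CONSTANT_KJ,
    MEModel,
    Metabolite,
    ProteinSpec,
    Reaction,
    translation_id,
    native_species,
    unfolded_species,
)
from .thermal import delta_g_unfold

__all__ = [
    "PH_VALIDITY",
    "AcidResponseSpec",
    "periplasmic_unfolding_keq",
    "membrane_lipid_composition",
    "membrane_activity_factor",
    "add_periplasmic_folding",
    "add_hdeb_protection",
]

PH_VALIDITY = (4.5, 7.5)


def _default_lipid_table() -> dict:
    # Anchor compositions (mol fractions of the membrane pseudo-reaction);
    # each row sums to 1 so total lipid mass is pH-invariant.
    return {
        7.0: {"fa_sat": 0.65, "fa_unsat": 0.35},
        5.0: {"fa_sat": 0.45, "fa_unsat": 0.55},
    }


def _default_activity_table() -> dict:
    return {7.5: 1.0, 7.0: 1.0, 6.0: 0.85, 5.0: 0.60, 4.5: 0.50}


@dataclass
class AcidResponseSpec:
    """Parameters of the acid response.

    ``slope_kj_per_ph`` destabilises periplasmic proteins by that many
    kJ/mol of unfolding free energy per pH unit below 7.  ``hdeb_gate_ph``
    is the activation threshold of the HdeB route.  ``hdeb_keff`` its
    folding turnover (s^-1).
    """

    slope_kj_per_ph: float = 12.0
    hdeb_gate_ph: float = 6.0
    hdeb_keff: float = 0.05
    lipid_table: dict = field(default_factory=_default_lipid_table)
    activity_table: dict = field(default_factory=_default_activity_table)

    def to_dict(self) -> dict:
        return {
            "slope_kj_per_ph": self.slope_kj_per_ph,
            "hdeb_gate_ph": self.hdeb_gate_ph,
            "hdeb_keff": self.hdeb_keff,
            "lipid_table": {str(k): dict(v)
                            for k, v in self.lipid_table.items()},
            "activity_table": {str(k): v
                               for k, v in self.activity_table.items()},
        }

    @classmethod
    def from_dict(cls, data: dict) -> "AcidResponseSpec":
        data = dict(data)
        data["lipid_table"] = {float(k): dict(v)
                               for k, v in data.get("lipid_table", {}).items()}
        data["activity_table"] = {
            float(k): float(v)
            for k, v in data.get("activity_table", {}).items()}
        return cls(**data)


def _check_ph(ph: float) -> float:
    lo, hi = PH_VALIDITY
    if not lo <= ph <= hi:
        warnings.warn(f"pH {ph:g} outside validity window [{lo}, {hi}]; "
                      f"clamping", stacklevel=3)
        return min(max(ph, lo), hi)
    return ph


def periplasmic_unfolding_keq(protein: ProteinSpec, t_kelvin: float,
                              ph: float,
                              spec: AcidResponseSpec | None = None) -> float:
    """Unfolding Keq of a periplasmic protein at temperature T and pH.

    The thermal unfolding free energy is reduced by
    ``slope * max(0, 7 - pH)`` before exponentiation.
    """
    if protein.compartment != "periplasm":
        raise ValueError(f"{protein.id} is not periplasmic")
    spec = spec or AcidResponseSpec()
    ph = _check_ph(ph)
    dg = delta_g_unfold(protein, t_kelvin) \
        - spec.slope_kj_per_ph * max(0.0, 7.0 - ph)
    return math.exp(-dg / (GAS_CONSTANT_KJ * t_kelvin))


def membrane_lipid_composition(spec: AcidResponseSpec, ph: float) -> dict:
    """Fatty-acid stoichiometric vector at a given pH.

    Linear interpolation between the tabulated anchor compositions;
    outside the table hull the nearest row is used (with a warning from
    the pH validity check where applicable).  The unsaturated share is
    non-decreasing as pH decreases as long as the anchors are.
    """
    grid = sorted(spec.lipid_table)
    if ph <= grid[0]:
        return dict(spec.lipid_table[grid[0]])
    if ph >= grid[-1]:
        return dict(spec.lipid_table[grid[-1]])
    import bisect
    hi = bisect.bisect_right(grid, ph)
    p0, p1 = grid[hi - 1], grid[hi]
    w = (ph - p0) / (p1 - p0)
    row0, row1 = spec.lipid_table[p0], spec.lipid_table[p1]
    keys = set(row0) | set(row1)
    return {k: (1 - w) * row0.get(k, 0.0) + w * row1.get(k, 0.0)
            for k in sorted(keys)}


def membrane_activity_factor(spec: AcidResponseSpec, ph: float) -> float:
    """Multiplier (<= 1) on keffs of membrane-located enzymes at this pH."""
    grid = sorted(spec.activity_table)
    vals = [spec.activity_table[p] for p in grid]
    if ph <= grid[0]:
        return vals[0]
    if ph >= grid[-1]:
        return vals[-1]
    import bisect
    hi = bisect.bisect_right(grid, ph)
    p0, p1 = grid[hi - 1], grid[hi]
    w = (ph - p0) / (p1 - p0)
    return (1 - w) * vals[hi - 1] + w * vals[hi]


def add_periplasmic_folding(model: MEModel, protein: ProteinSpec) -> MEModel:
    """Attach the periplasmic (spontaneous-only) folding cycle, in place.

    Translation is rewired to the unfolded species; an unprotected
    spontaneous folding route is coupled to the protein's own pool with a
    turnover that collapses as acid destabilisation grows, and the
    unfolding back-reaction tracks the pH- and T-dependent Keq.
    """
    if protein.compartment != "periplasm":
        raise ValueError(f"{protein.id} is not periplasmic")
    pid = protein.id
    unf = unfolded_species(pid)
    nat = native_species(pid)
    model.add_metabolite(Metabolite(unf, "periplasm", is_macromolecule=True))
    trans = model.reactions[translation_id(pid)]
    trans.stoichiometry.pop(nat)
    trans.stoichiometry[unf] = 1.0
    model.add_reaction(Reaction(
        id=f"fold_spontaneous__{pid}",
        kind="folding",
        stoichiometry={unf: -1.0, nat: 1.0},
        catalysts=(pid,),
        coupling_source="spontaneous_folding",
        client_protein=pid,
    ))
    model.add_reaction(Reaction(
        id=f"unfold__{pid}",
        kind="folding",
        stoichiometry={nat: -1.0, unf: 1.0},
        partition={"client_form": pid, "scope": "periplasmic"},
    ))
    return model


def add_hdeb_protection(model: MEModel, protein: ProteinSpec,
                        hdeb: str = "hdeB") -> MEModel:
    """Add the HdeB-protected folding route for a periplasmic protein.

    Unfolded protein is returned to the native state through spontaneous
    folding under HdeB protection; the route consumes HdeB capacity via
    the usual mu/keff coupling and is open only below the activation pH,
    so it carries no flux at neutral pH.
    """
    if protein.compartment != "periplasm":
        raise ValueError(f"{protein.id} is not periplasmic")
    if model.acid is None:
        raise ValueError("model has no acid configuration")
    if hdeb not in model.catalyst_forms:
        raise KeyError(f"HdeB complex {hdeb!r} not in model")
    pid = protein.id
    unf = unfolded_species(pid)
    if unf not in model.metabolites:
        raise ValueError(f"{pid}: build the periplasmic folding cycle first")
    model.add_reaction(Reaction(
        id=f"fold_hdeb__{pid}",
        kind="folding",
        stoichiometry={unf: -1.0, native_species(pid): 1.0},
        catalysts=(hdeb,),
        coupling_source="chaperone_folding",
        fixed_keff=model.acid.hdeb_keff * (1.0 + protein.agg),
        client_protein=pid,
        ph_gate=model.acid.hdeb_gate_ph,
    ))
    return model
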