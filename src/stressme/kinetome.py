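"""Keff vector management and sensitivity screening.

The *kinetome* is the vector of effective turnover rates (keff, s^-1) over
a model's catalysed metabolic reactions.  Published single-stress models
disagree on these values, so this module provides the quality-control
toolkit used to reconcile them: a single-effect sensitivity screen that
swaps one reaction's keff at a time between two vectors and re-optimises
growth, a consolidation step that applies a minimal set of overrides with
provenance, and a redundancy probe that sweeps one keff over a grid to
separate growth-critical reactions from redundant ones (whose catalyst
mass fraction moves while growth does not).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .core import MEModel, StressCondition
from .solver import maximize_growth
from .analysis import proteome_mass_fractions

__all__ = [
    "KeffVector",
    "SensitivityRecord",
    "sensitivity_screen",
    "consolidate",
    "redundancy_probe",
    "read_keff_tsv",
]


@dataclass
class KeffVector:
    """A labelled mapping reaction id -> keff (s^-1) with provenance."""

    label: str
    values: dict = field(default_factory=dict)
    provenance: tuple = ()

    def __post_init__(self) -> None:
        for rid, keff in self.values.items():
            if keff <= 0:
                raise ValueError(f"{self.label}: keff for {rid} must be "
                                 f"positive, got {keff}")

    def __getitem__(self, rid: str) -> float:
        return self.values[rid]

    def __contains__(self, rid: str) -> bool:
        return rid in self.values

    def covers(self, model: MEModel) -> list[str]:
        """Kinetome-coupled reactions missing from this vector."""
        return [rid for rid in model.kinetome_coupled_reactions()
                if rid not in self.values]

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("reaction_id\tkeff_per_s\n")
            for rid in sorted(self.values):
                fh.write(f"{rid}\t{self.values[rid]:.10g}\n")


def read_keff_tsv(path: str, label: str | None = None) -> KeffVector:
    """Read a two-column keff TSV (header line required)."""
    df = pd.read_csv(path, sep="\t")
    expected = ["reaction_id", "keff_per_s"]
    if list(df.columns[:2]) != expected:
        raise ValueError(f"keff TSV must have columns {expected}, "
                         f"got {list(df.columns)}")
    import os
    label = label or os.path.splitext(os.path.basename(path))[0]
    return KeffVector(label, dict(zip(df.reaction_id, df.keff_per_s)))


@dataclass(frozen=True)
class SensitivityRecord:
    """Growth effect of swapping one reaction's keff."""

    reaction_id: str
    mu_base: float
    mu_swapped: float
    status: str = "optimal"

    @property
    def delta(self) -> float:
        return self.mu_swapped - self.mu_base


def sensitivity_screen(model: MEModel, base: KeffVector, alt: KeffVector,
                       condition: StressCondition | None = None,
                       tol: float = 1e-6) -> list[SensitivityRecord]:
    """Single-effect keff sensitivity screen between two kinetomes.

    For every reaction whose keff differs between ``base`` and ``alt``,
    exactly that one keff is swapped to the alternative value, growth is
    re-maximised, and the keff restored.  Records are sorted by |delta|
    descending with ties broken by reaction id; evaluations are
    independent, so any execution order yields the same output and the
    model is left untouched.  An infeasible single solve produces a
    flagged record rather than aborting.
    """
    condition = condition or StressCondition()
    missing = base.covers(model) + alt.covers(model)
    if missing:
        raise ValueError(f"keff vectors do not cover the model: {missing}")
    base_sol = maximize_growth(model, condition, tol=tol,
                               keffs=base.values)
    mu_base = base_sol.mu if base_sol.optimal else 0.0
    records = []
    for rid in sorted(base.values):
        if rid not in alt or alt[rid] == base[rid]:
            continue
        swapped = dict(base.values)
        swapped[rid] = alt[rid]
        sol = maximize_growth(model, condition, tol=tol, keffs=swapped)
        records.append(SensitivityRecord(
            reaction_id=rid,
            mu_base=mu_base,
            mu_swapped=sol.mu if sol.optimal else 0.0,
            status=sol.status,
        ))
    records.sort(key=lambda r: (-abs(r.delta), r.reaction_id))
    return records


def screen_to_frame(records: list[SensitivityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"reaction_id": r.reaction_id, "mu_base": r.mu_base,
          "mu_swapped": r.mu_swapped, "delta": r.delta,
          "status": r.status} for r in records])


def consolidate(base: KeffVector, overrides: dict,
                label: str | None = None) -> KeffVector:
    """Apply keff overrides to a base vector, recording provenance.

    Returns a new labelled vector differing from ``base`` in exactly the
    overridden entries; applying the same overrides again is idempotent
    (up to the label).  Non-positive overrides and unknown reactions are
    rejected.
    """
    for rid, keff in overrides.items():
        if rid not in base:
            raise KeyError(f"override for unknown reaction {rid!r}")
        if keff <= 0:
            raise ValueError(f"override keff for {rid} must be positive")
    values = dict(base.values)
    notes = list(base.provenance)
    for rid in sorted(overrides):
        old, new = values[rid], overrides[rid]
        if old != new:
            notes.append(f"{rid}: {old:g} -> {new:g} s^-1")
        values[rid] = new
    return KeffVector(label or f"{base.label}+consolidated", values,
                      tuple(notes))


def redundancy_probe(model: MEModel, reaction_id: str, keff_grid,
                     condition: StressCondition | None = None,
                     catalyst: str | None = None,
                     tol: float = 1e-6) -> pd.DataFrame:
    """Sweep one reaction's keff and report growth and catalyst cost.

    For each keff in the grid the model is re-optimised and the mass
    fraction of the catalysing protein recorded.  Growth-critical
    reactions show mu* rising with keff until another constraint binds;
    redundant reactions (with bypass routes) show near-constant mu* while
    the catalyst's mass fraction collapses as keff grows.
    """
    if reaction_id not in model.reactions:
        raise KeyError(f"unknown reaction {reaction_id!r}")
    rxn = model.reactions[reaction_id]
    if catalyst is None:
        if not rxn.catalysts:
            raise ValueError(f"{reaction_id} is not catalysed")
        catalyst = model.catalyst_forms[rxn.catalysts[0]].protein
    condition = condition or StressCondition()
    rows = []
    for keff in keff_grid:
        if keff <= 0:
            raise ValueError("keff grid must be positive")
        swapped = dict(model.keffs())
        swapped[reaction_id] = float(keff)
        sol = maximize_growth(model, condition, tol=tol, keffs=swapped)
        if sol.optimal and sol.mu > 0:
            report = proteome_mass_fractions(model, sol)
            frac = report.fractions.get(catalyst, 0.0)
        else:
            frac = float("nan")
        rows.append({"keff_per_s": float(keff), "mu_per_h": sol.mu,
                     "catalyst": catalyst, "mass_fraction": frac,
                     "status": sol.status})
    return pd.DataFrame(rows)
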