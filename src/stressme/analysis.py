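"""Post-solution analytics: FVA, proteome mass fractions, QC and grids.

Flux variability analysis fixes growth at a fraction of its optimum and
minimises/maximises target exchange fluxes, mapping the boundedness of the
alternative-optima space (uptake is negative under the secretion-positive
sign convention).  Proteome mass fractions follow the standard ME-model
definition — ``mw_i * v_translation,i / mu`` normalised over modeled
proteins — and aggregate into functional categories.  The mass-balance
report checks per-metabolite residuals of an optimal solution, and
``condition_grid`` sweeps a Cartesian grid of (temperature, pH, ROS)
conditions, emitting the phenotypes/proteome/fluxome CSV set.
"""

from __future__ import annotations

import itertools
import os
from dataclasses import dataclass, field

import pandas as pd

from .core import MEModel, Solution, StressCondition, translation_id
from .solver import fix_growth_and_optimize, maximize_growth

__all__ = [
    "FVAResult",
    "ProteomeReport",
    "fva",
    "proteome_mass_fractions",
    "category_aggregate",
    "mass_balance_report",
    "condition_grid",
]

MASS_BALANCE_TOL = 1e-6


@dataclass(frozen=True)
class FVAResult:
    reaction_id: str
    growth_fraction: float
    min_flux: float
    max_flux: float
    status: str = "optimal"

    def __post_init__(self) -> None:
        if self.status == "optimal" and self.min_flux > self.max_flux + 1e-9:
            raise ValueError(f"{self.reaction_id}: min exceeds max")


@dataclass
class ProteomeReport:
    """Per-protein and per-category mass fractions of one solution.

    ``fractions`` are normalised over modeled proteins (they sum to 1);
    ``modeled_protein_fraction`` is the summed modeled mass relative to
    the total proteome budget, which should sit at 1 minus the unmodeled
    fraction.  A mu = 0 or non-optimal solution yields an empty, flagged
    report.
    """

    fractions: dict = field(default_factory=dict)
    masses: dict = field(default_factory=dict)
    categories: dict = field(default_factory=dict)
    modeled_protein_fraction: float = float("nan")
    mu: float = 0.0
    ok: bool = True


def fva(model: MEModel, condition: StressCondition | None = None,
        fractions=(0.95, 1.0), targets=(),
        solution: Solution | None = None,
        tol: float = 1e-6) -> list[FVAResult]:
    """Flux variability analysis over growth fractions and target fluxes.

    Growth is fixed at ``f * mu*`` for each fraction ``f`` and each target
    reaction is minimised then maximised.  Ranges at a higher growth
    fraction are nested inside those at a lower one (feasible-set
    containment).  Individual infeasible fixed-growth LPs are flagged, not
    fatal.
    """
    condition = condition or StressCondition()
    for f in fractions:
        if not 0.0 < f <= 1.0:
            raise ValueError(f"growth fraction {f} outside (0, 1]")
    if solution is None:
        solution = maximize_growth(model, condition, tol=tol)
    if not solution.optimal:
        raise ValueError("FVA requires an optimal base solution")
    mu_star = solution.mu
    results = []
    for f, target in itertools.product(fractions, targets):
        mu = f * mu_star
        lo = fix_growth_and_optimize(model, condition, mu, target, "min")
        hi = fix_growth_and_optimize(model, condition, mu, target, "max")
        if lo.optimal and hi.optimal:
            results.append(FVAResult(target, f, lo.objective_value,
                                     hi.objective_value))
        else:
            results.append(FVAResult(target, f, float("nan"), float("nan"),
                                     status="infeasible"))
    return results


def proteome_mass_fractions(model: MEModel,
                            solution: Solution) -> ProteomeReport:
    """Mass fractions mw_i * v_translation,i / mu over modeled proteins."""
    if not solution.optimal or solution.mu <= 0:
        return ProteomeReport(ok=False, mu=solution.mu)
    mu = solution.mu
    masses = {}
    for pid, spec in model.proteins.items():
        rid = translation_id(pid)
        if rid not in model.reactions:
            continue
        v = solution.flux.get(rid, 0.0)
        masses[pid] = spec.mw_kda * v / mu
    total = sum(masses.values())
    if total <= 0:
        return ProteomeReport(ok=False, mu=mu)
    fractions = {pid: m / total for pid, m in masses.items()}
    report = ProteomeReport(
        fractions=fractions,
        masses=masses,
        modeled_protein_fraction=total / model.total_proteome_mass,
        mu=mu,
    )
    report.categories = category_aggregate(report, {
        pid: spec.category for pid, spec in model.proteins.items()})
    return report


def category_aggregate(report: ProteomeReport,
                       annotation: dict) -> dict:
    """Aggregate per-protein fractions into category totals (sum to 1).

    Proteins missing from the annotation land in an ``"unknown"`` bucket
    with a warning.
    """
    import warnings
    totals: dict = {}
    for pid, frac in report.fractions.items():
        cat = annotation.get(pid)
        if cat is None:
            warnings.warn(f"protein {pid} has no category annotation",
                          stacklevel=2)
            cat = "unknown"
        totals[cat] = totals.get(cat, 0.0) + frac
    return dict(sorted(totals.items()))


def mass_balance_report(model: MEModel, solution: Solution,
                        tol: float = MASS_BALANCE_TOL):
    """Per-metabolite net-flux residuals of a solution.

    Returns ``(frame, passed)`` where ``frame`` has one row per metabolite
    and ``passed`` is True iff every |residual| <= tol — consumption and
    production match for every species.
    """
    rows = [{"metabolite": met, "residual": res}
            for met, res in sorted(solution.mass_balance_residuals.items())]
    frame = pd.DataFrame(rows, columns=["metabolite", "residual"])
    passed = bool(solution.optimal
                  and (frame.empty or frame.residual.abs().max() <= tol))
    return frame, passed


_PHENOTYPE_EXCHANGES = {
    "GUR": "EX_glc", "OUR": "EX_o2", "CO2": "EX_co2", "APR": "EX_ac",
}


def condition_grid(model: MEModel, temperatures, phs, ros_multipliers,
                   keff_label: str | None = None,
                   outdir: str | None = None,
                   tol: float = 1e-6,
                   aa_supplement: str = "none",
                   exchanges: dict | None = None) -> dict:
    """Solve a Cartesian grid of stress conditions and emit CSV tables.

    Returns (and optionally writes) three long-format tables:
    ``phenotypes`` (one row per condition with mu* and key exchange
    fluxes), ``proteome`` (condition x protein mass fraction) and
    ``fluxome`` (condition x reaction flux).  Infeasible conditions are
    flagged rows; the run continues.  Outputs are pure functions of
    (model, conditions, keff label) and reproduce byte-identically.
    """
    if not (len(list(temperatures)) and len(list(phs))
            and len(list(ros_multipliers))):
        raise ValueError("condition lists must be non-empty")
    exchanges = exchanges or {
        k: v for k, v in _PHENOTYPE_EXCHANGES.items()
        if v in model.reactions}
    label = keff_label or model.active_keff
    keffs = model.keffs(label)

    pheno_rows, proteome_rows, flux_rows = [], [], []
    for t, ph, ros in itertools.product(temperatures, phs, ros_multipliers):
        cond = StressCondition(temperature_c=t, ph=ph, ros_multiplier=ros,
                               aa_supplement=aa_supplement)
        cid = cond.label()
        sol = maximize_growth(model, cond, tol=tol, keffs=keffs)
        row = {"condition_id": cid, "temp_c": t, "ph": ph, "ros_mult": ros,
               "keff_label": label, "status": sol.status,
               "mu_per_h": sol.mu if sol.optimal else 0.0}
        for name, rid in exchanges.items():
            row[name] = sol.flux.get(rid, float("nan"))
        pheno_rows.append(row)
        if sol.optimal and sol.mu > 0:
            report = proteome_mass_fractions(model, sol)
            for pid in sorted(report.fractions):
                proteome_rows.append({
                    "condition_id": cid, "protein_id": pid,
                    "mass_fraction": report.fractions[pid],
                    "category": model.proteins[pid].category})
            for rid in sorted(model.reactions):
                flux_rows.append({"condition_id": cid, "reaction_id": rid,
                                  "flux": sol.flux.get(rid, 0.0)})

    tables = {
        "phenotypes": pd.DataFrame(pheno_rows),
        "proteome": pd.DataFrame(
            proteome_rows, columns=["condition_id", "protein_id",
                                    "mass_fraction", "category"]),
        "fluxome": pd.DataFrame(
            flux_rows, columns=["condition_id", "reaction_id", "flux"]),
    }
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        for name, frame in tables.items():
            frame.to_csv(os.path.join(outdir, f"{name}.csv"), index=False,
                         float_format="%.6g")
    return tables
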