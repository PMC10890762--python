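"""LP assembly and growth-rate optimisation for ME models.

At a fixed growth rate ``mu`` the ME problem is a linear program over
reaction fluxes:

* steady-state mass balance for every species (equalities);
* enzyme-coupling rows, one per catalyst form with any demand:
  ``sum_r (mu / keff_r) * v_r <= v_dilution`` — the synthesis/dilution of
  a catalyst must cover at least ``mu/keff`` per unit of catalysed flux
  (keffs are stored in s^-1 and converted to h^-1 here);
* unfolding-partition and damage rows pinning recycle and damage fluxes to
  dilution fluxes;
* the proteome budget: total modeled translation mass equals
  ``(1 - unmodeled_fraction) * mu * total_proteome_mass`` with the
  unmodeled sink carrying the remainder.

Feasibility of that LP is monotone in ``mu`` (relaxing growth relaxes
every mu-dependent demand), so the maximal growth rate is located by
bisection; a fixed-growth variant optimises an arbitrary reaction and
underlies flux variability analysis.  LPs are solved with HiGHS via
:func:`scipy.optimize.linprog`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .core import (
    AA_SUPPLEMENT_UPTAKE,
    MEModel,
    Reaction,
    Solution,
    StressCondition,
    dilution_id,
    translation_id,
)
from . import thermal as _thermal
from . import acid as _acid
from .oxidative import RosEnvironment

__all__ = [
    "enzyme_demand",
    "AssembledLP",
    "assemble_lp",
    "maximize_growth",
    "fix_growth_and_optimize",
    "knockout_gene",
    "solve_at_mu",
]

_SECONDS_PER_HOUR = 3600.0

#: Reaction id of the unmodeled-protein translation sink (if present).
UNMODELED_TRANSLATION = "translation__unmodeled"


def enzyme_demand(v: float, mu: float, keff: float) -> float:
    """Enzyme synthesis flux required to sustain a catalysed flux.

    ``mu * v / keff`` with keff given in s^-1 and converted to h^-1, so
    the result shares the mmol gDW^-1 h^-1 scale of ``v``.  Doubling keff
    halves the demand; the ratio of demands at two keffs equals the
    inverse keff ratio regardless of ``v`` and ``mu``.
    """
    if keff <= 0:
        raise ValueError(f"keff must be positive, got {keff}")
    if v < 0 or mu < 0:
        raise ValueError("flux and growth rate must be non-negative")
    return mu * v / (keff * _SECONDS_PER_HOUR)


@dataclass
class AssembledLP:
    """A fully evaluated LP at one (mu, condition) point."""

    mu: float
    columns: list  # (reaction_id, form_id | None)
    col_index: dict
    a_eq: "sparse.csr_matrix"
    b_eq: np.ndarray
    a_ub: "sparse.csr_matrix"
    b_ub: np.ndarray
    bounds: list
    row_labels: list
    metabolite_rows: dict = field(default_factory=dict)

    @property
    def n_cols(self) -> int:
        return len(self.columns)


def _column_keff(model: MEModel, rxn: Reaction, form_id: str,
                 condition: StressCondition, keffs: dict) -> float:
    """Effective keff (s^-1) of one LP column under a condition."""
    t_k = condition.temperature_k
    form = model.catalyst_forms[form_id]
    protein = model.proteins[form.protein]
    source = rxn.coupling_source
    if source == "kinetome":
        try:
            keff = keffs[rxn.id]
        except KeyError:
            raise KeyError(
                f"reaction {rxn.id!r} has no keff in the active vector"
            ) from None
        keff *= _thermal.arrhenius_factor(t_k, model.thermal) \
            if model.thermal is not None else 1.0
        if protein.compartment == "membrane" and model.acid is not None:
            keff *= _acid.membrane_activity_factor(model.acid, condition.ph)
        keff *= form.keff_scale
        keff *= rxn.keff_scale.get(form_id, 1.0)
        return keff
    if source == "fixed":
        return rxn.fixed_keff * form.keff_scale
    client = model.proteins[rxn.client_protein]
    if source == "spontaneous_folding":
        kf = _thermal.folding_rate(client, t_k, model.thermal)
        keff = kf / (1.0 + client.agg)
        if client.compartment == "periplasm" and model.acid is not None:
            keq = min(_acid.periplasmic_unfolding_keq(
                client, t_k, condition.ph, model.acid), _thermal.KEQ_CAP)
            keff /= (1.0 + keq)
        return keff
    if source == "chaperone_folding":
        # client-specific agg boost is precomputed into fixed_keff
        return rxn.fixed_keff * form.keff_scale
    raise ValueError(f"{rxn.id}: unknown coupling source {source!r}")


def _partition_keq(model: MEModel, rxn: Reaction,
                   condition: StressCondition) -> float:
    client = model.proteins[model.catalyst_forms[
        rxn.partition["client_form"]].protein]
    t_k = condition.temperature_k
    if rxn.partition.get("scope") == "periplasmic":
        keq = _acid.periplasmic_unfolding_keq(client, t_k, condition.ph,
                                              model.acid)
    else:
        keq = _thermal.unfolding_keq(client, t_k)
    return min(keq, _thermal.KEQ_CAP)


def _forced_scale(model: MEModel, rxn: Reaction,
                  condition: StressCondition) -> float:
    scale = rxn.forced_ratio.get("scale")
    if scale is None:
        return 1.0
    ros = (model.ros or RosEnvironment()).with_multiplier(
        condition.ros_multiplier)
    if scale == "superoxide_nm":
        return ros.superoxide_nm
    if scale == "h2o2_nm":
        return ros.h2o2_nm
    if scale == "ros_multiplier":
        return ros.multiplier
    raise ValueError(f"{rxn.id}: unknown forced-ratio scale {scale!r}")


def assemble_lp(model: MEModel, mu: float,
                condition: StressCondition | None = None,
                keffs: dict | None = None) -> AssembledLP:
    """Evaluate every mu- and condition-dependent coefficient into an LP.

    Deterministic: the same (model, mu, condition, keffs) yields identical
    matrices.  Raises if a kinetome-coupled reaction lacks a keff.
    """
    if mu < 0:
        raise ValueError("growth rate must be non-negative")
    condition = condition or StressCondition()
    keffs = keffs if keffs is not None else model.keffs()

    columns: list = []
    col_index: dict = {}
    bounds: list = []
    for rxn in model.reactions.values():
        lb, ub = rxn.bounds_at(mu)
        if rxn.is_growth:
            lb, ub = mu, mu
        if rxn.ph_gate is not None and condition.ph >= rxn.ph_gate:
            lb, ub = 0.0, 0.0
        if rxn.id == model.aa_exchange:
            lb = -AA_SUPPLEMENT_UPTAKE[condition.aa_supplement]
        cats = rxn.catalysts if len(rxn.catalysts) > 1 else (None,)
        if len(cats) > 1 and (lb < -1e-12):
            raise ValueError(
                f"{rxn.id}: reversible multi-catalyst reactions are not "
                f"supported")
        for cat in cats:
            if cat is None and rxn.catalysts:
                cat = rxn.catalysts[0]
            col_index[(rxn.id, cat)] = len(columns)
            columns.append((rxn.id, cat))
            bounds.append((lb, ub) if len(cats) == 1 else (0.0, ub))

    n = len(columns)
    eq_rows: list = []          # (label, {col: coef}, rhs)
    ub_rows: list = []
    met_entries: dict = {m: {} for m in model.metabolites}

    # metabolite balances
    for rxn in model.reactions.values():
        stoich = rxn.stoich_at(mu)
        for (rid, cat) in ([(rxn.id, c) for c in rxn.catalysts]
                           if len(rxn.catalysts) > 1
                           else [(rxn.id, rxn.catalysts[0]
                                  if rxn.catalysts else None)]):
            j = col_index[(rid, cat)]
            if rxn.lipid_pseudo and model.acid is not None:
                comp = _acid.membrane_lipid_composition(model.acid,
                                                        condition.ph)
                stoich_eff = dict(stoich)
                for fa, share in comp.items():
                    stoich_eff[fa] = -share
                use = stoich_eff
            else:
                use = stoich
            for met, coef in use.items():
                if coef != 0.0:
                    met_entries[met][j] = met_entries[met].get(j, 0.0) + coef

    metabolite_rows = {}
    for met, entries in met_entries.items():
        if entries:
            metabolite_rows[met] = len(eq_rows)
            eq_rows.append((f"mass_balance__{met}", entries, 0.0))

    # enzyme coupling: one inequality row per catalyst form with demand
    demands: dict = {}
    for rxn in model.reactions.values():
        if not rxn.catalysts or rxn.coupling_source is None:
            continue
        for cat in rxn.catalysts:
            key = (rxn.id, cat)
            if key not in col_index:
                continue
            keff = _column_keff(model, rxn, cat, condition, keffs)
            coef = mu / (keff * _SECONDS_PER_HOUR)
            demands.setdefault(cat, {})[col_index[key]] = \
                demands.get(cat, {}).get(col_index[key], 0.0) + coef
    for cat in sorted(demands):
        dil = dilution_id(cat)
        if dil not in model.reactions:
            raise ValueError(f"catalyst form {cat!r} has no dilution "
                             f"reaction")
        entries = dict(demands[cat])
        jd = col_index[(dil, None)]
        entries[jd] = entries.get(jd, 0.0) - 1.0
        ub_rows.append((f"coupling__{cat}", entries, 0.0))

    # partition and forced-ratio rows
    for rxn in model.reactions.values():
        j = col_index.get((rxn.id, rxn.catalysts[0] if rxn.catalysts
                           else None))
        if rxn.partition is not None:
            keq = _partition_keq(model, rxn, condition)
            dil = dilution_id(rxn.partition["client_form"])
            entries = {j: 1.0}
            jd = col_index[(dil, None)]
            entries[jd] = entries.get(jd, 0.0) - keq
            eq_rows.append((f"partition__{rxn.id}", entries, 0.0))
        if rxn.forced_ratio is not None:
            scale = _forced_scale(model, rxn, condition)
            entries = {j: 1.0}
            for ref, coef in rxn.forced_ratio["refs"].items():
                ref_rxn = model.reactions[ref]
                ref_cats = (ref_rxn.catalysts if len(ref_rxn.catalysts) > 1
                            else (ref_rxn.catalysts[0]
                                  if ref_rxn.catalysts else None,))
                for cat in (ref_cats if isinstance(ref_cats, tuple)
                            else (ref_cats,)):
                    jr = col_index[(ref, cat)]
                    entries[jr] = entries.get(jr, 0.0) - coef * scale
            eq_rows.append((f"forced__{rxn.id}", entries, 0.0))

    # proteome budget
    f_un = model.unmodeled_protein_fraction
    p_tot = model.total_proteome_mass
    modeled_entries = {}
    for pid, spec in model.proteins.items():
        rid = translation_id(pid)
        if rid in model.reactions:
            modeled_entries[col_index[(rid, None)]] = spec.mw_kda
    if modeled_entries:
        eq_rows.append(("proteome_modeled", modeled_entries,
                        (1.0 - f_un) * mu * p_tot))
    if UNMODELED_TRANSLATION in model.reactions:
        j = col_index[(UNMODELED_TRANSLATION, None)]
        eq_rows.append(("proteome_unmodeled", {j: model.unmodeled_mw_kda},
                        f_un * mu * p_tot))

    def build(rows):
        if not rows:
            return sparse.csr_matrix((0, n)), np.zeros(0)
        data, ri, ci, rhs = [], [], [], []
        for k, (_, entries, b) in enumerate(rows):
            rhs.append(b)
            for j, coef in entries.items():
                ri.append(k)
                ci.append(j)
                data.append(coef)
        mat = sparse.csr_matrix((data, (ri, ci)), shape=(len(rows), n))
        return mat, np.asarray(rhs, dtype=float)

    a_eq, b_eq = build(eq_rows)
    a_ub, b_ub = build(ub_rows)
    return AssembledLP(
        mu=mu, columns=columns, col_index=col_index,
        a_eq=a_eq, b_eq=b_eq, a_ub=a_ub, b_ub=b_ub, bounds=bounds,
        row_labels=[r[0] for r in eq_rows] + [r[0] for r in ub_rows],
        metabolite_rows=metabolite_rows,
    )


# Tight feasibility tolerances: coupling coefficients are O(mu/keff_h),
# i.e. down to 1e-6, so the default 1e-7 tolerance would let visible flux
# leak through zero-capacity enzymes.
_HIGHS_OPTIONS = {
    "primal_feasibility_tolerance": 1e-10,
    "dual_feasibility_tolerance": 1e-9,
}


def _solve(lp: AssembledLP, c: np.ndarray | None = None):
    if c is None:
        c = np.zeros(lp.n_cols)
    return linprog(c, A_ub=lp.a_ub, b_ub=lp.b_ub, A_eq=lp.a_eq,
                   b_eq=lp.b_eq, bounds=lp.bounds, method="highs",
                   options=_HIGHS_OPTIONS)


def _feasible(model: MEModel, mu: float, condition: StressCondition,
              keffs: dict | None) -> bool:
    lp = assemble_lp(model, mu, condition, keffs)
    return _solve(lp).status == 0


def _solution_from(model: MEModel, lp: AssembledLP, res,
                   condition: StressCondition,
                   keff_label: str | None) -> Solution:
    flux: dict = {}
    for (rid, cat), x in zip(lp.columns, res.x):
        rxn = model.reactions[rid]
        if len(rxn.catalysts) > 1:
            flux[f"{rid}@{cat}"] = float(x)
            flux[rid] = flux.get(rid, 0.0) + float(x)
        else:
            flux[rid] = float(x)
    residual_vec = lp.a_eq @ res.x - lp.b_eq
    residuals = {met: float(residual_vec[row])
                 for met, row in lp.metabolite_rows.items()}
    return Solution(
        mu=lp.mu, flux=flux, status="optimal",
        mass_balance_residuals=residuals,
        objective_value=float(res.fun) if res.fun is not None else None,
        condition=condition, keff_label=keff_label,
    )


def solve_at_mu(model: MEModel, mu: float,
                condition: StressCondition | None = None,
                keffs: dict | None = None,
                objective: np.ndarray | None = None) -> Solution:
    """Solve the LP at a fixed growth rate (feasibility or given costs)."""
    condition = condition or StressCondition()
    label = model.active_keff if keffs is None else None
    lp = assemble_lp(model, mu, condition, keffs)
    res = _solve(lp, objective)
    if res.status != 0:
        return Solution(mu=mu, status="infeasible", condition=condition,
                        keff_label=label)
    return _solution_from(model, lp, res, condition, label)


def maximize_growth(model: MEModel,
                    condition: StressCondition | None = None,
                    tol: float = 1e-6,
                    mu_max: float = 3.0,
                    keffs: dict | None = None) -> Solution:
    """Locate the maximal feasible growth rate by bisection.

    Returns a solution whose ``mu`` is within ``tol`` (h^-1) of the
    supremum of the feasible growth interval, with the flux vector of the
    final feasible LP attached.  If the model is infeasible even at
    mu = 0, an infeasible solution (mu = 0) is returned, not an exception.
    """
    condition = condition or StressCondition()
    if not _feasible(model, 0.0, condition, keffs):
        return Solution(mu=0.0, status="infeasible", condition=condition,
                        keff_label=model.active_keff if keffs is None
                        else None)
    lo, hi = 0.0, mu_max
    if _feasible(model, mu_max, condition, keffs):
        lo = mu_max
    else:
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if _feasible(model, mid, condition, keffs):
                lo = mid
            else:
                hi = mid
    return solve_at_mu(model, lo, condition, keffs)


def fix_growth_and_optimize(model: MEModel,
                            condition: StressCondition | None,
                            mu: float,
                            objective: str,
                            sense: str = "max",
                            keffs: dict | None = None) -> Solution:
    """Fix the growth rate and optimise one reaction's net flux.

    ``sense`` is ``"max"`` or ``"min"``.  Infeasible fixed-growth LPs
    yield an infeasible solution.  The reported ``objective_value`` is the
    optimised net flux of the target reaction (signed as stored).
    """
    if sense not in ("max", "min"):
        raise ValueError("sense must be 'max' or 'min'")
    if objective not in model.reactions:
        raise KeyError(f"unknown objective reaction {objective!r}")
    condition = condition or StressCondition()
    lp = assemble_lp(model, mu, condition, keffs)
    c = np.zeros(lp.n_cols)
    sign = -1.0 if sense == "max" else 1.0
    rxn = model.reactions[objective]
    cats = rxn.catalysts if len(rxn.catalysts) > 1 else (
        rxn.catalysts[0] if rxn.catalysts else None,)
    for cat in (cats if isinstance(cats, tuple) else (cats,)):
        c[lp.col_index[(objective, cat)]] = sign
    res = _solve(lp, c)
    if res.status != 0:
        return Solution(mu=mu, status="infeasible", condition=condition)
    sol = _solution_from(model, lp, res, condition,
                         model.active_keff if keffs is None else None)
    sol.objective_value = sol.flux[objective]
    return sol


def knockout_gene(model: MEModel, gene: str) -> MEModel:
    """Return a copy of the model with a gene's protein synthesis off.

    The translation flux of every protein encoded by the gene is bounded
    to zero; reactions with alternative catalysts may still carry flux via
    the remaining ones.  Raises ``KeyError`` for an unknown gene.  The
    original model is untouched, and sequential knockouts commute.
    """
    hits = model.protein_by_gene(gene)  # KeyError if absent
    out = model.copy()
    for spec in hits:
        rxn = out.reactions[translation_id(spec.id)]
        rxn.lower_bound = 0.0
        rxn.upper_bound = 0.0
    return out
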