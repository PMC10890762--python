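"""Analytics: FVA (with a brute-force vertex oracle), proteome fractions,
mass-balance QC and condition grids."""

import itertools

import numpy as np
import pytest

from stressme.analysis import (
    category_aggregate,
    condition_grid,
    fva,
    mass_balance_report,
    proteome_mass_fractions,
)
from stressme.core import Solution, StressCondition
from stressme.solver import assemble_lp, maximize_growth

FVA_TARGETS = ("EX_glc", "EX_o2", "EX_co2", "EX_ac")


def brute_force_flux_range(lp, j_obj):
    """Enumerate LP vertices to bound one coordinate, independently of the
    simplex solver.

    Every vertex is the solution of a square system built from the
    equality rows plus a choice of active inequalities/bounds; feasible
    vertices are collected and the min/max of coordinate ``j_obj``
    returned.  Exponential, so only usable on the tiny model.
    """
    n = lp.n_cols
    a_eq = lp.a_eq.toarray()
    extra = []  # (row, rhs) candidate active constraints
    for k in range(lp.a_ub.shape[0]):
        extra.append((lp.a_ub.toarray()[k], lp.b_ub[k]))
    for jcol, (lo, hi) in enumerate(lp.bounds):
        e = np.zeros(n)
        e[jcol] = 1.0
        if np.isfinite(lo):
            extra.append((e.copy(), lo))
        if np.isfinite(hi):
            extra.append((e.copy(), hi))
    need = n - a_eq.shape[0]
    best_lo, best_hi = np.inf, -np.inf
    for combo in itertools.combinations(range(len(extra)), need):
        rows = np.vstack([a_eq] + [extra[k][0] for k in combo])
        rhs = np.concatenate([lp.b_eq, [extra[k][1] for k in combo]])
        if np.linalg.matrix_rank(rows) < n:
            continue
        x, *_ = np.linalg.lstsq(rows, rhs, rcond=None)
        if np.max(np.abs(rows @ x - rhs)) > 1e-8:
            continue
        ok = np.all(lp.a_ub @ x <= lp.b_ub + 1e-8)
        for jcol, (lo, hi) in enumerate(lp.bounds):
            ok = ok and (lo - 1e-8 <= x[jcol] <= hi + 1e-8)
        if ok:
            best_lo = min(best_lo, x[j_obj])
            best_hi = max(best_hi, x[j_obj])
    return best_lo, best_hi


@pytest.fixture(scope="module")
def results(toy):
    return fva(toy, None, fractions=(0.95, 1.0), targets=FVA_TARGETS,
               tol=1e-5)


class TestFVA:
    def test_full_growth_biomass_range_collapses_to_mu_star(self, toy):
        mu = maximize_growth(toy, tol=1e-5).mu
        (res,) = fva(toy, None, fractions=(1.0,), targets=("BIOMASS",),
                     tol=1e-5)
        assert res.min_flux == pytest.approx(mu, rel=1e-4)
        assert res.max_flux == pytest.approx(mu, rel=1e-4)

    def test_ranges_nest_across_growth_fractions(self, results):
        by_target = {}
        for r in results:
            by_target.setdefault(r.reaction_id, {})[r.growth_fraction] = r
        for target, by_f in by_target.items():
            tight, loose = by_f[1.0], by_f[0.95]
            assert loose.min_flux <= tight.min_flux + 1e-6
            assert loose.max_flux >= tight.max_flux - 1e-6

    def test_uptake_is_negative_secretion_positive(self, results):
        for r in results:
            if r.reaction_id in ("EX_glc", "EX_o2"):
                assert r.max_flux <= 1e-9
            if r.reaction_id == "EX_ac":
                assert r.min_flux >= -1e-9

    def test_matches_vertex_enumeration_oracle(self, tiny_model):
        """Simplex min/max agree with brute-force vertex enumeration on
        the 7-reaction model at 95% of maximal growth."""
        from stressme.solver import fix_growth_and_optimize
        mu = 0.95 * maximize_growth(tiny_model, tol=1e-6).mu
        lp = assemble_lp(tiny_model, mu, StressCondition())
        j = lp.col_index[("EX_s", None)]
        lo_ref, hi_ref = brute_force_flux_range(lp, j)
        lo = fix_growth_and_optimize(tiny_model, None, mu, "EX_s", "min")
        hi = fix_growth_and_optimize(tiny_model, None, mu, "EX_s", "max")
        assert lo.objective_value == pytest.approx(lo_ref, abs=1e-6)
        assert hi.objective_value == pytest.approx(hi_ref, abs=1e-6)

    def test_bad_fraction_rejected(self, toy):
        with pytest.raises(ValueError):
            fva(toy, None, fractions=(0.0,), targets=("EX_ac",))


class TestProteomeReport:
    def test_fractions_sum_to_one_and_budget_identity(self, toy, solve_toy):
        rep = proteome_mass_fractions(toy, solve_toy())
        assert sum(rep.fractions.values()) == pytest.approx(1.0)
        assert rep.modeled_protein_fraction == pytest.approx(
            1.0 - toy.unmodeled_protein_fraction, abs=1e-3)

    def test_invariant_under_uniform_mw_rescaling(self, toy, solve_toy):
        """Normalisation property: scaling every molecular weight by a
        common factor leaves the reported fractions unchanged."""
        sol = solve_toy()
        base = proteome_mass_fractions(toy, sol).fractions
        scaled_model = toy.copy()
        for spec in scaled_model.proteins.values():
            spec.mw_kda *= 3.7
        scaled = proteome_mass_fractions(scaled_model, sol).fractions
        for pid in base:
            assert scaled[pid] == pytest.approx(base[pid], rel=1e-12)

    def test_zero_growth_yields_flagged_empty_report(self, toy):
        rep = proteome_mass_fractions(toy, Solution(mu=0.0))
        assert not rep.ok
        assert rep.fractions == {}

    def test_category_totals_sum_to_one(self, toy, solve_toy):
        rep = proteome_mass_fractions(toy, solve_toy())
        assert sum(rep.categories.values()) == pytest.approx(1.0)

    def test_unannotated_protein_lands_in_unknown(self, toy, solve_toy):
        rep = proteome_mass_fractions(toy, solve_toy())
        partial = {pid: "metabolism" for pid in list(rep.fractions)[:-1]}
        with pytest.warns(UserWarning):
            cats = category_aggregate(rep, partial)
        assert "unknown" in cats

    def test_chaperone_category_rises_with_heat(self, toy, solve_toy):
        cold = proteome_mass_fractions(toy, solve_toy(temperature_c=30.0))
        hot = proteome_mass_fractions(toy, solve_toy(temperature_c=44.0))
        assert hot.categories["chaperone"] > cold.categories["chaperone"]

    def test_permutation_invariance_of_categories(self, toy, solve_toy):
        rep = proteome_mass_fractions(toy, solve_toy())
        ann = {pid: toy.proteins[pid].category for pid in toy.proteins}
        shuffled = dict(reversed(list(ann.items())))
        assert category_aggregate(rep, ann) \
            == category_aggregate(rep, shuffled)


class TestMassBalance:
    def test_optimal_solution_passes(self, toy, solve_toy):
        frame, passed = mass_balance_report(toy, solve_toy())
        assert passed
        assert frame.residual.abs().max() <= 1e-6

    def test_perturbed_flux_breaks_exactly_one_balance(self, toy,
                                                       solve_toy):
        sol = solve_toy()
        lp = assemble_lp(toy, sol.mu, StressCondition())
        x = np.array([sol.flux.get(
            rid if cat is None or len(toy.reactions[rid].catalysts) <= 1
            else f"{rid}@{cat}", 0.0) for rid, cat in lp.columns])
        j = lp.col_index[("EX_co2", None)]
        x[j] += 1.0
        resid = lp.a_eq @ x - lp.b_eq
        row = lp.metabolite_rows["co2"]
        assert resid[row] == pytest.approx(-1.0, abs=1e-6)

    def test_repeat_solves_give_identical_residuals(self, toy):
        cond = StressCondition(temperature_c=41.0)
        a = maximize_growth(toy, cond, tol=1e-4)
        b = maximize_growth(toy, cond, tol=1e-4)
        assert a.mass_balance_residuals == b.mass_balance_residuals


class TestConditionGrid:
    def test_row_counts_match_grid_shape(self, toy, tmp_path):
        tables = condition_grid(toy, [34.0, 37.0], [7.0], [1.0, 10.0],
                                outdir=str(tmp_path), tol=1e-4)
        assert len(tables["phenotypes"]) == 4
        n_prot = len(toy.proteins)
        assert len(tables["proteome"]) == 4 * n_prot
        assert len(tables["fluxome"]) == 4 * len(toy.reactions)
        for name in ("phenotypes", "proteome", "fluxome"):
            assert (tmp_path / f"{name}.csv").exists()

    def test_single_condition_single_row(self, toy):
        tables = condition_grid(toy, [37.0], [7.0], [1.0], tol=1e-4)
        assert len(tables["phenotypes"]) == 1
        row = tables["phenotypes"].iloc[0]
        assert row.mu_per_h > 0
        assert row.GUR < 0 < row.CO2  # uptake negative, secretion positive

    def test_reruns_reproduce_byte_identical_csvs(self, toy, tmp_path):
        out1, out2 = tmp_path / "a", tmp_path / "b"
        for out in (out1, out2):
            condition_grid(toy, [30.0, 42.0], [7.0, 5.0], [1.0],
                           outdir=str(out), tol=1e-4)
        for name in ("phenotypes", "proteome", "fluxome"):
            assert (out1 / f"{name}.csv").read_bytes() \
                == (out2 / f"{name}.csv").read_bytes()

    def test_empty_condition_list_rejected(self, toy):
        with pytest.raises(ValueError):
            condition_grid(toy, [], [7.0], [1.0])
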