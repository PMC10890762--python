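"""Shared fixtures: the packaged toy model and a hand-built tiny model.

The tiny model is small enough (7 reactions) for closed-form growth
analysis and brute-force LP oracles; the toy model exercises every stress
mechanism.  Solutions are memoised per (condition, kinetome) so the suite
does not re-run identical bisections.
"""

from __future__ import annotations

import pytest

from stressme.core import (
    MEModel,
    Metabolite,
    ProteinSpec,
    Reaction,
    Stability,
    StressCondition,
)
from stressme.solver import maximize_growth
from stressme.fixtures import ToyModelSpec, build_toy_model

#: Substrate uptake bound and catalyst keff of the tiny model; chosen so
#: the enzyme-coupling constraint (not substrate) limits growth:
#: mu* = 0.495/40 * keff_h / 2.5 with keff_h = 3600 * TINY_KEFF.
TINY_KEFF = 0.05
TINY_UPTAKE = 10.0


def make_tiny_model(keff: float = TINY_KEFF,
                    uptake: float = TINY_UPTAKE) -> MEModel:
    """A 7-reaction ME model with a closed-form maximal growth rate.

    One substrate fuels biomass directly (2 per unit growth) and amino
    acids (2 per substrate) for translation; a single enzyme catalyses the
    conversion.  Growth is capped by min(uptake/4.5,
    0.495/40 * keff_h / 2.5) — see test_core for the derivation.
    """
    m = MEModel(id="tiny", total_proteome_mass=0.55,
                unmodeled_protein_fraction=0.10, growth_reaction="BIOMASS")
    for mid in ("s", "aa", "atp", "adp", "dead"):
        m.add_metabolite(Metabolite(mid))
    m.add_protein(ProteinSpec(id="enz", gene="enzA", mw_kda=40.0,
                              stability=Stability()), atp_per_residue=0.0)
    m.add_reaction(Reaction(id="EX_s", kind="exchange",
                            stoichiometry={"s": -1.0},
                            lower_bound=-uptake, upper_bound=0.0))
    m.add_reaction(Reaction(id="CONV", kind="metabolic",
                            stoichiometry={"s": -1.0, "aa": 2.0},
                            catalysts=("enz",),
                            coupling_source="kinetome"))
    m.add_reaction(Reaction(id="BIOMASS", kind="sink",
                            stoichiometry={"s": -2.0}, is_growth=True))
    m.add_reaction(Reaction(id="BLOCKED", kind="metabolic",
                            stoichiometry={"dead": -1.0},
                            lower_bound=0.0, upper_bound=10.0))
    n_u = m.unmodeled_mw_kda / 0.11
    m.add_reaction(Reaction(id="translation__unmodeled", kind="translation",
                            stoichiometry={"aa": -n_u}))
    m.keff_vectors = {"wild_type": {"CONV": keff}}
    return m


def tiny_mu_star(keff: float = TINY_KEFF,
                 uptake: float = TINY_UPTAKE) -> float:
    """Closed-form maximal growth rate of the tiny model."""
    keff_h = keff * 3600.0
    enzyme_cap = 0.495 / 40.0 * keff_h / 2.5
    substrate_cap = uptake / 4.5
    return min(enzyme_cap, substrate_cap)


@pytest.fixture(scope="session")
def tiny_model() -> MEModel:
    return make_tiny_model()


@pytest.fixture(scope="session")
def toy() -> MEModel:
    return build_toy_model(ToyModelSpec())


class _SolveCache:
    """Memoised maximize_growth over a fixed model."""

    def __init__(self, model: MEModel, tol: float = 1e-5) -> None:
        self.model = model
        self.tol = tol
        self._cache: dict = {}

    def __call__(self, temperature_c: float = 37.0, ph: float = 7.0,
                 ros_multiplier: float = 1.0, label: str = "wild_type",
                 aa_supplement: str = "none"):
        key = (temperature_c, ph, ros_multiplier, label, aa_supplement)
        if key not in self._cache:
            cond = StressCondition(
                temperature_c=temperature_c, ph=ph,
                ros_multiplier=ros_multiplier, aa_supplement=aa_supplement)
            self._cache[key] = maximize_growth(
                self.model, cond, tol=self.tol,
                keffs=self.model.keffs(label))
        return self._cache[key]


@pytest.fixture(scope="session")
def solve_toy(toy) -> _SolveCache:
    return _SolveCache(toy)
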