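"""Shared toy-model fixtures for the test suite."""

from __future__ import annotations

import cobra
import numpy as np
import pytest

from cogem import synthetic
from cogem.core import DEFAULT_BOUND


def make_chain_model() -> cobra.Model:
    """EX_A (uptake <= 10) -> A->B -> EX_B; optimum is 10."""
    m = cobra.Model("chain")
    a = cobra.Metabolite("A_e", compartment="e")
    b = cobra.Metabolite("B_e", compartment="e")
    ex_a = cobra.Reaction("EX_A", lower_bound=-10, upper_bound=DEFAULT_BOUND)
    ab = cobra.Reaction("AB", lower_bound=0, upper_bound=DEFAULT_BOUND)
    ex_b = cobra.Reaction("EX_B", lower_bound=0, upper_bound=DEFAULT_BOUND)
    m.add_reactions([ex_a, ab, ex_b])
    ex_a.add_metabolites({a: -1})
    ab.add_metabolites({a: -1, b: 1})
    ex_b.add_metabolites({b: -1})
    m.objective = "EX_B"
    return m


def make_parallel_model() -> cobra.Model:
    """Two parallel A->B routes; neither is essential alone."""
    m = make_chain_model()
    m.id = "parallel"
    alt = cobra.Reaction("AB_alt", lower_bound=0, upper_bound=DEFAULT_BOUND)
    m.add_reactions([alt])
    alt.add_metabolites(
        {m.metabolites.A_e: -1, m.metabolites.B_e: 1}
    )
    return m


def make_box_model(widths: list[float]) -> cobra.Model:
    """Axis-aligned box polytope: one in/out reaction pair per dimension.

    For each dimension k the pair R{k}_in: -> X_k and R{k}_out: X_k ->
    (both bounded [0, width]) is coupled by mass balance to a single free
    coordinate uniform on [0, width] under uniform polytope sampling.
    """
    m = cobra.Model("box")
    reactions = []
    for k, w in enumerate(widths):
        x = cobra.Metabolite(f"X{k}_c", compartment="c")
        r_in = cobra.Reaction(f"R{k}_in", lower_bound=0, upper_bound=w)
        r_out = cobra.Reaction(f"R{k}_out", lower_bound=0, upper_bound=w)
        m.add_reactions([r_in, r_out])
        r_in.add_metabolites({x: 1})
        r_out.add_metabolites({x: -1})
        reactions.append((r_in, r_out))
    m.objective = "R0_out"
    return m


def make_random_model(seed: int, n_mets: int = 5, n_rxns: int = 9) -> cobra.Model:
    """Small random feasible model (sparse stoichiometry, boundary in/out)."""
    rng = np.random.default_rng(seed)
    m = cobra.Model(f"random{seed}")
    mets = [cobra.Metabolite(f"m{i}_c", compartment="c") for i in range(n_mets)]
    reactions = []
    # boundary: uptake of m0, secretion of all
    up = cobra.Reaction("up", lower_bound=-10, upper_bound=0)
    reactions.append((up, {mets[0]: -1}))
    for i, met in enumerate(mets):
        out = cobra.Reaction(f"out{i}", lower_bound=0, upper_bound=50)
        reactions.append((out, {met: -1}))
    for j in range(n_rxns):
        i, k = rng.choice(n_mets, size=2, replace=False)
        coeff = float(rng.integers(1, 3))
        r = cobra.Reaction(f"r{j}", lower_bound=0, upper_bound=50)
        reactions.append((r, {mets[i]: -1.0, mets[k]: coeff}))
    m.add_reactions([r for r, _ in reactions])
    for r, stoich in reactions:
        r.add_metabolites(stoich)
    m.objective = "out1"
    return m


@pytest.fixture(scope="session")
def chain_model():
    return make_chain_model()


@pytest.fixture(scope="session")
def parallel_model():
    return make_parallel_model()


@pytest.fixture(scope="session")
def host_model():
    return synthetic.generate_host_model(seed=101)


@pytest.fixture(scope="session")
def microbe_model():
    return synthetic.generate_microbe_model(
        panel=synthetic._panel(12),
        hard_auxotrophies=["fe3"],
        partial_dependencies=["thm"],
        decoy_uptakes=["ac", "glyc"],
        seed=102,
        model_id="MX",
    )


@pytest.fixture(scope="session")
def community_fixture():
    return synthetic.generate_community_fixture(seed=103)
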