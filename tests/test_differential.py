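"""Differential screening: restrictions, statistical kernels, key metabolites."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cogem.community import merge_models
from cogem.core import fva
from cogem.differential import (
    BiomassEffect,
    apply_restriction,
    bh_fdr,
    bootstrap_ci,
    classify_biomass_effect,
    differential_table,
    flux_change,
    flux_change_is_degenerate,
    ks_compare,
    screen_key_co_metabolites,
    screen_reactions,
)


def _joint(host_model, microbe_model):
    return merge_models(
        [microbe_model], ["biomass"], ["MX"],
        host=host_model, host_biomass_id="biomass_host",
    )


# ---------------------------------------------------------------------------
# restriction scenarios
# ---------------------------------------------------------------------------

def test_restricting_hard_auxotrophy_blocks_growth(host_model, microbe_model):
    joint = _joint(host_model, microbe_model)
    restricted, scenario = apply_restriction(joint, "fe3", "MX")
    assert scenario.reaction_ids == ["MX_IEX_fe3[u]tr"]
    assert restricted.optimize_member("MX").objective_value == pytest.approx(
        0.0, abs=1e-9
    )
    # the original joint model is untouched
    assert joint.optimize_member("MX").objective_value > 1.0


def test_restricting_unknown_route_is_an_error(host_model, microbe_model):
    joint = _joint(host_model, microbe_model)
    with pytest.raises(KeyError, match="no uptake route"):
        apply_restriction(joint, "succ", "MX")
    with pytest.raises(KeyError, match="unknown member"):
        apply_restriction(joint, "fe3", "ZZ")


def test_restricted_fva_ranges_nest_inside_unrestricted(host_model, microbe_model):
    joint = _joint(host_model, microbe_model)
    restricted, _ = apply_restriction(joint, "thm", "MX")
    rids = joint.member_reaction_ids("MX")
    before = fva(joint.model, fraction_of_optimum=0.0, reactions=rids)
    after = fva(restricted.model, fraction_of_optimum=0.0, reactions=rids)
    for rid in rids:
        assert after.loc[rid, "minimum"] >= before.loc[rid, "minimum"] - 1e-6
        assert after.loc[rid, "maximum"] <= before.loc[rid, "maximum"] + 1e-6


# ---------------------------------------------------------------------------
# KS test
# ---------------------------------------------------------------------------

def test_ks_identical_samples_give_zero_statistic():
    frame = pd.DataFrame({"r1": np.arange(50.0)})
    result = ks_compare(frame, frame.copy())
    assert result.loc["r1", "statistic"] == 0.0
    assert result.loc["r1", "pvalue"] == 1.0


def test_ks_disjoint_supports_give_unit_statistic():
    a = pd.DataFrame({"r1": np.linspace(0, 1, 50)})
    b = pd.DataFrame({"r1": np.linspace(5, 6, 50)})
    result = ks_compare(a, b)
    assert result.loc["r1", "statistic"] == pytest.approx(1.0)
    assert result.loc["r1", "pvalue"] < 1e-6


def test_ks_statistic_matches_brute_force_ecdf_sweep():
    rng = np.random.default_rng(42)
    a = rng.normal(0.0, 1.0, 50)
    b = rng.normal(0.4, 1.3, 50)
    result = ks_compare(pd.DataFrame({"r": a}), pd.DataFrame({"r": b}))
    pooled = np.concatenate([a, b])
    d_max = 0.0
    for t in pooled:
        ecdf_a = (a <= t).mean()
        ecdf_b = (b <= t).mean()
        d_max = max(d_max, abs(ecdf_a - ecdf_b))
    assert result.loc["r", "statistic"] == pytest.approx(d_max)


def test_ks_missing_reaction_treated_as_zero_flux():
    a = pd.DataFrame({"r1": np.full(30, 2.0)})
    b = pd.DataFrame({"r2": np.full(30, 3.0)})
    result = ks_compare(a, b)
    # r1 is missing from b: compared against a constant-zero sample
    assert result.loc["r1", "statistic"] == pytest.approx(1.0)
    assert result.loc["r2", "statistic"] == pytest.approx(1.0)


def test_ks_rejects_empty_samples():
    with pytest.raises(ValueError, match="empty"):
        ks_compare(pd.DataFrame(), pd.DataFrame({"r": [1.0]}))


# ---------------------------------------------------------------------------
# BH-FDR
# ---------------------------------------------------------------------------

def _bh_manual(p):
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    q = [0.0] * n
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        q[i] = running
    return q


def test_bh_fdr_hand_example():
    assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])


def test_bh_fdr_single_value_unchanged():
    assert bh_fdr([0.2]) == pytest.approx([0.2])


@settings(deadline=None, max_examples=60)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=10))
def test_bh_fdr_matches_manual_step_up(p):
    q = bh_fdr(p)
    assert np.allclose(q, _bh_manual(p))
    assert (q >= np.asarray(p) - 1e-12).all()
    assert (q <= 1.0 + 1e-12).all()


def test_bh_fdr_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.5])


# ---------------------------------------------------------------------------
# normalized flux change
# ---------------------------------------------------------------------------

def test_flux_change_tenfold_hits_threshold():
    assert flux_change(10.0, 1.0) == pytest.approx(9.0 / 11.0)
    assert round(flux_change(10.0, 1.0), 2) == 0.82


def test_flux_change_equal_and_zero_cases():
    assert flux_change(3.7, 3.7) == 0.0
    assert flux_change(0.0, 0.0) == 0.0
    assert flux_change(0.0, 5.0) == pytest.approx(-1.0)
    assert flux_change(5.0, 0.0) == pytest.approx(1.0)


def test_flux_change_degenerate_denominator_sentinel():
    fc = flux_change(1.0, -1.0)
    assert flux_change_is_degenerate(fc)
    assert not flux_change_is_degenerate(flux_change(10.0, 1.0))


@settings(deadline=None, max_examples=100)
@given(
    st.floats(min_value=-1e6, max_value=1e6),
    st.floats(min_value=-1e6, max_value=1e6),
)
def test_flux_change_antisymmetry(a, b):
    if abs(a + b) < 1e-6:
        return
    assert flux_change(a, b) == pytest.approx(-flux_change(b, a))


@settings(deadline=None, max_examples=100)
@given(
    st.floats(min_value=0.0, max_value=1e6),
    st.floats(min_value=0.0, max_value=1e6),
)
def test_flux_change_bounded_for_same_sign_means(a, b):
    assert abs(flux_change(a, b)) <= 1.0 + 1e-12


# ---------------------------------------------------------------------------
# bootstrap CI
# ---------------------------------------------------------------------------

def test_bootstrap_constant_sample_gives_degenerate_ci():
    assert bootstrap_ci([4.2] * 10) == (4.2, 4.2)


def test_bootstrap_is_seed_reproducible():
    rng = np.random.default_rng(0)
    x = rng.normal(size=10)
    assert bootstrap_ci(x, n_boot=2000, seed=5) == bootstrap_ci(x, n_boot=2000, seed=5)
    assert bootstrap_ci(x, n_boot=2000, seed=5) != bootstrap_ci(x, n_boot=2000, seed=6)


def test_bootstrap_coverage_near_nominal_level():
    rng = np.random.default_rng(1)
    hits = 0
    n_rep = 200
    for i in range(n_rep):
        x = rng.normal(0.0, 1.0, 40)  # true mean 0
        lo, hi = bootstrap_ci(x, n_boot=400, seed=i)
        hits += lo <= 0.0 <= hi
    coverage = hits / n_rep
    # percentile bootstrap at n=40: close to 0.95 within Monte-Carlo error
    assert 0.88 <= coverage <= 0.99


def test_bootstrap_requires_two_observations():
    with pytest.raises(ValueError):
        bootstrap_ci([1.0])


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

def _results_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["reaction", "qvalue", "fc", "ci_lower", "ci_upper"],
    )


def test_screen_reactions_conjunction_of_filters():
    frame = _results_frame([
        ("keep", 0.04, 0.9, 0.1, 0.5),
        ("fc_too_small", 0.04, 0.5, 0.1, 0.5),
        ("q_too_big", 0.10, 0.9, 0.1, 0.5),
        ("ci_covers_zero", 0.04, 0.9, -0.1, 0.5),
    ])
    assert screen_reactions(frame) == ["keep"]


def test_screen_reactions_monotone_in_thresholds():
    rng = np.random.default_rng(3)
    frame = _results_frame([
        (f"r{i}", rng.uniform(0, 0.2), rng.uniform(-1.5, 1.5),
         rng.uniform(-0.5, 0.1), rng.uniform(0.1, 0.9))
        for i in range(40)
    ])
    base = set(screen_reactions(frame, alpha=0.05, fc_threshold=0.82))
    assert set(screen_reactions(frame, alpha=0.01, fc_threshold=0.82)) <= base
    assert set(screen_reactions(frame, alpha=0.05, fc_threshold=0.95)) <= base


def test_differential_table_recovers_planted_shift():
    """A strongly shifted reaction passes all three filters; a null one fails."""
    rng = np.random.default_rng(9)
    n = 400
    unrestricted = pd.DataFrame({
        "shifted": rng.normal(10.0, 1.0, n),
        "null": rng.normal(5.0, 1.0, n),
    })
    restricted = pd.DataFrame({
        "shifted": rng.normal(0.5, 0.2, n),
        "null": rng.normal(5.0, 1.0, n),
    })
    table = differential_table(restricted, unrestricted, seed=1)
    kept = set(screen_reactions(table))
    assert kept == {"shifted"}
    fc = table.set_index("reaction").loc["shifted", "fc"]
    assert fc < -0.82


# ---------------------------------------------------------------------------
# biomass effects and key co-metabolites
# ---------------------------------------------------------------------------

def _biomass_frames(before_mean, after_mean, sd=0.5, n=300, seed=0):
    rng = np.random.default_rng(seed)
    before = pd.DataFrame({"bio": rng.normal(before_mean, sd, n)})
    if after_mean == 0.0:
        after = pd.DataFrame({"bio": np.zeros(n)})
    else:
        after = pd.DataFrame({"bio": rng.normal(after_mean, sd, n)})
    return before, after


def test_classify_blocked_reduced_unchanged():
    before, after = _biomass_frames(10.0, 0.0)
    assert classify_biomass_effect(before, after, "bio").effect == "blocked"
    before, after = _biomass_frames(10.0, 4.0)
    assert classify_biomass_effect(before, after, "bio").effect == "reduced"
    before, after = _biomass_frames(10.0, 10.0)
    assert classify_biomass_effect(before, after, "bio").effect == "unchanged"


def test_classify_small_noise_is_not_a_reduction():
    before, after = _biomass_frames(10.0, 9.7)  # 3% drop: below the guard
    assert classify_biomass_effect(before, after, "bio").effect == "unchanged"


def test_classify_requires_biomass_column():
    before, after = _biomass_frames(10.0, 5.0)
    with pytest.raises(KeyError):
        classify_biomass_effect(before, after, "other")


def test_key_co_metabolite_screen_exact_recovery():
    effects = [
        BiomassEffect("M1", "fe3", 10, 0, "blocked"),
        BiomassEffect("M2", "fe3", 10, 0, "blocked"),
        BiomassEffect("M1", "thm", 10, 4, "reduced"),
        BiomassEffect("M1", "ac", 10, 10, "unchanged"),
        BiomassEffect("M2", "ac", 10, 10, "unchanged"),
        BiomassEffect("M2", "glyc", 10, 10, "unchanged"),
    ]
    keys = screen_key_co_metabolites(effects)
    assert [k.co_metabolite for k in keys] == ["fe3", "thm"]
    fe3 = keys[0]
    assert fe3.affected_members == ["M1", "M2"]
    assert fe3.effects == {"M1": "blocked", "M2": "blocked"}


def test_key_screen_empty_when_all_unchanged():
    effects = [BiomassEffect("M1", "ac", 10, 10, "unchanged")]
    assert screen_key_co_metabolites(effects) == []


def test_key_screen_sorts_and_dedupes_members():
    effects = [
        BiomassEffect("M2", "fe3", 10, 0, "blocked"),
        BiomassEffect("M1", "fe3", 10, 4, "reduced"),
        BiomassEffect("M2", "fe3", 10, 0, "blocked"),
    ]
    keys = screen_key_co_metabolites(effects)
    assert keys[0].affected_members == ["M1", "M2"]
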