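"""Differential metabolic analysis under restricted co-metabolite supply.

A restriction scenario zeroes a microbe's lumen uptake route for one
co-metabolite (lb = ub = 0), mimicking a host that has lost the capacity
to supply that substrate. Per-reaction flux distributions from ACHR
sampling of the restricted and unrestricted joint models are then compared
with a two-sample Kolmogorov-Smirnov test, Benjamini-Hochberg FDR
correction, the normalized flux change

    FC = (S_Restricted - S_Unrestricted) / |S_Restricted + S_Unrestricted|

with the screening threshold |FC| >= 0.82 (about a 10-fold flux ratio),
and a percentile-bootstrap 95% CI of the mean flux difference. A reaction
counts as significantly changed only when all three filters agree.

Co-metabolites whose restriction significantly reduces (or abolishes) a
member's biomass flux are "key co-metabolites".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from cogem.community import (
    JointModel,
    extract_member_submodel,
    host_supply_capacities,
    identify_co_metabolites,
    merge_models,
)
from cogem.sampling import FluxSample, SamplerConfig, achr_sample, derive_seed

#: Paper-style defaults for the screening stage.
ALPHA = 0.05
FC_THRESHOLD = 0.82

#: Biomass mean below this (flux units) counts as blocked growth.
ZERO_TOL = 1e-9

#: Degenerate-denominator guard for the normalized flux change.
_FC_EPS = 1e-12
_FC_SENTINEL = 1e12


@dataclass
class RestrictionScenario:
    """Zero-flux restriction of one member's uptake of one co-metabolite."""

    co_metabolite: str
    member: str
    reaction_ids: list[str]
    bounds: tuple[float, float] = (0.0, 0.0)


def apply_restriction(
    joint: JointModel, co_metabolite: str, member: str
) -> tuple[JointModel, RestrictionScenario]:
    """Return a scenario-stamped copy with the uptake route closed.

    The member's interspace reactions for the metabolite get lb = ub = 0;
    every other bound is untouched. Unknown member or a metabolite without
    a registered uptake route for that member raises ``KeyError``.
    """
    if member not in joint.interspace:
        raise KeyError(f"unknown member tag {member!r}")
    registry = joint.interspace[member]
    if co_metabolite not in registry:
        raise KeyError(
            f"member {member!r} has no uptake route for {co_metabolite!r}"
        )
    out = joint.copy()
    rids = [registry[co_metabolite]]
    for rid in rids:
        out.model.reactions.get_by_id(rid).bounds = (0.0, 0.0)
    out.model.id = f"{joint.model.id}__restrict_{member}_{co_metabolite}"
    return out, RestrictionScenario(co_metabolite, member, rids)


# ---------------------------------------------------------------------------
# Statistical kernels
# ---------------------------------------------------------------------------

def ks_compare(
    sample_a: FluxSample | pd.DataFrame,
    sample_b: FluxSample | pd.DataFrame,
) -> pd.DataFrame:
    """Per-reaction two-sample KS test over the union of reactions.

    D = sup |ECDF_a - ECDF_b| with the asymptotic two-sided p-value. A
    reaction missing from one sample is treated as a constant-zero flux
    distribution in that sample.
    """
    fa = sample_a.to_frame() if isinstance(sample_a, FluxSample) else sample_a
    fb = sample_b.to_frame() if isinstance(sample_b, FluxSample) else sample_b
    if fa.empty or fb.empty:
        raise ValueError("empty flux samples")
    union = sorted(set(fa.columns) | set(fb.columns))
    records = []
    zeros_a = np.zeros(len(fa))
    zeros_b = np.zeros(len(fb))
    for rid in union:
        a = fa[rid].to_numpy(float) if rid in fa.columns else zeros_a
        b = fb[rid].to_numpy(float) if rid in fb.columns else zeros_b
        if np.ptp(a) == 0.0 and np.ptp(b) == 0.0 and a[0] == b[0]:
            statistic, pvalue = 0.0, 1.0
        else:
            res = stats.ks_2samp(a, b, method="asymp")
            statistic, pvalue = float(res.statistic), float(res.pvalue)
        records.append((rid, statistic, min(pvalue, 1.0)))
    return pd.DataFrame(
        records, columns=["reaction", "statistic", "pvalue"]
    ).set_index("reaction")


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(list(p_values), dtype=float)
    if len(p) == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def flux_change(s_restricted: float, s_unrestricted: float) -> float:
    """Normalized flux change FC = (S_R - S_U) / |S_R + S_U|.

    Both means zero gives 0. A vanishing denominator with unequal means is
    replaced by a small epsilon and the result clipped to +/-1e12 (use
    :func:`flux_change_is_degenerate` to detect the sentinel).
    """
    s_r, s_u = float(s_restricted), float(s_unrestricted)
    if s_r == 0.0 and s_u == 0.0:
        return 0.0
    denom = abs(s_r + s_u)
    if denom < _FC_EPS:
        denom = _FC_EPS
    return float(np.clip((s_r - s_u) / denom, -_FC_SENTINEL, _FC_SENTINEL))


def flux_change_is_degenerate(fc: float) -> bool:
    """True when the FC value is the clipped vanishing-denominator sentinel."""
    return abs(fc) >= _FC_SENTINEL


def bootstrap_ci(
    diff_samples: Sequence[float],
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI of the mean of a flux-difference sample."""
    x = np.asarray(list(diff_samples), dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 observations for a bootstrap CI")
    if np.ptp(x) == 0.0:
        return float(x[0]), float(x[0])
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(x), size=(n_boot, len(x)))
    means = x[idx].mean(axis=1)
    lo = (1.0 - level) / 2.0
    return (
        float(np.quantile(means, lo)),
        float(np.quantile(means, 1.0 - lo)),
    )


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------

@dataclass
class DifferentialResult:
    """Per-reaction differential statistics for one restriction scenario."""

    reaction: str
    mean_restricted: float
    mean_unrestricted: float
    ks_statistic: float
    pvalue: float
    qvalue: float
    fc: float
    ci_lower: float
    ci_upper: float
    significant: bool


def differential_table(
    restricted: FluxSample | pd.DataFrame,
    unrestricted: FluxSample | pd.DataFrame,
    alpha: float = ALPHA,
    fc_threshold: float = FC_THRESHOLD,
    n_boot: int = 1000,
    seed: int = 0,
    reactions: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Full per-reaction differential analysis for one scenario.

    Combines the KS test (BH-FDR corrected across the scenario's
    reactions), the normalized flux change, and the paired bootstrap CI of
    the mean flux difference; ``significant`` is the conjunction
    q < alpha AND |FC| >= fc_threshold AND 0 not in CI.
    """
    fr = restricted.to_frame() if isinstance(restricted, FluxSample) else restricted
    fu = (unrestricted.to_frame()
          if isinstance(unrestricted, FluxSample) else unrestricted)
    if reactions is not None:
        keep = [r for r in reactions if r in fr.columns or r in fu.columns]
        fr = fr[[c for c in fr.columns if c in keep]]
        fu = fu[[c for c in fu.columns if c in keep]]
    ks = ks_compare(fr, fu)
    qvalues = pd.Series(bh_fdr(ks["pvalue"].to_numpy()), index=ks.index)

    n_pairs = min(len(fr), len(fu))
    rows = []
    for rid in ks.index:
        a = (fr[rid].to_numpy(float)[:n_pairs]
             if rid in fr.columns else np.zeros(n_pairs))
        b = (fu[rid].to_numpy(float)[:n_pairs]
             if rid in fu.columns else np.zeros(n_pairs))
        mean_r, mean_u = float(a.mean()), float(b.mean())
        fc = flux_change(mean_r, mean_u)
        # independent chains are aligned by rank before pairing the
        # per-sample differences (quantile coupling; the mean is unaffected)
        lo, hi = bootstrap_ci(
            np.sort(a) - np.sort(b), n_boot=n_boot,
            seed=derive_seed(seed, "boot", rid),
        )
        q = float(qvalues[rid])
        significant = (
            q < alpha and abs(fc) >= fc_threshold and not (lo <= 0.0 <= hi)
        )
        rows.append(
            DifferentialResult(
                rid, mean_r, mean_u,
                float(ks.loc[rid, "statistic"]), float(ks.loc[rid, "pvalue"]),
                q, fc, lo, hi, significant,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def screen_reactions(
    results: pd.DataFrame,
    alpha: float = ALPHA,
    fc_threshold: float = FC_THRESHOLD,
) -> list[str]:
    """Reactions passing q < alpha, |FC| >= fc_threshold, and 0 not in CI."""
    keep = (
        (results["qvalue"] < alpha)
        & (results["fc"].abs() >= fc_threshold)
        & ~((results["ci_lower"] <= 0.0) & (results["ci_upper"] >= 0.0))
    )
    return results.loc[keep, "reaction"].tolist()


# ---------------------------------------------------------------------------
# Biomass effects and key co-metabolites
# ---------------------------------------------------------------------------

@dataclass
class BiomassEffect:
    """Effect of one restriction on one member's biomass flux."""

    member: str
    co_metabolite: str
    mean_before: float
    mean_after: float
    effect: str  # unchanged | reduced | blocked

    def __post_init__(self) -> None:
        if self.effect not in {"unchanged", "reduced", "blocked"}:
            raise ValueError(f"invalid effect class {self.effect!r}")


def classify_biomass_effect(
    sample_before: FluxSample | pd.DataFrame,
    sample_after: FluxSample | pd.DataFrame,
    biomass_id: str,
    member: str = "",
    co_metabolite: str = "",
    zero_tol: float = ZERO_TOL,
    alpha: float = ALPHA,
    min_relative_drop: float = 0.2,
) -> BiomassEffect:
    """Blocked / reduced / unchanged classification of a biomass flux shift.

    blocked: post-restriction mean below ``zero_tol``; reduced: a
    KS-significant decrease in mean that is not blocked and amounts to at
    least ``min_relative_drop`` of the pre-restriction mean (the
    effect-size guard plays the role the FC threshold plays for ordinary
    reactions: Monte-Carlo noise between two finite chains must not count
    as a biomass reduction); unchanged otherwise.
    """
    fb = (sample_before.to_frame()
          if isinstance(sample_before, FluxSample) else sample_before)
    fa = (sample_after.to_frame()
          if isinstance(sample_after, FluxSample) else sample_after)
    for frame, name in ((fb, "before"), (fa, "after")):
        if biomass_id not in frame.columns:
            raise KeyError(f"biomass reaction {biomass_id!r} missing from "
                           f"{name} sample")
    before = fb[biomass_id].to_numpy(float)
    after = fa[biomass_id].to_numpy(float)
    mean_before, mean_after = float(before.mean()), float(after.mean())
    if mean_after < zero_tol:
        effect = "blocked"
    else:
        ks = ks_compare(fb[[biomass_id]], fa[[biomass_id]])
        significant = float(ks["pvalue"].iloc[0]) < alpha
        drop = (mean_before - mean_after) / mean_before if mean_before > 0 else 0.0
        effect = (
            "reduced"
            if (significant and drop >= min_relative_drop)
            else "unchanged"
        )
    return BiomassEffect(member, co_metabolite, mean_before, mean_after, effect)


@dataclass
class KeyCoMetabolite:
    """A co-metabolite whose restriction affects >=1 member's biomass."""

    co_metabolite: str
    affected_members: list[str]
    effects: dict[str, str]


def screen_key_co_metabolites(
    effects: Iterable[BiomassEffect],
) -> list[KeyCoMetabolite]:
    """Key co-metabolites: >=1 member with a reduced or blocked biomass."""
    by_met: dict[str, dict[str, str]] = {}
    for eff in effects:
        by_met.setdefault(eff.co_metabolite, {})[eff.member] = eff.effect
    out = []
    for met in sorted(by_met):
        affected = sorted(
            {m for m, e in by_met[met].items() if e != "unchanged"}
        )
        if affected:
            out.append(
                KeyCoMetabolite(
                    co_metabolite=met,
                    affected_members=affected,
                    effects={m: by_met[met][m] for m in affected},
                )
            )
    return out


def biomass_effect_table(effects: Iterable[BiomassEffect]) -> pd.DataFrame:
    """Members x metabolites class-label matrix (heatmap-shaped export)."""
    frame = pd.DataFrame([e.__dict__ for e in effects])
    if frame.empty:
        return frame
    return frame.pivot_table(
        index="member", columns="co_metabolite", values="effect",
        aggfunc="first",
    ).fillna("not-tested")


def key_co_metabolite_table(keys: Iterable[KeyCoMetabolite]) -> pd.DataFrame:
    """Key-metabolite report: metabolite, related members, effect classes."""
    rows = [
        (
            k.co_metabolite,
            ", ".join(k.affected_members),
            ", ".join(sorted(set(k.effects.values()))),
        )
        for k in keys
    ]
    return pd.DataFrame(
        rows,
        columns=["key_metabolite", "related_gut_microbiota", "influence"],
    )


# ---------------------------------------------------------------------------
# Host-single-strain pipeline
# ---------------------------------------------------------------------------

@dataclass
class DifferentialAnalysis:
    """End-to-end differential stage output across members and scenarios."""

    results: pd.DataFrame = field(repr=False)
    biomass_effects: list[BiomassEffect] = field(default_factory=list)
    key_co_metabolites: list[KeyCoMetabolite] = field(default_factory=list)
    significant_reactions: dict = field(default_factory=dict)
    co_metabolite_classes: dict = field(default_factory=dict)
    baseline_samples: dict = field(default_factory=dict, repr=False)
    joint_models: dict = field(default_factory=dict, repr=False)


def run_differential_pipeline(
    host,
    host_biomass_id: str,
    microbes: Sequence,
    microbe_biomass_ids: Sequence[str],
    tags: Sequence[str],
    sampler_config: Optional[SamplerConfig] = None,
    alpha: float = ALPHA,
    fc_threshold: float = FC_THRESHOLD,
    n_boot: int = 1000,
    seed: int = 0,
    metabolites: Optional[Iterable[str]] = None,
    lumen_influx: float = 0.0,
    remove_cycles: bool = True,
    keep_samples: bool = False,
    precomputed_baselines: Optional[Mapping[str, FluxSample]] = None,
) -> DifferentialAnalysis:
    """Host-single-strain differential screen.

    For each microbe a pairwise host + strain joint model is assembled, its
    co-metabolites identified, and every co-metabolite the strain can take
    up (optionally filtered to ``metabolites``) is restricted in turn. The
    restricted and unrestricted joint models are ACHR-sampled and the
    member's reactions compared, yielding the per-reaction differential
    table, the biomass-effect grid, and the key co-metabolite list.
    """
    if sampler_config is None:
        sampler_config = SamplerConfig(n_samples=2000, thinning=10, seed=seed)
    wanted = set(metabolites) if metabolites is not None else None

    all_results = []
    effects: list[BiomassEffect] = []
    significant: dict[tuple[str, str], list[str]] = {}
    classes: dict[str, pd.DataFrame] = {}
    baselines: dict[str, FluxSample] = {}
    joints: dict[str, JointModel] = {}

    for microbe, bio_id, tag in zip(microbes, microbe_biomass_ids, tags):
        joint = merge_models(
            [microbe], [bio_id], [tag],
            host=host, host_biomass_id=host_biomass_id,
            lumen_influx=lumen_influx, remove_cycles=remove_cycles,
        )
        co_mets, class_table = identify_co_metabolites(joint)
        classes[tag] = class_table
        if keep_samples:
            joints[tag] = joint

        # flux distributions are estimated on the member's submodel under
        # joint-model lumen supply (the bacterial model, not the full joint
        # polytope), then compared per bacterial reaction
        supply = host_supply_capacities(joint)
        member_rids = joint.member_reaction_ids(tag)
        base_cfg = SamplerConfig(
            n_samples=sampler_config.n_samples,
            thinning=sampler_config.thinning,
            n_warmup=sampler_config.n_warmup,
            seed=derive_seed(seed, tag, "baseline"),
        )
        if precomputed_baselines is not None:
            if tag not in precomputed_baselines:
                raise KeyError(f"no precomputed baseline sample for {tag!r}")
            baseline = precomputed_baselines[tag]
        else:
            baseline = achr_sample(
                extract_member_submodel(joint, tag, supply), base_cfg
            )
        if keep_samples:
            baselines[tag] = baseline
        baseline_member = baseline.to_frame()[
            [c for c in baseline.reaction_ids if c in set(member_rids)]
        ]
        biomass_rid = joint.biomass[tag]

        scenario_mets = [
            c.base_id for c in co_mets
            if tag in c.microbial_uptake_reactions
            and (wanted is None or c.base_id in wanted)
        ]
        for base in scenario_mets:
            restricted_joint, scenario = apply_restriction(joint, base, tag)
            cfg = SamplerConfig(
                n_samples=sampler_config.n_samples,
                thinning=sampler_config.thinning,
                n_warmup=sampler_config.n_warmup,
                seed=derive_seed(seed, tag, base, "restricted"),
            )
            restricted = achr_sample(
                extract_member_submodel(restricted_joint, tag, supply), cfg
            )
            restricted_member = restricted.to_frame()[
                [c for c in restricted.reaction_ids if c in set(member_rids)]
            ]
            table = differential_table(
                restricted_member, baseline_member,
                alpha=alpha, fc_threshold=fc_threshold,
                n_boot=n_boot, seed=derive_seed(seed, tag, base, "diff"),
            )
            table.insert(0, "member", tag)
            table.insert(1, "co_metabolite", base)
            all_results.append(table)
            significant[(tag, base)] = screen_reactions(
                table, alpha=alpha, fc_threshold=fc_threshold
            )
            effects.append(
                classify_biomass_effect(
                    baseline_member, restricted_member, biomass_rid,
                    member=tag, co_metabolite=base, alpha=alpha,
                )
            )

    results = (
        pd.concat(all_results, ignore_index=True)
        if all_results
        else pd.DataFrame(
            columns=["member", "co_metabolite"]
            + list(DifferentialResult.__dataclass_fields__)
        )
    )
    return DifferentialAnalysis(
        results=results,
        biomass_effects=effects,
        key_co_metabolites=screen_key_co_metabolites(effects),
        significant_reactions=significant,
        co_metabolite_classes=classes,
        baseline_samples=baselines,
        joint_models=joints,
    )
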