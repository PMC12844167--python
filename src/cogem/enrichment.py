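"""Hypergeometric subsystem enrichment of significantly changed reactions.

With N reactions in the model, K of them in a subsystem, and n
significantly changed reactions, the probability that the subsystem holds
exactly k of the changed reactions is the hypergeometric point mass

    P(X = k) = C(K, k) C(N - K, n - k) / C(N, n).

The default enrichment criterion is the upper-tail probability
P(X >= k) (standard over-representation practice); the literal point-mass
criterion P(X = k) < alpha is available as ``mode="point"``. Both
probabilities are always reported, and a Benjamini-Hochberg correction is
applied across subsystems.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import cobra
import pandas as pd
from scipy import stats

from cogem.differential import bh_fdr

#: Label pooled over reactions without a subsystem annotation.
UNASSIGNED = "unassigned"


def _check_support(N: int, K: int, n: int, k: int) -> bool:
    """True when (N, K, n, k) lies in the hypergeometric support."""
    for name, value in (("N", N), ("K", K), ("n", n), ("k", k)):
        if int(value) != value or value < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {value}")
    if K > N or n > N:
        raise ValueError(f"K={K} and n={n} must not exceed N={N}")
    return max(0, n - (N - K)) <= k <= min(K, n)


def hypergeom_point(N: int, K: int, n: int, k: int) -> float:
    """P(X = k): probability that the subsystem holds exactly k hits.

    Out-of-support k returns 0 by convention (with a warning).
    """
    if not _check_support(N, K, n, k):
        warnings.warn(
            f"hypergeometric point mass outside support: N={N} K={K} n={n} k={k}",
            stacklevel=2,
        )
        return 0.0
    return float(stats.hypergeom.pmf(k, N, K, n))


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper tail P(X >= k) = sum_{j >= k} P(X = j)."""
    lo = max(0, n - (N - K))
    hi = min(K, n)
    if k <= lo:
        _check_support(N, K, n, max(k, 0) if k >= 0 else 0)
        return 1.0
    if k > hi:
        warnings.warn(
            f"hypergeometric tail outside support: N={N} K={K} n={n} k={k}",
            stacklevel=2,
        )
        return 0.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass
class EnrichmentResult:
    """Hypergeometric enrichment of one subsystem."""

    subsystem: str
    N: int
    K: int
    n: int
    k: int
    p_point: float
    p_tail: float
    qvalue: float
    enriched: bool


def subsystem_labels(model: cobra.Model) -> dict[str, str]:
    """reaction id -> subsystem label, pooling unlabelled into 'unassigned'."""
    return {
        r.id: (r.subsystem if r.subsystem else UNASSIGNED)
        for r in model.reactions
    }


def enrich_subsystems(
    model: cobra.Model | Mapping[str, str],
    significant_reactions: Iterable[str],
    mode: str = "tail",
    alpha: float = 0.05,
    exclude_subsystems: Iterable[str] = (),
) -> pd.DataFrame:
    """Per-subsystem hypergeometric enrichment of the significant set.

    ``model`` may be a cobra model or a reaction -> subsystem mapping. The
    background N is the full reaction count after dropping any
    ``exclude_subsystems`` (e.g. transport/exchange classes). The q-value
    column is the BH correction across subsystems of the chosen mode's
    p-value; ``enriched`` flags q < alpha. An empty significant set yields
    all-null results with no flags.
    """
    if mode not in {"point", "tail"}:
        raise ValueError("mode must be 'point' or 'tail'")
    labels = (
        subsystem_labels(model) if isinstance(model, cobra.Model) else dict(model)
    )
    excluded = set(exclude_subsystems)
    labels = {rid: sub for rid, sub in labels.items() if sub not in excluded}

    significant = set(significant_reactions)
    unknown = significant - set(labels)
    if unknown and isinstance(model, cobra.Model):
        raise KeyError(
            f"significant reactions not in model: {sorted(unknown)[:5]}"
        )
    significant &= set(labels)

    N = len(labels)
    n = len(significant)
    rows = []
    for subsystem in sorted(set(labels.values())):
        members = {rid for rid, sub in labels.items() if sub == subsystem}
        K = len(members)
        k = len(members & significant)
        if n == 0:
            p_point, p_tail = 1.0, 1.0
        else:
            p_point = hypergeom_point(N, K, n, k)
            p_tail = hypergeom_tail(N, K, n, k)
        rows.append((subsystem, N, K, n, k, p_point, p_tail))
    frame = pd.DataFrame(
        rows, columns=["subsystem", "N", "K", "n", "k", "p_point", "p_tail"]
    )
    chosen = frame["p_point"] if mode == "point" else frame["p_tail"]
    frame["qvalue"] = bh_fdr(chosen.to_numpy()) if len(frame) else []
    frame["enriched"] = (frame["qvalue"] < alpha) & (n > 0)
    return frame


def enrichment_results(frame: pd.DataFrame) -> list[EnrichmentResult]:
    """Dataclass view of an ``enrich_subsystems`` table."""
    return [
        EnrichmentResult(
            row.subsystem, int(row.N), int(row.K), int(row.n), int(row.k),
            float(row.p_point), float(row.p_tail), float(row.qvalue),
            bool(row.enriched),
        )
        for row in frame.itertuples(index=False)
    ]


def build_enrichment_grid(
    per_scenario: Mapping[tuple[str, str], pd.DataFrame],
) -> pd.DataFrame:
    """Long-format subsystem x co-metabolite x member enrichment grid.

    ``per_scenario`` maps (member, co_metabolite) to an
    ``enrich_subsystems`` table. The output has one row per (member,
    co_metabolite, subsystem) with the probabilities and flags, suitable
    for pivoting into a heatmap matrix with
    ``grid.pivot_table(index="subsystem", columns=["member", "co_metabolite"],
    values="enriched")``.
    """
    frames = []
    for (member, metabolite), table in sorted(per_scenario.items()):
        if table.empty:
            continue
        t = table.copy()
        t.insert(0, "member", member)
        t.insert(1, "co_metabolite", metabolite)
        frames.append(t)
    if not frames:
        return pd.DataFrame(
            columns=["member", "co_metabolite", "subsystem", "N", "K", "n",
                     "k", "p_point", "p_tail", "qvalue", "enriched"]
        )
    return pd.concat(frames, ignore_index=True)
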