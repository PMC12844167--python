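"""Uniform sampling of the steady-state flux polytope.

Artificial-centering hit-and-run (ACHR): warmup points are vertices of the
polytope {v : S.v = 0, lb <= v <= ub} obtained from LPs (minimum and
maximum of each reaction first, then random objectives), and the chain
steps uniformly along chords through the running centre. Every
``thinning``-th point is retained. Directions are differences of feasible
points, so they lie in the null space of S and the equality constraints
are preserved along the walk; the chain point is re-snapped onto the null
space periodically to keep the steady-state residual at solver level.

Sampling is bit-for-bit reproducible given (model, config, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import cobra
import numpy as np
import pandas as pd
from scipy import linalg
from scipy.optimize import linprog

from cogem.core import (
    BOUND_TOL,
    InfeasibleModelError,
    STEADY_STATE_TOL,
    model_to_arrays,
)

#: Components of a direction below this magnitude do not constrain the chord.
_DIRECTION_TOL = 1e-11

#: Warmup cap (toy scale): at most this many warmup LPs.
_MAX_WARMUP = 2000


def derive_seed(seed: int, *parts: object) -> int:
    """Deterministically derive a sub-seed below 2**31 from a seed and keys."""
    digest = hashlib.blake2b(
        ":".join([str(seed), *map(str, parts)]).encode(), digest_size=8
    ).digest()
    return int.from_bytes(digest, "big") % (2**31)


@dataclass
class SamplerConfig:
    """ACHR configuration.

    ``n_samples`` retained points (default 10000) with ``thinning`` chain
    steps between retained points (default 100), matching standard flux
    sampling practice for converged flux distributions.
    """

    n_samples: int = 10000
    thinning: int = 100
    n_warmup: Optional[int] = None  # default: min(2 * n_reactions, 2000)
    seed: int = 0
    steady_state_tol: float = STEADY_STATE_TOL
    bound_tol: float = BOUND_TOL

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FluxSample:
    """Matrix of sampled steady-state flux vectors for one model/scenario."""

    data: np.ndarray = field(repr=False)
    reaction_ids: list[str]
    provenance: dict

    def __post_init__(self) -> None:
        if self.data.ndim != 2 or self.data.shape[1] != len(self.reaction_ids):
            raise ValueError("sample matrix does not match reaction index")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, columns=self.reaction_ids)

    def column(self, reaction_id: str) -> np.ndarray:
        return self.data[:, self.reaction_ids.index(reaction_id)]

    def save(self, prefix: str | Path) -> None:
        """Persist as <prefix>.tsv plus a <prefix>.meta.json sidecar."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(prefix.with_suffix(".tsv"), sep="\t", index=False)
        prefix.with_suffix(".meta.json").write_text(
            json.dumps(self.provenance, indent=2, sort_keys=True)
        )

    @classmethod
    def load(cls, prefix: str | Path) -> "FluxSample":
        prefix = Path(prefix)
        frame = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t")
        provenance = json.loads(prefix.with_suffix(".meta.json").read_text())
        return cls(frame.to_numpy(float), list(frame.columns), provenance)


def _solve_lp(c, S, lb, ub):
    res = linprog(
        c, A_eq=S, b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(lb, ub)), method="highs",
    )
    return res


def generate_warmup(
    model: cobra.Model,
    n_warmup: Optional[int] = None,
    seed: int = 0,
) -> tuple[np.ndarray, list[str]]:
    """Warmup points: per-reaction min/max vertices, then random objectives.

    Returns ``(points, reaction_ids)`` with one feasible flux vector per
    row. Raises :class:`InfeasibleModelError` for an infeasible model and a
    ``ValueError`` naming the unbounded reactions when the polytope has
    unbounded directions (uniform sampling is undefined there).
    """
    S, lb, ub, _, rxn_ids, _ = model_to_arrays(model)
    r = len(rxn_ids)
    if n_warmup is None:
        n_warmup = min(2 * r, _MAX_WARMUP)
    n_warmup = max(n_warmup, 2)

    rng = np.random.default_rng(seed)
    objectives = []
    per_reaction = []
    for j in range(r):
        e = np.zeros(r)
        e[j] = 1.0
        per_reaction.extend([(e.copy(), j), (-e, j)])
    objectives.extend(per_reaction[:n_warmup])
    while len(objectives) < n_warmup:
        objectives.append((rng.standard_normal(r), None))

    points = []
    unbounded: list[str] = []
    for c, j in objectives:
        res = _solve_lp(c, S, lb, ub)
        if res.status == 2:
            raise InfeasibleModelError(f"model {model.id} is infeasible")
        if res.status == 3:
            if j is not None:
                unbounded.append(rxn_ids[j])
            continue
        if res.status != 0:
            raise RuntimeError(f"warmup LP failed with status {res.status}")
        x = np.clip(res.x, lb, ub)
        resid = np.abs(S @ x).max() if S.size else 0.0
        if resid > STEADY_STATE_TOL:
            raise RuntimeError(f"warmup point violates S.v=0 (residual {resid:g})")
        points.append(x)
    if unbounded:
        raise ValueError(
            "flux polytope is unbounded along reactions: "
            + ", ".join(sorted(set(unbounded)))
        )
    if not points:
        raise InfeasibleModelError(f"model {model.id}: no warmup points found")
    return np.array(points), rxn_ids


def achr_sample(model: cobra.Model, config: SamplerConfig) -> FluxSample:
    """Artificial-centering hit-and-run sample of the flux polytope.

    Keeps every ``config.thinning``-th chain point until exactly
    ``config.n_samples`` rows are collected. Numerically empty chords lead
    to a resampled direction (counted in the provenance); more than 1000
    consecutive failures abort.
    """
    warmup, rxn_ids = generate_warmup(
        model, n_warmup=config.n_warmup, seed=derive_seed(config.seed, "warmup")
    )
    S, lb, ub, _, _, _ = model_to_arrays(model)
    rng = np.random.default_rng(derive_seed(config.seed, "chain"))
    n_points, r = warmup.shape

    provenance = {
        "model_id": model.id,
        "config": config.to_dict(),
        "n_warmup_points": int(n_points),
        "n_chord_failures": 0,
        "burn_in": "warmup phase only; no additional discard",
    }

    spread = warmup.max(axis=0) - warmup.min(axis=0)
    if np.all(spread <= 1e-12):
        # fully determined polytope: a single point
        data = np.tile(warmup[0], (config.n_samples, 1))
        return FluxSample(data, rxn_ids, provenance)

    # null-space projector for periodic re-snapping of the chain point
    nullspace = linalg.null_space(S) if S.size else np.eye(r)
    x0 = warmup[0]

    center = warmup.mean(axis=0)
    x = center.copy()
    n_seen = float(n_points)
    samples = np.empty((config.n_samples, r))
    kept = 0
    step = 0
    failures = 0
    snap_every = 50_000
    while kept < config.n_samples:
        d = warmup[rng.integers(n_points)] - center
        norm = np.linalg.norm(d)
        if norm < 1e-12:
            failures += 1
            if failures > 1000:
                raise RuntimeError("too many degenerate ACHR directions")
            continue
        d /= norm
        mask = np.abs(d) > _DIRECTION_TOL
        dm = d[mask]
        a1 = (lb[mask] - x[mask]) / dm
        a2 = (ub[mask] - x[mask]) / dm
        alpha_min = np.minimum(a1, a2).max()
        alpha_max = np.maximum(a1, a2).min()
        if alpha_max - alpha_min < 1e-12:
            failures += 1
            provenance["n_chord_failures"] += 1
            if failures > 1000:
                raise RuntimeError("too many empty ACHR chords")
            continue
        failures = 0
        alpha = rng.uniform(alpha_min, alpha_max)
        x = np.clip(x + alpha * d, lb, ub)
        step += 1
        if step % snap_every == 0 and S.size:
            x = np.clip(x0 + nullspace @ (nullspace.T @ (x - x0)), lb, ub)
        n_seen += 1.0
        center += (x - center) / n_seen
        if step % config.thinning == 0:
            samples[kept] = x
            kept += 1
    return FluxSample(samples, rxn_ids, provenance)


@dataclass
class SampleReport:
    """Validity report for a flux sample."""

    max_steady_state_residual: float
    max_bound_violation: float
    per_reaction: pd.DataFrame = field(repr=False)
    split_half_shift_se: float = float("nan")
    flagged_rows: list[int] = field(default_factory=list)
    passed: bool = True


def validate_sample(sample: FluxSample, model: cobra.Model) -> SampleReport:
    """Check S.v = 0 and bound satisfaction for every sampled row.

    Also reports per-reaction means/SDs and a split-half convergence
    diagnostic: the largest first-half vs second-half mean shift across
    reactions, in units of the standard error of the half-means.
    """
    S, lb, ub, _, rxn_ids, _ = model_to_arrays(model)
    if rxn_ids != sample.reaction_ids:
        raise ValueError("sample reaction index does not match model")
    X = sample.data
    residuals = np.abs(S @ X.T).max(axis=0) if S.size else np.zeros(len(X))
    below = np.maximum(lb[None, :] - X, 0.0).max(axis=1)
    above = np.maximum(X - ub[None, :], 0.0).max(axis=1)
    violation = np.maximum(below, above)
    flagged = sorted(
        set(np.nonzero(residuals > STEADY_STATE_TOL)[0])
        | set(np.nonzero(violation > 1e-6)[0])
    )
    per_reaction = pd.DataFrame(
        {"mean": X.mean(axis=0), "sd": X.std(axis=0, ddof=1) if len(X) > 1 else 0.0},
        index=rxn_ids,
    )
    shift = float("nan")
    n = len(X)
    if n >= 4:
        half = n // 2
        a, b = X[:half], X[half:]
        se = np.sqrt(a.var(axis=0, ddof=1) / len(a) + b.var(axis=0, ddof=1) / len(b))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.abs(a.mean(axis=0) - b.mean(axis=0)) / se
        z = z[np.isfinite(z)]
        shift = float(z.max()) if len(z) else 0.0
    return SampleReport(
        max_steady_state_residual=float(residuals.max()) if len(X) else 0.0,
        max_bound_violation=float(violation.max()) if len(X) else 0.0,
        per_reaction=per_reaction,
        split_half_shift_se=shift,
        flagged_rows=[int(i) for i in flagged],
        passed=not flagged,
    )
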