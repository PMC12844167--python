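"""Tissue-specific model construction from expression data.

Workflow: aggregate a gene x sample TPM table to per-gene means, call genes
active at TPM > 1, prune reactions whose GPR evaluates inactive (greedy
expression-weighted extraction with feasibility repair), then tighten flux
bounds in proportion to expression (E-flux). ``compare_models`` quantifies
the contraction of the solution space (structure, FVA spans with a paired
Wilcoxon test, reaction essentiality).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Set

import cobra
import numpy as np
import pandas as pd
from scipy import stats

from cogem.core import (
    DEFAULT_BOUND,
    InfeasibleModelError,
    fba,
    fva,
    reaction_scores,
    single_reaction_deletion,
)

#: Genes with mean TPM strictly above this are called active.
ACTIVE_TPM_THRESHOLD = 1.0

#: Objective below this fraction of wild type counts as "not growing"
#: during extraction feasibility repair.
_FEASIBLE_FRACTION = 1e-6


@dataclass
class ExpressionProfile:
    """Per-gene mean TPM plus the sample count behind the mean."""

    mean_tpm: pd.Series
    n_samples: int

    def __post_init__(self) -> None:
        if self.mean_tpm.isna().any():
            raise ValueError("expression profile contains NaN after aggregation")
        if (self.mean_tpm < 0).any():
            raise ValueError("TPM values must be non-negative")

    def as_dict(self) -> dict[str, float]:
        return self.mean_tpm.to_dict()


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample TPM table from TSV (first column = gene id)."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    if table.shape[1] < 1:
        raise ValueError(f"{path}: expression table has no sample columns")
    return table


def aggregate_expression(tpm_table: pd.DataFrame) -> ExpressionProfile:
    """Arithmetic per-gene mean TPM across samples.

    Duplicate gene rows are rejected: isoform-to-gene aggregation is assumed
    to have happened upstream, so duplicates indicate a malformed table.
    """
    if tpm_table.shape[1] < 1:
        raise ValueError("need at least one sample column")
    if tpm_table.index.duplicated().any():
        dupes = tpm_table.index[tpm_table.index.duplicated()].unique()
        raise ValueError(f"duplicate gene rows: {', '.join(map(str, dupes[:5]))}")
    if (tpm_table < 0).any().any():
        raise ValueError("TPM table contains negative entries")
    return ExpressionProfile(
        mean_tpm=tpm_table.mean(axis=1), n_samples=tpm_table.shape[1]
    )


def filter_active_genes(
    profile: ExpressionProfile, threshold: float = ACTIVE_TPM_THRESHOLD
) -> Set[str]:
    """Genes whose mean TPM is strictly greater than ``threshold``."""
    mask = profile.mean_tpm > threshold
    return set(profile.mean_tpm.index[mask])


def _inactive_reactions(
    model: cobra.Model, active_genes: Set[str]
) -> list[str]:
    """Reactions whose GPR scores 0 when active genes score 1."""
    gene_values = {g.id: (1.0 if g.id in active_genes else 0.0)
                   for g in model.genes}
    scores = reaction_scores(model, gene_values)
    return [rid for rid, s in scores.items() if s is not None and s == 0.0]


def extract_context_model(
    model: cobra.Model,
    active_genes: Set[str],
    protected_reactions: Optional[Iterable[str]] = None,
    expression: Optional[Mapping[str, float]] = None,
) -> tuple[cobra.Model, pd.DataFrame]:
    """Greedy expression-weighted core extraction.

    Removes every reaction whose GPR evaluates inactive under
    ``active_genes`` (GPR-less and protected reactions are always kept),
    then restores removed reactions one at a time — highest reaction
    expression score first, using ``expression`` when given, otherwise the
    0/1 activity score — until the objective is feasible again.

    Returns the contextualized model and a report of removed/restored
    reactions. Raises :class:`InfeasibleModelError` if the objective is
    infeasible even with every reaction present.
    """
    protected = set(protected_reactions or [])
    objective_ids = {
        r.id for r in cobra.util.solver.linear_reaction_coefficients(model)
    }
    protected |= objective_ids

    wild = fba(model)
    if not wild.ok or wild.objective_value <= 0:
        raise InfeasibleModelError(
            f"objective infeasible in the generic model {model.id}"
        )
    target = _FEASIBLE_FRACTION * wild.objective_value

    removable = [
        rid for rid in _inactive_reactions(model, active_genes)
        if rid not in protected
    ]
    out = model.copy()
    out.id = f"{model.id}_context"
    out.remove_reactions(
        [out.reactions.get_by_id(rid) for rid in removable],
        remove_orphans=True,
    )

    restored: list[str] = []
    check = fba(out)
    if not (check.ok and check.objective_value > target):
        score_of = {}
        gene_values = dict(expression) if expression is not None else {
            g.id: (1.0 if g.id in active_genes else 0.0) for g in model.genes
        }
        raw = reaction_scores(model, gene_values)
        for rid in removable:
            s = raw.get(rid)
            score_of[rid] = -1.0 if s is None else float(s)
        for rid in sorted(removable, key=lambda r: score_of[r], reverse=True):
            rxn = model.reactions.get_by_id(rid).copy()
            out.add_reactions([rxn])
            restored.append(rid)
            check = fba(out)
            if check.ok and check.objective_value > target:
                break
        else:
            raise InfeasibleModelError(
                f"objective of {model.id} cannot be made feasible "
                "by restoring removed reactions"
            )

    report = pd.DataFrame(
        {
            "reaction": removable,
            "removed": [rid not in restored for rid in removable],
            "restored_for_feasibility": [rid in restored for rid in removable],
        }
    )
    return out, report


def apply_eflux(
    model: cobra.Model,
    profile: ExpressionProfile | Mapping[str, float],
    scaling: str = "quantile",
    default_bound: float = DEFAULT_BOUND,
    quantile: float = 0.95,
) -> cobra.Model:
    """Constrain flux bounds in proportion to expression (E-flux).

    Each reaction with a measured GPR score s gets bounds
    ``lb' = max(lb, -B * s_hat)`` and ``ub' = min(ub, B * s_hat)`` where
    ``s_hat`` is s normalized to [0, 1]: by the score maximum for
    ``scaling="absolute"``, or by the ``quantile``-th score quantile
    (clipped to 1) for ``scaling="quantile"``. Unmeasured reactions keep
    their bounds. Bounds are never widened.
    """
    if scaling not in {"absolute", "quantile"}:
        raise ValueError("scaling must be 'absolute' or 'quantile'")
    gene_values = (
        profile.as_dict() if isinstance(profile, ExpressionProfile)
        else dict(profile)
    )
    scores = reaction_scores(model, gene_values)
    measured = {rid: s for rid, s in scores.items() if s is not None}
    out = model.copy()
    out.id = f"{model.id}_eflux"
    if not measured:
        return out
    values = np.array(list(measured.values()), dtype=float)
    if scaling == "absolute":
        denom = values.max()
    else:
        denom = float(np.quantile(values, quantile))
    if denom <= 0:
        denom = 1.0
    for rid, s in measured.items():
        s_hat = min(s / denom, 1.0)
        rxn = out.reactions.get_by_id(rid)
        cap = default_bound * s_hat
        new_lb = max(rxn.lower_bound, -cap)
        new_ub = min(rxn.upper_bound, cap)
        rxn.bounds = (min(new_lb, new_ub), new_ub)
    return out


@dataclass
class ModelComparison:
    """Generic vs. contextualized model comparison report."""

    gene_reduction: float
    reaction_reduction: float
    gpr_coverage_generic: float
    gpr_coverage_specific: float
    fva_spans: pd.DataFrame = field(repr=False)
    test_name: str = "signed-rank"
    test_statistic: float = float("nan")
    test_pvalue: float = float("nan")
    essential_generic: frozenset = frozenset()
    essential_specific: frozenset = frozenset()

    @property
    def essentiality_difference(self) -> frozenset:
        return self.essential_generic ^ self.essential_specific

    def summary(self) -> dict:
        return {
            "gene_reduction": self.gene_reduction,
            "reaction_reduction": self.reaction_reduction,
            "gpr_coverage_generic": self.gpr_coverage_generic,
            "gpr_coverage_specific": self.gpr_coverage_specific,
            "n_shared_reactions": int(len(self.fva_spans)),
            "test_name": self.test_name,
            "test_statistic": self.test_statistic,
            "test_pvalue": self.test_pvalue,
            "n_essential_generic": len(self.essential_generic),
            "n_essential_specific": len(self.essential_specific),
            "n_essentiality_difference": len(self.essentiality_difference),
        }


def _gpr_coverage(model: cobra.Model) -> float:
    if len(model.reactions) == 0:
        return 0.0
    n = sum(1 for r in model.reactions if r.gene_reaction_rule)
    return n / len(model.reactions)


def compare_models(
    generic: cobra.Model,
    specific: cobra.Model,
    paired_test: str = "signed-rank",
    fraction_of_optimum: float = 0.0,
    essentiality_tolerance: float = 0.01,
) -> ModelComparison:
    """Structural + functional comparison of a generic/contextualized pair.

    FVA spans (max - min) are computed for reactions shared by both models
    and compared with a paired Wilcoxon signed-rank test by default
    (``paired_test="rank-sum"`` switches to the unpaired rank-sum test).
    All-tied spans yield p = 1 with a zero statistic rather than an error.
    """
    if paired_test not in {"signed-rank", "rank-sum"}:
        raise ValueError("paired_test must be 'signed-rank' or 'rank-sum'")
    shared = sorted(
        {r.id for r in generic.reactions} & {r.id for r in specific.reactions}
    )
    if not shared:
        raise ValueError("models share no reactions; nothing to compare")

    fva_g = fva(generic, fraction_of_optimum, reactions=shared)
    fva_s = fva(specific, fraction_of_optimum, reactions=shared)
    spans = pd.DataFrame(
        {
            "span_generic": (fva_g["maximum"] - fva_g["minimum"]).loc[shared],
            "span_specific": (fva_s["maximum"] - fva_s["minimum"]).loc[shared],
        }
    )
    diffs = spans["span_specific"] - spans["span_generic"]
    if np.allclose(diffs, 0.0):
        statistic, pvalue = 0.0, 1.0
    elif paired_test == "signed-rank":
        statistic, pvalue = stats.wilcoxon(
            spans["span_specific"], spans["span_generic"], zero_method="wilcox"
        )
    else:
        statistic, pvalue = stats.ranksums(
            spans["span_specific"], spans["span_generic"]
        )

    ess_g = single_reaction_deletion(generic, essentiality_tolerance)
    ess_s = single_reaction_deletion(specific, essentiality_tolerance)

    n_genes_g, n_genes_s = len(generic.genes), len(specific.genes)
    n_rxn_g, n_rxn_s = len(generic.reactions), len(specific.reactions)
    return ModelComparison(
        gene_reduction=(n_genes_g - n_genes_s) / n_genes_g if n_genes_g else 0.0,
        reaction_reduction=(n_rxn_g - n_rxn_s) / n_rxn_g if n_rxn_g else 0.0,
        gpr_coverage_generic=_gpr_coverage(generic),
        gpr_coverage_specific=_gpr_coverage(specific),
        fva_spans=spans,
        test_name=paired_test,
        test_statistic=float(statistic),
        test_pvalue=float(pvalue),
        essential_generic=frozenset(
            ess_g.loc[ess_g["essential"], "reaction"]
        ),
        essential_specific=frozenset(
            ess_s.loc[ess_s["essential"], "reaction"]
        ),
    )
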