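"""Core constraint-based model layer.

Thin, contract-checked wrappers around cobrapy: model I/O (SBML Level 3 +
FBC v2 and the cobrapy JSON dialect), structural validation, stoichiometric
matrix assembly, flux balance analysis (FBA), flux variability analysis
(FVA), single-reaction deletion, and gene-protein-reaction (GPR) scoring
with the E-flux convention (AND = min, OR = max).

Flux units are mmol per gram dry weight per hour throughout. The in-memory
container is ``cobra.Model``; member tags for community models are carried
in reaction/metabolite ``notes`` under the key ``"member"``.
"""

from __future__ import annotations

import ast
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

import cobra
import libsbml
import numpy as np
import pandas as pd
from cobra.core.gene import GPR
from scipy import sparse

#: Default magnitude used for "effectively unconstrained" flux bounds.
DEFAULT_BOUND = 1000.0

#: Maximum allowed |S.v| residual for a flux vector to count as steady state.
STEADY_STATE_TOL = 1e-6

#: Maximum allowed bound violation for a flux vector.
BOUND_TOL = 1e-9

#: A reaction is essential if removing it drops the optimum below this
#: fraction of the wild-type optimum.
ESSENTIALITY_TOL = 0.01


class ModelParseError(ValueError):
    """A model file could not be parsed under the named standard."""


class ModelValidationError(ValueError):
    """A model violates a structural invariant."""


class InfeasibleModelError(RuntimeError):
    """An LP that the caller required to be feasible was not."""


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".xml", ".sbml"}:
        return "sbml-fbc"
    if suffix == ".json":
        return "json"
    raise ValueError(f"cannot infer model format from suffix {suffix!r}")


def _prescan_sbml(path: Path) -> None:
    """Reject malformed or non-FBC SBML with actionable messages."""
    doc = libsbml.readSBML(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        msg = err.getMessage().strip() if err is not None else "unknown error"
        raise ModelParseError(f"malformed SBML in {path}: {msg}")
    if doc.getLevel() < 3:
        raise ModelParseError(
            f"unsupported SBML level {doc.getLevel()} in {path}; "
            "only Level 3 with the FBC package is supported"
        )
    model = doc.getModel()
    if model is None:
        raise ModelParseError(f"{path} contains no <model> element")
    missing = []
    for i in range(model.getNumReactions()):
        rxn = model.getReaction(i)
        fbc = rxn.getPlugin("fbc")
        if fbc is None or not fbc.isSetLowerFluxBound() or not fbc.isSetUpperFluxBound():
            missing.append(rxn.getIdAttribute())
    if missing:
        raise ModelParseError(
            f"{path}: reactions lacking FBC flux bounds: {', '.join(missing)}"
        )


def read_model(path: str | Path, format: Optional[str] = None) -> cobra.Model:
    """Read a model from SBML Level 3 FBC (``sbml-fbc``) or JSON dialect.

    Subsystem labels stored as SBML groups are mapped back onto
    ``Reaction.subsystem``. Raises :class:`ModelParseError` for malformed
    files, naming the offending element where libSBML reports one.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "sbml-fbc":
        _prescan_sbml(path)
        model = cobra.io.read_sbml_model(str(path))
        for group in model.groups:
            for member in group.members:
                if isinstance(member, cobra.Reaction) and not member.subsystem:
                    member.subsystem = group.name or group.id
        return model
    if fmt == "json":
        try:
            return cobra.io.load_json_model(str(path))
        except Exception as exc:  # json/schema errors from cobra
            raise ModelParseError(f"malformed JSON model {path}: {exc}") from exc
    raise ValueError(f"unknown model format {fmt!r}")


def _sort_sbml_group_members(path: Path) -> None:
    """Rewrite an SBML file with group members in id order.

    cobra stores group members as a set, so the serialized member order is
    run-dependent; sorting keeps model files byte-reproducible.
    """
    doc = libsbml.readSBML(str(path))
    plugin = doc.getModel().getPlugin("groups") if doc.getModel() else None
    if plugin is None:
        return
    for i in range(plugin.getNumGroups()):
        group = plugin.getGroup(i)
        members = sorted(
            (
                group.getMember(j).clone()
                for j in range(group.getNumMembers())
            ),
            key=lambda m: m.getIdRef(),
        )
        while group.getNumMembers():
            group.removeMember(0)
        for member in members:
            group.addMember(member)
    libsbml.writeSBMLToFile(doc, str(path))


def write_model(model: cobra.Model, path: str | Path,
                format: Optional[str] = None) -> None:
    """Write a model as SBML-FBC or JSON; subsystems become SBML groups."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "sbml-fbc":
        model = model.copy()
        by_subsystem: dict[str, list[cobra.Reaction]] = {}
        for rxn in model.reactions:
            if rxn.subsystem:
                by_subsystem.setdefault(rxn.subsystem, []).append(rxn)
        existing = {g.name or g.id for g in model.groups}
        for name, members in by_subsystem.items():
            if name in existing:
                continue
            gid = "g_" + "".join(c if c.isalnum() else "_" for c in name)
            model.add_groups([cobra.core.Group(gid, name=name, members=members)])
        cobra.io.write_sbml_model(model, str(path))
        _sort_sbml_group_members(path)
    elif fmt == "json":
        cobra.io.save_json_model(model, str(path), sort=True)
    else:
        raise ValueError(f"unknown model format {fmt!r}")


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_model(model: cobra.Model) -> pd.DataFrame:
    """Structural validation report.

    Returns a dataframe with columns ``element``, ``issue`` (empty when the
    model is clean). Checked invariants: bounds are finite-ordered numbers,
    stoichiometry keys resolve, GPR leaves are declared genes, the objective
    resolves to a declared reaction, non-exchange reactions have non-empty
    stoichiometry, and compartment ids are unique.
    """
    issues: list[tuple[str, str]] = []
    gene_ids = {g.id for g in model.genes}
    for rxn in model.reactions:
        lb, ub = rxn.lower_bound, rxn.upper_bound
        if any(math.isnan(b) for b in (lb, ub)):
            issues.append((rxn.id, "NaN flux bound"))
        elif lb > ub:
            issues.append((rxn.id, f"lower bound {lb} exceeds upper bound {ub}"))
        if len(rxn.metabolites) == 0:
            issues.append((rxn.id, "empty stoichiometry"))
        for gene in rxn.genes:
            if gene.id not in gene_ids:
                issues.append((rxn.id, f"dangling gene leaf {gene.id}"))
    if not cobra.util.solver.linear_reaction_coefficients(model):
        issues.append((model.id or "<model>", "no objective reaction set"))
    seen_mets = set()
    for met in model.metabolites:
        key = (met.id, met.compartment)
        if key in seen_mets:
            issues.append((met.id, "duplicate (id, compartment) pair"))
        seen_mets.add(key)
        if not met.reactions:
            issues.append((met.id, "orphan metabolite (no reactions)"))
    return pd.DataFrame(issues, columns=["element", "issue"])


def ensure_valid(model: cobra.Model) -> None:
    """Raise :class:`ModelValidationError` if ``validate_model`` finds issues."""
    report = validate_model(model)
    if len(report):
        lines = "; ".join(f"{e}: {i}" for e, i in report.itertuples(index=False))
        raise ModelValidationError(f"model {model.id}: {lines}")


# ---------------------------------------------------------------------------
# Stoichiometry
# ---------------------------------------------------------------------------

def build_stoichiometric_matrix(
    model: cobra.Model,
) -> tuple[sparse.csr_matrix, list[str], list[str]]:
    """Assemble the sparse stoichiometric matrix S (metabolites x reactions).

    Returns ``(S, metabolite_ids, reaction_ids)`` where ``S[i, j]`` is the
    signed coefficient of metabolite i in reaction j and every entry not set
    by a reaction is zero.
    """
    met_ids = [m.id for m in model.metabolites]
    rxn_ids = [r.id for r in model.reactions]
    met_index = {mid: i for i, mid in enumerate(met_ids)}
    rows, cols, data = [], [], []
    for j, rxn in enumerate(model.reactions):
        for met, coeff in rxn.metabolites.items():
            rows.append(met_index[met.id])
            cols.append(j)
            data.append(float(coeff))
    S = sparse.csr_matrix(
        (data, (rows, cols)), shape=(len(met_ids), len(rxn_ids))
    )
    return S, met_ids, rxn_ids


def model_to_arrays(model: cobra.Model):
    """Dense (S, lb, ub, c, reaction_ids, metabolite_ids) for LP back-ends."""
    S, met_ids, rxn_ids = build_stoichiometric_matrix(model)
    lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
    coeffs = {r.id: w for r, w in
              cobra.util.solver.linear_reaction_coefficients(model).items()}
    c = np.array([coeffs.get(rid, 0.0) for rid in rxn_ids], dtype=float)
    return S.toarray(), lb, ub, c, rxn_ids, met_ids


# ---------------------------------------------------------------------------
# FBA / FVA / deletions
# ---------------------------------------------------------------------------

@dataclass
class FBAResult:
    """Outcome of one flux balance optimisation."""

    status: str
    objective_value: Optional[float]
    fluxes: Optional[pd.Series]

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


def fba(model: cobra.Model, direction: str = "max") -> FBAResult:
    """Optimise the model objective; never raises on infeasibility.

    Returns status ``"optimal"`` with the optimum and a flux vector
    satisfying S.v = 0 and the bounds within solver tolerance, or status
    ``"infeasible"``/``"unbounded"`` with ``None`` values.
    """
    if direction not in {"max", "min"}:
        raise ValueError("direction must be 'max' or 'min'")
    with model:
        model.objective_direction = direction
        solution = model.optimize(raise_error=False)
    if solution.status != "optimal":
        return FBAResult(status=solution.status, objective_value=None, fluxes=None)
    return FBAResult("optimal", float(solution.objective_value),
                     solution.fluxes.copy())


def fva(
    model: cobra.Model,
    fraction_of_optimum: float = 0.0,
    reactions: Optional[Iterable] = None,
) -> pd.DataFrame:
    """Per-reaction (minimum, maximum) flux at a fraction of the optimum.

    With fraction f the constraint c.v >= f * z* is enforced during both
    optimisations. Raises :class:`InfeasibleModelError` when the base model
    is infeasible.
    """
    if not 0.0 <= fraction_of_optimum <= 1.0:
        raise ValueError("fraction_of_optimum must lie in [0, 1]")
    base = fba(model)
    if not base.ok:
        raise InfeasibleModelError(f"model {model.id} is {base.status}")
    return cobra.flux_analysis.flux_variability_analysis(
        model,
        reaction_list=list(reactions) if reactions is not None else None,
        fraction_of_optimum=fraction_of_optimum,
        processes=1,
    )


def single_reaction_deletion(
    model: cobra.Model, essentiality_tolerance: float = ESSENTIALITY_TOL
) -> pd.DataFrame:
    """Knock out each reaction in turn and flag essential ones.

    A reaction is essential iff the post-deletion optimum falls below
    ``essentiality_tolerance`` times the wild-type optimum. Returns a
    dataframe with columns ``reaction``, ``growth``, ``essential``.
    """
    wild = fba(model)
    if not wild.ok:
        raise InfeasibleModelError(f"model {model.id} is {wild.status}")
    raw = cobra.flux_analysis.single_reaction_deletion(model, processes=1)
    records = []
    cutoff = essentiality_tolerance * wild.objective_value
    for ids, growth in zip(raw["ids"], raw["growth"]):
        (rid,) = tuple(ids)
        g = 0.0 if (growth is None or math.isnan(growth)) else float(growth)
        records.append((rid, g, g < cutoff))
    out = pd.DataFrame(records, columns=["reaction", "growth", "essential"])
    return out.sort_values("reaction").reset_index(drop=True)


# ---------------------------------------------------------------------------
# GPR evaluation
# ---------------------------------------------------------------------------

#: Sentinel returned when a reaction's expression level cannot be scored
#: (no GPR, or its genes are unmeasured): the reaction stays unconstrained.
UNCONSTRAINED = None


def _eval_node(node, gene_values: Mapping[str, float]):
    if isinstance(node, ast.Name):
        return gene_values.get(node.id, None)
    if isinstance(node, ast.BoolOp):
        vals = [_eval_node(v, gene_values) for v in node.values]
        if isinstance(node.op, ast.And):
            # an unmeasured conjunct makes the conjunction unmeasured
            if any(v is None for v in vals):
                return None
            return min(vals)
        if isinstance(node.op, ast.Or):
            measured = [v for v in vals if v is not None]
            return max(measured) if measured else None
    if isinstance(node, ast.Expression):
        return _eval_node(node.body, gene_values)
    raise ModelValidationError(f"malformed GPR node {ast.dump(node)}")


def evaluate_gpr(
    gpr: GPR | str | None, gene_values: Mapping[str, float]
) -> Optional[float]:
    """Score a GPR with AND = min, OR = max over non-negative gene scores.

    Missing genes are treated as unmeasured: they are dropped from OR
    alternatives and make any AND containing them unmeasured. A GPR that
    cannot be scored (empty, or fully unmeasured) returns ``None``, the
    "unconstrained" sentinel.
    """
    if gpr is None:
        return UNCONSTRAINED
    if isinstance(gpr, str):
        if not gpr.strip():
            return UNCONSTRAINED
        gpr = GPR.from_string(gpr)
    if not gpr.body:
        return UNCONSTRAINED
    for value in gene_values.values():
        if value < 0:
            raise ValueError("gene scores must be non-negative")
    return _eval_node(gpr.body, gene_values)


def reaction_scores(
    model: cobra.Model, gene_values: Mapping[str, float]
) -> dict[str, Optional[float]]:
    """Per-reaction GPR score; ``None`` where the reaction is unconstrained."""
    return {
        rxn.id: evaluate_gpr(rxn.gpr if rxn.gene_reaction_rule else None,
                             gene_values)
        for rxn in model.reactions
    }
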