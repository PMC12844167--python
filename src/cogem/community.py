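"""Host + multi-microbe joint model assembly.

The joint model couples every member's extracellular compartment [e] to a
shared luminal compartment [u] through reversible interspace (IEX)
transport reactions met[e] <=> met[u] whose stoichiometric block over the
([e]; [u]) rows is [-I; I]. The host additionally gets a body-fluid layer
[b] that re-homes its boundary exchanges (nutrient intake and systemic
disposal), so the lumen is fed by host secretion. Microbial members lose
their own boundary exchanges at merge time: their only environment access
is through the lumen.

A co-metabolite is a lumen metabolite that the host can secrete
(host IEX flux > 0 feasible) and at least one microbe can take up
(microbe IEX flux < 0 feasible), certified by FVA on the joint model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import cobra
import pandas as pd
from cobra.manipulation.modify import rename_genes

from cogem.core import (
    DEFAULT_BOUND,
    FBAResult,
    ModelValidationError,
    fba,
    fva,
    read_model,
    write_model,
)

#: Reserved compartment labels at the joint-model level.
LUMEN_COMPARTMENT = "u"
EXTRACELLULAR_COMPARTMENT = "e"
BODY_FLUID_COMPARTMENT = "b"

#: Default tag for the host member.
HOST_TAG = "Host"

_FLUX_TOL = 1e-6


def _boundary_reactions(model: cobra.Model) -> list[cobra.Reaction]:
    """Exchange/sink reactions: exactly one metabolite in the stoichiometry."""
    return [r for r in model.reactions if len(r.metabolites) == 1]


def tag_model(model: cobra.Model, tag: str, merge_genes: bool = False) -> cobra.Model:
    """Prefix every reaction, metabolite, gene and compartment id with a tag.

    The untagged ("base") ids are kept in ``notes["base_id"]`` and the tag
    itself in ``notes["member"]``; internal references (stoichiometry, GPRs,
    objective) stay consistent. With ``merge_genes=True`` gene ids are left
    untouched so identical genes unify across members at merge time.
    Tagging an already-tagged model, or producing an id collision, raises.
    """
    if not tag.isidentifier():
        raise ValueError(f"tag {tag!r} is not a valid identifier")
    for rxn in model.reactions:
        if rxn.notes.get("member") is not None:
            raise ValueError(
                f"model {model.id} already carries member tag "
                f"{rxn.notes['member']!r}; refusing to tag twice"
            )
        break
    out = model.copy()
    objective_ids = [
        r.id for r in cobra.util.solver.linear_reaction_coefficients(out)
    ]
    prefix = f"{tag}_"
    new_rxn_ids = {f"{prefix}{r.id}" for r in out.reactions}
    if len(new_rxn_ids) != len(out.reactions):
        raise ValueError(f"id collision after tagging with {tag!r}")
    for met in out.metabolites:
        met.notes["base_id"] = met.id
        met.notes["member"] = tag
        met.id = f"{prefix}{met.id}"
        met.compartment = f"{prefix}{met.compartment}"
    for rxn in out.reactions:
        rxn.notes["base_id"] = rxn.id
        rxn.notes["member"] = tag
        rxn.id = f"{prefix}{rxn.id}"
    out.repair()
    if not merge_genes and out.genes:
        rename_genes(out, {g.id: f"{prefix}{g.id}" for g in out.genes})
    out.id = f"{tag}_{model.id}"
    if objective_ids:
        out.objective = f"{prefix}{objective_ids[0]}"
    return out


def _lumen_base(met: cobra.Metabolite, tag: str) -> str:
    """Shared-namespace base id for a tagged extracellular metabolite."""
    base = met.notes.get("base_id", met.id)
    for suffix in ("_e", "[e]"):
        if base.endswith(suffix):
            return base[: -len(suffix)]
    return base


def iex_reaction_id(tag: str, base: str) -> str:
    """Interspace reaction naming: ``<tag>_IEX_<base>[u]tr``."""
    return f"{tag}_IEX_{base}[u]tr"


def create_interspace(
    model: cobra.Model, tag: str, bound: float = DEFAULT_BOUND
) -> tuple[cobra.Model, dict[str, str]]:
    """Connect a tagged member's [e] metabolites to the shared lumen [u].

    For each of the n extracellular metabolites one lumen metabolite
    ``<base>_u`` (shared namespace, untagged) and one reversible transport
    reaction met[e] <=> met[u] with coefficients -1/+1 are added, so the new
    stoichiometric columns restricted to the ([e]; [u]) rows form the
    [-I; I] block. Returns the extended model and a ``base -> reaction id``
    registry. A model without an [e] compartment is rejected; a model with
    zero extracellular metabolites is returned unchanged.
    """
    ext = f"{tag}_{EXTRACELLULAR_COMPARTMENT}"
    declared = set(model.compartments) | set(getattr(model, "_compartments", {}))
    if ext not in declared:
        raise ModelValidationError(
            f"model {model.id} has no extracellular compartment {ext!r}"
        )
    out = model.copy()
    registry: dict[str, str] = {}
    new_reactions = []
    for met in [m for m in out.metabolites if m.compartment == ext]:
        base = _lumen_base(met, tag)
        lumen_met = cobra.Metabolite(
            f"{base}_u", name=f"{base} (lumen)", compartment=LUMEN_COMPARTMENT
        )
        lumen_met.notes["base_id"] = base
        rxn = cobra.Reaction(
            iex_reaction_id(tag, base), lower_bound=-bound, upper_bound=bound
        )
        rxn.notes["member"] = tag
        rxn.notes["interspace"] = base
        rxn.subsystem = "Interspace transport"
        rxn.add_metabolites({met: -1.0, lumen_met: 1.0})
        new_reactions.append(rxn)
        registry[base] = rxn.id
    out.add_reactions(new_reactions)
    return out, registry


@dataclass
class CoMetabolite:
    """A lumen metabolite exchangeable between host and >=1 microbe."""

    base_id: str
    lumen_metabolite: str
    host_secretion_reaction: str
    microbial_uptake_reactions: dict[str, str]

    def __post_init__(self) -> None:
        if not self.microbial_uptake_reactions:
            raise ValueError(
                f"co-metabolite {self.base_id} has no microbial uptake reaction"
            )


@dataclass
class JointModel:
    """Merged multi-member model with a member registry.

    ``interspace[tag][base]`` is the IEX reaction id coupling member ``tag``
    to the lumen metabolite ``<base>_u``; ``biomass[tag]`` is the tagged
    biomass reaction id; ``lumen_exchanges[base]`` is the lumen boundary
    exchange id.
    """

    model: cobra.Model
    member_tags: list[str]
    biomass: dict[str, str]
    interspace: dict[str, dict[str, str]]
    lumen_exchanges: dict[str, str]
    host_tag: Optional[str] = None
    body_fluid_exchanges: dict[str, str] = field(default_factory=dict)

    @property
    def microbe_tags(self) -> list[str]:
        return [t for t in self.member_tags if t != self.host_tag]

    @property
    def lumen_metabolites(self) -> list[str]:
        bases = set()
        for registry in self.interspace.values():
            bases.update(registry)
        return sorted(bases)

    def copy(self) -> "JointModel":
        return JointModel(
            model=self.model.copy(),
            member_tags=list(self.member_tags),
            biomass=dict(self.biomass),
            interspace={t: dict(r) for t, r in self.interspace.items()},
            lumen_exchanges=dict(self.lumen_exchanges),
            host_tag=self.host_tag,
            body_fluid_exchanges=dict(self.body_fluid_exchanges),
        )

    def member_reaction_ids(self, tag: str) -> list[str]:
        """A member's own reactions plus its interspace reactions."""
        return [
            r.id for r in self.model.reactions if r.notes.get("member") == tag
        ]

    def optimize_member(self, tag: str) -> FBAResult:
        """FBA with the member's biomass as the (maximised) objective."""
        with self.model:
            self.model.objective = self.biomass[tag]
            return fba(self.model)

    def interspace_table(self) -> pd.DataFrame:
        rows = [
            (tag, base, rid)
            for tag, registry in self.interspace.items()
            for base, rid in registry.items()
        ]
        return pd.DataFrame(rows, columns=["member", "metabolite", "reaction"])

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_model(self.model, directory / "joint_model.json")
        meta = {
            "member_tags": self.member_tags,
            "biomass": self.biomass,
            "interspace": self.interspace,
            "lumen_exchanges": self.lumen_exchanges,
            "host_tag": self.host_tag,
            "body_fluid_exchanges": self.body_fluid_exchanges,
        }
        (directory / "joint_registry.json").write_text(
            json.dumps(meta, indent=2, sort_keys=True)
        )

    @classmethod
    def load(cls, directory: str | Path) -> "JointModel":
        directory = Path(directory)
        model = read_model(directory / "joint_model.json")
        meta = json.loads((directory / "joint_registry.json").read_text())
        return cls(model=model, **meta)


def _rehome_host_exchanges(
    host: cobra.Model, tag: str, bound: float = DEFAULT_BOUND,
    keep: frozenset = frozenset(),
) -> tuple[cobra.Model, dict[str, str]]:
    """Move the host's boundary exchanges from [e] onto a body-fluid layer.

    Each original exchange EX on met[e] becomes: a reversible transport
    met[e] <=> met[b] plus a boundary exchange on met[b] carrying the
    original exchange bounds, so host nutrition and disposal run through
    the body fluid rather than the lumen.
    """
    out = host.copy()
    bf = f"{tag}_{BODY_FLUID_COMPARTMENT}"
    exchanges: dict[str, str] = {}
    new_reactions = []
    boundary = [r for r in _boundary_reactions(out) if r.id not in keep]
    for ex in boundary:
        (met,) = ex.metabolites
        base = _lumen_base(met, tag)
        bf_met = cobra.Metabolite(
            f"{tag}_{base}_b", name=f"{base} (body fluid)", compartment=bf
        )
        bf_met.notes["base_id"] = base
        bf_met.notes["member"] = tag
        transport = cobra.Reaction(
            f"{tag}_BT_{base}tr", lower_bound=-bound, upper_bound=bound
        )
        transport.notes["member"] = tag
        transport.subsystem = "Body fluid transport"
        transport.add_metabolites({met: -1.0, bf_met: 1.0})
        new_ex = cobra.Reaction(
            f"EX_{tag}_{base}_b",
            lower_bound=ex.lower_bound,
            upper_bound=ex.upper_bound,
        )
        new_ex.notes["member"] = tag
        new_ex.subsystem = "Exchange"
        new_ex.add_metabolites({bf_met: -1.0})
        new_reactions.extend([transport, new_ex])
        exchanges[base] = new_ex.id
    out.remove_reactions(boundary)
    out.add_reactions(new_reactions)
    return out, exchanges


def merge_models(
    members: Sequence[cobra.Model],
    biomass_ids: Sequence[str],
    tags: Sequence[str],
    host: Optional[cobra.Model] = None,
    host_biomass_id: Optional[str] = None,
    host_tag: str = HOST_TAG,
    merge_genes: bool = False,
    remove_cycles: bool = False,
    lumen_influx: float = 0.0,
    lumen_efflux: float = DEFAULT_BOUND,
    bound: float = DEFAULT_BOUND,
) -> JointModel:
    """Assemble the joint host + microbes model around a shared lumen.

    Each member is tagged, coupled to the lumen via interspace reactions,
    and merged into one block-diagonal model plus the lumen coupling
    columns; lumen metabolites with identical base ids are unified across
    members. Microbial boundary exchanges are removed (lumen-only
    environment access); the host keeps its exchanges re-homed onto the
    body-fluid [b] layer. Every lumen metabolite gets a boundary exchange
    with influx bound ``lumen_influx`` (default closed: the host is the
    sole supplier) and efflux bound ``lumen_efflux``.
    """
    if len(members) != len(biomass_ids) or len(members) != len(tags):
        raise ValueError("members, biomass_ids and tags must have equal length")
    all_tags = list(tags) + ([host_tag] if host is not None else [])
    if len(set(all_tags)) != len(all_tags):
        raise ValueError(f"duplicate member tags: {all_tags}")
    if host is not None and host_biomass_id is None:
        raise ValueError("host model given without host_biomass_id")

    joint = cobra.Model("joint")
    biomass: dict[str, str] = {}
    interspace: dict[str, dict[str, str]] = {}
    body_fluid_exchanges: dict[str, str] = {}

    prepared: list[cobra.Model] = []
    for model, bio_id, tag in zip(members, biomass_ids, tags):
        if bio_id not in model.reactions.list_attr("id"):
            raise ValueError(f"biomass reaction {bio_id!r} not in model {model.id}")
        tagged = tag_model(model, tag, merge_genes=merge_genes)
        tagged.remove_reactions(
            [r for r in _boundary_reactions(tagged)
             if r.id != f"{tag}_{bio_id}"]
        )
        extended, registry = create_interspace(tagged, tag, bound=bound)
        interspace[tag] = registry
        biomass[tag] = f"{tag}_{bio_id}"
        prepared.append(extended)

    if host is not None:
        if host_biomass_id not in host.reactions.list_attr("id"):
            raise ValueError(
                f"host biomass reaction {host_biomass_id!r} not in {host.id}"
            )
        tagged = tag_model(host, host_tag, merge_genes=merge_genes)
        rehomed, body_fluid_exchanges = _rehome_host_exchanges(
            tagged, host_tag, bound=bound,
            keep=frozenset({f"{host_tag}_{host_biomass_id}"}),
        )
        extended, registry = create_interspace(rehomed, host_tag, bound=bound)
        interspace[host_tag] = registry
        biomass[host_tag] = f"{host_tag}_{host_biomass_id}"
        prepared.append(extended)

    for model in prepared:
        joint.add_reactions([r for r in model.reactions])

    lumen_exchanges: dict[str, str] = {}
    lumen_mets = [m for m in joint.metabolites
                  if m.compartment == LUMEN_COMPARTMENT]
    new_exchanges = []
    for met in sorted(lumen_mets, key=lambda m: m.id):
        base = met.notes.get("base_id", met.id)
        ex = cobra.Reaction(
            f"EX_{base}_u", lower_bound=-abs(lumen_influx),
            upper_bound=lumen_efflux,
        )
        ex.subsystem = "Lumen exchange"
        ex.add_metabolites({met: -1.0})
        new_exchanges.append(ex)
        lumen_exchanges[base] = ex.id
    joint.add_reactions(new_exchanges)

    member_tags = list(tags) + ([host_tag] if host is not None else [])
    joint.objective = (
        biomass[host_tag] if host is not None else biomass[member_tags[0]]
    )
    joint.id = "joint_" + "_".join(member_tags)
    result = JointModel(
        model=joint,
        member_tags=member_tags,
        biomass=biomass,
        interspace=interspace,
        lumen_exchanges=lumen_exchanges,
        host_tag=host_tag if host is not None else None,
        body_fluid_exchanges=body_fluid_exchanges,
    )
    if remove_cycles:
        result = remove_futile_cycles(result)
    return result


def _interspace_fva(joint: JointModel, closed: bool) -> pd.DataFrame:
    """FVA over all interspace reactions, optionally with boundary closed."""
    iex_ids = [
        rid for registry in joint.interspace.values() for rid in registry.values()
    ]
    with joint.model as model:
        if closed:
            for rxn in _boundary_reactions(model):
                rxn.bounds = (0.0, 0.0)
        return fva(model, fraction_of_optimum=0.0, reactions=iex_ids)


def remove_futile_cycles(joint: JointModel) -> JointModel:
    """Prune secrete-and-reuptake loops through the lumen.

    With every boundary exchange closed, any interspace reaction still able
    to carry flux is part of a net-zero circular transport loop. For each
    lumen metabolite flagged this way, microbial interspace reactions are
    restricted to uptake-only and the host's to secretion-only — the
    minimal directional restriction. A restriction that shifts any member's
    biomass optimum by more than 1e-6 is reverted for that metabolite, so
    all optima are preserved.
    """
    ranges = _interspace_fva(joint, closed=True)
    flagged: set[str] = set()
    for tag, registry in joint.interspace.items():
        for base, rid in registry.items():
            lo, hi = ranges.loc[rid, "minimum"], ranges.loc[rid, "maximum"]
            if hi > _FLUX_TOL or lo < -_FLUX_TOL:
                flagged.add(base)
    if not flagged:
        return joint

    before = {
        tag: joint.optimize_member(tag).objective_value or 0.0
        for tag in joint.member_tags
    }
    out = joint.copy()
    for base in sorted(flagged):
        saved: dict[str, tuple[float, float]] = {}
        for tag, registry in out.interspace.items():
            rid = registry.get(base)
            if rid is None:
                continue
            rxn = out.model.reactions.get_by_id(rid)
            saved[rid] = rxn.bounds
            if tag == out.host_tag:
                rxn.bounds = (0.0, rxn.upper_bound)  # secretion-only
            else:
                rxn.bounds = (rxn.lower_bound, 0.0)  # uptake-only
        preserved = all(
            abs((out.optimize_member(tag).objective_value or 0.0) - before[tag])
            < 1e-6
            for tag in out.member_tags
        )
        if not preserved:
            for rid, bounds in saved.items():
                out.model.reactions.get_by_id(rid).bounds = bounds
    return out


def host_supply_capacities(joint: JointModel) -> dict[str, float]:
    """Maximum host secretion flux into the lumen, per lumen metabolite.

    Certified by FVA over the host's interspace reactions on the joint
    model; metabolites without a host interspace reaction get 0.
    """
    if joint.host_tag is None:
        raise ValueError("joint model has no host")
    host_reg = joint.interspace[joint.host_tag]
    if not host_reg:
        return {}
    ranges = fva(
        joint.model, fraction_of_optimum=0.0, reactions=list(host_reg.values())
    )
    return {
        base: max(0.0, float(ranges.loc[rid, "maximum"]))
        for base, rid in host_reg.items()
    }


def extract_member_submodel(
    joint: JointModel,
    tag: str,
    supply: Optional[dict[str, float]] = None,
) -> cobra.Model:
    """One member's model in its joint-model context, for flux sampling.

    The submodel holds the member's own reactions plus its interspace
    reactions (ids and bounds exactly as in the joint model, so a
    restriction applied to the joint carries over), and one boundary
    exchange per lumen metabolite the member touches whose influx bound is
    the host's maximum secretion flux for that metabolite (``supply``;
    computed via :func:`host_supply_capacities` when not given). Flux
    sampling distributions over bacterial reactions are estimated on this
    model: it has the member's flux polytope under joint-model supply
    without the host's (much larger) flux dimensions.
    """
    if tag not in joint.interspace:
        raise KeyError(f"unknown member tag {tag!r}")
    if supply is None:
        supply = (
            host_supply_capacities(joint) if joint.host_tag is not None else {}
        )
    member_rids = joint.member_reaction_ids(tag)
    sub = cobra.Model(f"{joint.model.id}__{tag}")
    sub.add_reactions(
        [joint.model.reactions.get_by_id(rid).copy() for rid in member_rids]
    )
    exchanges = []
    for met in [m for m in sub.metabolites
                if m.compartment == LUMEN_COMPARTMENT]:
        base = met.notes.get("base_id", met.id)
        joint_ex = joint.model.reactions.get_by_id(joint.lumen_exchanges[base])
        ex = cobra.Reaction(
            joint_ex.id,
            lower_bound=-supply.get(base, -joint_ex.lower_bound),
            upper_bound=joint_ex.upper_bound,
        )
        ex.subsystem = "Lumen exchange"
        ex.add_metabolites({met: -1.0})
        exchanges.append(ex)
    sub.add_reactions(exchanges)
    sub.objective = joint.biomass[tag]
    return sub


def identify_co_metabolites(
    joint: JointModel,
) -> tuple[list[CoMetabolite], pd.DataFrame]:
    """Classify lumen metabolites and list co-metabolites.

    FVA on the joint model certifies which interspace reactions can carry
    secretion flux (member -> lumen, positive) or uptake flux (lumen ->
    member, negative). Classes partition the lumen metabolites:

    - ``co-metabolite``: host secretion feasible AND >=1 microbial uptake;
    - ``host-specific``: the host interspace reaction can carry flux but no
      microbe can take the metabolite up;
    - ``microbe-specific``: everything else (only microbial interspace
      reactions can carry flux).
    """
    if joint.host_tag is None:
        raise ValueError("joint model has no host; co-metabolites undefined")
    ranges = _interspace_fva(joint, closed=False)

    def can_secrete(rid: str) -> bool:
        return ranges.loc[rid, "maximum"] > _FLUX_TOL

    def can_uptake(rid: str) -> bool:
        return ranges.loc[rid, "minimum"] < -_FLUX_TOL

    host_reg = joint.interspace.get(joint.host_tag, {})
    records = []
    co_metabolites = []
    for base in joint.lumen_metabolites:
        host_rid = host_reg.get(base)
        host_secretes = host_rid is not None and can_secrete(host_rid)
        host_active = host_rid is not None and (
            can_secrete(host_rid) or can_uptake(host_rid)
        )
        uptakers = {
            tag: registry[base]
            for tag, registry in joint.interspace.items()
            if tag != joint.host_tag and base in registry
            and can_uptake(registry[base])
        }
        if host_secretes and uptakers:
            label = "co-metabolite"
            co_metabolites.append(
                CoMetabolite(
                    base_id=base,
                    lumen_metabolite=f"{base}_u",
                    host_secretion_reaction=host_rid,
                    microbial_uptake_reactions=uptakers,
                )
            )
        elif host_active:
            label = "host-specific"
        else:
            label = "microbe-specific"
        records.append((base, label, host_secretes, sorted(uptakers)))
    table = pd.DataFrame(
        records,
        columns=["metabolite", "class", "host_secretes", "microbial_uptakers"],
    )
    return co_metabolites, table
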