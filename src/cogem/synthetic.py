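"""Synthetic toy models and fixtures with planted ground truth.

The generators emulate the shape of the real study inputs at desk scale: a
host model with cytosolic/extracellular compartments, gene-protein-reaction
(GPR) rules, and biosynthesis + secretion routes for a panel of
metabolites; microbial models whose biomass stoichiometrically requires
planted metabolites (hard auxotrophies), requires them only partially (a
low-capacity internal bypass exists), or merely degrades them (decoys);
log-normal TPM tables with a controllable active-gene fraction; and a
community fixture wiring all of it together with a machine-readable ground
truth.

Every generator is a deterministic function of (seed, parameters): the
same seed reproduces the same models byte for byte.

Host capacities are sized so that no global resource constraint couples
unrelated pathways: each biosynthesis route is capped well below the diet
intake bound, which keeps a decoy's flux subspace independent of the
biomass subspace in the joint model (restricting a decoy must not move the
biomass flux distribution).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import cobra
import numpy as np
import pandas as pd

from cogem.core import DEFAULT_BOUND, ensure_valid, fba
from cogem.community import merge_models
from cogem.differential import apply_restriction

#: Canonical secretable-metabolite panel (first entries echo common gut
#: co-metabolites; extended generically when a larger panel is requested).
DEFAULT_PANEL = [
    "glc", "ac", "succ", "cl", "fe2", "fe3", "zn2", "so4",
    "glyc", "ribflv", "thm", "fol", "spmd", "orn", "hxan", "thymd",
]

#: Subsystem layout used by the microbe generator; "planted" marks the
#: subsystem wired downstream of a dependency for enrichment recovery.
DEFAULT_SUBSYSTEM_LAYOUT = {
    "exchange": "Exchange",
    "transport": "Transport",
    "central": "Central carbon metabolism",
    "biosynthesis": "Biosynthesis",
    "degradation": "Degradation",
    "planted": "Glycerophospholipid metabolism",
}

#: Per-route host biosynthesis capacity; kept far below the diet intake
#: bound so routes do not compete for carbon.
HOST_SYNTHESIS_CAPACITY = 50.0

#: Capacity of the internal bypass behind a partial dependency.
BYPASS_CAPACITY = 0.3


def _panel(panel_size: int) -> list[str]:
    if panel_size <= len(DEFAULT_PANEL):
        return DEFAULT_PANEL[:panel_size]
    extra = [f"met{i:02d}" for i in range(panel_size - len(DEFAULT_PANEL))]
    return DEFAULT_PANEL + extra


def _gpr(rng: np.random.Generator, genes: list[str]) -> str:
    """A random small GPR: single gene, OR pair, or AND pair."""
    shape = rng.integers(0, 3)
    if shape == 0 or len(genes) < 2:
        return rng.choice(genes)
    g1, g2 = rng.choice(genes, size=2, replace=False)
    op = "or" if shape == 1 else "and"
    return f"{g1} {op} {g2}"


def generate_host_model(
    n_core_metabolites: int = 4,
    n_exchange: int = 13,
    seed: int = 0,
    diet_uptake: float = DEFAULT_BOUND,
    synthesis_capacity: float = HOST_SYNTHESIS_CAPACITY,
    n_genes: int = 40,
) -> cobra.Model:
    """Toy host model with secretion routes for a metabolite panel.

    Compartments: cytosol ``c`` and extracellular ``e``. The host imports a
    diet carbon source, runs it through a linear core chain into biomass,
    and can synthesize and secrete each of ``n_exchange - 1`` panel
    metabolites (the first extracellular metabolite is the diet input), so
    there are exactly ``n_exchange`` extracellular metabolites with an
    exchange reaction. At least 60% of reactions carry GPR rules drawn
    from ``n_genes`` host genes.
    """
    if n_core_metabolites < 1 or n_exchange < 3:
        raise ValueError("need n_core_metabolites >= 1 and n_exchange >= 3")
    rng = np.random.default_rng(seed)
    genes = [f"HG{i:04d}" for i in range(n_genes)]
    secretables = _panel(n_exchange - 1)

    model = cobra.Model("host")
    mets: dict[str, cobra.Metabolite] = {}

    def met(mid: str, comp: str) -> cobra.Metabolite:
        if mid not in mets:
            mets[mid] = cobra.Metabolite(mid, compartment=comp)
        return mets[mid]

    reactions = []

    def rxn(rid, stoich, lb, ub, subsystem, gpr=None):
        r = cobra.Reaction(rid, lower_bound=lb, upper_bound=ub)
        r.subsystem = subsystem
        reactions.append((r, stoich, gpr))
        return r

    B = DEFAULT_BOUND
    rxn("EX_diet_e", {met("diet_e", "e"): -1}, -diet_uptake, B, "Exchange")
    rxn("HT_diet", {met("diet_e", "e"): -1, met("diet_c", "c"): 1},
        0, B, "Transport", _gpr(rng, genes))

    prev = met("diet_c", "c")
    for i in range(1, n_core_metabolites + 1):
        nxt = met(f"core{i}_c", "c")
        rxn(f"HC{i}", {prev: -1, nxt: 1}, 0, 100.0,
            "Central carbon metabolism", _gpr(rng, genes))
        prev = nxt
    rxn("HGEN_NRG", {met("diet_c", "c"): -1, met("nrg_c", "c"): 1},
        0, 100.0, "Central carbon metabolism", _gpr(rng, genes))
    rxn("biomass_host", {prev: -1, met("nrg_c", "c"): -1},
        0, synthesis_capacity, "Biomass")

    for s in secretables:
        rxn(f"HSYN_{s}", {met("diet_c", "c"): -1, met(f"{s}_c", "c"): 1},
            0, synthesis_capacity, "Biosynthesis", _gpr(rng, genes))
        rxn(f"HTR_{s}", {met(f"{s}_c", "c"): -1, met(f"{s}_e", "e"): 1},
            0, B, "Transport", _gpr(rng, genes))
        rxn(f"EX_{s}_e", {met(f"{s}_e", "e"): -1}, 0, B, "Exchange")

    model.add_reactions([r for r, _, _ in reactions])
    for r, stoich, gpr in reactions:
        r.add_metabolites(stoich)
        if gpr:
            r.gene_reaction_rule = gpr
    model.objective = "biomass_host"
    ensure_valid(model)
    result = fba(model)
    if not result.ok or result.objective_value <= 0:
        raise RuntimeError("generated host model is not viable")
    return model


def generate_microbe_model(
    panel: Sequence[str],
    hard_auxotrophies: Sequence[str] = (),
    partial_dependencies: Sequence[str] = (),
    decoy_uptakes: Sequence[str] = (),
    subsystem_layout: Optional[Mapping[str, str]] = None,
    seed: int = 0,
    model_id: str = "microbe",
    carbon_source: str = "glc",
    uptake_bound: float = 10.0,
    bypass_capacity: float = BYPASS_CAPACITY,
    n_genes: int = 12,
) -> cobra.Model:
    """Toy microbe with planted metabolite dependencies.

    Biomass stoichiometrically requires every hard-auxotrophy metabolite
    (no internal synthesis route exists), requires the precursor behind
    each partial dependency (a low-capacity glucose bypass keeps growth
    possible but reduced when the metabolite is cut), and is untouched by
    decoy metabolites, which are merely degraded to a secreted waste
    product. A three-step pathway consuming the first planted dependency is
    labelled with the layout's "planted" subsystem so that cutting that
    metabolite silences an entire subsystem.
    """
    layout = dict(DEFAULT_SUBSYSTEM_LAYOUT)
    if subsystem_layout:
        layout.update(subsystem_layout)
    for m in (*hard_auxotrophies, *partial_dependencies, *decoy_uptakes):
        if m not in panel:
            raise ValueError(f"planted metabolite {m!r} not in panel")
    overlap = (set(hard_auxotrophies) & set(partial_dependencies)) | (
        set(decoy_uptakes) & (set(hard_auxotrophies) | set(partial_dependencies))
    )
    if overlap:
        raise ValueError(f"metabolites with conflicting roles: {sorted(overlap)}")
    if carbon_source in (*hard_auxotrophies, *partial_dependencies, *decoy_uptakes):
        raise ValueError("carbon source cannot carry a planted role")

    rng = np.random.default_rng(seed)
    genes = [f"{model_id}_G{i:03d}" for i in range(n_genes)]
    model = cobra.Model(model_id)
    mets: dict[str, cobra.Metabolite] = {}

    def met(mid: str, comp: str) -> cobra.Metabolite:
        if mid not in mets:
            mets[mid] = cobra.Metabolite(mid, compartment=comp)
        return mets[mid]

    reactions = []

    def rxn(rid, stoich, lb, ub, subsystem, gpr=None):
        r = cobra.Reaction(rid, lower_bound=lb, upper_bound=ub)
        r.subsystem = subsystem
        reactions.append((r, stoich, gpr))
        return r

    B = DEFAULT_BOUND
    rxn(f"EX_{carbon_source}_e", {met(f"{carbon_source}_e", "e"): -1},
        -uptake_bound, B, layout["exchange"])
    rxn(f"T_{carbon_source}",
        {met(f"{carbon_source}_e", "e"): -1, met(f"{carbon_source}_c", "c"): 1},
        0, B, layout["transport"], _gpr(rng, genes))
    rxn("CAT_energy",
        {met(f"{carbon_source}_c", "c"): -1, met("atp_c", "c"): 2},
        0, B, layout["central"], _gpr(rng, genes))

    biomass_stoich = {met("atp_c", "c"): -2.0,
                      met(f"{carbon_source}_c", "c"): -0.1}

    def uptake_route(m: str) -> None:
        rxn(f"EX_{m}_e", {met(f"{m}_e", "e"): -1}, -uptake_bound, B,
            layout["exchange"])
        rxn(f"T_{m}", {met(f"{m}_e", "e"): -1, met(f"{m}_c", "c"): 1},
            0, B, layout["transport"], _gpr(rng, genes))

    for m in hard_auxotrophies:
        uptake_route(m)
        biomass_stoich[met(f"{m}_c", "c")] = -0.5
    for m in partial_dependencies:
        uptake_route(m)
        prec = met(f"prec_{m}_c", "c")
        rxn(f"CONV_{m}", {met(f"{m}_c", "c"): -1, prec: 1},
            0, B, layout["biosynthesis"], _gpr(rng, genes))
        rxn(f"BYP_{m}", {met(f"{carbon_source}_c", "c"): -1, prec: 1},
            0, bypass_capacity, layout["biosynthesis"])
        biomass_stoich[prec] = -0.5
    for m in decoy_uptakes:
        uptake_route(m)
        rxn(f"DEG_{m}", {met(f"{m}_c", "c"): -1, met("waste_c", "c"): 1},
            0, B, layout["degradation"], _gpr(rng, genes))

    # planted-enriched subsystem downstream of the strongest dependency
    anchor = None
    if hard_auxotrophies:
        anchor = f"{hard_auxotrophies[0]}_c"
    elif partial_dependencies:
        anchor = f"{partial_dependencies[0]}_c"
    if anchor is not None:
        rxn("GPL1", {met(anchor, "c"): -1, met("gpl1_c", "c"): 1},
            0, B, layout["planted"], _gpr(rng, genes))
        rxn("GPL2", {met("gpl1_c", "c"): -1, met("gpl2_c", "c"): 1},
            0, B, layout["planted"], _gpr(rng, genes))
        rxn("GPL3", {met("gpl2_c", "c"): -1, met("waste_c", "c"): 1},
            0, B, layout["planted"])

    rxn("T_waste", {met("waste_c", "c"): -1, met("waste_e", "e"): 1},
        0, B, layout["transport"])
    rxn("EX_waste_e", {met("waste_e", "e"): -1}, 0, B, layout["exchange"])
    rxn("biomass", biomass_stoich, 0, B, "Biomass")

    model.add_reactions([r for r, _, _ in reactions])
    for r, stoich, gpr in reactions:
        r.add_metabolites(stoich)
        if gpr:
            r.gene_reaction_rule = gpr
    model.objective = "biomass"
    ensure_valid(model)
    _verify_planted(model, hard_auxotrophies, partial_dependencies,
                    decoy_uptakes)
    return model


def _verify_planted(model, hard, partial, decoys) -> None:
    """Generation-time check of the planted dependency classes by FBA."""
    wild = fba(model)
    if not wild.ok or wild.objective_value <= 0:
        raise RuntimeError(f"microbe {model.id} is not viable unrestricted")

    def optimum_without(m: str) -> float:
        with model:
            model.reactions.get_by_id(f"EX_{m}_e").bounds = (0.0, 0.0)
            res = fba(model)
            return res.objective_value if res.ok else 0.0

    for m in hard:
        if optimum_without(m) > 1e-9:
            raise RuntimeError(f"hard auxotrophy {m} is not growth-blocking")
    for m in partial:
        opt = optimum_without(m)
        if not (1e-9 < opt < wild.objective_value - 1e-6):
            raise RuntimeError(f"partial dependency {m} is not partial "
                               f"(optimum {opt:g} vs {wild.objective_value:g})")
    for m in decoys:
        if abs(optimum_without(m) - wild.objective_value) > 1e-6:
            raise RuntimeError(f"decoy {m} affects the optimum")


def generate_expression_table(
    model: cobra.Model,
    active_fraction: float = 0.4,
    n_samples: int = 20,
    seed: int = 0,
    active_log_mean: float = np.log(30.0),
    inactive_log_mean: float = np.log(0.05),
) -> pd.DataFrame:
    """Log-normal TPM table (gene x sample) with a planted active fraction.

    Active genes draw per-gene log-mean TPM around ``active_log_mean``
    (well above the TPM > 1 calling threshold), inactive genes around
    ``inactive_log_mean`` (well below it), with multiplicative per-sample
    noise.
    """
    if not 0.0 <= active_fraction <= 1.0:
        raise ValueError("active_fraction must lie in [0, 1]")
    genes = [g.id for g in model.genes]
    if not genes:
        raise ValueError(f"model {model.id} has no genes")
    rng = np.random.default_rng(seed)
    n_active = int(round(active_fraction * len(genes)))
    active = set(rng.choice(genes, size=n_active, replace=False)) if n_active else set()
    mu = np.where(
        [g in active for g in genes],
        rng.normal(active_log_mean, 0.8, size=len(genes)),
        rng.normal(inactive_log_mean, 0.5, size=len(genes)),
    )
    noise = rng.normal(0.0, 0.3, size=(len(genes), n_samples))
    tpm = np.exp(mu[:, None] + noise)
    return pd.DataFrame(
        tpm, index=pd.Index(genes, name="gene"),
        columns=[f"sample{j:03d}" for j in range(n_samples)],
    )


@dataclass
class PlantedSpec:
    """Which panel metabolites play which role, per microbe tag."""

    hard: dict[str, list[str]]
    partial: dict[str, list[str]]
    decoys: list[str]

    @property
    def key_co_metabolites(self) -> list[str]:
        keys = set()
        for mets in self.hard.values():
            keys.update(mets)
        for mets in self.partial.values():
            keys.update(mets)
        return sorted(keys)

    @property
    def scenario_metabolites(self) -> list[str]:
        return sorted(set(self.key_co_metabolites) | set(self.decoys))


def default_planted_spec(tags: Sequence[str]) -> PlantedSpec:
    """Standard planted layout: 3 key co-metabolites and 2 decoys.

    ``fe3`` is a hard auxotrophy for the first two microbes, ``fol`` for
    the third; ``thm`` is a partial dependency for the remaining microbes;
    ``ac`` and ``glyc`` are decoys degraded by every microbe.
    """
    if len(tags) < 1:
        raise ValueError("need at least one microbe tag")
    hard: dict[str, list[str]] = {}
    partial: dict[str, list[str]] = {}
    for i, tag in enumerate(tags):
        if i < 2:
            hard[tag] = ["fe3"]
        elif i == 2:
            hard[tag] = ["fol"]
        else:
            partial[tag] = ["thm"]
    return PlantedSpec(hard=hard, partial=partial, decoys=["ac", "glyc"])


@dataclass
class CommunityFixture:
    """Host + microbes + expression + machine-readable ground truth."""

    host: cobra.Model = field(repr=False)
    microbes: list[cobra.Model] = field(repr=False)
    tags: list[str]
    host_biomass_id: str
    microbe_biomass_ids: list[str]
    expression: pd.DataFrame = field(repr=False)
    ground_truth: dict
    seed: int
    params: dict

    def save(self, directory: str | Path) -> None:
        from cogem.core import write_model

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_model(self.host, directory / "host.json")
        write_model(self.host, directory / "host.xml")
        for tag, model in zip(self.tags, self.microbes):
            write_model(model, directory / f"{tag}.json")
            write_model(model, directory / f"{tag}.xml")
        self.expression.to_csv(directory / "expression.tsv", sep="\t")
        (directory / "ground_truth.json").write_text(
            json.dumps(self.ground_truth, indent=2, sort_keys=True)
        )
        (directory / "fixture.json").write_text(
            json.dumps(
                {
                    "tags": self.tags,
                    "host_biomass_id": self.host_biomass_id,
                    "microbe_biomass_ids": self.microbe_biomass_ids,
                    "seed": self.seed,
                    "params": self.params,
                },
                indent=2, sort_keys=True,
            )
        )

    @classmethod
    def load(cls, directory: str | Path) -> "CommunityFixture":
        from cogem.core import read_model

        directory = Path(directory)
        meta = json.loads((directory / "fixture.json").read_text())
        return cls(
            host=read_model(directory / "host.json"),
            microbes=[read_model(directory / f"{t}.json") for t in meta["tags"]],
            tags=meta["tags"],
            host_biomass_id=meta["host_biomass_id"],
            microbe_biomass_ids=meta["microbe_biomass_ids"],
            expression=pd.read_csv(
                directory / "expression.tsv", sep="\t", index_col=0,
                float_precision="round_trip",
            ),
            ground_truth=json.loads(
                (directory / "ground_truth.json").read_text()
            ),
            seed=meta["seed"],
            params=meta["params"],
        )


def generate_community_fixture(
    n_microbes: int = 5,
    panel_size: int = 12,
    planted_spec: Optional[PlantedSpec] = None,
    seed: int = 0,
    active_fraction: float = 0.4,
    n_expression_samples: int = 20,
    verify_joint: bool = True,
) -> CommunityFixture:
    """The standard synthetic community with planted ground truth.

    ``panel_size`` counts the host's secretable metabolites (the carbon
    source ``glc`` included). Ground truth records, per microbe, the hard
    auxotrophies (restriction blocks growth), partial dependencies
    (restriction reduces growth), and the decoy metabolites (restriction
    changes nothing); the key co-metabolites are exactly the planted
    hard + partial metabolites. The carbon source is excluded from the
    restriction scenario panel (it is the growth-limiting control
    substrate, not a screened co-metabolite).

    With ``verify_joint`` every microbe is merged pairwise with the host
    and the planted classes are re-verified by FBA on the joint model.
    """
    tags = [f"M{i+1}" for i in range(n_microbes)]
    spec = planted_spec or default_planted_spec(tags)
    panel = _panel(panel_size)
    for m in spec.scenario_metabolites:
        if m not in panel:
            raise ValueError(f"planted metabolite {m!r} outside the panel")

    host = generate_host_model(
        n_exchange=panel_size + 1, seed=seed,
    )
    microbes = []
    for i, tag in enumerate(tags):
        microbes.append(
            generate_microbe_model(
                panel=panel,
                hard_auxotrophies=spec.hard.get(tag, []),
                partial_dependencies=spec.partial.get(tag, []),
                decoy_uptakes=spec.decoys,
                seed=seed * 1000 + i + 1,
                model_id=tag,
            )
        )
    expression = generate_expression_table(
        host, active_fraction=active_fraction,
        n_samples=n_expression_samples, seed=seed,
    )

    ground_truth = {
        "hard": spec.hard,
        "partial": spec.partial,
        "decoys": spec.decoys,
        "key_co_metabolites": spec.key_co_metabolites,
        "scenario_metabolites": spec.scenario_metabolites,
        "planted_subsystem": DEFAULT_SUBSYSTEM_LAYOUT["planted"],
        "active_gene_fraction": active_fraction,
    }
    fixture = CommunityFixture(
        host=host,
        microbes=microbes,
        tags=tags,
        host_biomass_id="biomass_host",
        microbe_biomass_ids=["biomass"] * n_microbes,
        expression=expression,
        ground_truth=ground_truth,
        seed=seed,
        params={
            "n_microbes": n_microbes,
            "panel_size": panel_size,
            "active_fraction": active_fraction,
            "n_expression_samples": n_expression_samples,
        },
    )
    if verify_joint:
        _verify_fixture_joint(fixture)
    return fixture


def _verify_fixture_joint(fixture: CommunityFixture) -> None:
    """Re-verify planted classes on pairwise host + microbe joint models."""
    gt = fixture.ground_truth
    for microbe, bio_id, tag in zip(
        fixture.microbes, fixture.microbe_biomass_ids, fixture.tags
    ):
        joint = merge_models(
            [microbe], [bio_id], [tag],
            host=fixture.host, host_biomass_id=fixture.host_biomass_id,
        )
        wild = joint.optimize_member(tag)
        if not wild.ok or wild.objective_value <= 1e-6:
            raise RuntimeError(f"{tag} cannot grow in the joint model")
        for m in gt["hard"].get(tag, []):
            restricted, _ = apply_restriction(joint, m, tag)
            opt = restricted.optimize_member(tag).objective_value or 0.0
            if opt > 1e-9:
                raise RuntimeError(f"joint hard auxotrophy {tag}/{m} not blocking")
        for m in gt["partial"].get(tag, []):
            restricted, _ = apply_restriction(joint, m, tag)
            opt = restricted.optimize_member(tag).objective_value or 0.0
            if not (1e-9 < opt < wild.objective_value - 1e-6):
                raise RuntimeError(f"joint partial dependency {tag}/{m} not partial")
        for m in gt["decoys"]:
            restricted, _ = apply_restriction(joint, m, tag)
            opt = restricted.optimize_member(tag).objective_value or 0.0
            if abs(opt - wild.objective_value) > 1e-6:
                raise RuntimeError(f"joint decoy {tag}/{m} shifts the optimum")


def generate_enrichment_fixture(
    n_reactions: int = 200,
    n_subsystems: int = 8,
    n_significant: int = 60,
    enrichment_factor: float = 5.0,
    seed: int = 0,
) -> tuple[dict[str, str], list[str], str]:
    """Abstract enrichment fixture with one over-represented subsystem.

    Reactions are split evenly over subsystems; the significant set is
    drawn without replacement with selection weight ``enrichment_factor``
    for reactions in the planted subsystem (factor 1 gives the uniform
    null). Returns ``(labels, significant_reactions, planted_subsystem)``.

    Sizing: with 200 reactions over 8 subsystems and a 5x selection
    weight, a 60-reaction significant set puts ~19 hits in the planted
    subsystem (25 expected under the null would be ~7.5), a large enough
    separation that the upper-tail test detects it essentially always —
    a design-time power choice, mirroring the broad reaction sets a real
    restriction silences.
    """
    if n_significant > n_reactions:
        raise ValueError("n_significant cannot exceed n_reactions")
    rng = np.random.default_rng(seed)
    reactions = [f"r{i:04d}" for i in range(n_reactions)]
    labels = {
        rid: f"S{i % n_subsystems:02d}" for i, rid in enumerate(reactions)
    }
    planted = "S00"
    weights = np.array(
        [enrichment_factor if labels[r] == planted else 1.0 for r in reactions]
    )
    significant = rng.choice(
        reactions, size=n_significant, replace=False, p=weights / weights.sum()
    )
    return labels, sorted(significant), planted
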