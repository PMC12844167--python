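"""Joint-model assembly: tagging, interspace, merge, cycles, co-metabolites."""

import cobra
import numpy as np
import pytest

from cogem import synthetic
from cogem.community import (
    JointModel,
    create_interspace,
    extract_member_submodel,
    host_supply_capacities,
    identify_co_metabolites,
    merge_models,
    remove_futile_cycles,
    tag_model,
)
from cogem.core import DEFAULT_BOUND, build_stoichiometric_matrix, fba

def _microbe(seed=201, **kwargs):
    defaults = dict(
        panel=synthetic._panel(12),
        hard_auxotrophies=["fe3"],
        decoy_uptakes=["ac"],
        model_id=f"m{seed}",
    )
    defaults.update(kwargs)
    return synthetic.generate_microbe_model(seed=seed, **defaults)


# ---------------------------------------------------------------------------
# tagging
# ---------------------------------------------------------------------------

def test_tag_model_prefixes_all_ids(chain_model):
    tagged = tag_model(chain_model, "FN")
    assert sorted(r.id for r in tagged.reactions) == ["FN_AB", "FN_EX_A", "FN_EX_B"]
    assert all(m.id.startswith("FN_") for m in tagged.metabolites)
    assert all(c.startswith("FN_") for c in tagged.compartments)


def test_tag_model_twice_is_rejected(chain_model):
    tagged = tag_model(chain_model, "FN")
    with pytest.raises(ValueError, match="refusing to tag twice"):
        tag_model(tagged, "BF")


def test_tagged_model_fba_optimum_unchanged(microbe_model):
    base = fba(microbe_model).objective_value
    tagged = tag_model(microbe_model, "AM")
    assert fba(tagged).objective_value == pytest.approx(base)


def test_tag_model_updates_gprs(microbe_model):
    tagged = tag_model(microbe_model, "AM")
    rxn = tagged.reactions.get_by_id("AM_CAT_energy")
    assert all(g.id.startswith("AM_") for g in rxn.genes)


# ---------------------------------------------------------------------------
# interspace (Eq-style [-I; I] block)
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("n_ext", [1, 3, 5])
def test_interspace_block_is_minus_identity_over_identity(n_ext):
    m = cobra.Model("ext")
    reactions = []
    for i in range(n_ext):
        met_e = cobra.Metabolite(f"x{i}_e", compartment="e")
        met_c = cobra.Metabolite(f"x{i}_c", compartment="c")
        r = cobra.Reaction(f"t{i}", lower_bound=-10, upper_bound=10)
        reactions.append((r, {met_c: -1, met_e: 1}))
    m.add_reactions([r for r, _ in reactions])
    for r, stoich in reactions:
        r.add_metabolites(stoich)
    m.objective = "t0"
    tagged = tag_model(m, "GM")
    extended, registry = create_interspace(tagged, "GM")
    assert len(registry) == n_ext

    S, met_ids, rxn_ids = build_stoichiometric_matrix(extended)
    bases = sorted(registry)
    e_rows = [met_ids.index(f"GM_{b}_e") for b in bases]
    u_rows = [met_ids.index(f"{b}_u") for b in bases]
    cols = [rxn_ids.index(registry[b]) for b in bases]
    block_e = S.toarray()[np.ix_(e_rows, cols)]
    block_u = S.toarray()[np.ix_(u_rows, cols)]
    assert np.array_equal(block_e, -np.eye(n_ext))
    assert np.array_equal(block_u, np.eye(n_ext))
    for base in bases:
        rxn = extended.reactions.get_by_id(registry[base])
        assert rxn.lower_bound < 0 < rxn.upper_bound  # reversible


def test_interspace_no_extracellular_metabolites_is_noop():
    m = cobra.Model("cytosol_only")
    met = cobra.Metabolite("x_c", compartment="c")
    r_in = cobra.Reaction("r_in", lower_bound=0, upper_bound=10)
    r_out = cobra.Reaction("r_out", lower_bound=0, upper_bound=10)
    m.add_reactions([r_in, r_out])
    r_in.add_metabolites({met: 1})
    r_out.add_metabolites({met: -1})
    m.objective = "r_out"
    tagged = tag_model(m, "GM")
    # declared extracellular compartment that holds no metabolites
    tagged.compartments = {"GM_e": "extracellular"}
    extended, registry = create_interspace(tagged, "GM")
    assert registry == {}
    assert len(extended.reactions) == len(tagged.reactions)


def test_interspace_requires_extracellular_compartment(chain_model):
    from cogem.core import ModelValidationError

    # chain model's compartment is "e" but untagged model lacks "GM_e"
    with pytest.raises(ModelValidationError, match="no extracellular"):
        create_interspace(chain_model, "GM")


# ---------------------------------------------------------------------------
# merge
# ---------------------------------------------------------------------------

def test_merge_unifies_shared_lumen_metabolites():
    m1 = _microbe(211, model_id="m1")
    m2 = _microbe(212, model_id="m2")
    joint = merge_models([m1, m2], ["biomass", "biomass"], ["A", "B"])
    glc_u = [m for m in joint.model.metabolites if m.id == "glc_u"]
    assert len(glc_u) == 1
    uptakers = [t for t, reg in joint.interspace.items() if "glc" in reg]
    assert sorted(uptakers) == ["A", "B"]


def test_merge_single_member_matches_standalone_with_open_lumen():
    microbe = _microbe(213)
    standalone = fba(microbe).objective_value
    joint = merge_models(
        [microbe], ["biomass"], ["GM"],
        lumen_influx=10.0,  # same supply bound as the standalone exchanges
    )
    assert joint.optimize_member("GM").objective_value == pytest.approx(
        standalone, abs=1e-6
    )


def test_merge_metabolite_count_oracle(host_model):
    microbe = _microbe(214)
    joint = merge_models(
        [microbe], ["biomass"], ["GM"],
        host=host_model, host_biomass_id="biomass_host",
    )
    host_ext = {m.id[: -len("_e")] for m in host_model.metabolites
                if m.compartment == "e"}
    microbe_ext = {m.id[: -len("_e")] for m in microbe.metabolites
                   if m.compartment == "e"}
    n_host_exchanges = sum(
        1 for r in host_model.reactions if len(r.metabolites) == 1
    )
    expected = (
        len(host_model.metabolites)
        + len(microbe.metabolites)
        + len(host_ext | microbe_ext)  # unified lumen
        + n_host_exchanges  # body-fluid layer additions
    )
    assert len(joint.model.metabolites) == expected


def test_merge_order_invariance(host_model):
    m1, m2 = _microbe(215, model_id="m1"), _microbe(216, model_id="m2")
    j_ab = merge_models([m1, m2], ["biomass"] * 2, ["A", "B"],
                        host=host_model, host_biomass_id="biomass_host")
    j_ba = merge_models([m2, m1], ["biomass"] * 2, ["B", "A"],
                        host=host_model, host_biomass_id="biomass_host")
    for tag in ("A", "B", "Host"):
        assert j_ab.optimize_member(tag).objective_value == pytest.approx(
            j_ba.optimize_member(tag).objective_value, abs=1e-6
        )


def test_merge_rejects_duplicate_tags_and_missing_biomass():
    m1, m2 = _microbe(217, model_id="m1"), _microbe(218, model_id="m2")
    with pytest.raises(ValueError, match="duplicate"):
        merge_models([m1, m2], ["biomass", "biomass"], ["A", "A"])
    with pytest.raises(ValueError, match="not in model"):
        merge_models([m1], ["nope"], ["A"])


def test_member_cannot_outgrow_standalone_with_open_supply(community_fixture):
    fx = community_fixture
    microbe, bio, tag = fx.microbes[0], fx.microbe_biomass_ids[0], fx.tags[0]
    with microbe as open_model:
        for rxn in open_model.reactions:
            if len(rxn.metabolites) == 1 and rxn.lower_bound <= 0:
                rxn.lower_bound = -DEFAULT_BOUND
        ceiling = fba(open_model).objective_value
    joint = merge_models([microbe], [bio], [tag], host=fx.host,
                         host_biomass_id=fx.host_biomass_id)
    assert joint.optimize_member(tag).objective_value <= ceiling + 1e-6


def test_joint_model_save_load_round_trip(tmp_path, host_model):
    microbe = _microbe(219)
    joint = merge_models([microbe], ["biomass"], ["GM"], host=host_model,
                         host_biomass_id="biomass_host")
    joint.save(tmp_path / "joint")
    back = JointModel.load(tmp_path / "joint")
    assert back.member_tags == joint.member_tags
    assert back.interspace == joint.interspace
    assert back.optimize_member("GM").objective_value == pytest.approx(
        joint.optimize_member("GM").objective_value, abs=1e-6
    )


# ---------------------------------------------------------------------------
# futile cycles
# ---------------------------------------------------------------------------

def _looped_joint(host_model):
    """Joint model with a deliberate duplicate-transport lumen loop."""
    microbe = _microbe(220)
    joint = merge_models([microbe], ["biomass"], ["GM"], host=host_model,
                         host_biomass_id="biomass_host")
    # duplicate interspace transport for fe3: a net-zero circulation channel
    met_e = joint.model.metabolites.get_by_id("GM_fe3_e")
    met_u = joint.model.metabolites.get_by_id("fe3_u")
    dup = cobra.Reaction("GM_IEX_fe3_dup", lower_bound=-DEFAULT_BOUND,
                         upper_bound=DEFAULT_BOUND)
    dup.notes["member"] = "GM"
    joint.model.add_reactions([dup])
    dup.add_metabolites({met_e: -1, met_u: 1})
    joint.interspace["GM"]["fe3_dup"] = dup.id
    return joint


def _closed_exchange_flux_range(joint, rxn_id):
    from cogem.core import fva

    with joint.model as model:
        for rxn in model.reactions:
            if len(rxn.metabolites) == 1:
                rxn.bounds = (0.0, 0.0)
        ranges = fva(model, fraction_of_optimum=0.0, reactions=[rxn_id])
    return ranges.loc[rxn_id, "minimum"], ranges.loc[rxn_id, "maximum"]


def test_futile_loop_pruned_and_optima_preserved(host_model):
    joint = _looped_joint(host_model)
    lo, hi = _closed_exchange_flux_range(joint, "GM_IEX_fe3_dup")
    assert hi > 1e-6 or lo < -1e-6  # the loop can carry flux before pruning
    before = {t: joint.optimize_member(t).objective_value
              for t in joint.member_tags}
    pruned = remove_futile_cycles(joint)
    lo, hi = _closed_exchange_flux_range(pruned, "GM_IEX_fe3_dup")
    assert abs(lo) < 1e-6 and abs(hi) < 1e-6
    for tag in joint.member_tags:
        assert pruned.optimize_member(tag).objective_value == pytest.approx(
            before[tag], abs=1e-6
        )


def test_loop_free_joint_model_unchanged(host_model):
    microbe = _microbe(221)
    joint = merge_models([microbe], ["biomass"], ["GM"], host=host_model,
                         host_biomass_id="biomass_host")
    pruned = remove_futile_cycles(joint)
    for rxn in joint.model.reactions:
        assert pruned.model.reactions.get_by_id(rxn.id).bounds == rxn.bounds


# ---------------------------------------------------------------------------
# co-metabolite identification
# ---------------------------------------------------------------------------

def test_planted_co_metabolite_identified(host_model):
    microbe = _microbe(222)
    joint = merge_models([microbe], ["biomass"], ["GM"], host=host_model,
                         host_biomass_id="biomass_host")
    co_mets, table = identify_co_metabolites(joint)
    by_id = {c.base_id: c for c in co_mets}
    assert "fe3" in by_id
    assert by_id["fe3"].host_secretion_reaction == "Host_IEX_fe3[u]tr"
    assert by_id["fe3"].microbial_uptake_reactions == {"GM": "GM_IEX_fe3[u]tr"}


def test_host_only_metabolite_is_host_specific(host_model):
    microbe = _microbe(223)
    joint = merge_models([microbe], ["biomass"], ["GM"], host=host_model,
                         host_biomass_id="biomass_host")
    _, table = identify_co_metabolites(joint)
    labels = table.set_index("metabolite")["class"]
    # host secretes the full panel; the microbe only takes up fe3/ac/glc
    assert labels["thm"] == "host-specific"
    assert labels["waste"] == "microbe-specific"


def test_classification_partitions_lumen_metabolites(host_model):
    microbe = _microbe(224)
    joint = merge_models([microbe], ["biomass"], ["GM"], host=host_model,
                         host_biomass_id="biomass_host")
    _, table = identify_co_metabolites(joint)
    assert sorted(table["metabolite"]) == sorted(joint.lumen_metabolites)
    assert set(table["class"]) <= {
        "co-metabolite", "host-specific", "microbe-specific"
    }


def test_co_metabolites_match_fva_sign_oracle(host_model):
    from cogem.core import fva

    microbe = _microbe(225)
    joint = merge_models([microbe], ["biomass"], ["GM"], host=host_model,
                         host_biomass_id="biomass_host")
    co_mets, _ = identify_co_metabolites(joint)
    found = {c.base_id for c in co_mets}
    iex = [rid for reg in joint.interspace.values() for rid in reg.values()]
    ranges = fva(joint.model, fraction_of_optimum=0.0, reactions=iex)
    expected = set()
    for base, host_rid in joint.interspace["Host"].items():
        if ranges.loc[host_rid, "maximum"] <= 1e-6:
            continue
        for tag, reg in joint.interspace.items():
            if tag == "Host" or base not in reg:
                continue
            if ranges.loc[reg[base], "minimum"] < -1e-6:
                expected.add(base)
    assert found == expected


def test_identify_requires_host():
    microbe = _microbe(226)
    joint = merge_models([microbe], ["biomass"], ["GM"])
    with pytest.raises(ValueError, match="no host"):
        identify_co_metabolites(joint)


# ---------------------------------------------------------------------------
# member submodel extraction
# ---------------------------------------------------------------------------

def test_submodel_preserves_member_optimum(host_model):
    microbe = _microbe(227)
    joint = merge_models([microbe], ["biomass"], ["GM"], host=host_model,
                         host_biomass_id="biomass_host")
    sub = extract_member_submodel(joint, "GM")
    joint_opt = joint.optimize_member("GM").objective_value
    assert fba(sub).objective_value == pytest.approx(joint_opt, abs=1e-6)


def test_submodel_supply_bounded_by_host_secretion(host_model):
    microbe = _microbe(228)
    joint = merge_models([microbe], ["biomass"], ["GM"], host=host_model,
                         host_biomass_id="biomass_host")
    supply = host_supply_capacities(joint)
    sub = extract_member_submodel(joint, "GM", supply)
    for base, cap in supply.items():
        if f"EX_{base}_u" in [r.id for r in sub.reactions]:
            assert sub.reactions.get_by_id(f"EX_{base}_u").lower_bound == \
                pytest.approx(-cap)
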