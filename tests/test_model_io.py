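import json

import numpy as np
import pytest

from cafba import (
    ModelError,
    SectorConfig,
    apply_patches,
    category_report,
    classify_reactions,
    load_model,
    solve_cafba,
    write_json,
)
from cafba.model import CATEGORIES
from cafba.toys import make_linear_chain, make_loop_toy, make_random_toy


@pytest.mark.parametrize("seed", [0, 1, 7])
def test_json_round_trip_preserves_structure(tmp_path, seed):
    model, _ = make_random_toy(seed)
    path = tmp_path / "toy.json"
    write_json(model, path)
    loaded = load_model(path, format="json")
    assert loaded.reaction_ids == model.reaction_ids
    assert loaded.metabolite_ids == model.metabolite_ids
    np.testing.assert_allclose(
        loaded.S.toarray(), model.S.toarray(), atol=1e-12
    )
    np.testing.assert_allclose(loaded.lower_bounds, model.lower_bounds)
    np.testing.assert_allclose(loaded.upper_bounds, model.upper_bounds)
    # categories are re-derivable from the same config
    config = SectorConfig(
        carbon_source="EX_glc", carbon_intake_reactions=["UPT"]
    )
    reclassified = classify_reactions(loaded, config)
    assert reclassified.category == model.category


def test_loader_requires_biomass_reaction(tmp_path):
    data = {
        "metabolites": [{"id": "a_c", "compartment": "c"}],
        "reactions": [
            {
                "id": "EX_a",
                "metabolites": {"a_c": -1.0},
                "lower_bound": -10,
                "upper_bound": 10,
                "gene_reaction_rule": "",
            }
        ],
        "genes": [],
        "id": "nobiomass",
    }
    path = tmp_path / "nobiomass.json"
    path.write_text(json.dumps(data))
    with pytest.raises(ModelError, match="biomass"):
        load_model(path, format="json")


def test_loader_missing_file():
    with pytest.raises(ModelError, match="not found"):
        load_model("/nonexistent/model.xml")


def test_objective_flag_sets_biomass(tmp_path):
    data = {
        "metabolites": [{"id": "a_c", "compartment": "c"}],
        "reactions": [
            {
                "id": "EX_a",
                "metabolites": {"a_c": -1.0},
                "lower_bound": -10,
                "upper_bound": 10,
            },
            {
                "id": "BIOMASS",
                "metabolites": {"a_c": -1.0},
                "lower_bound": 0,
                "upper_bound": 1000,
                "objective_coefficient": 1.0,
            },
        ],
        "genes": [],
        "id": "tiny",
    }
    path = tmp_path / "tiny.json"
    path.write_text(json.dumps(data))
    model = load_model(path, format="json")
    assert model.biomass_reaction == "BIOMASS"


def test_infinite_bounds_mapped_to_big_bound(tmp_path):
    data = {
        "metabolites": [{"id": "a_c", "compartment": "c"}],
        "reactions": [
            {
                "id": "EX_a",
                "metabolites": {"a_c": -1.0},
                "lower_bound": -1e7,
                "upper_bound": 1e7,
            },
            {
                "id": "BIOMASS",
                "metabolites": {"a_c": -1.0},
                "lower_bound": 0,
                "upper_bound": 1e7,
                "objective_coefficient": 1.0,
            },
        ],
        "genes": [],
        "id": "wide",
    }
    path = tmp_path / "wide.json"
    path.write_text(json.dumps(data))
    model = load_model(path, format="json", big_bound=500.0)
    assert model.lower_bounds[0] == -500.0
    assert model.upper_bounds[1] == 500.0


class TestClassification:
    def test_chain_has_single_enzymatic_reaction(self):
        model, _, _ = make_linear_chain(k=1)
        assert model.reactions_in_category("enzymatic") == ["E1"]
        assert model.category["EX_glc"] == "exchange"
        assert model.category["UPT"] == "carbon_intake"
        assert model.category["BIOMASS"] == "biomass"

    def test_compartment_crossing_translocation_is_transport(self):
        model, _ = make_loop_toy()
        assert model.category["T1"] == "transport"
        assert model.category["T2"] == "transport"
        # UPT crosses compartments AND transforms (glc -> a): by config it
        # is carbon intake, not transport
        assert model.category["UPT"] == "carbon_intake"

    def test_category_partition(self, core_model):
        counts = category_report(core_model)["category"].value_counts()
        assert counts.sum() == core_model.n_reactions
        assert set(counts.index) <= set(CATEGORIES)

    def test_core_model_sectors(self, core_model):
        assert core_model.category["GLCpts"] == "carbon_intake"
        assert core_model.category["ATPM"] == "maintenance"
        assert core_model.category["EX_glc__D_e"] == "exchange"
        assert core_model.category["Biomass_Ecoli_core"] == "biomass"
        # biomass/maintenance never enzymatic (structural invariant)
        assert core_model.category[core_model.biomass_reaction] != "enzymatic"

    def test_idempotent(self, core_model):
        config = SectorConfig(
            carbon_source="EX_glc__D_e", carbon_intake_reactions=["GLCpts"]
        )
        again = classify_reactions(core_model, config)
        assert again.category == core_model.category

    def test_override_applied_last(self):
        model, _, _ = make_linear_chain(k=2, w_path=[0.1, 0.1])
        config = SectorConfig(
            carbon_source="EX_glc",
            carbon_intake_reactions=["UPT"],
            category_overrides={"E2": "zero_cost"},
        )
        model = classify_reactions(model, config)
        assert model.category["E2"] == "zero_cost"
        assert model.category_source["E2"] == "override"

    def test_unknown_override_rejected(self):
        model, _, _ = make_linear_chain()
        config = SectorConfig(
            carbon_source="EX_glc",
            carbon_intake_reactions=["UPT"],
            category_overrides={"NOPE": "enzymatic"},
        )
        with pytest.raises(ModelError, match="NOPE"):
            classify_reactions(model, config)

    def test_carbon_source_must_be_exchange(self):
        model, _, _ = make_linear_chain()
        config = SectorConfig(
            carbon_source="E1", carbon_intake_reactions=["UPT"]
        )
        with pytest.raises(ModelError, match="exchange"):
            classify_reactions(model, config)


class TestPatches:
    def test_empty_patch_list_is_identity(self):
        model, _, _ = make_linear_chain()
        patched = apply_patches(
            model, SectorConfig(carbon_source="EX_glc", patches=[])
        )
        np.testing.assert_array_equal(
            patched.lower_bounds, model.lower_bounds
        )
        np.testing.assert_array_equal(
            patched.upper_bounds, model.upper_bounds
        )

    def test_patch_zeroes_bounds_and_logs(self):
        model, _, _ = make_linear_chain()
        patched = apply_patches(
            model, SectorConfig(carbon_source="EX_glc", patches=["E1"])
        )
        j = patched.index("E1")
        assert patched.lower_bounds[j] == patched.upper_bounds[j] == 0.0
        assert any("E1" in line for line in patched.provenance)

    def test_patching_biomass_kills_growth(self):
        model, weights, _ = make_linear_chain()
        patched = apply_patches(
            model, SectorConfig(carbon_source="EX_glc", patches=["BIOMASS"])
        )
        sol = solve_cafba(patched, weights)
        assert sol.optimal
        assert sol.growth_rate == pytest.approx(0.0, abs=1e-9)

    def test_unknown_patch_rejected(self):
        model, _, _ = make_linear_chain()
        with pytest.raises(ModelError, match="GONE"):
            apply_patches(
                model, SectorConfig(carbon_source="EX_glc", patches=["GONE"])
            )

    def test_glucose_dehydrogenase_shut_off(self, genome_model):
        j = genome_model.index("GLCDpp")
        assert genome_model.lower_bounds[j] == 0.0
        assert genome_model.upper_bounds[j] == 0.0


def test_sector_config_from_yaml(tmp_path):
    path = tmp_path / "cfg.yaml"
    path.write_text(
        "carbon_source: EX_glc\n"
        "carbon_intake_reactions: [UPT]\n"
        "category_overrides:\n  E1: zero_cost\n"
        "patches: []\n"
    )
    cfg = SectorConfig.from_file(path)
    assert cfg.carbon_source == "EX_glc"
    assert cfg.category_overrides == {"E1": "zero_cost"}
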