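"""Knowledge-base loading, spec round-trips and case discretization."""

import json

import pytest
from hypothesis import given, strategies as st

from nutridss import (
    DIAGNOSES,
    KnowledgeBase,
    PatientCase,
    discretize_case,
    list_diagnoses,
    load_network_spec,
    serialize_network,
    validate_network,
)
from nutridss.errors import KnowledgeBaseError, NetworkSpecError, UnitMismatchError
from nutridss.knowledge import DIAGNOSIS_STATES


def make_case(**overrides) -> PatientCase:
    base = dict(patient_id="p1", gender="female", age=35.0)
    base.update(overrides)
    return PatientCase.model_validate(base)


class TestShippedKnowledgeBase:
    def test_five_diagnoses_in_order(self, kb):
        assert list_diagnoses(kb) == list(DIAGNOSES)
        assert set(DIAGNOSES) == {
            "malnutrition",
            "iron_deficiency_anemia",
            "vitamin_b12_deficiency",
            "folic_acid_deficiency",
            "thiamine_deficiency",
        }

    def test_every_subnet_valid_with_three_state_diagnosis(self, kb):
        for diag in DIAGNOSES:
            net = kb.network(diag)
            assert validate_network(net) == []
            assert net.node(diag).states == DIAGNOSIS_STATES

    def test_provenance_marks_placeholder_cpts(self, kb):
        for net in kb.networks.values():
            assert net.metadata.get("cpt_provenance") == "placeholder"

    def test_missing_subnet_file_named_in_error(self, kb, tmp_path):
        kb.save(tmp_path)
        (tmp_path / "thiamine_deficiency.json").unlink()
        with pytest.raises(KnowledgeBaseError, match="thiamine_deficiency"):
            KnowledgeBase.load(tmp_path)

    def test_diagnosis_node_missing_risk_state_rejected(self, kb, tmp_path):
        kb.save(tmp_path)
        doc = json.loads((tmp_path / "folic_acid_deficiency.json").read_text())
        for node in doc["nodes"]:
            if node["name"] == "folic_acid_deficiency":
                node["states"] = ["present", "absent"]
                node["cpt"] = [
                    {"given": row["given"], "dist": {"present": 0.2, "absent": 0.8}}
                    for row in node["cpt"]
                ]
            elif "folic_acid_deficiency" in node.get("parents", []):
                node["cpt"] = [row for row in node["cpt"] if row["given"]["folic_acid_deficiency"] != "at_risk"]
        (tmp_path / "folic_acid_deficiency.json").write_text(json.dumps(doc))
        with pytest.raises(KnowledgeBaseError, match="at_risk|states"):
            KnowledgeBase.load(tmp_path)

    def test_shared_roots_identical_across_subnets(self, kb):
        # e.g. `intake` appears in all five subnets and must carry one prior
        priors = {
            diag: net.node("intake").cpt[()]
            for diag, net in kb.networks.items()
            if "intake" in net
        }
        assert len(set(priors.values())) == 1
        with pytest.raises(KnowledgeBaseError, match="shared root"):
            nets = dict(kb.networks)
            broken = json.loads(json.dumps(serialize_network(nets["folic_acid_deficiency"])))
            for node in broken["nodes"]:
                if node["name"] == "intake":
                    node["cpt"] = [{"given": {}, "dist": {"adequate": 0.9, "inadequate": 0.1}}]
            nets["folic_acid_deficiency"] = load_network_spec(broken)
            KnowledgeBase(nets)


class TestNetworkSpecDocuments:
    def test_round_trip_is_structurally_equal(self, kb):
        for net in kb.networks.values():
            again = load_network_spec(serialize_network(net))
            assert again.name == net.name
            assert set(again.nodes) == set(net.nodes)
            for name, node in net.nodes.items():
                other = again.nodes[name]
                assert other.states == node.states
                assert other.parents == node.parents
                assert other.cpt == node.cpt

    def test_parse_error_for_bad_json(self):
        with pytest.raises(NetworkSpecError, match="JSON"):
            load_network_spec("{not json")

    def test_schema_error_for_missing_fields(self):
        with pytest.raises(NetworkSpecError):
            load_network_spec({"name": "x", "nodes": [{"name": "A"}]})

    def test_semantic_error_carries_diagnostics(self):
        doc = {
            "name": "bad",
            "version": "1",
            "nodes": [
                {"name": "A", "states": ["t", "f"], "parents": [],
                 "cpt": [{"given": {}, "dist": {"t": 0.5, "f": 0.4}}]}
            ],
        }
        with pytest.raises(NetworkSpecError) as exc:
            load_network_spec(doc)
        assert any(d.kind == "non_normalized_row" for d in exc.value.diagnostics)


class TestDiscretization:
    def test_low_below_lower_bound(self, ranges):
        case = make_case(labs={"hemoglobin": {"value": 10.0, "unit": "g/dL"}})
        assert discretize_case(case, ranges)["hemoglobin"] == "low"

    def test_boundary_value_is_normal(self, ranges):
        # closed interval: exactly the lower bound counts as normal
        case = make_case(labs={"hemoglobin": {"value": 12.0, "unit": "g/dL"}})
        assert discretize_case(case, ranges)["hemoglobin"] == "normal"

    def test_gender_stratified_bounds(self, ranges):
        male = make_case(gender="male", labs={"hemoglobin": {"value": 13.0, "unit": "g/dL"}})
        female = make_case(labs={"hemoglobin": {"value": 13.0, "unit": "g/dL"}})
        assert discretize_case(male, ranges)["hemoglobin"] == "low"
        assert discretize_case(female, ranges)["hemoglobin"] == "normal"

    def test_intake_1200_kcal_is_inadequate(self, ranges):
        case = make_case(intake={"energy_kcal": 1200})
        assert discretize_case(case, ranges)["intake"] == "inadequate"

    def test_intake_threshold_is_adequate(self, ranges):
        case = make_case(intake={"energy_kcal": 1600})
        assert discretize_case(case, ranges)["intake"] == "adequate"

    def test_direct_kcal_takes_precedence_over_portions(self, ranges):
        case = make_case(intake={"energy_kcal": 1700, "portions": {"grains": 1}})
        assert discretize_case(case, ranges)["intake"] == "adequate"

    def test_energy_estimated_from_portions(self, ranges):
        # 6*150 + 4*25 + 3*60 + 2*120 + 2*150 = 1720 kcal
        portions = {"grains": 6, "vegetables": 4, "fruits": 3, "dairy": 2, "meat_beans": 2}
        case = make_case(intake={"portions": portions})
        assert ranges.energy_from_portions(portions) == pytest.approx(1720)
        assert discretize_case(case, ranges)["intake"] == "adequate"

    def test_unit_mismatch_names_marker_and_unit(self, ranges):
        case = make_case(labs={"ferritin": {"value": 50.0, "unit": "ug/L"}})
        with pytest.raises(UnitMismatchError) as exc:
            discretize_case(case, ranges)
        assert exc.value.marker == "ferritin"
        assert exc.value.expected_unit == "ng/mL"

    def test_surgery_time_bands(self, ranges):
        assert discretize_case(make_case(months_since_surgery=3), ranges)["surgery_time"] == "under_6mo"
        assert discretize_case(make_case(months_since_surgery=6), ranges)["surgery_time"] == "6mo_to_2y"
        assert discretize_case(make_case(months_since_surgery=40), ranges)["surgery_time"] == "over_2y"

    def test_signs_symptoms_and_pooling(self, ranges):
        case = make_case(
            signs={"hair_loss": True, "nail_changes": False, "skin_changes": True, "paleness": False},
            symptoms={"weakness": True, "vomiting": False},
        )
        ev = discretize_case(case, ranges)
        assert ev["hair_loss"] == "present"
        assert ev["paleness"] == "absent"
        assert ev["nail_skin_changes"] == "present"  # either raw flag suffices
        assert ev["weakness"] == "present"
        assert ev["vomiting"] == "absent"
        assert "paresthesia" not in ev  # missing flag -> no evidence

    def test_missing_measurements_yield_no_evidence(self, ranges):
        assert discretize_case(make_case(), ranges) == {}

    def test_unknown_marker_rejected(self, ranges):
        case = make_case(labs={"unobtainium": {"value": 1.0, "unit": "mg"}})
        with pytest.raises(KeyError):
            discretize_case(case, ranges)

    @given(st.floats(min_value=1.0, max_value=40.0), st.floats(min_value=1.0, max_value=40.0))
    def test_monotone_in_lab_value(self, ranges, v1, v2):
        """Raising a lab value never moves its state from high toward low."""
        order = {"low": 0, "normal": 1, "high": 2}
        lo, hi = sorted([v1, v2])
        states = [
            discretize_case(
                make_case(labs={"hemoglobin": {"value": v, "unit": "g/dL"}}), ranges
            )["hemoglobin"]
            for v in (lo, hi)
        ]
        assert order[states[0]] <= order[states[1]]

    def test_every_evidence_node_exists_in_some_subnet(self, kb, ranges):
        case = make_case(
            months_since_surgery=12,
            labs={
                m: {"value": sum(ranges.bounds_for(m, "female")) / 2, "unit": spec.unit}
                for m, spec in ranges.markers.items()
            },
            intake={"energy_kcal": 1500},
            signs={"hair_loss": True, "nail_changes": True, "skin_changes": False, "paleness": True},
            symptoms={s: True for s in ("weakness", "paresthesia", "vomiting", "diarrhea", "blood_loss")},
        )
        evidence = discretize_case(case, ranges)
        all_nodes = {n for net in kb.networks.values() for n in net.nodes}
        assert set(evidence) <= all_nodes
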