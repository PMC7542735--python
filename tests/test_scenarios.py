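"""Fixture fidelity, synthetic generation, fault injection."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from symbio import (
    FaultNotApplicableError,
    InstantiationTuple,
    RelationTuple,
    build_scenario,
    generate_synthetic,
    inject_fault,
    validate,
)

FAULT_RULE = {
    "drop_participant": "R1",
    "same_species": "R2",
    "precedes_cycle": "R6",
    "all_neutral": "R7",
    "endo_spatial_contradiction": "R3",
}


class TestFixtureFidelity:
    @pytest.mark.parametrize(
        "sid,n_inst,n_rel", [(1, 4, 5), (2, 9, 19), (3, 6, 11)]
    )
    def test_tuple_counts(self, sid, n_inst, n_rel):
        s = build_scenario(sid)
        assert len(s.instantiations) == n_inst
        assert len(s.relations) == n_rel

    def test_scenario1_exact_tuples(self, scenario1):
        assert {
            (t.particular, t.type_label, t.region)
            for t in scenario1.instantiations
        } == {
            ("IUI-1", "human being", "t_1"),
            ("IUI-2", "object aggregate", "t_2"),
            ("IUI-3", "skin of posterior part of right elbow", "t_1"),
            ("IUI-4", "ectoparasitism", "t_3"),
        }
        assert {
            (t.subject, t.relation, t.object, t.holds_at)
            for t in scenario1.relations
        } == {
            ("IUI-4", "has-participant", "IUI-1", "t_3"),
            ("IUI-4", "has-participant", "IUI-2", "t_3"),
            ("IUI-4", "occurs-in", "IUI-3", "t_3"),
            ("IUI-3", "part-of", "IUI-1", "t_1"),
            ("t_3", "part-of-occurrent", "t_1", "t_max"),
        }

    def test_scenario1_taxa_follow_scenario_description(self, scenario1):
        """The fungal colony carries the T. rubrum taxid (5551); the
        human host 9606."""
        assert scenario1.taxa == {"IUI-1": "9606", "IUI-2": "5551"}

    def test_scenario2_interaction_typing(self, scenario2):
        types = {
            t.particular: t.type_label for t in scenario2.instantiations
        }
        assert types["IUI-9"] == "obligatory endoparasitism"
        assert types["IUI-10"] == "obligatory endocommensalism"
        assert types["IUI-11"] == "obligatory endoparasitism"
        assert types["IUI-12"] == "obligatory endocommensalism"
        assert scenario2.taxa["IUI-5"] == "7165"
        assert scenario2.taxa["IUI-6"] == "5855"

    def test_scenario2_relation_shape(self, scenario2):
        by_kind = {}
        for t in scenario2.relations:
            by_kind.setdefault(t.relation, 0)
            by_kind[t.relation] += 1
        assert by_kind == {
            "has-participant": 8,
            "precedes": 3,
            "occupies-temporal-region": 4,
            "part-of-occurrent": 4,
        }

    def test_scenario3_key_rows(self, scenario3):
        assert RelationTuple(
            "IUI-15", "precedes", "IUI-16", "t_15",
            "The tryptophan biosynthetic process precedes the translation "
            "process in the host",
        ) in scenario3.relations
        assert InstantiationTuple(
            "IUI-18", "obligatory endomutualism", "t_18"
        ) in scenario3.instantiations
        assert scenario3.taxa == {"IUI-13": "7029", "IUI-14": "9"}

    def test_rebuilding_is_idempotent(self):
        for sid in (1, 2, 3):
            assert build_scenario(sid) == build_scenario(sid)

    def test_unknown_scenario(self):
        with pytest.raises(ValueError):
            build_scenario(4)


class TestSyntheticGeneration:
    def test_same_seed_identical_stores(self):
        assert generate_synthetic(42) == generate_synthetic(42)

    def test_different_seeds_differ(self):
        assert generate_synthetic(1) != generate_synthetic(2)

    def test_chain_precedes_path(self):
        for k in (1, 3, 5):
            s = generate_synthetic(7, chain_length=k)
            assert len(s.relations_by("precedes")) == k - 1

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10**6), k=st.integers(1, 6))
    def test_generated_stores_validate_clean(self, seed, k):
        report = validate(generate_synthetic(seed, chain_length=k))
        assert report.ok, report.summary()

    def test_custom_type_mix(self):
        s = generate_synthetic(
            0, chain_length=4,
            type_mix=("obligatory endoparasitism",
                      "obligatory endocommensalism"),
        )
        types = {
            t.type_label for t in s.instantiations
            if t.type_label.startswith("obligatory")
        }
        assert types <= {"obligatory endoparasitism",
                         "obligatory endocommensalism"}
        assert validate(s).ok

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            generate_synthetic(0, chain_length=0)
        with pytest.raises(Exception):
            generate_synthetic(0, type_mix=("not a class",))


class TestFaultInjection:
    @pytest.mark.parametrize("fault,rule", sorted(FAULT_RULE.items()))
    def test_each_fault_triggers_its_rule(self, fault, rule):
        for seed in range(5):
            store = generate_synthetic(seed, chain_length=3)
            mutated = inject_fault(store, fault, seed)
            report = validate(mutated)
            assert any(
                f.severity == "error" for f in report.by_rule(rule)
            ), f"{fault} seed {seed}: {report.summary()}"

    def test_injection_deterministic(self):
        store = generate_synthetic(11)
        assert inject_fault(store, "drop_participant", 3) == inject_fault(
            store, "drop_participant", 3
        )

    def test_original_store_untouched(self):
        store = generate_synthetic(5)
        before = store.copy()
        inject_fault(store, "precedes_cycle", 0)
        assert store == before

    def test_fault_on_scenario_fixtures(self, scenario1, scenario2):
        assert not validate(inject_fault(scenario1, "drop_participant", 0)).ok
        assert not validate(inject_fault(scenario2, "precedes_cycle", 0)).ok

    def test_inapplicable_fault_raises(self, scenario1):
        # scenario 1 is an ectoparasitism: no endo interaction to contradict
        with pytest.raises(FaultNotApplicableError):
            inject_fault(scenario1, "endo_spatial_contradiction", 0)
        # and asserts no precedes tuples
        with pytest.raises(FaultNotApplicableError):
            inject_fault(scenario1, "precedes_cycle", 0)

    def test_unknown_fault_kind(self, scenario1):
        with pytest.raises(ValueError):
            inject_fault(scenario1, "chaos", 0)
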