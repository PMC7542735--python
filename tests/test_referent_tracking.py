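"""Referent-tracking store: minting, integrity, tuples, temporal order."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from symbio import (
    IntegrityError,
    RTStore,
    SortError,
    VocabularyError,
)
from symbio.referent_tracking import RELATIONS, T_MAX


class TestMinting:
    def test_first_iui_and_successors(self):
        s = RTStore()
        assert s.mint_iui() == "IUI-1"
        assert s.mint_iui() == "IUI-2"
        assert s.mint_iui() == "IUI-3"
        assert s.mint_iui() == "IUI-4"

    def test_configured_start_index(self):
        s = RTStore(start_index=13)
        assert s.mint_iui() == "IUI-13"

    def test_minting_continues_after_explicit_declaration(self):
        s = RTStore()
        s.declare_iui("IUI-7")
        assert s.mint_iui() == "IUI-8"

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.integers(1, 30), min_size=1, max_size=10, unique=True))
    def test_minted_ids_pairwise_distinct(self, declared):
        s = RTStore()
        for n in declared:
            s.declare_iui(f"IUI-{n}")
        minted = [s.mint_iui() for _ in range(5)]
        assert len(set(minted)) == 5
        assert all(m not in {f"IUI-{n}" for n in declared} for m in minted)

    def test_malformed_identifiers_rejected(self):
        s = RTStore()
        with pytest.raises(ValueError):
            s.declare_iui("IUI_1")
        with pytest.raises(ValueError):
            s.declare_region("region-1")


class TestAssertions:
    @pytest.fixture()
    def store(self):
        s = RTStore()
        for n in (1, 2):
            s.declare_iui(f"IUI-{n}")
        s.declare_region("t_1")
        return s

    def test_instantiation_recorded_and_idempotent(self, store):
        store.assert_instantiation("IUI-1", "human being", "t_1")
        assert len(store.instantiations) == 1
        store.assert_instantiation("IUI-1", "human being", "t_1")
        assert len(store.instantiations) == 1

    def test_instantiation_integrity(self, store):
        with pytest.raises(IntegrityError):
            store.assert_instantiation("IUI-99", "organism", "t_1")
        with pytest.raises(IntegrityError):
            store.assert_instantiation("IUI-1", "organism", "t_9")

    def test_relation_recorded_and_idempotent(self, store):
        store.assert_relation("IUI-1", "has-participant", "IUI-2", "t_1")
        store.assert_relation("IUI-1", "has-participant", "IUI-2", "t_1")
        assert len(store.relations) == 1

    def test_closed_vocabulary(self, store):
        with pytest.raises(VocabularyError):
            store.assert_relation("IUI-1", "eats", "IUI-2", "t_1")

    @pytest.mark.parametrize(
        "subject,relation,object",
        [
            ("t_1", "has-participant", "IUI-1"),   # region subject
            ("IUI-1", "occupies-temporal-region", "IUI-2"),  # iui object
            ("IUI-1", "part-of-occurrent", "t_1"),  # mixed sorts
            ("t_1", "precedes", "IUI-1"),           # mixed sorts
        ],
    )
    def test_sort_mismatches(self, store, subject, relation, object):
        with pytest.raises(SortError):
            store.assert_relation(subject, relation, object, T_MAX)

    def test_region_region_parthood_allowed(self, store):
        store.declare_region("t_2")
        store.assert_relation("t_1", "part-of-occurrent", "t_2", T_MAX)

    def test_t_max_always_declared(self):
        assert T_MAX in RTStore().regions

    def test_vocabulary_matches_published_relations(self):
        assert set(RELATIONS) == {
            "has-participant", "occurs-in", "part-of", "precedes",
            "occupies-temporal-region", "part-of-occurrent",
            "proper-part-of-occurrent", "has-output", "has-input",
            "located-in", "spatially-disjoint-from",
        }


class TestQueries:
    def test_participants_of_scenarios(self, scenario2, scenario3):
        assert scenario2.participants_of("IUI-10") == {"IUI-5", "IUI-6"}
        assert scenario3.participants_of("IUI-15") == {"IUI-14"}

    def test_participants_of_process_without_tuples(self, scenario3):
        assert scenario3.participants_of("IUI-18") == set()

    def test_participants_of_undeclared_process(self, scenario2):
        with pytest.raises(IntegrityError):
            scenario2.participants_of("IUI-99")

    def test_region_of_prefers_occupies(self, scenario2):
        assert scenario2.region_of("IUI-9") == "t_9"


class TestTemporal:
    def test_scenario2_order(self, scenario2):
        report = scenario2.temporal_check()
        assert report.consistent
        assert report.order == ["IUI-9", "IUI-10", "IUI-11", "IUI-12"]

    def test_cycle_reported(self):
        s = RTStore()
        a, b = s.mint_iui(), s.mint_iui()
        s.assert_relation(a, "precedes", b, T_MAX)
        s.assert_relation(b, "precedes", a, T_MAX)
        report = s.temporal_check()
        assert not report.precedes_consistent
        assert report.cycles
        assert report.order == []

    def test_irreflexivity_violation(self):
        s = RTStore()
        a = s.mint_iui()
        s.assert_relation(a, "precedes", a, T_MAX)
        assert not s.temporal_check().precedes_consistent

    def test_proper_parthood_irreflexive(self):
        s = RTStore()
        s.declare_region("t_1")
        s.assert_relation("t_1", "proper-part-of-occurrent", "t_1", T_MAX)
        assert not s.temporal_check().parthood_consistent

    def test_empty_store_trivially_consistent(self):
        report = RTStore().temporal_check()
        assert report.consistent
        assert report.order == []

    def test_proper_parthood_in_closure(self, scenario3):
        closure = scenario3.parthood_closure()
        # proper part implies part, transitively: t_15 < t_18 asserted
        assert ("t_15", "t_18") in closure
        # reflexive tolerance of plain parthood
        assert ("t_15", "t_15") in closure


class TestEquality:
    def test_double_build_identical(self, scenario1):
        from symbio import build_scenario

        assert scenario1 == build_scenario(1)

    def test_copy_is_deep_enough(self, scenario1):
        clone = scenario1.copy()
        assert clone == scenario1
        clone.mint_iui()
        assert clone != scenario1
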