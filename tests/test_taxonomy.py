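"""Taxonomy structure and differentia-driven classification."""

import warnings

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from symbio import (
    AmbiguousProfileError,
    ContactMode,
    InteractionProfile,
    Necessity,
    NeutralismContradictionError,
    Outcome,
    OutcomeValue,
    SpatialMode,
    SymbioError,
    UnknownLabelError,
    UnsupportedCombinationError,
    classify_interaction,
    differentia_of,
    enumerate_profile_space,
    is_subclass,
    resolve_label,
)
from symbio.taxonomy import ECTO_LABEL, ENDO_LABEL, REFINEABLE, ROOT_LABEL


# ---------------------------------------------------------------- structure

class TestStructure:
    def test_branch_contains_34_classes(self, taxonomy):
        assert len(taxonomy.branch(ROOT_LABEL)) == 34

    def test_root_ancestry_is_the_imported_go_chain(self, taxonomy):
        assert taxonomy.ancestors(ROOT_LABEL) == [
            "interspecies interaction between organisms",
            "multi-organism process",
        ]

    def test_location_partition(self, taxonomy):
        """Ecto and endo are the only structural children of the root and
        no class descends from both."""
        root_id = taxonomy.get(ROOT_LABEL).id
        children = {
            taxonomy.get(c).label
            for c, p in taxonomy.edges
            if p == root_id
        }
        assert children == {ECTO_LABEL, ENDO_LABEL}
        ecto = taxonomy.descendants(ECTO_LABEL)
        endo = taxonomy.descendants(ENDO_LABEL)
        assert not ecto & endo

    def test_refinement_counts(self, taxonomy):
        branch = taxonomy.branch(ROOT_LABEL)
        assert sum(1 for lab in branch if lab.startswith("obligatory ")) == 8
        assert sum(1 for lab in branch if lab.startswith("facultative ")) == 8

    def test_minted_classes_have_definitions(self, taxonomy):
        assert all(c.definition for c in taxonomy.minted())

    def test_published_curies(self, taxonomy):
        assert taxonomy.get(ECTO_LABEL).id == "APOLLO_SV:00000337"
        assert taxonomy.get(ENDO_LABEL).id == "APOLLO_SV:00000354"
        assert taxonomy.get("bodily harm").id == "APOLLO_SV:00000371"
        assert taxonomy.get("bodily benefit").id == "APOLLO_SV:00000372"
        assert {c.id for c in taxonomy.imported()} == {
            "GO:0044419", "GO:0051704", "GO:0051705",
        }

    def test_outcome_classes_outside_branch(self, taxonomy):
        branch = taxonomy.branch(ROOT_LABEL)
        assert "bodily harm" not in branch
        assert "bodily benefit" not in branch

    @pytest.mark.parametrize(
        "child,ancestor,expected",
        [
            ("grazing", "transient agonism", True),
            ("endosymbiotic mutualism", ECTO_LABEL, False),
            ("obligatory endosymbiotic mutualism", ROOT_LABEL, True),
            ("predation", "agonism", True),
            ("amensalism", "agonism", False),
            (ROOT_LABEL, ROOT_LABEL, True),  # reflexive
        ],
    )
    def test_is_subclass(self, child, ancestor, expected):
        assert is_subclass(child, ancestor) is expected

    def test_is_subclass_unknown_label(self):
        with pytest.raises(UnknownLabelError):
            is_subclass("neutralism", ROOT_LABEL)

    def test_contracted_synonyms_resolve(self):
        assert resolve_label("obligatory endoparasitism") == (
            "obligatory endosymbiotic parasitism"
        )
        assert resolve_label("ectoparasitism") == "ectosymbiotic parasitism"
        assert resolve_label("no such thing") is None


# ------------------------------------------------------------ classification

def _profile(symbols, **kw):
    return InteractionProfile.from_symbols(symbols, **kw)


class TestClassify:
    @pytest.mark.parametrize(
        "symbols,kw,expected",
        [
            ("+,-", dict(fatal=False, spatial="endo", necessity="obligate"),
             ["obligatory endosymbiotic parasitism"]),
            ("+,-", dict(fatal=True, spatial="ecto", contact="transient"),
             ["predation"]),
            ("+,+", dict(spatial="endo", necessity="obligate"),
             ["obligatory endosymbiotic mutualism"]),
            ("+,-", dict(fatal=False, spatial="ecto",
                         contact="intimate_persistent"),
             ["ectosymbiotic parasitism"]),
            ("+,-", dict(fatal=True, spatial="endo"),
             ["endosymbiotic parasitoidism"]),
            ("+,-", dict(fatal=False, spatial="ecto", contact="transient"),
             ["grazing"]),
            ("-,0", dict(spatial="ecto"), ["amensalism"]),
            ("-,-", dict(spatial="ecto"), ["antagonism"]),
            ("+,0", dict(spatial="ecto", necessity="facultative"),
             ["facultative ectosymbiotic commensalism"]),
            ("+,0", dict(spatial="endo"), ["endosymbiotic commensalism"]),
            # necessity does not refine classes without obligatory children
            ("-,-", dict(spatial="ecto", necessity="obligate"),
             ["antagonism"]),
        ],
    )
    def test_pairwise_examples(self, symbols, kw, expected):
        assert classify_interaction(_profile(symbols, **kw)) == expected

    def test_tripartite_union(self):
        """One beneficiary, one harmed host, one unaffected bystander is
        both a parasitism and a commensalism."""
        labels = classify_interaction(
            _profile("+,-,0", fatal=False, spatial="endo")
        )
        assert labels == [
            "endosymbiotic parasitism", "endosymbiotic commensalism",
        ]

    def test_neutralism_contradiction(self):
        with pytest.raises(NeutralismContradictionError):
            classify_interaction(_profile("0,0"))
        with pytest.raises(NeutralismContradictionError):
            classify_interaction(_profile("0,0,0", spatial="endo"))

    def test_endo_harm_only_patterns_unsupported(self):
        for symbols in ("-,0", "-,-"):
            with pytest.raises(UnsupportedCombinationError):
                classify_interaction(_profile(symbols, spatial="endo"))

    def test_ecto_agonism_requires_contact_mode(self):
        with pytest.raises(AmbiguousProfileError):
            classify_interaction(_profile("+,-", fatal=False, spatial="ecto"))

    def test_unspecified_spatial_mode_is_ambiguous(self):
        with pytest.raises(AmbiguousProfileError):
            classify_interaction(_profile("+,+"))

    def test_harm_without_fatality_warns_and_defaults_nonfatal(self):
        with pytest.warns(UserWarning, match="fatality"):
            labels = classify_interaction(
                _profile("+,-", spatial="endo")
            )
        assert labels == ["endosymbiotic parasitism"]

    def test_fatal_requires_harm(self):
        with pytest.raises(ValueError):
            Outcome(OutcomeValue.BENEFIT, fatal=True)

    def test_profile_needs_two_participants(self):
        with pytest.raises(ValueError):
            InteractionProfile(outcomes=(Outcome(OutcomeValue.BENEFIT),))


# ----------------------------------------------------- exhaustive properties

def _pair_facts(profile):
    """(pattern, spatial, contact, effective fatal, necessity) of a
    2-participant profile, mirroring what a differentia constrains."""
    a, b = profile.outcomes
    pattern = (a.value.symbol, b.value.symbol)
    harmed = a if a.value is OutcomeValue.HARM else b
    fatal = bool(harmed.fatal) if harmed.value is OutcomeValue.HARM else False
    return (pattern, profile.spatial_mode, profile.contact_mode, fatal,
            profile.necessity)


class TestExhaustiveness:
    def test_every_profile_classifies_or_raises_defined_error(self):
        """Total over the finite discrete profile space: never silently
        empty, never an undefined exception."""
        defined = (
            NeutralismContradictionError,
            UnsupportedCombinationError,
            AmbiguousProfileError,
        )
        n_labelled = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for profile in enumerate_profile_space():
                try:
                    labels = classify_interaction(profile)
                except defined:
                    continue
                assert labels, f"empty classification for {profile}"
                n_labelled += 1
        assert n_labelled > 0

    def test_ancestor_differentia_satisfied(self, taxonomy):
        """Brute-force oracle: every profile satisfies the differentia of
        every ancestor of every label it is classified under."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for profile in enumerate_profile_space():
                try:
                    labels = classify_interaction(profile)
                except SymbioError:
                    continue
                facts = _pair_facts(profile)
                for label in labels:
                    lineage = [label] + taxonomy.ancestors(label)
                    for anc in lineage:
                        cl = taxonomy.get(anc)
                        if cl.differentia is None:
                            continue
                        assert cl.differentia.satisfied_by_pair(*facts), (
                            f"{profile} classified {label} but violates "
                            f"differentia of ancestor {anc}"
                        )

    def test_differentia_round_trip(self, taxonomy):
        """Any profile satisfying differentia_of(L) classifies to L or a
        descendant of L (over the enumerated space)."""
        minted_with_diff = [
            c.label for c in taxonomy.minted()
            if c.differentia is not None and c.label in taxonomy.branch()
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for profile in enumerate_profile_space():
                try:
                    labels = classify_interaction(profile)
                except SymbioError:
                    continue
                facts = _pair_facts(profile)
                for target in minted_with_diff:
                    if not differentia_of(target).satisfied_by_pair(*facts):
                        continue
                    assert any(
                        taxonomy.is_subclass(lab, target) for lab in labels
                    ), f"{profile} satisfies {target} but got {labels}"

    def test_ecto_endo_disjointness(self, taxonomy):
        """No profile classifies into both location branches."""
        ecto = taxonomy.branch(ECTO_LABEL)
        endo = taxonomy.branch(ENDO_LABEL)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for profile in enumerate_profile_space():
                try:
                    labels = set(classify_interaction(profile))
                except SymbioError:
                    continue
                assert not (labels & ecto and labels & endo)


# ----------------------------------------------------------- property-based

@st.composite
def profiles(draw):
    n = draw(st.integers(2, 4))
    outcomes = []
    for _ in range(n):
        value = draw(st.sampled_from(list(OutcomeValue)))
        fatal = (
            draw(st.sampled_from([True, False]))
            if value is OutcomeValue.HARM else None
        )
        outcomes.append(Outcome(value, fatal))
    return InteractionProfile(
        outcomes=tuple(outcomes),
        spatial_mode=draw(st.sampled_from([SpatialMode.ECTO, SpatialMode.ENDO])),
        contact_mode=draw(st.sampled_from(list(ContactMode))),
        necessity=draw(st.sampled_from(list(Necessity))),
    )


@settings(max_examples=200, derandomize=True)
@given(profiles())
def test_classification_is_total_and_specific(profile):
    """Random multi-party profiles either raise a defined error or yield a
    non-empty antichain of labels (no label an ancestor of another)."""
    from symbio import build_taxonomy

    g = build_taxonomy()
    try:
        labels = classify_interaction(profile)
    except SymbioError:
        return
    assert labels
    for a in labels:
        for b in labels:
            if a != b:
                assert not g.is_subclass(a, b)


@pytest.mark.parametrize("label", REFINEABLE)
def test_refineable_classes_have_both_children(taxonomy, label):
    assert taxonomy.is_subclass(f"obligatory {label}", label)
    assert taxonomy.is_subclass(f"facultative {label}", label)
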