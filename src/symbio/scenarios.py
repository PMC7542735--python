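"""Worked scenario fixtures and the synthetic store generator.

Three scenarios transcribe the published referent-tracking tables
verbatim:

1. *Trichophyton rubrum* (taxid 5551) causing ringworm on a human host
   — an ectoparasitism (4 instantiation tuples, 5 relation tuples).
2. *Plasmodium vivax* (taxid 5855) transmitted between human hosts
   (taxid 9606) by an *Anopheles gambiae* mosquito (taxid 7165) —
   a chain of obligatory endoparasitisms and obligatory
   endocommensalisms (9 particulars, 19 relation tuples).
3. *Buchnera aphidicola* (taxid 9) supplying tryptophan to its pea
   aphid host *Acyrthosiphon pisum* (taxid 7029) — an obligatory
   endomutualism (6 particulars, 11 relation tuples).

Known transcription errata are resolved in favour of the scenario
descriptions and the tables' identifier columns; see ``docs/methods.md``.

:func:`generate_synthetic` emulates stores of the Scenario-2 shape — a
symbiont aggregate passing through a chain of host/vector organisms —
for property testing, and :func:`inject_fault` mutates a valid store so
that a chosen validator rule is guaranteed to fire.
"""

from __future__ import annotations

import random

from .errors import FaultNotApplicableError
from .referent_tracking import RTStore, T_MAX
from .taxonomy import ENDO_LABEL, build_taxonomy
from .validator import _interaction_instances

__all__ = [
    "SCENARIO_IDS",
    "FAULT_KINDS",
    "build_scenario",
    "generate_synthetic",
    "inject_fault",
]

SCENARIO_IDS = (1, 2, 3)

FAULT_KINDS = (
    "drop_participant",
    "same_species",
    "precedes_cycle",
    "all_neutral",
    "endo_spatial_contradiction",
)

#: NCBI taxon identifiers as printed in the scenarios (opaque strings).
TAXID = {
    "Trichophyton rubrum": "5551",
    "Anopheles gambiae": "7165",
    "Plasmodium vivax": "5855",
    "Acyrthosiphon pisum": "7029",
    "Buchnera aphidicola": "9",
    "Staphylococcus aureus": "1280",
    "Homo sapiens": "9606",
}


def _scenario_1() -> RTStore:
    s = RTStore()
    for n in (1, 2, 3, 4):
        s.declare_iui(f"IUI-{n}")
    for r in ("t_1", "t_2", "t_3"):
        s.declare_region(r)

    s.assert_instantiation("IUI-1", "human being", "t_1")
    s.assert_instantiation("IUI-2", "object aggregate", "t_2")
    s.assert_instantiation("IUI-3", "skin of posterior part of right elbow", "t_1")
    s.assert_instantiation("IUI-4", "ectoparasitism", "t_3")

    s.assert_relation("IUI-4", "has-participant", "IUI-1", "t_3",
                      "Ectoparasitism has participant Mr. Jones")
    s.assert_relation("IUI-4", "has-participant", "IUI-2", "t_3",
                      "Ectoparasitism has participant the colony of T. rubrum")
    s.assert_relation("IUI-4", "occurs-in", "IUI-3", "t_3",
                      "The ectoparasitism occurs in the skin of the posterior "
                      "part of Mr. Jones' right elbow")
    s.assert_relation("IUI-3", "part-of", "IUI-1", "t_1",
                      "The skin of the posterior part of Mr. Jones' right "
                      "elbow is part of Mr. Jones")
    s.assert_relation("t_3", "part-of-occurrent", "t_1", T_MAX,
                      "The temporal interval occupied by the ectoparasitism "
                      "is part of the temporal interval occupied by Mr. "
                      "Jones existence")

    s.set_taxon("IUI-1", TAXID["Homo sapiens"])
    s.set_taxon("IUI-2", TAXID["Trichophyton rubrum"])
    return s


def _scenario_2() -> RTStore:
    s = RTStore(start_index=4)
    for n in range(4, 13):
        s.declare_iui(f"IUI-{n}")
    for n in range(4, 13):
        s.declare_region(f"t_{n}")

    types = {
        4: "human being",
        5: "Anopheles gambiae",
        6: "object aggregate",
        7: "human being",
        8: "object aggregate",
        9: "obligatory endoparasitism",
        10: "obligatory endocommensalism",
        11: "obligatory endoparasitism",
        12: "obligatory endocommensalism",
    }
    for n, label in types.items():
        s.assert_instantiation(f"IUI-{n}", label, f"t_{n}")

    participant_rows = [
        (9, 4, "The obligatory endoparasitism denoted by IUI-9 has "
               "participant Mr. Joaquin"),
        (9, 6, "The obligatory endoparasitism denoted by IUI-9 has "
               "participant the aggregate of P. vivax parasites denoted "
               "by IUI-6"),
        (10, 5, "The obligatory endocommensalism denoted by IUI-10 has "
                "participant the A. gambiae mosquito denoted by IUI-5"),
        (10, 6, "The obligatory endocommensalism denoted by IUI-10 has "
                "participant the aggregate of P. vivax parasites denoted "
                "by IUI-6"),
        (11, 7, "The obligatory endoparasitism denoted by IUI-11 has "
                "participant Mrs. Chang"),
        (11, 8, "The obligatory endoparasitism denoted by IUI-11 has "
                "participant the aggregate of P. vivax sporozoites "
                "denoted by IUI-8"),
        (12, 5, "The obligatory endocommensalism denoted by IUI-12 has "
                "participant the A. gambiae mosquito denoted by IUI-5"),
        (12, 8, "The obligatory endocommensalism denoted by IUI-12 has "
                "participant the aggregate of P. vivax sporozoites "
                "denoted by IUI-8"),
    ]
    for proc, part, note in participant_rows:
        s.assert_relation(f"IUI-{proc}", "has-participant", f"IUI-{part}",
                          f"t_{proc}", note)

    for a, b in ((9, 10), (10, 11), (11, 12)):
        s.assert_relation(
            f"IUI-{a}", "precedes", f"IUI-{b}", f"t_{a}",
            f"The interaction denoted by IUI-{a} precedes the interaction "
            f"denoted by IUI-{b}",
        )
    for n in (9, 10, 11, 12):
        s.assert_relation(
            f"IUI-{n}", "occupies-temporal-region", f"t_{n}", T_MAX,
            f"The interaction denoted by IUI-{n} occupies the temporal "
            f"interval t_{n}",
        )
    parthood_rows = [
        (9, 4, "The temporal interval occupied by the first obligatory "
               "endoparasitism is part of the temporal interval in which "
               "Mr. Joaquin has lived"),
        (10, 5, "The temporal interval occupied by the first obligatory "
                "endocommensalism is part of the temporal interval in "
                "which the mosquito has lived"),
        (11, 7, "The temporal interval occupied by the second obligatory "
                "endoparasitism is part of the temporal interval in which "
                "Mrs. Chang has lived"),
        (12, 5, "The temporal interval occupied by the second obligatory "
                "endocommensalism is part of the temporal interval in "
                "which the mosquito has lived"),
    ]
    for a, b, note in parthood_rows:
        s.assert_relation(f"t_{a}", "part-of-occurrent", f"t_{b}", T_MAX, note)

    s.set_taxon("IUI-4", TAXID["Homo sapiens"])
    s.set_taxon("IUI-5", TAXID["Anopheles gambiae"])
    s.set_taxon("IUI-6", TAXID["Plasmodium vivax"])
    s.set_taxon("IUI-7", TAXID["Homo sapiens"])
    s.set_taxon("IUI-8", TAXID["Plasmodium vivax"])
    return s


def _scenario_3(augmented: bool = False) -> RTStore:
    s = RTStore(start_index=13)
    for n in range(13, 19):
        s.declare_iui(f"IUI-{n}")
    for n in range(13, 19):
        s.declare_region(f"t_{n}")

    types = {
        13: "Acyrthosiphon pisum",
        14: "Buchnera aphidicola (Acyrthosiphon pisum)",
        15: "tryptophan biosynthetic process",
        16: "translation",
        17: "tryptophan",
        18: "obligatory endomutualism",
    }
    for n, label in types.items():
        s.assert_instantiation(f"IUI-{n}", label, f"t_{n}")

    s.assert_relation("IUI-15", "has-participant", "IUI-14", "t_15",
                      "The tryptophan biosynthetic process has participant "
                      "the B. aphidicola bacterium")
    s.assert_relation("IUI-15", "has-output", "IUI-17", "t_15",
                      "The tryptophan biosynthetic process has the "
                      "tryptophan molecule")
    s.assert_relation("IUI-16", "has-participant", "IUI-13", "t_16",
                      "The translation process has participant the A. pisum "
                      "aphid")
    s.assert_relation("IUI-16", "has-input", "IUI-17", "t_16",
                      "The translation process has input the tryptophan "
                      "molecule")
    s.assert_relation("IUI-15", "precedes", "IUI-16", "t_15",
                      "The tryptophan biosynthetic process precedes the "
                      "translation process in the host")
    s.assert_relation("IUI-15", "proper-part-of-occurrent", "IUI-18", "t_15",
                      "The tryptophan biosynthetic process is a proper "
                      "occurrent part of the obligatory endomutualism")
    s.assert_relation("IUI-18", "occupies-temporal-region", "t_18", T_MAX,
                      "The obligatory endomutualism occupies the temporal "
                      "interval t_18")
    s.assert_relation("t_15", "proper-part-of-occurrent", "t_14", T_MAX,
                      "The temporal interval occupied by the tryptophan "
                      "biosynthetic process is a proper occurrent part of "
                      "the temporal interval in which the B. aphidicola "
                      "bacterium has lived")
    s.assert_relation("t_16", "proper-part-of-occurrent", "t_13", T_MAX,
                      "The temporal interval occupied by the translation "
                      "process is a proper occurrent part of the temporal "
                      "interval in which the aphid has lived")
    s.assert_relation("t_16", "proper-part-of-occurrent", "t_18", T_MAX,
                      "The temporal interval occupied by the translation "
                      "process is a proper occurrent part of the temporal "
                      "interval occupied by the obligatory endomutualism")
    s.assert_relation("t_15", "proper-part-of-occurrent", "t_18", T_MAX,
                      "The temporal interval occupied by the tryptophan "
                      "biosynthetic process is a proper occurrent part of "
                      "the temporal interval occupied by the obligatory "
                      "endomutualism")

    s.set_taxon("IUI-13", TAXID["Acyrthosiphon pisum"])
    s.set_taxon("IUI-14", TAXID["Buchnera aphidicola"])

    if augmented:
        # participation left implicit by the printed tables
        s.assert_relation("IUI-18", "has-participant", "IUI-13", "t_18")
        s.assert_relation("IUI-18", "has-participant", "IUI-14", "t_18")
        s.assert_relation("IUI-14", "located-in", "IUI-13", "t_18")
    return s


def build_scenario(scenario_id: int, augmented: bool = False) -> RTStore:
    """Build one of the three worked scenarios verbatim.

    ``augmented`` (scenario 3 only) additionally asserts the
    endomutualism's participation and location tuples that the printed
    tables leave implicit, so the store also satisfies the participant
    and location axioms rather than merely not contradicting them.
    """
    if scenario_id == 1:
        return _scenario_1()
    if scenario_id == 2:
        return _scenario_2()
    if scenario_id == 3:
        return _scenario_3(augmented=augmented)
    raise ValueError(f"unknown scenario id {scenario_id!r} (expected 1, 2 or 3)")


# --------------------------------------------------------------------------
# synthetic generation
# --------------------------------------------------------------------------

_HOST_POOL = [
    ("human being", TAXID["Homo sapiens"]),
    ("Anopheles gambiae", TAXID["Anopheles gambiae"]),
    ("Acyrthosiphon pisum", TAXID["Acyrthosiphon pisum"]),
]

_SYMBIONT_POOL = [
    ("object aggregate", TAXID["Plasmodium vivax"]),
    ("object aggregate", TAXID["Buchnera aphidicola"]),
    ("object aggregate", TAXID["Staphylococcus aureus"]),
    ("object aggregate", TAXID["Trichophyton rubrum"]),
]

DEFAULT_TYPE_MIX = ("obligatory endoparasitism", "obligatory endocommensalism")


def generate_synthetic(
    seed: int,
    chain_length: int = 4,
    n_symbionts: int = 1,
    type_mix: tuple[str, ...] = DEFAULT_TYPE_MIX,
) -> RTStore:
    """Generate a referentially intact host/symbiont chain store.

    Emulates the Scenario-2 shape: each symbiont aggregate engages in
    ``chain_length`` successive interactions with distinct host
    organisms, and consecutive interactions are linked by ``precedes``
    (``chain_length - 1`` tuples per chain).  Interaction types are
    sampled from ``type_mix`` (taxonomy labels, contracted synonyms
    allowed); participant, occupies-temporal-region, temporal-parthood
    and — for endosymbioses — located-in tuples are asserted so the
    store validates with zero errors.  Deterministic given ``seed``.
    """
    if chain_length < 1 or n_symbionts < 1:
        raise ValueError("chain_length and n_symbionts must be >= 1")
    if not type_mix:
        raise ValueError("type_mix must not be empty")
    taxonomy = build_taxonomy()
    for label in type_mix:
        taxonomy.get(label)  # raises UnknownLabelError for stray labels

    rng = random.Random(seed)
    s = RTStore()
    region_counter = 0

    def next_region() -> str:
        nonlocal region_counter
        region_counter += 1
        return s.declare_region(f"t_{region_counter}")

    for _ in range(n_symbionts):
        sym_label, sym_taxid = rng.choice(_SYMBIONT_POOL)
        symbiont = s.mint_iui()
        sym_region = next_region()
        s.assert_instantiation(symbiont, sym_label, sym_region)
        s.set_taxon(symbiont, sym_taxid)

        previous = None
        for _ in range(chain_length):
            host_label, host_taxid = rng.choice(
                [h for h in _HOST_POOL if h[1] != sym_taxid]
            )
            host = s.mint_iui()
            host_region = next_region()
            s.assert_instantiation(host, host_label, host_region)
            s.set_taxon(host, host_taxid)

            interaction = s.mint_iui()
            int_region = next_region()
            itype = rng.choice(type_mix)
            s.assert_instantiation(interaction, itype, int_region)
            s.assert_relation(interaction, "has-participant", symbiont, int_region)
            s.assert_relation(interaction, "has-participant", host, int_region)
            s.assert_relation(interaction, "occupies-temporal-region",
                              int_region, T_MAX)
            s.assert_relation(int_region, "part-of-occurrent", host_region, T_MAX)
            s.assert_relation(int_region, "part-of-occurrent", sym_region, T_MAX)
            if taxonomy.is_subclass(itype, ENDO_LABEL):
                s.assert_relation(symbiont, "located-in", host, int_region)
            else:
                s.assert_relation(symbiont, "spatially-disjoint-from", host,
                                  int_region)
            if previous is not None:
                s.assert_relation(previous, "precedes", interaction, int_region)
            previous = interaction
    return s


# --------------------------------------------------------------------------
# fault injection
# --------------------------------------------------------------------------

def inject_fault(store: RTStore, fault: str, seed: int = 0) -> RTStore:
    """Return a mutated copy of ``store`` guaranteed to trigger a rule.

    ========================== ====
    fault kind                 rule
    ========================== ====
    drop_participant           R1
    same_species               R2
    precedes_cycle             R6
    all_neutral                R7
    endo_spatial_contradiction R3
    ========================== ====

    Raises :class:`FaultNotApplicableError` when the store offers no
    site for the requested fault.  Deterministic given ``seed``.
    """
    if fault not in FAULT_KINDS:
        raise ValueError(f"unknown fault kind {fault!r}")
    rng = random.Random(seed)
    taxonomy = build_taxonomy()
    out = store.copy()
    interactions = _interaction_instances(out, taxonomy)

    if fault == "drop_participant":
        candidates = [
            (iui, tuples)
            for iui, _label in interactions
            if len(tuples := [
                t for t in out.relations_by("has-participant")
                if t.subject == iui
            ]) >= 2
        ]
        if not candidates:
            raise FaultNotApplicableError(
                "no interaction with >= 2 participant tuples"
            )
        _iui, tuples = rng.choice(candidates)
        out.relations.discard(rng.choice(tuples))
        return out

    if fault == "same_species":
        candidates = [
            (iui, parts)
            for iui, _label in interactions
            if len(parts := sorted(out.participants_of(iui))) >= 2
        ]
        if not candidates:
            raise FaultNotApplicableError(
                "no interaction with >= 2 participants"
            )
        _iui, parts = rng.choice(candidates)
        shared = out.taxa.get(parts[0], TAXID["Homo sapiens"])
        for p in parts:
            out.set_taxon(p, shared)
        return out

    if fault == "precedes_cycle":
        precedes = out.relations_by("precedes")
        if not precedes:
            raise FaultNotApplicableError("store asserts no precedes tuples")
        t = rng.choice(precedes)
        out.assert_relation(t.object, "precedes", t.subject, t.holds_at,
                            "injected precedence cycle")
        return out

    if fault == "all_neutral":
        if not interactions:
            raise FaultNotApplicableError("store contains no interaction")
        iui, _label = rng.choice(interactions)
        n = max(2, len(out.participants_of(iui)))
        out.annotate_outcomes(iui, ("0",) * n)
        return out

    # endo_spatial_contradiction
    candidates = []
    for iui, label in interactions:
        if not taxonomy.is_subclass(label, ENDO_LABEL):
            continue
        parts = sorted(out.participants_of(iui))
        if len(parts) >= 2:
            candidates.append((iui, parts))
    if not candidates:
        raise FaultNotApplicableError(
            "no endosymbiosis instance with >= 2 participants"
        )
    iui, parts = rng.choice(candidates)
    # drop any located-in between the chosen pair so the contradiction
    # is the only spatial assertion
    for t in list(out.relations):
        if (
            t.relation == "located-in"
            and t.subject in parts
            and t.object in parts
        ):
            out.relations.discard(t)
    region = out.region_of(iui) or T_MAX
    out.assert_relation(parts[0], "spatially-disjoint-from", parts[1], region,
                        "injected spatial contradiction")
    return out
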