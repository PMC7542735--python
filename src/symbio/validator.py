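"""Rule-based consistency checking of referent-tracking stores.

Each rule operationalizes one axiom of the symbiosis representation:

========  =======================  ==========================================
rule id   name                     axiom / rationale
========  =======================  ==========================================
R1        MIN_PARTICIPANTS         a symbiosis has 'has participant' min 2
R2        INTERSPECIES             participants span >= 2 species (taxa)
R3        ENDO_LOCATION            endosymbiosis: one organism located in
                                   another; a spatially-disjoint-from
                                   assertion between participants contradicts
R4        ECTO_LOCATION            ectosymbiosis: participants spatially
                                   disjoint; located-in contradicts
R5        TEMPORAL_PARTHOOD        the interval occupied by an interaction is
                                   part of each participant's life interval
R6        PRECEDES_ORDER           precedes is a strict partial order
R7        NEUTRALISM               no symbiosis is annotated all-neutral
R8        INTIMACY_EVIDENCE        advisory: ectosymbiosis without contact or
                                   multi-organism-behaviour evidence
========  =======================  ==========================================

Severity conventions (an artifact decision — the axioms themselves carry
none): contradictions and closed-world count violations are ``error``;
open-world absences (an expected tuple simply not asserted) are
``warning``; advisory notes are ``info``.  In particular R1 reports an
interaction with *exactly one* asserted participant as an error (positive
evidence of a malformed interaction) but one with *no* participant
assertions as a warning, so that verbatim scenario transcriptions that
leave participation implicit validate clean at error level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .referent_tracking import RTStore
from .taxonomy import (
    ECTO_LABEL,
    ENDO_LABEL,
    ROOT_LABEL,
    TaxonomyGraph,
    build_taxonomy,
    resolve_label,
)

__all__ = [
    "MIN_PARTICIPANTS",
    "Rule",
    "ValidationFinding",
    "ValidationReport",
    "list_rules",
    "validate",
]

#: Minimum participant cardinality in the symbiosis equivalence axiom.
MIN_PARTICIPANTS = 2


@dataclass(frozen=True)
class Rule:
    rule_id: str
    name: str
    severity: str
    description: str


_RULES = [
    Rule(
        "R1",
        "MIN_PARTICIPANTS",
        "error",
        f"Any instance of a symbiosis-branch class must have at least "
        f"{MIN_PARTICIPANTS} has-participant tuples (warning when none "
        f"are asserted, error when exactly one is).",
    ),
    Rule(
        "R2",
        "INTERSPECIES",
        "error",
        "Participants of a symbiosis with known taxa must span at least "
        "two distinct taxa; an interspecies interaction cannot occur "
        "within one species.",
    ),
    Rule(
        "R3",
        "ENDO_LOCATION",
        "warning",
        "An endosymbiosis instance should assert located-in between its "
        "participants (warning if absent; error if spatially-disjoint-from "
        "contradicts it).",
    ),
    Rule(
        "R4",
        "ECTO_LOCATION",
        "warning",
        "An ectosymbiosis instance should assert spatially-disjoint-from "
        "between its participants (warning if absent; error if located-in "
        "contradicts it).",
    ),
    Rule(
        "R5",
        "TEMPORAL_PARTHOOD",
        "warning",
        "The temporal region occupied by an interaction should be an "
        "occurrent part of each participant's existence region.",
    ),
    Rule(
        "R6",
        "PRECEDES_ORDER",
        "error",
        "precedes must be irreflexive and acyclic (a strict partial "
        "order); occurrent parthood must be acyclic.",
    ),
    Rule(
        "R7",
        "NEUTRALISM",
        "error",
        "No symbiosis instance may be annotated with all-neutral "
        "outcomes; such an interaction is a logical contradiction.",
    ),
    Rule(
        "R8",
        "INTIMACY_EVIDENCE",
        "info",
        "Advisory: an ectosymbiosis with neither contact evidence (an "
        "occurs-in assertion) nor multi-organism-behaviour evidence.",
    ),
]


def list_rules() -> list[Rule]:
    """The published rule catalogue, R1..R8."""
    return list(_RULES)


@dataclass(frozen=True)
class ValidationFinding:
    rule_id: str
    severity: str
    subject: str
    offending: tuple = ()
    message: str = ""


@dataclass
class ValidationReport:
    findings: list[ValidationFinding] = field(default_factory=list)

    @property
    def errors(self) -> list[ValidationFinding]:
        return [f for f in self.findings if f.severity == "error"]

    @property
    def warnings(self) -> list[ValidationFinding]:
        return [f for f in self.findings if f.severity == "warning"]

    @property
    def infos(self) -> list[ValidationFinding]:
        return [f for f in self.findings if f.severity == "info"]

    @property
    def ok(self) -> bool:
        """True when no error-severity findings are present."""
        return not self.errors

    def by_rule(self, rule_id: str) -> list[ValidationFinding]:
        return [f for f in self.findings if f.rule_id == rule_id]

    def summary(self) -> str:
        lines = [
            f"{f.rule_id} {f.severity:<7} {f.subject}: {f.message}"
            for f in self.findings
        ]
        lines.append(
            f"-- {len(self.errors)} error(s), {len(self.warnings)} "
            f"warning(s), {len(self.infos)} info"
        )
        return "\n".join(lines)


def _interaction_instances(
    store: RTStore, taxonomy: TaxonomyGraph
) -> list[tuple[str, str]]:
    """(interaction IUI, canonical class label) pairs, sorted.

    An instantiation tuple marks its particular as an interaction when
    its type label resolves (directly or through a contracted synonym)
    to a class inside the symbiosis branch.
    """
    branch = taxonomy.branch(ROOT_LABEL)
    found: dict[str, str] = {}
    for tup in sorted(
        store.instantiations, key=lambda t: (t.particular, t.type_label)
    ):
        label = resolve_label(tup.type_label)
        if label is not None and label in branch:
            found[tup.particular] = label
    return sorted(found.items())


def validate(store: RTStore, taxonomy: TaxonomyGraph | None = None) -> ValidationReport:
    """Run the full rule catalogue over a store.

    A pure function of (store, taxonomy): findings are deterministic,
    sorted by (rule id, subject identifier).
    """
    g = taxonomy if taxonomy is not None else build_taxonomy()
    findings: list[ValidationFinding] = []
    interactions = _interaction_instances(store, g)
    closure = store.parthood_closure()

    for iui, label in interactions:
        parts = sorted(store.participants_of(iui))
        is_endo = g.is_subclass(label, ENDO_LABEL)
        is_ecto = g.is_subclass(label, ECTO_LABEL)

        # R1: participant cardinality
        if len(parts) == 0:
            findings.append(ValidationFinding(
                "R1", "warning", iui, (),
                f"{label} instance {iui} has no has-participant "
                f"assertions (axiom requires min {MIN_PARTICIPANTS})",
            ))
        elif len(parts) < MIN_PARTICIPANTS:
            findings.append(ValidationFinding(
                "R1", "error", iui, tuple(parts),
                f"{label} instance {iui} has {len(parts)} participant(s); "
                f"the symbiosis axiom requires min {MIN_PARTICIPANTS}",
            ))

        # R2: interspecies
        if len(parts) >= 2:
            untaxed = [p for p in parts if p not in store.taxa]
            known = sorted({store.taxa[p] for p in parts if p in store.taxa})
            if untaxed:
                findings.append(ValidationFinding(
                    "R2", "info", iui, tuple(untaxed),
                    f"participants {', '.join(untaxed)} of {iui} have no "
                    f"taxon; skipped by the interspecies check",
                ))
            if len(parts) - len(untaxed) >= 2 and len(known) < 2:
                findings.append(ValidationFinding(
                    "R2", "error", iui, tuple(parts),
                    f"all taxed participants of {label} instance {iui} "
                    f"share taxid {known[0]}; an interspecies interaction "
                    f"requires organisms of different species",
                ))

        # R3/R4: location axioms
        part_set = set(parts)
        located = [
            t for t in store.relations_by("located-in")
            if t.subject in part_set and t.object in part_set
        ]
        disjoint = [
            t for t in store.relations_by("spatially-disjoint-from")
            if t.subject in part_set and t.object in part_set
        ]
        if is_endo:
            if disjoint:
                findings.append(ValidationFinding(
                    "R3", "error", iui, tuple(disjoint),
                    f"endosymbiosis instance {iui} has participants "
                    f"asserted spatially disjoint, contradicting the "
                    f"located-in axiom",
                ))
            elif not located:
                findings.append(ValidationFinding(
                    "R3", "warning", iui, (),
                    f"no located-in tuple asserted between participants "
                    f"of endosymbiosis instance {iui}",
                ))
        if is_ecto:
            if located:
                findings.append(ValidationFinding(
                    "R4", "error", iui, tuple(located),
                    f"ectosymbiosis instance {iui} has one participant "
                    f"located in another, contradicting the "
                    f"spatially-disjoint axiom",
                ))
            elif not disjoint:
                findings.append(ValidationFinding(
                    "R4", "warning", iui, (),
                    f"no spatially-disjoint-from tuple asserted between "
                    f"participants of ectosymbiosis instance {iui}",
                ))

        # R5: temporal parthood toward each participant's life interval
        region = store.region_of(iui)
        if region is not None:
            for p in parts:
                p_region = store.region_of(p)
                if p_region is None:
                    continue
                if (region, p_region) not in closure:
                    findings.append(ValidationFinding(
                        "R5", "warning", iui, (region, p_region),
                        f"interval {region} of {iui} is not asserted to "
                        f"be an occurrent part of participant {p}'s "
                        f"interval {p_region}",
                    ))

        # R7: neutralism contradiction
        symbols = store.outcome_annotations.get(iui)
        if symbols and all(s == "0" for s in symbols):
            findings.append(ValidationFinding(
                "R7", "error", iui, (symbols,),
                f"{label} instance {iui} is annotated with all-neutral "
                f"outcomes; an interaction affecting none of its "
                f"participants is contradictory",
            ))

        # R8: advisory intimacy evidence (ecto branch only)
        if is_ecto:
            contact_evidence = any(
                t.subject == iui for t in store.relations_by("occurs-in")
            )
            behaviour_evidence = any(
                "behavior" in t.type_label or "behaviour" in t.type_label
                for t in store.instantiations
            )
            if not contact_evidence and not behaviour_evidence:
                findings.append(ValidationFinding(
                    "R8", "info", iui, (),
                    f"no contact (occurs-in) or multi-organism-behaviour "
                    f"evidence recorded for ectosymbiosis instance {iui}",
                ))

    # R6: temporal ordering, store-wide
    report = store.temporal_check()
    if not report.consistent:
        for cycle in report.cycles:
            findings.append(ValidationFinding(
                "R6", "error", cycle[0] if cycle else "", tuple(cycle),
                f"temporal ordering violation: cycle "
                f"{' -> '.join(cycle + cycle[:1])}",
            ))

    findings.sort(key=lambda f: (f.rule_id, f.subject, f.message))
    return ValidationReport(findings=findings)
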