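"""Referent tracking: instance-level tuples about particulars.

Referent tracking represents *particulars* — this human, this colony of
fungi, this parasitic interaction — rather than types.  The analysis
follows three steps: (1) assign each particular an Instance Unique
Identifier of the form ``IUI-n``; (2) record the types each particular
instantiates and the temporal regions (``t_n``) involved; (3) record
the relations that hold between particulars, each qualified by the
temporal region during which it holds (``t_max`` denoting "at all
times").

An :class:`RTStore` holds one scenario's identifiers and tuples with
set semantics and referential integrity: every tuple must reference
declared identifiers, and re-asserting a tuple is a no-op.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import networkx as nx

from .errors import IntegrityError, SortError, VocabularyError

__all__ = [
    "T_MAX",
    "RELATIONS",
    "InstantiationTuple",
    "RelationTuple",
    "TemporalReport",
    "RTStore",
    "is_iui",
    "is_region",
]

T_MAX = "t_max"

_IUI_RE = re.compile(r"^IUI-(\d+)$")
_REGION_RE = re.compile(r"^t_(\d+)$")


def is_iui(identifier: str) -> bool:
    return bool(_IUI_RE.match(identifier))


def is_region(identifier: str) -> bool:
    return identifier == T_MAX or bool(_REGION_RE.match(identifier))


def _iui_index(iui: str) -> int:
    m = _IUI_RE.match(iui)
    if not m:
        raise ValueError(f"not an IUI: {iui!r}")
    return int(m.group(1))


#: Closed relation vocabulary with admissible (subject, object) sorts.
#: ``"iui"`` / ``"region"`` constrain one sort; ``"same"`` admits
#: IUI–IUI or region–region pairs (temporal parthood and precedence are
#: asserted both between processes and between the regions they occupy).
RELATIONS: dict[str, tuple[str, str]] = {
    "has-participant": ("iui", "iui"),
    "occurs-in": ("iui", "iui"),
    "part-of": ("iui", "iui"),
    "precedes": ("same", "same"),
    "occupies-temporal-region": ("iui", "region"),
    "part-of-occurrent": ("same", "same"),
    "proper-part-of-occurrent": ("same", "same"),
    "has-output": ("iui", "iui"),
    "has-input": ("iui", "iui"),
    "located-in": ("iui", "iui"),
    "spatially-disjoint-from": ("iui", "iui"),
}


@dataclass(frozen=True)
class InstantiationTuple:
    """``particular`` instantiates ``type_label`` at temporal region."""

    particular: str
    type_label: str
    region: str


@dataclass(frozen=True)
class RelationTuple:
    """``subject relation object``, holding at ``holds_at``."""

    subject: str
    relation: str
    object: str
    holds_at: str
    note: str = ""


@dataclass
class TemporalReport:
    """Result of :meth:`RTStore.temporal_check`.

    ``order`` is a topological order of the process IUIs mentioned in
    precedes tuples (empty when the precedence graph is cyclic);
    ``cycles`` lists one witness cycle per violated constraint.
    """

    precedes_consistent: bool
    parthood_consistent: bool
    order: list[str] = field(default_factory=list)
    cycles: list[list[str]] = field(default_factory=list)

    @property
    def consistent(self) -> bool:
        return self.precedes_consistent and self.parthood_consistent


def _sort_of(identifier: str) -> str:
    if is_iui(identifier):
        return "iui"
    if is_region(identifier):
        return "region"
    raise SortError(f"identifier {identifier!r} is neither an IUI nor a temporal region")


class RTStore:
    """A set of IUIs, temporal regions, and instance-level tuples.

    ``taxa`` attaches NCBI taxon identifiers (opaque strings) to
    organism particulars; ``outcome_annotations`` optionally records
    the per-participant outcome symbols (``"+"``, ``"-"``, ``"0"``) of
    an interaction particular.  Both are metadata consumed by the
    consistency validator.
    """

    def __init__(self, start_index: int = 1):
        self.iuis: set[str] = set()
        self.regions: set[str] = {T_MAX}
        self.instantiations: set[InstantiationTuple] = set()
        self.relations: set[RelationTuple] = set()
        self.taxa: dict[str, str] = {}
        self.outcome_annotations: dict[str, tuple[str, ...]] = {}
        self._start_index = start_index

    # -- identifier management -------------------------------------------

    def mint_iui(self) -> str:
        """Mint the next IUI: ``IUI-n`` with n = 1 + max existing index."""
        indices = [_iui_index(i) for i in self.iuis]
        n = max(indices) + 1 if indices else self._start_index
        iui = f"IUI-{n}"
        self.iuis.add(iui)
        return iui

    def declare_iui(self, iui: str) -> str:
        """Declare an explicitly numbered IUI (used by fixtures)."""
        if not is_iui(iui):
            raise ValueError(f"malformed IUI {iui!r}")
        self.iuis.add(iui)
        return iui

    def declare_region(self, region: str) -> str:
        if not is_region(region):
            raise ValueError(f"malformed temporal region {region!r}")
        self.regions.add(region)
        return region

    def _require(self, identifier: str) -> None:
        if is_iui(identifier):
            if identifier not in self.iuis:
                raise IntegrityError(f"undeclared particular {identifier}")
        elif is_region(identifier):
            if identifier not in self.regions:
                raise IntegrityError(f"undeclared temporal region {identifier}")
        else:
            raise IntegrityError(f"unrecognized identifier {identifier!r}")

    # -- assertions -------------------------------------------------------

    def assert_instantiation(
        self, particular: str, type_label: str, region: str
    ) -> InstantiationTuple:
        """Record that ``particular`` instantiates ``type_label`` at
        ``region``.  Idempotent; both identifiers must be declared.

        ``type_label`` may be a taxonomy label (canonical or
        contracted), a CURIE, a taxon identifier, or free text such as
        ``"object aggregate"``.
        """
        self._require(particular)
        self._require(region)
        if not is_iui(particular):
            raise SortError("instantiation subject must be a particular (IUI)")
        tup = InstantiationTuple(particular, type_label, region)
        self.instantiations.add(tup)
        return tup

    def assert_relation(
        self,
        subject: str,
        relation: str,
        object: str,
        holds_at: str,
        note: str = "",
    ) -> RelationTuple:
        """Record ``subject relation object`` holding at ``holds_at``.

        The relation must belong to the closed vocabulary and the
        subject/object sorts must match its signature.  Idempotent.
        """
        if relation not in RELATIONS:
            raise VocabularyError(
                f"unknown relation {relation!r}; vocabulary: "
                f"{', '.join(sorted(RELATIONS))}"
            )
        self._require(subject)
        self._require(object)
        self._require(holds_at)
        if not is_region(holds_at):
            raise SortError("holds_at must be a temporal region")
        s_sort, o_sort = RELATIONS[relation]
        subj_sort, obj_sort = _sort_of(subject), _sort_of(object)
        if s_sort == "same":
            if subj_sort != obj_sort:
                raise SortError(
                    f"{relation} relates two particulars or two temporal "
                    f"regions, got {subject} / {object}"
                )
        else:
            if subj_sort != s_sort or obj_sort != o_sort:
                raise SortError(
                    f"{relation} expects ({s_sort}, {o_sort}), got "
                    f"({subj_sort}, {obj_sort})"
                )
        tup = RelationTuple(subject, relation, object, holds_at, note)
        self.relations.add(tup)
        return tup

    def set_taxon(self, iui: str, taxid: str) -> None:
        self._require(iui)
        self.taxa[iui] = str(taxid)

    def annotate_outcomes(self, interaction: str, symbols: tuple[str, ...]) -> None:
        """Attach per-participant outcome symbols to an interaction."""
        self._require(interaction)
        for s in symbols:
            if s not in ("+", "-", "0"):
                raise ValueError(f"outcome symbol must be +/-/0, got {s!r}")
        self.outcome_annotations[interaction] = tuple(symbols)

    # -- queries ----------------------------------------------------------

    def relations_by(self, relation: str) -> list[RelationTuple]:
        """Tuples of one relation, deterministically ordered."""
        return sorted(
            (t for t in self.relations if t.relation == relation),
            key=lambda t: (t.subject, t.object, t.holds_at),
        )

    def participants_of(self, process: str) -> set[str]:
        """Objects of has-participant tuples whose subject is ``process``."""
        self._require(process)
        return {
            t.object
            for t in self.relations
            if t.relation == "has-participant" and t.subject == process
        }

    def region_of(self, particular: str) -> str | None:
        """The temporal region a particular exists in / occupies.

        Prefers an explicit occupies-temporal-region tuple, falling
        back to the region of the particular's instantiation tuple(s).
        """
        for t in self.relations_by("occupies-temporal-region"):
            if t.subject == particular:
                return t.object
        regions = sorted(
            t.region for t in self.instantiations if t.particular == particular
        )
        return regions[0] if regions else None

    def parthood_closure(self) -> set[tuple[str, str]]:
        """Transitive closure of (proper-)part-of-occurrent pairs.

        Proper parthood implies parthood; plain parthood is
        reflexive-tolerant, so reflexive pairs are admitted.
        """
        g = nx.DiGraph()
        for t in self.relations:
            if t.relation in ("part-of-occurrent", "proper-part-of-occurrent"):
                g.add_edge(t.subject, t.object)
        closure: set[tuple[str, str]] = set()
        for node in g.nodes:
            for reachable in nx.descendants(g, node):
                closure.add((node, reachable))
            closure.add((node, node))
        return closure

    def temporal_check(self) -> TemporalReport:
        """Verify temporal ordering constraints.

        Checks that precedes is irreflexive and acyclic (a strict
        partial order after transitive closure) and that occurrent
        parthood is acyclic (proper parthood irreflexive).  Violations
        are reported, not raised.
        """
        cycles: list[list[str]] = []

        precedes = nx.DiGraph()
        for t in self.relations:
            if t.relation == "precedes":
                if t.subject == t.object:
                    cycles.append([t.subject])
                else:
                    precedes.add_edge(t.subject, t.object)
        try:
            cyc = nx.find_cycle(precedes)
            cycles.append([edge[0] for edge in cyc])
            precedes_ok = False
        except nx.NetworkXNoCycle:
            precedes_ok = not any(len(c) == 1 for c in cycles)

        parthood = nx.DiGraph()
        parthood_ok = True
        for t in self.relations:
            if t.relation == "proper-part-of-occurrent" and t.subject == t.object:
                cycles.append([t.subject])
                parthood_ok = False
            if t.relation in ("part-of-occurrent", "proper-part-of-occurrent"):
                if t.subject != t.object:
                    parthood.add_edge(t.subject, t.object)
        try:
            cyc = nx.find_cycle(parthood)
            cycles.append([edge[0] for edge in cyc])
            parthood_ok = False
        except nx.NetworkXNoCycle:
            pass

        order: list[str] = []
        if precedes_ok:
            process_nodes = {n for n in precedes.nodes if is_iui(n)}
            def _key(n: str):
                # numeric IUI order first, then regions lexicographically
                return (0, _iui_index(n), "") if is_iui(n) else (1, 0, n)

            order = [
                n
                for n in nx.lexicographical_topological_sort(precedes, key=_key)
                if n in process_nodes
            ]
        return TemporalReport(
            precedes_consistent=precedes_ok,
            parthood_consistent=parthood_ok,
            order=order,
            cycles=cycles,
        )

    # -- structural equality / copying ------------------------------------

    def copy(self) -> "RTStore":
        new = RTStore(start_index=self._start_index)
        new.iuis = set(self.iuis)
        new.regions = set(self.regions)
        new.instantiations = set(self.instantiations)
        new.relations = set(self.relations)
        new.taxa = dict(self.taxa)
        new.outcome_annotations = dict(self.outcome_annotations)
        return new

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RTStore):
            return NotImplemented
        return (
            self.iuis == other.iuis
            and self.regions == other.regions
            and self.instantiations == other.instantiations
            and self.relations == other.relations
            and self.taxa == other.taxa
            and self.outcome_annotations == other.outcome_annotations
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<RTStore: {len(self.iuis)} IUIs, {len(self.regions)} regions, "
            f"{len(self.instantiations)} instantiations, "
            f"{len(self.relations)} relations>"
        )
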