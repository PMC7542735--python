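"""Symbiosis taxonomy and the differentia-driven interaction classifier.

The taxonomy follows the realism-based treatment of symbiosis in the de
Bary sense: a symbiosis is an interspecies interaction between two or
more organisms in intimate association, independently of outcome.  Three
characteristics differentiate its subtypes:

* the outcome of the interaction for each organism (benefit, harm or
  neutral, with harm optionally fatal),
* the relative location of the organisms (ectosymbiosis vs.
  endosymbiosis), and
* whether the interaction is necessary for a biological function of a
  beneficiary (obligatory) or merely advantageous (facultative).

The symbiosis branch — the root class plus all of its descendants —
contains exactly 34 classes.  Three classes are re-used from the Gene
Ontology (``GO:0044419`` *interspecies interaction between organisms*,
``GO:0051704`` *multi-organism process* and ``GO:0051705``
*multi-organism behavior*); two auxiliary outcome-process classes
(*bodily harm*, *bodily benefit*) sit outside the branch.

Each minted class carries a machine-readable :class:`Differentia` — the
partial interaction profile that distinguishes it from its parent — and
:func:`classify_interaction` maps a concrete
:class:`InteractionProfile` to the most specific class label(s) by
pairwise reduction over the participants.
"""

from __future__ import annotations

import enum
import functools
import itertools
import json
import warnings
from dataclasses import dataclass, field

import networkx as nx

from .errors import (
    AmbiguousProfileError,
    NeutralismContradictionError,
    SymbioError,
    UnknownLabelError,
    UnsupportedCombinationError,
)

__all__ = [
    "OutcomeValue",
    "Outcome",
    "SpatialMode",
    "ContactMode",
    "Necessity",
    "InteractionProfile",
    "Differentia",
    "SymbiosisClass",
    "TaxonomyGraph",
    "build_taxonomy",
    "is_subclass",
    "classify_interaction",
    "differentia_of",
    "resolve_label",
    "enumerate_profile_space",
    "SYNONYMS",
]


# --------------------------------------------------------------------------
# profile vocabulary
# --------------------------------------------------------------------------

class OutcomeValue(str, enum.Enum):
    """Outcome of an interaction for one participant: '+', '-' or '0'."""

    BENEFIT = "benefit"
    HARM = "harm"
    NEUTRAL = "neutral"

    @property
    def symbol(self) -> str:
        return {"benefit": "+", "harm": "-", "neutral": "0"}[self.value]

    @classmethod
    def from_symbol(cls, symbol: str) -> "OutcomeValue":
        table = {"+": cls.BENEFIT, "-": cls.HARM, "0": cls.NEUTRAL}
        try:
            return table[symbol.strip()]
        except KeyError:
            raise ValueError(f"unknown outcome symbol {symbol!r}") from None


@dataclass(frozen=True)
class Outcome:
    """Outcome for one participant.

    ``fatal`` is meaningful only for harm; ``None`` means "harm asserted
    without fatality information" and is treated as non-fatal at
    classification time (with a warning), since sibling classes split
    only on fatality.
    """

    value: OutcomeValue
    fatal: bool | None = None

    def __post_init__(self) -> None:
        if self.fatal and self.value is not OutcomeValue.HARM:
            raise ValueError("fatal=True requires value=harm")


class SpatialMode(str, enum.Enum):
    """Relative location of participants throughout the interaction."""

    ECTO = "ecto"
    ENDO = "endo"
    UNSPECIFIED = "unspecified"


class ContactMode(str, enum.Enum):
    """Degree of physical contact; consulted only for ectosymbioses."""

    INTIMATE_PERSISTENT = "intimate_persistent"
    TRANSIENT = "transient"
    UNSPECIFIED = "unspecified"


class Necessity(str, enum.Enum):
    """Whether the interaction is required for a biological function of
    a beneficiary (obligate), merely advantageous (facultative), or
    unannotated."""

    OBLIGATE = "obligate"
    FACULTATIVE = "facultative"
    NONE = "none"


@dataclass(frozen=True)
class InteractionProfile:
    """Classifier input: one outcome per participant plus modifiers.

    Parameters
    ----------
    outcomes
        One :class:`Outcome` per participant, length >= 2.
    spatial_mode
        ``ecto`` (participants remain physically external) or ``endo``
        (one organism located within another extended organism).
    contact_mode
        Intimate-persistent vs. transient contact; consulted only when
        the pairwise pattern requires it (ecto +/-).
    necessity
        Applied to the beneficiary side when refining a class to its
        obligatory/facultative child.
    participant_taxa
        Optional NCBI taxon identifiers, one per participant.
    """

    outcomes: tuple[Outcome, ...]
    spatial_mode: SpatialMode = SpatialMode.UNSPECIFIED
    contact_mode: ContactMode = ContactMode.UNSPECIFIED
    necessity: Necessity = Necessity.NONE
    participant_taxa: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "outcomes", tuple(self.outcomes))
        if len(self.outcomes) < 2:
            raise ValueError("an interaction profile needs >= 2 participants")
        if self.participant_taxa is not None:
            object.__setattr__(
                self, "participant_taxa", tuple(self.participant_taxa)
            )
            if len(self.participant_taxa) != len(self.outcomes):
                raise ValueError("one taxon per participant expected")

    @classmethod
    def from_symbols(
        cls,
        symbols: str,
        *,
        fatal: bool | None = None,
        spatial: str = "unspecified",
        contact: str = "unspecified",
        necessity: str = "none",
        taxa: tuple[str, ...] | None = None,
    ) -> "InteractionProfile":
        """Build a profile from a compact symbol string such as ``"+,-"``.

        ``fatal`` applies to every harmed participant.
        """
        outcomes = []
        for sym in symbols.split(","):
            value = OutcomeValue.from_symbol(sym)
            outcomes.append(
                Outcome(value, fatal if value is OutcomeValue.HARM else None)
            )
        return cls(
            outcomes=tuple(outcomes),
            spatial_mode=SpatialMode(spatial),
            contact_mode=ContactMode(contact),
            necessity=Necessity(necessity),
            participant_taxa=taxa,
        )


# --------------------------------------------------------------------------
# differentia
# --------------------------------------------------------------------------

_SYMBOL_ORDER = {"+": 0, "-": 1, "0": 2}


def _canonical_pattern(a: str, b: str) -> tuple[str, str]:
    return tuple(sorted((a, b), key=_SYMBOL_ORDER.__getitem__))  # type: ignore[return-value]


@dataclass(frozen=True)
class Differentia:
    """Partial interaction-profile constraints attached to a class.

    Every field is optional; ``None`` means "unconstrained".  A pairwise
    profile satisfies a differentia iff it matches every constrained
    field.  The root class *symbiosis* carries the empty differentia
    (no constraints beyond two or more organisms of different species).
    """

    pattern: tuple[str, str] | None = None
    spatial: SpatialMode | None = None
    contact: ContactMode | None = None
    fatal: bool | None = None
    necessity: Necessity | None = None

    def satisfied_by_pair(
        self,
        pattern: tuple[str, str],
        spatial: SpatialMode,
        contact: ContactMode,
        fatal: bool | None,
        necessity: Necessity,
    ) -> bool:
        if self.pattern is not None and _canonical_pattern(*pattern) != self.pattern:
            return False
        if self.spatial is not None and spatial is not self.spatial:
            return False
        if self.contact is not None and contact is not self.contact:
            return False
        if self.fatal is not None and bool(fatal) is not self.fatal:
            return False
        if self.necessity is not None and necessity is not self.necessity:
            return False
        return True

    def to_dict(self) -> dict:
        out: dict = {}
        if self.pattern is not None:
            out["pattern"] = list(self.pattern)
        if self.spatial is not None:
            out["spatial"] = self.spatial.value
        if self.contact is not None:
            out["contact"] = self.contact.value
        if self.fatal is not None:
            out["fatal"] = self.fatal
        if self.necessity is not None:
            out["necessity"] = self.necessity.value
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "Differentia":
        return cls(
            pattern=tuple(data["pattern"]) if "pattern" in data else None,
            spatial=SpatialMode(data["spatial"]) if "spatial" in data else None,
            contact=ContactMode(data["contact"]) if "contact" in data else None,
            fatal=data.get("fatal"),
            necessity=Necessity(data["necessity"]) if "necessity" in data else None,
        )


# --------------------------------------------------------------------------
# classes and graph
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SymbiosisClass:
    """One taxonomy node.

    ``provenance`` is ``"minted"`` for classes created here (each with a
    non-empty verbatim textual definition) and ``"imported"`` for the
    three GO classes re-used with their published CURIEs.
    """

    id: str
    label: str
    definition: str
    parents: tuple[str, ...] = ()
    differentia: Differentia | None = None
    provenance: str = "minted"

    def __post_init__(self) -> None:
        object.__setattr__(self, "parents", tuple(self.parents))
        if self.provenance == "minted" and not self.definition:
            raise ValueError(f"minted class {self.label!r} lacks a definition")

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "label": self.label,
            "definition": self.definition,
            "parents": list(self.parents),
            "differentia": (
                None if self.differentia is None else self.differentia.to_dict()
            ),
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SymbiosisClass":
        return cls(
            id=data["id"],
            label=data["label"],
            definition=data["definition"],
            parents=tuple(data["parents"]),
            differentia=(
                None
                if data.get("differentia") is None
                else Differentia.from_dict(data["differentia"])
            ),
            provenance=data["provenance"],
        )


ROOT_LABEL = "symbiosis"
ECTO_LABEL = "ectosymbiosis"
ENDO_LABEL = "endosymbiosis"

#: The 8 classes that take obligatory/facultative children.
REFINEABLE = (
    "ectosymbiotic parasitism",
    "ectosymbiotic parasitoidism",
    "ectosymbiotic commensalism",
    "ectosymbiotic mutualism",
    "endosymbiotic parasitism",
    "endosymbiotic parasitoidism",
    "endosymbiotic commensalism",
    "endosymbiotic mutualism",
)


class TaxonomyGraph:
    """The class hierarchy: nodes plus is-a edges (child, parent).

    Structural subsumption only — ancestor queries walk the parent
    edges; no description-logic reasoner is involved.
    """

    def __init__(self, classes: list[SymbiosisClass]):
        self._by_id: dict[str, SymbiosisClass] = {}
        self._by_label: dict[str, SymbiosisClass] = {}
        self._dag = nx.DiGraph()
        for cl in classes:
            if cl.id in self._by_id or cl.label in self._by_label:
                raise ValueError(f"duplicate class {cl.id} / {cl.label!r}")
            self._by_id[cl.id] = cl
            self._by_label[cl.label] = cl
            self._dag.add_node(cl.id)
        for cl in classes:
            for parent in cl.parents:
                if parent not in self._by_id:
                    raise ValueError(f"{cl.id}: unknown parent {parent}")
                self._dag.add_edge(cl.id, parent)  # child -> parent
        if not nx.is_directed_acyclic_graph(self._dag):
            raise ValueError("is-a graph contains a cycle")

    # -- basic access -----------------------------------------------------

    @property
    def classes(self) -> list[SymbiosisClass]:
        """All classes, sorted by CURIE for deterministic iteration."""
        return [self._by_id[i] for i in sorted(self._by_id)]

    @property
    def edges(self) -> set[tuple[str, str]]:
        """(child, parent) CURIE pairs."""
        return set(self._dag.edges())

    def get(self, label_or_id: str) -> SymbiosisClass:
        if label_or_id in self._by_id:
            return self._by_id[label_or_id]
        label = resolve_label(label_or_id)
        if label is not None and label in self._by_label:
            return self._by_label[label]
        raise UnknownLabelError(label_or_id)

    def __contains__(self, label_or_id: str) -> bool:
        try:
            self.get(label_or_id)
            return True
        except UnknownLabelError:
            return False

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TaxonomyGraph):
            return NotImplemented
        return set(self._by_id.values()) == set(other._by_id.values())

    def __hash__(self) -> int:  # pragma: no cover
        return hash(frozenset(self._by_id))

    # -- hierarchy queries ------------------------------------------------

    def ancestors(self, label: str) -> list[str]:
        """Labels of all strict ancestors, nearest first."""
        cl = self.get(label)
        order = list(nx.topological_sort(self._dag.subgraph(
            nx.descendants(self._dag, cl.id))))
        # child->parent edges: nx.descendants along edges == ancestors
        return [self._by_id[i].label for i in order]

    def descendants(self, label: str) -> set[str]:
        cl = self.get(label)
        return {
            self._by_id[i].label for i in nx.ancestors(self._dag, cl.id)
        }

    def branch(self, label: str = ROOT_LABEL) -> set[str]:
        """Labels of ``label`` plus all of its descendants."""
        return {self.get(label).label} | self.descendants(label)

    def is_subclass(self, child_label: str, ancestor_label: str) -> bool:
        """Reflexive is-a reachability between two labels."""
        child = self.get(child_label)
        ancestor = self.get(ancestor_label)
        return child.id == ancestor.id or nx.has_path(
            self._dag, child.id, ancestor.id
        )

    def minted(self) -> list[SymbiosisClass]:
        return [c for c in self.classes if c.provenance == "minted"]

    def imported(self) -> list[SymbiosisClass]:
        return [c for c in self.classes if c.provenance == "imported"]

    def differentia_of(self, label: str) -> Differentia:
        """The constraint set distinguishing a minted class.

        Any profile satisfying it (and the ancestors' constraints, which
        it subsumes by construction) classifies to this label or to a
        descendant.
        """
        cl = self.get(label)
        if cl.provenance != "minted" or cl.differentia is None:
            raise UnknownLabelError(f"{label!r} has no differentia")
        return cl.differentia

    def classify(self, profile: InteractionProfile) -> list[str]:
        return classify_interaction(profile, taxonomy=self)

    def to_json_dict(self) -> dict:
        """Stable JSON dump of the class table (consumed by the exporter)."""
        return {
            "kind": "taxonomy",
            "classes": [c.to_dict() for c in self.classes],
        }

    @classmethod
    def from_json_dict(cls, data: dict) -> "TaxonomyGraph":
        return cls([SymbiosisClass.from_dict(d) for d in data["classes"]])


# --------------------------------------------------------------------------
# construction
# --------------------------------------------------------------------------

_GO_CLASSES = [
    SymbiosisClass(
        id="GO:0051704",
        label="multi-organism process",
        definition="",
        parents=(),
        provenance="imported",
    ),
    SymbiosisClass(
        id="GO:0044419",
        label="interspecies interaction between organisms",
        definition=(
            "Any process in which an organism has an effect on an organism "
            "of a different species."
        ),
        parents=("GO:0051704",),
        provenance="imported",
    ),
    SymbiosisClass(
        id="GO:0051705",
        label="multi-organism behavior",
        definition=(
            "Any process in which an organism has a behavioral effect on "
            "another organism of the same or different species."
        ),
        parents=("GO:0051704",),
        provenance="imported",
    ),
]

_ROOT_DEFINITION = (
    "An interspecies interaction between two or more organisms in intimate "
    "association."
)

_ECTO_DEFINITION = (
    "A symbiosis where the organisms that are interacting remain physically "
    "external to one another."
)

_ENDO_DEFINITION = (
    "A symbiosis where one organism is physically contained within another "
    "extended organism."
)

_BODILY_HARM_DEFINITION = (
    "A process consisting of a change in the structure integrity of some "
    "anatomical structure that weakens or strengthens some homeostasis "
    "disposition or function inhering in that anatomical structure, such "
    "that the strength of the disposition (function) deviates outside of "
    "the range that is necessary to maintain in homeostatic range those "
    "bodily qualities that its realization influences."
)

_BODILY_BENEFIT_DEFINITION = (
    "A process that facilitates the realization of one or more normal "
    "homeostasis dispositions borne by an organism and/or one or more "
    "causally relatively isolated parts of the organism."
)

# The 31 subtype rows, in printed order: (label, definition, parent label,
# differentia).  Definitions are verbatim.
_SUBTYPE_ROWS: list[tuple[str, str, str, Differentia]] = [
    (
        "agonism",
        "An ectosymbiosis that results in harm to one of the participating "
        "organisms and benefit to another participating organism",
        ECTO_LABEL,
        Differentia(pattern=("+", "-"), spatial=SpatialMode.ECTO),
    ),
    (
        "intimate agonism",
        "An agonism where the participating organisms, although physically "
        "external to one another, nevertheless have close and persistent "
        "physical contact for most or all of the interaction",
        "agonism",
        Differentia(
            pattern=("+", "-"),
            spatial=SpatialMode.ECTO,
            contact=ContactMode.INTIMATE_PERSISTENT,
        ),
    ),
    (
        "ectosymbiotic parasitism",
        "An intimate agonism in which the harm is not fatal to the host",
        "intimate agonism",
        Differentia(
            pattern=("+", "-"),
            spatial=SpatialMode.ECTO,
            contact=ContactMode.INTIMATE_PERSISTENT,
            fatal=False,
        ),
    ),
    (
        "ectosymbiotic parasitoidism",
        "An intimate agonism in which the harm is fatal to the host",
        "intimate agonism",
        Differentia(
            pattern=("+", "-"),
            spatial=SpatialMode.ECTO,
            contact=ContactMode.INTIMATE_PERSISTENT,
            fatal=True,
        ),
    ),
    (
        "transient agonism",
        "An agonism where the participating organisms maintain significant "
        "physical separation from one another through most or all of the "
        "interaction",
        "agonism",
        Differentia(
            pattern=("+", "-"),
            spatial=SpatialMode.ECTO,
            contact=ContactMode.TRANSIENT,
        ),
    ),
    (
        "grazing",
        "A transient agonism in which the harm is not fatal",
        "transient agonism",
        Differentia(
            pattern=("+", "-"),
            spatial=SpatialMode.ECTO,
            contact=ContactMode.TRANSIENT,
            fatal=False,
        ),
    ),
    (
        "predation",
        "A transient agonism in which the harm is fatal",
        "transient agonism",
        Differentia(
            pattern=("+", "-"),
            spatial=SpatialMode.ECTO,
            contact=ContactMode.TRANSIENT,
            fatal=True,
        ),
    ),
    (
        "amensalism",
        "An ectosymbiosis that results in harm to one of the participating "
        "organisms but neither harms nor benefits the other participating "
        "organisms",
        ECTO_LABEL,
        Differentia(pattern=("-", "0"), spatial=SpatialMode.ECTO),
    ),
    (
        "antagonism",
        "An ectosymbiosis that results in harm to all participating "
        "organisms",
        ECTO_LABEL,
        Differentia(pattern=("-", "-"), spatial=SpatialMode.ECTO),
    ),
    (
        "ectosymbiotic commensalism",
        "An ectosymbiosis that results in benefit to one participating "
        "organism and neither harm nor benefit to the other participating "
        "organisms",
        ECTO_LABEL,
        Differentia(pattern=("+", "0"), spatial=SpatialMode.ECTO),
    ),
    (
        "ectosymbiotic mutualism",
        "An ectosymbiosis that results in benefit to all participating "
        "organisms",
        ECTO_LABEL,
        Differentia(pattern=("+", "+"), spatial=SpatialMode.ECTO),
    ),
    (
        "endosymbiotic parasitism",
        "An endosymbiosis that results in benefit to the parasite and harm "
        "to the host",
        ENDO_LABEL,
        Differentia(pattern=("+", "-"), spatial=SpatialMode.ENDO, fatal=False),
    ),
    (
        "endosymbiotic parasitoidism",
        "An endosymbiosis that results in benefit to the parasitoid and "
        "death to the host",
        ENDO_LABEL,
        Differentia(pattern=("+", "-"), spatial=SpatialMode.ENDO, fatal=True),
    ),
    (
        "endosymbiotic commensalism",
        "An endosymbiosis that results in benefit to one organism and "
        "neither harm nor benefit to the other participating organisms",
        ENDO_LABEL,
        Differentia(pattern=("+", "0"), spatial=SpatialMode.ENDO),
    ),
    (
        "endosymbiotic mutualism",
        "An endosymbiosis that results in benefit to all participating "
        "organisms",
        ENDO_LABEL,
        Differentia(pattern=("+", "+"), spatial=SpatialMode.ENDO),
    ),
]

_OBLIGATORY_DEFS = {
    "ectosymbiotic parasitism": (
        "An ectosymbiotic parasitism that realizes a biological function "
        "that inheres in some proper part of the parasite"
    ),
    "ectosymbiotic parasitoidism": (
        "An ectosymbiotic parasitoidism that realizes a biological function "
        "that inheres in some proper part of the parasitoid"
    ),
    "ectosymbiotic commensalism": (
        "An ectosymbiotic commensalism that realizes a biological function "
        "that inheres in some proper part of the commensal organism that "
        "benefits"
    ),
    "ectosymbiotic mutualism": (
        "An ectosymbiotic mutualism that realizes a biological function "
        "that inheres in some proper part of at least one of the organisms "
        "participating"
    ),
    "endosymbiotic parasitism": (
        "An endosymbiotic parasitism that realizes a biological function "
        "that inheres in some proper part of the parasite"
    ),
    "endosymbiotic parasitoidism": (
        "An endosymbiotic parasitoidism that realizes a biological function "
        "that inheres in some proper part of the parasitoid"
    ),
    "endosymbiotic commensalism": (
        "An endosymbiotic commensalism that realizes a biological function "
        "that inheres in some proper part of the commensal organism that "
        "benefits"
    ),
    "endosymbiotic mutualism": (
        "An endosymbiotic mutualism that realizes a biological function "
        "that inheres in some proper part of at least one of the organisms "
        "participating"
    ),
}

_FACULTATIVE_ROLE = {
    "parasitism": "parasite",
    "parasitoidism": "parasitoid",
    "commensalism": "commensal",
    "mutualism": "mutualist",
}


def _facultative_definition(base: str) -> str:
    family = base.split()[-1]
    return (
        f"An {base} that realizes some facultative "
        f"{_FACULTATIVE_ROLE[family]} role inhering in an organism that is "
        f"also realized by a bodily benefit to that organism"
    )


@functools.lru_cache(maxsize=1)
def build_taxonomy() -> TaxonomyGraph:
    """Build the full class hierarchy.

    The symbiosis branch (root + descendants) contains exactly 34
    classes: the root, the ecto/endo location partition, the 15 base
    subtypes, and obligatory/facultative refinements of the 8
    parasitism/parasitoidism/commensalism/mutualism classes.  Local
    CURIEs (``SYMB:``) are minted deterministically in row order; the
    four classes with published Apollo-SV identifiers keep them.
    """
    classes: list[SymbiosisClass] = list(_GO_CLASSES)
    label_to_id: dict[str, str] = {c.label: c.id for c in classes}
    counter = itertools.count(1)

    def mint(label, definition, parents, differentia, curie=None):
        cid = curie if curie is not None else f"SYMB:{next(counter):04d}"
        cl = SymbiosisClass(
            id=cid,
            label=label,
            definition=definition,
            parents=tuple(label_to_id[p] for p in parents),
            differentia=differentia,
            provenance="minted",
        )
        classes.append(cl)
        label_to_id[label] = cid
        return cl

    mint(ROOT_LABEL, _ROOT_DEFINITION, ("interspecies interaction between organisms",), Differentia())
    mint(ECTO_LABEL, _ECTO_DEFINITION, (ROOT_LABEL,),
         Differentia(spatial=SpatialMode.ECTO), curie="APOLLO_SV:00000337")
    mint(ENDO_LABEL, _ENDO_DEFINITION, (ROOT_LABEL,),
         Differentia(spatial=SpatialMode.ENDO), curie="APOLLO_SV:00000354")

    for label, definition, parent, diff in _SUBTYPE_ROWS:
        mint(label, definition, (parent,), diff)

    for base in REFINEABLE:
        base_diff = next(
            d for (lbl, _d, _p, d) in _SUBTYPE_ROWS if lbl == base
        )
        mint(
            f"obligatory {base}",
            _OBLIGATORY_DEFS[base],
            (base,),
            Differentia(
                pattern=base_diff.pattern,
                spatial=base_diff.spatial,
                contact=base_diff.contact,
                fatal=base_diff.fatal,
                necessity=Necessity.OBLIGATE,
            ),
        )
    for base in REFINEABLE:
        base_diff = next(
            d for (lbl, _d, _p, d) in _SUBTYPE_ROWS if lbl == base
        )
        mint(
            f"facultative {base}",
            _facultative_definition(base),
            (base,),
            Differentia(
                pattern=base_diff.pattern,
                spatial=base_diff.spatial,
                contact=base_diff.contact,
                fatal=base_diff.fatal,
                necessity=Necessity.FACULTATIVE,
            ),
        )

    # auxiliary outcome-process classes, outside the symbiosis branch
    mint("bodily harm", _BODILY_HARM_DEFINITION, (), None,
         curie="APOLLO_SV:00000371")
    mint("bodily benefit", _BODILY_BENEFIT_DEFINITION, (), None,
         curie="APOLLO_SV:00000372")

    return TaxonomyGraph(classes)


# --------------------------------------------------------------------------
# label synonyms
# --------------------------------------------------------------------------

def _build_synonyms() -> dict[str, str]:
    syn: dict[str, str] = {}
    for family in ("parasitism", "parasitoidism", "commensalism", "mutualism"):
        for side, prefix in (("ecto", "ectosymbiotic"), ("endo", "endosymbiotic")):
            canonical = f"{prefix} {family}"
            syn[f"{side}{family}"] = canonical
            for mode in ("obligatory", "facultative"):
                syn[f"{mode} {side}{family}"] = f"{mode} {canonical}"
    return syn


#: Contracted labels used in the worked scenarios ("obligatory
#: endoparasitism", "ectoparasitism", ...) mapped to canonical labels.
SYNONYMS: dict[str, str] = _build_synonyms()


def resolve_label(label: str) -> str | None:
    """Resolve a canonical or contracted label; ``None`` if neither."""
    g = build_taxonomy()
    if label in g._by_label:
        return label
    return SYNONYMS.get(label)


# --------------------------------------------------------------------------
# classification
# --------------------------------------------------------------------------

def _effective_fatal(outcome: Outcome) -> bool:
    if outcome.value is not OutcomeValue.HARM:
        return False
    if outcome.fatal is None:
        warnings.warn(
            "harm asserted without fatality information; assuming non-fatal",
            stacklevel=4,
        )
        return False
    return outcome.fatal


def _classify_pair(
    a: Outcome,
    b: Outcome,
    spatial: SpatialMode,
    contact: ContactMode,
    necessity: Necessity,
) -> str:
    """Most specific label for one unordered participant pair."""
    pattern = _canonical_pattern(a.value.symbol, b.value.symbol)
    if pattern == ("0", "0"):
        raise NeutralismContradictionError(
            "an interaction affecting none of its participants is "
            "self-contradictory (no neutralism class exists)"
        )
    if spatial is SpatialMode.UNSPECIFIED:
        raise AmbiguousProfileError(
            "spatial mode (ecto/endo) is required to classify"
        )
    harmed = a if a.value is OutcomeValue.HARM else b
    # fatality only differentiates siblings within the +/- family
    fatal = _effective_fatal(harmed) if pattern == ("+", "-") else False

    if spatial is SpatialMode.ENDO:
        if pattern == ("+", "+"):
            label = "endosymbiotic mutualism"
        elif pattern == ("+", "0"):
            label = "endosymbiotic commensalism"
        elif pattern == ("+", "-"):
            label = (
                "endosymbiotic parasitoidism"
                if fatal
                else "endosymbiotic parasitism"
            )
        else:  # ("-","0") or ("-","-")
            raise UnsupportedCombinationError(
                f"endosymbiosis is not defined for the "
                f"{'/'.join(pattern)} pattern (only mutualism, "
                f"commensalism, parasitism and parasitoidism occur "
                f"endosymbiotically)"
            )
    else:  # ECTO
        if pattern == ("+", "+"):
            label = "ectosymbiotic mutualism"
        elif pattern == ("+", "0"):
            label = "ectosymbiotic commensalism"
        elif pattern == ("-", "0"):
            label = "amensalism"
        elif pattern == ("-", "-"):
            label = "antagonism"
        else:  # ("+","-") — the agonism family splits on contact mode
            if contact is ContactMode.INTIMATE_PERSISTENT:
                label = (
                    "ectosymbiotic parasitoidism"
                    if fatal
                    else "ectosymbiotic parasitism"
                )
            elif contact is ContactMode.TRANSIENT:
                label = "predation" if fatal else "grazing"
            else:
                raise AmbiguousProfileError(
                    "contact mode (intimate_persistent/transient) is "
                    "required to classify an ectosymbiotic +/- pattern"
                )

    if label in REFINEABLE and necessity in (
        Necessity.OBLIGATE,
        Necessity.FACULTATIVE,
    ):
        prefix = (
            "obligatory" if necessity is Necessity.OBLIGATE else "facultative"
        )
        label = f"{prefix} {label}"
    return label


def classify_interaction(
    profile: InteractionProfile, taxonomy: TaxonomyGraph | None = None
) -> list[str]:
    """Classify a profile into its most specific subtype label(s).

    Each unordered pair of participants is classified independently and
    the union of pairwise labels is returned (deduplicated, with
    ancestors of other returned labels pruned, sorted by CURIE).  For a
    tripartite profile such as (+, -, 0) this yields both a parasitism
    and a commensalism; pairs whose pattern has no class on the
    requested branch are skipped as long as some pair classifies.

    Raises
    ------
    NeutralismContradictionError
        All-neutral outcome pattern.
    UnsupportedCombinationError
        Harm-only pattern (-/0 or -/-) on the endo branch.
    AmbiguousProfileError
        Spatial mode unspecified, or contact mode required but missing.
    """
    g = taxonomy if taxonomy is not None else build_taxonomy()
    outcomes = profile.outcomes
    labels: list[str] = []
    errors: list[SymbioError] = []
    for a, b in itertools.combinations(outcomes, 2):
        try:
            label = _classify_pair(
                a, b, profile.spatial_mode, profile.contact_mode,
                profile.necessity,
            )
        except SymbioError as exc:
            errors.append(exc)
            continue
        if label not in labels:
            labels.append(label)

    if not labels:
        if all(o.value is OutcomeValue.NEUTRAL for o in outcomes):
            raise NeutralismContradictionError(
                "an interaction affecting none of its participants is "
                "self-contradictory (no neutralism class exists)"
            )
        raise errors[0]

    # keep only the most specific labels
    pruned = [
        lab
        for lab in labels
        if not any(
            other != lab and g.is_subclass(other, lab) for other in labels
        )
    ]
    return sorted(pruned, key=lambda lab: g.get(lab).id)


def is_subclass(child_label: str, ancestor_label: str) -> bool:
    """Reflexive is-a reachability in the default taxonomy."""
    return build_taxonomy().is_subclass(child_label, ancestor_label)


def differentia_of(label: str) -> Differentia:
    """Differentia of a minted class in the default taxonomy."""
    return build_taxonomy().differentia_of(label)


# --------------------------------------------------------------------------
# finite profile space (for exhaustiveness checks)
# --------------------------------------------------------------------------

def enumerate_profile_space() -> list[InteractionProfile]:
    """Enumerate the discrete pairwise profile space.

    All unordered outcome-value pairs (including the contradictory
    all-neutral one) crossed with {ecto, endo} spatial modes, the three
    contact modes, the three necessity values and fatality in
    {True, False, None} for harmed participants.
    """
    value_pairs = list(
        itertools.combinations_with_replacement(
            (OutcomeValue.BENEFIT, OutcomeValue.HARM, OutcomeValue.NEUTRAL), 2
        )
    )
    profiles = []
    for (va, vb), spatial, contact, necessity in itertools.product(
        value_pairs,
        (SpatialMode.ECTO, SpatialMode.ENDO),
        tuple(ContactMode),
        tuple(Necessity),
    ):
        fatal_options = (
            (True, False, None)
            if OutcomeValue.HARM in (va, vb)
            else (None,)
        )
        for fatal in fatal_options:
            outcomes = tuple(
                Outcome(v, fatal if v is OutcomeValue.HARM else None)
                for v in (va, vb)
            )
            profiles.append(
                InteractionProfile(
                    outcomes=outcomes,
                    spatial_mode=spatial,
                    contact_mode=contact,
                    necessity=necessity,
                )
            )
    return profiles
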