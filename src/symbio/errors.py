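"""Exception hierarchy shared across the package."""


class SymbioError(Exception):
    """Base class for all domain errors raised by this package."""


class UnknownLabelError(SymbioError, KeyError):
    """A class label (or synonym) does not resolve to any taxonomy class."""


class NeutralismContradictionError(SymbioError):
    """Raised for an all-neutral outcome pattern.

    A symbiotic interaction is a process in which the participating
    organisms undergo change; asserting that none of them are affected
    is self-contradictory, so no "neutralism" class exists and profiles
    with this pattern are rejected rather than classified.
    """


class UnsupportedCombinationError(SymbioError):
    """Outcome pattern has no class on the requested location branch.

    Endosymbiosis is defined only for mutualism, commensalism,
    parasitism and parasitoidism; harm-only patterns (-/0, -/-) exist
    only on the ectosymbiotic branch.
    """


class AmbiguousProfileError(SymbioError):
    """The profile underdetermines the class (e.g. missing contact mode)."""


class IntegrityError(SymbioError):
    """A tuple references an identifier not declared in the store."""


class VocabularyError(SymbioError):
    """A relation name outside the closed referent-tracking vocabulary."""


class SortError(SymbioError):
    """Subject/object sorts incompatible with the relation."""


class FaultNotApplicableError(SymbioError):
    """The requested fault cannot be injected into the given store."""


class ParseError(SymbioError):
    """An export document could not be parsed back into an object."""
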