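# Methods

## The taxonomy and its differentia

The class hierarchy is fixed: a root class *symbiosis* (subclass of the
imported GO:0044419 *interspecies interaction between organisms*, itself
under GO:0051704 *multi-organism process*), partitioned structurally by
location into *ectosymbiosis* and *endosymbiosis*, then by outcome
pattern, contact intimacy and fatality, and finally by necessity into
obligatory/facultative children of the eight
parasitism/parasitoidism/commensalism/mutualism classes. The branch
census is 1 (root) + 2 (location) + 5 (ecto outcome families) + 2
(agonism intimacy split) + 2 + 2 (fatality splits) + 4 (endo families)
+ 16 (necessity refinements) = 34 classes. Two auxiliary
outcome-process classes, *bodily harm* and *bodily benefit*, are minted
outside the branch; they annotate what `+`/`−` mean physiologically
(departure from vs. support of homeostasis) but are not simulated.

Each minted class carries a *differentia*: the partial profile
constraint (pattern, spatial mode, contact mode, fatality, necessity)
that separates it from its parent. A child's differentia always
entails its parent's, which is what makes the brute-force oracle in the
tests possible: for every label returned by the classifier, the profile
must satisfy the differentia of every ancestor.

Identifier policy: the four classes with published Apollo-SV CURIEs
keep them (`APOLLO_SV:00000337` ectosymbiosis, `00000354`
endosymbiosis, `00000371` bodily harm, `00000372` bodily benefit); the
three GO classes are imported references; all other classes receive
deterministic local CURIEs `SYMB:0001…` in table-row order so exports
are reproducible. Contracted labels used in the worked scenarios
("obligatory endoparasitism", "ectoparasitism") resolve through a fixed
synonym table generated from the
`{obligatory,facultative} × {ecto,endo} × family` grid.

## Classification

`classify_interaction` reduces a profile to unordered participant
pairs and maps each pair's pattern through the family table, splitting
ecto `+/−` on contact mode (intimate-persistent → parasitism/
parasitoidism; transient → grazing/predation) and `+/−` generally on
fatality. Design choices where the source material is open:

* **Totality.** Over the discrete space {5 patterns + 0/0} × {ecto,
  endo} × contact × necessity × fatality, the classifier either returns
  ≥ 1 label or raises one of exactly three defined errors: the
  neutralism contradiction (all-neutral), unsupported combination
  (endo `−/0`, `−/−`), or ambiguity (spatial mode unspecified, or
  contact mode missing when an ecto `+/−` pattern needs it). An
  unspecified spatial mode is treated as ambiguity rather than guessed.
* **Multi-party profiles.** The union of pairwise labels is returned,
  pruned to the most specific antichain. Pairs that would individually
  error are skipped whenever at least one pair classifies — this is
  what makes a benefit/harm/neutral triple "both a commensalism and a
  parasitism" instead of an error about its harm/neutral pair. Errors
  surface only when *no* pair classifies.
* **Fatality default.** Harm asserted without fatality information is
  treated as non-fatal, with a `UserWarning`, since fatality only
  separates sibling classes.
* **Necessity.** A single profile-level value applied to the
  beneficiary side; when both sides of a mutualism are obligate the one
  "obligatory …" class is returned once. "Exclusively realizes" in the
  obligatory definition is not decidable from profile data and is
  represented by the necessity flag, not a modal check.

## Referent tracking

Stores have set semantics and referential integrity: identifiers are
declared before use, re-assertion is a no-op, and minting returns
`IUI-(1 + max existing index)` (a configurable start index lets a
fixture continue another's numbering). Temporal regions carry no
numeric endpoints — none are available — so ordering is purely
relational: `precedes` must be a strict partial order and occurrent
parthood acyclic (`proper-part-of-occurrent` irreflexive, plain
parthood reflexive-tolerant, proper implying plain in the closure).
`t_max` denotes "holds at all times" and participates in no parthood
edges. `precedes`, `part-of-occurrent` and `proper-part-of-occurrent`
accept either two particulars or two regions, because the source
tables assert both (processes precede processes; intervals are parts
of intervals). Taxon identifiers and per-participant outcome symbols
are store metadata attached to IUIs, since the tables convey species
through entity descriptions and outcomes through the interaction's
type.

## Validation

Eight rules with severities {error, warning, info} — a convention of
this artifact, chosen so that *contradictions and closed-count
violations* are errors while *open-world absences* are warnings:

* **R1 MIN_PARTICIPANTS** (threshold 2): an interaction with exactly
  one asserted participant is an error; one with *none* is a warning,
  because absence of assertions is not evidence of a one-participant
  interaction. This split lets the verbatim scenario transcriptions —
  one of which never asserts participation for its interaction —
  validate clean at error level while still failing genuinely
  malformed stores.
* **R2 INTERSPECIES**: all-same-taxid participants are an error;
  participants without taxa are skipped with an info note.
* **R3/R4 location**: an endosymbiosis whose participants are asserted
  spatially disjoint (or an ectosymbiosis with `located-in`) is an
  error; a merely missing location tuple is a warning.
* **R5 temporal parthood** and **R8 intimacy evidence** are
  warning/info only. **R6** (precedence order) and **R7** (all-neutral
  annotation) are errors.

`validate` is a pure function; findings are sorted by (rule id,
subject) and byte-stable across runs.

## Scenario fixtures and the synthetic generator

The three worked scenarios are transcribed tuple-for-tuple
(4/5, 9/19, 6/11 instantiation/relation tuples). Transcription errata
resolved: the fungal colony in scenario 1 carries taxid 5551 per the
scenario description (the running text once prints 1280, another
organism's taxid); prose references to "the mosquito denoted by IUI-8"
follow the identifier columns (the mosquito is IUI-5); the
endomutualism's interval is t_18 per the tables (the text once says
t_21). Scenario 3's tables assert no `has-participant` tuples for the
endomutualism itself; the verbatim fixture preserves that (an R1
warning), and `build_scenario(3, augmented=True)` adds the
participation and `located-in` tuples for tests that need a fully
axiom-satisfying store.

`generate_synthetic(seed, chain_length, n_symbionts, type_mix)`
emulates the scenario-2 shape: a symbiont aggregate engaging a chain of
host/vector organisms drawn from the scenarios' taxon pool (9606, 7165,
7029 hosts; 5855, 9, 1280, 5551 symbionts), one interaction per host,
consecutive interactions linked by `precedes`. Defaults (chain of 4,
one symbiont, types sampled from obligatory endoparasitism/
endocommensalism) mirror that scenario's four-interaction
parasitism/commensalism alternation. Generated stores assert
participation, occupation, temporal parthood and location tuples and
therefore validate with zero errors. What the generator does *not*
emulate: outcome fluidity over time (one interaction converting into
another), one-to-many host/population interactions, and free-text
entity descriptions — so a clean validation of synthetic stores
exercises the rules' logic, not their robustness to messy real-world
typing. `inject_fault` mutates a copy to guarantee exactly the
targeted rule class fires (dropping a participant tuple, equalizing
taxa, reversing a precedes edge, annotating all-neutral outcomes, or
asserting spatial disjointness inside an endosymbiosis); choices are
made with a seeded RNG over sorted candidate lists, so injection is
deterministic.

## Serialization

Three formats, all deterministic and lossless: JSON (sorted dumps),
Turtle, and a functional-syntax-like line format. In Turtle, classes
are `owl:Class` nodes with label, IAO-style definition annotation and
`rdfs:subClassOf` links; the three equivalence axioms are emitted as
OWL class expressions (the symbiosis axiom with a
`minQualifiedCardinality 2` participant restriction; the behaviour
disjunct referencing GO:0051705) with deterministic blank-node labels.
Each class's differentia additionally travels as a sorted-JSON
annotation literal, so import reconstructs the graph exactly without
parsing class expressions — the expressions are write-only. Relation
tuples are reified with the standard RDF reification vocabulary plus
`holdsAt`/`note` annotations (statement reification rather than named
graphs, for portability); statement URIs are content-hashed so equal
stores serialize to equal bytes. A CSV dialect (one file per tuple
kind, mirroring the printed table columns) is provided for the CLI.

## Problem sizes and numerical choices

Everything here is discrete; there are no tolerances. The exhaustive
classifier checks enumerate the full 216-profile space. The acceptance
script and test suite use 100 synthetic stores per fault kind with
chains of length 3 — large enough that every fault site class (first,
middle, last interaction) is hit across seeds, and the whole battery
runs in about a second. Seeds are reduced modulo 2^20 before deriving
per-store seeds.

## Known limitations

Subsumption is structural, not DL reasoning: the exported OWL axioms
are faithful renderings but are never fed to a reasoner, and the
description-logic limitation noted in the source analysis (no variables
to say the harmed organism differs from the benefited one) applies to
the exports. Intimacy is taken as given input (`contact_mode`), not
inferred from contact or behaviour assertions — the validator's R8 only
advises. Outcome annotations on stores are flat symbol tuples, not
time-indexed, so a commensalism-turned-parasitism is represented as two
interaction particulars, never as one particular with changing
outcomes.
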