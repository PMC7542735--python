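# symbio

Realism-based representation of symbiotic interactions: a 34-class
taxonomy of symbiosis subtypes with a differentia-driven classifier, an
instance-level (referent-tracking) tuple store, a rule-based
consistency validator, and deterministic OWL/RDF export.

## The problem

From vector-borne disease to the gut microbiome, interactions between
organisms of different species shape human health, and the type of
interaction is fluid: a *Staphylococcus aureus* colony may live
commensally on a host's skin for years and then turn parasitic.
Capturing such data requires two things most terminologies get wrong:

1. **A consistent subtype taxonomy.** Following the de Bary consensus,
   *symbiosis* is an interspecies interaction between two or more
   organisms in intimate association, **independently of outcome** —
   parasitism is as symbiotic as mutualism. Prominent resources define
   it circularly, restrict it to mutualism, or place it at the species
   level.
2. **Instance-level assertions.** Interactions occur between individual
   organisms, not between species. The same individual *Plasmodium
   vivax* aggregate is an endoparasite of a human and an endocommensal
   of a mosquito; only instance-level ("referent tracking") records can
   say so.

`symbio` is aimed at ontologists and infectious-disease / ecology
informaticians who need to encode, check and exchange such records.

## The model

Subtypes of symbiosis are differentiated by three characteristics:

* **outcome** per organism — benefit (`+`), harm (`−`), neutral (`0`),
  with harm optionally fatal;
* **location** — *ectosymbiosis* (participants physically external to
  one another) vs. *endosymbiosis* (one organism located within another
  extended organism);
* **necessity** — *obligatory* (the interaction realizes a biological
  function of an organism) vs. *facultative* (merely advantageous,
  realizing a role).

Pairwise outcome patterns map to families: `+/+` mutualism, `+/0`
commensalism, `+/−` agonism (splitting on contact intimacy into
parasitism/parasitoidism vs. grazing/predation, and on fatality within
each), `−/0` amensalism, `−/−` antagonism. The harm-only patterns exist
only ectosymbiotically. The root plus its descendants total 34 classes;
an all-neutral `0/0` pattern ("neutralism") is a logical contradiction —
a process of change that changes none of its participants — and is
rejected rather than classified. Axiomatically, symbiosis is

```
'interspecies interaction between organisms' and
  (('has participant' min 2 ('organism' and ('is bearer of' some 'contact')))
   or ('has occurrent part' some 'multi-organism behavior'
       and ('has participant' min 2 'organism')))
```

with ecto/endo distinguished by `'spatially disjoint from' some
'organism'` vs. `'located in' some 'organism'`. Three classes are
re-used from the Gene Ontology (GO:0044419, GO:0051704, GO:0051705);
two auxiliary outcome-process classes (*bodily harm*, *bodily benefit*)
sit outside the branch.

Referent tracking assigns each particular an IUI (`IUI-n`), records the
types it instantiates and the temporal regions (`t_n`, with `t_max` =
"at all times") involved, and relates particulars through a closed
vocabulary (`has-participant`, `precedes`, `part-of-occurrent`,
`located-in`, …). A rule catalogue (R1–R8) checks stores against the
axioms: participant cardinality, interspecies-ness, location
(non-)contradiction, temporal parthood, precedence order, and the
neutralism ban.

## Worked example

```python
>>> from symbio import InteractionProfile, classify_interaction
>>> p = InteractionProfile.from_symbols("+,-", fatal=False,
...                                     spatial="endo", necessity="obligate")
>>> classify_interaction(p)
['obligatory endosymbiotic parasitism']
>>> classify_interaction(InteractionProfile.from_symbols("+,-,0", fatal=False,
...                                                      spatial="endo"))
['endosymbiotic parasitism', 'endosymbiotic commensalism']
```

The first profile — one organism benefits, the other is non-fatally
harmed, inside a host, and the interaction is required for a function
of the beneficiary — is exactly the malaria-parasite/human case. The
tripartite profile shows the multi-party rule: each participant pair is
classified separately, so an interaction that benefits one organism,
harms a second and leaves a third unaffected is *both* a parasitism and
a commensalism.

The same from the shell, plus a worked scenario and its validation:

```sh
$ symbio classify --outcomes "+,-" --fatal false --spatial endo --necessity obligate
obligatory endosymbiotic parasitism
$ symbio scenario 2 --out s2.json
scenario 2: 9 instantiation and 19 relation tuples -> s2.json
$ symbio validate s2.json ; echo "exit $?"
...
-- 0 error(s), 8 warning(s), 0 info
exit 0
```

Scenario 2 is the malaria transmission chain: a mosquito acquires
*P. vivax* from an infected human and infects a second human — four
interactions (two obligatory endoparasitisms with the human hosts, two
obligatory endocommensalisms with the mosquito vector) ordered by
`precedes`. It validates with zero errors; the warnings flag tuples the
source tables leave unasserted (endo `located-in`, some temporal
parthood links). Exit code 0 means no error-severity findings.

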