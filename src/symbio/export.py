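"""Serialization of the taxonomy and referent-tracking stores.

Three formats are supported, all deterministic (identical inputs yield
byte-identical documents) and all round-trippable through
:func:`import_document`:

``json``
    A plain dump of the class table / tuple sets with stable key order.
``ttl``
    RDF Turtle.  Classes are emitted as ``owl:Class`` nodes with label,
    textual-definition annotation and ``rdfs:subClassOf`` links, and
    the three equivalence axioms (symbiosis, ectosymbiosis,
    endosymbiosis) as genuine OWL class expressions.  Each class's
    machine-readable differentia travels as a JSON annotation literal
    so the import is lossless without parsing class expressions.
    Relation tuples are reified with the standard RDF reification
    vocabulary, each statement carrying its ``holdsAt`` temporal
    qualification and optional note.
``ofn``
    An OWL functional-syntax-like line format (one axiom per line,
    strings JSON-escaped), convenient for diffing.

The temporal qualification of relation tuples via statement reification
(rather than named graphs) is this package's documented dialect.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass
from pathlib import Path

from rdflib import BNode, Graph, Literal, Namespace, URIRef
from rdflib.collection import Collection
from rdflib.namespace import OWL, RDF, RDFS, XSD

from .errors import ParseError
from .referent_tracking import RTStore
from .taxonomy import SymbiosisClass, TaxonomyGraph

__all__ = [
    "FORMATS",
    "ExportDocument",
    "export_taxonomy",
    "export_store",
    "import_document",
    "write_document",
    "load_path",
    "store_to_csv_dir",
    "store_from_csv_dir",
]

FORMATS = ("json", "ttl", "ofn")

SYMB = Namespace("https://w3id.org/symbio/vocab#")
INST = Namespace("https://w3id.org/symbio/instance#")
OBO = Namespace("http://purl.obolibrary.org/obo/")
SYMB_CLASS = Namespace("https://w3id.org/symbio/class#")

#: annotation property for textual definitions (IAO 'definition')
DEFINITION = OBO["IAO_0000115"]


@dataclass(frozen=True)
class ExportDocument:
    """A serialized taxonomy or store."""

    format: str
    kind: str  # "taxonomy" | "store"
    content: str


def _curie_to_uri(curie: str) -> URIRef:
    prefix, _, local = curie.partition(":")
    if prefix in ("GO", "APOLLO_SV"):
        return OBO[f"{prefix}_{local}"]
    if prefix == "SYMB":
        return SYMB_CLASS[f"SYMB_{local}"]
    raise ValueError(f"unknown CURIE prefix in {curie!r}")


def _uri_to_curie(uri: URIRef) -> str:
    text = str(uri)
    for ns, sep in ((str(OBO), "_"), (str(SYMB_CLASS), "_")):
        if text.startswith(ns):
            local = text[len(ns):]
            prefix, _, ident = local.rpartition(sep)
            # APOLLO_SV contains an underscore itself
            if local.startswith("APOLLO_SV_"):
                return "APOLLO_SV:" + local[len("APOLLO_SV_"):]
            return f"{prefix}:{ident}"
    raise ParseError(f"cannot map {uri} back to a CURIE")


# ==========================================================================
# taxonomy export
# ==========================================================================

def export_taxonomy(graph: TaxonomyGraph, format: str = "ttl") -> ExportDocument:
    """Serialize a taxonomy graph.  See the module docstring for dialects."""
    if format == "json":
        content = json.dumps(graph.to_json_dict(), indent=2, sort_keys=True) + "\n"
    elif format == "ttl":
        content = _taxonomy_to_ttl(graph)
    elif format == "ofn":
        content = _taxonomy_to_ofn(graph)
    else:
        raise ValueError(f"unsupported format {format!r}; choose from {FORMATS}")
    return ExportDocument(format=format, kind="taxonomy", content=content)


def _axiom_expressions(g: Graph, graph: TaxonomyGraph, counter: list[int]):
    """Attach the three printed equivalence axioms as class expressions."""

    def bnode() -> BNode:
        counter[0] += 1
        return BNode(f"ax{counter[0]:03d}")

    def restriction(prop: URIRef, **kw) -> BNode:
        node = bnode()
        g.add((node, RDF.type, OWL.Restriction))
        g.add((node, OWL.onProperty, prop))
        for key, value in kw.items():
            g.add((node, getattr(OWL, key), value))
        return node

    def intersection(*members) -> BNode:
        node = bnode()
        lst = bnode()
        g.add((node, RDF.type, OWL.Class))
        Collection(g, lst, list(members))
        g.add((node, OWL.intersectionOf, lst))
        return node

    def union(*members) -> BNode:
        node = bnode()
        lst = bnode()
        g.add((node, RDF.type, OWL.Class))
        Collection(g, lst, list(members))
        g.add((node, OWL.unionOf, lst))
        return node

    organism = SYMB.Organism
    contact = SYMB.Contact
    two = Literal(2, datatype=XSD.nonNegativeInteger)

    # symbiosis == 'interspecies interaction between organisms' and
    # (('has participant' min 2 ('organism' and ('is bearer of' some
    # 'contact'))) or ('has occurrent part' some 'multi-organism
    # behavior' and ('has participant' min 2 'organism')))
    symbiosis_expr = intersection(
        _curie_to_uri(graph.get("interspecies interaction between organisms").id),
        union(
            restriction(
                SYMB["has-participant"],
                minQualifiedCardinality=two,
                onClass=intersection(
                    organism,
                    restriction(SYMB["is-bearer-of"], someValuesFrom=contact),
                ),
            ),
            intersection(
                restriction(
                    SYMB["has-occurrent-part"],
                    someValuesFrom=_curie_to_uri(
                        graph.get("multi-organism behavior").id
                    ),
                ),
                restriction(
                    SYMB["has-participant"],
                    minQualifiedCardinality=two,
                    onClass=organism,
                ),
            ),
        ),
    )
    g.add((_curie_to_uri(graph.get("symbiosis").id),
           OWL.equivalentClass, symbiosis_expr))

    symbiosis_uri = _curie_to_uri(graph.get("symbiosis").id)
    for label, prop in (
        ("ectosymbiosis", SYMB["spatially-disjoint-from"]),
        ("endosymbiosis", SYMB["located-in"]),
    ):
        expr = intersection(
            symbiosis_uri,
            restriction(
                SYMB["has-participant"],
                someValuesFrom=intersection(
                    organism,
                    restriction(prop, someValuesFrom=organism),
                ),
            ),
        )
        g.add((_curie_to_uri(graph.get(label).id), OWL.equivalentClass, expr))


def _taxonomy_to_ttl(graph: TaxonomyGraph) -> str:
    g = Graph()
    g.bind("owl", OWL)
    g.bind("symb", SYMB)
    g.bind("sclass", SYMB_CLASS)
    g.bind("obo", OBO)
    for cl in graph.classes:
        uri = _curie_to_uri(cl.id)
        g.add((uri, RDF.type, OWL.Class))
        g.add((uri, RDFS.label, Literal(cl.label)))
        g.add((uri, DEFINITION, Literal(cl.definition)))
        g.add((uri, SYMB.provenance, Literal(cl.provenance)))
        if cl.differentia is not None:
            g.add((uri, SYMB.differentia,
                   Literal(json.dumps(cl.differentia.to_dict(), sort_keys=True))))
        for parent in cl.parents:
            g.add((uri, RDFS.subClassOf, _curie_to_uri(parent)))
    _axiom_expressions(g, graph, [0])
    return g.serialize(format="turtle")


def _taxonomy_from_ttl(content: str) -> TaxonomyGraph:
    g = Graph()
    try:
        g.parse(data=content, format="turtle")
    except Exception as exc:
        raise ParseError(f"Turtle parse failure: {exc}") from exc
    classes = []
    for subject in g.subjects(SYMB.provenance, None):
        cid = _uri_to_curie(subject)
        label = str(g.value(subject, RDFS.label))
        definition = str(g.value(subject, DEFINITION))
        provenance = str(g.value(subject, SYMB.provenance))
        diff_lit = g.value(subject, SYMB.differentia)
        differentia = None
        if diff_lit is not None:
            from .taxonomy import Differentia
            differentia = Differentia.from_dict(json.loads(str(diff_lit)))
        parents = tuple(sorted(
            _uri_to_curie(o)
            for o in g.objects(subject, RDFS.subClassOf)
            if isinstance(o, URIRef)
        ))
        classes.append(SymbiosisClass(
            id=cid, label=label, definition=definition,
            parents=parents, differentia=differentia, provenance=provenance,
        ))
    if not classes:
        raise ParseError("document contains no taxonomy classes")
    return TaxonomyGraph(classes)


_OFN_TAXONOMY_HEADER = "Ontology(<https://w3id.org/symbio/taxonomy>"


def _ofn_expr(graph: TaxonomyGraph, label: str) -> str:
    cid = graph.get(label).id
    return cid


def _taxonomy_to_ofn(graph: TaxonomyGraph) -> str:
    lines = [_OFN_TAXONOMY_HEADER]
    for cl in graph.classes:
        lines.append(f"Declaration(Class({cl.id}))")
        lines.append(
            f"AnnotationAssertion(rdfs:label {cl.id} {json.dumps(cl.label)})"
        )
        lines.append(
            f"AnnotationAssertion(symb:definition {cl.id} "
            f"{json.dumps(cl.definition)})"
        )
        lines.append(
            f"AnnotationAssertion(symb:provenance {cl.id} "
            f"{json.dumps(cl.provenance)})"
        )
        if cl.differentia is not None:
            lines.append(
                f"AnnotationAssertion(symb:differentia {cl.id} "
                f"{json.dumps(json.dumps(cl.differentia.to_dict(), sort_keys=True))})"
            )
        for parent in cl.parents:
            lines.append(f"SubClassOf({cl.id} {parent})")
    e = lambda lbl: _ofn_expr(graph, lbl)  # noqa: E731
    organism, contact = "symb:Organism", "symb:Contact"
    lines.append(
        f"EquivalentClasses({e('symbiosis')} ObjectIntersectionOf("
        f"{e('interspecies interaction between organisms')} ObjectUnionOf("
        f"ObjectMinCardinality(2 symb:has-participant ObjectIntersectionOf("
        f"{organism} ObjectSomeValuesFrom(symb:is-bearer-of {contact}))) "
        f"ObjectIntersectionOf(ObjectSomeValuesFrom(symb:has-occurrent-part "
        f"{e('multi-organism behavior')}) ObjectMinCardinality(2 "
        f"symb:has-participant {organism})))))"
    )
    for label, prop in (
        ("ectosymbiosis", "symb:spatially-disjoint-from"),
        ("endosymbiosis", "symb:located-in"),
    ):
        lines.append(
            f"EquivalentClasses({e(label)} ObjectIntersectionOf("
            f"{e('symbiosis')} ObjectSomeValuesFrom(symb:has-participant "
            f"ObjectIntersectionOf({organism} ObjectSomeValuesFrom({prop} "
            f"{organism})))))"
        )
    lines.append(")")
    return "\n".join(lines) + "\n"


_OFN_PATTERNS = {
    "declaration": re.compile(r"^Declaration\(Class\((\S+)\)\)$"),
    "annotation": re.compile(
        r"^AnnotationAssertion\((rdfs:label|symb:definition|"
        r"symb:provenance|symb:differentia) (\S+) (\".*\")\)$"
    ),
    "subclass": re.compile(r"^SubClassOf\((\S+) (\S+)\)$"),
    "equivalent": re.compile(r"^EquivalentClasses\(.*\)$"),
}


def _taxonomy_from_ofn(content: str) -> TaxonomyGraph:
    lines = content.splitlines()
    if not lines or lines[0] != _OFN_TAXONOMY_HEADER or lines[-1].strip() != ")":
        raise ParseError("not a taxonomy functional-syntax document "
                         "(missing header or closing parenthesis)")
    records: dict[str, dict] = {}
    parents: dict[str, list[str]] = {}
    for lineno, line in enumerate(lines[1:-1], start=2):
        if not line.strip():
            continue
        if m := _OFN_PATTERNS["declaration"].match(line):
            records.setdefault(m.group(1), {"id": m.group(1)})
            continue
        if m := _OFN_PATTERNS["annotation"].match(line):
            prop, cid, payload = m.groups()
            value = json.loads(payload)
            rec = records.setdefault(cid, {"id": cid})
            if prop == "rdfs:label":
                rec["label"] = value
            elif prop == "symb:definition":
                rec["definition"] = value
            elif prop == "symb:provenance":
                rec["provenance"] = value
            else:
                rec["differentia"] = json.loads(value)
            continue
        if m := _OFN_PATTERNS["subclass"].match(line):
            parents.setdefault(m.group(1), []).append(m.group(2))
            continue
        if _OFN_PATTERNS["equivalent"].match(line):
            continue
        raise ParseError(f"line {lineno}: unrecognized statement {line!r}")
    from .taxonomy import Differentia
    classes = []
    for cid, rec in records.items():
        try:
            classes.append(SymbiosisClass(
                id=cid,
                label=rec["label"],
                definition=rec["definition"],
                parents=tuple(sorted(parents.get(cid, []))),
                differentia=(
                    Differentia.from_dict(rec["differentia"])
                    if "differentia" in rec else None
                ),
                provenance=rec["provenance"],
            ))
        except KeyError as exc:
            raise ParseError(f"class {cid}: missing annotation {exc}") from exc
    return TaxonomyGraph(classes)


# ==========================================================================
# store export
# ==========================================================================

def _store_json_dict(store: RTStore) -> dict:
    return {
        "kind": "rtstore",
        "iuis": sorted(store.iuis),
        "regions": sorted(store.regions),
        "instantiations": sorted(
            [t.particular, t.type_label, t.region]
            for t in store.instantiations
        ),
        "relations": sorted(
            [t.subject, t.relation, t.object, t.holds_at, t.note]
            for t in store.relations
        ),
        "taxa": dict(sorted(store.taxa.items())),
        "outcome_annotations": {
            k: list(v) for k, v in sorted(store.outcome_annotations.items())
        },
    }


def _store_from_json_dict(data: dict) -> RTStore:
    s = RTStore()
    for iui in data["iuis"]:
        s.declare_iui(iui)
    for region in data["regions"]:
        s.declare_region(region)
    for particular, label, region in data["instantiations"]:
        s.assert_instantiation(particular, label, region)
    for subject, relation, obj, holds_at, note in data["relations"]:
        s.assert_relation(subject, relation, obj, holds_at, note)
    for iui, taxid in data["taxa"].items():
        s.set_taxon(iui, taxid)
    for iui, symbols in data["outcome_annotations"].items():
        s.annotate_outcomes(iui, tuple(symbols))
    return s


def export_store(store: RTStore, format: str = "ttl") -> ExportDocument:
    """Serialize a referent-tracking store (lossless round trip)."""
    if format == "json":
        content = json.dumps(_store_json_dict(store), indent=2, sort_keys=True) + "\n"
    elif format == "ttl":
        content = _store_to_ttl(store)
    elif format == "ofn":
        content = _store_to_ofn(store)
    else:
        raise ValueError(f"unsupported format {format!r}; choose from {FORMATS}")
    return ExportDocument(format=format, kind="store", content=content)


def _stmt_uri(parts: tuple[str, ...]) -> URIRef:
    digest = hashlib.sha1("\t".join(parts).encode()).hexdigest()[:12]
    return INST[f"stmt-{digest}"]


def _store_to_ttl(store: RTStore) -> str:
    g = Graph()
    g.bind("symb", SYMB)
    g.bind("inst", INST)
    for iui in sorted(store.iuis):
        g.add((INST[iui], RDF.type, SYMB.Particular))
    for region in sorted(store.regions):
        g.add((INST[region], RDF.type, SYMB.TemporalRegion))
    for iui, taxid in sorted(store.taxa.items()):
        g.add((INST[iui], SYMB.taxon, Literal(taxid)))
    for iui, symbols in sorted(store.outcome_annotations.items()):
        g.add((INST[iui], SYMB.outcomes, Literal(",".join(symbols))))
    for t in sorted(store.instantiations,
                    key=lambda t: (t.particular, t.type_label, t.region)):
        node = _stmt_uri(("inst", t.particular, t.type_label, t.region))
        g.add((node, RDF.type, SYMB.Instantiation))
        g.add((node, SYMB.particular, INST[t.particular]))
        g.add((node, SYMB.typeLabel, Literal(t.type_label)))
        g.add((node, SYMB.at, INST[t.region]))
    for t in sorted(store.relations,
                    key=lambda t: (t.subject, t.relation, t.object,
                                   t.holds_at, t.note)):
        node = _stmt_uri(("rel", t.subject, t.relation, t.object,
                          t.holds_at, t.note))
        g.add((node, RDF.type, RDF.Statement))
        g.add((node, RDF.subject, INST[t.subject]))
        g.add((node, RDF.predicate, SYMB[t.relation]))
        g.add((node, RDF.object, INST[t.object]))
        g.add((node, SYMB.holdsAt, INST[t.holds_at]))
        if t.note:
            g.add((node, SYMB.note, Literal(t.note)))
    return g.serialize(format="turtle")


def _local(uri) -> str:
    return str(uri)[len(str(INST)):]


def _store_from_ttl(content: str) -> RTStore:
    g = Graph()
    try:
        g.parse(data=content, format="turtle")
    except Exception as exc:
        raise ParseError(f"Turtle parse failure: {exc}") from exc
    s = RTStore()
    for subj in g.subjects(RDF.type, SYMB.Particular):
        s.declare_iui(_local(subj))
    for subj in g.subjects(RDF.type, SYMB.TemporalRegion):
        s.declare_region(_local(subj))
    for subj, _p, obj in g.triples((None, SYMB.taxon, None)):
        s.set_taxon(_local(subj), str(obj))
    for node in g.subjects(RDF.type, SYMB.Instantiation):
        s.assert_instantiation(
            _local(g.value(node, SYMB.particular)),
            str(g.value(node, SYMB.typeLabel)),
            _local(g.value(node, SYMB.at)),
        )
    for node in g.subjects(RDF.type, RDF.Statement):
        note = g.value(node, SYMB.note)
        s.assert_relation(
            _local(g.value(node, RDF.subject)),
            str(g.value(node, RDF.predicate))[len(str(SYMB)):],
            _local(g.value(node, RDF.object)),
            _local(g.value(node, SYMB.holdsAt)),
            str(note) if note is not None else "",
        )
    for subj, _p, obj in g.triples((None, SYMB.outcomes, None)):
        s.annotate_outcomes(_local(subj), tuple(str(obj).split(",")))
    return s


_OFN_STORE_HEADER = "RTStore(<https://w3id.org/symbio/store>"

_STORE_PATTERNS = {
    "iui": re.compile(r"^IUI\((\S+)\)$"),
    "region": re.compile(r"^Region\((\S+)\)$"),
    "instantiation": re.compile(r"^Instantiation\((\S+) (\".*\") (\S+)\)$"),
    "relation": re.compile(
        r"^Relation\((\S+) (\S+) (\S+) (\S+) (\".*\")\)$"
    ),
    "taxon": re.compile(r"^Taxon\((\S+) (\".*\")\)$"),
    "outcomes": re.compile(r"^Outcomes\((\S+) (\".*\")\)$"),
}


def _store_to_ofn(store: RTStore) -> str:
    lines = [_OFN_STORE_HEADER]
    for iui in sorted(store.iuis):
        lines.append(f"IUI({iui})")
    for region in sorted(store.regions):
        lines.append(f"Region({region})")
    for iui, taxid in sorted(store.taxa.items()):
        lines.append(f"Taxon({iui} {json.dumps(taxid)})")
    for t in sorted(store.instantiations,
                    key=lambda t: (t.particular, t.type_label, t.region)):
        lines.append(
            f"Instantiation({t.particular} {json.dumps(t.type_label)} "
            f"{t.region})"
        )
    for t in sorted(store.relations,
                    key=lambda t: (t.subject, t.relation, t.object,
                                   t.holds_at, t.note)):
        lines.append(
            f"Relation({t.subject} {t.relation} {t.object} {t.holds_at} "
            f"{json.dumps(t.note)})"
        )
    for iui, symbols in sorted(store.outcome_annotations.items()):
        lines.append(f"Outcomes({iui} {json.dumps(','.join(symbols))})")
    lines.append(")")
    return "\n".join(lines) + "\n"


def _store_from_ofn(content: str) -> RTStore:
    lines = content.splitlines()
    if not lines or lines[0] != _OFN_STORE_HEADER or lines[-1].strip() != ")":
        raise ParseError("not a store functional-syntax document "
                         "(missing header or closing parenthesis)")
    s = RTStore()
    deferred: list[tuple[str, tuple]] = []
    for lineno, line in enumerate(lines[1:-1], start=2):
        if not line.strip():
            continue
        if m := _STORE_PATTERNS["iui"].match(line):
            s.declare_iui(m.group(1))
        elif m := _STORE_PATTERNS["region"].match(line):
            s.declare_region(m.group(1))
        elif m := _STORE_PATTERNS["taxon"].match(line):
            deferred.append(("taxon", (m.group(1), json.loads(m.group(2)))))
        elif m := _STORE_PATTERNS["instantiation"].match(line):
            deferred.append(("inst", (m.group(1), json.loads(m.group(2)),
                                      m.group(3))))
        elif m := _STORE_PATTERNS["relation"].match(line):
            deferred.append(("rel", (m.group(1), m.group(2), m.group(3),
                                     m.group(4), json.loads(m.group(5)))))
        elif m := _STORE_PATTERNS["outcomes"].match(line):
            deferred.append(("out", (m.group(1),
                                     tuple(json.loads(m.group(2)).split(",")))))
        else:
            raise ParseError(f"line {lineno}: unrecognized statement {line!r}")
    for kind, args in deferred:
        if kind == "taxon":
            s.set_taxon(*args)
        elif kind == "inst":
            s.assert_instantiation(*args)
        elif kind == "rel":
            s.assert_relation(*args)
        else:
            s.annotate_outcomes(*args)
    return s


# ==========================================================================
# import dispatch and file helpers
# ==========================================================================

def import_document(doc: ExportDocument):
    """Reconstruct the object a document serializes.

    Returns a :class:`TaxonomyGraph` or an :class:`RTStore`;
    ``import_document(export_*(x)) == x`` in every supported format.
    """
    if doc.format == "json":
        try:
            data = json.loads(doc.content)
        except json.JSONDecodeError as exc:
            raise ParseError(
                f"JSON parse failure at line {exc.lineno}: {exc.msg}"
            ) from exc
        if data.get("kind") == "taxonomy":
            return TaxonomyGraph.from_json_dict(data)
        if data.get("kind") == "rtstore":
            return _store_from_json_dict(data)
        raise ParseError("JSON document lacks a recognized 'kind'")
    if doc.format == "ttl":
        if doc.kind == "taxonomy":
            return _taxonomy_from_ttl(doc.content)
        return _store_from_ttl(doc.content)
    if doc.format == "ofn":
        if doc.kind == "taxonomy":
            return _taxonomy_from_ofn(doc.content)
        return _store_from_ofn(doc.content)
    raise ValueError(f"unsupported format {doc.format!r}")


_SUFFIX_TO_FORMAT = {".json": "json", ".ttl": "ttl", ".ofn": "ofn"}


def write_document(doc: ExportDocument, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(doc.content)
    return path


def load_path(path: str | Path):
    """Load a taxonomy or store from a file, sniffing format and kind."""
    path = Path(path)
    fmt = _SUFFIX_TO_FORMAT.get(path.suffix)
    if fmt is None:
        raise ValueError(f"cannot infer format from suffix of {path.name!r}")
    content = path.read_text()
    if fmt == "json":
        return import_document(ExportDocument(fmt, "", content))
    if fmt == "ofn":
        kind = "taxonomy" if content.startswith("Ontology(") else "store"
        return import_document(ExportDocument(fmt, kind, content))
    # ttl: a taxonomy document carries provenance annotations
    kind = "taxonomy" if "symb:provenance" in content else "store"
    return import_document(ExportDocument(fmt, kind, content))


# ==========================================================================
# CSV dialect (one file per tuple kind, mirroring the printed tables)
# ==========================================================================

def store_to_csv_dir(store: RTStore, directory: str | Path) -> Path:
    """Write a store as CSV files mirroring the scenario table columns."""
    import csv

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    def write(name: str, header: list[str], rows: list[list[str]]) -> None:
        with open(directory / name, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(header)
            w.writerows(rows)

    write("particulars.csv", ["IUI", "Taxon"],
          [[iui, store.taxa.get(iui, "")] for iui in sorted(store.iuis)])
    write("regions.csv", ["Temporal region"],
          [[r] for r in sorted(store.regions)])
    write("instantiations.csv", ["IUI", "Temporal region", "Type"],
          sorted([t.particular, t.region, t.type_label]
                 for t in store.instantiations))
    write("relations.csv",
          ["IUI", "Relation", "IUI", "Temporal region when relation holds",
           "Notes"],
          sorted([t.subject, t.relation, t.object, t.holds_at, t.note]
                 for t in store.relations))
    write("outcomes.csv", ["IUI", "Outcomes"],
          [[iui, ",".join(symbols)]
           for iui, symbols in sorted(store.outcome_annotations.items())])
    return directory


def store_from_csv_dir(directory: str | Path) -> RTStore:
    import csv

    directory = Path(directory)
    s = RTStore()

    def rows(name: str) -> list[list[str]]:
        path = directory / name
        if not path.exists():
            raise ParseError(f"missing CSV file {name}")
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            next(reader, None)  # header
            return [row for row in reader if row]

    for region, in rows("regions.csv"):
        s.declare_region(region)
    for iui, taxid in rows("particulars.csv"):
        s.declare_iui(iui)
        if taxid:
            s.set_taxon(iui, taxid)
    for iui, region, label in rows("instantiations.csv"):
        s.assert_instantiation(iui, label, region)
    for subject, relation, obj, holds_at, note in rows("relations.csv"):
        s.assert_relation(subject, relation, obj, holds_at, note)
    for iui, symbols in rows("outcomes.csv"):
        s.annotate_outcomes(iui, tuple(symbols.split(",")))
    return s
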