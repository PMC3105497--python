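"""Automatic domain construction from ACD tool descriptors and an OBO ontology.

EMBOSS ships one ACD (Ajax Command Definition) file per tool, describing the
application and its parameters grouped into sections (``input``, ``required``,
``additional``, ``advanced``, ``output``).  Parameters and the application
itself may carry ``relation`` attributes referencing terms of an ontology
such as EDAM.  This module parses the ACD dialect, imports OBO ontologies,
derives symbolic input/output types per tool, and links services and types to
ontology terms, producing a complete :class:`~flowsynth.domain_model.DomainModel`.

Derived type naming
-------------------
For a parameter of application *app* with ACD datatype *dt*:

* a ``relation`` whose term does **not** resolve in the imported ontology
  names the type after the term's label (sanitised) and places it directly
  under the taxonomy root — annotated but (yet) unclassified;
* a resolvable relation on an *input* names the type after the ontology
  term, i.e. the requirement is the taxonomy class itself;
* a resolvable relation on an *output* keeps a tool-specific generated name
  and makes it an instance of the term's class;
* generated names come from the parameter's ``knowntype`` attribute when
  present (sanitised), else ``<app>_<dt>_output`` / ``<app>_<dt>_input``.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import obonet

from .domain_model import ROOT, DomainModel, ServiceSpec, Taxonomy
from .errors import ParseError, UnknownNameError

# ---------------------------------------------------------------------------
# ACD documents
# ---------------------------------------------------------------------------

#: Section kinds that contribute I/O types; others are parsed but inert.
INPUT_SECTIONS = ("input",)
OUTPUT_SECTIONS = ("output",)


@dataclass(frozen=True)
class TermRef:
    """A lenient ontology-term reference like ``"EDAM: 0001929 ! sequence_record"``."""

    id: str | None
    label: str | None

    _REF_RE = re.compile(r"^\s*(?P<prefix>[A-Za-z][A-Za-z0-9_]*)\s*:\s*(?P<local>[^!\s]+)\s*(?:!\s*(?P<label>.*?))?\s*$")

    @classmethod
    def parse(cls, text: str) -> "TermRef":
        m = cls._REF_RE.match(text)
        if not m:
            return cls(id=None, label=text.strip() or None)
        label = (m["label"] or "").strip() or None
        return cls(id=f"{m['prefix']}:{m['local']}", label=label)


@dataclass(frozen=True)
class ACDParameter:
    name: str
    datatype: str
    attributes: dict[str, str] = field(default_factory=dict)
    relations: tuple[TermRef, ...] = ()

    def __post_init__(self) -> None:
        if not self.datatype:
            raise ValueError("parameter datatype token must be non-empty")


@dataclass(frozen=True)
class ACDSection:
    kind: str
    parameters: tuple[ACDParameter, ...] = ()


@dataclass(frozen=True)
class ACDApplication:
    name: str
    attributes: dict[str, str] = field(default_factory=dict)
    relations: tuple[TermRef, ...] = ()


@dataclass(frozen=True)
class ACDDocument:
    application: ACDApplication
    sections: tuple[ACDSection, ...] = ()

    def parameters(self) -> list[ACDParameter]:
        return [p for s in self.sections for p in s.parameters]

    def section_parameters(self, kinds: Sequence[str]) -> list[ACDParameter]:
        return [p for s in self.sections if s.kind in kinds for p in s.parameters]


class _ACDLexer:
    """Tokens: words, ':', '[', ']', quoted strings (may span lines).

    ``#`` starts a comment to end of line.  Every token carries its 1-based
    line for error reporting.
    """

    _WORD = re.compile(r"[A-Za-z0-9_.$()@/+-]+")

    def __init__(self, text: str):
        self.tokens: list[tuple[str, str, int]] = []
        line = 1
        i = 0
        n = len(text)
        while i < n:
            c = text[i]
            if c == "\n":
                line += 1
                i += 1
            elif c.isspace():
                i += 1
            elif c == "#":
                while i < n and text[i] != "\n":
                    i += 1
            elif c in ":[]":
                self.tokens.append((c, c, line))
                i += 1
            elif c == '"':
                start_line = line
                j = i + 1
                while j < n and text[j] != '"':
                    if text[j] == "\n":
                        line += 1
                    j += 1
                if j >= n:
                    raise ParseError("unterminated quoted string", line=start_line)
                self.tokens.append(("string", text[i + 1 : j], start_line))
                i = j + 1
            else:
                m = self._WORD.match(text, i)
                if not m:
                    raise ParseError(f"unexpected character {c!r}", line=line)
                self.tokens.append(("word", m.group(0), line))
                i = m.end()
        self.i = 0

    def peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def take(self, expect: str | None = None):
        tok = self.peek()
        if tok is None:
            raise ParseError("unexpected end of file", line=self.tokens[-1][2] if self.tokens else 1)
        if expect is not None and tok[0] != expect:
            raise ParseError(f"expected {expect!r} but found {tok[1]!r}", line=tok[2])
        self.i += 1
        return tok


def _parse_attr_block(lex: _ACDLexer) -> tuple[dict[str, str], tuple[TermRef, ...]]:
    """Parse ``[ key: value ... ]``; values are strings or bare words."""
    attrs: dict[str, str] = {}
    relations: list[TermRef] = []
    open_tok = lex.take("[")
    while True:
        tok = lex.peek()
        if tok is None:
            raise ParseError("unbalanced '[': block never closed", line=open_tok[2])
        if tok[0] == "]":
            lex.take()
            return attrs, tuple(relations)
        key = lex.take("word")[1]
        lex.take(":")
        val_tok = lex.peek()
        if val_tok is None or val_tok[0] not in ("word", "string"):
            raise ParseError(f"attribute {key!r} has no value", line=tok[2])
        value = lex.take()[1]
        if key == "relation":
            relations.append(TermRef.parse(value))
        else:
            attrs[key] = value


def parse_acd(text: str) -> ACDDocument:
    """Parse an ACD tool descriptor in the supported dialect.

    The document must start with an ``application: <name> [ ... ]`` block;
    parameter blocks are ``<datatype>: <name> [ ... ]`` and live inside
    ``section: <kind> [ ... ] ... endsection: <kind>`` brackets.  Unknown
    attributes are preserved verbatim; ``relation`` attributes are parsed
    into term references.
    """
    lex = _ACDLexer(text)
    first = lex.peek()
    if first is None or first[1] != "application":
        raise ParseError(
            "ACD document must begin with an application block",
            line=1 if first is None else first[2],
        )
    lex.take()
    lex.take(":")
    app_name = lex.take("word")[1]
    app_attrs, app_rels = _parse_attr_block(lex)
    application = ACDApplication(app_name, app_attrs, app_rels)

    sections: list[ACDSection] = []
    seen_params: set[str] = set()
    while lex.peek() is not None:
        kind_tok = lex.take("word")
        lex.take(":")
        if kind_tok[1] != "section":
            raise ParseError(
                f"expected a section but found {kind_tok[1]!r} outside any section",
                line=kind_tok[2],
            )
        sec_kind = lex.take("word")[1]
        _parse_attr_block(lex)  # section attributes are not used further
        params: list[ACDParameter] = []
        while True:
            tok = lex.peek()
            if tok is None:
                raise ParseError(f"section {sec_kind!r} never closed", line=kind_tok[2])
            if tok[1] == "endsection":
                lex.take()
                lex.take(":")
                end_name = lex.take("word")
                if end_name[1] != sec_kind:
                    raise ParseError(
                        f"endsection {end_name[1]!r} does not match section {sec_kind!r}",
                        line=end_name[2],
                    )
                break
            dt_tok = lex.take("word")
            lex.take(":")
            pname = lex.take("word")[1]
            attrs, rels = _parse_attr_block(lex)
            if pname in seen_params:
                raise ParseError(f"duplicate parameter {pname!r}", line=dt_tok[2])
            seen_params.add(pname)
            params.append(ACDParameter(pname, dt_tok[1], attrs, rels))
        sections.append(ACDSection(sec_kind, tuple(params)))
    return ACDDocument(application, tuple(sections))


# ---------------------------------------------------------------------------
# OBO ontologies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Term:
    id: str
    name: str
    parents: tuple[str, ...] = ()
    obsolete: bool = False


@dataclass
class Ontology:
    terms: dict[str, Term] = field(default_factory=dict)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def children(self, term_id: str) -> list[str]:
        return sorted(t.id for t in self.terms.values() if term_id in t.parents)

    def top_level(self) -> list[Term]:
        return sorted(
            (t for t in self.terms.values() if not t.parents and not t.obsolete),
            key=lambda t: t.id,
        )


_STANZA_RE = re.compile(r"^\[(?P<kind>[^\]]+)\]\s*$")


def parse_obo(text: str) -> Ontology:
    """Parse OBO 1.x stanza text into an :class:`Ontology`.

    Every ``[Term]`` stanza becomes a term; ``is_a`` lines become parent
    links and ``is_obsolete: true`` flags the term (obsolete terms are kept
    here but excluded from taxonomy building).  A ``[Term]`` stanza without
    an ``id`` line is a parse error.
    """
    # obonet silently skips id-less stanzas; detect them up front.
    current_kind = None
    has_id = True
    stanza_line = 0
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("!")[0].strip()
        m = _STANZA_RE.match(line)
        if m:
            if current_kind == "Term" and not has_id:
                raise ParseError("[Term] stanza without id", line=stanza_line)
            current_kind, has_id, stanza_line = m["kind"], False, lineno
        elif line.startswith("id:") and line[3:].strip():
            has_id = True
    if current_kind == "Term" and not has_id:
        raise ParseError("[Term] stanza without id", line=stanza_line)

    if not text.strip():
        return Ontology()
    graph = obonet.read_obo(io.StringIO(text), ignore_obsolete=False)
    ontology = Ontology()
    for term_id, data in graph.nodes(data=True):
        parents = tuple(
            sorted(v for _, v, key in graph.out_edges(term_id, keys=True) if key == "is_a")
        )
        ontology.terms[term_id] = Term(
            id=term_id,
            name=data.get("name", term_id),
            parents=parents,
            obsolete=str(data.get("is_obsolete", "")).lower() == "true",
        )
    return ontology


def sanitize(label: str) -> str:
    """Symbolic-name form of an ontology term label or knowntype string."""
    cleaned = re.sub(r"[^A-Za-z0-9]+", "_", label.strip()).strip("_").lower()
    return cleaned or "_"


def _taxonomy_with_index(
    ontology: Ontology, roots: Iterable[str], root_class: str = ROOT
) -> tuple[Taxonomy, dict[str, str]]:
    """Taxonomy of the non-obsolete terms below *roots*, plus id -> class map."""
    roots = sorted(set(roots))
    for r in roots:
        if r not in ontology.terms:
            raise UnknownNameError(r, "not an ontology term", ())
    tax = Taxonomy(root=root_class)
    index: dict[str, str] = {}

    included: set[str] = set()
    frontier = [r for r in roots if not ontology.terms[r].obsolete]
    while frontier:
        tid = frontier.pop()
        if tid in included:
            continue
        included.add(tid)
        for child in ontology.children(tid):
            if not ontology.terms[child].obsolete:
                frontier.append(child)

    for tid in sorted(included):
        term = ontology.terms[tid]
        cls = sanitize(term.name)
        index[tid] = cls
        parent_terms = [p for p in term.parents if p in included] if tid not in roots else []
        parents = [sanitize(ontology.terms[p].name) for p in parent_terms]
        tax.add_class(cls, parents or [root_class])
    return tax, index


def taxonomy_from_ontology(ontology: Ontology, roots: Iterable[str], root_class: str = ROOT) -> Taxonomy:
    """Build a class taxonomy from the ontology terms reachable below *roots*."""
    tax, _ = _taxonomy_with_index(ontology, roots, root_class)
    return tax


# ---------------------------------------------------------------------------
# Automatic domain construction
# ---------------------------------------------------------------------------

def _split_roots(ontology: Ontology) -> tuple[list[str], list[str]]:
    """Top-level terms named ``operation`` seed the service taxonomy, the
    rest the type taxonomy (EDAM's data/operation branch convention)."""
    service_roots, type_roots = [], []
    for term in ontology.top_level():
        (service_roots if sanitize(term.name) == "operation" else type_roots).append(term.id)
    return type_roots, service_roots


def _derived_type(
    app: str, param: ACDParameter, role: str, ontology: Ontology, type_index: dict[str, str]
) -> tuple[str, str | None]:
    """(type name, taxonomy class or None) for one I/O parameter."""
    term: Term | None = None
    ref_label: str | None = None
    for ref in param.relations:
        if ref.id is not None and ref.id in ontology.terms:
            term = ontology.terms[ref.id]
        ref_label = ref.label or ref_label or (ref.id.split(":", 1)[-1] if ref.id else None)
        if term is not None:
            break
    if term is not None and term.id in type_index:
        cls = type_index[term.id]
        if role == "input":
            return cls, None  # the requirement is the class itself
        name = sanitize(param.attributes["knowntype"]) if "knowntype" in param.attributes \
            else f"{app}_{param.datatype}_{role}"
        return name, cls
    if param.relations and ref_label:
        return sanitize(ref_label), None  # annotated but unclassified -> root
    if "knowntype" in param.attributes:
        return sanitize(param.attributes["knowntype"]), None
    return f"{app}_{param.datatype}_{role}", None


def build_auto_domain(
    acds: Iterable[ACDDocument],
    ontology: Ontology,
    type_roots: Iterable[str] | None = None,
    service_roots: Iterable[str] | None = None,
) -> DomainModel:
    """Derive a complete domain model from ACD documents and an ontology.

    One service per ACD application; input types come from input-section
    parameters and output types from output-section parameters (naming rule
    in the module docstring).  Services are placed in the service taxonomy
    under the class of their first resolvable application relation, types
    under the class of their parameter relation; anything unannotated or
    unresolvable becomes a direct instance of the root.
    """
    if type_roots is None or service_roots is None:
        auto_type, auto_service = _split_roots(ontology)
        type_roots = auto_type if type_roots is None else type_roots
        service_roots = auto_service if service_roots is None else service_roots
    type_tax, type_index = _taxonomy_with_index(ontology, type_roots)
    service_tax, service_index = _taxonomy_with_index(ontology, service_roots)

    domain = DomainModel(type_taxonomy=type_tax, service_taxonomy=service_tax)
    pending_types: dict[str, set[str]] = {}

    for doc in acds:
        app = doc.application.name
        inputs: set[str] = set()
        outputs: set[str] = set()
        for role, kinds, bucket in (
            ("input", INPUT_SECTIONS, inputs),
            ("output", OUTPUT_SECTIONS, outputs),
        ):
            for param in doc.section_parameters(kinds):
                name, cls = _derived_type(app, param, role, ontology, type_index)
                bucket.add(name)
                if name not in type_tax.classes:
                    pending_types.setdefault(name, set())
                    if cls is not None:
                        pending_types[name].add(cls)
        service_classes: list[str] = []
        for ref in doc.application.relations:
            if ref.id is not None and ref.id in service_index:
                service_classes = [service_index[ref.id]]
                break
        domain.add_service(
            ServiceSpec(
                name=app,
                inputs=frozenset(inputs),
                outputs=frozenset(outputs),
                description=doc.application.attributes.get("documentation", ""),
            ),
            service_classes,
        )

    for name, classes in sorted(pending_types.items()):
        type_tax.add_instance(name, sorted(classes))
    return domain


# ---------------------------------------------------------------------------
# Annotation coverage statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnotationStats:
    """EDAM-annotation coverage over a collection of ACD documents.

    The per-file min/max/mean triples are taken over the files that carry at
    least one relation of the respective kind (all zero when none do).
    """

    n_files: int
    pct_files_with_any_relation: float
    pct_files_with_application_relation: float
    pct_files_with_parameter_relation: float
    pct_parameters_with_relation: float
    app_relations_per_file: tuple[int, int, float]
    param_relations_per_file: tuple[int, int, float]


def annotation_stats(acds: Iterable[ACDDocument]) -> AnnotationStats:
    docs = list(acds)
    n = len(docs)
    if n == 0:
        return AnnotationStats(0, 0.0, 0.0, 0.0, 0.0, (0, 0, 0.0), (0, 0, 0.0))

    app_counts = [len(d.application.relations) for d in docs]
    param_counts = [sum(len(p.relations) for p in d.parameters()) for d in docs]
    n_params = sum(len(d.parameters()) for d in docs)
    n_params_annotated = sum(
        1 for d in docs for p in d.parameters() if p.relations
    )

    def pct(k: int, total: int) -> float:
        return 100.0 * k / total if total else 0.0

    def spread(counts: list[int]) -> tuple[int, int, float]:
        present = [c for c in counts if c > 0]
        if not present:
            return (0, 0, 0.0)
        return (min(present), max(present), sum(present) / len(present))

    return AnnotationStats(
        n_files=n,
        pct_files_with_any_relation=pct(
            sum(1 for a, p in zip(app_counts, param_counts) if a + p > 0), n
        ),
        pct_files_with_application_relation=pct(sum(1 for a in app_counts if a > 0), n),
        pct_files_with_parameter_relation=pct(sum(1 for p in param_counts if p > 0), n),
        pct_parameters_with_relation=pct(n_params_annotated, n_params),
        app_relations_per_file=spread(app_counts),
        param_relations_per_file=spread(param_counts),
    )
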