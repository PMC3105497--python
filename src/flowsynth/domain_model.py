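"""Symbolic domain models for service composition.

A domain model describes a collection of services purely in terms of symbolic
type names: each service consumes a set of input types and produces a set of
output types.  Two taxonomies — one for types, one for services — organise the
symbolic names into is-a hierarchies rooted at a most-general class (``Thing``
by default), with concrete names attached to classes via instance-of links.

Execution semantics is *type accumulation*: a state is the set of type names
available so far; a service is applicable when every one of its input
requirements is satisfied by some available type (through subsumption), and
applying it adds its output types to the state.  States therefore only grow
along an execution, which is what makes the implicit transition system (the
configuration universe) amenable to breadth-first synthesis.
"""

from __future__ import annotations

import difflib
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import yaml

from .errors import ContractViolation, ParseError, UnknownNameError

#: The conventional most-general class of every taxonomy.
ROOT = "Thing"

#: A state of the configuration universe: the set of available type names.
State = frozenset

_NAME_RE = re.compile(r"^\S+$")


def _check_name(name: str, what: str) -> str:
    if not name or not _NAME_RE.match(name):
        raise ValueError(f"invalid {what} name {name!r}: must be non-empty, no whitespace")
    return name


def _suggest(name: str, known: Iterable[str]) -> tuple[str, ...]:
    return tuple(difflib.get_close_matches(name, list(known), n=3))


@dataclass
class Taxonomy:
    """An is-a hierarchy of classes with concrete instances.

    Parameters
    ----------
    classes:
        Abstract class names, always including ``root``.
    is_a:
        Maps a class to its parent classes.  The relation must be acyclic;
        classes with no entry are implicit children of ``root``.
    instance_of:
        Maps a concrete name to the classes it instantiates.  A concrete name
        may instantiate several classes; one with no entry (or an empty entry)
        is implicitly a direct instance of ``root``.
    root:
        The distinguished most-general class.
    """

    classes: set[str] = field(default_factory=set)
    is_a: dict[str, set[str]] = field(default_factory=dict)
    instance_of: dict[str, set[str]] = field(default_factory=dict)
    root: str = ROOT

    def __post_init__(self) -> None:
        self.classes = set(self.classes)
        self.classes.add(self.root)
        self.is_a = {c: set(ps) for c, ps in self.is_a.items()}
        self.instance_of = {i: set(ps) for i, ps in self.instance_of.items()}

    # -- construction helpers -------------------------------------------------

    def add_class(self, name: str, parents: Iterable[str] = ()) -> None:
        _check_name(name, "class")
        self.classes.add(name)
        parents = set(parents)
        if parents:
            self.is_a.setdefault(name, set()).update(parents)

    def add_instance(self, name: str, parents: Iterable[str] = ()) -> None:
        _check_name(name, "instance")
        self.instance_of.setdefault(name, set()).update(parents)

    # -- queries --------------------------------------------------------------

    @property
    def instances(self) -> set[str]:
        return set(self.instance_of)

    def known(self, name: str) -> bool:
        return name in self.classes or name in self.instance_of

    def _require_known(self, name: str) -> None:
        if not self.known(name):
            raise UnknownNameError(
                name, "not in taxonomy", _suggest(name, self.classes | self.instances)
            )

    def parents(self, name: str) -> set[str]:
        """Direct generalisations of *name* (instance-of or is-a step)."""
        if name in self.instance_of:
            direct = set(self.instance_of[name])
            return direct if direct else {self.root}
        if name in self.classes:
            if name == self.root:
                return set()
            direct = set(self.is_a.get(name, ()))
            return direct if direct else {self.root}
        raise UnknownNameError(name, "not in taxonomy", _suggest(name, self.classes | self.instances))

    def ancestors(self, name: str) -> set[str]:
        """All names subsuming *name*, including *name* itself."""
        self._require_known(name)
        seen = {name}
        frontier = [name]
        while frontier:
            for parent in self.parents(frontier.pop()):
                if parent not in seen:
                    seen.add(parent)
                    frontier.append(parent)
        return seen

    def instances_of(self, class_name: str) -> set[str]:
        """All concrete instances subsumed by *class_name*."""
        self._require_known(class_name)
        return {i for i in self.instance_of if class_name in self.ancestors(i)}

    def cycles(self) -> list[list[str]]:
        """Cycles in the is_a relation (well-formed taxonomies have none)."""
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.classes)
        for child, ps in self.is_a.items():
            for p in ps:
                g.add_edge(child, p)
        return [list(c) for c in nx.simple_cycles(g)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Taxonomy):
            return NotImplemented
        return (
            self.root == other.root
            and self.classes == other.classes
            and {c: ps for c, ps in self.is_a.items() if ps}
            == {c: ps for c, ps in other.is_a.items() if ps}
            and self.instance_of == other.instance_of
        )


def subsumes(taxonomy: Taxonomy, general: str, specific: str) -> bool:
    """True iff *general* subsumes *specific* in the taxonomy.

    ``specific`` may be a class or a concrete instance; it is subsumed by
    ``general`` when the two are equal or ``general`` is reachable from
    ``specific`` via an instance-of link followed by zero or more is-a steps.
    The root subsumes every known name.
    """
    taxonomy._require_known(general)
    if general == specific:
        taxonomy._require_known(specific)
        return True
    return general in taxonomy.ancestors(specific)


@dataclass(frozen=True)
class ServiceSpec:
    """A service characterised by symbolic input and output type sets.

    All inputs are mandatory; both sets may be empty (sources produce from
    nothing, sinks such as pure display services produce nothing).
    """

    name: str
    inputs: frozenset[str] = frozenset()
    outputs: frozenset[str] = frozenset()
    description: str = ""

    def __post_init__(self) -> None:
        _check_name(self.name, "service")
        object.__setattr__(self, "inputs", frozenset(self.inputs))
        object.__setattr__(self, "outputs", frozenset(self.outputs))


@dataclass
class DomainModel:
    """Services plus the type and service taxonomies and global constraints."""

    services: dict[str, ServiceSpec] = field(default_factory=dict)
    type_taxonomy: Taxonomy = field(default_factory=Taxonomy)
    service_taxonomy: Taxonomy = field(default_factory=Taxonomy)
    global_constraints: list[str] = field(default_factory=list)

    def add_service(self, service: ServiceSpec, service_classes: Iterable[str] = ()) -> None:
        self.services[service.name] = service
        self.service_taxonomy.add_instance(service.name, service_classes)

    def service(self, name: str) -> ServiceSpec:
        try:
            return self.services[name]
        except KeyError:
            raise UnknownNameError(name, "not a service", _suggest(name, self.services)) from None

    def service_names(self) -> list[str]:
        return sorted(self.services)

    @property
    def type_universe(self) -> set[str]:
        """Every type name a state may contain (instances and classes)."""
        t = self.type_taxonomy
        return t.instances | t.classes

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DomainModel):
            return NotImplemented
        return (
            self.services == other.services
            and self.type_taxonomy == other.type_taxonomy
            and self.service_taxonomy == other.service_taxonomy
            and self.global_constraints == other.global_constraints
        )


# ---------------------------------------------------------------------------
# Execution semantics
# ---------------------------------------------------------------------------

def satisfies_requirement(state: State, required: str, taxonomy: Taxonomy) -> bool:
    """True iff some available type satisfies the requirement.

    A member ``t`` of the state satisfies ``required`` when ``required``
    subsumes ``t`` (specific-satisfies-general); in particular a concrete
    member satisfies a requirement for itself.
    """
    taxonomy._require_known(required)
    return any(taxonomy.known(t) and subsumes(taxonomy, required, t) for t in state)


def applicable(service: ServiceSpec, state: State, taxonomy: Taxonomy) -> bool:
    """True iff every input requirement of *service* is satisfied by *state*."""
    return all(satisfies_requirement(state, req, taxonomy) for req in service.inputs)


def successor(state: State, service: ServiceSpec, taxonomy: Taxonomy | None = None) -> State:
    """The state after executing *service*: union with its output types.

    When a taxonomy is given, applicability is checked first and a
    :class:`ContractViolation` raised if the service cannot run.
    """
    if taxonomy is not None and not applicable(service, state, taxonomy):
        missing = sorted(
            req for req in service.inputs if not satisfies_requirement(state, req, taxonomy)
        )
        raise ContractViolation(
            f"service {service.name!r} not applicable: unsatisfied inputs {missing}"
        )
    return frozenset(state) | service.outputs


def replay(domain: DomainModel, start: State, services: Iterable[str]) -> list[State]:
    """States along the execution of *services* from *start*.

    Raises :class:`ContractViolation` if any step is inapplicable, which makes
    this the validity check for candidate solutions.
    """
    states = [frozenset(start)]
    for name in services:
        svc = domain.service(name)
        states.append(successor(states[-1], svc, domain.type_taxonomy))
    return states


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Diagnostic:
    code: str  # e.g. "unknown-type", "cycle", "duplicate", "never-applicable"
    message: str

    def __str__(self) -> str:
        return f"[{self.code}] {self.message}"


def validate_domain(domain: DomainModel, starts: Iterable[State] | None = None) -> list[Diagnostic]:
    """Well-formedness diagnostics for a domain model; empty iff clean.

    Checks: type references resolving in the type taxonomy, services present
    in the service taxonomy, is-a cycles in both taxonomies, duplicate
    class/instance names within a taxonomy namespace, input requirements that
    no type in the universe could ever satisfy, and — only when ``starts``
    states are declared — services never applicable in the accumulation
    closure of any start.
    """
    diags: list[Diagnostic] = []
    tt, st = domain.type_taxonomy, domain.service_taxonomy

    for tax, label in ((tt, "type"), (st, "service")):
        for cyc in tax.cycles():
            diags.append(Diagnostic("cycle", f"{label} taxonomy is_a cycle: {' -> '.join(cyc)}"))
        dup = tax.classes & tax.instances
        for name in sorted(dup):
            diags.append(
                Diagnostic("duplicate", f"{label} taxonomy name {name!r} is both class and instance")
            )
        for child, ps in tax.is_a.items():
            for p in ps:
                if p not in tax.classes:
                    diags.append(
                        Diagnostic("unknown-class", f"{label} taxonomy is_a parent {p!r} undeclared")
                    )
        for inst, ps in tax.instance_of.items():
            for p in ps:
                if p not in tax.classes:
                    diags.append(
                        Diagnostic("unknown-class", f"{label} taxonomy instance parent {p!r} undeclared")
                    )

    for name, svc in domain.services.items():
        if name != svc.name:
            diags.append(Diagnostic("duplicate", f"service registered as {name!r} but named {svc.name!r}"))
        if name not in st.instances:
            diags.append(Diagnostic("unknown-service", f"service {name!r} missing from service taxonomy"))
        for t in sorted(svc.inputs | svc.outputs):
            if not tt.known(t):
                diags.append(Diagnostic("unknown-type", f"service {name!r} references unknown type {t!r}"))

    if any(d.code == "cycle" or d.code == "unknown-type" for d in diags):
        return diags  # closure queries below would be unreliable

    # a requirement must be satisfiable by some type that can ever be in a
    # state: a declared concrete type or a name some service outputs
    producible = frozenset(tt.instances) | frozenset(
        t for svc in domain.services.values() for t in svc.outputs
    )
    for name, svc in sorted(domain.services.items()):
        for req in sorted(svc.inputs):
            if not satisfies_requirement(producible, req, tt):
                diags.append(
                    Diagnostic(
                        "unsatisfiable-input",
                        f"service {name!r} input {req!r} has no satisfying type in the universe",
                    )
                )

    if starts is not None:
        reachable: set[str] = set()
        for start in starts:
            state = frozenset(start)
            changed = True
            while changed:
                changed = False
                for svc in domain.services.values():
                    if svc.name not in reachable and applicable(svc, state, tt):
                        reachable.add(svc.name)
                        new = state | svc.outputs
                        if new != state:
                            state = new
                            changed = True
            # one more sweep so no-op services applicable at the fixpoint count
            for svc in domain.services.values():
                if applicable(svc, state, tt):
                    reachable.add(svc.name)
        for name in sorted(set(domain.services) - reachable):
            diags.append(
                Diagnostic("never-applicable", f"service {name!r} never applicable from declared starts")
            )

    return diags


# ---------------------------------------------------------------------------
# Canonical domain file (YAML)
# ---------------------------------------------------------------------------

def _taxonomy_to_dict(tax: Taxonomy) -> dict:
    return {
        "root": tax.root,
        "classes": sorted(tax.classes - {tax.root}),
        "is_a": {c: sorted(ps) for c, ps in sorted(tax.is_a.items()) if ps},
        "instances": {i: sorted(ps) for i, ps in sorted(tax.instance_of.items())},
    }


def _taxonomy_from_dict(data: Mapping, where: str) -> Taxonomy:
    try:
        tax = Taxonomy(
            classes=set(data.get("classes", ())),
            is_a={c: set(ps) for c, ps in (data.get("is_a") or {}).items()},
            instance_of={i: set(ps) for i, ps in (data.get("instances") or {}).items()},
            root=data.get("root", ROOT),
        )
    except (TypeError, AttributeError) as exc:
        raise ParseError(f"malformed {where} section: {exc}") from None
    return tax


def domain_to_dict(domain: DomainModel) -> dict:
    """Plain-data form of a domain model (the canonical file's structure)."""
    return {
        "types": sorted(domain.type_taxonomy.instances),
        "services": {
            s.name: {
                "inputs": sorted(s.inputs),
                "outputs": sorted(s.outputs),
                "description": s.description,
            }
            for s in sorted(domain.services.values(), key=lambda s: s.name)
        },
        "type_taxonomy": _taxonomy_to_dict(domain.type_taxonomy),
        "service_taxonomy": _taxonomy_to_dict(domain.service_taxonomy),
        "constraints": list(domain.global_constraints),
    }


def domain_from_dict(data: Mapping) -> DomainModel:
    for section in ("services", "type_taxonomy", "service_taxonomy"):
        if section not in data:
            raise ParseError(f"domain file missing required section {section!r}")
    domain = DomainModel(
        type_taxonomy=_taxonomy_from_dict(data["type_taxonomy"], "type_taxonomy"),
        service_taxonomy=_taxonomy_from_dict(data["service_taxonomy"], "service_taxonomy"),
        global_constraints=list(data.get("constraints") or ()),
    )
    for name, spec in (data["services"] or {}).items():
        spec = spec or {}
        domain.services[name] = ServiceSpec(
            name=name,
            inputs=frozenset(spec.get("inputs") or ()),
            outputs=frozenset(spec.get("outputs") or ()),
            description=spec.get("description") or "",
        )
        if name not in domain.service_taxonomy.instances:
            domain.service_taxonomy.add_instance(name)
    for t in data.get("types") or ():
        if t not in domain.type_taxonomy.instances and t not in domain.type_taxonomy.classes:
            domain.type_taxonomy.add_instance(t)
    return domain


def write_domain(domain: DomainModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(domain_to_dict(domain), fh, sort_keys=False)


def read_domain(path) -> DomainModel:
    with open(path) as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            mark = getattr(exc, "problem_mark", None)
            raise ParseError(
                f"invalid YAML in domain file: {getattr(exc, 'problem', exc)}",
                line=None if mark is None else mark.line + 1,
                column=None if mark is None else mark.column + 1,
            ) from None
    if not isinstance(data, Mapping):
        raise ParseError("domain file does not contain a mapping")
    return domain_from_dict(data)
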