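"""Model checking of fully concretised process graphs.

A property holds *at a node* when the formula is satisfied on every maximal
control-flow path starting there: paths that end at a sink are finite
executions (the executed services followed by termination, where the ``End``
atom holds), while paths that enter a cycle are infinite and evaluated with
standard infinite-trace semantics on their lasso form.  ``Exec(C)`` holds at
a position when the node executed there runs a service subsumed by ``C`` in
the service taxonomy, so properties can be stated over abstract service
groups as well as concrete tools.

Path enumeration is bounded: every edge may be traversed at most
``edge_budget`` times (default 2) and every closed cycle is additionally
evaluated as a lasso.  On acyclic graphs this is exhaustive and the verdicts
are exact; on cyclic graphs it is a bounded check that is exact for
violations requiring no more than ``edge_budget`` traversals of any edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from . import sltl
from .domain_model import DomainModel, Taxonomy, subsumes
from .errors import ContractViolation, FlowsynthError
from .process import ProcessModel
from .sltl import (
    And,
    Avail,
    End,
    Eventually,
    Exec,
    FalseF,
    Formula,
    Globally,
    Implies,
    Next,
    Not,
    Or,
    Trace,
    TrueF,
    Until,
    WeakUntil,
    parse,
)

#: PLTL concrete syntax parser (atoms are service names or classes).
parse_pltl = parse


@dataclass(frozen=True)
class Witness:
    """A maximal path demonstrating a violation.

    ``cycle`` is empty for a finite path ending at a sink; otherwise the path
    is ``stem`` followed by ``cycle`` repeated forever.
    """

    stem: tuple[str, ...]
    cycle: tuple[str, ...] = ()

    def __str__(self) -> str:
        text = " -> ".join(self.stem)
        if self.cycle:
            loop = " -> ".join(self.cycle)
            text = (text + " -> " if text else "") + f"({loop})*"
        return text


@dataclass
class Verdict:
    """Per-node outcome of a check; every node of the process has an entry."""

    holds: dict[str, bool] = field(default_factory=dict)
    witnesses: dict[str, Witness] = field(default_factory=dict)

    def violated_nodes(self) -> list[str]:
        return sorted(n for n, ok in self.holds.items() if not ok)

    def all_hold(self) -> bool:
        return all(self.holds.values())


# ---------------------------------------------------------------------------
# Evaluation on label sequences
# ---------------------------------------------------------------------------

def _eval_finite(formula: Formula, labels: tuple[str, ...], taxonomy: Taxonomy) -> bool:
    """Finite execution: the labelled services run, then the path ends."""
    states = tuple(frozenset() for _ in range(len(labels) + 1))
    return sltl.evaluate(formula, Trace(states, labels), taxonomy)


def _eval_lasso(
    formula: Formula, stem: tuple[str, ...], cycle: tuple[str, ...], taxonomy: Taxonomy
) -> bool:
    """Infinite execution ``stem . cycle^ω``, by per-subformula fixpoints."""
    labels = stem + cycle
    n = len(labels)
    s = len(stem)

    def succ(i: int) -> int:
        return i + 1 if i + 1 < n else s

    @lru_cache(maxsize=None)
    def sat_set(f: Formula) -> frozenset[int]:
        every = frozenset(range(n))
        if isinstance(f, TrueF):
            return every
        if isinstance(f, (FalseF, End)):
            return frozenset()
        if isinstance(f, Exec):
            return frozenset(i for i in range(n) if subsumes(taxonomy, f.name, labels[i]))
        if isinstance(f, Avail):
            raise FlowsynthError("type-availability atoms are not supported in process checking")
        if isinstance(f, Not):
            return every - sat_set(f.sub)
        if isinstance(f, And):
            return sat_set(f.left) & sat_set(f.right)
        if isinstance(f, Or):
            return sat_set(f.left) | sat_set(f.right)
        if isinstance(f, Implies):
            return (every - sat_set(f.left)) | sat_set(f.right)
        if isinstance(f, Next):
            sub = sat_set(f.sub)
            return frozenset(i for i in range(n) if succ(i) in sub)
        if isinstance(f, Eventually):
            return sat_set(Until(sltl.TRUE, f.sub))
        if isinstance(f, Globally):
            # greatest fixpoint: drop positions whose successor falls out
            sub = sat_set(f.sub)
            current = set(sub)
            changed = True
            while changed:
                changed = False
                for i in sorted(current):
                    if succ(i) not in current:
                        current.discard(i)
                        changed = True
            return frozenset(current)
        if isinstance(f, Until):
            left, right = sat_set(f.left), sat_set(f.right)
            current = set(right)  # least fixpoint
            changed = True
            while changed:
                changed = False
                for i in range(n):
                    if i not in current and i in left and succ(i) in current:
                        current.add(i)
                        changed = True
            return frozenset(current)
        if isinstance(f, WeakUntil):
            return sat_set(Globally(f.left)) | sat_set(Until(f.left, f.right))
        raise TypeError(f"not a formula: {f!r}")

    return 0 in sat_set(formula)


# ---------------------------------------------------------------------------
# Path enumeration and checking
# ---------------------------------------------------------------------------

def _candidates(process: ProcessModel, start: str, edge_budget: int):
    """Maximal finite paths and lasso paths from *start* (node-id tuples)."""
    outgoing: dict[str, list[str]] = {}
    for e in process.edges:
        outgoing.setdefault(e.src, []).append(e.dst)
    for dsts in outgoing.values():
        dsts.sort()

    finite: set[tuple[str, ...]] = set()
    lassos: set[tuple[tuple[str, ...], tuple[str, ...]]] = set()
    counts: dict[tuple[str, str], int] = {}
    path: list[str] = [start]

    def dfs() -> None:
        node = path[-1]
        dsts = outgoing.get(node, [])
        if not dsts:
            finite.add(tuple(path))
            return
        for dst in dsts:
            for i, x in enumerate(path):
                if x == dst:  # closing edge: the walk from i loops forever
                    lassos.add((tuple(path[:i]), tuple(path[i:])))
            key = (node, dst)
            if counts.get(key, 0) < edge_budget:
                counts[key] = counts.get(key, 0) + 1
                path.append(dst)
                dfs()
                path.pop()
                counts[key] -= 1

    dfs()
    return finite, lassos


def check_process(
    process: ProcessModel,
    formula: Formula,
    domain: DomainModel,
    edge_budget: int = 2,
) -> Verdict:
    """Check *formula* at every node of a fully concretised process."""
    if process.loose_edges():
        raise ContractViolation(
            "process contains loosely specified edges; run synthesis to concretise them first"
        )
    for atom in sltl.atoms(formula):
        if isinstance(atom, Avail):
            raise FlowsynthError("type-availability atoms are not supported in process checking")
        domain.service_taxonomy._require_known(atom.name)
    taxonomy = domain.service_taxonomy

    def label(node: str) -> str:
        return process.service_of(node)

    verdict = Verdict()
    for node in sorted(process.nodes):
        finite, lassos = _candidates(process, node, edge_budget)
        ok = True
        witness: Witness | None = None
        for p in sorted(finite):
            if not _eval_finite(formula, tuple(label(x) for x in p), taxonomy):
                ok, witness = False, Witness(stem=p)
                break
        if ok:
            for stem, cycle in sorted(lassos):
                if not _eval_lasso(
                    formula,
                    tuple(label(x) for x in stem),
                    tuple(label(x) for x in cycle),
                    taxonomy,
                ):
                    ok, witness = False, Witness(stem=stem, cycle=cycle)
                    break
        verdict.holds[node] = ok
        if witness is not None:
            verdict.witnesses[node] = witness
    return verdict
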