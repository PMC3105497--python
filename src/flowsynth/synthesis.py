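"""Synthesis of service sequences for loosely specified workflow branches.

The search space is the *configuration universe*: states are sets of
available type names, and a service labels an edge out of every state that
satisfies all of its input requirements, leading to the state enlarged by its
output types.  The universe is never built explicitly — states are expanded
on the fly, in parallel with *progression* of the constraint formula, so each
search node is a (state, residual-obligation) pair.

A solution for a problem is a (possibly empty) service sequence that replays
validly from the start state, satisfies every goal type in its final state,
and satisfies the conjoined constraint formula on its full finite trace.
Solutions are enumerated breadth-first, so they come out ordered by length;
equal-length solutions are ordered lexicographically by service names.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from . import sltl
from .domain_model import (
    DomainModel,
    State,
    applicable,
    replay,
    satisfies_requirement,
    successor,
)
from .errors import ContractViolation, FlowsynthError
from .process import Edge, ProcessModel
from .sltl import Formula, Trace, accepts_empty, conjoin, evaluate, progress


@dataclass
class SynthesisProblem:
    """A loose branch reduced to its formal essentials.

    ``start`` is the set of types guaranteed available where the branch
    begins; ``goal`` the types the synthesised sequence must make available
    (matched through subsumption, like service inputs); ``constraints`` the
    temporal-logic obligations on the inserted sequence.
    """

    domain: DomainModel
    start: State
    goal: frozenset[str]
    constraints: list[Formula] = field(default_factory=list)
    depth_bound: int = 6
    solution_cap: int = 1000

    def __post_init__(self) -> None:
        self.start = frozenset(self.start)
        self.goal = frozenset(self.goal)
        if self.depth_bound < 0 or self.solution_cap <= 0:
            raise ValueError("depth_bound must be >= 0 and solution_cap positive")
        for t in sorted(self.goal):
            self.domain.type_taxonomy._require_known(t)

    def goal_satisfied(self, state: State) -> bool:
        tt = self.domain.type_taxonomy
        return all(satisfies_requirement(state, g, tt) for g in self.goal)

    def formula(self) -> Formula:
        return conjoin(self.constraints)


@dataclass(frozen=True)
class Solution:
    """An ordered service sequence together with the state it ends in."""

    services: tuple[str, ...]
    final_state: State

    def __len__(self) -> int:
        return len(self.services)


def _trace_for(problem: SynthesisProblem, services: tuple[str, ...]) -> Trace:
    states = replay(problem.domain, problem.start, services)
    return Trace.from_replay(states, services)


def is_valid_solution(problem: SynthesisProblem, services: tuple[str, ...]) -> bool:
    """Replay-validity + goal + constraint satisfaction, checked directly."""
    try:
        trace = _trace_for(problem, tuple(services))
    except (ContractViolation, FlowsynthError):
        return False
    if not problem.goal_satisfied(trace.states[-1]):
        return False
    return evaluate(
        problem.formula(),
        trace,
        problem.domain.service_taxonomy,
        problem.domain.type_taxonomy,
    )


def synthesize(problem: SynthesisProblem, shortest_only: bool = False) -> list[Solution]:
    """Enumerate solutions by product breadth-first search.

    With ``shortest_only`` the search stops at the first length that admits
    solutions and returns exactly those (visited (state, residue) pairs are
    pruned across levels — a revisited pair cannot start a shorter suffix).
    Otherwise every solution up to ``depth_bound`` is produced, capped at
    ``solution_cap``, ordered by length and then lexicographically.  In the
    exhaustive mode pairs are merged only within a level: prefixes reaching
    the same pair share all continuations but remain distinct solutions.
    """
    domain = problem.domain
    st_tax, ty_tax = domain.service_taxonomy, domain.type_taxonomy
    services = [domain.services[n] for n in domain.service_names()]

    root = problem.formula()
    level: dict[tuple[State, Formula], list[tuple[str, ...]]] = {
        (problem.start, root): [()]
    }
    visited: set[tuple[State, Formula]] = set(level) if shortest_only else set()

    solutions: list[Solution] = []
    for depth in range(problem.depth_bound + 1):
        emitted_here: list[Solution] = []
        for (state, residue), prefixes in level.items():
            if problem.goal_satisfied(state) and accepts_empty(residue, state, st_tax, ty_tax):
                emitted_here.extend(Solution(p, state) for p in prefixes)
        emitted_here.sort(key=lambda s: s.services)
        solutions.extend(emitted_here)
        if shortest_only and solutions:
            return solutions
        if len(solutions) >= problem.solution_cap:
            return solutions[: problem.solution_cap]
        if depth == problem.depth_bound:
            break

        nxt: dict[tuple[State, Formula], list[tuple[str, ...]]] = {}
        for (state, residue), prefixes in level.items():
            for svc in services:
                if not applicable(svc, state, ty_tax):
                    continue
                new_residue = progress(residue, state, svc.name, st_tax, ty_tax)
                if isinstance(new_residue, sltl.FalseF):
                    continue
                new_state = successor(state, svc)
                key = (new_state, new_residue)
                if shortest_only and key in visited:
                    continue
                nxt.setdefault(key, []).extend(p + (svc.name,) for p in prefixes)
        if shortest_only:
            visited.update(nxt)
        for key in nxt:
            nxt[key].sort()
        level = nxt
        if not level:
            break
    return solutions


def brute_force_oracle(problem: SynthesisProblem) -> list[Solution]:
    """Independent oracle: enumerate every applicable sequence to the bound.

    Replay-validity is prefix-closed, so depth-first enumeration over
    applicable extensions visits exactly the valid sequences; each one is
    then checked directly against the goal and — via :func:`sltl.evaluate`
    on the reconstructed trace — the conjoined constraints.  No progression,
    no state merging: this is deliberately the naive computation.
    """
    domain = problem.domain
    ty_tax = domain.type_taxonomy
    names = domain.service_names()
    out: list[Solution] = []

    def rec(state: State, seq: tuple[str, ...]) -> None:
        if is_valid_solution(problem, seq):
            out.append(Solution(seq, state))
        if len(seq) >= problem.depth_bound:
            return
        for name in names:
            svc = domain.services[name]
            if applicable(svc, state, ty_tax):
                rec(successor(state, svc), seq + (name,))

    rec(problem.start, ())
    out.sort(key=lambda s: (len(s.services), s.services))
    return out[: problem.solution_cap]


# ---------------------------------------------------------------------------
# From process graphs to problems and back
# ---------------------------------------------------------------------------

def infer_start_types(process: ProcessModel, loose_edge: Edge, domain: DomainModel) -> State:
    """Data-flow start types at a loose branch.

    Along each simple control-flow path from the initial node to the loose
    edge's source node (source inclusive) the outputs of the executed
    services accumulate; the start set is the intersection over all such
    paths — the largest type set consistent with every way of reaching the
    branch.
    """
    if loose_edge not in process.edges:
        raise ContractViolation(f"edge {loose_edge} does not belong to this process")
    g = process.graph()
    if loose_edge.src == process.initial:
        paths = [[process.initial]]
    else:
        paths = [list(p) for p in nx.all_simple_paths(g, process.initial, loose_edge.src)]
    if not paths:
        raise ContractViolation(
            f"loose edge source {loose_edge.src!r} unreachable from initial node {process.initial!r}"
        )
    per_path: list[frozenset[str]] = []
    for path in paths:
        acc: set[str] = set()
        for node in path:
            acc |= domain.service(process.service_of(node)).outputs
        per_path.append(frozenset(acc))
    start = per_path[0]
    for s in per_path[1:]:
        start &= s
    return start


def problem_from_loose_edge(
    process: ProcessModel,
    loose_edge: Edge,
    domain: DomainModel,
    constraints: list[Formula] | None = None,
    depth_bound: int = 6,
    solution_cap: int = 1000,
) -> SynthesisProblem:
    """The synthesis problem a loose edge defines: inferred start types, the
    target service's input types as goal, plus local and global constraints."""
    start = infer_start_types(process, loose_edge, domain)
    goal = domain.service(process.service_of(loose_edge.dst)).inputs
    all_constraints = list(constraints or [])
    for text in domain.global_constraints:
        all_constraints.append(sltl.template_to_formula(text, domain))
    return SynthesisProblem(
        domain=domain,
        start=start,
        goal=frozenset(goal),
        constraints=all_constraints,
        depth_bound=depth_bound,
        solution_cap=solution_cap,
    )


def insert_solution(process: ProcessModel, loose_edge: Edge, solution: Solution,
                    domain: DomainModel | None = None) -> ProcessModel:
    """Replace the loose edge by the solution's service chain.

    When a domain is supplied the solution is re-validated against the edge's
    inferred problem (replay from the inferred start, goal satisfied) and a
    :class:`ContractViolation` raised if it does not fit.
    """
    if domain is not None:
        problem = problem_from_loose_edge(process, loose_edge, domain)
        trace_states = replay(domain, problem.start, solution.services)  # raises if invalid
        if not problem.goal_satisfied(trace_states[-1]):
            raise ContractViolation("solution does not satisfy the loose edge's goal types")
    return process.replace_loose_edge(loose_edge, list(solution.services))
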