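"""Product search vs brute-force oracle, start-type inference, insertion."""

import random

import pytest

from flowsynth import sltl, workbench
from flowsynth.domain_model import DomainModel, ServiceSpec, Taxonomy, replay
from flowsynth.errors import ContractViolation
from flowsynth.process import Edge, ProcessModel
from flowsynth.sltl import Trace, evaluate
from flowsynth.synthesis import (
    SynthesisProblem,
    brute_force_oracle,
    infer_start_types,
    insert_solution,
    is_valid_solution,
    problem_from_loose_edge,
    synthesize,
)


def sequences(solutions):
    return [s.services for s in solutions]


class TestExamples:
    """The alignment/display workflows over both HMMER-subset domains."""

    def test_nucleotide_to_alignment_manual(self, manual_domain):
        problem = SynthesisProblem(
            manual_domain, frozenset({"MultipleNucleotideSequence"}),
            frozenset({"Alignment"}), depth_bound=4,
        )
        shortest = synthesize(problem, shortest_only=True)
        assert sequences(shortest) == [("edialign",), ("emma",)]

    def test_nucleotide_to_alignment_auto_has_no_solution(self, auto_domain):
        problem = SynthesisProblem(
            auto_domain, frozenset({"makenucseq_seqoutall_output"}),
            frozenset({"sequence_alignment_data"}), depth_bound=6,
        )
        assert synthesize(problem) == []

    def test_protein_to_display_shortest_is_empty_sequence(self, manual_domain):
        problem = SynthesisProblem(
            manual_domain, frozenset({"MultipleProteinSequence"}),
            frozenset({"Sequence"}), depth_bound=4,
        )
        shortest = synthesize(problem, shortest_only=True)
        assert sequences(shortest) == [()]

    def test_enforcing_emission_needs_three_steps(self, manual_domain):
        constraint = sltl.template_to_formula(
            "Enforce the use of module ehmmemit", manual_domain
        )
        problem = SynthesisProblem(
            manual_domain, frozenset({"MultipleProteinSequence"}),
            frozenset({"Sequence"}), constraints=[constraint], depth_bound=4,
        )
        shortest = synthesize(problem, shortest_only=True)
        assert all(len(s.services) == 3 for s in shortest)
        assert sequences(shortest) == [
            ("edialign", "ehmmbuild", "ehmmemit"),
            ("emma", "ehmmbuild", "ehmmemit"),
        ]

    def test_constraint_never_shortens_shortest_solution(self, manual_domain):
        base = SynthesisProblem(
            manual_domain, frozenset({"MultipleProteinSequence"}),
            frozenset({"Sequence"}), depth_bound=4,
        )
        unconstrained = synthesize(base, shortest_only=True)
        for text in ("Enforce the use of module ehmmemit", "Do not use emma",
                     "Use showfeat as last service in solution"):
            constrained = SynthesisProblem(
                manual_domain, base.start, base.goal,
                constraints=[sltl.template_to_formula(text, manual_domain)],
                depth_bound=4,
            )
            got = synthesize(constrained, shortest_only=True)
            if got:
                assert len(got[0].services) >= len(unconstrained[0].services)


class TestSolutionContract:
    def test_returned_solutions_replay_and_satisfy(self, manual_domain):
        constraint = sltl.template_to_formula(
            "Use showalign as last service in solution", manual_domain
        )
        problem = SynthesisProblem(
            manual_domain, frozenset({"MultipleNucleotideSequence"}),
            frozenset({"Alignment"}), constraints=[constraint], depth_bound=3,
        )
        solutions = synthesize(problem)
        assert solutions
        for sol in solutions:
            states = replay(manual_domain, problem.start, sol.services)
            assert states[-1] == sol.final_state
            assert problem.goal_satisfied(sol.final_state)
            trace = Trace.from_replay(states, sol.services)
            assert evaluate(constraint, trace, manual_domain.service_taxonomy,
                            manual_domain.type_taxonomy)
            # monotone state growth along the trace
            for a, b in zip(states, states[1:]):
                assert a <= b

    def test_trivial_goal_yields_empty_solution_first(self, manual_domain):
        problem = SynthesisProblem(
            manual_domain, frozenset({"Alignment"}), frozenset({"Alignment"}),
            depth_bound=1,
        )
        oracle = brute_force_oracle(problem)
        assert oracle[0].services == ()
        assert sequences(synthesize(problem)) == sequences(oracle)

    def test_ordering_is_length_then_lexicographic(self, manual_domain):
        problem = SynthesisProblem(
            manual_domain, frozenset({"MultipleNucleotideSequence"}),
            frozenset({"Alignment"}), depth_bound=2,
        )
        got = sequences(synthesize(problem))
        assert got == sorted(got, key=lambda s: (len(s), s))

    def test_solution_cap_truncates(self, manual_domain):
        problem = SynthesisProblem(
            manual_domain, frozenset({"MultipleNucleotideSequence"}),
            frozenset({"Alignment"}), depth_bound=3, solution_cap=5,
        )
        assert len(synthesize(problem)) == 5


class TestOracleEquivalence:
    """Completeness to bound: the product search equals naive enumeration."""

    def test_fixture_problem_agreement(self, manual_domain):
        for constraints in ([], ["Enforce the use of module ehmmemit"],
                            ["Do not use emma"]):
            formulas = [sltl.template_to_formula(c, manual_domain) for c in constraints]
            problem = SynthesisProblem(
                manual_domain, frozenset({"MultipleProteinSequence"}),
                frozenset({"Sequence"}), constraints=formulas,
                depth_bound=3, solution_cap=100_000,
            )
            assert sequences(synthesize(problem)) == sequences(brute_force_oracle(problem))

    @pytest.mark.parametrize("batch", range(4))
    def test_seeded_random_domains(self, batch):
        """A 40-domain slice of the 200-domain suite per batch run here; the
        acceptance suite runs the full set."""
        rng = random.Random(1000 + batch)
        for _ in range(40):
            seed = rng.randrange(2**31)
            domain = workbench.generate_random_domain(workbench.RandomDomainSpec(seed=seed))
            problem = workbench.random_problem(domain, random.Random(seed ^ 0x5EED),
                                               depth_bound=rng.choice((2, 3, 4)))
            got = sequences(synthesize(problem))
            expected = sequences(brute_force_oracle(problem))
            assert got == expected, f"divergence for seed {seed}"


class TestStartTypeInference:
    def test_linear_chain(self, manual_domain):
        process = workbench.load_fixture("example1")
        edge = process.loose_edges()[0]
        assert infer_start_types(process, edge, manual_domain) == {
            "MultipleNucleotideSequence"
        }

    def test_single_node_no_outputs(self, manual_domain):
        process = ProcessModel(
            nodes={"n": "showalign", "m": "showfeat"},
            edges=[Edge("n", "m", loose=True)],
            initial="n",
        )
        assert infer_start_types(process, process.edges[0], manual_domain) == frozenset()

    def test_branch_intersection(self):
        """Two branches produce {A,B} and {A,C}; only A is guaranteed."""
        tax = Taxonomy()
        for t in "ABC":
            tax.add_instance(t)
        domain = DomainModel(type_taxonomy=tax)
        domain.add_service(ServiceSpec("split", frozenset(), frozenset()))
        domain.add_service(ServiceSpec("mkAB", frozenset(), frozenset({"A", "B"})))
        domain.add_service(ServiceSpec("mkAC", frozenset(), frozenset({"A", "C"})))
        domain.add_service(ServiceSpec("merge", frozenset(), frozenset()))
        domain.add_service(ServiceSpec("sink", frozenset(), frozenset()))
        process = ProcessModel(
            nodes={"s": "split", "l": "mkAB", "r": "mkAC", "m": "merge", "t": "sink"},
            edges=[Edge("s", "l"), Edge("s", "r"), Edge("l", "m"), Edge("r", "m"),
                   Edge("m", "t", loose=True)],
            initial="s",
        )
        assert infer_start_types(process, process.edges[-1], domain) == {"A"}

    def test_unreachable_loose_edge(self, manual_domain):
        process = ProcessModel(
            nodes={"a": "makenucseq", "b": "showalign", "c": "showfeat"},
            edges=[Edge("b", "c", loose=True)],
            initial="a",
        )
        with pytest.raises(ContractViolation, match="unreachable"):
            infer_start_types(process, process.edges[0], manual_domain)


class TestInsertSolution:
    def test_single_service_insertion(self, manual_domain):
        process = workbench.load_fixture("example1")
        edge = process.loose_edges()[0]
        problem = problem_from_loose_edge(process, edge, manual_domain)
        emma = next(s for s in synthesize(problem, shortest_only=True)
                    if s.services == ("emma",))
        completed = insert_solution(process, edge, emma, manual_domain)
        assert not completed.loose_edges()
        chain = [completed.service_of(completed.initial)]
        node = completed.initial
        while completed.successors(node):
            node = completed.successors(node)[0]
            chain.append(completed.service_of(node))
        assert chain == ["makenucseq", "emma", "showalign"]

    def test_empty_solution_becomes_direct_edge(self, manual_domain):
        process = workbench.load_fixture("example2")
        edge = process.loose_edges()[0]
        problem = problem_from_loose_edge(process, edge, manual_domain)
        empty = synthesize(problem, shortest_only=True)[0]
        completed = insert_solution(process, edge, empty, manual_domain)
        assert completed.nodes == process.nodes
        assert not completed.loose_edges()
        assert Edge("start", "end") in completed.edges

    def test_three_step_insertion_gives_five_node_chain(self, manual_domain):
        process = workbench.load_fixture("example2")
        edge = process.loose_edges()[0]
        constraint = sltl.template_to_formula(
            "Enforce the use of module ehmmemit", manual_domain
        )
        problem = problem_from_loose_edge(process, edge, manual_domain,
                                          constraints=[constraint])
        emma_first = next(s for s in synthesize(problem, shortest_only=True)
                          if s.services[0] == "emma")
        completed = insert_solution(process, edge, emma_first, manual_domain)
        assert len(completed.nodes) == 5
        assert completed.service_of("syn1") == "emma"

    def test_invalid_solution_rejected(self, manual_domain):
        from flowsynth.synthesis import Solution

        process = workbench.load_fixture("example1")
        edge = process.loose_edges()[0]
        bogus = Solution(("ehmmalign",), frozenset())
        with pytest.raises(ContractViolation):
            insert_solution(process, edge, bogus, manual_domain)


class TestValidityPredicate:
    def test_rejects_non_replayable_sequence(self, manual_domain):
        problem = SynthesisProblem(
            manual_domain, frozenset(), frozenset(), depth_bound=2
        )
        assert is_valid_solution(problem, ())
        assert not is_valid_solution(problem, ("ehmmalign",))
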