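# Methods

## The domain model

A domain is a finite set of services, each characterised by two sets of
symbolic type names — mandatory inputs and produced outputs — plus two
taxonomies (one over types, one over services) and an ordered list of global
constraint strings.  A taxonomy is an acyclic is-a hierarchy of classes
rooted at a most-general class (`Thing`), with concrete names attached to
one or more classes by instance-of links; a concrete name with no explicit
parent is implicitly a direct instance of the root.  `subsumes(g, s)` holds
when `s = g` or `g` is reachable from `s` via instance-of followed by is-a
steps; it is reflexive and transitive, and the root subsumes every known
name.

Execution is *type accumulation*.  A state is a set of available type
names.  A requirement `r` is satisfied by a state `S` when some `t ∈ S` is
subsumed by `r` (specific satisfies general: a `MultipleNucleotideSequence`
in the state satisfies a requirement for `MultipleSequence`).  A service is
applicable when all its inputs are satisfied, and its successor state is
`S ∪ outputs`.  Consequences used throughout: states grow monotonically
along executions, applicability is monotone in the state, and the successor
commutes with state enlargement.  Requirements may themselves be abstract
class names; matching uses the same closure, which the generated domain
exploits (service inputs like `sequence_record` are taxonomy classes).

`validate_domain` reports unknown type references, is-a cycles, names used
as both class and instance, inputs that no declared or producible type could
ever satisfy, and — only when explicit start states are passed — services
that can never fire in the accumulation closure of those starts.  The
reachability check is opt-in because a well-formed catalogue legitimately
contains services (the HMM-database tools in the bundled subset) whose
inputs no bundled generator produces.

## Temporal logic over executions

Constraints are interpreted over finite traces `s0 a1 s1 … an sn` with an
LTLf-style semantics: `Exec(C)` holds at position `i < n` iff the next
executed service `a_{i+1}` is subsumed by `C` in the service taxonomy (an
abstract name is thus equivalent to the disjunction of its instances);
`Avail(T)` consults the state through the type taxonomy; `End` holds exactly
at position `n`; `Next` is strong; `WeakUntil(p, q) ≡ G p ∨ p U q`.  The
empty trace has one position, so `F Exec(x)` is false and `G ¬Exec(x)` true
on it — which is why “Use X as last service in solution” (`F(Exec(X) ∧ X
End)`) rejects the empty solution: there is no last service.

Natural-language templates supported: *Enforce the use of module X*,
*Use X as last service in solution*, *Do not use X*, and *Use A before B*
(`¬Exec(B) WU Exec(A)`).  The first two are the scenario-bearing ones; the
other two are routine avoidance/ordering forms.  Template formulas render
back to their sentences, and a conventional infix grammar
(`! & | => X F G U WU`, atoms are service names or classes, `@name` for
type availability) serves logs, process files and the checker.

## Synthesis

A problem is (domain, start state, goal types, constraints, depth bound,
solution cap).  The search space — the configuration universe — is never
materialised; the search expands `(state, residual-formula)` pairs on the
fly.  The residual is computed by *formula progression*: the obligation that
must hold on the rest of the trace after executing one service, with
constant folding so equal obligations merge.  A solution is emitted when the
goal types are all satisfied in the current state (same subsumption matching
as service inputs, since the goal is literally the downstream service's
input set) and the residual is accepted at a final position.  Pairs whose
residual simplifies to false are pruned — the “parallel evaluation” of
search space and specification.

Two modes:

* *Exhaustive to bound* (default): every solution of length ≤ bound is
  enumerated, ordered by length then lexicographically by service names,
  truncated at the cap (default 1000 — unconstrained domains easily admit
  thousands of sequence-to-sequence variations).  Pairs are merged only
  within a BFS level: prefixes reaching the same pair share all
  continuations but remain distinct solutions, so the enumeration is
  provably identical to brute force.
* *Shortest only*: visited pairs are additionally pruned across levels
  (a revisited pair cannot begin a shorter suffix) and the search stops at
  the first emitting depth, returning all shortest solutions.

`brute_force_oracle` is the independent correctness reference: depth-first
enumeration of applicable sequences (replay-validity is prefix-closed, so
pruning invalid prefixes equals filtering the full enumeration), each
checked directly with whole-trace evaluation rather than progression.  The
test and acceptance suites assert sequence-exact agreement on the fixture
problems and on 200 seeded random domains with depth bounds 2–4; the bounds
keep naive enumeration affordable while covering empty, singleton and
branching result sets.

Start types at a loose edge are inferred by data-flow analysis: the
intersection, over all simple control-flow paths from the initial node to
the edge's source (inclusive), of the accumulated output types — the
largest set consistent with every way of reaching the branch.  Tie-breaking
among equal-length solutions is lexicographic so that a command-line run is
deterministic where an interactive tool would offer a choice list.  Cost-
weighted ranking is deliberately only a hook: solutions are returned in a
stable order for downstream selection, but no cost model is implemented.

## Verification

Finished (loose-edge-free) processes are checked per node: a property holds
at node `v` iff it is satisfied on every maximal control-flow path from
`v`.  Traces here are node-labelled: position `i` executes the `i`-th
node's service, so `Exec` atoms refer to the node at the current position,
and a finite path (ending at a sink) is evaluated exactly like a finite
execution whose `End` position follows the sink.  On chains this provably
coincides with trace evaluation, which the suite asserts on randomized
chains.  Paths that enter a cycle are infinite; they are evaluated in lasso
form (`stem · cycle^ω`) by per-subformula fixpoint computation over the
lasso positions (least fixpoints for `U`/`F`, greatest for `G`).

Path enumeration is bounded: each edge may be traversed at most
`edge_budget` times (default 2), and every cycle closure encountered is also
evaluated as a lasso.  On acyclic graphs the enumeration is exhaustive and
verdicts are exact; on cyclic graphs the check is a bounded one, exact
whenever a violation needs no more than the budgeted number of traversals
of any edge — which covers the nested-loop-free process graphs this package
targets.  A full Büchi-product checker would remove the bound but is out of
proportion for graphs of this size.  `Avail` atoms are rejected in process
checking: a process graph fixes the service order but not the data states,
so type-availability properties are only meaningful during synthesis.

## Automatic domain construction

The importer consumes the ACD dialect `kind: name [ attr: value … ]` with
`section:`/`endsection:` brackets, multiline quoted strings, `#` comments,
and `relation` attributes holding `"PREFIX: id ! label"` term references
(parsed leniently).  Sections `required`, `additional` and `advanced` are
parsed but contribute no I/O types; one input/output-section parameter
contributes at most one type.  OBO ontologies are read through `obonet`;
obsolete terms are kept in the ontology object but excluded from taxonomy
building.  Top-level terms named `operation` seed the service taxonomy and
the remaining top-level terms the type taxonomy, following the EDAM
data/operation branch convention; both can be overridden explicitly.

Derived type naming, reconstructed to reproduce the bundled reference table
and pinned by fixture tests:

1. a parameter whose relation term does *not* resolve in the imported
   ontology contributes a type named after the term's label (sanitised:
   lower-cased, non-alphanumerics collapsed to `_`), placed directly under
   the root — annotated but not (yet) covered by the ontology;
2. an *input* whose term resolves contributes the taxonomy class itself as
   the requirement;
3. an *output* whose term resolves keeps a tool-specific generated name and
   becomes an instance of the term's class;
4. generated names use the parameter's `knowntype` attribute when present
   (sanitised), else `<application>_<datatype>_output` (resp. `_input`).

Services are placed under the class of their first resolvable application
relation (additional relations are retained in the document object only);
everything unannotated stays a direct instance of the root.  Annotation
statistics report, over a descriptor collection: the percentage of files
with any/application/parameter relations, the percentage of parameters with
relations, and min/max/mean relation counts per file taken over the files
that have any (zeros otherwise).

## Fixtures and the random-domain generator

The bundled fixtures transcribe the HMMER subset of the EMBOSS collection:
17 services — the nine `ehmm*` tools plus the alignment, sequence-generation
and display tools — in a curated domain (high-level names,
Edit/Display/AlignmentMultiple/HMM service groups, a
Text/Sequence/Protein-Nucleotide-Multiple type hierarchy) and in a generated
domain built at load time from 17 bundled ACD descriptors and a compact
EDAM-style ontology (synthetic fixture files authored for this package; the
ontology's `mini_edam.obo` models the data/operation branches with local
term ids).  One source names a `showtext` display tool where the service
table lists `showalign/showfeat/showpep/showseq`; the fixtures follow the
table.  The remote-loop scenario ships as a scaled-down fixture: stub
services with declared output types stand for the DDBJ/BLAST/Uniprot steps,
and a handful of reconstructed protein-structure/report tools (`pepwheel`,
`garnier`, `pepcoil`, `showreport`) plus a `Protein2dStructure` group make
the abstract-constraint workflow expressible; its tests assert structural
properties of the solutions (an enforced structure-analysis step, a
display-class terminal service), not any specific sequence, since the full
tool collection is out of scope.

The random-domain generator is a pure function of its spec (seed, 6 types,
8 services, ≤2 inputs/outputs, taxonomy depth 2, grouping probability 0.5
by default — sized so that brute-force enumeration to depth 4 stays cheap
while subsumption, sources, sinks and dead ends all occur).  It guarantees
at least one no-input source service and only ever uses satisfiable
requirements, so generated domains validate cleanly; random problems
deliberately include unsatisfiable goals so both empty and non-empty result
sets are exercised.  What passing these suites shows is agreement between
two independent computations of the same semantics on small symbolic
domains; it says nothing about whether a real tool collection's annotations
are semantically adequate — the two bundled domains exist precisely to show
both outcomes of that adequacy question.

## Numerical and degenerate-input choices

* Default synthesis depth bound 6, solution cap 1000; caps apply after
  ordering (length, then lexicographic), so truncation is deterministic.
* The empty service sequence is a legitimate solution considered at depth 0.
* Applying an inapplicable service raises a contract violation; `replay` of
  a candidate sequence is therefore also its validity check.
* Unknown symbolic names raise lookup errors carrying near-miss suggestions.
* Domain and process files are YAML with a fixed section layout; read/write
  round-trips are identity on all fixtures, and malformed files raise parse
  errors with line positions where the underlying parser provides them.
* CLI exit codes separate legitimate negative outcomes (3: no solution,
  property violated) from errors (1) and usage problems (2).

## Known limitations

* Process checking is bounded on cyclic graphs (see above) and rejects
  type-availability atoms.
* The ACD dialect omits expression evaluation (`$(var)` substitution,
  computed defaults); such values are captured verbatim.
* OWL ontologies are not read; the is-a/instance-of structure carried by
  the OBO import is the supported equivalent.
* Optional tool parameters are not modelled: all declared inputs are
  mandatory, matching the flat input sets of the reference tables.
* Cost-based solution ranking is an interface hook only.
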