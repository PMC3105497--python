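# flowsynth

Semantics-based composition and verification of bioinformatics service
workflows.

Suites like EMBOSS offer hundreds of command-line tools whose inputs and
outputs are compatible in ways no single user can keep in their head.
`flowsynth` models such a collection as a *domain*: every service is
described by two sets of symbolic type names (its inputs and outputs), and
both services and types are organised in is-a taxonomies with concrete
instances — e.g. `MultipleNucleotideSequence` *instance-of*
`MultipleSequence` *is-a* `Sequence`.  On top of that model the package
provides:

* **Synthesis of loosely specified branches.**  A workflow graph may mark an
  edge as *loose*; `flowsynth` computes the types guaranteed to be available
  there (data-flow intersection over all incoming paths), takes the
  downstream service's inputs as the goal, and searches the *configuration
  universe* — states are sets of available types `S`, and an applicable
  service `a` yields `S' = S ∪ out(a)` whenever every `t ∈ in(a)` is
  satisfied by some available type through subsumption — for service
  sequences that close the gap.  The breadth-first search runs in parallel
  with a linear-temporal-logic constraint formula (finite-trace semantics,
  evaluated by formula progression), so constraints such as
  `F Exec(ehmmemit)` prune the search rather than filter its output.
  Constraints can be written as natural-language templates
  (“Enforce the use of module X”, “Use X as last service in solution”, …).
* **Model checking of finished processes.**  A PLTL property such as
  `ehmmbuild ⇒ (¬ehmmemit WU ehmmcalibrate)` is checked at every node of a
  process graph: a node satisfies the property when every maximal
  control-flow path from it does (finite paths end with `End`; cyclic paths
  are evaluated as lassos with infinite-trace semantics).
* **Automatic domain construction.**  An importer parses EMBOSS ACD tool
  descriptors and an OBO ontology (EDAM-style), derives symbolic I/O types
  per tool from the parameter annotations, links services and types to
  ontology terms, and reports annotation-coverage statistics.

Bundled fixtures transcribe the HMMER subset of the EMBOSS collection in two
forms — a curated, manually named domain and one generated from descriptors —
so every feature is exercisable offline.

## Worked example

```
$ flowsynth fixtures export fx
$ flowsynth synthesize fx/processes/example1.yaml \
      --domain fx/manual_hmmer.domain.yaml --shortest
2 solution(s) for loose edge start -> end (start types: MultipleNucleotideSequence; goal: Alignment):
  edialign
  emma
```

The process generates random nucleotide sequences (`makenucseq`) and wants
to display an alignment (`showalign`).  The only type available at the loose
edge is `MultipleNucleotideSequence`; the goal is `showalign`'s input type
`Alignment`.  Both multiple-alignment services accept the start type
(through `MultipleNucleotideSequence` instance-of `MultipleSequence`) and
produce `Alignment`, so the two one-step completions are the shortest
solutions.  Over the automatically generated domain the same request fails —
exit code 3 distinguishes “no solution” from an error:

```
$ flowsynth synthesize fx/processes/example1.yaml --domain fx/auto_hmmer.domain.yaml
no solution for loose edge start -> end within bound 6
```

because no generated annotation produces `sequence_alignment_data`, the
derived input of `showalign`; the alignment tools' outputs are only
classified as `sequence_record`.  Constrained synthesis and checking:

```
$ flowsynth synthesize fx/processes/example2.yaml \
      --domain fx/manual_hmmer.domain.yaml \
      --constraint "Enforce the use of module ehmmemit"
2 solution(s) for loose edge start -> end (start types: MultipleProteinSequence; goal: Sequence):
  edialign -> ehmmbuild -> ehmmemit
  emma -> ehmmbuild -> ehmmemit

$ flowsynth check fx/processes/fig11_build.yaml \
      --domain fx/manual_hmmer.domain.yaml \
      --formula "ehmmbuild => (!ehmmemit WU ehmmcalibrate)"
n_build (ehmmbuild): VIOLATED  [witness: n_build -> n_emit -> n_show]
n_emit (ehmmemit): holds
n_emma (emma): holds
n_show (showseq): holds
violated at: n_build
```

## Layout

```
src/flowsynth/
  domain_model.py   types, taxonomies, subsumption, type-accumulation semantics
  sltl.py           temporal-logic AST, finite-trace evaluation, progression,
                    constraint templates, concrete syntax
  synthesis.py      product BFS, brute-force oracle, start-type inference
  verification.py   per-node PLTL checking with lasso semantics
  importers.py      ACD + OBO import, auto domain build, annotation stats
  process.py        workflow graphs and process files
  workbench.py      bundled fixtures, seeded random-domain generator
  cli.py            `flowsynth` command-line interface
  data/             ACD descriptors, mini ontology, example processes
```

See `docs/methods.md` for the model, its assumptions and the numerical and
design choices.
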