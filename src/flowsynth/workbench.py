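"""Bundled fixtures and the seeded random-domain generator.

The fixtures transcribe the HMMER subset of the EMBOSS collection in two
forms: a *manual* domain with curated high-level type names
(``MultipleNucleotideSequence``, ``Alignment``, ``HMM`` ...) and an *auto*
domain derived at load time from the bundled ACD descriptors and the compact
EDAM-style ontology via :mod:`flowsynth.importers`.  Example processes (the
loose alignment/display workflows, the HMM-calibration checking trio and the
remote-services loop skeleton) are shipped as process files.

The random-domain generator produces small, well-formed domains as a pure
function of a seed, used by the property suites that compare the product
search against the brute-force oracle.
"""

from __future__ import annotations

import difflib
import random
from dataclasses import dataclass
from importlib import resources

import yaml

from . import importers, sltl
from .domain_model import DomainModel, ServiceSpec, Taxonomy
from .errors import UnknownNameError
from .process import process_from_dict
from .synthesis import SynthesisProblem

_TABLE_DESCRIPTIONS = {
    "edialign": "Local multiple alignment of sequences.",
    "ehmmalign": "Align sequences to an HMM profile.",
    "ehmmbuild": "Build a profile HMM from an alignment.",
    "ehmmcalibrate": "Calibrate HMM search statistics.",
    "ehmmconvert": "Convert between profile HMM file formats.",
    "ehmmemit": "Generate sequences from a profile HMM.",
    "ehmmfetch": "Retrieve an HMM from an HMM database.",
    "ehmmindex": "Create a binary SSI index for an HMM database.",
    "ehmmpfam": "Search one or more sequences against an HMM database.",
    "ehmmsearch": "Search sequence database with a profile HMM.",
    "emma": "Global multiple alignment of sequences.",
    "makenucseq": "Create random nucleotide sequences.",
    "makeprotseq": "Create random protein sequences.",
    "showalign": "Display a multiple sequence alignment in pretty format.",
    "showfeat": "Display features of a sequence in pretty format.",
    "showpep": "Displays protein sequences with features in pretty format.",
    "showseq": "Display sequences with features in pretty format.",
}

# service -> (input types, output types), curated nomenclature
_MANUAL_IO: dict[str, tuple[set[str], set[str]]] = {
    "edialign": ({"MultipleSequence"}, {"Alignment"}),
    "ehmmalign": ({"HMM", "Sequence"}, {"Alignment"}),
    "ehmmbuild": ({"Alignment"}, {"HMM"}),
    "ehmmcalibrate": ({"HMM"}, {"HMM"}),
    "ehmmconvert": ({"HMM"}, {"HMM"}),
    "ehmmemit": ({"HMM"}, {"EhmmemitOutput"}),
    "ehmmfetch": ({"HMMDatabase"}, {"HMM"}),
    "ehmmindex": ({"HMMDatabase"}, {"HMMDatabase"}),
    "ehmmpfam": ({"HMMDatabase", "Sequence"}, {"EhmmpfamOutput"}),
    "ehmmsearch": ({"HMM", "SequenceDatabase"}, {"EhmmsearchOutput"}),
    "emma": ({"MultipleSequence"}, {"Alignment", "Tree"}),
    "makenucseq": (set(), {"MultipleNucleotideSequence"}),
    "makeprotseq": (set(), {"MultipleProteinSequence"}),
    "showalign": ({"Alignment"}, set()),
    "showfeat": ({"Sequence"}, set()),
    "showpep": ({"ProteinSequence"}, set()),
    "showseq": ({"NucleotideSequence"}, set()),
}

# service group -> members (the display group follows the service table; a
# figure caption in the source material instead names a "showtext" tool that
# the table does not list)
_MANUAL_SERVICE_GROUPS = {
    "Edit": ["makenucseq", "makeprotseq"],
    "Display": ["showalign", "showfeat", "showpep", "showseq"],
    "AlignmentMultiple": ["edialign", "emma"],
    "HMM": [
        "ehmmalign", "ehmmbuild", "ehmmcalibrate", "ehmmconvert", "ehmmemit",
        "ehmmfetch", "ehmmindex", "ehmmpfam", "ehmmsearch",
    ],
}


def manual_hmmer_domain() -> DomainModel:
    """The curated HMMER-subset domain: 17 services, high-level type names."""
    type_tax = Taxonomy()
    type_tax.add_class("Text", ["Thing"])
    type_tax.add_class("Sequence", ["Text"])
    for cls in ("ProteinSequence", "NucleotideSequence", "MultipleSequence"):
        type_tax.add_class(cls, ["Sequence"])
    type_tax.add_instance("MultipleNucleotideSequence", ["MultipleSequence", "NucleotideSequence"])
    type_tax.add_instance("MultipleProteinSequence", ["MultipleSequence", "ProteinSequence"])
    for t in ("Alignment", "HMM", "HMMDatabase", "SequenceDatabase", "Tree",
              "EhmmemitOutput", "EhmmpfamOutput", "EhmmsearchOutput"):
        type_tax.add_instance(t, ["Text"])

    service_tax = Taxonomy()
    member_groups: dict[str, list[str]] = {}
    for group, members in _MANUAL_SERVICE_GROUPS.items():
        service_tax.add_class(group, ["Thing"])
        for m in members:
            member_groups.setdefault(m, []).append(group)

    domain = DomainModel(type_taxonomy=type_tax, service_taxonomy=service_tax)
    for name, (ins, outs) in _MANUAL_IO.items():
        domain.add_service(
            ServiceSpec(name, frozenset(ins), frozenset(outs), _TABLE_DESCRIPTIONS[name]),
            member_groups.get(name, []),
        )
    return domain


def example3_domain() -> DomainModel:
    """Manual domain extended with remote-service stubs and a few protein
    structure/report tools, enough to exercise abstract-group constraints.

    The stub services stand for the DDBJ/BLAST/Uniprot steps of the remote
    workflow skeleton; their I/O types are declared here, not executed.  The
    extra EMBOSS entries (pepwheel, garnier, pepcoil, showreport) are
    reconstructions in the same nomenclature as the curated table.
    """
    domain = manual_hmmer_domain()
    tt, st = domain.type_taxonomy, domain.service_taxonomy

    tt.add_class("Report", ["Text"])
    tt.add_instance("DdbjNucleotideSequence", ["NucleotideSequence"])
    tt.add_instance("SingleProteinSequence", ["ProteinSequence"])
    for t in ("BlastReport", "UniprotID", "PepwheelPlot"):
        tt.add_instance(t, ["Text"])
    for t in ("GarnierReport", "PepcoilReport"):
        tt.add_instance(t, ["Report"])

    st.add_class("Protein2dStructure", ["Thing"])
    st.add_class("Remote", ["Thing"])

    stubs = [
        ("fetch_ddbj_entry", set(), {"DdbjNucleotideSequence"},
         "Stub: fetch a nucleotide entry from DDBJ."),
        ("blast_search", {"NucleotideSequence"}, {"BlastReport"},
         "Stub: BLAST search against a protein database."),
        ("extract_uniprot_ids", {"BlastReport"}, {"UniprotID"},
         "Stub: extract Uniprot identifiers from a BLAST report."),
        ("fetch_uniprot_entry", {"UniprotID"}, {"SingleProteinSequence"},
         "Stub: fetch the Uniprot entry for an identifier."),
        ("next_uniprot_id", set(), set(), "Stub: advance the identifier loop."),
        ("collect_results", set(), set(), "Stub: gather per-entry results."),
    ]
    for name, ins, outs, doc in stubs:
        domain.add_service(ServiceSpec(name, frozenset(ins), frozenset(outs), doc), ["Remote"])

    extras = [
        ("pepwheel", {"ProteinSequence"}, {"PepwheelPlot"},
         "Draw a helical wheel diagram for a protein sequence.",
         ["Protein2dStructure", "Display"]),
        ("garnier", {"ProteinSequence"}, {"GarnierReport"},
         "Predict protein secondary structure.", ["Protein2dStructure"]),
        ("pepcoil", {"ProteinSequence"}, {"PepcoilReport"},
         "Predict coiled-coil regions in protein sequences.", ["Protein2dStructure"]),
        ("showreport", {"Report"}, set(),
         "Display the textual content of a report.", ["Display"]),
    ]
    for name, ins, outs, doc, groups in extras:
        domain.add_service(ServiceSpec(name, frozenset(ins), frozenset(outs), doc), groups)
    return domain


# ---------------------------------------------------------------------------
# Fixture loading
# ---------------------------------------------------------------------------

def _data_text(*parts: str) -> str:
    path = resources.files("flowsynth").joinpath("data", *parts)
    return path.read_text()


def acd_texts() -> dict[str, str]:
    """All bundled ACD descriptor texts, keyed by application name."""
    base = resources.files("flowsynth").joinpath("data", "acd")
    return {p.name[:-4]: p.read_text() for p in sorted(base.iterdir(), key=lambda p: p.name)
            if p.name.endswith(".acd")}


def auto_hmmer_domain() -> DomainModel:
    """The HMMER-subset domain derived from the bundled ACD files and the
    compact EDAM-style ontology through the import pipeline."""
    ontology = importers.parse_obo(_data_text("mini_edam.obo"))
    acds = [importers.parse_acd(text) for text in acd_texts().values()]
    return importers.build_auto_domain(acds, ontology)

_PROCESS_NAMES = (
    "example1", "example2", "example3",
    "fig11_build", "fig11_calibrated", "fig11_fetch",
)

_TEXT_FIXTURES = {
    "edialign_acd": ("acd", "edialign.acd"),
    "mini_edam_obo": ("mini_edam.obo",),
}


def load_fixture(name: str):
    """Load a bundled fixture by name.

    Domains: ``manual_hmmer``, ``auto_hmmer``, ``example3_domain``.
    Processes: ``example1``, ``example2``, ``example3``, ``fig11_build``,
    ``fig11_calibrated``, ``fig11_fetch``.
    Texts: ``edialign_acd``, ``mini_edam_obo``.
    """
    if name == "manual_hmmer":
        return manual_hmmer_domain()
    if name == "auto_hmmer":
        return auto_hmmer_domain()
    if name == "example3_domain":
        return example3_domain()
    if name in _PROCESS_NAMES:
        return process_from_dict(yaml.safe_load(_data_text("processes", f"{name}.yaml")))
    if name in _TEXT_FIXTURES:
        return _data_text(*_TEXT_FIXTURES[name])
    known = ["manual_hmmer", "auto_hmmer", "example3_domain", *_PROCESS_NAMES, *_TEXT_FIXTURES]
    raise UnknownNameError(name, "not a fixture", tuple(difflib.get_close_matches(name, known, n=3)))


# ---------------------------------------------------------------------------
# Seeded random domains
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RandomDomainSpec:
    """Parameters of the random-domain generator (a pure function of these)."""

    seed: int
    n_types: int = 6
    n_services: int = 8
    max_inputs: int = 2
    max_outputs: int = 2
    taxonomy_depth: int = 2
    p_abstract_grouping: float = 0.5

    def __post_init__(self) -> None:
        if min(self.n_types, self.n_services, self.max_outputs, self.taxonomy_depth) < 1:
            raise ValueError("all counts must be positive")


def generate_random_domain(spec: RandomDomainSpec) -> DomainModel:
    """A small well-formed domain, deterministic for a given spec.

    At least one service has no inputs, so every generated domain admits
    non-trivial synthesis problems; groupings give subsumption something to
    do with probability ``p_abstract_grouping``.
    """
    rng = random.Random(spec.seed)
    type_tax = Taxonomy()
    n_classes = max(1, spec.n_types // 2)
    depth = {type_tax.root: 0}
    class_names = []
    for i in range(n_classes):
        cls = f"TGroup{i + 1:02d}"
        candidates = [c for c in (type_tax.root, *class_names) if depth[c] < spec.taxonomy_depth]
        parent = rng.choice(candidates)
        type_tax.add_class(cls, [] if parent == type_tax.root else [parent])
        depth[cls] = depth[parent] + 1
        class_names.append(cls)
    type_names = [f"t{i + 1:02d}" for i in range(spec.n_types)]
    for t in type_names:
        if rng.random() < spec.p_abstract_grouping:
            parents = rng.sample(class_names, k=min(len(class_names), rng.choice((1, 1, 2))))
            type_tax.add_instance(t, parents)
        else:
            type_tax.add_instance(t)

    service_tax = Taxonomy()
    service_groups = []
    for i in range(max(1, spec.n_services // 4)):
        grp = f"SGroup{i + 1:02d}"
        service_tax.add_class(grp, [])
        service_groups.append(grp)

    domain = DomainModel(type_taxonomy=type_tax, service_taxonomy=service_tax)
    n_sources = max(1, spec.n_services // 4)
    # only classes with instances make satisfiable requirements
    requirable = type_names + [c for c in class_names if type_tax.instances_of(c)]
    for i in range(spec.n_services):
        name = f"svc{i + 1:02d}"
        if i < n_sources:
            inputs: list[str] = []
        else:
            k = rng.randint(0, spec.max_inputs)
            inputs = rng.sample(requirable, k=min(k, len(requirable)))
        n_out = rng.randint(0 if inputs else 1, spec.max_outputs)
        outputs = rng.sample(type_names, k=min(n_out, len(type_names)))
        groups = [rng.choice(service_groups)] if rng.random() < spec.p_abstract_grouping else []
        domain.add_service(
            ServiceSpec(name, frozenset(inputs), frozenset(outputs), f"random service {name}"),
            groups,
        )
    return domain


def random_problem(
    domain: DomainModel,
    rng: random.Random,
    depth_bound: int = 3,
    with_constraints: bool = True,
) -> SynthesisProblem:
    """A seeded synthesis problem over *domain* for the property suites.

    Starts from the outputs of a random no-input service (plus occasionally
    an extra type), aims at up to two random types, and attaches up to two
    template constraints; unsatisfiable combinations are intentionally kept,
    so empty and non-empty result sets both occur.
    """
    sources = [s for s in domain.services.values() if not s.inputs]
    start = set(rng.choice(sources).outputs) if sources else set()
    instances = sorted(domain.type_taxonomy.instances)
    if instances and rng.random() < 0.3:
        start.add(rng.choice(instances))
    goal = frozenset(rng.sample(instances, k=min(len(instances), rng.randint(0, 2))))

    constraints = []
    if with_constraints:
        service_names = sorted(domain.services)
        groups = sorted(domain.service_taxonomy.classes - {domain.service_taxonomy.root})
        pool = service_names + groups
        for _ in range(rng.randint(0, 2)):
            target = rng.choice(pool)
            kind = rng.choice(("enforce", "avoid", "last", "before"))
            if kind == "enforce":
                text = f"Enforce the use of module {target}"
            elif kind == "avoid":
                text = f"Do not use {target}"
            elif kind == "last":
                text = f"Use {target} as last service in solution"
            else:
                text = f"Use {target} before {rng.choice(pool)}"
            constraints.append(sltl.template_to_formula(text, domain))
    return SynthesisProblem(
        domain=domain,
        start=frozenset(start),
        goal=goal,
        constraints=constraints,
        depth_bound=depth_bound,
        solution_cap=100_000,
    )
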