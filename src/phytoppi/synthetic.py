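"""A fully synthetic organism for end-to-end testing of the pipeline.

The generator plants the statistical structure the predictor's features
assume: interacting proteins are organized into small *modules*
(complex-like groups) whose members

* share low-complexity sequence segments drawn from a small common pool
  (a learnable, if artificial, signal for the sequence branch),
* share a module-specific Cellular Component GO term with probability
  ``funsim_boost`` (plus their compartment's CC term, always),
* are co-expressed with target correlation ``coexpr_rho`` on both
  platforms,
* share their phylogenetic presence pattern across reference genomes
  with per-genome probability ``profile_overlap``,
* co-occur (via their module BP/CC terms) in a toy literature corpus.

Non-module "background" proteins carry none of these signals.  All
generators are pure functions of (spec, seed): the same spec always
yields byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import io
from .go_semantics import GoDag
from .io import AnnotationRecord, PairRecord, ProteinRecord

AA = "ACDEFGHIKLMNPQRSTVWY"
# background amino-acid frequencies: mildly nonuniform, vertebrate-like
AA_FREQ = np.array(
    [8.3, 1.4, 5.4, 6.7, 3.9, 7.1, 2.3, 6.0, 5.8, 9.7,
     2.4, 4.1, 4.7, 3.9, 5.5, 6.6, 5.4, 6.9, 1.1, 2.9]
)
AA_FREQ = AA_FREQ / AA_FREQ.sum()

#: Low-complexity dipeptide repeats shared by interacting proteins.  Four
#: compositionally extreme families keep the pool small enough to learn.
MOTIF_UNITS = ("KE", "FW", "GP", "RD")


@dataclass
class FixtureSpec:
    """Parameters of the synthetic organism.

    The signal strengths (``coexpr_rho``, ``profile_overlap``,
    ``funsim_boost``) are the planted effect sizes; setting one to zero
    removes that feature's information entirely.
    """

    n_proteins: int = 400
    length_range: tuple[int, int] = (60, 300)
    n_compartments: int = 6
    dag_terms_per_aspect: int = 24
    n_positive_pairs: int = 400
    module_size: int = 4
    coexpr_rho: float = 0.8
    profile_overlap: float = 0.9
    funsim_boost: float = 0.8
    motif_share: float = 1.0
    motif_length: int = 48
    extra_cc_prob: float = 0.2
    coexpr_coverage: float = 0.9
    n_reference_genomes: int = 100
    n_samples: int = 50
    n_noise_documents: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("coexpr_rho", "profile_overlap", "funsim_boost",
                     "motif_share", "extra_cc_prob", "coexpr_coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if self.length_range[0] < 50:
            raise ValueError("generated proteins must be at least 50 residues")
        pairs_per_module = self.module_size * (self.module_size - 1) // 2
        self.n_modules = math.ceil(self.n_positive_pairs / pairs_per_module)
        if self.n_modules * self.module_size > self.n_proteins:
            raise ValueError(
                f"{self.n_positive_pairs} positive pairs need "
                f"{self.n_modules * self.module_size} module proteins, "
                f"but n_proteins={self.n_proteins}"
            )


@dataclass
class SyntheticWorld:
    """Everything the pipeline consumes, generated from one spec."""

    spec: FixtureSpec
    proteins: dict[str, ProteinRecord]
    positives: list[PairRecord]
    module_of: dict[str, int]
    cc_dag: GoDag
    bp_dag: GoDag
    mf_dag: GoDag
    documents: list[set[str]] = field(default_factory=list)
    microarray: pd.DataFrame | None = None
    rnaseq: pd.DataFrame | None = None
    profiles: pd.DataFrame | None = None

    @property
    def localizations(self) -> dict[str, set[str]]:
        return {pid: p.localizations for pid, p in self.proteins.items()}

    def annotations_by_aspect(self, aspect: str) -> dict[str, set[str]]:
        return {
            pid: p.terms(aspect) for pid, p in self.proteins.items() if p.terms(aspect)
        }


def _toy_dag(prefix: str, aspect: str, n_terms: int, rng) -> tuple[GoDag, list[str]]:
    """A small random DAG: root -> mid layer -> leaves; returns (dag, leaves)."""
    root = f"{prefix}:root"
    n_mid = max(2, n_terms // 4)
    mids = [f"{prefix}:m{i}" for i in range(n_mid)]
    leaves = [f"{prefix}:l{i}" for i in range(n_terms)]
    g = nx.DiGraph()
    for m in mids:
        g.add_edge(m, root)
    for leaf in leaves:
        parents = rng.choice(n_mid, size=1 + int(rng.random() < 0.25), replace=False)
        for p in parents:
            g.add_edge(leaf, mids[p])
    dag = GoDag(g, aspect_of={t: aspect for t in g})
    return dag, leaves


def _cc_dag(spec: FixtureSpec) -> tuple[GoDag, list[str], list[str]]:
    """CC DAG: root -> compartment terms -> module terms."""
    root = "CC:root"
    comps = [f"CC:comp{i}" for i in range(spec.n_compartments)]
    mods = [f"CC:mod{i}" for i in range(spec.n_modules)]
    g = nx.DiGraph()
    for c in comps:
        g.add_edge(c, root)
    for i, m in enumerate(mods):
        g.add_edge(m, comps[i % spec.n_compartments])
    dag = GoDag(g, aspect_of={t: "CC" for t in g})
    return dag, comps, mods


def _random_sequence(length: int, rng) -> str:
    idx = rng.choice(20, size=length, p=AA_FREQ)
    return "".join(AA[i] for i in idx)


def _motif(module: int, length: int) -> str:
    unit = MOTIF_UNITS[module % len(MOTIF_UNITS)]
    return (unit * (length // len(unit) + 1))[:length]


def generate_universe(spec: FixtureSpec) -> SyntheticWorld:
    """Generate proteins, annotations, localizations and positive pairs."""
    rng = np.random.default_rng(spec.seed)
    cc_dag, comp_terms, mod_terms = _cc_dag(spec)
    bp_dag, bp_leaves = _toy_dag("BP", "BP", max(spec.dag_terms_per_aspect, spec.n_modules), rng)
    mf_dag, mf_leaves = _toy_dag("MF", "MF", spec.dag_terms_per_aspect, rng)

    n_module_proteins = spec.n_modules * spec.module_size
    proteins: dict[str, ProteinRecord] = {}
    module_of: dict[str, int] = {}
    width = len(str(spec.n_proteins))
    for i in range(spec.n_proteins):
        pid = f"SYN{i:0{width}d}"
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        seq = _random_sequence(length, rng)
        in_module = i < n_module_proteins
        module = i // spec.module_size if in_module else None
        if in_module and rng.random() < spec.motif_share:
            pos = int(rng.integers(0, length + 1))
            seq = seq[:pos] + _motif(module, spec.motif_length) + seq[pos:]
        compartment = (
            module % spec.n_compartments if in_module else int(rng.integers(spec.n_compartments))
        )
        annots = [AnnotationRecord(comp_terms[compartment], "CC")]
        if in_module:
            module_of[pid] = module
            if rng.random() < spec.funsim_boost:
                annots.append(AnnotationRecord(mod_terms[module], "CC"))
            annots.append(AnnotationRecord(bp_leaves[module % len(bp_leaves)], "BP"))
        else:
            annots.append(
                AnnotationRecord(bp_leaves[int(rng.integers(len(bp_leaves)))], "BP")
            )
        if rng.random() < spec.extra_cc_prob:
            annots.append(
                AnnotationRecord(mod_terms[int(rng.integers(len(mod_terms)))], "CC")
            )
        annots.append(AnnotationRecord(mf_leaves[int(rng.integers(len(mf_leaves)))], "MF"))
        proteins[pid] = ProteinRecord(
            pid, seq, localizations={f"comp{compartment}"}, annotations=annots
        )

    # all within-module pairs, globally shuffled, truncated to the target count
    ids = sorted(module_of)
    candidates = []
    for m in range(spec.n_modules):
        members = [pid for pid in ids if module_of[pid] == m]
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                candidates.append((a, b))
    order = rng.permutation(len(candidates))
    positives = [
        PairRecord(*candidates[i], label="positive", evidence_system="physical")
        for i in order[: spec.n_positive_pairs]
    ]

    # toy literature corpus: module term bundles plus noise documents
    documents: list[set[str]] = []
    for m in range(spec.n_modules):
        for _ in range(2):
            doc = {mod_terms[m], bp_leaves[m % len(bp_leaves)]}
            doc.add(mf_leaves[int(rng.integers(len(mf_leaves)))])
            documents.append(doc)
    for _ in range(spec.n_noise_documents):
        documents.append(
            {
                bp_leaves[int(rng.integers(len(bp_leaves)))],
                mf_leaves[int(rng.integers(len(mf_leaves)))],
            }
        )

    return SyntheticWorld(
        spec=spec,
        proteins=proteins,
        positives=positives,
        module_of=module_of,
        cc_dag=cc_dag,
        bp_dag=bp_dag,
        mf_dag=mf_dag,
        documents=documents,
    )


def generate_expression(world: SyntheticWorld) -> None:
    """Gaussian expression matrices for two platforms.

    Module members load on a shared per-module factor with weight
    sqrt(rho), giving within-module pair correlation ~ ``coexpr_rho``;
    all other genes are independent.  A fraction ``1 - coexpr_coverage``
    of genes is left out of each platform, creating pairs with missing
    co-expression (as real compendia do).
    """
    spec = world.spec
    if spec.n_samples < 3:
        raise ValueError("n_samples must be at least 3")
    rng = np.random.default_rng(spec.seed + 1)
    ids = sorted(world.proteins)
    rho = spec.coexpr_rho
    for attr in ("microarray", "rnaseq"):
        factors = rng.standard_normal((spec.n_modules, spec.n_samples))
        data = np.empty((len(ids), spec.n_samples))
        for row, pid in enumerate(ids):
            noise = rng.standard_normal(spec.n_samples)
            m = world.module_of.get(pid)
            if m is not None and rho > 0:
                data[row] = math.sqrt(rho) * factors[m] + math.sqrt(1 - rho) * noise
            else:
                data[row] = noise
        keep = rng.random(len(ids)) < spec.coexpr_coverage
        df = pd.DataFrame(data[keep], index=[i for i, k in zip(ids, keep) if k])
        df.columns = [f"s{j}" for j in range(spec.n_samples)]
        df.index.name = "gene_id"
        setattr(world, attr, df)


def generate_profiles(world: SyntheticWorld) -> None:
    """Bit-score-ratio phylogenetic profiles over the reference genomes.

    Each module has a presence pattern (Bernoulli 0.5 per genome) and a
    per-genome ratio value; a member copies pattern and value per genome
    with probability ``profile_overlap``, otherwise draws its own.
    Background proteins draw everything independently.  Ratios lie in
    (0, 1]; absence is 0.
    """
    spec = world.spec
    rng = np.random.default_rng(spec.seed + 2)
    n = spec.n_reference_genomes
    ids = sorted(world.proteins)
    mod_presence = rng.random((spec.n_modules, n)) < 0.5
    mod_values = rng.uniform(0.2, 1.0, size=(spec.n_modules, n))
    data = np.zeros((len(ids), n))
    for row, pid in enumerate(ids):
        m = world.module_of.get(pid)
        own_presence = rng.random(n) < 0.5
        own_values = rng.uniform(0.2, 1.0, size=n)
        if m is not None:
            copy = rng.random(n) < spec.profile_overlap
            presence = np.where(copy, mod_presence[m], own_presence)
            values = np.where(copy, mod_values[m], own_values)
        else:
            presence, values = own_presence, own_values
        data[row] = presence * values
    df = pd.DataFrame(data, index=ids, columns=[f"g{k}" for k in range(n)])
    df.index.name = "protein_id"
    world.profiles = df


def generate_world(spec: FixtureSpec | None = None, **overrides) -> SyntheticWorld:
    """Generate the complete synthetic organism (universe + expression + profiles)."""
    if spec is None:
        spec = FixtureSpec(**overrides)
    elif overrides:
        raise ValueError("pass either a spec or keyword overrides, not both")
    world = generate_universe(spec)
    generate_expression(world)
    generate_profiles(world)
    return world


def write_world(world: SyntheticWorld, outdir: str | Path) -> None:
    """Serialize the world in the package's standard file formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_fasta(world.proteins.values(), outdir / "proteins.fasta")
    io.write_pair_table(world.positives, outdir / "positives.tsv")
    io.write_localizations(world.localizations, outdir / "localizations.tsv")
    annots = {pid: p.annotations for pid, p in world.proteins.items()}
    io.write_annotations(annots, outdir / "annotations.tsv")
    for name, dag in (("cc", world.cc_dag), ("bp", world.bp_dag), ("mf", world.mf_dag)):
        io.write_dag(dag.graph, outdir / f"dag_{name}.tsv")
    if world.microarray is not None:
        io.write_matrix(world.microarray, outdir / "expression_microarray.tsv")
    if world.rnaseq is not None:
        io.write_matrix(world.rnaseq, outdir / "expression_rnaseq.tsv")
    if world.profiles is not None:
        io.write_matrix(world.profiles, outdir / "profiles.tsv")
    rows = [(" ".join(sorted(doc)),) for doc in world.documents]
    pd.DataFrame(rows, columns=["terms"]).to_csv(
        outdir / "documents.tsv", sep="\t", index=False
    )
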