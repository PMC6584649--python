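"""GO-based pair features: FunSim semantic similarity and association scores.

Two kinds of quantity are computed from Gene Ontology annotations:

* **FunSim** — the average pairwise Lin similarity between the Cellular
  Component terms of two proteins, used both as a co-localization
  pre-screen and as a functional-similarity feature.  Lin similarity of
  two terms is ``2 * IC(MICA) / (IC(t1) + IC(t2))`` where MICA is their
  common ancestor of maximal information content and IC is estimated from
  an annotation corpus as ``-log(p(term))`` with counts propagated to
  ancestors.

* **Association scores** (IAS / CAS / PAS) — pointwise-mutual-information
  style log-odds of two GO terms co-occurring in a corpus of events:
  interacting protein pairs (IAS), per-gene annotation sets (CAS), or
  literature abstracts (PAS).  A protein pair's score is aggregated over
  all cross term pairs (sum by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .io import ParseError


@dataclass
class GoDag:
    """A GO DAG (child->parent edges) with per-term aspect and information content.

    ``ic`` maps term -> nonnegative IC; terms never seen in the corpus get
    ``math.inf`` as a sentinel and are excluded from MICA searches.
    """

    graph: nx.DiGraph
    aspect_of: dict[str, str] = field(default_factory=dict)
    ic: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ParseError("GO graph contains a cycle")

    def ancestors(self, term: str) -> set[str]:
        """All ancestors of ``term`` including itself (child->parent closure)."""
        if term not in self.graph:
            raise KeyError(f"term {term!r} not in DAG")
        return nx.descendants(self.graph, term) | {term}

    def roots(self) -> set[str]:
        return {t for t in self.graph if self.graph.out_degree(t) == 0}


def build_ic(
    dag: GoDag, annotations: Mapping[str, Iterable[str]]
) -> GoDag:
    """Estimate information content from an annotation corpus.

    ``annotations`` maps protein -> direct GO terms (one aspect).  A
    protein annotated to a term counts toward that term and all its
    ancestors; ``IC(t) = -log(n_t / n_total)`` where ``n_total`` is the
    number of annotated proteins.  Roots (and any term annotating every
    protein) get IC 0; unseen terms get the +inf sentinel.
    """
    counts: dict[str, int] = {t: 0 for t in dag.graph}
    n_total = 0
    for _protein, terms in annotations.items():
        propagated: set[str] = set()
        for t in terms:
            if t in dag.graph:
                propagated |= dag.ancestors(t)
        if propagated:
            n_total += 1
            for t in propagated:
                counts[t] += 1
    if n_total == 0:
        raise ValueError("annotation corpus annotates no protein in the DAG")
    ic = {}
    for t, c in counts.items():
        ic[t] = math.inf if c == 0 else abs(-math.log(c / n_total))
    dag.ic = ic
    return dag


def term_similarity(t1: str, t2: str, dag: GoDag) -> float:
    """Lin similarity of two terms of the same aspect, in [0, 1].

    Returns 1 for identical terms of positive IC and 0 when the only
    common ancestor carries no information (IC 0).
    """
    if dag.aspect_of and dag.aspect_of.get(t1) != dag.aspect_of.get(t2):
        raise ValueError(f"terms {t1!r}, {t2!r} belong to different aspects")
    if not dag.ic:
        raise ValueError("DAG has no information content; call build_ic first")
    common = dag.ancestors(t1) & dag.ancestors(t2)
    finite = [dag.ic[t] for t in common if math.isfinite(dag.ic.get(t, math.inf))]
    if not finite:
        return 0.0
    ic_mica = max(finite)
    ic1, ic2 = dag.ic.get(t1, math.inf), dag.ic.get(t2, math.inf)
    if not (math.isfinite(ic1) and math.isfinite(ic2)):
        # an unobserved query term carries no usable information
        return 0.0
    denom = ic1 + ic2
    if denom == 0.0:
        return 0.0
    return min(1.0, 2.0 * ic_mica / denom)


def funsim(
    terms_a: Iterable[str], terms_b: Iterable[str], dag: GoDag
) -> float:
    """Average pairwise term similarity over all cross pairs, in [0, 1].

    Raises on an empty annotation set — callers exclude such proteins
    upstream rather than treating missing annotation as dissimilarity.
    """
    sa, sb = set(terms_a), set(terms_b)
    if not sa or not sb:
        raise ValueError("funsim is undefined for an empty annotation set")
    total = 0.0
    for t1 in sa:
        for t2 in sb:
            total += term_similarity(t1, t2, dag)
    return total / (len(sa) * len(sb))


# ---------------------------------------------------------------------------
# Association scores (IAS / CAS / PAS)
# ---------------------------------------------------------------------------

ASSOCIATION_KINDS = ("IAS", "CAS", "PAS")


@dataclass
class AssociationTable:
    """Symmetric GO-term-pair -> score table for one association kind."""

    score_kind: str
    entries: dict[frozenset, float] = field(default_factory=dict)
    provenance: str = "computed_from_corpus"

    def get(self, t1: str, t2: str) -> float:
        """Score of an unordered term pair; unseen pairs contribute 0."""
        return self.entries.get(frozenset((t1, t2)), 0.0)

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for key, score in self.entries.items():
            pair = sorted(key)
            t1, t2 = (pair[0], pair[0]) if len(pair) == 1 else pair
            rows.append((t1, t2, score, self.score_kind))
        pd.DataFrame(rows, columns=["term1", "term2", "score", "kind"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path, score_kind: str | None = None):
        df = pd.read_csv(path, sep="\t", comment="#")
        kinds = set(df["kind"]) if "kind" in df.columns else {score_kind}
        if score_kind is None:
            if len(kinds) != 1:
                raise ParseError(f"{path}: mixed association kinds {kinds}")
            score_kind = kinds.pop()
        entries = {
            frozenset((r.term1, r.term2)): float(r.score)
            for r in df.itertuples(index=False)
        }
        return cls(score_kind, entries, provenance="loaded_precomputed")


def build_association_table(
    score_kind: str,
    corpus: Sequence[Iterable[str]],
    pseudocount: float = 1.0,
) -> AssociationTable:
    """PMI-style log2 odds of term co-occurrence over a corpus of events.

    An *event* is a set of GO terms — the annotations of an interacting
    pair (IAS), of one gene (CAS), or of one abstract (PAS).  For terms
    co-occurring in at least one event,

        score(t1, t2) = log2[ (C(t1,t2) + p) * N / ((C(t1) + p) * (C(t2) + p)) ]

    with C the event co-occurrence/occurrence counts, N the number of
    events and p the pseudocount.
    """
    if score_kind not in ASSOCIATION_KINDS:
        raise ValueError(f"unknown association kind {score_kind!r}")
    events = [set(e) for e in corpus if e]
    if not events:
        raise ValueError("association corpus is empty")
    n_events = len(events)
    single: dict[str, int] = {}
    joint: dict[frozenset, int] = {}
    for ev in events:
        terms = sorted(ev)
        for t in terms:
            single[t] = single.get(t, 0) + 1
        for i, t1 in enumerate(terms):
            for t2 in terms[i + 1 :]:
                key = frozenset((t1, t2))
                joint[key] = joint.get(key, 0) + 1
    entries = {}
    p = pseudocount
    for key, c12 in joint.items():
        t1, t2 = tuple(key) if len(key) == 2 else (next(iter(key)),) * 2
        entries[key] = math.log2(
            (c12 + p) * n_events / ((single[t1] + p) * (single[t2] + p))
        )
    return AssociationTable(score_kind, entries)


def ias_events(
    pairs: Iterable[tuple[str, str]],
    annotations: Mapping[str, Iterable[str]],
) -> list[set[str]]:
    """Corpus events for IAS: the union of GO terms of each interacting pair."""
    events = []
    for a, b in pairs:
        ev = set(annotations.get(a, ())) | set(annotations.get(b, ()))
        if ev:
            events.append(ev)
    return events


def pair_association(
    terms_a: Iterable[str],
    terms_b: Iterable[str],
    table: AssociationTable,
    aggregate: str = "sum",
) -> float:
    """Aggregate association score of a protein pair over all cross term pairs.

    Missing term pairs contribute 0. ``aggregate`` is one of sum|mean|max.
    """
    sa, sb = set(terms_a), set(terms_b)
    if not sa or not sb:
        raise ValueError("pair_association requires annotations on both proteins")
    scores = [table.get(t1, t2) for t1 in sa for t2 in sb]
    if aggregate == "sum":
        return float(sum(scores))
    if aggregate == "mean":
        return float(sum(scores) / len(scores))
    if aggregate == "max":
        return float(max(scores))
    raise ValueError(f"unknown aggregation {aggregate!r}")
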