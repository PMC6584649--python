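"""Domain types and readers/writers for the tabular formats used across the package.

All tables are plain TSV with ``#`` comment lines; sequences are FASTA.
Identifiers are opaque strings — no accession-format validation is attempted,
since real inputs freely mix TAIR AGI codes and UniProt accessions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("phytoppi")

VALID_ASPECTS = frozenset({"CC", "BP", "MF"})
VALID_SOURCES = frozenset({"experimental", "predicted"})

#: IUPAC amino-acid codes: the 20 standard residues plus ambiguity/rare codes.
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY" "BZXUO*")


class ParseError(ValueError):
    """Raised when an input file violates its documented dialect."""


@dataclass
class AnnotationRecord:
    """A single GO annotation of a protein.

    Predicted annotations carry a confidence score and participate in
    similarity computations only above a configurable threshold
    (default 10000, the high-confidence cutoff for function-prediction
    scores); experimental annotations always participate.
    """

    term_id: str
    aspect: str
    source: str = "experimental"
    confidence: float = 0.0

    def __post_init__(self) -> None:
        if self.aspect not in VALID_ASPECTS:
            raise ValueError(f"unknown GO aspect {self.aspect!r}")
        if self.source not in VALID_SOURCES:
            raise ValueError(f"unknown annotation source {self.source!r}")
        if self.confidence < 0:
            raise ValueError("annotation confidence must be nonnegative")


@dataclass
class ProteinRecord:
    """A protein with its sequence, localization labels and GO annotations."""

    protein_id: str
    sequence: str
    localizations: set[str] = field(default_factory=set)
    annotations: list[AnnotationRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValueError("protein_id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"{self.protein_id}: empty sequence")
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise ValueError(
                f"{self.protein_id}: non-IUPAC residue(s) {sorted(bad)}"
            )

    def terms(self, aspect: str, min_predicted_confidence: float = 10000.0) -> set[str]:
        """GO terms of one aspect usable for similarity computations.

        Experimental annotations always qualify; predicted ones only when
        their confidence exceeds ``min_predicted_confidence`` (strict).
        """
        out = set()
        for a in self.annotations:
            if a.aspect != aspect:
                continue
            if a.source == "experimental" or a.confidence > min_predicted_confidence:
                out.add(a.term_id)
        return out


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Canonical (lexicographically sorted) form of an unordered pair."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class PairRecord:
    """An unordered protein pair with an interaction label.

    Stored canonically (ids sorted); self-pairs are rejected.
    """

    protein_a: str
    protein_b: str
    label: str = "unknown"  # positive | negative | unknown
    evidence_system: str = "unspecified"  # physical | genetic | unspecified

    def __post_init__(self) -> None:
        if self.protein_a == self.protein_b:
            raise ValueError(f"self-pair {self.protein_a!r} is not allowed")
        a, b = canonical_pair(self.protein_a, self.protein_b)
        object.__setattr__(self, "protein_a", a)
        object.__setattr__(self, "protein_b", b)
        if self.label not in {"positive", "negative", "unknown"}:
            raise ValueError(f"unknown pair label {self.label!r}")
        if self.evidence_system not in {"physical", "genetic", "unspecified"}:
            raise ValueError(f"unknown evidence system {self.evidence_system!r}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.protein_a, self.protein_b)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, ProteinRecord]:
    """Read a FASTA file into ``{protein_id: ProteinRecord}``.

    The id is the header token before the first whitespace; sequences are
    uppercased. Duplicate ids raise; an empty file returns an empty dict
    with a warning.
    """
    records: dict[str, ProteinRecord] = {}
    for entry in SeqIO.parse(str(path), "fasta"):
        pid = entry.id
        if pid in records:
            raise ParseError(f"{path}: duplicate protein id {pid!r}")
        records[pid] = ProteinRecord(pid, str(entry.seq).upper())
    if not records:
        logger.warning("%s: no FASTA entries found", path)
    return records


def write_fasta(proteins: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.protein_id}\n")
            seq = p.sequence
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    return df


def read_pair_table(path: str | Path) -> list[PairRecord]:
    """Read a pair list (columns protein_a, protein_b, [label], [evidence_system]).

    Pairs are canonicalized, exact duplicates collapsed, and self-pairs
    dropped (with counts logged).
    """
    df = _read_tsv(path, ["protein_a", "protein_b"])
    has_label = "label" in df.columns
    has_ev = "evidence_system" in df.columns
    seen: dict[tuple[str, str], PairRecord] = {}
    n_self = 0
    for row in df.itertuples(index=False):
        a, b = row.protein_a, row.protein_b
        if a == b:
            n_self += 1
            continue
        rec = PairRecord(
            a,
            b,
            label=getattr(row, "label") if has_label else "unknown",
            evidence_system=getattr(row, "evidence_system") if has_ev else "unspecified",
        )
        seen.setdefault(rec.key, rec)
    if n_self:
        logger.info("%s: dropped %d self-pair row(s)", path, n_self)
    n_dup = len(df) - n_self - len(seen)
    if n_dup:
        logger.info("%s: collapsed %d duplicate pair row(s)", path, n_dup)
    return list(seen.values())


def write_pair_table(pairs: Iterable[PairRecord], path: str | Path) -> None:
    rows = [
        (p.protein_a, p.protein_b, p.label, p.evidence_system) for p in pairs
    ]
    pd.DataFrame(
        rows, columns=["protein_a", "protein_b", "label", "evidence_system"]
    ).to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> dict[str, list[AnnotationRecord]]:
    """Read an annotation table (protein_id, term_id, aspect, source, confidence)."""
    df = _read_tsv(path, ["protein_id", "term_id", "aspect"])
    out: dict[str, list[AnnotationRecord]] = {}
    for row in df.itertuples(index=False):
        source = getattr(row, "source", "experimental") or "experimental"
        conf = float(getattr(row, "confidence", 0.0) or 0.0)
        out.setdefault(row.protein_id, []).append(
            AnnotationRecord(row.term_id, row.aspect, source, conf)
        )
    return out


def write_annotations(
    annots: Mapping[str, list[AnnotationRecord]], path: str | Path
) -> None:
    rows = [
        (pid, a.term_id, a.aspect, a.source, a.confidence)
        for pid, lst in annots.items()
        for a in lst
    ]
    pd.DataFrame(
        rows, columns=["protein_id", "term_id", "aspect", "source", "confidence"]
    ).to_csv(path, sep="\t", index=False)


def read_localizations(path: str | Path) -> dict[str, set[str]]:
    """Read a localization table (protein_id, compartment) into id -> label set."""
    df = _read_tsv(path, ["protein_id", "compartment"])
    out: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.protein_id, set()).add(row.compartment)
    return out


def write_localizations(loc: Mapping[str, set[str]], path: str | Path) -> None:
    rows = [(pid, c) for pid, comps in loc.items() for c in sorted(comps)]
    pd.DataFrame(rows, columns=["protein_id", "compartment"]).to_csv(
        path, sep="\t", index=False
    )


def read_dag(path: str | Path) -> nx.DiGraph:
    """Read a GO DAG edge table (child_term, parent_term) as a child->parent digraph.

    Raises on cycles (including self-edges).
    """
    df = _read_tsv(path, ["child_term", "parent_term"])
    g = nx.DiGraph()
    for row in df.itertuples(index=False):
        g.add_edge(row.child_term, row.parent_term)
    if not nx.is_directed_acyclic_graph(g):
        raise ParseError(f"{path}: DAG edge table contains a cycle")
    return g


def write_dag(g: nx.DiGraph, path: str | Path) -> None:
    pd.DataFrame(list(g.edges()), columns=["child_term", "parent_term"]).to_csv(
        path, sep="\t", index=False
    )


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a numeric matrix (first column row id, remaining columns samples)."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    try:
        return df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric matrix cell ({exc})") from exc


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def read_profiles(path: str | Path) -> pd.DataFrame:
    """Read phylogenetic bit-score-ratio profiles (protein_id + n ratio columns)."""
    df = read_matrix(path)
    if (df.values < 0).any():
        raise ParseError(f"{path}: negative bit-score ratio")
    return df
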