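"""Benchmark dataset construction: positive filtering, negative sampling,
identity pruning and cross-validation folds.

Positive interaction pairs are filtered (short proteins < 50 residues,
genetic-evidence pairs, duplicates, self-pairs, pairs referencing unknown
proteins), then balanced with an equal number of constructed negatives.
Two negative schemes are supported: *loc* pairs proteins whose
subcellular localization sets are disjoint (highly unlikely to interact)
and *rand* randomly pairs proteins of the positive set excluding known
positives.  Every filter logs its drop count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align
from sklearn.model_selection import StratifiedKFold

from .io import PairRecord, ProteinRecord, canonical_pair

logger = logging.getLogger("phytoppi")

MIN_PROTEIN_LENGTH = 50
DEFAULT_FOLDS = 6


@dataclass
class LabeledPairDataset:
    """Balanced positive/negative pairs with outer-CV fold assignments."""

    pairs: list[PairRecord]
    negative_scheme: str  # loc | rand
    fold_of: dict[tuple[str, str], int] = field(default_factory=dict)
    provenance_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = [p.label for p in self.pairs]
        n_pos = labels.count("positive")
        n_neg = labels.count("negative")
        if n_pos != n_neg:
            raise ValueError(f"dataset unbalanced: {n_pos} positives, {n_neg} negatives")
        keys = [p.key for p in self.pairs]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate pair in dataset")

    @property
    def n_positive(self) -> int:
        return sum(p.label == "positive" for p in self.pairs)

    def labels(self) -> np.ndarray:
        return np.array([1 if p.label == "positive" else 0 for p in self.pairs])

    def folds(self) -> np.ndarray:
        return np.array([self.fold_of[p.key] for p in self.pairs])


def filter_positives(
    raw_pairs: Iterable[PairRecord],
    proteins: Mapping[str, ProteinRecord],
    min_length: int = MIN_PROTEIN_LENGTH,
) -> tuple[list[PairRecord], dict[str, int]]:
    """Filter raw positive pairs; returns (kept, per-rule drop counts).

    Drops pairs with a protein shorter than ``min_length`` residues
    (strict: length 50 survives a 50 cutoff), genetic-evidence pairs,
    duplicates, and pairs referencing proteins absent from the collection.
    """
    counts = {"unknown_protein": 0, "short": 0, "genetic": 0, "duplicate": 0}
    kept: list[PairRecord] = []
    seen: set[tuple[str, str]] = set()
    for pair in raw_pairs:
        if pair.protein_a not in proteins or pair.protein_b not in proteins:
            counts["unknown_protein"] += 1
            logger.warning("pair %s references an unknown protein", pair.key)
            continue
        if (
            len(proteins[pair.protein_a].sequence) < min_length
            or len(proteins[pair.protein_b].sequence) < min_length
        ):
            counts["short"] += 1
            continue
        if pair.evidence_system == "genetic":
            counts["genetic"] += 1
            continue
        if pair.key in seen:
            counts["duplicate"] += 1
            continue
        seen.add(pair.key)
        kept.append(
            PairRecord(pair.protein_a, pair.protein_b, "positive", pair.evidence_system)
        )
    logger.info(
        "filter_positives: kept %d of %d pairs (drops: %s)",
        len(kept), len(kept) + sum(counts.values()), counts,
    )
    return kept, counts


def negatives_by_localization(
    proteins: Mapping[str, ProteinRecord],
    positives: Iterable[PairRecord],
    n_required: int,
    seed: int,
) -> list[PairRecord]:
    """Sample non-interacting pairs from proteins in disjoint compartments.

    Proteins without localization labels are ineligible; known positives
    are excluded.  Raises if the eligible pool is smaller than
    ``n_required``.
    """
    pos_keys = {p.key for p in positives}
    ids = sorted(pid for pid, p in proteins.items() if p.localizations)
    eligible = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if proteins[a].localizations.isdisjoint(proteins[b].localizations):
                key = canonical_pair(a, b)
                if key not in pos_keys:
                    eligible.append(key)
    if len(eligible) < n_required:
        raise ValueError(
            f"localization-negative pool has {len(eligible)} pairs, "
            f"need {n_required}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(eligible), size=n_required, replace=False)
    return [
        PairRecord(*eligible[i], label="negative") for i in sorted(idx)
    ]


def negatives_random(
    positive_pairs: Sequence[PairRecord], seed: int
) -> list[PairRecord]:
    """Randomly pair proteins of the positive set, excluding known positives.

    Returns exactly as many negatives as there are positives; raises when
    the universe of non-positive pairs is exhausted.
    """
    pos_keys = {p.key for p in positive_pairs}
    universe = sorted({pid for p in positive_pairs for pid in p.key})
    if len(universe) < 2:
        raise ValueError("need at least 2 distinct proteins to sample negatives")
    n_required = len(positive_pairs)
    n_all = len(universe) * (len(universe) - 1) // 2
    if n_all - len(pos_keys) < n_required:
        raise ValueError(
            f"only {n_all - len(pos_keys)} non-positive pairs available, "
            f"need {n_required}"
        )
    rng = np.random.default_rng(seed)
    chosen: set[tuple[str, str]] = set()
    while len(chosen) < n_required:
        a, b = rng.choice(len(universe), size=2, replace=False)
        key = canonical_pair(universe[a], universe[b])
        if key not in pos_keys and key not in chosen:
            chosen.add(key)
    return [PairRecord(*key, label="negative") for key in sorted(chosen)]


# ---------------------------------------------------------------------------
# Sequence identity and redundancy pruning
# ---------------------------------------------------------------------------

def _aligner(match: float, mismatch: float, gap: float) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = match
    al.mismatch_score = mismatch
    al.open_gap_score = gap
    al.extend_gap_score = gap
    return al


def global_identity(
    seq_a: str,
    seq_b: str,
    match: float = 1.0,
    mismatch: float = 0.0,
    gap: float = -1.0,
) -> float:
    """Percent identity from a Needleman-Wunsch global alignment.

    Identity = matches / alignment length (gap columns included) * 100,
    taken from one optimal alignment under the given linear scoring.
    """
    if not seq_a or not seq_b:
        raise ValueError("global_identity requires non-empty sequences")
    al = _aligner(match, mismatch, gap)
    alignment = al.align(seq_a, seq_b)[0]
    counts = alignment.counts()
    return 100.0 * counts.identities / alignment.length


def prune_by_identity(
    pairs: Sequence[PairRecord],
    proteins: Mapping[str, ProteinRecord],
    cutoff: float,
    **scoring,
) -> list[PairRecord]:
    """Greedy redundancy reduction of a pair list at a percent-identity cutoff.

    A single pass in input order keeps a pair only if neither of its
    proteins exceeds ``cutoff`` percent identity to any protein of an
    already-kept pair.  Deterministic for a fixed input order; lowering
    the cutoff can only shrink the survivor set.
    """
    kept: list[PairRecord] = []
    kept_proteins: list[str] = []
    cache: dict[tuple[str, str], float] = {}

    def ident(a: str, b: str) -> float:
        key = canonical_pair(a, b)
        if key not in cache:
            cache[key] = (
                100.0
                if proteins[a].sequence == proteins[b].sequence
                else global_identity(proteins[a].sequence, proteins[b].sequence, **scoring)
            )
        return cache[key]

    for pair in pairs:
        redundant = any(
            ident(pid, other) > cutoff
            for pid in pair.key
            for other in kept_proteins
        )
        if not redundant:
            kept.append(pair)
            for pid in pair.key:
                if pid not in kept_proteins:
                    kept_proteins.append(pid)
    logger.info(
        "prune_by_identity(cutoff=%s): kept %d of %d pairs", cutoff, len(kept), len(pairs)
    )
    return kept


def assign_folds(
    pairs: Sequence[PairRecord], k: int = DEFAULT_FOLDS, seed: int = 0
) -> dict[tuple[str, str], int]:
    """Stratified k-fold assignment (folds 1..k), balanced in both classes."""
    if k > len(pairs):
        raise ValueError(f"cannot split {len(pairs)} pairs into {k} folds")
    y = [1 if p.label == "positive" else 0 for p in pairs]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_of: dict[tuple[str, str], int] = {}
    for fold, (_train, test) in enumerate(skf.split(np.zeros(len(pairs)), y), start=1):
        for i in test:
            fold_of[pairs[i].key] = fold
    return fold_of


def build_dataset(
    positives: Sequence[PairRecord],
    proteins: Mapping[str, ProteinRecord],
    scheme: str,
    seed: int,
    k: int = DEFAULT_FOLDS,
    provenance_counts: dict[str, int] | None = None,
) -> LabeledPairDataset:
    """Balance filtered positives with scheme-constructed negatives and fold them."""
    if scheme == "loc":
        negatives = negatives_by_localization(proteins, positives, len(positives), seed)
    elif scheme == "rand":
        negatives = negatives_random(positives, seed)
    else:
        raise ValueError(f"unknown negative scheme {scheme!r}")
    pairs = list(positives) + negatives
    ds = LabeledPairDataset(
        pairs, scheme, provenance_counts=dict(provenance_counts or {})
    )
    ds.fold_of = assign_folds(pairs, k=k, seed=seed)
    return ds


def coexpression_view(
    dataset: LabeledPairDataset,
    complete: set[tuple[str, str]],
    seed: int = 0,
    k: int = DEFAULT_FOLDS,
) -> LabeledPairDataset:
    """Restrict to pairs with complete co-expression, then rebalance.

    The forest branch trains only on pairs whose co-expression features
    are all present; positives lacking them are removed and the larger
    class is down-sampled (seeded) to restore balance.
    """
    pos = [p for p in dataset.pairs if p.label == "positive" and p.key in complete]
    neg = [p for p in dataset.pairs if p.label == "negative" and p.key in complete]
    n = min(len(pos), len(neg))
    if n < k:
        raise ValueError("too few co-expression-complete pairs to rebalance")
    rng = np.random.default_rng(seed)
    if len(pos) > n:
        pos = [pos[i] for i in sorted(rng.choice(len(pos), size=n, replace=False))]
    if len(neg) > n:
        neg = [neg[i] for i in sorted(rng.choice(len(neg), size=n, replace=False))]
    pairs = pos + neg
    ds = LabeledPairDataset(pairs, dataset.negative_scheme)
    ds.fold_of = assign_folds(pairs, k=k, seed=seed)
    return ds
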