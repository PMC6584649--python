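"""Phylogenetic-profile similarity and co-expression (PCC / mutual rank) features.

A phylogenetic profile is a vector of BLAST bit-score ratios R_ik =
B_ik / B_ii over a panel of n reference genomes (0 where no homolog is
found); two proteins' co-evolution is scored as the cosine similarity of
their profiles, which lies in [0, 1] because the entries are nonnegative.

Co-expression between two genes is summarized per platform (microarray,
RNA-seq) as the Pearson correlation of their expression vectors and the
mutual rank MR = sqrt(rank_{A->B} * rank_{B->A}), the geometric mean of
each gene's descending-correlation rank in the other's list (self
excluded, ties averaged).  Lower MR means stronger co-expression; MR = 1
for reciprocal best partners.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io import ParseError, canonical_pair

logger = logging.getLogger("phytoppi")

PLATFORMS = ("microarray", "rnaseq")


def profile_similarity(p: np.ndarray, q: np.ndarray) -> float:
    """Cosine similarity of two nonnegative bit-score-ratio profiles.

    Returns NaN (undefined) for an all-zero profile; raises on length
    mismatch.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"profile length mismatch: {p.shape} vs {q.shape}")
    np_, nq = np.dot(p, p), np.dot(q, q)
    if np_ == 0.0 or nq == 0.0:
        return math.nan
    return float(np.dot(p, q) / math.sqrt(np_ * nq))


def pearson(matrix: pd.DataFrame, gene_a: str, gene_b: str) -> float:
    """Pearson correlation of two genes across samples; NaN when undefined.

    Requires >= 3 samples; zero-variance or absent genes yield NaN with a
    warning rather than an error, since genome-scale tables routinely
    contain flat genes.
    """
    if matrix.shape[1] < 3:
        raise ValueError("Pearson correlation requires at least 3 samples")
    for g in (gene_a, gene_b):
        if g not in matrix.index:
            return math.nan
    x = matrix.loc[gene_a].to_numpy(dtype=float)
    y = matrix.loc[gene_b].to_numpy(dtype=float)
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        logger.warning("zero-variance expression for %s or %s", gene_a, gene_b)
        return math.nan
    return float(stats.pearsonr(x, y)[0])


def correlation_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """All-against-all Pearson correlation of the rows of an expression matrix."""
    corr = np.corrcoef(matrix.to_numpy(dtype=float))
    return pd.DataFrame(corr, index=matrix.index, columns=matrix.index)


def mutual_rank(corr: pd.DataFrame, gene_a: str, gene_b: str) -> float:
    """Mutual rank from a full correlation table; NaN when a gene is absent.

    rank_{A->B} is the rank of B's correlation in A's descending list with
    A itself excluded and ties averaged, so MR is symmetric and >= 1.
    """
    for g in (gene_a, gene_b):
        if g not in corr.index:
            return math.nan
    if gene_a == gene_b:
        raise ValueError("mutual rank of a gene with itself is undefined")

    def directed_rank(src: str, dst: str) -> float:
        row = corr.loc[src].drop(index=src)
        # rankdata ranks ascending; negate for descending-correlation ranks
        ranks = stats.rankdata(-row.to_numpy(dtype=float))
        return float(ranks[row.index.get_loc(dst)])

    r_ab = directed_rank(gene_a, gene_b)
    r_ba = directed_rank(gene_b, gene_a)
    return math.sqrt(r_ab * r_ba)


@dataclass
class CoexpressionScore:
    """Per-pair co-expression record; missing values are NaN."""

    pcc_microarray: float = math.nan
    mr_microarray: float = math.nan
    pcc_rnaseq: float = math.nan
    mr_rnaseq: float = math.nan

    def is_complete(self) -> bool:
        return all(
            not math.isnan(v)
            for v in (
                self.pcc_microarray,
                self.mr_microarray,
                self.pcc_rnaseq,
                self.mr_rnaseq,
            )
        )

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.mr_microarray, self.pcc_microarray, self.mr_rnaseq, self.pcc_rnaseq]
        )


def read_coexpression_table(path) -> dict[tuple[str, str, str], tuple[float, float]]:
    """Read a precomputed co-expression TSV (gene_a, gene_b, platform, pcc, mr).

    Keys are (canonical pair..., platform); conflicting duplicates raise.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("gene_a", "gene_b", "platform", "pcc", "mr"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    out: dict[tuple[str, str, str], tuple[float, float]] = {}
    for row in df.itertuples(index=False):
        a, b = canonical_pair(row.gene_a, row.gene_b)
        key = (a, b, row.platform)
        val = (float(row.pcc), float(row.mr))
        if key in out and out[key] != val:
            raise ParseError(f"{path}: conflicting duplicate rows for {key}")
        out[key] = val
    return out


def coexpression_features(
    pairs: Iterable[tuple[str, str]],
    microarray_matrix: pd.DataFrame | None = None,
    rnaseq_matrix: pd.DataFrame | None = None,
    precomputed: Mapping[tuple[str, str, str], tuple[float, float]] | None = None,
) -> dict[tuple[str, str], CoexpressionScore]:
    """Assemble the four co-expression features for each pair.

    Precomputed (ATTED-style) entries take precedence over values derived
    from the expression matrices; a platform with neither source yields
    NaN for its two features.
    """
    pairs = [canonical_pair(a, b) for a, b in pairs]
    precomputed = precomputed or {}
    corr = {
        "microarray": correlation_matrix(microarray_matrix)
        if microarray_matrix is not None
        else None,
        "rnaseq": correlation_matrix(rnaseq_matrix) if rnaseq_matrix is not None else None,
    }
    matrices = {"microarray": microarray_matrix, "rnaseq": rnaseq_matrix}
    out = {}
    for a, b in pairs:
        score = CoexpressionScore()
        for platform in PLATFORMS:
            if (a, b, platform) in precomputed:
                pcc, mr = precomputed[(a, b, platform)]
            elif corr[platform] is not None:
                pcc = pearson(matrices[platform], a, b)
                mr = (
                    mutual_rank(corr[platform], a, b)
                    if not math.isnan(pcc)
                    else math.nan
                )
            else:
                continue
            if platform == "microarray":
                score.pcc_microarray, score.mr_microarray = pcc, mr
            else:
                score.pcc_rnaseq, score.mr_rnaseq = pcc, mr
        out[(a, b)] = score
    return out
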