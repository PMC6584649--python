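"""Auto-covariance (AC) encoding of protein sequences.

Each residue is mapped to seven physicochemical property values
(hydrophobicity, hydrophilicity, side-chain volume, polarity,
polarizability, solvent-accessible surface area, net charge index of the
side chain).  For property *j* and lag *d* the auto-covariance is

    AC(d, j) = (1 / (L - d)) * sum_{i=1..L-d} (P_ij - mean_j) (P_{i+d,j} - mean_j)

where mean_j is the mean of property *j* over the whole sequence of length
L.  With lags 1..30 this yields a 7 x 30 = 210-dimensional vector per
protein and a 420-dimensional vector per pair (the two proteins'
vectors concatenated in canonical id order).

The raw property tables below are the standard published amino-acid
indices used throughout the auto-covariance PPI literature.  Because AC is
computed on deviations from the sequence mean after each scale is
standardized to zero mean / unit SD over the 20 residues, the encoding is
invariant to affine changes of the raw tables.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import ProteinRecord, canonical_pair

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Ambiguous / rare codes mapped to the scale mean (0 after normalization).
AMBIGUOUS_AA = frozenset("BZXUO*")

DEFAULT_MAX_LAG = 30

# Raw per-residue property tables (order follows STANDARD_AA).
_RAW_SCALES: dict[str, dict[str, float]] = {
    "hydrophobicity": dict(zip(STANDARD_AA, [
        0.62, 0.29, -0.90, -0.74, 1.19, 0.48, -0.40, 1.38, -1.50, 1.06,
        0.64, -0.78, 0.12, -0.85, -2.53, -0.18, -0.05, 1.08, 0.81, 0.26,
    ])),
    "hydrophilicity": dict(zip(STANDARD_AA, [
        -0.5, -1.0, 3.0, 3.0, -2.5, 0.0, -0.5, -1.8, 3.0, -1.8,
        -1.3, 0.2, 0.0, 0.2, 3.0, 0.3, -0.4, -1.5, -3.4, -2.3,
    ])),
    "side_chain_volume": dict(zip(STANDARD_AA, [
        27.5, 44.6, 40.0, 62.0, 115.5, 0.0, 79.0, 93.5, 100.0, 93.5,
        94.1, 58.7, 41.9, 80.7, 105.0, 29.3, 51.3, 71.5, 145.5, 117.3,
    ])),
    "polarity": dict(zip(STANDARD_AA, [
        8.1, 5.5, 13.0, 12.3, 5.2, 9.0, 10.4, 5.2, 11.3, 4.9,
        5.7, 11.6, 8.0, 10.5, 10.5, 9.2, 8.6, 5.9, 5.4, 6.2,
    ])),
    "polarizability": dict(zip(STANDARD_AA, [
        0.046, 0.128, 0.105, 0.151, 0.290, 0.000, 0.230, 0.186, 0.219, 0.186,
        0.221, 0.134, 0.131, 0.180, 0.291, 0.062, 0.108, 0.140, 0.409, 0.298,
    ])),
    "sasa": dict(zip(STANDARD_AA, [
        1.181, 1.461, 1.587, 1.862, 2.228, 0.881, 2.025, 1.810, 2.258, 1.931,
        2.034, 1.655, 1.468, 1.932, 2.560, 1.298, 1.525, 1.645, 2.663, 2.368,
    ])),
    "net_charge_index": dict(zip(STANDARD_AA, [
        0.007187, -0.036610, -0.023820, 0.006802, 0.037552,
        0.179052, -0.010690, 0.021631, 0.017708, 0.051672,
        0.002683, 0.005392, 0.239531, 0.049211, 0.043587,
        0.004627, 0.003352, 0.057004, 0.037977, 0.023599,
    ])),
}

SCALE_NAMES = tuple(_RAW_SCALES)
N_SCALES = len(SCALE_NAMES)


@dataclass(frozen=True)
class PhysicochemicalScales:
    """Seven named residue->value mappings, optionally standardized."""

    scales: dict[str, dict[str, float]]
    normalized: bool = False

    def __post_init__(self) -> None:
        for name, table in self.scales.items():
            missing = set(STANDARD_AA) - set(table)
            if missing:
                raise ValueError(f"scale {name!r} missing residues {sorted(missing)}")

    def matrix(self) -> np.ndarray:
        """(n_scales, 20) array in STANDARD_AA residue order."""
        return np.array(
            [[self.scales[s][aa] for aa in STANDARD_AA] for s in self.scales]
        )


def raw_scales() -> PhysicochemicalScales:
    """The built-in raw (un-normalized) property tables."""
    return PhysicochemicalScales({k: dict(v) for k, v in _RAW_SCALES.items()})


def normalize_scales(raw: PhysicochemicalScales) -> PhysicochemicalScales:
    """Standardize each scale to zero mean, unit SD over the 20 residues.

    Raises on a zero-variance scale.
    """
    normed = {}
    for name, table in raw.scales.items():
        vals = np.array([table[aa] for aa in STANDARD_AA], dtype=float)
        sd = vals.std()
        if sd < 1e-12:
            raise ValueError(f"scale {name!r} has zero variance")
        z = (vals - vals.mean()) / sd
        normed[name] = dict(zip(STANDARD_AA, z.tolist()))
    return replace(raw, scales=normed, normalized=True)


def default_scales() -> PhysicochemicalScales:
    """The built-in tables, standardized — what the pipeline uses by default."""
    return normalize_scales(raw_scales())


def _sequence_properties(sequence: str, scales: PhysicochemicalScales) -> np.ndarray:
    """Map a sequence to a (n_scales, L) property matrix.

    Ambiguous residues (B, Z, X, U, O) contribute the scale mean: 0 for
    normalized scales, the 20-residue mean otherwise.
    """
    mat = scales.matrix()  # (S, 20)
    fill = np.zeros(mat.shape[0]) if scales.normalized else mat.mean(axis=1)
    index = {aa: i for i, aa in enumerate(STANDARD_AA)}
    cols = np.empty((mat.shape[0], len(sequence)))
    for pos, aa in enumerate(sequence):
        if aa in index:
            cols[:, pos] = mat[:, index[aa]]
        elif aa in AMBIGUOUS_AA:
            cols[:, pos] = fill
        else:
            raise KeyError(f"residue {aa!r} not covered by the property scales")
    return cols


def encode_ac(
    sequence: str,
    scales: PhysicochemicalScales | None = None,
    max_lag: int = DEFAULT_MAX_LAG,
) -> np.ndarray:
    """Encode one sequence as its AC vector of shape (n_scales * max_lag,).

    Values are ordered scale-major: ``[AC(1, s1) .. AC(max_lag, s1),
    AC(1, s2), ...]``.  Requires L > max_lag.
    """
    if scales is None:
        scales = default_scales()
    L = len(sequence)
    if L <= max_lag:
        raise ValueError(
            f"sequence length {L} must exceed max_lag {max_lag} for AC encoding"
        )
    props = _sequence_properties(sequence, scales)  # (S, L)
    centered = props - props.mean(axis=1, keepdims=True)
    out = np.empty((props.shape[0], max_lag))
    for lag in range(1, max_lag + 1):
        prod = centered[:, : L - lag] * centered[:, lag:]
        out[:, lag - 1] = prod.sum(axis=1) / (L - lag)
    vec = out.ravel()
    if not np.all(np.isfinite(vec)):
        raise ValueError("non-finite AC value encountered")
    return vec


def pair_vector(
    protein_a: ProteinRecord,
    protein_b: ProteinRecord,
    scales: PhysicochemicalScales | None = None,
    max_lag: int = DEFAULT_MAX_LAG,
) -> np.ndarray:
    """The concatenated AC vector of an unordered pair (canonical id order).

    Ordering by id makes the representation identical for (a, b) and (b, a).
    With the default seven scales and max_lag 30 the result has 420 entries.
    """
    first, _ = canonical_pair(protein_a.protein_id, protein_b.protein_id)
    if protein_a.protein_id != first:
        protein_a, protein_b = protein_b, protein_a
    try:
        va = encode_ac(protein_a.sequence, scales, max_lag)
    except ValueError as exc:
        raise ValueError(f"{protein_a.protein_id}: {exc}") from exc
    try:
        vb = encode_ac(protein_b.sequence, scales, max_lag)
    except ValueError as exc:
        raise ValueError(f"{protein_b.protein_id}: {exc}") from exc
    return np.concatenate([va, vb])
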