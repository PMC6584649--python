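"""Auto-covariance encoding of protein sequences.

Each protein becomes a 210-dimensional vector: for each of 7
physicochemical scales and each lag 1..30, the covariance of the scale
value between residues `lag` apart.  A pair of proteins is the 420-dim
concatenation in canonical id order.
"""

import numpy as np

from phytoppi import ProteinRecord, encode_ac, pair_vector
from phytoppi.seq_features import SCALE_NAMES

rng = np.random.default_rng(0)
seq_a = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=120))
seq_b = "MKV" + "KE" * 30 + seq_a[:60]  # a charged low-complexity repeat

vec = encode_ac(seq_a)
print(f"protein A: length {len(seq_a)}, AC vector shape {vec.shape}")
print(f"first scale ({SCALE_NAMES[0]}), lags 1-5: {np.round(vec[:5], 4)}")
# near-zero values: a random sequence has no periodic property structure

vec_b = encode_ac(seq_b)
print(f"\nprotein B (KE-repeat), {SCALE_NAMES[0]}, lags 1-5: {np.round(vec_b[:5], 4)}")
# the dipeptide repeat makes properties alternate, so AC oscillates in
# sign with lag parity and is far larger in magnitude

pv = pair_vector(ProteinRecord("A1", seq_a), ProteinRecord("B1", seq_b))
print(f"\npair vector shape: {pv.shape} (A's 210 values then B's 210)")
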