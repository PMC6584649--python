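"""Phylogenetic-profile similarity and co-expression features.

Profiles are bit-score-ratio vectors over reference genomes, compared
by cosine similarity; co-expression is summarized as Pearson
correlation plus mutual rank (geometric mean of the two reciprocal
correlation ranks; 1 = reciprocal best partners).
"""

import numpy as np

from phytoppi import generate_world, FixtureSpec
from phytoppi.profiles import (
    correlation_matrix, mutual_rank, pearson, profile_similarity,
)

world = generate_world(FixtureSpec(
    n_proteins=60, n_positive_pairs=30, n_samples=40,
    n_reference_genomes=50, seed=3,
))

pos = world.positives[0]
a, b = pos.key
ids = sorted(world.proteins)
bg = next(i for i in ids if i not in world.module_of)

sim_pos = profile_similarity(
    world.profiles.loc[a].to_numpy(), world.profiles.loc[b].to_numpy()
)
sim_bg = profile_similarity(
    world.profiles.loc[a].to_numpy(), world.profiles.loc[bg].to_numpy()
)
print(f"profile similarity, interacting pair ({a},{b}): {sim_pos:.3f}")
print(f"profile similarity, unrelated pair   ({a},{bg}): {sim_bg:.3f}")
# interacting (co-evolving) proteins share presence patterns -> near 1

pcc = pearson(world.microarray, a, b)
corr = correlation_matrix(world.microarray)
mr = mutual_rank(corr, a, b)
print(f"\nco-expression of the interacting pair: PCC = {pcc:.3f}, MR = {mr:.2f}")
print(f"co-expression with the background protein: "
      f"PCC = {pearson(world.microarray, a, bg):.3f}, "
      f"MR = {mutual_rank(corr, a, bg):.2f}")
# low MR (near 1) marks mutual top-ranked co-expression partners
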