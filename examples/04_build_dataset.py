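"""Benchmark dataset construction.

Positive pairs are filtered (short proteins, genetic-evidence pairs,
duplicates), balanced with constructed negatives (localization-disjoint
or random), redundancy-reduced by global-alignment identity, and split
into stratified cross-validation folds.
"""

from phytoppi import FixtureSpec, generate_world
from phytoppi.datasets import (
    build_dataset, filter_positives, global_identity, prune_by_identity,
)

world = generate_world(FixtureSpec(n_proteins=60, n_positive_pairs=30, seed=4))

kept, counts = filter_positives(world.positives, world.proteins)
print(f"positives kept: {len(kept)} (drop counts: {counts})")

for scheme in ("loc", "rand"):
    ds = build_dataset(kept, world.proteins, scheme=scheme, seed=1)
    sizes = [int((ds.folds() == f).sum()) for f in range(1, 7)]
    print(f"{scheme}-scheme dataset: {len(ds.pairs)} pairs "
          f"({ds.n_positive} per class), fold sizes {sizes}")
# equal positives and negatives by construction; folds stratified

a, b = kept[0].key
ident = global_identity(world.proteins[a].sequence, world.proteins[b].sequence)
print(f"\nglobal identity of pair ({a},{b}): {ident:.1f}%")

pruned = prune_by_identity(kept[:10], world.proteins, cutoff=80)
print(f"identity pruning at 80%: {len(kept[:10])} -> {len(pruned)} pairs")
# pairs re-using near-identical proteins are removed greedily
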