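"""Nested cross-validation of the sequence SVM branch.

Hyperparameters (C, gamma of the radial kernel) are selected by an
inner 5-fold grid search on the training folds only; each outer fold is
scored exactly once, so reported accuracy is never optimistic.
"""

import numpy as np

from phytoppi import FixtureSpec, generate_world
from phytoppi.datasets import build_dataset
from phytoppi.learners import nested_cv, pooled_report
from phytoppi.pipeline import pair_ac_matrix

world = generate_world(FixtureSpec(
    n_proteins=80, n_positive_pairs=48, n_samples=30,
    n_reference_genomes=60, seed=11,
))
ds = build_dataset(world.positives, world.proteins, scheme="loc", seed=1)
X = pair_ac_matrix(ds.pairs, world.proteins)

results = nested_cv(
    X, ds.labels(), ds.folds(), learner="svm",
    grid={"log2_C": [-1, 1, 5], "log2_gamma": [-11, -9, -5]},
)
for r in results:
    sel = {k: int(np.log2(v)) for k, v in r.selected_params.items()}
    print(f"fold {r.fold}: accuracy {r.report.accuracy:.3f}, "
          f"AUC {r.report.auc:.3f}, selected log2 {sel}")
pooled = pooled_report(results)
print(f"\npooled: accuracy {pooled.accuracy:.3f}, "
      f"precision {pooled.precision:.3f}, recall {pooled.recall:.3f}")
# high accuracy: interacting pairs share planted low-complexity segments
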