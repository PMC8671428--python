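"""Train the weighted logistic factorization and its squared-error rival.

Generates a synthetic spontaneous-report world, splits drugs in half
(drug-level split: 70/10/20 of positive pairs into train/validation/test
roles), trains both model families, and compares the mean PR-AUC over the
severe side-effect set on held-out test pairs.
"""

from sidefactor import (
    TrainConfig,
    binarize,
    compute_weights,
    evaluate,
    split_dataset,
    train,
)
from sidefactor.synthetic import generate_world

world = generate_world(m=150, n=200, k_true=5, n_severe=30, seed=17)
A = binarize(world.counts, t=3)
split = split_dataset(A, seed=17)
print(f"world: {A.shape[0]} drugs x {A.shape[1]} side effects, "
      f"{A.assoc.sum()} associations "
      f"({A.assoc.sum() / A.assoc.shape[0] / A.assoc.shape[1]:.1%})")

cfg = TrainConfig(k=5, lambda_l2=5e-3, max_epochs=200, patience=20,
                  decay_patience=8, lr_init=0.05, seed=0)

# weighted logistic model: alpha/beta weights from the report counts
W = compute_weights(world.counts, t=3, alpha=10.0, beta=0.8)
lmf, hist = train("logistic_mf", A, split, cfg, world.severe, W=W)
res_lmf = evaluate(lmf.score_matrix(), split, world.severe)

# squared-error baseline: no weighting, linear scores
mf, _ = train("mf", A, split, cfg, world.severe)
res_mf = evaluate(mf.score_matrix(), split, world.severe)

print(f"logistic (weighted log loss): mean severe PR-AUC = "
      f"{res_lmf.mean_severe:.3f}  (best epoch {hist.best_epoch})")
print(f"squared-error baseline:       mean severe PR-AUC = "
      f"{res_mf.mean_severe:.3f}")
print("\nEach number is the area under the precision-recall curve, "
      "averaged over the severe side effects, when test drugs are ranked "
      "against their held-out test-role associations; higher is better, "
      "and the weighted logistic loss is built for exactly this "
      "implicit-feedback ranking task.")
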