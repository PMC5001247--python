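"""Choose a marker panel by feed-forward-network test AUC.

Simulates a training and an independent test cohort (40 health vs 40
cancer each) sharing 5 informative and 21 noise markers, then
exhaustively evaluates all C(26, 2) = 325 two-marker panels: each panel
trains an N-7-2 sigmoid network on the training cohort and is ranked by
the AUC of its cancer score on the test cohort.
"""

from isopept import (EncodedDataset, SimulationConfig, encode, evaluate,
                     predict, roc_auc, select_panel, simulate_study, train)


def cohort(seed):
    cfg = SimulationConfig(seed=seed, n_planted=5, n_null_peptides=21)
    intensities, groups, _ = simulate_study(cfg)
    X = (~intensities.isna()).astype(float).T.to_numpy()
    return EncodedDataset(X, encode(groups), list(groups),
                          list(intensities.index))


train_ds, test_ds = cohort(100), cohort(200)
result = select_panel(train_ds, test_ds, N=2, mode="exhaustive", seed=1)

print(f"combinations evaluated: {result.n_evaluated}")
print(f"best panel:             {result.best_combination}")
print(f"best test AUC:          {result.best_auc:.3f}")

cols = [train_ds.markers.index(m) for m in result.best_combination]
net = train(train_ds.subset(cols), seed=1)
scores, labels = predict(net, test_ds.X[:, cols])
overall, per_class = evaluate(labels, test_ds.labels)
print(f"refit panel test AUC:   {roc_auc(scores, test_ds.labels):.3f}")
print(f"test accuracy:          {100 * overall:.1f}% overall, "
      f"{100 * per_class['cancer']:.1f}% on cancer samples")
print("""
Panels containing planted markers separate the cohorts (AUC near 1);
noise-only panels hover near AUC 0.5.  Accuracy uses the two-node argmax
decoding (cancer node vs health node).""")
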