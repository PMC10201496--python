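"""Train a relevance vector machine on the synthetic cohort.

Fits the sparse Bayesian kernel classifier with a Gaussian kernel on an
80:20 split and reports the held-out confusion-matrix metrics. The number
of relevance vectors shows the sparsity of the fitted expansion relative
to the basis size.
"""

import numpy as np

from borvm import (
    KernelSpec,
    TrainConfig,
    classification_metrics,
    confusion_matrix,
    encode_features,
    load_printed_margins,
    predict_proba,
    roc_auc,
    sample_cohort,
    split_stratified,
    train_rvm,
)

cohort = sample_cohort(load_printed_margins(), mode="exact", seed=0)
train_df, test_df = split_stratified(cohort.reset_index(drop=True), ratio=0.8, seed=0)
X, y, names = encode_features(cohort)
tr, te = train_df.index.to_numpy(), test_df.index.to_numpy()

spec = KernelSpec("gaussian", gamma=1.0)
model = train_rvm(X[tr], y[tr], spec, TrainConfig(max_basis=400, rng_seed=0))
print(f"features: {names}")
print(f"relevance vectors: {model.n_relevance_vectors} of {len(model.basis_points)} basis points")

proba = predict_proba(model, X[te])
cm = confusion_matrix(y[te], (proba >= 0.5).astype(int))
m = classification_metrics(cm)
print(f"test confusion matrix: tp={cm.tp} fp={cm.fp} fn={cm.fn} tn={cm.tn}")
print(
    f"accuracy={m.accuracy:.3f} ppv={m.ppv:.3f} npv={m.npv:.3f} "
    f"tpr={m.tpr:.3f} tnr={m.tnr:.3f} f1={m.f1:.3f}"
)
print(f"ROC AUC={roc_auc(y[te], proba):.3f}")
print("\n('died' is the positive class; accuracy is bounded by the overlap")
print("between survivor and death profiles in the reconstructed tables.)")
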