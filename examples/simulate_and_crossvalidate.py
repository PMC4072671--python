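"""Generate a synthetic 8-class dataset and cross-validate the SVM ensemble.

Simulates 30 sequences per class with a compositional separation of 0.15
(each class enriches three high-variance residues), encodes them as amino
acid composition, grid-searches the RBF width and positive-class cost
factor, and reports stratified five-fold CV metrics per class. Accuracy
well above the 87.5% majority baseline means the classifier recovers the
planted compositional signal.
"""

import numpy as np

import transpred as tp
from transpred.constants import CLASS_LABELS
from transpred.evaluate import metrics_report
from transpred.features import encode_dataset

config = tp.SimConfig(n_per_class=30, separation=0.15, seed=1)
sequences, manifest, _ = tp.make_dataset(config)
X = encode_dataset(sequences, "AAC").to_numpy()
labels = np.array([manifest.labels[s.id] for s in sequences])
print(f"dataset: {len(sequences)} sequences, 8 classes of {config.n_per_class}")

y = (labels == "amino_acid").astype(int)
best = tp.grid_search(X, y, tp.SvmConfig(seed=1))
print(f"grid search: gamma={best.gamma:g}, cost_factor={best.cost_factor:g}")

result = tp.cross_validate(X, labels, best, tp.CvPlan(seed=1))
print("\nstratified 5-fold CV (one-vs-rest, threshold 0):")
print(metrics_report(result["per_class"], result["average"]).to_string(
    float_format=lambda v: f"{v:.2f}"))
print("\nSn = recovered positives (= coverage); Sp = recognised negatives; "
      "MCC in [-1, 1]; AUC is threshold-free.")
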