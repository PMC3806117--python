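"""Train both classifiers on synthetic features and compare them.

A one-against-all Gaussian-kernel SVM and a first-order Sugeno ANFIS are
trained on the same (LLE, entropy) features and evaluated on held-out
parts from unseen subjects.
"""

from srs_chaos import (
    DatasetDesign,
    confusion,
    extract_features,
    generate_dataset,
    make_split,
    metrics,
    segments_to_parts,
    train_anfis,
    train_ova_svm,
)
from srs_chaos.core import features_to_arrays

design = DatasetDesign(
    [(s, label, 6) for s in ("p1", "p2", "p3", "p4")
     for label in ("snore", "breathing", "silence")]
)
segments = generate_dataset(design, seed=9)
split = make_split(segments, "II", test_subjects={"p3", "p4"})

feats = {
    phase: extract_features(segments_to_parts(segs))
    for phase, segs in (("train", split.train(segments)), ("test", split.test(segments)))
}
X_train, y_train = features_to_arrays(feats["train"])
X_test, y_test = features_to_arrays(feats["test"])

svm = train_ova_svm((X_train, y_train))
anfis = train_anfis((X_train, y_train))

for name, model in (("M-SVM", svm), ("ANFIS", anfis)):
    rep = metrics(confusion(y_test, model.predict(X_test)))
    print(f"{name}: test total accuracy {rep.total_accuracy_pct:.2f}%")
    for c in ("snore", "breathing", "silence"):
        print(f"   {c:10s} sensitivity {rep.sensitivity_pct[c]:6.2f}%  PPV {rep.ppv_pct[c]:6.2f}%")
print("Sensitivity = per-class recall; PPV = per-class precision;")
print("total accuracy = overall fraction of correctly classified parts.")
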