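"""Show the class-conditional (entropy, LLE) clusters of the synthetic corpus.

Each 3200-sample part is reduced to two numbers: the Shannon entropy of its
amplitude histogram (bits) and its largest Lyapunov exponent (nats/sample).
Snore parts sit at high entropy / low LLE, silence at near-zero entropy /
high LLE, breathing in between — the structure both classifiers exploit.
"""

import numpy as np

from srs_chaos import DatasetDesign, extract_features, generate_dataset, segments_to_parts

design = DatasetDesign(
    [(s, label, 5) for s in ("p1", "p2") for label in ("snore", "breathing", "silence")]
)
parts = segments_to_parts(generate_dataset(design, seed=3))
features = extract_features(parts)

print(f"{len(features)} parts")
print(f"{'class':10s} {'entropy (bits)':>22s} {'LLE (nats/sample)':>22s}")
for label in ("snore", "breathing", "silence"):
    ent = np.array([f.entropy for f in features if f.label == label])
    lle = np.array([f.lle for f in features if f.label == label])
    print(f"{label:10s} {ent.mean():8.2f} +/- {ent.std():5.2f} {lle.mean():13.3f} +/- {lle.std():6.3f}")
print("Cluster centroids are separated by more than the within-class spread,")
print("which is what makes the three classes learnable from just two features.")
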