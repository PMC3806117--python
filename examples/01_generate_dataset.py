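"""Generate a small labelled snore/breathing/silence dataset and inspect it.

Builds a 2-subject design, synthesises 16 kHz segments, and prints the
per-class segment and part counts.  Parts are the 3200-sample windows the
classifiers actually see.
"""

from collections import Counter

from srs_chaos import DatasetDesign, generate_dataset, segments_to_parts

design = DatasetDesign(
    [(subj, label, 5) for subj in ("patient_a", "patient_b")
     for label in ("snore", "breathing", "silence")]
)
segments = generate_dataset(design, seed=7)
parts = segments_to_parts(segments)

print(f"{len(segments)} segments -> {len(parts)} parts of 3200 samples")
for (subj, label), n in sorted(Counter((s.subject_id, s.label) for s in segments).items()):
    n_parts = sum(1 for p in parts if p.subject_id == subj and p.label == label)
    print(f"  {subj:10s} {label:10s} {n} segments, {n_parts} parts")
print("Segment durations vary (0.5-2.0 s), so part counts differ per segment.")
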