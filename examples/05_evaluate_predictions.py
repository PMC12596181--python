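"""Evaluate a predicted probability volume against ground-truth labels.

Simulates a 5-class voxel classifier (background, helix, sheet, coil,
RNA) that is right most of the time, discretizes its probabilities at
the 0.8 threshold, and reports per-label and aggregate precision,
recall, and F1.
"""

import numpy as np

from cryoset import PredictionVolume, confusion, discretize, score_metrics

rng = np.random.default_rng(5)
shape = (24, 24, 24)
truth = rng.integers(0, 5, size=shape)

# probabilities peaked on the true class, corrupted on 15% of voxels
wrong = rng.random(shape) < 0.15
peak = np.where(wrong, rng.integers(0, 5, size=shape), truth)
probs = np.full((5, *shape), 0.02)
np.put_along_axis(probs, peak[None], 0.92, axis=0)
probs /= probs.sum(axis=0)

pred = discretize(PredictionVolume(probs), threshold=0.8)
scores = score_metrics(confusion(pred.grid, truth, labels=range(5)))

print(f"overall accuracy: {scores['accuracy'] * 100:.2f}%")
print(f"micro precision/recall/F1 over non-background labels: "
      f"{scores['precision']:.3f} / {scores['recall']:.3f} / {scores['f1']:.3f}")
for k, m in scores["per_label"].items():
    print(f"  label {k}: precision {m.precision:.3f}  recall {m.recall:.3f}  "
          f"F1 {m.f1:.3f}")
print("Voxels whose best non-background probability stays below 0.8 fall")
print("back to background, trading recall for precision.")
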