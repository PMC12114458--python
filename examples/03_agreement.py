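"""Method comparison: FCM calls versus the standard suspension tests.

Pools the packaged per-disinfectant concordance counts into overall
categorical and essential agreement, then demonstrates the ROC machinery
on synthetic normalized counts (low counts predict a kill).
"""

import numpy as np

from cytocide import pooled_percentage, roc_analysis
from cytocide.data import load_agreement_counts

counts = load_agreement_counts()
for label, (num, den) in {
    "categorical agreement": ("exact_num", "exact_den"),
    "within +/-1 dilution": ("within1_num", "within1_den"),
    "within +/-2 dilutions": ("within2_num", "within2_den"),
}.items():
    pairs = list(zip(counts[num].astype(int), counts[den].astype(int)))
    pooled = pooled_percentage(pairs)
    n, d = sum(a for a, _ in pairs), sum(b for _, b in pairs)
    print(f"{label:>24}: {n}/{d} = {pooled}%")

# ROC on synthetic normalized counts: kills cluster low, survivals high
rng = np.random.default_rng(0)
scores = np.concatenate([rng.uniform(0.0, 0.15, 30),   # bactericidal
                         rng.uniform(0.05, 1.2, 30)])  # not bactericidal
truth = [1] * 30 + [0] * 30
roc = roc_analysis(scores, truth)
print(f"\nsynthetic ROC: AUC = {roc.auc:.3f}, Youden-optimal cut-off = "
      f"{roc.chosen_threshold:.3f} (sens {roc.sensitivity:.2f}, "
      f"spec {roc.specificity:.2f})")
print("-> a sample is predicted bactericidal when its normalized count "
      "falls below the cut-off.")
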