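"""End-to-end parameter recovery on a small virtual cohort.

Generates 4 controls and 4 patients with known per-task B*/K* ratios,
pushes every trial through preprocessing and canonical-correlation
identification, and prints the recovered vs true ratios.  The median
relative error quantifies how well the full pipeline inverts its own
generative model at the study noise level (20 dB envelope SNR).
"""

from wristid import SyntheticConfig, generate_cohort
from wristid.pipeline import recover_cohort

cohort = generate_cohort(4, 4, seed=5, config=SyntheticConfig())
scores = recover_cohort(cohort)

print(scores[["subject_id", "group", "task", "ratio_true", "ratio",
              "rel_error", "cc"]].to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print(f"\nmedian |relative error| = {scores['rel_error'].median():.1%} "
      f"over {len(scores)} subject/task fits")
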