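"""Decode task context from insula trial patterns of one synthetic subject.

Simulates a 4-run session (2 vitality runs, 2 velocity runs) at reduced
resolution, estimates single-trial betas in the left insula and a control
ROI, and decodes the three cross-task contrasts (rude vs fast, neutral vs
medium, gentle vs slow) with a linear SVM over the four alternate-run folds,
with a 200-permutation chance estimate for rude vs fast.
"""

import numpy as np

from vitalmvpa import (
    PipelineConfig,
    attach_null,
    build_pattern_set,
    cross_task_contrasts,
    decode_contrast,
    permutation_null,
)
from vitalmvpa.pipeline import simulate_subject

cfg = PipelineConfig(seed=0, geometry_scale=0.1)
rois, designs, runs = simulate_subject(cfg, 3)

for roi in ("left_insula", "ctrl_white_matter"):
    patterns = build_pattern_set(runs, designs, rois, roi, "sub-00")
    accs = {
        c.name: decode_contrast(patterns, c).mean_accuracy
        for c in cross_task_contrasts()
    }
    c0 = cross_task_contrasts()[0]
    result = attach_null(
        decode_contrast(patterns, c0),
        permutation_null(patterns, c0, n_perm=200, seed=0),
    )
    per = " ".join(f"{k}={v:.2f}" for k, v in accs.items())
    print(
        f"{roi:18s} mean accuracy {np.mean(list(accs.values())):.3f}  ({per})\n"
        f"{'':18s} rude_vs_fast chance {result.chance_estimate:.3f}, p {result.p_value:.3f}"
    )
# The insula, which carries the planted task-tuning pattern, decodes in the
# 55-60% band while the signal-free control ROI hovers near the permutation
# chance level; single-subject accuracies are noisy, which is why the study
# statistic is the 16-subject Wilcoxon test (see cohort_group_maps.py).
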