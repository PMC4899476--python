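"""Run the full synthetic cohort and summarize the group discriminative maps.

Simulates 16 subjects at reduced resolution, decodes all contrasts in all
four ROIs, builds the 50%-threshold group overlap maps for both insulae
(collapsing the three cross-task contrasts) and applies the exact binomial
independence null with Benjamini-Hochberg FDR at q = 0.05.
"""

from vitalmvpa import PipelineConfig, run_pipeline

cfg = PipelineConfig(seed=0, geometry_scale=0.1)
result = run_pipeline(cfg)

insula = result.cohort_mean(["left_insula", "right_insula"], cross_task=True)
control = result.cohort_mean(["ctrl_white_matter", "ctrl_ba21"], cross_task=True)
print(f"cohort mean cross-task accuracy  insula {insula:.3f} | control {control:.3f}")
for roi in ("left_insula", "right_insula"):
    g = result.summary[f"group_map:{roi}"]
    print(
        f"{roi:13s}: {g['n_surviving']} FDR-surviving voxels "
        f"(min overlap {g['min_surviving_overlap']}/16, "
        f"{100 * g['frac_survivors_in_planted_cluster']:.0f}% in planted cluster, "
        f"{g['n_surviving_positive']} vitality-signed vs {g['n_surviving_negative']})"
    )
# Survivors concentrate in the planted vitality-preferring cluster with
# positive (vitality) sign, while control ROIs decode at chance.
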