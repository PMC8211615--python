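"""Reference paired-difference summaries for the eight vessel categories.

Printed summary statistics (mean and standard deviation of the before-minus-
after quality-score differences, n = 44 cases) for the basilar artery, the
left/right vertebral arteries, PICA, AICA and the all-vessel sum.  They
drive the summary-based paired t-test reproduction (``stats summary`` on the
CLI) and the validation suite; no raw per-case scores are needed.
"""
from __future__ import annotations

VESSEL_QUALITY_PAIRED_SUMMARIES: dict[str, dict[str, float | int]] = {
    "BA": {"mean_diff": -0.386, "sd_diff": 1.573, "n": 44},
    "LVA": {"mean_diff": -1.955, "sd_diff": 1.916, "n": 44},
    "RVA": {"mean_diff": -2.227, "sd_diff": 1.987, "n": 44},
    "L_PICA": {"mean_diff": -1.432, "sd_diff": 2.005, "n": 44},
    "R_PICA": {"mean_diff": -1.227, "sd_diff": 1.903, "n": 44},
    "L_AICA": {"mean_diff": -0.341, "sd_diff": 1.380, "n": 44},
    "R_AICA": {"mean_diff": -0.068, "sd_diff": 0.661, "n": 44},
    "SUM": {"mean_diff": -7.705, "sd_diff": 7.070, "n": 44},
}
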