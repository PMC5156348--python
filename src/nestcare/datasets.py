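"""Bundled reference summary statistics.

Printed within-day repeatability summaries from a captive zebra finch
biparental-care study (10 nests per reproductive stage, 07:00-19:00
full-day recordings split into 1h and 3h sampling windows).  Values are
exactly as printed, to two decimals; ``r`` is None where the one-way ANOVA
was not significant and no estimate was reported.  These serve as
regression inputs for the balanced Harper conversion and the 1h-vs-3h
paired-comparison utilities.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

# metric -> (r_1h, F_1h, r_3h, F_3h); k = 10 groups throughout.
# 1h designs: n = 12 (df 9,110); 3h designs: n = 4 (df 9,30).
INCUBATION_DAY3: Dict[str, Tuple[Optional[float], float, Optional[float], float]] = {
    "male_care":         (0.23, 4.68, 0.45, 4.29),
    "male_attendance":   (0.19, 3.83, 0.38, 3.44),
    "female_care":       (0.18, 3.64, 0.32, 2.93),
    "female_attendance": (0.18, 3.68, 0.34, 3.08),
    "joint_care":        (0.36, 7.84, 0.49, 4.78),
    "joint_attendance":  (None, 1.79, None, 1.45),
    "total_care":        (0.19, 3.86, 0.39, 3.55),
    "total_attendance":  (None, 1.33, None, 1.25),
}

# day 13: a ~1.5h footage loss at one nest gives unbalanced designs
# (1h df 9,107; 3h df 9,29)
INCUBATION_DAY13: Dict[str, Tuple[Optional[float], float, Optional[float], float]] = {
    "male_care":         (0.47, 11.85, 0.75, 13.06),
    "male_attendance":   (0.15, 3.07, 0.34, 3.02),
    "female_care":       (0.27, 5.44, 0.57, 6.27),
    "female_attendance": (0.16, 3.22, 0.43, 4.00),
    "joint_care":        (0.58, 17.44, 0.75, 12.81),
    "joint_attendance":  (0.13, 2.80, 0.28, 2.57),
    "total_care":        (0.73, 33.14, 0.85, 24.27),
    "total_attendance":  (0.43, 10.00, 0.56, 6.00),
}

PROVISIONING_DAY3: Dict[str, Tuple[Optional[float], float, Optional[float], float]] = {
    "male_care":           (0.54, 15.18, 0.78, 15.57),
    "female_care":         (0.27, 5.50, 0.58, 6.46),
    "joint_care":          (0.62, 20.47, 0.86, 24.95),
    "total_care":          (0.39, 8.67, 0.62, 7.50),
    "prop_male_feedings":  (0.48, 5.39, 0.64, 8.14),
}

PROVISIONING_DAY17: Dict[str, Tuple[Optional[float], float, Optional[float], float]] = {
    "male_care":           (0.48, 12.03, 0.57, 6.23),
    "female_care":         (0.54, 15.26, 0.69, 9.77),
    "joint_care":          (0.25, 4.91, 0.28, 2.57),
    "total_care":          (0.49, 12.72, 0.60, 7.05),
    "prop_male_feedings":  (0.40, 6.43, 0.57, 6.34),
}

K_GROUPS = 10
N_PER_GROUP_1H = 12
N_PER_GROUP_3H = 4


def significant_r_pairs(table: Dict[str, Tuple]) -> Dict[str, Tuple[float, float]]:
    """(r_1h, r_3h) for metrics with estimates reported at both widths."""
    return {m: (v[0], v[2]) for m, v in table.items()
            if v[0] is not None and v[2] is not None}
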