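"""Reference values for the ten matched subject pairs.

The cohort this package targets (ten schizophrenia subjects, each matched to
an unaffected comparison subject) was previously assayed for prefrontal CB1R
with both ligand-binding autoradiography and antibody-based optical density.
These printed per-pair ratios, terminal-type CB1R group means, and demographic
counts serve as inputs: the ratio table feeds the pair-ratio arithmetic, the
group means parameterize synthetic cohorts, and the demographic counts feed
the categorical tests.
"""

from __future__ import annotations

import pandas as pd

#: Per-pair SZ/Ctrl ratios (%) from the prior assays of the same pairs:
#: antibody (IHC optical density) and OMAR ligand binding (fm/mg).
PAIR_RATIOS = pd.DataFrame(
    {
        "pair_id": range(1, 11),
        "ihc_ratio_pct": [
            -5.57, -11.04, -20.18, -31.61, -24.01,
            -6.17, -30.19, -23.15, -14.64, -21.75,
        ],
        "ligand_ratio_pct": [
            25.76, 41.18, 2.51, 74.85, -0.74,
            29.19, 43.08, -5.18, 47.74, 14.52,
        ],
    }
)

#: Mean CB1R intensity (ADU) by terminal class and subject group from the
#: terminal-type-specific quantification of this cohort; defaults of the
#: synthetic generator.
GROUP_MEAN_CB1R_ADU = {
    "vglut1": {"Ctrl": 770.537, "SZ": 1042.193},
    "vgat_high": {"Ctrl": 2510.098, "SZ": 2137.309},
    "vgat_low": {"Ctrl": 435.461, "SZ": 460.420},
}

#: Pooled SEM printed alongside the group means above.
GROUP_MEAN_SEM_ADU = 48.073

#: Control-group median of mean CB1R intensity in vGAT boutons (ADU), the
#: reference high/low expressor split point in the original cohort.
CONTROL_VGAT_MEDIAN_ADU = 712.0

#: Cannabis use history counts (yes, total) per group in the cohort.
CANNABIS_HISTORY_COUNTS = {"Ctrl": (0, 10), "SZ": (3, 10)}

#: Summary demographics (mean, SD) per group.
DEMOGRAPHICS = {
    "age_years": {"Ctrl": (46.9, 15.9), "SZ": (48.4, 13.7)},
    "pmi_hours": {"Ctrl": (17.9, 5.9), "SZ": (20.3, 11.2)},
    "storage_months": {"Ctrl": (187.8, 16.3), "SZ": (188.8, 24.4)},
    "ph": {"Ctrl": (6.96, 0.24), "SZ": (6.92, 0.20)},
}
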