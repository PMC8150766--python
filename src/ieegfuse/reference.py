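"""Published reference numbers from the clinical SEEG validation study.

These constants record the five-patient cohort summary (epileptogenic :
non-epileptogenic lead counts and per-class segment counts) and the
per-patient accuracies of the fused model under the intra-subject and
leave-one-subject-out schemes, as printed in the study's result tables.
They serve as fixed inputs for the aggregation arithmetic
(:func:`ieegfuse.evaluation.aggregate_folds`) and for sanity checks of
report formatting; nothing here is produced by this package.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "CLINICAL_COHORT",
    "INTRA_SUBJECT_FUSED",
    "CROSS_SUBJECT_FUSED",
    "total_segment_count",
]

#: per-patient lead imbalance and balanced segment counts
CLINICAL_COHORT = pd.DataFrame(
    [
        {"patient": "Pt1", "epi_leads": 4, "non_epi_leads": 69, "es": 2596, "nes": 2622},
        {"patient": "Pt2", "epi_leads": 10, "non_epi_leads": 66, "es": 10350, "nes": 10362},
        {"patient": "Pt3", "epi_leads": 6, "non_epi_leads": 56, "es": 8640, "nes": 8680},
        {"patient": "Pt4", "epi_leads": 4, "non_epi_leads": 71, "es": 2880, "nes": 2928},
        {"patient": "Pt5", "epi_leads": 11, "non_epi_leads": 23, "es": 7920, "nes": 7912},
    ]
)

#: fused-model per-patient metrics (percent), intra-subject scheme
INTRA_SUBJECT_FUSED = pd.DataFrame(
    [
        {"patient": "Pt1", "ACC": 97.14, "SE": 96.85, "SP": 97.44},
        {"patient": "Pt2", "ACC": 87.35, "SE": 88.47, "SP": 85.82},
        {"patient": "Pt3", "ACC": 91.09, "SE": 92.09, "SP": 89.96},
        {"patient": "Pt4", "ACC": 91.96, "SE": 92.63, "SP": 91.40},
        {"patient": "Pt5", "ACC": 95.13, "SE": 95.84, "SP": 94.43},
    ]
)

#: fused-model per-fold metrics (percent), leave-one-subject-out scheme
CROSS_SUBJECT_FUSED = pd.DataFrame(
    [
        {"held_out": "Pt5", "ACC": 87.59, "SE": 88.58, "SP": 86.62},
        {"held_out": "Pt1", "ACC": 87.68, "SE": 87.16, "SP": 88.21},
        {"held_out": "Pt2", "ACC": 90.30, "SE": 89.06, "SP": 91.58},
        {"held_out": "Pt3", "ACC": 88.93, "SE": 88.42, "SP": 89.41},
        {"held_out": "Pt4", "ACC": 85.63, "SE": 87.91, "SP": 83.42},
    ]
)


def total_segment_count() -> int:
    """Total balanced ES + NES segment count across the cohort."""
    return int((CLINICAL_COHORT["es"] + CLINICAL_COHORT["nes"]).sum())
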