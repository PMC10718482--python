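"""Published summary tables of the reference wearable-chronotype cohort.

The cohort that motivates this pipeline (47 adults with metabolic-syndrome
risk factors wearing their own wrist devices for one week) is not deposited;
what survives in print are its marginal summaries.  The cross-tabulations of
the stable/shifting weekly pattern groups against the binary characteristics
are reproduced here so the worked examples and the statistical layer can be
exercised against known answers.  Rows are the characteristic's two levels,
columns are (stable, shifting).
"""

from __future__ import annotations

import numpy as np

#: participants in the reference cohort
N_PARTICIPANTS = 47
#: consecutive measurement days per participant (starting on a Monday)
N_DAYS = 7
#: person-day bookkeeping implied by the study frame
PERSON_DAYS = 329
WEEKDAY_PERSON_DAYS = 235
WEEKEND_PERSON_DAYS = 94

#: stable/shifting group sizes
GROUP_SIZES = {"stable": 35, "shifting": 12}

#: characteristic x group cross-tabs; columns (stable, shifting)
GROUP_TABLES = {
    "sex": {"levels": ("male", "female"), "counts": np.array([[15, 8], [20, 4]])},
    "age": {"levels": ("<40", ">=40"), "counts": np.array([[27, 3], [8, 9]])},
    "work": {"levels": ("sitting", "other"), "counts": np.array([[31, 11], [4, 1]])},
    "pa_change": {
        "levels": ("no_change_or_decrease", "increase"),
        "counts": np.array([[21, 8], [14, 4]]),
    },
    "risk_factors": {"levels": ("1", ">1"), "counts": np.array([[21, 4], [14, 8]])},
}

#: printed two-sided p-values for the cross-tabs above (all Fisher exact)
PRINTED_P = {
    "sex": 0.19,
    "age": 0.004,
    "work": 1.0,  # printed as >.99
    "pa_change": 0.74,
    "risk_factors": 0.18,
}

#: daily energy expenditure by group, mean (SD) kcal, and group n
EE_SUMMARY = {
    "weekday": {"stable": (169, 130, 35), "shifting": (383, 194, 12)},
    "weekend": {"stable": (145, 100, 35), "shifting": (327, 230, 12)},
}
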