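"""Published summary data from the Clew Bay (west of Ireland) tag-recapture study.

These are the study's printed aggregates, shipped as reference inputs: the
tagging/recapture counts, the per-size-class increment and weight-gain
summaries for the ~1-year and ~2-year liberty periods, and the growth
parameters it reported.  Individual-level records were not published; the
size-class tables are therefore the finest granularity available and are
used for table arithmetic (weighted overall means, cohort biomass gain),
never as a stand-in for record-level estimation.
"""

from __future__ import annotations

import numpy as np

#: tagging and recapture counts
N_RELEASED = 1177
N_RECAPTURED_YEAR1 = 207
N_RECAPTURED_YEAR2 = 38
#: year-1 exclusions: zero/negative growth and unreadable tags
N_ZERO_OR_NEGATIVE_YEAR1 = 7
N_UNREADABLE_YEAR1 = 1

#: reported growth parameters (Powell-Wetherall / forced Gulland-Holt, pooled)
REPORTED = {
    "M": {"L_inf": 70.8, "k": 0.161, "k_year1": 0.157, "k_year2": 0.192},
    "F": {"L_inf": 55.2, "k": 0.077, "k_year1": 0.067, "k_year2": 0.117},
}

#: 2-mm size-class boundaries (mm CL) of the published tables: [26,28) ... [38,40)
SIZE_CLASS_EDGES = np.arange(26.0, 42.0, 2.0)

#: year-1 (~344 days) per-size-class summaries: n, mean dCL, mean dTL, mean dW
TABLE_YEAR1 = {
    "M": {
        "n": [1, 5, 18, 27, 30, 14, 4],
        "mean_dcl": [7.3, 6.5, 6.0, 4.7, 4.9, 4.1, 5.3],
        "mean_dtl": [24.2, 21.6, 19.9, 15.7, 16.1, 13.7, 17.5],
        "mean_dw": [16.2, 16.6, 17.3, 15.1, 17.9, 16.5, 24.1],
    },
    "F": {
        "n": [2, 7, 14, 22, 30, 20, 5],
        "mean_dcl": [3.5, 0.8, 1.7, 1.3, 1.5, 1.2, 1.2],
        "mean_dtl": [11.4, 2.7, 5.6, 4.3, 4.9, 4.1, 4.4],
        "mean_dw": [7.0, 1.7, 4.1, 3.6, 4.6, 4.3, 4.6],
    },
}

#: year-2 (~654-665 days) per-size-class summaries (no TL column published)
TABLE_YEAR2 = {
    "M": {
        "n": [0, 1, 3, 2, 3, 3, 0],
        "mean_dcl": [np.nan, 14.9, 13.2, 9.1, 12.8, 10.9, np.nan],
        "mean_dw": [np.nan, 47.3, 49.2, 27.4, 49.6, 46.5, np.nan],
    },
    "F": {
        "n": [0, 1, 9, 5, 7, 3, 0],
        "mean_dcl": [np.nan, 5.5, 4.9, 3.7, 4.8, 4.2, np.nan],
        "mean_dw": [np.nan, 14.6, 13.1, 11.2, 15.7, 11.3, np.nan],
    },
}

#: mean weight (kg) of a tagged individual at release (2013) and recapture (2014)
MEAN_WEIGHT_2013_KG = 0.029
MEAN_WEIGHT_2014_KG = 0.039


def recapture_rate_percent() -> float:
    """Overall recapture rate over both liberty periods, in percent."""
    return 100.0 * (N_RECAPTURED_YEAR1 + N_RECAPTURED_YEAR2) / N_RELEASED


def class_midpoints() -> np.ndarray:
    """Midpoints of the seven published size classes (27 ... 39 mm)."""
    return SIZE_CLASS_EDGES[:-1] + 1.0
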