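"""Published reference values for the Lingkong Mountain study system.

Small, fully printed result tables from the vegetation-mapping study of the
Lingkong Mountain Nature Reserve (seven classes, six Sentinel-2 dates) are
bundled as worked-example inputs: the candidate screening scores for the four
modified indices, the random-forest accuracies per feature set, and the
verification confusion matrix of the knowledge decision tree.  They let the
screening rule and the accuracy arithmetic be exercised against published
numbers without any imagery.
"""

from __future__ import annotations

import numpy as np

from .classes import CLASS_ORDER
from .evaluate import ConfusionMatrix

#: Candidate feature-band combinations and their published summed standard
#: deviations (x10^4 reflectance scale), per target class.  Each entry is
#: (operand label pair, sd_sum); the screening winner is the smallest sum.
SCREENING_CANDIDATES: dict[str, list[tuple[str, float]]] = {
    "pine_oak": [
        ("RE4@FEB and SWIR1@FEB", 391.40),
        ("RE4@DEC and SWIR1@DEC", 456.15),
    ],
    "quercus": [
        ("NIR@JUN and NIR@OCT", 720.60),
        ("RE4@JUN and RE4@OCT", 719.15),
    ],
    "scrub_grass": [
        ("RE2@JUN and RE2@AUG", 724.87),
        ("RE3@JUN and RE3@AUG", 897.84),
        ("NIR@JUN and NIR@AUG", 976.94),
        ("RE4@JUN and RE4@AUG", 877.05),
    ],
    "shaw": [
        ("RE2@JUN and RE2@OCT", 545.04),
        ("RE3@JUN and RE3@OCT", 683.33),
        ("NIR@JUN and NIR@OCT", 785.02),
        ("RE4@JUN and RE4@OCT", 743.65),
    ],
}

#: The combination selected for each modified index in the published screening.
SCREENING_WINNERS: dict[str, str] = {
    "pine_oak": "RE4@FEB and SWIR1@FEB",
    "quercus": "RE4@JUN and RE4@OCT",
    "scrub_grass": "RE2@JUN and RE2@AUG",
    "shaw": "RE2@JUN and RE2@OCT",
}

#: Published random-forest overall accuracy (%) per classification feature set.
RF_OVERALL_ACCURACY_PCT: dict[str, float] = {
    "optimal": 98.41,
    "time_series_ndvi": 96.03,
    "time_series_rvi": 95.56,
    "time_series_dvi": 91.27,
}

#: Published random-forest Kappa per classification feature set.
RF_KAPPA: dict[str, float] = {
    "optimal": 0.98,
    "time_series_ndvi": 0.95,
    "time_series_rvi": 0.95,
    "time_series_dvi": 0.90,
}

#: Published OA gains (percentage points) of the optimal feature set over each
#: time-series typical-index set, as printed (note the published RVI gain of
#: 2.86 differs by 0.01 from differencing the published 2-dp OAs).
RF_OA_GAIN_PCT: dict[str, float] = {
    "time_series_ndvi": 2.38,
    "time_series_rvi": 2.86,
    "time_series_dvi": 7.14,
}

#: Verification confusion matrix of the knowledge decision tree on the optimal
#: feature set: rows = classified, columns = ground truth, class order as in
#: CLASS_ORDER (crops, scrub grass, Pinus, Quercus, pine-oak, Larix, shaw).
DECISION_TREE_CONFUSION = ConfusionMatrix(
    counts=np.array([
        [62,  0,   0,   0,   0,  0,  0],
        [0,  72,   0,   0,   0,  0,  0],
        [0,   0, 117,   0,   0,  0,  0],
        [1,   0,   0, 125,   9,  0,  0],
        [0,   0,   0,   0, 108, 14,  3],
        [0,   0,   0,   1,   0, 58,  0],
        [0,   0,   0,   0,   0,  0, 60],
    ]),
    classes=CLASS_ORDER,
)

#: Published accuracy figures for that confusion matrix.
DECISION_TREE_OA_PCT = 95.56
DECISION_TREE_KAPPA_2DP = 0.95
DECISION_TREE_PA_PCT: dict[str, float] = dict(zip(CLASS_ORDER, (
    98.41, 100.0, 100.0, 99.21, 92.31, 80.57, 95.24)))
DECISION_TREE_UA_PCT: dict[str, float] = dict(zip(CLASS_ORDER, (
    100.0, 100.0, 100.0, 92.59, 86.4, 98.31, 100.0)))
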