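"""Bundled worked-example tables from a 616-patient sleep-clinic cohort.

These printed summary tables — four-class confusion matrices from a
tenfold-CV oximetry classifier, gender-by-severity and sleep-time-by-
severity contingency tables, and per-severity group summaries of the
desaturation indices — serve as ground truth for the evaluation module's
worked examples and for the test suite. ``all`` denotes the full cohort
(n=616); ``tst_ge_4h`` the sub-cohort with total sleep time >= 4 h (n=540).
"""

from __future__ import annotations

import numpy as np

from .evaluation import ConfusionMatrix, GroupSummary
from .scoring import SEVERITIES

__all__ = [
    "CONFUSION_4CLASS",
    "GENDER_SEVERITY_COUNTS",
    "TST_SEVERITY_COUNTS",
    "GROUP_SUMMARIES",
    "PUBLISHED_AHI_ODI4A_FIT",
]

#: Four-class confusion matrices (rows true, columns predicted, severity
#: order normal/mild/moderate/severe) of the combined-ODI classifier.
CONFUSION_4CLASS: dict[str, ConfusionMatrix] = {
    "all": ConfusionMatrix(
        labels=SEVERITIES,
        counts=np.array(
            [
                [53, 18, 1, 0],
                [25, 80, 20, 2],
                [3, 48, 55, 26],
                [1, 11, 22, 251],
            ]
        ),
    ),
    "tst_ge_4h": ConfusionMatrix(
        labels=SEVERITIES,
        counts=np.array(
            [
                [51, 17, 0, 0],
                [21, 85, 14, 1],
                [3, 39, 53, 19],
                [0, 10, 19, 208],
            ]
        ),
    ),
}

#: Gender x severity counts; rows female, male; columns severity order.
GENDER_SEVERITY_COUNTS = np.array(
    [
        [32, 49, 31, 29],
        [40, 78, 101, 256],
    ]
)

#: TST group x severity counts; rows TST < 4 h, TST >= 4 h.
TST_SEVERITY_COUNTS = np.array(
    [
        [4, 6, 18, 48],
        [68, 121, 114, 237],
    ]
)

_GROUP_NS = (72, 127, 132, 285)


def _summaries(stats: tuple[tuple[float, float], ...]) -> tuple[GroupSummary, ...]:
    return tuple(
        GroupSummary(n=n, mean=m, sd=s, label=lab)
        for n, (m, s), lab in zip(_GROUP_NS, stats, SEVERITIES)
    )


#: Per-severity (n, mean, sd) summaries of the cohort table.
GROUP_SUMMARIES: dict[str, tuple[GroupSummary, ...]] = {
    "odi2": _summaries(((10.25, 7.18), (19.81, 10.57), (29.60, 12.31), (56.11, 18.94))),
    "odi3": _summaries(((3.10, 2.78), (8.18, 6.02), (15.54, 8.87), (44.92, 22.37))),
    "odi4t": _summaries(((1.28, 1.43), (4.18, 3.80), (9.52, 7.01), (37.58, 23.66))),
    "odi4a": _summaries(((1.14, 1.41), (5.20, 3.94), (12.01, 7.62), (45.10, 24.97))),
    "age": _summaries(((36.2, 10.2), (42.1, 11.5), (45.9, 12.8), (48.4, 12.5))),
    "bmi": _summaries(((23.88, 3.15), (25.60, 3.75), (26.18, 3.68), (28.22, 4.33))),
    "arousal_index": _summaries(((19.3, 10.8), (20.6, 10.1), (26.6, 11.2), (46.3, 21.9))),
}

#: Published least-squares calibration of AHI on ODI4A in the full cohort.
PUBLISHED_AHI_ODI4A_FIT = {"slope": 1.014, "intercept": 9.091, "r_squared": 0.878}
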