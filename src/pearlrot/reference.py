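"""Published benchmark figures from the original Tahitian-pearl rotation study.

These constants are *inputs* (printed tables from the reference study on 47
real pearls), kept here so that the package's arithmetic -- macro-average F1
from per-class scores, survival percentages from graft counts -- can be
recomputed and cross-checked without access to the raw (request-only) data.
They are never used to train or tune anything.
"""

from __future__ import annotations

__all__ = [
    "PER_CLASS_F1",
    "PUBLISHED_MACRO_F1",
    "GRAFT_SURVIVAL_ROWS",
    "LOSSES_DURING_CULTIVATION",
    "PUBLISHED_ACCURACY",
    "PUBLISHED_SPEED_MEAN",
    "PUBLISHED_SPEED_SD",
    "PUBLISHED_HOURS_PER_REV",
]

#: Per-class F1 on the real cohort, by dataset variant, in the order
#: (Other, Atypical, Round).
PER_CLASS_F1: dict[str, tuple[float, float, float]] = {
    "day": (0.640, 0.272, 0.382),
    "week": (0.734, 0.672, 0.654),
    "month": (0.787, 0.520, 0.575),
    "full": (0.826, 0.752, 0.852),
}

#: Printed macro-average F1 per variant (the "full" row prints 2 decimals).
PUBLISHED_MACRO_F1: dict[str, float] = {"day": 0.431, "week": 0.687, "month": 0.627, "full": 0.81}

#: Per-pearl test accuracy on the real cohort, by dataset variant.
PUBLISHED_ACCURACY: dict[str, float] = {"day": 0.471, "week": 0.734, "month": 0.701, "full": 0.819}

#: Graft-survival counts after one month at the three grafting experiments:
#: (experiment, nucleus quality, n grafted, n remaining).
GRAFT_SURVIVAL_ROWS: list[tuple[str, str, int, int]] = [
    ("a", "Excellent", 15, 9),
    ("a", "Medium", 22, 14),
    ("a", "Poor", 10, 2),
    ("b", "Medium", 20, 14),
    ("b", "Poor", 20, 0),
    ("c", "Medium", 50, 38),
]

#: Oysters lost during cultivation (death, detachment, transport) -- the
#: difference between surviving grafts and oysters actually monitored.
LOSSES_DURING_CULTIVATION: int = 25

#: Measured rotation-speed distribution of rotating pearls, deg/min.
PUBLISHED_SPEED_MEAN: float = 0.69
PUBLISHED_SPEED_SD: float = 0.13
#: Equivalent revolution time as printed (per-pearl averaging; the naive
#: identity 360/(0.69*60) gives 8.70 h instead).
PUBLISHED_HOURS_PER_REV: float = 8.66
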