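"""Published reference inputs from the original field deployment.

The field recordings themselves are not available, but the study that
motivated this package printed several artifacts that serve as fixed
inputs here: the per-element cycle-time summaries that parameterize the
simulator, the observed activity time shares, and the confusion matrices
of the two selected models (3-s/90% choker setter, 1-s/90% chaser), from
which the whole metric layer can be recomputed exactly.
"""

from __future__ import annotations

import numpy as np

from .io import CHASER, CHOKER_SETTER
from .model import ConfusionMatrix

#: Per-element cycle-time mean/SD (seconds) from the field time study.
CYCLE_TIME_STATS = {
    CHOKER_SETTER: {
        "travel_to_log": (17.27, 12.30),
        "set_choker": (19.80, 16.06),
        "travel_away": (13.11, 6.83),
        "clear": (220.31, 519.17),
    },
    CHASER: {
        "travel_to_log": (4.59, 4.42),
        "unhook": (8.00, 6.42),
        "travel_away": (6.69, 3.73),
        "clear": (264.48, 481.49),
    },
}

#: Observed fraction of labeled time per activity in the field data.
ACTIVITY_TIME_SHARES = {
    CHOKER_SETTER: {
        "travel_to_log": 0.1026,
        "set_choker": 0.1241,
        "travel_away": 0.0429,
        "clear": 0.7304,
    },
    CHASER: {
        "travel_to_log": 0.0164,
        "unhook": 0.0295,
        "travel_away": 0.0245,
        "clear": 0.9295,
    },
}

#: Confusion matrix of the selected choker-setter model (3-s window, 90%
#: overlap); rows = predicted, columns = actual.
CHOKER_SETTER_CONFUSION = ConfusionMatrix(
    classes=["set_choker", "travel_away", "travel_to_log", "clear"],
    counts=np.array(
        [
            [18655, 455, 1898, 11254],
            [888, 6409, 554, 7622],
            [1743, 365, 14455, 11407],
            [1031, 487, 1526, 101095],
        ]
    ),
)

#: Confusion matrix of the selected chaser model (1-s window, 90% overlap).
CHASER_CONFUSION = ConfusionMatrix(
    classes=["clear", "travel_away", "travel_to_log", "unhook"],
    counts=np.array(
        [
            [366814, 972, 1022, 1099],
            [53458, 11028, 372, 978],
            [39715, 409, 7061, 714],
            [49828, 1052, 536, 13385],
        ]
    ),
)

BENCHMARK_CONFUSIONS = {
    CHOKER_SETTER: CHOKER_SETTER_CONFUSION,
    CHASER: CHASER_CONFUSION,
}
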