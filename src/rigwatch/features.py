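"""Sliding-window segmentation and time-domain feature extraction.

Windows are backward-looking, fixed-length segments of the filtered
acceleration magnitude.  Ten time-domain summary statistics are computed
per window: mean, standard deviation, maximum, minimum, median absolute
deviation, mean absolute deviation, skewness, interquartile range, range,
and kurtosis.  The estimator variants (MAD scale constant, sd denominator,
quantile interpolation, moment vs bias-adjusted shape statistics) are
configurable because different computing environments default differently.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np
import pandas as pd

from .io import UNLABELED, LabeledMagnitudeSeries

FEATURE_NAMES = (
    "mean",
    "sd",
    "maximum",
    "minimum",
    "mad_median",
    "mad_mean",
    "skewness",
    "iqr",
    "range",
    "kurtosis",
)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclasses.dataclass
class EstimatorConfig:
    """Estimator variants for the window features.

    mad_constant
        Scale constant for the median absolute deviation; 1.4826 makes it
        a consistent sigma estimator under normality (the common default),
        1.0 gives the raw MAD.
    sd_ddof
        Delta degrees of freedom for the standard deviation (1 = the n-1
        sample estimator).
    skew_kind / kurtosis_kind
        "moment": g1 = m3/m2^1.5 and excess g2 = m4/m2^2 - 3 from the
        population moments; "adjusted": the bias-adjusted G1/G2 sample
        versions.
    iqr_method
        Quantile interpolation method name passed to numpy ("linear" is
        the type-7 default).
    """

    mad_constant: float = 1.4826
    sd_ddof: int = 1
    skew_kind: str = "moment"
    kurtosis_kind: str = "moment"
    iqr_method: str = "linear"


@dataclasses.dataclass
class WindowConfig:
    """Sliding-window geometry.

    ``overlap_pct`` is the shared fraction of consecutive windows; e.g.
    25% overlap means the next window begins when the current one is 75%
    complete.  The step is rounded half-up and never below one sample.
    """

    window_s: float
    overlap_pct: float
    rate_hz: float = 25.0

    def __post_init__(self):
        if not 0 <= self.overlap_pct < 100:
            raise ValueError("overlap_pct must be in [0, 100)")
        if self.window_samples < 2:
            raise ValueError("window must span at least 2 samples")

    @property
    def window_samples(self) -> int:
        return _round_half_up(self.window_s * self.rate_hz)

    @property
    def step_samples(self) -> int:
        w = self.window_samples
        # (100 - pct)/100 avoids the 1 - 0.9 = 0.0999... rounding trap
        return max(1, _round_half_up(w * (100.0 - self.overlap_pct) / 100.0))


def window_indices(n_samples: int, config: WindowConfig) -> np.ndarray:
    """Half-open (start, end) index pairs of the sliding windows.

    The first window ends at sample ``w``; consecutive starts differ by the
    step; the last window ends at or before ``n_samples``.  Returns an
    empty (0, 2) array when the series is shorter than one window.
    """
    w, step = config.window_samples, config.step_samples
    if n_samples < w:
        return np.empty((0, 2), dtype=np.int64)
    starts = np.arange(0, n_samples - w + 1, step, dtype=np.int64)
    return np.stack([starts, starts + w], axis=1)


def _moments(W: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    mean = W.mean(axis=1)
    d = W - mean[:, None]
    m2 = (d**2).mean(axis=1)
    m3 = (d**3).mean(axis=1)
    m4 = (d**4).mean(axis=1)
    return mean, m2, m3, m4


def feature_matrix(W: np.ndarray, estimators: EstimatorConfig | None = None) -> pd.DataFrame:
    """Compute the ten features for each row of a windows-by-samples matrix.

    Zero-variance rows get skewness and kurtosis of 0 (quiescent windows
    must still yield finite predictors).
    """
    est = estimators or EstimatorConfig()
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[1] < 2:
        raise ValueError("expected a 2-D matrix with >= 2 samples per window")
    n = W.shape[1]
    mean, m2, m3, m4 = _moments(W)
    sd = np.sqrt(m2 * n / (n - est.sd_ddof))
    mx = W.max(axis=1)
    mn = W.min(axis=1)
    med = np.median(W, axis=1)
    mad_median = est.mad_constant * np.median(np.abs(W - med[:, None]), axis=1)
    mad_mean = np.abs(W - mean[:, None]).mean(axis=1)
    q75, q25 = np.quantile(W, [0.75, 0.25], axis=1, method=est.iqr_method)

    # m2**2 can underflow for near-constant segments; those count as
    # zero-variance and get shape statistics of 0
    nz = (m2**2 > 0) & (m2**1.5 > 0)
    skew = np.zeros(len(W))
    kurt = np.zeros(len(W))
    skew[nz] = m3[nz] / m2[nz] ** 1.5
    kurt[nz] = m4[nz] / m2[nz] ** 2 - 3.0
    if est.skew_kind == "adjusted":
        skew[nz] *= np.sqrt(n * (n - 1)) / (n - 2)
    elif est.skew_kind != "moment":
        raise ValueError(f"unknown skew_kind {est.skew_kind!r}")
    if est.kurtosis_kind == "adjusted":
        kurt[nz] = ((n + 1) * kurt[nz] + 6) * (n - 1) / ((n - 2) * (n - 3))
    elif est.kurtosis_kind != "moment":
        raise ValueError(f"unknown kurtosis_kind {est.kurtosis_kind!r}")

    return pd.DataFrame(
        {
            "mean": mean,
            "sd": sd,
            "maximum": mx,
            "minimum": mn,
            "mad_median": mad_median,
            "mad_mean": mad_mean,
            "skewness": skew,
            "iqr": q75 - q25,
            "range": mx - mn,
            "kurtosis": kurt,
        }
    )


def extract_window_features(
    segment: Iterable[float], estimators: EstimatorConfig | None = None
) -> pd.Series:
    """The ten features of a single magnitude segment (length >= 2)."""
    seg = np.asarray(list(segment) if not isinstance(segment, np.ndarray) else segment, dtype=float)
    if seg.size < 2:
        raise ValueError("segment must contain at least 2 samples")
    return feature_matrix(seg[None, :], estimators).iloc[0]


def assign_window_label(labels_in_window) -> str:
    """Majority label of a window's samples.

    UNLABELED samples do not vote; an all-UNLABELED window is UNLABELED.
    Ties go to the latest-occurring sample whose label is among the tied
    candidates (for a two-way tie this is the label of the final voting
    sample).
    """
    labels = list(labels_in_window)
    if not labels:
        raise ValueError("empty window")
    counts: dict[str, int] = {}
    for lab in labels:
        if lab != UNLABELED:
            counts[lab] = counts.get(lab, 0) + 1
    if not counts:
        return UNLABELED
    top = max(counts.values())
    tied = {lab for lab, c in counts.items() if c == top}
    if len(tied) == 1:
        return tied.pop()
    for lab in reversed(labels):
        if lab in tied:
            return lab
    raise AssertionError("unreachable: tied labels must occur in the window")


@dataclasses.dataclass
class WindowDataset:
    """Per-window feature vectors with window labels for one configuration."""

    config: WindowConfig
    features: pd.DataFrame  # columns FEATURE_NAMES
    labels: np.ndarray  # activity per window
    end_t: np.ndarray  # timestamp (ms) of each window's last sample

    def __len__(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        df = self.features.copy()
        df.insert(0, "label", self.labels)
        df.insert(0, "end_t", self.end_t)
        return df

    def class_counts(self) -> pd.Series:
        return pd.Series(self.labels).value_counts()


def _majority_labels(codes: np.ndarray, spans: np.ndarray, n_codes: int) -> np.ndarray:
    """Vectorized per-window majority vote over integer label codes.

    ``codes`` maps UNLABELED to -1.  Tie-break: latest sample in the window
    whose label is among the tied candidates.
    """
    n = len(codes)
    counts = np.zeros((len(spans), n_codes), dtype=np.int64)
    for c in range(n_codes):
        csum = np.concatenate([[0], np.cumsum(codes == c)])
        counts[:, c] = csum[spans[:, 1]] - csum[spans[:, 0]]
    top = counts.max(axis=1)
    out = np.full(len(spans), -1, dtype=np.int64)
    voted = top > 0
    is_tied = (counts == top[:, None]).sum(axis=1) > 1
    simple = voted & ~is_tied
    out[simple] = counts[simple].argmax(axis=1)
    for i in np.nonzero(voted & is_tied)[0]:
        tied = set(np.nonzero(counts[i] == top[i])[0])
        seg = codes[spans[i, 0] : spans[i, 1]]
        for code in seg[::-1]:
            if code in tied:
                out[i] = code
                break
    return out


def build_dataset(
    series: LabeledMagnitudeSeries,
    config: WindowConfig,
    estimators: EstimatorConfig | None = None,
) -> WindowDataset:
    """Window a labeled magnitude series into a feature/label dataset.

    One row per sliding window; windows whose voting label is UNLABELED
    (i.e. containing no labeled samples) are dropped.
    """
    spans = window_indices(len(series), config)
    if len(spans) == 0:
        return WindowDataset(
            config=config,
            features=pd.DataFrame(columns=list(FEATURE_NAMES)),
            labels=np.empty(0, dtype=object),
            end_t=np.empty(0, dtype=np.int64),
        )
    w = config.window_samples
    step = spans[1, 0] - spans[0, 0] if len(spans) > 1 else w
    windows = np.lib.stride_tricks.sliding_window_view(series.amag, w)[::step]
    windows = windows[: len(spans)]
    feats = feature_matrix(windows, estimators)

    uniq = sorted(set(series.labels) - {UNLABELED})
    code_of = {lab: i for i, lab in enumerate(uniq)}
    codes = np.array([code_of.get(lab, -1) for lab in series.labels], dtype=np.int64)
    votes = _majority_labels(codes, spans, len(uniq))

    keep = votes >= 0
    labels = np.array([uniq[v] for v in votes[keep]], dtype=object)
    end_t = series.t[spans[keep, 1] - 1]
    return WindowDataset(
        config=config,
        features=feats.loc[keep].reset_index(drop=True),
        labels=labels,
        end_t=end_t,
    )


def write_dataset_csv(dataset: WindowDataset, path) -> None:
    dataset.to_frame().to_csv(path, index=False, float_format="%.6f")
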