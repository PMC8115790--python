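"""Per-cycle feature tables and PCA-based predictor selection.

Predictors for the classifiers are not chosen per window but from a
coarser table: the same ten time-domain features computed over each whole
activity episode.  A principal component analysis of that table (centered,
unscaled by default) keeps the smallest leading set of components that
explains more than a variance threshold, and any feature with an absolute
loading above a threshold inside those components becomes a model
predictor.  With unscaled features the high-variance amplitude summaries
(maximum and range) dominate, which is exactly the behaviour the rule is
meant to surface.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, EstimatorConfig, feature_matrix
from .io import LabeledMagnitudeSeries, TimeStudyLog


def cycle_feature_table(
    series: LabeledMagnitudeSeries,
    log: TimeStudyLog,
    estimators: EstimatorConfig | None = None,
) -> pd.DataFrame:
    """One feature row per time-study episode, over the episode's full segment.

    Episodes containing fewer than 2 samples are skipped with a warning.
    Returns a DataFrame with an ``activity`` column plus the ten features.
    """
    rows = []
    activities = []
    for ep in log.episodes:
        lo = np.searchsorted(series.t, ep.start, side="left")
        hi = np.searchsorted(series.t, ep.stop, side="left")
        if hi - lo < 2:
            warnings.warn(
                f"episode {ep.activity!r} [{ep.start}, {ep.stop}) has "
                f"{hi - lo} samples; skipped"
            )
            continue
        rows.append(series.amag[lo:hi])
        activities.append(ep.activity)
    if not rows:
        return pd.DataFrame(columns=["activity", *FEATURE_NAMES])
    # ragged episodes: compute one at a time via the shared matrix kernel
    feats = pd.concat(
        [feature_matrix(seg[None, :], estimators) for seg in rows],
        ignore_index=True,
    )
    feats.insert(0, "activity", activities)
    return feats


@dataclasses.dataclass
class PcaSelection:
    """Outcome of the PCA predictor-selection rule."""

    variance_fractions: np.ndarray  # per component, descending
    loadings: pd.DataFrame  # components (rows) x features (columns)
    retained_components: list[int]
    selected_features: list[str]
    var_threshold: float
    loading_threshold: float

    def report(self) -> pd.DataFrame:
        """Loadings table with a percent-of-variance row, features as rows."""
        out = self.loadings.T
        out.columns = [f"PC{i + 1}" for i in range(out.shape[1])]
        pct = pd.DataFrame(
            [self.variance_fractions * 100.0],
            index=["percent_of_variance"],
            columns=out.columns,
        )
        return pd.concat([pct, out])


def pca_feature_selection(
    table: pd.DataFrame,
    var_threshold: float = 0.95,
    loading_threshold: float = 0.4,
    scaled: bool = False,
) -> PcaSelection:
    """Select predictors: features loading > |threshold| in the leading PCs.

    The eigendecomposition is of the feature covariance matrix (centered,
    unscaled) by default; ``scaled=True`` uses the correlation matrix
    instead.  Retained components are the smallest leading set whose
    cumulative variance fraction exceeds ``var_threshold``; the selection
    is invariant to component sign flips and to row order.
    """
    X = table[list(FEATURE_NAMES)].to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(
            f"PCA needs more rows than features ({n} rows for {p} features)"
        )
    sd = X.std(axis=0, ddof=1)
    zero_var = sd == 0
    if np.any(zero_var):
        warnings.warn(
            "zero-variance feature(s): "
            + ", ".join(np.array(FEATURE_NAMES)[zero_var])
        )
    if scaled:
        Xs = X.copy()
        Xs[:, ~zero_var] = (X[:, ~zero_var] - X[:, ~zero_var].mean(0)) / sd[~zero_var]
        C = np.cov(Xs, rowvar=False, ddof=1)
    else:
        C = np.cov(X, rowvar=False, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(C)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    fractions = eigvals / eigvals.sum()

    cum = np.cumsum(fractions)
    n_keep = int(np.searchsorted(cum, var_threshold, side="right")) + 1
    n_keep = min(n_keep, p)
    retained = list(range(n_keep))

    loadings = pd.DataFrame(
        eigvecs.T, columns=list(FEATURE_NAMES),
        index=[f"PC{i + 1}" for i in range(p)],
    )
    mask = (loadings.iloc[retained].abs() > loading_threshold).any(axis=0)
    selected = [f for f in FEATURE_NAMES if mask[f]]
    return PcaSelection(
        variance_fractions=fractions,
        loadings=loadings,
        retained_components=retained,
        selected_features=selected,
        var_threshold=var_threshold,
        loading_threshold=loading_threshold,
    )
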