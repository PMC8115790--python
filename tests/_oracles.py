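"""Independent straight-line oracles used by the test suite.

Everything here is deliberately naive — plain loops, textbook formulas,
explicit enumeration — and shares no code path with the package.
"""

from __future__ import annotations

import math

import numpy as np


def naive_features(seg: list[float], mad_constant: float = 1.4826,
                   sd_ddof: int = 1) -> dict[str, float]:
    """Textbook implementations of the ten window features."""
    n = len(seg)
    mean = sum(seg) / n
    m2 = sum((x - mean) ** 2 for x in seg) / n
    m3 = sum((x - mean) ** 3 for x in seg) / n
    m4 = sum((x - mean) ** 4 for x in seg) / n
    sd = math.sqrt(sum((x - mean) ** 2 for x in seg) / (n - sd_ddof))
    srt = sorted(seg)

    def quantile_type7(q: float) -> float:
        h = (n - 1) * q
        lo = math.floor(h)
        hi = min(lo + 1, n - 1)
        return srt[lo] + (h - lo) * (srt[hi] - srt[lo])

    med = quantile_type7(0.5)
    mad_median = mad_constant * sorted(abs(x - med) for x in seg)[len(seg) // 2] \
        if n % 2 == 1 else mad_constant * _median_even(
            sorted(abs(x - med) for x in seg))
    mad_mean = sum(abs(x - mean) for x in seg) / n
    skew = m3 / m2**1.5 if m2 > 0 else 0.0
    kurt = m4 / m2**2 - 3.0 if m2 > 0 else 0.0
    return {
        "mean": mean,
        "sd": sd,
        "maximum": max(seg),
        "minimum": min(seg),
        "mad_median": mad_median,
        "mad_mean": mad_mean,
        "skewness": skew,
        "iqr": quantile_type7(0.75) - quantile_type7(0.25),
        "range": max(seg) - min(seg),
        "kurtosis": kurt,
    }


def _median_even(srt: list[float]) -> float:
    n = len(srt)
    return (srt[n // 2 - 1] + srt[n // 2]) / 2


def enumerate_windows(n: int, w: int, step: int) -> list[tuple[int, int]]:
    """Every (start, start+w) with start = 0, step, 2*step, ... fitting in n."""
    out = []
    start = 0
    while start + w <= n:
        out.append((start, start + w))
        start += step
    return out


def brute_force_hand_till(scores: np.ndarray, actual: list[str]) -> float:
    """Hand-and-Till M by explicit enumeration of all case pairs."""
    classes = sorted(set(actual))
    actual = list(actual)

    def a_given(i: str, j: str) -> float:
        col = classes.index(i)
        wins = 0.0
        n = 0
        for a, sa in zip(actual, scores):
            if a != i:
                continue
            for b, sb in zip(actual, scores):
                if b != j:
                    continue
                n += 1
                if sa[col] > sb[col]:
                    wins += 1.0
                elif sa[col] == sb[col]:
                    wins += 0.5
        return wins / n

    total = 0.0
    pairs = 0
    for x in range(len(classes)):
        for y in range(x + 1, len(classes)):
            i, j = classes[x], classes[y]
            total += (a_given(i, j) + a_given(j, i)) / 2
            pairs += 1
    return total / pairs


def brute_force_pca(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Variance fractions and loadings from an explicitly formed covariance."""
    n, p = X.shape
    means = X.mean(axis=0)
    C = np.zeros((p, p))
    for a in range(p):
        for b in range(p):
            C[a, b] = sum(
                (X[i, a] - means[a]) * (X[i, b] - means[b]) for i in range(n)
            ) / (n - 1)
    eigvals, eigvecs = np.linalg.eig(C)
    order = np.argsort(eigvals.real)[::-1]
    eigvals = eigvals.real[order]
    eigvecs = eigvecs.real[:, order]
    return eigvals / eigvals.sum(), eigvecs
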