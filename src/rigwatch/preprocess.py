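"""FIR bandpass preprocessing and orientation-invariant acceleration magnitude.

Each raw axis is filtered with a short linear-phase FIR bandpass before the
Euclidean magnitude is taken, which removes the static gravity component and
damps slow posture changes while keeping body-movement energy.  The band
edges are expressed as fractions of the Nyquist frequency, the convention of
``fir1``-style windowed-sinc designers: the defaults 0.5 and 0.9 correspond
to 6.25-11.25 Hz at 25 Hz sampling.  A Hz interpretation is selectable for
sensitivity experiments.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.signal import firwin, lfilter

from .io import AccelStream


@dataclasses.dataclass
class FilterSpec:
    """Windowed-sinc FIR bandpass specification.

    ``order`` is the filter order (number of taps minus one) and must be
    even so the linear-phase design has an integer group delay.  Edges are
    fractions of Nyquist unless ``edges_in_hz`` is set.
    """

    order: int = 8
    low_edge: float = 0.5
    high_edge: float = 0.9
    window: str = "hamming"
    edges_in_hz: bool = False
    rate_hz: float = 25.0

    def __post_init__(self):
        if self.order <= 0 or self.order % 2 != 0:
            raise ValueError("order must be a positive even integer")
        lo, hi = self.normalized_edges()
        if not (0.0 < lo < hi < 1.0):
            raise ValueError(
                f"band edges must satisfy 0 < low < high < 1 of Nyquist, "
                f"got ({lo}, {hi})"
            )

    def normalized_edges(self) -> tuple[float, float]:
        if self.edges_in_hz:
            nyq = self.rate_hz / 2.0
            return self.low_edge / nyq, self.high_edge / nyq
        return self.low_edge, self.high_edge


def design_bandpass(spec: FilterSpec) -> np.ndarray:
    """Design the symmetric bandpass coefficients with exact DC/Nyquist nulls.

    A Hamming-windowed sinc bandpass of the requested order is the base
    design; because a short even-order (Type I) filter has small residual
    gain at 0 and at Nyquist, a symmetric two-point correction
    ``alpha + beta * (-1)**k`` is subtracted so that the DC and Nyquist
    gains are exactly zero.  The correction preserves coefficient symmetry
    (linear phase) and perturbs the passband by well under 3 dB at these
    orders.
    """
    lo, hi = spec.normalized_edges()
    h = firwin(spec.order + 1, [lo, hi], pass_zero=False, window=spec.window)
    k = np.arange(len(h))
    signs = (-1.0) ** k
    n = float(len(h))
    s = float(signs.sum())
    # solve for (alpha, beta): gain at DC = sum(h), at Nyquist = sum(h*signs)
    alpha, beta = np.linalg.solve(
        np.array([[n, s], [s, n]]), np.array([h.sum(), (h * signs).sum()])
    )
    return h - (alpha + beta * signs)


def frequency_response(coeffs: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Complex response of an FIR at normalized frequencies (1 = Nyquist)."""
    k = np.arange(len(coeffs))
    return np.exp(-1j * np.pi * np.outer(np.asarray(freqs, float), k)) @ coeffs


def filter_axes(
    stream: AccelStream, spec: FilterSpec | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Causally filter each axis; returns (fx, fy, fz, warmup_mask).

    Filtering is forward-only (as it would run on the watch), so the first
    ``order`` output samples are transient; they are returned but flagged
    in ``warmup_mask``.
    """
    spec = spec or FilterSpec(rate_hz=stream.rate_hz)
    if len(stream) <= spec.order:
        raise ValueError(
            f"stream of {len(stream)} samples is too short for an order-"
            f"{spec.order} filter"
        )
    b = design_bandpass(spec)
    fx = lfilter(b, 1.0, stream.ax)
    fy = lfilter(b, 1.0, stream.ay)
    fz = lfilter(b, 1.0, stream.az)
    warmup = np.zeros(len(stream), dtype=bool)
    warmup[: spec.order] = True
    return fx, fy, fz, warmup


def acceleration_magnitude(fx, fy, fz) -> np.ndarray:
    """Euclidean norm sqrt(fx^2 + fy^2 + fz^2) of the filtered axes.

    Invariant to axis permutations and sign flips, which is the point: it
    suppresses the dependence of the signal on watch orientation.
    """
    fx, fy, fz = (np.asarray(a, dtype=float) for a in (fx, fy, fz))
    if not (len(fx) == len(fy) == len(fz)):
        raise ValueError("axis series must have equal length")
    return np.sqrt(fx**2 + fy**2 + fz**2)


def filtered_magnitude(
    stream: AccelStream, spec: FilterSpec | None = None
) -> np.ndarray:
    """Convenience: bandpass each axis, then take the magnitude."""
    fx, fy, fz, _ = filter_axes(stream, spec)
    return acceleration_magnitude(fx, fy, fz)
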