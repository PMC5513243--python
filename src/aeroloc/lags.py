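"""Arrival-lag estimation by cross-correlation of band-pass-filtered audio.

Given synchronized segments around a scheduled call time, each channel is
band-pass filtered to the call's frequency band, every channel pair is
cross-correlated, and the lag of the normalized correlation peak — bounded
by the physically possible lag for that pair's separation — is the observed
TDOA in samples.  A call is usable only if it is detectable on every
channel; detectability is judged by the peak correlation against the
reference channel, automating what a human screener does on spectrograms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import (
    InvalidParameterError,
    TruncationError,
    UndefinedCorrelationError,
)
from .geometry import ArrayLayout, pair_lag_bound
from .simulate import MultichannelRecording

__all__ = [
    "LagSet",
    "bandpass",
    "extract_segment",
    "segment_padding",
    "cross_correlation_lag",
    "build_lag_set",
]

#: Extra samples added to each pair's physical lag bound when searching,
#: absorbing rounding at the bound itself.
DEFAULT_BOUND_MARGIN = 2

#: Default minimum normalized peak correlation against the reference channel
#: for a channel to count as having detected the call.
DEFAULT_MIN_PEAK = 0.3


@dataclass(frozen=True)
class LagSet:
    """Pairwise arrival lags for one call, with quality diagnostics.

    ``lags`` maps each mic id to its signed lag relative to ``reference``
    (positive = arrives later than the reference); the reference maps to 0.
    ``pairwise`` holds all ordered pairs antisymmetrically.  ``detected``
    is True only when every channel passed screening; a rejected call still
    carries its per-channel diagnostics.
    """

    reference: str
    lags: dict[str, float]
    pairwise: dict[tuple[str, str], float]
    peak_correlations: dict[tuple[str, str], float]
    quality_flags: dict[str, bool]
    min_peak: float = DEFAULT_MIN_PEAK
    _ok: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        if self.lags.get(self.reference, 0) != 0:
            raise InvalidParameterError("reference lag must be 0")

    @property
    def detected(self) -> bool:
        return self._ok and all(self.quality_flags.values())

    @property
    def undetected_channels(self) -> list[str]:
        return [m for m, ok in self.quality_flags.items() if not ok]

    def pair_lag(self, i: str, j: str) -> float:
        return self.pairwise[(i, j)]


def bandpass(
    samples: np.ndarray, f_lo: float, f_hi: float, sample_rate: float, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass, same length as the input.

    Forward-backward filtering (``sosfiltfilt``) introduces no group delay,
    so filtering cannot shift correlation peaks; the effective order is
    doubled, steepening the stopband.
    """
    if not (0 < f_lo < f_hi < sample_rate / 2):
        raise InvalidParameterError(
            f"band ({f_lo}, {f_hi}) must satisfy 0 < f_lo < f_hi < Nyquist"
        )
    sos = sps.butter(order, [f_lo, f_hi], btype="bandpass", fs=sample_rate, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(samples, dtype=float))


def segment_padding(
    layout: ArrayLayout, template_duration: float = 0.1, max_range: float = 175.0
) -> float:
    """Padding (seconds) guaranteeing a call falls fully inside all segments.

    Segments are cut around the scheduled *emission* time, but arrivals trail
    it by up to ``max_range / v`` seconds of propagation; the worst-case
    spread between two mics is the largest pair lag bound; the template
    duration covers the call tail.
    """
    worst = max(pair_lag_bound(layout, i, j) for i, j in layout.pairs())
    return (
        max_range / layout.sound_speed
        + worst / layout.sample_rate
        + template_duration
    )


def extract_segment(
    recording: MultichannelRecording,
    scheduled_time: float,
    window: float,
    pad: float = 0.0,
) -> tuple[dict[str, np.ndarray], int]:
    """Cut synchronized equal-length segments centered on a scheduled time.

    Returns (segments keyed by mic id, start sample index).  The half-width
    is window/2 + pad; compute ``pad`` with :func:`segment_padding` so true
    arrivals land inside every segment.  Raises TruncationError if the
    requested span leaves the recording.
    """
    if window <= 0:
        raise InvalidParameterError("window must be > 0")
    sr = recording.sample_rate
    half = window / 2.0 + pad
    start = int(round((scheduled_time - recording.start_time - half) * sr))
    stop = int(round((scheduled_time - recording.start_time + half) * sr))
    if start < 0 or stop > recording.n_samples:
        raise TruncationError(
            f"segment [{scheduled_time - half:.3f}, {scheduled_time + half:.3f}] s "
            f"extends beyond the recording (0 to {recording.duration:.3f} s)"
        )
    segments = {m: recording.data[k, start:stop] for k, m in enumerate(recording.mic_ids)}
    return segments, start


def cross_correlation_lag(
    a: np.ndarray,
    b: np.ndarray,
    max_abs_lag: int,
    subsample: bool = False,
) -> tuple[float, float]:
    """Lag of the normalized cross-correlation peak between two segments.

    Positive lag means ``b`` receives the signal later than ``a``.  The
    search is restricted to |lag| <= max_abs_lag.  Exact peak ties break to
    the smallest |lag|, then negative before positive, so output is
    deterministic.  With ``subsample`` a three-point parabolic fit refines
    the peak to fractional samples.

    Returns (lag, peak) with peak in [-1, 1].
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidParameterError("segments must be equal-length 1-D arrays")
    n = len(a)
    if max_abs_lag >= n:
        raise InvalidParameterError("max_abs_lag must be smaller than segment length")
    energy = np.sqrt(np.dot(a, a) * np.dot(b, b))
    if energy == 0:
        raise UndefinedCorrelationError("cross-correlation of an all-zero segment")
    full = sps.correlate(b, a, mode="full", method="fft")
    lags_axis = np.arange(-(n - 1), n)
    mask = np.abs(lags_axis) <= max_abs_lag
    vals = full[mask] / energy
    lags_in = lags_axis[mask]
    best = np.max(vals)
    # FFT round-off blurs exact ties; treat peaks within 1e-9 of the max
    # as tied and break deterministically: smallest |lag|, then negative
    ties = np.flatnonzero(vals >= best - 1e-9 * max(1.0, abs(best)))
    pick = min(ties, key=lambda k: (abs(int(lags_in[k])), int(lags_in[k])))
    lag = float(lags_in[pick])
    peak = float(vals[pick])
    if subsample and 0 < pick < len(vals) - 1:
        y0, y1, y2 = vals[pick - 1], vals[pick], vals[pick + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:  # genuine local maximum
            lag += 0.5 * (y0 - y2) / denom
    return lag, peak


def build_lag_set(
    segments: dict[str, np.ndarray],
    layout: ArrayLayout,
    reference: str | None = None,
    band: tuple[float, float] | None = None,
    min_peak: float = DEFAULT_MIN_PEAK,
    bound_margin: int = DEFAULT_BOUND_MARGIN,
    subsample: bool = False,
) -> LagSet:
    """Filter, correlate all pairs, and screen channels for one call.

    Every ordered microphone pair is correlated with its search window
    bounded by the pair's physical lag bound plus ``bound_margin``.  A
    channel is marked undetected when its peak correlation against the
    reference falls below ``min_peak``; the reference itself must correlate
    with at least one other channel.  A call with any undetected channel is
    returned as a rejected LagSet (``detected`` False) rather than raising,
    preserving diagnostics — localization requires the call on all channels.
    """
    if reference is None:
        reference = layout.ids[0]
    if set(segments) != set(layout.ids):
        raise InvalidParameterError("need exactly one segment per microphone")
    if band is not None:
        f_lo, f_hi = band
        filtered = {
            m: bandpass(s, f_lo, f_hi, layout.sample_rate) for m, s in segments.items()
        }
    else:
        filtered = {m: np.asarray(s, dtype=float) for m, s in segments.items()}

    pairwise: dict[tuple[str, str], float] = {}
    peaks: dict[tuple[str, str], float] = {}
    degenerate = False
    for i, j in layout.pairs():
        bound = pair_lag_bound(layout, i, j) + bound_margin
        try:
            lag, peak = cross_correlation_lag(
                filtered[i], filtered[j], bound, subsample=subsample
            )
        except UndefinedCorrelationError:
            lag, peak = 0.0, 0.0
            degenerate = True
        pairwise[(i, j)] = lag
        pairwise[(j, i)] = -lag
        peaks[(i, j)] = peak
        peaks[(j, i)] = peak

    quality: dict[str, bool] = {}
    for m in layout.ids:
        if m == reference:
            others = [peaks[(reference, o)] for o in layout.ids if o != reference]
            quality[m] = max(others) >= min_peak
        else:
            quality[m] = peaks[(reference, m)] >= min_peak

    lags = {m: (0.0 if m == reference else pairwise[(reference, m)]) for m in layout.ids}
    return LagSet(
        reference=reference,
        lags=lags,
        pairwise=pairwise,
        peak_correlations=peaks,
        quality_flags=quality,
        min_peak=min_peak,
        _ok=not degenerate,
    )
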