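"""Validation statistics: retrievals paired with a truth track.

Pairs each localized call with the truth position interpolated to the call
time, decomposes the error by axis and Euclidean distance, and summarizes:
medians, means, quartiles, Tukey outliers, and the fraction of retrievals
within given thresholds (e.g. the truth sensor's own per-axis uncertainty).
Per-call-type summaries expose systematic differences between call kinds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import EmptySummaryError, InvalidParameterError
from .simulate import TruthTrack

__all__ = [
    "PairedRetrieval",
    "AxisStats",
    "ErrorSummary",
    "match_to_truth",
    "summarize_errors",
    "per_label_summary",
    "euclidean_uncertainty",
]

AXES = ("x", "y", "z", "euclidean")


@dataclass(frozen=True)
class PairedRetrieval:
    """One retrieval matched with interpolated truth and its error vector."""

    call_id: str
    time_s: float
    label: str
    retrieval: tuple[float, float, float]
    truth: tuple[float, float, float]

    @property
    def errors(self) -> tuple[float, float, float]:
        return (
            self.retrieval[0] - self.truth[0],
            self.retrieval[1] - self.truth[1],
            self.retrieval[2] - self.truth[2],
        )

    @property
    def euclidean_error(self) -> float:
        return math.sqrt(sum(e * e for e in self.errors))


@dataclass(frozen=True)
class AxisStats:
    """Boxplot-style summary of |error| magnitudes along one axis."""

    median: float
    mean: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    outliers: tuple[float, ...]


@dataclass(frozen=True)
class ErrorSummary:
    """Error statistics for a set of paired retrievals.

    ``fraction_within[axis][threshold]`` is the proportion of retrievals
    whose error magnitude on that axis (or Euclidean distance) is within the
    threshold; monotone non-decreasing in the threshold.
    """

    n: int
    axes: dict[str, AxisStats]
    fraction_within: dict[str, dict[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ax, fr in self.fraction_within.items():
            vals = [fr[t] for t in sorted(fr)]
            if any(not (0 <= v <= 1) for v in vals):
                raise InvalidParameterError("proportions must lie in [0, 1]")
            if any(b < a for a, b in zip(vals, vals[1:])):
                raise InvalidParameterError(
                    f"fraction_within[{ax!r}] must be monotone in the threshold"
                )


def match_to_truth(
    retrievals: list,
    track: TruthTrack,
    max_gap: float = 10.0,
) -> tuple[list[PairedRetrieval], int]:
    """Pair retrievals with truth interpolated linearly to each call time.

    Calls whose time is farther than ``max_gap`` seconds from every track
    point are dropped; the second return value counts them.  Accepts the
    CallResult records produced by localization (rejected ones are skipped)
    or any object with ``call_id``, ``time_s``, ``label`` and ``estimate``.
    """
    if track.points.shape[0] == 0:
        raise InvalidParameterError("truth track is empty")
    times = track.times
    pairs: list[PairedRetrieval] = []
    dropped = 0
    for result in retrievals:
        est = getattr(result, "estimate", None)
        if est is None:
            continue
        t = result.time_s
        if np.min(np.abs(times - t)) > max_gap:
            dropped += 1
            continue
        truth = tuple(
            float(np.interp(t, times, track.positions[:, ax])) for ax in range(3)
        )
        pairs.append(
            PairedRetrieval(
                call_id=result.call_id,
                time_s=t,
                label=getattr(result, "label", ""),
                retrieval=(est.x, est.y, est.z),
                truth=truth,
            )
        )
    return pairs, dropped


def _axis_stats(magnitudes: np.ndarray) -> AxisStats:
    q1, med, q3 = np.percentile(magnitudes, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = magnitudes[(magnitudes >= lo_fence) & (magnitudes <= hi_fence)]
    outliers = magnitudes[(magnitudes < lo_fence) | (magnitudes > hi_fence)]
    return AxisStats(
        median=float(med),
        mean=float(np.mean(magnitudes)),
        q1=float(q1),
        q3=float(q3),
        whisker_lo=float(inside.min()) if inside.size else float(med),
        whisker_hi=float(inside.max()) if inside.size else float(med),
        outliers=tuple(float(v) for v in np.sort(outliers)),
    )


def _error_matrix(pairs: list[PairedRetrieval]) -> dict[str, np.ndarray]:
    err = np.array([p.errors for p in pairs])
    return {
        "x": np.abs(err[:, 0]),
        "y": np.abs(err[:, 1]),
        "z": np.abs(err[:, 2]),
        "euclidean": np.linalg.norm(err, axis=1),
    }


def summarize_errors(
    pairs: list[PairedRetrieval],
    thresholds: list[float] | None = None,
) -> ErrorSummary:
    """Per-axis and Euclidean error statistics with threshold fractions.

    Signed errors are summarized by magnitude (|dx|, |dy|, |dz|, Euclidean
    distance).  ``thresholds`` lists the within-threshold fractions to
    report, e.g. [5, 10] meters.
    """
    if not pairs:
        raise EmptySummaryError("no paired retrievals to summarize")
    mags = _error_matrix(pairs)
    axes = {ax: _axis_stats(m) for ax, m in mags.items()}
    fraction: dict[str, dict[float, float]] = {}
    for ax, m in mags.items():
        fraction[ax] = {
            float(t): float(np.mean(m <= t)) for t in sorted(thresholds or [])
        }
    return ErrorSummary(n=len(pairs), axes=axes, fraction_within=fraction)


def per_label_summary(
    pairs: list[PairedRetrieval],
    thresholds: list[float] | None = None,
) -> dict[str, ErrorSummary]:
    """Group paired retrievals by call-type label and summarize each group."""
    groups: dict[str, list[PairedRetrieval]] = {}
    for p in pairs:
        groups.setdefault(p.label, []).append(p)
    return {
        label: summarize_errors(members, thresholds)
        for label, members in sorted(groups.items())
    }


def euclidean_uncertainty(per_axis_sigma: float) -> float:
    """Euclidean-distance uncertainty implied by a per-axis sigma: sqrt(3)*sigma.

    Three independent axes each uncertain by sigma combine in quadrature;
    for a 5 m per-axis sensor this gives the 8.66 m distance band.
    """
    if per_axis_sigma < 0:
        raise InvalidParameterError("per_axis_sigma must be >= 0")
    return math.sqrt(3.0) * per_axis_sigma
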