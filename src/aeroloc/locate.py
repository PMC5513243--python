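"""Hyperbolic TDOA solver: from range differences to a 3D source position.

Each reference-relative lag converts to a range difference
``delta_i = v * lag_i / tau``: the source is ``delta_i`` meters farther from
mic i than from the reference mic, one sheet of a hyperboloid per mic.  With
N >= 5 microphones the N-1 constraints overdetermine the four unknowns
(source x, y, z and the reference range R_ref).  The solver chain is:

1. closed-form linearization — squaring each range equation and subtracting
   the reference equation leaves a system linear in (x, y, z, R_ref), solved
   by least squares; exact for exact inputs, an initializer otherwise;
2. damped Gauss-Newton on the true hyperbolic residual
   r_i = |s - m_i| - |s - m_ref| - delta_i, which never increases the
   residual of its starting point;
3. a multi-level exhaustive grid search minimizing the same residual, used
   as an independent brute-force verifier in tests rather than in the
   production path.

Below-ground and negative-range solutions are reported with flags, never
clamped or discarded: near-ground retrievals are a meaningful symptom of
ground-based interferers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .errors import InfeasibleLagError, InvalidParameterError, TruncationError
from .geometry import ArrayLayout
from .lags import LagSet, build_lag_set, extract_segment, segment_padding
from .simulate import MultichannelRecording

__all__ = [
    "SourceEstimate",
    "CallResult",
    "range_differences",
    "linear_tdoa_solve",
    "refine_gauss_newton",
    "grid_oracle",
    "grid_final_step",
    "localize_call",
]

#: Condition number above which the linear design matrix is flagged.
CONDITION_THRESHOLD = 1e8

#: Slack (meters) allowed on the |delta| <= separation feasibility check,
#: absorbing one-sample quantization at the bound.
FEASIBILITY_TOL = 0.1


@dataclass(frozen=True)
class SourceEstimate:
    """A retrieved source position with residual and diagnostic flags.

    ``emission_time_offset`` is the emission time relative to the arrival at
    the reference microphone, ``-R_ref / v`` (always <= 0 for a physical
    source).  ``residual_rms`` is the RMS over non-reference mics of the
    hyperbolic residual in meters.
    """

    position: np.ndarray
    reference: str
    r_ref: float
    emission_time_offset: float
    residual_rms: float
    method: str
    flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if self.residual_rms < 0:
            raise InvalidParameterError("residual_rms must be >= 0")
        if "negative_range" not in self.flags and self.r_ref < 0:
            raise InvalidParameterError("negative r_ref requires the negative_range flag")

    def has_flag(self, name: str) -> bool:
        return name in self.flags

    @property
    def x(self) -> float:
        return float(self.position[0])

    @property
    def y(self) -> float:
        return float(self.position[1])

    @property
    def z(self) -> float:
        return float(self.position[2])


@dataclass(frozen=True)
class CallResult:
    """Outcome of localizing one scheduled call: an estimate or a rejection."""

    call_id: str
    time_s: float
    label: str
    estimate: SourceEstimate | None
    lagset: LagSet | None
    rejected: bool
    reason: str = ""


def _delta_array(
    layout: ArrayLayout, delta: dict[str, float], reference: str
) -> tuple[np.ndarray, list[str]]:
    """Order non-reference range differences to layout order."""
    others = [m for m in layout.ids if m != reference]
    return np.array([delta[m] for m in others], dtype=float), others


def _residuals(
    s: np.ndarray, layout: ArrayLayout, delta: dict[str, float], reference: str
) -> np.ndarray:
    """Hyperbolic residuals |s-m_i| - |s-m_ref| - delta_i, meters."""
    d_arr, others = _delta_array(layout, delta, reference)
    ref_pos = layout.position(reference)
    coords = np.array([layout.position(m) for m in others])
    ranges = np.linalg.norm(coords - s, axis=1)
    r_ref = np.linalg.norm(ref_pos - s)
    return ranges - r_ref - d_arr


def _residual_rms(
    s: np.ndarray, layout: ArrayLayout, delta: dict[str, float], reference: str
) -> float:
    r = _residuals(s, layout, delta, reference)
    return float(np.sqrt(np.mean(r**2)))


def range_differences(lagset: LagSet, layout: ArrayLayout) -> dict[str, float]:
    """Convert reference-relative lags to range differences, meters.

    delta_i = v * lag_i / tau; the reference maps to exactly 0.
    """
    v, tau = layout.sound_speed, layout.sample_rate
    if lagset.reference not in layout.ids:
        raise InvalidParameterError(f"reference {lagset.reference!r} not in layout")
    return {m: v * lag / tau for m, lag in lagset.lags.items()}


def linear_tdoa_solve(
    layout: ArrayLayout,
    delta: dict[str, float],
    reference: str | None = None,
    condition_threshold: float = CONDITION_THRESHOLD,
) -> SourceEstimate:
    """Closed-form linearized least-squares TDOA solution.

    For each non-reference mic i, |s - m_i| = R_ref + delta_i; squaring and
    subtracting the reference equation eliminates |s|^2, leaving

        2 (m_i - m_ref) . s + 2 delta_i R_ref = |m_i|^2 - |m_ref|^2 - delta_i^2,

    a linear system in (x, y, z, R_ref) solved by least squares over the
    N - 1 >= 4 equations.  Raises InfeasibleLagError when any |delta_i|
    exceeds the pair separation (no hyperboloid exists); flags
    ``negative_range`` when the recovered R_ref is negative and
    ``ill_conditioned`` when the design matrix condition number exceeds the
    threshold.
    """
    if reference is None:
        reference = layout.ids[0]
    if len(layout) < 5:
        raise InvalidParameterError("linear TDOA solve requires >= 5 microphones")
    for m in layout.ids:
        if m == reference:
            continue
        sep = layout.separation(reference, m)
        if abs(delta[m]) > sep + FEASIBILITY_TOL:
            raise InfeasibleLagError(reference, m, delta[m], sep)

    d_arr, others = _delta_array(layout, delta, reference)
    ref_pos = layout.position(reference)
    coords = np.array([layout.position(m) for m in others])
    a = np.hstack([2.0 * (coords - ref_pos), 2.0 * d_arr[:, None]])
    b = (
        np.sum(coords**2, axis=1)
        - np.sum(ref_pos**2)
        - d_arr**2
    )
    solution, *_ = np.linalg.lstsq(a, b, rcond=None)
    cond = float(np.linalg.cond(a))
    position = solution[:3]
    r_ref = float(solution[3])
    flags = set()
    if r_ref < 0:
        flags.add("negative_range")
    if cond > condition_threshold:
        flags.add("ill_conditioned")
    if position[2] < 0:
        flags.add("below_ground")
    return SourceEstimate(
        position=position,
        reference=reference,
        r_ref=r_ref,
        emission_time_offset=-r_ref / layout.sound_speed,
        residual_rms=_residual_rms(position, layout, delta, reference),
        method="linear",
        flags=frozenset(flags),
    )


def refine_gauss_newton(
    initial: SourceEstimate,
    layout: ArrayLayout,
    delta: dict[str, float],
    max_iter: int = 50,
    tol: float = 1e-9,
) -> SourceEstimate:
    """Damped Gauss-Newton refinement on the hyperbolic residual.

    Minimizes sum_i (|s - m_i| - |s - m_ref| - delta_i)^2 in the three
    position coordinates (R_ref follows as |s - m_ref|).  Step halving
    guarantees the returned residual never exceeds the initial one; on
    failure to improve at the damping floor the initial estimate is returned
    with an ``ill_conditioned`` flag.
    """
    reference = initial.reference
    s = np.asarray(initial.position, dtype=float).copy()
    if not np.all(np.isfinite(s)):
        raise InvalidParameterError("initial position must be finite")
    d_arr, others = _delta_array(layout, delta, reference)
    ref_pos = layout.position(reference)
    coords = np.array([layout.position(m) for m in others])

    def res(p: np.ndarray) -> np.ndarray:
        return (
            np.linalg.norm(coords - p, axis=1)
            - np.linalg.norm(ref_pos - p)
            - d_arr
        )

    best = s
    best_cost = float(np.sum(res(s) ** 2))
    diverged = False
    for _ in range(max_iter):
        r = res(s)
        ranges = np.linalg.norm(coords - s, axis=1)
        r_ref = np.linalg.norm(ref_pos - s)
        if r_ref == 0 or np.any(ranges == 0):
            break  # on a microphone: gradient undefined
        jac = (s - coords) / ranges[:, None] - (s - ref_pos) / r_ref
        step, *_ = np.linalg.lstsq(jac, -r, rcond=None)
        if not np.all(np.isfinite(step)):
            diverged = True
            break
        # damped line search: halve until the cost decreases
        scale = 1.0
        improved = False
        while scale >= 2.0**-20:
            trial = s + scale * step
            cost = float(np.sum(res(trial) ** 2))
            if cost < best_cost:
                s, best, best_cost = trial, trial, cost
                improved = True
                break
            scale *= 0.5
        if not improved:
            break
        if np.linalg.norm(scale * step) < tol:
            break
    else:
        pass

    flags = set(initial.flags) - {"below_ground"}
    if diverged:
        flags.add("ill_conditioned")
        best = np.asarray(initial.position, dtype=float)
    r_ref = float(np.linalg.norm(layout.position(reference) - best))
    if best[2] < 0:
        flags.add("below_ground")
    return SourceEstimate(
        position=best,
        reference=reference,
        r_ref=r_ref,
        emission_time_offset=-r_ref / layout.sound_speed,
        residual_rms=_residual_rms(best, layout, delta, reference),
        method="refined",
        flags=frozenset(flags),
    )


def grid_final_step(coarse_step: float, refine_levels: int, shrink: float = 5.0) -> float:
    """Grid spacing at the last level of :func:`grid_oracle`."""
    return coarse_step / shrink**refine_levels


def grid_oracle(
    layout: ArrayLayout,
    delta: dict[str, float],
    reference: str | None = None,
    bounds: tuple[tuple[float, float], ...] = ((-150, 150), (-150, 150), (-5, 150)),
    coarse_step: float = 10.0,
    refine_levels: int = 4,
    shrink: float = 5.0,
    beam: int = 4,
) -> SourceEstimate:
    """Brute-force multi-level grid minimizer of the hyperbolic residual.

    A coarse exhaustive scan of the bounding box seeds ``beam`` well
    separated low-cost candidates; each is refined by a pattern search that
    first *walks* its evaluation box downhill at the current grid step (so
    it can slide along the elongated, shallow residual valleys typical of
    distant sources) and only then divides the step by ``shrink``, for
    ``refine_levels`` levels, finishing with a derivative-free simplex
    polish (the valleys are too anisotropic for an axis-aligned grid alone
    to descend to the floor).  Never fails: infeasible range differences
    just return the minimum-residual point with a large residual.  Shares
    no code with the linear or Gauss-Newton solvers; used in tests as an
    independent verifier of that chain.
    """
    if reference is None:
        reference = layout.ids[0]
    d_arr, others = _delta_array(layout, delta, reference)
    ref_pos = layout.position(reference)
    coords = np.array([layout.position(m) for m in others])

    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    if np.any(hi <= lo):
        raise InvalidParameterError("bounds must be non-empty intervals")

    def eval_pts(pts: np.ndarray) -> np.ndarray:
        r_ref = np.linalg.norm(pts - ref_pos, axis=1)
        cost = np.zeros(len(pts))
        for k in range(len(others)):
            cost += (
                np.linalg.norm(pts - coords[k], axis=1) - r_ref - d_arr[k]
            ) ** 2
        return cost

    def box_pts(center: np.ndarray, half: float, step: float) -> np.ndarray:
        offs = np.arange(-half, half + step / 2, step)
        gx, gy, gz = np.meshgrid(*([offs] * 3), indexing="ij")
        return center + np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    # coarse exhaustive scan
    axes = [np.arange(lo[k], hi[k] + coarse_step / 2, coarse_step) for k in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    cost = eval_pts(pts)
    # greedily pick low-cost seeds at least 4 steps apart
    seeds: list[np.ndarray] = []
    for idx in np.argsort(cost):
        p = pts[idx]
        if all(np.linalg.norm(p - s) > 4 * coarse_step for s in seeds):
            seeds.append(p)
        if len(seeds) >= beam:
            break

    walked: list[tuple[float, np.ndarray]] = []
    for seed_pt in seeds:
        center = seed_pt.astype(float)
        step = float(coarse_step)
        for _ in range(refine_levels + 1):
            # walk the box at this scale until the minimum is interior
            for _ in range(120):
                local = box_pts(center, 3 * step, step)
                local_cost = eval_pts(local)
                new_center = np.clip(local[int(np.argmin(local_cost))], lo, hi)
                moved = np.linalg.norm(new_center - center)
                center = new_center
                if moved <= 2 * step:  # minimum no longer on the box rim
                    break
            step /= shrink
        walked.append((float(eval_pts(center[None, :])[0]), center))
    walked.sort(key=lambda t: t[0])

    # simplex-polish the best two basins only; the rest lost already
    final_step = grid_final_step(coarse_step, refine_levels, shrink)
    best: np.ndarray | None = None
    best_cost = np.inf
    for cost0, center in walked[:2]:
        polish = minimize(
            lambda p: float(eval_pts(p[None, :])[0]),
            center,
            method="Nelder-Mead",
            options={
                "xatol": final_step / 10,
                "fatol": 1e-18,
                "maxiter": 2000,
                "maxfev": 2000,
            },
        )
        cand = np.clip(polish.x, lo, hi)
        cand_cost = float(eval_pts(cand[None, :])[0])
        if cand_cost < best_cost:
            best, best_cost = cand, cand_cost
    assert best is not None
    r_ref = float(np.linalg.norm(layout.position(reference) - best))
    flags = set()
    if best[2] < 0:
        flags.add("below_ground")
    return SourceEstimate(
        position=best,
        reference=reference,
        r_ref=r_ref,
        emission_time_offset=-r_ref / layout.sound_speed,
        residual_rms=_residual_rms(best, layout, delta, reference),
        method="grid",
        flags=frozenset(flags),
    )


def localize_call(
    recording: MultichannelRecording,
    scheduled_time: float,
    band: tuple[float, float],
    layout: ArrayLayout,
    *,
    call_id: str = "call",
    label: str = "",
    window: float = 0.4,
    template_duration: float = 0.1,
    max_range: float = 175.0,
    out_of_bounds_factor: float = 2.0,
    reference: str | None = None,
    min_peak: float = 0.3,
    refine: bool = True,
    subsample: bool = False,
) -> CallResult:
    """End-to-end localization of one scheduled call.

    Extracts padded synchronized segments, builds the screened lag set,
    converts lags to range differences, runs the linear solve and (by
    default) Gauss-Newton refinement.  A call failing screening, or with
    infeasible lags, yields a rejected CallResult carrying diagnostics
    rather than raising.

    Corrupted lag sets (e.g. period slips on tonal calls) can push the
    residual minimum arbitrarily far from the array — the hyperboloids then
    only constrain a direction.  An estimate whose reference range exceeds
    ``out_of_bounds_factor * max_range`` is flagged ``out_of_bounds``; it is
    still reported, but downstream truth comparison should exclude it.
    """
    pad = segment_padding(layout, template_duration, max_range)
    try:
        segments, _ = extract_segment(recording, scheduled_time, window, pad)
    except TruncationError as err:
        return CallResult(
            call_id=call_id,
            time_s=scheduled_time,
            label=label,
            estimate=None,
            lagset=None,
            rejected=True,
            reason=str(err),
        )
    lagset = build_lag_set(
        segments,
        layout,
        reference=reference,
        band=band,
        min_peak=min_peak,
        subsample=subsample,
    )
    if not lagset.detected:
        return CallResult(
            call_id=call_id,
            time_s=scheduled_time,
            label=label,
            estimate=None,
            lagset=lagset,
            rejected=True,
            reason=f"undetected channels: {lagset.undetected_channels}",
        )
    delta = range_differences(lagset, layout)
    try:
        estimate = linear_tdoa_solve(layout, delta, reference=lagset.reference)
    except InfeasibleLagError as err:
        return CallResult(
            call_id=call_id,
            time_s=scheduled_time,
            label=label,
            estimate=None,
            lagset=lagset,
            rejected=True,
            reason=str(err),
        )
    if estimate.has_flag("negative_range"):
        # the linear stage is only an initializer; reflect and refine
        estimate = replace(
            estimate,
            r_ref=abs(estimate.r_ref),
            emission_time_offset=-abs(estimate.r_ref) / layout.sound_speed,
        )
    if refine:
        estimate = refine_gauss_newton(estimate, layout, delta)
    if estimate.r_ref > out_of_bounds_factor * max_range:
        estimate = replace(
            estimate, flags=frozenset(set(estimate.flags) | {"out_of_bounds"})
        )
    return CallResult(
        call_id=call_id,
        time_s=scheduled_time,
        label=label,
        estimate=estimate,
        lagset=lagset,
        rejected=False,
    )
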