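"""Microphone-array geometry and the lag-quantization resolution model.

A time-difference-of-arrival (TDOA) localizer observes, for each microphone
pair, an arrival-time *lag* quantized to whole recording samples.  At sound
speed ``v`` and sample rate ``tau`` the distance a wavefront travels in one
sample period is ``delta_d = v / tau``: the smallest range difference the
array can distinguish.  For a pair separated by ``d`` the lag can take at
most ``l_max = d / delta_d`` samples (source on the pair axis), at least 0
(source on the perpendicular bisector plane), so for a one-sided geometry
there are ``l_max + 1`` possible lags and ``l_max - 1`` distinct intermediate
hyperboloids between the degenerate plane (lag 0) and line (lag l_max).  The
hyperboloid count is the natural resolution proxy: more surfaces, finer
localization.  Raising the sample rate or widening the pair are the only two
ways to add surfaces.

Practical 3D localization needs at least five synchronized microphones and
height diversity: an all-coplanar array constrains altitude poorly.  The
reference layout built by :func:`build_tower_array` is three towers on an
equilateral triangle (20 m sides), each carrying a low (1.5 m) and a high
(9.14 m) microphone, sampled at 22,050 Hz in 340 m/s air.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError, LookupMicError

__all__ = [
    "Microphone",
    "ArrayLayout",
    "LagResolution",
    "sample_distance",
    "max_lag",
    "lag_alphabet_size",
    "hyperboloid_count",
    "lag_resolution",
    "pair_lag_bound",
    "build_tower_array",
]

#: Relative tolerance used when flooring d / delta_d, so ratios that are exact
#: in decimal (1.54 / 0.154 = 10) survive binary floating point.
_FLOOR_RTOL = 1e-9

#: Rank tolerance for the collinearity check, meters.
_COLLINEAR_TOL = 1e-9


@dataclass(frozen=True)
class Microphone:
    """One microphone: an id and a 3D position in the local frame.

    The local frame is right-handed, x east, y north, z height above ground
    level, all in meters.
    """

    id: str
    x: float
    y: float
    z: float

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass(frozen=True)
class ArrayLayout:
    """The fixed observing system: microphones, sample rate, sound speed.

    Parameters
    ----------
    microphones
        At least five non-coincident, non-collinear microphones.  Order is
        significant: recordings index channels in this order.
    sample_rate
        Recorder sample rate ``tau`` in Hz.
    sound_speed
        Atmospheric speed of sound ``v`` in m/s.

    Raises
    ------
    InvalidParameterError
        If fewer than five microphones are given, any two coincide, all are
        collinear, or the rate/speed is not positive.
    """

    microphones: tuple[Microphone, ...]
    sample_rate: float
    sound_speed: float
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        mics = tuple(self.microphones)
        object.__setattr__(self, "microphones", mics)
        if len(mics) < 5:
            raise InvalidParameterError(
                f"3D TDOA needs at least 5 microphones, got {len(mics)}"
            )
        if self.sample_rate <= 0 or self.sound_speed <= 0:
            raise InvalidParameterError("sample_rate and sound_speed must be > 0")
        ids = [m.id for m in mics]
        if len(set(ids)) != len(ids):
            raise InvalidParameterError("duplicate microphone ids")
        coords = np.array([[m.x, m.y, m.z] for m in mics], dtype=float)
        for (a, b) in itertools.combinations(range(len(mics)), 2):
            if np.linalg.norm(coords[a] - coords[b]) <= 0.0:
                raise InvalidParameterError(
                    f"microphones {ids[a]!r} and {ids[b]!r} are coincident"
                )
        centered = coords - coords.mean(axis=0)
        rank = np.linalg.matrix_rank(centered, tol=_COLLINEAR_TOL)
        if rank < 2:
            raise InvalidParameterError("microphones must not all be collinear")
        object.__setattr__(self, "_index", {m.id: i for i, m in enumerate(mics)})

    # -- lookups -----------------------------------------------------------

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(m.id for m in self.microphones)

    @property
    def coordinates(self) -> np.ndarray:
        """(N, 3) array of microphone positions, layout order."""
        return np.array([[m.x, m.y, m.z] for m in self.microphones], dtype=float)

    def __len__(self) -> int:
        return len(self.microphones)

    def index(self, mic_id: str) -> int:
        try:
            return self._index[mic_id]
        except KeyError:
            raise LookupMicError(f"unknown microphone id {mic_id!r}") from None

    def position(self, mic_id: str) -> np.ndarray:
        return self.microphones[self.index(mic_id)].position

    def separation(self, i: str, j: str) -> float:
        """Euclidean distance between microphones ``i`` and ``j``, meters."""
        return float(np.linalg.norm(self.position(i) - self.position(j)))

    def pairs(self) -> list[tuple[str, str]]:
        """All unordered microphone pairs in layout order."""
        return list(itertools.combinations(self.ids, 2))

    @property
    def sample_distance(self) -> float:
        """Distance sound travels in one sample period, v / tau, meters."""
        return sample_distance(self.sound_speed, self.sample_rate)


@dataclass(frozen=True)
class LagResolution:
    """Quantization-resolution summary for one microphone pair.

    ``lag_alphabet_size`` counts the possible one-sided lags 0..l_max;
    ``hyperboloid_count`` counts the distinct intermediate constant-lag
    surfaces, excluding the degenerate lag-0 plane and lag-l_max line.
    """

    sample_distance: float
    max_lag: int
    lag_alphabet_size: int
    hyperboloid_count: int

    def __post_init__(self) -> None:
        if self.sample_distance <= 0:
            raise InvalidParameterError("sample_distance must be > 0")
        if self.max_lag < 0:
            raise InvalidParameterError("max_lag must be >= 0")
        if self.lag_alphabet_size != self.max_lag + 1:
            raise InvalidParameterError("lag_alphabet_size must equal max_lag + 1")
        if self.hyperboloid_count != max(self.max_lag - 1, 0):
            raise InvalidParameterError("hyperboloid_count must be max(max_lag-1, 0)")


def sample_distance(sound_speed: float, sample_rate: float) -> float:
    """Minimum distinguishable range difference, ``v / tau`` in meters.

    >>> round(sample_distance(340.0, 22050.0), 6)
    0.015420
    """
    if sound_speed <= 0 or sample_rate <= 0:
        raise InvalidParameterError("sound_speed and sample_rate must be > 0")
    return sound_speed / sample_rate


def max_lag(separation: float, sample_dist: float) -> int:
    """Largest possible lag for a pair ``separation`` meters apart, in samples.

    Computed as ``floor(d / delta_d)`` with a small relative tolerance so that
    ratios exact in decimal arithmetic return the exact integer
    (``max_lag(1.54, 0.154) == 10``).
    """
    if sample_dist <= 0:
        raise InvalidParameterError("sample_dist must be > 0")
    if separation < 0:
        raise InvalidParameterError("separation must be >= 0")
    ratio = separation / sample_dist
    return int(math.floor(ratio + _FLOOR_RTOL * (ratio + 1.0)))


def lag_alphabet_size(l_max: int) -> int:
    """Number of possible one-sided lags 0..l_max, i.e. ``l_max + 1``."""
    if l_max < 0:
        raise InvalidParameterError("l_max must be >= 0")
    return l_max + 1


def hyperboloid_count(l_max: int) -> int:
    """Number of intermediate constant-lag hyperboloids, ``max(l_max - 1, 0)``.

    Lag 0 degenerates to the bisector plane and lag l_max to the pair axis;
    every lag strictly between traces one hyperboloid sheet.
    """
    if l_max < 0:
        raise InvalidParameterError("l_max must be >= 0")
    return max(l_max - 1, 0)


def lag_resolution(separation: float, sample_dist: float) -> LagResolution:
    """Bundle the resolution quantities for one pair into a LagResolution."""
    l_max = max_lag(separation, sample_dist)
    return LagResolution(
        sample_distance=sample_dist,
        max_lag=l_max,
        lag_alphabet_size=lag_alphabet_size(l_max),
        hyperboloid_count=hyperboloid_count(l_max),
    )


def pair_lag_bound(layout: ArrayLayout, i: str, j: str) -> int:
    """Largest physically possible |lag| for pair (i, j), in samples.

    No source position can produce a range difference exceeding the pair
    separation, so ``ceil(separation * tau / v)`` bounds the cross-correlation
    search window.
    """
    sep = layout.separation(i, j)
    return int(math.ceil(sep * layout.sample_rate / layout.sound_speed - _FLOOR_RTOL))


def build_tower_array(
    side: float = 20.0,
    low_height: float = 1.5,
    high_height: float = 9.14,
    sample_rate: float = 22050.0,
    sound_speed: float = 340.0,
) -> ArrayLayout:
    """Three-tower reference array: equilateral triangle, paired mic heights.

    Towers stand on the vertices of an equilateral triangle with sides
    ``side`` meters (circumradius ``side / sqrt(3)`` from the origin, one
    vertex on the +x axis); each carries a low and a high microphone, giving
    six channels.  The origin is the ground-level centroid; z is height above
    ground.

    Microphone ids are ``t{1,2,3}_low`` / ``t{1,2,3}_high``, low mics first
    in channel order tower by tower.
    """
    if side <= 0:
        raise InvalidParameterError("side must be > 0")
    if not (0 <= low_height < high_height):
        raise InvalidParameterError("need 0 <= low_height < high_height")
    radius = side / math.sqrt(3.0)
    mics = []
    for t in range(3):
        angle = 2.0 * math.pi * t / 3.0
        x = radius * math.cos(angle)
        y = radius * math.sin(angle)
        mics.append(Microphone(f"t{t + 1}_low", x, y, low_height))
        mics.append(Microphone(f"t{t + 1}_high", x, y, high_height))
    return ArrayLayout(tuple(mics), sample_rate=sample_rate, sound_speed=sound_speed)
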