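import numpy as np
import pytest

import aeroloc as al


@pytest.fixture(scope="session")
def layout() -> al.ArrayLayout:
    """Six-mic tower array: 20 m triangle, mics at 1.5 / 9.14 m, 22.05 kHz."""
    return al.build_tower_array()


@pytest.fixture(scope="session")
def templates() -> list[al.CallTemplate]:
    return al.default_template_bank()


@pytest.fixture(scope="session")
def chirp(templates) -> al.CallTemplate:
    """A broadband chirp template (unambiguous under cross-correlation)."""
    return next(t for t in templates if t.label == "INBU")


def random_cylinder_source(
    rng: np.random.Generator,
    r_max: float = 100.0,
    z_min: float = 10.0,
    z_max: float = 130.0,
) -> np.ndarray:
    """Uniform random source in the airspace cylinder over the array."""
    angle = rng.uniform(0, 2 * np.pi)
    r = np.sqrt(rng.uniform(0, 1)) * r_max
    return np.array([r * np.cos(angle), r * np.sin(angle), rng.uniform(z_min, z_max)])


def exact_delta(layout: al.ArrayLayout, source: np.ndarray) -> dict[str, float]:
    """Unquantized range differences, computed from plain distances.

    Independent of the package's arrival-time code: ranges via numpy norms
    only, differenced against the first (reference) microphone.
    """
    dists = np.linalg.norm(layout.coordinates - np.asarray(source, float), axis=1)
    ref = dists[0]
    return {m: float(dists[k] - ref) for k, m in enumerate(layout.ids)}


def rounded_delta(layout: al.ArrayLayout, source: np.ndarray) -> dict[str, float]:
    """Range differences after per-channel nearest-sample arrival rounding.

    Mirrors what a recorder produces: each arrival time is rounded to a
    sample index first, then differenced against the reference.
    """
    dists = np.linalg.norm(layout.coordinates - np.asarray(source, float), axis=1)
    samples = np.round(dists / layout.sound_speed * layout.sample_rate)
    dd = layout.sound_speed / layout.sample_rate
    ref = samples[0]
    return {m: float((samples[k] - ref) * dd) for k, m in enumerate(layout.ids)}
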