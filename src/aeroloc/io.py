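"""File formats: multichannel WAV, array config YAML/JSON, CSV tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from .errors import InvalidParameterError
from .geometry import ArrayLayout, Microphone
from .simulate import MultichannelRecording, TruthTrack

__all__ = [
    "write_wav",
    "read_wav",
    "save_array_config",
    "load_array_config",
    "write_schedule_csv",
    "read_schedule_csv",
    "write_track_csv",
    "read_track_csv",
    "write_retrievals_csv",
    "read_retrievals_csv",
]


def write_wav(path: str | Path, recording: MultichannelRecording) -> None:
    """Write an N-channel recording as 32-bit float PCM WAV."""
    data = recording.data.T.astype(np.float32)  # (samples, channels)
    wavfile.write(str(path), int(round(recording.sample_rate)), data)


def read_wav(
    path: str | Path, mic_ids: tuple[str, ...], start_time: float = 0.0
) -> MultichannelRecording:
    """Read an N-channel WAV; channel order must match ``mic_ids``.

    WAV carries no timestamp, so a pre-roll recorded before t=0 must be
    declared through ``start_time``.
    """
    rate, data = wavfile.read(str(path))
    if data.ndim == 1:
        data = data[:, None]
    if data.shape[1] != len(mic_ids):
        raise InvalidParameterError(
            f"WAV has {data.shape[1]} channels but the layout has {len(mic_ids)}"
        )
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / np.iinfo(data.dtype).max
    return MultichannelRecording(
        mic_ids=tuple(mic_ids),
        data=np.ascontiguousarray(data.T, dtype=np.float64),
        sample_rate=float(rate),
        start_time=start_time,
    )


def save_array_config(path: str | Path, layout: ArrayLayout) -> None:
    payload = {
        "schema_version": 1,
        "sample_rate_hz": layout.sample_rate,
        "sound_speed_mps": layout.sound_speed,
        "microphones": [
            {"id": m.id, "x_m": m.x, "y_m": m.y, "z_m": m.z}
            for m in layout.microphones
        ],
    }
    path = Path(path)
    with open(path, "w") as fh:
        if path.suffix == ".json":
            json.dump(payload, fh, indent=2)
        else:
            yaml.safe_dump(payload, fh, sort_keys=False)


def load_array_config(path: str | Path) -> ArrayLayout:
    path = Path(path)
    with open(path) as fh:
        payload = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    try:
        mics = tuple(
            Microphone(str(m["id"]), float(m["x_m"]), float(m["y_m"]), float(m["z_m"]))
            for m in payload["microphones"]
        )
        return ArrayLayout(
            microphones=mics,
            sample_rate=float(payload["sample_rate_hz"]),
            sound_speed=float(payload["sound_speed_mps"]),
        )
    except (KeyError, TypeError) as err:
        raise InvalidParameterError(f"malformed array config {path}: {err}") from err


def write_schedule_csv(path: str | Path, events) -> None:
    """Call schedule: time_s,label,f_lo_hz,f_hi_hz,duration_s."""
    rows = [
        {
            "time_s": e.t0,
            "label": e.template.label,
            "f_lo_hz": e.template.band[0],
            "f_hi_hz": e.template.band[1],
            "duration_s": e.template.duration,
        }
        for e in events
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_schedule_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"time_s", "label", "f_lo_hz", "f_hi_hz"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidParameterError(f"schedule CSV missing columns: {sorted(missing)}")
    return df


def write_track_csv(path: str | Path, track: TruthTrack) -> None:
    df = pd.DataFrame(track.points, columns=["time_s", "x_m", "y_m", "z_m"])
    df.to_csv(path, index=False)


def read_track_csv(path: str | Path, per_axis_sigma: float = 0.0) -> TruthTrack:
    df = pd.read_csv(path)
    required = ["time_s", "x_m", "y_m", "z_m"]
    missing = set(required) - set(df.columns)
    if missing:
        raise InvalidParameterError(f"track CSV missing columns: {sorted(missing)}")
    return TruthTrack(
        points=df[required].to_numpy(dtype=float), per_axis_sigma=per_axis_sigma
    )


def write_retrievals_csv(path: str | Path, results) -> None:
    """Retrievals table: call_id,time_s,label,x_m,y_m,z_m,residual_m,flags."""
    rows = []
    for r in results:
        if r.estimate is None:
            rows.append(
                {
                    "call_id": r.call_id,
                    "time_s": r.time_s,
                    "label": r.label,
                    "x_m": "",
                    "y_m": "",
                    "z_m": "",
                    "residual_m": "",
                    "flags": "rejected",
                }
            )
        else:
            e = r.estimate
            rows.append(
                {
                    "call_id": r.call_id,
                    "time_s": r.time_s,
                    "label": r.label,
                    "x_m": f"{e.x:.6f}",
                    "y_m": f"{e.y:.6f}",
                    "z_m": f"{e.z:.6f}",
                    "residual_m": f"{e.residual_rms:.6f}",
                    "flags": "|".join(sorted(e.flags)),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_retrievals_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"call_id", "time_s", "x_m", "y_m", "z_m"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidParameterError(f"retrievals CSV missing columns: {sorted(missing)}")
    return df
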