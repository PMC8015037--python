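"""File conventions: multi-page TIFF video + JSON sidecar, CSV traces.

Videos are stored as grayscale 16-bit multi-page TIFF (one page per frame,
10-bit values in the 16-bit container) with a ``<stem>.json`` sidecar
carrying the clock and geometry metadata.  Scalar traces are 2-column CSV
(time_s, value); R-peaks a 1-column CSV of times.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .datatypes import RPeakSeries, SampledTrace, VideoRecording


def save_video(path: str | Path, video: VideoRecording) -> Path:
    path = Path(path)
    frames = np.clip(np.round(video.frames), 0, video.max_count).astype(np.uint16)
    tifffile.imwrite(path, frames, photometric="minisblack")
    sidecar = path.with_suffix(".json")
    meta = {
        "frame_rate_hz": video.frame_rate_hz,
        "t0": video.t0,
        "pixel_pitch_um": video.pixel_pitch_um,
        "bit_depth": video.bit_depth,
        **{k: v for k, v in video.meta.items() if _json_safe(v)},
    }
    sidecar.write_text(json.dumps(meta, indent=2))
    return path


def load_video(path: str | Path) -> VideoRecording:
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return VideoRecording(
        frames=frames.astype(np.float32),
        frame_rate_hz=float(meta.get("frame_rate_hz", 100.0)),
        t0=float(meta.get("t0", 0.0)),
        pixel_pitch_um=float(meta.get("pixel_pitch_um", float("nan"))),
        bit_depth=int(meta.get("bit_depth", 10)),
        meta={k: v for k, v in meta.items()
              if k not in {"frame_rate_hz", "t0", "pixel_pitch_um", "bit_depth"}},
    )


def save_trace(path: str | Path, trace: SampledTrace) -> Path:
    path = Path(path)
    df = pd.DataFrame({"time_s": trace.times_s, trace.name or "value": trace.values})
    df.to_csv(path, index=False)
    return path


def load_trace(path: str | Path, name: str = "") -> SampledTrace:
    df = pd.read_csv(path)
    t = df.iloc[:, 0].to_numpy(dtype=float)
    v = df.iloc[:, 1].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("trace needs at least two samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError("trace is not regularly sampled")
    return SampledTrace(values=v, rate_hz=1.0 / dt[0], t0=t[0],
                        name=name or df.columns[1])


def save_rpeaks(path: str | Path, rpeaks: RPeakSeries) -> Path:
    path = Path(path)
    np.savetxt(path, rpeaks.times_s, fmt="%.6f", header="time_s", comments="")
    return path


def load_rpeaks(path: str | Path) -> RPeakSeries:
    times = np.loadtxt(path, skiprows=1, ndmin=1)
    return RPeakSeries(times_s=times, source="provided")


def save_schedule(path: str | Path, schedule: pd.DataFrame) -> Path:
    path = Path(path)
    path.write_text(json.dumps(schedule.to_dict(orient="records"), indent=2))
    return path


def load_schedule(path: str | Path) -> pd.DataFrame:
    return pd.DataFrame(json.loads(Path(path).read_text()))


def load_config(path: str | Path) -> dict:
    """Read a simulation/analysis configuration (YAML or JSON) into the
    spec dataclasses.

    Recognized top-level keys: ``protocol`` -> TrialProtocol,
    ``hemodynamics`` -> HemoDynamicsSpec, ``design`` -> ExperimentDesign
    (with ``drug_effect`` given as name -> {apc: [...], ois: [...]}); other
    keys pass through untouched.
    """
    import yaml

    from .synth.experiment import DrugEffect, ExperimentDesign
    from .synth.kinetics import HemoDynamicsSpec, TrialProtocol

    raw = yaml.safe_load(Path(path).read_text())
    out = dict(raw)
    if "protocol" in raw:
        out["protocol"] = TrialProtocol(**raw["protocol"])
    if "hemodynamics" in raw:
        out["hemodynamics"] = HemoDynamicsSpec(**raw["hemodynamics"])
    if "design" in raw:
        d = dict(raw["design"])
        if "groups" in d:
            d["groups"] = [tuple(g) for g in d["groups"]]
        if "drug_effect" in d:
            d["drug_effect"] = {k: DrugEffect(apc=tuple(v.get("apc", (1, 1, 1))),
                                              ois=tuple(v.get("ois", (1, 1, 1))))
                                for k, v in d["drug_effect"].items()}
        out["design"] = ExperimentDesign(**d)
    return out


def _json_safe(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False
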