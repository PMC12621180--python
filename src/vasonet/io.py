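"""Reading and writing of masks, traces, tables and ground truth.

Interchange formats are deliberately lowest-common-denominator: integer
TIFF/PNG label masks, delimited-text traces (first column time in seconds,
one column per cell id), CSV tables and JSON for nested structures.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .events import TraceSet

__all__ = [
    "read_mask",
    "write_mask",
    "read_traces",
    "write_traces",
    "write_ground_truth",
    "read_ground_truth",
]


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, np.asarray(mask, dtype=np.int32))
    elif path.suffix.lower() == ".png":
        import imageio.v3 as iio

        iio.imwrite(path, np.asarray(mask, dtype=np.uint16))
    else:
        raise ValueError(f"unsupported mask format: {path.suffix}")


def read_mask(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return np.asarray(tifffile.imread(path))
    if path.suffix.lower() == ".png":
        import imageio.v3 as iio

        return np.asarray(iio.imread(path))
    raise ValueError(f"unsupported mask format: {path.suffix}")


def write_traces(traces: TraceSet, path: str | Path) -> None:
    df = pd.DataFrame(traces.values, columns=[str(c) for c in traces.cell_ids])
    df.insert(0, "time", traces.time)
    df.to_csv(path, index=False)


def read_traces(
    path: str | Path, stimulus_onset: float | None = None
) -> TraceSet:
    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise ValueError("traces file must have a 'time' column (seconds)")
    time = df["time"].to_numpy(dtype=float)
    steps = np.diff(time)
    if steps.size and steps.min() <= 0:
        raise ValueError("time column must be strictly increasing")
    cell_ids = [int(c) for c in df.columns if c != "time"]
    frame_rate = 1.0 / float(np.median(steps)) if steps.size else 1.0
    return TraceSet(
        time=time,
        values=df.drop(columns="time").to_numpy(dtype=float),
        frame_rate=frame_rate,
        cell_ids=cell_ids,
        stimulus_onset=stimulus_onset,
    )


def write_ground_truth(truth, path: str | Path) -> None:
    """Serialize a GroundTruth (sensitivity, communities, true events) as JSON."""
    payload = {
        "sensitivity": {str(c): sorted(s) for c, s in truth.sensitivity.items()},
        "communities": {
            ag: {str(c): int(i) for c, i in comm.items()}
            for ag, comm in truth.communities.items()
        },
        "events": truth.events.to_dict(orient="list") if len(truth.events) else {},
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path: str | Path):
    from .simulate import GroundTruth

    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        sensitivity={int(c): frozenset(s) for c, s in payload["sensitivity"].items()},
        communities={
            ag: {int(c): int(i) for c, i in comm.items()}
            for ag, comm in payload["communities"].items()
        },
        events=pd.DataFrame(payload["events"]),
    )
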