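"""Session container I/O: HDF5 round-trip, CSV/TIFF export.

A *session container* stores everything one simulated (or recorded) session
produces: the neurons x trials response matrix, the trial table, per-neuron
metadata/ground truth, and provenance (config hash, seeds, schema version).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .population import ResponseMatrix
from .stimuli import StimulusMovie

__all__ = ["write_session", "read_session", "write_movie_tiff",
           "export_trial_table", "SCHEMA_VERSION"]

SCHEMA_VERSION = "figground-session-1"


def _frame_to_group(df: pd.DataFrame, group: h5py.Group) -> None:
    group.attrs["columns"] = json.dumps(list(df.columns))
    for col in df.columns:
        values = df[col].to_numpy()
        if values.dtype == object:
            group.create_dataset(
                col, data=np.array([str(v) for v in values],
                                   dtype=h5py.string_dtype()))
        else:
            group.create_dataset(col, data=values)


def _frame_from_group(group: h5py.Group) -> pd.DataFrame:
    columns = json.loads(group.attrs["columns"])
    data = {}
    for col in columns:
        values = group[col][()]
        if values.dtype.kind in ("O", "S"):
            values = np.array([v.decode() if isinstance(v, bytes) else v
                               for v in values])
        data[col] = values
    return pd.DataFrame(data)


def write_session(path: str | Path, responses: ResponseMatrix,
                  provenance: dict | None = None) -> None:
    """Write a session container (responses, trials, neurons, provenance)."""
    with h5py.File(path, "w") as f:
        f.attrs["schema"] = SCHEMA_VERSION
        f.create_dataset("responses", data=responses.responses,
                         compression="gzip")
        _frame_to_group(responses.trials, f.create_group("trials"))
        _frame_to_group(responses.neurons, f.create_group("neurons"))
        f.create_group("provenance").attrs["json"] = json.dumps(
            provenance or {}, sort_keys=True, default=str)


def read_session(path: str | Path) -> tuple[ResponseMatrix, dict]:
    """Read a session container; raises on schema mismatch."""
    with h5py.File(path, "r") as f:
        schema = f.attrs.get("schema")
        if schema != SCHEMA_VERSION:
            raise ValueError(f"unsupported session schema {schema!r}; "
                             f"expected {SCHEMA_VERSION!r}")
        responses = f["responses"][()]
        trials = _frame_from_group(f["trials"])
        neurons = _frame_from_group(f["neurons"])
        provenance = json.loads(f["provenance"].attrs["json"])
    return ResponseMatrix(responses, neurons, trials), provenance


def export_trial_table(trials: pd.DataFrame, path: str | Path) -> None:
    trials.to_csv(path, index=False)


def write_movie_tiff(movie: StimulusMovie, path: str | Path) -> None:
    """Export a movie as multi-page 8-bit TIFF with a JSON sidecar.

    Quantization to 8 bits happens only here; all internal math uses the
    [0, 1] float representation.
    """
    import tifffile

    path = Path(path)
    frames8 = np.clip(np.round(movie.frames * 255.0), 0, 255).astype(np.uint8)
    tifffile.imwrite(path, frames8)
    sidecar = {
        "frame_rate_hz": movie.frame_rate_hz,
        "figure_disp_deg": movie.figure_disp_deg.tolist(),
        "background_disp_deg": movie.background_disp_deg.tolist(),
        "spec": movie.spec.to_dict() if movie.spec is not None else None,
        "canvas": {"width_deg": movie.canvas.width_deg,
                   "height_deg": movie.canvas.height_deg,
                   "px_per_deg": movie.canvas.px_per_deg},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
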