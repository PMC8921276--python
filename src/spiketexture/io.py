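"""Readers and writers for the spike-data formats.

Two formats are supported:

* a tabular CSV dialect (one row per spike, plus a companion trials table
  that declares every trial so that zero-spike trials are representable), and
* a single hierarchical HDF5 container holding both tables, the
  neuron/texture metadata, and a provenance block (generator seed, config
  hash).

Round-trips are bit-exact: spike times are written at full float64
precision (17 significant digits in CSV, native float64 in HDF5).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .data_model import (
    IngestError,
    ResponseSet,
    SpikeTrain,
    StudyDesign,
    ValidationError,
    neuron_table,
    spike_train_from_raw,
    texture_table,
)

SPIKE_COLUMNS = ["neuron_id", "texture_id", "repeat", "speed_mm_s", "spike_time_ms"]
TRIAL_COLUMNS = ["neuron_id", "texture_id", "repeat", "speed_mm_s"]


def trials_path_for(spikes_path: str | Path) -> Path:
    """Default companion trials table path: foo.csv -> foo.trials.csv."""
    p = Path(spikes_path)
    return p.with_suffix(".trials" + (p.suffix or ".csv"))


def _spike_frame(rs: ResponseSet) -> tuple[pd.DataFrame, pd.DataFrame]:
    rows = {c: [] for c in SPIKE_COLUMNS}
    trials = {c: [] for c in TRIAL_COLUMNS}
    for tr in rs.trains:
        trials["neuron_id"].append(tr.neuron_id)
        trials["texture_id"].append(tr.texture_id)
        trials["repeat"].append(tr.repeat_index)
        trials["speed_mm_s"].append(tr.speed)
        for t in tr.times:
            rows["neuron_id"].append(tr.neuron_id)
            rows["texture_id"].append(tr.texture_id)
            rows["repeat"].append(tr.repeat_index)
            rows["speed_mm_s"].append(tr.speed)
            rows["spike_time_ms"].append(t)
    return pd.DataFrame(rows), pd.DataFrame(trials)


def write_spike_table(rs: ResponseSet, path: str | Path, trials_path: str | Path | None = None) -> None:
    """Write the CSV dialect (spikes + companion trials table)."""
    spikes, trials = _spike_frame(rs)
    trials_path = trials_path or trials_path_for(path)
    spikes.to_csv(path, index=False, float_format="%.17g")
    trials.to_csv(trials_path, index=False, float_format="%.17g")


def read_spike_table(
    path: str | Path,
    trials_path: str | Path | None = None,
    design: StudyDesign | None = None,
    neurons: pd.DataFrame | None = None,
    textures: pd.DataFrame | None = None,
    validate: bool = True,
) -> ResponseSet:
    """Read the CSV dialect back into a ResponseSet.

    If metadata/design are not given, they are inferred from the trials
    table (areas/submodalities default to unknown/unclassified; id order
    follows first appearance).
    """
    trials_path = trials_path or trials_path_for(path)
    try:
        spikes = pd.read_csv(path, dtype={"neuron_id": str, "texture_id": str}, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise IngestError(f"cannot parse spike table {path}: {exc}") from exc
    try:
        trials = pd.read_csv(trials_path, dtype={"neuron_id": str, "texture_id": str}, float_precision="round_trip")
    except Exception as exc:
        raise IngestError(f"cannot parse trials table {trials_path}: {exc}") from exc

    for name, frame, cols in (("spike", spikes, SPIKE_COLUMNS), ("trials", trials, TRIAL_COLUMNS)):
        missing = [c for c in cols if c not in frame.columns]
        if missing:
            raise IngestError(f"{name} table missing column(s) {missing} (header line 1)")
        bad = frame[cols].isna()
        if bad.to_numpy().any():
            line = int(np.argwhere(bad.to_numpy().any(axis=1))[0][0]) + 2  # 1-based + header
            raise IngestError(f"malformed row in {name} table at line {line}")

    grouped: dict[tuple, list[float]] = {}
    for row in trials.itertuples(index=False):
        key = (row.neuron_id, row.texture_id, int(row.repeat), float(row.speed_mm_s))
        if key in grouped:
            raise IngestError(f"duplicate trial declaration {key}")
        grouped[key] = []
    for row in spikes.itertuples(index=False):
        key = (row.neuron_id, row.texture_id, int(row.repeat), float(row.speed_mm_s))
        if key not in grouped:
            raise IngestError(f"spike row references undeclared trial {key}")
        grouped[key].append(float(row.spike_time_ms))

    trains = [
        spike_train_from_raw(n, t, r, s, times) for (n, t, r, s), times in grouped.items()
    ]
    if neurons is None:
        neurons = neuron_table(list(dict.fromkeys(trials["neuron_id"])))
    if textures is None:
        textures = texture_table(list(dict.fromkeys(trials["texture_id"])))
    if design is None:
        design = StudyDesign(
            n_repeats=int(trials["repeat"].max()) + 1,
            speeds=tuple(sorted(set(float(s) for s in trials["speed_mm_s"]))),
        )
    rs = ResponseSet(trains=trains, neurons=neurons, textures=textures, design=design)
    if validate:
        rs.validate()
    return rs


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------

_STR = h5py.string_dtype(encoding="utf-8")


def _write_frame(grp: h5py.Group, name: str, frame: pd.DataFrame) -> None:
    g = grp.create_group(name)
    g.attrs["columns"] = json.dumps(list(frame.columns))
    for col in frame.columns:
        vals = frame[col].to_numpy()
        if vals.dtype.kind in "OU":
            g.create_dataset(col, data=vals.astype(object), dtype=_STR, track_times=False)
        else:
            g.create_dataset(col, data=vals, track_times=False)


def _read_frame(grp: h5py.Group, name: str) -> pd.DataFrame:
    g = grp[name]
    cols = json.loads(g.attrs["columns"])
    data = {}
    for col in cols:
        vals = g[col][()]
        if vals.dtype.kind in "OS":
            vals = np.array([v.decode() if isinstance(v, bytes) else v for v in vals], dtype=object)
        data[col] = vals
    return pd.DataFrame(data)


def write_container(rs: ResponseSet, path: str | Path) -> None:
    """Write the full ResponseSet to one HDF5 container.

    Datasets are created with track_times=False so that identical inputs
    produce byte-identical files.
    """
    spikes, trials = _spike_frame(rs)
    with h5py.File(path, "w", track_order=True) as f:
        _write_frame(f, "spikes", spikes)
        _write_frame(f, "trials", trials)
        _write_frame(f, "neurons", rs.neurons)
        _write_frame(f, "textures", rs.textures)
        d = f.create_group("design")
        d.attrs["n_repeats"] = rs.design.n_repeats
        d.attrs["speeds"] = np.asarray(rs.design.speeds, dtype=float)
        p = f.create_group("provenance")
        p.attrs["provenance_json"] = json.dumps(rs.provenance, sort_keys=True, default=str)


def read_container(path: str | Path, validate: bool = True) -> ResponseSet:
    with h5py.File(path, "r") as f:
        spikes = _read_frame(f, "spikes")
        trials = _read_frame(f, "trials")
        neurons = _read_frame(f, "neurons")
        textures = _read_frame(f, "textures")
        design = StudyDesign(
            n_repeats=int(f["design"].attrs["n_repeats"]),
            speeds=tuple(float(s) for s in f["design"].attrs["speeds"]),
        )
        provenance = json.loads(f["provenance"].attrs["provenance_json"])

    grouped: dict[tuple, list[float]] = {}
    for row in trials.itertuples(index=False):
        grouped[(str(row.neuron_id), str(row.texture_id), int(row.repeat), float(row.speed_mm_s))] = []
    for row in spikes.itertuples(index=False):
        key = (str(row.neuron_id), str(row.texture_id), int(row.repeat), float(row.speed_mm_s))
        if key not in grouped:
            raise IngestError(f"container spike references undeclared trial {key}")
        grouped[key].append(float(row.spike_time_ms))
    trains = [SpikeTrain(n, t, r, s, np.asarray(times)) for (n, t, r, s), times in grouped.items()]
    rs = ResponseSet(
        trains=trains, neurons=neurons, textures=textures, design=design, provenance=provenance
    )
    if validate:
        rs.validate()
    return rs
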