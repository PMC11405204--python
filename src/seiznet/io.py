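"""File formats: spike CSVs, FC tables, trajectories, voltage containers,
scenario configs.

Spike lists are CSV with header ``electrode,time_s`` (0-based electrode
index, seconds to 6 decimals). Voltage traces use an HDF5 container
(dataset ``/voltage`` as channels × samples float32 µV; attributes
``fs_hz``, ``electrode_rows``, ``electrode_cols``, ``stage``) with a
flat-binary + JSON-sidecar fallback for HDF5-free consumers.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .connectivity import FCMatrix, NetworkGraph, pair_index
from .preprocess import VoltageRecording
from .spikes import BurstMask, SpikeTrainSet
from .synth import TreatmentDesign, WellConfig

__all__ = [
    "write_spike_csv",
    "read_spike_csv",
    "write_burst_csv",
    "write_fc_long_csv",
    "write_fc_matrix_csv",
    "read_fc_long_csv",
    "write_network_csv",
    "write_voltage_h5",
    "read_voltage_h5",
    "write_voltage_flat",
    "read_voltage_flat",
    "load_scenario",
    "dump_scenario",
]


def write_spike_csv(trains: SpikeTrainSet, path) -> None:
    rows = []
    for idx, t in zip(trains.electrode_ids, trains.trains):
        for s in t:
            rows.append((int(idx), s))
    df = pd.DataFrame(rows, columns=["electrode", "time_s"])
    df["time_s"] = df["time_s"].map(lambda v: f"{v:.6f}")
    df.to_csv(path, index=False)


def read_spike_csv(path, duration: float, n_electrodes: int | None = None) -> SpikeTrainSet:
    df = pd.read_csv(path)
    if list(df.columns) != ["electrode", "time_s"]:
        raise ValueError("spike CSV must have header 'electrode,time_s'")
    if n_electrodes is None:
        n_electrodes = int(df["electrode"].max()) + 1 if len(df) else 0
    trains = []
    for e in range(n_electrodes):
        t = np.sort(df.loc[df["electrode"] == e, "time_s"].to_numpy(dtype=float))
        trains.append(t)
    return SpikeTrainSet(trains=trains, duration=duration, provenance="loaded")


def write_burst_csv(mask: BurstMask, path) -> None:
    pd.DataFrame(mask.intervals, columns=["start_s", "end_s"]).to_csv(
        path, index=False
    )


def write_fc_long_csv(fc: FCMatrix, path) -> None:
    i, j = pair_index(fc.n_electrodes)
    df = pd.DataFrame(
        {"i": i, "j": j, "z": fc.z[i, j], "valid": fc.valid[i, j].astype(int)}
    )
    df.to_csv(path, index=False)


def read_fc_long_csv(path, n_electrodes: int) -> FCMatrix:
    df = pd.read_csv(path)
    z = np.zeros((n_electrodes, n_electrodes))
    valid = np.zeros((n_electrodes, n_electrodes), dtype=bool)
    ii = df["i"].to_numpy(int)
    jj = df["j"].to_numpy(int)
    z[ii, jj] = z[jj, ii] = df["z"].to_numpy(float)
    valid[ii, jj] = valid[jj, ii] = df["valid"].to_numpy(bool)
    return FCMatrix(z=z, valid=valid, n_bins_used=0, burst_excluded=True)


def write_fc_matrix_csv(fc: FCMatrix, path) -> None:
    pd.DataFrame(fc.z, index=fc.electrode_ids, columns=fc.electrode_ids).to_csv(path)


def write_network_csv(net: NetworkGraph, path) -> None:
    pd.DataFrame(net.edges, columns=["i", "j", "z"]).astype(
        {"i": int, "j": int}
    ).to_csv(path, index=False)


def write_voltage_h5(rec: VoltageRecording, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("voltage", data=rec.data.astype(np.float32))
        f.attrs["fs_hz"] = rec.fs
        f.attrs["electrode_rows"] = rec.grid_positions[:, 0]
        f.attrs["electrode_cols"] = rec.grid_positions[:, 1]
        f.attrs["electrode_ids"] = rec.electrode_ids
        f.attrs["stage"] = rec.stage


def read_voltage_h5(path) -> VoltageRecording:
    with h5py.File(path, "r") as f:
        data = f["voltage"][...].astype(float)
        fs = float(f.attrs["fs_hz"])
        rows = np.asarray(f.attrs["electrode_rows"])
        cols = np.asarray(f.attrs["electrode_cols"])
        ids = np.asarray(f.attrs["electrode_ids"])
        stage = str(f.attrs.get("stage", "raw"))
    return VoltageRecording(
        data=data,
        fs=fs,
        electrode_ids=ids,
        grid_positions=np.column_stack([rows, cols]),
        stage=stage,
    )


def write_voltage_flat(rec: VoltageRecording, path) -> None:
    """Flat binary (float32, C order) with a JSON sidecar."""
    path = Path(path)
    rec.data.astype(np.float32).tofile(path)
    sidecar = {
        "fs_hz": rec.fs,
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "dtype": "float32",
        "order": "C",
        "electrode_ids": [int(i) for i in rec.electrode_ids],
        "electrode_rows": [int(r) for r in rec.grid_positions[:, 0]],
        "electrode_cols": [int(c) for c in rec.grid_positions[:, 1]],
        "stage": rec.stage,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_voltage_flat(path) -> VoltageRecording:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    data = np.fromfile(path, dtype=np.float32).reshape(
        sidecar["n_channels"], sidecar["n_samples"]
    )
    return VoltageRecording(
        data=data.astype(float),
        fs=sidecar["fs_hz"],
        electrode_ids=np.array(sidecar["electrode_ids"]),
        grid_positions=np.column_stack(
            [sidecar["electrode_rows"], sidecar["electrode_cols"]]
        ),
        stage=sidecar["stage"],
    )


_WELL_KEYS = {
    "n_electrodes", "duration", "base_rate", "coupling", "burst_rate",
    "burst_duration", "burst_gain", "seed",
}
_DESIGN_KEYS = {
    "n_days", "rate_multipliers", "coupling_boost", "n_treated_wells",
    "n_control_wells", "boosted_edges",
}


def load_scenario(path) -> tuple[WellConfig, TreatmentDesign, dict]:
    """Read a YAML scenario mirroring WellConfig / TreatmentDesign fields.

    Top-level keys: ``well``, ``design``, and optional ``coupling``
    shorthand under ``well`` as ``{fraction, weight, symmetric}`` to
    draw a random coupling matrix from the well seed. Unknown keys are
    rejected.
    """
    from ._seeds import child_rng
    from .synth import random_coupling

    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or not set(raw) <= {"well", "design"}:
        raise ValueError(f"scenario must contain only 'well'/'design', got {set(raw)}")
    well_raw = dict(raw.get("well", {}))
    design_raw = dict(raw.get("design", {}))
    unknown = (set(well_raw) - _WELL_KEYS) | (set(design_raw) - _DESIGN_KEYS)
    if unknown:
        raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
    extra = {}
    coupling = well_raw.pop("coupling", None)
    well = WellConfig(**well_raw)
    if isinstance(coupling, dict):
        rng = child_rng(well.seed, 0xC0)
        w, pairs = random_coupling(
            well.n_electrodes,
            float(coupling.get("fraction", 0.05)),
            float(coupling.get("weight", 0.3)),
            rng,
            symmetric=bool(coupling.get("symmetric", False)),
        )
        well.coupling = w
        extra["true_pairs"] = pairs
    elif coupling is not None:
        well.coupling = np.asarray(coupling, dtype=float)
    if "rate_multipliers" in design_raw:
        design_raw["rate_multipliers"] = tuple(design_raw["rate_multipliers"])
    design = TreatmentDesign(**design_raw)
    return well, design, extra


def dump_scenario(well: WellConfig, design: TreatmentDesign, path) -> None:
    doc = {
        "well": {
            "n_electrodes": well.n_electrodes,
            "duration": well.duration,
            "base_rate": well.base_rate,
            "burst_rate": well.burst_rate,
            "burst_duration": well.burst_duration,
            "burst_gain": well.burst_gain,
            "seed": well.seed,
            "coupling": np.asarray(well.coupling).tolist(),
        },
        "design": {
            "n_days": design.n_days,
            "rate_multipliers": list(design.rate_multipliers),
            "coupling_boost": design.coupling_boost,
            "n_treated_wells": design.n_treated_wells,
            "n_control_wells": design.n_control_wells,
        },
    }
    Path(path).write_text(yaml.safe_dump(doc))
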