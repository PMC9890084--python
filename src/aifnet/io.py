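"""Reading and writing curve files, cohorts, and AIF-pair batches.

Curves are CSV with columns ``time_s,value``; acquisition context travels
in a JSON sidecar (``<name>.json`` next to ``<name>.csv``).  Preprocessed
AIF pairs can be stored either as one HDF5 container or as per-pair CSV
files; both forms round-trip exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .signal_model import AcquisitionParams, ConcentrationCurve, SignalCurve

__all__ = [
    "write_signal_curve",
    "read_signal_curve",
    "write_concentration_curve",
    "read_concentration_curve",
    "write_pairs_hdf5",
    "read_pairs_hdf5",
    "write_pair_csv",
    "read_pair_csv",
]

_FLOAT_FMT = "%.9g"


def _write_curve_csv(path: Path, times, values) -> None:
    df = pd.DataFrame({"time_s": times, "value": values})
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_signal_curve(
    path: str | Path,
    curve: SignalCurve,
    acq: AcquisitionParams | None = None,
) -> None:
    path = Path(path)
    _write_curve_csv(path, curve.times, curve.values)
    sidecar = {"ts": curve.ts, "baseline_n": curve.baseline_n}
    if acq is not None:
        sidecar["acquisition"] = acq.to_dict()
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def read_signal_curve(path: str | Path) -> tuple[SignalCurve, AcquisitionParams | None]:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    curve = SignalCurve(
        times=df["time_s"].to_numpy(),
        values=df["value"].to_numpy(),
        ts=meta["ts"],
        baseline_n=meta.get("baseline_n", 4),
    )
    acq = meta.get("acquisition")
    return curve, (AcquisitionParams.from_dict(acq) if acq else None)


def write_concentration_curve(path: str | Path, curve: ConcentrationCurve) -> None:
    _write_curve_csv(Path(path), curve.times, curve.values)


def read_concentration_curve(path: str | Path) -> ConcentrationCurve:
    df = pd.read_csv(path)
    return ConcentrationCurve(times=df["time_s"].to_numpy(), values=df["value"].to_numpy())


def write_pairs_hdf5(path: str | Path, pairs) -> None:
    """Store a list of AIFPair objects in one HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("sat", data=np.stack([p.sat for p in pairs]))
        f.create_dataset("unsat", data=np.stack([p.unsat for p in pairs]))
        f.create_dataset("scale", data=np.array([p.scale for p in pairs]))
        f.create_dataset("dt", data=np.array([p.dt for p in pairs]))
        f.create_dataset("arrival_index", data=np.array([p.arrival_index for p in pairs]))


def read_pairs_hdf5(path: str | Path):
    from .prep import AIFPair

    with h5py.File(path, "r") as f:
        return [
            AIFPair(
                sat=f["sat"][i],
                unsat=f["unsat"][i],
                scale=float(f["scale"][i]),
                dt=float(f["dt"][i]),
                arrival_index=int(f["arrival_index"][i]),
            )
            for i in range(f["sat"].shape[0])
        ]


def write_pair_csv(path: str | Path, pair) -> None:
    path = Path(path)
    df = pd.DataFrame({"sat": pair.sat, "unsat": pair.unsat})
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    meta = {"scale": pair.scale, "dt": pair.dt, "arrival_index": pair.arrival_index}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_pair_csv(path: str | Path):
    from .prep import AIFPair

    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return AIFPair(
        sat=df["sat"].to_numpy(),
        unsat=df["unsat"].to_numpy(),
        scale=meta["scale"],
        dt=meta["dt"],
        arrival_index=meta["arrival_index"],
    )
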