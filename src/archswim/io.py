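"""HDF5 serialization of beat records.

Layout: ``/params`` (JSON-encoded attribute), ``/time``, ``/theta``, ``/m``,
``/X0``, ``/beat_boundaries``, optional ``/forces`` group (``f``, ``phi``,
``X0dot``, ``thetadot`` per stored step) and a ``/diagnostics`` group.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .assembly import BeatRecord, solve_rates, _Discretization
from .params import DimensionlessParameters

__all__ = ["save_record", "load_record"]


def save_record(record: BeatRecord, path: str | Path,
                with_forces: bool = False, force_stride: int = 1,
                diagnostics: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["params"] = json.dumps(record.params.to_dict())
        f.attrs["status"] = record.status
        f.create_dataset("time", data=record.times)
        f.create_dataset("theta", data=record.theta)
        f.create_dataset("m", data=record.m)
        f.create_dataset("X0", data=record.X0)
        f.create_dataset("beat_boundaries", data=record.beat_boundaries)
        if with_forces:
            disc = _Discretization(record.params)
            idx = np.arange(0, len(record.times), force_stride)
            sols = [solve_rates(record.state_at(int(i)), record.params, disc)
                    for i in idx]
            g = f.create_group("forces")
            g.create_dataset("index", data=idx)
            g.create_dataset("f", data=np.stack([s.f for s in sols]))
            g.create_dataset("f_rep", data=np.stack([s.f_rep for s in sols]))
            g.create_dataset("phi", data=np.stack([s.phi for s in sols]))
            g.create_dataset("X0dot", data=np.stack([s.X0dot for s in sols]))
            g.create_dataset("thetadot", data=np.stack([s.thetadot for s in sols]))
        if diagnostics:
            g = f.create_group("diagnostics")
            for k, v in diagnostics.items():
                g.attrs[k] = v


def load_record(path: str | Path) -> BeatRecord:
    with h5py.File(path, "r") as f:
        params = DimensionlessParameters.from_dict(json.loads(f.attrs["params"]))
        rec = BeatRecord(
            params=params,
            times=f["time"][:],
            X0=f["X0"][:],
            theta=f["theta"][:],
            m=f["m"][:],
            beat_boundaries=f["beat_boundaries"][:],
            status=str(f.attrs.get("status", "ok")),
        )
    return rec
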