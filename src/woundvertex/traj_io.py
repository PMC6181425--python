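"""HDF5 trajectory serialisation.

Round trips are lossless for floating-point state, and files written from
the same trajectory are byte-identical (dataset timestamps are disabled),
so archived runs can be diffed.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .engine import Trajectory, Snapshot
from .params import ModelParams
from .substrate import Substrate

__all__ = ["write_trajectory", "read_trajectory", "events_to_csv", "FORMAT_VERSION"]

FORMAT_VERSION = 1


def _ds(group, name, data):
    group.create_dataset(name, data=data, track_times=False)


def write_trajectory(traj: Trajectory, path) -> None:
    with h5py.File(path, "w", libver="v108") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["params"] = json.dumps(traj.params.to_dict(), sort_keys=True)
        f.attrs["seed"] = -1 if traj.seed is None else int(traj.seed)
        f.attrs["closure_time"] = (np.nan if traj.closure_time is None
                                   else traj.closure_time)
        _ds(f, "wound_center", traj.wound_center)
        _ds(f, "area_times", np.asarray(traj.area_times))
        _ds(f, "areas", np.asarray(traj.areas))
        f.attrs["events"] = json.dumps(traj.events)
        if traj.substrate is not None:
            g = f.create_group("substrate")
            _ds(g, "r_ref", traj.substrate.r_ref)
            _ds(g, "springs", traj.substrate.springs)
            _ds(g, "pinned", traj.substrate.pinned)
            g.attrs["k_s"] = traj.substrate.k_s
            g.attrs["h_s"] = traj.substrate.h_s
            g.attrs["spacing"] = traj.substrate.spacing
        snaps = f.create_group("snapshots")
        for i, s in enumerate(traj.snapshots):
            g = snaps.create_group(f"{i:06d}")
            g.attrs["t"] = s.t
            g.attrs["wound_area"] = s.wound_area
            _ds(g, "x", s.x)
            _ds(g, "cell_flat", np.concatenate(s.cells) if s.cells else np.empty(0, np.int64))
            _ds(g, "cell_len", np.asarray([len(c) for c in s.cells], dtype=np.int64))
            _ds(g, "mode", s.mode)
            _ds(g, "theta", s.theta)
            _ds(g, "adh_node", s.adh_node)
            _ds(g, "adh_rest", s.adh_rest)
            _ds(g, "border_vertices", s.border_vertices)
            _ds(g, "centroids", s.centroids)
            if s.sub_u is not None:
                _ds(g, "sub_u", s.sub_u)


def read_trajectory(path) -> Trajectory:
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("format_version", -1))
        if version != FORMAT_VERSION:
            raise ValueError(f"unsupported trajectory format version {version}")
        params = ModelParams.from_dict(json.loads(f.attrs["params"]))
        seed = int(f.attrs["seed"])
        traj = Trajectory(params=params, seed=None if seed == -1 else seed,
                          wound_center=f["wound_center"][...])
        ct = float(f.attrs["closure_time"])
        traj.closure_time = None if np.isnan(ct) else ct
        traj.area_times = list(f["area_times"][...])
        traj.areas = list(f["areas"][...])
        traj.events = json.loads(f.attrs["events"])
        if "substrate" in f:
            g = f["substrate"]
            sub = Substrate(g["r_ref"][...], g["springs"][...],
                            float(g.attrs["k_s"]), float(g.attrs["h_s"]),
                            g["pinned"][...], float(g.attrs["spacing"]))
            traj.substrate = sub
        for key in sorted(f["snapshots"].keys()):
            g = f["snapshots"][key]
            flat = g["cell_flat"][...]
            lens = g["cell_len"][...]
            cells = list(np.split(flat, np.cumsum(lens)[:-1])) if len(lens) else []
            traj.snapshots.append(Snapshot(
                t=float(g.attrs["t"]), x=g["x"][...], cells=cells,
                mode=g["mode"][...], theta=g["theta"][...],
                adh_node=g["adh_node"][...], adh_rest=g["adh_rest"][...],
                sub_u=g["sub_u"][...] if "sub_u" in g else None,
                wound_area=float(g.attrs["wound_area"]),
                border_vertices=g["border_vertices"][...],
                centroids=g["centroids"][...]))
            traj.times.append(float(g.attrs["t"]))
    return traj


def events_to_csv(traj: Trajectory, path) -> None:
    import pandas as pd
    pd.DataFrame(traj.events).to_csv(path, index=False)
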