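"""HDF5 persistence of simulation recordings.

Layout: ``/frames`` (n_frames, nx, ny) with a ``times`` attribute,
``/traces/<x>_<y>`` voltage vectors sharing ``/traces/time``, and ``/meta``
holding the fully resolved config as a YAML string plus a format version.
Files without ``/meta`` are rejected as foreign.
"""

from __future__ import annotations

import numpy as np
import yaml

from .solver import Recording

__all__ = ["write_recording", "read_recording", "FORMAT_VERSION"]

FORMAT_VERSION = 1


def write_recording(rec: Recording, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        meta = f.create_group("meta")
        meta.attrs["format_version"] = FORMAT_VERSION
        meta.attrs["config_yaml"] = yaml.safe_dump(_plain(rec.meta))
        tr = f.create_group("traces")
        tr.create_dataset("time", data=rec.trace_t)
        for (x, y), V in rec.traces.items():
            tr.create_dataset(f"{x}_{y}", data=V)
        fr = f.create_dataset("frames", data=rec.frames,
                              compression="gzip", compression_opts=4)
        fr.attrs["times"] = rec.frame_t


def read_recording(path) -> Recording:
    import h5py

    with h5py.File(path, "r") as f:
        if "meta" not in f:
            raise ValueError(f"{path}: no /meta group; not a recording file")
        ver = int(f["meta"].attrs.get("format_version", -1))
        if ver != FORMAT_VERSION:
            raise ValueError(f"{path}: format version {ver} != {FORMAT_VERSION}")
        meta = yaml.safe_load(f["meta"].attrs["config_yaml"])
        trace_t = f["traces/time"][()]
        traces = {}
        for key in f["traces"]:
            if key == "time":
                continue
            x, y = key.split("_")
            traces[(int(x), int(y))] = f[f"traces/{key}"][()]
        frames = f["frames"][()]
        frame_t = np.asarray(f["frames"].attrs["times"])
        if len(frame_t) and np.any(np.diff(frame_t) <= 0):
            raise ValueError(f"{path}: frame times are not increasing")
    return Recording(trace_t=trace_t, traces=traces, frame_t=frame_t,
                     frames=frames, meta=meta)


def _plain(obj):
    """Recursively convert numpy scalars/arrays for YAML round-tripping."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
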