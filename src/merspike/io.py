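"""Signal and table I/O: WAV / HDF5 recordings with JSON metadata sidecars.

WAV float traces round-trip exactly; PCM WAV is scaled to [-1, 1] floats on
read.  HDF5 stores the samples dataset with rate / role / depth / site
attributes.  A sidecar ``<path>.json`` can supply or override depth and site
metadata.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import h5py
import numpy as np
import yaml
from scipy.io import wavfile

from .core import Recording
from .errors import InvalidParameterError

logger = logging.getLogger(__name__)

_H5_DATASET = "samples"


def _sidecar(path: Path) -> dict:
    sc = path.with_suffix(path.suffix + ".json")
    if sc.exists():
        return json.loads(sc.read_text())
    logger.warning("no metadata sidecar for %s; depth unknown", path.name)
    return {}


def read_signal(path: str | Path) -> Recording:
    """Read a recording from WAV or HDF5 (with its JSON sidecar, if any)."""
    path = Path(path)
    if path.suffix.lower() == ".wav":
        rate, data = wavfile.read(path)
        data = np.asarray(data)
        if data.ndim > 1:
            data = data[:, 0]
        if np.issubdtype(data.dtype, np.integer):
            scale = float(np.iinfo(data.dtype).max)
            data = data.astype(float) / scale
            logger.info("PCM WAV scaled to [-1, 1] floats (/%g)", scale)
        else:
            data = data.astype(float)
        meta = _sidecar(path)
        return Recording(data, float(rate),
                         meta.get("channel_role", "MER"),
                         meta.get("depth_mm"), meta.get("site_id", path.stem))
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            if _H5_DATASET not in f or "rate" not in f[_H5_DATASET].attrs:
                raise InvalidParameterError(
                    "HDF5 file lacks a samples dataset with a rate attribute")
            ds = f[_H5_DATASET]
            meta = {k: ds.attrs[k] for k in ds.attrs}
            data = ds[...]
        side = _sidecar(path)
        depth = side.get("depth_mm", meta.get("depth_mm"))
        depth = None if depth is None or (isinstance(depth, float)
                                          and np.isnan(depth)) else float(depth)
        return Recording(np.asarray(data, dtype=float), float(meta["rate"]),
                         str(side.get("channel_role",
                                      meta.get("channel_role", "MER"))),
                         depth,
                         str(side.get("site_id", meta.get("site_id",
                                                          path.stem))))
    raise InvalidParameterError(f"unknown signal format: {path.suffix}")


def write_signal(rec: Recording, path: str | Path) -> Path:
    """Write a recording as float WAV or HDF5; metadata goes to a sidecar
    (WAV) or attributes (HDF5)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".wav":
        wavfile.write(path, int(round(rec.rate)),
                      rec.samples.astype(np.float32))
        meta = {"channel_role": rec.channel_role, "depth_mm": rec.depth_mm,
                "site_id": rec.site_id, "rate": rec.rate}
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(meta, indent=1))
        return path
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            ds = f.create_dataset(_H5_DATASET, data=rec.samples)
            ds.attrs["rate"] = rec.rate
            ds.attrs["channel_role"] = rec.channel_role
            ds.attrs["site_id"] = rec.site_id
            if rec.depth_mm is not None:
                ds.attrs["depth_mm"] = rec.depth_mm
        return path
    raise InvalidParameterError(f"unknown signal format: {path.suffix}")


def load_yaml_config(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def save_yaml_config(cfg: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(cfg, sort_keys=True))
    return path
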