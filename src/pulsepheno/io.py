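"""File I/O: multiband TIFF stacks, VI maps, and YAML configs.

Stacks are stored as plain multiband TIFF with the band order and
calibration state recorded as JSON in the ImageDescription tag (blue, green,
red, red-edge, NIR). Tables are CSV; configuration round-trips through YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .radiometric import BAND_ORDER, BandStack

__all__ = ["write_bandstack", "read_bandstack", "write_vi_map", "read_vi_map",
           "write_yaml", "read_yaml"]


def write_bandstack(path, stack: BandStack) -> None:
    """Write a five-band stack as multiband TIFF with a JSON description tag."""
    desc = json.dumps({"bands": list(stack.bands), "state": stack.state})
    tifffile.imwrite(
        str(path), stack.data.astype(np.float32), description=desc,
        photometric="minisblack",
    )


def read_bandstack(path) -> BandStack:
    """Read a multiband TIFF written by :func:`write_bandstack`.

    Raises ``ValueError`` naming the missing band(s) if the file does not
    carry all five, before any computation is attempted on it.
    """
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        desc = tif.pages[0].tags.get("ImageDescription")
        meta = {}
        if desc is not None:
            try:
                meta = json.loads(desc.value)
            except (json.JSONDecodeError, TypeError):
                meta = {}
    data = np.atleast_3d(np.asarray(data, dtype=float))
    if data.ndim == 3 and data.shape[0] not in (len(BAND_ORDER),) and data.shape[-1] == len(BAND_ORDER):
        data = np.moveaxis(data, -1, 0)
    bands = tuple(meta.get("bands", BAND_ORDER))
    if data.shape[0] != len(BAND_ORDER):
        present = bands[: data.shape[0]]
        missing = [b for b in BAND_ORDER if b not in present]
        raise ValueError(f"raster {path} is missing band(s): {missing}")
    return BandStack(data, state=meta.get("state", "raw"), bands=bands)


def write_vi_map(path, vi: np.ndarray, name: str) -> None:
    """Write a single vegetation-index map as single-band TIFF."""
    tifffile.imwrite(str(path), vi.astype(np.float32),
                     description=json.dumps({"index": name}))


def read_vi_map(path) -> np.ndarray:
    return np.asarray(tifffile.imread(str(path)), dtype=float)


def write_yaml(path, obj: dict) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))


def read_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
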