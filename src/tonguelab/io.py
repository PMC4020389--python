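"""Mask, contour and result-file input/output."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .config import SCHEMA_VERSION
from .errors import FormatError

__all__ = ["read_mask", "write_mask", "write_contour_csv", "write_result_json"]


def read_mask(path) -> np.ndarray:
    """Read a single-channel PNG mask (0 = background, 255 = tongue)."""
    from PIL import Image

    with Image.open(path) as im:
        if im.mode not in ("L", "1"):
            raise FormatError(f"{path}: mask must be single-channel, got mode {im.mode!r}")
        arr = np.asarray(im.convert("L"))
    return arr >= 128


def write_mask(path, mask: np.ndarray) -> None:
    from PIL import Image

    arr = (np.asarray(mask, dtype=bool) * np.uint8(255))
    Image.fromarray(arr, mode="L").save(path)


def write_contour_csv(path, contour: np.ndarray) -> None:
    verts = np.asarray(contour, dtype=float)
    header = "row,col"
    np.savetxt(path, verts, delimiter=",", header=header, comments="")


def write_result_json(path, payload: dict, *, config_hash: str, seed: int) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "config_hash": config_hash,
        "seed": seed,
        **payload,
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True, default=_coerce))


def _coerce(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
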