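"""Periodic (minimum-image) geometry for orthorhombic boxes.

All distances in the package go through these helpers.  Boxes are
orthorhombic; ``mode="xy"`` wraps and measures only the lateral (x, y)
components, which is what every in-leaflet analysis uses.
"""

from __future__ import annotations

import numpy as np

__all__ = ["min_image_displacement", "minimum_image_distance", "wrap_coords"]


def _check_box(box: np.ndarray) -> np.ndarray:
    box = np.asarray(box, dtype=float)
    if box.shape[-1] < 2 or not np.all(np.isfinite(box)) or np.any(box <= 0):
        raise ValueError(f"box edges must be finite and positive, got {box}")
    return box


def min_image_displacement(d: np.ndarray, box, mode: str = "xyz") -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors.

    ``d`` has shape (..., 3) (or (..., 2) with mode="xy"); wrapped axes
    are x, y and -- for mode "xyz" -- z.
    """
    box = _check_box(box)
    d = np.array(d, dtype=float, copy=True)
    if mode == "xyz":
        n_wrap = d.shape[-1]
    elif mode == "xy":
        n_wrap = 2
    else:
        raise ValueError(f"mode must be 'xy' or 'xyz', got {mode!r}")
    for ax in range(n_wrap):
        d[..., ax] -= box[ax] * np.round(d[..., ax] / box[ax])
    return d


def minimum_image_distance(p1, p2, box, mode: str = "xyz"):
    """Minimum-image Euclidean distance between points (broadcasting).

    With ``mode="xy"`` only the lateral components are wrapped and used.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if not (np.all(np.isfinite(p1)) and np.all(np.isfinite(p2))):
        raise ValueError("non-finite coordinates")
    d = min_image_displacement(p2 - p1, box, mode=mode)
    if mode == "xy":
        d = d[..., :2]
    out = np.sqrt(np.sum(d * d, axis=-1))
    return float(out) if out.ndim == 0 else out


def wrap_coords(coords: np.ndarray, box) -> np.ndarray:
    """Wrap coordinates into [0, box) on every axis."""
    box = _check_box(box)
    return np.mod(coords, box[: coords.shape[-1]])
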