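"""Bilinear sampling of cell-centered grid fields at arbitrary points."""

from __future__ import annotations

import numpy as np

__all__ = ["bilinear"]


def bilinear(field: np.ndarray, x0: float, y0: float, h: float,
             pts: np.ndarray) -> np.ndarray:
    """Sample ``field[j, i]`` (value at x = x0 + i h, y = y0 + j h) at ``pts``.

    Points outside the grid are clamped to the boundary cells.
    """
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    ny, nx = field.shape
    fx = (pts[:, 0] - x0) / h
    fy = (pts[:, 1] - y0) / h
    i0 = np.clip(np.floor(fx).astype(int), 0, nx - 2)
    j0 = np.clip(np.floor(fy).astype(int), 0, ny - 2)
    tx = np.clip(fx - i0, 0.0, 1.0)
    ty = np.clip(fy - j0, 0.0, 1.0)
    f00 = field[j0, i0]
    f01 = field[j0, i0 + 1]
    f10 = field[j0 + 1, i0]
    f11 = field[j0 + 1, i0 + 1]
    return (f00 * (1 - tx) * (1 - ty) + f01 * tx * (1 - ty)
            + f10 * (1 - tx) * ty + f11 * tx * ty)
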