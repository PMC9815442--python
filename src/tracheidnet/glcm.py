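"""Gray-level co-occurrence texture features over sliding windows.

A gray-level co-occurrence matrix (GLCM) is the normalized histogram of
ordered gray-level pairs ``(p, p + offset)`` inside a window.  Nine
Haralick-style statistics are computed from it:

====  =========================  ==========================================
W1    ASM  (angular 2nd moment)  sum m(i,j)^2
W2    CON  (contrast)            sum (i-j)^2 m(i,j)
W3    CORR (correlation)         [sum ij m(i,j) - u_i u_j] / (d_i d_j)
W4    ENT  (entropy)             -sum m log m          (0 log 0 == 0)
W5    VAR  (variance)            sum (i - a)^2 m(i,j), a = GLCM row mean
W6    SA   (sum average)         sum_k k p_{x+y}(k)
W7    SV   (sum variance)        sum_k (k - SA)^2 p_{x+y}(k)
W8    IDM  (inverse difference)  sum m / [1 + (i-j)^2]
W9    SE   (sum entropy)         -sum_k p_{x+y}(k) log p_{x+y}(k)
====  =========================  ==========================================

where ``p_{x+y}(k) = sum_{i+j=k} m(i,j)``, ``k = 2..2g``, gray levels are
1-based, and logs are natural.  Per-image features are the unweighted mean
over all complete windows tiled at a fixed stride.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

#: Canonical feature order (W1..W9).
FEATURE_NAMES: tuple[str, ...] = (
    "ASM", "CON", "CORR", "ENT", "VAR", "SA", "SV", "IDM", "SE",
)


@dataclass(frozen=True)
class GLCMParams:
    """Sliding-window co-occurrence parameters.

    ``angle`` selects the pair direction (0 deg pairs each pixel with its
    right neighbour at ``distance`` px); pairs are counted asymmetrically
    (only the +offset direction).
    """

    window: int = 8
    levels: int = 16
    step: int = 4
    angle: int = 0
    distance: int = 1

    def __post_init__(self) -> None:
        if self.window < 2:
            raise ValueError("window must be >= 2")
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.distance < 1:
            raise ValueError("distance must be >= 1")
        if self.angle not in (0, 45, 90, 135):
            raise ValueError("angle must be one of 0, 45, 90, 135")

    @property
    def offset(self) -> tuple[int, int]:
        """(row, col) displacement of the second pixel of each pair."""
        d = self.distance
        return {0: (0, d), 45: (-d, d), 90: (-d, 0), 135: (-d, -d)}[self.angle]


def quantize(image: np.ndarray, levels: int = 16) -> np.ndarray:
    """Uniformly bin 8-bit gray values into ``levels`` levels 1..levels.

    Bin widths partition [0, 255] equally; level = floor(v*levels/256) + 1,
    so 0 maps to level 1 and 255 to the top level.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("cannot quantize an empty image")
    if image.min() < 0 or image.max() > 255:
        raise ValueError("gray values must lie in [0, 255]")
    return (image.astype(np.int64) * levels) // 256 + 1


def cooccurrence(levels_window: np.ndarray, params: GLCMParams) -> np.ndarray:
    """Normalized co-occurrence matrix of a level grid (values 1..levels).

    Counts ordered pairs ``(p, p + offset)`` lying inside the grid and
    normalizes to probabilities.  Returns a ``levels x levels`` matrix.
    """
    lw = np.asarray(levels_window)
    g = params.levels
    dr, dc = params.offset
    h, w = lw.shape
    # first-pixel region such that the partner stays inside the grid
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r1 <= r0 or c1 <= c0:
        raise ValueError("window too small for the requested offset: no valid pairs")
    a = lw[r0:r1, c0:c1]
    b = lw[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    counts = np.bincount(((a - 1) * g + (b - 1)).ravel(), minlength=g * g)
    m = counts.reshape(g, g).astype(float)
    return m / m.sum()


def _feature_weights(g: int):
    """Precompute flat index/weight vectors reused across windows."""
    i = np.repeat(np.arange(1, g + 1), g).astype(float)      # row level per cell
    j = np.tile(np.arange(1, g + 1), g).astype(float)        # col level per cell
    ksum = (i + j).astype(int)                               # 2..2g per cell
    # one-hot map from g*g cells onto the 2g-1 possible level sums
    sum_map = np.zeros((g * g, 2 * g - 1))
    sum_map[np.arange(g * g), ksum - 2] = 1.0
    kvals = np.arange(2, 2 * g + 1, dtype=float)
    return i, j, sum_map, kvals


def _features_from_distributions(m: np.ndarray, g: int) -> np.ndarray:
    """Vectorized W1..W9 for a stack of flattened GLCMs, shape (N, g*g)."""
    i, j, sum_map, kvals = _feature_weights(g)
    asm = (m ** 2).sum(axis=1)
    con = m @ ((i - j) ** 2)
    u_i = m @ i
    u_j = m @ j
    var_i = m @ (i ** 2) - u_i ** 2
    var_j = m @ (j ** 2) - u_j ** 2
    d_i = np.sqrt(np.maximum(var_i, 0.0))
    d_j = np.sqrt(np.maximum(var_j, 0.0))
    denom = d_i * d_j
    num = m @ (i * j) - u_i * u_j
    degenerate = denom == 0
    if degenerate.any():
        warnings.warn(
            "constant window: correlation undefined, reported as 0",
            RuntimeWarning,
            stacklevel=3,
        )
    corr = np.where(degenerate, 0.0, num / np.where(degenerate, 1.0, denom))
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.where(m > 0, m * np.log(np.where(m > 0, m, 1.0)), 0.0).sum(axis=1)
    var = m @ (i ** 2) - u_i ** 2          # (i - a)^2 weighted by m, a = u_i
    psum = m @ sum_map                      # (N, 2g-1) sum distribution
    sa = psum @ kvals
    sv = (psum * (kvals[None, :] - sa[:, None]) ** 2).sum(axis=1)
    idm = m @ (1.0 / (1.0 + (i - j) ** 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        se = -np.where(
            psum > 0, psum * np.log(np.where(psum > 0, psum, 1.0)), 0.0
        ).sum(axis=1)
    return np.stack([asm, con, corr, ent, var, sa, sv, idm, se], axis=1)


def texture_features(glcm: np.ndarray) -> np.ndarray:
    """The nine texture features W1..W9 of a normalized GLCM.

    Returns an array ordered as :data:`FEATURE_NAMES`.
    """
    glcm = np.asarray(glcm, dtype=float)
    g = glcm.shape[0]
    if glcm.shape != (g, g):
        raise ValueError("GLCM must be square")
    if not np.isclose(glcm.sum(), 1.0, atol=1e-9):
        raise ValueError("GLCM must be normalized to sum 1")
    return _features_from_distributions(glcm.reshape(1, -1), g)[0]


def image_texture(
    image: np.ndarray,
    params: GLCMParams = GLCMParams(),
    aggregate: str = "mean",
) -> pd.Series:
    """Mean of per-window texture features over an image.

    Windows of ``params.window`` px tile the image at stride ``params.step``
    starting at (0, 0); partial windows at the right/bottom edges are
    discarded.  Feature vectors are averaged component-wise.
    """
    if aggregate != "mean":
        raise ValueError("only mean aggregation is supported")
    image = np.asarray(image)
    w, g, step = params.window, params.levels, params.step
    if image.ndim != 2 or image.shape[0] < w or image.shape[1] < w:
        raise ValueError(
            f"image {image.shape} smaller than the {w}x{w} analysis window"
        )
    lv = quantize(image, g)
    dr, dc = params.offset
    # pair code image: one entry per ordered pair anchored at its first pixel
    h, wd = lv.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(wd, wd - dc)
    a = lv[r0:r1, c0:c1]
    b = lv[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    code = (a - 1) * g + (b - 1)
    # window over the code image; pair anchors live in a (w-|dr|, w-|dc|) box
    bh, bw = w - abs(dr), w - abs(dc)
    if bh <= 0 or bw <= 0:
        raise ValueError("window too small for the requested offset")
    view = sliding_window_view(code, (bh, bw))[::step, ::step]
    # keep only anchor boxes of windows fully inside the image
    n_r = (h - w) // step + 1
    n_c = (wd - w) // step + 1
    view = view[:n_r, :n_c]
    codes = view.reshape(-1, bh * bw)
    n_win = codes.shape[0]
    flat = (codes + np.arange(n_win)[:, None] * (g * g)).ravel()
    counts = np.bincount(flat, minlength=n_win * g * g).reshape(n_win, g * g)
    m = counts / counts.sum(axis=1, keepdims=True)
    feats = _features_from_distributions(m, g).mean(axis=0)
    return pd.Series(feats, index=list(FEATURE_NAMES))


def extract_features(
    images: dict[str, np.ndarray] | list[tuple[str, np.ndarray]],
    params: GLCMParams = GLCMParams(),
) -> pd.DataFrame:
    """Texture table for many images; index = image id, columns = W1..W9 names."""
    items = images.items() if isinstance(images, dict) else images
    rows = {name: image_texture(img, params) for name, img in items}
    table = pd.DataFrame(rows).T
    table.index.name = "image_id"
    return table
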