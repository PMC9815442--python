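"""Tracheid lumen morphometry from labeled segmentation masks.

A labeled mask assigns 0 to wall/background pixels and 1..R to lumen
regions.  Each region contributes its pixel area and an exposed-edge
perimeter: the number of 4-neighbour pixel edges between the region and
anything else (other labels, background, or the image boundary).  The
exposed-edge count is an integer, exactly reproducible, which is why it is
preferred here over contour-length estimators.  Region statistics are
converted to physical units with a magnification-dependent pixel pitch and
averaged into the two morphology features AREA (um^2) and PERIMETER (um).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

#: Default pixel pitch in um/px per magnification.  These are free
#: calibration constants of the instrument, not universal values; override
#: them to match a real microscope.
DEFAULT_SCALE_UM_PER_PX: dict[int, float] = {200: 0.5, 500: 0.2}


@dataclass(frozen=True)
class RegionStats:
    """Raw per-region statistics in pixel units (or um after calibration)."""

    label: int
    area: float
    perimeter: float


@dataclass(frozen=True)
class MorphologyVector:
    """Mean lumen area (um^2) and perimeter (um) of one image."""

    area_um2: float
    perimeter_um: float


def region_stats(mask: np.ndarray) -> list[RegionStats]:
    """Area and exposed-edge perimeter of every labeled region.

    Area is the pixel count of the label; perimeter counts 4-neighbour
    edges from a region pixel to any pixel of different value (the image
    border counts as different).
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be a 2-D label image")
    n = int(mask.max())
    if n < 1:
        raise ValueError("mask contains no labeled regions")
    areas = np.bincount(mask.ravel(), minlength=n + 1)
    padded = np.pad(mask, 1, constant_values=0)
    perim = np.zeros(n + 1, dtype=np.int64)
    core = padded[1:-1, 1:-1]
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        neigh = padded[1 + dr:padded.shape[0] - 1 + dr,
                       1 + dc:padded.shape[1] - 1 + dc]
        exposed = (core != 0) & (neigh != core)
        perim += np.bincount(core[exposed].ravel(), minlength=n + 1)
    return [
        RegionStats(label=lab, area=float(areas[lab]), perimeter=float(perim[lab]))
        for lab in range(1, n + 1)
        if areas[lab] > 0
    ]


def calibrate(
    stats: RegionStats,
    magnification: int,
    scale_table: dict[int, float] = DEFAULT_SCALE_UM_PER_PX,
) -> RegionStats:
    """Convert pixel-unit region stats to um using the magnification's scale.

    Area scales with the square of the pixel pitch, perimeter linearly.
    """
    if magnification not in scale_table:
        raise KeyError(
            f"no um/px scale configured for magnification x{magnification}"
        )
    s = scale_table[magnification]
    if s <= 0:
        raise ValueError("um/px scale must be positive")
    return replace(stats, area=stats.area * s * s, perimeter=stats.perimeter * s)


def _border_labels(mask: np.ndarray) -> set[int]:
    edges = np.concatenate([mask[0], mask[-1], mask[:, 0], mask[:, -1]])
    return set(np.unique(edges[edges > 0]).tolist())


def image_morphology(
    mask: np.ndarray,
    magnification: int,
    scale_table: dict[int, float] = DEFAULT_SCALE_UM_PER_PX,
    exclude_border: bool = True,
) -> MorphologyVector:
    """Mean calibrated lumen area and perimeter of one mask.

    Regions touching the image border are partial tracheids and bias the
    mean downward, so they are excluded by default.
    """
    mask = np.asarray(mask)
    stats = region_stats(mask)
    if exclude_border:
        skip = _border_labels(mask)
        stats = [s for s in stats if s.label not in skip]
    if not stats:
        raise ValueError("no lumen regions retained (all touch the border?)")
    cal = [calibrate(s, magnification, scale_table) for s in stats]
    return MorphologyVector(
        area_um2=float(np.mean([s.area for s in cal])),
        perimeter_um=float(np.mean([s.perimeter for s in cal])),
    )


def extract_morphology(
    masks: dict[str, tuple[np.ndarray, int]],
    scale_table: dict[int, float] = DEFAULT_SCALE_UM_PER_PX,
    exclude_border: bool = True,
) -> pd.DataFrame:
    """Morphology table for many masks.

    ``masks`` maps image id -> (label image, magnification).  Columns are
    ``AREA`` (um^2) and ``PERIMETER`` (um).
    """
    rows = {}
    for name, (mask, mag) in masks.items():
        v = image_morphology(mask, mag, scale_table, exclude_border)
        rows[name] = {"AREA": v.area_um2, "PERIMETER": v.perimeter_um}
    table = pd.DataFrame(rows).T
    table.index.name = "image_id"
    return table
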