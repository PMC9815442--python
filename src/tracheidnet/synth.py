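"""Synthetic tracheid micrographs, lumen masks and failure loads.

Real data for this problem are destructive compression tests plus electron
micrographs of the crushed specimens — neither is readily available, so
this module emulates the acquisition protocol: ``n`` specimens, a number of
imaging positions per specimen, one image per position and magnification,
and one failure load per specimen.

The tissue model is a jittered hexagonal packing of elliptical lumens
(dark) separated by cell walls (bright), Gaussian-blurred and overlaid
with speckle noise.  Grade-dependent morphology drives both the texture
and the mechanics: stronger wood has smaller lumens and thicker walls.
The failure stress is a linear function of the wall/lumen area ratio and
the lattice spatial frequency,

    sigma_target = a0 + a1 * (cell_area - lumen_area)/lumen_area
                 + a2 / pitch + noise,

a link chosen deliberately simple so that feature-importance recovery
downstream has a known ground truth.  The failure load is then
``P_max = sigma_target * b * t``.

Every specimen owns an RNG stream spawned from the master seed, so
regeneration is reproducible and stable under reordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from tracheidnet.grading import GRADE_LABELS, classify_grade, compressive_strength

#: Mean lumen radius per grade, um.  Strong wood = small lumens.
DEFAULT_LUMEN_RADIUS_UM: dict[str, float] = {
    "Ic": 9.0, "IIc": 11.0, "IIIc": 13.0, "IVc": 15.0, "Vc": 18.0,
}
#: Mean double-wall thickness per grade, um.  Strong wood = thick walls.
DEFAULT_WALL_THICKNESS_UM: dict[str, float] = {
    "Ic": 6.5, "IIc": 6.1, "IIIc": 5.5, "IVc": 4.5, "Vc": 2.1,
}
#: (a0, a1, a2) of the strength link: intercept MPa, MPa per unit
#: wall/lumen area ratio, MPa*um per unit lattice frequency (1/pitch).
DEFAULT_STRENGTH_COEFFS: tuple[float, float, float] = (8.0, 15.0, 20.0)

#: um per pixel at each magnification (x500 is 2.5x denser than x200).
DEFAULT_SCALE_UM_PER_PX: dict[int, float] = {200: 0.5, 500: 0.2}

_WALL_GRAY = 190.0
_LUMEN_GRAY = 70.0


@dataclass(frozen=True)
class SynthConfig:
    """Conditions of one synthetic acquisition campaign."""

    n_specimens: int
    positions_per_specimen: int = 4
    magnifications: tuple[int, ...] = (200, 500)
    image_size: tuple[int, int] = (256, 256)          # (height, width) px
    mean_lumen_radius_by_grade: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LUMEN_RADIUS_UM))
    wall_thickness_by_grade: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_WALL_THICKNESS_UM))
    speckle_sd: float = 8.0                           # gray levels
    strength_coeffs: tuple[float, float, float] = DEFAULT_STRENGTH_COEFFS
    strength_noise_sd: float = 1.0                    # MPa
    specimen_width_b: float = 20.0                    # mm
    specimen_thickness_t: float = 20.0                # mm
    scale_um_per_px: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_SCALE_UM_PER_PX))
    morphology_jitter: float = 0.05     # specimen-level sd as fraction of mean
    lattice_jitter: float = 0.06        # site jitter as fraction of pitch
    radius_jitter: float = 0.08         # per-lumen radius sd, fractional
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_specimens < 1 or self.positions_per_specimen < 1:
            raise ValueError("counts must be positive")
        if not self.magnifications:
            raise ValueError("need at least one magnification")
        if any(v <= 0 for v in self.mean_lumen_radius_by_grade.values()):
            raise ValueError("lumen radii must be positive")
        if any(v <= 0 for v in self.wall_thickness_by_grade.values()):
            raise ValueError("wall thicknesses must be positive")
        if min(self.image_size) < 8:
            raise ValueError("image smaller than the GLCM analysis window")


@dataclass(frozen=True)
class Micrograph:
    """One synthetic gray-scale micrograph."""

    pixels: np.ndarray          # (H, W) uint8
    magnification: int
    specimen_id: int
    position_id: int

    @property
    def image_id(self) -> str:
        return f"s{self.specimen_id:04d}_p{self.position_id}_x{self.magnification}"


@dataclass(frozen=True)
class SpecimenRecord:
    """Mechanical test outcome of one specimen."""

    specimen_id: int
    failure_load_Pmax: float    # N
    width_b: float              # mm
    thickness_t: float          # mm
    true_grade: str
    sigma_target: float         # MPa, before load/strength round trip
    lumen_radius_um: float
    wall_thickness_um: float


def _strength_from_morphology(
    r_um: float, w_um: float, coeffs: tuple[float, float, float]
) -> float:
    """Deterministic part of the strength link (MPa)."""
    a0, a1, a2 = coeffs
    pitch = 2.0 * r_um + w_um
    cell_area = np.sqrt(3.0) / 2.0 * pitch ** 2       # hexagonal cell
    lumen_area = np.pi * r_um ** 2
    ratio = (cell_area - lumen_area) / lumen_area
    return a0 + a1 * ratio + a2 / pitch


def sample_records(config: SynthConfig) -> list[SpecimenRecord]:
    """Draw specimen-level morphology and failure loads (no images).

    Grades are assigned round-robin so campaigns are balanced by design;
    the recorded ``true_grade`` is nevertheless derived from the realized
    strength, so labels always agree with the grading rule.
    """
    master = np.random.SeedSequence(config.seed)
    streams = master.spawn(config.n_specimens)
    records = []
    for i in range(config.n_specimens):
        rng = np.random.default_rng(streams[i])
        grade = GRADE_LABELS[i % len(GRADE_LABELS)]
        r_mu = config.mean_lumen_radius_by_grade[grade]
        w_mu = config.wall_thickness_by_grade[grade]
        jf = config.morphology_jitter
        r = max(1e-3, rng.normal(r_mu, jf * r_mu))
        w = max(1e-3, rng.normal(w_mu, jf * w_mu))
        sigma = _strength_from_morphology(r, w, config.strength_coeffs)
        if config.strength_noise_sd > 0:
            sigma += rng.normal(0.0, config.strength_noise_sd)
        sigma = max(0.0, sigma)
        b, t = config.specimen_width_b, config.specimen_thickness_t
        pmax = sigma * b * t
        records.append(SpecimenRecord(
            specimen_id=i + 1,
            failure_load_Pmax=pmax,
            width_b=b,
            thickness_t=t,
            true_grade=classify_grade(compressive_strength(pmax, b, t)),
            sigma_target=sigma,
            lumen_radius_um=r,
            wall_thickness_um=w,
        ))
    return records


def render_micrograph(
    rng: np.random.Generator,
    r_um: float,
    w_um: float,
    image_size: tuple[int, int],
    scale_um_per_px: float,
    speckle_sd: float = 8.0,
    lattice_jitter: float = 0.06,
    radius_jitter: float = 0.08,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one honeycomb image and its ground-truth lumen mask.

    Returns (uint8 image, uint16 label mask); labels are contiguous 1..R.
    """
    h, w = image_size
    r_px = r_um / scale_um_per_px
    pitch = (2.0 * r_um + w_um) / scale_um_per_px
    if 2.0 * r_px > min(h, w):
        raise ValueError(
            f"image {image_size} smaller than one lumen diameter "
            f"({2 * r_px:.0f} px) at this magnification"
        )
    if r_px < 2.0:
        raise ValueError("lumen radius below 2 px; increase magnification or size")
    mask = np.zeros((h, w), dtype=np.uint16)
    dy = pitch * np.sqrt(3.0) / 2.0
    label = 0
    row = 0
    cy = -pitch
    while cy < h + pitch:
        x0 = -pitch + (pitch / 2.0 if row % 2 else 0.0)
        cx = x0
        while cx < w + pitch:
            jx = rng.normal(0.0, lattice_jitter * pitch)
            jy = rng.normal(0.0, lattice_jitter * pitch)
            ea = max(2.0, r_px * (1.0 + rng.normal(0.0, radius_jitter)))
            eb = max(2.0, r_px * (1.0 + rng.normal(0.0, radius_jitter)))
            theta = rng.uniform(0.0, np.pi)
            ceny, cenx = cy + jy, cx + jx
            rmax = max(ea, eb)
            y0, y1 = int(np.floor(ceny - rmax)), int(np.ceil(ceny + rmax)) + 1
            x0, x1 = int(np.floor(cenx - rmax)), int(np.ceil(cenx + rmax)) + 1
            y0, y1 = max(0, y0), min(h, y1)
            x0, x1 = max(0, x0), min(w, x1)
            if y1 > y0 and x1 > x0:
                yy, xx = np.mgrid[y0:y1, x0:x1]
                ct, st = np.cos(theta), np.sin(theta)
                u = (xx - cenx) * ct + (yy - ceny) * st
                v = -(xx - cenx) * st + (yy - ceny) * ct
                inside = (u / ea) ** 2 + (v / eb) ** 2 <= 1.0
                clipped = inside & (mask[y0:y1, x0:x1] == 0)  # lumens never merge
                if clipped.any():
                    if not clipped.all() or clipped.sum() != inside.sum():
                        # overlap clipping can split the ellipse; keep the
                        # largest 4-connected piece so regions stay connected
                        lab, nlab = ndimage.label(clipped)
                        if nlab > 1:
                            sizes = ndimage.sum_labels(
                                np.ones_like(lab), lab, index=range(1, nlab + 1))
                            clipped = lab == (1 + int(np.argmax(sizes)))
                    label += 1
                    mask[y0:y1, x0:x1][clipped] = label
            cx += pitch
        cy += dy
        row += 1
    base = np.where(mask > 0, _LUMEN_GRAY, _WALL_GRAY)
    blur_sigma = max(0.8, 0.15 * w_um / scale_um_per_px)
    img = ndimage.gaussian_filter(base, blur_sigma)
    if speckle_sd > 0:
        img = img + rng.normal(0.0, speckle_sd, size=img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)
    # relabel contiguously in case a lumen was fully overwritten (cannot
    # normally happen, but keeps the 1..R contract robust)
    present = np.unique(mask)
    present = present[present > 0]
    remap = np.zeros(int(mask.max()) + 1, dtype=np.uint16)
    remap[present] = np.arange(1, present.size + 1, dtype=np.uint16)
    return img, remap[mask]


def generate_dataset(
    config: SynthConfig,
) -> tuple[list[Micrograph], list[np.ndarray], list[SpecimenRecord]]:
    """Generate the full campaign: images, paired masks, specimen records.

    Produces exactly ``n_specimens * positions_per_specimen *
    len(magnifications)`` micrographs; ``masks[i]`` is the ground-truth
    lumen segmentation of ``micrographs[i]``.
    """
    records = sample_records(config)
    master = np.random.SeedSequence(config.seed)
    streams = master.spawn(config.n_specimens)
    n_img = config.positions_per_specimen * len(config.magnifications)
    micrographs: list[Micrograph] = []
    masks: list[np.ndarray] = []
    for rec, stream in zip(records, streams):
        img_streams = stream.spawn(1 + n_img)   # stream 0 mirrors sample_records
        idx = 1
        for pos in range(1, config.positions_per_specimen + 1):
            for mag in config.magnifications:
                rng = np.random.default_rng(img_streams[idx])
                idx += 1
                img, mask = render_micrograph(
                    rng,
                    rec.lumen_radius_um,
                    rec.wall_thickness_um,
                    config.image_size,
                    config.scale_um_per_px[mag],
                    speckle_sd=config.speckle_sd,
                    lattice_jitter=config.lattice_jitter,
                    radius_jitter=config.radius_jitter,
                )
                micrographs.append(Micrograph(
                    pixels=img, magnification=mag,
                    specimen_id=rec.specimen_id, position_id=pos,
                ))
                masks.append(mask)
    return micrographs, masks, records


def records_to_frame(records: list[SpecimenRecord]) -> pd.DataFrame:
    """Specimen records as the canonical CSV layout."""
    return pd.DataFrame({
        "specimen_id": [r.specimen_id for r in records],
        "Pmax_N": [r.failure_load_Pmax for r in records],
        "b_mm": [r.width_b for r in records],
        "t_mm": [r.thickness_t for r in records],
        "grade": [r.true_grade for r in records],
    })


#: Plausible value ranges of each pipeline feature, used by
#: :func:`random_feature_table`.
FEATURE_RANGES: dict[str, tuple[float, float]] = {
    "ASM": (0.0, 0.6), "CON": (0.0, 0.8), "CORR": (0.2, 0.95),
    "ENT": (0.3, 0.9), "VAR": (0.0, 0.7), "SA": (0.1, 0.8),
    "SV": (0.0, 0.3), "IDM": (0.1, 0.7), "SE": (0.1, 1.0),
    "AREA": (400.0, 900.0), "PERIMETER": (80.0, 120.0),
}


def random_feature_table(
    n_rows: int,
    seed: int = 0,
    columns: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Smooth, bounded synthetic feature table (no outliers).

    Values are Beta(2, 2) draws rescaled to plausible per-feature ranges.
    Bounded draws keep every clean record within ~2.3 column SDs of the
    mean, so planted gross outliers are the only records a 3-sigma rule
    can flag — which makes the table a calibration fixture for the filter.
    """
    if n_rows < 1:
        raise ValueError("n_rows must be positive")
    cols = tuple(columns) if columns is not None else tuple(FEATURE_RANGES)
    rng = np.random.default_rng(seed)
    data = {}
    for c in cols:
        lo, hi = FEATURE_RANGES.get(c, (0.0, 1.0))
        data[c] = lo + (hi - lo) * rng.beta(2.0, 2.0, size=n_rows)
    return pd.DataFrame(data)


def plant_outliers(
    table: pd.DataFrame,
    n_outliers: int,
    magnitude_sd: float,
    seed: int = 0,
    columns: tuple[str, ...] | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Perturb ``n_outliers`` rows, each on one feature, by ``magnitude_sd``
    sample SDs of that feature's original column.

    Signs alternate so the column mean stays put.  Returns the perturbed
    copy and the sorted row positions of the planted outliers.  A
    magnitude at or below 3 SDs is rejected: such perturbations are not
    guaranteed detectable by a 3-sigma rule.
    """
    if magnitude_sd <= 3.0:
        raise ValueError("magnitude_sd must exceed 3 for guaranteed detectability")
    if n_outliers >= len(table):
        raise ValueError("n_outliers must be smaller than the row count")
    out = table.copy()
    if n_outliers == 0:
        return out, np.array([], dtype=int)
    cols = list(columns) if columns is not None else [
        c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])
        and c not in ("specimen_id", "sigma_w_MPa")
    ]
    rng = np.random.default_rng(seed)
    rows = np.sort(rng.choice(len(table), size=n_outliers, replace=False))
    sds = {c: table[c].std(ddof=1) for c in cols}
    for sign_idx, row in enumerate(rows):
        col = cols[int(rng.integers(len(cols)))]
        sign = 1.0 if sign_idx % 2 == 0 else -1.0
        out.iloc[row, out.columns.get_loc(col)] += sign * magnitude_sd * sds[col]
    return out, rows
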