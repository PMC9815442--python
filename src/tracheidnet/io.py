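"""Disk formats: 8-bit gray PNG micrographs, 16-bit TIFF label masks, CSVs."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from tracheidnet.synth import Micrograph, SpecimenRecord, records_to_frame


def write_dataset(
    out_dir: str | Path,
    micrographs: list[Micrograph],
    masks: list[np.ndarray],
    records: list[SpecimenRecord],
) -> None:
    """Write a synthetic campaign: images/, masks/ and records.csv."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    for mic, mask in zip(micrographs, masks):
        Image.fromarray(mic.pixels, mode="L").save(
            out / "images" / f"{mic.image_id}.png")
        tifffile.imwrite(out / "masks" / f"{mic.image_id}.tif",
                         mask.astype(np.uint16))
    records_to_frame(records).to_csv(out / "records.csv", index=False)


def _magnification_from_name(name: str) -> int | None:
    for token in name.split("_"):
        if token.startswith("x") and token[1:].isdigit():
            return int(token[1:])
    return None


def read_images(images_dir: str | Path) -> dict[str, np.ndarray]:
    """Read every PNG/TIFF in a directory as 8-bit gray, keyed by stem."""
    out = {}
    for path in sorted(Path(images_dir).iterdir()):
        if path.suffix.lower() in (".png", ".tif", ".tiff"):
            if path.suffix.lower() == ".png":
                arr = np.asarray(Image.open(path).convert("L"))
            else:
                arr = np.asarray(tifffile.imread(path))
            out[path.stem] = arr
    if not out:
        raise FileNotFoundError(f"no PNG/TIFF images in {images_dir}")
    return out


def read_masks(masks_dir: str | Path) -> dict[str, tuple[np.ndarray, int]]:
    """Read label TIFFs; magnification parsed from the ``_x<mag>`` token."""
    out = {}
    for path in sorted(Path(masks_dir).iterdir()):
        if path.suffix.lower() in (".tif", ".tiff"):
            mag = _magnification_from_name(path.stem)
            if mag is None:
                raise ValueError(
                    f"cannot parse magnification from {path.name}; "
                    "expected an _x200 / _x500 token"
                )
            out[path.stem] = (np.asarray(tifffile.imread(path)), mag)
    if not out:
        raise FileNotFoundError(f"no TIFF masks in {masks_dir}")
    return out


def read_strength(csv_path: str | Path) -> pd.DataFrame:
    """Specimen CSV with columns specimen_id, Pmax_N, b_mm, t_mm[, grade]."""
    df = pd.read_csv(csv_path)
    missing = {"specimen_id", "Pmax_N", "b_mm", "t_mm"} - set(df.columns)
    if missing:
        raise ValueError(f"strength CSV missing columns: {sorted(missing)}")
    return df
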