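"""File formats: images, label masks, ROIs, manifests and reports.

Masks are stored as single-channel 8-bit PNGs holding the literal values
{0,1,2} (not visually rescaled) and validated on read. ROIs are GeoJSON
polygons in 0-based pixel coordinates, y down. Case manifests and reports
are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .quantify import CellTally, roi_from_geojson
from .synthetic import SyntheticCase

__all__ = [
    "read_image", "write_image",
    "read_mask", "write_mask",
    "load_roi", "write_case", "load_case_manifest",
]


def read_image(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        img = tifffile.imread(path)
    else:
        img = np.asarray(Image.open(path).convert("RGB"))
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"{path}: expected an RGB image")
    return img.astype(np.uint8)


def write_image(path, image: np.ndarray) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image)
    else:
        Image.fromarray(image, mode="RGB").save(path)


def read_mask(path) -> np.ndarray:
    mask = np.asarray(Image.open(path))
    if mask.ndim != 2:
        raise ValueError(f"{path}: mask PNG must be single-channel")
    if not np.isin(mask, (0, 1, 2)).all():
        raise ValueError(f"{path}: mask values outside {{0,1,2}}")
    return mask.astype(np.uint8)


def write_mask(path, mask: np.ndarray) -> None:
    if not np.isin(mask, (0, 1, 2)).all():
        raise ValueError("mask values outside {0,1,2}")
    Image.fromarray(mask.astype(np.uint8), mode="L").save(path)


def load_roi(path):
    """Read an ROI geometry from a GeoJSON file (QuPath-style export)."""
    with open(path) as fh:
        return roi_from_geojson(json.load(fh))


def write_case(case: SyntheticCase, out_dir) -> dict:
    """Write a synthetic case's patches, masks and manifest under out_dir."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, (img, msk) in enumerate(case.patches):
        img_name = f"{case.case_id}_patch{i:02d}.png"
        msk_name = f"{case.case_id}_patch{i:02d}_mask.png"
        write_image(out_dir / img_name, img)
        write_mask(out_dir / msk_name, msk)
        entries.append({"image": img_name, "mask": msk_name,
                        "n_positive": case.per_patch_tallies[i].n_positive,
                        "n_negative": case.per_patch_tallies[i].n_negative})
    manifest = {
        "case_id": case.case_id,
        "seed": case.seed,
        "category": case.category,
        "true_n_positive": case.true_tally.n_positive,
        "true_n_negative": case.true_tally.n_negative,
        "true_tps": case.true_tps,
        "patches": entries,
    }
    with open(out_dir / f"{case.case_id}_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def load_case_manifest(path) -> tuple[dict, list[tuple[np.ndarray, np.ndarray]]]:
    """Load a case manifest plus its (image, mask) pairs."""
    path = Path(path)
    with open(path) as fh:
        manifest = json.load(fh)
    pairs = [(read_image(path.parent / p["image"]),
              read_mask(path.parent / p["mask"]))
             for p in manifest["patches"]]
    return manifest, pairs


def tally_from_manifest(manifest: dict) -> CellTally:
    return CellTally(manifest["true_n_positive"], manifest["true_n_negative"])
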