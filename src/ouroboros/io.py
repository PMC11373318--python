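"""File I/O: wide-format expression tables and lossless image patches."""

from __future__ import annotations

import logging
import os

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

log = logging.getLogger(__name__)

PATCH_EXTENSIONS = (".png", ".tif", ".tiff")


class TableFormatError(ValueError):
    """An expression table is missing columns or contains unparsable cells."""


def read_spots_table(path, marker_names) -> pd.DataFrame:
    """Read a wide-format spot expression table (CSV or TSV).

    The header must contain ``wsi_id``, ``row``, ``col`` and one column per
    marker; marker columns may appear in any order and are returned re-ordered
    to ``marker_names``. Row/col are 0-based grid indices. Negative counts are
    accepted with a logged warning (transformed space is unconstrained).
    """
    marker_names = list(marker_names)
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    required = ["wsi_id", "row", "col"]
    missing = [c for c in required + marker_names if c not in df.columns]
    if missing:
        raise TableFormatError(
            f"table {path} is missing column(s): {missing}")
    for col in marker_names:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() and not df[col].isna().any():
            bad = int(np.flatnonzero(vals.isna() & ~df[col].isna())[0])
            raise TableFormatError(
                f"non-numeric value in column {col!r} at data row {bad}")
        df[col] = vals
    if (df[marker_names].to_numpy(dtype=float) < 0).any():
        log.warning("read_spots_table: table %s contains negative values", path)
    return df[required + marker_names]


def write_spots_table(df: pd.DataFrame, path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df.to_csv(path, sep=sep, index=False)


def save_dataset(ds, out_dir) -> None:
    """Persist a SpotDataset as a directory of PNG patches + CSV tables."""
    import json

    os.makedirs(out_dir, exist_ok=True)
    patch_dir = os.path.join(out_dir, "patches")
    os.makedirs(patch_dir, exist_ok=True)
    rows = []
    for i in range(ds.n_spots):
        fname = f"spot_{i:05d}.png"
        write_patch(ds.images[i], os.path.join(patch_dir, fname))
        rows.append({"wsi_id": ds.patients[i], "row": int(ds.spot_ids[i]),
                     "col": 0, "patch": fname,
                     **{m: ds.expression[i, j]
                        for j, m in enumerate(ds.marker_names)}})
    pd.DataFrame(rows).to_csv(os.path.join(out_dir, "spots.csv"), index=False)
    manifest = {"marker_names": list(ds.marker_names),
                "transformed": bool(ds.transformed),
                "n_spots": int(ds.n_spots)}
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    if ds.latents is not None:
        np.savetxt(os.path.join(out_dir, "latents.csv"), ds.latents,
                   delimiter=",", header="density,size,hema,eos", comments="")


def load_dataset(in_dir):
    """Load a SpotDataset saved by :func:`save_dataset`."""
    import json

    from .data import SpotDataset

    with open(os.path.join(in_dir, "manifest.json")) as fh:
        manifest = json.load(fh)
    markers = manifest["marker_names"]
    df = pd.read_csv(os.path.join(in_dir, "spots.csv"))
    images = np.stack([read_patch(os.path.join(in_dir, "patches", f))
                       for f in df["patch"]])
    latents = None
    lat_path = os.path.join(in_dir, "latents.csv")
    if os.path.exists(lat_path):
        latents = np.loadtxt(lat_path, delimiter=",", skiprows=1)
    return SpotDataset(expression=df[markers].to_numpy(dtype=float),
                       images=images, patients=df["wsi_id"].to_numpy(),
                       marker_names=tuple(markers),
                       transformed=manifest["transformed"], latents=latents)


def write_patch(img: np.ndarray, path) -> None:
    """Write an 8-bit RGB patch losslessly (PNG or uncompressed TIFF)."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3 or img.dtype != np.uint8:
        raise ValueError("patch must be an (H, W, 3) uint8 array")
    ext = os.path.splitext(str(path))[1].lower()
    if ext == ".png":
        Image.fromarray(img).save(path, format="PNG")
    elif ext in (".tif", ".tiff"):
        tifffile.imwrite(path, img)
    else:
        raise ValueError(
            f"unsupported patch extension {ext!r}; supported: {PATCH_EXTENSIONS}")


def read_patch(path, promote_grayscale: bool = False) -> np.ndarray:
    """Read a patch back as (H, W, 3) uint8.

    A grayscale file raises unless ``promote_grayscale`` is set, in which
    case the single channel is replicated to RGB.
    """
    ext = os.path.splitext(str(path))[1].lower()
    if ext == ".png":
        arr = np.asarray(Image.open(path))
    elif ext in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        raise ValueError(
            f"unsupported patch extension {ext!r}; supported: {PATCH_EXTENSIONS}")
    if arr.ndim == 2:
        if not promote_grayscale:
            raise ValueError(
                f"{path} is grayscale; pass promote_grayscale=True to expand")
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:  # drop alpha
        arr = arr[..., :3]
    return arr.astype(np.uint8)
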