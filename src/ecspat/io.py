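"""Readers and writers for the package's interchange formats.

All point tables are CSV with µm-suffixed column names (``x_um`` …) so
nm/µm mix-ups cannot survive a round-trip; images and masks are
single-plane TIFF (masks 8-bit binary).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .foci import FOCI_COLUMNS, LARGE_FOCI_COLUMNS, FociSet, LargeFociSet

__all__ = [
    "read_foci_table",
    "write_foci_table",
    "read_large_foci_table",
    "read_image",
    "write_image",
    "write_mask",
]

_REQUIRED = ("nucleus_id",) + FOCI_COLUMNS


def read_foci_table(path, bounding_radius: float = 5.0) -> list[FociSet]:
    """Read a foci CSV into one FociSet per nucleus.

    Required columns: ``nucleus_id, channel, x_um, y_um, z_um``; extra
    columns are preserved on each nucleus table.  Rows may appear in
    any order; nuclei are returned in first-appearance order.
    """
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    for col in ("x_um", "y_um", "z_um"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()]
        if len(bad):
            # +2: one for the header line, one for 0- vs 1-based
            raise ValueError(f"{path}: non-numeric {col} on line {bad[0] + 2}")
        if vals.isna().any():
            raise ValueError(f"{path}: empty {col} on line {vals.index[vals.isna()][0] + 2}")
        df[col] = vals
    out = []
    for nid in dict.fromkeys(df["nucleus_id"]):
        sub = df[df["nucleus_id"] == nid].drop(columns=["nucleus_id"]).reset_index(drop=True)
        out.append(FociSet(nucleus_id=str(nid), table=sub, bounding_radius=bounding_radius))
    return out


def write_foci_table(foci_sets, path) -> None:
    """Write FociSets to one CSV (coordinates at 4 decimals, µm)."""
    frames = []
    for fs in foci_sets:
        t = fs.table.copy()
        for col in ("x_um", "y_um", "z_um"):
            t[col] = t[col].round(4)
        t.insert(0, "nucleus_id", fs.nucleus_id)
        frames.append(t)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_large_foci_table(path) -> list[LargeFociSet]:
    """Read a large-foci CSV (``nucleus_id`` + coordinates + ``diameter_um``)."""
    df = pd.read_csv(path)
    required = ("nucleus_id",) + LARGE_FOCI_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return [
        LargeFociSet(nucleus_id=str(nid),
                     table=df[df["nucleus_id"] == nid].drop(columns=["nucleus_id"]))
        for nid in dict.fromkeys(df["nucleus_id"])
    ]


def read_image(path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_image(image: np.ndarray, path) -> None:
    tifffile.imwrite(str(path), np.asarray(image, dtype=np.float32))


def write_mask(mask: np.ndarray, path) -> None:
    """Masks are written 8-bit binary (0 / 255)."""
    tifffile.imwrite(str(path), (np.asarray(mask).astype(bool) * np.uint8(255)))


def read_mask(path) -> np.ndarray:
    return tifffile.imread(str(path)) > 0
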