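"""Containers for detected FISH / immunofluorescence foci.

A :class:`FociSet` holds every detected focus of one nucleus as a tidy
table of channel labels and 3D centroid coordinates in micrometres,
together with the bounding-sphere radius used as the null geometry for
spatial tests.  A :class:`LargeFociSet` holds large protein foci (for
example RNA polymerase II accumulations) that additionally carry a
diameter, since "large" is defined by a diameter threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

FOCI_COLUMNS = ("channel", "x_um", "y_um", "z_um")
LARGE_FOCI_COLUMNS = ("x_um", "y_um", "z_um", "diameter_um")


def _as_table(table: pd.DataFrame | Mapping | Iterable, columns: Sequence[str]) -> pd.DataFrame:
    if not isinstance(table, pd.DataFrame):
        table = pd.DataFrame(table, columns=list(columns))
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise ValueError(f"foci table is missing required column(s): {missing}")
    return table.reset_index(drop=True)


@dataclass
class FociSet:
    """All detected foci of one nucleus, coordinates in µm.

    Parameters
    ----------
    nucleus_id:
        Identifier of the nucleus the foci belong to.
    table:
        DataFrame with columns ``channel, x_um, y_um, z_um`` (extra
        columns such as ``parent_id`` are preserved).
    bounding_radius:
        Radius in µm of the bounding sphere used as the uniform null
        geometry; 5 µm is the conventional value for these nuclei.
    metadata:
        Free-form mapping carried along unchanged.
    """

    nucleus_id: str
    table: pd.DataFrame
    bounding_radius: float = 5.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.table = _as_table(self.table, FOCI_COLUMNS)
        if self.bounding_radius <= 0:
            raise ValueError("bounding_radius must be positive")
        coords = self.table[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
        if coords.size and not np.all(np.isfinite(coords)):
            raise ValueError(f"non-finite coordinate in nucleus {self.nucleus_id!r}")

    def __len__(self) -> int:
        return len(self.table)

    def channels(self) -> list[str]:
        """Channel labels present, in first-appearance order."""
        return list(dict.fromkeys(self.table["channel"]))

    def _select(self, channel) -> pd.DataFrame:
        if channel is None:
            return self.table
        labels = [channel] if isinstance(channel, str) else list(channel)
        known = set(self.table["channel"])
        unknown = [c for c in labels if c not in known]
        if unknown and len(self.table):
            raise ValueError(
                f"unknown channel label(s) {unknown} in nucleus {self.nucleus_id!r}; "
                f"present: {sorted(known)}"
            )
        return self.table[self.table["channel"].isin(labels)]

    def coords(self, channel=None) -> np.ndarray:
        """(n, 3) array of centroid coordinates, optionally one channel
        or a sequence of channels pooled together."""
        sel = self._select(channel)
        return sel[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)

    def count(self, channel=None) -> int:
        return len(self._select(channel))


@dataclass
class LargeFociSet:
    """Large foci (≥ diameter threshold candidates) of one nucleus."""

    nucleus_id: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.table = _as_table(self.table, LARGE_FOCI_COLUMNS)
        d = self.table["diameter_um"].to_numpy(dtype=float)
        if d.size and (not np.all(np.isfinite(d)) or np.any(d <= 0)):
            raise ValueError("diameter_um must be finite and positive")

    def __len__(self) -> int:
        return len(self.table)

    def coords(self) -> np.ndarray:
        return self.table[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
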