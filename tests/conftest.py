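"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the code paths of the implementation
(KD-trees, sorted searches): nearest-neighbour distances by an O(n²)
scan and Ripley pair counts by explicit row-wise distance evaluation.
"""

import numpy as np
import pandas as pd
import pytest

from ecspat import FociSet


def brute_force_nearest(source: np.ndarray, target: np.ndarray, same: bool) -> np.ndarray:
    out = []
    for i, p in enumerate(source):
        d = np.sqrt(((target - p) ** 2).sum(axis=1))
        if same:
            d[i] = np.inf
        out.append(d.min())
    return np.array(out)


def brute_force_k(points: np.ndarray, radii, volume: float) -> np.ndarray:
    n = len(points)
    counts = np.zeros(len(radii), dtype=int)
    for i in range(n):
        d = np.sqrt(((points - points[i]) ** 2).sum(axis=1))
        d[i] = np.inf
        for j, r in enumerate(radii):
            counts[j] += int((d <= r).sum())
    # scale exactly as K is defined (integer counts times V/n²)
    return counts * (volume / n ** 2)


def make_fociset(coords, channel="EGFR", nucleus_id="fix", bounding_radius=5.0):
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    table = pd.DataFrame(
        {"channel": [channel] * len(coords) if isinstance(channel, str) else channel,
         "x_um": coords[:, 0], "y_um": coords[:, 1], "z_um": coords[:, 2]}
    )
    return FociSet(nucleus_id=nucleus_id, table=table, bounding_radius=bounding_radius)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
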