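"""Poisson-disk spatial thinning of candidate training pixels.

Training rows drawn from neighboring 1-km pixels are strongly spatially
autocorrelated; enforcing a minimum pairwise distance (default 5 km)
between selected pixel centers decorrelates the training set while keeping
it spatially representative.  Candidates are grid cells, so dart throwing
over the finite candidate lattice — visit candidates in seeded random
order, accept a pixel iff no previously accepted pixel lies within the
minimum distance — is used rather than a continuous blue-noise algorithm:
the result is maximal under the visiting order, which matters more here
than spectral quality.  A uniform-grid spatial hash makes each acceptance
check O(1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SampleSet", "poisson_disk_sample"]


@dataclass
class SampleSet:
    """Selected pixels with the guarantee that every pairwise center
    distance is at least ``min_distance_km``."""

    pixel_id: np.ndarray
    row: np.ndarray
    col: np.ndarray
    min_distance_km: float
    seed: int

    def __len__(self) -> int:
        return len(self.pixel_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"pixel_id": self.pixel_id, "row": self.row,
                             "col": self.col})


def poisson_disk_sample(
    candidates: pd.DataFrame,
    min_distance_km: float = 5.0,
    seed: int = 0,
    cell_km: float = 1.0,
) -> SampleSet:
    """Maximal random subset with all pairwise distances >= the minimum.

    Parameters
    ----------
    candidates
        Frame with ``pixel_id``, ``row``, ``col`` columns (one row per
        candidate cell; duplicates not expected).
    min_distance_km
        Hard minimum center-to-center distance; 0 accepts every candidate.
    cell_km
        Grid cell size, converting index offsets to km.
    """
    if len(candidates) == 0:
        raise ValueError("no candidate pixels")
    if min_distance_km < 0:
        raise ValueError("min_distance_km must be non-negative")
    pid = candidates["pixel_id"].to_numpy()
    rows = candidates["row"].to_numpy(dtype=float)
    cols = candidates["col"].to_numpy(dtype=float)
    order = np.random.default_rng(seed).permutation(len(pid))
    if min_distance_km == 0:
        sel = np.sort(order)  # keep input order for the degenerate case
        return SampleSet(pid[sel], candidates["row"].to_numpy()[sel],
                         candidates["col"].to_numpy()[sel], 0.0, seed)

    d_cells = min_distance_km / cell_km
    d2 = d_cells * d_cells
    # hash bucket width = d_cells: any point closer than d lies in one of
    # the 3x3 neighboring buckets
    buckets: dict[tuple[int, int], list[int]] = {}
    accepted: list[int] = []
    for i in order:
        r, c = rows[i], cols[i]
        br, bc = int(r // d_cells), int(c // d_cells)
        ok = True
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                for j in buckets.get((br + dr, bc + dc), ()):
                    if (rows[j] - r) ** 2 + (cols[j] - c) ** 2 < d2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            buckets.setdefault((br, bc), []).append(i)
            accepted.append(i)
    sel = np.sort(np.asarray(accepted))
    return SampleSet(
        pixel_id=pid[sel],
        row=candidates["row"].to_numpy()[sel],
        col=candidates["col"].to_numpy()[sel],
        min_distance_km=min_distance_km,
        seed=seed,
    )
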