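"""Covariate engineering for annual fire-probability modeling.

Transforms gridded climate, human-activity and fire-history layers into the
nine per-pixel-year covariates used by the binomial GAM:

====================== ======================================================
``aet_normal``         base-period mean annual actual evapotranspiration (mm)
``cwd_normal``         base-period mean annual climatic water deficit (mm)
``aet_dev3``           mean AET deviation from normal over the three years
                       preceding the year of interest (mm)
``cwd_dev3``           same for CWD (mm)
``housing_density_25km`` mean housing density within a 25-km radius (units/ha)
``cultivated_fraction`` proportion of the pixel under cultivation
``dist_roads``         Euclidean distance to the nearest road pixel (km)
``dist_electrical``    distance to the nearest electrical-infrastructure
                       pixel (km)
``years_since_fire``   years since the pixel's most recent recorded burn,
                       capped (default 100)
====================== ======================================================

The response is binary: did the pixel burn in that year.  All operations are
pure functions of their inputs, so rebuilding a design table from the same
panel and history is bit-identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "COVARIATES",
    "CLIMATE_COVARIATES",
    "HUMAN_COVARIATES",
    "FireEvent",
    "FireHistory",
    "FUEL_SIZE_THRESHOLDS_KM2",
    "compute_normal",
    "compute_three_year_deviation",
    "years_since_fire",
    "years_since_fire_stack",
    "focal_mean_density",
    "interpolate_decadal",
    "fractional_cover",
    "distance_to_features",
    "filter_fire_events",
    "build_design_table",
]

#: canonical covariate (column) names, in the order terms enter the model
COVARIATES = (
    "aet_normal",
    "cwd_normal",
    "aet_dev3",
    "cwd_dev3",
    "housing_density_25km",
    "cultivated_fraction",
    "dist_roads",
    "dist_electrical",
    "years_since_fire",
)

CLIMATE_COVARIATES = ("aet_normal", "cwd_normal", "aet_dev3", "cwd_dev3")
HUMAN_COVARIATES = (
    "housing_density_25km",
    "cultivated_fraction",
    "dist_roads",
    "dist_electrical",
)

#: minimum area (km^2) a fire event must *exceed* to enter the record,
#: by fuel class: timber fires >10 acres, brush >30 acres, grass >300 acres.
FUEL_SIZE_THRESHOLDS_KM2 = {"timber": 0.04, "brush": 0.12, "grass": 1.21}


# ---------------------------------------------------------------------------
# fire history container
# ---------------------------------------------------------------------------

@dataclass
class FireEvent:
    """One fire perimeter: the set of grid cells it burned, in one year."""

    event_id: int
    year: int
    cells: np.ndarray  # (n, 2) int array of (row, col)
    area_km2: float
    fuel_class: str


@dataclass
class FireHistory:
    """Binary per-pixel burn record over a contiguous span of years.

    ``burned[t, r, c]`` is True iff pixel (r, c) burned in year
    ``record_start + t``.  A pixel burns at most once per year (binary
    encoding); multiple perimeters in one cell-year collapse to one burn.
    """

    record_start: int
    burned: np.ndarray  # bool, (n_years, n_rows, n_cols)
    events: list[FireEvent] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def record_end(self) -> int:
        return self.record_start + self.burned.shape[0] - 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.record_start, self.record_end + 1)

    def burn_years(self, row: int, col: int) -> np.ndarray:
        """Sorted years in which pixel (row, col) burned."""
        return self.record_start + np.flatnonzero(self.burned[:, row, col])

    def to_frame(self) -> pd.DataFrame:
        """Long-format record (pixel_id,row,col,burn_year), row-major ids."""
        t, r, c = np.nonzero(self.burned)
        ncols = self.burned.shape[2]
        return pd.DataFrame(
            {
                "pixel_id": r * ncols + c,
                "row": r,
                "col": c,
                "burn_year": self.record_start + t,
            }
        ).sort_values(["burn_year", "pixel_id"], ignore_index=True)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, shape: tuple[int, int],
        record_start: int, record_end: int,
    ) -> "FireHistory":
        burned = np.zeros((record_end - record_start + 1, *shape), dtype=bool)
        yr = frame["burn_year"].to_numpy()
        if len(yr) and (yr.min() < record_start or yr.max() > record_end):
            raise ValueError("burn years outside the stated record window")
        burned[yr - record_start, frame["row"].to_numpy(),
               frame["col"].to_numpy()] = True
        return cls(record_start=record_start, burned=burned)


# ---------------------------------------------------------------------------
# climate covariates
# ---------------------------------------------------------------------------

def compute_normal(
    annual_layers: np.ndarray, years: np.ndarray, base_period: tuple[int, int]
) -> np.ndarray:
    """Per-pixel mean of an annual layer series over the base period.

    Parameters
    ----------
    annual_layers
        Array of shape (n_years, n_rows, n_cols).
    years
        The calendar year of each leading slice.
    base_period
        Inclusive (first, last) year of the averaging window, e.g. the
        1951-1980 normal period.
    """
    years = np.asarray(years)
    lo, hi = base_period
    if hi < lo:
        raise ValueError(f"empty base period {base_period}")
    sel = (years >= lo) & (years <= hi)
    if not sel.any():
        raise ValueError(f"base period {base_period} not covered by series")
    missing = set(range(lo, hi + 1)) - set(int(y) for y in years[sel])
    if missing:
        raise ValueError(f"base period years missing from series: {sorted(missing)}")
    return annual_layers[sel].mean(axis=0)


def compute_three_year_deviation(
    annual_layers: np.ndarray,
    years: np.ndarray,
    normal: np.ndarray,
    year_of_interest: int,
) -> np.ndarray:
    """Mean deviation from the normal over the three *preceding* years.

    The window is {y-3, y-2, y-1}; the year of interest itself is excluded,
    so the covariate is known before that year's fire season.
    """
    years = np.asarray(years)
    idx = []
    for lag in (3, 2, 1):
        pos = np.flatnonzero(years == year_of_interest - lag)
        if pos.size == 0:
            raise ValueError(
                f"year {year_of_interest - lag} missing from series; cannot "
                f"form the 3-year deviation for {year_of_interest}"
            )
        idx.append(pos[0])
    return (annual_layers[idx] - normal[None]).mean(axis=0)


# ---------------------------------------------------------------------------
# fire-history covariates
# ---------------------------------------------------------------------------

def years_since_fire(
    history: FireHistory, row: int, col: int, year: int, cap: int = 100
) -> int:
    """Years since the most recent burn strictly before ``year``, capped.

    A pixel never observed to burn (or whose last burn is further back than
    the cap) is treated as having gone ``cap`` years without fire.  A burn
    in the query year itself does not count: it is the label, not history.
    """
    burns = history.burn_years(row, col)
    prior = burns[burns < year]
    if prior.size == 0:
        return cap
    return min(int(year - prior[-1]), cap)


def years_since_fire_stack(
    history: FireHistory, years: np.ndarray, cap: int = 100
) -> np.ndarray:
    """Vectorized YSF rasters for each requested year (in ascending order).

    Equivalent to calling :func:`years_since_fire` per pixel, but walks the
    record once.  Requested years must not precede the record start.
    """
    years = np.asarray(years)
    if (np.diff(years) <= 0).any():
        raise ValueError("years must be strictly increasing")
    if years[0] < history.record_start:
        raise ValueError("requested year precedes the fire record")
    shape = history.burned.shape[1:]
    # last burn year strictly before the walker position, -inf if none
    last_burn = np.full(shape, -np.inf)
    out = np.empty((len(years),) + shape, dtype=np.int64)
    pos = history.record_start  # burns in [record_start, pos) are absorbed
    for i, y in enumerate(years):
        while pos < min(y, history.record_end + 1):
            t = pos - history.record_start
            last_burn[history.burned[t]] = pos
            pos += 1
        ysf = y - last_burn
        out[i] = np.minimum(ysf, cap).astype(np.int64)
    return out


def filter_fire_events(
    events: list[FireEvent],
    shape: tuple[int, int],
    record_start: int,
    record_end: int,
    thresholds_km2: dict[str, float] | None = None,
) -> FireHistory:
    """Apply the per-fuel-class minimum-size filter and build a history.

    Events are retained only when their area is *strictly above* the
    threshold for their fuel class (timber >0.04 km2, brush >0.12 km2,
    grass >1.21 km2); boundary areas are dropped.  Retained events are
    merged into the binary per-pixel-year record.
    """
    thr = FUEL_SIZE_THRESHOLDS_KM2 if thresholds_km2 is None else thresholds_km2
    burned = np.zeros((record_end - record_start + 1, *shape), dtype=bool)
    kept = []
    for ev in events:
        if ev.fuel_class not in thr:
            raise ValueError(f"unknown fuel class {ev.fuel_class!r}")
        if not (record_start <= ev.year <= record_end):
            raise ValueError(f"event year {ev.year} outside record window")
        if ev.area_km2 > thr[ev.fuel_class]:
            cells = np.asarray(ev.cells)
            burned[ev.year - record_start, cells[:, 0], cells[:, 1]] = True
            kept.append(ev)
    return FireHistory(record_start=record_start, burned=burned, events=kept)


# ---------------------------------------------------------------------------
# human-activity covariates
# ---------------------------------------------------------------------------

def _disk_kernel(radius_km: float, cell_km: float) -> np.ndarray:
    r_cells = int(np.floor(radius_km / cell_km))
    ax = np.arange(-r_cells, r_cells + 1)
    dist = np.hypot(*np.meshgrid(ax, ax, indexing="ij")) * cell_km
    return (dist <= radius_km).astype(float)


def focal_mean_density(
    density: np.ndarray,
    cell_km: float = 1.0,
    radius_km: float = 25.0,
    valid_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Mean over the disk of cells whose center lies within ``radius_km``.

    Edge pixels average over the in-grid portion of the disk; masked cells
    are excluded from both numerator and denominator.  A neighborhood with
    no valid cell yields NaN.
    """
    if radius_km < cell_km:
        raise ValueError("radius must be at least one cell")
    kernel = _disk_kernel(radius_km, cell_km)
    valid = np.ones_like(density, dtype=float) if valid_mask is None \
        else valid_mask.astype(float)
    vals = np.where(valid > 0, density, 0.0)
    num = ndimage.convolve(vals, kernel, mode="constant", cval=0.0)
    den = ndimage.convolve(valid, kernel, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def interpolate_decadal(
    snapshot_years: np.ndarray, snapshots: np.ndarray, year: int | float
) -> np.ndarray:
    """Piecewise-linear interpolation between decadal snapshots.

    ``snapshots`` has the snapshot axis first and may be scalar-per-year or
    a raster stack.  Queries beyond the first/last snapshot clamp to the
    nearest snapshot with a warning (no extrapolation).
    """
    snapshot_years = np.asarray(snapshot_years, dtype=float)
    snapshots = np.asarray(snapshots, dtype=float)
    if (np.diff(snapshot_years) <= 0).any():
        raise ValueError("snapshot years must be strictly increasing")
    if year < snapshot_years[0] or year > snapshot_years[-1]:
        warnings.warn(
            f"year {year} outside snapshot span "
            f"[{snapshot_years[0]:.0f}, {snapshot_years[-1]:.0f}]; clamping",
            stacklevel=2,
        )
        year = float(np.clip(year, snapshot_years[0], snapshot_years[-1]))
    j = int(np.searchsorted(snapshot_years, year, side="right") - 1)
    j = min(j, len(snapshot_years) - 2)
    y0, y1 = snapshot_years[j], snapshot_years[j + 1]
    w = (year - y0) / (y1 - y0)
    return (1 - w) * snapshots[j] + w * snapshots[j + 1]


def fractional_cover(
    fine_class_grid: np.ndarray,
    block: int,
    target_class: int,
) -> np.ndarray:
    """Fraction of fine-resolution cells of ``target_class`` per coarse cell.

    The fine grid must tile the coarse grid integrally with ``block`` fine
    cells per coarse cell along each axis (e.g. 30-m land-cover classes
    aggregated to ~1-km pixels).
    """
    fr, fc = fine_class_grid.shape
    if block < 1 or fr % block or fc % block:
        raise ValueError(
            f"fine grid {fine_class_grid.shape} does not nest in coarse grid "
            f"with block size {block}"
        )
    hits = (fine_class_grid == target_class).astype(float)
    return hits.reshape(fr // block, block, fc // block, block).mean(axis=(1, 3))


def distance_to_features(
    feature_mask: np.ndarray, cell_km: float = 1.0
) -> np.ndarray:
    """Euclidean distance (km) from each cell center to the nearest feature
    cell center; 0 on feature cells themselves."""
    feature_mask = np.asarray(feature_mask, dtype=bool)
    if not feature_mask.any():
        raise ValueError("feature mask is empty; distances undefined")
    return ndimage.distance_transform_edt(~feature_mask) * cell_km


# ---------------------------------------------------------------------------
# design table
# ---------------------------------------------------------------------------

def build_design_table(
    panel,
    history: FireHistory,
    years,
    ysf_cap: int = 100,
    housing_radius_km: float = 25.0,
) -> pd.DataFrame:
    """Assemble one modeling row per valid pixel and requested year.

    Masking follows the study rules: cells outside the validity mask, cells
    with ``water_fraction >= 0.5`` and cells with missing climate are
    excluded.  The label ``burned`` is 1 iff the pixel burns in that year.

    Returns a DataFrame with columns ``pixel_id,row,col,year,region_id,
    burned`` plus the nine covariates; pixel ids are row-major.
    """
    years = np.asarray(sorted(int(y) for y in np.atleast_1d(years)))
    if years[0] < panel.year_start or years[-1] > panel.year_end:
        raise ValueError(
            f"requested years [{years[0]}, {years[-1]}] outside panel window "
            f"[{panel.year_start}, {panel.year_end}]"
        )
    if years[-1] > history.record_end:
        raise ValueError("fire record does not cover all requested years")

    climate_ok = (
        np.isfinite(panel.aet_annual).all(axis=0)
        & np.isfinite(panel.cwd_annual).all(axis=0)
    )
    valid = panel.valid_mask & (panel.water_fraction < 0.5) & climate_ok
    rows, cols = np.nonzero(valid)
    pixel_id = rows * panel.n_cols + cols
    n_pix = rows.size

    aet_normal = compute_normal(panel.aet_annual, panel.annual_years,
                                panel.normal_base_period)
    cwd_normal = compute_normal(panel.cwd_annual, panel.annual_years,
                                panel.normal_base_period)
    dist_roads = distance_to_features(panel.road_mask, panel.cell_km)
    dist_elec = distance_to_features(panel.electrical_mask, panel.cell_km)

    # focal mean commutes with linear interpolation in time, so smooth the
    # decadal snapshots once and interpolate the smoothed stacks annually
    housing_focal = np.stack([
        focal_mean_density(h, panel.cell_km, housing_radius_km,
                           valid_mask=panel.valid_mask)
        for h in panel.housing_density
    ])
    ysf = years_since_fire_stack(history, years, cap=ysf_cap)

    frames = []
    for i, y in enumerate(years):
        aet_d = compute_three_year_deviation(
            panel.aet_annual, panel.annual_years, aet_normal, y)
        cwd_d = compute_three_year_deviation(
            panel.cwd_annual, panel.annual_years, cwd_normal, y)
        housing = interpolate_decadal(panel.housing_decades, housing_focal, y)
        burned = history.burned[y - history.record_start]
        frames.append(pd.DataFrame({
            "pixel_id": pixel_id,
            "row": rows,
            "col": cols,
            "year": np.full(n_pix, y, dtype=np.int64),
            "region_id": panel.region_id[rows, cols],
            "burned": burned[rows, cols].astype(np.int8),
            "aet_normal": aet_normal[rows, cols],
            "cwd_normal": cwd_normal[rows, cols],
            "aet_dev3": aet_d[rows, cols],
            "cwd_dev3": cwd_d[rows, cols],
            "housing_density_25km": housing[rows, cols],
            "cultivated_fraction": panel.cultivated_fraction[rows, cols],
            "dist_roads": dist_roads[rows, cols],
            "dist_electrical": dist_elec[rows, cols],
            "years_since_fire": ysf[i][rows, cols].astype(float),
        }))
    table = pd.concat(frames, ignore_index=True)
    if table[list(COVARIATES)].isna().any().any():
        bad = [c for c in COVARIATES if table[c].isna().any()]
        raise ValueError(f"missing covariate values after masking: {bad}")
    return table
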