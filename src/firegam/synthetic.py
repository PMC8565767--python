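"""Synthetic landscapes and fire histories from a known additive truth.

The generator emulates the statistical structure of the real inputs — a
spatially autocorrelated climate normal surface with interannual anomalies,
smooth housing-density gradients with urban cores that intensify by decade,
scattered linear road/transmission infrastructure, cultivated and water
fractions, and a fire process whose per-pixel annual burn probability is an
additive function of the covariates (including a years-since-fire feedback)
passed through an inverse-logit link.  Because the generating effect
functions are known, every downstream stage (feature engineering, GAM
fitting, cross-validation, decomposition) can be tested against ground
truth without any external dataset.

Burns are independent Bernoulli draws per pixel-year: the generator models
fire *probability*, not fire spread, so no event contiguity is imposed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import xarray as xr
from scipy import ndimage
from scipy.special import expit
from skimage.draw import line as _draw_line

from . import features as ft
from .features import COVARIATES, FireHistory

__all__ = [
    "SyntheticConfig",
    "LandscapePanel",
    "EffectSpec",
    "make_effect",
    "default_true_effects",
    "generate_correlated_field",
    "generate_landscape",
    "simulate_fire_history",
    "generate_dataset",
]


# ---------------------------------------------------------------------------
# effect functions (the generating truth)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectSpec:
    """Serializable spec of one generating effect on the log-odds scale.

    kinds
    -----
    ``hump``        amplitude * exp(-((x-center)/width)^2 / 2)
    ``rise_fall``   skewed bump: rises to ``center`` then falls with
                    ``fall_width`` (may differ from ``rise_width``)
    ``saturating``  amplitude * (1 - exp(-x / scale)) — rapid early rise
                    that levels off (years-since-fire shape)
    ``decay``       amplitude * exp(-x / scale) — strongest at zero,
                    fading with distance (infrastructure-proximity shape)
    ``linear``      slope * x
    ``constant``    value (useful for switching a covariate off explicitly)
    """

    kind: str
    params: dict = field(default_factory=dict)

    def __call__(self, x):
        return make_effect(self)(x)


def make_effect(spec):
    """Turn an effect spec (or a bare callable) into a callable effect."""
    if callable(spec) and not isinstance(spec, EffectSpec):
        return spec
    if isinstance(spec, dict):
        spec = EffectSpec(**spec)
    p = spec.params
    if spec.kind == "hump":
        c, w, a = p["center"], p["width"], p["amplitude"]
        return lambda x: a * np.exp(-0.5 * ((np.asarray(x, float) - c) / w) ** 2)
    if spec.kind == "rise_fall":
        c, wr, wf, a = p["center"], p["rise_width"], p["fall_width"], p["amplitude"]

        def f(x):
            x = np.asarray(x, float)
            w = np.where(x < c, wr, wf)
            return a * np.exp(-0.5 * ((x - c) / w) ** 2)

        return f
    if spec.kind == "saturating":
        s, a = p["scale"], p["amplitude"]
        return lambda x: a * (1.0 - np.exp(-np.asarray(x, float) / s))
    if spec.kind == "decay":
        s, a = p["scale"], p["amplitude"]
        return lambda x: a * np.exp(-np.asarray(x, float) / s)
    if spec.kind == "linear":
        b = p["slope"]
        return lambda x: b * np.asarray(x, float)
    if spec.kind == "constant":
        v = p["value"]
        return lambda x: np.full_like(np.asarray(x, float), v)
    raise ValueError(f"unknown effect kind {spec.kind!r}")


def default_true_effects() -> dict[str, EffectSpec]:
    """Generating effects shaped like the relationships seen in real fire
    data: hump-shaped response to AET normals (productivity), a rise-then-
    fall response to CWD normals (dryness helps until fuels run out), mild
    positive responses to recent climate deviations, a hump in housing
    density (intermediate development burns most), suppression by
    cultivation, decay with distance from infrastructure, and a saturating
    years-since-fire ramp that rises rapidly over the first ~20 years."""
    return {
        "aet_normal": EffectSpec("hump", {"center": 450.0, "width": 140.0,
                                          "amplitude": 2.2}),
        "cwd_normal": EffectSpec("rise_fall", {"center": 850.0,
                                               "rise_width": 260.0,
                                               "fall_width": 160.0,
                                               "amplitude": 2.0}),
        "aet_dev3": EffectSpec("linear", {"slope": 0.012}),
        "cwd_dev3": EffectSpec("linear", {"slope": 0.010}),
        "housing_density_25km": EffectSpec("hump", {"center": 6.0,
                                                    "width": 3.0,
                                                    "amplitude": 1.8}),
        "cultivated_fraction": EffectSpec("linear", {"slope": -2.5}),
        "dist_roads": EffectSpec("decay", {"scale": 6.0, "amplitude": 1.2}),
        "dist_electrical": EffectSpec("decay", {"scale": 8.0,
                                                "amplitude": 1.0}),
        "years_since_fire": EffectSpec("saturating", {"scale": 9.0,
                                                      "amplitude": 2.5}),
    }


# ---------------------------------------------------------------------------
# configuration and panel containers
# ---------------------------------------------------------------------------

@dataclass
class SyntheticConfig:
    """Parameters of the synthetic landscape and fire process.

    The defaults describe a 64 km x 64 km landscape observed annually over
    1970-2016 with climate normals estimated over 1951-1980, i.e. the same
    temporal layout as the real study system at a reduced spatial extent.
    """

    n_rows: int = 64
    n_cols: int = 64
    cell_km: float = 1.0
    year_start: int = 1970
    year_end: int = 2016
    normal_base_period: tuple[int, int] = (1951, 1980)
    field_correlation_range_km: float = 10.0
    anomaly_sd: float = 50.0
    aet_normal_mean: float = 450.0
    aet_normal_sd: float = 150.0
    cwd_normal_mean: float = 850.0
    cwd_normal_sd: float = 250.0
    housing_core_count: int = 3
    housing_growth_per_decade: float = 0.15
    n_roads: int = 4
    n_lines: int = 2
    true_effects: dict = field(default_factory=default_true_effects)
    # calibrated so the default effects give a ~1-2% marginal annual burn rate
    true_intercept: float = -10.6
    burn_in_years: int = 100
    record_lead_years: int = 30
    ysf_cap: int = 100
    region_layout: int = 4
    seed: int = 0

    def validate(self) -> list[str]:
        errs = []
        if self.n_rows < 8 or self.n_cols < 8:
            errs.append("n_rows and n_cols must each be >= 8")
        if self.year_end <= self.year_start:
            errs.append("year_end must exceed year_start")
        if self.field_correlation_range_km <= 0:
            errs.append("field_correlation_range_km must be positive")
        if self.anomaly_sd < 0:
            errs.append("anomaly_sd must be non-negative")
        if self.region_layout < 1:
            errs.append("region_layout must be >= 1")
        unknown = set(self.true_effects) - set(COVARIATES)
        if unknown:
            errs.append(f"true_effects names not among the nine model "
                        f"covariates: {sorted(unknown)}")
        return errs

    def to_dict(self) -> dict:
        d = asdict(self)
        d["normal_base_period"] = list(self.normal_base_period)
        d["true_effects"] = {
            k: {"kind": v.kind, "params": dict(v.params)}
            if isinstance(v, EffectSpec) else v
            for k, v in self.true_effects.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "normal_base_period" in d:
            d["normal_base_period"] = tuple(d["normal_base_period"])
        if "true_effects" in d:
            d["true_effects"] = {
                k: v if isinstance(v, EffectSpec) else EffectSpec(**v)
                for k, v in d["true_effects"].items()
            }
        return cls(**d)


@dataclass
class LandscapePanel:
    """Gridded static, annual and decadal covariate layers on one grid.

    Annual climate layers cover ``annual_years`` (which extends back far
    enough to compute normals and 3-year deviations); the modeling window
    is [``year_start``, ``year_end``].  Invalid cells carry NaN in float
    layers, never silent zeros.
    """

    n_rows: int
    n_cols: int
    cell_km: float
    year_start: int
    year_end: int
    normal_base_period: tuple[int, int]
    annual_years: np.ndarray          # (T,)
    aet_annual: np.ndarray            # (T, R, C), mm
    cwd_annual: np.ndarray            # (T, R, C), mm
    housing_decades: np.ndarray       # (D,) snapshot years
    housing_density: np.ndarray       # (D, R, C), units/ha
    cultivated_fraction: np.ndarray   # (R, C) in [0, 1]
    water_fraction: np.ndarray        # (R, C) in [0, 1]
    road_mask: np.ndarray             # (R, C) bool
    electrical_mask: np.ndarray       # (R, C) bool
    region_id: np.ndarray             # (R, C) int
    valid_mask: np.ndarray            # (R, C) bool
    truth: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def check(self) -> None:
        layers2d = [self.cultivated_fraction, self.water_fraction,
                    self.road_mask, self.electrical_mask, self.region_id,
                    self.valid_mask]
        for lay in layers2d:
            assert lay.shape == self.shape, "layer grid mismatch"
        assert self.aet_annual.shape == (len(self.annual_years), *self.shape)
        v = self.valid_mask
        assert np.nanmin(self.cultivated_fraction[v]) >= 0
        assert np.nanmax(self.cultivated_fraction[v]) <= 1
        assert np.nanmin(self.water_fraction[v]) >= 0
        assert np.nanmax(self.water_fraction[v]) <= 1
        assert np.nanmin(self.housing_density) >= 0

    def to_dataset(self) -> xr.Dataset:
        return xr.Dataset(
            {
                "aet_annual": (("year", "row", "col"), self.aet_annual),
                "cwd_annual": (("year", "row", "col"), self.cwd_annual),
                "housing_density": (("decade", "row", "col"),
                                    self.housing_density),
                "cultivated_fraction": (("row", "col"),
                                        self.cultivated_fraction),
                "water_fraction": (("row", "col"), self.water_fraction),
                "road_mask": (("row", "col"), self.road_mask.astype(np.int8)),
                "electrical_mask": (("row", "col"),
                                    self.electrical_mask.astype(np.int8)),
                "region_id": (("row", "col"), self.region_id.astype(np.int32)),
                "valid_mask": (("row", "col"), self.valid_mask.astype(np.int8)),
            },
            coords={
                "year": self.annual_years,
                "decade": self.housing_decades,
                "row": np.arange(self.n_rows),
                "col": np.arange(self.n_cols),
            },
            attrs={
                "cell_km": self.cell_km,
                "year_start": self.year_start,
                "year_end": self.year_end,
                "normal_base_start": self.normal_base_period[0],
                "normal_base_end": self.normal_base_period[1],
                "index_convention": "0-based row/col, row-major pixel ids",
            },
        )

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "LandscapePanel":
        return cls(
            n_rows=ds.sizes["row"], n_cols=ds.sizes["col"],
            cell_km=float(ds.attrs["cell_km"]),
            year_start=int(ds.attrs["year_start"]),
            year_end=int(ds.attrs["year_end"]),
            normal_base_period=(int(ds.attrs["normal_base_start"]),
                                int(ds.attrs["normal_base_end"])),
            annual_years=ds["year"].values.astype(int),
            aet_annual=ds["aet_annual"].values,
            cwd_annual=ds["cwd_annual"].values,
            housing_decades=ds["decade"].values.astype(int),
            housing_density=ds["housing_density"].values,
            cultivated_fraction=ds["cultivated_fraction"].values,
            water_fraction=ds["water_fraction"].values,
            road_mask=ds["road_mask"].values.astype(bool),
            electrical_mask=ds["electrical_mask"].values.astype(bool),
            region_id=ds["region_id"].values.astype(int),
            valid_mask=ds["valid_mask"].values.astype(bool),
        )

    @classmethod
    def from_netcdf(cls, path) -> "LandscapePanel":
        with xr.open_dataset(path, engine="scipy") as ds:
            return cls.from_dataset(ds.load())


# ---------------------------------------------------------------------------
# field generation
# ---------------------------------------------------------------------------

def generate_correlated_field(
    shape: tuple[int, int],
    correlation_range_km: float,
    mean: float,
    sd: float,
    seed,
    cell_km: float = 1.0,
) -> np.ndarray:
    """Spatially autocorrelated Gaussian surface.

    White noise smoothed by a Gaussian kernel whose bandwidth equals the
    correlation range, then standardized to the requested mean and sd, so
    the empirical autocorrelation decays with distance on the scale of
    ``correlation_range_km``.  ``seed`` may be an int or a Generator.
    """
    if correlation_range_km <= 0:
        raise ValueError("correlation_range_km must be positive")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if sd == 0:
        return np.full(shape, float(mean))
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(z, sigma=correlation_range_km / cell_km,
                                mode="reflect")
    f = (f - f.mean()) / f.std()
    return mean + sd * f


def _random_lines(shape, n, rng) -> np.ndarray:
    """Mask with n straight lines between random points on opposite edges."""
    mask = np.zeros(shape, dtype=bool)
    R, C = shape
    for _ in range(n):
        if rng.random() < 0.5:  # roughly top-to-bottom
            r0, c0 = 0, int(rng.integers(C))
            r1, c1 = R - 1, int(rng.integers(C))
        else:
            r0, c0 = int(rng.integers(R)), 0
            r1, c1 = int(rng.integers(R)), C - 1
        rr, cc = _draw_line(r0, c0, r1, c1)
        mask[rr, cc] = True
    return mask


def _region_tiling(shape, n_regions) -> np.ndarray:
    """Tile the grid into n rectangular regions, as square as n allows."""
    a = int(math.sqrt(n_regions))
    while n_regions % a:
        a -= 1
    b = n_regions // a
    rows = np.array_split(np.arange(shape[0]), a)
    cols = np.array_split(np.arange(shape[1]), b)
    region = np.empty(shape, dtype=np.int32)
    rid = 0
    for rblock in rows:
        for cblock in cols:
            region[np.ix_(rblock, cblock)] = rid
            rid += 1
    return region


def generate_landscape(config: SyntheticConfig) -> LandscapePanel:
    """Build the full covariate panel for one synthetic landscape.

    Annual climate = normal surface + independent per-year anomaly field;
    decadal housing snapshots grow multiplicatively around urban cores;
    roads and transmission lines are straight rasterized transects; the
    region map is a rectangular tiling.  The generating surfaces and effect
    specs are stored in ``panel.truth`` for downstream recovery tests.
    """
    errs = config.validate()
    if errs:
        raise ValueError("; ".join(errs))
    shape = (config.n_rows, config.n_cols)
    root = np.random.SeedSequence(config.seed)
    keys = root.spawn(10)
    rngs = {name: np.random.default_rng(k) for name, k in zip(
        ["aet", "cwd", "anom", "housing", "cult", "water", "roads",
         "lines", "fire", "misc"], keys)}

    rng_km = config.field_correlation_range_km
    aet_norm = np.clip(generate_correlated_field(
        shape, rng_km, config.aet_normal_mean, config.aet_normal_sd,
        rngs["aet"], config.cell_km), 1.0, None)
    cwd_norm = np.clip(generate_correlated_field(
        shape, rng_km, config.cwd_normal_mean, config.cwd_normal_sd,
        rngs["cwd"], config.cell_km), 0.0, None)

    first_annual = min(config.normal_base_period[0], config.year_start - 3)
    last_annual = max(config.year_end, config.normal_base_period[1])
    annual_years = np.arange(first_annual, last_annual + 1)
    T = len(annual_years)

    def anomalies(rng):
        if config.anomaly_sd == 0:
            return np.zeros((T, *shape))
        return np.stack([
            generate_correlated_field(shape, rng_km, 0.0, config.anomaly_sd,
                                      rng, config.cell_km)
            for _ in range(T)
        ])

    aet_annual = np.clip(aet_norm[None] + anomalies(rngs["anom"]), 0.0, None)
    cwd_annual = np.clip(cwd_norm[None] + anomalies(rngs["anom"]), 0.0, None)

    # housing: smooth low background plus a few urban cores, growing by decade
    hr = rngs["housing"]
    background = np.clip(generate_correlated_field(
        shape, rng_km, 0.5, 0.5, hr, config.cell_km), 0.0, None)
    cores = np.zeros(shape)
    ax_r, ax_c = np.ogrid[: shape[0], : shape[1]]
    for _ in range(config.housing_core_count):
        cr, cc = hr.integers(shape[0]), hr.integers(shape[1])
        amp = 10.0 + 20.0 * hr.random()
        width = 4.0 + 6.0 * hr.random()  # km
        d2 = ((ax_r - cr) ** 2 + (ax_c - cc) ** 2) * config.cell_km ** 2
        cores += amp * np.exp(-0.5 * d2 / width**2)
    base_density = background + cores
    dec0 = (config.year_start // 10) * 10
    dec1 = -(-config.year_end // 10) * 10  # ceil to next decade
    decades = np.arange(dec0, dec1 + 1, 10)
    growth = 1.0 + config.housing_growth_per_decade * np.arange(len(decades))
    housing = np.clip(base_density[None] * growth[:, None, None], 0.0, None)

    cultivated = np.clip(generate_correlated_field(
        shape, rng_km, 0.15, 0.3, rngs["cult"], config.cell_km), 0.0, 1.0)

    # water: a couple of compact bodies plus faint shoreline noise
    wr = rngs["water"]
    water = np.zeros(shape)
    for _ in range(2):
        cr, cc = wr.integers(shape[0]), wr.integers(shape[1])
        width = 1.0 + 2.0 * wr.random()
        d2 = ((ax_r - cr) ** 2 + (ax_c - cc) ** 2) * config.cell_km ** 2
        water += 0.95 * np.exp(-0.5 * d2 / width**2)
    water = np.clip(water, 0.0, 1.0)

    roads = _random_lines(shape, config.n_roads, rngs["roads"])
    lines = _random_lines(shape, max(1, config.n_lines), rngs["lines"])

    panel = LandscapePanel(
        n_rows=config.n_rows, n_cols=config.n_cols, cell_km=config.cell_km,
        year_start=config.year_start, year_end=config.year_end,
        normal_base_period=config.normal_base_period,
        annual_years=annual_years,
        aet_annual=aet_annual, cwd_annual=cwd_annual,
        housing_decades=decades, housing_density=housing,
        cultivated_fraction=cultivated, water_fraction=water,
        road_mask=roads, electrical_mask=lines,
        region_id=_region_tiling(shape, config.region_layout),
        valid_mask=np.ones(shape, dtype=bool),
        truth={
            "aet_normal": aet_norm,
            "cwd_normal": cwd_norm,
            "effects": dict(config.true_effects),
            "intercept": config.true_intercept,
            "config": config,
        },
    )
    panel.check()
    return panel


# ---------------------------------------------------------------------------
# fire simulation
# ---------------------------------------------------------------------------

def simulate_fire_history(
    panel: LandscapePanel,
    true_effects: dict[str, EffectSpec] | None = None,
    true_intercept: float | None = None,
    burn_in_years: int = 100,
    seed: int = 0,
    record_lead_years: int = 30,
    ysf_cap: int = 100,
) -> FireHistory:
    """Draw a fire history from the generating additive model.

    For each year in order, each pixel's burn probability is
    ``invlogit(intercept + sum_j f_j(x_j))`` evaluated at the *current*
    covariates (including the dynamic years-since-fire state); burns are
    independent Bernoulli draws; the state then advances.  A burn-in period
    (default 100 years, dev3 = 0 and first-decade housing held fixed) runs
    before the recorded window so the years-since-fire distribution at the
    window start resembles a left-censored real record, and the final
    ``record_lead_years`` of burn-in are recorded so prior burns are
    observable, as in a fire-perimeter archive that predates the modeling
    window.

    ``history.meta`` stores the mean generating probability and realized
    burn fraction over the modeling window for calibration checks.
    """
    if true_effects is None:
        true_effects = panel.truth.get("effects")
    if true_effects is None:
        raise ValueError("true_effects not given and panel carries no truth")
    if true_intercept is None:
        true_intercept = panel.truth.get("intercept")
    if true_intercept is None:
        raise ValueError("true_intercept not given and panel carries no truth")
    effects = {k: make_effect(v) for k, v in true_effects.items()}

    rng = np.random.default_rng(seed)
    shape = panel.shape
    record_lead_years = min(record_lead_years, burn_in_years)
    record_start = panel.year_start - record_lead_years

    # static covariate surfaces, in the same covariate space the GAM sees
    aet_norm = ft.compute_normal(panel.aet_annual, panel.annual_years,
                                 panel.normal_base_period)
    cwd_norm = ft.compute_normal(panel.cwd_annual, panel.annual_years,
                                 panel.normal_base_period)
    dist_roads = ft.distance_to_features(panel.road_mask, panel.cell_km)
    dist_elec = ft.distance_to_features(panel.electrical_mask, panel.cell_km)
    housing_focal = np.stack([
        ft.focal_mean_density(h, panel.cell_km, 25.0,
                              valid_mask=panel.valid_mask)
        for h in panel.housing_density
    ])

    static = {
        "aet_normal": aet_norm,
        "cwd_normal": cwd_norm,
        "cultivated_fraction": panel.cultivated_fraction,
        "dist_roads": dist_roads,
        "dist_electrical": dist_elec,
    }
    static_eta = np.zeros(shape)
    for name, surf in static.items():
        if name in effects:
            static_eta += effects[name](surf)

    usable = panel.valid_mask & np.isfinite(static_eta)

    ysf = np.full(shape, float(ysf_cap))
    zero = np.zeros(shape)
    years = np.arange(panel.year_start - burn_in_years, panel.year_end + 1)
    burned = np.zeros((panel.year_end - record_start + 1, *shape), dtype=bool)
    p_sum = 0.0
    burn_sum = 0.0
    n_window_years = 0

    for y in years:
        in_window = y >= panel.year_start
        eta = static_eta.copy()
        if "years_since_fire" in effects:
            eta += effects["years_since_fire"](ysf)
        if in_window:
            aet_d = ft.compute_three_year_deviation(
                panel.aet_annual, panel.annual_years, aet_norm, y)
            cwd_d = ft.compute_three_year_deviation(
                panel.cwd_annual, panel.annual_years, cwd_norm, y)
            housing = ft.interpolate_decadal(panel.housing_decades,
                                             housing_focal, y)
        else:
            aet_d, cwd_d = zero, zero
            housing = housing_focal[0]
        for name, surf in (("aet_dev3", aet_d), ("cwd_dev3", cwd_d),
                           ("housing_density_25km", housing)):
            if name in effects:
                eta = eta + effects[name](surf)
        p = np.where(usable, expit(true_intercept + eta), 0.0)
        draws = rng.random(shape) < p
        if y >= record_start:
            burned[y - record_start] = draws
        if in_window:
            p_sum += float(p[usable].mean())
            burn_sum += float(draws[usable].mean())
            n_window_years += 1
        ysf = np.where(draws, 1.0, np.minimum(ysf + 1.0, ysf_cap))

    return FireHistory(
        record_start=record_start,
        burned=burned,
        meta={
            "mean_generating_p": p_sum / n_window_years,
            "burn_fraction": burn_sum / n_window_years,
            "true_intercept": float(true_intercept),
            "seed": int(seed),
            "ysf_cap": int(ysf_cap),
        },
    )


def generate_dataset(config: SyntheticConfig) -> tuple[LandscapePanel, FireHistory]:
    """Panel plus simulated history, fully determined by ``config.seed``."""
    panel = generate_landscape(config)
    fire_seed = int(np.random.SeedSequence(config.seed).spawn(11)[10]
                    .generate_state(1)[0] % (2**31))
    history = simulate_fire_history(
        panel,
        burn_in_years=config.burn_in_years,
        seed=fire_seed,
        record_lead_years=config.record_lead_years,
        ysf_cap=config.ysf_cap,
    )
    return panel, history
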