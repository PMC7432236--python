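"""Synthetic urban district generator.

Everything the exposure pipeline consumes — district geometry with census
attributes, drive-test field measurements, monitoring-node time series and
indoor surrogate training sets — can be generated here with the statistical
structure the real inputs have, so the full pipeline runs and is testable
without any external dataset:

* the outdoor log-field is a Gaussian random field with exponential
  covariance (lognormal field in linear scale), optionally with hotspots;
* drive-test points cluster along pseudo-street segments, giving the uneven
  sampling density that makes local-neighborhood kriging meaningful;
* sensor nodes record a diurnal power profile with multiplicative noise;
* indoor surrogate training sets pair space-filling input designs with an
  analytic whole-body SAR oracle (inverse-square law with a smooth angular
  gain and a near-field distance clamp).

All randomness flows through a single seed; a fixed seed reproduces every
artifact byte for byte.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dfield

import numpy as np
import pandas as pd
from scipy.stats import qmc
from shapely.geometry import Polygon, box

from .exceptions import InvalidConfigError, UnderdeterminedDesignError

__all__ = [
    "SceneConfig",
    "Grid",
    "Scene",
    "DOWNLINK_PROFILE_BANDS",
    "DRIVE_TEST_BANDS",
    "gen_district",
    "gen_drive_test",
    "gen_sensor_series",
    "gen_indoor_training",
    "sar_oracle",
    "diurnal_shape",
    "simulate_gaussian_field",
]

#: The three downlink bands monitored by the fixed sensor networks (MHz).
DOWNLINK_PROFILE_BANDS = ("925-960", "1805-1880", "2110-2170")

#: The five downlink bands swept during the drive test (MHz).
DRIVE_TEST_BANDS = ("800", "900", "1800", "2100", "2600")

#: Relative power shares of the drive-test bands in the synthetic total field
#: (root-sum-of-squares of the per-band fields recovers the total exactly).
_BAND_POWER_SHARES = (0.15, 0.35, 0.25, 0.15, 0.10)


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of a synthetic district.

    ``extent`` is (x0, y0, x1, y1) in meters of a local projected frame;
    the analysis grid tiles it at ``cell_size`` (100 m by default).
    ``median_level`` (V/m), ``log_variance`` and ``correlation_range_m``
    parameterize the lognormal outdoor field; ``hotspots`` is a list of
    (x, y, log_amplitude, width_m) Gaussian bumps added to the log mean.
    ``diurnal_amplitude`` maps band -> relative amplitude of the 24 h power
    profile and ``diurnal_phase_h`` is the hour of its peak.
    """

    extent: tuple[float, float, float, float] = (0.0, 0.0, 1000.0, 1000.0)
    cell_size: float = 100.0
    n_zones: int = 5
    n_buildings: int = 60
    population: int = 24_000
    child_fraction: float = 0.15
    workers: int = 9_000
    median_level: float = 0.6
    log_variance: float = 0.6
    correlation_range_m: float = 250.0
    # two station hotspots plus a broad elevated band along the southern
    # edge — the spatial structure a dense urban district shows
    hotspots: tuple[tuple[float, float, float, float], ...] = (
        (250.0, 750.0, 1.3, 140.0),
        (700.0, 300.0, 1.2, 120.0),
        (500.0, 60.0, 1.1, 260.0),
    )
    diurnal_amplitude: dict[str, float] = dfield(
        default_factory=lambda: {b: 0.3 for b in DOWNLINK_PROFILE_BANDS}
    )
    diurnal_phase_h: float = 15.0
    sensor_noise_sigma: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.extent
        if not (x1 > x0 and y1 > y0):
            raise InvalidConfigError("extent must have positive area")
        if self.cell_size <= 0:
            raise InvalidConfigError("cell_size must be positive")
        if self.correlation_range_m <= 0:
            raise InvalidConfigError("correlation_range_m must be positive")
        if self.log_variance < 0 or self.median_level <= 0:
            raise InvalidConfigError("invalid outdoor field parameters")
        if not 0 <= self.child_fraction <= 1:
            raise InvalidConfigError("child_fraction must lie in [0, 1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["extent"] = list(self.extent)
        d["hotspots"] = [list(h) for h in self.hotspots]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneConfig":
        d = dict(d)
        d["extent"] = tuple(d["extent"])
        d["hotspots"] = tuple(tuple(h) for h in d.get("hotspots", ()))
        return cls(**d)


@dataclass(frozen=True)
class Grid:
    """Regular analysis grid tiling the extent, row-major cell ids."""

    x0: float
    y0: float
    cell_size: float
    nx: int
    ny: int

    @classmethod
    def from_config(cls, config: SceneConfig) -> "Grid":
        x0, y0, x1, y1 = config.extent
        cs = config.cell_size
        nx = int(round((x1 - x0) / cs))
        ny = int(round((y1 - y0) / cs))
        if nx < 1 or ny < 1:
            raise InvalidConfigError("extent smaller than one grid cell")
        return cls(x0, y0, cs, nx, ny)

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    def centers(self) -> np.ndarray:
        """(n_cells, 2) array of cell-center coordinates, row-major."""
        ix = np.arange(self.nx)
        iy = np.arange(self.ny)
        cx = self.x0 + (ix + 0.5) * self.cell_size
        cy = self.y0 + (iy + 0.5) * self.cell_size
        gx, gy = np.meshgrid(cx, cy)
        return np.column_stack([gx.ravel(), gy.ravel()])

    def cell_polygon(self, cell_id: int) -> Polygon:
        iy, ix = divmod(cell_id, self.nx)
        x = self.x0 + ix * self.cell_size
        y = self.y0 + iy * self.cell_size
        return box(x, y, x + self.cell_size, y + self.cell_size)

    def cell_of(self, x: float, y: float) -> int:
        ix = int((x - self.x0) // self.cell_size)
        iy = int((y - self.y0) // self.cell_size)
        ix = min(max(ix, 0), self.nx - 1)
        iy = min(max(iy, 0), self.ny - 1)
        return iy * self.nx + ix


@dataclass
class Scene:
    """A generated district: grid plus zone and building tables."""

    config: SceneConfig
    grid: Grid
    zones: pd.DataFrame  # zone_id, geometry, pop_child, pop_adult, workers, housing_area_m2
    buildings: pd.DataFrame  # building_id, geometry, declared_use, floors, office_share


# ---------------------------------------------------------------------------
# Gaussian random field

def simulate_gaussian_field(
    coords: np.ndarray,
    variance: float,
    range_m: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Zero-mean Gaussian random field with exponential covariance.

    The covariance is ``variance * exp(-3 h / range_m)`` so ``range_m`` is
    the practical range matching the kriging module's variogram convention.
    Simulated exactly by Cholesky factorization; intended for desk-scale
    scenes (up to a few thousand locations).
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if variance == 0.0:
        return np.zeros(n)
    d = np.hypot(
        coords[:, 0][:, None] - coords[:, 0][None, :],
        coords[:, 1][:, None] - coords[:, 1][None, :],
    )
    cov = variance * np.exp(-3.0 * d / range_m)
    cov[np.diag_indices(n)] += 1e-10 * variance
    L = np.linalg.cholesky(cov)
    return L @ rng.standard_normal(n)


def _log_mean_surface(config: SceneConfig, coords: np.ndarray) -> np.ndarray:
    """ln(median field) plus Gaussian hotspot bumps."""
    m = np.full(len(coords), np.log(config.median_level))
    for hx, hy, amp, width in config.hotspots:
        d2 = (coords[:, 0] - hx) ** 2 + (coords[:, 1] - hy) ** 2
        m += amp * np.exp(-0.5 * d2 / width**2)
    return m


# ---------------------------------------------------------------------------
# District geometry and census

def _split_rects(extent, n, rng) -> list[tuple[float, float, float, float]]:
    """Partition the extent into n rectangles by recursive random splits."""
    rects = [tuple(extent)]
    while len(rects) < n:
        areas = [(r[2] - r[0]) * (r[3] - r[1]) for r in rects]
        i = int(np.argmax(areas))
        x0, y0, x1, y1 = rects.pop(i)
        f = rng.uniform(0.35, 0.65)
        if (x1 - x0) >= (y1 - y0):
            xm = x0 + f * (x1 - x0)
            rects += [(x0, y0, xm, y1), (xm, y0, x1, y1)]
        else:
            ym = y0 + f * (y1 - y0)
            rects += [(x0, y0, x1, ym), (x0, ym, x1, y1)]
    return rects


def _largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    """Integer apportionment of ``total`` by ``weights``; sums exactly."""
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        out = np.zeros(len(w), dtype=int)
        out[0] = total
        return out
    quota = total * w / w.sum()
    base = np.floor(quota).astype(int)
    short = total - base.sum()
    order = np.argsort(-(quota - base), kind="stable")
    base[order[:short]] += 1
    return base


def gen_district(config: SceneConfig) -> Scene:
    """Generate grid, statistical zones and buildings with census attributes.

    The grid tiles the extent exactly; zones partition it; each building is
    an axis-aligned rectangle inside the extent, tagged with a declared use
    (dwelling / office / mixed), a floor count and, for mixed use, an office
    floor-area share.  Zone child/adult populations are apportioned from the
    configured district population proportionally to zone housing area and
    sum to it exactly.
    """
    rng = np.random.default_rng(config.seed)
    grid = Grid.from_config(config)
    x0, y0, x1, y1 = config.extent

    zone_rects = _split_rects(config.extent, max(config.n_zones, 1), rng)
    zones = pd.DataFrame(
        {
            "zone_id": [f"Z{i:03d}" for i in range(len(zone_rects))],
            "geometry": [box(*r) for r in zone_rects],
        }
    )

    rows = []
    uses = ["dwelling", "office", "mixed"]
    for i in range(config.n_buildings):
        w = rng.uniform(8.0, 30.0)
        h = rng.uniform(8.0, 30.0)
        bx = rng.uniform(x0, max(x1 - w, x0))
        by = rng.uniform(y0, max(y1 - h, y0))
        use = uses[int(rng.choice(3, p=[0.65, 0.2, 0.15]))]
        floors = int(rng.integers(1, 9))
        office_share = float(rng.uniform(0.2, 0.8)) if use == "mixed" else (
            1.0 if use == "office" else 0.0
        )
        rows.append(
            (f"B{i:04d}", box(bx, by, bx + w, by + h), use, floors, office_share)
        )
    buildings = pd.DataFrame(
        rows, columns=["building_id", "geometry", "declared_use", "floors", "office_share"]
    )

    # zone housing area = residential floor area of buildings intersecting it
    housing = np.zeros(len(zones))
    for _, b in buildings.iterrows():
        res_area = b.geometry.area * b.floors * (1.0 - b.office_share)
        if res_area <= 0:
            continue
        for zi, z in zones.iterrows():
            inter = b.geometry.intersection(z.geometry).area
            if inter > 0:
                housing[zi] += res_area * inter / b.geometry.area
    zones["housing_area_m2"] = housing

    n_child = int(round(config.population * config.child_fraction))
    zones["pop_child"] = _largest_remainder(n_child, housing)
    zones["pop_adult"] = _largest_remainder(config.population - n_child, housing)
    zones["workers"] = _largest_remainder(config.workers, housing)
    return Scene(config, grid, zones, buildings)


# ---------------------------------------------------------------------------
# Drive test

def gen_drive_test(
    config: SceneConfig,
    n_points: int,
    truth_at: np.ndarray | None = None,
) -> pd.DataFrame | tuple[pd.DataFrame, np.ndarray]:
    """Generate drive-test measurement points along pseudo-streets.

    The total log field is a Gaussian random field (exponential covariance,
    ``correlation_range_m`` practical range, ``log_variance``) around the
    hotspot-modulated log median; per-band values split the total power by
    fixed shares so the root-sum-of-squares of a point's five band records
    reproduces its total field exactly.

    When ``truth_at`` (an (m, 2) coordinate array) is given, the same field
    realization is simulated jointly at those locations and the true total
    log-field values there are returned alongside the measurements frame.
    """
    if n_points < 1:
        raise InvalidConfigError("n_points must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    x0, y0, x1, y1 = config.extent

    # pseudo-streets: random straight segments; points jittered along them
    n_streets = max(3, int(np.sqrt(n_points) / 2))
    pts = []
    per = _largest_remainder(n_points, np.ones(n_streets))
    for k in range(n_streets):
        a = rng.uniform([x0, y0], [x1, y1])
        b = rng.uniform([x0, y0], [x1, y1])
        t = rng.uniform(0, 1, per[k])
        p = a + t[:, None] * (b - a)
        p += rng.normal(0.0, 4.0, p.shape)  # cross-street jitter
        pts.append(p)
    coords = np.clip(
        np.vstack(pts), [x0, y0], [np.nextafter(x1, x0), np.nextafter(y1, y0)]
    )

    all_coords = coords if truth_at is None else np.vstack([coords, truth_at])
    z = simulate_gaussian_field(
        all_coords, config.log_variance, config.correlation_range_m, rng
    )
    logE = _log_mean_surface(config, all_coords) + z
    logE_pts = logE[: len(coords)]

    t0 = pd.Timestamp("2020-03-02T09:00:00")
    times = t0 + pd.to_timedelta(np.arange(len(coords)) * 5, unit="s")
    frames = []
    for band, share in zip(DRIVE_TEST_BANDS, _BAND_POWER_SHARES):
        frames.append(
            pd.DataFrame(
                {
                    "x": coords[:, 0],
                    "y": coords[:, 1],
                    "timestamp": times,
                    "band": band,
                    "E_vpm": np.exp(logE_pts) * np.sqrt(share),
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    if truth_at is not None:
        return df, logE[len(coords):]
    return df


# ---------------------------------------------------------------------------
# Sensor network

def diurnal_shape(config: SceneConfig, band: str) -> np.ndarray:
    """24-value diurnal power profile, normalized to mean 1 over the day.

    A cosine with the configured per-band amplitude peaking at
    ``diurnal_phase_h`` — the single-peak afternoon-maximum shape typical of
    downlink network load.
    """
    h = np.arange(24.0)
    amp = config.diurnal_amplitude.get(band, 0.0)
    shape = 1.0 + amp * np.cos(2.0 * np.pi * (h - config.diurnal_phase_h) / 24.0)
    return shape / shape.mean()


def gen_sensor_series(
    config: SceneConfig,
    n_nodes: int,
    n_days: int,
    sample_period_s: float = 900.0,
) -> pd.DataFrame:
    """Simulate monitoring-node time series for the three downlink bands.

    Each node records ``E(t) = level_node * sqrt(shape(hour)) * noise`` per
    band, with node levels lognormal across the network and multiplicative
    lognormal noise, so the squared field follows the configured diurnal
    power profile.  Sample period defaults to 15 minutes.
    """
    if n_nodes < 1 or n_days < 1:
        raise InvalidConfigError("n_nodes and n_days must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    t0 = pd.Timestamp("2020-01-06T00:00:00")
    n_per_day = int(round(86400.0 / sample_period_s))
    times = t0 + pd.to_timedelta(
        np.arange(n_per_day * n_days) * sample_period_s, unit="s"
    )
    hours = times.hour.to_numpy()
    frames = []
    for i in range(n_nodes):
        node = f"N{i:03d}"
        level = config.median_level * np.exp(rng.normal(0.0, 0.5))
        for band in DOWNLINK_PROFILE_BANDS:
            shape = diurnal_shape(config, band)
            noise = (
                np.exp(rng.normal(0.0, config.sensor_noise_sigma, len(times)))
                if config.sensor_noise_sigma > 0
                else 1.0
            )
            e = level * np.sqrt(shape[hours]) * noise
            frames.append(
                pd.DataFrame(
                    {"node_id": node, "timestamp": times, "band": band, "E_vpm": e}
                )
            )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Indoor SAR oracle and training designs

#: Near-field distance clamp of the SAR oracle (m).
D_MIN = 0.3

#: Oracle source power constant, mW m^2 / kg.
P0_DEFAULT = 1.5

#: Amplitude of the smooth angular antenna/body gain.
G_AMP = 0.3

#: Height of the exposed child's torso center (m).
CHILD_HEIGHT = 1.0

#: Mounting-height range of the ceiling-level source (m).
SOURCE_HEIGHT = (2.4, 2.8)

#: Input domain of the 5-D indoor design: source horizontal position along
#: the wall, source height, child x, child y, child rotation.
def indoor_domain(room: tuple[float, float] = (3.0, 4.0)) -> np.ndarray:
    w, l = room
    return np.array(
        [[0.0, w], list(SOURCE_HEIGHT), [0.0, w], [0.0, l], [0.0, 2.0 * np.pi]]
    )


def sar_oracle(X: np.ndarray, room=(3.0, 4.0), p0: float = P0_DEFAULT) -> np.ndarray:
    """Analytic whole-body SAR ground truth for a child in a room.

    ``X`` columns: source horizontal position s (along the wall y = 0),
    source mounting height, child x, child y, child rotation about the
    vertical axis.  The dose follows an inverse-square law clamped below
    ``D_MIN`` with a smooth angular modulation of the child's orientation:

        SAR = p0 * (1 + G_AMP cos(theta)) / max(d^2, D_MIN^2)

    where d is the source-to-torso distance.  The source sits near the
    ceiling (access points and femtocells are wall/ceiling mounted), which
    keeps the dose bounded and the surface smooth — a synthetic stand-in
    ground truth with the separably approximable structure surrogate-model
    recovery tests need.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    s, hs, x, y, theta = X.T
    d2 = (x - s) ** 2 + y**2 + (CHILD_HEIGHT - hs) ** 2
    gain = 1.0 + G_AMP * np.cos(theta)
    return p0 * gain / np.maximum(d2, D_MIN**2)


def gen_indoor_training(
    config: SceneConfig,
    n_designs: int,
    room: tuple[float, float] = (3.0, 4.0),
    min_coefficients: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Space-filling experimental set (X0, Y0) for surrogate training.

    X0 is a Latin-hypercube sample of the 5-D input domain; Y0 the oracle
    SAR at those designs.  ``min_coefficients`` lets the caller enforce that
    the design determines a surrogate with that many free coefficients.
    """
    if room[0] <= 0 or room[1] <= 0:
        raise InvalidConfigError("room dimensions must be positive")
    if n_designs < min_coefficients:
        raise UnderdeterminedDesignError(
            f"{n_designs} designs cannot determine {min_coefficients} coefficients"
        )
    dom = indoor_domain(room)
    sampler = qmc.LatinHypercube(d=len(dom), seed=np.random.default_rng(
        np.random.SeedSequence([config.seed, 3])
    ))
    u = sampler.random(n_designs)
    X0 = qmc.scale(u, dom[:, 0], dom[:, 1])
    return X0, sar_oracle(X0, room=room)
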