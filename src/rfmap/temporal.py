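"""Diurnal rescaling of outdoor exposure estimates.

Fixed monitoring nodes record the downlink field around the clock.  Each
day of each node's series is normalized so long-term (seasonal, network)
trends cancel, leaving only the within-day shape:

    eta_i = E_i^2 / Ebar_day^2

with ``Ebar_day`` the day's average field.  Pooling the normalized samples
across nodes and days and averaging per hour of day yields one diurnal
power profile per frequency band.  A kriged grid-cell estimate (mean and
variance in linear scale) is then expanded into a 20,000-sample
time-varying exposure distribution by scaling normal base draws with the
profile at a uniformly drawn hour, and the resulting samples are summarized
by the better of a gamma and a normal fit under the Kolmogorov–Smirnov
statistic.

Two readings of ``Ebar_day`` are shipped: the literal arithmetic mean of E
(default) and an RMS variant (mean of E^2) under which the day-average of
eta is exactly one.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    DegenerateDistributionError,
    InsufficientDataError,
    InvalidVarianceError,
    ZeroDayError,
)

__all__ = [
    "TimeProfile",
    "CellExposureDistribution",
    "normalize_day",
    "build_profile",
    "flat_profile",
    "temporalize_cell",
    "fit_best",
]


@dataclass
class TimeProfile:
    """Diurnal profile of one band: mean normalized squared field per hour."""

    band: str
    eta_hour: np.ndarray  # 24 values
    n_samples_hour: np.ndarray  # 24 counts
    interpolated_hours: list[int] = dfield(default_factory=list)

    def __post_init__(self) -> None:
        self.eta_hour = np.asarray(self.eta_hour, dtype=float)
        self.n_samples_hour = np.asarray(self.n_samples_hour, dtype=int)
        if self.eta_hour.shape != (24,) or self.n_samples_hour.shape != (24,):
            raise ValueError("profile must have exactly 24 hourly values")
        if np.any(self.eta_hour < 0):
            raise ValueError("eta values must be nonnegative")


@dataclass
class CellExposureDistribution:
    """Monte-Carlo field samples of one grid cell and their best fit."""

    cell_id: int | str
    samples: np.ndarray
    seed: int
    fitted_family: str
    fit_params: tuple
    ks_stats: dict[str, float]


def normalize_day(e_values: np.ndarray, mode: str = "literal") -> np.ndarray:
    """Normalize one node-day of field samples to dimensionless eta values.

    ``mode='literal'`` divides the squared samples by the squared arithmetic
    mean of E; ``mode='rms'`` divides by the mean of E^2, making the day
    average of eta exactly 1.  Either way eta is invariant to rescaling the
    whole day by a positive constant.
    """
    e = np.asarray(e_values, dtype=float)
    if len(e) < 2:
        raise InsufficientDataError("a day needs at least 2 samples")
    if np.all(e == 0):
        raise ZeroDayError("all-zero day cannot be normalized")
    if mode == "literal":
        denom = float(np.mean(e)) ** 2
    elif mode == "rms":
        denom = float(np.mean(e**2))
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return e**2 / denom


def build_profile(
    sensors: pd.DataFrame,
    band: str,
    mode: str = "literal",
) -> TimeProfile:
    """Estimate the diurnal profile of one band from node series.

    ``sensors`` columns: node_id, timestamp, band, E_vpm.  Days are
    normalized per node, eta samples pooled across the network and averaged
    within each hour-of-day bin.  Hours without samples are filled by linear
    interpolation between the adjacent (circularly) observed hours and
    recorded in ``interpolated_hours``.  All-zero days are skipped.
    """
    df = sensors[sensors["band"] == band]
    if df.empty:
        raise InsufficientDataError(f"no samples for band {band!r}")
    ts = pd.to_datetime(df["timestamp"])
    work = pd.DataFrame(
        {
            "node": df["node_id"].to_numpy(),
            "day": ts.dt.normalize().to_numpy(),
            "hour": ts.dt.hour.to_numpy(),
            "E": df["E_vpm"].to_numpy(dtype=float),
        }
    )
    etas, hours = [], []
    for (_, _), g in work.groupby(["node", "day"], sort=True):
        if len(g) < 2:
            continue
        try:
            eta = normalize_day(g["E"].to_numpy(), mode=mode)
        except ZeroDayError:
            continue
        etas.append(eta)
        hours.append(g["hour"].to_numpy())
    if not etas:
        raise InsufficientDataError("no usable node-day in the series")
    eta = np.concatenate(etas)
    hour = np.concatenate(hours)
    prof = np.full(24, np.nan)
    counts = np.zeros(24, dtype=int)
    for h in range(24):
        m = hour == h
        counts[h] = m.sum()
        if counts[h]:
            prof[h] = eta[m].mean()
    missing = [int(h) for h in np.nonzero(np.isnan(prof))[0]]
    if missing:
        good = np.nonzero(~np.isnan(prof))[0]
        # circular linear interpolation over hour of day
        prof[missing] = np.interp(
            missing, good, prof[good], period=24
        )
    return TimeProfile(band, prof, counts, missing)


def flat_profile(band: str) -> TimeProfile:
    """All-ones profile (no diurnal variation); neutral in temporalization."""
    return TimeProfile(band, np.ones(24), np.ones(24, dtype=int))


def temporalize_cell(
    cell_id: int | str,
    z_lin: float,
    s2_lin: float,
    profiles: dict[str, TimeProfile],
    band_weights: dict[str, float] | None = None,
    n: int = 20_000,
    seed: int = 0,
) -> CellExposureDistribution:
    """Expand a kriged cell estimate into a time-varying sample distribution.

    Base field samples are drawn from Normal(z_lin, s2_lin) truncated at 0
    (negative draws are redrawn); each sample gets a uniform hour of day and
    a band drawn by ``band_weights`` (equal weights by default), its squared
    value is scaled by that profile's eta for the hour, and the square root
    is returned.  The best of a gamma and a normal fit is attached.
    """
    if s2_lin < 0:
        raise InvalidVarianceError("negative linear-scale variance")
    if band_weights is None:
        band_weights = {b: 1.0 / len(profiles) for b in profiles}
    bands = sorted(band_weights)
    w = np.array([band_weights[b] for b in bands], dtype=float)
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("band weights must sum to 1")
    eta = np.vstack([profiles[b].eta_hour for b in bands])

    rng = np.random.default_rng(seed)
    sd = float(np.sqrt(s2_lin))
    base = rng.normal(z_lin, sd, n)
    bad = base < 0.0
    while bad.any():  # truncate at 0 by redrawing
        base[bad] = rng.normal(z_lin, sd, int(bad.sum()))
        bad = base < 0.0
    hour = rng.integers(0, 24, n)
    band_idx = rng.choice(len(bands), size=n, p=w)
    samples = np.sqrt(base**2 * eta[band_idx, hour])

    family, params, ks = fit_best(samples)
    return CellExposureDistribution(cell_id, samples, seed, family, params, ks)


def fit_best(samples: np.ndarray) -> tuple[str, tuple, dict[str, float]]:
    """Fit gamma and normal by maximum likelihood; pick the smaller KS stat.

    Returns ``(family, params, ks_stats)`` where ``params`` are the scipy
    shape/loc/scale parameters of the selected family.
    """
    x = np.asarray(samples, dtype=float)
    if len(x) < 100:
        raise InsufficientDataError("distribution fitting needs >= 100 samples")
    if np.ptp(x) == 0.0:
        raise DegenerateDistributionError("zero-variance sample vector")
    norm_p = stats.norm.fit(x)
    gamma_p = stats.gamma.fit(x, floc=min(0.0, x.min()) - 1e-12)
    ks = {
        "normal": float(stats.kstest(x, "norm", args=norm_p).statistic),
        "gamma": float(stats.kstest(x, "gamma", args=gamma_p).statistic),
    }
    if ks["gamma"] <= ks["normal"]:
        return "gamma", tuple(gamma_p), ks
    return "normal", tuple(norm_p), ks
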