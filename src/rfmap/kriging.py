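"""Lognormal ordinary kriging of outdoor electric-field measurements.

Outdoor downlink exposure is approximately lognormal, so interpolation is
carried out on ``ln E``: an empirical semivariogram is estimated from the
log-transformed measurements, a parametric model (exponential by default) is
fitted by weighted least squares, and each target location is predicted by
ordinary kriging over a local neighborhood whose radius defaults to four
times the variogram range.  Log-scale predictions and kriging variances are
back-transformed to linear scale with the exact lognormal moment formulas

    z = exp(z_log + s2_log / 2)
    s2 = exp(2 z_log + s2_log) * (exp(s2_log) - 1)

The module follows a model/results split: :class:`OrdinaryKriging` holds the
data, ``fit()`` estimates the variogram and returns a
:class:`KrigingResults` carrying prediction, grid-mapping and
cross-validation methods.

Conventions
-----------
* Coordinates are planar metric (a local projected frame).
* The semivariance at lag zero equals the nugget, gamma(0) = nugget, and the
  same convention is used on the diagonal of the kriging matrix.  With a
  zero nugget the predictor is an exact interpolator.
* ``range_m`` is the *practical* range: the lag at which the exponential and
  gaussian models reach ~95% of the sill (gstat convention), and the exact
  sill-reaching lag for the spherical model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.spatial import cKDTree

from .exceptions import (
    DegenerateFieldError,
    InsufficientDataError,
    InvalidVarianceError,
    NoNeighborError,
)

__all__ = [
    "VariogramModel",
    "OrdinaryKriging",
    "KrigingResults",
    "CvReport",
    "empirical_variogram",
    "fit_variogram",
    "krige_point",
    "krige_grid",
    "loo_cv",
    "backtransform",
    "rss_combine_bands",
]

_FAMILIES = ("exponential", "spherical", "gaussian")

#: Minimum number of measurement points required to fit a variogram.
MIN_POINTS = 30


@dataclass(frozen=True)
class VariogramModel:
    """Parametric isotropic semivariogram gamma(h) = nugget + psill * g(h)."""

    family: str
    nugget: float
    partial_sill: float
    range_m: float

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown variogram family {self.family!r}")
        if self.nugget < 0 or self.partial_sill < 0 or self.range_m <= 0:
            raise ValueError("variogram parameters out of range")

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    def structure(self, h: np.ndarray) -> np.ndarray:
        """Normalized structure g(h) in [0, 1], g(0) = 0."""
        h = np.asarray(h, dtype=float)
        a = self.range_m
        if self.family == "exponential":
            return 1.0 - np.exp(-3.0 * h / a)
        if self.family == "gaussian":
            return 1.0 - np.exp(-3.0 * (h / a) ** 2)
        # spherical
        hr = np.clip(h / a, 0.0, 1.0)
        return 1.5 * hr - 0.5 * hr**3

    def semivariance(self, h: np.ndarray) -> np.ndarray:
        """gamma(h); gamma(0) = nugget by this package's convention."""
        return self.nugget + self.partial_sill * self.structure(h)

    def __call__(self, h: np.ndarray) -> np.ndarray:
        return self.semivariance(h)


@dataclass
class CvReport:
    """Leave-one-out cross-validation result on the log scale."""

    table: pd.DataFrame  # columns: x, y, observed_log, predicted_log, residual
    rmse: float
    mean_error: float
    exclusion_radius: float
    n_unpredictable: int = 0


def rss_combine_bands(df: pd.DataFrame, value_col: str = "E_vpm") -> pd.DataFrame:
    """Combine per-band field strengths at each location into one total field.

    Fields from different frequency bands add in power, so the total field is
    the root sum of squares of the per-band values recorded at the same
    (x, y) location.
    """
    g = df.groupby(["x", "y"], sort=False)[value_col].apply(
        lambda v: float(np.sqrt(np.sum(np.square(v))))
    )
    out = g.reset_index().rename(columns={value_col: value_col})
    return out


def empirical_variogram(
    coords: np.ndarray,
    values: np.ndarray,
    n_bins: int = 15,
    max_dist: float | None = None,
) -> pd.DataFrame:
    """Binned empirical semivariogram of ``values`` at planar ``coords``.

    Returns a frame with bin center distance, semivariance and pair counts.
    ``max_dist`` defaults to half the point-cloud diameter.
    """
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    n = len(values)
    iu, ju = np.triu_indices(n, k=1)
    d = np.hypot(*(coords[iu] - coords[ju]).T)
    sv = 0.5 * (values[iu] - values[ju]) ** 2
    if max_dist is None:
        max_dist = 0.5 * d.max()
    keep = d <= max_dist
    d, sv = d[keep], sv[keep]
    edges = np.linspace(0.0, max_dist, n_bins + 1)
    which = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        m = which == b
        if not m.any():
            continue
        rows.append((float(d[m].mean()), float(sv[m].mean()), int(m.sum())))
    return pd.DataFrame(rows, columns=["distance", "semivariance", "n_pairs"])


def _dedup_log(coords: np.ndarray, logvals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average log values recorded at duplicate coordinates."""
    df = pd.DataFrame({"x": coords[:, 0], "y": coords[:, 1], "v": logvals})
    g = df.groupby(["x", "y"], sort=False, as_index=False)["v"].mean()
    return g[["x", "y"]].to_numpy(), g["v"].to_numpy()


def fit_variogram(
    coords: np.ndarray,
    log_values: np.ndarray,
    family: str = "exponential",
    n_bins: int = 15,
    max_dist: float | None = None,
) -> VariogramModel:
    """Fit a parametric variogram to log-field data by pair-count-weighted WLS.

    Raises
    ------
    InsufficientDataError
        Fewer than :data:`MIN_POINTS` observations.
    DegenerateFieldError
        All observations identical.
    """
    coords = np.asarray(coords, dtype=float)
    log_values = np.asarray(log_values, dtype=float)
    if len(log_values) < MIN_POINTS:
        raise InsufficientDataError(
            f"variogram fitting needs >= {MIN_POINTS} points, got {len(log_values)}"
        )
    if np.ptp(log_values) == 0.0:
        raise DegenerateFieldError("constant field: variogram undefined")
    coords, log_values = _dedup_log(coords, log_values)
    emp = empirical_variogram(coords, log_values, n_bins=n_bins, max_dist=max_dist)
    h = emp["distance"].to_numpy()
    gamma = emp["semivariance"].to_numpy()
    w = np.sqrt(emp["n_pairs"].to_numpy(dtype=float))
    var = float(np.var(log_values))
    hmax = float(h.max())

    def resid(p):
        nug, psill, rng = p
        m = VariogramModel(family, max(nug, 0.0), max(psill, 0.0), max(rng, 1e-9))
        return w * (m.semivariance(h) - gamma)

    x0 = np.array([0.1 * var + 1e-9, 0.9 * var + 1e-9, hmax / 3.0])
    sol = least_squares(
        resid,
        x0,
        bounds=([0.0, 0.0, 1e-6], [5.0 * var + 1.0, 5.0 * var + 1.0, 10.0 * hmax]),
        xtol=1e-12,
        ftol=1e-12,
    )
    nug, psill, rng = sol.x
    return VariogramModel(family, float(nug), float(psill), float(rng))


def backtransform(z_log: float, s2_log: float) -> tuple[float, float]:
    """Back-transform a log-scale prediction/variance to linear scale.

    Applies the exact lognormal moment identities; accepts scalars or arrays.
    """
    z_log = np.asarray(z_log, dtype=float)
    s2_log = np.asarray(s2_log, dtype=float)
    if np.any(s2_log < 0):
        raise InvalidVarianceError("negative log-scale kriging variance")
    z_lin = np.exp(z_log + s2_log / 2.0)
    s2_lin = np.exp(2.0 * z_log + s2_log) * (np.exp(s2_log) - 1.0)
    if z_lin.ndim == 0:
        return float(z_lin), float(s2_lin)
    return z_lin, s2_lin


def krige_point(
    coords: np.ndarray,
    log_values: np.ndarray,
    target: tuple[float, float],
    vg: VariogramModel,
    neighborhood_radius: float | None = None,
) -> tuple[float, float]:
    """Ordinary kriging prediction at one target from a local neighborhood.

    Only the measurements within ``neighborhood_radius`` of the target (four
    variogram ranges by default) enter the kriging system, giving a locally
    varying mean.  Returns ``(z_log, s2_log)``.

    Raises :class:`NoNeighborError` when the neighborhood is empty.
    """
    coords = np.asarray(coords, dtype=float)
    log_values = np.asarray(log_values, dtype=float)
    if neighborhood_radius is None:
        neighborhood_radius = 4.0 * vg.range_m
    d0 = np.hypot(coords[:, 0] - target[0], coords[:, 1] - target[1])
    sel = d0 <= neighborhood_radius
    if not sel.any():
        raise NoNeighborError(
            f"no measurement within {neighborhood_radius:.1f} m of target {target}"
        )
    c, v, d0 = coords[sel], log_values[sel], d0[sel]
    try:
        return _solve_ok(c, v, d0, vg)
    except np.linalg.LinAlgError:
        # singular system, typically duplicate coordinates: average and retry
        warnings.warn("singular kriging system: deduplicating neighbors", stacklevel=2)
        c, v = _dedup_log(c, v)
        d0 = np.hypot(c[:, 0] - target[0], c[:, 1] - target[1])
        return _solve_ok(c, v, d0, vg)


def _solve_ok(
    c: np.ndarray, v: np.ndarray, d0: np.ndarray, vg: VariogramModel
) -> tuple[float, float]:
    """Dense solve of the ordinary-kriging system in semivariance form."""
    n = len(v)
    # exact hit with zero nugget: return the sample itself
    hit = d0 <= 1e-12
    if hit.any() and vg.nugget == 0.0:
        i = int(np.argmax(hit))
        return float(v[i]), 0.0
    dd = np.hypot(
        c[:, 0][:, None] - c[:, 0][None, :], c[:, 1][:, None] - c[:, 1][None, :]
    )
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = vg.semivariance(dd)  # diagonal = gamma(0) = nugget
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    A[n, n] = 0.0
    b = np.empty(n + 1)
    b[:n] = vg.semivariance(d0)
    b[n] = 1.0
    sol = np.linalg.solve(A, b)
    w, mu = sol[:n], sol[n]
    z = float(w @ v)
    s2 = float(w @ b[:n] + mu)
    return z, max(s2, 0.0)


def krige_grid(
    coords: np.ndarray,
    log_values: np.ndarray,
    cell_centers: np.ndarray,
    vg: VariogramModel,
    neighborhood_radius: float | None = None,
) -> pd.DataFrame:
    """Krige every grid-cell center; see :meth:`KrigingResults.predict`."""
    res = KrigingResults(
        model=None, variogram=vg, coords=np.asarray(coords, float),
        log_values=np.asarray(log_values, float),
    )
    return res.predict(cell_centers, neighborhood_radius=neighborhood_radius)


def loo_cv(
    coords: np.ndarray,
    log_values: np.ndarray,
    vg: VariogramModel,
    exclusion_radius: float = 0.0,
    neighborhood_radius: float | None = None,
) -> CvReport:
    """Leave-one-out cross-validation with optional neighbor exclusion."""
    res = KrigingResults(
        model=None, variogram=vg, coords=np.asarray(coords, float),
        log_values=np.asarray(log_values, float),
    )
    return res.loo_cv(exclusion_radius, neighborhood_radius=neighborhood_radius)


class OrdinaryKriging:
    """Lognormal ordinary-kriging model for sparse field measurements.

    Parameters
    ----------
    x, y : array-like
        Planar metric coordinates of the measurement points.
    field : array-like
        Electric-field strengths, V/m, strictly positive (log-transformed
        internally).
    family : str
        Variogram family, one of exponential (default), spherical, gaussian.
    n_bins : int
        Number of distance bins for the empirical variogram.

    Examples
    --------
    >>> ok = OrdinaryKriging(x, y, e_vpm)          # doctest: +SKIP
    >>> res = ok.fit()                             # doctest: +SKIP
    >>> grid = res.predict(cell_centers)           # doctest: +SKIP
    """

    def __init__(self, x, y, field, *, family: str = "exponential", n_bins: int = 15):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        field = np.asarray(field, dtype=float)
        if np.any(field <= 0):
            raise ValueError("field values must be positive for log transformation")
        coords, logv = _dedup_log(np.column_stack([x, y]), np.log(field))
        self.coords = coords
        self.log_values = logv
        self.family = family
        self.n_bins = n_bins

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, value_col: str = "E_vpm", combine_bands: bool = True, **kw
    ) -> "OrdinaryKriging":
        """Build the model from a measurements frame (x, y[, band], E_vpm).

        When the frame records several frequency bands per location and
        ``combine_bands`` is true, the bands are pooled into one total field
        by root sum of squares before kriging.
        """
        if combine_bands and "band" in df.columns:
            df = rss_combine_bands(df, value_col)
        return cls(df["x"], df["y"], df[value_col], **kw)

    def fit(self, variogram: VariogramModel | None = None) -> "KrigingResults":
        """Estimate the variogram (unless given) and return results."""
        if variogram is None:
            variogram = fit_variogram(
                self.coords, self.log_values, family=self.family, n_bins=self.n_bins
            )
        return KrigingResults(
            model=self,
            variogram=variogram,
            coords=self.coords,
            log_values=self.log_values,
        )


@dataclass
class KrigingResults:
    """Fitted kriging interpolator: variogram plus conditioning data."""

    model: OrdinaryKriging | None
    variogram: VariogramModel
    coords: np.ndarray
    log_values: np.ndarray
    global_mean_log: float = field(init=False)

    def __post_init__(self) -> None:
        self.global_mean_log = float(np.mean(self.log_values))
        self._tree = cKDTree(self.coords)

    def predict(
        self,
        targets: np.ndarray,
        neighborhood_radius: float | None = None,
    ) -> pd.DataFrame:
        """Predict at an (m, 2) array of target locations.

        Cells without any neighbor fall back to the global log mean with the
        total sill as variance and are flagged (``no_neighbor`` = True); the
        grid never aborts.
        """
        targets = np.atleast_2d(np.asarray(targets, dtype=float))
        vg = self.variogram
        if neighborhood_radius is None:
            neighborhood_radius = 4.0 * vg.range_m
        rows = []
        for tx, ty in targets:
            try:
                z, s2 = krige_point(
                    self.coords, self.log_values, (tx, ty), vg, neighborhood_radius
                )
                flag = False
            except NoNeighborError:
                z, s2 = self.global_mean_log, vg.sill
                flag = True
            zl, s2l = backtransform(z, s2)
            rows.append((tx, ty, z, s2, zl, s2l, flag))
        return pd.DataFrame(
            rows, columns=["x", "y", "z_log", "s2_log", "z_lin", "s2_lin", "no_neighbor"]
        )

    def loo_cv(
        self,
        exclusion_radius: float = 0.0,
        neighborhood_radius: float | None = None,
    ) -> CvReport:
        """Leave-one-out CV; ``exclusion_radius`` removes all predictors
        within that distance of the held-out point, probing increasingly
        large unmeasured areas.  Points left with no predictor are counted
        and excluded from the RMSE.
        """
        n = len(self.log_values)
        if n < 2:
            raise InsufficientDataError("cross-validation needs at least 2 points")
        vg = self.variogram
        rows = []
        n_bad = 0
        for i in range(n):
            d = np.hypot(*(self.coords - self.coords[i]).T)
            keep = d > max(exclusion_radius, 0.0)
            keep[i] = False
            if not keep.any():
                n_bad += 1
                continue
            try:
                z, _ = krige_point(
                    self.coords[keep],
                    self.log_values[keep],
                    tuple(self.coords[i]),
                    vg,
                    neighborhood_radius,
                )
            except NoNeighborError:
                n_bad += 1
                continue
            rows.append(
                (
                    self.coords[i, 0],
                    self.coords[i, 1],
                    self.log_values[i],
                    z,
                    z - self.log_values[i],
                )
            )
        table = pd.DataFrame(
            rows, columns=["x", "y", "observed_log", "predicted_log", "residual"]
        )
        resid = table["residual"].to_numpy()
        rmse = float(np.sqrt(np.mean(resid**2))) if len(resid) else float("nan")
        me = float(np.mean(resid)) if len(resid) else float("nan")
        return CvReport(table, rmse, me, exclusion_radius, n_bad)

    def summary(self) -> str:
        vg = self.variogram
        lines = [
            "Ordinary kriging (log-field)",
            "=" * 34,
            f"n observations     : {len(self.log_values)}",
            f"variogram family   : {vg.family}",
            f"nugget             : {vg.nugget:.6g}",
            f"partial sill       : {vg.partial_sill:.6g}",
            f"range (practical)  : {vg.range_m:.6g} m",
            f"default search rad : {4.0 * vg.range_m:.6g} m",
            f"global log mean    : {self.global_mean_log:.6g}",
        ]
        return "\n".join(lines)
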