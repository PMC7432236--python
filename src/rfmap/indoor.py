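"""Indoor exposure: surrogate models, building penetration and profiles.

Three mechanisms drive indoor exposure:

1. whole-body / whole-brain SAR from in-room WLAN and femtocell sources,
   predicted by the low-rank tensor surrogate (:mod:`rfmap.lra`) or, when
   no surrogate is trained, drawn from lognormals calibrated to the
   published reference profile statistics;
2. a 2D electric-field map of an apartment for a Wi-Fi source at an
   uncertain position, via a linear-kernel PCA of training maps plus one
   ordinary-kriging surrogate per retained component over source-position
   space;
3. outdoor fields penetrating the facade with a fixed loss (9.5 dB by
   default for the 900 MHz-equivalent field),

       V_I = V_O * 10^(-dB / 20).

``indoor_profiles`` combines them per building into Monte-Carlo sample sets
per tissue and age group; per-source components are kept so aggregation
can attribute contribution shares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from . import calibration
from .dosimetry import field_to_sar
from .exceptions import InsufficientTrainingError, InvalidConfigError
from .kriging import VariogramModel, krige_point
from .lra import LraResults

__all__ = [
    "PenetrationParams",
    "penetrate",
    "PcaKrigingSurrogate",
    "Pca2dResults",
    "indoor_profiles",
    "BuildingExposure",
]


@dataclass(frozen=True)
class PenetrationParams:
    """Building penetration loss in dB; 9.5 dB literature mean by default."""

    loss_db: float = 9.5

    def __post_init__(self) -> None:
        if self.loss_db < 0:
            raise InvalidConfigError("penetration loss must be >= 0 dB")

    @property
    def attenuation(self) -> float:
        return 10.0 ** (-self.loss_db / 20.0)


def penetrate(v_outdoor, params: PenetrationParams = PenetrationParams()):
    """Indoor field after facade penetration: V_I = V_O 10^(-dB/20)."""
    v = np.asarray(v_outdoor, dtype=float)
    if np.any(v < 0):
        raise ValueError("outdoor field must be nonnegative")
    out = v * params.attenuation
    if out.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# PCA + kriging 2D map surrogate

class PcaKrigingSurrogate:
    """2D field-map surrogate over uncertain source position.

    Training maps (one per known source position, all on a common spatial
    grid) are centered and decomposed by linear-kernel PCA; the smallest d
    components reaching the explained-variance threshold are retained, and
    each component score is interpolated over source-position space by
    ordinary kriging with a smooth (gaussian) variogram.  Prediction at a
    new source position kriges the d scores and inverts the PCA.
    """

    def __init__(
        self,
        training_maps: np.ndarray,
        source_positions: np.ndarray,
        variance_threshold: float = 0.99,
    ):
        maps = np.asarray(training_maps, dtype=float)
        if maps.ndim == 3:
            self.map_shape = maps.shape[1:]
            maps = maps.reshape(maps.shape[0], -1)
        else:
            self.map_shape = (maps.shape[1],)
        if maps.shape[0] < 3:
            raise InsufficientTrainingError("need at least 3 training maps")
        self.maps = maps
        self.positions = np.asarray(source_positions, dtype=float)
        if len(self.positions) != len(maps):
            raise ValueError("one source position per training map required")
        self.variance_threshold = variance_threshold

    def fit(self) -> "Pca2dResults":
        n = len(self.maps)
        total_var = float(np.var(self.maps - self.maps.mean(axis=0)))
        if total_var == 0.0:
            # all maps identical: the surrogate is the common map everywhere
            return Pca2dResults(
                mean_map=self.maps.mean(axis=0),
                components=np.zeros((1, self.maps.shape[1])),
                variograms=[None],
                positions=self.positions,
                scores=np.zeros((n, 1)),
                map_shape=self.map_shape,
                explained_variance_ratio=np.array([1.0]),
            )
        pca = PCA(n_components=min(n - 1, self.maps.shape[1]))
        scores = pca.fit_transform(self.maps)
        cum = np.cumsum(pca.explained_variance_ratio_)
        d = int(np.searchsorted(cum, min(self.variance_threshold, cum[-1] - 1e-12)) + 1)
        scores = scores[:, :d]
        span = np.linalg.norm(self.positions.max(axis=0) - self.positions.min(axis=0))
        variograms = []
        for k in range(d):
            var = float(np.var(scores[:, k]))
            # smooth interpolator of the score surface; the tiny nugget is a
            # numerical regularizer (gaussian kriging matrices are nearly
            # singular), small enough to keep training maps reproduced to
            # ~1e-4 relative
            variograms.append(
                VariogramModel(
                    "gaussian",
                    nugget=1e-8 * max(var, 1e-300),
                    partial_sill=max(var, 1e-300),
                    range_m=max(span, 1e-6),
                )
            )
        return Pca2dResults(
            mean_map=pca.mean_,
            components=pca.components_[:d],
            variograms=variograms,
            positions=self.positions,
            scores=scores,
            map_shape=self.map_shape,
            explained_variance_ratio=pca.explained_variance_ratio_[:d],
        )


@dataclass
class Pca2dResults:
    """Fitted PCA + kriging surrogate: d component maps and score kriges."""

    mean_map: np.ndarray
    components: np.ndarray  # (d, n_pixels)
    variograms: list
    positions: np.ndarray
    scores: np.ndarray  # (n_maps, d)
    map_shape: tuple
    explained_variance_ratio: np.ndarray

    @property
    def d(self) -> int:
        return self.components.shape[0]

    def predict(self, source_position, clip_negative: bool = True) -> np.ndarray:
        """Field map at a new source position (kriged scores -> inverse PCA).

        Negative reconstructed field values are clipped to zero.  Positions
        outside the training hull are evaluated but flagged by a warning.
        """
        p = np.asarray(source_position, dtype=float)
        lo, hi = self.positions.min(axis=0), self.positions.max(axis=0)
        if np.any(p < lo) or np.any(p > hi):
            import warnings

            warnings.warn("source position outside the training hull", stacklevel=2)
        rec = self.mean_map.copy()
        for k in range(self.d):
            vg = self.variograms[k]
            if vg is None:  # degenerate all-identical training set
                continue
            z, _ = krige_point(
                self.positions, self.scores[:, k], tuple(p), vg,
                neighborhood_radius=np.inf,
            )
            rec = rec + z * self.components[k]
        if clip_negative:
            rec = np.maximum(rec, 0.0)
        return rec.reshape(self.map_shape)

    def summary(self) -> str:
        evr = ", ".join(f"{v:.3f}" for v in self.explained_variance_ratio)
        return "\n".join(
            [
                "PCA + kriging 2D map surrogate",
                "=" * 32,
                f"training maps        : {len(self.positions)}",
                f"retained components d: {self.d}",
                f"explained var ratio  : [{evr}]",
            ]
        )


# ---------------------------------------------------------------------------
# Per-building indoor exposure profiles

@dataclass
class BuildingExposure:
    """Monte-Carlo indoor exposure of one building, one tissue, one age.

    ``components`` holds the per-sample additive contributions in mW/kg:
    'wlan_femtocell', 'wifi_use' and 'outdoor_penetrated'; ``total`` is
    their exact per-sample sum.
    """

    building_id: str
    tissue: str
    age: str
    components: dict[str, np.ndarray]

    @property
    def total(self) -> np.ndarray:
        return sum(self.components.values())

    @property
    def indoor_part(self) -> np.ndarray:
        """Exposure originating from in-room devices (WLAN/femtocell, Wi-Fi)."""
        return self.components["wlan_femtocell"] + self.components["wifi_use"]

    @property
    def outdoor_part(self) -> np.ndarray:
        """Exposure originating from outdoor sources, after penetration."""
        return self.components["outdoor_penetrated"]


def _wlan_femto_samples(
    tissue: str, age: str, n: int, rng: np.random.Generator,
    surrogate: LraResults | None, room: tuple[float, float] = (3.0, 4.0),
) -> np.ndarray:
    """WLAN + femtocell SAR samples.

    The surrogate (trained on a child) is used for adults too — a
    deliberately conservative choice, child doses being the higher.  The
    surrogate route covers whole-body SAR; whole-brain and the calibrated
    fallback draw from the reference-statistics lognormals.
    """
    if surrogate is not None and tissue == "whole_body":
        from .scene import indoor_domain

        dom = indoor_domain(room)
        X = rng.uniform(dom[:, 0], dom[:, 1], size=(n, len(dom)))
        return np.maximum(surrogate.predict(X, check_domain=False), 0.0)
    mu, sigma = calibration.indoor_lognormal_params("wlan_femtocell", tissue)
    return rng.lognormal(mu, sigma, n)


def indoor_profiles(
    buildings,
    outdoor_field: dict[str, np.ndarray | float],
    *,
    tissues=("whole_body", "whole_brain"),
    ages=("child", "adult"),
    surrogate: LraResults | None = None,
    sources: tuple[str, ...] = ("wlan_femtocell", "wifi_use"),
    penetration: PenetrationParams = PenetrationParams(),
    downlink_tf: dict | None = None,
    n: int = 20_000,
    seed: int = 0,
) -> dict[tuple[str, str, str], BuildingExposure]:
    """Monte-Carlo indoor exposure distributions per building, tissue, age.

    Per sample the three indoor mechanisms add: WLAN + femtocell SAR (from
    the surrogate or the calibrated lognormal), Wi-Fi-use SAR (calibrated,
    sampled independently of occupant position), and the penetrated outdoor
    field converted to SAR with the age/tissue downlink transfer function.

    ``buildings`` is any iterable of building ids (or the buildings frame);
    ``outdoor_field`` maps building id to the outdoor field at the building
    (scalar V/m or a sample vector to resample from).
    """
    if downlink_tf is None:
        downlink_tf = calibration.DOWNLINK_TF
    try:
        ids = list(buildings["building_id"])
    except (TypeError, KeyError, IndexError):
        ids = list(buildings)
    out: dict[tuple[str, str, str], BuildingExposure] = {}
    for b_i, bid in enumerate(ids):
        vo = np.atleast_1d(np.asarray(outdoor_field[bid], dtype=float))
        for tissue in tissues:
            for age in ages:
                tf = downlink_tf.get((tissue, age))
                if tf is None:
                    raise InvalidConfigError(
                        f"missing downlink transfer function for {(tissue, age)}"
                    )
                rng = np.random.default_rng(
                    np.random.SeedSequence(
                        [seed, 10, b_i, tissues.index(tissue), ages.index(age)]
                    )
                )
                if "wlan_femtocell" in sources:
                    wlan = _wlan_femto_samples(tissue, age, n, rng, surrogate)
                else:
                    wlan = np.zeros(n)
                if "wifi_use" in sources:
                    mu, sigma = calibration.indoor_lognormal_params(
                        "wifi_use", tissue, age
                    )
                    wifi = rng.lognormal(mu, sigma, n)
                else:
                    wifi = np.zeros(n)
                vo_s = vo if len(vo) == n else vo[rng.integers(0, len(vo), n)]
                pen = field_to_sar(penetrate(vo_s, penetration), tf)
                out[(bid, tissue, age)] = BuildingExposure(
                    bid,
                    tissue,
                    age,
                    {
                        "wlan_femtocell": wlan,
                        "wifi_use": wifi,
                        "outdoor_penetrated": np.asarray(pen, dtype=float),
                    },
                )
    return out
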