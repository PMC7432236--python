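"""Mobile-phone (uplink, near-field) SAR exposure.

The daily time-averaged uplink dose rate combines voice-call and
data-traffic use of the 3G network:

    E_tel = 0.25 p3G / 86400 * t * SAR_v * p_v * Pbar_v
          + 0.25 / 86400 * p3G * V_d * SAR_d * p_d * Pbar_d / Tbar

with t the voice-call duration (s/day), V_d the data volume (bits/day),
Tbar the network connection speed (bits/s), p3G / p_v / p_d the fractions
of 3G connections, voice users and data users, Pbar_x the mean transmitted
powers (W) and SAR_x the reference SAR transfer values per watt emitted.
The 0.25 factor appears in both terms of the published formula and is kept
verbatim; ``quarter_factor=False`` disables it for sensitivity analysis.

Calibrated mode draws a person-level usage-intensity factor (one lognormal
shared by all population groups — behavioral differences across groups are
not modelled) scaling voice duration and data volume together, plus an
age/tissue-specific lognormal spread on the transfer functions sized so
the resulting dose distribution reproduces the published mobile profile
mean and median per tissue and age group.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import calibration
from .exceptions import InvalidConfigError, InvalidUsageError

__all__ = [
    "UplinkUsage",
    "TfEntry",
    "SarTransferFunctions",
    "UplinkExposure",
    "uplink_sar",
    "uplink_profiles",
    "calibrated_usage_and_tf",
]

_DAY_S = 24.0 * 3600.0


@dataclass(frozen=True)
class UplinkUsage:
    """Mobile usage parameters; see module docstring for units."""

    p3g: float = 0.8
    p_v: float = 0.7
    p_d: float = 0.6
    t_s: float = 120.0
    v_d_bits: float = 8e8
    pbar_v_w: float = 0.25
    pbar_d_w: float = 0.25
    tbar_bps: float = 1e6
    intensity_sigma: float = 0.0  # lognormal spread of the usage intensity

    def __post_init__(self) -> None:
        for name in ("p3g", "p_v", "p_d"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name} must lie in [0, 1]")
        for name in ("t_s", "v_d_bits", "pbar_v_w", "pbar_d_w", "tbar_bps",
                     "intensity_sigma"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be nonnegative")
        if self.v_d_bits > 0 and self.p_d > 0 and self.tbar_bps == 0:
            raise InvalidUsageError("data traffic with zero connection speed")


@dataclass(frozen=True)
class TfEntry:
    """One reference SAR transfer value with an optional lognormal spread.

    ``value`` is the median transfer level; units are mW/kg per W emitted
    for the uplink voice/data modes and mW/kg per W/m^2 for downlink.
    """

    value: float
    sigma_log: float = 0.0
    unit: str = "mW/kg per W"

    def __post_init__(self) -> None:
        if self.value <= 0 or self.sigma_log < 0:
            raise InvalidConfigError("transfer entry out of range")


class SarTransferFunctions(dict):
    """Mapping (tissue, age, mode) -> :class:`TfEntry`."""

    def entry(self, tissue: str, age: str, mode: str) -> TfEntry:
        try:
            return self[(tissue, age, mode)]
        except KeyError:
            raise InvalidConfigError(
                f"missing SAR transfer function for {(tissue, age, mode)}"
            ) from None


@dataclass
class UplinkExposure:
    """Uplink dose rate: deterministic value and optional MC samples."""

    e_tel: float
    samples: np.ndarray | None = None
    tissue: str = "whole_body"
    age: str = "adult"


def _e_tel(
    usage: UplinkUsage, sar_v: float, sar_d: float, quarter_factor: bool
) -> float | np.ndarray:
    q = 0.25 if quarter_factor else 1.0
    voice = q * usage.p3g / _DAY_S * usage.t_s * sar_v * usage.p_v * usage.pbar_v_w
    if usage.v_d_bits > 0 and usage.p_d > 0:
        data = (
            q / _DAY_S * usage.p3g * usage.v_d_bits * sar_d * usage.p_d
            * usage.pbar_d_w / usage.tbar_bps
        )
    else:
        data = 0.0 * voice
    return voice + data


def uplink_sar(
    usage: UplinkUsage,
    tf: SarTransferFunctions,
    tissue: str = "whole_body",
    age: str = "adult",
    *,
    quarter_factor: bool = True,
    n: int | None = None,
    seed: int = 0,
) -> UplinkExposure:
    """Evaluate the uplink dose-rate formula for one tissue and age group.

    With ``n`` set (or when transfer entries carry a spread), an MC sample
    vector is drawn: the usage intensity scales t and V_d together and the
    transfer-function spread scales both modes.
    """
    sv = tf.entry(tissue, age, "voice")
    sd = tf.entry(tissue, age, "data")
    det = float(_e_tel(usage, sv.value, sd.value, quarter_factor))
    spread = max(sv.sigma_log, sd.sigma_log)
    if n is None and usage.intensity_sigma == 0.0 and spread == 0.0:
        return UplinkExposure(det, None, tissue, age)
    n = n or 20_000
    rng = np.random.default_rng(np.random.SeedSequence([seed, 20]))
    u = (
        np.exp(rng.normal(0.0, usage.intensity_sigma, n))
        if usage.intensity_sigma > 0
        else np.ones(n)
    )
    lv = np.exp(rng.normal(0.0, sv.sigma_log, n)) if sv.sigma_log > 0 else np.ones(n)
    # equal voice/data spreads model one person-level transfer factor shared
    # across modes (keeps the total dose lognormal); unequal spreads draw
    # independently
    if sd.sigma_log == sv.sigma_log:
        ld = lv
    elif sd.sigma_log > 0:
        ld = np.exp(rng.normal(0.0, sd.sigma_log, n))
    else:
        ld = np.ones(n)
    base = replace(usage, intensity_sigma=0.0)
    # the formula is linear in t and V_d, so the intensity and transfer
    # spreads factor out of each term
    voice_base = float(_e_tel(replace(base, v_d_bits=0.0), sv.value, sd.value,
                              quarter_factor))
    data_base = det - voice_base
    samples = voice_base * u * lv + data_base * u * ld
    return UplinkExposure(det, samples, tissue, age)


def calibrated_usage_and_tf(
    tissues=("whole_body", "whole_brain"), ages=("adult", "child")
) -> tuple[UplinkUsage, SarTransferFunctions]:
    """Default usage distribution and transfer functions calibrated so each
    (tissue, age) dose distribution reproduces the published mobile profile
    median and mean.

    The usage intensity carries a shared log-variance
    (:data:`rfmap.calibration.USAGE_INTENSITY_SIGMA2`); the per-(tissue,
    age) transfer spread absorbs the remainder of the row's implied total
    log-variance, and the transfer median is solved so the deterministic
    dose at median usage equals the row median.
    """
    usage = UplinkUsage(intensity_sigma=float(np.sqrt(
        calibration.USAGE_INTENSITY_SIGMA2)))
    unit_tf = SarTransferFunctions()
    tf = SarTransferFunctions()
    for tissue in tissues:
        for age in ages:
            unit_tf[(tissue, age, "voice")] = TfEntry(1.0)
            unit_tf[(tissue, age, "data")] = TfEntry(1.0)
    for tissue in tissues:
        for age in ages:
            median, s2_total = calibration.mobile_lognormal_sigma2(tissue, age)
            s2_tf = s2_total - calibration.USAGE_INTENSITY_SIGMA2
            if s2_tf < 0:
                raise InvalidConfigError(
                    "usage-intensity variance exceeds the calibrated total"
                )
            base = float(
                _e_tel(replace(usage, intensity_sigma=0.0), 1.0, 1.0, True)
            )
            ref = median / base
            tf[(tissue, age, "voice")] = TfEntry(ref, float(np.sqrt(s2_tf)))
            tf[(tissue, age, "data")] = TfEntry(ref, float(np.sqrt(s2_tf)))
    return usage, tf


def uplink_profiles(
    groups: dict[str, str],
    usage: UplinkUsage | None = None,
    tf: SarTransferFunctions | None = None,
    tissues=("whole_body", "whole_brain"),
    n: int = 20_000,
    seed: int = 0,
    quarter_factor: bool = True,
) -> dict[tuple[str, str], UplinkExposure]:
    """Uplink dose distributions per population group and tissue.

    ``groups`` maps group name -> age ('child' or 'adult'); the same usage
    distribution applies to every group, only the age-specific transfer
    functions differ.  Defaults to the calibrated usage/transfer tables.
    """
    if not groups:
        raise InvalidConfigError("group list must be nonempty")
    if usage is None or tf is None:
        cal_usage, cal_tf = calibrated_usage_and_tf(tissues=tissues)
        usage = usage or cal_usage
        tf = tf or cal_tf
    out = {}
    for g_i, (group, age) in enumerate(sorted(groups.items())):
        for t_i, tissue in enumerate(tissues):
            out[(group, tissue)] = uplink_sar(
                usage, tf, tissue, age,
                quarter_factor=quarter_factor, n=n,
                seed=int(np.random.default_rng(
                    np.random.SeedSequence([seed, 21, g_i, t_i])
                ).integers(0, 2**31 - 1)),
            )
    return out
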