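"""Published calibration defaults for the indoor and mobile exposure profiles.

When no surrogate model is trained (the full-wave electromagnetic training
stage is outside this package), the indoor and mobile-phone exposure
profiles default to parametric distributions calibrated to the descriptive
statistics of the reference cumulative distribution functions measured for
a dense urban district: WLAN + femtocell and Wi-Fi-use SAR profiles per
tissue and age group, and mobile-phone SAR profiles per tissue and age
group.  All SAR statistics are in mW/kg.

Lognormals are used throughout (SAR profiles are strongly right-skewed):
indoor profiles are moment-matched to (mean, SD); mobile profiles are
matched to (mean, median), since a two-parameter lognormal cannot honor
mean, median and SD simultaneously and the mobile reference statistics pin
the median.  The WLAN + femtocell whole-body reference table carries a
median below its first quartile — an inconsistency in the source table —
so that cell is ignored and only mean/SD are used for that profile.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "INDOOR_PROFILE_STATS",
    "MOBILE_PROFILE_STATS",
    "DOWNLINK_TF",
    "lognormal_from_moments",
    "lognormal_from_mean_median",
    "indoor_lognormal_params",
    "mobile_lognormal_sigma2",
    "USAGE_INTENSITY_SIGMA2",
]

#: Reference statistics of the indoor exposure profiles (SAR, mW/kg).
#: columns: source, tissue, age, p25, p50, p75, mean, sd (age None = both).
INDOOR_PROFILE_STATS = pd.DataFrame(
    [
        ("wlan_femtocell", "whole_body", None, 6.9e-2, 1.7e-2, 3.4e-1, 2.4e-1, 1.7e-1),
        ("wlan_femtocell", "whole_brain", None, 3.2e-2, 5.6e-2, 9.1e-2, 6.7e-2, 4.9e-2),
        ("wifi_use", "whole_body", "adult", 8.2e-6, 2.1e-5, 4.8e-5, 3.6e-5, 4.2e-5),
        ("wifi_use", "whole_body", "child", 10e-6, 2.6e-5, 5.9e-5, 4.3e-5, 5.1e-5),
        ("wifi_use", "whole_brain", "adult", 1.1e-5, 2.9e-5, 6.6e-5, 4.9e-5, 5.7e-5),
        ("wifi_use", "whole_brain", "child", 1.2e-5, 3e-5, 6.8e-5, 5e-5, 5.9e-5),
    ],
    columns=["source", "tissue", "age", "p25", "p50", "p75", "mean", "sd"],
)

#: Reference statistics of the mobile-phone use exposure profiles (mW/kg).
MOBILE_PROFILE_STATS = pd.DataFrame(
    [
        ("whole_body", "adult", 1.1e-4, 2e-3, 1.6e-2, 6.3e-3, 3.1e-2),
        ("whole_body", "child", 4.5e-5, 8.3e-4, 6.8e-3, 3.5e-3, 1.5e-1),
        ("whole_brain", "adult", 6.8e-5, 1.3e-3, 1e-2, 3.6e-3, 1.4e-2),
        ("whole_brain", "child", 1.6e-5, 2.9e-4, 2.4e-3, 8.4e-4, 1.7e-3),
    ],
    columns=["tissue", "age", "p25", "p50", "p75", "mean", "sd"],
)

#: Placeholder downlink SAR transfer functions, (mW/kg) per (W/m^2) of
#: incident plane-wave power density, per (tissue, age).  The published
#: conversion tool's internals are not public; the whole-body values sit in
#: the 2-9 mW/kg per W/m^2 range plane-wave dosimetry studies report (with
#: the child-above-adult ordering), and the whole-brain values carry the
#: larger outdoor-to-indoor relativity the published contribution curves
#: imply for brain tissue.  Plain user config — override for any serious
#: assessment.
DOWNLINK_TF = {
    ("whole_body", "adult"): 4.7,
    ("whole_body", "child"): 8.0,
    ("whole_brain", "adult"): 10.0,
    ("whole_brain", "child"): 11.0,
}

#: Shared log-variance of the person-level usage-intensity factor (the same
#: usage distribution applies to every population group; age enters only
#: through the transfer functions).  Chosen below the smallest total
#: log-variance implied by the mobile reference rows so the per-(tissue,
#: age) transfer-function spread can absorb the remainder.
USAGE_INTENSITY_SIGMA2 = 1.5


def lognormal_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the lognormal with the given linear mean and SD."""
    if mean <= 0 or sd < 0:
        raise ValueError("mean must be positive, sd nonnegative")
    s2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - s2 / 2.0
    return float(mu), float(np.sqrt(s2))


def lognormal_from_mean_median(mean: float, median: float) -> tuple[float, float]:
    """(mu, sigma) of the lognormal with the given mean and median."""
    if median <= 0 or mean < median:
        raise ValueError("need mean >= median > 0 for a lognormal")
    mu = np.log(median)
    s2 = 2.0 * (np.log(mean) - mu)
    return float(mu), float(np.sqrt(s2))


def indoor_lognormal_params(source: str, tissue: str, age: str | None = None):
    """Moment-matched lognormal (mu, sigma) of one indoor profile row."""
    df = INDOOR_PROFILE_STATS
    m = (df["source"] == source) & (df["tissue"] == tissue)
    if age is not None and df.loc[m, "age"].notna().any():
        m &= df["age"] == age
    row = df.loc[m]
    if row.empty:
        raise KeyError(f"no indoor calibration row for {(source, tissue, age)}")
    r = row.iloc[0]
    return lognormal_from_moments(float(r["mean"]), float(r["sd"]))


def mobile_lognormal_sigma2(tissue: str, age: str) -> tuple[float, float]:
    """(median, total log-variance) implied by one mobile profile row."""
    df = MOBILE_PROFILE_STATS
    r = df[(df["tissue"] == tissue) & (df["age"] == age)].iloc[0]
    _, sigma = lognormal_from_mean_median(float(r["mean"]), float(r["p50"]))
    return float(r["p50"]), float(sigma**2)
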