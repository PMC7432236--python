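"""Field-to-SAR conversion for far-field (downlink) exposure.

An incident electric field E (V/m) is converted to a plane-wave power
density S = E^2 / Z0 with the free-space impedance Z0 = 377 ohm, and then
to a tissue dose with a transfer function expressed in (mW/kg) per (W/m^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidConfigError

__all__ = ["Z0_OHM", "TissueDose", "field_to_sar", "power_density"]

#: Free-space wave impedance, ohm.
Z0_OHM = 377.0

TISSUES = ("whole_body", "whole_brain")
AGES = ("child", "adult")


@dataclass(frozen=True)
class TissueDose:
    tissue: str
    sar_mw_per_kg: float

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise InvalidConfigError(f"unknown tissue {self.tissue!r}")
        if self.sar_mw_per_kg < 0:
            raise InvalidConfigError("SAR must be nonnegative")


def power_density(e_vpm: np.ndarray) -> np.ndarray:
    """Plane-wave power density S = E^2 / Z0, W/m^2."""
    e = np.asarray(e_vpm, dtype=float)
    if np.any(e < 0):
        raise ValueError("field strength must be nonnegative")
    return e**2 / Z0_OHM


def field_to_sar(e_vpm, tf_mwkg_per_wm2: float):
    """Convert field strength (V/m) to SAR (mW/kg) via a downlink transfer
    function in (mW/kg)/(W/m^2).  Accepts scalars or arrays."""
    if tf_mwkg_per_wm2 is None:
        raise InvalidConfigError("missing downlink transfer function entry")
    s = power_density(e_vpm)
    out = tf_mwkg_per_wm2 * s
    if np.ndim(out) == 0:
        return float(out)
    return out
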