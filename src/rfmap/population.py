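"""Census-to-building population allocation and person-hours.

Zone (census micro-zone) populations are allocated to buildings by housing
surface ratio,

    P_i = sum_j (S_ij / S_j) * P_j,

with S_ij the housing area of building i intersecting zone j and S_j the
zone's total housing area; the allocation runs separately per age class
(children < 15 y, adults >= 15 y).  The occupational population (15-64 y)
is allocated analogously over office floor areas using the district-level
aggregate.  Person-hours per microenvironment (home, office, outdoor) are
the product of the allocated populations and configurable daily time
budgets; outdoor person-hours accrue to the grid cell holding the building.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dfield

import numpy as np
import pandas as pd

from .exceptions import InvalidConfigError
from .scene import Grid

__all__ = [
    "TimeBudgets",
    "DEFAULT_BUDGETS",
    "classify_buildings",
    "allocate_population",
    "person_hours",
]

MICROENVS = ("home", "office", "outdoor")

#: Sliver intersections below this area (m^2) are dropped for robustness.
SLIVER_M2 = 0.5

_USE_MAP = {
    "dwelling": "residential",
    "residential": "residential",
    "house": "residential",
    "apartment": "residential",
    "office": "office",
    "commercial": "office",
    "mixed": "mixed",
}


@dataclass(frozen=True)
class TimeBudgets:
    """Daily hours per population group and microenvironment (sum = 24).

    Derived from national time-activity surveys: residents spend the large
    majority of the day indoors (home + office close to 90% of 24 h).
    """

    budgets: dict[str, dict[str, float]] = dfield(
        default_factory=lambda: {
            "residential_child": {"home": 21.5, "office": 0.0, "outdoor": 2.5},
            "residential_adult": {"home": 21.5, "office": 0.0, "outdoor": 2.5},
            "occupational": {"home": 16.0, "office": 6.0, "outdoor": 2.0},
        }
    )

    def __post_init__(self) -> None:
        for group, b in self.budgets.items():
            if set(b) != set(MICROENVS):
                raise InvalidConfigError(
                    f"group {group!r} must budget exactly {MICROENVS}"
                )
            if any(v < 0 for v in b.values()):
                raise InvalidConfigError("time budgets must be nonnegative")
            if abs(sum(b.values()) - 24.0) > 1e-9:
                raise InvalidConfigError(
                    f"group {group!r} budgets must sum to 24 h"
                )


DEFAULT_BUDGETS = TimeBudgets()


def classify_buildings(buildings: pd.DataFrame) -> pd.DataFrame:
    """Map declared uses onto {residential, office, mixed}.

    Unknown codes default to residential with a warning — the conservative
    choice for residential exposure.  Mixed buildings keep their declared
    office floor-area share; pure uses get share 0 (residential) or 1
    (office).
    """
    out = buildings.copy()
    typology, office_share = [], []
    for _, b in out.iterrows():
        use = _USE_MAP.get(str(b.get("declared_use", "")).lower())
        if use is None:
            warnings.warn(
                f"building {b.get('building_id')}: unknown use "
                f"{b.get('declared_use')!r}, defaulting to residential",
                stacklevel=2,
            )
            use = "residential"
        typology.append(use)
        if use == "residential":
            office_share.append(0.0)
        elif use == "office":
            office_share.append(1.0)
        else:
            office_share.append(float(b.get("office_share", 0.5)))
    out["typology"] = typology
    out["office_share"] = office_share
    return out


def allocate_population(
    buildings: pd.DataFrame, zones: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Allocate zone populations to buildings by housing surface ratio.

    Returns ``(buildings, unallocated)``: the buildings frame gains
    ``housing_area_m2``, ``office_area_m2``, ``pop_child``, ``pop_adult``
    and ``workers`` columns; ``unallocated`` reports zones whose population
    could not be assigned (populated zone without housing area), which are
    logged rather than fatal.
    """
    b = classify_buildings(buildings)
    b["housing_area_m2"] = [
        geom.area * fl * (1.0 - osh)
        for geom, fl, osh in zip(b["geometry"], b["floors"], b["office_share"])
    ]
    b["office_area_m2"] = [
        geom.area * fl * osh
        for geom, fl, osh in zip(b["geometry"], b["floors"], b["office_share"])
    ]

    n_b = len(b)
    pop_child = np.zeros(n_b)
    pop_adult = np.zeros(n_b)
    bad_zones = []
    for _, z in zones.iterrows():
        pj_child = float(z.get("pop_child", 0.0))
        pj_adult = float(z.get("pop_adult", 0.0))
        sj = float(z["housing_area_m2"])
        if pj_child + pj_adult <= 0:
            continue
        if sj <= 0:
            warnings.warn(
                f"zone {z['zone_id']}: population without housing area; "
                "left unallocated",
                stacklevel=2,
            )
            bad_zones.append((z["zone_id"], pj_child, pj_adult))
            continue
        for i in range(n_b):
            ha = b["housing_area_m2"].iat[i]
            if ha <= 0:
                continue
            geom = b["geometry"].iat[i]
            inter = geom.intersection(z["geometry"]).area
            if inter <= SLIVER_M2:
                continue
            s_ij = ha * inter / geom.area
            pop_child[i] += s_ij / sj * pj_child
            pop_adult[i] += s_ij / sj * pj_adult
    b["pop_child"] = pop_child
    b["pop_adult"] = pop_adult

    # occupational population: district aggregate over office areas
    total_workers = float(zones["workers"].sum()) if "workers" in zones else 0.0
    office = b["office_area_m2"].to_numpy()
    if office.sum() > 0 and total_workers > 0:
        b["workers"] = total_workers * office / office.sum()
    else:
        b["workers"] = 0.0
        if total_workers > 0:
            warnings.warn("no office area: occupational population unallocated",
                          stacklevel=2)
            bad_zones.append(("__district_workers__", 0.0, total_workers))
    unallocated = pd.DataFrame(
        bad_zones, columns=["zone_id", "pop_child", "pop_adult"]
    )
    return b, unallocated


def person_hours(
    buildings: pd.DataFrame,
    grid: Grid,
    budgets: TimeBudgets = DEFAULT_BUDGETS,
) -> pd.DataFrame:
    """Person-hours per (location, group, microenvironment) and day.

    Home and office person-hours are attached to buildings; outdoor
    person-hours of a building's residents and workers accrue to the grid
    cell containing the building centroid.  ``buildings`` must carry the
    allocation columns from :func:`allocate_population`.

    Returns a frame with columns location_id, location_type ('building' or
    'cell'), cell_id, group, microenv, person_hours.
    """
    bud = budgets.budgets
    rows = []
    group_pops = {
        "residential_child": "pop_child",
        "residential_adult": "pop_adult",
        "occupational": "workers",
    }
    for _, b in buildings.iterrows():
        cell = grid.cell_of(b["geometry"].centroid.x, b["geometry"].centroid.y)
        for group, col in group_pops.items():
            pop = float(b.get(col, 0.0))
            if pop <= 0 or group not in bud:
                continue
            for env, hours in bud[group].items():
                if hours <= 0:
                    continue
                if env == "outdoor":
                    rows.append((cell, "cell", cell, group, env, pop * hours))
                elif env == "home" and group == "occupational":
                    # workers' home hours belong to their residence, which
                    # is already counted through the residential groups
                    continue
                else:
                    rows.append(
                        (b["building_id"], "building", cell, group, env,
                         pop * hours)
                    )
    df = pd.DataFrame(
        rows,
        columns=["location_id", "location_type", "cell_id", "group",
                 "microenv", "person_hours"],
    )
    if df.empty:
        return df
    return (
        df.groupby(
            ["location_id", "location_type", "cell_id", "group", "microenv"],
            as_index=False, sort=True,
        )["person_hours"].sum()
    )
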