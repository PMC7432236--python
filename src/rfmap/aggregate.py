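"""Monte-Carlo fusion of exposure distributions into SAR percentile maps.

Every grid cell pools samples from its exposure components — the
time-varying outdoor distribution (per age group) and the indoor
distributions of the buildings intersecting the cell — with sample counts
proportional to each component's person-hours (20,000 samples per cell by
default).  Each ambient sample receives an additive mobile-phone (uplink)
draw for its population group; the per-sample decomposition into indoor,
outdoor and mobile parts is retained so source contribution shares can be
reported per percentile.  Pooled samples per tissue are summarized into
vigintiles (P5, P10, ..., P100), the 99th percentile, mean and SD.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dfield

import numpy as np
import pandas as pd
from shapely.geometry import mapping

from .scene import Grid

__all__ = [
    "ExposureComponent",
    "AggregatedCell",
    "PERCENTILE_LEVELS",
    "aggregate_cell",
    "contribution_curves",
    "write_maps",
]

#: Reported percentile levels: vigintiles plus the 99th percentile.
PERCENTILE_LEVELS = tuple(range(5, 101, 5)) + (99,)

SOURCE_CLASSES = ("indoor", "outdoor", "mobile")


@dataclass
class ExposureComponent:
    """One occupancy component of a cell.

    ``ambient`` maps source class ('indoor' and/or 'outdoor') to aligned
    sample pools (SAR, mW/kg) that add per sample — e.g. a building pool
    carries an 'indoor' part (in-room devices) and an 'outdoor' part (the
    penetrated outdoor field), so contribution shares attribute the
    penetrated exposure to its outdoor sources.  ``uplink`` is the group's
    mobile-phone pool, added to every drawn sample.  A plain array is
    accepted for single-class components via ``source_class``.
    """

    source_class: str | None
    group: str
    person_hours: float
    ambient: dict[str, np.ndarray] | np.ndarray
    uplink: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.ambient, dict):
            if self.source_class not in ("indoor", "outdoor"):
                raise ValueError(
                    "ambient source class must be indoor or outdoor"
                )
            self.ambient = {self.source_class: np.asarray(self.ambient)}
        if not self.ambient:
            raise ValueError("component needs at least one ambient pool")
        sizes = {len(v) for v in self.ambient.values()}
        if len(sizes) != 1:
            raise ValueError("ambient pools must be sample-aligned")
        for cls in self.ambient:
            if cls not in ("indoor", "outdoor"):
                raise ValueError(f"unknown ambient class {cls!r}")
        if self.person_hours < 0:
            raise ValueError("person-hours must be nonnegative")

    @property
    def pool_size(self) -> int:
        return len(next(iter(self.ambient.values())))


@dataclass
class AggregatedCell:
    """Per-tissue pooled SAR samples and summary statistics of one cell."""

    cell_id: int
    person_hours: float
    empty: bool = False
    percentiles: dict = dfield(default_factory=dict)  # tissue -> {level: value}
    mean: dict = dfield(default_factory=dict)
    sd: dict = dfield(default_factory=dict)
    samples: dict = dfield(default_factory=dict)  # tissue -> total samples
    parts: dict = dfield(default_factory=dict)  # tissue -> (n, 3) indoor/outdoor/mobile


def _apportion(n: int, weights: np.ndarray) -> np.ndarray:
    """Integer sample counts proportional to weights, summing to n."""
    w = np.asarray(weights, dtype=float)
    quota = n * w / w.sum()
    base = np.floor(quota).astype(int)
    short = n - base.sum()
    order = np.argsort(-(quota - base), kind="stable")
    base[order[:short]] += 1
    return base


def aggregate_cell(
    cell_id: int,
    components: dict[str, list[ExposureComponent]],
    n: int = 20_000,
    seed: int = 0,
) -> AggregatedCell:
    """Fuse a cell's exposure components into its percentile summary.

    ``components`` maps tissue -> list of :class:`ExposureComponent`.
    Sample counts are apportioned by person-hours; each drawn ambient
    sample gets an uplink draw added (mobile exposure is cumulative with
    ambient exposure).  A cell whose person-hours are all zero is flagged
    empty and carries no statistics.
    """
    tissues = sorted(components)
    out = AggregatedCell(cell_id, 0.0)
    ph_total = max(
        (sum(c.person_hours for c in components[t]) for t in tissues),
        default=0.0,
    )
    out.person_hours = float(ph_total)
    if ph_total <= 0:
        out.empty = True
        return out
    for t_i, tissue in enumerate(tissues):
        comps = [c for c in components[tissue] if c.person_hours > 0]
        counts = _apportion(n, np.array([c.person_hours for c in comps]))
        total = np.empty(n)
        parts = np.zeros((n, 3))  # indoor, outdoor, mobile
        pos = 0
        for k, (c, m) in enumerate(zip(comps, counts)):
            if m == 0:
                continue
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, 30, cell_id, t_i, k])
            )
            idx = rng.integers(0, c.pool_size, m)
            upl = (
                c.uplink[rng.integers(0, len(c.uplink), m)]
                if c.uplink is not None and len(c.uplink)
                else np.zeros(m)
            )
            sl = slice(pos, pos + m)
            amb_total = np.zeros(m)
            for cls, pool in c.ambient.items():
                part = pool[idx]
                amb_total += part
                parts[sl, SOURCE_CLASSES.index(cls)] += part
            total[sl] = amb_total + upl
            parts[sl, 2] = upl
            pos += m
        out.samples[tissue] = total
        out.parts[tissue] = parts
        out.percentiles[tissue] = {
            lv: float(np.percentile(total, lv)) for lv in PERCENTILE_LEVELS
        }
        out.mean[tissue] = float(total.mean())
        out.sd[tissue] = float(total.std())
    return out


def _shares_by_percentile(
    total: np.ndarray, parts: np.ndarray, weights: np.ndarray | None = None
) -> pd.DataFrame:
    """Source shares within each vigintile band of the total distribution."""
    order = np.argsort(total, kind="stable")
    total, parts = total[order], parts[order]
    w = np.ones(len(total)) if weights is None else weights[order]
    cw = np.cumsum(w) / w.sum()
    rows = []
    lo = 0.0
    for lv in range(5, 101, 5):
        m = (cw > lo / 100.0) & (cw <= lv / 100.0)
        if not m.any():
            continue
        denom = float((total[m] * w[m]).sum())
        for j, src in enumerate(SOURCE_CLASSES):
            share = float((parts[m, j] * w[m]).sum()) / denom if denom > 0 else 0.0
            rows.append((lv, src, share))
        lo = float(lv)
    return pd.DataFrame(rows, columns=["percentile", "source", "share"])


def contribution_curves(
    cells: list[AggregatedCell], method: str = "pool"
) -> pd.DataFrame:
    """District-wide source contribution shares per percentile and tissue.

    ``method='pool'`` pools all cells' samples weighted by cell
    person-hours before banding; ``method='cells'`` averages the per-cell
    share curves with person-hour weights instead.
    """
    live = [c for c in cells if not c.empty]
    if not live:
        return pd.DataFrame(columns=["tissue", "percentile", "source", "share"])
    tissues = sorted(live[0].samples)
    frames = []
    for tissue in tissues:
        if method == "pool":
            total = np.concatenate([c.samples[tissue] for c in live])
            parts = np.vstack([c.parts[tissue] for c in live])
            w = np.concatenate(
                [np.full(len(c.samples[tissue]), c.person_hours / len(c.samples[tissue]))
                 for c in live]
            )
            df = _shares_by_percentile(total, parts, w)
        elif method == "cells":
            per = [
                _shares_by_percentile(c.samples[tissue], c.parts[tissue])
                .assign(weight=c.person_hours)
                for c in live
            ]
            allc = pd.concat(per, ignore_index=True)
            allc["ws"] = allc["share"] * allc["weight"]
            g = allc.groupby(["percentile", "source"], as_index=False).sum(
                numeric_only=True
            )
            g["share"] = g["ws"] / g["weight"]
            df = g[["percentile", "source", "share"]]
        else:
            raise ValueError(f"unknown method {method!r}")
        df.insert(0, "tissue", tissue)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Map output

_NODATA = -9999.0


def _write_asc(path, grid: Grid, values: np.ndarray) -> None:
    """ESRI ASCII grid raster (plain text); rows from north to south."""
    arr = np.asarray(values, dtype=float).reshape(grid.ny, grid.nx)
    with open(path, "w") as f:
        f.write(f"ncols {grid.nx}\n")
        f.write(f"nrows {grid.ny}\n")
        f.write(f"xllcorner {grid.x0:.6f}\n")
        f.write(f"yllcorner {grid.y0:.6f}\n")
        f.write(f"cellsize {grid.cell_size:.6f}\n")
        f.write(f"NODATA_value {_NODATA:.1f}\n")
        for row in arr[::-1]:
            f.write(
                " ".join(
                    f"{_NODATA:.1f}" if np.isnan(v) else f"{v:.8g}" for v in row
                )
                + "\n"
            )


def write_maps(cells: list[AggregatedCell], grid: Grid, outdir) -> list[str]:
    """Write rasters, the per-cell percentile table and contribution CSV.

    One ASCII-grid raster per (tissue, statistic in {P50, mean, SD}) with
    empty cells as no-data, a GeoJSON feature collection carrying the full
    percentile tables, and the district contribution curves as CSV.
    Returns the list of files written.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    by_id = {c.cell_id: c for c in cells}
    tissues = sorted(
        {t for c in cells if not c.empty for t in c.percentiles}
    )
    written = []
    for tissue in tissues:
        for stat in ("p50", "mean", "sd"):
            vals = np.full(grid.n_cells, np.nan)
            for cid in range(grid.n_cells):
                c = by_id.get(cid)
                if c is None or c.empty:
                    continue
                if stat == "p50":
                    vals[cid] = c.percentiles[tissue][50]
                elif stat == "mean":
                    vals[cid] = c.mean[tissue]
                else:
                    vals[cid] = c.sd[tissue]
            path = os.path.join(outdir, f"sar_{tissue}_{stat}.asc")
            _write_asc(path, grid, vals)
            written.append(path)

    features = []
    for cid in range(grid.n_cells):
        c = by_id.get(cid)
        props = {"cell_id": cid}
        if c is not None and not c.empty:
            props["person_hours"] = round(c.person_hours, 6)
            for tissue in tissues:
                for lv in PERCENTILE_LEVELS:
                    props[f"{tissue}_p{lv}"] = float(c.percentiles[tissue][lv])
                props[f"{tissue}_mean"] = c.mean[tissue]
                props[f"{tissue}_sd"] = c.sd[tissue]
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(grid.cell_polygon(cid)),
                "properties": props,
            }
        )
    gj = os.path.join(outdir, "cells.geojson")
    with open(gj, "w") as f:
        json.dump({"type": "FeatureCollection", "features": features}, f,
                  sort_keys=True)
    written.append(gj)

    contrib = contribution_curves(cells)
    csv_path = os.path.join(outdir, "contributions.csv")
    contrib.to_csv(csv_path, index=False, float_format="%.8g")
    written.append(csv_path)
    return written
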