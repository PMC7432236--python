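"""Plain-text I/O: CSV measurement tables, GeoJSON geometry tables, YAML
scene manifests.  All writers are deterministic (sorted keys, fixed float
formats) so a fixed seed reproduces every artifact byte for byte."""

from __future__ import annotations

import json
import os

import pandas as pd
import yaml
from shapely.geometry import mapping, shape

from .scene import Scene, SceneConfig

__all__ = [
    "write_geojson",
    "read_geojson",
    "write_scene",
    "read_scene",
]


def write_geojson(df: pd.DataFrame, path) -> None:
    """Write a frame with a shapely ``geometry`` column as GeoJSON."""
    features = []
    for _, row in df.iterrows():
        props = {
            k: (v.item() if hasattr(v, "item") else v)
            for k, v in row.items()
            if k != "geometry"
        }
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(row["geometry"]),
                "properties": props,
            }
        )
    with open(path, "w") as f:
        json.dump({"type": "FeatureCollection", "features": features}, f,
                  sort_keys=True)


def read_geojson(path) -> pd.DataFrame:
    """Read a GeoJSON feature collection into a frame with shapely geometry."""
    with open(path) as f:
        gj = json.load(f)
    rows = []
    for feat in gj["features"]:
        props = dict(feat.get("properties") or {})
        props["geometry"] = shape(feat["geometry"])
        rows.append(props)
    return pd.DataFrame(rows)


def write_scene(
    scene: Scene,
    outdir,
    measurements: pd.DataFrame | None = None,
    sensors: pd.DataFrame | None = None,
) -> None:
    """Write a scene (manifest, zones, buildings, optional data tables)."""
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "scene.yml"), "w") as f:
        yaml.safe_dump(scene.config.to_dict(), f, sort_keys=True)
    write_geojson(scene.zones, os.path.join(outdir, "zones.geojson"))
    write_geojson(scene.buildings, os.path.join(outdir, "buildings.geojson"))
    if measurements is not None:
        measurements.to_csv(
            os.path.join(outdir, "measurements.csv"), index=False,
            float_format="%.10g",
        )
    if sensors is not None:
        sensors.to_csv(
            os.path.join(outdir, "sensors.csv"), index=False,
            float_format="%.10g",
        )


def read_scene(outdir) -> Scene:
    """Rebuild a scene from a directory written by :func:`write_scene`."""
    from .scene import Grid

    with open(os.path.join(outdir, "scene.yml")) as f:
        config = SceneConfig.from_dict(yaml.safe_load(f))
    zones = read_geojson(os.path.join(outdir, "zones.geojson"))
    buildings = read_geojson(os.path.join(outdir, "buildings.geojson"))
    return Scene(config, Grid.from_config(config), zones, buildings)
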