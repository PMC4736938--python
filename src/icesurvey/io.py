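"""Serialization of scenario objects to plain-text formats.

Grids and flight tracks go to GeoJSON (planar km coordinates; the CRS is
declared in metadata as a local planar frame), density surfaces and
count/effort tables to CSV keyed by unit_id, and configurations to YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .scenario import FlightDesign, SurveyGrid

__all__ = [
    "grid_to_geojson",
    "design_to_geojson",
    "density_to_csv",
    "density_from_csv",
    "effort_to_csv",
    "effort_from_csv",
    "counts_to_csv",
    "counts_from_csv",
    "summary_to_json",
    "save_config",
    "load_config",
]

_CRS_NOTE = "local planar grid, kilometres; origin at the southwest corner"


def grid_to_geojson(grid: SurveyGrid, path: str | Path) -> None:
    """Write survey units as GeoJSON polygons with unit attributes."""
    s = grid.cell_size
    features = []
    for j in range(grid.n_units):
        x0, y0 = float(grid.col[j] * s), float(grid.row[j] * s)
        ring = [
            [x0, y0], [x0 + s, y0], [x0 + s, y0 + s], [x0, y0 + s], [x0, y0],
        ]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {
                    "unit_id": int(grid.unit_id[j]),
                    "R": float(grid.R[j]),
                    "stratum": str(grid.stratum[j]),
                    "dist_land": float(grid.dist_land[j]),
                },
            }
        )
    obj = {
        "type": "FeatureCollection",
        "metadata": {"crs_note": _CRS_NOTE, "cell_area_km2": grid.cell_area},
        "features": features,
    }
    Path(path).write_text(json.dumps(obj))


def design_to_geojson(design: FlightDesign, path: str | Path) -> None:
    """Write flight tracks as GeoJSON line strings."""
    features = [
        {
            "type": "Feature",
            "geometry": {
                "type": "LineString",
                "coordinates": [[float(x), float(y)] for x, y in track],
            },
            "properties": {"flight": i + 1, "design_id": design.design_id},
        }
        for i, track in enumerate(design.tracks)
    ]
    obj = {
        "type": "FeatureCollection",
        "metadata": {
            "crs_note": _CRS_NOTE,
            "thermal_swath_km": design.thermal_swath,
            "photo_fraction": design.photo_fraction,
        },
        "features": features,
    }
    Path(path).write_text(json.dumps(obj))


def density_to_csv(grid: SurveyGrid, d: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"unit_id": grid.unit_id, "d": d}).to_csv(path, index=False)


def density_from_csv(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path).sort_values("unit_id")
    return df["d"].to_numpy()


def effort_to_csv(grid: SurveyGrid, effort, path: str | Path) -> None:
    pd.DataFrame(
        {"unit_id": grid.unit_id, "A": effort.A, "track_km": effort.track_km}
    ).to_csv(path, index=False)


def counts_to_csv(grid: SurveyGrid, counts, path: str | Path) -> None:
    surveyed = counts.surveyed
    pd.DataFrame(
        {"unit_id": grid.unit_id[surveyed], "C": counts.C[surveyed]}
    ).to_csv(path, index=False)


def effort_from_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path).sort_values("unit_id").reset_index(drop=True)


def counts_from_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path).sort_values("unit_id").reset_index(drop=True)


def summary_to_json(summary, path: str | Path) -> None:
    """Write a fitted model's posterior summary (point estimate, SE, CV,
    interval, acceptance rates, instability count) as JSON."""
    Path(path).write_text(json.dumps(summary.to_dict(), indent=2))


def save_config(config: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=False))


def load_config(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
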