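"""Data model and I/O for spatial units, panel observations and individual records.

The central container is :class:`PanelTable`: a set of spatial units (with
centroids and optional polygons, WGS84 lon/lat) plus one row per (unit, year)
holding a prevalence fraction ``y`` and named covariates.  Individual-level
records carry 14 binary chronic-condition flags; ``aggregate_prevalence``
collapses them to comorbidity prevalence — the fraction of persons at or above
a minimum age with two or more conditions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import shape as _shapely_shape

from .errors import DomainError, SchemaError

logger = logging.getLogger(__name__)

N_CONDITIONS = 14
DEFAULT_MIN_AGE = 45


@dataclass(frozen=True)
class SpatialUnit:
    """A spatial analysis unit (province-like) with a WGS84 centroid."""

    unit_id: str
    name: str
    centroid_lon: float
    centroid_lat: float
    polygon: list[list[tuple[float, float]]] | None = None

    def __post_init__(self) -> None:
        if not -180.0 <= self.centroid_lon <= 180.0:
            raise DomainError(f"unit {self.unit_id!r}: lon {self.centroid_lon} outside [-180, 180]")
        if not -90.0 <= self.centroid_lat <= 90.0:
            raise DomainError(f"unit {self.unit_id!r}: lat {self.centroid_lat} outside [-90, 90]")
        if self.polygon is not None:
            for ring in self.polygon:
                if len(ring) < 4 or tuple(ring[0]) != tuple(ring[-1]):
                    raise DomainError(f"unit {self.unit_id!r}: polygon ring not closed")


@dataclass(frozen=True)
class PanelObservation:
    """One (unit, year) row: prevalence fraction plus named covariates."""

    unit_id: str
    year: int
    y: float
    covariates: dict[str, float]

    def __post_init__(self) -> None:
        if not 0.0 <= self.y <= 1.0:
            raise DomainError(f"({self.unit_id}, {self.year}): y={self.y} outside [0, 1]")
        for k, v in self.covariates.items():
            if not np.isfinite(v):
                raise DomainError(f"({self.unit_id}, {self.year}): covariate {k!r} not finite")


@dataclass
class PanelTable:
    """Spatial units plus panel observations with an ordered covariate list."""

    units: list[SpatialUnit]
    observations: list[PanelObservation]
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [u.unit_id for u in self.units]
        if len(set(ids)) != len(ids):
            raise SchemaError("duplicate unit_id among units")
        known = set(ids)
        seen: set[tuple[str, int]] = set()
        for obs in self.observations:
            if obs.unit_id not in known:
                raise SchemaError(f"observation references unknown unit {obs.unit_id!r}")
            key = (obs.unit_id, obs.year)
            if key in seen:
                raise SchemaError(f"duplicate observation for {key}")
            seen.add(key)

    @property
    def years(self) -> list[int]:
        return sorted({o.year for o in self.observations})

    @property
    def is_balanced(self) -> bool:
        by_unit: dict[str, set[int]] = {}
        for o in self.observations:
            by_unit.setdefault(o.unit_id, set()).add(o.year)
        year_sets = list(by_unit.values())
        return all(s == year_sets[0] for s in year_sets)

    def unit(self, unit_id: str) -> SpatialUnit:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(unit_id)

    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame: unit_id, year, y, covariates (spec order)."""
        rows = [
            {"unit_id": o.unit_id, "year": o.year, "y": o.y, **o.covariates}
            for o in self.observations
        ]
        cols = ["unit_id", "year", "y", *self.covariate_names]
        return pd.DataFrame(rows, columns=cols)


@dataclass(frozen=True)
class IndividualRecord:
    """One survey respondent: spatial unit, year, age, 14 condition flags."""

    unit_id: str
    year: int
    conditions: tuple[int, ...]
    age: float

    def __post_init__(self) -> None:
        if len(self.conditions) != N_CONDITIONS:
            raise DomainError(f"expected {N_CONDITIONS} condition flags, got {len(self.conditions)}")
        if any(c not in (0, 1) for c in self.conditions):
            raise DomainError("condition flags must be 0/1")
        if self.age < 0:
            raise DomainError(f"age {self.age} < 0")

    @property
    def n_conditions(self) -> int:
        return int(sum(self.conditions))


def _polygon_rings(geom) -> list[list[tuple[float, float]]]:
    """Exterior + interior rings of a shapely (Multi)Polygon as lon/lat lists."""
    polys = list(geom.geoms) if geom.geom_type == "MultiPolygon" else [geom]
    rings = []
    for poly in polys:
        rings.append([(float(x), float(y)) for x, y in poly.exterior.coords])
        for interior in poly.interiors:
            rings.append([(float(x), float(y)) for x, y in interior.coords])
    return rings


def read_units_geojson(path: str | Path) -> list[SpatialUnit]:
    """Read spatial units from a GeoJSON FeatureCollection.

    Each feature needs properties ``unit_id`` and ``name`` and a Point,
    Polygon or MultiPolygon geometry.  Polygonal geometry yields an
    area-weighted centroid; units are returned sorted by ``unit_id`` so
    repeated reads are deterministic.
    """
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise SchemaError(f"{path}: not a GeoJSON FeatureCollection")
    units: list[SpatialUnit] = []
    seen: set[str] = set()
    for feat in doc.get("features", []):
        props = feat.get("properties") or {}
        if "unit_id" not in props:
            raise SchemaError(f"{path}: feature missing 'unit_id' property")
        uid = str(props["unit_id"])
        if uid in seen:
            raise SchemaError(f"{path}: duplicate unit_id {uid!r}")
        seen.add(uid)
        geom = _shapely_shape(feat["geometry"])
        if geom.geom_type == "Point":
            lon, lat = geom.x, geom.y
            poly = None
        elif geom.geom_type in ("Polygon", "MultiPolygon"):
            c = geom.centroid
            lon, lat = c.x, c.y
            poly = _polygon_rings(geom)
        else:
            raise SchemaError(f"{path}: unsupported geometry {geom.geom_type} for {uid!r}")
        units.append(
            SpatialUnit(
                unit_id=uid,
                name=str(props.get("name", uid)),
                centroid_lon=float(lon),
                centroid_lat=float(lat),
                polygon=poly,
            )
        )
    units.sort(key=lambda u: u.unit_id)
    return units


def write_units_geojson(units: Sequence[SpatialUnit], path: str | Path) -> None:
    """Write units as a GeoJSON FeatureCollection (Polygon if available, else Point)."""
    features = []
    for u in sorted(units, key=lambda u: u.unit_id):
        if u.polygon is not None:
            geometry = {
                "type": "Polygon",
                "coordinates": [[list(pt) for pt in ring] for ring in u.polygon],
            }
        else:
            geometry = {"type": "Point", "coordinates": [u.centroid_lon, u.centroid_lat]}
        features.append(
            {
                "type": "Feature",
                "properties": {"unit_id": u.unit_id, "name": u.name},
                "geometry": geometry,
            }
        )
    doc = {"type": "FeatureCollection", "features": features}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, sort_keys=True, separators=(",", ":"))
        fh.write("\n")


def read_panel_csv(path: str | Path, covariate_names: Sequence[str] | None = None) -> tuple[list[PanelObservation], list[str]]:
    """Read panel observations from CSV with columns unit_id, year, y, <covariates>.

    Returns (observations, covariate_names).  Parsing is strict: any
    non-numeric cell raises a :class:`SchemaError` naming the row and column,
    and y outside [0, 1] raises :class:`DomainError`.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["unit_id", "year", "y"]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    if covariate_names is None:
        covariate_names = [c for c in df.columns if c not in required]
    else:
        missing = [c for c in covariate_names if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing covariate columns {missing}")
    covariate_names = list(covariate_names)

    def _num(row_idx: int, col: str, raw: str) -> float:
        try:
            return float(raw)
        except ValueError:
            raise SchemaError(f"{path}: non-numeric value {raw!r} at row {row_idx + 2}, column {col!r}") from None

    observations = []
    for i, row in enumerate(df.itertuples(index=False)):
        rec = dict(zip(df.columns, row))
        year_f = _num(i, "year", rec["year"])
        if year_f != int(year_f):
            raise SchemaError(f"{path}: non-integer year {rec['year']!r} at row {i + 2}")
        observations.append(
            PanelObservation(
                unit_id=str(rec["unit_id"]),
                year=int(year_f),
                y=_num(i, "y", rec["y"]),
                covariates={c: _num(i, c, rec[c]) for c in covariate_names},
            )
        )
    return observations, covariate_names


def write_panel_csv(observations: Sequence[PanelObservation], covariate_names: Sequence[str], path: str | Path) -> None:
    """Write observations to CSV; floats use repr (shortest round-trip) formatting."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(["unit_id", "year", "y", *covariate_names]) + "\n")
        for o in observations:
            vals = [o.unit_id, str(o.year), repr(float(o.y))]
            vals += [repr(float(o.covariates[c])) for c in covariate_names]
            fh.write(",".join(vals) + "\n")


def aggregate_prevalence(
    records: Iterable[IndividualRecord],
    min_age: float = DEFAULT_MIN_AGE,
    min_conditions: int = 2,
) -> list[PanelObservation]:
    """Aggregate individual records to comorbidity prevalence per (unit, year).

    y(unit, year) = #{age >= min_age and >= min_conditions conditions} /
    #{age >= min_age}.  Unit-years with no age-eligible records are omitted
    with a logged warning; record order does not affect the result.
    """
    eligible: dict[tuple[str, int], int] = {}
    comorbid: dict[tuple[str, int], int] = {}
    all_keys: set[tuple[str, int]] = set()
    for rec in records:
        key = (rec.unit_id, rec.year)
        all_keys.add(key)
        if rec.age >= min_age:
            eligible[key] = eligible.get(key, 0) + 1
            if rec.n_conditions >= min_conditions:
                comorbid[key] = comorbid.get(key, 0) + 1
    dropped = sorted(all_keys - set(eligible))
    if dropped:
        logger.warning("dropping %d unit-years with no age-eligible records: %s", len(dropped), dropped)
    return [
        PanelObservation(unit_id=uid, year=year, y=comorbid.get((uid, year), 0) / eligible[(uid, year)], covariates={})
        for uid, year in sorted(eligible)
    ]
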