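"""Spatial weight matrices: contiguity, k-nearest-neighbour and inverse distance.

Weights are dense n×n arrays (n is at most a few hundred administrative
units).  Queen contiguity links polygons sharing at least one boundary
point, rook requires a shared boundary segment of positive length.  All
centroid-based schemes use great-circle (haversine) distances with Earth
radius 6371 km.  ``row_standardize`` rescales each nonempty row to sum to 1;
islands (zero-neighbour units) pass through with a logged warning.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .errors import ConfigurationError, DegenerateGeometryError, ParameterError
from .panel import SpatialUnit

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0


@dataclass
class WeightMatrix:
    """An n×n nonnegative spatial weight matrix aligned to ``unit_ids``."""

    unit_ids: list[str]
    w: np.ndarray
    scheme: str
    standardized: bool = False

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        n = len(self.unit_ids)
        if self.w.shape != (n, n):
            raise ParameterError(f"weight matrix shape {self.w.shape} != ({n}, {n})")
        if np.any(self.w < 0):
            raise ParameterError("negative weights are not allowed")
        if np.any(np.diag(self.w) != 0):
            raise ParameterError("weight matrix diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.unit_ids)

    @property
    def S0(self) -> float:
        """Sum of all weights."""
        return float(self.w.sum())

    @property
    def islands(self) -> list[str]:
        """Units with no neighbours (all-zero row)."""
        return [uid for uid, row in zip(self.unit_ids, self.w) if not row.any()]

    def neighbors(self, unit_id: str) -> list[str]:
        i = self.unit_ids.index(unit_id)
        return [self.unit_ids[j] for j in np.flatnonzero(self.w[i])]


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km between points given in decimal degrees."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def pairwise_haversine_km(units: Sequence[SpatialUnit]) -> np.ndarray:
    lon = np.array([u.centroid_lon for u in units])
    lat = np.array([u.centroid_lat for u in units])
    return haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])


def _unit_geometry(unit: SpatialUnit):
    if unit.polygon is None:
        raise ConfigurationError(f"unit {unit.unit_id!r} has no polygon; contiguity needs polygons")
    return unary_union([Polygon(ring) for ring in unit.polygon])


def queen_contiguity(units: Sequence[SpatialUnit], rook: bool = False) -> WeightMatrix:
    """Binary contiguity weights from polygons.

    Queen: any shared boundary point (corner contact counts).  ``rook=True``
    requires a shared boundary segment of positive length.
    """
    geoms = [_unit_geometry(u) for u in units]
    n = len(units)
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            inter = geoms[i].boundary.intersection(geoms[j].boundary)
            if inter.is_empty:
                continue
            if rook and inter.length <= 0:
                continue
            w[i, j] = w[j, i] = 1.0
    wm = WeightMatrix([u.unit_id for u in units], w, scheme="rook" if rook else "queen")
    if wm.islands:
        logger.warning("contiguity islands (no neighbours): %s", wm.islands)
    return wm


def knn_weights(units: Sequence[SpatialUnit], k: int) -> WeightMatrix:
    """Binary k-nearest-neighbour weights on haversine centroid distance.

    Generally asymmetric; exact distance ties are broken by ascending
    unit_id so construction is deterministic.
    """
    n = len(units)
    if not 1 <= k <= n - 1:
        raise ParameterError(f"k={k} must satisfy 1 <= k <= n-1={n - 1}")
    d = pairwise_haversine_km(units)
    ids = [u.unit_id for u in units]
    # tie-break: sort candidates by (distance, unit_id)
    id_rank = np.argsort(np.argsort(ids))
    w = np.zeros((n, n))
    for i in range(n):
        order = sorted((j for j in range(n) if j != i), key=lambda j: (d[i, j], id_rank[j]))
        w[i, order[:k]] = 1.0
    return WeightMatrix(ids, w, scheme="knn")


def inverse_distance_weights(
    units: Sequence[SpatialUnit], power: float = 1.0, cutoff_km: float | None = None
) -> WeightMatrix:
    """w_ij = d_ij^(-power) for haversine distance within the cutoff, else 0."""
    if power <= 0:
        raise ParameterError(f"power must be > 0, got {power}")
    if cutoff_km is not None and cutoff_km <= 0:
        raise ParameterError(f"cutoff_km must be > 0, got {cutoff_km}")
    d = pairwise_haversine_km(units)
    off = ~np.eye(len(units), dtype=bool)
    if np.any(d[off] == 0):
        raise DegenerateGeometryError("coincident centroids give infinite inverse-distance weight")
    w = np.zeros_like(d)
    w[off] = d[off] ** (-power)
    if cutoff_km is not None:
        w[d > cutoff_km] = 0.0
    wm = WeightMatrix([u.unit_id for u in units], w, scheme="inverse_distance")
    if wm.islands:
        logger.warning("inverse-distance islands under cutoff %s km: %s", cutoff_km, wm.islands)
    return wm


def fixed_band_weights(units: Sequence[SpatialUnit], band_km: float) -> WeightMatrix:
    """Binary weights for all pairs within a fixed haversine distance band."""
    if band_km <= 0:
        raise ParameterError(f"band_km must be > 0, got {band_km}")
    d = pairwise_haversine_km(units)
    w = ((d <= band_km) & ~np.eye(len(units), dtype=bool)).astype(float)
    wm = WeightMatrix([u.unit_id for u in units], w, scheme="fixed_band")
    if wm.islands:
        logger.warning("fixed-band islands at %s km: %s", band_km, wm.islands)
    return wm


def row_standardize(wm: WeightMatrix) -> WeightMatrix:
    """Divide each nonempty row by its sum (idempotent); islands pass through."""
    sums = wm.w.sum(axis=1, keepdims=True)
    zero = sums[:, 0] == 0
    if zero.any():
        logger.warning("row-standardizing with %d island rows", int(zero.sum()))
    safe = np.where(sums == 0, 1.0, sums)
    return replace(wm, w=wm.w / safe, standardized=True)


def default_weights(units: Sequence[SpatialUnit], k_fallback: int = 4) -> WeightMatrix:
    """Queen contiguity when all units have polygons, else knn(k=4)."""
    if all(u.polygon is not None for u in units):
        return queen_contiguity(units)
    return knn_weights(units, min(k_fallback, len(units) - 1))


def write_weights_csv(wm: WeightMatrix, path: str | Path) -> None:
    """Export as a 3-column edge list (i, j, w) plus a JSON sidecar."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("i,j,w\n")
        for i, uid in enumerate(wm.unit_ids):
            for j in np.flatnonzero(wm.w[i]):
                fh.write(f"{uid},{wm.unit_ids[j]},{float(wm.w[i, j])!r}\n")
    sidecar = {"scheme": wm.scheme, "standardized": wm.standardized, "unit_ids": wm.unit_ids}
    with open(path.with_suffix(".json"), "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, sort_keys=True, separators=(",", ":"))
        fh.write("\n")


def read_weights_csv(path: str | Path) -> WeightMatrix:
    """Read an edge-list export written by :func:`write_weights_csv`."""
    path = Path(path)
    with open(path.with_suffix(".json"), encoding="utf-8") as fh:
        sidecar = json.load(fh)
    ids = list(sidecar["unit_ids"])
    index = {uid: i for i, uid in enumerate(ids)}
    w = np.zeros((len(ids), len(ids)))
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if header.strip() != "i,j,w":
            raise ConfigurationError(f"{path}: unexpected header {header!r}")
        for line in fh:
            a, b, val = line.rstrip("\n").split(",")
            w[index[a], index[b]] = float(val)
    return WeightMatrix(ids, w, scheme=sidecar["scheme"], standardized=sidecar["standardized"])
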