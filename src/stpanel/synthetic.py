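"""Synthetic spatial panels with known ground truth.

Every pipeline stage can be exercised without restricted survey microdata:
this module generates

* lattice study areas of square "province" polygons,
* spatially autocorrelated attribute fields via a simultaneous
  autoregressive (SAR) process x = (I − ρW)⁻¹ε,
* balanced panels whose outcome follows a varying-coefficient process with
  a known exposure-coefficient surface β_pm25(u, v, t), and
* individual-level records whose chronic-condition counts aggregate back to
  a prescribed comorbidity prevalence.

The reference process emulates the geometry of a national provincial panel:
30 units (a 10×3 east-west-elongated lattice) observed at 4 survey waves
with 7 regressors.  The exposure is an annual-mean PM2.5 concentration
(µg/m³) with a smooth north-south gradient, a slow secular decline and a
large province-level idiosyncratic component; its coefficient on prevalence
rises from west to east and grows over time, so the effect surface is
recoverable by a space-time varying-coefficient model but invisible to a
global fit.  Placing the exposure's spatial pattern and the coefficient
gradient on orthogonal axes keeps the surface identifiable: if both ran
west-east, the within-window coefficient gradient would be absorbed into
the local exposure slope.  All generators are pure functions of
(spec, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .autocorr import AttributeField
from .errors import ParameterError
from .panel import (
    IndividualRecord,
    PanelObservation,
    PanelTable,
    SpatialUnit,
    write_panel_csv,
    write_units_geojson,
)
from .weights import WeightMatrix

logger = logging.getLogger(__name__)

REFERENCE_SEED = 20240222
REFERENCE_YEARS = (2011, 2013, 2015, 2018)
CONTROL_NAMES = ("area", "pop_density", "dependency_ratio", "hospitals",
                 "primary_care", "public_health")

# lattice anchor: roughly central-China lon/lat so projected distances are
# realistic for a provincial study area
_LAT0 = 30.0
_LON0 = 100.0
_KM_PER_DEG_LAT = 111.19492664455873  # 6371 km * pi/180


def gen_lattice_units(nx: int = 10, ny: int = 3, cell_km: float = 300.0) -> list[SpatialUnit]:
    """A ny×nx lattice of square units with ids ``r{row}c{col}``.

    Cells are ``cell_km`` across (converted to degrees about a mid-latitude
    anchor); centroids sit at cell centers.  Ordering is row-major and
    deterministic.
    """
    if nx <= 0 or ny <= 0:
        raise ParameterError("lattice dimensions must be positive")
    if nx * ny < 4:
        raise ParameterError("need at least 4 units (nx*ny >= 4)")
    dlat = cell_km / _KM_PER_DEG_LAT
    dlon = cell_km / (_KM_PER_DEG_LAT * np.cos(np.radians(_LAT0)))
    # shared grid lines so adjacent cells have bit-identical boundary coords
    lons = _LON0 + np.arange(nx + 1) * dlon
    lats = _LAT0 + np.arange(ny + 1) * dlat
    units = []
    for r in range(ny):
        for c in range(nx):
            x0, x1 = lons[c], lons[c + 1]
            y0, y1 = lats[r], lats[r + 1]
            ring = [(x0, y0), (x1, y0), (x1, y1), (x0, y1), (x0, y0)]
            units.append(
                SpatialUnit(
                    unit_id=f"r{r}c{c}",
                    name=f"Unit r{r}c{c}",
                    centroid_lon=(x0 + x1) / 2,
                    centroid_lat=(y0 + y1) / 2,
                    polygon=[ring],
                )
            )
    return units


def gen_sar_field(wm: WeightMatrix, rho: float, sigma: float = 1.0,
                  seed: int | None = None) -> AttributeField:
    """Simultaneous autoregressive Gaussian field x = (I − ρW)⁻¹ε.

    With row-standardized W and ρ ∈ (−1, 1) the system is nonsingular; ρ=0
    gives an i.i.d. field and increasing ρ increasingly positive spatial
    autocorrelation.
    """
    if not -1.0 < rho < 1.0:
        raise ParameterError(f"rho must be in (-1, 1), got {rho}")
    n = wm.n
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, sigma, n)
    A = np.eye(n) - rho * wm.w
    if abs(np.linalg.det(A)) < 1e-12:
        raise ParameterError(f"(I - rho W) is singular for rho={rho}")
    return AttributeField(list(wm.unit_ids), np.linalg.solve(A, eps))


@dataclass
class TruthSpec:
    """Closed-form specification of the generating coefficient surfaces.

    The exposure coefficient is
    ``β_pm25(ū, t) = scale · (base + spatial_amp·ū + temporal_amp·(t − t0))``
    where ū ∈ [0, 1] is the normalised west-east coordinate.  ``scale``
    converts the surface to per-(µg/m³) units so that prevalence stays in
    (0, 1).  Controls carry constant small coefficients.
    """

    beta0: float = 0.1
    base: float = 0.1
    spatial_amp: float = 0.4
    temporal_amp: float = 0.03
    scale: float = 0.01
    control_coef: float = 0.01
    noise_sigma: float = 0.018  # ≈ binomial SE of a ~700-respondent prevalence
    pm25_base: float = 50.0
    pm25_spatial_amp: float = 20.0  # north-south smooth gradient
    pm25_drift: float = -1.0  # µg/m³ per year, secular decline
    pm25_noise_sd: float = 18.0  # province-year idiosyncratic variation

    def beta_pm25(self, u_norm: np.ndarray, t: np.ndarray, t0: float) -> np.ndarray:
        return self.scale * (self.base + self.spatial_amp * np.asarray(u_norm)
                             + self.temporal_amp * (np.asarray(t) - t0))


def constant_truth_spec(**kw) -> TruthSpec:
    """Spatially and temporally constant exposure coefficient."""
    return TruthSpec(spatial_amp=0.0, temporal_amp=0.0, base=0.25, **kw)


def temporal_truth_spec(**kw) -> TruthSpec:
    """Purely temporal coefficient drift (no spatial variation)."""
    return TruthSpec(spatial_amp=0.0, temporal_amp=0.08, **kw)


@dataclass
class SyntheticTruth:
    """Generating surfaces evaluated at each observation, plus noise/seed."""

    spec: TruthSpec
    seed: int
    obs_keys: list[tuple[str, int]]
    beta0: np.ndarray
    beta: dict[str, np.ndarray]  # per-covariate generating coefficients
    noise_sigma: float
    u_norm: np.ndarray
    t0: float

    def reevaluate_beta_pm25(self) -> np.ndarray:
        """Re-evaluate the closed-form exposure surface (round-trip check)."""
        t = np.array([year for _, year in self.obs_keys], dtype=float)
        return self.spec.beta_pm25(self.u_norm, t, self.t0)

    def to_json_dict(self) -> dict:
        return {
            "spec": asdict(self.spec),
            "seed": self.seed,
            "obs_keys": [[u, y] for u, y in self.obs_keys],
            "beta0": self.beta0.tolist(),
            "beta": {k: v.tolist() for k, v in self.beta.items()},
            "noise_sigma": self.noise_sigma,
            "u_norm": self.u_norm.tolist(),
            "t0": self.t0,
        }


@dataclass
class SyntheticDataset:
    units: list[SpatialUnit]
    panel: PanelTable
    truth: SyntheticTruth

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write units (GeoJSON), panel (CSV) and truth (JSON) to a directory."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "units": out / "units.geojson",
            "panel": out / "panel.csv",
            "truth": out / "truth.json",
        }
        write_units_geojson(self.units, paths["units"])
        write_panel_csv(self.panel.observations, self.panel.covariate_names, paths["panel"])
        with open(paths["truth"], "w", encoding="utf-8") as fh:
            json.dump(self.truth.to_json_dict(), fh, sort_keys=True, separators=(",", ":"))
            fh.write("\n")
        return paths


def _norm01(vals: np.ndarray) -> np.ndarray:
    span = vals.max() - vals.min()
    return (vals - vals.min()) / span if span > 0 else np.zeros(len(vals))


def _unit_axes_norm(units: Sequence[SpatialUnit]) -> tuple[np.ndarray, np.ndarray]:
    """Normalised west-east (ū) and south-north (v̄) positions in [0, 1]."""
    lon = np.array([u.centroid_lon for u in units])
    lat = np.array([u.centroid_lat for u in units])
    return _norm01(lon), _norm01(lat)


def gen_varying_coefficient_panel(
    units: Sequence[SpatialUnit] | None = None,
    years: Sequence[int] = REFERENCE_YEARS,
    truth_spec: TruthSpec | None = None,
    seed: int = REFERENCE_SEED,
) -> SyntheticDataset:
    """Generate a balanced panel from the varying-coefficient process.

    y_it = β0 + β_pm25(ū_i, t)·pm25_it + Σ_c β_c·c_it + ε_it, ε ~ N(0, σ²),
    with pm25_it = pm25_base + pm25_spatial_amp·sin(π·v̄_i) + drift·(t − t0)
    + N(0, pm25_noise_sd²) and standard-normal controls.  y is clipped to
    [0.01, 0.99]; a clip rate above 20% logs a warning advising smaller
    effects.  The generating coefficients are recorded per observation.
    """
    if units is None:
        units = gen_lattice_units()
    years = sorted(int(y) for y in years)
    if len(years) < 2:
        raise ParameterError("need >= 2 years for temporal variation")
    spec = truth_spec if truth_spec is not None else TruthSpec()
    rng = np.random.default_rng(seed)
    t0 = float(years[0])
    units = list(units)
    u_by_unit, v_by_unit = _unit_axes_norm(units)

    # observation order matches build_design: (year, unit_id)
    order = sorted(range(len(units)), key=lambda i: units[i].unit_id)
    obs_keys: list[tuple[str, int]] = []
    u_norm_list, v_norm_list, t_list = [], [], []
    for year in years:
        for i in order:
            obs_keys.append((units[i].unit_id, year))
            u_norm_list.append(u_by_unit[i])
            v_norm_list.append(v_by_unit[i])
            t_list.append(float(year))
    u_norm = np.array(u_norm_list)
    v_norm = np.array(v_norm_list)
    t = np.array(t_list)
    n = len(obs_keys)

    pm25 = (spec.pm25_base + spec.pm25_spatial_amp * np.sin(np.pi * v_norm)
            + spec.pm25_drift * (t - t0) + rng.normal(0.0, spec.pm25_noise_sd, n))
    controls = {name: rng.normal(0.0, 1.0, n) for name in CONTROL_NAMES}
    beta_pm25 = spec.beta_pm25(u_norm, t, t0)
    eps = rng.normal(0.0, spec.noise_sigma, n)
    lin = spec.beta0 + beta_pm25 * pm25 + sum(spec.control_coef * c for c in controls.values()) + eps
    y = np.clip(lin, 0.01, 0.99)
    n_clipped = int(np.sum(y != lin))
    if n_clipped:
        rate = n_clipped / n
        logger.log(
            logging.WARNING if rate > 0.2 else logging.INFO,
            "clipped %d/%d observations (%.1f%%)%s", n_clipped, n, 100 * rate,
            "; consider smaller effect sizes" if rate > 0.2 else "",
        )

    covariate_names = ["pm25", *CONTROL_NAMES]
    observations = []
    for idx, (uid, year) in enumerate(obs_keys):
        cov = {"pm25": float(pm25[idx])}
        cov.update({name: float(controls[name][idx]) for name in CONTROL_NAMES})
        observations.append(PanelObservation(unit_id=uid, year=year, y=float(y[idx]), covariates=cov))
    panel = PanelTable(units=list(units), observations=observations, covariate_names=covariate_names)
    beta = {"pm25": beta_pm25}
    beta.update({name: np.full(n, spec.control_coef) for name in CONTROL_NAMES})
    truth = SyntheticTruth(
        spec=spec, seed=seed, obs_keys=obs_keys, beta0=np.full(n, spec.beta0),
        beta=beta, noise_sigma=spec.noise_sigma, u_norm=u_norm, t0=t0,
    )
    return SyntheticDataset(units=list(units), panel=panel, truth=truth)


def gen_individual_records(
    observations: Sequence[PanelObservation],
    n_per_unit_year: int = 1000,
    seed: int | None = None,
) -> list[IndividualRecord]:
    """Individual records whose comorbidity prevalence matches each unit-year's y.

    Condition counts follow a zero-inflated mixture calibrated so that
    P(count ≥ 2) equals the target prevalence exactly: with probability y
    the count is 2 + Binomial(12, 0.25), otherwise 0 or 1 (P(1|<2) = 0.4).
    Ages are uniform on [45, 90].
    """
    if n_per_unit_year < 30:
        raise ParameterError(f"n_per_unit_year must be >= 30, got {n_per_unit_year}")
    rng = np.random.default_rng(seed)
    records: list[IndividualRecord] = []
    for obs in observations:
        if not 0.0 < obs.y < 1.0:
            raise ParameterError(
                f"target prevalence must be in (0, 1), got y={obs.y} for ({obs.unit_id}, {obs.year})"
            )
        comorbid = rng.random(n_per_unit_year) < obs.y
        counts = np.where(
            comorbid,
            2 + rng.binomial(12, 0.25, n_per_unit_year),
            (rng.random(n_per_unit_year) < 0.4).astype(int),
        )
        ages = rng.uniform(45.0, 90.0, n_per_unit_year)
        for c, age in zip(counts, ages):
            flags = np.zeros(14, dtype=int)
            if c > 0:
                flags[rng.choice(14, size=int(c), replace=False)] = 1
            records.append(
                IndividualRecord(unit_id=obs.unit_id, year=obs.year,
                                 conditions=tuple(int(f) for f in flags), age=float(age))
            )
    return records


def generate_reference_dataset(seed: int = REFERENCE_SEED) -> SyntheticDataset:
    """The frozen reference process: 10×3 lattice, 4 survey waves, default truth."""
    return gen_varying_coefficient_panel(
        units=gen_lattice_units(10, 3, cell_km=300.0),
        years=REFERENCE_YEARS,
        truth_spec=TruthSpec(),
        seed=seed,
    )
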