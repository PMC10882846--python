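"""End-to-end analysis pipeline behind a single validated YAML config.

Stages mirror the standard spatial-epidemiology workflow: descriptive
summaries per year, global and local spatial autocorrelation of prevalence,
a collinearity screen, the four-model regression comparison (OLS, GWR, TWR,
GTWR) and export of local exposure coefficients with significance flags.
Every numeric artifact is reproducible from the config and inputs alone;
reports carry a config hash and the seed so two runs with equal hashes are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .autocorr import AttributeField, general_g, gi_star, global_morans_i, local_morans
from .errors import ConfigurationError, ParameterError, SchemaError
from .panel import PanelTable, read_panel_csv, read_units_geojson
from .regression import build_design, collinearity_verdict, compare_models, fit_ols
from .weights import (
    WeightMatrix,
    fixed_band_weights,
    inverse_distance_weights,
    knn_weights,
    queen_contiguity,
    row_standardize,
)

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

_ALLOWED = {
    "": {"schema_version", "paths", "weights", "inference", "regression"},
    "paths": {"units", "panel", "out_dir"},
    "weights": {"scheme", "knn_k", "power", "cutoff_km", "band_km"},
    "inference": {"alpha", "n_perm", "seed"},
    "regression": {"kernel", "models", "tau_grid", "standardize", "alpha"},
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see ``_ALLOWED`` for the schema)."""

    units_path: str
    panel_path: str
    out_dir: str
    weights_scheme: str = "queen"
    knn_k: int = 4
    idw_power: float = 1.0
    cutoff_km: float | None = None
    band_km: float | None = None
    alpha: float = 0.05
    n_perm: int = 999
    seed: int = 0
    kernel: str = "gaussian"
    models: tuple[str, ...] = ("ols", "gwr", "twr", "gtwr")
    tau_grid: tuple[float, ...] | None = None
    standardize: bool = False
    raw: dict = field(default_factory=dict, repr=False)

    @property
    def hash(self) -> str:
        """Hash of the canonicalised raw config (provenance key)."""
        canon = json.dumps(self.raw, sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _reject_unknown(section: str, mapping: dict) -> None:
    unknown = set(mapping) - _ALLOWED[section]
    if unknown:
        where = section or "top level"
        raise SchemaError(f"unknown config keys at {where}: {sorted(unknown)}")


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline config; unknown keys are rejected."""
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    _reject_unknown("", doc)
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise SchemaError(f"{path}: schema_version must be {SCHEMA_VERSION}")
    paths = doc.get("paths") or {}
    _reject_unknown("paths", paths)
    for key in ("units", "panel", "out_dir"):
        if key not in paths:
            raise SchemaError(f"{path}: paths.{key} is required")
    weights = doc.get("weights") or {}
    _reject_unknown("weights", weights)
    inference = doc.get("inference") or {}
    _reject_unknown("inference", inference)
    regression = doc.get("regression") or {}
    _reject_unknown("regression", regression)
    base = Path(path).parent
    tau = regression.get("tau_grid")
    return PipelineConfig(
        units_path=str(base / paths["units"]),
        panel_path=str(base / paths["panel"]),
        out_dir=str(base / paths["out_dir"]),
        weights_scheme=weights.get("scheme", "queen"),
        knn_k=int(weights.get("knn_k", 4)),
        idw_power=float(weights.get("power", 1.0)),
        cutoff_km=weights.get("cutoff_km"),
        band_km=weights.get("band_km"),
        alpha=float(inference.get("alpha", 0.05)),
        n_perm=int(inference.get("n_perm", 999)),
        seed=int(inference.get("seed", 0)),
        kernel=regression.get("kernel", "gaussian"),
        models=tuple(regression.get("models", ["ols", "gwr", "twr", "gtwr"])),
        tau_grid=tuple(tau) if tau else None,
        standardize=bool(regression.get("standardize", False)),
        raw=doc,
    )


def build_weights(config: PipelineConfig, units) -> WeightMatrix:
    scheme = config.weights_scheme
    if scheme in ("queen", "rook"):
        return queen_contiguity(units, rook=scheme == "rook")
    if scheme == "knn":
        return knn_weights(units, config.knn_k)
    if scheme == "inverse_distance":
        return inverse_distance_weights(units, config.idw_power, config.cutoff_km)
    if scheme == "fixed_band":
        if config.band_km is None:
            raise ConfigurationError("weights.band_km required for fixed_band scheme")
        return fixed_band_weights(units, config.band_km)
    raise ConfigurationError(f"unknown weights scheme {scheme!r}")


def load_panel(config: PipelineConfig) -> PanelTable:
    units = read_units_geojson(config.units_path)
    observations, covariate_names = read_panel_csv(config.panel_path)
    return PanelTable(units=units, observations=observations, covariate_names=covariate_names)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, lineterminator="\n")


def _sig_marks(p: float) -> str:
    """Annotate significance at the 0.05 and 0.1 levels."""
    if p <= 0.05:
        return "significant at 0.05"
    if p <= 0.1:
        return "significant at 0.1"
    return ""


def run_describe(config: PipelineConfig, panel: PanelTable | None = None) -> pd.DataFrame:
    """Per-year summaries of prevalence and exposure with extreme units named."""
    panel = panel or load_panel(config)
    df = panel.to_frame()
    rows = []
    for year, grp in df.groupby("year"):
        row: dict[str, Any] = {"year": int(year)}
        for var in ("y", "pm25"):
            if var not in grp.columns:
                continue
            row[f"{var}_min"] = float(grp[var].min())
            row[f"{var}_max"] = float(grp[var].max())
            row[f"{var}_mean"] = float(grp[var].mean())
            row[f"{var}_lowest_unit"] = grp.loc[grp[var].idxmin(), "unit_id"]
            row[f"{var}_highest_unit"] = grp.loc[grp[var].idxmax(), "unit_id"]
        rows.append(row)
    out = pd.DataFrame(rows)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _write_csv(out, out_dir / "describe.csv")
    return out


def _local_geojson_join(config: PipelineConfig, panel: PanelTable,
                        records: Sequence[dict], path: Path) -> None:
    """Write units GeoJSON with local-statistic properties joined per unit."""
    by_unit = {r["unit_id"]: r for r in records}
    features = []
    for u in sorted(panel.units, key=lambda u: u.unit_id):
        props = {"unit_id": u.unit_id, "name": u.name}
        rec = by_unit.get(u.unit_id)
        if rec:
            props.update({k: v for k, v in rec.items() if k != "unit_id"})
        if u.polygon is not None:
            geometry = {"type": "Polygon",
                        "coordinates": [[list(pt) for pt in ring] for ring in u.polygon]}
        else:
            geometry = {"type": "Point", "coordinates": [u.centroid_lon, u.centroid_lat]}
        features.append({"type": "Feature", "properties": props, "geometry": geometry})
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": features},
                  fh, sort_keys=True, separators=(",", ":"), allow_nan=True)
        fh.write("\n")


def run_autocorr(config: PipelineConfig, panel: PanelTable | None = None) -> pd.DataFrame:
    """Per-year global Moran's I and General G plus LISA / Gi* local exports.

    Moran's I and LISA use row-standardized weights; General G and Gi* the
    raw (binary/distance) weights, matching conventional usage of each
    statistic family.
    """
    panel = panel or load_panel(config)
    w_raw = build_weights(config, panel.units)
    w_std = row_standardize(w_raw)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for year in panel.years:
        obs = sorted((o for o in panel.observations if o.year == year), key=lambda o: o.unit_id)
        ids = [o.unit_id for o in obs]
        if ids != w_raw.unit_ids:
            raise ConfigurationError(f"year {year}: observed units do not match weight matrix")
        fld = AttributeField(ids, np.array([o.y for o in obs]))
        moran = global_morans_i(fld, w_std)
        g = general_g(fld, w_raw)
        rows.append({
            "year": year,
            "morans_i": moran.observed, "morans_z": moran.z, "morans_p": moran.p,
            "morans_sig": _sig_marks(moran.p),
            "general_g": g.observed, "general_g_z": g.z, "general_g_p": g.p,
            "general_g_sig": _sig_marks(g.p),
        })
        lisa = local_morans(fld, w_std, alpha=config.alpha,
                            n_perm=config.n_perm, seed=config.seed + year)
        gi = gi_star(fld, w_raw)
        lisa_df = pd.DataFrame(lisa.to_records())
        gi_df = pd.DataFrame(gi.to_records())
        _write_csv(lisa_df, out_dir / f"lisa_{year}.csv")
        _write_csv(gi_df, out_dir / f"gi_star_{year}.csv")
        _local_geojson_join(config, panel, lisa.to_records(), out_dir / f"lisa_{year}.geojson")
        _local_geojson_join(config, panel, gi.to_records(), out_dir / f"gi_star_{year}.geojson")
    table = pd.DataFrame(rows)
    _write_csv(table, out_dir / "global_autocorr.csv")
    return table


def run_regression(config: PipelineConfig, panel: PanelTable | None = None,
                   override_collinearity: bool = False) -> dict:
    """Collinearity screen, four-model comparison and local-coefficient export.

    Fails with :class:`ConfigurationError` when any VIF >= 5 unless
    ``override_collinearity`` is set.
    """
    panel = panel or load_panel(config)
    design = build_design(panel)
    if config.standardize:
        Xc = design.X[:, 1:]
        design.X[:, 1:] = (Xc - Xc.mean(axis=0)) / Xc.std(axis=0, ddof=1)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    ols = fit_ols(design)
    verdict = collinearity_verdict(ols.vif)
    vif_table = pd.DataFrame({
        "covariate": design.covariate_names,
        "B": ols.beta[1:], "se": ols.se[1:],
        "tolerance": ols.tolerance, "VIF": ols.vif,
    })
    _write_csv(vif_table, out_dir / "vif.csv")
    if np.any(ols.vif >= 5.0) and not override_collinearity:
        raise ConfigurationError(
            f"collinearity screen failed ({verdict}); max VIF = {ols.vif.max():.3f}. "
            "Pass override_collinearity to proceed anyway."
        )

    comparison, fits = compare_models(design, models=config.models,
                                      kernel=config.kernel, tau_grid=config.tau_grid)
    comp_df = pd.DataFrame(comparison.rows)
    _write_csv(comp_df, out_dir / "model_comparison.csv")
    with open(out_dir / "model_comparison.json", "w", encoding="utf-8") as fh:
        json.dump({"rows": comparison.rows, "best_model": comparison.best_model,
                   "aicc_margin": comparison.aicc_margin, "note": comparison.note},
                  fh, sort_keys=True, separators=(",", ":"))
        fh.write("\n")

    local_export = None
    best = comparison.best_model.lower()
    local_fit = fits.get(best) if best != "ols" else None
    if local_fit is None:
        local_fit = next((fits[m] for m in ("gtwr", "gwr", "twr") if m in fits), None)
    if local_fit is not None and "pm25" in design.covariate_names:
        j = 1 + design.covariate_names.index("pm25")
        local_export = pd.DataFrame({
            "unit_id": [k[0] for k in local_fit.obs_keys],
            "year": [k[1] for k in local_fit.obs_keys],
            "beta_pm25": local_fit.beta_local[:, j],
            "se": local_fit.se_local[:, j],
            "t": local_fit.t_local[:, j],
            "significant": local_fit.significant[:, j],
        })
        _write_csv(local_export, out_dir / "local_pm25_coefficients.csv")
        for year in sorted(local_export["year"].unique()):
            sub = local_export[local_export["year"] == year]
            _local_geojson_join(config, panel, sub.to_dict("records"),
                                out_dir / f"local_pm25_{year}.geojson")
    return {
        "vif_table": vif_table, "verdict": verdict, "comparison": comparison,
        "fits": fits, "local_export": local_export,
    }


def run_all(config: PipelineConfig, override_collinearity: bool = False) -> dict:
    """Full pipeline: describe, autocorrelation, regression, provenance report."""
    panel = load_panel(config)
    describe = run_describe(config, panel)
    autocorr_table = run_autocorr(config, panel)
    regression = run_regression(config, panel, override_collinearity=override_collinearity)
    out_dir = Path(config.out_dir)
    report = {
        "schema_version": SCHEMA_VERSION,
        "config_hash": config.hash,
        "seed": config.seed,
        "software_version": __version__,
        "n_units": len(panel.units),
        "n_observations": len(panel.observations),
        "years": panel.years,
        "collinearity_verdict": regression["verdict"],
        "best_model": regression["comparison"].best_model,
        "aicc_margin": regression["comparison"].aicc_margin,
    }
    with open(out_dir / "run_report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, sort_keys=True, separators=(",", ":"))
        fh.write("\n")
    return {"describe": describe, "autocorr": autocorr_table, "regression": regression,
            "report": report}
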