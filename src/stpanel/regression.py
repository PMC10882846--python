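"""OLS and the geographically/temporally weighted regression family.

The varying-coefficient models share one engine: at each observation i a
diagonal kernel weight matrix W_i is formed from distances in a chosen
metric and a weighted least-squares fit gives the local coefficients

    β̂(u_i, v_i, t_i) = (Xᵀ W_i X)⁻¹ Xᵀ W_i y.

The metric decides the model: purely spatial distance (GWR), purely
temporal distance (TWR), or the additive spatiotemporal metric

    d²_ST = (Δu² + Δv²) + τ·Δt²

with a single spatial-to-temporal scale ratio τ in km²/yr² (GTWR; τ = 0
recovers GWR).  Longitude/latitude are projected to local planar km by an
equirectangular projection about the study-area centroid before any kernel
computation.

Kernels: gaussian ``exp(−d²/b²)`` and bisquare ``(1 − d²/b²)²`` for d < b.
The adaptive bandwidth at i is the distance to the q-th nearest observation
(self included); ties at the q-th distance all receive the same weight.
Model fit is summarised by R², adjusted R² and the corrected AIC

    AICc = 2n·ln(σ̂) + n·ln(2π) + n·(n + tr(S))/(n − 2 − tr(S)),

with σ̂² = RSS/n and tr(S) the trace of the hat matrix — the effective
number of parameters.  The same AICc definition (tr(S) = k+1) is applied to
OLS so all four models are compared on one scale; a gap larger than 3 is
treated as a meaningful difference in fit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dc_field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .errors import DomainError, ParameterError, SingularDesignError
from .panel import PanelTable
from .weights import EARTH_RADIUS_KM

logger = logging.getLogger(__name__)

Model = Literal["ols", "gwr", "twr", "gtwr"]
Kernel = Literal["gaussian", "bisquare"]

AICC_MEANINGFUL_MARGIN = 3.0
# τ grid: 7 half-decade steps; beyond 10⁵ km²/yr² one year would outweigh
# >300 km, which is implausible for an annual provincial panel
DEFAULT_TAU_GRID = tuple(10.0 ** (2.0 + 0.5 * i) for i in range(7))


@dataclass
class DesignMatrix:
    """Response, intercept-augmented design, and space-time coordinates."""

    y: np.ndarray
    X: np.ndarray  # n × (k+1), leading intercept column
    covariate_names: list[str]
    obs_keys: list[tuple[str, int]]
    coords: np.ndarray  # n × 2 planar km (u east, v north)
    times: np.ndarray  # real years

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        n, p = self.X.shape
        if p != len(self.covariate_names) + 1:
            raise ParameterError("X must have one intercept column plus one column per covariate")
        if not (np.all(np.isfinite(self.y)) and np.all(np.isfinite(self.X))):
            raise DomainError("design contains non-finite values")
        if n < p + 2:
            raise ParameterError(f"need n > k+2 observations, got n={n}, k+1={p}")
        if np.linalg.matrix_rank(self.X) < p:
            raise SingularDesignError(f"rank-deficient design; columns: {self._deficient_columns()}")

    def _deficient_columns(self) -> list[str]:
        names = ["intercept", *self.covariate_names]
        _, R = np.linalg.qr(self.X)
        d = np.abs(np.diag(R))
        tol = d.max() * max(self.X.shape) * np.finfo(float).eps
        return [names[j] for j in np.flatnonzero(d < tol)]

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def k(self) -> int:
        """Number of covariates (excluding the intercept)."""
        return self.X.shape[1] - 1


def project_lonlat_km(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    """Equirectangular projection to planar km about the point-set centroid."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    lon0, lat0 = lon.mean(), lat.mean()
    u = EARTH_RADIUS_KM * np.cos(np.radians(lat0)) * np.radians(lon - lon0)
    v = EARTH_RADIUS_KM * np.radians(lat - lat0)
    return np.column_stack([u, v])


def build_design(panel: PanelTable, covariates: Sequence[str] | None = None) -> DesignMatrix:
    """Assemble a DesignMatrix from a PanelTable (projected coords, real-year times)."""
    cov = list(covariates) if covariates is not None else list(panel.covariate_names)
    unit_pos = {u.unit_id: (u.centroid_lon, u.centroid_lat) for u in panel.units}
    obs = sorted(panel.observations, key=lambda o: (o.year, o.unit_id))
    y = np.array([o.y for o in obs])
    X = np.column_stack([np.ones(len(obs))] + [[o.covariates[c] for o in obs] for c in cov]) \
        if cov else np.ones((len(obs), 1))
    lon = np.array([unit_pos[o.unit_id][0] for o in obs])
    lat = np.array([unit_pos[o.unit_id][1] for o in obs])
    return DesignMatrix(
        y=y,
        X=X,
        covariate_names=cov,
        obs_keys=[(o.unit_id, o.year) for o in obs],
        coords=project_lonlat_km(lon, lat),
        times=np.array([float(o.year) for o in obs]),
    )


@dataclass
class KernelSpec:
    """Kernel family, bandwidth parameterization and space-time ratio."""

    model: Model
    kernel: Kernel = "gaussian"
    bandwidth_mode: Literal["adaptive_neighbors", "fixed_distance"] = "adaptive_neighbors"
    bandwidth: float = 0.0  # neighbor count q (adaptive) or distance h (fixed)
    st_ratio: float = 0.0  # τ, km² per yr²; only used by gtwr

    def validate(self, design: DesignMatrix) -> None:
        if self.st_ratio < 0:
            raise ParameterError(f"st_ratio τ must be >= 0, got {self.st_ratio}")
        if self.bandwidth_mode == "adaptive_neighbors":
            q = int(self.bandwidth)
            if not design.k + 3 <= q <= design.n:
                raise ParameterError(
                    f"adaptive bandwidth q={q} outside [k+3={design.k + 3}, n={design.n}]"
                )
        elif self.bandwidth <= 0:
            raise ParameterError(f"fixed bandwidth must be > 0, got {self.bandwidth}")


@dataclass
class GlobalFit:
    """OLS fit with collinearity diagnostics."""

    beta: np.ndarray
    se: np.ndarray
    residuals: np.ndarray
    yhat: np.ndarray
    vif: np.ndarray
    tolerance: np.ndarray
    covariate_names: list[str]
    R2: float
    AdjR2: float
    AICc: float
    RSS: float
    n: int

    @property
    def trace_S(self) -> float:
        return float(len(self.beta))


@dataclass
class LocalFit:
    """Per-observation coefficient surfaces with diagnostics."""

    beta_local: np.ndarray  # n × (k+1)
    se_local: np.ndarray
    t_local: np.ndarray
    significant: np.ndarray  # boolean n × (k+1)
    yhat: np.ndarray
    residuals: np.ndarray
    trace_S: float
    R2: float
    AdjR2: float
    AICc: float
    RSS: float
    kernel: KernelSpec
    covariate_names: list[str]
    obs_keys: list[tuple[str, int]]
    hat_matrix: np.ndarray | None = None


@dataclass
class BandwidthSearchResult:
    evaluated: list[tuple[float, float, float]]  # (bandwidth, τ, AICc)
    chosen: KernelSpec
    search_method: str


@dataclass
class ModelComparison:
    rows: list[dict]  # model, R2, AdjR2, AICc, RSS
    best_model: str
    aicc_margin: float
    note: str = ""


def fit_ols(design: DesignMatrix, alpha: float = 0.05) -> GlobalFit:
    """Ordinary least squares with classical SEs, VIFs and the shared AICc."""
    X, y = design.X, design.y
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    yhat = X @ beta
    resid = y - yhat
    rss = float(resid @ resid)
    sigma2 = rss / (n - p)
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * np.diag(XtX_inv))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p)
    if design.k >= 2:
        vifs, tols = vif(design)
    else:
        vifs, tols = np.full(design.k, 1.0), np.full(design.k, 1.0)
    try:
        aicc_val = aicc_value(n, rss, p)
    except DomainError:  # toy-sized n: the corrected penalty is undefined
        aicc_val = math.nan
    return GlobalFit(
        beta=beta, se=se, residuals=resid, yhat=yhat, vif=vifs, tolerance=tols,
        covariate_names=design.covariate_names,
        R2=r2, AdjR2=adj, AICc=aicc_val, RSS=rss, n=n,
    )


def vif(design: DesignMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Variance inflation factors and tolerances from auxiliary regressions.

    VIF_j = 1/(1 − R²_j) where R²_j is from regressing covariate j on all
    other covariates plus an intercept; tolerance_j = 1 − R²_j.  Perfect
    collinearity raises :class:`SingularDesignError`.
    """
    k = design.k
    if k < 2:
        raise ParameterError("VIF needs at least 2 covariates")
    Xc = design.X[:, 1:]
    vifs = np.empty(k)
    for j in range(k):
        target = Xc[:, j]
        others = np.column_stack([np.ones(design.n), np.delete(Xc, j, axis=1)])
        b, *_ = np.linalg.lstsq(others, target, rcond=None)
        resid = target - others @ b
        tss = float(np.sum((target - target.mean()) ** 2))
        r2j = 1.0 - float(resid @ resid) / tss
        if r2j >= 1.0 - 1e-12:
            raise SingularDesignError(
                f"covariate {design.covariate_names[j]!r} is perfectly collinear (infinite VIF)"
            )
        vifs[j] = 1.0 / (1.0 - r2j)
    return vifs, 1.0 / vifs


def collinearity_verdict(vifs: np.ndarray, vif_limit: float = 5.0, tol_limit: float = 0.3) -> str:
    """Screening verdict: no collinearity when all VIF < limit and tolerances > limit."""
    tols = 1.0 / vifs
    if np.all(vifs < vif_limit) and np.all(tols > tol_limit):
        return "no collinearity"
    bad = [i for i, v in enumerate(vifs) if v >= vif_limit or 1.0 / v <= tol_limit]
    return f"collinearity suspected (covariate indices {bad})"


def st_distance2(design: DesignMatrix, model: Model, st_ratio: float = 0.0) -> np.ndarray:
    """Squared distance matrix in the model's metric.

    gwr: Δu² + Δv² (km²); twr: Δt² (yr²); gtwr: Δu² + Δv² + τ·Δt².
    """
    if st_ratio < 0:
        raise ParameterError(f"st_ratio τ must be >= 0, got {st_ratio}")
    du = design.coords[:, 0][:, None] - design.coords[:, 0][None, :]
    dv = design.coords[:, 1][:, None] - design.coords[:, 1][None, :]
    dt = design.times[:, None] - design.times[None, :]
    if model == "twr":
        return dt**2
    d2 = du**2 + dv**2
    if model == "gtwr":
        d2 = d2 + st_ratio * dt**2
    return d2


def _kernel_weights(d2_row: np.ndarray, b2: float, kernel: Kernel) -> np.ndarray:
    if b2 <= 0:  # degenerate bandwidth: only exactly coincident points
        return (d2_row == 0).astype(float)
    if kernel == "gaussian":
        return np.exp(-d2_row / b2)
    w = 1.0 - d2_row / b2
    w[w < 0] = 0.0
    return w**2


def fit_local(design: DesignMatrix, spec: KernelSpec, alpha: float = 0.05,
              keep_hat_matrix: bool = False) -> LocalFit:
    """Fit GWR / TWR / GTWR by per-observation weighted least squares.

    At each observation the kernel bandwidth is either fixed or adaptive
    (distance to the q-th nearest observation in the model metric, self
    included).  Local standard errors use σ̂² = RSS/(n − tr(S)) and the rows
    C_i = (XᵀW_iX)⁻¹XᵀW_i; pseudo-t values are tested two-tailed against a
    t distribution with n − tr(S) degrees of freedom.
    """
    if spec.model == "ols":
        raise ParameterError("use fit_ols for the global model")
    spec.validate(design)
    if spec.model in ("twr", "gtwr") and len(np.unique(design.times)) < 2:
        if spec.model == "twr":
            raise ParameterError("TWR needs at least 2 distinct years")
    D2 = st_distance2(design, spec.model, spec.st_ratio)
    X, y = design.X, design.y
    n, p = X.shape
    beta = np.empty((n, p))
    cct = np.empty((n, p))
    s_diag = np.empty(n)
    yhat = np.empty(n)
    S_rows = np.empty((n, n)) if keep_hat_matrix else None
    for i in range(n):
        if spec.bandwidth_mode == "adaptive_neighbors":
            q = int(spec.bandwidth)
            b2 = float(np.partition(D2[i], q - 1)[q - 1])
        else:
            b2 = float(spec.bandwidth) ** 2
        w = _kernel_weights(D2[i], b2, spec.kernel)
        Xw = X * w[:, None]
        A = X.T @ Xw
        try:
            Ainv = np.linalg.inv(A)
        except np.linalg.LinAlgError:
            raise SingularDesignError(
                f"local design singular at observation {design.obs_keys[i]}; "
                "increase the bandwidth"
            ) from None
        if np.linalg.cond(A) > 1e12:
            raise SingularDesignError(
                f"local design ill-conditioned at observation {design.obs_keys[i]}; "
                "increase the bandwidth"
            )
        Ci = Ainv @ Xw.T  # p × n
        beta[i] = Ci @ y
        cct[i] = np.sum(Ci**2, axis=1)
        s_row = X[i] @ Ci
        s_diag[i] = s_row[i]
        yhat[i] = X[i] @ beta[i]
        if keep_hat_matrix:
            S_rows[i] = s_row
    resid = y - yhat
    rss = float(resid @ resid)
    tr_S = float(s_diag.sum())
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - tr_S)
    df = n - tr_S
    if df <= 0:
        raise DomainError(f"effective dof n - tr(S) = {df:.3f} <= 0; bandwidth too small")
    sigma2 = rss / df
    se = np.sqrt(sigma2 * cct)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.nan)
    crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    signif = np.abs(tvals) > crit
    return LocalFit(
        beta_local=beta, se_local=se, t_local=tvals, significant=signif,
        yhat=yhat, residuals=resid, trace_S=tr_S,
        R2=r2, AdjR2=adj, AICc=aicc_value(n, rss, tr_S), RSS=rss,
        kernel=spec, covariate_names=design.covariate_names, obs_keys=design.obs_keys,
        hat_matrix=S_rows,
    )


def aicc_value(n: int, rss: float, trace_s: float) -> float:
    """Corrected AIC: 2n·ln(σ̂) + n·ln(2π) + n(n + tr S)/(n − 2 − tr S), σ̂² = RSS/n."""
    if n - trace_s - 2 <= 0:
        raise DomainError(f"AICc undefined: n - tr(S) - 2 = {n - trace_s - 2:.3f} <= 0")
    if rss <= 0:
        return -math.inf
    sigma_hat = math.sqrt(rss / n)
    return 2 * n * math.log(sigma_hat) + n * math.log(2 * math.pi) + n * (n + trace_s) / (n - 2 - trace_s)


def aicc(fit: GlobalFit | LocalFit) -> float:
    """AICc of a fitted model, recomputed from its RSS and effective parameters."""
    n = fit.n if isinstance(fit, GlobalFit) else len(fit.yhat)
    return aicc_value(n, fit.RSS, fit.trace_S)


def _golden_section_int(f, lo: int, hi: int) -> dict[int, float]:
    """Golden-section minimisation over an integer range, with memoisation.

    Returns the map of evaluated points; assumes approximate unimodality.
    The final bracket (width <= 4) is swept exhaustively.
    """
    phi = (math.sqrt(5.0) - 1.0) / 2.0
    cache: dict[int, float] = {}

    def ev(q: int) -> float:
        if q not in cache:
            try:
                cache[q] = f(q)
            except (SingularDesignError, DomainError):
                cache[q] = math.inf
        return cache[q]

    a, b = lo, hi
    while b - a > 4:
        x1 = int(round(b - phi * (b - a)))
        x2 = int(round(a + phi * (b - a)))
        if x1 == x2:
            x2 += 1
        if ev(x1) <= ev(x2):
            b = x2
        else:
            a = x1
    for q in range(a, b + 1):
        ev(q)
    return cache


def select_bandwidth(
    design: DesignMatrix,
    model: Model,
    kernel: Kernel = "gaussian",
    search: Literal["golden_section", "grid"] = "golden_section",
    q_range: tuple[int, int] | None = None,
    tau_grid: Sequence[float] | None = None,
) -> BandwidthSearchResult:
    """Select the adaptive bandwidth (and τ for GTWR) minimising AICc.

    The τ grid (GTWR only) is searched in an outer loop, the bandwidth by
    golden-section (or exhaustive grid) search on the integer neighbour
    count in [k+3, n].
    """
    if model == "ols":
        raise ParameterError("OLS has no bandwidth")
    if model in ("twr", "gtwr") and len(np.unique(design.times)) < 2:
        raise ParameterError(f"{model} bandwidth search needs >= 2 distinct years")
    lo, hi = q_range if q_range is not None else (design.k + 3, design.n)
    if lo > hi:
        raise ParameterError(f"empty bandwidth search range [{lo}, {hi}]")
    taus = list(tau_grid) if tau_grid is not None else (list(DEFAULT_TAU_GRID) if model == "gtwr" else [0.0])
    evaluated: list[tuple[float, float, float]] = []
    best: tuple[float, float, float] | None = None  # (aicc, q, tau)
    for tau in taus:
        def f(q: int, _tau=tau) -> float:
            spec = KernelSpec(model=model, kernel=kernel, bandwidth=q, st_ratio=_tau)
            return fit_local(design, spec).AICc

        if search == "golden_section":
            cache = _golden_section_int(f, lo, hi)
        else:
            cache = {}
            for q in range(lo, hi + 1):
                try:
                    cache[q] = f(q)
                except (SingularDesignError, DomainError):
                    cache[q] = math.inf
        for q in sorted(cache):
            evaluated.append((float(q), tau, cache[q]))
        q_best = min(sorted(cache), key=lambda q: cache[q])
        if math.isfinite(cache[q_best]) and (best is None or cache[q_best] < best[0]):
            best = (cache[q_best], float(q_best), tau)
    if best is None:
        raise SingularDesignError("all bandwidths in the search range produced singular fits")
    chosen = KernelSpec(model=model, kernel=kernel, bandwidth=best[1], st_ratio=best[2])
    return BandwidthSearchResult(evaluated=evaluated, chosen=chosen, search_method=search)


def compare_models(
    design: DesignMatrix,
    models: Sequence[Model] = ("ols", "gwr", "twr", "gtwr"),
    kernel: Kernel = "gaussian",
    tau_grid: Sequence[float] | None = None,
) -> tuple[ModelComparison, dict[str, GlobalFit | LocalFit]]:
    """Fit each requested model (bandwidths independently selected) and rank by AICc."""
    if len(models) < 2:
        raise ParameterError("compare_models needs at least 2 models")
    fits: dict[str, GlobalFit | LocalFit] = {}
    rows = []
    for model in models:
        if model == "ols":
            fit = fit_ols(design)
        else:
            sel = select_bandwidth(design, model, kernel=kernel, tau_grid=tau_grid)
            fit = fit_local(design, sel.chosen)
        fits[model] = fit
        rows.append({"model": model.upper(), "R2": fit.R2, "AdjR2": fit.AdjR2,
                     "AICc": fit.AICc, "RSS": fit.RSS})
    rows_by_aicc = sorted(rows, key=lambda r: r["AICc"])
    best = rows_by_aicc[0]["model"]
    margin = rows_by_aicc[1]["AICc"] - rows_by_aicc[0]["AICc"]
    note = ""
    if margin > AICC_MEANINGFUL_MARGIN:
        note = (f"{best} attains the lowest AICc and the AICc difference with other models "
                f"exceeds {AICC_MEANINGFUL_MARGIN:g}, indicating a better fit")
        logger.info(note)
    best_r2 = max(rows, key=lambda r: r["R2"])["model"]
    if best_r2 != best:
        logger.info("AICc-best model %s differs from R2-best model %s", best, best_r2)
    return ModelComparison(rows=rows, best_model=best, aicc_margin=float(margin), note=note), fits
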