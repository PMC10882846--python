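"""Global and local spatial autocorrelation statistics.

Implements the four classical statistics used to characterise spatial
clustering of an attribute (here, disease prevalence) over administrative
units:

* **Global Moran's I** — overall spatial autocorrelation,
  ``I = (n/S0) · Σ_i Σ_j w_ij (x_i − x̄)(x_j − x̄) / Σ_i (x_i − x̄)²``,
  with expectation −1/(n−1) under the null.
* **Getis-Ord General G** — distinguishes high-value from low-value
  clustering, ``G = Σ_{i≠j} w_ij x_i x_j / Σ_{i≠j} x_i x_j``.
* **Local Moran (LISA)** — ``I_i = n (x_i − x̄) Σ_j w_ij (x_j − x̄) / Σ_k (x_k − x̄)²``
  with Anselin quadrant classification into high-high / low-low clusters and
  high-low / low-high outliers.
* **Getis-Ord Gi*** — self-inclusive hot-spot statistic, returned directly
  as a z-score and binned at the 90/95/99% confidence levels.

Inference for the global statistics is either analytic under the
randomization assumption (the exact first two moments of the permutation
distribution) or by seeded Monte-Carlo permutation.  Local Moran p-values
use conditional permutation (the value at i held fixed).  All p-values are
two-tailed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

from .errors import AlignmentError, DegenerateFieldError, DomainError
from .weights import WeightMatrix

logger = logging.getLogger(__name__)

Inference = Literal["analytic_randomization", "permutation"]

GI_BINS = (
    (2.576, "hot_99"),
    (1.96, "hot_95"),
    (1.645, "hot_90"),
)


@dataclass
class AttributeField:
    """Attribute values aligned one-to-one with a weight matrix's units."""

    unit_ids: list[str]
    x: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.x.ndim != 1 or len(self.x) != len(self.unit_ids):
            raise AlignmentError("x must be a 1-d array aligned with unit_ids")
        if len(self.x) < 3:
            raise DomainError("need at least 3 units")
        if not np.all(np.isfinite(self.x)):
            raise DomainError("attribute values must be finite")

    @property
    def n(self) -> int:
        return len(self.x)

    @property
    def x_bar(self) -> float:
        return float(self.x.mean())

    @property
    def S(self) -> float:
        """Sample standard deviation (ddof=1)."""
        return float(self.x.std(ddof=1))


@dataclass
class GlobalAutocorrResult:
    statistic_name: str
    observed: float
    expected: float
    variance: float
    z: float
    p: float
    inference: str
    n_perm: int | None = None
    seed: int | None = None


@dataclass
class LocalUnitResult:
    unit_id: str
    statistic: float
    z: float
    p: float
    category: str


@dataclass
class LocalAutocorrResult:
    statistic_name: str
    units: list[LocalUnitResult]

    def categories(self) -> dict[str, str]:
        return {u.unit_id: u.category for u in self.units}

    def to_records(self) -> list[dict]:
        return [
            {"unit_id": u.unit_id, "statistic": u.statistic, "z": u.z, "p": u.p, "category": u.category}
            for u in self.units
        ]


def _check_alignment(field: AttributeField, wm: WeightMatrix) -> None:
    if field.unit_ids != wm.unit_ids:
        raise AlignmentError("field unit_ids do not match weight matrix unit_ids")


def _two_tailed_p(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


def _perm_two_tailed_p(null: np.ndarray, observed: float) -> float:
    """Two-tailed pseudo p-value from a Monte-Carlo null sample."""
    n_perm = len(null)
    p_hi = (np.sum(null >= observed) + 1) / (n_perm + 1)
    p_lo = (np.sum(null <= observed) + 1) / (n_perm + 1)
    return float(min(1.0, 2.0 * min(p_hi, p_lo)))


def _s1_s2(w: np.ndarray) -> tuple[float, float]:
    s1 = 0.5 * np.sum((w + w.T) ** 2)
    s2 = np.sum((w.sum(axis=1) + w.sum(axis=0)) ** 2)
    return float(s1), float(s2)


def _moran_observed(z: np.ndarray, w: np.ndarray, s0: float) -> float:
    return float(len(z) / s0 * (z @ w @ z) / (z @ z))


def global_morans_i(
    field: AttributeField,
    wm: WeightMatrix,
    inference: Inference = "analytic_randomization",
    n_perm: int = 999,
    seed: int | None = None,
) -> GlobalAutocorrResult:
    """Global Moran's I with randomization or permutation inference.

    The analytic variance is the exact variance of I over all n! relabelings
    of the values onto the units (the "randomization" null), which depends
    on the sample kurtosis b2.
    """
    _check_alignment(field, wm)
    n = field.n
    z = field.x - field.x_bar
    if np.all(z == 0):
        raise DegenerateFieldError("Moran's I undefined for a constant field")
    s0 = wm.S0
    observed = _moran_observed(z, wm.w, s0)
    expected = -1.0 / (n - 1)
    if inference == "analytic_randomization":
        s1, s2 = _s1_s2(wm.w)
        b2 = n * np.sum(z**4) / (np.sum(z**2) ** 2)
        num = n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2) - b2 * (
            (n**2 - n) * s1 - 2 * n * s2 + 6 * s0**2
        )
        den = (n - 1) * (n - 2) * (n - 3) * s0**2
        variance = num / den - expected**2
        zscore = (observed - expected) / np.sqrt(variance)
        return GlobalAutocorrResult(
            "morans_i", observed, expected, float(variance), float(zscore), _two_tailed_p(zscore),
            inference="analytic_randomization",
        )
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for k in range(n_perm):
        null[k] = _moran_observed(rng.permutation(z), wm.w, s0)
    variance = float(null.var(ddof=1))
    mean = float(null.mean())
    zscore = (observed - mean) / np.sqrt(variance)
    return GlobalAutocorrResult(
        "morans_i", observed, mean, variance, float(zscore), _perm_two_tailed_p(null, observed),
        inference="permutation", n_perm=n_perm, seed=seed,
    )


def _general_g_observed(x: np.ndarray, w: np.ndarray) -> float:
    num = x @ w @ x  # diagonal of w is zero
    outer_sum = np.sum(x) ** 2 - np.sum(x**2)  # Σ_{i≠j} x_i x_j
    return float(num / outer_sum)


def general_g(
    field: AttributeField,
    wm: WeightMatrix,
    inference: Inference = "analytic_randomization",
    n_perm: int = 999,
    seed: int | None = None,
) -> GlobalAutocorrResult:
    """Getis-Ord General G; positive z indicates clustering of high values.

    Meaningful for nonnegative attributes; negative values trigger a warning
    but the ratio is still computed.  The analytic variance is the exact
    permutation variance (Getis & Ord 1992).
    """
    _check_alignment(field, wm)
    x = field.x
    n = field.n
    if np.any(x < 0):
        logger.warning("General G computed on a field with negative values; interpret with care")
    if np.all(x == 0):
        raise DegenerateFieldError("General G undefined for an all-zero field")
    observed = _general_g_observed(x, wm.w)
    s0 = wm.S0
    expected = s0 / (n * (n - 1))
    if inference == "analytic_randomization":
        s1, s2 = _s1_s2(wm.w)
        m1, m2, m3, m4 = (float(np.sum(x**j)) for j in (1, 2, 3, 4))
        b0 = (n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2
        b1 = -((n**2 - n) * s1 - 2 * n * s2 + 6 * s0**2)
        b2 = -(2 * n * s1 - (n + 3) * s2 + 6 * s0**2)
        b3 = 4 * (n - 1) * s1 - 2 * (n + 1) * s2 + 8 * s0**2
        b4 = s1 - s2 + s0**2
        eg2 = (b0 * m2**2 + b1 * m4 + b2 * m1**2 * m2 + b3 * m1 * m3 + b4 * m1**4) / (
            (m1**2 - m2) ** 2 * n * (n - 1) * (n - 2) * (n - 3)
        )
        variance = eg2 - expected**2
        if variance <= 0:
            # constant field: the permutation distribution is degenerate
            return GlobalAutocorrResult("general_g", observed, expected, 0.0, 0.0, 1.0,
                                        inference="analytic_randomization")
        zscore = (observed - expected) / np.sqrt(variance)
        return GlobalAutocorrResult(
            "general_g", observed, expected, float(variance), float(zscore), _two_tailed_p(zscore),
            inference="analytic_randomization",
        )
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for k in range(n_perm):
        null[k] = _general_g_observed(rng.permutation(x), wm.w)
    variance = float(null.var(ddof=1))
    mean = float(null.mean())
    zscore = 0.0 if variance == 0 else (observed - mean) / np.sqrt(variance)
    return GlobalAutocorrResult(
        "general_g", observed, mean, variance, float(zscore), _perm_two_tailed_p(null, observed),
        inference="permutation", n_perm=n_perm, seed=seed,
    )


def local_morans(
    field: AttributeField,
    wm: WeightMatrix,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int | None = None,
    fdr: bool = False,
) -> LocalAutocorrResult:
    """Local Moran's I with conditional-permutation inference and
    Anselin cluster/outlier classification.

    ``I_i = n (x_i − x̄) Σ_j w_ij (x_j − x̄) / Σ_k (x_k − x̄)²``, so that
    Σ_i I_i = S0 · I (the global statistic).  For each unit the value at i is
    held fixed and the remaining values are randomly reassigned to the other
    units; the two-tailed pseudo p-value and a z-score against the empirical
    null are reported.  Categories: significant units are HH/LL clusters or
    HL/LH outliers by the signs of the centered value and its spatial lag;
    everything else (and islands) is NS.  ``fdr=True`` applies a
    Benjamini-Hochberg correction before classification.
    """
    _check_alignment(field, wm)
    n = field.n
    z = field.x - field.x_bar
    denom = float(np.sum(z**2))
    if denom == 0:
        raise DegenerateFieldError("local Moran undefined for a constant field")
    rng = np.random.default_rng(seed)
    lag = wm.w @ z
    I = n * z * lag / denom
    results = []
    for i in range(n):
        nbr = np.flatnonzero(wm.w[i])
        nbr = nbr[nbr != i]
        if len(nbr) == 0:  # island: excluded from inference
            results.append(LocalUnitResult(wm.unit_ids[i], float(I[i]), np.nan, np.nan, "NS"))
            continue
        others = np.delete(z, i)
        k = len(nbr)
        # draw n_perm samples of k values without replacement from the others
        draws = rng.random((n_perm, len(others))).argsort(axis=1)[:, :k]
        lag_null = (others[draws] * wm.w[i, nbr]).sum(axis=1)
        null = n * z[i] * lag_null / denom
        p = _perm_two_tailed_p(null, I[i])
        sd = null.std(ddof=1)
        zsc = (I[i] - null.mean()) / sd if sd > 0 else np.nan
        results.append(LocalUnitResult(wm.unit_ids[i], float(I[i]), float(zsc), p, "NS"))
    pvals = np.array([r.p for r in results])
    signif = _significance_mask(pvals, alpha, fdr)
    for i, r in enumerate(results):
        if not signif[i]:
            continue
        hi_own = z[i] > 0
        hi_lag = lag[i] > 0
        r.category = {(True, True): "HH", (False, False): "LL", (True, False): "HL", (False, True): "LH"}[
            (bool(hi_own), bool(hi_lag))
        ]
    return LocalAutocorrResult("local_morans_i", results)


def _significance_mask(pvals: np.ndarray, alpha: float, fdr: bool) -> np.ndarray:
    ok = np.isfinite(pvals)
    out = np.zeros(len(pvals), dtype=bool)
    if not fdr:
        out[ok] = pvals[ok] <= alpha
        return out
    p = pvals[ok]
    m = len(p)
    order = np.argsort(p)
    thresh = alpha * (np.arange(1, m + 1)) / m
    passed = p[order] <= thresh
    k = np.max(np.nonzero(passed)[0]) + 1 if passed.any() else 0
    mask = np.zeros(m, dtype=bool)
    mask[order[:k]] = True
    out[ok] = mask
    return out


def gi_star(field: AttributeField, wm: WeightMatrix) -> LocalAutocorrResult:
    """Getis-Ord Gi* hot-spot statistic (self-inclusive, w_ii = 1).

    ``Gi* = (Σ_j w_ij x_j − X̄ Σ_j w_ij) / (S·sqrt((n Σ_j w_ij² − (Σ_j w_ij)²)/(n−1)))``
    with X̄ and S the mean and population standard deviation over all n
    units.  The statistic is already a z-score; confidence bins at
    |z| ≥ 1.645 / 1.96 / 2.576 give 90 / 95 / 99% hot (positive) or cold
    (negative) spots.
    """
    _check_alignment(field, wm)
    x = field.x
    n = field.n
    xbar = x.mean()
    S = np.sqrt(np.sum(x**2) / n - xbar**2)  # population sd, per the Gi* formula
    if S == 0:
        raise DegenerateFieldError("Gi* undefined for a constant field")
    wstar = wm.w.copy()
    np.fill_diagonal(wstar, 1.0)
    results = []
    for i in range(n):
        wi = wstar[i]
        sw = wi.sum()
        num = wi @ x - xbar * sw
        inner = (n * np.sum(wi**2) - sw**2) / (n - 1)
        if inner <= 0:
            logger.warning("Gi* denominator degenerate for unit %s; z set to 0", wm.unit_ids[i])
            zsc = 0.0
        else:
            zsc = num / (S * np.sqrt(inner))
        results.append(LocalUnitResult(wm.unit_ids[i], float(zsc), float(zsc), _two_tailed_p(zsc), _gi_category(zsc)))
    return LocalAutocorrResult("gi_star", results)


def _gi_category(z: float) -> str:
    for cut, label in GI_BINS:
        if abs(z) >= cut:
            return label if z > 0 else label.replace("hot", "cold")
    return "NS"
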