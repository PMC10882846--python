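"""Autocorrelation statistics against brute-force and enumeration oracles."""

import itertools

import numpy as np
import pytest

from stpanel.autocorr import AttributeField, general_g, gi_star, global_morans_i, local_morans
from stpanel.errors import DegenerateFieldError
from stpanel.synthetic import gen_lattice_units, gen_sar_field
from stpanel.weights import WeightMatrix, queen_contiguity, row_standardize

from conftest import checkerboard_field


def _random_weights(n, seed, symmetric=False):
    rng = np.random.default_rng(seed)
    w = rng.random((n, n))
    if symmetric:
        w = (w + w.T) / 2
    np.fill_diagonal(w, 0.0)
    return WeightMatrix([f"u{i}" for i in range(n)], w, scheme="inverse_distance")


def _brute_moran(x, w):
    n = len(x)
    xb = x.mean()
    num = sum(w[i, j] * (x[i] - xb) * (x[j] - xb) for i in range(n) for j in range(n))
    return n / w.sum() * num / sum((xi - xb) ** 2 for xi in x)


def _brute_g(x, w):
    n = len(x)
    num = sum(w[i, j] * x[i] * x[j] for i in range(n) for j in range(n) if i != j)
    den = sum(x[i] * x[j] for i in range(n) for j in range(n) if i != j)
    return num / den


def _brute_local_moran(x, w):
    n = len(x)
    xb = x.mean()
    den = sum((xk - xb) ** 2 for xk in x)
    return np.array([n * (x[i] - xb) * sum(w[i, j] * (x[j] - xb) for j in range(n)) / den
                     for i in range(n)])


def _brute_gi_star(x, w):
    n = len(x)
    xbar = x.mean()
    s = np.sqrt(sum(xi**2 for xi in x) / n - xbar**2)
    ws = w.copy()
    np.fill_diagonal(ws, 1.0)
    out = []
    for i in range(n):
        sw = ws[i].sum()
        num = sum(ws[i, j] * x[j] for j in range(n)) - xbar * sw
        den = s * np.sqrt((n * sum(ws[i, j] ** 2 for j in range(n)) - sw**2) / (n - 1))
        out.append(num / den)
    return np.array(out)


class TestOracleEquivalence:
    """Each statistic equals a literal double-loop evaluation of its formula."""

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_global_moran(self, seed):
        wm = _random_weights(8, seed)
        x = np.random.default_rng(seed + 100).normal(size=8)
        fld = AttributeField(wm.unit_ids, x)
        assert global_morans_i(fld, wm).observed == pytest.approx(_brute_moran(x, wm.w), abs=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_general_g(self, seed):
        wm = _random_weights(7, seed)
        x = np.random.default_rng(seed + 200).uniform(0.5, 3.0, 7)
        fld = AttributeField(wm.unit_ids, x)
        assert general_g(fld, wm).observed == pytest.approx(_brute_g(x, wm.w), abs=1e-10)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_local_moran(self, seed):
        wm = _random_weights(9, seed)
        x = np.random.default_rng(seed + 300).normal(size=9)
        fld = AttributeField(wm.unit_ids, x)
        res = local_morans(fld, wm, n_perm=99, seed=1)
        got = np.array([r.statistic for r in res.units])
        assert got == pytest.approx(_brute_local_moran(x, wm.w), abs=1e-10)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_gi_star(self, seed):
        wm = _random_weights(6, seed)
        x = np.random.default_rng(seed + 400).uniform(1.0, 5.0, 6)
        fld = AttributeField(wm.unit_ids, x)
        got = np.array([r.statistic for r in gi_star(fld, wm).units])
        assert got == pytest.approx(_brute_gi_star(x, wm.w), abs=1e-10)


class TestEnumerationMoments:
    """Analytic randomization moments equal exhaustive-permutation moments."""

    def test_moran_expectation_and_variance(self):
        wm = _random_weights(6, 5, symmetric=True)
        x = np.random.default_rng(55).normal(size=6)
        res = global_morans_i(AttributeField(wm.unit_ids, x), wm)
        vals = np.array([_brute_moran(np.array(p), wm.w) for p in itertools.permutations(x)])
        assert res.expected == pytest.approx(vals.mean(), abs=1e-10)
        assert res.variance == pytest.approx(vals.var(), abs=1e-10)

    def test_general_g_expectation_and_variance(self):
        wm = _random_weights(6, 6)
        x = np.random.default_rng(66).uniform(0.2, 2.0, 6)
        res = general_g(AttributeField(wm.unit_ids, x), wm)
        vals = np.array([_brute_g(np.array(p), wm.w) for p in itertools.permutations(x)])
        assert res.expected == pytest.approx(vals.mean(), abs=1e-10)
        assert res.variance == pytest.approx(vals.var(), abs=1e-10)


class TestClosedForms:
    def test_checkerboard_moran_is_minus_one(self, lattice_4x4, rook_4x4):
        wm = row_standardize(rook_4x4)
        fld = checkerboard_field(lattice_4x4, wm)
        assert global_morans_i(fld, wm).observed == pytest.approx(-1.0, abs=1e-12)

    def test_constant_field_general_g_z_zero(self):
        units = gen_lattice_units(3, 3)
        wm = queen_contiguity(units)
        fld = AttributeField(wm.unit_ids, np.full(9, 2.5))
        res = general_g(fld, wm)
        assert res.observed == pytest.approx(res.expected, abs=1e-12)
        assert res.z == 0.0

    def test_constant_field_moran_degenerate(self):
        units = gen_lattice_units(3, 3)
        wm = queen_contiguity(units)
        with pytest.raises(DegenerateFieldError):
            global_morans_i(AttributeField(wm.unit_ids, np.ones(9)), wm)


class TestInvariances:
    def test_moran_affine_invariant(self, lattice_30):
        units, wm = lattice_30
        x = np.random.default_rng(9).normal(size=30)
        a = global_morans_i(AttributeField(wm.unit_ids, x), wm).observed
        b = global_morans_i(AttributeField(wm.unit_ids, 3.2 * x + 7.0), wm).observed
        assert a == pytest.approx(b, abs=1e-12)

    def test_gi_star_affine_invariant(self, lattice_30):
        units, wm = lattice_30
        x = np.random.default_rng(10).uniform(1, 4, 30)
        za = [r.z for r in gi_star(AttributeField(wm.unit_ids, x), wm).units]
        zb = [r.z for r in gi_star(AttributeField(wm.unit_ids, 0.5 * x + 2.0), wm).units]
        assert za == pytest.approx(zb, abs=1e-10)

    def test_general_g_scale_invariant(self, lattice_30):
        units, wm = lattice_30
        x = np.random.default_rng(11).uniform(0.1, 2.0, 30)
        a = general_g(AttributeField(wm.unit_ids, x), wm).observed
        b = general_g(AttributeField(wm.unit_ids, 10.0 * x), wm).observed
        assert a == pytest.approx(b, abs=1e-12)

    def test_permutation_p_reproducible(self, lattice_30):
        units, wm = lattice_30
        fld = gen_sar_field(wm, rho=0.4, seed=3)
        r1 = global_morans_i(fld, wm, inference="permutation", n_perm=499, seed=77)
        r2 = global_morans_i(fld, wm, inference="permutation", n_perm=499, seed=77)
        assert (r1.p, r1.z) == (r2.p, r2.z)


class TestLisaClassification:
    def test_checkerboard_significant_units_are_outliers(self, lattice_4x4, rook_4x4):
        wm = row_standardize(rook_4x4)
        fld = checkerboard_field(lattice_4x4, wm)
        res = local_morans(fld, wm, n_perm=499, seed=5)
        assert all(r.statistic < 0 for r in res.units)
        for r in res.units:
            assert r.category in {"HL", "LH", "NS"}

    def test_high_block_interior_classified_hh(self):
        units = gen_lattice_units(9, 9)
        wm = row_standardize(queen_contiguity(units))
        x = np.zeros(81)
        ids = wm.unit_ids
        for r in (3, 4, 5):
            for c in (3, 4, 5):
                x[ids.index(f"r{r}c{c}")] = 10.0
        fld = AttributeField(ids, x + np.random.default_rng(1).normal(0, 0.1, 81))
        res = local_morans(fld, wm, n_perm=999, seed=2)
        assert res.categories()["r4c4"] == "HH"

    def test_sum_of_local_equals_s0_times_global(self, lattice_30):
        units, wm = lattice_30
        rng = np.random.default_rng(12)
        for _ in range(20):
            x = rng.normal(size=30)
            fld = AttributeField(wm.unit_ids, x)
            total = sum(r.statistic for r in local_morans(fld, wm, n_perm=19, seed=0).units)
            glob = global_morans_i(fld, wm).observed
            assert total == pytest.approx(wm.S0 * glob, abs=1e-9)


class TestGiStarStructure:
    def test_reflection_equivariance(self):
        units = gen_lattice_units(5, 5)
        wm = queen_contiguity(units)
        ids = wm.unit_ids
        rng = np.random.default_rng(21)
        x = rng.uniform(0, 1, 25)
        z = {r.unit_id: r.z for r in gi_star(AttributeField(ids, x), wm).units}
        # reflect rows: r -> 4 - r
        reflect = {f"r{r}c{c}": f"r{4 - r}c{c}" for r in range(5) for c in range(5)}
        x_ref = np.array([x[ids.index(reflect[uid])] for uid in ids])
        z_ref = {r.unit_id: r.z for r in gi_star(AttributeField(ids, x_ref), wm).units}
        for uid in ids:
            assert z_ref[uid] == pytest.approx(z[reflect[uid]], abs=1e-10)

    def test_max_at_cluster_interior(self):
        units = gen_lattice_units(9, 9)
        wm = queen_contiguity(units)
        ids = wm.unit_ids
        x = np.zeros(81)
        for r in (3, 4, 5):
            for c in (3, 4, 5):
                x[ids.index(f"r{r}c{c}")] = 5.0
        res = gi_star(AttributeField(ids, x), wm)
        best = max(res.units, key=lambda r: r.z)
        assert best.unit_id == "r4c4"
        assert best.category == "hot_99"


def test_iid_null_mean_matches_expectation(lattice_30):
    """Mean Moran's I over i.i.d. fields approaches -1/(n-1)."""
    units, wm = lattice_30
    rng = np.random.default_rng(42)
    vals = [global_morans_i(AttributeField(wm.unit_ids, rng.normal(size=30)), wm).observed
            for _ in range(200)]
    vals = np.array(vals)
    mc_se = vals.std(ddof=1) / np.sqrt(len(vals))
    assert abs(vals.mean() - (-1 / 29)) < 3 * mc_se
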