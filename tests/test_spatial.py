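import numpy as np
import pytest

from basindiv import spatial
from basindiv.grid import great_circle_km


def full_grid_cells(nx, ny):
    return [f"{x}_{y}" for x in range(nx) for y in range(ny)]


class TestWeights:
    def test_interior_queen_eight_neighbors(self):
        cells = full_grid_cells(5, 5)
        w = spatial.build_weights(cells, scheme="queen")
        i = cells.index("2_2")
        assert len(w.neighbors(i)) == 8

    def test_corner_queen_three_neighbors(self):
        cells = full_grid_cells(3, 3)
        w = spatial.build_weights(cells, scheme="queen")
        assert len(w.neighbors(cells.index("0_0"))) == 3

    def test_isolated_cell_flagged(self):
        with pytest.warns(UserWarning, match="no neighbors"):
            w = spatial.build_weights(["0_0", "50_50"], scheme="queen")
        assert len(w.neighbors(0)) == 0

    def test_dateline_wrap(self):
        w = spatial.build_weights(["-180_10", "179_10"], scheme="queen")
        assert 1 in w.neighbors(0)
        d = great_circle_km(-179.5, 10.5, 179.5, 10.5)
        assert d < 150  # truly adjacent on the sphere

    def test_band_scheme(self):
        cells = ["0_0", "0_2", "0_40"]
        with pytest.warns(UserWarning):
            w = spatial.build_weights(cells, scheme="band", band_km=400)
        assert 1 in w.neighbors(0)
        assert 2 not in w.neighbors(0)

    def test_symmetry(self):
        cells = full_grid_cells(4, 4)
        w = spatial.build_weights(cells, scheme="queen")
        np.testing.assert_array_equal(w.matrix, w.matrix.T)

    def test_row_standardize(self):
        cells = full_grid_cells(3, 3)
        w = spatial.build_weights(cells, scheme="queen", row_standardize=True)
        np.testing.assert_allclose(w.matrix.sum(axis=1), 1.0)


class TestMoran:
    def rook_2x2(self):
        cells = ["0_0", "1_0", "0_1", "1_1"]
        m = np.zeros((4, 4))
        pairs = [(0, 1), (0, 2), (1, 3), (2, 3)]
        for a, b in pairs:
            m[a, b] = m[b, a] = 1.0
        return spatial.WeightsMatrix(cells=cells, matrix=m, scheme="rook")

    def test_checkerboard_minus_one(self):
        w = self.rook_2x2()
        res = spatial.morans_i(np.array([1.0, 0.0, 0.0, 1.0]), w, n_perm=0)
        assert res.i == pytest.approx(-1.0, rel=1e-12)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        cells = full_grid_cells(5, 4)
        w = spatial.build_weights(cells, scheme="queen")
        x = rng.normal(size=len(cells))
        res = spatial.morans_i(x, w, n_perm=0)
        # independent double loop
        z = x - x.mean()
        num = sum(w.matrix[i, j] * z[i] * z[j]
                  for i in range(len(x)) for j in range(len(x)))
        i_expected = len(x) / w.matrix.sum() * num / (z ** 2).sum()
        assert res.i == pytest.approx(i_expected, abs=1e-12)

    def test_permutation_null_mean(self):
        rng = np.random.default_rng(5)
        cells = full_grid_cells(4, 4)
        w = spatial.build_weights(cells, scheme="queen")
        x = rng.normal(size=16)
        z = x - x.mean()
        n_perm = 2000
        sims = np.empty(n_perm)
        prng = np.random.default_rng(9)
        for k in range(n_perm):
            zp = prng.permutation(z)
            sims[k] = (16 / w.matrix.sum()) * (zp @ w.matrix @ zp) / (zp ** 2).sum()
        se = sims.std(ddof=1) / np.sqrt(n_perm)
        assert abs(sims.mean() - (-1 / 15)) <= 3 * se

    def test_affine_invariance(self):
        rng = np.random.default_rng(6)
        cells = full_grid_cells(4, 4)
        w = spatial.build_weights(cells, scheme="queen")
        x = rng.normal(size=16)
        a = spatial.morans_i(x, w, n_perm=0)
        b = spatial.morans_i(3.5 * x + 11.0, w, n_perm=0)
        assert a.i == pytest.approx(b.i, abs=1e-12)

    def test_constant_field_errors(self):
        cells = full_grid_cells(3, 3)
        w = spatial.build_weights(cells, scheme="queen")
        with pytest.raises(ValueError, match="zero variance"):
            spatial.morans_i(np.ones(9), w)

    def test_permutation_p_seeded(self):
        rng = np.random.default_rng(7)
        cells = full_grid_cells(4, 4)
        w = spatial.build_weights(cells, scheme="queen")
        x = rng.normal(size=16)
        a = spatial.morans_i(x, w, n_perm=99, seed=1)
        b = spatial.morans_i(x, w, n_perm=99, seed=1)
        assert a.p_perm == b.p_perm


class TestGstar:
    def test_uniform_field_all_zero(self):
        cells = full_grid_cells(3, 3)
        w = spatial.build_weights(cells, scheme="queen", include_self=True)
        with pytest.warns(UserWarning, match="zero variance"):
            out = spatial.getis_ord_gstar(np.full(9, 4.0), w)
        assert (out["z"] == 0).all()
        assert (out["class"] == "not significant").all()

    def test_requires_self_weights(self):
        cells = full_grid_cells(3, 3)
        w = spatial.build_weights(cells, scheme="queen")
        with pytest.raises(ValueError, match="self"):
            spatial.getis_ord_gstar(np.arange(9.0), w)

    def test_single_spike_maximal(self):
        cells = full_grid_cells(5, 5)
        w = spatial.build_weights(cells, scheme="queen", include_self=True)
        x = np.zeros(25)
        x[12] = 10.0
        out = spatial.getis_ord_gstar(x, w)
        # the spike cell ties with its immediate neighbors (same window sum)
        assert out["z"].iloc[12] == pytest.approx(out["z"].max())
        far = out["z"].iloc[0]  # corner far from the spike
        assert out["z"].iloc[12] > far

    def test_brute_force_oracle_5x5(self):
        rng = np.random.default_rng(8)
        cells = full_grid_cells(5, 5)
        w = spatial.build_weights(cells, scheme="queen", include_self=True)
        x = rng.normal(size=25)
        out = spatial.getis_ord_gstar(x, w)
        n = 25
        xbar = x.mean()
        s = np.sqrt((x ** 2).sum() / n - xbar ** 2)
        for i in range(n):
            wi = w.matrix[i]
            num = (wi * x).sum() - xbar * wi.sum()
            den = s * np.sqrt((n * (wi ** 2).sum() - wi.sum() ** 2) / (n - 1))
            assert out["z"].iloc[i] == pytest.approx(num / den, abs=1e-10)

    def test_mean_z_near_zero_on_complete_grid(self):
        rng = np.random.default_rng(9)
        cells = full_grid_cells(6, 6)
        w = spatial.build_weights(cells, scheme="queen", include_self=True)
        out = spatial.getis_ord_gstar(rng.normal(size=36), w)
        assert abs(out["z"].mean()) < 0.2

    def test_class_thresholds(self):
        cells = full_grid_cells(3, 3)
        w = spatial.build_weights(cells, scheme="queen", include_self=True)
        out = spatial.getis_ord_gstar(np.array([9.0, 0, 0, 0, 0, 0, 0, 0, 0]), w)
        for _, row in out.iterrows():
            z = row["z"]
            if abs(z) < 1.65:
                assert row["class"] == "not significant"
            elif z >= 2.58:
                assert row["class"] == "hot99"


class TestIdw:
    def test_exact_at_sample(self):
        out = spatial.idw([0.0, 2.0], [0.0, 0.0], [5.0, 9.0], [0.0], [0.0])
        assert out[0] == 5.0

    def test_two_equidistant_samples(self):
        out = spatial.idw([-1.0, 1.0], [0.0, 0.0], [0.0, 10.0], [0.0], [0.0])
        assert out[0] == pytest.approx(5.0, rel=1e-12)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(10)
        slon = rng.uniform(-10, 10, 8)
        slat = rng.uniform(-10, 10, 8)
        sval = rng.normal(size=8)
        tlon, tlat = np.array([1.3]), np.array([-2.7])
        out = spatial.idw(slon, slat, sval, tlon, tlat, power=2)
        d = np.array([great_circle_km(tlon[0], tlat[0], slon[i], slat[i])
                      for i in range(8)])
        wgt = d ** -2.0
        expected = np.clip((wgt * sval).sum() / wgt.sum(), sval.min(), sval.max())
        assert out[0] == pytest.approx(expected, abs=1e-12)

    def test_clamped_to_input_range(self):
        rng = np.random.default_rng(11)
        slon = rng.uniform(-5, 5, 10)
        slat = rng.uniform(-5, 5, 10)
        sval = rng.normal(size=10)
        tlon = rng.uniform(-5, 5, 30)
        tlat = rng.uniform(-5, 5, 30)
        out = spatial.idw(slon, slat, sval, tlon, tlat)
        assert (out >= sval.min() - 1e-12).all()
        assert (out <= sval.max() + 1e-12).all()

    def test_max_dist(self):
        out = spatial.idw([0.0], [0.0], [5.0], [50.0], [50.0], max_dist_km=100)
        assert np.isnan(out[0])


class TestKriging:
    def _samples(self):
        rng = np.random.default_rng(12)
        lon = rng.uniform(-5, 5, 10)
        lat = rng.uniform(-5, 5, 10)
        val = np.sin(lon / 3) + 0.3 * lat / 5 + rng.normal(scale=0.05, size=10)
        return lon, lat, val

    def test_exact_at_sample_zero_nugget(self):
        lon, lat, val = self._samples()
        preds, var, _ = spatial.ordinary_kriging(lon, lat, val, lon[:3], lat[:3],
                                                 params=(0.0, 1.0, 500.0))
        np.testing.assert_allclose(preds, val[:3], atol=1e-8)
        np.testing.assert_allclose(var, 0.0, atol=1e-8)

    def test_constant_samples(self):
        lon, lat, _ = self._samples()
        val = np.full(10, 7.5)
        preds, _, _ = spatial.ordinary_kriging(lon, lat, val, [0.0, 2.0], [0.0, 1.0],
                                               params=(0.0, 1.0, 500.0))
        np.testing.assert_allclose(preds, 7.5, atol=1e-8)

    def test_duplicate_samples_error(self):
        lon = np.array([0.0, 0.0, 1, 2, 3])
        lat = np.array([0.0, 0.0, 1, 2, 3])
        with pytest.raises(ValueError, match="duplicate|singular"):
            spatial.ordinary_kriging(lon, lat, np.arange(5.0), [0.5], [0.5],
                                     params=(0.0, 1.0, 500.0))

    def test_linear_algebra_oracle(self):
        """Kriging weights solved independently with numpy reproduce predictions."""
        lon, lat, val = self._samples()
        params = (0.0, 1.2, 700.0)
        tlon, tlat = np.array([0.7, -2.0]), np.array([1.1, 3.0])
        preds, variances, _ = spatial.ordinary_kriging(lon, lat, val, tlon, tlat,
                                                       params=params)
        g = spatial._variogram_model("spherical")
        m = len(val)
        d = great_circle_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
        A = np.zeros((m + 1, m + 1))
        A[:m, :m] = g(d, *params)
        A[:m, :m][np.eye(m, dtype=bool)] = 0.0
        A[m, :m] = A[:m, m] = 1.0
        for t in range(2):
            d0 = great_circle_km(tlon[t], tlat[t], lon, lat)
            b = np.append(g(d0, *params), 1.0)
            sol = np.linalg.solve(A, b)
            assert preds[t] == pytest.approx(sol[:m] @ val, abs=1e-8)
            assert variances[t] == pytest.approx(max(sol[:m] @ b[:m] + sol[m], 0.0),
                                                 abs=1e-8)

    def test_fitted_variogram_path(self):
        lon, lat, val = self._samples()
        preds, variances, (model, params) = spatial.ordinary_kriging(
            lon, lat, val, [0.0], [0.0])
        assert model == "spherical"
        assert np.isfinite(preds).all()
        assert (variances >= 0).all()

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="at least 5"):
            spatial.ordinary_kriging([0, 1], [0, 1], [1.0, 2.0], [0.5], [0.5])
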