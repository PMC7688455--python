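"""LLE embedding, Pearson correlation, dimension selection, Gamma assembly."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from respivox import assemble_gamma, lle_embed, pearson, select_dimension
from respivox.errors import DimensionError, UndefinedCorrelationError


def curve_dataset(n=200, D=50, seed=0):
    """Points on a smooth 1D curve lifted into D dimensions."""
    rng = np.random.default_rng(seed)
    t = np.sort(rng.uniform(0, 1, n))
    A = rng.normal(size=(3, D))
    X = np.column_stack([np.sin(2 * t), np.cos(1.5 * t), t**2]) @ A
    return t, X


class TestLleEmbed:
    def test_recovers_curve_parameter(self):
        t, X = curve_dataset()
        psi = lle_embed(X, K=10, d=1)
        rho = spearmanr(psi[:, 0], t).statistic
        assert abs(rho) > 0.99

    def test_affine_plane_recovery(self):
        rng = np.random.default_rng(1)
        uv = rng.uniform(-1, 1, size=(150, 2))
        A = rng.normal(size=(2, 40))
        X = uv @ A + rng.normal(size=40) * 0  # exact plane
        psi = lle_embed(X, K=12, d=2)
        # embedding is an affine function of the plane coordinates
        design = np.column_stack([uv, np.ones(len(uv))])
        _, residual, _, _ = np.linalg.lstsq(design, psi, rcond=None)
        fitted = design @ np.linalg.lstsq(design, psi, rcond=None)[0]
        rel = np.linalg.norm(psi - fitted) / np.linalg.norm(psi)
        assert rel < 1e-3

    def test_duplicated_rows_embed_identically(self):
        _, X = curve_dataset(n=80)
        Xdup = np.repeat(X, 2, axis=0)
        psi = lle_embed(Xdup, K=8, d=2)
        np.testing.assert_allclose(psi[::2], psi[1::2], atol=1e-6)

    def test_matches_sklearn_oracle_on_curve(self):
        from sklearn.manifold import LocallyLinearEmbedding

        t, X = curve_dataset(n=150, D=30, seed=2)
        ours = lle_embed(X, K=10, d=1)[:, 0]
        ref = LocallyLinearEmbedding(n_neighbors=10, n_components=1, random_state=0)
        theirs = ref.fit_transform(X)[:, 0]
        assert abs(pearson(ours, theirs)) > 0.99

    def test_row_permutation_equivariance_up_to_sign(self):
        _, X = curve_dataset(n=100)
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(X))
        a = lle_embed(X, K=8, d=2)
        b = lle_embed(X[perm], K=8, d=2)
        restored = np.empty_like(b)
        restored[perm] = b
        for j in range(a.shape[1]):
            sign = np.sign(np.dot(a[:, j], restored[:, j]))
            np.testing.assert_allclose(a[:, j], sign * restored[:, j], atol=1e-4)

    def test_sign_convention_is_deterministic(self):
        _, X = curve_dataset()
        a = lle_embed(X, K=10, d=3)
        b = lle_embed(X, K=10, d=3)
        np.testing.assert_array_equal(a, b)

    def test_neighbor_count_validation(self):
        _, X = curve_dataset(n=20)
        with pytest.raises(ValueError):
            lle_embed(X, K=20, d=2)
        with pytest.raises(ValueError):
            lle_embed(X, K=5, d=8)

    def test_identical_rows_rejected(self):
        with pytest.raises(ValueError):
            lle_embed(np.ones((10, 5)), K=3, d=1)


class TestPearson:
    def test_self_correlation_is_one(self):
        x = np.array([1.0, 5.0, 2.0, 8.0])
        assert pearson(x, x) == 1.0
        assert pearson(x, -x) == -1.0

    def test_hand_computed_example(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 4.0, 5.0, 9.0])
        # independent oracle: direct covariance formula
        expected = np.mean((x - x.mean()) * (y - y.mean())) / (x.std() * y.std())
        assert pearson(x, y) == pytest.approx(expected, abs=1e-15)
        # by hand: cov = 11/4, sigma_x = sqrt(5/4), sigma_y = sqrt(13/2)
        assert pearson(x, y) == pytest.approx(2.75 / np.sqrt(1.25 * 6.5), abs=1e-12)

    def test_constant_series_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson(np.ones(5), np.arange(5.0))

    def test_bounded_on_randomized_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(3, 50)
            x, y = rng.normal(size=(2, n))
            assert abs(pearson(x, y)) <= 1.0


class TestSelectDimension:
    def test_planted_signal_column(self):
        rng = np.random.default_rng(0)
        tumor = np.sin(np.linspace(0, 20, 200))
        psi = rng.normal(size=(200, 6))
        psi[:, 3] = tumor
        idx, rho, all_rhos = select_dimension(psi, tumor)
        assert idx == 3 and rho == pytest.approx(1.0)
        assert len(all_rhos) == 6

    def test_pure_noise_warns_and_stays_low(self, caplog):
        rng = np.random.default_rng(1)
        tumor = rng.normal(size=200)
        psi = rng.normal(size=(200, 10))
        with caplog.at_level("WARNING", logger="respivox.features"):
            _, rho, _ = select_dimension(psi, tumor)
        # null Monte-Carlo: max |rho| over 10 independent columns at n=200
        # stays far below 0.5 (99.9th pct ~ 0.26)
        assert rho < 0.4
        assert any("expected exactly 1" in r.message for r in caplog.records)

    def test_single_column_returns_index_zero(self):
        t = np.linspace(0, 1, 50)
        idx, _, _ = select_dimension(t[:, None] * 2.0, t)
        assert idx == 0


class TestAssembleGamma:
    def test_m_zero_keeps_only_physical_features(self):
        V, S = np.arange(5.0), np.arange(5.0) * 2
        psi = np.random.default_rng(0).normal(size=(5, 3))
        fs = assemble_gamma(V, S, psi, m=0)
        assert fs.gamma.shape == (5, 2)

    def test_full_m_and_round_trip(self):
        rng = np.random.default_rng(1)
        V, S = rng.normal(size=5), rng.normal(size=5)
        psi = rng.normal(size=(5, 4))
        fs = assemble_gamma(V, S, psi, m=4)
        assert fs.gamma.shape == (5, 6)
        np.testing.assert_array_equal(fs.gamma[:, 0], V)
        np.testing.assert_array_equal(fs.gamma[:, 1], S)
        np.testing.assert_array_equal(fs.gamma[:, 2:], psi)

    def test_m_exceeding_d_rejected(self):
        with pytest.raises(DimensionError):
            assemble_gamma(np.ones(3), np.ones(3), np.ones((3, 2)), m=3)

    def test_normalization_metadata_present(self):
        fs = assemble_gamma(np.arange(4.0), np.arange(4.0), np.ones((4, 1)) * np.arange(4)[:, None], m=1)
        assert fs.normalization["components"] == ["V_mm3", "S_mm2", "psi_1"]
        assert len(fs.normalization["mean"]) == 3
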