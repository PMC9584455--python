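"""Covariance constructors: formulas, normalization, eigenstructure, errors."""

import numpy as np
import pytest

import neurorf as nr
from neurorf.covariance import select_harmonics

from conftest import random_psd


class TestStationary:
    def test_single_harmonic_unit_diagonal(self, small_grid):
        # one harmonic with lambda = 1: C(t,t) = cos(0) = 1 everywhere,
        # so the trace is already d and normalization is a no-op
        cov = nr.build_stationary_cov(small_grid, (20, 20))
        assert np.allclose(np.diag(cov.C), 1.0)

    def test_toeplitz(self, small_grid):
        cov = nr.build_stationary_cov(small_grid, (20, 100))
        C = cov.C
        for k in range(1, C.shape[0]):
            diag = np.diagonal(C, offset=k)
            assert np.allclose(diag, diag[0], atol=1e-12)

    def test_eigenbasis_spans_selected_sinusoids(self):
        # d=8 grid, passband covering harmonics {1, 2}: the numerical
        # eigenvectors must span {cos w_k t, sin w_k t} for k = 1, 2
        grid = nr.Grid1D(8, 1.0)
        df = 1.0 / grid.duration_s
        cov = nr.build_stationary_cov(grid, (df, 2 * df))
        t = grid.times_s
        basis = []
        for k in (1, 2):
            w = 2 * np.pi * k / grid.duration_s
            basis += [np.cos(w * t), np.sin(w * t)]
        B = np.linalg.qr(np.column_stack(basis))[0]
        vecs = cov.eigenvectors[:, :4]
        from scipy.linalg import subspace_angles

        assert np.max(subspace_angles(B, vecs)) < 1e-8
        # the four nonzero eigenvalues are equal (flat spectrum in the band)
        vals = cov.eigenvalues
        assert np.allclose(vals[:4], vals[0], rtol=1e-10)
        assert np.allclose(vals[4:], 0.0, atol=1e-10 * vals[0])

    def test_compound_angle_expansion_identity(self, small_grid):
        # sum_k cos(w_k (t - t')) == sum_k cos cos + sin sin, entrywise
        ks = select_harmonics(small_grid, 40, 120)
        t = small_grid.times_s
        direct = np.zeros((t.size, t.size))
        expanded = np.zeros_like(direct)
        for k in ks:
            w = 2 * np.pi * k / small_grid.duration_s
            direct += np.cos(w * (t[:, None] - t[None, :]))
            expanded += np.outer(np.cos(w * t), np.cos(w * t)) + np.outer(
                np.sin(w * t), np.sin(w * t)
            )
        assert np.max(np.abs(direct - expanded)) < 1e-12 * len(ks)

    def test_empty_passband_raises(self, small_grid):
        with pytest.raises(ValueError, match="empty passband"):
            nr.build_stationary_cov(small_grid, (25, 30))  # between harmonics

    def test_passband_above_nyquist_raises(self, small_grid):
        with pytest.raises(ValueError, match="Nyquist"):
            nr.build_stationary_cov(small_grid, (100, 10_000))

    def test_custom_weights(self, small_grid):
        cov = nr.build_stationary_cov(
            small_grid, (20, 40), weights={1: 2.0, 2: 1.0}
        )
        vals = cov.eigenvalues
        # two harmonics, eigenvalue groups in ratio 2:1
        assert vals[0] / vals[2] == pytest.approx(2.0, rel=1e-9)
        with pytest.raises(ValueError, match="nonnegative"):
            nr.build_stationary_cov(small_grid, (20, 40), weights={1: -1.0})


class TestSensilla:
    def test_diagonal_decay_is_exponential(self, small_grid):
        gamma = 20.0
        cov = nr.build_sensilla_cov(small_grid, nr.SensillaParams(40, 160, gamma))
        diag = np.diag(cov.C)
        t = small_grid.times_ms
        assert np.allclose(diag / diag[0], np.exp(-2 * t / gamma), rtol=1e-10)

    def test_envelope_removed_is_toeplitz(self, small_grid):
        gamma = 20.0
        cov = nr.build_sensilla_cov(small_grid, nr.SensillaParams(40, 160, gamma))
        env = np.exp(-small_grid.times_ms / gamma)
        S = cov.C / np.outer(env, env)
        for k in range(1, 6):
            diag = np.diagonal(S, offset=k)
            assert np.allclose(diag, diag[0], rtol=1e-8)

    def test_large_gamma_limit_is_stationary(self, small_grid):
        cov_inf = nr.build_sensilla_cov(
            small_grid, nr.SensillaParams(40, 160, 1e12)
        )
        stat = nr.build_stationary_cov(small_grid, (40, 160))
        assert np.allclose(cov_inf.C, stat.C, atol=1e-6)

    def test_oscillatory_banded_structure(self):
        # fitted parameters on the mechanosensor grid (scaled to 4 kHz):
        # positive main diagonal, negative lobes off it, decay from origin
        grid = nr.Grid1D(160, 0.25)
        cov = nr.build_sensilla_cov(grid, nr.SensillaParams(75, 200, 12.17))
        C = cov.C
        assert np.all(np.diag(C) > 0)
        assert C.min() < 0  # oscillatory off-diagonal bands
        d0 = np.diag(C)
        assert d0[0] > d0[40] > d0[100]  # decays away from the origin

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            nr.SensillaParams(60, 40, 10)  # f_lo > f_hi
        with pytest.raises(ValueError):
            nr.SensillaParams(10, 40, -1)  # gamma <= 0


class TestV1:
    def test_center_variance_is_unity_prenormalization(self, small_grid2d):
        p = nr.V1Params(2.0, 1.0, small_grid2d.center)
        cov = nr.build_v1_cov(small_grid2d, p)
        # normalization rescales uniformly; undo it to check C(c,c) = 1
        c_flat = small_grid2d.center[0] * small_grid2d.width + small_grid2d.center[1]
        g = np.exp(
            -((small_grid2d.coords - np.array(small_grid2d.center)) ** 2).sum(1)
            / (2 * p.size_px**2)
        )
        raw_trace = (g**2).sum()
        prenorm = cov.C * raw_trace / small_grid2d.size
        assert prenorm[c_flat, c_flat] == pytest.approx(1.0, rel=1e-10)

    def test_symmetry(self, v1_cov):
        assert np.allclose(v1_cov.C, v1_cov.C.T, atol=1e-12)

    def test_offdiagonal_increases_with_f(self):
        grid = nr.Grid2D(6, 6)
        covs = [
            nr.build_v1_cov(grid, nr.V1Params(2.0, f, grid.center)).C
            for f in (0.5, 1.0, 2.0)
        ]
        off = ~np.eye(grid.size, dtype=bool)
        assert np.all(covs[1][off] > covs[0][off])
        assert np.all(covs[2][off] > covs[1][off])

    def test_center_outside_grid_rejected(self, small_grid2d):
        with pytest.raises(ValueError, match="outside grid"):
            nr.build_v1_cov(small_grid2d, nr.V1Params(2.0, 1.0, (20, 3)))


class TestNullModels:
    def test_unstructured_is_identity(self, small_grid):
        cov = nr.build_null_cov("unstructured", small_grid)
        assert np.array_equal(cov.C, np.eye(small_grid.size))
        assert cov.trace == pytest.approx(small_grid.size)

    def test_translation_invariant_v1_depends_on_offset_only(self, small_grid2d):
        cov = nr.build_null_cov(
            "v1_translation_invariant", small_grid2d, {"freq_px": 1.0}
        )
        h, w = small_grid2d.shape
        C = cov.C

        def entry(r1, c1, r2, c2):
            return C[r1 * w + c1, r2 * w + c2]

        # same pixel offset -> same covariance value, anywhere on the grid
        assert entry(0, 0, 2, 1) == pytest.approx(entry(3, 4, 5, 5), rel=1e-10)
        assert entry(1, 1, 1, 3) == pytest.approx(entry(6, 2, 6, 4), rel=1e-10)

    def test_fourier_null_equals_stationary(self, small_grid):
        a = nr.build_null_cov("fourier", small_grid,
                              {"f_lo_hz": 40, "f_hi_hz": 160})
        b = nr.build_stationary_cov(small_grid, (40, 160))
        assert np.allclose(a.C, b.C)

    def test_unknown_kind(self, small_grid):
        with pytest.raises(ValueError, match="unknown null model"):
            nr.build_null_cov("bogus", small_grid)

    def test_kind_grid_mismatch(self, small_grid, small_grid2d):
        with pytest.raises(ValueError):
            nr.build_null_cov("fourier", small_grid2d,
                              {"f_lo_hz": 10, "f_hi_hz": 20})
        with pytest.raises(ValueError):
            nr.build_null_cov("v1_translation_invariant", small_grid,
                              {"freq_px": 1.0})


class TestNormalizeTrace:
    def test_identity_unchanged_at_target_d(self, identity_cov):
        out = nr.normalize_trace(identity_cov, identity_cov.d)
        assert np.array_equal(out.C, identity_cov.C)

    def test_target_two_exact(self, sensilla_cov):
        out = nr.normalize_trace(sensilla_cov, 2.0)
        assert np.trace(out.C) == pytest.approx(2.0, abs=1e-12)

    def test_eigenvectors_preserved(self, sensilla_cov):
        out = nr.normalize_trace(sensilla_cov, 2.0)
        assert np.allclose(out.eigenvectors, sensilla_cov.eigenvectors)
        assert np.allclose(
            out.eigenvalues,
            sensilla_cov.eigenvalues * 2.0 / sensilla_cov.trace,
        )

    def test_invalid_targets(self, sensilla_cov):
        with pytest.raises(ValueError):
            nr.normalize_trace(sensilla_cov, 0.0)
        zero = nr.CovarianceModel(
            C=np.zeros((4, 4)), grid=nr.Grid1D(4, 1.0), kind="zero"
        )
        with pytest.raises(ValueError):
            nr.normalize_trace(zero, 4.0)


class TestEigendecompose:
    def test_identity(self):
        vals, vecs = nr.eigendecompose(np.eye(5))
        assert np.allclose(vals, 1.0)
        assert np.allclose(vecs @ vecs.T, np.eye(5), atol=1e-12)

    def test_rank_one(self):
        rng = np.random.default_rng(1)
        v = rng.standard_normal(10)
        vals, vecs = nr.eigendecompose(np.outer(v, v))
        assert vals[0] == pytest.approx(v @ v, rel=1e-12)
        assert np.allclose(vals[1:], 0.0, atol=1e-10 * vals[0])

    @pytest.mark.parametrize("d,rank,seed", [(20, 5, 0), (30, 30, 1), (15, 2, 2)])
    def test_reconstruction(self, d, rank, seed):
        C = random_psd(d, rank, seed)
        vals, vecs = nr.eigendecompose(C)
        recon = (vecs * vals) @ vecs.T
        assert np.linalg.norm(recon - C) / np.linalg.norm(C) < 1e-8

    def test_descending_order_and_sign_convention(self, sensilla_cov):
        vals = sensilla_cov.eigenvalues
        assert np.all(np.diff(vals) <= 1e-12)
        vecs = sensilla_cov.eigenvectors
        idx = np.abs(vecs).argmax(axis=0)
        assert np.all(vecs[idx, np.arange(vecs.shape[1])] >= 0)

    def test_asymmetric_rejected(self):
        A = np.arange(9.0).reshape(3, 3)
        with pytest.raises(ValueError, match="not symmetric"):
            nr.eigendecompose(A)

    def test_substantially_negative_rejected(self):
        C = np.diag([1.0, -0.5])
        with pytest.raises(ValueError, match="not PSD"):
            nr.eigendecompose(C)


@pytest.mark.parametrize("maker", ["stationary", "sensilla", "v1", "unstructured"])
def test_constructor_invariants(maker, small_grid, small_grid2d):
    """Symmetry, PSD after clipping, and exact trace for every constructor."""
    if maker == "stationary":
        cov = nr.build_stationary_cov(small_grid, (40, 160))
    elif maker == "sensilla":
        cov = nr.build_sensilla_cov(small_grid, nr.SensillaParams(40, 160, 20))
    elif maker == "v1":
        cov = nr.build_v1_cov(small_grid2d, nr.V1Params(2.0, 1.0, (3, 3)))
    else:
        cov = nr.build_null_cov("unstructured", small_grid)
    d = cov.d
    assert np.allclose(cov.C, cov.C.T, atol=1e-12)
    assert np.trace(cov.C) == pytest.approx(d, rel=1e-10)
    assert cov.eigenvalues.min() >= 0.0
    recon = (cov.eigenvectors * cov.eigenvalues) @ cov.eigenvectors.T
    assert np.linalg.norm(recon - cov.C) / np.linalg.norm(cov.C) < 1e-8
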