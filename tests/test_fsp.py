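"""FSP solver: generator structure, propagators, cycle operators, oracles."""

import math

import numpy as np
import pytest
from scipy.linalg import expm

import txcycle as tx
from txcycle import fsp
from txcycle.simulate import sample_at_ages


def _params(**kw):
    base = dict(kon=0.05, koff=0.1, kini=0.5, tres=3.5, kd=0.01,
                trep=100.0, tdiv=200.0, alpha=1.0)
    base.update(kw)
    return tx.KineticParams(**base)


class TestGenerator:
    def test_columns_sum_to_zero_below_truncation(self):
        gen = fsp.build_generator(_params(), "pre", 40)
        colsums = np.asarray(gen.Q.sum(axis=0)).ravel()
        # all columns except the top mRNA block (truncation sink) sum to 0
        assert np.allclose(colsums[: 4 * 40], 0.0, atol=1e-12)
        assert np.all(colsums[4 * 40:] <= 1e-12)

    def test_post_replication_activation_entries(self):
        p = _params(alpha=0.55)
        gen = fsp.build_generator(p, "post", 5)
        a = p.alpha * p.kon
        A = gen.A
        assert A[0, 0] == pytest.approx(-2 * a)
        assert A[1, 0] == pytest.approx(a)
        assert A[3, 1] == pytest.approx(a)
        assert A[3, 3] == pytest.approx(-2 * p.koff)

    def test_pure_switching_reaches_telegraph_duty(self):
        """With kini = kd = 0 the ON fraction of copy 1 is kon/(kon+koff)."""
        p = _params(kini=0.0, kd=0.0)
        gen = fsp.build_generator(p, "pre", 3)
        P = np.zeros(4 * 4)
        P[0] = 1.0
        out = fsp.propagate(P, gen, 0.0, 500.0, backend="uniform")
        on = out.reshape(-1, 4)[:, 1].sum() + out.reshape(-1, 4)[:, 3].sum()
        assert on == pytest.approx(p.kon / (p.kon + p.koff), abs=1e-9)

    def test_invalid_regime_and_mmax(self):
        with pytest.raises(ValueError):
            fsp.build_generator(_params(), "mid", 10)
        with pytest.raises(ValueError):
            fsp.build_generator(_params(), "pre", 0)


class TestPropagate:
    def test_zero_generator_is_identity(self):
        p = _params(kon=0.0, koff=0.0, kini=0.0, kd=0.0)
        gen = fsp.build_generator(p, "pre", 10)
        P = np.random.default_rng(0).dirichlet(np.ones(44))
        for backend in ("discrete", "expm", "uniform"):
            assert np.allclose(fsp.propagate(P, gen, 0, 10, backend), P)

    def test_pure_death_is_binomial_thinning(self):
        """Degradation alone thins a delta at m=10 binomially with e^{-kd t}."""
        from scipy.stats import binom

        p = _params(kon=0.0, koff=0.0, kini=0.0, kd=0.05)
        gen = fsp.build_generator(p, "pre", 15)
        P = np.zeros(4 * 16)
        P[4 * 10] = 1.0
        out = fsp.propagate(P, gen, 0.0, 30.0, backend="uniform")
        marg = out.reshape(-1, 4).sum(axis=1)
        expect = binom.pmf(np.arange(16), 10, math.exp(-0.05 * 30.0))
        assert np.abs(marg - expect).max() < 1e-9

    def test_discrete_matches_matrix_exponential(self):
        """Euler stepping at dt=0.001 min tracks the dense exponential.

        Mass agreement at 1e-6 (the solver's convergence criterion); the
        pointwise L1 deviation of the first-order propagator is O(dt),
        about 1e-5 on this segment.
        """
        p = _params()
        gen = fsp.build_generator(p, "pre", 30)
        P = np.zeros(4 * 31)
        P[0] = 1.0
        dense = expm(gen.Q.toarray() * 60.0) @ P
        disc = fsp.propagate(P, gen, 0.0, 60.0, backend="discrete")
        assert abs(dense.sum() - disc.sum()) < 1e-6
        assert np.abs(dense - disc).sum() < 2e-5
        uni = fsp.propagate(P, gen, 0.0, 60.0, backend="uniform")
        assert np.abs(dense - uni).sum() < 1e-9


class TestCycleOperators:
    def test_replication_copies_state(self):
        P = np.zeros(4 * 8)
        P[4 * 5 + 1] = 1.0  # (s1=ON, s2=OFF, m=5)
        out = fsp.apply_replication(P)
        assert out[4 * 5 + 3] == 1.0
        assert out.sum() == pytest.approx(1.0)

    def test_replication_operator_idempotent(self):
        R = fsp.replication_operator(12)
        assert (R @ R - R).nnz == 0

    def test_b_and_v_commute(self):
        B = fsp.division_operator(25)
        V = fsp.state_collapse_operator(25)
        rng = np.random.default_rng(1)
        for _ in range(5):
            v = rng.random(4 * 26)
            assert np.abs(B @ (V @ v) - V @ (B @ v)).max() < 1e-12

    def test_division_halves_mean_and_keeps_zero(self):
        mmax = 40
        P = np.zeros(4 * (mmax + 1))
        P[4 * 30] = 1.0  # delta at m=30
        out = fsp.apply_division(P)
        m = np.arange(mmax + 1)
        marg = out.reshape(-1, 4).sum(axis=1)
        assert (m * marg).sum() == pytest.approx(15.0)
        P0 = np.zeros(4 * (mmax + 1))
        P0[1] = 1.0  # m=0, s1=ON
        out0 = fsp.apply_division(P0)
        assert out0.reshape(-1, 4).sum(axis=1)[0] == pytest.approx(1.0)


class TestCyclostationary:
    def test_columns_normalised_and_residual_small(self, fast_cycle_params):
        grid = fsp.solve_cyclostationary(fast_cycle_params, mmax=60,
                                         backend="discrete")
        sums = grid.locus_P.sum(axis=0)
        assert np.all(np.abs(sums - 1.0) < 1e-6)
        assert grid.residuals[-1] < 1e-6
        assert grid.locus_P.min() >= 0.0

    def test_constitutive_limit_matches_deterministic_mean(self):
        """Always-ON gene: FSP mean equals the closed-form mean model."""
        from txcycle import deterministic as det

        p = tx.KineticParams(kon=1.0, koff=0.0, kini=0.5, tres=2.0, kd=0.02,
                             trep=150.0, tdiv=300.0, alpha=1.0)
        grid = fsp.solve_cyclostationary(p, mmax=120, backend="uniform")
        dp = det.DeterministicParams(kini_eff=0.5, kd_eff=0.02, trep=150.0,
                                     tdiv=300.0, t1=150.0, t2=150.0001)
        R = det.mean_trajectory(dp, grid.times)
        means = (np.arange(121)[:, None] * grid.mature_locus).sum(axis=0)
        assert np.max(np.abs(means - R) / R) < 0.005

    def test_matches_gillespie_histograms(self, fast_cycle_params):
        """Mature and nascent distributions match the stochastic oracle.

        10^4 independent lineages observed at each recorded time point;
        total variation below 0.03 everywhere.
        """
        p = fast_cycle_params
        grid = fsp.solve_cyclostationary(p, mmax=60, backend="uniform")
        mat, sig, _ = sample_at_ages(p, grid.times, 10_000, seed=21)
        mature = grid.mature_locus
        for j in range(len(grid.times)):
            h = np.bincount(mat[:, j], minlength=61)[:61] / mat.shape[0]
            assert 0.5 * np.abs(h - mature[:, j]).sum() < 0.03
        # nascent: per-copy integer signal versus the Monte Carlo pmf
        nas = fsp.nascent_distribution(p, grid.times, n_paths=200_000, seed=5)
        for j in (0, 5, 14, 19):
            s = sig[:, j, 0]
            k = np.floor(s + 0.5).astype(int)
            h = np.bincount(k, minlength=nas.shape[0])[: nas.shape[0]] / len(k)
            assert 0.5 * np.abs(h - nas[:, j]).sum() < 0.03


class TestNascent:
    def test_no_initiation_is_point_mass_at_zero(self):
        p = _params(kini=0.0)
        d = fsp.nascent_distribution(p, [10.0], n_paths=5000, seed=1)
        assert d[0, 0] == 1.0

    def test_always_on_mean(self):
        """ON copy: mean signal = kini*tres/2 under uniform probes."""
        p = tx.KineticParams(kon=1.0, koff=0.0, kini=2.0, tres=3.0, kd=0.01,
                             trep=100.0, tdiv=200.0)
        pmf = fsp._nascent_pmf(p, "pre", 400_000, seed=2)
        mean = (np.arange(len(pmf)) * pmf).sum()
        assert mean == pytest.approx(0.5 * 2.0 * 3.0, rel=0.02)

    def test_mean_matches_closed_form_both_regimes(self, oct4_like):
        """MC mean reproduces lam*g*kini*tres*duty within 1% per copy."""
        for regime in ("pre", "post"):
            pmf = fsp._nascent_pmf(oct4_like, regime, 400_000, seed=3)
            mean = (np.arange(len(pmf)) * pmf).sum()
            expect = fsp.nascent_mean(oct4_like, regime)
            assert abs(mean - expect) / expect < 0.01


class TestConvolve:
    def test_delta_and_mean_doubling(self):
        d = np.zeros(5)
        d[0] = 1.0
        assert fsp.convolve_copies(d, 2)[0] == 1.0
        rng = np.random.default_rng(3)
        p = rng.dirichlet(np.ones(20))
        m1 = (np.arange(20) * p).sum()
        c = fsp.convolve_copies(p, 2)
        assert (np.arange(len(c)) * c).sum() == pytest.approx(2 * m1)

    def test_poisson_identity(self):
        from scipy.stats import poisson

        lam = 3.0
        k = np.arange(80)
        c2 = fsp.convolve_copies(poisson.pmf(k, lam), 2)[:80]
        assert np.abs(c2 - poisson.pmf(k, 2 * lam)).max() < 1e-10
        c4 = fsp.convolve_copies(poisson.pmf(k, lam), 4)[:80]
        assert np.abs(c4 - poisson.pmf(k, 4 * lam)).max() < 1e-9

    def test_truncation_renormalises_with_warning(self):
        from scipy.stats import poisson

        with pytest.warns(UserWarning, match="truncated"):
            out = fsp.convolve_copies(poisson.pmf(np.arange(30), 10.0), 2, mmax=25)
        assert out.sum() == pytest.approx(1.0)


def test_grid_round_trip_hdf5(fast_cycle_params, tmp_path):
    grid = fsp.solve_cyclostationary(fast_cycle_params, mmax=70, backend="uniform")
    path = tmp_path / "grid.h5"
    grid.save(path)
    back = fsp.DistributionGrid.load(path)
    assert np.array_equal(back.locus_P, grid.locus_P)
    assert back.mmax == grid.mmax
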