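"""Per-lineage and joint fitness inference."""

import numpy as np
import pytest

from pepfit import Experiment, classify_lineage, fit_experiment, fit_lineage
from pepfit.inference import (
    LineageFitError,
    align_gauge,
    fisher_weight,
    pearson_kappa,
    profile_kappa,
    read_filter,
)
from pepfit.likelihoods import expected_reads, loglik


def _grid_mle(counts, N, W, kappa, iters=5):
    """Brute-force 2-D nested grid maximization, independent of Newton."""
    counts = np.asarray(counts, dtype=float)
    t = np.arange(1, len(counts) + 1)
    a = np.asarray(N, dtype=float) / np.cumprod(W)
    lo0, hi0 = -25.0, -0.5
    lo1, hi1 = -3.0, 3.0
    best = None
    for _ in range(iters):
        g0 = np.linspace(lo0, hi0, 41)
        g1 = np.linspace(lo1, hi1, 41)
        vals = np.array(
            [[loglik(counts, np.exp(x0 + t * x1) * a, kappa) for x1 in g1] for x0 in g0]
        )
        i, j = np.unravel_index(np.argmax(vals), vals.shape)
        best = (g0[i], g1[j])
        s0, s1 = g0[1] - g0[0], g1[1] - g1[0]
        lo0, hi0 = best[0] - 2 * s0, best[0] + 2 * s0
        lo1, hi1 = best[1] - 2 * s1, best[1] + 2 * s1
    return np.exp(best[0]), np.exp(best[1])


class TestFitLineage:
    def test_constant_counts_give_neutral_fit(self):
        p0, omega, _ = fit_lineage([10, 10, 10, 10], [1000] * 4, np.ones(4))
        assert omega == pytest.approx(1.0, abs=1e-8)
        assert p0 == pytest.approx(0.01, abs=1e-8)

    def test_exact_geometric_counts(self):
        p0, omega, _ = fit_lineage([10, 20, 40, 80], [1000] * 4, np.ones(4))
        assert omega == pytest.approx(2.0, abs=1e-6)
        # timepoint 1 already follows one selection round: lam_1 = N * p0 * omega
        assert p0 == pytest.approx(0.005, abs=1e-6)

    def test_poisson_moment_conditions_hold(self, rng):
        for _ in range(20):
            counts = rng.poisson(rng.uniform(3, 80), size=4)
            if np.count_nonzero(counts) < 2:
                continue
            N = np.full(4, 10_000.0)
            W = np.array([1.0, 1.05, 1.1, 1.2])
            p0, omega, _ = fit_lineage(counts, N, W)
            lam = expected_reads(p0, omega, W, N)
            t = np.arange(1, 5)
            assert lam.sum() == pytest.approx(counts.sum(), abs=1e-6)
            assert (t * lam).sum() == pytest.approx((t * counts).sum(), abs=1e-6)

    @pytest.mark.parametrize("kappa", [1.0, 2.0])
    def test_matches_grid_search_oracle(self, rng, kappa):
        N = np.full(4, 50_000.0)
        W = np.array([1.0, 0.95, 1.08, 1.1])
        checked = 0
        while checked < 50:
            lam_true = expected_reads(
                rng.uniform(1e-4, 5e-3), rng.uniform(0.5, 1.8), W, N
            )
            counts = rng.poisson(lam_true)
            if np.count_nonzero(counts) < 2 or counts.sum() < 5:
                continue
            p0, omega, _ = fit_lineage(counts, N, W, kappa)
            _, omega_grid = _grid_mle(counts, N, W, kappa)
            assert omega == pytest.approx(omega_grid, abs=1e-3)
            checked += 1

    def test_single_day_reads_rejected(self):
        with pytest.raises(LineageFitError):
            fit_lineage([0, 9, 0, 0], [1000] * 4, np.ones(4))


class TestReadFilter:
    @pytest.mark.parametrize(
        "counts,ok",
        [([3, 2, 0, 0], True), ([4, 0, 0, 0], False), ([2, 2, 0, 0], False),
         ([0, 0, 0, 9], False)],
    )
    def test_min_reads_and_two_days(self, counts, ok):
        assert read_filter(np.array(counts), min_reads=5)[0] is ok


class TestFisherWeight:
    def test_weight_is_inverse_squared_se(self, rng):
        N = np.full(4, 10_000.0)
        W = np.ones(4)
        counts = rng.poisson(40, size=4)
        p0, omega, _ = fit_lineage(counts, N, W)
        se, weight = fisher_weight(counts, N, W, 1.0, p0, omega)
        assert weight * se**2 == pytest.approx(1.0)

    @pytest.mark.parametrize("kappa", [1.0, 2.2])
    def test_matches_finite_difference_hessian(self, rng, kappa):
        N = np.full(4, 20_000.0)
        W = np.array([1.0, 1.02, 1.07, 1.1])
        for _ in range(20):
            counts = rng.poisson(rng.uniform(10, 200), size=4)
            if np.count_nonzero(counts) < 2:
                continue
            p0, omega, _ = fit_lineage(counts, N, W, kappa)
            se, _ = fisher_weight(counts, N, W, kappa, p0, omega)

            def negll(p, w):
                t = np.arange(1, 5)
                return -loglik(counts, p * w**t * (N / np.cumprod(W)), kappa)

            hp, hw = p0 * 1e-4, omega * 1e-4
            H = np.empty((2, 2))
            H[0, 0] = (negll(p0 + hp, omega) - 2 * negll(p0, omega)
                       + negll(p0 - hp, omega)) / hp**2
            H[1, 1] = (negll(p0, omega + hw) - 2 * negll(p0, omega)
                       + negll(p0, omega - hw)) / hw**2
            H[0, 1] = H[1, 0] = (
                negll(p0 + hp, omega + hw) - negll(p0 + hp, omega - hw)
                - negll(p0 - hp, omega + hw) + negll(p0 - hp, omega - hw)
            ) / (4 * hp * hw)
            se_num = np.sqrt(np.linalg.inv(H)[1, 1])
            assert se == pytest.approx(se_num, rel=1e-3)

    def test_se_halves_when_information_quadruples(self, rng):
        N = np.full(4, 10_000.0)
        W = np.ones(4)
        counts = np.array([30, 42, 35, 28])
        p0, omega, _ = fit_lineage(counts, N, W)
        se1, _ = fisher_weight(counts, N, W, 1.0, p0, omega)
        p0b, omegab, _ = fit_lineage(counts * 4, N * 4, W)
        se2, _ = fisher_weight(counts * 4, N * 4, W, 1.0, p0b, omegab)
        assert se2 == pytest.approx(se1 / 2, rel=0.05)


class TestClassify:
    @pytest.mark.parametrize(
        "omega,se,expected",
        [(1.5, 0.1, "increase"), (1.0, 0.1, "not_supported"),
         (0.5, 0.1, "decrease"), (1.5, 0.3, "not_supported"),
         (1.2, np.inf, "not_supported")],
    )
    def test_wald_classification(self, omega, se, expected):
        assert classify_lineage(omega, se) == expected


class TestFitExperiment:
    def test_constant_frequencies_are_neutral(self):
        counts = np.array([[[50], [50], [50], [50]], [[80], [80], [80], [80]]])
        exp = Experiment(["a", "b"], counts, np.full((4, 1), 10_000))
        fit = fit_experiment(exp, model="poisson")
        for f in fit.fits:
            assert f.omega == pytest.approx(1.0, abs=1e-6)
        np.testing.assert_allclose(fit.trajectory.W, 1.0, atol=1e-6)
        assert fit.trajectory.W[0] == 1.0
        assert fit.converged

    def test_read_filter_reports_rejections(self):
        counts = np.array([[[50], [50], [50], [50]], [[2], [1], [0], [0]],
                           [[0], [0], [9], [0]]])
        exp = Experiment(["keep", "few", "oneday"], counts, np.full((4, 1), 10_000))
        fit = fit_experiment(exp, model="poisson")
        assert {f.id for f in fit.fits} == {"keep"}
        assert set(fit.rejected) == {"few", "oneday"}

    def test_poisson_score_equations_at_joint_mle(self, recovery_sim):
        _, sim, _ = recovery_sim
        fitp = fit_experiment(sim["experiment"], model="poisson")
        summed = sim["experiment"].summed()
        ids = summed.peptide_ids
        N = summed.totals[:, 0]
        gaps = []
        for f in fitp.fits:
            n = summed.counts[ids.index(f.id), :, 0]
            lam = expected_reads(f.p0, f.omega, fitp.trajectory.W, N)
            gaps.append(abs(n.sum() - lam.sum()))
        assert max(gaps) < 1e-6

    def test_simulation_recovery_nb(self, recovery_sim):
        _, sim, fit = recovery_sim
        omega_true = np.array([sim["omega_true"][f.id] for f in fit.fits])
        omega_hat = np.array([f.omega for f in fit.fits])
        r = np.corrcoef(np.log(omega_hat), np.log(omega_true))[0, 1]
        assert r >= 0.95
        assert fit.dispersion.kappa == pytest.approx(2.0, rel=0.2)
        assert fit.converged

    def test_W_recovery_after_gauge_alignment(self, recovery_sim):
        _, sim, fit = recovery_sim
        W_ref = sim["W_true"] / sim["W_true"][0]
        c = align_gauge(fit.trajectory.W, W_ref)
        W_aligned = fit.trajectory.W.copy()
        W_aligned[1:] *= c
        assert np.max(np.abs(W_aligned / W_ref - 1)) < 0.05

    def test_wald_interval_coverage(self, recovery_sim):
        _, sim, fit = recovery_sim
        W_ref = sim["W_true"] / sim["W_true"][0]
        c = align_gauge(fit.trajectory.W, W_ref)
        omega_true = np.array(
            [sim["omega_true"][f.id] for f in fit.fits]
        ) / sim["W_true"][0]
        omega_hat = c * np.array([f.omega for f in fit.fits])
        se = c * np.array([f.se for f in fit.fits])
        covered = (omega_hat - 1.96 * se <= omega_true) & (
            omega_true <= omega_hat + 1.96 * se
        )
        assert 0.90 <= covered.mean() <= 0.98

    def test_type_one_error_under_neutral_truth(self, neutral_sim):
        _, _, fit = neutral_sim
        frac = np.mean([f.classification != "not_supported" for f in fit.fits])
        assert frac <= 0.075

    def test_kappa_recovered_by_moments_not_profile(self, recovery_sim):
        # the Pearson moment estimator sees the planted overdispersion; the
        # naive profile estimator at the fitted means collapses to Poisson
        _, sim, fit = recovery_sim
        assert 1.6 <= fit.dispersion.kappa <= 2.4
        summed = sim["experiment"].summed()
        C = summed.counts[:, :, 0].astype(float)
        keep = C.sum(axis=1) >= 5
        lam = np.stack(
            [expected_reads(f.p0, f.omega, fit.trajectory.W, summed.totals[:, 0])
             for f in fit.fits]
        )
        assert profile_kappa(C[keep], lam) < 1.3

    def test_single_lineage_fixes_W_at_anchor(self):
        counts = np.array([[[30], [45], [60], [80]]])
        exp = Experiment(["only"], counts, np.full((4, 1), 10_000))
        fit = fit_experiment(exp, model="poisson")
        np.testing.assert_array_equal(fit.trajectory.W, np.ones(4))


class TestPearsonKappa:
    def test_clamped_at_poisson_boundary(self):
        lam = np.full((50, 4), 100.0)
        C = lam.copy()  # zero residual dispersion
        assert pearson_kappa(C, lam, n_params=0) == 1.0

    def test_recovers_inflation_at_known_means(self, rng):
        lam = np.full((400, 4), 80.0)
        C = rng.negative_binomial(lam / 1.5, 1 / 2.5)
        est = pearson_kappa(C, lam, n_params=0)
        assert est == pytest.approx(2.5, rel=0.1)
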