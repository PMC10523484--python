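"""BAR/Zwanzig estimators, λ composition, cycle closure, kNN corrections."""

import numpy as np
import pytest

from qtrap import fep, synthetic
from qtrap.constants import KB, kt
from qtrap.exceptions import LambdaCoverageError, QtrapError
from qtrap.io_tables import FepWindowSamples

TEMP = 310.0


def _crooks_window(dg, sigma, n, seed, n_rev=None):
    rng = np.random.default_rng(seed)
    shift = sigma ** 2 / (2.0 * KB * TEMP)
    return FepWindowSamples(
        0.0, 1.0,
        dg + shift + sigma * rng.standard_normal(n),
        dg - shift + sigma * rng.standard_normal(n_rev or n),
    )


class TestZwanzig:
    def test_constant_samples_return_constant(self):
        assert fep.zwanzig_dg([2.5] * 7, TEMP) == pytest.approx(2.5)

    def test_single_sample_identity(self):
        assert fep.zwanzig_dg([0.3], TEMP) == pytest.approx(0.3)

    def test_gaussian_closed_form(self):
        """For ΔU ~ N(μ, σ²): ΔG = μ − σ²/(2·kB·T)."""
        mu, sigma, n = 2.0, 1.0, 40000
        rng = np.random.default_rng(0)
        est = fep.zwanzig_dg(mu + sigma * rng.standard_normal(n), TEMP)
        expected = mu - sigma ** 2 / (2.0 * KB * TEMP)
        assert abs(est - expected) < 3 * 2.0 * sigma / np.sqrt(n)

    def test_empty_rejected(self):
        with pytest.raises(QtrapError):
            fep.zwanzig_dg([], TEMP)


class TestBar:
    def test_symmetric_distributions_give_zero(self):
        rng = np.random.default_rng(1)
        w = FepWindowSamples(0.0, 1.0, rng.standard_normal(4000),
                             rng.standard_normal(4000))
        est = fep.bar_dg(w, TEMP)
        assert abs(est.delta_g) < 3 * est.stderr

    def test_crooks_gaussian_recovery(self):
        est = fep.bar_dg(_crooks_window(1.0, 1.0, 4000, seed=3), TEMP)
        assert est.converged
        assert est.delta_g == pytest.approx(1.0, abs=0.05)

    def test_antisymmetry_exact(self):
        w = _crooks_window(0.8, 1.2, 300, seed=4, n_rev=200)
        flipped = FepWindowSamples(0.0, 1.0, -w.reverse_du, -w.forward_du)
        a = fep.bar_dg(w, TEMP).delta_g
        b = fep.bar_dg(flipped, TEMP).delta_g
        assert a == pytest.approx(-b, abs=1e-7)

    def test_unequal_sample_counts_handled(self):
        est = fep.bar_dg(_crooks_window(1.0, 1.0, 4000, seed=5, n_rev=1000), TEMP)
        assert est.delta_g == pytest.approx(1.0, abs=0.1)

    def test_reverse_empty_directs_to_zwanzig(self):
        w = FepWindowSamples(0.0, 1.0, np.array([0.1, 0.2]))
        with pytest.raises(QtrapError, match="zwanzig"):
            fep.bar_dg(w, TEMP)

    def test_no_overlap_flags_unconverged(self):
        rng = np.random.default_rng(6)
        w = FepWindowSamples(
            0.0, 1.0,
            200.0 + 0.01 * rng.standard_normal(50),
            -200.0 + 0.01 * rng.standard_normal(50),
        )
        with pytest.warns(UserWarning, match="overlap"):
            est = fep.bar_dg(w, TEMP)
        assert not est.converged

    def test_stderr_scales_as_inverse_sqrt_n(self):
        """Asymptotic standard error shrinks like 1/√n."""
        scaled = []
        for n in (500, 2000, 8000):
            (w,) = synthetic.generate_fep_samples([1.0], 1.0, n, TEMP, seed=4,
                                                  lambdas=(0.0, 1.0))
            scaled.append(fep.bar_dg(w, TEMP).stderr * np.sqrt(n))
        assert np.ptp(scaled) / np.mean(scaled) < 0.2

    def test_bar_beats_zwanzig_in_rmse(self):
        """Two-sided BAR dominates one-sided exponential averaging."""
        true_dg, sigma, n = 1.0, 2.0, 100
        bar_err, zw_err = [], []
        for seed in range(50):
            w = _crooks_window(true_dg, sigma, n, seed=100 + seed)
            bar_err.append(fep.bar_dg(w, TEMP).delta_g - true_dg)
            zw_err.append(fep.zwanzig_dg(w.forward_du, TEMP) - true_dg)
        assert np.sqrt(np.mean(np.square(bar_err))) <= np.sqrt(
            np.mean(np.square(zw_err))
        )


class TestComposeWindows:
    def _windows(self, dg=0.4, sigma=0.5, n=200, seed=0):
        return synthetic.generate_fep_samples([dg] * 10, sigma, n, TEMP, seed=seed)

    def test_ten_windows_sum(self):
        windows = synthetic.generate_fep_samples([0.4] * 10, 0.0, 1, TEMP, seed=0)
        ests = [fep.bar_dg(w, TEMP) for w in windows]
        total = fep.compose_windows(ests, windows, TEMP)
        assert total.delta_g == pytest.approx(4.0, abs=1e-6)

    def test_study_lambda_schedule_accepted(self):
        windows = self._windows()
        ests = [fep.bar_dg(w, TEMP) for w in windows]
        total = fep.compose_windows(ests, windows, TEMP)
        assert len(total.per_window) == 10
        assert total.hysteresis is not None and total.hysteresis >= 0.0

    def test_missing_window_names_interval(self):
        windows = self._windows()
        dropped = [w for w in windows if not (w.lambda_from == 0.25)]
        ests = [fep.bar_dg(w, TEMP) for w in dropped]
        with pytest.raises(LambdaCoverageError, match="0.25"):
            fep.compose_windows(ests, dropped, TEMP)

    def test_overlapping_windows_rejected(self):
        w1 = FepWindowSamples(0.0, 0.6, np.array([0.1]), np.array([0.1]))
        w2 = FepWindowSamples(0.5, 1.0, np.array([0.1]), np.array([0.1]))
        ests = [fep.bar_dg(w, TEMP) for w in (w1, w2)]
        with pytest.raises(LambdaCoverageError, match="overlap"):
            fep.compose_windows(ests, [w1, w2], TEMP)


class TestCycle:
    def test_arithmetic(self):
        assert fep.ddg_cycle(10.0, 6.0).ddg_bind == 4.0
        assert fep.ddg_cycle(3.3, 3.3).ddg_bind == 0.0

    def test_identity_invariant(self):
        r = fep.ddg_cycle(9.7, 6.2, 0.05, 0.04)
        assert r.ddg_bind == r.dg_mut_unbound - r.dg_mut_bound

    def test_full_pipeline_recovery(self):
        """Synthetic cycle with true ΔΔG = 4 recovered within 0.1 kcal/mol."""
        data = synthetic.generate_cycle_dataset(10.0, 6.0, sigma=1.0, n=4000,
                                                seed=1)
        results = fep.AlchemicalCycleModel(data.unbound, data.bound, TEMP).fit()
        assert results.ddg_bind == pytest.approx(4.0, abs=0.1)
        assert results.stderr < 0.1
        assert "ΔΔG_bind" in results.summary()

    def test_four_state_cycle_closes(self):
        """Legs around a closed 4-state cycle sum to ~0 (3σ)."""
        leg_dgs = [2.0, 3.0, -1.0, -4.0]
        total, var = 0.0, 0.0
        for i, dg in enumerate(leg_dgs):
            windows = synthetic.generate_fep_samples([dg / 10] * 10, 1.0, 1000,
                                                     TEMP, seed=50 + i)
            ests = [fep.bar_dg(w, TEMP) for w in windows]
            leg = fep.compose_windows(ests, windows, TEMP)
            total += leg.delta_g
            var += leg.stderr ** 2
        assert abs(total) < 3.0 * np.sqrt(var)


class TestKnnCorrection:
    def test_identical_ensembles_give_zero(self):
        r = np.linspace(0.1, 2.0, 50)
        corr = fep.knn_correction(r, r, dimension=3)
        assert corr.correction == 0.0
        assert corr.k == 4  # fourth nearest neighbor by default

    def test_density_calibrated_on_gaussian_mode(self):
        """Geometric-mean ρ̂ at a 3-D Gaussian mode is within 15% of truth."""
        rng = np.random.default_rng(5)
        logs = []
        for _ in range(200):
            r = np.linalg.norm(rng.standard_normal((5000, 3)), axis=1)
            logs.append(np.log(fep.knn_density(r, 4, dimension=3)))
        truth = (2.0 * np.pi) ** -1.5
        assert np.exp(np.mean(logs)) == pytest.approx(truth, rel=0.15)

    def test_known_density_ratio(self):
        """Two Gaussian ensembles of different width: known log-density gap."""
        rng = np.random.default_rng(8)
        corrs = []
        for _ in range(100):
            ra = np.linalg.norm(rng.standard_normal((4000, 3)), axis=1)
            rb = 2.0 * np.linalg.norm(rng.standard_normal((4000, 3)), axis=1)
            corrs.append(
                fep.knn_correction(ra, rb, dimension=3, temperature=TEMP).correction
            )
        expected = -kt(TEMP) * np.log(8.0)  # ρ_a/ρ_b = 2³ at the mode
        assert np.mean(corrs) == pytest.approx(expected, abs=0.1)

    def test_too_few_samples_rejected(self):
        with pytest.raises(QtrapError, match="more than k"):
            fep.knn_density([0.1, 0.2, 0.3], 4, dimension=3)

    def test_duplicate_reference_samples_rejected(self):
        with pytest.raises(QtrapError, match="zero"):
            fep.knn_density([0.0] * 10, 4, dimension=3)
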