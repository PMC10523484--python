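"""Distance-distribution modes and tunneling-rate ratios."""

import numpy as np
import pytest
from hypothesis import assume, given, strategies as st

from qtrap import synthetic, tunneling
from qtrap.exceptions import QtrapError
from qtrap.io_tables import DistanceSeries


def _series(values, label=""):
    values = np.asarray(values, dtype=float)
    return DistanceSeries(np.arange(values.size) * 1e-3, values, label=label)


def _mixture(components, n, seed, label=""):
    return synthetic.generate_distance_mixture(
        synthetic.MixtureSpec(list(components), n, seed=seed, label=label)
    )


class TestFindModes:
    def test_unimodal_recovers_single_mode(self):
        series = _mixture([(1.0, 14.1, 0.2)], 100000, seed=2, label="WT")
        modes = tunneling.find_modes(series)
        assert len(modes) == 1
        assert modes.primary == pytest.approx(14.1, abs=0.03)

    def test_bimodal_prominence_ordering(self):
        """60/40 mixture at 13.5/14.1 Å: prominent mode first."""
        series = _mixture([(0.6, 13.5, 0.15), (0.4, 14.1, 0.15)], 100000,
                          seed=2, label="A52T")
        modes = tunneling.find_modes(series)
        assert len(modes) == 2
        assert modes.modes[0][0] == pytest.approx(13.5, abs=0.05)
        assert modes.modes[1][0] == pytest.approx(14.1, abs=0.05)
        assert modes.modes[0][1] > modes.modes[1][1]

    def test_equal_weights_equal_heights(self):
        series = _mixture([(0.5, 12.0, 0.1), (0.5, 16.0, 0.1)], 100000, seed=3)
        modes = tunneling.find_modes(series)
        assert len(modes) == 2
        h1, h2 = modes.modes[0][1], modes.modes[1][1]
        assert abs(h1 - h2) / max(h1, h2) < 0.05

    def test_constant_series_rejected(self):
        with pytest.raises(QtrapError, match="constant"):
            tunneling.find_modes(_series(np.full(200, 14.1)))

    def test_auto_bandwidth_needs_samples(self):
        with pytest.raises(QtrapError, match="100"):
            tunneling.find_modes(_series([13.0, 14.0, 15.0]))

    @given(
        sep=st.floats(min_value=1.4, max_value=3.0),
        sd=st.floats(min_value=0.1, max_value=0.2),
        w=st.floats(min_value=0.35, max_value=0.65),
        seed=st.integers(min_value=0, max_value=100),
    )
    def test_recovers_well_separated_component_means(self, sep, sd, w, seed):
        """Mixture means come back within 0.05 Å when separation > 3 bandwidths."""
        m1 = 13.0
        series = _mixture([(w, m1, sd), (1.0 - w, m1 + sep, sd)], 20000,
                          seed=seed)
        modes = tunneling.find_modes(series)
        assume(sep > 3.0 * (modes.bandwidth + sd))
        found = sorted(modes.positions[:2])
        assert found[0] == pytest.approx(m1, abs=0.05)
        assert found[1] == pytest.approx(m1 + sep, abs=0.05)

    def test_em_crosscheck_agrees_with_kde(self):
        series = _mixture([(0.6, 13.5, 0.15), (0.4, 14.1, 0.15)], 50000, seed=4)
        means, sds, weights = tunneling.fit_two_gaussians(series, seed=0)
        assert means[0] == pytest.approx(13.5, abs=0.05)
        assert means[1] == pytest.approx(14.1, abs=0.05)
        assert weights[0] == pytest.approx(0.6, abs=0.03)


class TestRateRatioPeaks:
    def test_equal_distances_unity(self):
        assert tunneling.rate_ratio_peaks(14.1, 14.1, 1.8) == 1.0

    def test_reciprocal_antisymmetry(self):
        a = tunneling.rate_ratio_peaks(14.1, 13.5, 1.8)
        b = tunneling.rate_ratio_peaks(13.5, 14.1, 1.8)
        assert a * b == pytest.approx(1.0, rel=1e-12)

    @given(
        a=st.floats(min_value=5.0, max_value=25.0),
        b=st.floats(min_value=5.0, max_value=25.0),
        c=st.floats(min_value=5.0, max_value=25.0),
    )
    def test_composition(self, a, b, c):
        beta = 1.8
        lhs = (tunneling.rate_ratio_peaks(a, b, beta)
               * tunneling.rate_ratio_peaks(b, c, beta))
        assert lhs == pytest.approx(tunneling.rate_ratio_peaks(a, c, beta),
                                    rel=1e-9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(QtrapError):
            tunneling.rate_ratio_peaks(14.1, 13.5, -1.0)
        with pytest.raises(QtrapError):
            tunneling.rate_ratio_peaks(-14.1, 13.5, 1.8)


class TestRateRatioEnsemble:
    def test_identical_series_unity(self):
        s = _series([13.5, 13.9, 14.4, 14.0])
        assert tunneling.rate_ratio_ensemble(s, s, 1.8) == pytest.approx(1.0)

    def test_degenerate_series_match_peak_ratio(self):
        ref = _series(np.full(10, 14.1))
        alt = _series(np.full(10, 13.5))
        ens = tunneling.rate_ratio_ensemble(ref, alt, 1.8)
        assert ens == pytest.approx(tunneling.rate_ratio_peaks(14.1, 13.5, 1.8),
                                    abs=1e-6)

    def test_invariant_under_reordering_and_duplication(self):
        rng = np.random.default_rng(0)
        vals = 14.0 + 0.3 * rng.standard_normal(500)
        ref = _series(np.full(500, 14.1))
        a = tunneling.rate_ratio_ensemble(ref, _series(vals), 1.8)
        b = tunneling.rate_ratio_ensemble(ref, _series(rng.permutation(vals)), 1.8)
        c = tunneling.rate_ratio_ensemble(ref, _series(np.tile(vals, 3)), 1.8)
        assert a == pytest.approx(b, rel=1e-12)
        assert a == pytest.approx(c, rel=1e-12)

    def test_mutant_ensemble_between_unity_and_peak_ratio(self):
        """Bimodal mutant vs unimodal reference: 1 < ensemble ≤ peak ratio."""
        wt = _mixture([(1.0, 14.1, 0.2)], 100000, seed=2, label="WT")
        mut = _mixture([(0.6, 13.5, 0.15), (0.4, 14.1, 0.15)], 100000,
                       seed=3, label="A52T")
        ens = tunneling.rate_ratio_ensemble(wt, mut, 1.8)
        peak = tunneling.rate_ratio_peaks(14.1, 13.5, 1.8)
        assert 1.0 < ens <= peak * 1.15  # ensemble averaging tempers the peak value


class TestMarcusRate:
    PARAMS = dict(beta_decay=1.8, coupling_h0=1.0, reorganization_lambda=20.0,
                  r_ref=14.1)

    def test_activationless_point_maximizes_rate(self):
        lam = self.PARAMS["reorganization_lambda"]
        rates = [
            tunneling.marcus_rate(
                tunneling.EtParams(**self.PARAMS, driving_dg0=dg0), 14.1
            )
            for dg0 in np.linspace(-2 * lam, 0.0, 41)
        ]
        assert np.argmax(rates) == 20  # ΔG° = −λ

    def test_coupling_squared_dependence(self):
        p1 = tunneling.EtParams(**self.PARAMS, driving_dg0=-5.0)
        p2 = tunneling.EtParams(**{**self.PARAMS, "coupling_h0": 2.0},
                                driving_dg0=-5.0)
        r1 = tunneling.marcus_rate(p1, 14.1)
        assert tunneling.marcus_rate(p2, 14.1) == pytest.approx(4.0 * r1, rel=1e-12)

    def test_distance_dependence_reduces_to_peak_ratio(self):
        p = tunneling.EtParams(**self.PARAMS, driving_dg0=-5.0)
        ratio = tunneling.marcus_rate(p, 13.5) / tunneling.marcus_rate(p, 14.1)
        assert ratio == pytest.approx(
            tunneling.rate_ratio_peaks(14.1, 13.5, 1.8), rel=1e-9
        )

    def test_missing_parameters_rejected(self):
        with pytest.raises(QtrapError, match="requires"):
            tunneling.marcus_rate(tunneling.EtParams(beta_decay=1.8), 14.1)


class TestModelObjects:
    def test_rate_ratio_vs_reference(self):
        wt = _mixture([(1.0, 14.1, 0.2)], 100000, seed=2, label="WT")
        mut = _mixture([(0.6, 13.5, 0.15), (0.4, 14.1, 0.15)], 100000,
                       seed=3, label="A52T")
        res_wt = tunneling.DistanceDistributionModel(wt).fit()
        res_mut = tunneling.DistanceDistributionModel(mut).fit()
        ratio = res_mut.rate_ratio_vs(res_wt)
        assert ratio == pytest.approx(
            tunneling.rate_ratio_peaks(res_wt.primary_mode,
                                       res_mut.primary_mode, 1.8)
        )
        assert "modes" in res_mut.summary()
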