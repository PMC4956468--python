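import numpy as np
import pytest
from scipy.integrate import quad

from gatecycle import (
    AnalysisWindow,
    DwellSet,
    EventTable,
    GatingScheme,
    cob_loglik,
    extract_dwells,
    fit_cob,
    impose_dead_time,
    level_dwell_density,
    simulate_path,
    superpose,
    time_average_po,
)
from gatecycle.idealize import events_from_level_path
from gatecycle.kinetics import CobModel, window_events


def _dwellset_from_path(scheme, duration, seed, n_channels=1, td=0.006):
    paths = [simulate_path(scheme, duration, seed=seed + i) for i in range(n_channels)]
    ev = events_from_level_path(superpose(paths))
    return extract_dwells(impose_dead_time(ev, td), n_channels=n_channels)


class TestExtractDwells:
    def test_single_channel_two_level_groups(self, flicker_scheme):
        ds = _dwellset_from_path(flicker_scheme, 200.0, seed=0)
        assert set(ds.dwells) == {0, 1}
        assert np.all(ds.dwells[0] >= ds.td)

    def test_boundary_events_dropped(self):
        ev = EventTable(
            np.array([0, 1, 0, 1, 0]),
            np.array([1.0, 0.5, 1.0, 0.5, 1.0]),
            n_channels=1,
            dead_time=0.006,
        )
        # window cuts into the first and last events; both must be excluded
        ds = extract_dwells(ev, AnalysisWindow(0.5, 3.5))
        assert ds.n_events == 3
        assert ds.counts() == {0: 1, 1: 2}

    def test_too_many_channels_rejected(self):
        ev = EventTable(
            np.array([0, 1]), np.array([1.0, 1.0]), n_channels=8, dead_time=0.006
        )
        with pytest.raises(ValueError, match="rejected"):
            extract_dwells(ev)
        assert extract_dwells(ev, allow_many_channels=True).n_channels == 8

    def test_dead_time_required_first(self):
        ev = EventTable(np.array([0, 1]), np.array([1.0, 1.0]), n_channels=1)
        with pytest.raises(ValueError, match="dead time"):
            extract_dwells(ev)


class TestLevelDwellDensity:
    def test_single_open_state_is_exponential(self, flicker_scheme):
        t = np.array([0.05, 0.3, 1.0])
        f = level_dwell_density(flicker_scheme, 1, 1, t, td=0.0)
        lam = flicker_scheme.r_OC + flicker_scheme.r_OB
        np.testing.assert_allclose(f, lam * np.exp(-lam * t), rtol=1e-9)

    def test_closed_without_flickers_is_exponential(self):
        s = GatingScheme(0.7, 1.0, 1e-12, 100.0)
        t = np.array([0.1, 1.0, 3.0])
        f = level_dwell_density(s, 1, 0, t, td=0.0)
        np.testing.assert_allclose(f, 0.7 * np.exp(-0.7 * t), rtol=1e-6)

    @pytest.mark.parametrize("n,k,td", [(1, 0, 0.006), (2, 1, 0.006), (3, 2, 0.0)])
    def test_normalized_over_resolvable_dwells(self, slow_scheme, n, k, td):
        val, _ = quad(
            lambda t: level_dwell_density(slow_scheme, n, k, [t], td)[0],
            td,
            200.0,
            points=[0.01, 0.1, 1.0],
            limit=200,
        )
        assert val == pytest.approx(1.0, abs=1e-4)

    def test_invalid_level_and_subresolution_dwell_rejected(self, slow_scheme):
        with pytest.raises(ValueError):
            level_dwell_density(slow_scheme, 1, 2, [0.1])
        with pytest.raises(ValueError):
            level_dwell_density(slow_scheme, 1, 1, [0.001], td=0.006)


class TestCobLoglik:
    def test_exponential_mle_closed_form(self):
        rng = np.random.default_rng(0)
        data = rng.exponential(0.5, 200)
        lam_hat = 1.0 / data.mean()
        rates = np.array([1.0, lam_hat - 1e-9, 1e-9, 100.0])
        ds = DwellSet({1: data, 0: np.empty(0)}, n_channels=1, td=0.0)
        ll = cob_loglik(rates, ds)
        assert ll == pytest.approx(200 * (np.log(lam_hat) - 1), rel=1e-6)

    def test_doubling_data_doubles_loglik(self, flicker_scheme):
        ds1 = _dwellset_from_path(flicker_scheme, 100.0, seed=1)
        doubled = DwellSet(
            {k: np.concatenate([v, v]) for k, v in ds1.dwells.items()},
            n_channels=1,
            td=ds1.td,
        )
        assert cob_loglik(flicker_scheme, doubled) == pytest.approx(
            2 * cob_loglik(flicker_scheme, ds1), rel=1e-12
        )

    def test_permutation_invariance(self, flicker_scheme):
        ds = _dwellset_from_path(flicker_scheme, 100.0, seed=2)
        rng = np.random.default_rng(0)
        shuffled = DwellSet(
            {k: rng.permutation(v) for k, v in ds.dwells.items()},
            n_channels=1,
            td=ds.td,
        )
        assert cob_loglik(flicker_scheme, shuffled) == pytest.approx(
            cob_loglik(flicker_scheme, ds), rel=1e-12
        )

    def test_truth_beats_perturbed_rates(self, slow_scheme):
        ds = _dwellset_from_path(slow_scheme, 5000.0, seed=3)
        ll_true = cob_loglik(slow_scheme, ds)
        for factor in (0.7, 1.4):
            assert ll_true > cob_loglik(slow_scheme.rates * factor, ds)

    def test_invalid_rates_give_minus_inf(self, flicker_scheme):
        ds = _dwellset_from_path(flicker_scheme, 50.0, seed=4)
        assert cob_loglik(np.array([1.0, -1.0, 1.0, 1.0]), ds) == -np.inf


class TestFitCob:
    def test_flicker_free_reduces_to_two_exponential_mle(self, no_flicker_scheme):
        ds = _dwellset_from_path(no_flicker_scheme, 3000.0, seed=5)
        res = fit_cob(ds, seed=0)
        shut, opens = ds.dwells[0], ds.dwells[1]
        # truncated-exponential MLE: rate = 1/(mean - td)
        assert res.rates["r_CO"] == pytest.approx(1 / (shut.mean() - ds.td), rel=0.02)
        assert res.rates["r_OC"] + res.rates["r_OB"] == pytest.approx(
            1 / (opens.mean() - ds.td), rel=0.02
        )
        assert res.tau_b == pytest.approx(1 / res.rates["r_OC"], rel=0.01)

    def test_derived_quantities_satisfy_invariants(self, flicker_scheme):
        ds = _dwellset_from_path(flicker_scheme, 500.0, seed=6)
        res = fit_cob(ds, seed=0)
        r = res.rates
        assert res.tau_b == pytest.approx((1 / r["r_OC"]) * (1 + r["r_OB"] / r["r_BO"]))
        assert res.tau_ib == pytest.approx(1 / r["r_CO"])
        assert res.opening_rate == pytest.approx(1 / res.tau_ib)
        assert res.closing_rate == pytest.approx(1 / res.tau_b)
        assert 0 < res.p_open < 1
        assert res.converged

    def test_degenerate_single_level_rejected(self):
        ds = DwellSet({0: np.full(20, 1.0)}, n_channels=1, td=0.006)
        with pytest.raises(ValueError, match="single level"):
            CobModel(ds)

    def test_sparse_levels_warn(self, flicker_scheme):
        ds = _dwellset_from_path(flicker_scheme, 6.0, seed=7)
        with pytest.warns(UserWarning, match="unreliable"):
            CobModel(ds)

    def test_summary_renders(self, flicker_scheme):
        ds = _dwellset_from_path(flicker_scheme, 300.0, seed=8)
        res = fit_cob(ds, seed=0)
        text = res.summary()
        assert "r_CO" in text and "tau_b" in text and "P_o" in text


class TestTimeAveragePo:
    def test_always_closed_and_half_open(self):
        closed = EventTable(np.array([0]), np.array([10.0]), n_channels=1)
        assert time_average_po(closed, None, 1) == 0.0
        half = EventTable(np.array([0, 1]), np.array([5.0, 5.0]), n_channels=1)
        assert time_average_po(half, None, 1) == pytest.approx(0.5)

    def test_multichannel_normalization(self):
        ev = EventTable(np.array([2, 0]), np.array([3.0, 1.0]), n_channels=2)
        # 6 channel-seconds open over 8 channel-seconds total
        assert time_average_po(ev, None, 2) == pytest.approx(0.75)

    def test_window_clips_boundary_events(self):
        ev = EventTable(np.array([0, 1, 0]), np.array([1.0, 1.0, 1.0]), n_channels=1)
        assert time_average_po(ev, AnalysisWindow(0.5, 2.5), 1) == pytest.approx(0.5)

    def test_matches_stationary_open_probability(self, slow_scheme):
        pos = []
        for s in range(6):
            path = simulate_path(slow_scheme, 1500.0, seed=20 + s)
            ev = events_from_level_path(superpose([path]))
            pos.append(time_average_po(ev, None, 1))
        pos = np.array(pos)
        sem = pos.std(ddof=1) / np.sqrt(pos.size)
        assert abs(pos.mean() - slow_scheme.p_open) < 3 * sem
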