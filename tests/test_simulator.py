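import numpy as np
import pytest

from cardioergm.simulator import (
    ConfigurationError,
    LatticeConfig,
    StateSeries,
    arrhythmia_metrics,
    build_lattice,
    initial_phase,
    simulate,
    step,
)


class TestLatticeConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"nu": -0.1},
            {"nu": 1.5},
            {"epsilon": 2.0},
            {"tau_jitter": 50},  # must stay below tau_mean
            {"n_dysfunctional": 10**9},
            {"misfire_mode": "bogus"},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            LatticeConfig(**kwargs)


class TestBuildLattice:
    def test_fully_coupled_and_uncoupled_limits(self):
        full = build_lattice(LatticeConfig(L=30, nu=1.0, n_dysfunctional=5))
        assert full.lateral_links.all()
        none = build_lattice(LatticeConfig(L=30, nu=0.0, n_dysfunctional=5))
        assert not none.lateral_links.any()

    def test_link_fraction_matches_bernoulli_rate(self):
        cfg = LatticeConfig(L=200, nu=0.5, seed=3)
        lat = build_lattice(cfg)
        n = lat.lateral_links.size
        se = np.sqrt(0.25 / n)
        assert abs(lat.lateral_links.mean() - 0.5) < 3 * se

    def test_quenched_disorder_counts_and_ranges(self):
        cfg = LatticeConfig(L=40, nu=0.3, n_dysfunctional=17, seed=1)
        lat = build_lattice(cfg)
        assert lat.dysfunctional_mask.sum() == 17
        assert lat.tau_cell.min() >= cfg.tau_mean - cfg.tau_jitter
        assert lat.tau_cell.max() <= cfg.tau_mean + cfg.tau_jitter

    def test_deterministic_given_seed(self):
        cfg = LatticeConfig(L=25, nu=0.4, n_dysfunctional=30, seed=9)
        a, b = build_lattice(cfg), build_lattice(cfg)
        assert np.array_equal(a.lateral_links, b.lateral_links)
        assert np.array_equal(a.tau_cell, b.tau_cell)


class TestStep:
    def test_planar_wave_hand_trace_5x5(self):
        """Fully coupled defect-free 5x5: the paced wave advances one
        column per step, exciting a full column of 5 cells."""
        cfg = LatticeConfig(
            L=5, nu=1.0, n_dysfunctional=0, epsilon=0.0,
            tau_mean=3, tau_jitter=0, pacing_period=100, horizon=9, seed=0,
        )
        series = simulate(cfg)
        for t in range(5):
            expected = np.zeros((5, 5), dtype=np.uint8)
            expected[:, t] = 1
            assert np.array_equal(series.excitation[t], expected)
            assert series.excited_count[t] == 5
        assert series.excited_count[5:].sum() == 0

    def test_refractory_cell_ignores_stimulation(self):
        cfg = LatticeConfig(L=4, nu=1.0, n_dysfunctional=0, tau_mean=10,
                            tau_jitter=0, pacing_period=500, horizon=1)
        lat = build_lattice(cfg)
        phase = initial_phase(lat)
        phase[:, 0] = lat.tau_cell[:, 0] + 1  # column 0 fires now
        phase[:, 1] = 10  # column 1 deep in refractory countdown
        nxt = step(lat, phase, t=0)
        assert (nxt[:, 1] == 9).all()  # decremented, not excited
        assert (nxt[:, 0] == lat.tau_cell[:, 0]).all()

    def test_certain_misfire_blocks_excitation(self):
        # every cell dysfunctional with epsilon=1: the wave cannot leave
        # the paced column
        cfg = LatticeConfig(L=6, nu=1.0, n_dysfunctional=36, epsilon=1.0,
                            tau_mean=4, tau_jitter=0, pacing_period=50,
                            horizon=10, seed=2)
        series = simulate(cfg)
        assert series.excited_count[0] == 6  # paced column
        assert series.excited_count[1:].sum() == 0


class TestSimulate:
    def test_empty_horizon(self):
        series = simulate(LatticeConfig(L=10, nu=0.5, n_dysfunctional=0,
                                        horizon=0))
        assert series.excitation.shape == (0, 10, 10)
        assert series.excited_count.sum() == 0

    def test_bitwise_reproducible(self):
        cfg = LatticeConfig(L=30, nu=0.2, n_dysfunctional=45, horizon=150,
                            tau_mean=10, tau_jitter=2, pacing_period=40,
                            seed=13)
        a, b = simulate(cfg), simulate(cfg)
        assert np.array_equal(a.excitation, b.excitation)

    def test_periodic_planar_waves_no_reentry(self, small_planar_series):
        s = small_planar_series
        m = arrhythmia_metrics(s)
        assert m.time_in_arrhythmia == 0.0
        assert not m.sustained_reentry
        # activity dies out between beats
        assert (s.excited_count == 0).any()

    def test_refractory_safety_invariant(self, small_noisy_series):
        """Consecutive firings of any cell are separated by at least
        tau_cell + 1 steps, even amid wavebreak."""
        s = small_noisy_series
        tau = s.lattice.tau_cell
        exc = s.excitation.reshape(s.horizon, -1)
        tau_flat = tau.reshape(-1)
        for c in range(exc.shape[1]):
            times = np.nonzero(exc[:, c])[0]
            if len(times) > 1:
                assert np.diff(times).min() >= tau_flat[c] + 1

    def test_mean_risk_nonincreasing_in_nu(self):
        """Statistical monotonicity of time-in-arrhythmia over the
        coupling grid (one inversion allowed within Monte-Carlo error)."""
        means = []
        for nu in (0.1, 0.3, 0.5, 0.7, 0.9):
            vals = [
                arrhythmia_metrics(
                    simulate(LatticeConfig(L=100, nu=nu, n_dysfunctional=500,
                                           seed=s))
                ).time_in_arrhythmia
                for s in range(10)
            ]
            means.append(np.mean(vals))
        inversions = sum(
            means[k + 1] > means[k] + 1e-9 for k in range(len(means) - 1)
        )
        assert inversions <= 1
        assert means[0] > means[-1]


class TestArrhythmiaMetrics:
    def _series(self, counts, L=200, factor=1.1):
        cfg = LatticeConfig(L=L, nu=0.5, arrhythmia_factor=factor,
                            horizon=len(counts))
        exc = np.zeros((len(counts), 1, 1), dtype=np.uint8)
        return StateSeries(excitation=exc,
                           excited_count=np.asarray(counts), config=cfg)

    def test_all_quiet_is_zero_risk(self):
        m = arrhythmia_metrics(self._series(np.zeros(50, dtype=int)))
        assert m.time_in_arrhythmia == 0.0 and not m.sustained_reentry

    def test_persistently_high_count_is_full_risk(self):
        m = arrhythmia_metrics(self._series(np.full(50, 400)))
        assert m.time_in_arrhythmia == 1.0 and m.sustained_reentry

    def test_single_planar_wave_below_threshold(self):
        # one excited column contributes exactly L = 200 <= 1.1 L
        m = arrhythmia_metrics(self._series(np.full(50, 200)))
        assert m.time_in_arrhythmia == 0.0

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            arrhythmia_metrics(self._series(np.zeros(0, dtype=int)))
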