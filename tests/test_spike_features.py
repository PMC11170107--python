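import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meahazard import spike_features as sf
from meahazard.io_formats import ScoringConfig, ValidationError

from conftest import make_recording, make_train, poisson_train
from oracles import (
    brute_force_bursts,
    brute_force_median_over_mean,
    brute_force_wmfr,
    log10_poisson_tail,
)


class TestActiveElectrodes:
    def test_strict_threshold_boundary(self):
        rec = make_recording(
            {
                "hot": np.linspace(0.5, 1795.0, 181),  # 0.1006 Hz
                "cold": np.linspace(0.5, 1795.0, 180),  # exactly 0.1 Hz
            }
        )
        active = sf.active_electrodes(rec, 0.1)
        assert active == {"hot"}

    def test_silent_well(self):
        rec = make_recording({f"e{i}": [] for i in range(16)})
        assert sf.active_electrodes(rec, 0.1) == set()

    def test_all_active(self, rng):
        rec = make_recording(
            {f"e{i}": poisson_train(rng, 1.0, 1800.0) for i in range(16)}
        )
        assert len(sf.active_electrodes(rec, 0.1)) == 16


class TestWellQC:
    @pytest.mark.parametrize(
        "n_active,expected", [(7, True), (6, False), (0, False)]
    )
    def test_threshold_arithmetic(self, n_active, expected, cfg):
        trains = {
            f"a{i}": np.arange(1.0, 1800.0, 2.0) for i in range(n_active)
        }
        trains.update({f"s{i}": [] for i in range(16 - n_active)})
        rec = make_recording(trains)
        assert sf.well_qc(rec, cfg) is expected

    def test_exact_fraction_fails(self):
        # 7/16 = 0.4375 exactly at the configured fraction -> strict fail
        cfg = ScoringConfig(qc_active_fraction=0.4375)
        trains = {f"a{i}": np.arange(1.0, 1800.0, 2.0) for i in range(7)}
        rec = make_recording(trains)
        assert sf.well_qc(rec, cfg) is False


class TestWMFR:
    def test_no_active_is_zero(self):
        rec = make_recording({"e1": []})
        assert sf.weighted_mean_firing_rate(rec, set()) == 0.0

    def test_homogeneous_case(self):
        rec = make_recording(
            {f"e{i}": np.arange(0.5, 1800.0, 1.0) for i in range(16)}
        )
        active = sf.active_electrodes(rec, 0.1)
        assert sf.weighted_mean_firing_rate(rec, active) == pytest.approx(1.0)

    def test_poisson_rate_recovery(self, rng):
        rec = make_recording(
            {f"e{i}": poisson_train(rng, 2.0, 1800.0) for i in range(16)}
        )
        active = sf.active_electrodes(rec, 0.1)
        wmfr = sf.weighted_mean_firing_rate(rec, active)
        se = math.sqrt(2.0 / (16 * 1800.0))  # Poisson count SE on the mean
        assert wmfr == pytest.approx(2.0, abs=3 * se)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            trains = {
                f"e{i}": poisson_train(rng, rng.uniform(0.05, 0.5), 60.0)
                for i in range(rng.integers(1, 8))
            }
            rec = make_recording(trains, duration_s=60.0)
            active = sf.active_electrodes(rec, 0.1)
            expected = brute_force_wmfr(
                {k: list(v.timestamps) for k, v in rec.trains.items()}, 60.0, 0.1
            )
            assert sf.weighted_mean_firing_rate(rec, active) == pytest.approx(
                expected
            )

    def test_permutation_invariant(self, rng):
        ts = {f"e{i}": poisson_train(rng, 1.0, 100.0) for i in range(5)}
        rec1 = make_recording(ts, duration_s=100.0)
        rec2 = make_recording(
            {f"x{i}": ts[f"e{4 - i}"] for i in range(5)}, duration_s=100.0
        )
        a1 = sf.active_electrodes(rec1, 0.1)
        a2 = sf.active_electrodes(rec2, 0.1)
        assert sf.weighted_mean_firing_rate(rec1, a1) == pytest.approx(
            sf.weighted_mean_firing_rate(rec2, a2)
        )


class TestMedianOverMeanISI:
    def test_regular_train(self):
        train = make_train("e1", np.arange(0.0, 100.0, 0.5))
        assert sf.median_over_mean_isi(train) == pytest.approx(1.0)

    def test_exponential_limit(self, rng):
        isis = rng.exponential(0.1, size=10_000)
        train = make_train("e1", np.cumsum(isis))
        assert sf.median_over_mean_isi(train) == pytest.approx(
            math.log(2.0), abs=0.02
        )

    def test_single_spike_missing(self):
        assert math.isnan(sf.median_over_mean_isi(make_train("e1", [5.0])))

    def test_matches_oracle(self, rng):
        for _ in range(20):
            ts = poisson_train(rng, 1.0, 50.0)
            if ts.size < 2:
                continue
            assert sf.median_over_mean_isi(
                make_train("e1", ts)
            ) == pytest.approx(brute_force_median_over_mean(list(ts)))


class TestDetectBursts:
    def test_too_few_spikes(self):
        train = make_train("e1", [1.0, 2.0, 3.0])
        assert sf.detect_bursts(train, 100.0, min_spikes=5) == []

    def test_injected_burst_recovered(self, rng):
        bg = poisson_train(rng, 0.5, 100.0)
        injected = 40.0 + np.sort(rng.uniform(0.0, 0.5, size=20))
        ts = np.unique(np.concatenate([bg, injected]))
        train = make_train("e1", ts)
        bursts = sf.detect_bursts(train, 100.0, min_spikes=3)
        assert len(bursts) >= 1
        main = max(bursts, key=lambda b: b.surprise)
        assert main.start_s >= 39.0 and main.end_s <= 41.5
        # surprise matches the direct tail-sum oracle for the same window
        rate = ts.size / 100.0
        expected = -log10_poisson_tail(
            main.n_spikes, rate * (main.end_s - main.start_s)
        )
        assert main.surprise == pytest.approx(expected, rel=1e-9)

    def test_false_positive_rate_on_poisson(self, rng):
        n_bursts = 0
        for _ in range(100):
            ts = poisson_train(rng, 1.0, 1800.0)
            n_bursts += len(
                sf.detect_bursts(make_train("e", ts), 1800.0)
            )
        assert n_bursts / 100 <= 0.1

    def test_matches_exhaustive_oracle_small_trains(self, rng):
        """Exact boundary agreement with the brute-force maximizer."""
        checked = 0
        for i in range(60):
            bg = poisson_train(rng, 0.4, 40.0)
            if rng.random() < 0.7:  # usually plant a dense cluster
                k = int(rng.integers(4, 10))
                t0 = rng.uniform(5.0, 30.0)
                burst = t0 + np.sort(rng.uniform(0, 0.3, size=k))
                ts = np.unique(np.concatenate([bg, burst]))
            else:
                ts = bg
            if ts.size < 3 or ts.size > 50:
                continue
            got = sf.detect_bursts(
                make_train("e", ts), 40.0, surprise_threshold=5.0
            )
            expected = brute_force_bursts(
                list(ts), 40.0, surprise_threshold=5.0
            )
            got_idx = [
                (
                    int(np.searchsorted(ts, b.start_s)),
                    int(np.searchsorted(ts, b.end_s)),
                )
                for b in got
            ]
            assert got_idx == [(a, b) for a, b, _ in expected]
            checked += 1
        assert checked >= 30

    def test_bursts_non_overlapping_and_bounded(self, rng):
        ts = np.unique(
            np.concatenate(
                [
                    poisson_train(rng, 1.0, 200.0),
                    50.0 + np.sort(rng.uniform(0, 0.4, 15)),
                    120.0 + np.sort(rng.uniform(0, 0.4, 15)),
                ]
            )
        )
        bursts = sf.detect_bursts(make_train("e", ts), 200.0)
        for b1, b2 in zip(bursts, bursts[1:]):
            assert b1.end_s <= b2.start_s
        assert sum(b.n_spikes for b in bursts) <= ts.size
        for b in bursts:
            inside = np.sum((ts >= b.start_s) & (ts <= b.end_s))
            assert inside == b.n_spikes


class TestMeanBurstDuration:
    def test_empty_missing(self):
        assert math.isnan(sf.mean_burst_duration([]))

    def test_two_bursts(self):
        bursts = [
            sf.BurstEvent("e", 0.0, 0.2, 5, 12.0),
            sf.BurstEvent("e", 1.0, 1.4, 5, 12.0),
        ]
        assert sf.mean_burst_duration(bursts) == pytest.approx(0.3)

    def test_sample_mean_recovery(self, rng):
        durations = rng.exponential(0.5, size=200)
        bursts = [
            sf.BurstEvent("e", float(i), float(i + d), 5, 12.0)
            for i, d in enumerate(durations)
        ]
        se = float(np.std(durations, ddof=1) / np.sqrt(200))
        assert sf.mean_burst_duration(bursts) == pytest.approx(
            float(durations.mean())
        )
        assert sf.mean_burst_duration(bursts) == pytest.approx(0.5, abs=3 * se)


class TestAuCC:
    def test_identical_trains_maximal(self, rng):
        ts = poisson_train(rng, 2.0, 300.0)
        rec = make_recording({"a": ts, "b": ts}, duration_s=300.0)
        same = sf.area_under_cross_correlation(rec)
        jit = np.sort(ts + rng.normal(0, 0.05, ts.size))
        jit = np.unique(np.clip(jit, 0, 299.999))
        rec2 = make_recording({"a": ts, "b": jit}, duration_s=300.0)
        jittered = sf.area_under_cross_correlation(rec2)
        assert same > jittered

    def test_independent_trains_near_zero(self, rng):
        areas = []
        for _ in range(30):
            rec = make_recording(
                {f"e{i}": poisson_train(rng, 1.0, 600.0) for i in range(6)},
                duration_s=600.0,
            )
            areas.append(sf.area_under_cross_correlation(rec))
        # clipped at 0, so the mean must sit close to 0
        assert np.mean(areas) < 0.02

    def test_jitter_monotonicity(self, rng):
        wins = 0
        for _ in range(30):
            driver = np.sort(rng.uniform(0, 600.0, 120))
            def well(sigma):
                trains = {}
                for i in range(6):
                    t = driver + rng.normal(0, sigma, driver.size)
                    trains[f"e{i}"] = np.unique(np.clip(np.sort(t), 0, 599.99))
                return make_recording(trains, duration_s=600.0)
            tight = sf.area_under_cross_correlation(well(0.005))
            loose = sf.area_under_cross_correlation(well(0.050))
            wins += tight > loose
        assert wins >= 28

    def test_symmetry_and_floor(self, rng):
        trains = {f"e{i}": poisson_train(rng, 1.0, 300.0) for i in range(4)}
        rec = make_recording(trains, duration_s=300.0)
        rev = make_recording(
            dict(reversed(list(trains.items()))), duration_s=300.0
        )
        a1 = sf.area_under_cross_correlation(rec)
        a2 = sf.area_under_cross_correlation(rev)
        assert a1 == pytest.approx(a2)
        assert a1 >= 0.0

    def test_single_electrode_missing(self, rng):
        rec = make_recording(
            {"e1": poisson_train(rng, 1.0, 300.0)}, duration_s=300.0
        )
        assert math.isnan(sf.area_under_cross_correlation(rec))


class TestNetworkBursts:
    def test_no_bursts_empty(self):
        assert sf.network_bursts({}, 8) == []

    def test_below_participation_empty(self):
        bursts = {
            "e1": [sf.BurstEvent("e1", 1.0, 1.2, 5, 12.0)],
            "e2": [],
            "e3": [],
            "e4": [],
        }
        assert sf.network_bursts(bursts, 4, participation_fraction=0.5) == []

    def test_generative_rate_recovery(self, cfg):
        from meahazard.synthetic_mea import SimulationDesign, VEHICLE, simulate_well

        design = SimulationDesign(
            duration_s=600.0,
            network_burst_rate_hz=0.2,
            background_rate_hz=0.3,
            seed=7,
        )
        rec = simulate_well(
            design, VEHICLE, "A1", "baseline", np.random.SeedSequence(7)
        )
        feats = sf.compute_features(rec, cfg)
        rate_hz = feats.extended["network_burst_rate_per_min"] / 60.0
        se = math.sqrt(0.2 / 600.0)
        assert rate_hz == pytest.approx(0.2, abs=3 * se)


class TestCessationFlags:
    def _features(self, wmfr, n_active=16, nb=5.0, qc=True):
        return sf.WellFeatures(
            well_id="A1",
            phase="baseline",
            wmfr_hz=wmfr,
            mean_burst_duration_s=0.2,
            aucc=1.0,
            median_over_mean_isi=0.7,
            n_active_electrodes=n_active,
            qc_pass=qc,
            extended={"n_network_bursts": nb},
        )

    def test_silent_well_both_flags(self, cfg):
        base = self._features(2.0)
        treated = self._features(0.0, n_active=0, nb=0.0, qc=False)
        assert sf.cessation_flags(base, treated, cfg) == (True, True)

    def test_unchanged_well_no_flags(self, cfg):
        base = self._features(2.0)
        assert sf.cessation_flags(base, self._features(2.0), cfg) == (
            False,
            False,
        )

    def test_decoupling_network_only(self, cfg):
        base = self._features(2.0, nb=5.0)
        treated = self._features(2.0, nb=0.0)
        assert sf.cessation_flags(base, treated, cfg) == (False, True)

    def test_baseline_qc_fail_rejected(self, cfg):
        base = self._features(2.0, qc=False)
        with pytest.raises(ValidationError):
            sf.cessation_flags(base, self._features(2.0), cfg)


class TestComputeFeatures:
    def test_silent_well(self, cfg):
        rec = make_recording({f"e{i}": [] for i in range(16)})
        feats = sf.compute_features(rec, cfg)
        assert feats.wmfr_hz == 0.0
        assert math.isnan(feats.mean_burst_duration_s)
        assert math.isnan(feats.aucc)
        assert math.isnan(feats.median_over_mean_isi)
        assert not feats.qc_pass

    def test_deterministic_snapshot(self, cfg, rng):
        trains = {
            f"e{i:02d}": poisson_train(rng, 1.5, 300.0) for i in range(16)
        }
        rec = make_recording(trains, duration_s=300.0)
        f1 = sf.compute_features(rec, cfg)
        f2 = sf.compute_features(rec, cfg)
        assert sf.features_to_row(f1) == sf.features_to_row(f2)

    def test_relabel_invariance(self, cfg, rng):
        trains = {
            f"e{i:02d}": poisson_train(rng, 1.0, 200.0) for i in range(8)
        }
        rec1 = make_recording(trains, duration_s=200.0)
        relabeled = {
            f"z{7 - i:02d}": trains[f"e{i:02d}"] for i in range(8)
        }
        rec2 = make_recording(relabeled, duration_s=200.0)
        f1 = sf.compute_features(rec1, cfg)
        f2 = sf.compute_features(rec2, cfg)
        for name in sf.PARAMETER_PANEL:
            v1, v2 = f1.extended[name], f2.extended[name]
            if math.isnan(v1):
                assert math.isnan(v2)
            else:
                assert v1 == pytest.approx(v2, rel=1e-9), name

    def test_panel_complete(self, cfg, rng):
        rec = make_recording(
            {f"e{i}": poisson_train(rng, 1.0, 100.0) for i in range(16)},
            duration_s=100.0,
        )
        feats = sf.compute_features(rec, cfg)
        assert set(feats.extended) == set(sf.PARAMETER_PANEL)
        assert len(sf.PARAMETER_PANEL) == 43

    def test_row_round_trip(self, cfg, rng):
        rec = make_recording(
            {f"e{i}": poisson_train(rng, 1.0, 100.0) for i in range(16)},
            duration_s=100.0,
        )
        feats = sf.compute_features(rec, cfg)
        row = sf.features_to_row(feats)
        back = sf.features_from_row(row)
        assert back.wmfr_hz == feats.wmfr_hz
        assert back.qc_pass == feats.qc_pass


@settings(max_examples=25, deadline=None)
@given(
    isis=st.lists(
        st.floats(min_value=1e-3, max_value=10.0), min_size=2, max_size=200
    )
)
def test_median_over_mean_in_unit_range(isis):
    ts = np.cumsum(np.asarray(isis))
    ratio = sf.median_over_mean_isi(make_train("e", ts))
    assert 0.0 < ratio
    assert ratio == pytest.approx(
        brute_force_median_over_mean(list(ts)), rel=1e-9
    )


@settings(max_examples=20, deadline=None)
@given(seed=st.integers(min_value=0, max_value=10_000))
def test_burst_spikes_bounded_by_total(seed):
    rng = np.random.default_rng(seed)
    ts = np.unique(np.sort(rng.uniform(0, 30.0, size=rng.integers(3, 40))))
    bursts = sf.detect_bursts(
        make_train("e", ts), 30.0, surprise_threshold=3.0
    )
    assert sum(b.n_spikes for b in bursts) <= ts.size
    for b1, b2 in zip(bursts, bursts[1:]):
        assert b1.end_s <= b2.start_s
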