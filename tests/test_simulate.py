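"""Ground-truth generator: arrival statistics, rendering geometry,
bleed construction, determinism, and presets."""

import dataclasses

import numpy as np
import pytest

from difc import (
    CHANNELS,
    ChannelId,
    SimConfig,
    preset_config,
    render_scan,
    sample_events,
    simulate_scan,
)
from difc.simulate import GroundTruthEvent, read_events, write_events


class TestSampleEvents:
    def test_zero_concentration_zero_events(self):
        cfg = SimConfig(duration_s=600.0,
                        concentration_per_ml={"green": 0.0, "orange": 0.0})
        assert sample_events(cfg, 0) == []

    def test_poisson_mean_phantom_conditions(self):
        """10^3 cells/mL at 25 uL/min for 60 min -> mean 1500 per color."""
        cfg = SimConfig(duration_s=3600.0,
                        concentration_per_ml={"green": 1000.0, "orange": 0.0})
        counts = [len(sample_events(cfg, seed)) for seed in range(8)]
        for c in counts:
            assert abs(c - 1500) <= 3 * np.sqrt(1500)

    def test_same_seed_identical_events(self):
        cfg = preset_config("phantom_single", duration_s=60.0)
        assert sample_events(cfg, 7) == sample_events(cfg, 7)

    def test_different_seed_differs(self):
        cfg = preset_config("phantom_single", duration_s=60.0)
        assert sample_events(cfg, 7) != sample_events(cfg, 8)

    def test_cluster_sizes_and_mixing(self):
        cfg = SimConfig(
            duration_s=600.0, cluster_size_mean=8.0, two_fp_mixing=1.0,
            concentration_per_ml={"green": 1000.0, "orange": 1000.0},
        )
        events = sample_events(cfg, 3)
        sizes = [e.n_green + e.n_orange for e in events]
        assert np.mean(sizes) == pytest.approx(8.0, rel=0.15)
        mixed = [e for e in events if e.n_green + e.n_orange >= 2]
        assert all(e.n_green >= 1 and e.n_orange >= 1 for e in mixed)

    def test_event_invariant(self):
        with pytest.raises(ValueError):
            GroundTruthEvent(
                time_s=0.0, population="green", n_green=0, n_orange=0,
                amps_green=(), amps_orange=(), direction="forward",
                speed_mm_s=30.0,
            )


class TestRenderScan:
    def _single_event(self, **kw):
        base = dict(
            time_s=10.0, population="green", n_green=1, n_orange=0,
            amps_green=(100.0,), amps_orange=(), direction="forward",
            speed_mm_s=30.0,
        )
        base.update(kw)
        return GroundTruthEvent(**base)

    def _quiet_config(self, **kw):
        base = dict(
            duration_s=20.0, noise_sigma_mv=0.0, drift_amp_mv=0.0,
            background_mv=0.0,
        )
        base.update(kw)
        return SimConfig(**base)

    def test_probe2_delay_matches_speed(self):
        cfg = self._quiet_config()
        scan = render_scan([self._single_event()], cfg, 0)
        g1 = scan.signal[ChannelId(1, "green")]
        g2 = scan.signal[ChannelId(2, "green")]
        t1 = np.argmax(g1) / cfg.sampling_rate
        t2 = np.argmax(g2) / cfg.sampling_rate
        assert t1 == pytest.approx(10.0, abs=1e-3)
        assert t2 - t1 == pytest.approx(3.0 / 30.0, abs=1e-3)  # 0.1 s

    def test_bleed_ratio_by_construction(self):
        cfg = self._quiet_config(tr_true={"green": 0.05, "orange": 0.06})
        scan = render_scan([self._single_event()], cfg, 0)
        g = scan.signal[ChannelId(1, "green")]
        o = scan.signal[ChannelId(1, "orange")]
        assert o.max() / g.max() == pytest.approx(0.05, rel=1e-6)

    def test_zero_noise_zero_events_is_background(self):
        cfg = self._quiet_config(background_mv=37.0)
        scan = render_scan([], cfg, 0)
        for ch in CHANNELS:
            np.testing.assert_allclose(scan.signal[ch], 37.0)

    def test_saturation_clips_pulse(self):
        ev = self._single_event(amps_green=(5000.0,))
        cfg = self._quiet_config(background_mv=10.0)
        scan = render_scan([ev], cfg, 0)
        assert scan.signal[ChannelId(1, "green")].max() == pytest.approx(1500.0)

    def test_artifact_renders_on_all_channels(self):
        ev = GroundTruthEvent(
            time_s=5.0, population="artifact", n_green=0, n_orange=0,
            amps_green=(), amps_orange=(), direction="forward",
            speed_mm_s=30.0, is_artifact=True, artifact_amp_mv=200.0,
        )
        scan = render_scan([ev], self._quiet_config(), 0)
        for ch in CHANNELS:
            peak_t = np.argmax(scan.signal[ch]) / scan.sampling_rate
            assert peak_t == pytest.approx(5.0, abs=1e-3)
            assert scan.signal[ch].max() == pytest.approx(200.0, rel=1e-6)

    def test_too_fast_event_skipped_with_warning(self):
        ev = self._single_event(speed_mm_s=5000.0)
        with pytest.warns(UserWarning):
            scan = render_scan([ev], self._quiet_config(sampling_rate=500.0), 0)
        assert scan.signal[ChannelId(1, "green")].max() == 0.0

    def test_reverse_event_probe2_leads(self):
        ev = self._single_event(direction="reverse")
        scan = render_scan([ev], self._quiet_config(), 0)
        t1 = np.argmax(scan.signal[ChannelId(1, "green")]) / 2000.0
        t2 = np.argmax(scan.signal[ChannelId(2, "green")]) / 2000.0
        assert t2 - t1 == pytest.approx(-0.1, abs=1e-3)


class TestSimulateScanDeterminism:
    def test_identical_seed_identical_scan(self):
        cfg = preset_config("phantom_single", duration_s=30.0)
        s1, e1 = simulate_scan(cfg, 42)
        s2, e2 = simulate_scan(cfg, 42)
        assert e1 == e2
        for ch in CHANNELS:
            np.testing.assert_array_equal(s1.signal[ch], s2.signal[ch])


class TestPresets:
    def test_phantom_single_concentrations(self):
        cfg = preset_config("phantom_single")
        assert cfg.concentration_per_ml == {"green": 1000.0, "orange": 1000.0}
        assert cfg.flow_rate_ul_min == 25.0
        assert cfg.cluster_size_mean == 1.0

    def test_phantom_cluster_is_thousand_clusters_per_ml(self):
        cfg = preset_config("phantom_cluster")
        assert cfg.concentration_per_ml == {"green": 1000.0, "orange": 1000.0}
        # mean size 10 -> ~10^4 cells/mL as cultured-cluster suspensions
        assert cfg.cluster_size_mean == 10.0

    def test_invivo_has_rate_modulation(self):
        cfg = preset_config("invivo_mm")
        assert cfg.modulation_sigma > 0

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            preset_config("marsupial")

    def test_overrides_apply(self):
        cfg = preset_config("invivo_mm", duration_s=120.0, modulation_shared=1.0)
        assert cfg.duration_s == 120.0 and cfg.modulation_shared == 1.0


class TestEventTableRoundTrip:
    def test_round_trip(self, tmp_path):
        cfg = preset_config("phantom_cluster", duration_s=30.0,
                            two_fp_mixing=0.5, artifact_rate_per_min=2.0)
        events = sample_events(cfg, 5)
        p = tmp_path / "truth.csv"
        write_events(events, p)
        assert read_events(p) == events
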