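"""Epoch aggregation, baseline comparisons and direction-bias measures."""

import warnings

import numpy as np
import pandas as pd
import pytest

from lfpwaves.epochs import (
    TrialEpochs,
    _two_means_cutoff,
    align_preferred,
    direction_bias_timecourse,
    direction_histogram,
    epoch_wave_counts,
    rho_histograms,
    spike_rate_by_wavelength,
    standing_wave_instants,
)
from lfpwaves.geometry import circular_std
from lfpwaves.preprocess import PhaseMapSeries


class TestTrialEpochs:
    def test_layout(self):
        ep = TrialEpochs()
        w = ep.windows()
        assert w["baseline"] == (0.0, 0.5)
        assert w["delay"] == (1.5, 3.5)
        assert ep.duration == 4.0
        assert ep.epoch_of(2.0) == "delay"
        assert len(ep.intervals(0.5)) == 8


class TestEpochWaveCounts:
    def test_elevated_delay_marked_significant(self, rng):
        """A 3x baseline wave rate during the delay is marked significant
        above baseline at p < 0.01."""
        rows = []
        for tr in range(30):
            for t in rng.uniform(0.0, 0.5, rng.poisson(2)):
                rows.append({"trial": tr, "t": t})
            for t in rng.uniform(1.5, 3.5, rng.poisson(24)):
                rows.append({"trial": tr, "t": t})
        ev = pd.DataFrame(rows)
        out = epoch_wave_counts(ev, TrialEpochs(), 30, bin_s=0.5, n_perm=500, rng=0)
        delay = out[out["epoch"] == "delay"]
        assert delay["significant"].all()
        assert (delay["mean_count"] > delay["baseline_mean"]).all()

    def test_identical_rates_rarely_marked(self, rng):
        """Type-I control: equal rates everywhere -> few significant bins."""
        rows = [
            {"trial": tr, "t": t}
            for tr in range(30)
            for t in rng.uniform(0.0, 4.0, rng.poisson(8))
        ]
        out = epoch_wave_counts(pd.DataFrame(rows), TrialEpochs(), 30, bin_s=0.25,
                                n_perm=500, rng=0)
        assert out["significant"].mean() <= 2 / len(out)

    def test_no_events_no_marks(self):
        out = epoch_wave_counts(pd.DataFrame(columns=["trial", "t"]), TrialEpochs(), 10,
                                n_perm=200, rng=0)
        assert not out["significant"].any()


class TestDirectionHistograms:
    def test_alignment_puts_mode_at_zero(self, rng):
        edges, h = direction_histogram(np.full(50, 37.0), bin_deg=12.0)
        _, aligned = align_preferred([(edges, h)])
        assert aligned.argmax() == 0

    def test_mixture_ratio_preserved(self, rng):
        d = np.concatenate([np.full(700, 80.0), np.full(300, 260.0)])
        edges, h = direction_histogram(d + rng.normal(0, 2, size=1000), bin_deg=12.0)
        _, aligned = align_preferred([(edges, h)])
        n_bins = len(aligned)
        lobe0 = aligned[[0, 1, n_bins - 1]].sum()
        lobe180 = aligned[n_bins // 2 - 1 : n_bins // 2 + 2].sum()
        assert lobe0 / lobe180 == pytest.approx(7 / 3, rel=0.15)

    def test_uniform_has_no_dominant_bin(self, rng):
        edges, h = direction_histogram(rng.uniform(0, 360, 3000), bin_deg=12.0)
        assert h.max() < 2.0 / len(h[h >= 0]) * 2  # < twice uniform expectation

    def test_empty_input(self):
        edges, h = direction_histogram(np.array([]))
        assert h.sum() == 0


class TestRhoHistograms:
    def _rho(self, rng, n_trials=20, bias_delay=0.8):
        """Synthetic rho series: waves appear as +-0.6 excursions."""
        ep = TrialEpochs()
        T = int(ep.duration * 1000)
        rho = rng.normal(0.0, 0.08, size=(n_trials, T))
        for tr in range(n_trials):
            for a, b, bias in ((0.0, 0.5, 0.5), (1.5, 3.5, bias_delay)):
                for t in rng.uniform(a, b, rng.poisson(3 * (b - a))):
                    i = int(t * 1000)
                    sign = 1.0 if rng.random() < bias else -1.0
                    rho[tr, i : i + 150] = sign * 0.6
        return rho

    def test_bias_reshapes_delay_histogram(self, rng):
        rho = self._rho(rng)
        out = rho_histograms(rho, TrialEpochs(), 1000.0, n_perm=200, rng=0)
        bins = out["delay"]["bins"]
        centers = 0.5 * (bins[:-1] + bins[1:])
        base, cur = out["delay"]["baseline_hist"], out["delay"]["epoch_hist"]
        # baseline bimodal outside the chance zone
        assert base[centers > 0.3].sum() > 0.02
        assert base[centers < -0.3].sum() > 0.02
        # delay: positive lobe grows, negative shrinks
        assert cur[centers > 0.3].sum() > base[centers > 0.3].sum()
        assert cur[centers < -0.3].sum() < base[centers < -0.3].sum()

    def test_pure_noise_mass_in_chance_zone(self, rng):
        rho = rng.normal(0.0, 0.08, size=(10, 4000))
        out = rho_histograms(rho, TrialEpochs(), 1000.0, n_perm=100, rng=0)
        bins = out["sample"]["bins"]
        centers = 0.5 * (bins[:-1] + bins[1:])
        inside = np.abs(centers) < 0.3
        assert out["sample"]["epoch_hist"][inside].sum() >= 0.98

    def test_sign_flip_mirrors_histogram(self, rng):
        rho = self._rho(rng, n_trials=5)
        a = rho_histograms(rho, TrialEpochs(), 1000.0, n_perm=100, rng=0)
        b = rho_histograms(-rho, TrialEpochs(), 1000.0, n_perm=100, rng=0)
        assert np.allclose(a["delay"]["epoch_hist"], b["delay"]["epoch_hist"][::-1])


class TestDirectionBias:
    def test_delta_definitions(self, rng):
        ep = TrialEpochs()
        rho = np.zeros((4, int(ep.duration * 1000)))
        rho[:, 2000:2500] = 0.6  # positive waves in one delay interval
        out = direction_bias_timecourse(rho, ep, 1000.0)
        row = out[(out["t0"] == 2.0)].iloc[0]
        assert row["delta_positive"] == pytest.approx(1.0)
        assert row["delta_negative"] == pytest.approx(0.0)

    def test_null_stays_near_zero(self, rng):
        rho = rng.normal(0.0, 0.1, size=(20, 4000))
        out = direction_bias_timecourse(rho, TrialEpochs(), 1000.0)
        assert np.abs(out[["delta_positive", "delta_negative"]].to_numpy()).max() < 0.02

    def test_sign_orientation_flip_negates(self, rng):
        rho = rng.normal(0.0, 0.3, size=(5, 4000))
        a = direction_bias_timecourse(rho, TrialEpochs(), 1000.0)
        b = direction_bias_timecourse(-rho, TrialEpochs(), 1000.0)
        assert np.allclose(a["delta_positive"], b["delta_negative"])
        assert np.allclose(a["delta_negative"], b["delta_positive"])


class TestStandingWaves:
    def test_synchronous_oscillation_labeled_standing(self, rng):
        T = 600
        phase = np.empty((T, 8, 8))
        # half the instants: synchronous (same phase everywhere, tiny jitter)
        phase[:300] = rng.normal(0, 0.05, (300, 1, 1)) + rng.normal(0, 0.02, (300, 8, 8))
        # other half: spatially random phases
        phase[300:] = rng.uniform(-np.pi, np.pi, (300, 8, 8))
        series = PhaseMapSeries(phase=phase, amplitude=np.ones_like(phase), fs=1000.0)
        out = standing_wave_instants(series, wave_mask=np.zeros(T, bool))
        assert (out["label"][:300] == "standing").mean() > 0.95
        assert (out["label"][300:] == "neither").mean() > 0.95

    def test_traveling_wave_sd_exceeds_standing(self, rng):
        from lfpwaves.simulate import WaveTemplate, simulate_wave

        tpl = WaveTemplate(name="t", kind="planar", k=0.5, sigma=0.0, direction_deg=45.0)
        g, _ = simulate_wave(tpl, 0.2, 1000.0, 0)
        sd_wave = circular_std(np.angle(g).reshape(200, -1), axis=1).mean()
        sync = np.zeros((200, 64))
        sd_sync = circular_std(sync + rng.normal(0, 0.02, sync.shape), axis=1).mean()
        assert sd_wave > 5 * sd_sync

    def test_two_means_cutoff_separates_modes(self, rng):
        x = np.concatenate([rng.normal(0.2, 0.03, 200), rng.normal(1.2, 0.1, 300)])
        cut = _two_means_cutoff(x)
        assert 0.35 < cut < 1.0


class TestSpikeRateByWavelength:
    def _inputs(self, rng, coupled=True):
        inst = pd.DataFrame(
            {
                "t": np.arange(1000) / 1000.0,
                "wavelength_class": rng.choice(["short", "long"], 1000),
            }
        )
        rates = np.where(inst["wavelength_class"] == "short", 40.0, 10.0) if coupled else np.full(1000, 20.0)
        rows = []
        for i, r in enumerate(rates):
            n = rng.poisson(r * 64 / 1000.0)
            for _ in range(n):
                rows.append({"electrode": rng.integers(64), "t": i / 1000.0})
        return pd.DataFrame(rows), inst

    def test_amplitude_coupled_spikes_differ(self, rng):
        spikes, inst = self._inputs(rng, coupled=True)
        out = spike_rate_by_wavelength(spikes, inst, 1000.0, 64, n_perm=300, rng=0)
        assert out["short_rate"] > out["long_rate"]
        assert out["significant"]

    def test_uncoupled_spikes_do_not_differ(self, rng):
        spikes, inst = self._inputs(rng, coupled=False)
        out = spike_rate_by_wavelength(spikes, inst, 1000.0, 64, n_perm=300, rng=0)
        assert not out["significant"]

    def test_empty_class_skipped_with_warning(self, rng):
        spikes, inst = self._inputs(rng)
        inst["wavelength_class"] = "short"
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            out = spike_rate_by_wavelength(spikes, inst, 1000.0, 64, n_perm=100, rng=0)
        assert out is None
        assert any("empty" in str(x.message) for x in w)

    def test_no_spikes_skipped(self):
        with warnings.catch_warnings(record=True):
            warnings.simplefilter("always")
            out = spike_rate_by_wavelength(pd.DataFrame(), pd.DataFrame(), 1000.0, 64)
        assert out is None
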