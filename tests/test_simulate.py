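"""Wave simulation: phase inputs, the g(t, phi) field, the reference
library, and full synthetic sessions."""

import warnings

import numpy as np
import pytest

from lfpwaves.circular import circ_corr
from lfpwaves.errors import LibraryDegeneracyError
from lfpwaves.geometry import circular_std, wrap_angle
from lfpwaves.simulate import (
    ROTATING_CENTERS,
    SyntheticSessionSpec,
    WaveTemplate,
    build_reference_library,
    phase_input_planar,
    phase_input_rotating,
    simulate_wave,
    synthesize_session,
)


class TestPhaseInputs:
    def test_planar_rightward_increases_left_to_right(self):
        m = phase_input_planar(0.0)
        assert np.all(np.diff(m, axis=1) > 0)
        assert np.allclose(np.diff(m, axis=0), 0.0)

    def test_planar_antisymmetry(self):
        assert np.allclose(phase_input_planar(180.0), -phase_input_planar(0.0))

    def test_planar_diagonal_span(self):
        """Projection arithmetic: the corner-to-corner span along the
        45-degree diagonal is 7*sqrt(2) grid units."""
        m = phase_input_planar(45.0)
        assert abs(m.max() - m.min()) == pytest.approx(7 * np.sqrt(2))

    def test_rotating_polar_definition(self):
        m = phase_input_rotating((4.5, 4.5), "ccw")
        # site (8, 4) or (8, 5) lies along +x from the centre: angle near 0
        assert abs(m[3, 7]) < np.pi / 6 or abs(m[4, 7]) < np.pi / 6

    def test_chirality_flip_negates_map(self):
        a = phase_input_rotating((2.2, 6.7), "ccw")
        b = phase_input_rotating((2.2, 6.7), "cw")
        assert np.allclose(a, -b)

    def test_singular_node_marked(self):
        m = phase_input_rotating((4.0, 4.0), "ccw")
        assert np.isnan(m[3, 3])
        assert np.isfinite(np.delete(m.ravel(), 3 * 8 + 3)).all()

    def test_far_center_approaches_planar(self):
        """A rotation centre far off-grid looks planar: circular correlation
        with the matching planar projection map exceeds 0.99."""
        rot = phase_input_rotating((-100.0, 4.5), "cw")
        rot = rot - rot.mean()
        # tangential direction at the array for this centre/sense is vertical
        planar = phase_input_planar(90.0)
        scale = (rot.max() - rot.min()) / (planar.max() - planar.min())
        assert abs(circ_corr(rot, planar * scale)) > 0.99


class TestSimulateWave:
    def test_phase_difference_matches_k_exactly(self):
        tpl = WaveTemplate(name="t", kind="planar", k=0.4, sigma=0.0, direction_deg=0.0)
        g, _ = simulate_wave(tpl, 0.2, 1000.0, 0)
        phase = np.angle(g)
        dphi = wrap_angle(phase[:, :, 4] - phase[:, :, 2])  # two columns apart
        assert np.allclose(dphi, -0.4 * 2.0, atol=1e-12)

    def test_temporal_advance_w_over_fs(self):
        tpl = WaveTemplate(name="t", kind="planar", k=0.4, sigma=0.0, direction_deg=0.0)
        g, _ = simulate_wave(tpl, 0.2, 1000.0, 0)
        step = wrap_angle(np.diff(np.angle(g[:, 0, 0])))
        assert np.allclose(step, tpl.w / 1000.0, atol=1e-12)

    def test_noise_averages_to_clean_phase(self, rng):
        """Monte-Carlo: mean phase over realizations converges on the
        noise-free phase, with circular spread shrinking ~ 1/sqrt(n)."""
        tpl = WaveTemplate(name="t", kind="planar", k=0.4, sigma=0.5, direction_deg=30.0)
        clean = WaveTemplate(name="c", kind="planar", k=0.4, sigma=0.0, direction_deg=30.0)
        g0, _ = simulate_wave(clean, 0.1, 1000.0, 0)
        reps = np.stack([np.angle(simulate_wave(tpl, 0.1, 1000.0, rng)[0][50]) for _ in range(40)])
        mean_phase = np.angle(np.exp(1j * reps).mean(axis=0))
        err = np.abs(wrap_angle(mean_phase - np.angle(g0[50])))
        assert err.mean() < 0.15
        sd_all = circular_std(reps, axis=0).mean()
        sd_mean20 = circular_std(
            np.stack([np.angle(np.exp(1j * reps[i : i + 20]).mean(axis=0)) for i in (0, 20)]),
            axis=0,
        ).mean()
        assert sd_mean20 < sd_all

    def test_deterministic_given_seed(self):
        tpl = WaveTemplate(name="t", kind="planar", k=0.4, sigma=0.3, direction_deg=10.0)
        a, _ = simulate_wave(tpl, 0.2, 1000.0, 7)
        b, _ = simulate_wave(tpl, 0.2, 1000.0, 7)
        assert np.array_equal(a, b)

    def test_rejects_short_duration(self):
        tpl = WaveTemplate(name="t", kind="planar", k=0.4, direction_deg=0.0)
        with pytest.raises(ValueError):
            simulate_wave(tpl, 0.05, 1000.0)  # < 2 cycles at 20 Hz

    def test_rotating_wavelength_grows_with_radius(self):
        """Along rings of increasing radius about the rotation centre, the
        local spatial wavelength (distance per radian of phase) grows."""
        tpl = WaveTemplate(name="t", kind="rotating", k=0.6, sigma=0.0,
                           center=(4.5, 4.5), chirality="ccw")
        g, _ = simulate_wave(tpl, 0.2, 1000.0, 0)
        p = np.angle(g[0])
        y, x = np.mgrid[1:9, 1:9].astype(float)
        r = np.hypot(x - 4.5, y - 4.5)
        # phase change per unit arc length ~ k / r: wavelength ~ r * 2pi / k
        gx = np.abs(wrap_angle(np.diff(p, axis=1)))
        r_mid = 0.5 * (r[:, :-1] + r[:, 1:])
        inner = gx[(r_mid < 2)].mean()
        outer = gx[(r_mid > 3.5)].mean()
        assert outer < inner  # shallower gradient -> longer wavelength


class TestReferenceLibrary:
    def test_counts_and_spacing(self, library):
        assert len(library) == 72
        assert library.n_planar == 32
        assert library.n_rotating == 40
        dirs = sorted(
            e.template.direction_deg for e in library.entries if e.template.kind == "planar"
        )
        gaps = np.diff(dirs + [dirs[0] + 360.0])
        assert np.allclose(gaps, 11.25)

    def test_rotating_k_range(self, library):
        ks = [e.template.k for e in library.entries if e.template.kind == "rotating"]
        assert min(ks) == pytest.approx(0.1)
        assert max(ks) == pytest.approx(0.9)

    def test_every_entry_clears_chance_threshold(self, library):
        mx = np.abs(library.fingerprint_matrix()).max(axis=1)
        assert mx.min() > 0.3

    def test_reproducible_given_seed(self, library):
        again = build_reference_library(seed=0)
        assert np.array_equal(library.fingerprint_matrix(), again.fingerprint_matrix())

    def test_json_roundtrip(self, library, tmp_path):
        path = tmp_path / "lib.json"
        library.to_json(path)
        back = type(library).from_json(path)
        assert np.allclose(library.fingerprint_matrix(), back.fingerprint_matrix())
        assert [e.name for e in back.entries] == [e.name for e in library.entries]

    def test_degenerate_config_raises(self):
        """Rotation centres far off-array at low k leave no coefficient
        above chance: the builder must refuse such a library."""
        import lfpwaves.simulate as sim

        orig = sim.ROTATING_CENTERS
        sim.ROTATING_CENTERS = ((-10.5, 19.5),) + orig[1:]
        try:
            with pytest.raises(LibraryDegeneracyError):
                build_reference_library(seed=0)
        finally:
            sim.ROTATING_CENTERS = orig


class TestSynthesizeSession:
    def test_degenerate_bias_gives_single_direction(self):
        spec = SyntheticSessionSpec(n_trials=4, seed=1)
        spec.schedule["delay"] = (2.0, 1.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, log, _ = synthesize_session(spec)
        delay = log[log["epoch"] == "delay"]
        assert len(delay) > 0
        assert (delay["direction_deg"] == spec.preferred_direction_deg).all()

    def test_deterministic_given_seed(self):
        spec = SyntheticSessionSpec(n_trials=2, seed=9)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a, la, _ = synthesize_session(spec)
            b, lb, _ = synthesize_session(spec)
        assert np.array_equal(a.voltage, b.voltage)
        assert la.equals(lb)

    def test_zero_rate_session_is_pure_noise(self):
        spec = SyntheticSessionSpec(
            n_trials=2, seed=2,
            schedule={k: (0.0, 0.5) for k in ("baseline", "fixation", "sample", "delay", "test")},
        )
        sess, log, _ = synthesize_session(spec)
        assert len(log) == 0
        assert sess.voltage.shape == (64, 2 * 4000)

    def test_events_follow_task_layout(self):
        spec = SyntheticSessionSpec(n_trials=3, seed=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sess, _, _ = synthesize_session(spec)
        ev = sess.events
        t0 = ev[(ev["trial"] == 1) & (ev["event"] == "fixation_on")]["t"].item()
        t1 = ev[(ev["trial"] == 1) & (ev["event"] == "sample_on")]["t"].item()
        t3 = ev[(ev["trial"] == 1) & (ev["event"] == "test_on")]["t"].item()
        assert t1 - t0 == pytest.approx(0.5)
        assert t3 - t1 == pytest.approx(2.5)  # 0.5 s sample + 2 s delay

    def test_spikes_track_wave_amplitude(self):
        spec = SyntheticSessionSpec(n_trials=4, seed=4, spikes=True,
                                    spike_base_rate=2.0, spike_gain=3.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sess, log, spikes = synthesize_session(spec)
        assert spikes is not None and len(spikes)
        # rate during logged wave windows should exceed the base rate
        in_wave = np.zeros(sess.n_samples, bool)
        for _, r in log.iterrows():
            i = int(r["t"] * sess.fs)
            in_wave[i : i + int(0.2 * sess.fs)] = True
        idx = (spikes["t"].to_numpy() * sess.fs).astype(int)
        rate_in = (in_wave[idx]).sum() / max(in_wave.sum(), 1)
        rate_out = (~in_wave[idx]).sum() / max((~in_wave).sum(), 1)
        assert rate_in > rate_out
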