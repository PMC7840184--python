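import numpy as np
import pytest
from scipy import ndimage

from tubuliflow.core_io import TimeLapseRecording
from tubuliflow.synthetic_data import (
    PhantomParams,
    advection_profile,
    alpha_kinetics,
    corrupt,
    make_contracting_tubule,
    make_dose_response,
    make_transport_movie,
    make_wave_movie,
    transport_rois,
)


class TestKinetics:
    def test_zero_before_onset(self):
        t = np.array([-5.0, -0.1, 0.0])
        assert alpha_kinetics(t, 2.0, 8.0).max() == 0.0

    def test_normalized_peak(self):
        t = np.linspace(0, 100, 20001)
        k = alpha_kinetics(t, 2.0, 8.0)
        assert k.max() == pytest.approx(1.0, abs=1e-6)


class TestContractingTubule:
    def test_zero_amplitude_static(self):
        p = PhantomParams(seed=1, contraction_amplitude_um=0.0, n_frames=8)
        rec, truth = make_contracting_tubule(p)
        bf = rec["brightfield"]
        for i in range(1, 8):
            np.testing.assert_array_equal(bf[i], bf[0])
        assert np.abs(truth.displacement).max() == 0.0

    def test_max_edge_displacement_in_truth(self):
        p = PhantomParams(
            seed=1, contraction_amplitude_um=5.0, pixel_size=1.0, n_frames=30,
            onset_s=5.0, tau_decay_s=50.0,
        )
        rec, truth = make_contracting_tubule(p)
        # kinetics never exactly reaches 1 on a discrete grid; compare to a_series
        expected = truth.contraction_px.max()
        norms = np.sqrt((truth.displacement ** 2).sum(-1))
        assert norms.max() == pytest.approx(expected, rel=1e-6)
        assert expected > 4.5  # close to the configured 5 px

    def test_rendered_edge_matches_truth_within_half_pixel(self):
        p = PhantomParams(seed=3, contraction_amplitude_um=4.0, n_frames=20, onset_s=5.0)
        rec, truth = make_contracting_tubule(p)
        gc = rec["gcamp"]
        i = int(np.argmax(truth.contraction_px))
        cy, cx = truth.extras["center"]
        H, W = rec.shape
        rows, cols = np.mgrid[0:H, 0:W]
        r = np.hypot(rows - cy, cols - cx)

        def outer_edge(img):
            # mean radius of the outermost supra-threshold pixels per angle
            band = img > (img.min() + 0.4 * np.ptp(img))
            return r[band].max()

        shrink = outer_edge(gc[0]) - outer_edge(gc[i])
        assert shrink == pytest.approx(truth.contraction_px[i], abs=0.75)

    def test_determinism(self):
        p = PhantomParams(seed=11, noise_sigma=2.0, n_frames=6)
        rec1, _ = make_contracting_tubule(p)
        rec2, _ = make_contracting_tubule(p)
        for ch in rec1.channels:
            np.testing.assert_array_equal(rec1[ch], rec2[ch])

    def test_amplitude_exceeding_radius_rejected(self):
        with pytest.raises(ValueError, match="amplitude"):
            make_contracting_tubule(
                PhantomParams(contraction_amplitude_um=25.0, radius_um=22.0)
            )

    def test_coupling_delay_recorded_exactly(self):
        p = PhantomParams(seed=1, coupling_delay_s=3.0, n_frames=25)
        _, truth = make_contracting_tubule(p)
        assert truth.coupling_delay_s == 3.0
        # contraction trace lags the Ca2+ trace by the configured delay
        t_ca = truth.times[np.argmax(truth.ca_trace > 0)]
        t_con = truth.times[np.argmax(truth.contraction_px > 0)]
        assert t_con - t_ca == pytest.approx(3.0, abs=p.dt)

    def test_fura_pair_channels(self):
        p = PhantomParams(seed=2, n_frames=6)
        rec, _ = make_contracting_tubule(p, channels=("f340", "f380", "brightfield"))
        assert set(rec.channels) == {"f340", "f380", "brightfield"}
        assert (rec["f380"] > 0).all()


class TestWaveMovie:
    def test_onset_spacing_by_construction(self):
        p = PhantomParams(
            seed=1, wave_velocity_um_s=50.0, tubule_length_um=500.0,
            pixel_size=2.0, radius_um=10.0, n_frames=20,
        )
        _, truth = make_wave_movie(p)
        x1, x2 = 30, 130  # px -> 60, 260 µm
        dt_onset = truth.onset_by_position_s[x2] - truth.onset_by_position_s[x1]
        assert dt_onset == pytest.approx((x2 - x1) * 2.0 / 50.0)

    def test_negative_velocity_mirrors_onsets(self):
        kw = dict(
            seed=1, tubule_length_um=400.0, pixel_size=2.0, radius_um=10.0, n_frames=20,
        )
        _, fwd = make_wave_movie(PhantomParams(wave_velocity_um_s=40.0, **kw))
        _, bwd = make_wave_movie(PhantomParams(wave_velocity_um_s=-40.0, **kw))
        np.testing.assert_allclose(
            fwd.onset_by_position_s, bwd.onset_by_position_s[::-1]
        )

    def test_same_params_two_seeds_same_truth_different_noise(self):
        kw = dict(
            wave_velocity_um_s=50.0, tubule_length_um=400.0, pixel_size=2.0,
            radius_um=10.0, n_frames=10, noise_sigma=3.0,
        )
        rec1, t1 = make_wave_movie(PhantomParams(seed=1, **kw))
        rec2, t2 = make_wave_movie(PhantomParams(seed=2, **kw))
        assert t1.wave_velocity_um_s == t2.wave_velocity_um_s
        assert not np.array_equal(rec1["brightfield"], rec2["brightfield"])

    def test_unresolvable_velocity_flagged(self):
        with pytest.raises(ValueError, match="unresolvable"):
            make_wave_movie(
                PhantomParams(
                    wave_velocity_um_s=5000.0, tubule_length_um=300.0,
                    pixel_size=2.0, radius_um=10.0, dt=1.0,
                )
            )

    def test_short_tubule_rejected(self):
        with pytest.raises(ValueError, match="length"):
            make_wave_movie(
                PhantomParams(wave_velocity_um_s=50.0, tubule_length_um=100.0, radius_um=20.0)
            )


class TestTransportMovie:
    def test_roi0_only_profile(self):
        p = PhantomParams(advection_mode="roi0_only", n_side_rois=2)
        prof = advection_profile(p)
        assert prof[0] > 0
        assert all(prof[i] == 0 for i in prof if i != 0)

    def test_ascending_bias(self):
        p = PhantomParams(advection_mode="ascending", n_side_rois=3)
        prof = advection_profile(p)
        for i in range(1, 4):
            assert prof[i] > prof[-i]

    def test_symmetric_mirror(self):
        p = PhantomParams(advection_mode="symmetric", n_side_rois=3)
        prof = advection_profile(p)
        for i in range(1, 4):
            assert prof[i] == -prof[-i]

    def test_rois_tile_and_label(self):
        p = PhantomParams(n_side_rois=3, section_length_um=40.0)
        rois = transport_rois(p)
        assert [r.index for r in rois] == [-3, -2, -1, 0, 1, 2, 3]
        total = np.zeros(rois[0].mask.shape, dtype=int)
        for r in rois:
            total += r.mask
        assert total.max() == 1  # no overlaps

    def test_protocol_encodes_stimulus(self):
        p = PhantomParams(seed=1, n_frames=5, onset_s=20.0)
        _, truth = make_transport_movie(p)
        assert truth.protocol.onsets == [20.0]
        assert truth.protocol.duration == 10.0
        assert truth.protocol.concentration == 100.0

    def test_determinism(self):
        p = PhantomParams(seed=9, n_frames=5, noise_sigma=2.0)
        rec1, _ = make_transport_movie(p)
        rec2, _ = make_transport_movie(p)
        np.testing.assert_array_equal(rec1["brightfield"], rec2["brightfield"])


class TestDoseResponse:
    def test_half_maximal_at_ec50(self):
        resp, _ = make_dose_response(10.0, 1.3, 2.0, np.array([10.0]))
        assert resp[0] == pytest.approx(1.0)

    def test_saturation(self):
        resp, _ = make_dose_response(10.0, 1.0, 1.5, np.array([1e9]))
        assert resp[0] == pytest.approx(1.5, rel=1e-6)

    def test_paper_series_concentrations(self):
        conc = np.array([1.0, 10.0, 100.0, 1000.0])
        resp, truth = make_dose_response(10.0, 1.0, 1.0, conc)
        assert np.all(np.diff(resp) > 0)
        assert truth.ec50 == 10.0

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError):
            make_dose_response(10.0, 1.0, 1.0, np.array([0.0, 1.0]))


class TestCorrupt:
    @pytest.fixture
    def recording(self, rng):
        frames = {
            "gcamp": rng.random((12, 24, 24)) * 100,
            "background": rng.random((12, 24, 24)) * 50,
        }
        return TimeLapseRecording(frames=frames, dt=1.0, pixel_size=1.0)

    def test_identity_with_zero_params(self, recording):
        out, truth = corrupt(recording)
        for ch in recording.channels:
            np.testing.assert_array_equal(out[ch], recording[ch])
        assert truth.alpha == 0.0

    def test_drift_shifts_frames(self):
        params = PhantomParams(seed=2, contraction_amplitude_um=0.0, n_frames=12)
        rec, _ = make_contracting_tubule(params)
        out, truth = corrupt(rec, drift_px_per_frame=(0.5, 0.0))
        from skimage.registration import phase_cross_correlation

        shift, _, _ = phase_cross_correlation(
            out["brightfield"][0], out["brightfield"][10],
            upsample_factor=20, normalization=None,
        )
        # content moved +5 px in rows by frame 10
        assert -shift[0] == pytest.approx(5.0, abs=0.3)
        assert truth.drift_px_per_frame == (0.5, 0.0)

    def test_bleed_recoverable_by_regression(self, recording):
        out, truth = corrupt(
            recording, bleed_alpha=0.4, target_channel="gcamp"
        )
        t = out["gcamp"].ravel()
        b = out["background"].ravel()
        alpha_hat = np.cov(t, b)[0, 1] / b.var()
        # random target/background correlate by chance at this sample size
        assert alpha_hat == pytest.approx(0.4, rel=0.1)
        assert truth.alpha == 0.4

    def test_flicker_gains_recorded(self, recording):
        out, truth = corrupt(recording, flicker_amplitude=0.2)
        ratio = out["gcamp"].mean(axis=(1, 2)) / recording["gcamp"].mean(axis=(1, 2))
        np.testing.assert_allclose(ratio, truth.flicker_gains, rtol=1e-12)
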