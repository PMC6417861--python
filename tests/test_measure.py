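"""Measurement-operator tests: domain extent, multipass PIV, kymographs."""

import numpy as np
import pytest

from parpolar.measure import domain_extent, flow_kymograph, piv_multipass
from parpolar.synth import FlowSpec, SyntheticSpec, make_profile, make_speckle_movie


class TestDomainExtent:
    def test_noiseless_tophat_recovered_exactly(self):
        spec = SyntheticSpec(domains=((60.0, 30.0, 10.0),), noise=0.0, n=512)
        x, tr, _ = make_profile(spec)
        m = domain_extent(tr, x)
        assert m.n_domains == 1
        assert m.extent == pytest.approx(30.0, abs=x[1] - x[0])

    def test_flat_noise_yields_zero_extent(self):
        hits = 0
        for seed in range(50):
            spec = SyntheticSpec(seed=seed, domains=(), noise=1.0, background=5.0, n=512)
            _, tr, _ = make_profile(spec)
            if domain_extent(tr).extent > 0:
                hits += 1
        assert hits <= 2  # <= ~5% false-positive rate

    @pytest.mark.parametrize("snr", [5.0, 10.0])
    def test_two_domain_recovery_within_5pct(self, snr):
        worst = 0.0
        for seed in range(10):
            spec = SyntheticSpec(
                seed=seed,
                domains=((30.0, 28.0, 10.0), (95.0, 20.0, 10.0)),
                noise=10.0 / snr,
                n=512,
            )
            x, tr, _ = make_profile(spec)
            m = domain_extent(tr, x)
            assert m.n_domains == 2
            worst = max(worst, abs(m.extent - 48.0) / 48.0)
        assert worst < 0.05

    def test_scale_covariance(self):
        spec = SyntheticSpec(seed=9, domains=((30.0, 28.0, 10.0),), noise=2.0, n=512)
        x, tr, _ = make_profile(spec)
        m1 = domain_extent(tr, x)
        m2 = domain_extent(37.0 * tr, x)
        assert m1.extent == pytest.approx(m2.extent, rel=1e-9)
        assert m2.threshold == pytest.approx(37.0 * m1.threshold, rel=1e-9)

    def test_in_domain_intensity(self):
        spec = SyntheticSpec(domains=((60.0, 30.0, 10.0),), noise=0.0, n=512)
        x, tr, _ = make_profile(spec)
        m = domain_extent(tr, x)
        assert 7.0 < m.intensity <= 10.0

    def test_short_profile_rejected(self):
        with pytest.raises(ValueError):
            domain_extent(np.ones(23))


class TestPiv:
    def test_identical_frames_zero_field(self):
        frames, _ = make_speckle_movie(SyntheticSpec(seed=1), 1)
        f = piv_multipass(frames[0], frames[0])
        assert np.all(f.u == 0.0) and np.all(f.v == 0.0)

    def test_integer_translation_exact(self):
        frames, _ = make_speckle_movie(SyntheticSpec(seed=2), 1)
        b = np.roll(frames[0], shift=(0, 3), axis=(0, 1))
        f = piv_multipass(frames[0], b)
        assert f.valid.any()
        assert np.max(np.abs(f.u[f.valid] - 3.0)) == 0.0
        assert np.max(np.abs(f.v[f.valid])) == 0.0

    def test_sinusoidal_field_rms_below_fifth_pixel(self):
        spec = SyntheticSpec(
            seed=3,
            image_shape=(128, 256),
            flow=FlowSpec(kind="sinusoidal", amplitude=2.0, wavelength=256.0),
        )
        frames, truth = make_speckle_movie(spec, 2)
        f = piv_multipass(frames[0], frames[1])
        ux_true = truth[0, 0][np.ix_(f.y, f.x)]
        rms = np.sqrt(np.mean((f.u - ux_true) ** 2))
        assert rms < 0.2

    def test_flat_frames_flagged_invalid(self):
        a = np.zeros((64, 64))
        f = piv_multipass(a, a)
        assert not f.valid.any()
        assert np.all(f.u == 0.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            piv_multipass(np.zeros((64, 64)), np.zeros((64, 65)))


class TestFlowKymograph:
    def test_static_movie_zero_kymograph(self):
        frames, _ = make_speckle_movie(
            SyntheticSpec(seed=4, flow=FlowSpec(kind="uniform", ux=0.0)), 3
        )
        vk = flow_kymograph(frames, frame_interval=10.0, pixel_size=0.1)
        assert np.allclose(vk.values, 0.0)
        assert vk.peak_velocity == 0.0

    def test_uniform_advection_physical_units(self):
        # 5 px/frame at 0.1 um/px and 10 s/frame = 3 um/min
        frames, _ = make_speckle_movie(
            SyntheticSpec(seed=5, flow=FlowSpec(kind="uniform", ux=5.0)), 3
        )
        vk = flow_kymograph(frames, frame_interval=10.0, pixel_size=0.1)
        assert vk.units == "um/min"
        assert np.mean(vk.values) == pytest.approx(3.0, rel=1e-3)
        assert vk.peak_velocity == pytest.approx(3.0, rel=1e-2)

    def test_bipolar_flow_antisymmetric_about_midline(self):
        spec = SyntheticSpec(
            seed=6,
            image_shape=(128, 256),
            flow=FlowSpec(kind="bipolar_inward", amplitude=2.0),
        )
        frames, _ = make_speckle_movie(spec, 2)
        vk = flow_kymograph(frames, frame_interval=1.0, pixel_size=1.0)
        row = vk.values[0]
        mid = row.size // 2
        left, right = row[1:mid], row[mid + 1 :][::-1]
        m = min(left.size, right.size)
        assert np.mean(left[:m]) > 0 > np.mean(right[:m])

    def test_missing_units_warns_and_emits_px_per_frame(self):
        frames, _ = make_speckle_movie(
            SyntheticSpec(seed=7, flow=FlowSpec(kind="uniform", ux=2.0)), 2
        )
        with pytest.warns(UserWarning):
            vk = flow_kymograph(frames)
        assert vk.units == "px/frame"
        assert np.mean(vk.values) == pytest.approx(2.0, rel=1e-3)
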