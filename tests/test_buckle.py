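"""Height-field fitting and mean-curvature sampling on buckled membranes."""

import numpy as np
import pytest

from curvesense import buckle, synthgen
from curvesense.buckle import BeadFrame, HeightField


def _cosine_frame(a=2.0, box=(60.0, 30.0), n=800, seed=0, z_offset=0.0):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, box[0], n)
    y = rng.uniform(0, box[1], n)
    z = a * np.cos(2 * np.pi * x / box[0]) + z_offset
    return BeadFrame(beads=np.column_stack([x, y, z]),
                     tracer_xy=np.array([0.0, 15.0]), box=box)


class TestHeightFieldFit:
    def test_cosine_coefficients_recovered(self):
        field = buckle.fit_height_field(_cosine_frame(), order=2)
        expected = np.zeros((5, 5))
        expected[1, 0] = 2.0  # cos_1(x) * 1(y)
        assert field.coeffs == pytest.approx(expected, abs=1e-9)
        assert field.rms_residual < 1e-9

    def test_flat_surface_constant_coefficient(self):
        field = buckle.fit_height_field(_cosine_frame(a=0.0, z_offset=3.5),
                                        order=2)
        assert field.coeffs[0, 0] == pytest.approx(3.5)
        assert field.rms_residual < 1e-12

    def test_two_leaflets_fit_midsurface(self):
        """Beads at h +- t/2 in equal numbers fit to the midsurface h."""
        box = (60.0, 30.0)
        rng = np.random.default_rng(1)
        x = rng.uniform(0, box[0], 1000)
        y = rng.uniform(0, box[1], 1000)
        h = 2.0 * np.cos(2 * np.pi * x / box[0])
        x2, y2 = np.concatenate([x, x]), np.concatenate([y, y])
        z = np.concatenate([h + 2.0, h - 2.0])
        frame = BeadFrame(np.column_stack([x2, y2, z]),
                          np.array([0.0, 0.0]), box)
        field = buckle.fit_height_field(frame, order=2)
        assert field.coeffs[1, 0] == pytest.approx(2.0, abs=1e-6)
        assert field.coeffs[0, 0] == pytest.approx(0.0, abs=1e-6)
        assert field.rms_residual == pytest.approx(2.0, abs=1e-6)

    def test_fit_idempotence(self):
        """Refitting beads sampled from a fitted field reproduces it."""
        field = buckle.fit_height_field(_cosine_frame(seed=2), order=2)
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 60, 600)
        y = rng.uniform(0, 30, 600)
        z = buckle.evaluate(field, x, y)
        refit = buckle.fit_height_field(
            BeadFrame(np.column_stack([x, y, z]), np.array([0, 0]), (60, 30)),
            order=2)
        assert refit.coeffs == pytest.approx(field.coeffs, abs=1e-9)

    def test_too_few_beads_errors(self):
        with pytest.raises(ValueError):
            buckle.fit_height_field(_cosine_frame(n=10), order=2)

    def test_degenerate_layout_errors(self):
        # all beads on one line in x: cannot resolve y-dependence
        x = np.full(200, 5.0)
        y = np.linspace(0, 30, 200)
        frame = BeadFrame(np.column_stack([x, y, y * 0]),
                          np.array([0, 0]), (60, 30))
        with pytest.raises(ValueError):
            buckle.fit_height_field(frame, order=2)


class TestMeanCurvature:
    def test_flat_field_zero(self):
        field = HeightField(coeffs=np.zeros((5, 5)) + np.diag([3.0, 0, 0, 0, 0]),
                            box=(60, 30), order=2)
        field.coeffs[:] = 0
        field.coeffs[0, 0] = 3.0
        xs = np.linspace(0, 60, 13)
        assert buckle.mean_curvature(field, xs, xs * 0.5) == pytest.approx(
            0.0, abs=1e-12)

    def test_cosine_crest_closed_form(self):
        """h = a cos(kx): H at the crest is -a k^2 / 2 (slopes vanish)."""
        a, box = 2.0, (60.0, 30.0)
        field = buckle.fit_height_field(_cosine_frame(a=a, box=box), order=2)
        k = 2 * np.pi / box[0]
        assert buckle.mean_curvature(field, 0.0, 10.0) == pytest.approx(
            -a * k**2 / 2, rel=1e-6)
        # trough has the opposite sign
        assert buckle.mean_curvature(field, box[0] / 2, 10.0) == pytest.approx(
            a * k**2 / 2, rel=1e-6)

    def test_shallow_bump_apex_matches_osculating_sphere(self):
        """Apex of a shallow periodic bump vs 1/R of its osculating sphere.

        h = a cos(kx) cos(ky) osculates a sphere of radius R = 1/(a k^2)
        at the apex; the fitted H there must agree with -1/R within 1%.
        """
        box = (60.0, 60.0)
        k = 2 * np.pi / 60.0
        a = 0.25  # nm; shallow slopes
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 60, 1500)
        y = rng.uniform(0, 60, 1500)
        z = a * np.cos(k * x) * np.cos(k * y)
        frame = BeadFrame(np.column_stack([x, y, z]), np.array([0, 0]), box)
        field = buckle.fit_height_field(frame, order=2)
        R = 1.0 / (a * k**2)
        assert buckle.mean_curvature(field, 0.0, 0.0) == pytest.approx(
            -1.0 / R, rel=0.01)

    def test_shallow_limit_consistency(self):
        """As amplitude -> 0 the full H converges to the linearization h_xx/2."""
        k = 2 * np.pi / 60.0
        xs = np.linspace(0, 60, 120, endpoint=False)
        rel_err = []
        for a in (4.0, 0.4):
            field = buckle.fit_height_field(_cosine_frame(a=a), order=2)
            H = buckle.mean_curvature(field, xs, np.full_like(xs, 10.0))
            linear = -a * k**2 * np.cos(k * xs) / 2
            scale = np.max(np.abs(linear))
            rel_err.append(np.max(np.abs(H - linear)) / scale)
        assert rel_err[1] < rel_err[0]
        assert rel_err[1] < 2e-3

    def test_translation_covariance(self):
        """Shifting beads and tracer by the same (dx, dy) mod box leaves H."""
        frame = _cosine_frame(seed=5)
        field = buckle.fit_height_field(frame, order=2)
        h0 = buckle.mean_curvature(field, 12.0, 7.0)
        shift = np.array([13.7, 4.2])
        beads2 = frame.beads.copy()
        beads2[:, 0] = (beads2[:, 0] + shift[0]) % 60
        beads2[:, 1] = (beads2[:, 1] + shift[1]) % 30
        frame2 = BeadFrame(beads2, frame.tracer_xy + shift, frame.box)
        field2 = buckle.fit_height_field(frame2, order=2)
        h1 = buckle.mean_curvature(field2, 12.0 + shift[0], 7.0 + shift[1])
        assert h1 == pytest.approx(h0, abs=1e-9)

    def test_periodic_box_mean_H_near_zero(self):
        """Shallow band-limited periodic surface integrates H to ~0."""
        field = buckle.fit_height_field(_cosine_frame(a=0.5), order=2)
        xs = np.linspace(0, 60, 200, endpoint=False)
        ys = np.linspace(0, 30, 100, endpoint=False)
        xg, yg = np.meshgrid(xs, ys)
        H = buckle.mean_curvature(field, xg.ravel(), yg.ravel())
        assert abs(H.mean()) < 1e-4


class TestSampling:
    def test_tracer_pinned_at_crest_constant(self):
        frames = [_cosine_frame(seed=s) for s in range(5)]
        k = 2 * np.pi / 60.0
        samples = buckle.sample_curvature_series(frames, order=2, rng=0)
        assert samples.h_tracer == pytest.approx(-2.0 * k**2 / 2, rel=1e-6)

    def test_beta_zero_no_preference(self):
        frames, _ = synthgen.gen_buckled_trajectory(synthgen.BuckleConfig(
            seed=2, n_frames=40, placement="boltzmann", beta=0.0))
        s = buckle.sample_curvature_series(frames, order=2, rng=4)
        delta = s.h_tracer.mean() - s.h_random.mean()
        se = np.sqrt(s.h_tracer.var(ddof=1) / s.h_tracer.size
                     + s.h_random.var(ddof=1) / s.h_random.size)
        assert abs(delta) < 3 * se

    def test_argmax_placement_recovers_max_H(self):
        frames, gt = synthgen.gen_buckled_trajectory(synthgen.BuckleConfig(
            seed=3, n_frames=30, placement="argmax"))
        s = buckle.sample_curvature_series(frames, order=2, rng=1)
        se = s.h_tracer.std(ddof=1) / np.sqrt(s.h_tracer.size)
        assert abs(s.h_tracer.mean() - gt.params["max_H_nm_inv"]) < 3 * se

    def test_preference_monotone_in_beta(self):
        means = []
        for beta in (0.0, 200.0, 1000.0):
            frames, _ = synthgen.gen_buckled_trajectory(synthgen.BuckleConfig(
                seed=7, n_frames=25, placement="boltzmann", beta=beta))
            s = buckle.sample_curvature_series(frames, order=2, rng=9)
            means.append(s.h_tracer.mean())
        assert means[0] < means[1] < means[2]


class TestPreferenceSummary:
    def test_identical_series_no_delta(self):
        s = buckle.CurvatureSamples(h_tracer=np.array([0.01, 0.02, -0.01]),
                                    h_random=np.array([0.01, 0.02, -0.01]),
                                    times_ns=np.arange(3.0))
        summ = buckle.preference_summary(s)
        assert summ.delta_mean_um == 0.0
        assert summ.hist_tracer == pytest.approx(summ.hist_random)

    def test_unit_conversion_nm_to_um(self):
        """H = 0.016 nm^-1 is reported as 16 um^-1."""
        s = buckle.CurvatureSamples(h_tracer=np.full(4, 0.016),
                                    h_random=np.zeros(4),
                                    times_ns=np.arange(4.0))
        summ = buckle.preference_summary(s)
        assert summ.mean_tracer_um == pytest.approx(16.0)

    def test_planted_bias_recovered(self):
        frames, gt = synthgen.gen_buckled_trajectory(synthgen.BuckleConfig(
            seed=5, n_frames=30, placement="boltzmann", beta=800.0))
        s = buckle.sample_curvature_series(frames, order=2, rng=6)
        summ = buckle.preference_summary(s)
        assert summ.delta_mean_um > 0


class TestTrajectoryGenerator:
    def test_argmax_tracer_at_trough(self):
        """For h = a cos(kx), a > 0, max H sits at the trough x = Lx/2."""
        frames, gt = synthgen.gen_buckled_trajectory(synthgen.BuckleConfig(
            seed=1, n_frames=3, placement="argmax"))
        Lx = frames[0].box[0]
        for fr in frames:
            assert fr.tracer_xy[0] == pytest.approx(Lx / 2, abs=Lx / 256)

    def test_zero_jitter_exact_refit(self):
        frames, _ = synthgen.gen_buckled_trajectory(synthgen.BuckleConfig(
            seed=1, n_frames=1, jitter_sd_nm=0.0, leaflet_offset_nm=0.0,
            n_beads=600))
        field = buckle.fit_height_field(frames[0], order=2)
        assert field.rms_residual < 1e-9
        assert field.coeffs[1, 0] == pytest.approx(2.0, abs=1e-9)

    def test_excessive_jitter_rejected(self):
        with pytest.raises(ValueError):
            synthgen.gen_buckled_trajectory(synthgen.BuckleConfig(
                jitter_sd_nm=3.0, amplitude_nm=2.0))

    def test_determinism(self):
        f1, g1 = synthgen.gen_buckled_trajectory(synthgen.BuckleConfig(
            seed=4, n_frames=2, n_beads=300))
        f2, g2 = synthgen.gen_buckled_trajectory(synthgen.BuckleConfig(
            seed=4, n_frames=2, n_beads=300))
        assert np.array_equal(f1[0].beads, f2[0].beads)
        assert np.array_equal(f1[1].tracer_xy, f2[1].tracer_xy)
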