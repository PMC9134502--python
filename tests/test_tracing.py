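"""Tracing: detection, centerline accuracy, resampling, length statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import filakit as fk

from conftest import center_chain, field_center_um, render_chains_and_trace


def straight_path(rp, length_um=10.0, angle_deg=0.0, n=80):
    c = field_center_um(rp)
    a = np.deg2rad(angle_deg)
    d = np.array([np.cos(a), np.sin(a)])
    t = np.linspace(-length_um / 2, length_um / 2, n)
    return fk.FilamentPath(points=c + t[:, None] * d, pixel_um=rp.pixel_um)


class TestTraceFilaments:
    def test_blank_image_empty_list(self):
        assert fk.trace_filaments(np.zeros((64, 64)), fk.TraceConfig(), 0.155) == []
        assert (
            fk.trace_filaments(np.full((64, 64), 7.0), fk.TraceConfig(), 0.155) == []
        )

    def test_non_2d_rejected(self):
        with pytest.raises(ValueError):
            fk.trace_filaments(np.zeros((4, 64, 64)), fk.TraceConfig(), 0.155)

    def test_single_straight_filament_length(self, noise_free_render):
        rp = noise_free_render
        img = fk.render_filaments([straight_path(rp, 10.0)], rp)
        paths = fk.trace_filaments(img, fk.TraceConfig(), rp.pixel_um)
        assert len(paths) == 1
        assert abs(paths[0].length_um - 10.0) <= 2 * rp.pixel_um

    @pytest.mark.parametrize("angle_deg", [15, 45, 75])
    def test_length_isotropy(self, noise_free_render, angle_deg):
        rp = noise_free_render
        img = fk.render_filaments([straight_path(rp, 10.0, angle_deg)], rp)
        paths = fk.trace_filaments(img, fk.TraceConfig(), rp.pixel_um)
        assert len(paths) == 1
        assert abs(paths[0].length_um - 10.0) <= 2 * rp.pixel_um

    def test_crossing_filaments_split_and_conserve_length(self, noise_free_render):
        rp = noise_free_render
        a = straight_path(rp, 12.0, 0.0)
        b = straight_path(rp, 12.0, 90.0)
        img = fk.render_filaments([a, b], rp)
        paths = fk.trace_filaments(img, fk.TraceConfig(), rp.pixel_um)
        assert len(paths) >= 2
        total = sum(p.length_um for p in paths)
        assert total == pytest.approx(24.0, rel=0.10)

    def test_noise_free_round_trip_three_percent(self, noise_free_render):
        # render->trace error <= 3% of true contour length for stiff chains
        rp = noise_free_render
        errors = []
        for s in range(100):
            rng = np.random.default_rng(s)
            L = rng.uniform(5, 18)
            chain = fk.sample_wlc(
                fk.WLCParams(persistence_length_um=12, contour_length_um=L, seed=900 + s)
            )
            placed = center_chain(chain, rp)
            if placed is None:
                continue
            img = fk.render_filaments([placed], rp)
            traced = fk.trace_filaments(img, fk.TraceConfig(), rp.pixel_um)
            assert traced, "noise-free filament must be detected"
            err = abs(sum(p.length_um for p in traced) - chain.length_um)
            errors.append(err / chain.length_um)
        assert len(errors) >= 60
        assert np.mean(np.asarray(errors) <= 0.03) >= 0.95

    def test_translation_and_rotation_invariance(self, noise_free_render):
        rp = noise_free_render
        base = straight_path(rp, 8.0, 30.0)
        img = fk.render_filaments([base], rp)
        L0 = fk.trace_filaments(img, fk.TraceConfig(), rp.pixel_um)[0].length_um
        shifted = fk.FilamentPath(points=base.points + 2.17, pixel_um=rp.pixel_um)
        img_t = fk.render_filaments([shifted], rp)
        Lt = fk.trace_filaments(img_t, fk.TraceConfig(), rp.pixel_um)[0].length_um
        img_r = fk.render_filaments([base], rp)[::-1, :].T  # 90 deg rotation
        Lr = fk.trace_filaments(np.ascontiguousarray(img_r), fk.TraceConfig(), rp.pixel_um)[
            0
        ].length_um
        assert abs(Lt - L0) <= 2 * rp.pixel_um
        assert abs(Lr - L0) <= 2 * rp.pixel_um

    def test_min_length_monotonicity(self, noisy_render):
        rp = noisy_render
        img = fk.render_filaments(
            [straight_path(rp, 9.0, 20.0), straight_path(rp, 4.0, 110.0)], rp
        )
        counts = [
            len(fk.trace_filaments(img, fk.TraceConfig(min_length_um=m), rp.pixel_um))
            for m in (0.0, 1.0, 3.0, 5.0, 8.0, 20.0)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_deterministic_for_fixed_input(self, noisy_render):
        rp = noisy_render
        img = fk.render_filaments([straight_path(rp, 10.0, 40.0)], rp)
        p1 = fk.trace_filaments(img, fk.TraceConfig(), rp.pixel_um)
        p2 = fk.trace_filaments(img, fk.TraceConfig(), rp.pixel_um)
        assert len(p1) == len(p2)
        for a, b in zip(p1, p2):
            assert np.array_equal(a.points, b.points)


class TestResamplePath:
    def test_straight_segment_exact_spacing(self):
        pts = np.stack([np.linspace(0, 6.2, 7), np.zeros(7)], axis=1)
        path = fk.FilamentPath(points=pts, pixel_um=0.155)
        rs = fk.resample_path(path, 0.62)
        assert rs.n_points == 11
        seg = np.linalg.norm(np.diff(rs.points, axis=0), axis=1)
        assert np.allclose(seg, 0.62, rtol=1e-9)

    def test_idempotence(self):
        rng = np.random.default_rng(4)
        pts = np.cumsum(rng.normal(0.3, 0.05, size=(40, 2)), axis=0)
        path = fk.FilamentPath(points=pts, pixel_um=0.155)
        once = fk.resample_path(path, 0.62)
        twice = fk.resample_path(once, 0.62)
        assert once.n_points == twice.n_points
        assert np.allclose(once.points, twice.points, atol=1e-6)

    def test_arc_chord_spacing(self):
        # step much smaller than radius: chord ~ arc within 0.1%
        R, step = 50.0, 0.62
        th = np.linspace(0, np.pi / 2, 4000)
        path = fk.FilamentPath(
            points=np.stack([R * np.cos(th), R * np.sin(th)], axis=1), pixel_um=0.155
        )
        rs = fk.resample_path(path, step)
        seg = np.linalg.norm(np.diff(rs.points, axis=0), axis=1)
        assert np.allclose(seg, step, rtol=1e-3)

    def test_step_larger_than_path_rejected(self):
        path = fk.FilamentPath(points=[[0, 0], [0.3, 0]], pixel_um=0.155)
        with pytest.raises(ValueError):
            fk.resample_path(path, 0.62)

    @given(step=st.floats(0.2, 1.5), length=st.floats(4.0, 20.0))
    @settings(max_examples=25, deadline=None)
    def test_endpoint_preserved_within_step(self, step, length):
        pts = np.stack([np.linspace(0, length, 200), np.zeros(200)], axis=1)
        rs = fk.resample_path(fk.FilamentPath(points=pts, pixel_um=0.155), step)
        assert np.allclose(rs.points[0], pts[0])
        assert np.linalg.norm(rs.points[-1] - pts[-1]) <= step + 1e-9


class TestLengthStats:
    def test_single_path(self):
        p = fk.FilamentPath(points=[[0, 0], [3, 4]], pixel_um=0.155)
        s = fk.length_stats([p])
        assert s["n"] == 1 and s["mean_um"] == pytest.approx(5.0) and s["sd_um"] == 0.0

    def test_known_sample_moments(self):
        paths = [
            fk.FilamentPath(points=[[0, 0], [L, 0]], pixel_um=0.155) for L in (4, 6, 8)
        ]
        s = fk.length_stats(paths)
        assert s["mean_um"] == pytest.approx(6.0)
        assert s["sd_um"] == pytest.approx(2.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fk.length_stats([])

    def test_lognormal_population_recovery(self):
        # population shaped like the unbundled-filament length distribution:
        # mean 6.8 um, SD 4.3 um
        mean, sd = 6.8, 4.3
        mu = np.log(mean**2 / np.sqrt(mean**2 + sd**2))
        sig = np.sqrt(np.log(1 + (sd / mean) ** 2))
        rng = np.random.default_rng(12)
        lengths = rng.lognormal(mu, sig, size=1000)
        paths = [
            fk.FilamentPath(points=[[0, 0], [L, 0]], pixel_um=0.155) for L in lengths
        ]
        s = fk.length_stats(paths)
        assert s["mean_um"] == pytest.approx(mean, rel=0.05)


def test_traced_paths_sorted_by_length(noise_free_render):
    rp = noise_free_render
    a = straight_path(rp, 12.0, 10.0)
    b_pts = straight_path(rp, 5.0, 100.0).points + np.array([6.0, -6.0])
    img = fk.render_filaments(
        [a, fk.FilamentPath(points=b_pts, pixel_um=rp.pixel_um)], rp
    )
    paths = fk.trace_filaments(img, fk.TraceConfig(), rp.pixel_um)
    lengths = [p.length_um for p in paths]
    assert lengths == sorted(lengths, reverse=True)
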