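"""Generator correctness: closed forms, limits, and seeded reproducibility."""

import numpy as np
import pytest
from scipy.optimize import curve_fit

import filakit as fk
from filakit.synthdata import soumpasis_recovery

from conftest import center_chain


class TestSampleWLC:
    def test_point_count_and_spacing(self):
        p = fk.sample_wlc(
            fk.WLCParams(persistence_length_um=10, contour_length_um=6.2, step_um=0.62)
        )
        assert p.n_points == 11
        seg = np.linalg.norm(np.diff(p.points, axis=0), axis=1)
        assert np.allclose(seg, 0.62)

    def test_rigid_limit_collinear(self):
        # P -> infinity: angle variance -> 0, all points collinear
        p = fk.sample_wlc(
            fk.WLCParams(persistence_length_um=1e12, contour_length_um=10, seed=3)
        )
        t = np.diff(p.points, axis=0)
        t /= np.linalg.norm(t, axis=1, keepdims=True)
        assert np.allclose(t @ t[0], 1.0, atol=1e-5)

    def test_per_step_angular_sd_closed_form(self):
        # sd = sqrt(step/P); P = 21.7 um is the dextran-bundled stiffness scale
        P, step = 21.7, 0.62
        dth = []
        for s in range(300):
            p = fk.sample_wlc(
                fk.WLCParams(persistence_length_um=P, contour_length_um=31, seed=s)
            )
            t = np.diff(p.points, axis=0)
            ang = np.arctan2(t[:, 1], t[:, 0])
            dth.extend(np.diff(np.unwrap(ang)))
        sd = np.std(dth)
        assert sd == pytest.approx(np.sqrt(step / P), rel=0.02)  # ~0.169 rad

    def test_mean_step_cosine_matches_exponential(self):
        # E[cos eta] = exp(-sigma^2/2) = exp(-step/2P)
        P, step = 5.0, 0.62
        cs = []
        for s in range(10_000):
            p = fk.sample_wlc(
                fk.WLCParams(persistence_length_um=P, contour_length_um=2 * step, seed=s)
            )
            t = np.diff(p.points, axis=0)
            t /= np.linalg.norm(t, axis=1, keepdims=True)
            cs.append(float(t[0] @ t[1]))
        expect = np.exp(-step / (2 * P))  # 0.9399
        se = np.std(cs) / np.sqrt(len(cs))
        assert abs(np.mean(cs) - expect) < 3 * se

    @pytest.mark.parametrize("P_um", [2.0, 5.0, 10.0, 20.0])
    def test_lag_correlation_exponential_all_lags(self, P_um):
        # pooled lag-k correlation = exp(-k*step/2P) within 3 MC SE
        step = 0.62
        chains = [
            fk.sample_wlc(
                fk.WLCParams(
                    persistence_length_um=P_um, contour_length_um=10 * step, seed=s
                )
            )
            for s in range(10_000)
        ]
        prof = fk.tangent_correlation(chains, step_um=step, max_lag=8, resample=False)
        for k in range(1, 9):
            expect = np.exp(-k * step / (2 * P_um))
            se = np.sqrt(max(1.0 - expect**2, 1e-6) / prof.n_pairs[k])
            assert abs(prof.mean_corr[k] - expect) < 3 * se + 1e-3

    def test_too_short_contour_rejected(self):
        with pytest.raises(ValueError):
            fk.WLCParams(persistence_length_um=5, contour_length_um=0.62, step_um=0.62)

    def test_seed_reproducibility(self):
        a = fk.sample_wlc(fk.WLCParams(persistence_length_um=7, contour_length_um=9, seed=11))
        b = fk.sample_wlc(fk.WLCParams(persistence_length_um=7, contour_length_um=9, seed=11))
        assert np.array_equal(a.points, b.points)


class TestRenderFilaments:
    def test_empty_path_list_gives_background(self, noise_free_render):
        img = fk.render_filaments([], noise_free_render)
        assert np.allclose(img, noise_free_render.background)

    def test_perpendicular_profile_is_psf_gaussian(self, noise_free_render):
        rp = noise_free_render
        pix = rp.pixel_um
        H, W = rp.image_shape
        cy = (H - 1) / 2 * pix
        pts = np.stack([np.linspace(5, 30, 100), np.full(100, cy)], axis=1)
        img = fk.render_filaments([fk.FilamentPath(points=pts, pixel_um=pix)], rp)
        col = img[:, W // 2] - rp.background

        def gauss(x, a, mu, sd):
            return a * np.exp(-((x - mu) ** 2) / (2 * sd**2))

        x = np.arange(H, dtype=float)
        popt, _ = curve_fit(gauss, x, col, p0=[col.max(), H / 2, 2.0])
        assert abs(popt[2]) == pytest.approx(rp.psf_sigma_um / pix, rel=0.05)

    def test_out_of_field_path_rejected_with_index(self, noise_free_render):
        pix = noise_free_render.pixel_um
        inside = np.stack([np.linspace(5, 10, 20), np.full(20, 10.0)], axis=1)
        outside = np.stack([np.linspace(-5, 5, 20), np.full(20, 10.0)], axis=1)
        good = fk.FilamentPath(points=inside, pixel_um=pix)
        bad = fk.FilamentPath(points=outside, pixel_um=pix)
        with pytest.raises(ValueError, match="path 1"):
            fk.render_filaments([good, bad], noise_free_render)

    def test_seeded_noise_reproducible(self):
        rp = fk.RenderParams(seed=9)
        pts = np.stack([np.linspace(5, 30, 60), np.full(60, 15.0)], axis=1)
        fp = fk.FilamentPath(points=pts, pixel_um=rp.pixel_um)
        assert np.array_equal(
            fk.render_filaments([fp], rp), fk.render_filaments([fp], rp)
        )


class TestPorositySeries:
    def test_no_bleach_no_noise_is_ground_truth(self):
        kp = fk.KineticsParams(
            tau_assembly_min=10, uv_events_min=[2.0], duration_min=20
        )
        sim = fk.simulate_porosity_series(kp)
        assert np.array_equal(sim.p_raw, sim.p_true)

    def test_single_event_first_order_relaxation(self):
        kp = fk.KineticsParams(
            tau_assembly_min=10,
            porosity_assembled=1.0,
            porosity_disassembled=0.18,
            uv_events_min=[0.0],
            duration_min=30,
            dt_min=0.5,
        )
        sim = fk.simulate_porosity_series(kp)
        expect = 0.18 + 0.82 * (1 - np.exp(-sim.t_min / 10))
        assert np.allclose(sim.p_true, expect)

    def test_drift_construction_at_event(self):
        # at the event instant the true porosity is exactly the disassembled
        # level and the raw value carries the full multiplicative drift
        kp = fk.KineticsParams(
            tau_assembly_min=10,
            bleach_slope_per_min=0.005,
            uv_events_min=[10.0],
            duration_min=30,
            dt_min=0.5,
        )
        sim = fk.simulate_porosity_series(kp)
        i = int(np.argmin(np.abs(sim.t_min - 10.0)))
        assert sim.p_true[i] == pytest.approx(0.18)
        assert sim.p_raw[i] == pytest.approx(0.18 / (1 - 0.005 * 10.0))

    def test_nonphysical_bleach_rejected(self):
        with pytest.raises(ValueError):
            fk.KineticsParams(
                tau_assembly_min=10, bleach_slope_per_min=0.05, duration_min=30
            )


class TestGUVScene:
    def test_signal_conservation_across_peripheral_fraction(self):
        rp = fk.RenderParams(
            pixel_um=0.2, image_shape=(160, 160), shot_noise=False, read_noise_sd=0.0
        )
        totals = []
        for pf in (0.0, 0.5, 1.0):
            gp = fk.GUVSceneParams(radius_um=10, peripheral_fraction=pf, seed=1)
            _, fil = fk.render_guv_scene(gp, rp)
            totals.append((fil - rp.background).sum())
        assert np.ptp(totals) / np.mean(totals) < 0.02

    def test_zero_peripheral_fraction_empty_annulus_excess(self):
        rp = fk.RenderParams(
            pixel_um=0.2, image_shape=(160, 160), shot_noise=False, read_noise_sd=0.0
        )
        gp = fk.GUVSceneParams(radius_um=10, peripheral_fraction=0.0, seed=1)
        _, fil = fk.render_guv_scene(gp, rp)
        H, W = rp.image_shape
        yy, xx = np.mgrid[0:H, 0:W]
        r = np.hypot(
            (xx - (W - 1) / 2) * rp.pixel_um, (yy - (H - 1) / 2) * rp.pixel_um
        )
        inside = fil[r < 9.0] - rp.background
        shell_only_excess = fil[(r > 9.3) & (r < 9.9)].mean() - fil[r < 7].mean()
        assert inside.min() > 0  # lumen uniformly filled
        assert abs(shell_only_excess) < 0.05 * inside.mean()

    def test_vesicle_must_fit(self):
        rp = fk.RenderParams(pixel_um=0.2, image_shape=(64, 64))
        with pytest.raises(ValueError, match="fit"):
            fk.render_guv_scene(fk.GUVSceneParams(radius_um=10, peripheral_fraction=0.5), rp)

    def test_axis_ratio_below_one_rejected(self):
        with pytest.raises(ValueError):
            fk.GUVSceneParams(radius_um=5, peripheral_fraction=0.5, axis_ratio=0.5)


class TestSimulateFRAP:
    def test_fully_immobile_flat_curve(self):
        fp = fk.FRAPParams(
            D_um2_per_s=1.0, bleach_depth=0.8, immobile_fraction=0.999999, noise_sd=0
        )
        # immobile fraction ~1: nothing exchanges, curve stays at 1 - depth
        c = fk.simulate_frap(fp)
        assert np.allclose(c.intensity_norm, 0.2, atol=1e-4)

    def test_full_recovery_limit(self):
        fp = fk.FRAPParams(D_um2_per_s=5.0, t_max_s=2000, dt_s=10, noise_sd=0)
        c = fk.simulate_frap(fp)
        assert c.intensity_norm[-1] == pytest.approx(1.0, abs=5e-3)

    def test_bessel_closed_form_value(self):
        # D = 2.3 um^2/s (lipid-tile regime), r = 5 um: tau_D = 25/9.2 s
        tau_d = 25.0 / 9.2
        t = 2 * tau_d
        from scipy.special import ive

        expect = ive(0, 1.0) + ive(1, 1.0)
        assert soumpasis_recovery(np.array([t]), tau_d)[0] == pytest.approx(expect)
        fp = fk.FRAPParams(D_um2_per_s=2.3, t_max_s=60, dt_s=tau_d / 4, noise_sd=0)
        c = fk.simulate_frap(fp)
        i = int(np.argmin(np.abs(c.t_s - t)))
        assert c.intensity_norm[i] == pytest.approx(0.2 + 0.8 * expect, abs=1e-9)

    def test_monotone_when_noise_free(self):
        c = fk.simulate_frap(fk.FRAPParams(D_um2_per_s=0.5, noise_sd=0))
        assert np.all(np.diff(c.intensity_norm) >= -1e-12)

    def test_dt_must_be_below_t_max(self):
        with pytest.raises(ValueError):
            fk.FRAPParams(D_um2_per_s=1.0, t_max_s=10, dt_s=10)


def test_all_generators_bit_reproducible(noisy_render):
    chain = lambda: fk.sample_wlc(
        fk.WLCParams(persistence_length_um=8, contour_length_um=10, seed=5)
    )
    assert np.array_equal(chain().points, chain().points)
    kp = fk.KineticsParams(
        tau_assembly_min=5, uv_events_min=[1.0], duration_min=10, noise_sd=0.01, seed=4
    )
    assert np.array_equal(
        fk.simulate_porosity_series(kp).p_raw, fk.simulate_porosity_series(kp).p_raw
    )
    gp = fk.GUVSceneParams(radius_um=8, peripheral_fraction=0.5, seed=2)
    rp = fk.RenderParams(pixel_um=0.2, image_shape=(128, 128), seed=7)
    m1, f1 = fk.render_guv_scene(gp, rp)
    m2, f2 = fk.render_guv_scene(gp, rp)
    assert np.array_equal(m1, m2) and np.array_equal(f1, f2)
    fp = fk.FRAPParams(D_um2_per_s=1.0, noise_sd=0.02, seed=3)
    assert np.array_equal(
        fk.simulate_frap(fp).intensity_norm, fk.simulate_frap(fp).intensity_norm
    )
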