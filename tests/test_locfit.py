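"""Detection significance maps, candidate selection, and MLE fitting."""

import numpy as np
import pytest

from mvsmlm import (CameraCalibration, EmitterGroundTruth, FitConfig,
                    GaussianPSF, PlaneGeometry, correct_frames,
                    find_candidates, fit_multiplane, fit_single_plane,
                    localize_movie, significance_map, simulate_movie)
from mvsmlm.locfit import FIT_MODE_PER_PLANE, fit_gaussian_mle
from mvsmlm.errors import ConfigurationError

from conftest import PIXEL_SIZE_NM, analytic_spline, render_expected


class TestSignificanceMap:
    def test_all_zero_frame(self):
        cal = CameraCalibration.from_scalars((64, 64), 0, 1, 1.0)
        smap = significance_map(np.zeros((64, 64)), 1.2, cal)
        np.testing.assert_allclose(smap, 0.0, atol=1e-12)

    def test_null_rate_on_pure_background(self, gauss2d):
        """On background-only frames pixels above 6 sigma are Gaussian-tail
        rare: expect essentially none in a 256^2 frame."""
        cal = CameraCalibration.from_scalars((256, 256), 100, 2, 1.6)
        stack = simulate_movie([], gauss2d, PlaneGeometry.single_plane(), cal,
                               20.0, 1, seed=13)[0]
        smap = significance_map(correct_frames(stack, cal).pixels[0], 1.2, cal)
        assert (smap > 6.0).sum() <= 3
        assert abs(smap.std() - 1.0) < 0.1  # calibrated sigma units

    def test_injected_spot_exceeds_8_sigma(self, gauss2d):
        cal = CameraCalibration.from_scalars((64, 64), 100, 2, 1.6)
        em = [EmitterGroundTruth(x=32.3, y=31.6, photons=2000.0)]
        stack = simulate_movie(em, gauss2d, PlaneGeometry.single_plane(), cal,
                               20.0, 1, seed=14)[0]
        smap = significance_map(correct_frames(stack, cal).pixels[0], 1.2, cal)
        assert smap.max() > 8.0

    def test_bad_sigma(self, cal_small):
        with pytest.raises(ConfigurationError):
            significance_map(np.zeros((32, 32)), 0.0, cal_small)


class TestFindCandidates:
    def test_threshold_monotonicity(self, gauss2d):
        cal = CameraCalibration.from_scalars((128, 128), 100, 2, 1.6)
        ems = [EmitterGroundTruth(x=x, y=y, photons=n) for x, y, n in
               [(30.2, 40.7, 3000), (80.5, 20.3, 700), (60.0, 100.0, 400),
                (100.8, 90.1, 1500)]]
        stack = simulate_movie(ems, gauss2d, PlaneGeometry.single_plane(), cal,
                               20.0, 1, seed=15)[0]
        smap = significance_map(correct_frames(stack, cal).pixels[0], 1.2, cal)
        hi = set(find_candidates(smap, 8.0))
        lo = set(find_candidates(smap, 6.0))
        assert hi <= lo

    def test_single_spot_single_candidate(self, gauss2d):
        cal = CameraCalibration.from_scalars((64, 64), 100, 2, 1.6)
        em = [EmitterGroundTruth(x=32.3, y=31.6, photons=2000.0)]
        stack = simulate_movie(em, gauss2d, PlaneGeometry.single_plane(), cal,
                               20.0, 1, seed=16)[0]
        smap = significance_map(correct_frames(stack, cal).pixels[0], 1.2, cal)
        cands = find_candidates(smap, 8.0)
        assert len(cands) == 1
        r, c = cands[0]
        assert abs(r - 31.6) <= 1 and abs(c - 32.3) <= 1

    def test_tie_keeps_smaller_row_then_col(self):
        smap = np.zeros((20, 20))
        smap[5, 5] = smap[6, 5] = 10.0
        assert find_candidates(smap, 3.0, min_separation=3.0) == [(5, 5)]
        smap2 = np.zeros((20, 20))
        smap2[5, 5] = smap2[5, 6] = 10.0
        assert find_candidates(smap2, 3.0, min_separation=3.0) == [(5, 5)]

    def test_empty_allowed(self):
        assert find_candidates(np.zeros((16, 16)), 6.0) == []


class TestSinglePlaneFit:
    def test_noiseless_recovery(self, gauss2d):
        """On an exact expectation frame the MLE recovers truth to 1e-3 px / 1%."""
        frame = render_expected(gauss2d, 10.30, 12.70, 0.0, 5000.0, 10.0, (24, 24))
        cal = CameraCalibration.from_scalars((24, 24), 0, 1, 0)
        table = fit_single_plane(frame, cal, [(13, 10)], FitConfig())
        row = table.df.iloc[0]
        assert row.status == "converged"
        assert abs(row.x - 10.30) < 1e-3 and abs(row.y - 12.70) < 1e-3
        assert abs(row.photons - 5000.0) < 0.01 * 5000.0
        assert abs(row.background - 10.0) < 0.1
        assert abs(row.sigma - 130.0) < 0.01 * 130.0

    def test_symmetric_spot_at_pixel_center(self, gauss2d):
        frame = render_expected(gauss2d, 12.0, 12.0, 0.0, 3000.0, 5.0, (25, 25))
        cal = CameraCalibration.from_scalars((25, 25), 0, 1, 0)
        row = fit_single_plane(frame, cal, [(12, 12)], FitConfig()).df.iloc[0]
        assert abs(row.x - 12.0) < 1e-6 and abs(row.y - 12.0) < 1e-6

    def test_likelihood_non_decreasing(self, gauss2d, rng):
        mu = 1000.0 * gauss2d.evaluate(7.3, 6.8, 0.0, 15) + 10.0
        patch = rng.poisson(mu).astype(float)
        res = fit_gaussian_mle(patch, 1.6)
        trace = np.asarray(res["trace"])
        assert np.all(np.diff(trace) >= -1e-6 * np.abs(trace[:-1]))

    def test_crb_attainment_quick(self, gauss2d, rng):
        """~600 Poisson spots at N=1000, b=10: std(x) tracks the CRB."""
        from mvsmlm import CRBInputs2D, mortensen_crb
        N, b = 1000.0, 10.0
        crb = mortensen_crb(CRBInputs2D(N, b)).sigma_x
        errs = []
        for _ in range(600):
            x = 7 + rng.uniform(-0.5, 0.5)
            y = 7 + rng.uniform(-0.5, 0.5)
            patch = rng.poisson(N * gauss2d.evaluate(x, y, 0, 15) + b).astype(float)
            res = fit_gaussian_mle(patch, 0.0, sigma0_px=130.0 / PIXEL_SIZE_NM)
            if res["converged"]:
                errs.append(res["x"] - x)
        std = np.std(errs, ddof=1) * PIXEL_SIZE_NM
        assert len(errs) > 550
        assert abs(std - crb) < 0.12 * crb

    def test_movie_driver_finds_emitters(self, gauss2d):
        cal = CameraCalibration.from_scalars((64, 64), 100, 2, 1.6)
        ems = [EmitterGroundTruth(x=20.3, y=40.2, photons=3000),
               EmitterGroundTruth(x=45.8, y=15.5, photons=3000)]
        stack = simulate_movie(ems, gauss2d, PlaneGeometry.single_plane(), cal,
                               15.0, 4, seed=17)
        table = localize_movie(correct_frames(stack[0], cal), cal,
                               FitConfig(threshold=8.0))
        conv = table.converged().df
        assert len(conv) == 8  # 2 emitters x 4 frames
        for _, row in conv.iterrows():
            truth = min(ems, key=lambda e: (e.x - row.x) ** 2 + (e.y - row.y) ** 2)
            assert abs(row.x - truth.x) < 0.3 and abs(row.y - truth.y) < 0.3


class TestMultiplaneFit:
    def test_symmetric_biplane_split(self, gauss3d, biplane):
        """Midway between two identical planes the fitted per-plane signals
        are equal (N/2 each) within 1%."""
        sp = analytic_spline(gauss3d)
        N, b = 4000.0, 10.0
        frames = [render_expected(gauss3d, 15.5, 15.5, -off, N / 2, b, (32, 32))
                  for off in biplane.focal_offsets]
        cal = CameraCalibration.from_scalars((32, 32), 0, 1, 0)
        cfg = FitConfig(fit_mode=FIT_MODE_PER_PLANE)
        table = fit_multiplane(frames, [cal, cal], [sp, sp], biplane,
                               [(15, 15)], cfg)
        row = table.df.iloc[0]
        assert row.status == "converged"
        assert abs(row.signal0 - row.signal1) < 0.01 * (N / 2)
        assert abs(row.signal0 - N / 2) < 0.02 * (N / 2)
        assert abs(row.z) < 10.0

    def test_noiseless_z_recovery(self, gauss3d, biplane):
        sp = analytic_spline(gauss3d)
        cal = CameraCalibration.from_scalars((32, 32), 0, 1, 0)
        for z_true in (-150.0, 0.0, 220.0):
            frames = [render_expected(gauss3d, 15.2, 15.8, z_true - off,
                                      0.5 * 4000.0, 10.0, (32, 32), window=21)
                      for off in biplane.focal_offsets]
            row = fit_multiplane(frames, [cal, cal], [sp, sp], biplane,
                                 [(15, 15)], FitConfig()).df.iloc[0]
            assert row.status == "converged"
            assert abs(row.z - z_true) < 5.0
            assert abs(row.x - 15.2) < 0.01 and abs(row.y - 15.8) < 0.01

    def test_quadplane_dark_plane(self, gauss3d, rng):
        """A plane seeing only background gets ~zero fitted signal and the
        joint fit still converges on the remaining planes."""
        geom = PlaneGeometry.quadplane()
        sp = analytic_spline(gauss3d, z_min=-1600, z_max=1600)
        cal = CameraCalibration.from_scalars((32, 32), 0, 1, 0)
        N, b = 8000.0, 10.0
        z_true = 0.0
        frames = []
        for p, off in enumerate(geom.focal_offsets):
            if p == 3:
                frames.append(np.full((32, 32), b))  # dark plane
            else:
                frames.append(render_expected(gauss3d, 15.5, 15.5, z_true - off,
                                              N / 4, b, (32, 32), window=21))
        cfg = FitConfig(fit_mode=FIT_MODE_PER_PLANE)
        row = fit_multiplane(frames, [cal] * 4, [sp] * 4, geom, [(15, 15)],
                             cfg).df.iloc[0]
        assert row.status == "converged"
        assert row.signal3 < 0.01 * N
        assert abs(row.signal0 - N / 4) < 0.05 * N / 4

    def test_z_escape_flagged(self, gauss3d, biplane):
        """An emitter far outside the calibrated z range ends at the range
        boundary and is flagged failed."""
        sp = analytic_spline(gauss3d, z_min=-400, z_max=400)
        cal = CameraCalibration.from_scalars((32, 32), 0, 1, 0)
        # true z=350 while the joint calibrated interval is [-100, 100]:
        # both planes push z against the upper boundary
        frames = [render_expected(gauss3d, 15.5, 15.5, 350.0 - off, 2000.0,
                                  10.0, (32, 32), window=21)
                  for off in biplane.focal_offsets]
        row = fit_multiplane(frames, [cal, cal], [sp, sp], biplane,
                             [(15, 15)], FitConfig()).df.iloc[0]
        assert row.status == "failed"


class TestFitConfigValidation:
    @pytest.mark.parametrize("kw", [dict(threshold=0), dict(window=8),
                                    dict(window=5), dict(fit_mode="bogus")])
    def test_invalid(self, kw):
        with pytest.raises(ConfigurationError):
            FitConfig(**kw)
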