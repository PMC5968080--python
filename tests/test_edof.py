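"""Focus measure, perspective rescaling, and EDOF compositing."""

import numpy as np
import pytest
from scipy import ndimage

from disc3d.edof import EdofParams, compose_edof, focus_measure, rescale_to_reference
from disc3d.errors import InvalidInputError, InvalidParameterError
from disc3d.optics import StackCalibration
from disc3d.synth import FocusStack, project_points


def _dot_image(shape, centers, sigma=1.5):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    img = np.ones(shape)
    for (r, c) in centers:
        img -= np.exp(-((rr - r) ** 2 + (cc - c) ** 2) / (2 * sigma**2))
    return np.clip(img, 0, 1)


class TestFocusMeasure:
    def test_constant_image_is_zero(self):
        assert focus_measure(np.full((32, 32), 0.37)).max() == 0.0

    def test_step_edge_peaks_on_edge(self):
        img = np.zeros((33, 33))
        img[:, 17:] = 1.0
        m = focus_measure(img, 9)
        # response is maximal in the edge columns, symmetric about it
        peak_cols = np.argmax(m, axis=1)
        assert np.all(np.abs(peak_cols - 16.5) <= 1.0)

    def test_argmax_identifies_sharp_slice(self, tilted_plane_bundle):
        """Per-pixel argmax picks the in-focus slice on the textured plane."""
        stack = tilted_plane_bundle["stack"]
        gt = tilted_plane_bundle["gt_index"]
        measures = np.stack([focus_measure(s, 9) for s in stack.slices])
        best = measures.argmax(axis=0)
        m = 8
        err = np.abs(best - gt)[m:-m, m:-m]
        assert (err <= 1.0).mean() >= 0.95

    def test_window_validation(self):
        with pytest.raises(InvalidParameterError):
            focus_measure(np.zeros((16, 16)), 4)
        with pytest.raises(InvalidParameterError):
            focus_measure(np.zeros((8, 8)), 9)


class TestRescale:
    def _cal(self, s):
        # one-slice-from-reference calibration with scale s for slice 1
        beta = (1.0 / s) - 1.0
        return StackCalibration(n_slices=2, step_um=500, ref_index=0, beta=beta)

    def test_identity(self):
        img = np.random.default_rng(0).random((40, 40, 3))
        out = rescale_to_reference(img, 0, self._cal(0.9), (19.5, 19.5))
        assert np.array_equal(out, img)

    def test_principal_point_is_fixed(self):
        img = _dot_image((41, 41), [(20.0, 20.0)])
        out = rescale_to_reference(img, 1, self._cal(0.5), (20.0, 20.0))
        w = 1.0 - out
        rr, cc = np.mgrid[0:41, 0:41]
        r0 = (w * rr).sum() / w.sum()
        c0 = (w * cc).sum() / w.sum()
        assert (r0, c0) == pytest.approx((20.0, 20.0), abs=0.05)

    def test_dot_separation_scales(self):
        img = _dot_image((81, 121), [(40.0, 10.0), (40.0, 110.0)])
        out = rescale_to_reference(img, 1, self._cal(100 / 110), (60.0, 40.0))
        w = np.clip(1.0 - out, 0, None)
        lab, n = ndimage.label(w > 0.3)
        assert n == 2
        cent = np.array(ndimage.center_of_mass(w, lab, [1, 2]))
        sep = abs(cent[0][1] - cent[1][1])
        assert sep == pytest.approx(100 * 100 / 110, abs=1.0)


class TestCompose:
    def _flat_cal(self, n):
        return StackCalibration(n_slices=n, step_um=500, ref_index=n // 2, beta=0.0)

    def test_identical_slices_idempotent(self):
        rng = np.random.default_rng(1)
        img = np.clip(rng.random((48, 48, 3)), 0, 1)
        stack = FocusStack(slices=[img.copy() for _ in range(5)],
                           rail_positions_mm=np.arange(5) * 0.5, step_um=500)
        res = compose_edof(stack, self._flat_cal(5))
        assert np.allclose(res.image, img, atol=1e-12)

    def test_output_in_range_no_nans(self, tilted_plane_bundle):
        res = compose_edof(tilted_plane_bundle["stack"], tilted_plane_bundle["cal"])
        assert np.isfinite(res.image).all()
        assert res.image.min() >= 0.0 and res.image.max() <= 1.0
        assert np.isfinite(res.depth.values).all()

    def test_depth_recovery_tilted_plane(self, tilted_plane_bundle):
        """Smoothed fractional depth map: RMS error <= 0.75 slices."""
        res = compose_edof(tilted_plane_bundle["stack"], tilted_plane_bundle["cal"])
        gt = tilted_plane_bundle["gt_index"]
        m = 8
        err = (res.depth.values - gt)[m:-m, m:-m]
        assert np.sqrt((err**2).mean()) <= 0.75
        assert (np.abs(err) <= 1.0).mean() >= 0.95

    def test_empty_and_mismatched_stacks_rejected(self):
        img = np.zeros((16, 16, 3))
        stack = FocusStack(slices=[img] * 3, rail_positions_mm=np.arange(3.0),
                           step_um=500)
        with pytest.raises(InvalidInputError):
            compose_edof(stack, self._flat_cal(5))

    @staticmethod
    def _dark_centroids(img, k_expected):
        g = img.mean(axis=2)
        m = g < 0.5
        lab, k = ndimage.label(m)
        assert k == k_expected
        c = np.array(ndimage.center_of_mass(np.where(m, 0.8 - g, 0), lab,
                                            range(1, k + 1)))
        return c[np.argsort(c[:, 1])]

    def test_pinhole_consistency_two_dots(self, two_dot_bundle):
        """Calibrated EDOF matches the reference pinhole projection (<1 px);
        uncalibrated compositing does not (>2 px)."""
        b = two_dot_bundle
        uv, _ = project_points(b["centers"], b["pose"], b["camera"])
        sep_ref = float(np.linalg.norm(uv[0] - uv[1]))

        res = compose_edof(b["stack"], b["cal"])
        cen = self._dark_centroids(res.image, 2)
        sep = float(np.hypot(*(cen[0] - cen[1])))
        assert abs(sep - sep_ref) < 1.0

        uncal = StackCalibration(n_slices=b["cal"].n_slices, step_um=b["cal"].step_um,
                                 ref_index=b["cal"].ref_index, beta=0.0)
        res_u = compose_edof(b["stack"], uncal)
        cen_u = self._dark_centroids(res_u.image, 2)
        sep_u = float(np.hypot(*(cen_u[0] - cen_u[1])))
        assert abs(sep_u - sep_ref) > 2.0
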