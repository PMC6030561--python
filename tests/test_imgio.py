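"""Image I/O round trips and distortion estimation/correction."""

import numpy as np
import pytest

from icmscope import (
    DistortionMap,
    FieldImage,
    apply_correction,
    estimate_distortion,
    read_field,
    write_field,
)
from icmscope.errors import (
    CalibrationError,
    DataError,
    DegenerateGeometryError,
    FormatError,
)
from icmscope.imgio import read_landmarks


class TestFieldIO:
    def test_roundtrip_is_bitwise(self, tmp_path, rng):
        channels = {
            "phase": rng.poisson(200, (64, 64)).astype(np.float64),
            "fluor": rng.poisson(100, (64, 64)).astype(np.float64),
            "adhesin": rng.poisson(100, (64, 64)).astype(np.float64),
        }
        f = FieldImage(channels=channels, pixel_size=0.065)
        p = tmp_path / "field.tif"
        write_field(f, p)
        g = read_field(p)
        assert g.pixel_size == 0.065
        assert set(g.channels) == set(channels)
        for k in channels:
            assert np.array_equal(g.channels[k], channels[k])

    def test_override_pixel_size_and_page_naming(self, tmp_path):
        import tifffile

        data = np.zeros((3, 16, 16), dtype=np.uint16)
        tifffile.imwrite(tmp_path / "plain.tif", data, photometric="minisblack")
        f = read_field(tmp_path / "plain.tif", pixel_size_override=0.065)
        assert f.pixel_size == 0.065
        assert set(f.channels) == {"phase", "fluor", "adhesin"}

    def test_missing_calibration_raises(self, tmp_path):
        import tifffile

        tifffile.imwrite(tmp_path / "plain.tif", np.zeros((16, 16), dtype=np.uint16))
        with pytest.raises(CalibrationError):
            read_field(tmp_path / "plain.tif")

    def test_channel_count_mismatch_raises(self, tmp_path):
        import tifffile

        tifffile.imwrite(tmp_path / "p.tif", np.zeros((2, 8, 8), dtype=np.uint16))
        with pytest.raises(FormatError):
            read_field(tmp_path / "p.tif", pixel_size_override=0.1,
                       channel_names=("phase", "fluor", "adhesin"))

    def test_fluor_only_field_lacks_phase(self, tmp_path):
        import tifffile

        tifffile.imwrite(tmp_path / "f.tif", np.zeros((8, 8), dtype=np.uint16))
        f = read_field(tmp_path / "f.tif", pixel_size_override=0.1,
                       channel_names=("fluor",))
        assert not f.has_channel("phase")
        with pytest.raises(FormatError):
            f.channel("phase")

    def test_landmark_csv_roundtrip(self, tmp_path):
        import pandas as pd

        df = pd.DataFrame(
            dict(x_fluor=[1.0, 2], y_fluor=[3.0, 4], x_phase=[1.5, 2.5],
                 y_phase=[3.5, 4.5])
        )
        df.to_csv(tmp_path / "lm.csv", index=False)
        arr = read_landmarks(tmp_path / "lm.csv")
        assert arr.shape == (2, 4)


class TestEstimateDistortion:
    def test_pure_shift_recovered_exactly(self, rng):
        pts = rng.uniform(0, 100, (10, 2))
        pairs = np.hstack([pts, pts + [2.0, -1.5]])
        dm = estimate_distortion(pairs, "affine")
        assert dm.coefficients[:, :2] == pytest.approx(np.eye(2), abs=1e-9)
        assert dm.coefficients[:, 2] == pytest.approx([2.0, -1.5], abs=1e-9)
        assert dm.residual_rms < 1e-9

    def test_aligned_pairs_give_identity(self, rng):
        pts = rng.uniform(0, 100, (5, 2))
        dm = estimate_distortion(np.hstack([pts, pts]), "affine")
        assert dm.is_identity()

    def test_collinear_points_raise(self):
        pts = np.array([[0.0, 0], [1, 1], [2, 2], [3, 3]])
        with pytest.raises(DegenerateGeometryError):
            estimate_distortion(np.hstack([pts, pts + 1.0]), "affine")

    def test_too_few_pairs_raise(self):
        with pytest.raises(DataError):
            estimate_distortion(np.zeros((4, 4)), "quadratic")

    def test_jittered_affine_recovery(self):
        """Monte Carlo: with landmark jitter sd 0.3 px the fitted entries stay
        within 3 standard errors of truth and residual_rms ≈ 0.3."""
        A = np.array([[1.02, -0.01, 2.5], [0.015, 0.99, -1.0]])
        hits, rms_vals = 0, []
        n_rep = 40
        for seed in range(n_rep):
            r = np.random.default_rng(seed)
            src = r.uniform(0, 500, (50, 2))
            B = np.stack([src[:, 0], src[:, 1], np.ones(50)], axis=1)
            dst = B @ A.T + r.normal(0, 0.3, (50, 2))
            dm = estimate_distortion(np.hstack([src, dst]), "affine")
            # standard errors of the LS coefficients
            cov = 0.3**2 * np.linalg.inv(B.T @ B)
            se = np.sqrt(np.diag(cov))
            ok = np.all(np.abs(dm.coefficients - A) <= 3 * se[None, :])
            hits += bool(ok)
            rms_vals.append(dm.residual_rms)
        assert hits >= 0.9 * n_rep
        assert np.median(rms_vals) == pytest.approx(0.3, abs=0.06)

    def test_quadratic_fits_quadratic_warp(self, rng):
        src = rng.uniform(0, 300, (40, 2))
        dst = src + 1e-5 * src**2 + [1.0, -2.0]
        dm = estimate_distortion(np.hstack([src, dst]), "quadratic")
        assert dm.residual_rms < 1e-6
        back = dm.inverse_transform(dm.transform(src))
        assert back == pytest.approx(src, abs=1e-6)

    def test_json_roundtrip(self, rng):
        pts = rng.uniform(0, 100, (10, 2))
        dm = estimate_distortion(np.hstack([pts, pts + [2.0, 3.0]]), "affine")
        dm2 = DistortionMap.from_json(dm.to_json())
        assert np.allclose(dm.coefficients, dm2.coefficients)


class TestApplyCorrection:
    def test_identity_is_bitwise(self, rng):
        img = rng.poisson(100, (64, 64)).astype(np.int32)
        out, oob = apply_correction(img, DistortionMap.identity())
        assert np.array_equal(out, img)
        assert not oob.any()

    def test_integer_shift_matches_roll(self, rng):
        img = rng.normal(100, 5, (64, 64))
        pts = rng.uniform(10, 50, (10, 2))
        dm = estimate_distortion(np.hstack([pts, pts + [3.0, -2.0]]), "affine")
        out, oob = apply_correction(img, dm)
        rolled = np.roll(np.roll(img, -2, axis=0), 3, axis=1)
        inner = ~oob
        inner[:4, :] = inner[-4:, :] = inner[:, :4] = inner[:, -4:] = False
        assert out[inner] == pytest.approx(rolled[inner], abs=1e-9)

    def test_warp_then_inverse_round_trip(self, rng):
        base = np.zeros((128, 128))
        for _ in range(30):  # smooth blobs
            x0, y0 = rng.uniform(20, 108, 2)
            yy, xx = np.mgrid[0:128, 0:128]
            base += 100 * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / 40)
        pts = rng.uniform(10, 118, (30, 2))
        A = np.array([[1.01, 0.02, 1.3], [-0.01, 0.995, -0.8]])
        B = np.stack([pts[:, 0], pts[:, 1], np.ones(len(pts))], axis=1)
        fwd = estimate_distortion(np.hstack([pts, B @ A.T]), "affine")
        inv = estimate_distortion(np.hstack([B @ A.T, pts]), "affine")
        warped, _ = apply_correction(base, inv)  # push image through the warp
        restored, oob = apply_correction(warped, fwd)
        inner = ~oob
        inner[:8, :] = inner[-8:, :] = inner[:, :8] = inner[:, -8:] = False
        rms = np.sqrt(np.mean((restored[inner] - base[inner]) ** 2))
        assert rms < 0.01 * np.ptp(base)

    def test_correction_reduces_landmark_misalignment(self, rng):
        """estimate + apply lowers the mean landmark error vs no correction."""
        pts = rng.uniform(20, 200, (25, 2))
        A = np.array([[1.02, 0.015, 3.0], [-0.02, 0.98, -2.5]])
        B = np.stack([pts[:, 0], pts[:, 1], np.ones(len(pts))], axis=1)
        warped = B @ A.T + rng.normal(0, 0.2, (25, 2))
        before = np.linalg.norm(warped - pts, axis=1).mean()
        dm = estimate_distortion(np.hstack([warped, pts]), "affine")
        after = np.linalg.norm(dm.transform(warped) - pts, axis=1).mean()
        assert after < before
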