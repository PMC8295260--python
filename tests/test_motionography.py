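"""Motionography: basal band, components, normalization, angles, quadrants."""

import numpy as np
import pandas as pd
import pytest

from lungmotion import motionography as motion
from lungmotion.errors import EmptyMaskError
from lungmotion.fields import AnalyticDeformation, LinearField, TranslationField
from lungmotion.registration import DeformationField
from lungmotion.volume import LungSegmentation, LOBE_CODES


def box_segmentation(shape=(20, 20, 20), spacing=2.0, z0=5, z1=15, side="left"):
    """Flat-bottomed box lung for arithmetic checks."""
    labels = np.zeros(shape, dtype=np.int16)
    code = LOBE_CODES["LLL"] if side == "left" else LOBE_CODES["RLL"]
    labels[4:16, 4:16, z0:z1] = code
    return LungSegmentation(labels, (spacing,) * 3)


UNIT_CTX = motion.NormalizationContext(v_in=2.0, v_ex=1.0)  # divisor = 1


class TestHeightMap:
    def test_flat_bottom_box(self):
        seg = box_segmentation(z0=5)
        hm = motion.diaphragm_height_map(seg, "left")
        inside = ~np.isnan(hm)
        assert np.all(hm[inside] == 10.0)  # z index 5 at 2 mm spacing

    def test_columns_outside_lung_are_absent(self):
        seg = box_segmentation()
        hm = motion.diaphragm_height_map(seg, "left")
        assert np.isnan(hm[0, 0])
        assert np.isnan(hm).sum() == 400 - 144

    def test_dome_phantom_matches_analytic_surface(self, small_pair):
        """Height map equals the analytic basal surface (dome capped by the
        eroded ellipsoid bottom) within one voxel, column by column."""
        spec = small_pair.spec
        model = small_pair.model
        g = model.lungs["left"]
        hm = motion.diaphragm_height_map(small_pair.expiration_seg, "left")
        cols = np.argwhere(~np.isnan(hm))
        margin = spec.segmentation_margin_mm
        semi = np.asarray(g.semi_axes) - margin
        errs = []
        for cx, cy in cols:
            x, y = cx * spec.spacing[0], cy * spec.spacing[1]
            r2 = ((x - g.center[0]) / semi[0]) ** 2 + ((y - g.center[1]) / semi[1]) ** 2
            if r2 >= 0.98:   # grazing columns: surface position ill-conditioned
                continue
            z_ell = g.center[2] - semi[2] * np.sqrt(1.0 - r2)
            analytic = max(model.dome_surface_z("left", x, y) + margin, z_ell)
            # height map snaps up to the first voxel centre at/above the surface
            expected = np.ceil(analytic / spec.spacing[2]) * spec.spacing[2]
            errs.append(hm[cx, cy] - expected)
        errs = np.asarray(errs)
        assert np.abs(errs).max() <= spec.spacing[2] + 1e-9

    def test_empty_side_raises(self):
        seg = box_segmentation(side="left")
        with pytest.raises(EmptyMaskError):
            motion.diaphragm_height_map(seg, "right")


class TestBasalBand:
    def test_five_mm_band_on_two_mm_voxels_selects_three_layers(self):
        seg = box_segmentation(z0=5)
        hm = motion.diaphragm_height_map(seg, "left")
        cfg = motion.BasalBandConfig(band_thickness=5.0, sample_pitch=2.0)
        pos = motion.extract_basal_band(seg, hm, "left", cfg)
        zs = np.unique(pos[:, 2])
        np.testing.assert_array_equal(zs, [10.0, 12.0, 14.0])  # offsets 0, 2, 4 mm

    def test_zero_thickness_keeps_only_bottom_surface(self):
        seg = box_segmentation(z0=5)
        hm = motion.diaphragm_height_map(seg, "left")
        cfg = motion.BasalBandConfig(band_thickness=0.0, sample_pitch=2.0)
        pos = motion.extract_basal_band(seg, hm, "left", cfg)
        assert np.all(pos[:, 2] == 10.0)
        assert len(pos) == 144

    def test_pitch_subsampling(self):
        seg = box_segmentation(z0=5)
        hm = motion.diaphragm_height_map(seg, "left")
        dense = motion.extract_basal_band(
            seg, hm, "left", motion.BasalBandConfig(sample_pitch=2.0)
        )
        sparse = motion.extract_basal_band(
            seg, hm, "left", motion.BasalBandConfig(sample_pitch=4.0)
        )
        assert len(sparse) < len(dense) / 4

    def test_dome_band_count_matches_shell_volume(self, default_pair):
        """Sample count ≈ basal-shell volume / effective pitch³ (oracle:
        fine integration of the continuum band indicator)."""
        spec = default_pair.spec
        model = default_pair.model
        margin = spec.segmentation_margin_mm
        cfg = motion.BasalBandConfig(band_thickness=5.0, sample_pitch=5.0)
        hm = motion.diaphragm_height_map(default_pair.expiration_seg, "left")
        pos = motion.extract_basal_band(default_pair.expiration_seg, hm, "left", cfg)

        step = 1.0
        ax = [np.arange(0.0, e + step, step) for e in spec.extent()]
        xs, ys, zs = np.meshgrid(*ax, indexing="ij")
        pts = np.stack([xs, ys, zs], axis=-1)
        inside = model.lung_indicator(pts, "left", margin)
        # continuum basal surface per column: lowest point inside the lung
        zcol = np.where(inside, pts[..., 2], np.inf).min(axis=2)
        band = inside & (pts[..., 2] <= zcol[:, :, None] + cfg.band_thickness)
        shell_mm3 = band.sum() * step**3
        eff_pitch = np.prod(
            [max(1, round(cfg.sample_pitch / s)) * s for s in spec.spacing]
        )
        assert len(pos) == pytest.approx(shell_mm3 / eff_pitch, rel=0.10)


class TestSampling:
    def test_constant_field_arithmetic(self):
        pos = np.array([[10.0, 12.0, 8.0], [20.0, 30.0, 12.0]])
        u = motion.sample_displacements(TranslationField((0.0, 2.0, -10.0)), pos)
        np.testing.assert_allclose(u, [[0, 2, -10], [0, 2, -10]])
        assert np.linalg.norm(u[0]) == pytest.approx(np.sqrt(104.0))

    def test_trilinear_exact_on_linear_fields(self):
        lin = LinearField(np.array([[0.02, 0.01, 0.0], [0.0, -0.01, 0.03],
                                    [0.01, 0.0, 0.02]]), t=(0.5, -0.2, 1.0))
        dense = DeformationField.from_analytic(lin, (12, 12, 12), (2.0, 2.0, 2.0))
        rng = np.random.default_rng(3)
        pos = rng.uniform(2.0, 20.0, (40, 3))
        got = motion.sample_displacements(dense, pos)
        np.testing.assert_allclose(got, lin.displacement(pos), atol=1e-9)

    def test_out_of_domain_positions_rejected(self):
        dense = DeformationField.from_analytic(
            TranslationField((1.0, 0.0, 0.0)), (8, 8, 8), (2.0, 2.0, 2.0)
        )
        with pytest.raises(ValueError):
            motion.sample_displacements(dense, np.array([[100.0, 0.0, 0.0]]))


class TestNormalization:
    def test_printed_formula(self):
        # s = 4.4 cm, ΔV = 2 L -> 4.4 / 2^(1/3)
        ctx = motion.NormalizationContext(v_in=6.0, v_ex=4.0)
        df = pd.DataFrame({"ux": [0.0], "uy": [0.0], "uz": [44.0],
                           "s3d_mm": [44.0]})
        out = motion.normalize(df, ctx)
        assert out["s3d_norm"].iloc[0] == pytest.approx(4.4 / 2 ** (1 / 3), rel=1e-12)

    def test_zero_displacement_and_unit_divisor(self):
        df = pd.DataFrame({"ux": [0.0, 13.0], "uy": [0.0, 0.0],
                           "uz": [0.0, 0.0], "s3d_mm": [0.0, 13.0]})
        out = motion.normalize(df, UNIT_CTX)
        assert out["s3d_norm"].iloc[0] == 0.0
        assert out["s3d_norm"].iloc[1] == pytest.approx(1.3)  # cm, divisor 1

    def test_inverted_volumes_rejected(self):
        with pytest.raises(ValueError):
            motion.NormalizationContext(v_in=3.0, v_ex=4.0)


class TestAngles:
    @pytest.mark.parametrize("side", ["left", "right"])
    def test_cardinal_directions(self, side):
        medial_x = -1.0 if side == "left" else 1.0
        assert motion.displacement_angle(0.0, 1.0, side) == pytest.approx(0.0)       # dorsal
        assert motion.displacement_angle(0.0, -1.0, side) == pytest.approx(180.0)    # ventral
        assert motion.displacement_angle(medial_x, 0.0, side) == pytest.approx(90.0)   # medial
        assert motion.displacement_angle(-medial_x, 0.0, side) == pytest.approx(270.0)  # lateral

    def test_mirrored_vectors_give_equal_theta(self, rng):
        ux = rng.normal(size=50)
        uy = rng.normal(size=50)
        left = motion.displacement_angle(ux, uy, np.full(50, "left"))
        right = motion.displacement_angle(-ux, uy, np.full(50, "right"))
        np.testing.assert_allclose(left, right, atol=1e-12)

    def test_zero_xy_projection_is_nan(self):
        assert np.isnan(motion.displacement_angle(0.0, 0.0, "left"))


class TestQuadrants:
    def test_symmetric_points_cover_all_quadrants(self):
        pos = np.array(
            [[1.0, -1.0, 0], [-1.0, -1.0, 0], [-1.0, 1.0, 0], [1.0, 1.0, 0]]
        )
        q = motion.assign_quadrant(pos, "left", (0.0, 0.0))
        assert sorted(q.tolist()) == [1, 2, 3, 4]
        # left lung: +x lateral; anterior = smaller y
        assert q.tolist() == [1, 2, 3, 4]

    def test_center_point_ties_to_q3(self):
        q = motion.assign_quadrant(np.array([[0.0, 0.0, 0.0]]), "right", (0.0, 0.0))
        assert q[0] == 3

    def test_partition_property(self, rng):
        pos = rng.normal(0.0, 5.0, (300, 3))
        center = motion.lung_center(pos)
        q = motion.assign_quadrant(pos, "right", center)
        assert np.isin(q, [1, 2, 3, 4]).all()
        assert sum((q == k).sum() for k in (1, 2, 3, 4)) == 300

    def test_center_from_coordinate_ranges(self):
        pos = np.array([[0.0, 2.0, 0.0], [4.0, 10.0, 0.0], [1.0, 3.0, 0.0]])
        assert motion.lung_center(pos) == (2.0, 6.0)


class TestSummarize:
    def test_signed_cancellation_example(self):
        # u = (0, 1, -3) and (0, -1, -3) cm with divisor 1
        df = pd.DataFrame(
            {
                "ux": [0.0, 0.0], "uy": [10.0, -10.0], "uz": [-30.0, -30.0],
                "side": ["left", "left"], "quadrant": [1, 2],
            }
        )
        df["s3d_mm"] = np.linalg.norm(df[["ux", "uy", "uz"]].to_numpy(), axis=1)
        df["theta"] = motion.displacement_angle(df["ux"], df["uy"], df["side"])
        out = motion.summarize(motion.normalize(df, UNIT_CTX))
        whole = out.regions["whole"]
        assert whole.dorsoventral == pytest.approx(0.0, abs=1e-12)
        assert whole.apicobasal == pytest.approx(3.0, rel=1e-12)
        assert whole.mean_s3d == pytest.approx(np.sqrt(10.0), rel=1e-12)

    def test_constant_field_summary(self, small_pair, default_ctx):
        samples = motion.build_samples(
            TranslationField((0.0, 3.0, -8.0)), small_pair.expiration_seg, default_ctx
        )
        out = motion.summarize(samples)
        whole = out.regions["whole"]
        div = default_ctx.divisor
        assert whole.apicobasal == pytest.approx(0.8 / div, rel=1e-9)
        assert whole.dorsoventral == pytest.approx(0.3 / div, rel=1e-9)
        assert whole.angle_sd == pytest.approx(0.0, abs=1e-12)
        assert whole.angle_mean == pytest.approx(0.0, abs=1e-12)  # pure dorsal

    def test_norm_of_mean_le_mean_of_norm(self, rng):
        n = 200
        df = pd.DataFrame(
            {
                "ux": rng.normal(size=n), "uy": rng.normal(size=n),
                "uz": rng.normal(size=n),
                "side": np.where(rng.random(n) < 0.5, "left", "right"),
                "quadrant": rng.integers(1, 5, n),
            }
        )
        df["s3d_mm"] = np.linalg.norm(df[["ux", "uy", "uz"]].to_numpy(), axis=1)
        df["theta"] = motion.displacement_angle(df["ux"], df["uy"], df["side"])
        out = motion.summarize(motion.normalize(df, UNIT_CTX))
        for st in out.regions.values():
            rms = np.sqrt(st.transverse**2 + st.apicobasal**2 + st.dorsoventral**2)
            assert st.mean_s3d >= rms - 1e-12

    def test_quadrant_counts_sum_to_whole(self, small_pair, default_ctx):
        _, out = motion.analyze(small_pair.truth, small_pair.expiration_seg, default_ctx)
        total = sum(out.regions[f"Q{k}"].n for k in (1, 2, 3, 4))
        assert out.regions["whole"].n == total

    def test_angle_jitter_increases_angle_sd(self, small_pair, default_ctx):
        class Jittered(AnalyticDeformation):
            def __init__(self, level):
                self.level = level

            def displacement(self, pts):
                # ventral base direction: angles cluster near 180°, far from
                # the 0/360 wrap, matching the regime the arithmetic SD assumes
                rng_local = np.random.default_rng(99)
                base = np.broadcast_to([0.0, -3.0, -8.0], pts.shape).copy()
                base[..., :2] += self.level * rng_local.standard_normal(
                    pts[..., :2].shape
                )
                return base

        sds = []
        for level in (0.0, 0.5, 1.5):
            samples = motion.build_samples(
                Jittered(level), small_pair.expiration_seg, default_ctx
            )
            sds.append(motion.summarize(samples).regions["whole"].angle_sd)
        assert sds[0] < sds[1] < sds[2]


class TestInvariances:
    def _scaled_pair(self, k):
        from lungmotion.phantom import PhantomSpec, build_phantom

        spec = PhantomSpec(
            grid_shape=(40, 40, 40), spacing=(4.0 * k, 4.0 * k, 4.0 * k),
            motion_amplitudes=(0.5 * k, 2.0 * k, -10.0 * k),
            dome_height=20.0 * k, noise_sd=0.0,
        )
        return build_phantom(spec)

    def test_world_scale_invariance_of_normalized_metrics(self):
        outs = []
        for k in (1.0, 2.0):
            pair = self._scaled_pair(k)
            from lungmotion import densitometry as dens

            ctx = motion.NormalizationContext(
                v_in=dens.lung_volume(pair.inspiration_seg),
                v_ex=dens.lung_volume(pair.expiration_seg),
            )
            cfg = motion.BasalBandConfig(
                band_thickness=5.0 * k, sample_pitch=5.0 * k
            )
            _, summary = motion.analyze(pair.truth, pair.expiration_seg, ctx, cfg)
            outs.append(summary.regions["whole"])
        a, b = outs
        assert b.mean_s3d == pytest.approx(a.mean_s3d, rel=1e-6)
        assert b.apicobasal == pytest.approx(a.apicobasal, rel=1e-6)
        assert b.dorsoventral == pytest.approx(a.dorsoventral, rel=1e-6)

    def test_left_right_mirror_invariance(self, small_pair, default_ctx):
        seg = small_pair.expiration_seg
        field = small_pair.truth
        _, base = motion.analyze(field, seg, default_ctx)

        # reflect the subject about the midline: flip labels and swap sides
        flipped = seg.labels[::-1, :, :].copy()
        swap = {1: 3, 2: 5, 3: 1, 4: 1, 5: 2}  # LUL<->RUL, LLL<->RLL, RML->LUL band
        mirrored_labels = np.zeros_like(flipped)
        for old, new in swap.items():
            mirrored_labels[flipped == old] = new
        mseg = LungSegmentation(mirrored_labels, seg.spacing, seg.origin)

        x_max = (seg.shape[0] - 1) * seg.spacing[0]

        class Mirrored(AnalyticDeformation):
            def displacement(self, pts):
                q = np.asarray(pts, dtype=float).copy()
                q[..., 0] = x_max - q[..., 0]
                u = field.displacement(q)
                u = u.copy()
                u[..., 0] = -u[..., 0]
                return u

        _, mirr = motion.analyze(Mirrored(), mseg, default_ctx)
        a, b = base.regions["whole"], mirr.regions["whole"]
        assert b.mean_s3d == pytest.approx(a.mean_s3d, abs=1e-9)
        assert b.transverse == pytest.approx(a.transverse, abs=1e-9)
        assert b.apicobasal == pytest.approx(a.apicobasal, abs=1e-9)
        assert b.dorsoventral == pytest.approx(a.dorsoventral, abs=1e-9)
        assert b.angle_mean == pytest.approx(a.angle_mean, abs=1e-9)
        assert b.angle_sd == pytest.approx(a.angle_sd, abs=1e-9)
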