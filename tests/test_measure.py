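import json
import math

import numpy as np
import pytest

import bodymetry as bm
from bodymetry import measure as me
from bodymetry import phantom as ph
from bodymetry import silhouette as sil
from bodymetry.errors import StageError, ValidationError

ANGLES = [float(a) for a in range(0, 181, 30)]


class TestPxToCm:
    def test_proportionality(self):
        assert me.px_to_cm(15.0, 100, 300) == pytest.approx(5.0, rel=1e-12)

    @pytest.mark.parametrize("h", [1.0, 15.0, 180.0])
    def test_zero_pixels(self, h):
        assert me.px_to_cm(h, 0, 123) == 0.0

    def test_render_oracle(self):
        # 1.50 cm full width at 20 px/cm inside a 15 cm / 300 px stature
        assert me.px_to_cm(15.0, 30, 300) == pytest.approx(1.50)

    def test_errors(self):
        with pytest.raises(ValidationError):
            me.px_to_cm(15.0, 10, 0)
        with pytest.raises(ValidationError):
            me.px_to_cm(-1.0, 10, 100)
        with pytest.raises(ValidationError):
            me.px_to_cm(15.0, -5, 100)


class TestMeasureConfig:
    def test_identical_bands_rejected(self):
        with pytest.raises(ValidationError):
            me.MeasureConfig(waist_band=(0.5, 0.6), hip_band=(0.5, 0.6))

    def test_waist_must_sit_above_hip(self):
        with pytest.raises(ValidationError):
            me.MeasureConfig(waist_band=(0.40, 0.50), hip_band=(0.55, 0.70))

    def test_band_bounds(self):
        with pytest.raises(ValidationError):
            me.MeasureConfig(waist_band=(0.7, 0.6))
        with pytest.raises(ValidationError):
            me.MeasureConfig(hip_band=(-0.1, 0.5))


def _profile_from_mask(mask, angle):
    return (angle, sil.width_profile(mask, angle))


class TestAlignViews:
    def test_rectangle_gives_constant_column(self, rectangle_mask):
        vs = me.ViewSet(
            views=[_profile_from_mask(rectangle_mask, a) for a in ANGLES],
            stature_cm=15.0,
        )
        m = me.align_views(vs, n_rows=50)
        expected = 15.0 * 10 / 20 / 2.0  # half width in cm
        assert np.allclose(m.half_widths_cm, expected)

    def test_identical_views_identical_columns(self, hourglass_views):
        mask = hourglass_views[0.0]
        vs = me.ViewSet(
            views=[_profile_from_mask(mask, a) for a in ANGLES], stature_cm=15.0
        )
        m = me.align_views(vs, n_rows=100)
        for j in range(1, m.half_widths_cm.shape[1]):
            assert np.array_equal(m.half_widths_cm[:, 0], m.half_widths_cm[:, j])

    def test_elliptic_cylinder_recovers_support_widths(self):
        spec = ph.preset("elliptic")
        vs = me.ViewSet(
            views=[
                _profile_from_mask(ph.render_view(spec, a, 20.0), a) for a in ANGLES
            ],
            stature_cm=spec.stature_cm,
        )
        m = me.align_views(vs, n_rows=200)
        for j, ang in enumerate(ANGLES):
            expected = ph.support_half_width(spec, 0.5, ang)
            mid = m.half_widths_cm[80:120, j]
            assert np.all(np.abs(mid - expected) / expected < 0.03)

    def test_needs_three_views(self, rectangle_mask):
        with pytest.raises(ValidationError):
            me.ViewSet(
                views=[_profile_from_mask(rectangle_mask, a) for a in (0.0, 180.0)],
                stature_cm=15.0,
            )


class TestGirthProfile:
    def _constant_matrix(self, r, n_rows=10):
        return me.RadialMatrix(
            half_widths_cm=np.full((n_rows, 7), r),
            angles_deg=np.array(ANGLES),
            stature_cm=15.0,
            height_frac=np.linspace(0, 1, n_rows),
        )

    def test_constant_radii(self):
        prof = me.girth_profile(self._constant_matrix(2.0))
        expected_cos = 12 * 2.0 * math.sqrt(2 - 2 * math.cos(math.radians(30)))
        assert np.allclose(prof.cosine_cm, expected_cos)
        assert np.allclose(prof.ellipse_cm, 2 * math.pi * 2.0)

    def test_zero_row(self):
        m = self._constant_matrix(1.0)
        m.half_widths_cm[3, :] = 0.0
        prof = me.girth_profile(m)
        assert prof.cosine_cm[3] == 0.0 and prof.ellipse_cm[3] == 0.0

    def test_reference_row_ellipse_value(self):
        # half-widths 0.75 at 0 deg and 0.56 at 90 deg -> 4.159
        m = self._constant_matrix(0.6, n_rows=1)
        m.half_widths_cm[0, 0] = 0.75
        m.half_widths_cm[0, 3] = 0.56
        prof = me.girth_profile(m)
        assert prof.ellipse_cm[0] == pytest.approx(4.159, abs=5e-4)

    def test_missing_90_degree_column(self):
        m = me.RadialMatrix(
            half_widths_cm=np.ones((5, 4)),
            angles_deg=np.array([0.0, 60.0, 120.0, 180.0]),
            stature_cm=15.0,
            height_frac=np.linspace(0, 1, 5),
        )
        with pytest.raises(ValidationError, match="90"):
            me.girth_profile(m)


class TestFindLandmarks:
    def test_tie_break_returns_band_centers(self, cylinder_views):
        res = me.measure_subject(cylinder_views, 15.0)
        cfg = me.MeasureConfig()
        assert res.waist_row_frac == pytest.approx(sum(cfg.waist_band) / 2, abs=0.005)
        assert res.hip_row_frac == pytest.approx(sum(cfg.hip_band) / 2, abs=0.005)

    def test_hourglass_designed_landmarks(self, hourglass_measured):
        assert hourglass_measured.waist_row_frac == pytest.approx(0.60, abs=0.02)
        assert hourglass_measured.hip_row_frac == pytest.approx(0.50, abs=0.02)

    def test_empty_band_rejected(self):
        prof = me.GirthProfiles(
            height_frac=np.linspace(0, 0.3, 10),
            cosine_cm=np.ones(10),
            ellipse_cm=np.ones(10),
        )
        with pytest.raises(ValidationError):
            me.find_landmarks(prof, me.MeasureConfig())


class TestMeasureSubject:
    def test_cylinder_recovery(self, cylinder_views):
        res = me.measure_subject(cylinder_views, 15.0)
        for landmark in (res.waist_cm, res.hip_cm):
            assert abs(landmark["cosine"] - 2 * math.pi) / (2 * math.pi) < 0.02

    def test_determinism(self, hourglass_views):
        r1 = me.measure_subject(hourglass_views, 15.0)
        r2 = me.measure_subject(hourglass_views, 15.0)
        assert r1.waist_cm == r2.waist_cm and r1.hip_cm == r2.hip_cm
        assert np.array_equal(r1.girth_cosine_cm, r2.girth_cosine_cm)

    def test_stature_homogeneity(self, hourglass_views):
        r1 = me.measure_subject(hourglass_views, 15.0)
        r2 = me.measure_subject(hourglass_views, 30.0)
        assert np.allclose(r2.girth_cosine_cm, 2 * r1.girth_cosine_cm, rtol=1e-12)
        assert r2.waist_cm["cosine"] == pytest.approx(2 * r1.waist_cm["cosine"])

    def test_thin_vs_overweight_delta(self):
        thin, over = ph.preset("thin"), ph.preset("overweight")
        rt = me.measure_subject(
            {a: ph.render_view(thin, a, 20.0) for a in ANGLES}, thin.stature_cm
        )
        ro = me.measure_subject(
            {a: ph.render_view(over, a, 20.0) for a in ANGLES}, over.stature_cm
        )
        designed = ph.true_girth(over, 0.60) - ph.true_girth(thin, 0.60)
        measured = ro.waist_cm["cosine"] - rt.waist_cm["cosine"]
        assert measured == pytest.approx(designed, rel=0.15)

    def test_resolution_stability(self, hourglass_spec):
        girths = {}
        for ppc in (10.0, 40.0):
            res = me.measure_subject(
                {a: ph.render_view(hourglass_spec, a, ppc) for a in ANGLES}, 15.0
            )
            girths[ppc] = res.waist_cm["cosine"]
        assert abs(girths[10.0] - girths[40.0]) / girths[40.0] < 0.02

    def test_accepts_photos(self, hourglass_spec, hourglass_measured):
        photos = {a: ph.render_photo(hourglass_spec, a, 20.0) for a in ANGLES}
        res = me.measure_subject(photos, hourglass_spec.stature_cm)
        assert res.waist_cm["cosine"] == pytest.approx(
            hourglass_measured.waist_cm["cosine"]
        )

    def test_stage_error_names_angle(self, cylinder_views):
        bad = dict(cylinder_views)
        bad[90.0] = np.zeros((10, 10), dtype=bool)
        with pytest.raises(StageError, match="90"):
            me.measure_subject(bad, 15.0)

    def test_angular_refinement_monotone_exact(self):
        # finer angular steps never shrink the estimate on a convex section
        spec = ph.preset("elliptic")
        values = []
        for step in (10, 15, 20, 30, 45, 60):
            angles = np.arange(0.0, 180.0 + step, step)
            radii = [ph.support_half_width(spec, 0.5, a) for a in angles]
            values.append(
                bm.cosine_perimeter(bm.RadialFan(angles, radii)).value
            )
        assert all(x >= y - 1e-12 for x, y in zip(values, values[1:]))

    def test_circle_refinement_approaches_oracle(self):
        spec = ph.preset("cylinder")
        oracle = ph.true_girth(spec, 0.5)
        errs = []
        for step in (10, 30):
            angles = np.arange(0.0, 180.0 + step, step)
            radii = [ph.support_half_width(spec, 0.5, a) for a in angles]
            errs.append(abs(bm.cosine_perimeter(bm.RadialFan(angles, radii)).value - oracle))
        assert errs[0] < errs[1]


class TestSerialization:
    def test_measurements_json(self, tmp_path, hourglass_measured):
        path = tmp_path / "m.json"
        hourglass_measured.to_json(path)
        data = json.loads(path.read_text())
        assert set(data["waist_cm"]) == {"cosine", "ellipse"}
        assert data["stature_cm"] == 15.0
        # reported values are rounded to 2 decimals
        assert data["waist_cm"]["cosine"] == round(data["waist_cm"]["cosine"], 2)

    def test_profile_csv(self, tmp_path, hourglass_measured):
        path = tmp_path / "profile.csv"
        hourglass_measured.profiles.to_csv(path)
        header = path.read_text().splitlines()[0]
        assert header == "height_frac,girth_cosine_cm,girth_ellipse_cm"

    def test_load_view_directory_manifest(self, tmp_path, hourglass_spec):
        ph.make_fixture_set(hourglass_spec, ANGLES, 20.0, tmp_path / "fx")
        views, stature = me.load_view_directory(tmp_path / "fx")
        assert stature == 15.0
        assert sorted(views) == ANGLES

    def test_load_view_directory_plain_files(self, tmp_path, rectangle_mask):
        for a in (0, 90, 180):
            sil.write_mask(tmp_path / f"view_{a}.png", rectangle_mask)
        views, stature = me.load_view_directory(tmp_path)
        assert stature is None
        assert sorted(views) == [0.0, 90.0, 180.0]
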