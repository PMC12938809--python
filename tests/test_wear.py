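import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hipwear.geometry import Circle
from hipwear.wear import (
    TimepointGeometry,
    center_distance,
    compute_wear_report,
    read_wear_report,
    superior_gap,
    wear_from_measurements,
    write_wear_report,
)

# worked-example measurement inputs and their expected derived values
CASE_1 = dict(
    r_fem_pre=126.310866, r_fem_post=123.661418,
    d_pre=4.976189, d_post=10.775240,
    g_pre=73.828397, g_post=73.340661,
)
CASE_1_EXPECTED = dict(sf=1.021425, delta_d=6.029910, delta_g=1.083589,
                       delta_total=6.126498)
CASE_2 = dict(
    r_fem_pre=74.425153, r_fem_post=70.160508,
    d_pre=6.184893, d_post=11.878518,
    g_pre=43.897086, g_post=44.981593,
)
CASE_2_EXPECTED = dict(sf=1.060784, delta_d=6.415648, delta_g=3.818667,
                       delta_total=7.466107)


def geometry_from_scalars(r_fem, d, g, label):
    """Circle pair realizing given femoral radius, center distance and
    superior gap: cup concentric in y (so the gap equals the radius excess)
    and offset in x by the center distance."""
    fem = Circle(100.0, 200.0, r_fem)
    cup = Circle(100.0 + d, 200.0, r_fem + g)
    return TimepointGeometry(fem, cup, label)


class TestPrimitives:
    @pytest.mark.parametrize(
        "fem_c, cup_c, expected",
        [((0, 0), (3, 4), 5.0), ((5, 5), (5, 5), 0.0), ((1, 2), (4, 6), 5.0)],
    )
    def test_center_distance(self, fem_c, cup_c, expected):
        t = TimepointGeometry(
            Circle(fem_c[0], fem_c[1], 10), Circle(cup_c[0], cup_c[1], 30)
        )
        assert center_distance(t) == pytest.approx(expected)

    def test_superior_gap_concentric(self):
        t = TimepointGeometry(Circle(0, 100, 50), Circle(0, 100, 70))
        assert superior_gap(t) == pytest.approx(20.0)

    def test_superior_gap_offset(self):
        t = TimepointGeometry(Circle(0, 100, 50), Circle(0, 105, 70))
        # y_top,fem = 50, y_top,cup = 35
        assert superior_gap(t) == pytest.approx(15.0)

    def test_superior_gap_translation_invariant(self):
        t1 = TimepointGeometry(Circle(0, 100, 50), Circle(3, 104, 70))
        t2 = TimepointGeometry(Circle(0, 130, 50), Circle(3, 134, 70))
        assert superior_gap(t1) == pytest.approx(superior_gap(t2))

    def test_cup_must_enclose(self):
        with pytest.raises(ValueError):
            TimepointGeometry(Circle(0, 0, 50), Circle(0, 0, 40))


class TestWearReport:
    @pytest.mark.parametrize(
        "case, expected", [(CASE_1, CASE_1_EXPECTED), (CASE_2, CASE_2_EXPECTED)]
    )
    def test_worked_examples_to_six_decimals(self, case, expected):
        """Reproduce the two worked wear examples at the printed precision.

        The inputs are themselves 6-decimal roundings; the scale-factor
        rounding multiplies measurements of magnitude ~45-75 px, which
        propagates up to ~7e-6 into the derived values.  1e-5 is the
        tightest bound the printed inputs support.
        """
        rep = wear_from_measurements(**case)
        assert rep.sf == pytest.approx(expected["sf"], abs=1e-6)
        assert rep.delta_d == pytest.approx(expected["delta_d"], abs=1e-5)
        assert rep.delta_g == pytest.approx(expected["delta_g"], abs=1e-5)
        assert rep.delta_total == pytest.approx(expected["delta_total"], abs=1e-5)

    def test_identity_pair_zero_wear(self):
        g = geometry_from_scalars(50.0, 5.0, 20.0, "PRE")
        rep = compute_wear_report(g, geometry_from_scalars(50.0, 5.0, 20.0, "POST"))
        assert rep.sf == 1.0
        assert rep.delta_d == rep.delta_g == rep.delta_total == 0.0

    def test_geometry_route_matches_scalar_route(self):
        pre = geometry_from_scalars(CASE_1["r_fem_pre"], CASE_1["d_pre"],
                                    CASE_1["g_pre"], "PRE")
        post = geometry_from_scalars(CASE_1["r_fem_post"], CASE_1["d_post"],
                                     CASE_1["g_post"], "POST")
        rep = compute_wear_report(pre, post)
        assert rep.delta_total == pytest.approx(CASE_1_EXPECTED["delta_total"], abs=1e-5)

    def test_resultant_is_euclidean_norm(self):
        rep = wear_from_measurements(50, 48, 4, 9, 20, 22)
        assert rep.delta_total**2 == pytest.approx(
            rep.delta_d**2 + rep.delta_g**2, rel=1e-12
        )

    def test_magnification_converts_to_mm(self):
        rep = wear_from_measurements(**CASE_1, magnification=10.0)
        assert rep.wear_mm == pytest.approx(rep.delta_total / 10.0)

    def test_bad_radius_rejected(self):
        with pytest.raises(ValueError):
            wear_from_measurements(50, 0, 1, 1, 1, 1)

    @settings(max_examples=100, deadline=None)
    @given(
        k=st.floats(min_value=0.05, max_value=20.0),
        d=st.floats(0, 30), g=st.floats(0, 60),
        d2=st.floats(0, 30), g2=st.floats(0, 60),
    )
    def test_post_scale_invariance(self, k, d, g, d2, g2):
        """Multiplying every POST measurement by k leaves the wear components
        unchanged — the femoral-radius scale factor cancels magnification."""
        base = wear_from_measurements(60.0, 58.0, d, d2, g, g2)
        scaled = wear_from_measurements(60.0, 58.0 * k, d, d2 * k, g, g2 * k)
        assert scaled.delta_d == pytest.approx(base.delta_d, abs=1e-8)
        assert scaled.delta_g == pytest.approx(base.delta_g, abs=1e-8)
        assert scaled.delta_total == pytest.approx(base.delta_total, abs=1e-8)

    def test_translation_invariance(self):
        pre1 = TimepointGeometry(Circle(10, 20, 50), Circle(14, 18, 70), "PRE")
        pre2 = TimepointGeometry(Circle(110, 70, 50), Circle(114, 68, 70), "PRE")
        post = TimepointGeometry(Circle(0, 0, 49), Circle(5, -2, 69), "POST")
        r1 = compute_wear_report(pre1, post)
        r2 = compute_wear_report(pre2, post)
        assert r1.delta_total == pytest.approx(r2.delta_total, abs=1e-9)


class TestReportFile:
    def test_roundtrip(self, tmp_path):
        rep = wear_from_measurements(**CASE_1, magnification=12.5)
        path = tmp_path / "report.txt"
        write_wear_report(rep, path)
        back = read_wear_report(path)
        path2 = tmp_path / "report2.txt"
        write_wear_report(back, path2)
        assert path.read_text() == path2.read_text()

    def test_contains_all_printed_quantities(self, tmp_path):
        rep = wear_from_measurements(**CASE_1)
        path = tmp_path / "report.txt"
        write_wear_report(rep, path)
        text = path.read_text()
        for key in ("sf", "d_pre", "d_post", "g_pre", "g_post",
                    "delta_d", "delta_g", "delta_total"):
            assert f"{key} " in text
        assert "1.021425" in text  # sf at 6-decimal fixed point

    def test_no_magnification_omits_mm_line(self, tmp_path):
        rep = wear_from_measurements(**CASE_1)
        path = tmp_path / "report.txt"
        write_wear_report(rep, path)
        assert "wear_mm" not in path.read_text()
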