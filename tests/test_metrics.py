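"""Reporting: PV metrics, loop area, strain sampling, stress averaging and
the comparison-table arithmetic, checked against hand-computed values."""

import numpy as np
import pytest

from cardioloop.kinematics import GeneralizedCoords
from cardioloop.metrics import (MetricsBundle, PVLoopMetrics, StrainReport,
                                StressReport, comparison_table, loop_area,
                                myofiber_stress_report, percent_change,
                                pv_metrics, strain_report)


class FakeTrace:
    def __init__(self, v, p, p_art=None):
        self.v_lv = np.asarray(v, dtype=float)
        self.p_lv = np.asarray(p, dtype=float)
        self.p_art = np.asarray(p_art if p_art is not None else p, dtype=float)


def rectangle_trace(v_lo=60.0, v_hi=100.0, p_lo=10.0, p_hi=90.0, n=40):
    """Counterclockwise rectangular loop in (V, P)."""
    v = np.concatenate([np.full(n, v_hi), np.linspace(v_hi, v_lo, n),
                        np.full(n, v_lo), np.linspace(v_lo, v_hi, n)])
    p = np.concatenate([np.linspace(p_lo, p_hi, n), np.full(n, p_hi),
                        np.linspace(p_hi, p_lo, n), np.full(n, p_lo)])
    return FakeTrace(v, p)


class TestPVMetrics:
    @pytest.mark.parametrize("edv, esv, expected_sv", [
        (158.30, 66.10, 92.20),
        (159.60, 77.40, 82.20),
    ])
    def test_stroke_volume_rule(self, edv, esv, expected_sv):
        m = PVLoopMetrics.from_values(edp=12.0, edv=edv, esp=110.0, esv=esv,
                                      map=95.0)
        assert m.sv == pytest.approx(expected_sv, abs=1e-12)

    def test_stroke_work_is_sv_times_map(self):
        m = PVLoopMetrics.from_values(edp=11.85, edv=158.30, esp=117.10,
                                      esv=66.10, sw=8747.50)
        assert m.sw == pytest.approx(8747.50, abs=1e-9)
        assert m.map == pytest.approx(8747.50 / 92.20)

    def test_constant_volume_trace_has_zero_stroke(self):
        tr = FakeTrace(np.full(50, 120.0), np.linspace(5, 50, 50))
        m = pv_metrics(tr)
        assert m.sv == 0.0
        assert m.sw == 0.0

    def test_non_finite_trace_refused(self):
        tr = FakeTrace([100, np.nan, 90], [10, 20, 30])
        with pytest.raises(ValueError):
            pv_metrics(tr)


class TestLoopArea:
    def test_rectangle(self):
        tr = rectangle_trace()
        assert loop_area(tr) == pytest.approx(40.0 * 80.0, rel=1e-12)

    def test_reversed_traversal_flips_sign(self):
        tr = rectangle_trace()
        rev = FakeTrace(tr.v_lv[::-1], tr.p_lv[::-1])
        assert loop_area(rev) == pytest.approx(-loop_area(tr), rel=1e-12)


class TestLoopAreaConsistency:
    def test_converged_loop_area_agrees_with_sv_times_map(self, baseline_bundle):
        """On a converged working loop the shoelace area and SV*MAP are two
        estimates of the same work; they agree to within 10%."""
        pv = baseline_bundle.pv
        assert pv.loop_area == pytest.approx(pv.sw, rel=0.10)


class TestStrainReport:
    def test_identical_states_give_zero_strain(self, mesh):
        q = GeneralizedCoords.identity()
        rep = strain_report(q, q, mesh)
        for fam in ("radial", "circumferential", "longitudinal"):
            assert getattr(rep, fam)[0] == pytest.approx(0.0, abs=1e-14)

    def test_forced_uniform_longitudinal_stretch_recovered_exactly(self, mesh):
        """An imposed uniform 0.84 longitudinal stretch appears as -0.16
        longitudinal strain at every site with zero spread."""
        q_es = GeneralizedCoords(lambda_long=np.full(4, 0.84))
        rep = strain_report(GeneralizedCoords.identity(), q_es, mesh)
        assert rep.longitudinal[0] == pytest.approx(-0.16, abs=1e-12)
        assert rep.longitudinal[1] == pytest.approx(0.0, abs=1e-12)
        for v in rep.regional_longitudinal.values():
            assert v == pytest.approx(-0.16, abs=1e-12)

    def test_regional_mean_equals_family_mean(self, mesh, rng):
        q_es = GeneralizedCoords(lambda_long=1 - 0.1 * rng.uniform(0.5, 1, 4),
                                 radial_scale=np.full(3, 0.9))
        rep = strain_report(GeneralizedCoords.identity(), q_es, mesh)
        assert rep.longitudinal[0] == pytest.approx(
            np.mean(list(rep.regional_longitudinal.values())), abs=1e-12)

    def test_strain_sign_conventions(self, mesh):
        """Contraction: thickening positive, circumferential and
        longitudinal shortening negative."""
        q_es = GeneralizedCoords(lambda_long=np.full(4, 0.9),
                                 radial_scale=np.full(3, 0.85))
        rep = strain_report(GeneralizedCoords.identity(), q_es, mesh)
        assert rep.radial[0] > 0
        assert rep.circumferential[0] < 0
        assert rep.longitudinal[0] < 0


class TestStressReport:
    def test_uniform_field(self, mesh):
        es = {"fiber_stress": np.full(mesh.n_points, 0.05)}
        rep = myofiber_stress_report(es, mesh)
        assert rep.mean_myofiber_stress == pytest.approx(0.05, rel=1e-12)
        assert rep.sd == pytest.approx(0.0, abs=1e-12)

    def test_volume_weighted_mean_of_two_halves(self, mesh):
        sig = np.where(np.arange(mesh.n_points) % 2 == 0, 0.04, 0.08)
        es = {"fiber_stress": sig}
        rep = myofiber_stress_report(es, mesh)
        w = mesh.quad_volume / mesh.quad_volume.sum()
        assert rep.mean_myofiber_stress == pytest.approx(float(w @ sig),
                                                         rel=1e-12)

    def test_uniform_weight_rescaling_leaves_mean_unchanged(self, mesh):
        sig = np.linspace(0.02, 0.1, mesh.n_points)
        rep1 = myofiber_stress_report({"fiber_stress": sig}, mesh)
        mesh2_quad = mesh.quad_volume.copy()
        try:
            mesh.quad_volume = 2.0 * mesh.quad_volume
            rep2 = myofiber_stress_report({"fiber_stress": sig}, mesh)
        finally:
            mesh.quad_volume = mesh2_quad
        assert rep2.mean_myofiber_stress == pytest.approx(
            rep1.mean_myofiber_stress, rel=1e-12)


class TestPercentChange:
    @pytest.mark.parametrize("ref, cmp, expected", [
        (92.20, 82.20, -10.85),
        (-0.17, -0.01, -94.12),
        (3.7, 3.7, 0.0),
    ])
    def test_values(self, ref, cmp, expected):
        assert percent_change(ref, cmp) == pytest.approx(expected, abs=5e-3)

    def test_zero_reference_undefined(self):
        assert np.isnan(percent_change(0.0, 1.0))


def table2_bundles():
    """The two absolute PV rows of the published comparison."""
    base = PVLoopMetrics.from_values(edp=11.85, edv=158.30, esp=117.10,
                                     esv=66.10, sw=8747.50)
    stiff = PVLoopMetrics.from_values(edp=12.86, edv=159.60, esp=106.40,
                                      esv=77.40, sw=7084.50)
    strain_b = StrainReport(radial=(0.63, 0.11), circumferential=(-0.20, 0.05),
                            longitudinal=(-0.16, 0.01),
                            regional_longitudinal={"septal": -0.17,
                                                   "anterior": -0.17,
                                                   "lateral": -0.15,
                                                   "posterior": -0.15})
    strain_s = StrainReport(radial=(0.50, 0.11), circumferential=(-0.18, 0.03),
                            longitudinal=(-0.08, 0.05),
                            regional_longitudinal={"septal": -0.01,
                                                   "anterior": -0.10,
                                                   "lateral": -0.13,
                                                   "posterior": -0.09})
    stress_b = StressReport(mean_myofiber_stress=0.056, sd=0.036)
    stress_s = StressReport(mean_myofiber_stress=0.076, sd=0.042)
    return (MetricsBundle(pv=base, strain=strain_b, stress=stress_b),
            MetricsBundle(pv=stiff, strain=strain_s, stress=stress_s))


class TestComparisonTable:
    def test_pv_percent_row_reproduces_published_arithmetic(self):
        ref, cmp = table2_bundles()
        table = comparison_table(ref, cmp)
        pct = table.pv.loc["percent_change"]
        assert pct["EDP"] == pytest.approx(8.52, abs=5e-3)
        assert pct["EDV"] == pytest.approx(0.82, abs=5e-3)
        assert pct["ESP"] == pytest.approx(-9.14, abs=5e-3)
        assert pct["ESV"] == pytest.approx(17.10, abs=5e-3)
        assert pct["SV"] == pytest.approx(-10.85, abs=5e-3)
        assert pct["SW"] == pytest.approx(-19.01, abs=5e-3)

    def test_regional_percent_row_reproduces_published_arithmetic(self):
        ref, cmp = table2_bundles()
        table = comparison_table(ref, cmp)
        pct = table.regional.loc["percent_change"]
        assert pct["septal"] == pytest.approx(-94.12, abs=5e-3)
        assert pct["anterior"] == pytest.approx(-41.18, abs=5e-3)
        assert pct["lateral"] == pytest.approx(-13.33, abs=5e-3)
        assert pct["posterior"] == pytest.approx(-40.00, abs=5e-3)

    def test_identical_bundles_give_all_zero_differences(self):
        ref, _ = table2_bundles()
        table = comparison_table(ref, ref)
        assert np.allclose(table.pv.loc["difference"].to_numpy(dtype=float), 0)
        assert np.allclose(table.regional.loc["difference"].to_numpy(dtype=float), 0)

    def test_incomplete_bundle_rejected(self):
        ref, cmp = table2_bundles()
        with pytest.raises(ValueError):
            comparison_table(MetricsBundle(pv=ref.pv), cmp)
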