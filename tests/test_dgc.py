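"""DGI arithmetic, analytic oracles, and curve construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dosegradient as dg
from dosegradient import datasets
from dosegradient.dgc import DGCTable, round_half_up


def _sphere_vs(r):
    return 4 / 3 * np.pi * r**3, 4 * np.pi * r**2


def _cube_vs(a):
    return a**3, 6 * a**2


class TestDGI:
    @pytest.mark.parametrize(
        "vl, sl, vh, sh, expected",
        [
            (5778.131, 1802.676, 4099.663, 1477.332, 1.023454),
            (10106.71, 2522.306, 4099.663, 1477.332, 3.003796),
            (7781.413, 2154.435, 4099.663, 1477.332, 2.027526),
        ],
    )
    def test_benchmark_layer_pairs(self, vl, sl, vh, sh, expected):
        # the benchmark's inputs are printed to 1e-3; rounding of inputs and
        # of the published quotients moves the 6th decimal by a few units
        assert dg.dgi(vl, sl, vh, sh) == pytest.approx(expected, abs=3e-6)

    def test_nesting_violation(self):
        with pytest.raises(dg.NestingError):
            dg.dgi(1.0, 10.0, 2.0, 10.0)

    def test_bad_areas(self):
        with pytest.raises(ValueError):
            dg.dgi(2.0, 0.0, 1.0, 10.0)

    def test_vanishing_gap_limit(self):
        assert dg.dgi(1000.0 + 1e-9, 500.0, 1000.0, 500.0) < 1e-11

    @given(
        r=st.floats(1.0, 50.0),
        d=st.floats(0.05, 5.0),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_exact_sphere_identity(self, r, d):
        """dgi() on exact concentric-sphere V, S equals the closed form."""
        vh, sh = _sphere_vs(r)
        vl, sl = _sphere_vs(r + d)
        got = dg.dgi(vl, sl, vh, sh)
        want = dg.dgi_sphere_analytic(dg.AnalyticShapeSpec("sphere", r, d))
        assert got == pytest.approx(want, rel=1e-12)

    @given(a=st.floats(1.0, 50.0), d=st.floats(0.05, 5.0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_exact_cube_identity(self, a, d):
        vh, sh = _cube_vs(a)
        vl, sl = _cube_vs(a + 2 * d)
        got = dg.dgi(vl, sl, vh, sh)
        want = dg.dgi_cube_analytic(dg.AnalyticShapeSpec("cube", a, d))
        assert got == pytest.approx(want, rel=1e-12)


class TestAnalytic:
    def test_sphere_value(self):
        got = dg.dgi_sphere_analytic(dg.AnalyticShapeSpec("sphere", 5.0, 1.0))
        assert got == pytest.approx((6 + 1 / 15) / (6 + 1 / 10), rel=1e-14)
        assert got == pytest.approx(0.994536, abs=5e-7)

    @pytest.mark.parametrize("d, expected", [(1.0, 0.0055), (0.3, 0.0006)])
    def test_relative_error_printed_values(self, d, expected):
        e = dg.dgi_relative_error(dg.AnalyticShapeSpec("sphere", 5.0, d))
        assert round_half_up(e, 4) == expected

    def test_sphere_cube_errors_coincide_at_matched_size(self):
        # with a = 2r the cube ratio's numerator and denominator are each
        # exactly twice the sphere's, so the errors are identical
        for d in (0.3, 1.0, 2.0):
            es = dg.dgi_relative_error(dg.AnalyticShapeSpec("sphere", 5.0, d))
            ec = dg.dgi_relative_error(dg.AnalyticShapeSpec("cube", 10.0, d))
            assert es == pytest.approx(ec, rel=1e-14)

    def test_estimator_exact_in_small_gap_limit(self):
        for shape, size in (("sphere", 7.0), ("cube", 9.0)):
            spec = dg.AnalyticShapeSpec(shape, size, 1e-6)
            fn = dg.dgi_sphere_analytic if shape == "sphere" else dg.dgi_cube_analytic
            assert fn(spec) / 1e-6 == pytest.approx(1.0, abs=1e-7)
            assert dg.dgi_relative_error(spec) == pytest.approx(0.0, abs=1e-7)


def _records(df):
    return datasets.srs_records(df)


class TestDifferential:
    @pytest.mark.parametrize("pct, expected", [(24, 0.99), (100, 0.13), (120, 2.29)])
    def test_printed_rows(self, srs_table, pct, expected):
        rows = srs_table[srs_table.dose_pct.isin([pct, pct + 1])]
        cfg = dg.DGCConfig(step=1.0, reference_dose=15.0)
        table = dg.differential_dgc(_records(rows), cfg)
        assert round_half_up(table.ddgi_at(pct), 2) == expected

    def test_all_contiguous_printed_rows(self, srs_table):
        """Every printed consecutive pair reproduces the printed dDGI."""
        cfg = dg.DGCConfig(step=1.0, reference_dose=15.0)
        for block in (srs_table[srs_table.dose_pct <= 30], srs_table[srs_table.dose_pct >= 90]):
            table = dg.differential_dgc(_records(block), cfg)
            got = round_half_up(table.frame["ddgi_mm"].to_numpy()[:-1], 2)
            want = block["ddgi_mm"].to_numpy()[:-1]
            np.testing.assert_allclose(got, want, atol=1e-12)

    def test_nonuniform_spacing_rejected(self, srs_table):
        rows = srs_table[srs_table.dose_pct.isin([90, 92, 93])]
        with pytest.raises(ValueError, match="uniformly spaced"):
            dg.differential_dgc(_records(rows), dg.DGCConfig(step=1.0, reference_dose=15.0))

    def test_flat_region_warns_and_reports_zero(self):
        recs = [
            dg.IsodoseLevelRecord(99.0, 14.85, 100.0, 500.0),
            dg.IsodoseLevelRecord(100.0, 15.0, 100.0, 500.0),
        ]
        cfg = dg.DGCConfig(step=1.0, reference_dose=15.0)
        with pytest.warns(UserWarning, match="flat dose region"):
            table = dg.differential_dgc(recs, cfg)
        assert table.ddgi_at(99.0) == 0.0


class TestCumulative:
    def _printed_block(self, srs_table):
        return srs_table[(srs_table.dose_pct >= 90) & (srs_table.dose_pct <= 100)]

    def test_accumulates_printed_ddgi(self, srs_table):
        """Summing the printed dDGI series reproduces the printed cDGI."""
        block = self._printed_block(srs_table).reset_index(drop=True)
        cfg = dg.DGCConfig(step=1.0, reference_dose=15.0)
        frame = block.rename(
            columns={"surface_area_mm2": "surface_area_mm2", "volume_mm3": "volume_mm3"}
        )[["dose_pct", "dose_gy", "surface_area_mm2", "volume_mm3", "ddgi_mm"]]
        table = dg.cumulative_dgc(DGCTable(frame, cfg))
        for pct, want in ((90, 1.13), (95, 0.60), (98, 0.28), (100, 0.0)):
            assert round_half_up(table.cdgi_at(pct), 2) == want

    def test_reference_anchor_is_exactly_zero(self, srs_table):
        block = self._printed_block(srs_table)
        cfg = dg.DGCConfig(step=1.0, reference_dose=15.0)
        table = dg.cumulative_dgc(
            DGCTable(block[["dose_pct", "dose_gy", "surface_area_mm2", "volume_mm3",
                            "ddgi_mm"]], cfg)
        )
        assert table.cdgi_at(100.0) == 0.0

    def test_above_reference_rejected(self, srs_table):
        cfg = dg.DGCConfig(step=1.0, reference_dose=15.0)
        table = dg.cumulative_dgc(
            DGCTable(self._printed_block(srs_table)[
                ["dose_pct", "dose_gy", "surface_area_mm2", "volume_mm3", "ddgi_mm"]
            ], cfg)
        )
        with pytest.raises(ValueError, match="undefined above"):
            table.cdgi_at(101.0)

    def test_monotone_increase_below_reference(self, srs_table):
        block = self._printed_block(srs_table)
        cfg = dg.DGCConfig(step=1.0, reference_dose=15.0)
        table = dg.cumulative_dgc(
            DGCTable(block[["dose_pct", "dose_gy", "surface_area_mm2", "volume_mm3",
                            "ddgi_mm"]], cfg)
        )
        c = table.frame["cdgi_mm"].to_numpy()
        assert np.all(np.diff(c) < 0)  # decreasing toward the reference


class TestNormalize:
    def test_unit_step_identity(self, srs_table):
        cfg = dg.DGCConfig(step=1.0, reference_dose=15.0)
        block = srs_table[srs_table.dose_pct >= 90]
        table = dg.normalize_ddgc(dg.differential_dgc(_records(block), cfg))
        np.testing.assert_array_equal(
            table.frame["ddgi_mm"].to_numpy(), table.frame["ddgi_norm_mm"].to_numpy()
        )

    def test_doubling_step_doubles_raw_ddgi_on_linear_falloff(self):
        # concentric spheres with radius falling 0.1 mm per percent
        def recs(step):
            out = []
            for pct in np.arange(90.0, 100.1, step):
                r = 20.0 + 0.1 * (100.0 - pct)
                out.append(
                    dg.IsodoseLevelRecord(pct, 0.15 * pct, 4 * np.pi * r**2,
                                          4 / 3 * np.pi * r**3)
                )
            return out

        t1 = dg.differential_dgc(recs(1.0), dg.DGCConfig(step=1.0, reference_dose=15.0))
        t2 = dg.differential_dgc(recs(2.0), dg.DGCConfig(step=2.0, reference_dose=15.0))
        assert t2.ddgi_at(90.0) == pytest.approx(2 * t1.ddgi_at(90.0), rel=2e-4)
        n1 = dg.normalize_ddgc(t1)
        n2 = dg.normalize_ddgc(t2)
        assert n2.frame["ddgi_norm_mm"].iloc[0] == pytest.approx(
            n1.frame["ddgi_norm_mm"].iloc[0], rel=2e-4
        )


class TestLevelTable:
    def test_radial_volumes_match_closed_form(self, radial_small):
        spec, dose, body, _ = radial_small
        domain = dg.crop_body(body, 3.0)
        cfg = dg.DGCConfig(step=5.0, reference_dose=spec.reference_dose)
        levels = dg.build_level_table(dose, domain, cfg, dose_range=(50.0, 121.0))
        assert len(levels) >= 14
        vols = np.array([r.volume for r in levels])
        assert np.all(np.diff(vols) < 0)  # strictly decreasing with dose
        for rec in levels:
            r_true = spec.isodose_radius(rec.dose_pct / 100.0)
            assert rec.volume == pytest.approx(4 / 3 * np.pi * r_true**3, rel=0.02)

    def test_truncation_at_cropped_body(self, radial_small):
        spec, dose, body, _ = radial_small
        domain = dg.crop_body(body, 3.0)
        cfg = dg.DGCConfig(step=1.0, reference_dose=spec.reference_dose)
        levels = dg.build_level_table(dose, domain, cfg)
        lowest = levels[0].dose_pct
        # cropped body radius 27 mm -> isodose (15/27)^2 ~ 30.9% is the limit
        assert 30.0 < lowest <= 34.0
        assert not any(r.dose_pct < lowest for r in levels)
        with pytest.raises(dg.OpenSurfaceError):
            dg.extract_isosurface(dose, (lowest - 2.0) / 100.0 * 15.0, domain)

    def test_csv_roundtrip_exact(self, srs_table, tmp_path):
        cfg = dg.DGCConfig(step=1.0, reference_dose=15.0)
        block = srs_table[srs_table.dose_pct >= 90]
        table = dg.cumulative_dgc(dg.normalize_ddgc(dg.differential_dgc(_records(block), cfg)))
        path = tmp_path / "dgc.csv"
        table.to_csv(path)
        back = DGCTable.from_csv(path)
        pd.testing.assert_frame_equal(table.frame, back.frame)
        assert back.config == table.config
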