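"""Calibration, quantification, compositions, relative changes and PCA."""

import numpy as np
import pandas as pd
import pytest

from vitiflora.volatiles import (
    CalibrationCurve,
    ConcentrationTable,
    composition,
    fit_calibration,
    pca,
    quantify,
    relative_change,
)


def _standards(conc, ratio, is_area=1e5):
    return pd.DataFrame(
        {
            "concentration": conc,
            "analyte_area": np.asarray(ratio) * is_area,
            "is_area": is_area,
        }
    )


def _peak_row(sample="s1", cultivar="X", stage="a", rep=1, compound="c",
              peak_area=4e5, is_area=1e5, mass=1.0):
    return {
        "sample_id": sample, "cultivar": cultivar, "stage": stage,
        "replicate": rep, "compound": compound, "peak_area": peak_area,
        "is_area": is_area, "tissue_mass": mass,
    }


class TestFitCalibration:
    def test_exact_line_through_origin(self):
        curve = fit_calibration(_standards([1, 2, 3], [2, 4, 6]))
        assert curve.slope == pytest.approx(2.0)
        assert curve.intercept == pytest.approx(0.0, abs=1e-12)
        assert curve.r_squared == pytest.approx(1.0)

    def test_two_points_have_unit_r_squared(self):
        curve = fit_calibration(_standards([1.0, 3.0], [2.1, 5.9]))
        assert curve.r_squared == pytest.approx(1.0)

    def test_noisy_slope_recovery(self):
        rng = np.random.default_rng(8)
        conc = np.linspace(0.1, 2.0, 20)
        ratio = 1.5 * conc + 0.1 + rng.normal(0, 0.01, size=20)
        curve = fit_calibration(_standards(conc, ratio))
        assert curve.slope == pytest.approx(1.5, abs=0.05)

    def test_identical_concentrations_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_calibration(_standards([1, 1, 1], [2, 2, 2]))


class TestQuantify:
    def test_hand_computed_concentration(self):
        peaks = pd.DataFrame([_peak_row()])
        curve = CalibrationCurve("c", slope=2.0, intercept=0.0,
                                 r_squared=1.0, conc_range=(0, 10))
        conc = quantify(peaks, {"c": curve})
        assert conc.wide.loc["s1", "c"] == pytest.approx(2.0)
        assert conc.modes["c"] == "standard"

    def test_below_intercept_clamps_to_zero_and_flags(self):
        peaks = pd.DataFrame([_peak_row(peak_area=1e4)])
        curve = CalibrationCurve("c", slope=2.0, intercept=0.5,
                                 r_squared=1.0, conc_range=(0, 10))
        conc = quantify(peaks, {"c": curve})
        assert conc.wide.loc["s1", "c"] == 0.0
        assert ("s1", "c") in conc.clamped

    def test_fallback_marks_semi_quantitative(self):
        peaks = pd.DataFrame([_peak_row(compound="nostandard")])
        fallback = CalibrationCurve("(+)-valencene", 2.0, 0.0, 1.0, (0, 10))
        conc = quantify(peaks, {}, fallback=fallback)
        assert conc.modes["nostandard"] == "semi-quantitative"

    def test_zero_is_area_names_sample(self):
        peaks = pd.DataFrame([_peak_row(sample="badvial", is_area=0.0)])
        with pytest.raises(ValueError, match="badvial"):
            quantify(peaks, {"c": CalibrationCurve("c", 1, 0, 1, (0, 1))})


def _conc_table(data, cultivars=None, stages=None):
    df = pd.DataFrame(data)
    n = len(df)
    df.insert(0, "replicate", range(1, n + 1))
    df.insert(0, "stage", stages or ["a"] * n)
    df.insert(0, "cultivar", cultivars or ["X"] * n)
    df.index = [f"s{i}" for i in range(n)]
    df.index.name = "sample_id"
    return ConcentrationTable(wide=df)


class TestComposition:
    def test_single_compound_class_is_100(self):
        conc = _conc_table({"a": [3.0, 5.0]})
        pct = composition(conc, ["a"])
        assert np.allclose(pct["a"], 100.0)

    def test_hand_ratios(self):
        conc = _conc_table({"a": [2.0], "b": [1.0], "c": [1.0]})
        pct = composition(conc)
        assert pct.iloc[0].tolist() == pytest.approx([50.0, 25.0, 25.0])

    def test_rows_sum_to_100_and_scale_invariance(self):
        rng = np.random.default_rng(12)
        vals = rng.uniform(0.1, 5.0, size=(6, 4))
        conc = _conc_table({f"c{i}": vals[:, i] for i in range(4)})
        pct = composition(conc)
        assert np.allclose(pct.sum(axis=1), 100.0, atol=1e-9)
        scaled = _conc_table({f"c{i}": vals[:, i] * 7.3 for i in range(4)})
        pd.testing.assert_frame_equal(pct, composition(scaled))

    def test_all_zero_samples_excluded(self):
        conc = _conc_table({"a": [1.0, 0.0], "b": [1.0, 0.0]})
        pct = composition(conc)
        assert list(pct.index) == ["s0"]
        assert pct.attrs["excluded"] == ["s1"]


class TestRelativeChange:
    def test_equal_means_zero(self):
        conc = _conc_table({"a": [2.0, 2.0]}, stages=["x", "y"])
        assert relative_change(conc, "a", ("X", "x"), ("X", "y")) == 0.0

    def test_hand_arithmetic_74_percent(self):
        conc = _conc_table({"a": [8.70, 5.00]}, stages=["x", "y"])
        r = relative_change(conc, "a", ("X", "x"), ("X", "y"))
        assert r == pytest.approx(74.0)

    def test_swap_identity(self):
        conc = _conc_table({"a": [8.7, 5.0]}, stages=["x", "y"])
        r_ab = relative_change(conc, "a", ("X", "x"), ("X", "y"))
        r_ba = relative_change(conc, "a", ("X", "y"), ("X", "x"))
        assert (1 + r_ab / 100) * (1 + r_ba / 100) == pytest.approx(1.0)

    def test_zero_reference_fails(self):
        conc = _conc_table({"a": [1.0, 0.0]}, stages=["x", "y"])
        with pytest.raises(ValueError, match="zero mean"):
            relative_change(conc, "a", ("X", "x"), ("X", "y"))


class TestPca:
    def test_collinear_data_puts_everything_on_pc1(self):
        x = np.arange(10.0)
        m = pd.DataFrame({"a": x, "b": 2 * x})
        res = pca(m)
        assert res["percent_variance"].iloc[0] == pytest.approx(100.0)

    def test_square_symmetry_gives_two_equal_components(self):
        m = pd.DataFrame([(-1, -1), (1, 1), (-1, 1), (1, -1)],
                         columns=["a", "b"], dtype=float)
        res = pca(m)
        assert np.allclose(res["percent_variance"], [50.0, 50.0])

    def test_agrees_with_covariance_eigendecomposition(self):
        """Dual-route check: SVD-based fractions vs eigh of the covariance
        matrix, on random 24 x 12 matrices."""
        rng = np.random.default_rng(7)
        for _ in range(10):
            m = pd.DataFrame(rng.normal(size=(24, 12)))
            res = pca(m)
            cov = np.cov(m.to_numpy(), rowvar=False)
            ev = np.sort(np.linalg.eigvalsh(cov))[::-1]
            expected = 100.0 * ev / ev.sum()
            np.testing.assert_allclose(
                res["percent_variance"].to_numpy()[: len(expected)],
                expected, atol=1e-8,
            )

    def test_percent_variance_sums_to_100_and_is_order_invariant(self):
        rng = np.random.default_rng(42)
        m = pd.DataFrame(rng.normal(size=(15, 6)),
                         columns=[f"c{i}" for i in range(6)])
        res = pca(m)
        assert res["percent_variance"].sum() == pytest.approx(100.0)
        shuffled = m[["c3", "c0", "c5", "c1", "c4", "c2"]]
        np.testing.assert_allclose(
            res["percent_variance"], pca(shuffled)["percent_variance"],
            atol=1e-9,
        )

    def test_zero_variance_compound_under_scaling_is_named(self):
        m = pd.DataFrame({"flatline": [1.0, 1.0, 1.0], "ok": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="flatline"):
            pca(m, scale=True)

    def test_loading_signs_deterministic(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.normal(size=(10, 4)))
        res = pca(m)
        for col in res["loadings"].columns:
            v = res["loadings"][col].to_numpy()
            assert v[np.argmax(np.abs(v))] > 0
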