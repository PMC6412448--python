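"""Agreement statistics: R², Bland–Altman, error bands, report shape."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from pulsebp.evaluate import (
    band_accuracy,
    bland_altman,
    build_report,
    dataset_summary,
    r_squared,
    render_tables,
)

paired = st.integers(2, 60).flatmap(lambda n: st.tuples(
    hnp.arrays(np.float64, n, elements=st.floats(50, 200)),
    hnp.arrays(np.float64, n, elements=st.floats(50, 200))))


class TestRSquared:
    def test_perfect_estimate(self):
        ref = np.array([100.0, 110.0, 120.0])
        assert r_squared(ref, ref) == pytest.approx(1.0)

    def test_mean_estimate_scores_zero(self):
        ref = np.array([100.0, 110.0, 120.0, 130.0])
        est = np.full(4, ref.mean())
        assert r_squared(ref, est) == pytest.approx(0.0)

    def test_worked_example(self):
        ref = np.array([100.0, 110.0, 120.0, 130.0])
        est = np.array([102.0, 108.0, 123.0, 128.0])
        # SS_res = 4+4+9+4 = 21, SS_tot = 500
        assert r_squared(ref, est) == pytest.approx(1 - 21 / 500)

    def test_zero_reference_variance_is_nan(self):
        assert np.isnan(r_squared(np.full(5, 120.0), np.arange(5.0)))

    def test_matches_sklearn(self):
        from sklearn.metrics import r2_score
        rng = np.random.default_rng(0)
        ref = rng.uniform(90, 150, 200)
        est = ref + rng.normal(0, 5, 200)
        assert r_squared(ref, est) == pytest.approx(r2_score(ref, est),
                                                    abs=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(paired)
    def test_never_exceeds_one(self, pair):
        ref, est = pair
        if np.var(ref) == 0:
            return
        assert r_squared(ref, est) <= 1.0 + 1e-12


class TestBlandAltman:
    def test_identical_series_zero_bias_and_limits(self):
        ref = np.array([100.0, 120.0, 140.0])
        bias, lo, hi, _ = bland_altman(ref, ref)
        assert bias == lo == hi == 0.0

    def test_constant_offset(self):
        ref = np.array([100.0, 120.0, 140.0])
        bias, lo, hi, _ = bland_altman(ref, ref + 5)
        assert (bias, lo, hi) == (5.0, 5.0, 5.0)

    def test_hand_computed_limits(self):
        ref = np.zeros(3)
        est = np.array([-2.0, 0.0, 2.0])  # sample SD = 2
        bias, lo, hi, _ = bland_altman(ref, est)
        assert bias == pytest.approx(0.0)
        assert lo == pytest.approx(-1.96 * 2)
        assert hi == pytest.approx(1.96 * 2)

    @settings(deadline=None, derandomize=True)
    @given(paired)
    def test_antisymmetric_under_swap(self, pair):
        ref, est = pair
        b1, lo1, hi1, _ = bland_altman(ref, est)
        b2, lo2, hi2, _ = bland_altman(est, ref)
        assert b2 == pytest.approx(-b1, abs=1e-9)
        assert lo2 == pytest.approx(-hi1, abs=1e-9)
        assert hi2 == pytest.approx(-lo1, abs=1e-9)


class TestBandAccuracy:
    def test_counting_example(self):
        d = np.array([0.0, 3.0, 7.0, 12.0, 20.0])
        np.testing.assert_allclose(band_accuracy(d), [0.4, 0.6, 0.8])

    def test_all_zero_and_all_large(self):
        np.testing.assert_allclose(band_accuracy(np.zeros(4)), [1, 1, 1])
        np.testing.assert_allclose(band_accuracy(np.full(4, 100.0)),
                                   [0, 0, 0])

    def test_threshold_boundary_is_strict(self):
        np.testing.assert_allclose(
            band_accuracy(np.array([5.0, -10.0, 15.0])), [0, 1 / 3, 2 / 3])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            band_accuracy(np.array([]))

    @settings(deadline=None, derandomize=True)
    @given(hnp.arrays(np.float64, st.integers(1, 100),
                      elements=st.floats(-30, 30)))
    def test_matches_bruteforce_count(self, d):
        fractions = band_accuracy(d, (5.0, 10.0, 15.0))
        for frac, thr in zip(fractions, (5.0, 10.0, 15.0)):
            count = sum(1 for v in d if abs(v) < thr)
            assert frac == pytest.approx(count / len(d))


class TestReport:
    def _predictions(self, perfect=True):
        rng = np.random.default_rng(1)
        out = {}
        for alg in ("RFR", "GBR", "ABR"):
            for tgt in ("SBP", "DBP"):
                ref = rng.uniform(90, 140, 50)
                est = ref if perfect else ref + rng.normal(0, 6, 50)
                out[(alg, tgt)] = (ref, est)
        return out

    def test_perfect_predictors_all_bands_full(self):
        report = build_report(self._predictions(perfect=True))
        for cell in report.cells.values():
            assert cell.r2 == pytest.approx(1.0)
            assert all(v == 1.0 for v in cell.band_fractions.values())

    def test_bands_non_decreasing_in_every_cell(self):
        report = build_report(self._predictions(perfect=False))
        for cell in report.cells.values():
            fr = list(cell.band_fractions.values())
            assert np.all(np.diff(fr) >= 0)
            assert cell.loa_low <= cell.bias <= cell.loa_high

    def test_missing_cell_reported_as_gap(self):
        preds = self._predictions()
        del preds[("ABR", "DBP")]
        report = build_report(preds)
        assert report.get("ABR", "DBP") is None
        tables = render_tables(report)
        assert "ABR" in tables["DBP"].index

    def test_rendered_table_shape(self):
        tables = render_tables(build_report(self._predictions()))
        assert set(tables) == {"SBP", "DBP"}
        for table in tables.values():
            assert list(table.index) == ["ABR", "GBR", "RFR"]
            band_cols = [c for c in table.columns if c.endswith("mmHg")
                         and c.startswith("<")]
            assert len(band_cols) == 3


class TestDatasetSummary:
    def test_counts_conserved_and_minmax(self):
        rng = np.random.default_rng(2)
        refs = pd.DataFrame({
            "sbp_mmHg": rng.uniform(98, 138, 300),
            "dbp_mmHg": rng.uniform(58, 81, 300)})
        out = dataset_summary(refs)
        for key, col in (("sbp", "sbp_mmHg"), ("dbp", "dbp_mmHg")):
            assert out[key]["counts"].sum() == 300
            assert out[key]["min"] == refs[col].min()
            assert out[key]["max"] == refs[col].max()

    def test_single_value_single_bin(self):
        refs = pd.DataFrame({"sbp_mmHg": [120.0] * 7,
                             "dbp_mmHg": [70.0] * 7})
        out = dataset_summary(refs)
        assert out["sbp"]["counts"].sum() == 7
        assert (out["sbp"]["counts"] > 0).sum() == 1
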