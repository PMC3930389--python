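"""Tumor-growth quantities and group statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from tumorperf import compare_groups, correlate, percent_change, tgi, tumor_volume
from tumorperf.roi_stats import group_summary, records_to_frame


class TestTumorVolume:
    def test_cube_like(self):
        assert tumor_volume(10.0, 10.0) == pytest.approx(500.0)

    def test_arithmetic(self):
        assert tumor_volume(12.0, 8.0) == pytest.approx(384.0)

    def test_swapped_inputs_warn_and_correct(self):
        with pytest.warns(UserWarning, match="swap"):
            assert tumor_volume(8.0, 12.0) == pytest.approx(384.0)

    @given(st.floats(1.0, 50.0), st.floats(0.1, 1.0), st.floats(1.5, 3.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_cubic_homogeneity(self, length, frac, s):
        width = length * frac
        assert tumor_volume(s * length, s * width) == pytest.approx(
            s**3 * tumor_volume(length, width), rel=1e-9
        )

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            tumor_volume(0.0, 1.0)


class TestTGI:
    def test_no_inhibition(self):
        assert tgi(663.0, 663.0, 86.0) == 0.0

    def test_complete_stasis(self):
        assert tgi(663.0, 86.0, 86.0) == pytest.approx(100.0)

    def test_group_mean_arithmetic(self):
        # regression below baseline gives TGI above 100%
        assert tgi(663.0, 74.0, 86.0) == pytest.approx(102.1, abs=0.05)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            tgi(500.0, 200.0, 500.0)


class TestPercentChange:
    def test_chronic_perfusion_change(self):
        assert percent_change(92.6, 44.8) == pytest.approx(-51.6, abs=0.05)

    def test_chronic_auc_change(self):
        assert percent_change(852.8, 499.5) == pytest.approx(-41.4, abs=0.05)

    def test_no_change(self):
        assert percent_change(42.0, 42.0) == 0.0

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 5.0)

    @given(st.floats(0.5, 1e4), st.floats(0.5, 1e4))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_reversal_identity(self, a, b):
        pc_ab = percent_change(a, b)
        pc_ba = percent_change(b, a)
        assert pc_ab == pytest.approx(-pc_ba / (1 + pc_ba / 100.0), rel=1e-9, abs=1e-9)


def _table(control, treated, timepoint="endpoint"):
    rows = []
    for g, vals in (("control", control), ("treated", treated)):
        for i, v in enumerate(vals):
            rows.append({"animal": f"{g}{i}", "group": g, "timepoint": timepoint, "y": v})
    return pd.DataFrame(rows)


class TestCompareGroups:
    def test_identical_groups_p_one(self):
        df = _table([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        res = compare_groups(df, "y")
        assert res["t"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)
        assert not res["significant"]

    def test_power_at_two_sd_separation(self, rng):
        hits = 0
        for _ in range(200):
            a = rng.normal(0.0, 1.0, 10)
            b = rng.normal(2.0, 1.0, 10)
            if compare_groups(_table(a, b), "y")["p"] < 0.05:
                hits += 1
        assert hits >= 190

    def test_permutation_null_matches_t_distribution(self, rng):
        vals = rng.normal(0, 1, 20)
        stats = []
        for _ in range(500):
            perm = rng.permutation(vals)
            stats.append(compare_groups(_table(perm[:10], perm[10:]), "y")["t"])
        _, p = sps.kstest(stats, sps.t(df=18).cdf)
        assert p > 0.01

    def test_small_cell_rejected(self):
        df = _table([1.0], [2.0, 3.0])
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_groups(df, "y")

    def test_two_way_detects_group_effect_and_reports_contrasts(self, rng):
        pre_c = rng.normal(100, 5, 8)
        post_c = rng.normal(100, 5, 8)
        pre_t = rng.normal(100, 5, 8)
        post_t = rng.normal(60, 5, 8)
        rows = []
        for g, (pre, post) in (("control", (pre_c, post_c)), ("treated", (pre_t, post_t))):
            for i in range(8):
                rows.append({"animal": f"{g}{i}", "group": g, "timepoint": "0h", "y": pre[i]})
                rows.append({"animal": f"{g}{i}", "group": g, "timepoint": "24h", "y": post[i]})
        res = compare_groups(pd.DataFrame(rows), "y", design="two-way")
        assert res["p"]["interaction"] < 0.05
        assert res["contrasts"]["within-treated:0h-vs-24h"]["p"] < 0.01
        assert res["contrasts"]["between-groups@24h"]["p"] < 0.01
        assert res["contrasts"]["within-treated:0h-vs-24h"]["paired"]

    def test_two_way_empty_cell_rejected(self):
        rows = [
            {"animal": "a", "group": "control", "timepoint": "0h", "y": 1.0},
            {"animal": "b", "group": "control", "timepoint": "0h", "y": 2.0},
            {"animal": "c", "group": "treated", "timepoint": "24h", "y": 3.0},
        ]
        with pytest.raises(ValueError, match="cell"):
            compare_groups(pd.DataFrame(rows), "y", design="two-way")


class TestCorrelate:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, p = correlate(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-8

    def test_perfect_anticorrelation(self):
        x = np.arange(10.0)
        assert correlate(x, -x)[0] == pytest.approx(-1.0)

    def test_null_distribution(self, rng):
        rs = []
        for _ in range(1000):
            rs.append(correlate(rng.normal(size=20), rng.normal(size=20))[0])
        rs = np.asarray(rs)
        assert abs(rs.mean()) < 0.03
        # analytic 95% null quantile of |r| for n=20: t-based c = sqrt(t^2/(t^2+18))
        t975 = sps.t.ppf(0.975, 18)
        c = np.sqrt(t975**2 / (t975**2 + 18))
        assert np.quantile(np.abs(rs), 0.95) == pytest.approx(c, abs=0.06)

    def test_insufficient_or_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            correlate([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="variance"):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_records_frame_and_summary_conservation():
    recs = [
        {"animal": "a", "group": "control", "timepoint": "0h", "roi_mean_f": 90.0},
        {"animal": "b", "group": "control", "timepoint": "0h", "roi_mean_f": 110.0},
        {"animal": "c", "group": "treated", "timepoint": "0h", "roi_mean_f": 50.0},
        {"animal": "d", "group": "treated", "timepoint": "0h", "roi_mean_f": 40.0},
    ]
    df = records_to_frame(recs)
    summary = group_summary(df, "roi_mean_f")
    control = summary.loc[summary.group == "control"].iloc[0]
    assert control["mean"] == pytest.approx(100.0)
    assert control["n"] == 2
    with pytest.raises(ValueError, match="duplicate"):
        records_to_frame(recs + [recs[0]])
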