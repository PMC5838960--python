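import numpy as np
import pandas as pd
import pytest

from mixqc.performance import (
    DEFAULT_TOLERANCE_LOG2,
    bias_precision,
    deviation_table,
    reliable_range,
)


def dev_frame(a, d, cls=None):
    frame = pd.DataFrame({"D": d, "A_avg": a},
                         index=[f"m{i}" for i in range(len(a))])
    if cls is not None:
        frame["class"] = cls
    return frame


def ratio_frame(m, a, ids=None):
    ids = ids or [f"m{i}" for i in range(len(m))]
    return pd.DataFrame({"M": m, "A": a}, index=ids)


class TestDeviationTable:
    def test_difference_and_average(self):
        pred = ratio_frame([1.0], [6.0])
        obs = ratio_frame([0.8], [5.0])
        out = deviation_table(pred, obs)
        assert out.loc["m0", "D"] == pytest.approx(-0.2)
        assert out.loc["m0", "A_avg"] == pytest.approx(5.5)

    def test_identical_inputs_all_zero(self):
        rng = np.random.default_rng(13)
        pred = ratio_frame(rng.normal(0, 1, 50), rng.uniform(2, 12, 50))
        out = deviation_table(pred, pred.copy())
        assert (out["D"] == 0.0).all()
        assert out.attrs["n_excluded"] == 0

    def test_disjoint_sets_warn_and_count(self):
        pred = ratio_frame([1.0], [5.0], ids=["a"])
        obs = ratio_frame([1.0], [5.0], ids=["b"])
        with pytest.warns(UserWarning, match="no miRNAs"):
            out = deviation_table(pred, obs)
        assert len(out) == 0
        assert out.attrs["n_excluded"] == 2


class TestBiasPrecision:
    def test_median_and_iqr_against_direct_quantiles(self):
        frame = dev_frame([1, 2, 3], [-1.0, 0.0, 1.0])
        bp = bias_precision(frame)
        assert bp.median == pytest.approx(0.0)
        assert bp.iqr == pytest.approx(
            np.percentile([-1, 0, 1], 75) - np.percentile([-1, 0, 1], 25)
        )
        assert bp.iqr == pytest.approx(1.0)

    def test_constant_deviation(self):
        frame = dev_frame(np.arange(5), np.full(5, 0.7))
        bp = bias_precision(frame)
        assert bp.median == pytest.approx(0.7)
        assert bp.iqr == 0.0

    def test_symmetric_noise_has_near_zero_median(self):
        meds = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            frame = dev_frame(np.arange(2000), rng.normal(0.0, 0.5, 2000))
            meds.append(bias_precision(frame).median)
        # sampling error of the median of n=2000 draws: ~1.25*sd/sqrt(n) ~ 0.014
        assert np.abs(np.mean(meds)) < 0.02

    def test_per_class_breakdown(self):
        frame = dev_frame([1, 2, 3, 4], [0.0, 0.0, 1.0, 1.0],
                          cls=["x", "x", "y", "y"])
        bp = bias_precision(frame, by_class=True)
        assert bp.per_class.loc["x", "median"] == 0.0
        assert bp.per_class.loc["y", "median"] == 1.0
        assert bp.per_class["n"].sum() == 4

    def test_empty_errors(self):
        with pytest.raises(ValueError, match="no deviation"):
            bias_precision(dev_frame([], []))


def brute_force_range(frame, tolerance, coverage, window_size, assess_upper=False):
    """Naive rescan oracle: explicit loop over every window."""
    sub = frame.sort_values("A_avg", kind="stable")
    a = sub["A_avg"].to_numpy()
    d = sub["D"].to_numpy()
    n = len(d)
    lo_q = (1 - coverage) / 2
    compliant = []
    centers = []
    for start in range(n - window_size + 1):
        w = d[start : start + window_size]
        lo = np.quantile(w, lo_q)
        hi = np.quantile(w, 1 - lo_q)
        compliant.append(lo >= -tolerance and hi <= tolerance)
        centers.append(a[start + window_size // 2])
    if not any(compliant):
        return None
    if assess_upper:
        best = (0, -1)
        i = 0
        while i < len(compliant):
            if compliant[i]:
                j = i
                while j < len(compliant) and compliant[j]:
                    j += 1
                if j - i >= best[0]:
                    best = (j - i, i)
                i = j
            else:
                i += 1
        return centers[best[1]], centers[best[1] + best[0] - 1]
    idx = None
    for i in range(len(compliant)):
        if all(compliant[i:]):
            idx = i
            break
    if idx is None:
        return None
    return centers[idx], float(a.max())


class TestReliableRange:
    def test_noise_free_spans_all_data(self):
        rng = np.random.default_rng(14)
        a = np.sort(rng.uniform(0, 20, 400))
        frame = dev_frame(a, np.zeros(400))
        rr = reliable_range(frame, window_size=50)
        assert rr.defined
        assert rr.lower_limit == pytest.approx(a[25])  # center of first window
        assert rr.upper_limit == pytest.approx(a.max())
        assert rr.range_span == pytest.approx(rr.upper_limit - rr.lower_limit)

    def test_noise_step_located_within_one_window_width(self):
        rng = np.random.default_rng(15)
        a = np.sort(rng.uniform(0, 16, 2000))
        sd = np.where(a < 8.0, 1.0, 0.05)
        frame = dev_frame(a, rng.normal(0, sd))
        rr = reliable_range(frame, tolerance=DEFAULT_TOLERANCE_LOG2, window_size=100)
        assert rr.defined
        window_width = a[np.searchsorted(a, rr.lower_limit) + 100] - rr.lower_limit
        assert abs(rr.lower_limit - 8.0) < max(window_width, 1.0)
        oracle = brute_force_range(frame, DEFAULT_TOLERANCE_LOG2, 0.95, 100)
        assert rr.lower_limit == pytest.approx(oracle[0])
        assert rr.upper_limit == pytest.approx(oracle[1])

    def test_all_windows_noncompliant_flagged_nd(self):
        rng = np.random.default_rng(16)
        frame = dev_frame(np.sort(rng.uniform(0, 10, 300)), rng.normal(0, 5.0, 300))
        rr = reliable_range(frame, window_size=50)
        assert not rr.defined
        assert rr.lower_limit is None and rr.upper_limit is None
        assert "tolerance" in rr.reason

    def test_insufficient_records_diagnostic(self):
        frame = dev_frame(np.arange(30.0), np.zeros(30))
        rr = reliable_range(frame, window_size=50)
        assert not rr.defined
        assert "insufficient" in rr.reason

    @pytest.mark.parametrize("assess_upper", [False, True])
    @pytest.mark.parametrize("seed", [21, 22, 23])
    def test_agrees_with_brute_force_rescan(self, seed, assess_upper):
        rng = np.random.default_rng(seed)
        n = 600
        a = np.sort(rng.uniform(0, 15, n))
        sd = 0.15 + 2.0 * np.exp(-a) + (0.5 if assess_upper else 0.0) * (a > 13)
        frame = dev_frame(a, rng.normal(0, sd))
        rr = reliable_range(frame, window_size=60, assess_upper=assess_upper)
        oracle = brute_force_range(frame, DEFAULT_TOLERANCE_LOG2, 0.95, 60,
                                   assess_upper)
        if oracle is None:
            assert not rr.defined
        else:
            assert rr.defined
            assert rr.lower_limit == pytest.approx(oracle[0])
            assert rr.upper_limit == pytest.approx(oracle[1])

    def test_lower_limit_monotone_in_tolerance(self):
        rng = np.random.default_rng(17)
        a = np.sort(rng.uniform(0, 16, 1500))
        frame = dev_frame(a, rng.normal(0, 0.1 + 3.0 * np.exp(-a / 2)))
        limits = []
        for tol in (0.3, 0.585, 1.0, 2.0):
            rr = reliable_range(frame, tolerance=tol, window_size=100)
            limits.append(rr.lower_limit if rr.defined else np.inf)
        assert limits == sorted(limits, reverse=True)

    def test_window_halfwidth_converges_to_normal_quantile(self):
        # constant-sd Gaussian deviations: central 95% interval half-width -> 1.96 sd
        halfwidths = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            d = rng.normal(0, 0.2, 200)
            lo = np.quantile(d, 0.025)
            hi = np.quantile(d, 0.975)
            halfwidths.append((hi - lo) / 2)
        assert np.mean(halfwidths) == pytest.approx(1.96 * 0.2, rel=0.10)
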