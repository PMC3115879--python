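import numpy as np
import pandas as pd
import pytest

from gmapkit.arrays import (
    RatioSet,
    ThresholdPolicy,
    background_threshold,
    cross_hyb_percent,
    cross_hyb_rate,
    cyclic_loess_normalize,
    detection_call,
    gcbg_correct,
    log2_ratios,
    round_percent,
    subpool_distribution,
    summarize_replicates,
)


class TestGcbgCorrect:
    def test_subtracts_matched_gc_median(self, feature_table):
        out = gcbg_correct(feature_table)
        b1 = out[out["barcode_id"] == "b1"]["intensity"]
        assert sorted(b1) == [60.0, 70.0, 80.0]  # minus median 40 of gc=8 probes
        assert "GCBG" not in set(out["class_id"])

    def test_floor_applied(self, feature_table):
        t = feature_table.copy()
        t.loc[t["barcode_id"] == "b1", "intensity"] = 10.0
        out = gcbg_correct(t, floor=1.0)
        assert (out[out["barcode_id"] == "b1"]["intensity"] == 1.0).all()

    def test_zero_background_idempotent(self, feature_table):
        t = feature_table.copy()
        t.loc[t["class_id"] == "GCBG", "intensity"] = 0.0
        out = gcbg_correct(t)
        fg = feature_table[feature_table["class_id"] != "GCBG"]
        assert np.allclose(out["intensity"].to_numpy(), fg["intensity"].to_numpy())

    def test_missing_gc_bin_falls_back_to_nearest(self, feature_table):
        t = feature_table.copy()
        t.loc[t["barcode_id"] == "b2", "gc_count"] = 13  # no gc=13 background
        out = gcbg_correct(t)
        b2 = out[out["barcode_id"] == "b2"]["intensity"]
        assert sorted(b2) == [220.0, 240.0, 4940.0]  # nearest bin is gc=12, median 60

    def test_no_background_rejected(self, feature_table):
        t = feature_table[feature_table["class_id"] != "GCBG"]
        with pytest.raises(ValueError, match="background"):
            gcbg_correct(t)

    def test_matches_per_bin_median_oracle(self):
        rng = np.random.default_rng(3)
        n = 300
        gc = rng.integers(5, 15, size=n)
        cls = np.where(rng.random(n) < 0.4, "GCBG", "HP")
        t = pd.DataFrame(
            {
                "feature_id": [f"F{i}" for i in range(n)],
                "class_id": cls,
                "barcode_id": np.where(cls == "HP", [f"b{i}" for i in range(n)], ""),
                "replicate_index": 1,
                "gc_count": gc,
                "intensity": rng.uniform(0, 1000, n),
            }
        )
        out = gcbg_correct(t).set_index("feature_id")["intensity"]
        bg = t[t["class_id"] == "GCBG"]
        bins = sorted(bg["gc_count"].unique())
        for _, row in t[t["class_id"] == "HP"].iterrows():
            nearest = min(bins, key=lambda b: abs(b - row.gc_count))
            med = bg[bg["gc_count"] == nearest]["intensity"].median()
            assert out[row.feature_id] == pytest.approx(max(row.intensity - med, 1.0))


class TestSummarizeReplicates:
    @pytest.mark.parametrize("reps,expected", [((5, 5, 5), 5.0), ((2, 4, 100), 4.0)])
    def test_median_of_triplicates(self, reps, expected):
        t = pd.DataFrame(
            {
                "feature_id": ["a", "b", "c"],
                "class_id": "HP",
                "barcode_id": "bc",
                "replicate_index": [1, 2, 3],
                "gc_count": 10,
                "intensity": reps,
            }
        )
        assert summarize_replicates(t)["bc"] == expected

    def test_permutation_invariant_and_matches_sort_oracle(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 100, 9)
        t = pd.DataFrame(
            {
                "feature_id": [f"f{i}" for i in range(9)],
                "class_id": "HP",
                "barcode_id": np.repeat(["x", "y", "z"], 3),
                "replicate_index": np.tile([1, 2, 3], 3),
                "gc_count": 10,
                "intensity": vals,
            }
        )
        shuffled = t.sample(frac=1, random_state=5)
        a, b = summarize_replicates(t), summarize_replicates(shuffled)
        pd.testing.assert_series_equal(a, b)
        for bc in "xyz":
            v = np.sort(t[t["barcode_id"] == bc]["intensity"].to_numpy())
            assert a[bc] == v[1]


class TestCyclicLoess:
    def test_identical_arrays_unchanged(self):
        rng = np.random.default_rng(2)
        sig = pd.Series(rng.lognormal(8, 1, 500), index=[f"b{i}" for i in range(500)])
        out = cyclic_loess_normalize({"a": sig, "b": sig.copy()})
        assert np.allclose(out["a"] - out["b"], 0.0, atol=1e-9)

    def test_constant_offset_removed(self):
        rng = np.random.default_rng(3)
        a = pd.Series(rng.lognormal(8, 1, 800), index=[f"b{i}" for i in range(800)])
        b = a * 2.0**1.7
        out = cyclic_loess_normalize({"a": a, "b": b})
        m = out["a"] - out["b"]
        assert abs(np.median(m)) < 0.01

    def test_total_log_signal_conserved(self):
        rng = np.random.default_rng(4)
        idx = [f"b{i}" for i in range(400)]
        arrays = {
            k: pd.Series(rng.lognormal(8, 1, 400), index=idx) for k in "abc"
        }
        out = cyclic_loess_normalize(arrays, tol=1e-4)
        before = sum(np.log2(v.to_numpy()) for v in arrays.values())
        after = sum(out[k].to_numpy() for k in arrays)
        assert np.allclose(before, after, atol=1e-8)

    def test_residual_trend_small(self):
        # replicate arrays: shared per-barcode signal, small per-array noise
        rng = np.random.default_rng(5)
        n = 1000
        idx = [f"b{i}" for i in range(n)]
        base = rng.lognormal(8, 1.0, n)
        arrays = {
            k: pd.Series(base * rng.lognormal(0, 0.15, n), index=idx) for k in "abc"
        }
        out = cyclic_loess_normalize(arrays, max_cycles=5, tol=1e-4)
        from statsmodels.nonparametric.smoothers_lowess import lowess

        for x, y in [("a", "b"), ("a", "c"), ("b", "c")]:
            m = out[x] - out[y]
            av = 0.5 * (out[x] + out[y])
            fit = lowess(m, av, frac=0.4, return_sorted=False)
            assert np.mean(np.abs(fit)) < 0.01

    def test_nonpositive_rejected(self):
        a = pd.Series([1.0, 0.0], index=["x", "y"])
        with pytest.raises(ValueError, match="non-positive"):
            cyclic_loess_normalize({"a": a, "b": a + 1})


class TestBackgroundThreshold:
    def test_constant_background(self):
        assert background_threshold([7.0, 7.0, 7.0]) == pytest.approx(7.0)

    def test_z_zero_gives_mean(self):
        vals = [6.0, 7.0, 8.0]
        assert background_threshold(vals, ThresholdPolicy(0.0)) == pytest.approx(7.0)

    def test_closed_form_on_normal_draws(self):
        rng = np.random.default_rng(6)
        draws = rng.normal(7.0, 0.45, 100_000)
        thr = background_threshold(draws)
        assert thr == pytest.approx(7.0 + 1.96 * 0.45, abs=0.01)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            background_threshold([7.0])


class TestDetectionCall:
    def test_all_above(self):
        s = pd.Series([8.0, 9.0], index=["a", "b"])
        _, frac = detection_call(s, 7.0)
        assert frac == 1.0

    def test_none_above(self):
        s = pd.Series([8.0, 9.0], index=["a", "b"])
        _, frac = detection_call(s, 10.0)
        assert frac == 0.0

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(7)
        s = pd.Series(rng.normal(8, 1, 500))
        fracs = [detection_call(s, t)[1] for t in np.linspace(5, 11, 13)]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))


class TestLog2Ratios:
    def _tables(self):
        idx = [f"b{i}" for i in range(20)]
        ref = pd.Series(np.linspace(8, 10, 20), index=idx)
        ann = pd.Series(["S" if i < 5 else "bulk" for i in range(20)], index=idx)
        return idx, ref, ann

    def test_identical_gives_zero(self):
        idx, ref, ann = self._tables()
        rs = log2_ratios(ref, ref, ann)
        assert np.allclose(rs.ratios["log2_ratio"], 0.0)

    def test_constant_shift_on_subpool(self):
        idx, ref, ann = self._tables()
        sample = ref.copy()
        sample[ann == "S"] -= 2.0
        rs = log2_ratios(sample, ref, ann)
        assert np.allclose(
            rs.ratios.loc[rs.ratios["subpool_label"] == "S", "log2_ratio"], -2.0
        )

    def test_missing_barcodes_dropped_and_logged(self):
        idx, ref, ann = self._tables()
        sample = ref.drop(idx[0])
        rs = log2_ratios(sample, ref, ann)
        assert idx[0] in rs.dropped
        assert idx[0] not in set(rs.ratios["barcode_id"])

    def test_centering_on_label(self):
        idx, ref, ann = self._tables()
        sample = ref + 0.7  # global offset
        sample[ann == "S"] -= 2.0
        rs = log2_ratios(sample, ref, ann, center="bulk")
        bulk = rs.ratios[rs.ratios["subpool_label"] == "bulk"]["log2_ratio"]
        sub = rs.ratios[rs.ratios["subpool_label"] == "S"]["log2_ratio"]
        assert np.median(bulk) == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(sub, -2.0)


class TestSubpoolDistribution:
    def test_all_zero_ratios(self):
        df = pd.DataFrame(
            {"barcode_id": [f"b{i}" for i in range(30)], "log2_ratio": 0.0, "subpool_label": "S"}
        )
        out = subpool_distribution(RatioSet(df))
        assert out.loc["S", "mode"] == 0.0
        assert out.loc["S", "iqr"] == 0.0

    def test_two_point_symmetric_median(self):
        df = pd.DataFrame(
            {
                "barcode_id": ["a", "b"],
                "log2_ratio": [-1.0, 1.0],
                "subpool_label": "S",
            }
        )
        out = subpool_distribution(RatioSet(df))
        assert out.loc["S", "median"] == 0.0
        assert out.loc["S", "mode_flagged"]

    def test_mode_near_center_of_gaussian(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(
            {
                "barcode_id": [f"b{i}" for i in range(2000)],
                "log2_ratio": rng.normal(-2.0, 0.3, 2000),
                "subpool_label": "S",
            }
        )
        out = subpool_distribution(RatioSet(df))
        assert out.loc["S", "mode"] == pytest.approx(-2.0, abs=0.1)


class TestCrossHyb:
    def test_printed_counts(self):
        assert cross_hyb_percent(2637, 77690) == 3.39

    def test_zero_rate(self):
        sig = pd.Series([5.0, 5.5], index=["a", "b"])
        n_sig, n_assessed, pct = cross_hyb_rate(sig, ["a", "b"], 7.89)
        assert (n_sig, n_assessed, pct) == (0, 2, 0.0)

    def test_exclusion_set_removed_before_assessment(self):
        sig = pd.Series([9.0, 5.0, 9.0], index=["a", "b", "c"])
        n_sig, n_assessed, pct = cross_hyb_rate(sig, ["a", "b", "c"], 7.89, {"c"})
        assert (n_sig, n_assessed) == (1, 2)
        assert pct == 50.0

    def test_percent_identity(self):
        n_sig, n_assessed, pct = cross_hyb_rate(
            pd.Series(np.linspace(0, 10, 100), index=[f"b{i}" for i in range(100)]),
            [f"b{i}" for i in range(100)],
            5.0,
        )
        assert pct == round_percent(100.0 * n_sig / n_assessed)

    def test_empty_assessed_rejected(self):
        with pytest.raises(ValueError):
            cross_hyb_rate(pd.Series(dtype=float), ["a"], 7.89, {"a"})
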