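"""Dominant barcodes, diversity, seeding clones, TIC frequency, overlap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from clonetrace import metrics


class TestDominantSet:
    def test_prefix_rule(self):
        cpm = pd.Series({"a": 0.50, "b": 0.30, "c": 0.15, "d": 0.05}) * 1e6
        assert metrics.dominant_set(cpm, 0.95) == {"a", "b", "c"}

    def test_single_barcode(self):
        assert metrics.dominant_set(pd.Series({"x": 1e6})) == {"x"}

    def test_uniform_hundred_gives_95(self):
        cpm = pd.Series({f"b{i:03d}": 1e4 for i in range(100)})
        assert len(metrics.dominant_set(cpm, 0.95)) == 95

    def test_threshold_one_returns_all(self):
        cpm = pd.Series({"a": 5.0, "b": 3.0, "c": 2.0})
        assert metrics.dominant_set(cpm, 1.0) == {"a", "b", "c"}

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="empty sample"):
            metrics.dominant_set(pd.Series({"a": 0.0}))

    @given(st.lists(st.floats(min_value=0.1, max_value=1e6), min_size=1,
                    max_size=30),
           st.floats(min_value=0.1, max_value=0.9),
           st.floats(min_value=0.0, max_value=0.1))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_threshold(self, values, thr, bump):
        cpm = pd.Series(values, index=[f"b{i}" for i in range(len(values))])
        low = metrics.dominant_set(cpm, thr)
        high = metrics.dominant_set(cpm, min(thr + bump, 1.0))
        assert low <= high

    def test_exclusive_boundary_variant(self):
        cpm = pd.Series({"a": 0.50, "b": 0.30, "c": 0.15, "d": 0.05}) * 1e6
        assert metrics.dominant_set(cpm, 0.95, inclusive=False) == {"a", "b"}


class TestShannonDiversity:
    def test_uniform_closed_form(self):
        counts = pd.Series([10, 10, 10, 10])
        assert metrics.shannon_diversity(counts) == pytest.approx(np.log(4))

    def test_single_barcode_zero(self):
        assert metrics.shannon_diversity(pd.Series([7])) == 0.0

    def test_half_quarter_quarter(self):
        # oracle: direct summation of -sum p ln p
        counts = pd.Series([2, 1, 1])
        assert metrics.shannon_diversity(counts) == pytest.approx(1.0397,
                                                                  abs=1e-4)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            metrics.shannon_diversity(pd.Series([0, 0]))

    @given(st.lists(st.integers(min_value=1, max_value=500), min_size=2,
                    max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_uniform_is_maximal_and_label_invariant(self, counts):
        s = pd.Series(counts, index=[f"b{i}" for i in range(len(counts))])
        h = metrics.shannon_diversity(s)
        assert h <= np.log(len(counts)) + 1e-12
        shuffled = s.sample(frac=1, random_state=0)
        assert metrics.shannon_diversity(shuffled) == pytest.approx(h)


class TestSeedingClones:
    def test_disjoint_sets(self):
        met = pd.Series({"a": 5})
        mfp = pd.Series({"b": 5})
        assert metrics.seeding_clones(met, mfp) == set()

    def test_intersection(self):
        met = pd.Series({"a": 1, "b": 500})
        mfp = pd.Series({"b": 2, "c": 9})
        assert metrics.seeding_clones(met, mfp) == {"b"}

    def test_subset(self):
        met = pd.Series({"a": 1, "b": 2})
        mfp = pd.Series({"a": 9, "b": 1, "c": 4})
        assert metrics.seeding_clones(met, mfp) == {"a", "b"}

    def test_cross_mouse_refused(self):
        s = pd.Series({"a": 1})
        with pytest.raises(ValueError, match="cross-mouse"):
            metrics.seeding_clones(s, s, met_mouse="A", mfp_mouse="B")


class TestTicFrequency:
    def test_published_bottleneck(self):
        assert round(metrics.tic_frequency(14322, 334810), 2) == 4.28

    def test_published_abundant_fraction(self):
        assert round(metrics.tic_frequency(500, 14322), 2) == 3.49

    def test_full_recovery(self):
        assert metrics.tic_frequency(1234, 1234) == 100.0

    def test_excess_warns(self):
        with pytest.warns(UserWarning):
            assert metrics.tic_frequency(200, 100) == 200.0

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            metrics.tic_frequency(1, 0)


class TestJaccard:
    @pytest.mark.parametrize("a,b,expected", [
        ({"x", "y"}, {"x", "y"}, 1.0),
        ({"x"}, {"y"}, 0.0),
        ({"a", "b", "c"}, {"b", "c", "d"}, 0.5),
    ])
    def test_values(self, a, b, expected):
        assert metrics.jaccard_index(a, b) == expected

    def test_empty_sets_warn(self):
        with pytest.warns(UserWarning):
            assert metrics.jaccard_index(set(), set()) == 0.0


class TestGroupCompare:
    def test_identical_groups(self):
        t, p = metrics.group_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_clear_shift(self):
        # oracle: textbook Welch formula, t = 10 / sqrt(2/3)
        t, p = metrics.group_compare([1, 2, 3], [11, 12, 13])
        assert p < 0.01
        assert t == pytest.approx(-10 / np.sqrt(2 / 3))

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            metrics.group_compare([1.0], [1.0, 2.0])

    def test_null_type_one_error_rate(self, rng):
        # oracle: Monte-Carlo type-I error of the Welch test at alpha=0.05
        a = rng.normal(size=(10_000, 6))
        b = rng.normal(size=(10_000, 6))
        p = stats.ttest_ind(a, b, axis=1, equal_var=False).pvalue
        rate = (p < 0.05).mean()
        assert abs(rate - 0.05) <= 0.01


class TestDensitySummary:
    def test_single_barcode_bin(self):
        s = pd.Series({"a": 1e6})
        out = metrics.barcode_density_summary(s, bins=5)
        assert out["log10_cpm"].iloc[0] == pytest.approx(6.0)

    def test_max_cpm_across_samples(self):
        cpm = pd.DataFrame({"s1": [10.0], "s2": [0.0], "s3": [3000.0]},
                           index=["b"])
        metas = [metrics.SampleMeta(s, "A", "lung", s)
                 for s in ("s1", "s2", "s3")]
        assert metrics.max_cpm_table(cpm, metas, "A")["b"] == 3000.0

    def test_dominance_separates_by_a_log_unit(self, noiseless_run):
        """The bulk of the planted dominant clones sits > 1 log10-CPM above
        the bulk of the ordinary seeders in every lesion (bimodality)."""
        gt, _, matrix = noiseless_run
        dom = {f"{a}:{b}" for a, b in gt.dominant_pairs("A")}
        for sample in gt.seeding_sets:           # metastatic lesions only
            cpm = matrix.cpm[sample]
            dom_cpms = [cpm[b] for b in dom if cpm.get(b, 0) > 0]
            rest = cpm[(cpm > 0) & ~cpm.index.isin(dom)]
            assert np.log10(np.median(dom_cpms)) \
                > np.log10(np.median(rest)) + 1


class TestClonalReport:
    def test_report_consistency(self, noiseless_run):
        gt, _, matrix = noiseless_run
        metas = [metrics.SampleMeta(**r)
                 for r in gt.sample_sheet.to_dict("records")]
        rep = metrics.clonal_report(matrix, metas)
        assert (rep.per_sample["n_dominant"]
                <= rep.per_sample["n_unique_barcodes"]).all()
        assert rep.per_metastasis["jaccard_vs_mfp"].between(0, 1).all()
        # every ground-truth seeding clone detected at this depth is reported
        for _, row in rep.per_metastasis.iterrows():
            truth_pairs = set()
            for clone in gt.seeding_sets[row["sample_id"]]:
                truth_pairs.update(gt.clone_labels["A"][clone])
            detected = {
                tuple(b.split(":")) for b in matrix.counts.index
                if matrix.counts.loc[b, row["sample_id"]] > 0
                and matrix.counts.loc[b, "A_MFP"] > 0}
            assert row["n_seeding"] >= len(detected & truth_pairs)

    def test_multiple_mfp_refused(self, noiseless_run):
        gt, _, matrix = noiseless_run
        metas = [metrics.SampleMeta(**r)
                 for r in gt.sample_sheet.to_dict("records")]
        metas.append(metrics.SampleMeta("A_MFP2", "A", "MFP", "MFP2"))
        with pytest.raises(ValueError, match="MFP"):
            metrics.clonal_report(matrix, metas)
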