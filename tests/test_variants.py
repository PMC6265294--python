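"""Variant filters, dMAF classification, artifact filter, qPCR, similarity."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clonetrace import variants
from clonetrace.variants import QpcrMeasurement


def vrow(vid, sample, ref, alt, callers=3, germline=0.0, db=False,
         silent=False, region="exonic", platform="WES"):
    return {"variant_id": vid, "sample_id": sample, "ref_reads": ref,
            "alt_reads": alt, "n_callers": callers, "germline_vaf": germline,
            "in_population_db": db, "is_silent": silent,
            "region_class": region, "platform": platform}


class TestConsensusFilter:
    def test_single_caller_dropped_in_wes(self):
        table = pd.DataFrame([vrow("v1", "s1", 100, 20, callers=1),
                              vrow("v2", "s1", 100, 20, callers=3)])
        out, log = variants.consensus_filter(table, "WES")
        assert set(out["variant_id"]) == {"v2"}
        assert log["single_caller"] == 1

    def test_clean_variant_retained(self):
        table = pd.DataFrame([vrow("v1", "s1", 90, 10)])
        out, _ = variants.consensus_filter(table, "WES")
        assert len(out) == 1

    @pytest.mark.parametrize("kwargs,rule", [
        (dict(germline=0.02), "germline"),
        (dict(db=True), "population_db"),
        (dict(silent=True), "noncoding_or_silent"),
        (dict(region="intronic"), "noncoding_or_silent"),
    ])
    def test_single_rule_eliminations(self, kwargs, rule):
        table = pd.DataFrame([vrow("v1", "s1", 100, 20, **kwargs)])
        out, log = variants.consensus_filter(table, "WES")
        assert out.empty and log[rule] == 1

    def test_low_coverage_requires_all_samples(self):
        # coverage 20 in one sample but 200 in another: retained
        table = pd.DataFrame([vrow("v1", "s1", 15, 5),
                              vrow("v1", "s2", 150, 50)])
        out, _ = variants.consensus_filter(table, "WES")
        assert not out.empty

    def test_targeted_per_sample_detection(self):
        table = pd.DataFrame([vrow("v1", "s1", 100, 2, platform="targeted"),
                              vrow("v1", "s2", 100, 50,
                                   platform="targeted")])
        out, _ = variants.consensus_filter(table, "targeted")
        status = out.set_index("sample_id")["detected"]
        assert not status["s1"] and status["s2"]

    def test_barcoded_mode_needs_100x(self):
        table = pd.DataFrame([vrow("v1", "s1", 40, 5),
                              vrow("v1", "s2", 200, 5)])
        out, _ = variants.consensus_filter(table, "targeted_barcoded")
        status = out.set_index("sample_id")["detected"]
        assert not status["s1"] and status["s2"]

    def test_idempotent_and_log_sums(self):
        rows = [vrow("v1", "s1", 100, 20, callers=1),
                vrow("v2", "s1", 100, 20, db=True),
                vrow("v3", "s1", 100, 20)]
        table = pd.DataFrame(rows)
        out1, log = variants.consensus_filter(table, "WES")
        out2, _ = variants.consensus_filter(out1, "WES")
        pd.testing.assert_frame_equal(out1, out2)
        assert log["variants_dropped"] == \
            log["variants_in"] - log["variants_out"] == 2

    def test_missing_column_named(self):
        with pytest.raises(ValueError, match="germline_vaf"):
            variants.consensus_filter(
                pd.DataFrame([{"variant_id": "v", "sample_id": "s",
                               "ref_reads": 1, "alt_reads": 1,
                               "n_callers": 2}]), "WES")


class TestDeltaMaf:
    def _table(self, met_mafs, pri_mafs, depth=100):
        rows = []
        for i, m in enumerate(met_mafs):
            alt = round(depth * m)
            rows.append(vrow("v1", f"met{i}", depth - alt, alt))
        for i, m in enumerate(pri_mafs):
            alt = round(depth * m)
            rows.append(vrow("v1", f"pri{i}", depth - alt, alt))
        return (pd.DataFrame(rows),
                [f"met{i}" for i in range(len(met_mafs))],
                [f"pri{i}" for i in range(len(pri_mafs))])

    def test_identical_groups_neutral(self):
        t, met, pri = self._table([0.3, 0.3, 0.3], [0.3, 0.3, 0.3])
        out = variants.delta_maf(t, met, pri)
        assert out.loc[0, "delta_maf"] == pytest.approx(0.0)
        assert out.loc[0, "class"] == "neutral"

    def test_strong_enrichment(self):
        # oracle: hand Welch t-test, delta = 0.60 - 0.11 = +0.49, p << 0.05
        t, met, pri = self._table([0.60, 0.62, 0.58], [0.10, 0.12, 0.11])
        out = variants.delta_maf(t, met, pri)
        assert out.loc[0, "delta_maf"] == pytest.approx(0.49, abs=1e-9)
        assert out.loc[0, "p"] < 1e-4
        assert out.loc[0, "class"] == "enriched"

    def test_small_shift_neutral_despite_significance(self):
        t, met, pri = self._table([0.20, 0.21, 0.19], [0.10, 0.11, 0.10])
        out = variants.delta_maf(t, met, pri)
        assert out.loc[0, "delta_maf"] == pytest.approx(0.0967, abs=1e-3)
        assert out.loc[0, "p"] < 0.05       # significant ...
        assert out.loc[0, "class"] == "neutral"  # ... but below |0.15|

    def test_antisymmetric_under_group_swap(self):
        t, met, pri = self._table([0.55, 0.60, 0.62], [0.15, 0.12, 0.13])
        fwd = variants.delta_maf(t, met, pri)
        rev = variants.delta_maf(t, pri, met)
        assert fwd.loc[0, "delta_maf"] == pytest.approx(
            -rev.loc[0, "delta_maf"])
        assert fwd.loc[0, "p"] == pytest.approx(rev.loc[0, "p"])

    def test_undefined_mafs_make_variant_untestable(self):
        rows = [vrow("v1", "met0", 0, 0), vrow("v1", "met1", 50, 50),
                vrow("v1", "pri0", 90, 10), vrow("v1", "pri1", 90, 10)]
        out = variants.delta_maf(pd.DataFrame(rows), ["met0", "met1"],
                                 ["pri0", "pri1"])
        assert out.loc[0, "class"] == "untestable"

    def test_overlapping_groups_rejected(self):
        t, met, pri = self._table([0.5, 0.5], [0.1, 0.1])
        with pytest.raises(ValueError):
            variants.delta_maf(t, met, met)


class TestDeNovoCandidates:
    def _meta(self):
        return pd.DataFrame([
            {"sample_id": "m1_MFP", "mouse": "m1", "site": "MFP"},
            {"sample_id": "m1_lung", "mouse": "m1", "site": "lung"},
            {"sample_id": "m2_MFP", "mouse": "m2", "site": "MFP"},
            {"sample_id": "m2_lung", "mouse": "m2", "site": "lung"},
        ])

    def _base(self, vid, mfp_wes=0, mfp_tgt=0, m1_lung=0, m2_lung=0):
        rows = []
        for mouse in ("m1", "m2"):
            rows.append(vrow(vid, f"{mouse}_MFP", 100, mfp_wes,
                             platform="WES"))
            rows.append(vrow(vid, f"{mouse}_MFP", 2000, mfp_tgt,
                             platform="targeted"))
        rows.append(vrow(vid, "m1_lung", 2000, m1_lung, platform="targeted"))
        rows.append(vrow(vid, "m2_lung", 2000, m2_lung, platform="targeted"))
        return pd.DataFrame(rows)

    def test_two_mouse_detection_excluded(self):
        table = self._base("v1", m1_lung=400, m2_lung=300)
        assert variants.de_novo_candidates(table, self._meta()).empty

    def test_subthreshold_mfp_reads_still_candidate(self):
        # 6 mutant deep-sequencing reads in the MFP are considered non-mutant
        table = self._base("v1", mfp_tgt=6, m1_lung=400)
        out = variants.de_novo_candidates(table, self._meta())
        assert list(out["variant_id"]) == ["v1"]
        assert out.loc[0, "mouse"] == "m1"

    def test_absent_everywhere_excluded(self):
        assert variants.de_novo_candidates(self._base("v1"),
                                           self._meta()).empty

    def test_wes_positive_mfp_excluded(self):
        table = self._base("v1", mfp_wes=3, m1_lung=400)
        assert variants.de_novo_candidates(table, self._meta()).empty

    def test_missing_platform_rejected(self):
        table = self._base("v1").drop(columns=["platform"])
        with pytest.raises(ValueError, match="platform"):
            variants.de_novo_candidates(table, self._meta())


class TestRepeatArtifactFilter:
    def test_perfect_correlation_discarded(self):
        cooc = pd.DataFrame([{"mut_a": "a", "mut_b": "b", "n_both": 50,
                              "n_only_a": 0, "n_only_b": 0,
                              "n_neither": 50}])
        out, discarded, log = variants.repeat_artifact_filter(cooc)
        assert out.loc[0, "flagged"] and out.loc[0, "discarded"]
        assert discarded == {"a", "b"}

    def test_independent_pair_not_flagged(self):
        # expected counts equal observed: chi-square statistic is 0
        cooc = pd.DataFrame([{"mut_a": "a", "mut_b": "b", "n_both": 1,
                              "n_only_a": 9, "n_only_b": 9,
                              "n_neither": 81}])
        out, discarded, _ = variants.repeat_artifact_filter(cooc)
        assert not out.loc[0, "flagged"] and not discarded

    def test_flagged_but_below_one_percent_retained(self):
        # strong association at large depth with n_both/total = 0.5 %
        n = 100_000
        cooc = pd.DataFrame([
            {"mut_a": "a", "mut_b": "b", "n_both": 500, "n_only_a": 100,
             "n_only_b": 100, "n_neither": n - 700}])
        out, discarded, _ = variants.repeat_artifact_filter(cooc)
        assert out.loc[0, "flagged"]
        assert not out.loc[0, "discarded"] and not discarded

    def test_zero_margin_untestable(self):
        cooc = pd.DataFrame([{"mut_a": "a", "mut_b": "b", "n_both": 0,
                              "n_only_a": 0, "n_only_b": 10,
                              "n_neither": 90}])
        out, _, log = variants.repeat_artifact_filter(cooc)
        assert log["n_untestable"] == 1
        assert np.isnan(out.loc[0, "p"])

    def test_hand_chi_square_agrees(self):
        tab = np.array([[30, 10], [10, 50]])
        cooc = pd.DataFrame([{"mut_a": "a", "mut_b": "b", "n_both": 30,
                              "n_only_a": 10, "n_only_b": 10,
                              "n_neither": 50}])
        out, _, _ = variants.repeat_artifact_filter(cooc)
        expected_p = stats.chi2_contingency(tab, correction=False)[1]
        assert out.loc[0, "p"] == pytest.approx(expected_p)


class TestHumanFraction:
    def test_symmetric_cts(self):
        assert variants.human_fraction(QpcrMeasurement(3.0, 3.0)) == \
            pytest.approx(50.0)

    def test_one_cycle_difference(self):
        # 0.5 / (0.5 + 0.25) = 2/3
        assert variants.human_fraction(QpcrMeasurement(1.0, 2.0)) == \
            pytest.approx(66.6667, abs=1e-3)

    def test_no_human_signal_limit(self):
        assert variants.human_fraction(QpcrMeasurement(np.inf, 2.0)) == 0.0


class TestSampleSimilarity:
    def _table(self, profiles):
        rows = []
        for sample, mafs in profiles.items():
            for i, m in enumerate(mafs):
                rows.append(vrow(f"v{i}", sample, int(1000 * (1 - m)),
                                 int(1000 * m)))
        return pd.DataFrame(rows)

    def test_duplicate_sample_perfect_correlation(self):
        t = self._table({"s1": [0.1, 0.5, 0.9], "s2": [0.1, 0.5, 0.9]})
        corr, order, _ = variants.sample_similarity(t)
        assert corr.loc["s1", "s2"] == pytest.approx(1.0)

    def test_anticorrelated_profiles(self):
        t = self._table({"s1": [0.0, 1.0], "s2": [1.0, 0.0]})
        corr, _, _ = variants.sample_similarity(t)
        assert corr.loc["s1", "s2"] == pytest.approx(-1.0)

    def test_identical_pair_joined_first(self):
        t = self._table({"sA": [0.1, 0.2, 0.3], "sB": [0.1, 0.2, 0.3],
                         "sC": [0.9, 0.8, 0.05]})
        _, order, link = variants.sample_similarity(t)
        # first merge joins the two zero-distance samples
        assert set(link[0, :2].astype(int)) == {0, 1}
        assert order.index("sA") + 1 == order.index("sB") \
            or order.index("sB") + 1 == order.index("sA")
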