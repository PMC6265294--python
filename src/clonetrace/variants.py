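"""Variant-level dynamics between primary tumors and metastases.

Operates on long-form variant tables with one row per (variant, sample)
carrying read counts and caller metadata.  Implements the consensus variant
filters for whole-exome (WES) and targeted deep sequencing, the dMAF
enrichment statistic with its +/-0.15 / p<=0.05 classification, de novo
mutation candidate criteria, a chi-square co-occurrence filter for
repeat-region alignment artifacts, qPCR-based human-DNA fraction, and
sample-relatedness summaries (Pearson correlation, complete-linkage
clustering).

MAF (mutant allele frequency) = alt_reads / (ref_reads + alt_reads); it is
undefined (NaN, never imputed as 0) where coverage is zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

__all__ = ["add_maf", "consensus_filter", "delta_maf", "de_novo_candidates",
           "repeat_artifact_filter", "human_fraction", "sample_similarity",
           "QpcrMeasurement"]

VARIANT_COLUMNS = ("variant_id", "sample_id", "ref_reads", "alt_reads")

_MODE_COLUMNS = {
    "WES": VARIANT_COLUMNS + ("n_callers", "germline_vaf",
                              "in_population_db", "is_silent",
                              "region_class"),
    "targeted": VARIANT_COLUMNS + ("n_callers",),
    "targeted_barcoded": VARIANT_COLUMNS + ("n_callers",),
}

NONCODING_CLASSES = ("intergenic", "intronic")


def add_maf(table: pd.DataFrame) -> pd.DataFrame:
    """Attach the derived ``maf`` column; NaN where coverage is zero."""
    out = table.copy()
    cov = out["ref_reads"] + out["alt_reads"]
    with np.errstate(invalid="ignore", divide="ignore"):
        out["maf"] = np.where(cov > 0, out["alt_reads"] / cov, np.nan)
    return out


def _require_columns(table: pd.DataFrame, mode: str) -> None:
    for col in _MODE_COLUMNS[mode]:
        if col not in table.columns:
            raise ValueError(f"mode {mode!r} requires column {col!r}")


def consensus_filter(table: pd.DataFrame, mode: str = "WES",
                     min_callers_wes: int = 2, min_coverage_wes: int = 30,
                     min_alt_wes: int = 5, max_germline_vaf: float = 0.01,
                     min_callers_targeted: int = 2, min_alt_targeted: int = 3,
                     min_coverage_barcoded: int = 100,
                     ) -> tuple[pd.DataFrame, dict]:
    """Apply the per-platform consensus elimination rules.

    WES mode eliminates a variant if it was identified by only one caller,
    has total coverage below 30 in every sample, has fewer than 5 alternate
    reads in every sample, shows germline VAF >= 1 %, appears in the
    population database, or is silent / intergenic / intronic.  Targeted
    modes keep variants called by >= 2 callers and mark per-sample detection
    status (alt reads >= 3; the barcoded panel additionally requires total
    coverage >= 100).  Returns the filtered table and a per-rule drop log.
    """
    if mode not in _MODE_COLUMNS:
        raise ValueError(f"unknown mode {mode!r}")
    _require_columns(table, mode)
    df = add_maf(table)
    log: dict[str, int] = {}
    per_variant = df.groupby("variant_id", sort=True)

    if mode == "WES":
        cov = df["ref_reads"] + df["alt_reads"]
        agg = pd.DataFrame({
            "single_caller": per_variant["n_callers"].max() < min_callers_wes,
            "low_coverage_all_samples":
                cov.groupby(df["variant_id"]).max() < min_coverage_wes,
            "low_alt_all_samples":
                per_variant["alt_reads"].max() < min_alt_wes,
            "germline": per_variant["germline_vaf"].max() >= max_germline_vaf,
            "population_db": per_variant["in_population_db"].any(),
            "noncoding_or_silent":
                per_variant["is_silent"].any()
                | per_variant["region_class"].agg(
                    lambda s: s.isin(NONCODING_CLASSES).any()),
        })
        for rule in agg.columns:
            log[rule] = int(agg[rule].sum())
        keep = agg.index[~agg.any(axis=1)]
        out = df[df["variant_id"].isin(keep)].copy()
    else:
        enough_callers = per_variant["n_callers"].max() >= min_callers_targeted
        log["too_few_callers"] = int((~enough_callers).sum())
        out = df[df["variant_id"].isin(
            enough_callers.index[enough_callers])].copy()
        detected = out["alt_reads"] >= min_alt_targeted
        if mode == "targeted_barcoded":
            detected &= (out["ref_reads"] + out["alt_reads"]
                         ) >= min_coverage_barcoded
        out["detected"] = detected
    log["variants_in"] = int(per_variant.ngroups)
    log["variants_out"] = int(out["variant_id"].nunique())
    log["variants_dropped"] = log["variants_in"] - log["variants_out"]
    return out.reset_index(drop=True), log


def delta_maf(table: pd.DataFrame, group_met: list[str],
              group_primary: list[str], min_delta: float = 0.15,
              alpha: float = 0.05, equal_var: bool = False) -> pd.DataFrame:
    """Per-variant MAF shift between metastases and primaries.

    dMAF = mean MAF across the metastasis group minus mean MAF across the
    primary group, with a two-sample two-tailed t-test (Welch by default).
    A variant is 'enriched' iff dMAF >= ``min_delta`` and p <= ``alpha``,
    'depleted' iff dMAF <= -``min_delta`` and p <= ``alpha``, else 'neutral'.
    Variants with fewer than two defined MAFs in either group are
    'untestable'.
    """
    df = add_maf(table)
    overlap = set(group_met) & set(group_primary)
    if overlap:
        raise ValueError(f"samples in both groups: {sorted(overlap)}")
    piv = df.pivot_table(index="variant_id", columns="sample_id",
                         values="maf", aggfunc="first")
    rows = []
    for vid, row in piv.iterrows():
        met = row.reindex(group_met).dropna().to_numpy()
        pri = row.reindex(group_primary).dropna().to_numpy()
        if len(met) < 2 or len(pri) < 2:
            rows.append({"variant_id": vid, "delta_maf": np.nan,
                         "t": np.nan, "p": np.nan, "class": "untestable"})
            continue
        d = float(met.mean() - pri.mean())
        t, p = stats.ttest_ind(met, pri, equal_var=equal_var)
        if np.isnan(t):   # zero variance in both groups
            t, p = 0.0, 1.0
        if d >= min_delta and p <= alpha:
            cls = "enriched"
        elif d <= -min_delta and p <= alpha:
            cls = "depleted"
        else:
            cls = "neutral"
        rows.append({"variant_id": vid, "delta_maf": d, "t": float(t),
                     "p": float(p), "class": cls})
    return pd.DataFrame(rows)


def de_novo_candidates(table: pd.DataFrame, sample_meta: pd.DataFrame,
                       max_targeted_alt_mfp: int = 7,
                       min_alt_detect: int = 3) -> pd.DataFrame:
    """Mutations absent from every primary tumor but detected in one mouse's mets.

    A candidate must show zero alternate WES reads and fewer than
    ``max_targeted_alt_mfp`` alternate deep-sequencing reads in every MFP
    sample (deep-sequenced samples below that cutoff are considered
    non-mutant), and be detected (alt reads >= ``min_alt_detect`` on the
    targeted platform) in at least one metastasis of exactly one mouse — a
    bona fide de novo event is vanishingly unlikely to recur in independent
    animals.
    """
    if "platform" not in table.columns:
        raise ValueError("de novo criteria require the 'platform' column")
    df = add_maf(table)
    meta = sample_meta.set_index("sample_id")
    df = df.join(meta[["mouse", "site"]], on="sample_id")
    mfp = df[df["site"] == "MFP"]
    platforms = set(mfp["platform"])
    if not {"WES", "targeted"} <= platforms:
        raise ValueError(
            "MFP samples must be present on both WES and targeted platforms; "
            f"found {sorted(platforms)}")
    rows = []
    for vid, grp in df.groupby("variant_id", sort=True):
        g_mfp = grp[grp["site"] == "MFP"]
        wes_clean = (g_mfp.loc[g_mfp["platform"] == "WES",
                               "alt_reads"] == 0).all()
        tgt_clean = (g_mfp.loc[g_mfp["platform"] == "targeted",
                               "alt_reads"] < max_targeted_alt_mfp).all()
        mets = grp[(grp["site"] != "MFP") & (grp["platform"] == "targeted")]
        det = mets[mets["alt_reads"] >= min_alt_detect]
        mice = sorted(det["mouse"].unique())
        if wes_clean and tgt_clean and len(mice) == 1 and len(det) >= 1:
            rows.append({"variant_id": vid, "mouse": mice[0],
                         "n_met_detections": int(len(det)),
                         "max_met_maf": float(det["maf"].max())})
    return pd.DataFrame(rows,
                        columns=["variant_id", "mouse", "n_met_detections",
                                 "max_met_maf"])


def repeat_artifact_filter(cooc: pd.DataFrame, fdr: float = 0.05,
                           frac_cut: float = 0.01,
                           ) -> tuple[pd.DataFrame, set, dict]:
    """Flag and discard mutation pairs that co-occur on reads more than chance.

    For each pair the 2x2 table (both, only A, only B, neither) over reads
    spanning both loci is tested for independence with a Pearson chi-square
    (no continuity correction; Fisher's exact test when any expected cell is
    below 5), followed by Benjamini-Hochberg across all testable pairs.  A
    pair is flagged iff q < ``fdr`` and discarded iff additionally
    co-occurring in more than ``frac_cut`` of its spanning reads; both
    members of a discarded pair are removed downstream.
    """
    required = {"mut_a", "mut_b", "n_both", "n_only_a", "n_only_b",
                "n_neither"}
    missing = required - set(cooc.columns)
    if missing:
        raise ValueError(f"co-occurrence table missing columns {missing}")
    pvals, testable_idx, untestable = [], [], []
    for idx, r in cooc.iterrows():
        tab = np.array([[r["n_both"], r["n_only_a"]],
                        [r["n_only_b"], r["n_neither"]]], dtype=float)
        total = tab.sum()
        if total == 0 or (tab.sum(axis=0) == 0).any() \
                or (tab.sum(axis=1) == 0).any():
            untestable.append(idx)
            continue
        expected = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / total
        if (expected < 5).any():
            p = stats.fisher_exact(tab.astype(int))[1]
        else:
            p = stats.chi2_contingency(tab, correction=False)[1]
        pvals.append(p)
        testable_idx.append(idx)
    out = cooc.copy()
    out["p"] = np.nan
    out["q"] = np.nan
    out["flagged"] = False
    out["discarded"] = False
    if pvals:
        q = multipletests(pvals, method="fdr_bh")[1]
        out.loc[testable_idx, "p"] = pvals
        out.loc[testable_idx, "q"] = q
        total = (out["n_both"] + out["n_only_a"] + out["n_only_b"]
                 + out["n_neither"])
        out["flagged"] = (out["q"] < fdr).fillna(False)
        frac = out["n_both"] / total.replace(0, np.nan)
        out["discarded"] = out["flagged"] & (frac > frac_cut)
    discarded_mutations = set(out.loc[out["discarded"], "mut_a"]) | \
        set(out.loc[out["discarded"], "mut_b"])
    log = {"n_pairs": int(len(cooc)), "n_testable": len(testable_idx),
           "n_untestable": len(untestable),
           "n_flagged": int(out["flagged"].sum()),
           "n_discarded_pairs": int(out["discarded"].sum()),
           "n_discarded_mutations": len(discarded_mutations)}
    return out, discarded_mutations, log


@dataclass(frozen=True)
class QpcrMeasurement:
    dct_human: float
    dct_mouse: float


def human_fraction(q: QpcrMeasurement) -> float:
    """Percent human genomic DNA from species-specific qPCR delta-Ct values:

    100 * 2^(-dCt_human) / (2^(-dCt_human) + 2^(-dCt_mouse)).
    """
    h = np.exp2(-q.dct_human)
    m = np.exp2(-q.dct_mouse)
    return float(100.0 * h / (h + m))


def sample_similarity(table: pd.DataFrame,
                      ) -> tuple[pd.DataFrame, list[str], np.ndarray]:
    """Pairwise Pearson correlation of MAF profiles and complete-linkage order.

    Correlations use the MAFs defined in both samples of a pair; the
    dendrogram is built from Euclidean distances between MAF vectors over
    variants defined in every sample.  Returns (correlation matrix, leaf
    order, scipy linkage matrix).  Pairs with a constant MAF vector get NaN
    correlation.
    """
    df = add_maf(table)
    piv = df.pivot_table(index="variant_id", columns="sample_id",
                         values="maf", aggfunc="first")
    piv = piv[sorted(piv.columns)]
    samples = list(piv.columns)
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    corr = piv.corr(method="pearson", min_periods=2)
    complete = piv.dropna(axis=0)
    if len(complete) < 2:
        raise ValueError("need >= 2 variants with MAF defined in all samples")
    dist = pdist(complete.to_numpy().T, metric="euclidean")
    link = hierarchy.linkage(dist, method="complete")
    order = [samples[i] for i in hierarchy.leaves_list(link)]
    return corr, order, link
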