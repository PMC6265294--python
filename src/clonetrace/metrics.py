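"""Clonal-architecture statistics from a barcode-pair count matrix.

Implements the descriptive statistics used to characterize the clonal
bottleneck of metastasis in barcoded xenografts: dominant barcodes (the
smallest set of most-abundant barcodes covering >= 95 % of a sample's reads),
Shannon diversity in nats, seeding clones (barcodes detected in both a
metastasis and its matched primary MFP tumor), tumor-initiating-cell (TIC)
frequency, Jaccard overlap, per-site group comparisons, and log-CPM
distribution summaries.  Barcode identity is only comparable within a mouse;
cross-mouse comparisons are refused.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import CountMatrix

METASTATIC_SITES = ("lung", "liver", "brain")

__all__ = ["SampleMeta", "ClonalReport", "dominant_set", "shannon_diversity",
           "seeding_clones", "tic_frequency", "jaccard_index",
           "group_compare", "barcode_density_summary", "clonal_report"]


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    mouse: str
    site: str      # MFP, lung, liver, brain or reference
    lesion: str


def load_sample_sheet(path) -> list[SampleMeta]:
    df = pd.read_csv(path)
    metas = [SampleMeta(**row[["sample_id", "mouse", "site", "lesion"]])
             for _, row in df.iterrows()]
    ids = [m.sample_id for m in metas]
    if len(set(ids)) != len(ids):
        raise ValueError("sample ids must be unique")
    return metas


def dominant_set(cpm_column: pd.Series, threshold: float = 0.95,
                 inclusive: bool = True) -> set[str]:
    """Barcodes forming the top ``threshold`` fraction of a sample's mass.

    Barcodes are ranked by CPM descending (ties broken by barcode id
    ascending) and the smallest prefix whose cumulative CPM reaches
    ``threshold`` of the total is returned.  ``inclusive=False`` excludes the
    barcode that crosses the threshold.
    """
    col = cpm_column[cpm_column > 0]
    if col.empty:
        raise ValueError("empty sample: no barcode has positive CPM")
    ranked = col.sort_index().sort_values(ascending=False, kind="stable")
    cum = ranked.cumsum() / ranked.sum()
    # positions strictly before the first crossing, plus the crossing barcode
    n_before = int((cum < threshold - 1e-12).sum())
    n = n_before + 1 if inclusive else max(n_before, 1)
    n = min(n, len(ranked))
    return set(ranked.index[:n])


def shannon_diversity(counts_column: pd.Series) -> float:
    """Shannon diversity H = -sum p_i ln p_i in nats, over all detected barcodes."""
    counts = np.asarray(counts_column, dtype=float)
    counts = counts[counts > 0]
    total = counts.sum()
    if total <= 0:
        raise ValueError("cannot compute diversity of an empty sample")
    p = counts / total
    return float(-(p * np.log(p)).sum())


def seeding_clones(met_counts: pd.Series, mfp_counts: pd.Series,
                   met_mouse: str | None = None, mfp_mouse: str | None = None,
                   min_count: int = 1) -> set[str]:
    """Barcodes detected (count >= ``min_count``) in both a metastasis and its MFP.

    When mouse labels are given the comparison is refused across mice:
    barcode identity is meaningless between animals engrafted with
    independently labeled cells.
    """
    if met_mouse is not None and mfp_mouse is not None \
            and met_mouse != mfp_mouse:
        raise ValueError(
            f"cross-mouse comparison refused ({met_mouse} vs {mfp_mouse}): "
            "barcodes are not comparable across mice")
    met = set(met_counts[met_counts >= min_count].index)
    mfp = set(mfp_counts[mfp_counts >= min_count].index)
    return met & mfp


def tic_frequency(tumor_unique: int, reference_unique: int) -> float:
    """Percent of reference clones detected in the tumor: 100 * tumor / reference."""
    if reference_unique == 0:
        raise ValueError("reference contains no barcodes")
    pct = 100.0 * tumor_unique / reference_unique
    if pct > 100.0:
        warnings.warn("tumor has more unique barcodes than the reference; "
                      "frequency exceeds 100%")
    return pct


def jaccard_index(set_a: set, set_b: set) -> float:
    union = set_a | set_b
    if not union:
        warnings.warn("Jaccard of two empty sets defined as 0")
        return 0.0
    return len(set_a & set_b) / len(union)


def group_compare(values_a, values_b, equal_var: bool = False,
                  ) -> tuple[float, float]:
    """Two-sample two-tailed t-test (Welch by default) on per-sample statistics."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    if np.isnan(t):  # both groups constant and identical
        return 0.0, 1.0
    return float(t), float(p)


def barcode_density_summary(cpm_column: pd.Series, threshold: float = 0.95,
                            bins: int = 50) -> dict:
    """log10-CPM histogram over a sample's dominant barcodes."""
    dom = dominant_set(cpm_column, threshold)
    logs = np.log10(cpm_column[sorted(dom)].astype(float))
    hist, edges = np.histogram(logs, bins=bins)
    return {"log10_cpm": logs, "hist": hist, "bin_edges": edges}


def max_cpm_table(cpm: pd.DataFrame, metas: list[SampleMeta],
                  mouse: str) -> pd.Series:
    """Per-barcode maximum CPM across all of one mouse's tumor samples."""
    samples = [m.sample_id for m in metas
               if m.mouse == mouse and m.site != "reference"]
    if not samples:
        raise ValueError(f"no tumor samples for mouse {mouse}")
    sub = cpm[samples]
    return sub.max(axis=1)[sub.max(axis=1) > 0]


@dataclass
class ClonalReport:
    per_sample: pd.DataFrame      # n_unique, n_dominant, shannon_nats
    per_metastasis: pd.DataFrame  # n_seeding, pct_* , jaccard_vs_mfp
    max_cpm: dict[str, pd.Series]

    def to_files(self, outdir) -> None:
        from pathlib import Path
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.per_sample.to_csv(outdir / "per_sample.tsv", sep="\t",
                               index=False)
        self.per_metastasis.to_csv(outdir / "per_metastasis.tsv", sep="\t",
                                   index=False)
        summary = {
            "n_samples": int(len(self.per_sample)),
            "mean_shannon_nats":
                float(self.per_sample["shannon_nats"].mean()),
            "mean_n_dominant": float(self.per_sample["n_dominant"].mean()),
        }
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)


def clonal_report(matrix: CountMatrix, metas: list[SampleMeta],
                  threshold: float = 0.95, min_count: int = 1,
                  ) -> ClonalReport:
    """Assemble the full per-sample / per-metastasis clonal report.

    Every metastasis is compared against the single MFP sample of its own
    mouse; a mouse with zero or multiple MFP samples makes its metastases
    non-comparable and raises.
    """
    by_id = {m.sample_id: m for m in metas}
    counts, cpm = matrix.counts, matrix.cpm
    rows = []
    for s in counts.columns:
        col = counts[s]
        meta = by_id.get(s)
        n_unique = int((col > 0).sum())
        if n_unique == 0:
            rows.append({"sample_id": s, "mouse": meta.mouse if meta else "",
                         "site": meta.site if meta else "",
                         "n_unique_barcodes": 0, "n_dominant": 0,
                         "shannon_nats": np.nan})
            continue
        rows.append({
            "sample_id": s,
            "mouse": meta.mouse if meta else "",
            "site": meta.site if meta else "",
            "n_unique_barcodes": n_unique,
            "n_dominant": len(dominant_set(cpm[s], threshold)),
            "shannon_nats": shannon_diversity(col),
        })
    per_sample = pd.DataFrame(rows)

    met_rows = []
    mice = {m.mouse for m in metas}
    for mouse in sorted(mice):
        mfp_samples = [m.sample_id for m in metas
                       if m.mouse == mouse and m.site == "MFP"]
        mets = [m for m in metas
                if m.mouse == mouse and m.site in METASTATIC_SITES]
        if not mets:
            continue
        if len(mfp_samples) != 1:
            raise ValueError(
                f"mouse {mouse} has {len(mfp_samples)} MFP samples; "
                "metastasis comparisons need exactly one")
        mfp = mfp_samples[0]
        mfp_detected = set(counts.index[counts[mfp] >= min_count])
        mfp_unique = len(mfp_detected)
        for m in mets:
            seeding = seeding_clones(counts[m.sample_id], counts[mfp],
                                     m.mouse, mouse, min_count)
            dom_met = dominant_set(cpm[m.sample_id], threshold)
            dom_mfp = dominant_set(cpm[mfp], threshold)
            met_rows.append({
                "sample_id": m.sample_id, "mouse": mouse, "site": m.site,
                "n_seeding": len(seeding),
                "pct_dominant_of_mfp": 100 * len(dom_met) / mfp_unique,
                "pct_seeding_of_mfp": 100 * len(seeding) / mfp_unique,
                "jaccard_vs_mfp": jaccard_index(dom_met, dom_mfp),
            })
    per_metastasis = pd.DataFrame(met_rows)
    max_cpm = {mouse: max_cpm_table(cpm, metas, mouse) for mouse in
               sorted(mice)
               if any(m.mouse == mouse and m.site != "reference"
                      for m in metas)}
    return ClonalReport(per_sample=per_sample, per_metastasis=per_metastasis,
                        max_cpm=max_cpm)
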