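"""Robustness testing of mutation clusters from MCMC assignment traces.

A Dirichlet-process clustering of variants (e.g. PyClone) yields, per MCMC
iteration, a cluster label for every variant.  Some reported clusters are
unstable: their members drift between clusters across iterations.  This
module post-processes the trace: it computes the pairwise co-assignment
probability matrix (fraction of post-burn-in iterations in which two variants
share a label), discretizes within-cluster pair probabilities into
below (p < 0.5), low (0.5 <= p < 0.9) and high (0.9 <= p <= 1) categories,
and tests each candidate cluster's category distribution against the
trace-wide baseline with a chi-square goodness-of-fit test, Bonferroni-
corrected over clusters.  Clusters with adjusted p < 0.05 are accepted as
robust.

It does not run the MCMC itself; upstream settings (e.g. 10,000 iterations
with 2,500 burn-in, beta-binomial density) are context, not computed here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synth import AssignmentTrace

__all__ = ["AssignmentTrace", "StabilityReport", "coassignment_matrix",
           "categorize_pairs", "test_cluster_robustness", "read_trace_tsv"]

DEFAULT_BURN_IN = 2500
CATEGORIES = ("below", "low", "high")


def read_trace_tsv(path) -> AssignmentTrace:
    """Load a long-form (iteration, variant_id, cluster_label) TSV."""
    df = pd.read_csv(path, sep="\t")
    piv = df.pivot_table(index="iteration", columns="variant_id",
                         values="cluster_label", aggfunc="first")
    if piv.isna().any().any():
        raise ValueError("every variant must be labeled at every iteration")
    return AssignmentTrace(labels=piv.to_numpy(),
                           variant_ids=tuple(piv.columns))


def write_trace_tsv(trace: AssignmentTrace, path) -> None:
    it, v = np.meshgrid(np.arange(trace.n_iterations),
                        np.arange(len(trace.variant_ids)), indexing="ij")
    pd.DataFrame({
        "iteration": it.ravel(),
        "variant_id": np.array(trace.variant_ids)[v.ravel()],
        "cluster_label": trace.labels.ravel(),
    }).to_csv(path, sep="\t", index=False)


def coassignment_matrix(trace: AssignmentTrace, burn_in: int = 0,
                        ) -> pd.DataFrame:
    """P[i, j] = fraction of post-burn-in iterations with label(i) == label(j)."""
    if burn_in >= trace.n_iterations:
        raise ValueError(
            f"burn_in {burn_in} >= {trace.n_iterations} iterations")
    labels = trace.labels[burn_in:]
    n_iter, n_var = labels.shape
    acc = np.zeros((n_var, n_var), dtype=np.int64)
    chunk = max(1, int(2e7) // (n_var * n_var))
    for start in range(0, n_iter, chunk):
        block = labels[start:start + chunk]
        acc += (block[:, :, None] == block[:, None, :]).sum(axis=0)
    P = acc / n_iter
    return pd.DataFrame(P, index=trace.variant_ids,
                        columns=trace.variant_ids)


def _categorize(values: np.ndarray) -> np.ndarray:
    """Counts in (below, low, high) with the half-open/closed bin boundaries."""
    below = int((values < 0.5).sum())
    low = int(((values >= 0.5) & (values < 0.9)).sum())
    high = int((values >= 0.9).sum())
    return np.array([below, low, high])


def _pair_values(P: pd.DataFrame, members: list) -> np.ndarray:
    idx = [P.index.get_loc(m) for m in members]
    sub = P.to_numpy()[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    return sub[iu]


def categorize_pairs(P: pd.DataFrame, members) -> dict[str, int]:
    """Category counts over the unordered within-member pairs of a cluster."""
    members = sorted(members)
    if len(members) < 2:
        raise ValueError("cluster is too small: needs >= 2 members")
    counts = _categorize(_pair_values(P, members))
    return dict(zip(CATEGORIES, counts.tolist()))


def modal_clusters(trace: AssignmentTrace, burn_in: int = 0,
                   ) -> dict[object, list]:
    """Candidate clusters: each variant's most frequent post-burn-in label.

    Ties are broken by the smallest label.
    """
    if burn_in >= trace.n_iterations:
        raise ValueError(
            f"burn_in {burn_in} >= {trace.n_iterations} iterations")
    labels = trace.labels[burn_in:]
    clusters: dict[object, list] = {}
    for j, vid in enumerate(trace.variant_ids):
        vals, counts = np.unique(labels[:, j], return_counts=True)
        modal = vals[counts == counts.max()].min()
        clusters.setdefault(modal, []).append(vid)
    return clusters


@dataclass
class StabilityReport:
    table: pd.DataFrame          # one row per candidate cluster
    retained_variants: list
    n_candidates: int
    baseline: np.ndarray         # category frequencies of the null

    @property
    def robust_clusters(self) -> list:
        return self.table.loc[self.table["robust"], "cluster"].tolist()


def test_cluster_robustness(trace: AssignmentTrace,
                            burn_in: int = DEFAULT_BURN_IN,
                            alpha: float = 0.05,
                            baseline: str = "global") -> StabilityReport:
    """Chi-square robustness test of every candidate cluster.

    Candidate clusters are the modal post-burn-in assignments.  For each
    cluster with >= 2 members, the within-cluster pair category counts
    (below/low/high co-assignment probability) are compared to the expected
    counts under the null that category frequencies follow the baseline:
    either the frequencies over ALL unordered variant pairs in the trace
    ('global', default) or a uniform distribution over categories
    ('uniform').  Raw p-values are Bonferroni-corrected over the candidate
    clusters; a cluster is robust iff adjusted p < ``alpha``.  Categories
    with zero expected count are merged into the adjacent lower bin.
    """
    if burn_in >= trace.n_iterations:
        raise ValueError(
            f"burn_in {burn_in} >= {trace.n_iterations} iterations")
    P = coassignment_matrix(trace, burn_in)
    all_pairs = _pair_values(P, list(P.index))
    if baseline == "global":
        global_counts = _categorize(all_pairs)
        freqs = global_counts / global_counts.sum()
    elif baseline == "uniform":
        freqs = np.full(3, 1 / 3)
    else:
        raise ValueError(f"unknown baseline {baseline!r}")

    clusters = modal_clusters(trace, burn_in)
    n_candidates = len(clusters)
    rows = []
    for label in sorted(clusters, key=str):
        members = sorted(clusters[label])
        if len(members) < 2:
            rows.append({"cluster": label, "n_members": len(members),
                         "below": 0, "low": 0, "high": 0,
                         "chi2": np.nan, "p_raw": np.nan, "p_adj": np.nan,
                         "robust": False, "reason": "too small"})
            continue
        obs = _categorize(_pair_values(P, members))
        exp = freqs * obs.sum()
        reason = ""
        if (exp == 0).any():
            # merge zero-expectation bins into 'below+low' so the partition
            # stays total
            obs = np.array([obs[0] + obs[1], obs[2]])
            exp = np.array([exp[0] + exp[1], exp[2]])
            reason = "merged below+low (zero expected count)"
        keep = ~((exp == 0) & (obs == 0))
        obs, exp = obs[keep], exp[keep]
        if ((exp == 0) & (obs > 0)).any():
            chi2, p = np.inf, 0.0
        elif len(obs) < 2:
            chi2, p = 0.0, 1.0
        else:
            chi2, p = stats.chisquare(obs, f_exp=exp)
        p_adj = min(1.0, float(p) * n_candidates)
        rows.append({"cluster": label, "n_members": len(members),
                     "below": int(_categorize(_pair_values(P, members))[0]),
                     "low": int(_categorize(_pair_values(P, members))[1]),
                     "high": int(_categorize(_pair_values(P, members))[2]),
                     "chi2": float(chi2), "p_raw": float(p), "p_adj": p_adj,
                     "robust": p_adj < alpha, "reason": reason})
    table = pd.DataFrame(rows)
    retained = sorted(
        v for label in table.loc[table["robust"], "cluster"]
        for v in clusters[label])
    return StabilityReport(table=table, retained_variants=retained,
                           n_candidates=n_candidates, baseline=freqs)
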