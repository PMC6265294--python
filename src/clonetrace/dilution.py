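"""Single-hit Poisson limiting-dilution analysis.

Estimates the frequency f of biologically active cells (metastasis-initiating
or tumor-initiating) from dose/response transplantation tables.  Under the
single-hit model a transplant of ``dose`` cells is positive with probability
1 - exp(-f * dose); the log-likelihood over assay rows is

    l(f) = sum_rows [ positive * ln(1 - exp(-f * dose))
                      - f * dose * (tested - positive) ].

The maximum-likelihood estimate is found by bounded 1-D maximization on
log(f); the default 95 % confidence interval is a Wald interval on log(f)
from the observed information (the interval a complementary-log-log binomial
GLM with log-dose offset would give), with a profile-likelihood interval
available via ``ci_method='profile'``.  Degenerate assays (no positives, or
all transplants positive) admit only a one-sided bound and are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = ["DilutionAssay", "FrequencyEstimate", "fit_single_hit",
           "recover_from_simulation", "TABLE1"]

#: Published limiting-dilution transplantation counts, per PDX model and
#: organ: list of (cells transplanted, organs assayed, organs positive).
TABLE1: dict[tuple[str, str], list[tuple[int, int, int]]] = {
    ("PIM1-CBRluc", "lung"): [(100, 4, 4), (10, 6, 5)],
    ("PIM1-CBRluc", "liver"): [(100, 3, 1), (10, 3, 2)],
    ("PIM1-CBRluc", "brain"): [(100, 3, 1), (10, 3, 1)],
    ("BC3_A2", "lung"): [(100, 5, 3), (10, 8, 0)],
}

_Z95 = 1.959963984540054
_CHI2_95_HALF = 1.9207294  # chi2(1, 0.95) / 2, profile-likelihood drop


@dataclass(frozen=True)
class DilutionAssay:
    """Rows of (dose in cells, number tested, number positive)."""

    rows: tuple[tuple[int, int, int], ...]

    def __post_init__(self):
        if not self.rows:
            raise ValueError("assay needs at least one row")
        for dose, tested, positive in self.rows:
            if dose < 1:
                raise ValueError("dose must be >= 1 cell")
            if not 0 <= positive <= tested:
                raise ValueError(
                    f"positives must lie in [0, tested]: {positive}/{tested}")

    @classmethod
    def from_csv(cls, path) -> "DilutionAssay":
        df = pd.read_csv(path)
        return cls(tuple(
            (int(r["dose"]), int(r["tested"]), int(r["positive"]))
            for _, r in df.iterrows()))

    def arrays(self):
        a = np.asarray(self.rows, dtype=float)
        return a[:, 0], a[:, 1], a[:, 2]


@dataclass(frozen=True)
class FrequencyEstimate:
    f_hat: float
    ci_low: float
    ci_high: float
    flag: str | None = None   # None | 'all_negative' | 'all_positive'

    @property
    def percent(self) -> float:
        return 100.0 * self.f_hat

    @property
    def percent_1dp(self) -> float:
        return round(self.percent, 1)

    @property
    def ci_percent(self) -> tuple[float, float]:
        return 100.0 * self.ci_low, 100.0 * self.ci_high


def _loglik(theta: float, dose, tested, pos) -> float:
    f = np.exp(theta)
    lam = f * dose
    with np.errstate(divide="ignore"):
        log_p = np.log1p(-np.exp(-lam))
    return float((pos * log_p - lam * (tested - pos)).sum())


def fit_single_hit(assay: DilutionAssay, ci_method: str = "wald",
                   f_max: float = 1.0) -> FrequencyEstimate:
    """Maximum-likelihood single-hit frequency with a 95 % CI.

    ``ci_method`` is 'wald' (normal interval on log f from the observed
    information) or 'profile' (likelihood-ratio interval).
    """
    dose, tested, pos = assay.arrays()
    total_pos = pos.sum()
    total_neg = (tested - pos).sum()
    if total_pos == 0:
        # no response at any dose: only an upper 95 % bound is estimable
        upper = np.log(20.0) / float((dose * tested).sum())
        return FrequencyEstimate(f_hat=np.nan, ci_low=0.0,
                                 ci_high=min(upper, f_max),
                                 flag="all_negative")
    if total_neg == 0:
        # every transplant positive: likelihood increases in f; lower bound
        def drop(theta):
            return _loglik(theta, dose, tested, pos) - np.log(0.05)
        lo = optimize.brentq(drop, np.log(1e-12), np.log(f_max), xtol=1e-12)
        return FrequencyEstimate(f_hat=f_max, ci_low=np.exp(lo),
                                 ci_high=f_max, flag="all_positive")

    res = optimize.minimize_scalar(
        lambda th: -_loglik(th, dose, tested, pos),
        bounds=(np.log(1e-9), np.log(f_max)), method="bounded",
        options={"xatol": 1e-12})
    if not np.isfinite(res.fun):
        raise RuntimeError(f"single-hit optimization failed: {res}")
    theta_hat = float(res.x)
    f_hat = float(np.exp(theta_hat))
    ll_hat = -float(res.fun)

    if ci_method == "wald":
        h = 1e-5
        info = -(_loglik(theta_hat + h, dose, tested, pos)
                 - 2 * ll_hat
                 + _loglik(theta_hat - h, dose, tested, pos)) / h ** 2
        if info <= 0:
            raise RuntimeError("non-positive observed information")
        se = 1.0 / np.sqrt(info)
        lo, hi = theta_hat - _Z95 * se, theta_hat + _Z95 * se
    elif ci_method == "profile":
        target = ll_hat - _CHI2_95_HALF

        def gap(th):
            return _loglik(th, dose, tested, pos) - target

        lo = optimize.brentq(gap, np.log(1e-12), theta_hat, xtol=1e-12)
        hi_bracket = min(np.log(f_max), theta_hat + 20)
        if gap(hi_bracket) > 0:   # CI runs into the f <= f_max boundary
            hi = hi_bracket
        else:
            hi = optimize.brentq(gap, theta_hat, hi_bracket, xtol=1e-12)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return FrequencyEstimate(f_hat=f_hat,
                             ci_low=float(np.exp(lo)),
                             ci_high=float(min(np.exp(hi), f_max)))


def recover_from_simulation(true_f: float, design: list[tuple[int, int]],
                            n_sims: int = 1000, seed: int = 0,
                            ci_method: str = "wald") -> dict:
    """Parametric-bootstrap validation of the single-hit estimator.

    Simulates positives ~ Binomial(tested, 1 - exp(-f * dose)) for each
    (dose, tested) design row and reports the mean bias of the MLE and the
    empirical coverage of the 95 % CI over the estimable replicates.
    """
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100 for a stable coverage figure")
    rng = np.random.default_rng(seed)
    doses = np.array([d for d, _ in design], dtype=float)
    tested = np.array([t for _, t in design])
    p = 1.0 - np.exp(-true_f * doses)
    estimates, covered, degenerate = [], 0, 0
    for _ in range(n_sims):
        pos = rng.binomial(tested, p)
        assay = DilutionAssay(tuple(
            (int(d), int(t), int(x))
            for d, t, x in zip(doses, tested, pos)))
        est = fit_single_hit(assay, ci_method=ci_method)
        if est.flag is not None:
            degenerate += 1
            continue
        estimates.append(est.f_hat)
        if est.ci_low <= true_f <= est.ci_high:
            covered += 1
    n_ok = len(estimates)
    return {
        "true_f": true_f,
        "n_sims": n_sims,
        "n_estimable": n_ok,
        "n_degenerate": degenerate,
        "mean_bias": float(np.mean(estimates) - true_f) if n_ok else np.nan,
        "coverage": covered / n_ok if n_ok else np.nan,
    }
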