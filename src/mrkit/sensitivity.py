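"""Heterogeneity, pleiotropy, outlier and influence diagnostics.

The battery mirrors standard summary-data MR practice:

* Cochran's Q against the fixed-effect IVW estimate (heterogeneity);
* the MR-Egger intercept (average directional pleiotropy);
* MR-PRESSO: a simulation-based global heterogeneity test with per-SNP
  outlier detection and a distortion assessment after outlier removal;
* leave-one-out re-estimation (single-SNP influence);
* a funnel table of per-SNP ratios against their precisions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError
from .estimators import (EggerResult, MRResult, P_FLOOR, RatioEstimate, ivw,
                         mr_egger, wald_ratio)
from .summary_data import HarmonizedInstrument


def heterogeneity_pvalue(q: float, df: int) -> float:
    """Upper-tail chi-square probability of a heterogeneity statistic."""
    if df < 1:
        raise DomainError("df must be >= 1")
    return float(stats.chi2.sf(q, df))


def egger_intercept_pvalue(intercept: float, se: float, n_snp: int) -> float:
    """Two-sided t test (J - 2 df) for the MR-Egger intercept."""
    if n_snp < 3:
        raise DomainError("needs at least 3 instruments")
    if not se > 0:
        raise DomainError("se must be positive")
    return float(max(2.0 * stats.t.sf(abs(intercept / se), n_snp - 2),
                     P_FLOOR))


def cochran_q(ratios: Sequence[RatioEstimate]) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity test of the Wald ratios.

    Q = sum_j w_j (theta_j - theta_IVW_fixed)^2 with w_j = sigma_j^-2,
    referred to chi-square with J - 1 degrees of freedom.
    """
    j = len(ratios)
    if j < 2:
        raise DomainError("Cochran's Q requires at least 2 ratios")
    theta = np.array([r.theta for r in ratios])
    w = np.array([r.se_theta for r in ratios]) ** -2.0
    pooled = float(np.sum(w * theta) / np.sum(w))
    q = float(np.sum(w * (theta - pooled) ** 2))
    return q, j - 1, heterogeneity_pvalue(q, j - 1)


@dataclass
class EggerInterceptTest:
    intercept: float
    se: float
    pval: float
    directional_pleiotropy: bool
    n_snp: int


def egger_intercept_test(instruments: Sequence[HarmonizedInstrument],
                         alpha: float = 0.05) -> EggerInterceptTest:
    """Directional-pleiotropy test via the MR-Egger intercept."""
    egger = mr_egger(instruments)
    return EggerInterceptTest(
        intercept=egger.intercept, se=egger.intercept_se,
        pval=egger.intercept_pval,
        directional_pleiotropy=egger.intercept_pval < alpha,
        n_snp=egger.n_snp,
    )


@dataclass
class LeaveOneOutResult:
    """IVW re-estimates with each instrument excluded in turn."""

    table: pd.DataFrame  # columns: SNP, beta, se, ci_low, ci_high, pval
    full: MRResult
    stable: bool


def leave_one_out(instruments: Sequence[HarmonizedInstrument],
                  model: str = "multiplicative_random",
                  second_order_se: bool = False) -> LeaveOneOutResult:
    """Re-run IVW J times, each time without one instrument.

    The ``stable`` flag is true when every leave-one-out estimate keeps the
    sign of the full estimate and every leave-one-out CI overlaps the full
    CI — a conservative summary of "no single SNP drives the result".
    """
    j = len(instruments)
    if j < 3:
        raise DomainError("leave-one-out requires at least 3 instruments")
    ratios = [wald_ratio(i, second_order_se) for i in instruments]
    full = ivw(ratios, model)
    rows = []
    stable = True
    for k, inst in enumerate(instruments):
        sub = ivw(ratios[:k] + ratios[k + 1:], model)
        rows.append({"SNP": inst.snp_id, "beta": sub.beta, "se": sub.se,
                     "ci_low": sub.ci_low, "ci_high": sub.ci_high,
                     "pval": sub.pval})
        same_sign = math.copysign(1, sub.beta) == math.copysign(1, full.beta)
        overlaps = sub.ci_low <= full.ci_high and full.ci_low <= sub.ci_high
        stable = bool(stable and same_sign and overlaps)
    return LeaveOneOutResult(pd.DataFrame(rows), full, stable)


def funnel_table(ratios: Sequence[RatioEstimate]) -> pd.DataFrame:
    """Per-SNP (theta, precision = 1/se) table, sorted by theta."""
    df = pd.DataFrame([{
        "SNP": r.snp_id, "theta": r.theta, "precision": 1.0 / r.se_theta,
    } for r in ratios])
    return df.sort_values("theta", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# MR-PRESSO
# ---------------------------------------------------------------------------

@dataclass
class PressoResult:
    """MR-PRESSO global, outlier and distortion test results."""

    global_rss: float
    global_pval: float
    outlier_pvals: dict[str, float]  # Bonferroni-adjusted, capped at 1
    outlier_ids: list[str]
    k_sim: int
    distortion_pval: float | None = None
    corrected_estimate: MRResult | None = None


def _loo_slopes(be: np.ndarray, bo: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out intercept-free WLS slopes for every SNP at once.

    Works on 2-D inputs (rows = simulated datasets) as well as 1-D.
    """
    s1 = (w * be * be).sum(axis=-1, keepdims=True)
    s2 = (w * be * bo).sum(axis=-1, keepdims=True)
    return (s2 - w * be * bo) / (s1 - w * be * be)


def mr_presso(instruments: Sequence[HarmonizedInstrument],
              k_sim: int = 1000, seed: int = 20220405,
              outlier_alpha: float = 0.05,
              ivw_model: str = "multiplicative_random") -> PressoResult:
    """MR-PRESSO: pleiotropy residual sum and outlier test.

    Global test: the observed weighted residual sum of squares
    RSS = sum_j w_j (beta_out_j - slope_(-j) * beta_exp_j)^2, with w_j =
    se_out_j^-2 and slope_(-j) the leave-one-out IVW slope, is compared
    against ``k_sim`` simulated datasets drawn under the no-pleiotropy model
    (beta_out_j* ~ N(slope_(-j)*beta_exp_j, se_out_j), beta_exp_j* ~
    N(beta_exp_j, se_exp_j)); the empirical p has resolution 1/(k_sim+1).

    Outlier test: each SNP's observed weighted squared residual is compared
    to its own simulated distribution; empirical p-values are Bonferroni
    multiplied by J, and SNPs below ``outlier_alpha`` are flagged.

    Distortion test (only when outliers are found): the shift of the IVW
    estimate after removing the flagged SNPs is compared to the shifts
    produced by removing equally many SNPs chosen at random.
    """
    j = len(instruments)
    if j < 4:
        raise DomainError("MR-PRESSO requires >= 4 instruments")
    if k_sim < 100:
        raise DomainError("k_sim must be >= 100")
    be = np.array([i.beta_exp for i in instruments])
    bo = np.array([i.beta_out for i in instruments])
    se_e = np.array([i.se_exp for i in instruments])
    se_o = np.array([i.se_out for i in instruments])
    w = se_o ** -2.0
    ids = [i.snp_id for i in instruments]

    slope_loo = _loo_slopes(be, bo, w)
    resid_obs = bo - slope_loo * be
    comp_obs = w * resid_obs ** 2
    rss_obs = float(comp_obs.sum())

    rng = np.random.default_rng(seed)
    be_sim = be + se_e * rng.standard_normal((k_sim, j))
    bo_sim = slope_loo * be + se_o * rng.standard_normal((k_sim, j))
    slope_sim = _loo_slopes(be_sim, bo_sim, w)
    comp_sim = w * (bo_sim - slope_sim * be_sim) ** 2
    rss_sim = comp_sim.sum(axis=1)

    global_pval = (1.0 + float((rss_sim >= rss_obs).sum())) / (k_sim + 1.0)
    raw_p = (1.0 + (comp_sim >= comp_obs[None, :]).sum(axis=0)) / (k_sim + 1.0)
    adj_p = np.minimum(raw_p * j, 1.0)
    outlier_ids = [ids[i] for i in range(j) if adj_p[i] < outlier_alpha]
    result = PressoResult(
        global_rss=rss_obs, global_pval=global_pval,
        outlier_pvals={ids[i]: float(adj_p[i]) for i in range(j)},
        outlier_ids=outlier_ids, k_sim=k_sim,
    )

    if outlier_ids and j - len(outlier_ids) >= 1:
        keep = [i for i in range(j) if ids[i] not in set(outlier_ids)]
        ratios_all = [wald_ratio(i) for i in instruments]
        beta_all = ivw(ratios_all, ivw_model).beta
        corrected = ivw([ratios_all[i] for i in keep], ivw_model)
        d_obs = abs(beta_all - corrected.beta)
        n_out = len(outlier_ids)
        d_sim = np.empty(k_sim)
        for s in range(k_sim):
            drop = rng.choice(j, size=n_out, replace=False)
            sub = [ratios_all[i] for i in range(j) if i not in set(drop)]
            d_sim[s] = abs(beta_all - ivw(sub, ivw_model).beta)
        result.distortion_pval = (1.0 + float((d_sim >= d_obs).sum())) \
            / (k_sim + 1.0)
        result.corrected_estimate = corrected
    return result


# ---------------------------------------------------------------------------
# Assembled report
# ---------------------------------------------------------------------------

@dataclass
class SensitivityConfig:
    k_sim: int = 1000
    seed: int = 20220405
    outlier_alpha: float = 0.05
    run_presso: bool = True
    ivw_model: str = "multiplicative_random"


@dataclass
class SensitivityReport:
    q_stat: float
    q_df: int
    q_pval: float
    egger_intercept: float
    egger_intercept_se: float
    egger_intercept_pval: float
    presso: PressoResult | None
    loo: LeaveOneOutResult
    funnel: pd.DataFrame

    def to_json_dict(self) -> dict:
        d = {
            "cochran_q": {"q": self.q_stat, "df": self.q_df,
                          "pval": self.q_pval},
            "egger_intercept": {
                "intercept": self.egger_intercept,
                "se": self.egger_intercept_se,
                "pval": self.egger_intercept_pval,
            },
            "leave_one_out_stable": self.loo.stable,
        }
        if self.presso is not None:
            d["mr_presso"] = {
                "global_rss": self.presso.global_rss,
                "global_pval": self.presso.global_pval,
                "outlier_ids": self.presso.outlier_ids,
                "outlier_pvals": self.presso.outlier_pvals,
                "distortion_pval": self.presso.distortion_pval,
                "k_sim": self.presso.k_sim,
            }
            if self.presso.corrected_estimate is not None:
                c = self.presso.corrected_estimate
                d["mr_presso"]["corrected_estimate"] = {
                    "beta": c.beta, "se": c.se, "pval": c.pval,
                    "n_snp": c.n_snp,
                }
        return d


def run_sensitivity(instruments: Sequence[HarmonizedInstrument],
                    config: SensitivityConfig | None = None,
                    ) -> SensitivityReport:
    """Run the full diagnostic battery on a filtered instrument set."""
    cfg = config or SensitivityConfig()
    ratios = [wald_ratio(i) for i in instruments]
    q, df, q_p = cochran_q(ratios)
    egger: EggerResult = mr_egger(instruments)
    presso = None
    if cfg.run_presso and len(instruments) >= 4:
        presso = mr_presso(instruments, cfg.k_sim, cfg.seed,
                           cfg.outlier_alpha, cfg.ivw_model)
    return SensitivityReport(
        q_stat=q, q_df=df, q_pval=q_p,
        egger_intercept=egger.intercept,
        egger_intercept_se=egger.intercept_se,
        egger_intercept_pval=egger.intercept_pval,
        presso=presso,
        loo=leave_one_out(instruments, cfg.ivw_model),
        funnel=funnel_table(ratios),
    )
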