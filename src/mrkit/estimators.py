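"""Causal-effect estimators for summary-data Mendelian randomization.

Five estimators over a harmonized instrument set, all expressed through the
per-SNP Wald ratio theta_j = beta_out_j / beta_exp_j with first-order
standard error sigma_j = se_out_j / |beta_exp_j|:

* ``ivw`` — inverse-variance-weighted meta-analysis of the ratios;
  algebraically identical to the intercept-free weighted regression of
  outcome on exposure effects with weights se_out^-2.
* ``mr_egger`` — the same regression with an unconstrained intercept; the
  slope is the causal estimate and the intercept measures average
  directional pleiotropy.
* ``weighted_median`` — the 50% weighted quantile of the ratio distribution,
  consistent when instruments carrying at least half of the weight are valid.
* ``mode_estimate`` — the peak of a kernel-smoothed density of the ratios
  (simple and inverse-variance-weighted variants), consistent when the
  largest cluster of instruments is valid.

Median and mode standard errors come from a seeded parametric bootstrap;
IVW and Egger have closed-form (weighted least squares) standard errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .errors import DomainError
from .summary_data import HarmonizedInstrument

P_FLOOR = 1e-300
Z975 = float(stats.norm.ppf(0.975))

METHOD_LABELS = {
    "wald_ratio": "Wald ratio",
    "ivw": "Inverse variance weighted",
    "egger": "MR Egger",
    "weighted_median": "Weighted median",
    "simple_mode": "Simple mode",
    "weighted_mode": "Weighted mode",
}


def _two_sided_normal_p(z: float) -> float:
    return max(2.0 * stats.norm.sf(abs(z)), P_FLOOR)


@dataclass(frozen=True)
class RatioEstimate:
    """Per-SNP Wald ratio estimate with its first-order standard error."""

    snp_id: str
    theta: float
    se_theta: float

    def __post_init__(self) -> None:
        if not self.se_theta > 0:
            raise DomainError(f"{self.snp_id}: se_theta must be positive")


@dataclass(frozen=True)
class MRResult:
    """One estimator's causal estimate on the log-odds scale."""

    method: str
    n_snp: int
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float

    @property
    def or_(self) -> float:
        return math.exp(self.beta)

    @property
    def or_ci_low(self) -> float:
        return math.exp(self.ci_low)

    @property
    def or_ci_high(self) -> float:
        return math.exp(self.ci_high)

    @classmethod
    def from_beta_se(cls, method: str, n_snp: int, beta: float, se: float,
                     df: int | None = None) -> "MRResult":
        """Build a result from (beta, se) with a normal or t reference.

        ``df=None`` uses the normal 97.5% quantile for the CI and a Wald z
        test; an integer ``df`` switches both to the t distribution (used by
        the Egger regression, whose coefficients are t-distributed with
        J - 2 degrees of freedom).
        """
        if df is None:
            mult = Z975
            pval = _two_sided_normal_p(beta / se) if se > 0 else P_FLOOR
        else:
            mult = float(stats.t.ppf(0.975, df))
            pval = max(2.0 * stats.t.sf(abs(beta / se), df), P_FLOOR) \
                if se > 0 else P_FLOOR
        return cls(method=method, n_snp=n_snp, beta=float(beta),
                   se=float(se), ci_low=float(beta - mult * se),
                   ci_high=float(beta + mult * se), pval=float(pval))


@dataclass
class EggerResult:
    """MR-Egger regression: causal slope plus pleiotropy intercept."""

    slope: MRResult
    intercept: float
    intercept_se: float
    intercept_pval: float
    n_snp: int


def wald_ratio(inst: HarmonizedInstrument,
               second_order: bool = False) -> RatioEstimate:
    """Per-SNP causal estimate beta_out/beta_exp with delta-method SE.

    The default first-order SE is se_out/|beta_exp|; ``second_order=True``
    adds the exposure-uncertainty term
    sqrt(se_out²/beta_exp² + beta_out²·se_exp²/beta_exp⁴).
    """
    if inst.beta_exp == 0:
        raise DomainError(f"{inst.snp_id}: beta_exp is zero")
    theta = inst.beta_out / inst.beta_exp
    if second_order:
        se = math.sqrt(inst.se_out ** 2 / inst.beta_exp ** 2
                       + inst.beta_out ** 2 * inst.se_exp ** 2
                       / inst.beta_exp ** 4)
    else:
        se = inst.se_out / abs(inst.beta_exp)
    return RatioEstimate(inst.snp_id, theta, se)


def ivw(ratios: Sequence[RatioEstimate],
        model: str = "multiplicative_random") -> MRResult:
    """Inverse-variance-weighted meta-analysis of Wald ratios.

    ``fixed`` uses SE = (sum of weights)^-1/2; ``multiplicative_random``
    multiplies it by max(1, sqrt(Q/(J-1))), so the two coincide whenever the
    heterogeneity statistic Q does not exceed its degrees of freedom.
    With a single ratio both models reduce to the Wald ratio itself.
    """
    if len(ratios) == 0:
        raise DomainError("IVW requires at least one ratio")
    if model not in ("fixed", "multiplicative_random"):
        raise DomainError(f"unknown IVW model {model!r}")
    theta = np.array([r.theta for r in ratios])
    w = np.array([r.se_theta for r in ratios]) ** -2.0
    beta = float(np.sum(w * theta) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    if model == "multiplicative_random" and len(ratios) >= 2:
        q = float(np.sum(w * (theta - beta) ** 2))
        se *= max(1.0, math.sqrt(q / (len(ratios) - 1)))
    return MRResult.from_beta_se("ivw", len(ratios), beta, se)


def mr_egger(instruments: Sequence[HarmonizedInstrument]) -> EggerResult:
    """MR-Egger: weighted regression of outcome on exposure effects.

    Instruments are first oriented so every exposure effect is positive
    (both betas flipped together, which leaves the Wald ratios untouched).
    The regression of beta_out on beta_exp with weights se_out^-2 and a free
    intercept gives the causal slope; a nonzero intercept indicates average
    directional pleiotropy.  Standard errors carry a multiplicative
    overdispersion scale floored at 1, and inference uses t with J - 2
    degrees of freedom.
    """
    j = len(instruments)
    if j < 3:
        raise DomainError("MR-Egger requires at least 3 instruments")
    sign = np.array([-1.0 if i.beta_exp < 0 else 1.0 for i in instruments])
    x = sign * np.array([i.beta_exp for i in instruments])
    y = sign * np.array([i.beta_out for i in instruments])
    w = np.array([i.se_out for i in instruments]) ** -2.0

    fit = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    scale = float(fit.scale)  # weighted RSS / (J - 2)
    cov_unit = np.diag(fit.normalized_cov_params)
    se = np.sqrt(max(scale, 1.0) * cov_unit)
    intercept, slope = float(fit.params[0]), float(fit.params[1])
    int_se, slope_se = float(se[0]), float(se[1])
    df = j - 2
    intercept_p = max(2.0 * stats.t.sf(abs(intercept / int_se), df), P_FLOOR) \
        if int_se > 0 else P_FLOOR
    return EggerResult(
        slope=MRResult.from_beta_se("egger", j, slope, slope_se, df=df),
        intercept=intercept, intercept_se=int_se, intercept_pval=intercept_p,
        n_snp=j,
    )


def _weighted_median_rows(theta: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Row-wise weighted median by interpolation of the weighted CDF.

    ``theta`` is (n_rows, J); ``w`` is (J,) and shared across rows.  The
    standardized cumulative weight of the j-th order statistic is
    s_j = (cumsum(w)_j - w_j/2) / sum(w); the estimate interpolates theta
    linearly at s = 0.5.
    """
    order = np.argsort(theta, axis=1, kind="stable")
    t = np.take_along_axis(theta, order, axis=1)
    ww = np.broadcast_to(w, theta.shape)
    ww = np.take_along_axis(ww, order, axis=1)
    ww = ww / ww.sum(axis=1, keepdims=True)
    s = np.cumsum(ww, axis=1) - ww / 2.0

    idx = (s < 0.5).sum(axis=1)  # first order statistic with s >= 0.5
    est = np.empty(theta.shape[0])
    lo_edge = idx == 0
    hi_edge = idx == theta.shape[1]
    est[lo_edge] = t[lo_edge, 0]
    est[hi_edge] = t[hi_edge, -1]
    mid = ~(lo_edge | hi_edge)
    if np.any(mid):
        i = idx[mid]
        rows = np.nonzero(mid)[0]
        s0, s1 = s[rows, i - 1], s[rows, i]
        t0, t1 = t[rows, i - 1], t[rows, i]
        frac = np.where(s1 > s0, (0.5 - s0) / np.where(s1 > s0, s1 - s0, 1.0),
                        0.0)
        est[mid] = t0 + (t1 - t0) * frac
    return est


def weighted_median(ratios: Sequence[RatioEstimate], n_boot: int = 1000,
                    seed: int = 20220405) -> MRResult:
    """Weighted-median estimator with parametric-bootstrap standard error.

    The point estimate is the inverse-variance-weighted 50% quantile of the
    Wald ratios; it is consistent when instruments carrying >= 50% of the
    total weight are valid.  The SE is the standard deviation of the
    estimate over ``n_boot`` resamples theta_j* ~ Normal(theta_j, sigma_j).
    """
    if len(ratios) < 3:
        raise DomainError("weighted median requires at least 3 ratios")
    if n_boot < 1:
        raise DomainError("n_boot must be >= 1")
    theta = np.array([r.theta for r in ratios])
    sig = np.array([r.se_theta for r in ratios])
    w = sig ** -2.0
    point = float(_weighted_median_rows(theta[None, :], w)[0])

    rng = np.random.default_rng(seed)
    resamples = theta + sig * rng.standard_normal((n_boot, len(ratios)))
    boot = _weighted_median_rows(resamples, w)
    se = float(boot.std(ddof=1)) if n_boot > 1 else float("nan")
    return MRResult.from_beta_se("weighted_median", len(ratios), point, se)


def _mode_point(theta: np.ndarray, w: np.ndarray, phi: float,
                n_grid: int = 512) -> float:
    """Argmax of the weighted Gaussian kernel density over the ratios.

    Bandwidth h = phi * 0.9 * min(sd, normalized MAD) * J^(-1/5); the
    density is evaluated on ``n_grid`` points spanning [min-3h, max+3h] and
    ties resolve toward the smaller theta (first argmax on the ascending
    grid).  A zero bandwidth (degenerate spread) returns the weighted
    median, which then equals the repeated value.
    """
    j = theta.size
    sd = float(theta.std(ddof=1)) if j > 1 else 0.0
    mad = float(np.median(np.abs(theta - np.median(theta)))) * 1.4826
    h = phi * 0.9 * min(sd, mad) * j ** (-1.0 / 5.0)
    if not (h > 0):
        return float(_weighted_median_rows(theta[None, :], w)[0])
    grid = np.linspace(theta.min() - 3 * h, theta.max() + 3 * h, n_grid)
    dens = (w[None, :] * np.exp(-0.5 * ((grid[:, None] - theta[None, :]) / h)
                                ** 2)).sum(axis=1)
    return float(grid[int(np.argmax(dens))])


def mode_estimate(ratios: Sequence[RatioEstimate], weighted: bool,
                  phi: float = 1.0, n_boot: int = 1000,
                  seed: int = 20220405) -> MRResult:
    """Mode-based estimate: the most common causal effect among instruments.

    ``weighted=False`` gives every ratio equal kernel weight (simple mode);
    ``weighted=True`` uses inverse-variance weights.  ``phi`` multiplies the
    rule-of-thumb bandwidth.  SE by seeded parametric bootstrap, as in
    :func:`weighted_median`.
    """
    if len(ratios) < 3:
        raise DomainError("mode estimation requires at least 3 ratios")
    if not phi > 0:
        raise DomainError("phi must be positive")
    theta = np.array([r.theta for r in ratios])
    sig = np.array([r.se_theta for r in ratios])
    w = sig ** -2.0 if weighted else np.ones_like(theta)
    w = w / w.sum()
    point = _mode_point(theta, w, phi)

    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        boot[b] = _mode_point(theta + sig * rng.standard_normal(theta.size),
                              w, phi)
    se = float(boot.std(ddof=1)) if n_boot > 1 else float("nan")
    method = "weighted_mode" if weighted else "simple_mode"
    return MRResult.from_beta_se(method, len(ratios), point, se)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class EstimatorConfig:
    """Settings shared by the estimator battery."""

    ivw_model: str = "multiplicative_random"
    phi: float = 1.0
    n_boot: int = 1000
    seed: int = 20220405
    second_order_se: bool = False


@dataclass
class MRAnalysis:
    """All estimates for one instrument set, plus the per-SNP ratios."""

    ratios: list[RatioEstimate]
    results: dict[str, MRResult | None]
    egger: EggerResult | None = None
    not_computable: dict[str, str] = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd
        rows = []
        for method in ("ivw", "egger", "weighted_median", "simple_mode",
                       "weighted_mode"):
            r = self.results.get(method)
            if r is None:
                continue
            rows.append({
                "method": METHOD_LABELS[method], "n_snp": r.n_snp,
                "beta": r.beta, "se": r.se, "or": r.or_,
                "or_ci_low": r.or_ci_low, "or_ci_high": r.or_ci_high,
                "pval": r.pval,
            })
        return pd.DataFrame(rows)

    def forest_frame(self):
        import pandas as pd
        return pd.DataFrame([{
            "SNP": r.snp_id, "theta": r.theta, "se_theta": r.se_theta,
            "ci_low": r.theta - Z975 * r.se_theta,
            "ci_high": r.theta + Z975 * r.se_theta,
        } for r in self.ratios])


def run_all_estimators(instruments: Sequence[HarmonizedInstrument],
                       config: EstimatorConfig | None = None) -> MRAnalysis:
    """Run the full estimator battery on a filtered instrument set.

    IVW is always computed (with one instrument it reduces to the Wald
    ratio); Egger, weighted median and the two mode estimators need at
    least three instruments and are reported as not computable below that.
    """
    cfg = config or EstimatorConfig()
    if len(instruments) == 0:
        raise DomainError("no instruments supplied")
    ratios = [wald_ratio(i, cfg.second_order_se) for i in instruments]
    results: dict[str, MRResult | None] = {}
    not_comp: dict[str, str] = {}
    analysis = MRAnalysis(ratios=ratios, results=results,
                          not_computable=not_comp)

    results["ivw"] = ivw(ratios, cfg.ivw_model)
    if len(instruments) >= 3:
        analysis.egger = mr_egger(instruments)
        results["egger"] = analysis.egger.slope
        results["weighted_median"] = weighted_median(
            ratios, cfg.n_boot, cfg.seed)
        results["simple_mode"] = mode_estimate(
            ratios, weighted=False, phi=cfg.phi, n_boot=cfg.n_boot,
            seed=cfg.seed)
        results["weighted_mode"] = mode_estimate(
            ratios, weighted=True, phi=cfg.phi, n_boot=cfg.n_boot,
            seed=cfg.seed)
    else:
        msg = f"requires >= 3 instruments, have {len(instruments)}"
        for m in ("egger", "weighted_median", "simple_mode", "weighted_mode"):
            results[m] = None
            not_comp[m] = msg
    return analysis


def ci_from_or_pval(or_: float, pval: float, level: float = 0.95,
                    ) -> tuple[float, float]:
    """Reconstruct a Wald confidence interval from a published OR and p.

    Audit helper: inverts the two-sided normal Wald test on log-OR to
    recover the standard error, then rebuilds the ``level`` CI on the OR
    scale.  Useful for checking internal consistency of reported results.
    """
    if not (0 < pval < 1):
        raise DomainError("pval must be in (0, 1)")
    log_or = math.log(or_)
    z = stats.norm.isf(pval / 2.0)
    se = abs(log_or) / z
    mult = stats.norm.ppf(0.5 + level / 2.0)
    return math.exp(log_or - mult * se), math.exp(log_or + mult * se)
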