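"""Two-sample MR estimators: IVW (multiplicative random effects), MR-Egger,
and the weighted median, plus the Wald ratio and OR/CI/P reporting helpers.

Conventions
-----------
* Inference is z-based throughout: ``p = 2 (1 - Phi(|beta/se|))`` and the
  95% CI is ``beta +/- 1.96 se``. Binary outcomes are reported additionally
  as odds ratios, ``OR = exp(beta)`` with exponentiated CI bounds, so the OR
  is always the geometric mean of its CI.
* The random-effects IVW uses a multiplicative overdispersion model: the
  fixed-effect SE is inflated by ``sqrt(Q / (n - 1))`` when Cochran's Q
  exceeds its degrees of freedom, and never deflated (dispersion floored at
  1). MR-Egger applies the same rule with ``n - 2`` degrees of freedom.
* Wald-ratio weights are first-order: exposure-side uncertainty is ignored
  in the weights (``w_j = beta_exp_j^2 / se_out_j^2``), the convention of
  the standard summary-data MR toolchain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

from .exceptions import InsufficientInstrumentsError
from .harmonize import HarmonizedDataset

logger = logging.getLogger(__name__)

Z95 = 1.96


class SummaryTriple(NamedTuple):
    """Reporting triple: point (OR or beta), 95% CI bounds, two-sided p."""

    point: float
    ci_low: float
    ci_high: float
    pval: float


@dataclass
class CausalEstimate:
    """One MR method's causal estimate.

    ``beta``/``se``/``ci_low``/``ci_high`` are on the log-odds scale for
    binary outcomes and the linear scale otherwise; ``or_`` and its bounds
    are present only for binary outcomes.
    """

    method: str  # {"wald_ratio", "ivw_re", "egger", "weighted_median"}
    n_snp: int
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    or_: float | None = None
    or_ci_low: float | None = None
    or_ci_high: float | None = None

    @property
    def binary_outcome(self) -> bool:
        return self.or_ is not None


@dataclass
class InterceptTest:
    """MR-Egger intercept: average directional pleiotropy and its test."""

    intercept: float
    se: float
    pval: float


def _zp(beta: float, se: float) -> float:
    return float(2.0 * sps.norm.sf(abs(beta / se)))


def estimate_to_summary(
    beta: float, se: float, binary_outcome: bool
) -> SummaryTriple:
    """Convert (beta, se) to the forest-plot reporting triple.

    For binary outcomes the point and CI are exponentiated to the OR scale;
    continuous outcomes report beta and its CI unchanged.
    """
    if se <= 0:
        raise ValueError("se must be positive")
    lo, hi = beta - Z95 * se, beta + Z95 * se
    p = _zp(beta, se)
    if binary_outcome:
        return SummaryTriple(float(np.exp(beta)), float(np.exp(lo)),
                             float(np.exp(hi)), p)
    return SummaryTriple(float(beta), float(lo), float(hi), p)


def _make_estimate(
    method: str, n_snp: int, beta: float, se: float, binary_outcome: bool
) -> CausalEstimate:
    lo, hi = beta - Z95 * se, beta + Z95 * se
    est = CausalEstimate(
        method=method,
        n_snp=int(n_snp),
        beta=float(beta),
        se=float(se),
        ci_low=float(lo),
        ci_high=float(hi),
        pval=_zp(beta, se),
    )
    if binary_outcome:
        est.or_ = float(np.exp(beta))
        est.or_ci_low = float(np.exp(lo))
        est.or_ci_high = float(np.exp(hi))
    return est


def wald_ratio(
    beta_exp: float,
    se_exp: float,
    beta_out: float,
    se_out: float,
    binary_outcome: bool = False,
) -> CausalEstimate:
    """Single-SNP causal estimate: beta_out / beta_exp.

    The first-order SE is ``se_out / |beta_exp|`` (exposure-side
    uncertainty neglected).
    """
    if beta_exp == 0:
        raise ValueError("wald ratio undefined for beta_exp = 0")
    beta = beta_out / beta_exp
    se = se_out / abs(beta_exp)
    return _make_estimate("wald_ratio", 1, beta, se, binary_outcome)


def heterogeneity_q(
    beta_exp: np.ndarray,
    beta_out: np.ndarray,
    se_out: np.ndarray,
    pooled_beta: float,
) -> float:
    """Cochran's Q over per-SNP Wald ratios around a pooled estimate.

    ``Q = sum_j v_j (theta_j - pooled)^2`` with ``theta_j = beta_out/beta_exp``
    and inverse-variance weights ``v_j = (se_out_j / |beta_exp_j|)^-2``;
    algebraically identical to the weighted residual sum of squares of the
    through-origin IVW regression. Shared by the random-effects IVW and the
    heterogeneity test so the two can never disagree.
    """
    v = (np.asarray(beta_exp) / np.asarray(se_out)) ** 2
    theta = np.asarray(beta_out) / np.asarray(beta_exp)
    return float(np.sum(v * (theta - pooled_beta) ** 2))


def ivw_random_effects(
    data: HarmonizedDataset, binary_outcome: bool | None = None
) -> CausalEstimate:
    """Inverse-variance-weighted estimate with multiplicative random effects.

    Weighted least squares of ``beta_out`` on ``beta_exp`` through the
    origin, weights ``1/se_out^2``. The reported SE is the fixed-effect SE
    times ``max(1, sqrt(Q/(n-1)))``. A single instrument degrades to the
    Wald ratio (logged).
    """
    if binary_outcome is None:
        binary_outcome = data.outcome_binary
    x, y, s = data.beta_exp, data.beta_out, data.se_out
    n = len(x)
    if n == 0:
        raise InsufficientInstrumentsError("IVW requires at least one SNP")
    if n == 1:
        logger.info(
            "%s -> %s: single instrument, IVW degrades to Wald ratio",
            data.exposure_name, data.outcome_name,
        )
        est = wald_ratio(x[0], data.se_exp[0], y[0], s[0], binary_outcome)
        est.method = "ivw_re"
        return est
    if np.all(x == 0):
        raise ValueError("degenerate design: all exposure betas are zero")

    w = 1.0 / s**2
    sxx = float(np.sum(w * x * x))
    beta = float(np.sum(w * x * y)) / sxx
    base_se = np.sqrt(1.0 / sxx)
    q = heterogeneity_q(x, y, s, beta)
    dispersion = q / (n - 1)
    se = base_se * np.sqrt(max(1.0, dispersion))
    return _make_estimate("ivw_re", n, beta, se, binary_outcome)


def egger_regression(
    data: HarmonizedDataset, binary_outcome: bool | None = None
) -> tuple[CausalEstimate, InterceptTest]:
    """MR-Egger: weighted regression of outcome on exposure effects with an
    unconstrained intercept.

    Each SNP is first oriented so its exposure beta is non-negative (both
    betas flipped otherwise), which the intercept's interpretation as average
    directional pleiotropy requires. Slope and intercept SEs use the same
    multiplicative-dispersion floor as the IVW (dispersion = weighted
    RSS / (n - 2), floored at 1). Requires at least 3 instruments.
    """
    if binary_outcome is None:
        binary_outcome = data.outcome_binary
    n = data.n_snp
    if n < 3:
        raise InsufficientInstrumentsError(
            f"MR-Egger requires >= 3 instruments, got {n}"
        )
    x, y, s = data.beta_exp.copy(), data.beta_out.copy(), data.se_out
    flip = x < 0
    x[flip] *= -1
    y[flip] *= -1
    w = 1.0 / s**2

    fit = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    # statsmodels scales coefficient SEs by the estimated dispersion
    # (weighted RSS / (n-2)); re-floor it at 1 so the SE never drops below
    # the fixed-dispersion value.
    scale_adj = np.sqrt(max(1.0, fit.scale) / fit.scale)
    intercept, slope = fit.params
    se_intercept, se_slope = fit.bse * scale_adj

    est = _make_estimate("egger", n, slope, se_slope, binary_outcome)
    itest = InterceptTest(
        intercept=float(intercept),
        se=float(se_intercept),
        pval=_zp(intercept, se_intercept),
    )
    return est, itest


def _weighted_median(theta: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median (cumulative weight centred per value)."""
    order = np.argsort(theta, kind="stable")
    th = theta[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w) - w / 2
    if 0.5 <= s[0]:
        return float(th[0])
    if 0.5 >= s[-1]:
        return float(th[-1])
    k = int(np.searchsorted(s, 0.5))
    return float(th[k - 1] + (th[k] - th[k - 1]) * (0.5 - s[k - 1]) / (s[k] - s[k - 1]))


def _weighted_median_rows(theta: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Row-wise interpolated weighted median for (n_rows, n_snp) arrays."""
    order = np.argsort(theta, axis=1, kind="stable")
    th = np.take_along_axis(theta, order, axis=1)
    w = np.take_along_axis(weights, order, axis=1)
    w = w / w.sum(axis=1, keepdims=True)
    s = np.cumsum(w, axis=1) - w / 2
    nrow, n = th.shape
    # first index where cumulative centred weight reaches 0.5, per row
    k = np.minimum((s < 0.5).sum(axis=1), n - 1).astype(int)
    rows = np.arange(nrow)
    km1 = np.maximum(k - 1, 0)
    s_lo, s_hi = s[rows, km1], s[rows, k]
    t_lo, t_hi = th[rows, km1], th[rows, k]
    with np.errstate(invalid="ignore", divide="ignore"):
        interp = t_lo + (t_hi - t_lo) * (0.5 - s_lo) / (s_hi - s_lo)
    out = np.where(k == 0, th[rows, 0], interp)
    out = np.where(0.5 >= s[rows, -1], th[rows, -1], out)
    return out


def weighted_median(
    data: HarmonizedDataset,
    n_boot: int = 1000,
    seed: int = 0,
    binary_outcome: bool | None = None,
) -> CausalEstimate:
    """Weighted median of per-SNP Wald ratios.

    Consistent when valid instruments contribute at least half the total
    weight. Weights are inverse Wald-ratio variances (first-order); the SE
    is the SD of a parametric bootstrap (``n_boot`` resamples of each
    beta from a normal with its reported SE, fixed ``seed``).
    """
    if binary_outcome is None:
        binary_outcome = data.outcome_binary
    n = data.n_snp
    if n < 3:
        raise InsufficientInstrumentsError(
            f"weighted median requires >= 3 instruments, got {n}"
        )
    x, y, sx, sy = data.beta_exp, data.beta_out, data.se_exp, data.se_out
    theta = y / x
    w = (x / sy) ** 2
    beta = _weighted_median(theta, w)

    rng = np.random.default_rng(seed)
    xb = rng.normal(x, sx, size=(n_boot, n))
    yb = rng.normal(y, sy, size=(n_boot, n))
    with np.errstate(divide="ignore", invalid="ignore"):
        thb = yb / xb
        wb = (xb / sy) ** 2
    boots = _weighted_median_rows(thb, wb)
    se = float(np.std(boots, ddof=1))
    return _make_estimate("weighted_median", n, beta, se, binary_outcome)


def fit_all_methods(
    data: HarmonizedDataset,
    n_boot: int = 1000,
    seed: int = 0,
    binary_outcome: bool | None = None,
) -> tuple[dict[str, CausalEstimate], InterceptTest | None, dict[str, str]]:
    """Run IVW, MR-Egger and weighted median, skipping (with a reason) any
    method whose instrument-count precondition fails.

    Returns ``(estimates by method, egger intercept test or None,
    skipped-method reasons)``.
    """
    estimates: dict[str, CausalEstimate] = {}
    skipped: dict[str, str] = {}
    itest: InterceptTest | None = None
    estimates["ivw_re"] = ivw_random_effects(data, binary_outcome)
    try:
        estimates["egger"], itest = egger_regression(data, binary_outcome)
    except InsufficientInstrumentsError as exc:
        skipped["egger"] = str(exc)
    try:
        estimates["weighted_median"] = weighted_median(
            data, n_boot=n_boot, seed=seed, binary_outcome=binary_outcome
        )
    except InsufficientInstrumentsError as exc:
        skipped["weighted_median"] = str(exc)
    return estimates, itest, skipped
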