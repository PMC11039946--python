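"""Sensitivity battery: Cochran's Q, MR-Egger intercept test, MR-PRESSO.

Availability follows instrument counts: Q needs at least 2 SNPs, the Egger
intercept 3, MR-PRESSO 4. When a precondition fails the test is reported as
unavailable with a reason rather than erroring, since a small instrument set
is a legitimate (and common) analysis state.

MR-PRESSO is a parametric-simulation test on the weighted residual sum of
squares of the through-origin IVW regression, computed with leave-one-out
slopes so each SNP's own residual is judged against a fit it did not
influence. All Monte-Carlo p-values use the ``(1 + exceedances)/(n_sim + 1)``
convention and are therefore never exactly zero.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats as sps

from .estimators import (
    CausalEstimate,
    InterceptTest,
    egger_regression,
    heterogeneity_q,
    ivw_random_effects,
)
from .exceptions import InsufficientInstrumentsError
from .harmonize import HarmonizedDataset

logger = logging.getLogger(__name__)


def cochrans_q(
    data: HarmonizedDataset, ivw_beta: float
) -> tuple[float, int, float]:
    """Cochran's Q around the IVW estimate; chi-square p on n_snp - 1 df."""
    n = data.n_snp
    if n < 2:
        raise InsufficientInstrumentsError("Cochran's Q requires >= 2 instruments")
    q = heterogeneity_q(data.beta_exp, data.beta_out, data.se_out, ivw_beta)
    df = n - 1
    return q, df, float(sps.chi2.sf(q, df))


def egger_intercept_test(intercept: float, intercept_se: float) -> float:
    """Two-sided normal p for the Egger intercept (directional pleiotropy)."""
    if intercept_se <= 0:
        raise ValueError("intercept_se must be positive")
    return float(2.0 * sps.norm.sf(abs(intercept / intercept_se)))


@dataclass
class PressoResult:
    """MR-PRESSO global, outlier and distortion test results."""

    global_pval: float
    outliers: list[str]
    outlier_pvals: dict[str, float]  # Bonferroni-corrected, capped at 1
    corrected: CausalEstimate | None
    distortion_coef: float | None
    distortion_pval: float | None
    n_sim: int


def _loo_slopes(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out through-origin WLS slopes; supports batched rows.

    ``x``/``y`` may be 1-d (n,) or 2-d (n_sim, n); ``w`` is always (n,).
    """
    sxy = np.sum(w * x * y, axis=-1, keepdims=True)
    sxx = np.sum(w * x * x, axis=-1, keepdims=True)
    return (sxy - w * x * y) / (sxx - w * x * x)


def mr_presso(
    data: HarmonizedDataset,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int = 0,
) -> PressoResult:
    """MR-PRESSO global, outlier-corrected and distortion tests.

    1. *Global*: observed weighted RSS (each SNP's residual taken against its
       leave-one-out IVW slope) is compared with RSS from ``n_sim`` parametric
       simulations (outcome betas regenerated around the leave-one-out fitted
       values with their reported SEs, exposure betas jittered likewise).
    2. *Outlier*: each SNP's observed squared residual is compared with its
       simulated distribution; per-SNP p-values are Bonferroni-multiplied by
       n_snp and SNPs below ``outlier_alpha`` are flagged.
    3. *Corrected estimate*: random-effects IVW on the non-flagged SNPs.
    4. *Distortion*: the percent change of the IVW estimate after outlier
       removal, referenced to the distribution obtained by removing the same
       number of SNPs uniformly at random.

    Requires at least 4 instruments.
    """
    n = data.n_snp
    if n < 4:
        raise InsufficientInstrumentsError(
            f"MR-PRESSO requires >= 4 instruments, got {n}"
        )
    rng = np.random.default_rng(seed)
    x, y = data.beta_exp, data.beta_out
    sx, sy = data.se_exp, data.se_out
    w = 1.0 / sy**2

    slopes_loo = _loo_slopes(x, y, w).reshape(-1)
    resid_obs = w * (y - slopes_loo * x) ** 2
    rss_obs = float(resid_obs.sum())

    x_sim = rng.normal(x, sx, size=(n_sim, n))
    y_sim = slopes_loo * x_sim + rng.normal(0.0, sy, size=(n_sim, n))
    slopes_sim = _loo_slopes(x_sim, y_sim, w)
    resid_sim = w * (y_sim - slopes_sim * x_sim) ** 2
    rss_sim = resid_sim.sum(axis=1)

    global_pval = (1.0 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1.0)

    p_raw = (1.0 + np.sum(resid_sim >= resid_obs, axis=0)) / (n_sim + 1.0)
    p_bonf = np.minimum(p_raw * n, 1.0)
    out_mask = p_bonf < outlier_alpha
    snp_ids = data.snp_ids
    outliers = [str(s) for s in snp_ids[out_mask]]
    outlier_pvals = dict(zip((str(s) for s in snp_ids), p_bonf))

    corrected: CausalEstimate | None = None
    distortion_coef: float | None = None
    distortion_pval: float | None = None
    if outliers:
        if out_mask.all():
            logger.error(
                "%s -> %s: MR-PRESSO flagged every SNP; no corrected estimate",
                data.exposure_name, data.outcome_name,
            )
        else:
            corrected = ivw_random_effects(data.subset(~out_mask))
            theta_all = ivw_random_effects(data).beta
            if theta_all != 0:
                k = int(out_mask.sum())
                distortion_coef = float(
                    100.0 * (corrected.beta - theta_all) / abs(theta_all)
                )
                null_coefs = np.empty(n_sim)
                sxy_all = float(np.sum(w * x * y))
                sxx_all = float(np.sum(w * x * x))
                for b in range(n_sim):
                    drop = rng.choice(n, size=k, replace=False)
                    sxy = sxy_all - np.sum(w[drop] * x[drop] * y[drop])
                    sxx = sxx_all - np.sum(w[drop] * x[drop] * x[drop])
                    null_coefs[b] = 100.0 * (sxy / sxx - theta_all) / abs(theta_all)
                distortion_pval = float(
                    (1.0 + np.sum(np.abs(null_coefs) >= abs(distortion_coef)))
                    / (n_sim + 1.0)
                )
    return PressoResult(
        global_pval=float(global_pval),
        outliers=outliers,
        outlier_pvals=outlier_pvals,
        corrected=corrected,
        distortion_coef=distortion_coef,
        distortion_pval=distortion_pval,
        n_sim=n_sim,
    )


@dataclass
class SensitivityReport:
    """Assembled sensitivity results for one exposure-outcome analysis."""

    n_snp: int
    q_stat: float | None = None
    q_df: int | None = None
    q_pval: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_pval: float | None = None
    presso_global_pval: float | None = None
    presso_outliers: list[str] = field(default_factory=list)
    presso_corrected: CausalEstimate | None = None
    presso_distortion_coef: float | None = None
    presso_distortion_pval: float | None = None
    n_sim: int = 0
    unavailable: dict[str, str] = field(default_factory=dict)

    @property
    def heterogeneity_present(self) -> bool:
        """Q test significant at 0.05. Annotation only: heterogeneity never
        invalidates a result here, the random-effects IVW absorbs it."""
        return self.q_pval is not None and self.q_pval < 0.05

    def to_dict(self) -> dict:
        d = {
            "n_snp": self.n_snp,
            "q_stat": self.q_stat,
            "q_df": self.q_df,
            "q_pval": self.q_pval,
            "egger_intercept": self.egger_intercept,
            "egger_intercept_se": self.egger_intercept_se,
            "egger_intercept_pval": self.egger_intercept_pval,
            "presso_global_pval": self.presso_global_pval,
            "presso_outliers": list(self.presso_outliers),
            "presso_distortion_coef": self.presso_distortion_coef,
            "presso_distortion_pval": self.presso_distortion_pval,
            "n_sim": self.n_sim,
            "unavailable": dict(self.unavailable),
        }
        if self.presso_corrected is not None:
            c = self.presso_corrected
            d["presso_corrected"] = {
                "beta": c.beta, "se": c.se, "pval": c.pval,
                "n_snp": c.n_snp, "or_": c.or_,
            }
        else:
            d["presso_corrected"] = None
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def run_sensitivity(
    data: HarmonizedDataset,
    estimates: Mapping[str, CausalEstimate],
    intercept_test: InterceptTest | None = None,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int = 0,
) -> SensitivityReport:
    """Assemble the full sensitivity report for one analysis.

    ``estimates`` must contain the IVW result under ``"ivw_re"``. Tests
    whose instrument-count preconditions fail are marked unavailable with a
    reason instead of raising. The Egger intercept is recomputed from the
    data when no ``intercept_test`` is passed in.
    """
    if "ivw_re" not in estimates:
        raise ValueError("run_sensitivity requires the IVW estimate")
    report = SensitivityReport(n_snp=data.n_snp)

    try:
        report.q_stat, report.q_df, report.q_pval = cochrans_q(
            data, estimates["ivw_re"].beta
        )
    except InsufficientInstrumentsError as exc:
        report.unavailable["cochrans_q"] = str(exc)

    if intercept_test is None and data.n_snp >= 3:
        try:
            _, intercept_test = egger_regression(data)
        except InsufficientInstrumentsError as exc:
            report.unavailable["egger_intercept"] = str(exc)
    if intercept_test is not None:
        report.egger_intercept = intercept_test.intercept
        report.egger_intercept_se = intercept_test.se
        report.egger_intercept_pval = egger_intercept_test(
            intercept_test.intercept, intercept_test.se
        )
    elif "egger_intercept" not in report.unavailable:
        report.unavailable["egger_intercept"] = (
            f"MR-Egger intercept requires >= 3 instruments, got {data.n_snp}"
        )

    try:
        presso = mr_presso(data, n_sim=n_sim, outlier_alpha=outlier_alpha, seed=seed)
        report.presso_global_pval = presso.global_pval
        report.presso_outliers = presso.outliers
        report.presso_corrected = presso.corrected
        report.presso_distortion_coef = presso.distortion_coef
        report.presso_distortion_pval = presso.distortion_pval
        report.n_sim = presso.n_sim
    except InsufficientInstrumentsError as exc:
        report.unavailable["mr_presso"] = str(exc)

    return report
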