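"""Study orchestration: run exposure-outcome pairs through the full chain
and render robustness verdicts.

A finding is called *robust* only when (a) the IVW estimate is significant
at p < 0.05 and (b) all available methods (IVW, MR-Egger, weighted median)
agree on the sign of the causal estimate. Methods unavailable because of
instrument-count preconditions are excluded from the sign comparison and the
reduced comparison is flagged. No multiple-testing correction is applied
across the exposure-outcome grid; a Bonferroni-adjusted p-value column is
emitted as opt-in annotation only.

Forward (trait -> disease) and reverse (disease -> trait) analyses of the
same pair are fully independent runs with their own instrument selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .estimators import CausalEstimate, InterceptTest, fit_all_methods
from .exceptions import (
    ConfigurationError,
    HarmonizationEmptyError,
    MrkitError,
    NoInstrumentsError,
)
from .gwas_io import SummaryStatistics, read_sumstats, write_results_table
from .harmonize import HarmonizedDataset, harmonize_pair
from .instruments import LdMatrix, select_instruments
from .sensitivity import SensitivityReport, run_sensitivity

logger = logging.getLogger(__name__)

#: methods entering the direction-consistency comparison, in reporting order
COMPARISON_METHODS = ["ivw_re", "egger", "weighted_median"]


@dataclass
class PipelineConfig:
    """Thresholds and method settings for one study run."""

    primary_threshold: float = 5e-8
    fallback_threshold: float = 5e-6
    post_clump_min: int = 2
    r2_max: float = 0.001
    window_kb: float = 10_000
    f_min: float = 10.0
    n_boot: int = 1000
    n_sim: int = 1000
    outlier_alpha: float = 0.05
    alpha: float = 0.05
    seed: int = 0


@dataclass
class RobustnessVerdict:
    """Two-criterion robustness call for one analysis."""

    ivw_significant: bool
    directions_consistent: bool
    methods_compared: list[str]
    reduced_comparison: bool = False  # fewer than the three methods available

    @property
    def robust(self) -> bool:
        return self.ivw_significant and self.directions_consistent


def make_verdict(
    estimates: Mapping[str, CausalEstimate], alpha: float = 0.05
) -> RobustnessVerdict:
    """Apply the robustness rule to a set of method estimates.

    Direction consistency requires every available method's beta to share
    one strict sign; a zero beta can support neither direction and fails
    the comparison.
    """
    ivw = estimates["ivw_re"]
    available = [m for m in COMPARISON_METHODS if m in estimates]
    betas = np.array([estimates[m].beta for m in available])
    consistent = bool(np.all(betas > 0) or np.all(betas < 0))
    return RobustnessVerdict(
        ivw_significant=bool(ivw.pval < alpha),
        directions_consistent=consistent,
        methods_compared=available,
        reduced_comparison=len(available) < len(COMPARISON_METHODS),
    )


@dataclass
class PairResult:
    """Everything computed for one exposure-outcome-stratum analysis."""

    exposure: str
    outcome: str
    stratum: str
    direction: str
    estimates: dict[str, CausalEstimate] = field(default_factory=dict)
    intercept_test: InterceptTest | None = None
    sensitivity: SensitivityReport | None = None
    verdict: RobustnessVerdict | None = None
    harmonized: HarmonizedDataset | None = None
    skipped_methods: dict[str, str] = field(default_factory=dict)
    error: str | None = None

    @property
    def estimable(self) -> bool:
        return self.error is None

    def result_rows(self) -> list[dict]:
        """Rows for the combined results table (one per method)."""
        base = {
            "exposure": self.exposure,
            "outcome": self.outcome,
            "stratum": self.stratum,
            "direction": self.direction,
        }
        if not self.estimable:
            return [
                {
                    **base,
                    "method": "not_estimable",
                    "n_snp": 0,
                    "beta": np.nan,
                    "se": np.nan,
                    "or_": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "pval": np.nan,
                    "robust_flag": False,
                }
            ]
        rows = []
        for method in COMPARISON_METHODS:
            if method not in self.estimates:
                continue
            e = self.estimates[method]
            binary = e.binary_outcome
            rows.append(
                {
                    **base,
                    "method": method,
                    "n_snp": e.n_snp,
                    "beta": e.beta,
                    "se": e.se,
                    "or_": e.or_ if binary else np.nan,
                    "ci_low": e.or_ci_low if binary else e.ci_low,
                    "ci_high": e.or_ci_high if binary else e.ci_high,
                    "pval": e.pval,
                    "robust_flag": self.verdict.robust,
                }
            )
        return rows


def run_pair(
    exposure: SummaryStatistics,
    outcome: SummaryStatistics,
    ld: LdMatrix,
    config: PipelineConfig | None = None,
    direction: str = "forward",
    seed: int | None = None,
) -> PairResult:
    """Full chain for one pair: select -> harmonize -> estimate -> sensitivity
    -> verdict.

    Selection or harmonization leaving nothing to analyse yields a
    ``not estimable`` result (``error`` set) rather than an exception, so
    batch runs can isolate failures.
    """
    config = config or PipelineConfig()
    seed = config.seed if seed is None else seed
    result = PairResult(
        exposure=exposure.trait_name,
        outcome=outcome.trait_name,
        stratum=outcome.stratum if direction == "reverse" else exposure.stratum,
        direction=direction,
    )
    try:
        instruments = select_instruments(
            exposure,
            ld,
            primary_threshold=config.primary_threshold,
            fallback_threshold=config.fallback_threshold,
            post_clump_min=config.post_clump_min,
            r2_max=config.r2_max,
            window_kb=config.window_kb,
            f_min=config.f_min,
        )
        harmonized = harmonize_pair(instruments, outcome, direction=direction)
    except (NoInstrumentsError, HarmonizationEmptyError) as exc:
        logger.warning("%s -> %s: %s", exposure.trait_name, outcome.trait_name, exc)
        result.error = str(exc)
        return result

    estimates, itest, skipped = fit_all_methods(
        harmonized, n_boot=config.n_boot, seed=seed
    )
    result.harmonized = harmonized
    result.estimates = estimates
    result.intercept_test = itest
    result.skipped_methods = skipped
    result.sensitivity = run_sensitivity(
        harmonized,
        estimates,
        intercept_test=itest,
        n_sim=config.n_sim,
        outlier_alpha=config.outlier_alpha,
        seed=seed,
    )
    result.verdict = make_verdict(estimates, alpha=config.alpha)
    return result


@dataclass
class PairSpec:
    """One manifest entry: an exposure/outcome analysis to run."""

    exposure_path: str
    outcome_path: str
    ld_path: str | None = None
    exposure_name: str | None = None
    outcome_name: str | None = None
    stratum: str = "all"
    direction: str = "forward"
    outcome_type: str = "binary"

    def key(self) -> tuple:
        exp = self.exposure_name or Path(self.exposure_path).stem
        out = self.outcome_name or Path(self.outcome_path).stem
        return (exp, out, self.stratum, self.direction)


@dataclass
class StudyManifest:
    """A batch of analyses plus shared configuration."""

    pairs: list[PairSpec]
    config: PipelineConfig = field(default_factory=PipelineConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        keys = [p.key() for p in self.pairs]
        if len(set(keys)) != len(keys):
            dupes = {k for k in keys if keys.count(k) > 1}
            raise ConfigurationError(f"duplicate manifest entries: {sorted(dupes)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyManifest":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = PipelineConfig(**raw.get("config", {}))
        pairs = [PairSpec(**p) for p in raw.get("pairs", [])]
        if not pairs:
            raise ConfigurationError(f"{path}: manifest lists no pairs")
        return cls(pairs=pairs, config=cfg, seed=raw.get("seed", cfg.seed))


def _pair_seed(base_seed: int, index: int) -> int:
    # deterministic, well-separated per-pair seeds below 2**31
    return int((base_seed + 1_000_003 * (index + 1)) % 2**31)


def run_study(
    manifest: StudyManifest,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, list[PairResult]]:
    """Run every manifest pair; emit a combined results table and per-pair
    sensitivity JSONs (when ``out_dir`` is given).

    Single-pair failures are isolated into ``not_estimable`` rows. The whole
    run is bit-reproducible for a fixed manifest seed.
    """
    results: list[PairResult] = []
    rows: list[dict] = []
    for idx, spec in enumerate(manifest.pairs):
        exp = read_sumstats(
            spec.exposure_path,
            trait_name=spec.exposure_name,
            trait_type="continuous" if spec.direction == "forward" else "binary",
            stratum=spec.stratum if spec.direction == "forward" else "all",
        )
        out = read_sumstats(
            spec.outcome_path,
            trait_name=spec.outcome_name,
            trait_type=spec.outcome_type,
            stratum=spec.stratum if spec.direction == "reverse" else "all",
        )
        ld = (
            LdMatrix.from_tsv(spec.ld_path)
            if spec.ld_path
            else LdMatrix.identity(exp.records["snp_id"])
        )
        logger.info(
            "[%d/%d] %s -> %s (%s, %s)",
            idx + 1, len(manifest.pairs),
            exp.trait_name, out.trait_name, spec.stratum, spec.direction,
        )
        try:
            res = run_pair(
                exp, out, ld,
                config=manifest.config,
                direction=spec.direction,
                seed=_pair_seed(manifest.seed, idx),
            )
        except MrkitError as exc:  # isolate anything a stage raises
            res = PairResult(
                exposure=exp.trait_name, outcome=out.trait_name,
                stratum=spec.stratum, direction=spec.direction, error=str(exc),
            )
        results.append(res)
        rows.extend(res.result_rows())

    table = pd.DataFrame(rows)
    n_tests = sum(1 for r in results if r.estimable)
    if "pval" in table.columns and n_tests:
        # opt-in annotation only; the robustness rule uses unadjusted p
        table["pval_bonferroni"] = np.minimum(table["pval"] * n_tests, 1.0)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_results_table(
            table.drop(columns=["pval_bonferroni"], errors="ignore"),
            out_dir / "mr_results.tsv",
        )
        for res in results:
            if res.sensitivity is not None:
                name = (
                    f"{res.exposure}__{res.outcome}__{res.stratum}"
                    f"__{res.direction}.sensitivity.json"
                )
                res.sensitivity.to_json(out_dir / name)
        robust = [
            r for r in results if r.verdict is not None and r.verdict.robust
        ]
        logger.info(
            "study complete: %d/%d analyses estimable, %d robust finding(s)",
            n_tests, len(results), len(robust),
        )
    return table, results
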