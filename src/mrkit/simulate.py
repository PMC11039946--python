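"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the structure of a two-sample MR design: a
standardized continuous exposure measured in one GWAS and an outcome
measured in an independent GWAS, linked by a structural model

    beta_out_j  ~  Normal(theta * gamma_j + alpha_j,  se_out_j^2)

where ``gamma_j`` is SNP j's true effect on the exposure, ``theta`` the
causal effect, and ``alpha_j`` a horizontal-pleiotropy term (zero for valid
instruments). Standard errors follow the standardized-trait GWAS asymptotics
``se = 1 / sqrt(2 n MAF (1 - MAF))``; binary outcomes reuse the same form as
a log-odds-scale approximation. Exposure and outcome sampling errors are
independent (the two-sample, no-overlap assumption).

Real-data messiness that the harmonizer must survive is injected on
purpose: palindromic (A/T, C/G) SNPs, outcome rows emitted with swapped
alleles and negated betas, and optional constant-correlation LD blocks whose
members share a scaled signal. The block structure doubles as the exported
LD matrix used by the clumper, so no genotype reference panel is needed
anywhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .estimators import fit_all_methods
from .exceptions import MrkitError
from .gwas_io import SummaryStatistics
from .harmonize import harmonize_pair
from .instruments import LdMatrix, select_instruments

_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_NONPALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]


@dataclass
class SimulationConfig:
    """Full specification of the synthetic two-sample data-generating process.

    Defaults describe a well-powered hormone-to-disease setting: a UK
    Biobank-scale exposure GWAS (n = 300,000 on a standardized trait) against
    an IBD-scale outcome GWAS (n = 35,000), with 2,000 candidate SNPs of
    which 20% carry a true exposure effect drawn from Normal(0, 0.05^2)
    (per-allele effects in SD units), and a small admixture of palindromic
    and allele-swapped records.
    """

    m: int = 2000  # candidate SNPs
    theta: float = 0.0  # causal effect (log-odds per exposure SD)
    n_exp: int = 300_000
    n_out: int = 35_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    gamma_dist: tuple[float, float, float] = (0.0, 0.05, 0.8)  # mean, sd, null-frac
    pi_invalid: float = 0.0  # fraction of SNPs with horizontal pleiotropy
    mu_alpha: float = 0.0  # mean pleiotropic effect
    sigma_alpha: float = 0.0  # sd of pleiotropic effects
    ld_blocks: Sequence[tuple[int, float]] = ()  # (block size, pairwise r)
    frac_palindromic: float = 0.05
    frac_flipped: float = 0.05
    seed: int = 0
    exposure_name: str = "exposure"
    outcome_name: str = "outcome"
    outcome_binary: bool = True

    def validate(self) -> None:
        if self.m < 1:
            raise MrkitError("m must be >= 1")
        if self.n_exp < 2 or self.n_out < 2:
            raise MrkitError("sample sizes must be >= 2")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise MrkitError("maf_range bounds must satisfy 0 < lo <= hi <= 0.5")
        for name in ("pi_invalid", "frac_palindromic", "frac_flipped"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise MrkitError(f"{name} must lie in [0, 1]")
        _, sd, nullfrac = self.gamma_dist
        if sd < 0 or not 0 <= nullfrac <= 1:
            raise MrkitError("gamma_dist requires sd >= 0 and null-fraction in [0,1]")
        for size, r in self.ld_blocks:
            if size < 1 or not 0 <= r <= 1:
                raise MrkitError("ld_blocks entries need size >= 1 and r in [0, 1]")
        if sum(size for size, _ in self.ld_blocks) > self.m:
            raise MrkitError("ld_blocks cover more SNPs than m")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "maf_range" in raw:
            raw["maf_range"] = tuple(raw["maf_range"])
        if "gamma_dist" in raw:
            raw["gamma_dist"] = tuple(raw["gamma_dist"])
        if "ld_blocks" in raw:
            raw["ld_blocks"] = [tuple(b) for b in raw["ld_blocks"]]
        return cls(**raw)


@dataclass
class TruthRecord:
    """Per-SNP ground truth of one simulated dataset (never emitted into the
    summary-statistics tables)."""

    theta: float
    snp_ids: list[str]
    gamma: np.ndarray
    alpha: np.ndarray
    valid: np.ndarray  # bool, no horizontal pleiotropy
    block_id: np.ndarray  # -1 for unlinked SNPs
    block_r: np.ndarray  # pairwise r of the SNP's block (0 if unlinked)
    flipped: np.ndarray  # outcome row emitted with swapped alleles
    palindromic: np.ndarray

    def ld_matrix(self) -> LdMatrix:
        """Block-diagonal LD (r) matrix implied by the block assignment."""
        k = len(self.snp_ids)
        r = np.eye(k)
        for b in np.unique(self.block_id):
            if b < 0:
                continue
            members = np.flatnonzero(self.block_id == b)
            rb = self.block_r[members[0]]
            for i in members:
                for j in members:
                    if i != j:
                        r[i, j] = rb
        return LdMatrix(list(self.snp_ids), r)

    def to_json(self, path: str | Path) -> None:
        d = {
            "theta": self.theta,
            "snp_ids": list(self.snp_ids),
            "gamma": self.gamma.tolist(),
            "alpha": self.alpha.tolist(),
            "valid": self.valid.astype(bool).tolist(),
            "block_id": self.block_id.tolist(),
            "block_r": self.block_r.tolist(),
            "flipped": self.flipped.astype(bool).tolist(),
            "palindromic": self.palindromic.astype(bool).tolist(),
        }
        Path(path).write_text(json.dumps(d))


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    return np.clip(2.0 * sps.norm.sf(np.abs(beta / se)), 1e-300, 1.0)


def simulate_two_sample(
    config: SimulationConfig,
) -> tuple[SummaryStatistics, SummaryStatistics, TruthRecord]:
    """Generate one paired exposure/outcome summary-statistics dataset.

    Bit-identical for a fixed ``config.seed``. Returns the exposure table,
    the outcome table (with allele corruption applied), and the ground
    truth; the LD matrix for clumping is available as ``truth.ld_matrix()``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    m = config.m

    snp_ids = [f"rs{i + 1}" for i in range(m)]

    # Block assignment: LD-block members sit 5 kb apart; independent units
    # are spaced 20,000 kb apart (outside the clumping window) across
    # chromosomes 1..22.
    block_id = np.full(m, -1, dtype=int)
    block_r = np.zeros(m)
    i = 0
    for b, (size, r) in enumerate(config.ld_blocks):
        block_id[i : i + size] = b
        block_r[i : i + size] = r
        i += size
    unit = np.zeros(m, dtype=int)  # consecutive independent-unit counter
    u = 0
    j = 0
    while j < m:
        if block_id[j] >= 0:
            members = np.flatnonzero(block_id == block_id[j])
            unit[members] = u
            j = members[-1] + 1
        else:
            unit[j] = u
            j += 1
        u += 1
    chrom = (unit % 22 + 1).astype(str)
    within = unit // 22  # unit index within its chromosome
    offset = np.zeros(m, dtype=np.int64)
    for b in range(len(config.ld_blocks)):
        members = np.flatnonzero(block_id == b)
        offset[members] = np.arange(len(members)) * 5_000
    pos = 1_000_000 + within * 20_000_000 + offset

    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    mean_g, sd_g, null_frac = config.gamma_dist
    is_null = rng.random(m) < null_frac
    gamma = np.where(is_null, 0.0, rng.normal(mean_g, sd_g, size=m))
    # within a block, tag SNPs carry the lead SNP's signal scaled by r
    for b in range(len(config.ld_blocks)):
        members = np.flatnonzero(block_id == b)
        lead = members[0]
        gamma[members[1:]] = block_r[lead] * gamma[lead]

    se_exp = 1.0 / np.sqrt(2.0 * config.n_exp * maf * (1.0 - maf))
    z = rng.standard_normal(m)
    # constant-correlation sampling errors within blocks:
    # z = sqrt(r) * z_block + sqrt(1-r) * z_indep
    for b in range(len(config.ld_blocks)):
        members = np.flatnonzero(block_id == b)
        r = block_r[members[0]]
        z_common = rng.standard_normal()
        z[members] = np.sqrt(r) * z_common + np.sqrt(1 - r) * z[members]
    beta_exp = gamma + se_exp * z

    invalid = rng.random(m) < config.pi_invalid
    alpha = np.where(
        invalid, rng.normal(config.mu_alpha, config.sigma_alpha, size=m), 0.0
    )
    se_out = 1.0 / np.sqrt(2.0 * config.n_out * maf * (1.0 - maf))
    beta_out = config.theta * gamma + alpha + se_out * rng.standard_normal(m)

    palindromic = rng.random(m) < config.frac_palindromic
    pair_choice = rng.integers(0, 8, size=m)
    pal_choice = rng.integers(0, 4, size=m)
    ea = np.empty(m, dtype=object)
    oa = np.empty(m, dtype=object)
    for j in range(m):
        if palindromic[j]:
            ea[j], oa[j] = _PALINDROMIC_PAIRS[pal_choice[j]]
        else:
            ea[j], oa[j] = _NONPALINDROMIC_PAIRS[pair_choice[j]]

    exposure = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": chrom,
            "pos": pos,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": maf,
            "beta": beta_exp,
            "se": se_exp,
            "pval": _two_sided_p(beta_exp, se_exp),
            "n": config.n_exp,
        }
    )

    flipped = rng.random(m) < config.frac_flipped
    out_ea = np.where(flipped, oa, ea)
    out_oa = np.where(flipped, ea, oa)
    outcome = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": chrom,
            "pos": pos,
            "effect_allele": out_ea,
            "other_allele": out_oa,
            "eaf": np.where(flipped, 1.0 - maf, maf),
            "beta": np.where(flipped, -beta_out, beta_out),
            "se": se_out,
            "pval": _two_sided_p(beta_out, se_out),
            "n": config.n_out,
        }
    )

    truth = TruthRecord(
        theta=config.theta,
        snp_ids=snp_ids,
        gamma=gamma,
        alpha=alpha,
        valid=~invalid,
        block_id=block_id,
        block_r=block_r,
        flipped=flipped,
        palindromic=palindromic,
    )
    exp_stats = SummaryStatistics(
        trait_name=config.exposure_name, records=exposure, trait_type="continuous"
    )
    out_stats = SummaryStatistics(
        trait_name=config.outcome_name,
        records=outcome,
        trait_type="binary" if config.outcome_binary else "continuous",
    )
    return exp_stats, out_stats, truth


@dataclass
class RejectionSummary:
    """Aggregate behaviour of one estimator over simulation replicates."""

    method: str
    n_reps: int
    n_used: int
    n_skipped: int
    rejection_rate: float
    mean_estimate: float
    sd_estimate: float
    mean_se: float
    estimates: np.ndarray = field(repr=False, default=None)


def run_chain(
    exposure: SummaryStatistics,
    outcome: SummaryStatistics,
    ld: LdMatrix,
    n_boot: int = 1000,
    seed: int = 0,
    **select_kwargs,
):
    """Select -> harmonize -> fit all three estimators on one dataset.

    Returns ``(estimates dict, intercept test, skipped reasons, harmonized
    dataset)``. Raises the selection/harmonization errors of the underlying
    stages.
    """
    instruments = select_instruments(exposure, ld, **select_kwargs)
    harmonized = harmonize_pair(instruments, outcome)
    estimates, itest, skipped = fit_all_methods(
        harmonized, n_boot=n_boot, seed=seed
    )
    return estimates, itest, skipped, harmonized


def simulate_replicates(
    config: SimulationConfig,
    n_reps: int,
    estimator: str | Sequence[str] = "ivw_re",
    alpha: float = 0.05,
    n_boot: int = 1000,
    **select_kwargs,
) -> RejectionSummary | dict[str, RejectionSummary]:
    """Run the full select->harmonize->estimate chain over seeded replicates.

    Replicates use seeds ``config.seed .. config.seed + n_reps - 1``.
    Replicates in which no instrument survives selection or harmonization
    (or a method's precondition fails) are skipped and counted separately.
    ``estimator`` may be one method name or a sequence; a sequence returns a
    dict of summaries computed from the same replicates.
    """
    from dataclasses import replace

    if n_reps < 1:
        raise MrkitError("n_reps must be >= 1")
    single = isinstance(estimator, str)
    methods = [estimator] if single else list(estimator)
    collected: dict[str, list[tuple[float, float, float]]] = {m: [] for m in methods}
    skipped: dict[str, int] = {m: 0 for m in methods}

    from .exceptions import HarmonizationEmptyError, NoInstrumentsError

    for rep in range(n_reps):
        cfg = replace(config, seed=config.seed + rep)
        exposure, outcome, truth = simulate_two_sample(cfg)
        ld = truth.ld_matrix()
        try:
            estimates, _, skip_reasons, _ = run_chain(
                exposure, outcome, ld, n_boot=n_boot, seed=cfg.seed, **select_kwargs
            )
        except (NoInstrumentsError, HarmonizationEmptyError):
            for m in methods:
                skipped[m] += 1
            continue
        for m in methods:
            if m in estimates:
                e = estimates[m]
                collected[m].append((e.beta, e.se, e.pval))
            else:
                skipped[m] += 1

    summaries: dict[str, RejectionSummary] = {}
    for m in methods:
        rows = np.array(collected[m]) if collected[m] else np.empty((0, 3))
        n_used = len(rows)
        summaries[m] = RejectionSummary(
            method=m,
            n_reps=n_reps,
            n_used=n_used,
            n_skipped=skipped[m],
            rejection_rate=float(np.mean(rows[:, 2] < alpha)) if n_used else np.nan,
            mean_estimate=float(rows[:, 0].mean()) if n_used else np.nan,
            sd_estimate=float(rows[:, 0].std(ddof=1)) if n_used > 1 else np.nan,
            mean_se=float(rows[:, 1].mean()) if n_used else np.nan,
            estimates=rows[:, 0] if n_used else np.empty(0),
        )
    return summaries[methods[0]] if single else summaries
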