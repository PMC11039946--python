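"""Instrumental-variable selection for two-sample MR.

Three filters are applied in sequence, mirroring the conventional
TwoSampleMR-style workflow:

1. genome-wide significance (``p < 5e-8``), relaxed to ``5e-6`` when the
   clumped genome-wide set holds fewer than two SNPs;
2. greedy LD clumping (``r^2 < 0.001`` within a 10,000 kb window), keeping
   the most significant SNP of each linked group;
3. instrument strength ``F = beta^2 / se^2`` strictly greater than 10, to
   avoid weak-instrument bias.

Every candidate SNP's disposition (kept / dropped and why) is recorded in an
audit frame. LD comes from an explicit correlation matrix (:class:`LdMatrix`)
rather than a genotype reference panel; SNPs absent from the matrix are
treated as unlinked with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import MrkitError, NoInstrumentsError
from .gwas_io import SummaryStatistics

logger = logging.getLogger(__name__)


def _chrom_key(chrom: str):
    """Sort key placing numeric chromosomes first, in numeric order."""
    s = str(chrom)
    try:
        return (0, int(s), "")
    except ValueError:
        return (1, 0, s)


@dataclass
class LdMatrix:
    """Pairwise LD correlations (r, signed) for a set of SNPs.

    The matrix must be symmetric with unit diagonal. ``r^2`` between two
    SNPs is the squared entry; SNP pairs absent from the matrix are treated
    as unlinked by the clumper.
    """

    snp_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.snp_ids = [str(s) for s in self.snp_ids]
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.snp_ids)
        if self.r.shape != (k, k):
            raise MrkitError(f"LD matrix shape {self.r.shape} != ({k}, {k})")
        if not np.allclose(self.r, self.r.T, atol=1e-10):
            raise MrkitError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-10):
            raise MrkitError("LD matrix diagonal is not 1")
        if np.any(np.abs(self.r) > 1 + 1e-10):
            raise MrkitError("LD correlations outside [-1, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    @classmethod
    def identity(cls, snp_ids) -> "LdMatrix":
        return cls(list(snp_ids), np.eye(len(snp_ids)))

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def r2(self, a: str, b: str) -> float:
        """Squared correlation; 0.0 for SNPs absent from the matrix."""
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            return 0.0
        return float(self.r[ia, ib] ** 2)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.r, index=self.snp_ids, columns=self.snp_ids).to_csv(
            path, sep="\t", index_label="SNP", float_format="%.10g"
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LdMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.columns.astype(str)), df.to_numpy(dtype=float))


@dataclass
class InstrumentSet:
    """Selected instruments for one exposure, with their audit trail."""

    exposure_name: str
    records: pd.DataFrame  # kept SNPs, canonical sumstat columns
    f_stats: pd.Series  # F per kept SNP, aligned with records
    threshold_used: float
    audit: pd.DataFrame  # snp_id, pval, f_stat, disposition
    trait_type: str = "continuous"
    stratum: str = "all"

    @property
    def n_snps(self) -> int:
        return len(self.records)

    def check_invariants(self, f_min: float = 10.0) -> None:
        assert (self.records["pval"] < self.threshold_used).all()
        assert (self.f_stats > f_min).all()


def f_statistic(beta, se):
    """Instrument strength F = beta^2 / se^2 (accepts scalars or arrays)."""
    se_arr = np.asarray(se, dtype=float)
    if np.any(se_arr <= 0) or not np.all(np.isfinite(se_arr)):
        raise ValueError("se must be positive and finite")
    out = (np.asarray(beta, dtype=float) / se_arr) ** 2
    return float(out) if np.isscalar(beta) or np.asarray(beta).ndim == 0 else out


def clump(
    records: pd.DataFrame,
    ld: LdMatrix,
    r2_max: float = 0.001,
    window_kb: float = 10_000,
) -> pd.DataFrame:
    """Greedy LD clumping of a candidate SNP table.

    Repeatedly keeps the unprocessed SNP with the smallest p-value (ties
    broken by genomic coordinate then snp_id) and removes every unprocessed
    SNP on the same chromosome within ``window_kb`` whose ``r^2`` with it is
    at least ``r2_max``. Output is sorted by chromosome then position, making
    the result independent of input row order.
    """
    if len(records) == 0:
        return records.copy()
    df = records.reset_index(drop=True)
    k = len(df)
    ids = df["snp_id"].to_numpy(dtype=object)
    missing = [s for s in ids if s not in ld]
    if missing:
        logger.warning(
            "%d SNP(s) absent from LD matrix, treated as unlinked (e.g. %s)",
            len(missing), missing[:3],
        )

    # r^2 submatrix in candidate order; SNPs absent from ld are unlinked
    present = np.array([s in ld for s in ids])
    r2 = np.zeros((k, k))
    if present.any():
        sub = np.flatnonzero(present)
        ld_idx = np.array([ld._index[ids[i]] for i in sub])
        r2[np.ix_(sub, sub)] = ld.r[np.ix_(ld_idx, ld_idx)] ** 2

    chrom_keys = [_chrom_key(c) for c in df["chrom"]]
    chrom_codes = pd.factorize(pd.Series(chrom_keys).map(str))[0]
    pos = df["pos"].to_numpy(dtype=np.int64)
    order = sorted(
        range(k),
        key=lambda i: (df.at[i, "pval"], chrom_keys[i], pos[i], str(ids[i])),
    )
    window_bp = window_kb * 1000
    alive = np.ones(k, dtype=bool)
    kept: list[int] = []
    for i in order:
        if not alive[i]:
            continue
        kept.append(i)
        alive[i] = False
        linked = (
            alive
            & (chrom_codes == chrom_codes[i])
            & (np.abs(pos - pos[i]) <= window_bp)
            & (r2[i] >= r2_max)
        )
        alive[linked] = False
    out = df.iloc[sorted(kept, key=lambda i: (chrom_keys[i], pos[i], str(ids[i])))]
    return out.reset_index(drop=True)


def filter_by_pvalue(
    stats: SummaryStatistics,
    ld: LdMatrix,
    primary_threshold: float = 5e-8,
    fallback_threshold: float = 5e-6,
    post_clump_min: int = 2,
    r2_max: float = 0.001,
    window_kb: float = 10_000,
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Significance filter + clumping, with the relaxed-threshold fallback.

    Applies the primary threshold, clumps, and — if fewer than
    ``post_clump_min`` SNPs survive — restarts from the full table at the
    fallback threshold. Returns ``(clumped records, pre-clump records,
    threshold_used)``.

    Raises :class:`NoInstrumentsError` when even the fallback yields nothing.
    """
    for threshold in (primary_threshold, fallback_threshold):
        candidates = stats.records[stats.records["pval"] < threshold]
        clumped = clump(candidates, ld, r2_max=r2_max, window_kb=window_kb)
        if len(clumped) >= post_clump_min:
            return clumped, candidates.reset_index(drop=True), threshold
    if len(clumped) > 0:  # fewer than post_clump_min but not empty: accept
        logger.warning(
            "%s: only %d instrument(s) even at fallback threshold %.1e",
            stats.trait_name, len(clumped), fallback_threshold,
        )
        return clumped, candidates.reset_index(drop=True), fallback_threshold
    raise NoInstrumentsError(stats.trait_name)


def select_instruments(
    stats: SummaryStatistics,
    ld: LdMatrix,
    primary_threshold: float = 5e-8,
    fallback_threshold: float = 5e-6,
    post_clump_min: int = 2,
    r2_max: float = 0.001,
    window_kb: float = 10_000,
    f_min: float = 10.0,
) -> InstrumentSet:
    """Full instrument selection: p-threshold (with fallback), clump, F filter.

    The F filter (strictly ``F > f_min``) is applied after clumping; the
    audit frame records each candidate's disposition so the order of
    operations can be inspected.
    """
    clumped, candidates, threshold = filter_by_pvalue(
        stats, ld, primary_threshold, fallback_threshold,
        post_clump_min, r2_max, window_kb,
    )
    f_all = f_statistic(clumped["beta"].to_numpy(), clumped["se"].to_numpy())
    f_all = np.atleast_1d(f_all)
    strong = f_all > f_min
    kept = clumped[strong].reset_index(drop=True)
    if len(kept) == 0:
        raise NoInstrumentsError(
            stats.trait_name,
            f"all clumped instruments for {stats.trait_name!r} have F <= {f_min}",
        )

    disposition = pd.Series("dropped_pval", index=stats.records.index, dtype=object)
    cand_ids = set(candidates["snp_id"])
    clump_ids = set(clumped["snp_id"])
    kept_ids = set(kept["snp_id"])
    ids = stats.records["snp_id"]
    disposition[ids.isin(cand_ids)] = "dropped_ld"
    disposition[ids.isin(clump_ids)] = "dropped_weak"
    disposition[ids.isin(kept_ids)] = "kept"
    f_by_id = dict(zip(clumped["snp_id"], f_all))
    audit = pd.DataFrame(
        {
            "snp_id": ids,
            "pval": stats.records["pval"],
            "f_stat": ids.map(f_by_id),
            "disposition": disposition,
        }
    )
    return InstrumentSet(
        exposure_name=stats.trait_name,
        records=kept,
        f_stats=pd.Series(f_all[strong], index=kept.index, name="f_stat"),
        threshold_used=threshold,
        audit=audit,
        trait_type=stats.trait_type,
        stratum=stats.stratum,
    )
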