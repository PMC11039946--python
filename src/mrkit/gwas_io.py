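"""Reading and writing GWAS summary statistics and MR result tables.

Summary statistics are held as a :class:`SummaryStatistics` object wrapping a
validated :class:`pandas.DataFrame` with one row per SNP. Input files are
plain TSV/CSV with configurable column names; the defaults follow the common
GWAS convention (``SNP, CHR, BP, A1, A2, EAF, BETA, SE, P, N``), where ``A1``
is the effect allele.

Validation is strict: rows violating the per-field invariants (non-positive
standard error, p-value outside ``(0, 1]``, non-ACGT alleles, identical
alleles, duplicated identifiers) are dropped and recorded with a per-row
reason so that the exclusion trail is auditable.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, EmptyInputError

VALID_ALLELES = frozenset("ACGT")

#: canonical internal column order for summary statistics frames
SUMSTAT_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]

#: default file-column -> internal-field mapping
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "SNP": "snp_id",
    "CHR": "chrom",
    "BP": "pos",
    "A1": "effect_allele",
    "A2": "other_allele",
    "EAF": "eaf",
    "BETA": "beta",
    "SE": "se",
    "P": "pval",
    "N": "n",
}

_MANDATORY = [
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pval",
]

#: stable method ordering used in results tables
METHOD_ORDER = ["wald_ratio", "ivw_re", "egger", "weighted_median", "not_estimable"]

RESULT_COLUMNS = [
    "exposure",
    "outcome",
    "stratum",
    "direction",
    "method",
    "n_snp",
    "beta",
    "se",
    "or_",
    "ci_low",
    "ci_high",
    "pval",
    "robust_flag",
    "display",
]


@dataclass(frozen=True)
class SnpAssociation:
    """One GWAS summary record for a single SNP."""

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    n: int | None = None

    def validation_error(self) -> str | None:
        """Return a reason string if any field invariant is violated, else None."""
        if self.effect_allele not in VALID_ALLELES:
            return f"invalid effect allele {self.effect_allele!r}"
        if self.other_allele not in VALID_ALLELES:
            return f"invalid other allele {self.other_allele!r}"
        if self.effect_allele == self.other_allele:
            return "identical alleles"
        if not np.isfinite(self.beta):
            return "nonfinite beta"
        if not (np.isfinite(self.se) and self.se > 0):
            return "nonpositive se"
        if not (np.isfinite(self.pval) and 0 < self.pval <= 1):
            return "pval outside (0, 1]"
        if self.eaf is not None and not np.isnan(self.eaf):
            if not 0 < self.eaf < 1:
                return "eaf outside (0, 1)"
        if self.n is not None and not np.isnan(self.n):
            if self.n <= 0:
                return "nonpositive n"
        return None


@dataclass
class SummaryStatistics:
    """A validated GWAS summary-statistics table for one trait.

    ``records`` uses the canonical internal columns (:data:`SUMSTAT_COLUMNS`);
    ``rejected`` records every dropped input row with its reason.
    For binary traits ``beta`` is on the log-odds scale.
    """

    trait_name: str
    records: pd.DataFrame
    trait_type: str = "continuous"  # {"continuous", "binary"}
    stratum: str = "all"  # {"all", "male", "female"}
    rejected: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["snp_id", "reason"])
    )

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ConfigurationError(f"unknown trait_type {self.trait_type!r}")
        if self.stratum not in ("all", "male", "female"):
            raise ConfigurationError(f"unknown stratum {self.stratum!r}")
        if len(self.records) == 0:
            raise EmptyInputError(f"no valid records for trait {self.trait_name!r}")

    @property
    def n_snps(self) -> int:
        return len(self.records)

    def lookup(self, snp_ids: Sequence[str]) -> pd.DataFrame:
        """Subset of records matching ``snp_ids`` (missing IDs are absent)."""
        idx = self.records.set_index("snp_id")
        present = [s for s in snp_ids if s in idx.index]
        return idx.loc[present].reset_index()


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _validate_frame(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vectorised row validation; returns (valid, rejected-with-reason)."""
    reasons = pd.Series("", index=df.index, dtype=object)

    def flag(mask: pd.Series, reason: str) -> None:
        new = mask & (reasons == "")
        reasons[new] = reason

    allele_ok = df["effect_allele"].isin(VALID_ALLELES) & df["other_allele"].isin(
        VALID_ALLELES
    )
    flag(~allele_ok, "invalid allele")
    flag(df["effect_allele"] == df["other_allele"], "identical alleles")
    flag(~np.isfinite(df["beta"]), "nonfinite beta")
    flag(~(np.isfinite(df["se"]) & (df["se"] > 0)), "nonpositive se")
    flag(~(np.isfinite(df["pval"]) & (df["pval"] > 0) & (df["pval"] <= 1)),
         "pval outside (0, 1]")
    eaf_present = df["eaf"].notna()
    flag(eaf_present & ~((df["eaf"] > 0) & (df["eaf"] < 1)), "eaf outside (0, 1)")
    n_present = df["n"].notna()
    flag(n_present & (df["n"] <= 0), "nonpositive n")
    flag(df["snp_id"].duplicated(keep="first"), "duplicate snp_id")

    bad = reasons != ""
    rejected = pd.DataFrame(
        {"snp_id": df.loc[bad, "snp_id"].astype(str), "reason": reasons[bad]}
    ).reset_index(drop=True)
    return df.loc[~bad].reset_index(drop=True), rejected


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_name: str | None = None,
    trait_type: str = "continuous",
    stratum: str = "all",
) -> SummaryStatistics:
    """Read a delimited GWAS summary-statistics file.

    The delimiter (tab or comma) is auto-detected from the header line.
    ``column_map`` maps file column names to internal field names; the
    default accepts the ``SNP/CHR/BP/A1/A2/EAF/BETA/SE/P/N`` convention.
    Alleles are uppercased before validation. Rows failing validation are
    dropped into ``SummaryStatistics.rejected`` with a reason; loading is
    order-preserving and deterministic.

    Raises
    ------
    ConfigurationError
        if a mandatory mapped column is absent from the file.
    EmptyInputError
        if no row survives validation.
    """
    path = Path(path)
    cmap = dict(column_map) if column_map is not None else dict(DEFAULT_COLUMN_MAP)
    sep = _detect_sep(path)
    raw = pd.read_csv(path, sep=sep, dtype={c: str for c in cmap
                                            if cmap[c] in ("snp_id", "chrom")})
    present = {src: dst for src, dst in cmap.items() if src in raw.columns}
    df = raw.rename(columns=present)
    missing = [f for f in _MANDATORY if f not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: missing mandatory column(s) for field(s) {missing} "
            f"(column map: {cmap})"
        )
    for opt in ("eaf", "n"):
        if opt not in df.columns:
            df[opt] = np.nan
    df = df[SUMSTAT_COLUMNS].copy()
    df["snp_id"] = df["snp_id"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce").astype("Int64")
    for col in ("eaf", "beta", "se", "pval", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()

    valid, rejected = _validate_frame(df)
    valid["pos"] = valid["pos"].astype(np.int64)
    if len(valid) == 0:
        raise EmptyInputError(f"{path}: zero valid rows after validation")
    return SummaryStatistics(
        trait_name=trait_name or path.stem,
        records=valid,
        trait_type=trait_type,
        stratum=stratum,
        rejected=rejected,
    )


def write_sumstats(stats: SummaryStatistics, path: str | Path) -> None:
    """Write summary statistics as TSV using the default column convention."""
    inv = {v: k for k, v in DEFAULT_COLUMN_MAP.items()}
    out = stats.records.rename(columns=inv)
    out.to_csv(path, sep="\t", index=False)


def _display_string(row: pd.Series) -> str:
    if pd.isna(row["beta"]):
        return "NA"
    if pd.notna(row.get("or_")):
        return (
            f"OR={row['or_']:.3f} "
            f"(95%CI: {row['ci_low']:.3f}, {row['ci_high']:.3f}), "
            f"P={row['pval']:.3f}"
        )
    return (
        f"beta={row['beta']:.3f} "
        f"(95%CI: {row['ci_low']:.3f}, {row['ci_high']:.3f}), "
        f"P={row['pval']:.3f}"
    )


def write_results_table(results: pd.DataFrame | Sequence[Mapping], path: str | Path) -> pd.DataFrame:
    """Write MR results as a TSV, one row per (exposure, outcome, stratum, method).

    Floats are serialised at full precision; a 3-decimal ``display`` column is
    added for human reading. Within each analysis the method rows are ordered
    IVW, MR-Egger, weighted median. Returns the frame actually written.

    Note: ``ci_low``/``ci_high`` are on the reporting scale — odds-ratio
    bounds for binary outcomes, beta bounds for continuous ones — matching
    the forest-plot convention.
    """
    df = pd.DataFrame(results)
    if len(df) == 0:
        raise EmptyInputError("no results to write")
    for col in RESULT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    rank = df["method"].map({m: i for i, m in enumerate(METHOD_ORDER)}).fillna(99)
    df = (
        df.assign(_rank=rank)
        .sort_values(["exposure", "outcome", "stratum", "direction", "_rank"],
                     kind="stable")
        .drop(columns="_rank")
        .reset_index(drop=True)
    )
    df["display"] = df.apply(_display_string, axis=1)
    df = df[RESULT_COLUMNS]
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=False, float_format="%.17g")
    Path(path).write_text(buf.getvalue())
    return df


def read_results_table(path: str | Path) -> pd.DataFrame:
    """Read back a results TSV written by :func:`write_results_table`."""
    return pd.read_csv(path, sep="\t")
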