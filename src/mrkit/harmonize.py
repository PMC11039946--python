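"""Allele harmonization between exposure instruments and outcome records.

For each instrument SNP the outcome record is aligned to the exposure's
effect allele:

* same allele pair -> kept as-is (``kept_same``);
* swapped pair -> outcome beta negated, EAF complemented (``kept_flipped``);
* palindromic pair (A/T or C/G on either side) -> dropped unconditionally —
  strand orientation is ambiguous and no frequency-based inference is
  attempted (``dropped_palindromic``);
* absent from the outcome GWAS -> dropped, no proxy lookup
  (``dropped_missing``);
* any other allele combination -> ``dropped_mismatch``.

The returned dataset carries both the kept records and a full audit of every
instrument's disposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import HarmonizationEmptyError
from .gwas_io import SummaryStatistics
from .instruments import InstrumentSet

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

ACTIONS = (
    "kept_same",
    "kept_flipped",
    "dropped_palindromic",
    "dropped_missing",
    "dropped_mismatch",
)

HARMONIZED_COLUMNS = ["snp_id", "beta_exp", "se_exp", "beta_out", "se_out"]


def is_palindromic(a1: str, a2: str) -> bool:
    """True for A/T, T/A, C/G, G/C allele pairs."""
    return COMPLEMENT.get(a1) == a2


@dataclass
class HarmonizedDataset:
    """Aligned exposure/outcome effect pairs for one analysis.

    ``records`` holds the kept SNPs (columns :data:`HARMONIZED_COLUMNS` plus
    ``action``); ``audit`` holds every instrument with its disposition.
    """

    exposure_name: str
    outcome_name: str
    records: pd.DataFrame
    audit: pd.DataFrame
    stratum: str = "all"
    direction: str = "forward"  # {"forward", "reverse"}
    outcome_binary: bool = True

    @property
    def n_snp(self) -> int:
        return len(self.records)

    @property
    def beta_exp(self) -> np.ndarray:
        return self.records["beta_exp"].to_numpy(dtype=float)

    @property
    def se_exp(self) -> np.ndarray:
        return self.records["se_exp"].to_numpy(dtype=float)

    @property
    def beta_out(self) -> np.ndarray:
        return self.records["beta_out"].to_numpy(dtype=float)

    @property
    def se_out(self) -> np.ndarray:
        return self.records["se_out"].to_numpy(dtype=float)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.records["snp_id"].to_numpy(dtype=object)

    def subset(self, keep) -> "HarmonizedDataset":
        """New dataset restricted to a boolean mask or list of snp_ids."""
        if isinstance(keep, (list, tuple, set, pd.Index)):
            mask = self.records["snp_id"].isin(set(keep)).to_numpy()
        else:
            mask = np.asarray(keep, dtype=bool)
        return HarmonizedDataset(
            exposure_name=self.exposure_name,
            outcome_name=self.outcome_name,
            records=self.records[mask].reset_index(drop=True),
            audit=self.audit,
            stratum=self.stratum,
            direction=self.direction,
            outcome_binary=self.outcome_binary,
        )

    @classmethod
    def from_arrays(
        cls,
        beta_exp,
        se_exp,
        beta_out,
        se_out,
        snp_ids=None,
        exposure_name: str = "exposure",
        outcome_name: str = "outcome",
        outcome_binary: bool = True,
        **kwargs,
    ) -> "HarmonizedDataset":
        """Convenience constructor from plain effect/SE arrays."""
        beta_exp = np.asarray(beta_exp, dtype=float)
        n = len(beta_exp)
        if snp_ids is None:
            snp_ids = [f"snp{i + 1}" for i in range(n)]
        records = pd.DataFrame(
            {
                "snp_id": list(snp_ids),
                "beta_exp": beta_exp,
                "se_exp": np.asarray(se_exp, dtype=float),
                "beta_out": np.asarray(beta_out, dtype=float),
                "se_out": np.asarray(se_out, dtype=float),
                "action": "kept_same",
            }
        )
        audit = records[["snp_id", "action"]].copy()
        return cls(
            exposure_name=exposure_name,
            outcome_name=outcome_name,
            records=records,
            audit=audit,
            outcome_binary=outcome_binary,
            **kwargs,
        )


def harmonize_pair(
    instruments: InstrumentSet,
    outcome: SummaryStatistics,
    direction: str = "forward",
) -> HarmonizedDataset:
    """Align outcome records to the instruments' effect alleles.

    Raises :class:`HarmonizationEmptyError` when no instrument survives.
    """
    exp = instruments.records
    merged = exp.merge(
        outcome.records[["snp_id", "effect_allele", "other_allele", "beta", "se"]],
        on="snp_id",
        how="left",
        suffixes=("", "_o"),
    )

    comp = merged["effect_allele"].map(COMPLEMENT)
    comp_o = merged["effect_allele_o"].map(COMPLEMENT)
    present = merged["beta_o"].notna()
    pal = (comp == merged["other_allele"]) | (
        present & (comp_o == merged["other_allele_o"])
    )
    same = present & (merged["effect_allele_o"] == merged["effect_allele"]) & (
        merged["other_allele_o"] == merged["other_allele"]
    )
    swapped = present & (merged["effect_allele_o"] == merged["other_allele"]) & (
        merged["other_allele_o"] == merged["effect_allele"]
    )

    # precedence: missing (no outcome record) > palindromic > same/swap > mismatch
    action = pd.Series("dropped_mismatch", index=merged.index, dtype=object)
    action[swapped] = "kept_flipped"
    action[same] = "kept_same"
    action[pal] = "dropped_palindromic"
    action[~present] = "dropped_missing"

    beta_out = merged["beta_o"].where(action.isin(("kept_same", "kept_flipped")))
    beta_out = beta_out.mask(action == "kept_flipped", -beta_out)
    se_out = merged["se_o"].where(action.isin(("kept_same", "kept_flipped")))

    audit = pd.DataFrame(
        {
            "snp_id": merged["snp_id"],
            "beta_exp": merged["beta"],
            "se_exp": merged["se"],
            "beta_out": beta_out,
            "se_out": se_out,
            "action": action,
        }
    )
    kept = audit[audit["action"].isin(("kept_same", "kept_flipped"))].reset_index(
        drop=True
    )
    if len(kept) == 0:
        raise HarmonizationEmptyError(instruments.exposure_name, outcome.trait_name)
    return HarmonizedDataset(
        exposure_name=instruments.exposure_name,
        outcome_name=outcome.trait_name,
        records=kept,
        audit=audit,
        stratum=outcome.stratum if direction == "reverse" else instruments.stratum,
        direction=direction,
        outcome_binary=(outcome.trait_type == "binary"),
    )
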