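"""iFISH spot-count classification and array-concordance tabulation.

Interphase FISH counts hybridisation spots per nucleus (>= 200 nuclei per
slide; doublet signals are assumed already collapsed to single spots
upstream). Per case and locus probe, the input is the fraction of nuclei
in each count class; classification applies percent-of-nuclei cutoffs:

* amplification  - > 10% of nuclei with locus:centromere ratio > 2 or
  tight signal clusters;
* homozygous deletion - >= 5% of nuclei with centromeric signals but no
  locus signal;
* gain - >= 5% of nuclei with increased spot number;
* loss - >= 10% of nuclei with decreased spot number;
* normal otherwise.

When several criteria fire, precedence is amplification > homozygous
deletion > gain > loss (the stronger call wins; the source protocol does
not state a combination rule, so the order is this package's choice).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .types import AMPLIFICATION, GAIN, HOMOZYGOUS_DELETION, LOSS

NORMAL = "normal"

MIN_NUCLEI = 200


@dataclass(frozen=True)
class IfishCount:
    """Per-case, per-locus spot-count summary as nuclei fractions."""

    case_id: str
    locus: str
    fraction_increased: float
    fraction_decreased: float
    fraction_no_locus_with_cep: float
    fraction_ratio_gt2_or_clusters: float
    n_nuclei: int

    def __post_init__(self) -> None:
        fracs = (
            self.fraction_increased,
            self.fraction_decreased,
            self.fraction_no_locus_with_cep,
            self.fraction_ratio_gt2_or_clusters,
        )
        if any(not 0 <= f <= 1 for f in fracs):
            raise ValueError(f"{self.case_id}/{self.locus}: fractions must be in [0, 1]")
        # increased / decreased / no-locus classes are mutually exclusive per nucleus
        if (
            self.fraction_increased
            + self.fraction_decreased
            + self.fraction_no_locus_with_cep
            > 1 + 1e-9
        ):
            raise ValueError(
                f"{self.case_id}/{self.locus}: mutually exclusive fractions sum > 1"
            )

    @property
    def low_nuclei(self) -> bool:
        """Flag slides below the 200-nuclei counting standard."""
        return self.n_nuclei < MIN_NUCLEI


def classify_ifish(count: IfishCount) -> str:
    """Classify one spot-count summary into a CN state (deterministic)."""
    if count.fraction_ratio_gt2_or_clusters > 0.10:
        return AMPLIFICATION
    if count.fraction_no_locus_with_cep >= 0.05:
        return HOMOZYGOUS_DELETION
    if count.fraction_increased >= 0.05:
        return GAIN
    if count.fraction_decreased >= 0.10:
        return LOSS
    return NORMAL


def _normalize(state: str) -> str:
    # array calls say "neutral" where iFISH says "normal"
    return NORMAL if state == "neutral" else state


def concordance_table(
    array_calls: Mapping[tuple[str, str], str],
    ifish_calls: Mapping[tuple[str, str], str],
) -> tuple[dict[str, pd.DataFrame], float]:
    """Per-locus contingency of array vs iFISH state, plus overall % agreement.

    Both inputs map (case_id, locus) -> state; only shared keys are
    tabulated. The array's "neutral" and iFISH's "normal" are treated as
    the same state for agreement.
    """
    shared = sorted(set(array_calls) & set(ifish_calls))
    if not shared:
        raise ValueError("no shared (case, locus) pairs between call sets")
    rows = pd.DataFrame(
        {
            "locus": [k[1] for k in shared],
            "array": [_normalize(array_calls[k]) for k in shared],
            "ifish": [_normalize(ifish_calls[k]) for k in shared],
        }
    )
    tables = {
        locus: pd.crosstab(sub["array"], sub["ifish"])
        for locus, sub in rows.groupby("locus")
    }
    agreement_pct = 100.0 * float((rows["array"] == rows["ifish"]).mean())
    return tables, agreement_pct


def classify_counts(counts: Sequence[IfishCount]) -> dict[tuple[str, str], str]:
    """Classify a batch of counts into a (case, locus) -> state mapping."""
    return {(c.case_id, c.locus): classify_ifish(c) for c in counts}
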