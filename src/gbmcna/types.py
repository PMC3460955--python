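"""Shared genomic value objects.

All coordinates in this library are 1-based and inclusive at both ends,
matching how positions are printed in tumor-genomics reports (e.g. a
deleted segment "from the 21,978,443 bp to the 22,119,128 bp position").
BED interchange converts to 0-based half-open at the I/O boundary only.
Segment lengths are reported as ``end - start`` base pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

AMPLIFICATION = "amplification"
HOMOZYGOUS_DELETION = "homozygous_deletion"
GAIN = "gain"
LOSS = "loss"
NEUTRAL = "neutral"

#: CN-altered event kinds (what a segment can be called).
EVENT_KINDS = (AMPLIFICATION, HOMOZYGOUS_DELETION, GAIN, LOSS)
#: All per-probe states, including the diploid baseline.
CN_STATES = (HOMOZYGOUS_DELETION, LOSS, NEUTRAL, GAIN, AMPLIFICATION)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A closed genomic interval (1-based, both ends inclusive)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")

    @property
    def length_bp(self) -> int:
        """Segment length as printed in region reports (end - start)."""
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the intervals share >= 1 bp on the same chromosome."""
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene locus used for region annotation and gene-level CN."""

    symbol: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.symbol}: start {self.start} > end {self.end}")

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


@dataclass(frozen=True)
class CnaEvent:
    """One contiguous amplified/deleted/gained/lost segment in one sample."""

    sample_id: str
    chrom: str
    start: int
    end: int
    kind: str
    n_probes: int
    mean_cn: float

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.n_probes < 1:
            raise ValueError("n_probes must be >= 1")

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


@dataclass(frozen=True)
class RecurrentRegion:
    """Cross-sample aggregation of events: a minimal common region.

    ``frequency_pct`` is the integer percent of the cohort carrying the
    region (``None`` when no cohort size was supplied); ``genes`` holds
    symbols of overlapping gene models in genomic order.
    """

    interval: GenomicInterval
    kind: str
    case_ids: tuple[str, ...]
    n_cases: int
    frequency_pct: int | None
    genes: tuple[str, ...]
    length_bp: int


_PROFILE_COLUMNS = ("probe_id", "chrom", "pos", "cn")


@dataclass
class CnProfile:
    """Per-sample ordered probe-level CN values on genomic coordinates.

    ``probes`` is a DataFrame with columns probe_id, chrom, pos, cn.  It is
    sorted by (chrom, pos) on construction; negative CN values or duplicate
    positions within a chromosome are rejected.
    """

    sample_id: str
    probes: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _PROFILE_COLUMNS if c not in self.probes.columns]
        if missing:
            raise ValueError(f"probe table missing columns: {missing}")
        df = self.probes.loc[:, list(_PROFILE_COLUMNS)].copy()
        df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
        cn = df["cn"].to_numpy(dtype=float)
        if (cn < 0).any() or pd.isna(cn).any():
            raise ValueError(f"sample {self.sample_id}: CN values must be >= 0")
        if df.duplicated(subset=["chrom", "pos"]).any():
            raise ValueError(f"sample {self.sample_id}: duplicate probe positions")
        self.probes = df

    def __len__(self) -> int:
        return len(self.probes)
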