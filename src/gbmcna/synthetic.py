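"""Synthetic GBM cohort generator and packaged clinical/dosage fixtures.

The generator emulates the statistical structure a 46-tumor SNP-array
cohort is assumed to have: a diploid baseline (CN ~ N(2, sd)) with
segmental events implanted at configured per-region prevalences, mRNA
expression linearly coupled to gene-level CN for a configurable gene
subset, exponential overall survival with an amplification-dependent
hazard, and iFISH nuclei-fraction summaries drawn binomially around
state-typical rates. Default prevalences follow the reported recurrence
rates: amplicons on chromosomes 7 (50%), 12 (22%), 1 (11%), 4 (9%),
11 (4%) and 17 (4%); homozygous deletions at 9p21 (52%) and 10q (22%).

Everything is driven by one integer seed: equal seeds give bit-identical
cohorts.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .integration import summarize_gene_cn
from .ifish import IfishCount
from .types import (
    AMPLIFICATION,
    GAIN,
    HOMOZYGOUS_DELETION,
    LOSS,
    NEUTRAL,
    CnProfile,
    GeneModel,
    GenomicInterval,
)

# ---------------------------------------------------------------------------
# configuration

# calling interval each implant level must respect (amp exclusive >5, etc.)
_KIND_BOUNDS = {
    AMPLIFICATION: (5.0, np.inf),
    HOMOZYGOUS_DELETION: (0.0, 0.8),
    GAIN: (2.5, 5.0),
    LOSS: (0.8, 1.3),
}


@dataclass(frozen=True)
class EventSpec:
    """One implantable segmental event: where, what, how often, how strong."""

    region: GenomicInterval
    kind: str
    prevalence: float
    cn_level: tuple[float, float]
    boundary_jitter: int = 100_000

    def __post_init__(self) -> None:
        if not 0 <= self.prevalence <= 1:
            raise ValueError("prevalence must be in [0, 1]")
        lo, hi = self.cn_level
        if lo > hi:
            raise ValueError("cn_level bounds out of order")
        bound_lo, bound_hi = _KIND_BOUNDS[self.kind]
        if self.kind == AMPLIFICATION and lo <= bound_lo:
            raise ValueError("amplification cn_level low bound must be > 5")
        if self.kind == HOMOZYGOUS_DELETION and hi >= bound_hi:
            raise ValueError("homozygous_deletion cn_level high bound must be < 0.8")
        if self.kind in (GAIN, LOSS) and not (bound_lo <= lo and hi <= bound_hi):
            raise ValueError(f"{self.kind} cn_level must lie within {_KIND_BOUNDS[self.kind]}")
        if self.boundary_jitter < 0:
            raise ValueError("boundary_jitter must be >= 0")


def default_chromosomes() -> list[tuple[str, int]]:
    """The eight recurrently altered chromosomes at hg17-like lengths."""
    return [
        ("chr1", 245_000_000),
        ("chr4", 191_000_000),
        ("chr7", 158_000_000),
        ("chr9", 138_000_000),
        ("chr10", 135_000_000),
        ("chr11", 134_000_000),
        ("chr12", 132_000_000),
        ("chr17", 78_000_000),
    ]


def default_event_specs() -> list[EventSpec]:
    """Implant table at the reported cohort recurrence rates.

    Regions sit at the recurrently involved loci (7p11.2/EGFR,
    12q14/CDK4-MDM2, 1q32.1/MDM4, 4q12/PDGFRA, 9p21.3/CDKN2A-MTAP,
    10q23.31/PTEN) and are sized >= 1.5 Mb so every implant spans well
    over ``min_probes_per_event`` probes at the default probe spacing.
    """
    amp = (5.5, 8.0)
    homdel = (0.0, 0.4)
    return [
        EventSpec(GenomicInterval("chr7", 54_500_001, 56_000_000), AMPLIFICATION, 0.50, amp),
        EventSpec(GenomicInterval("chr12", 56_000_001, 58_000_000), AMPLIFICATION, 0.22, amp),
        EventSpec(GenomicInterval("chr1", 202_000_001, 204_000_000), AMPLIFICATION, 0.11, amp),
        EventSpec(GenomicInterval("chr4", 54_000_001, 56_000_000), AMPLIFICATION, 0.09, amp),
        EventSpec(GenomicInterval("chr11", 32_000_001, 34_000_000), AMPLIFICATION, 0.04, amp),
        EventSpec(GenomicInterval("chr17", 70_000_001, 72_000_000), AMPLIFICATION, 0.04, amp),
        EventSpec(GenomicInterval("chr9", 21_000_001, 23_000_000), HOMOZYGOUS_DELETION, 0.52, homdel),
        EventSpec(GenomicInterval("chr10", 89_000_001, 91_000_000), HOMOZYGOUS_DELETION, 0.22, homdel),
    ]


def default_gene_models() -> list[GeneModel]:
    """Gene loci at plausible hg17-like coordinates for annotation and dosage.

    Genes inside the implant regions (EGFR, CDK4, PDGFRA, CDKN2A, MTAP,
    PTEN, ...) plus a handful of neutral-region genes; CDKN2A carries the
    printed 9p21.3 minimal-deletion coordinates.
    """
    return [
        GeneModel("MDM4", "chr1", 202_600_001, 202_800_000),
        GeneModel("SOX13", "chr1", 203_000_001, 203_200_000),
        GeneModel("TP73", "chr1", 3_500_001, 3_700_000),
        GeneModel("PDGFRA", "chr4", 54_200_001, 54_400_000),
        GeneModel("FIP1L1", "chr4", 54_600_001, 54_800_000),
        GeneModel("CLOCK", "chr4", 55_400_001, 55_600_000),
        GeneModel("EGFR", "chr7", 54_900_001, 55_200_000),
        GeneModel("LANCL2", "chr7", 55_400_001, 55_600_000),
        GeneModel("TES", "chr7", 115_000_001, 115_200_000),
        GeneModel("MTAP", "chr9", 21_800_001, 21_900_000),
        GeneModel("CDKN2A", "chr9", 21_978_443, 22_119_128),
        GeneModel("CDKN2B", "chr9", 22_190_001, 22_290_000),
        GeneModel("PTEN", "chr10", 89_600_001, 89_800_000),
        GeneModel("HK1", "chr10", 70_000_001, 70_200_000),
        GeneModel("EIF3M", "chr11", 32_600_001, 32_800_000),
        GeneModel("KRAS", "chr12", 25_200_001, 25_400_000),
        GeneModel("RAP1B", "chr12", 57_000_001, 57_200_000),
        GeneModel("CDK4", "chr12", 56_400_001, 56_600_000),
        GeneModel("MDM2", "chr12", 57_400_001, 57_600_000),
        GeneModel("GRB2", "chr17", 70_800_001, 71_000_000),
    ]


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition knobs for the synthetic cohort."""

    n_samples: int = 46
    probe_spacing: int = 100_000
    chromosomes: tuple[tuple[str, int], ...] = field(
        default_factory=lambda: tuple(default_chromosomes())
    )
    event_specs: tuple[EventSpec, ...] = field(
        default_factory=lambda: tuple(default_event_specs())
    )
    baseline_cn: float = 2.0
    noise_sd: float = 0.15
    dosage_coupled_fraction: float = 0.5
    expression_noise_sd: float = 1.0
    hazard_ratio_amplified: float = 6.5
    baseline_median_survival: float = 13.0
    censoring_rate: float = 0.02
    hazard_region: GenomicInterval = field(
        default_factory=lambda: GenomicInterval("chr4", 54_000_001, 56_000_000)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        for name in ("dosage_coupled_fraction", "censoring_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.hazard_ratio_amplified <= 0:
            raise ValueError("hazard_ratio_amplified must be positive")
        if self.noise_sd < 0 or self.expression_noise_sd < 0:
            raise ValueError("noise sds must be >= 0")
        specs = list(self.event_specs)
        for i, a in enumerate(specs):
            for b in specs[i + 1:]:
                if a.kind != b.kind and a.region.overlaps(b.region):
                    raise ValueError(
                        f"contradictory event specs overlap: {a.region} ({a.kind}) "
                        f"vs {b.region} ({b.kind})"
                    )


def sample_ids(n: int) -> list[str]:
    return [f"S{i + 1:02d}" for i in range(n)]


# ---------------------------------------------------------------------------
# generators

def build_probe_map(config: CohortConfig) -> pd.DataFrame:
    """Evenly spaced probe grid over the configured chromosomes."""
    rows = []
    for chrom, length in config.chromosomes:
        positions = np.arange(config.probe_spacing, length + 1, config.probe_spacing)
        for p in positions:
            rows.append((f"{chrom}_{p}", chrom, int(p)))
    df = pd.DataFrame(rows, columns=["probe_id", "chrom", "pos"])
    return df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def generate_cohort(
    config: CohortConfig,
) -> tuple[pd.DataFrame, list[CnProfile], pd.DataFrame]:
    """Simulate (probe map, per-sample profiles, truth table of implants).

    Each profile is a diploid baseline N(baseline_cn, noise_sd), clipped
    at 0, with event levels (uniform in the spec's cn_level bounds, plus
    the same probe noise) overriding the baseline inside the jittered
    implant interval. The truth table records the exact implanted
    intervals, kinds and levels.
    """
    rng = np.random.default_rng(config.seed)
    probe_map = build_probe_map(config)
    ids = sample_ids(config.n_samples)
    chrom_arr = probe_map["chrom"].to_numpy()
    pos_arr = probe_map["pos"].to_numpy()
    chrom_len = dict(config.chromosomes)

    baseline = rng.normal(
        config.baseline_cn, config.noise_sd, size=(len(probe_map), config.n_samples)
    )
    truth_rows: list[tuple] = []
    for spec in config.event_specs:
        carriers = rng.random(config.n_samples) < spec.prevalence
        for j in np.flatnonzero(carriers):
            jit = spec.boundary_jitter
            start = spec.region.start + (int(rng.integers(-jit, jit + 1)) if jit else 0)
            end = spec.region.end + (int(rng.integers(-jit, jit + 1)) if jit else 0)
            start = max(1, start)
            end = min(chrom_len[spec.region.chrom], max(end, start))
            level = float(rng.uniform(*spec.cn_level))
            mask = (chrom_arr == spec.region.chrom) & (pos_arr >= start) & (pos_arr <= end)
            baseline[mask, j] = level + rng.normal(0, config.noise_sd, size=mask.sum())
            truth_rows.append(
                (spec.region.chrom, start, end, ids[j], spec.kind, level)
            )
    np.clip(baseline, 0, None, out=baseline)

    profiles = [
        CnProfile(
            ids[j],
            probe_map.assign(cn=baseline[:, j]),
        )
        for j in range(config.n_samples)
    ]
    truth = pd.DataFrame(
        truth_rows, columns=["chrom", "start", "end", "sample", "kind", "cn_level"]
    ).sort_values(["sample", "chrom", "start"], kind="stable").reset_index(drop=True)
    return probe_map, profiles, truth


def select_coupled_genes(
    genes: Sequence[GeneModel], fraction: float, seed: int
) -> list[str]:
    """Seeded choice of the dosage-coupled gene subset."""
    rng = np.random.default_rng(seed)
    k = int(round(fraction * len(genes)))
    picked = rng.choice(len(genes), size=k, replace=False)
    return sorted(genes[i].symbol for i in picked)


def generate_expression(
    profiles: Sequence[CnProfile],
    gene_models: Sequence[GeneModel],
    coupled_genes: Sequence[str],
    noise_sd: float = 1.0,
    seed: int = 0,
    slope: float = 1.0,
    intercept: float = 6.0,
    baseline_expr_sd: float = 1.0,
) -> pd.DataFrame:
    """RMA-scale expression matrix (genes x samples), linearly CN-coupled.

    Coupled genes follow expr = intercept + slope * (gene-level CN) +
    N(0, noise_sd); uncoupled genes are drawn independently of CN around
    the diploid expectation. The achievable population R^2 of a coupled
    gene is slope^2 var(CN) / (slope^2 var(CN) + noise_sd^2).
    """
    if len(gene_models) == 0:
        raise ValueError("empty gene set")
    probe_chroms = set(profiles[0].probes["chrom"].unique()) if profiles else set()
    coupled = set(coupled_genes)
    known = {g.symbol for g in gene_models}
    unknown = coupled - known
    if unknown:
        raise ValueError(f"coupled genes missing from gene models: {sorted(unknown)}")
    for g in gene_models:
        if g.symbol in coupled and g.chrom not in probe_chroms:
            raise ValueError(f"coupled gene {g.symbol} on chromosome without probes")
    rng = np.random.default_rng(seed)
    cols = [p.sample_id for p in profiles]
    data = np.empty((len(gene_models), len(cols)))
    diploid_mean = intercept + slope * 2.0
    for i, gene in enumerate(gene_models):
        if gene.symbol in coupled:
            cn = np.array(
                [summarize_gene_cn(p, gene).value for p in profiles]
            )
            data[i] = intercept + slope * cn + rng.normal(0, noise_sd, len(cols))
        else:
            data[i] = rng.normal(diploid_mean, baseline_expr_sd, len(cols))
    return pd.DataFrame(
        data, index=pd.Index([g.symbol for g in gene_models], name="gene"), columns=cols
    )


def amplified_cases(
    truth: pd.DataFrame, region: GenomicInterval, kind: str = AMPLIFICATION
) -> set[str]:
    """Cases whose truth-table events of ``kind`` overlap ``region``."""
    hits = truth[
        (truth["kind"] == kind)
        & (truth["chrom"] == region.chrom)
        & (truth["start"] <= region.end)
        & (truth["end"] >= region.start)
    ]
    return set(hits["sample"])


def generate_survival(
    truth: pd.DataFrame, config: CohortConfig, seed: int | None = None
) -> pd.DataFrame:
    """Clinical table with exponential survival and event-dependent hazard.

    Cases carrying an amplification overlapping ``config.hazard_region``
    die at rate ``hazard_ratio_amplified`` times the baseline
    (ln 2 / baseline_median_survival per month); a ``censoring_rate``
    fraction of records is marked alive at its drawn time.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    ids = sample_ids(config.n_samples)
    carriers = amplified_cases(truth, config.hazard_region)
    base_rate = np.log(2.0) / config.baseline_median_survival
    rows = []
    for case in ids:
        rate = base_rate * (config.hazard_ratio_amplified if case in carriers else 1.0)
        t = float(rng.exponential(1.0 / rate))
        censored = bool(rng.random() < config.censoring_rate)
        rows.append((case, t, ALIVE_STATUS if censored else DECEASED_STATUS))
    return pd.DataFrame(rows, columns=["case_id", "survival_months", "vital_status"])


DECEASED_STATUS = "deceased"
ALIVE_STATUS = "alive"


# state-typical nuclei fractions for iFISH count simulation
_IFISH_RATES: dict[str, dict[str, float]] = {
    AMPLIFICATION: dict(incr=0.45, decr=0.01, nolocus=0.0, ratio=0.40),
    GAIN: dict(incr=0.30, decr=0.01, nolocus=0.0, ratio=0.01),
    LOSS: dict(incr=0.01, decr=0.35, nolocus=0.01, ratio=0.0),
    HOMOZYGOUS_DELETION: dict(incr=0.0, decr=0.20, nolocus=0.40, ratio=0.0),
    NEUTRAL: dict(incr=0.01, decr=0.02, nolocus=0.005, ratio=0.005),
    "normal": dict(incr=0.01, decr=0.02, nolocus=0.005, ratio=0.005),
}


def generate_ifish_counts(
    true_states: Mapping[tuple[str, str], str],
    n_nuclei: int = 200,
    seed: int = 0,
) -> list[IfishCount]:
    """Binomially noisy nuclei-fraction summaries around state-typical rates."""
    rng = np.random.default_rng(seed)
    counts = []
    for (case, locus), state in sorted(true_states.items()):
        rates = _IFISH_RATES[state]
        draw = lambda p: float(rng.binomial(n_nuclei, p)) / n_nuclei  # noqa: E731
        counts.append(
            IfishCount(
                case_id=case,
                locus=locus,
                fraction_increased=draw(rates["incr"]),
                fraction_decreased=draw(rates["decr"]),
                fraction_no_locus_with_cep=draw(rates["nolocus"]),
                fraction_ratio_gt2_or_clusters=draw(rates["ratio"]),
                n_nuclei=n_nuclei,
            )
        )
    return counts


def truth_states_at_loci(
    truth: pd.DataFrame,
    loci: Mapping[str, GenomicInterval],
    case_ids: Sequence[str],
) -> dict[tuple[str, str], str]:
    """Per (case, locus) true CN state implied by the truth table."""
    states: dict[tuple[str, str], str] = {}
    for case in case_ids:
        sub = truth[truth["sample"] == case]
        for locus, iv in loci.items():
            hit = sub[
                (sub["chrom"] == iv.chrom)
                & (sub["start"] <= iv.end)
                & (sub["end"] >= iv.start)
            ]
            states[(case, locus)] = str(hit["kind"].iloc[0]) if len(hit) else NEUTRAL
    return states


# ---------------------------------------------------------------------------
# packaged fixtures

_TABLE1_SHA256 = "bf1e6ebbc5ec61085c478ae476ec176d51a6bff3c7de0c473ac7a571c5dc3fe6"
_TABLE2_SHA256 = "487b7b7ffb009c5fc7ee6fb39cab51c4e4a898a89127e80643a1888626f4e3f5"


def _load_fixture(name: str, expected_sha256: str) -> pd.DataFrame:
    raw = (resources.files("gbmcna") / "data" / name).read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != expected_sha256:
        raise ValueError(f"fixture {name} checksum mismatch ({digest})")
    from io import BytesIO

    return pd.read_csv(BytesIO(raw), sep="\t", comment="#")


def load_table1_fixture() -> pd.DataFrame:
    """The packaged 46-case clinical cohort table."""
    df = _load_fixture("table1_clinical.tsv", _TABLE1_SHA256)
    assert len(df) == 46
    return df


def load_table2_fixture() -> pd.DataFrame:
    """The packaged 46-gene dosage-correlation table (gene, cytoband, R^2)."""
    df = _load_fixture("table2_dosage.tsv", _TABLE2_SHA256)
    assert len(df) == 46
    return df
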