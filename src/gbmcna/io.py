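"""Readers/writers for the pipeline's tab-separated formats, plus the
umbrella pipeline runner.

Native tables are TSV with a single ``#``-prefixed provenance line above a
plain header row; floats are written to 6 significant digits so reruns are
byte-identical. Genomic coordinates are 1-based inclusive everywhere in
memory and in native tables; BED import/export converts to 0-based
half-open at the file boundary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cn_calling import CallingThresholds, segment_cohort
from .ifish import classify_counts, concordance_table
from .integration import FilterConfig, dosage_screen, gene_cn_matrix
from .recurrence import minimal_common_region, recurrence_frequency
from .survival import (
    km_estimate,
    km_median,
    logrank_test,
    records_from_clinical,
    stratify_by_event,
)
from .synthetic import (
    AMPLIFICATION,
    CohortConfig,
    default_gene_models,
    generate_cohort,
    generate_expression,
    generate_ifish_counts,
    generate_survival,
    select_coupled_genes,
    truth_states_at_loci,
    sample_ids,
)
from .types import CnaEvent, CnProfile, GeneModel, GenomicInterval, HOMOZYGOUS_DELETION

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"


def _write_tsv(df: pd.DataFrame, path: Path | str, kind: str) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# gbmcna {kind} v{__version__}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FMT)


def _read_tsv(path: Path | str, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:  # pandas raises with line context
        raise ValueError(f"{path}: malformed table ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


# ---------------------------------------------------------------------------
# probe tables

def write_probe_table(
    probe_map: pd.DataFrame, profiles: Sequence[CnProfile], path: Path | str
) -> None:
    """Probe map plus one CN column per sample."""
    wide = probe_map[["probe_id", "chrom", "pos"]].copy()
    for p in profiles:
        aligned = p.probes.set_index(["chrom", "pos"])["cn"]
        wide[p.sample_id] = aligned.loc[
            list(zip(wide["chrom"], wide["pos"]))
        ].to_numpy()
    _write_tsv(wide, path, "probe-cn-table")


def read_probe_table(path: Path | str) -> tuple[pd.DataFrame, list[CnProfile]]:
    df = _read_tsv(path, ["probe_id", "chrom", "pos"])
    probe_map = df[["probe_id", "chrom", "pos"]].copy()
    samples = [c for c in df.columns if c not in ("probe_id", "chrom", "pos")]
    profiles = [
        CnProfile(s, probe_map.assign(cn=df[s].to_numpy(dtype=float)))
        for s in samples
    ]
    return probe_map, profiles


# ---------------------------------------------------------------------------
# genes (BED) and events

def read_bed(path: Path | str) -> list[GeneModel]:
    """Read gene models from BED (0-based half-open -> 1-based inclusive)."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: BED line needs >= 4 fields")
            chrom, start, end, name = parts[0], parts[1], parts[2], parts[3]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start_i < 0 or end_i <= start_i:
                raise ValueError(
                    f"{path}:{lineno}: invalid 0-based half-open interval"
                )
            genes.append(GeneModel(name, chrom, start_i + 1, end_i))
    return genes


def write_bed(genes: Sequence[GeneModel], path: Path | str) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.symbol}\n")


_EVENT_COLS = ["sample_id", "chrom", "start", "end", "kind", "n_probes", "mean_cn"]


def events_frame(events: Sequence[CnaEvent]) -> pd.DataFrame:
    return pd.DataFrame([asdict(e) for e in events], columns=_EVENT_COLS)


def write_events(events: Sequence[CnaEvent], path: Path | str) -> None:
    """Native 1-based inclusive event report."""
    _write_tsv(events_frame(events), path, "cna-events")


def read_events(path: Path | str) -> list[CnaEvent]:
    df = _read_tsv(path, _EVENT_COLS)
    return [
        CnaEvent(
            sample_id=str(r.sample_id),
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            kind=str(r.kind),
            n_probes=int(r.n_probes),
            mean_cn=float(r.mean_cn),
        )
        for r in df.itertuples()
    ]


def write_events_bed(events: Sequence[CnaEvent], path: Path | str) -> None:
    """BED export (0-based half-open) for genome browsers."""
    with open(path, "w") as fh:
        for e in sorted(events, key=lambda e: (e.chrom, e.start, e.sample_id)):
            fh.write(
                f"{e.chrom}\t{e.start - 1}\t{e.end}\t{e.sample_id}\t"
                f"{e.kind}\t{e.n_probes}\t{FLOAT_FMT % e.mean_cn}\n"
            )


def read_events_bed(path: Path | str) -> list[CnaEvent]:
    events = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 7:
                raise ValueError(f"{path}:{lineno}: expected 7 BED fields")
            events.append(
                CnaEvent(
                    sample_id=parts[3],
                    chrom=parts[0],
                    start=int(parts[1]) + 1,
                    end=int(parts[2]),
                    kind=parts[4],
                    n_probes=int(parts[5]),
                    mean_cn=float(parts[6]),
                )
            )
    return events


# ---------------------------------------------------------------------------
# clinical / expression

def write_clinical(df: pd.DataFrame, path: Path | str) -> None:
    _write_tsv(df, path, "clinical")


def read_clinical(path: Path | str) -> pd.DataFrame:
    return _read_tsv(path, ["case_id", "survival_months", "vital_status"])


def write_expression(df: pd.DataFrame, path: Path | str) -> None:
    _write_tsv(df.reset_index(), path, "expression")


def read_expression(path: Path | str) -> pd.DataFrame:
    return _read_tsv(path, ["gene"]).set_index("gene")


def write_truth(truth: pd.DataFrame, path: Path | str) -> None:
    _write_tsv(truth, path, "truth-events")


def write_report(tables: dict[str, pd.DataFrame], path: Path | str) -> None:
    """Concatenated multi-table report, one `## name` section per table."""
    with open(path, "w") as fh:
        fh.write(f"# gbmcna report v{__version__}\n")
        for name, df in tables.items():
            fh.write(f"## {name}\n")
            df.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# pipeline

@dataclass
class PipelineConfig:
    """Everything one run needs; round-trips losslessly through YAML."""

    outdir: str = "cna_run"
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    thresholds: CallingThresholds = field(default_factory=CallingThresholds)
    filter: FilterConfig = field(default_factory=FilterConfig)
    min_cases: int = 2
    log_level: str = "INFO"

    def to_yaml(self, path: Path | str) -> None:
        def encode(obj):
            if isinstance(obj, GenomicInterval):
                return {"chrom": obj.chrom, "start": obj.start, "end": obj.end}
            return asdict(obj)

        payload = {
            "outdir": self.outdir,
            "seed": self.seed,
            "cohort": asdict(self.cohort) | {
                "hazard_region": encode(self.cohort.hazard_region)
            },
            "thresholds": asdict(self.thresholds),
            "filter": asdict(self.filter),
            "min_cases": self.min_cases,
            "log_level": self.log_level,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        cohort_raw = payload.get("cohort", {})
        if "hazard_region" in cohort_raw:
            cohort_raw["hazard_region"] = GenomicInterval(**cohort_raw["hazard_region"])
        if "event_specs" in cohort_raw:
            from .synthetic import EventSpec

            cohort_raw["event_specs"] = tuple(
                EventSpec(
                    region=GenomicInterval(**s["region"]),
                    kind=s["kind"],
                    prevalence=s["prevalence"],
                    cn_level=tuple(s["cn_level"]),
                    boundary_jitter=s.get("boundary_jitter", 100_000),
                )
                for s in cohort_raw["event_specs"]
            )
        if "chromosomes" in cohort_raw:
            cohort_raw["chromosomes"] = tuple(
                (c, int(l)) for c, l in cohort_raw["chromosomes"]
            )
        return cls(
            outdir=payload.get("outdir", "cna_run"),
            seed=payload.get("seed", 0),
            cohort=CohortConfig(**cohort_raw),
            thresholds=CallingThresholds(**payload.get("thresholds", {})),
            filter=FilterConfig(**payload.get("filter", {})),
            min_cases=payload.get("min_cases", 2),
            log_level=payload.get("log_level", "INFO"),
        )


def run_pipeline(config: PipelineConfig) -> dict:
    """simulate -> call -> recur -> dosage -> survival -> iFISH concordance.

    Writes every stage's table under ``config.outdir`` plus a manifest
    (versions, seed, thresholds); identical configs give byte-identical
    outputs. Returns the manifest dict.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_cfg = replace(config.cohort, seed=config.seed)

    def stage(name):
        logger.info("[%s] running", name)

    try:
        stage("simulate")
        probe_map, profiles, truth = generate_cohort(cohort_cfg)
        covered = set(probe_map["chrom"].unique())
        genes = [g for g in default_gene_models() if g.chrom in covered]
        coupled = select_coupled_genes(
            genes, cohort_cfg.dosage_coupled_fraction, config.seed + 1
        )
        expr = generate_expression(
            profiles, genes, coupled,
            noise_sd=cohort_cfg.expression_noise_sd, seed=config.seed + 2,
        )
        clinical = generate_survival(truth, cohort_cfg, seed=config.seed + 3)
        write_probe_table(probe_map, profiles, out / "probes.tsv")
        write_truth(truth, out / "truth.tsv")
        write_expression(expr, out / "expression.tsv")
        write_clinical(clinical, out / "clinical.tsv")
        write_bed(genes, out / "genes.bed")
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc

    try:
        stage("call")
        events = segment_cohort(profiles, config.thresholds)
        write_events(events, out / "events.tsv")
        write_events_bed(events, out / "events.bed")
    except Exception as exc:
        raise RuntimeError(f"stage 'call' failed: {exc}") from exc

    try:
        stage("recur")
        regions = []
        for kind in (AMPLIFICATION, HOMOZYGOUS_DELETION):
            regions.extend(
                minimal_common_region(
                    events, kind, config.min_cases,
                    cohort_size=cohort_cfg.n_samples, genes=genes,
                )
            )
        region_rows = [
            {
                "chrom": r.interval.chrom,
                "start": r.interval.start,
                "end": r.interval.end,
                "kind": r.kind,
                "n_cases": r.n_cases,
                "frequency_pct": r.frequency_pct,
                "length_kb": r.length_bp / 1000.0,
                "case_ids": ",".join(r.case_ids),
                "genes": ",".join(r.genes),
            }
            for r in regions
        ]
        freq_rows = [
            {
                "chrom": spec.region.chrom,
                "start": spec.region.start,
                "end": spec.region.end,
                "kind": spec.kind,
                "n_cases": recurrence_frequency(
                    events, spec.region, spec.kind, cohort_cfg.n_samples
                )[0],
                "frequency_pct": recurrence_frequency(
                    events, spec.region, spec.kind, cohort_cfg.n_samples
                )[1],
            }
            for spec in cohort_cfg.event_specs
        ]
        _write_tsv(pd.DataFrame(region_rows), out / "regions.tsv", "recurrent-regions")
        _write_tsv(pd.DataFrame(freq_rows), out / "frequencies.tsv", "recurrence-frequencies")
    except Exception as exc:
        raise RuntimeError(f"stage 'recur' failed: {exc}") from exc

    try:
        stage("dosage")
        cn_mat = gene_cn_matrix(profiles, genes)
        results = dosage_screen(cn_mat, expr, config.filter)
        dosage_df = pd.DataFrame(
            [
                {
                    "gene": d.gene,
                    "n": d.n,
                    "r": d.r,
                    "r_squared": d.r_squared,
                    "p_value": d.p_value,
                    "passes_filter": d.passes_filter,
                }
                for d in results
            ]
        )
        _write_tsv(dosage_df, out / "dosage.tsv", "dosage-screen")
    except Exception as exc:
        raise RuntimeError(f"stage 'dosage' failed: {exc}") from exc

    try:
        stage("survival")
        records = records_from_clinical(clinical)
        pos, neg = stratify_by_event(records, events, cohort_cfg.hazard_region)
        rows = []
        if pos and neg:
            med_pos = km_median(km_estimate(pos))
            med_neg = km_median(km_estimate(neg))
            lr = logrank_test(pos, neg)
            rows.append(
                {
                    "group": "amplified",
                    "n": len(pos),
                    "median_months": med_pos,
                    "chi_square": lr.chi_square,
                    "p_value": lr.p_value,
                }
            )
            rows.append(
                {
                    "group": "non_amplified",
                    "n": len(neg),
                    "median_months": med_neg,
                    "chi_square": lr.chi_square,
                    "p_value": lr.p_value,
                }
            )
        _write_tsv(pd.DataFrame(rows), out / "survival.tsv", "survival")
    except Exception as exc:
        raise RuntimeError(f"stage 'survival' failed: {exc}") from exc

    try:
        stage("ifish")
        loci = {
            "EGFR": GenomicInterval("chr7", 54_900_001, 55_200_000),
            "CDKN2A": GenomicInterval("chr9", 21_978_443, 22_119_128),
        }
        truth_states = truth_states_at_loci(
            truth, loci, sample_ids(cohort_cfg.n_samples)
        )
        counts = generate_ifish_counts(truth_states, seed=config.seed + 4)
        ifish_calls = classify_counts(counts)
        array_calls = {
            (e.sample_id, locus): e.kind
            for locus, iv in loci.items()
            for e in events
            if e.interval.overlaps(iv)
        }
        for case_locus in truth_states:
            array_calls.setdefault(case_locus, "neutral")
        _, agreement = concordance_table(array_calls, ifish_calls)
        _write_tsv(
            pd.DataFrame([{"n_pairs": len(truth_states), "agreement_pct": agreement}]),
            out / "concordance.tsv",
            "ifish-concordance",
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'ifish' failed: {exc}") from exc

    manifest = {
        "gbmcna": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "n_samples": cohort_cfg.n_samples,
        "thresholds": asdict(config.thresholds),
        "filter": asdict(config.filter),
        "outputs": sorted(
            p.name for p in out.iterdir() if p.is_file() and p.name != "manifest.json"
        ),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
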