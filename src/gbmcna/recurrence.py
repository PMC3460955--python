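"""Cross-sample aggregation of CN events.

Recurrence frequencies count a case once if it carries at least one event
of the queried kind overlapping the region by >= 1 bp; percentages are
rounded half-away-from-zero to integers (24/46 -> 52%, 3/46 -> 7%).

Minimal common regions (MCRs) are delineated by a base-pair pileup of
per-case event coverage: within each maximal interval where coverage
reaches ``min_cases``, the maximal sub-interval(s) at the local coverage
maximum are reported, tie-broken by coordinate order.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping, Sequence

import pandas as pd

from .types import CnaEvent, GeneModel, GenomicInterval, RecurrentRegion


def round_pct(n_cases: int, cohort_size: int) -> int:
    """Integer percent, rounded half away from zero."""
    return int(math.floor(100.0 * n_cases / cohort_size + 0.5))


def recurrence_frequency(
    events: Iterable[CnaEvent],
    region: GenomicInterval,
    kind: str,
    cohort_size: int,
) -> tuple[int, int]:
    """(n_cases, integer percent) of cases with >= 1 overlapping event of ``kind``."""
    if cohort_size < 1:
        raise ValueError("cohort_size must be >= 1")
    cases = {
        e.sample_id for e in events if e.kind == kind and e.interval.overlaps(region)
    }
    n = len(cases)
    return n, round_pct(n, cohort_size)


def _merged_intervals_per_case(
    events: Sequence[CnaEvent],
) -> dict[str, list[tuple[int, int]]]:
    """Union of event intervals per case so a case covers each bp at most once."""
    merged: dict[str, list[tuple[int, int]]] = {}
    by_case: dict[str, list[tuple[int, int]]] = {}
    for e in events:
        by_case.setdefault(e.sample_id, []).append((e.start, e.end))
    for case, ivs in by_case.items():
        ivs.sort()
        out: list[tuple[int, int]] = []
        for s, t in ivs:
            if out and s <= out[-1][1] + 1:
                out[-1] = (out[-1][0], max(out[-1][1], t))
            else:
                out.append((s, t))
        merged[case] = out
    return merged


def coverage_segments(
    events: Sequence[CnaEvent],
) -> list[tuple[int, int, int]]:
    """Piecewise-constant per-case coverage on one chromosome.

    Returns contiguous half-open segments ``(start, end_exclusive, coverage)``
    spanning the covered range, in 1-based coordinates. Events must all lie
    on the same chromosome.
    """
    merged = _merged_intervals_per_case(events)
    delta: dict[int, int] = {}
    for ivs in merged.values():
        for s, t in ivs:
            delta[s] = delta.get(s, 0) + 1
            delta[t + 1] = delta.get(t + 1, 0) - 1
    segments: list[tuple[int, int, int]] = []
    cov = 0
    points = sorted(delta)
    for a, b in zip(points, points[1:]):
        cov += delta[a]
        segments.append((a, b, cov))
    return segments


def minimal_common_region(
    events: Sequence[CnaEvent],
    kind: str,
    min_cases: int,
    cohort_size: int | None = None,
    genes: Sequence[GeneModel] | None = None,
) -> list[RecurrentRegion]:
    """Delineate minimal common regions for one event kind.

    Within each maximal interval where the per-case coverage pileup is
    >= ``min_cases``, each maximal plateau at the local coverage maximum is
    reported as one MCR; its ``case_ids`` are the cases whose (merged)
    events contain the whole plateau, so every MCR is contained in every
    contributing case's event.
    """
    if min_cases < 2:
        raise ValueError("min_cases must be >= 2")
    kind_events = [e for e in events if e.kind == kind]
    regions: list[RecurrentRegion] = []
    chroms = sorted({e.chrom for e in kind_events})
    for chrom in chroms:
        chrom_events = [e for e in kind_events if e.chrom == chrom]
        merged = _merged_intervals_per_case(chrom_events)
        segments = coverage_segments(chrom_events)
        # maximal components with coverage >= min_cases
        components: list[list[tuple[int, int, int]]] = []
        current: list[tuple[int, int, int]] = []
        for seg in segments:
            if seg[2] >= min_cases:
                current.append(seg)
            elif current:
                components.append(current)
                current = []
        if current:
            components.append(current)
        for comp in components:
            peak = max(c for _, _, c in comp)
            # maximal plateaus at the peak, in coordinate order
            i = 0
            while i < len(comp):
                if comp[i][2] != peak:
                    i += 1
                    continue
                j = i
                while j + 1 < len(comp) and comp[j + 1][2] == peak:
                    j += 1
                start, end = comp[i][0], comp[j][1] - 1
                interval = GenomicInterval(chrom, start, end)
                case_ids = tuple(
                    sorted(
                        case
                        for case, ivs in merged.items()
                        if any(s <= start and end <= t for s, t in ivs)
                    )
                )
                regions.append(
                    RecurrentRegion(
                        interval=interval,
                        kind=kind,
                        case_ids=case_ids,
                        n_cases=len(case_ids),
                        frequency_pct=(
                            round_pct(len(case_ids), cohort_size)
                            if cohort_size
                            else None
                        ),
                        genes=tuple(annotate_genes(interval, genes)) if genes else (),
                        length_bp=interval.length_bp,
                    )
                )
                i = j + 1
    regions.sort(key=lambda r: (r.interval.chrom, r.interval.start, r.interval.end))
    return regions


def annotate_genes(
    region: GenomicInterval, genes: Sequence[GeneModel]
) -> list[str]:
    """Symbols of gene models overlapping the region by >= 1 bp, in genomic order."""
    hits = [g for g in genes if g.interval.overlaps(region)]
    hits.sort(key=lambda g: (g.chrom, g.start, g.end))
    return [g.symbol for g in hits]


RegionSpec = Mapping[str, tuple[GenomicInterval, str | None]]


def cooccurrence_matrix(
    events: Sequence[CnaEvent],
    regions: RegionSpec | Sequence[RecurrentRegion],
    case_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Binary case x region incidence table.

    ``regions`` is either a mapping ``label -> (interval, kind-or-None)``
    (``None`` matching any event kind) or a sequence of
    :class:`RecurrentRegion`. Row sums give per-case event multiplicity
    across the queried regions; ``case_ids`` may list event-free cases to
    include as all-zero rows.
    """
    if isinstance(regions, Mapping):
        specs = [(label, iv, kind) for label, (iv, kind) in regions.items()]
    else:
        specs = [
            (f"{r.interval.chrom}:{r.interval.start}-{r.interval.end}:{r.kind}",
             r.interval, r.kind)
            for r in regions
        ]
    rows = sorted(case_ids) if case_ids is not None else sorted(
        {e.sample_id for e in events}
    )
    table = pd.DataFrame(0, index=pd.Index(rows, name="case_id"),
                         columns=[label for label, _, _ in specs], dtype=int)
    for e in events:
        if case_ids is not None and e.sample_id not in table.index:
            continue
        for label, iv, kind in specs:
            if (kind is None or e.kind == kind) and e.interval.overlaps(iv):
                table.loc[e.sample_id, label] = 1
    return table
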