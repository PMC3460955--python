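"""Probe-level CN classification and per-sample segmentation.

Copy-number values are tumor-vs-paired-normal ratios in arbitrary units
with diploid ~= 2. A probe is classified into one of five states with the
fixed cutoffs used for SNP-array GBM profiling: loss when CN <= 1.30, gain
when CN >= 2.50, and the stronger calls amplification (CN > 5) and
homozygous deletion (CN < 0.8). The five intervals partition [0, inf).

Segmentation is a run-length scan over per-probe states after an optional
running-median smoothing; maximal same-state runs of at least
``min_probes_per_event`` probes become :class:`~gbmcna.types.CnaEvent`
segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import (
    AMPLIFICATION,
    GAIN,
    HOMOZYGOUS_DELETION,
    LOSS,
    NEUTRAL,
    CnaEvent,
    CnProfile,
)


@dataclass(frozen=True)
class CallingThresholds:
    """CN cutoffs and segmentation knobs.

    Boundary semantics follow the printed inequalities literally:
    loss <= ``loss_max`` and gain >= ``gain_min`` are inclusive;
    amplification > ``amp_min`` and homozygous deletion < ``homdel_max``
    are exclusive. ``smoothing_window`` is a running-median width in
    probes (odd; 1 disables smoothing).
    """

    loss_max: float = 1.30
    gain_min: float = 2.50
    amp_min: float = 5.0
    homdel_max: float = 0.8
    min_probes_per_event: int = 5
    smoothing_window: int = 3

    def __post_init__(self) -> None:
        if not (self.homdel_max < self.loss_max < self.gain_min < self.amp_min):
            raise ValueError(
                "thresholds must satisfy homdel_max < loss_max < gain_min < amp_min"
            )
        if self.min_probes_per_event < 1:
            raise ValueError("min_probes_per_event must be >= 1")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be odd and >= 1")


DEFAULT_THRESHOLDS = CallingThresholds()


def classify_cn_array(
    cn: np.ndarray, thresholds: CallingThresholds = DEFAULT_THRESHOLDS
) -> np.ndarray:
    """Vectorised five-state classification of CN values."""
    values = np.asarray(cn, dtype=float)
    if np.isnan(values).any():
        raise ValueError("CN values must not be NaN")
    if (values < 0).any():
        raise ValueError("CN values must be >= 0")
    conditions = [
        values < thresholds.homdel_max,
        values <= thresholds.loss_max,
        values < thresholds.gain_min,
        values <= thresholds.amp_min,
    ]
    choices = [HOMOZYGOUS_DELETION, LOSS, NEUTRAL, GAIN]
    return np.select(conditions, choices, default=AMPLIFICATION)


def classify_cn_value(
    cn: float, thresholds: CallingThresholds = DEFAULT_THRESHOLDS
) -> str:
    """Classify a single CN value into one of the five states."""
    return str(classify_cn_array(np.array([cn]), thresholds)[0])


def smooth_profile(profile: CnProfile, window: int) -> CnProfile:
    """Running-median smoothing per chromosome.

    The window is centred and shrinks at chromosome ends so the output has
    the same length and coordinates as the input. ``window=1`` is the
    identity.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    df = profile.probes.copy()
    if window > 1:
        df["cn"] = (
            df.groupby("chrom", sort=False)["cn"]
            .transform(lambda s: s.rolling(window, center=True, min_periods=1).median())
        )
    return CnProfile(profile.sample_id, df)


def segment_profile(
    profile: CnProfile, thresholds: CallingThresholds = DEFAULT_THRESHOLDS
) -> list[CnaEvent]:
    """Segment one sample's profile into maximal non-neutral runs.

    Smoothing (``thresholds.smoothing_window``) is applied before
    classification; the reported ``mean_cn`` is the mean of the smoothed
    values inside the run, so it always lies in the state's CN interval.
    Runs shorter than ``min_probes_per_event`` are discarded. Events are
    non-overlapping within the sample and sorted by (chrom, start).
    """
    if len(profile) == 0:
        return []
    smoothed = smooth_profile(profile, thresholds.smoothing_window)
    events: list[CnaEvent] = []
    for chrom, group in smoothed.probes.groupby("chrom", sort=False):
        pos = group["pos"].to_numpy()
        cn = group["cn"].to_numpy(dtype=float)
        states = classify_cn_array(cn, thresholds)
        # run boundaries where the state changes
        change = np.flatnonzero(states[1:] != states[:-1]) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(states)]))
        for lo, hi in zip(starts, ends):
            state = states[lo]
            if state == NEUTRAL or hi - lo < thresholds.min_probes_per_event:
                continue
            events.append(
                CnaEvent(
                    sample_id=profile.sample_id,
                    chrom=str(chrom),
                    start=int(pos[lo]),
                    end=int(pos[hi - 1]),
                    kind=str(state),
                    n_probes=int(hi - lo),
                    mean_cn=float(cn[lo:hi].mean()),
                )
            )
    events.sort(key=lambda e: (e.chrom, e.start, e.end))
    return events


def segment_cohort(
    profiles: list[CnProfile], thresholds: CallingThresholds = DEFAULT_THRESHOLDS
) -> list[CnaEvent]:
    """Segment every sample and return the pooled, sorted event list."""
    events: list[CnaEvent] = []
    for profile in profiles:
        events.extend(segment_profile(profile, thresholds))
    events.sort(key=lambda e: (e.sample_id, e.chrom, e.start))
    return events


def intersect_probe_maps(map_a: pd.DataFrame, map_b: pd.DataFrame) -> pd.DataFrame:
    """Probes present (by id) in both maps, preserving coordinates.

    Harmonises two array dialects before calling, mirroring the use of the
    probe set shared between a 500K and a SNP 6.0 array. Raises if a shared
    probe id maps to different coordinates in the two inputs.
    """
    merged = map_a.merge(
        map_b[["probe_id", "chrom", "pos"]],
        on="probe_id",
        how="inner",
        suffixes=("", "_b"),
    )
    bad = merged[(merged["chrom"] != merged["chrom_b"]) | (merged["pos"] != merged["pos_b"])]
    if not bad.empty:
        ids = ", ".join(bad["probe_id"].astype(str).head(5))
        raise ValueError(f"coordinate disagreement for shared probe ids: {ids}")
    out = merged[list(map_a.columns)].sort_values(["chrom", "pos"], kind="stable")
    return out.reset_index(drop=True)
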