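"""Array-level QC: detection filters, replicate-variance probe filter,
blacklist removal and the clock-correlation sample gate."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .core import (
    BLACKLIST_FLAGS,
    BetaMatrix,
    DetectionPMatrix,
    ParameterError,
    ProbeAnnotation,
    SampleSheet,
)

logger = logging.getLogger(__name__)


@dataclass
class ArrayQcReport:
    removed_samples_detection: dict[str, float] = field(default_factory=dict)
    removed_probes_detection: list[str] = field(default_factory=list)
    removed_probes_replicate_variance: list[str] = field(default_factory=list)
    removed_probes_blacklist: dict[str, list[str]] = field(default_factory=dict)
    removed_samples_clock_gate: dict[str, float | None] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "removed_samples_detection": self.removed_samples_detection,
            "removed_probes_detection": self.removed_probes_detection,
            "removed_probes_replicate_variance": self.removed_probes_replicate_variance,
            "removed_probes_blacklist": self.removed_probes_blacklist,
            "removed_samples_clock_gate": self.removed_samples_clock_gate,
        }


def filter_samples_by_detection(
    detp: DetectionPMatrix,
    min_detected_fraction: float = 0.99,
    p_threshold: float = 0.05,
) -> tuple[list[str], dict[str, float]]:
    """Retain samples whose fraction of detected probes (p <= threshold)
    is at least ``min_detected_fraction``.

    Returns (retained sample ids, removed sample id → detected fraction).
    """
    detected = (detp.data <= p_threshold).mean(axis=0)
    retained = [s for s in detp.sample_ids if detected[s] >= min_detected_fraction]
    removed = {s: float(detected[s]) for s in detp.sample_ids if detected[s] < min_detected_fraction}
    return retained, removed


def filter_probes_by_detection(
    detp: DetectionPMatrix,
    p_threshold: float = 0.05,
    max_failed_samples: int = 0,
) -> list[str]:
    """Retain probes failing detection (p > threshold) in at most
    ``max_failed_samples`` samples."""
    failures = (detp.data > p_threshold).sum(axis=1)
    return [p for p in detp.probe_ids if failures[p] <= max_failed_samples]


def replicate_pairs(sheet: SampleSheet) -> list[tuple[str, str]]:
    """All unordered within-replicate-group sample pairs."""
    pairs: list[tuple[str, str]] = []
    for _, grp in sheet.data.groupby("replicate_group"):
        sids = list(grp["sample_id"])
        if len(sids) >= 2:
            pairs.extend(combinations(sids, 2))
    return pairs


def replicate_variance_filter(
    beta: BetaMatrix,
    sheet: SampleSheet,
    sd_multiplier: float = 3.0,
    min_outlier_pairs: int = 2,
    method: str = "global_robust",
) -> list[str]:
    """Discard probes whose replicate-pair differences contain multiple
    outliers.

    Absolute β differences are computed per probe over every technical
    replicate/duplicate pair.  Under the default ``global_robust`` rule a
    pair is an outlier when its difference exceeds
    median + ``sd_multiplier``·(1.4826·MAD) of the pooled differences of all
    probes — this catches probes that are noisy in every pair, which a
    per-probe spread cannot flag by construction.  ``method='per_probe'``
    uses mean + ``sd_multiplier``·sd of that probe's own differences
    instead.  A probe is removed when at least ``min_outlier_pairs`` pairs
    are outliers; with fewer than 3 pairs cohort-wide this is a no-op.
    """
    pairs = [p for p in replicate_pairs(sheet)
             if p[0] in beta.data.columns and p[1] in beta.data.columns]
    if len(pairs) < 3:
        logger.warning("replicate_variance_filter: <3 replicate pairs; no probes removed")
        return []
    left = beta.data[[a for a, _ in pairs]].to_numpy()
    right = beta.data[[b for _, b in pairs]].to_numpy()
    diffs = np.abs(left - right)  # probes x pairs
    if method == "per_probe":
        mean = np.nanmean(diffs, axis=1, keepdims=True)
        sd = np.nanstd(diffs, axis=1, ddof=1, keepdims=True)
        cutoff = mean + sd_multiplier * sd
    elif method == "global_robust":
        med = np.nanmedian(diffs)
        sigma = 1.4826 * np.nanmedian(np.abs(diffs - med))
        cutoff = med + sd_multiplier * sigma
    else:
        raise ParameterError(f"unknown method {method!r}")
    outliers = (diffs > cutoff).sum(axis=1)
    return [p for p, n in zip(beta.probe_ids, outliers) if n >= min_outlier_pairs]


def blacklist_filter(
    annotation: ProbeAnnotation,
    flags: tuple[str, ...] = BLACKLIST_FLAGS,
) -> dict[str, list[str]]:
    """Probes to remove per selected blacklist flag.

    Returns flag → probe ids with that flag set (a probe may appear under
    several flags); the union is the removal set.
    """
    bad = set(flags) - set(BLACKLIST_FLAGS)
    if bad:
        raise ParameterError(f"unknown blacklist flag(s): {sorted(bad)}")
    df = annotation.data
    return {flag: list(df.loc[df[flag].astype(bool), "probe_id"]) for flag in flags}


def clock_correlation_gate(
    beta: BetaMatrix,
    gold_profile: pd.Series,
    r_threshold: float = 0.85,
) -> dict[str, float | None]:
    """Flag samples whose clock-CpG profile correlates poorly with the gold
    standard (Pearson r < ``r_threshold``).

    Returns removed sample id → r (None when the correlation is undefined,
    e.g. a constant sample vector).  Requires >= 3 clock CpGs shared between
    matrix and profile.
    """
    shared = [c for c in gold_profile.index if c in beta.data.index]
    if len(shared) < 3:
        raise ParameterError("clock gate needs >= 3 clock CpGs present in the matrix")
    gold = gold_profile.loc[shared].to_numpy(dtype=float)
    removed: dict[str, float | None] = {}
    for s in beta.sample_ids:
        vec = beta.data.loc[shared, s].to_numpy(dtype=float)
        ok = ~np.isnan(vec)
        if ok.sum() < 3 or np.std(vec[ok]) == 0 or np.std(gold[ok]) == 0:
            removed[s] = None  # undefined correlation
            continue
        r = float(np.corrcoef(vec[ok], gold[ok])[0, 1])
        if r < r_threshold:
            removed[s] = r
    return removed


def run_array_qc(
    beta: BetaMatrix,
    detp: DetectionPMatrix,
    sheet: SampleSheet,
    annotation: ProbeAnnotation,
    gold_profile: pd.Series | None = None,
    min_detected_fraction: float = 0.99,
    p_threshold: float = 0.05,
    max_failed_samples: int = 0,
    sd_multiplier: float = 3.0,
    min_outlier_pairs: int = 2,
    blacklist_flags: tuple[str, ...] = BLACKLIST_FLAGS,
    r_threshold: float = 0.85,
) -> tuple[BetaMatrix, ArrayQcReport]:
    """Full QC pipeline in the standard order: sample detection filter,
    probe detection filter, clock gate, replicate-variance filter,
    blacklist removal.  Values are never altered, only membership."""
    report = ArrayQcReport()

    retained_samples, report.removed_samples_detection = filter_samples_by_detection(
        detp, min_detected_fraction, p_threshold
    )
    detp_f = DetectionPMatrix(detp.data[retained_samples])
    beta_f = BetaMatrix(beta.data[retained_samples])

    retained_probes = filter_probes_by_detection(detp_f, p_threshold, max_failed_samples)
    report.removed_probes_detection = [p for p in beta_f.probe_ids if p not in set(retained_probes)]
    beta_f = BetaMatrix(beta_f.data.loc[retained_probes])

    if gold_profile is not None:
        report.removed_samples_clock_gate = clock_correlation_gate(
            beta_f, gold_profile, r_threshold
        )
        keep = [s for s in beta_f.sample_ids if s not in report.removed_samples_clock_gate]
        beta_f = BetaMatrix(beta_f.data[keep])

    report.removed_probes_replicate_variance = replicate_variance_filter(
        beta_f, sheet, sd_multiplier, min_outlier_pairs
    )
    beta_f = BetaMatrix(
        beta_f.data.drop(index=report.removed_probes_replicate_variance)
    )

    report.removed_probes_blacklist = blacklist_filter(annotation, blacklist_flags)
    black = set().union(*report.removed_probes_blacklist.values()) if blacklist_flags else set()
    keep_probes = [p for p in beta_f.probe_ids if p not in black]
    beta_f = BetaMatrix(beta_f.data.loc[keep_probes])
    return beta_f, report
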