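"""Amplicon (EpiTYPER-style) CpG-unit plate QC.

Implements unit-site averaging, duplicate averaging, the two-step
missingness filter, unit-mean imputation and the between-plate CV on the
highly methylated control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import SampleSheet, TwindiscordError, ValidationError


class EmptyPlateError(TwindiscordError):
    """All samples (or units) were removed by filtering."""

    def __init__(self, message: str, report: "EpityperQcReport | None" = None):
        super().__init__(message)
        self.report = report


@dataclass(frozen=True)
class EpityperPlate:
    """CpG units × samples percent-methylation matrix, NaN = missing.

    ``n_sites`` gives the number of CpG sites per unit (units quantified as
    fragments may cover several sites).  ``control_sample_ids`` mark the
    highly methylated control DNA wells.
    """

    data: pd.DataFrame
    n_sites: pd.Series
    plate_id: str = "plate1"
    control_sample_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        vals = self.data.to_numpy(dtype=float)
        finite = vals[~np.isnan(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 100):
            raise ValidationError("plate values must be percentages in [0, 100]")
        unknown = set(self.control_sample_ids) - set(self.data.columns)
        if unknown:
            raise ValidationError(f"control sample(s) not on plate: {sorted(unknown)}")

    @property
    def unit_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class EpityperQcReport:
    """Record of every removal made by :func:`two_step_filter`.

    Each removal map is id → missing fraction that triggered it.
    """

    removed_samples_step1: dict[str, float] = field(default_factory=dict)
    removed_units_step1: dict[str, float] = field(default_factory=dict)
    removed_samples_step2: dict[str, float] = field(default_factory=dict)
    removed_units_step2: dict[str, float] = field(default_factory=dict)
    n_imputed: int = 0
    plate_cv_percent: float | None = None

    def to_dict(self) -> dict:
        return {
            "removed_samples_step1": self.removed_samples_step1,
            "removed_units_step1": self.removed_units_step1,
            "removed_samples_step2": self.removed_samples_step2,
            "removed_units_step2": self.removed_units_step2,
            "n_imputed": self.n_imputed,
            "plate_cv_percent": self.plate_cv_percent,
        }


def average_unit_sites(site_values: Sequence[float]) -> float:
    """Mean of non-missing per-site percentages within one CpG unit.

    Returns NaN when every site is missing.
    """
    arr = np.asarray(site_values, dtype=float)
    if arr.size == 0 or np.isnan(arr).all():
        return float("nan")
    return float(np.nanmean(arr))


def average_duplicates(plate: EpityperPlate, sheet: SampleSheet) -> EpityperPlate:
    """Collapse duplicate wells to one column per replicate_group.

    Per unit, the mean over non-missing duplicate values; missing only when
    all duplicates are missing.  Output columns are named by replicate_group
    (sheet order of first appearance); singleton groups pass through.
    """
    meta = sheet.data.set_index("sample_id")
    groups: dict[str, list[str]] = {}
    for sid in plate.sample_ids:
        grp = str(meta.loc[sid, "replicate_group"]) if sid in meta.index else sid
        groups.setdefault(grp, []).append(sid)
    cols = {grp: plate.data[sids].mean(axis=1, skipna=True) for grp, sids in groups.items()}
    merged = pd.DataFrame(cols, index=plate.data.index)
    controls = tuple(
        grp for grp, sids in groups.items() if set(sids) & set(plate.control_sample_ids)
    )
    return EpityperPlate(merged, plate.n_sites, plate.plate_id, controls)


def _missing_frac(df: pd.DataFrame, axis: int) -> pd.Series:
    return df.isna().mean(axis=axis)


def two_step_filter(
    plate: EpityperPlate,
    fail_threshold: float = 0.90,
    low_detect_threshold: float = 0.15,
) -> tuple[EpityperPlate, EpityperQcReport]:
    """Two-step sample/unit missingness filter.

    Step 1 removes failed samples (missing fraction >= ``fail_threshold``)
    then failed units at the same threshold; step 2 removes low-detection
    samples (>= ``low_detect_threshold``) then low-detection units.
    Fractions are recomputed after every removal pass; thresholds are
    inclusive.
    """
    if plate.data.size == 0:
        raise ValidationError("empty plate")
    df = plate.data.copy()
    report = EpityperQcReport()

    # step 1: failed samples, then failed units
    frac = _missing_frac(df, axis=0)
    drop = frac[frac >= fail_threshold]
    report.removed_samples_step1 = {s: float(f) for s, f in drop.items()}
    df = df.drop(columns=drop.index)
    _require_nonempty(df, report)

    frac = _missing_frac(df, axis=1)
    drop = frac[frac >= fail_threshold]
    report.removed_units_step1 = {u: float(f) for u, f in drop.items()}
    df = df.drop(index=drop.index)
    _require_nonempty(df, report)

    # step 2: low-detection samples, then low-detection units
    frac = _missing_frac(df, axis=0)
    drop = frac[frac >= low_detect_threshold]
    report.removed_samples_step2 = {s: float(f) for s, f in drop.items()}
    df = df.drop(columns=drop.index)
    _require_nonempty(df, report)

    frac = _missing_frac(df, axis=1)
    drop = frac[frac >= low_detect_threshold]
    report.removed_units_step2 = {u: float(f) for u, f in drop.items()}
    df = df.drop(index=drop.index)
    _require_nonempty(df, report)

    out = EpityperPlate(
        df,
        plate.n_sites.loc[df.index],
        plate.plate_id,
        tuple(c for c in plate.control_sample_ids if c in df.columns),
    )
    return out, report


def _require_nonempty(df: pd.DataFrame, report: EpityperQcReport) -> None:
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise EmptyPlateError("filtering removed all samples or units", report)


def impute_unit_means(plate: EpityperPlate) -> EpityperPlate:
    """Replace remaining missing cells with the unit (row) mean."""
    df = plate.data
    all_missing = df.isna().all(axis=1)
    if all_missing.any():
        raise ValidationError(
            f"unit(s) with no data should have been filtered: {list(df.index[all_missing])}"
        )
    filled = df.apply(lambda row: row.fillna(row.mean()), axis=1)
    return EpityperPlate(filled, plate.n_sites, plate.plate_id, plate.control_sample_ids)


def plate_cv(control_values: Sequence[float]) -> float:
    """Between-plate coefficient of variation, percent: 100·sd/mean (ddof=1)."""
    arr = np.asarray(control_values, dtype=float)
    if arr.size < 2:
        raise ValidationError("plate CV needs at least 2 control values")
    mean = arr.mean()
    if mean == 0:
        raise ValidationError("plate CV undefined for zero mean")
    return float(100.0 * arr.std(ddof=1) / mean)


def read_plate(path: str | Path) -> EpityperPlate:
    """Read a plate TSV: units as rows, ``n_sites`` column, samples after it."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
    if "n_sites" not in df.columns:
        raise ValidationError("plate file needs an 'n_sites' column")
    n_sites = df["n_sites"].astype(int)
    values = df.drop(columns=["n_sites"]).astype(float)
    values.index.name = None
    n_sites.index.name = None
    return EpityperPlate(values, n_sites)


def write_plate(plate: EpityperPlate, path: str | Path) -> None:
    df = plate.data.copy()
    df.insert(0, "n_sites", plate.n_sites)
    df.index.name = "unit_id"
    df.to_csv(path, sep="\t", na_rep="NA")
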