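"""Shared domain types, matrix and sample-sheet I/O, and the β↔M transform.

Matrices are thin frozen wrappers around pandas DataFrames with rows as
probes/genes/units and columns as samples.  All readers validate ranges on
entry so downstream stages can assume well-formed values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DISEASE_STATUSES = ("affected", "unaffected", "asymptomatic_carrier", "control")
SEXES = ("F", "M")
COHORTS = ("twin", "case_control")
HIL_CATEGORIES = ("HC", "IC", "ICshore", "LC")
BLACKLIST_FLAGS = ("cross_hybridising", "sex_chromosome", "snp_overlap")

SAMPLE_SHEET_COLUMNS = (
    "sample_id",
    "individual_id",
    "twin_set_id",
    "disease_status",
    "sex",
    "age_at_collection",
    "collection_index",
    "replicate_group",
    "cohort",
)

ANNOTATION_COLUMNS = (
    "probe_id",
    "chromosome",
    "position",
    "genes",
    "distance_to_tss",
    "hil_category",
    "cross_hybridising",
    "sex_chromosome",
    "snp_overlap",
)

MISSING_TOKEN = "NA"


class TwindiscordError(Exception):
    """Base class for pipeline errors."""


class SchemaError(TwindiscordError):
    """A required column or field is missing."""


class ValidationError(TwindiscordError):
    """Data violates a domain invariant."""


class RangeError(TwindiscordError):
    """A value falls outside its permitted range."""


class AlignmentError(TwindiscordError):
    """Matrix columns cannot be reconciled with the sample sheet."""


class ParameterError(TwindiscordError):
    """A parameter is outside its valid domain."""


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleSheet:
    """Per-sample metadata table.

    One row per physical sample (array/plate/sequencing column).  Technical
    replicates of the same blood collection share a ``replicate_group``;
    longitudinal collections of one individual share ``individual_id`` and
    differ in ``collection_index``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"sample sheet missing column(s): {', '.join(missing)}")
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample_id(s): {dups}")
        bad_status = set(df["disease_status"]) - set(DISEASE_STATUSES)
        if bad_status:
            raise ValidationError(f"unknown disease_status value(s): {sorted(bad_status)}")
        bad_sex = set(df["sex"]) - set(SEXES)
        if bad_sex:
            raise ValidationError(f"unknown sex value(s): {sorted(bad_sex)}")
        bad_cohort = set(df["cohort"]) - set(COHORTS)
        if bad_cohort:
            raise ValidationError(f"unknown cohort value(s): {sorted(bad_cohort)}")
        if (df["collection_index"].astype(int) < 1).any():
            raise ValidationError("collection_index must be >= 1")
        twin = df[df["cohort"] == "twin"]
        for set_id, grp in twin.groupby("twin_set_id"):
            if grp["individual_id"].nunique() < 2:
                raise ValidationError(
                    f"twin set {set_id!r} has fewer than 2 distinct individuals"
                )
        for rep_id, grp in df.groupby("replicate_group"):
            if grp["individual_id"].nunique() > 1 or grp["collection_index"].nunique() > 1:
                raise ValidationError(
                    f"replicate_group {rep_id!r} spans multiple individuals or collections"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    def subset(self, sample_ids: Iterable[str]) -> "SampleSheet":
        wanted = list(sample_ids)
        df = self.data[self.data["sample_id"].isin(wanted)].copy()
        df = df.set_index("sample_id").loc[wanted].reset_index()
        return SampleSheet(df)

    def __len__(self) -> int:
        return len(self.data)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read and validate a sample sheet CSV/TSV."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str, "individual_id": str,
                                           "twin_set_id": str, "replicate_group": str})
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"sample sheet missing column(s): {', '.join(missing)}")
    df["age_at_collection"] = df["age_at_collection"].astype(float)
    df["collection_index"] = df["collection_index"].astype(int)
    return SampleSheet(df[list(SAMPLE_SHEET_COLUMNS)].copy())


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.data[list(SAMPLE_SHEET_COLUMNS)].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Matrix:
    data: pd.DataFrame

    @property
    def row_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def _check_unique(self) -> None:
        if self.data.index.duplicated().any():
            raise ValidationError("duplicate row identifiers")
        if self.data.columns.duplicated().any():
            raise ValidationError("duplicate sample identifiers")


@dataclass(frozen=True)
class BetaMatrix(_Matrix):
    """Probes × samples fraction methylation in [0, 1]; NaN = missing."""

    def __post_init__(self) -> None:
        self._check_unique()
        vals = self.data.to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            if np.nanmin(vals, initial=0.0) < 0 or np.nanmax(vals, initial=1.0) > 1:
                raise RangeError("beta values must lie in [0, 1]")

    @property
    def probe_ids(self) -> list[str]:
        return self.row_ids


@dataclass(frozen=True)
class MMatrix(_Matrix):
    """Probes × samples log2-ratio methylation values (unbounded, finite)."""

    def __post_init__(self) -> None:
        self._check_unique()
        vals = self.data.to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise RangeError("M-values must be finite (clip betas before transform)")

    @property
    def probe_ids(self) -> list[str]:
        return self.row_ids


@dataclass(frozen=True)
class DetectionPMatrix(_Matrix):
    """Probes × samples detection p-values in [0, 1]."""

    def __post_init__(self) -> None:
        self._check_unique()
        vals = self.data.to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            if np.nanmin(vals, initial=0.0) < 0 or np.nanmax(vals, initial=1.0) > 1:
                raise RangeError("detection p-values must lie in [0, 1]")

    @property
    def probe_ids(self) -> list[str]:
        return self.row_ids


@dataclass(frozen=True)
class CountMatrix(_Matrix):
    """Genes × samples nonnegative integer read counts."""

    def __post_init__(self) -> None:
        self._check_unique()
        vals = self.data.to_numpy()
        if np.isnan(vals.astype(float)).any():
            raise ValidationError("count matrix must not contain missing values")
        if not np.allclose(vals, np.round(vals)):
            raise ValidationError("counts must be integers")
        if (vals < 0).any():
            raise RangeError("counts must be nonnegative")

    @property
    def gene_ids(self) -> list[str]:
        return self.row_ids

    @property
    def library_sizes(self) -> pd.Series:
        return self.data.sum(axis=0)


def read_matrix(path: str | Path, kind: str) -> BetaMatrix | DetectionPMatrix | CountMatrix:
    """Read a dense TSV/CSV matrix (first column = row ids, header = samples).

    ``kind`` selects the typed wrapper and its range checks: ``beta``,
    ``detection_p`` or ``counts``.  Empty cells and ``NA`` are missing
    (disallowed for counts).
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=[MISSING_TOKEN, ""])
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    if kind == "beta":
        return BetaMatrix(df.astype(float))
    if kind == "detection_p":
        return DetectionPMatrix(df.astype(float))
    if kind == "counts":
        if df.isna().any().any():
            raise ValidationError("count matrix must not contain missing values")
        vals = df.to_numpy(dtype=float)
        if not np.allclose(vals, np.round(vals)):
            raise ValidationError("counts must be integers")
        return CountMatrix(df.round().astype(np.int64))
    raise ParameterError(f"unknown matrix kind {kind!r}")


def write_matrix(matrix: _Matrix, path: str | Path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = matrix.data.copy()
    df.index.name = "id"
    df.to_csv(path, sep=sep, na_rep=MISSING_TOKEN)


# ---------------------------------------------------------------------------
# Probe annotation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProbeAnnotation:
    """Per-probe gene mapping, CpG-density (HIL) category and blacklist flags.

    ``genes`` holds a semicolon-separated list of gene symbols (may be empty).
    Coordinates are 1-based.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"annotation missing column(s): {', '.join(missing)}")
        if df["probe_id"].duplicated().any():
            raise ValidationError("duplicate probe_id in annotation")
        bad = set(df["hil_category"]) - set(HIL_CATEGORIES)
        if bad:
            raise ValidationError(f"unknown hil_category value(s): {sorted(bad)}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data["probe_id"])

    def genes_for(self, probe_id: str) -> list[str]:
        row = self.data.set_index("probe_id").loc[probe_id]
        raw = row["genes"]
        if pd.isna(raw) or raw == "":
            return []
        return str(raw).split(";")

    def gene_map(self) -> dict[str, list[str]]:
        """probe_id → list of gene symbols (possibly empty)."""
        out: dict[str, list[str]] = {}
        for pid, raw in zip(self.data["probe_id"], self.data["genes"]):
            if pd.isna(raw) or raw == "":
                out[pid] = []
            else:
                out[pid] = str(raw).split(";")
        return out

    def hil_map(self) -> pd.Series:
        return self.data.set_index("probe_id")["hil_category"]


def read_probe_annotation(path: str | Path) -> ProbeAnnotation:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chromosome": str})
    df["genes"] = df["genes"].fillna("")
    for flag in BLACKLIST_FLAGS:
        if flag in df.columns:
            df[flag] = df[flag].astype(bool)
    return ProbeAnnotation(df)


def write_probe_annotation(annot: ProbeAnnotation, path: str | Path) -> None:
    annot.data[list(ANNOTATION_COLUMNS)].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Transforms and alignment
# ---------------------------------------------------------------------------


def beta_to_m(beta: BetaMatrix, epsilon: float = 1e-6) -> MMatrix:
    """logit2 transform: M = log2(b'/(1-b')) with b' = clip(b, eps, 1-eps).

    Missing values propagate.  ``epsilon`` must lie in (0, 0.5).
    """
    if not (0 < epsilon < 0.5):
        raise ParameterError(f"epsilon must be in (0, 0.5), got {epsilon}")
    clipped = beta.data.clip(lower=epsilon, upper=1 - epsilon)
    m = np.log2(clipped / (1 - clipped))
    return MMatrix(m)


def align_matrix_to_sheet(matrix: _Matrix, sheet: SampleSheet) -> _Matrix:
    """Reorder matrix columns to sheet order, dropping extras with a warning.

    Raises :class:`AlignmentError` if a sheet sample is absent from the matrix.
    """
    sheet_ids = sheet.sample_ids
    have = set(matrix.sample_ids)
    missing = [s for s in sheet_ids if s not in have]
    if missing:
        raise AlignmentError(f"sheet sample(s) absent from matrix: {missing}")
    extra = [s for s in matrix.sample_ids if s not in set(sheet_ids)]
    if extra:
        logger.warning("dropping %d matrix column(s) absent from sheet: %s", len(extra), extra)
    return type(matrix)(matrix.data[sheet_ids])


@dataclass(frozen=True)
class ClockModel:
    """Linear DNAm-age predictor: intercept + Σ coef·β, then an anti-transform.

    ``transform='identity'`` reports the linear predictor directly;
    ``'horvath'`` applies the piecewise exp/linear age anti-transform with
    pivot ``adult_age``.
    """

    intercept: float
    coefficients: dict[str, float]
    transform: str = "identity"
    adult_age: float = 20.0

    def __post_init__(self) -> None:
        if not self.coefficients:
            raise ValidationError("clock must have at least one coefficient")
        if self.transform not in ("identity", "horvath"):
            raise ParameterError(f"unknown clock transform {self.transform!r}")
        if self.transform == "horvath" and self.adult_age <= 0:
            raise ValidationError("adult_age must be > 0 for the horvath transform")

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.coefficients)


def read_clock(path: str | Path) -> ClockModel:
    """Read a clock CSV with columns ``cpg, weight`` and one ``(Intercept)`` row.

    Optional columns ``transform`` and ``adult_age`` (first row wins).
    """
    df = pd.read_csv(path)
    if "cpg" not in df.columns or "weight" not in df.columns:
        raise SchemaError("clock file needs columns 'cpg' and 'weight'")
    is_intercept = df["cpg"] == "(Intercept)"
    if not is_intercept.any():
        raise SchemaError("clock file needs an '(Intercept)' row")
    intercept = float(df.loc[is_intercept, "weight"].iloc[0])
    coefs = dict(zip(df.loc[~is_intercept, "cpg"], df.loc[~is_intercept, "weight"].astype(float)))
    transform = str(df["transform"].iloc[0]) if "transform" in df.columns else "identity"
    adult_age = float(df["adult_age"].iloc[0]) if "adult_age" in df.columns else 20.0
    return ClockModel(intercept=intercept, coefficients=coefs,
                      transform=transform, adult_age=adult_age)


def write_clock(clock: ClockModel, path: str | Path) -> None:
    rows = [{"cpg": "(Intercept)", "weight": clock.intercept,
             "transform": clock.transform, "adult_age": clock.adult_age}]
    for cpg, w in clock.coefficients.items():
        rows.append({"cpg": cpg, "weight": w,
                     "transform": clock.transform, "adult_age": clock.adult_age})
    pd.DataFrame(rows).to_csv(path, index=False)
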