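"""Per-sample methylome features: global and CpG-density-stratified mean
methylation, DNA-methylation age, and reference-based cell-type fractions."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from .core import (
    HIL_CATEGORIES,
    BetaMatrix,
    ClockModel,
    ProbeAnnotation,
    TwindiscordError,
    ValidationError,
)

logger = logging.getLogger(__name__)

DEFAULT_CELL_TYPES = ("CD4T", "CD8T", "monocytes", "B", "NK", "granulocytes")


@dataclass(frozen=True)
class CellReferenceMatrix:
    """Reference probes × cell types mean-β profiles."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.shape[1] < 2:
            raise ValidationError("cell reference needs >= 2 cell types")
        vals = self.data.to_numpy(dtype=float)
        if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
            raise ValidationError("reference β values must lie in [0, 1]")

    @property
    def cell_types(self) -> list[str]:
        return list(self.data.columns)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)


def read_cell_reference(path: str | Path) -> CellReferenceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CellReferenceMatrix(df.astype(float))


def write_cell_reference(ref: CellReferenceMatrix, path: str | Path) -> None:
    df = ref.data.copy()
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t")


def global_mean_methylation(
    beta: BetaMatrix, annotation: ProbeAnnotation
) -> pd.DataFrame:
    """Per-sample overall mean β plus one mean per HIL density category.

    Missing values are excluded pairwise; an empty category yields NaN with
    a warning.  Columns: global_mean_beta, hil_mean_<cat>.
    """
    hil = annotation.hil_map()
    missing = [p for p in beta.probe_ids if p not in hil.index]
    if missing:
        raise ValidationError(f"annotation missing {len(missing)} probe(s), e.g. {missing[:3]}")
    out = pd.DataFrame(index=pd.Index(beta.sample_ids, name="sample_id"))
    out["global_mean_beta"] = beta.data.mean(axis=0, skipna=True)
    cats = hil.loc[beta.probe_ids]
    for cat in HIL_CATEGORIES:
        probes = cats.index[cats == cat]
        if len(probes) == 0:
            logger.warning("no probes in HIL category %s; mean set to NaN", cat)
            out[f"hil_mean_{cat}"] = np.nan
        else:
            out[f"hil_mean_{cat}"] = beta.data.loc[probes].mean(axis=0, skipna=True)
    return out


def _anti_transform(x: np.ndarray, transform: str, adult_age: float) -> np.ndarray:
    if transform == "identity":
        return x
    # piecewise anti-transform: exponential below 0, linear above
    return np.where(
        x < 0,
        (1 + adult_age) * np.exp(x) - 1,
        (1 + adult_age) * x + adult_age,
    )


def age_transform(age: np.ndarray | float, transform: str, adult_age: float = 20.0):
    """Forward transform of chronological age onto the clock's linear scale."""
    age = np.asarray(age, dtype=float)
    if transform == "identity":
        return age
    return np.where(
        age <= adult_age,
        np.log(age + 1) - np.log(adult_age + 1),
        (age - adult_age) / (adult_age + 1),
    )


def dnam_age(beta: BetaMatrix, clock: ClockModel) -> pd.Series:
    """Predicted DNAm age per sample: anti-transform(intercept + Σ coef·β).

    Clock CpGs absent from the matrix are imputed at β = 0.5; missing cells
    at a present CpG are imputed with that CpG's cross-sample mean (logged).
    """
    cpgs = clock.cpg_ids
    present = [c for c in cpgs if c in beta.data.index]
    if not present:
        raise TwindiscordError("no clock CpGs present in the matrix")
    sub = beta.data.reindex(cpgs)
    absent = [c for c in cpgs if c not in beta.data.index]
    if absent:
        logger.warning("imputing %d absent clock CpG(s) at beta=0.5", len(absent))
        sub.loc[absent] = 0.5
    if sub.isna().any().any():
        logger.warning("imputing missing clock cells with per-CpG means")
        sub = sub.apply(lambda row: row.fillna(row.mean()), axis=1)
    weights = np.array([clock.coefficients[c] for c in cpgs])
    x = clock.intercept + weights @ sub.to_numpy()
    ages = _anti_transform(x, clock.transform, clock.adult_age)
    return pd.Series(ages, index=sub.columns, name="dnam_age")


def estimate_cell_proportions(
    beta: BetaMatrix,
    reference: CellReferenceMatrix,
    sum_to_one: bool = False,
) -> pd.DataFrame:
    """Constrained projection of each sample onto cell-type reference
    profiles: minimise ||R·w − b||² subject to w ≥ 0 and Σw ≤ 1
    (Σw = 1 when ``sum_to_one``).

    Missing β at reference probes are imputed with the reference row mean.
    Returns samples × cell types fractions.
    """
    shared = [p for p in reference.probe_ids if p in beta.data.index]
    k = len(reference.cell_types)
    if len(shared) < k:
        raise ValidationError(
            f"underdetermined: {len(shared)} reference probes < {k} cell types"
        )
    R = reference.data.loc[shared].to_numpy(dtype=float)
    B = beta.data.loc[shared].to_numpy(dtype=float)
    ref_means = R.mean(axis=1)
    out = np.empty((len(beta.sample_ids), k))
    for j in range(B.shape[1]):
        b = B[:, j].copy()
        nan = np.isnan(b)
        if nan.any():
            b[nan] = ref_means[nan]
        out[j] = _constrained_lsq(R, b, sum_to_one)
    return pd.DataFrame(out, index=pd.Index(beta.sample_ids, name="sample_id"),
                        columns=reference.cell_types)


def _constrained_lsq(R: np.ndarray, b: np.ndarray, sum_to_one: bool) -> np.ndarray:
    w, _ = optimize.nnls(R, b)
    total = w.sum()
    if (not sum_to_one and total <= 1.0 + 1e-12) or (sum_to_one and abs(total - 1) < 1e-12):
        return w
    # project onto the (sub-)simplex with an equality/inequality constraint
    k = R.shape[1]
    cons = (
        {"type": "eq" if sum_to_one else "ineq",
         "fun": (lambda w: w.sum() - 1.0) if sum_to_one else (lambda w: 1.0 - w.sum()),
         "jac": (lambda w: np.ones(k)) if sum_to_one else (lambda w: -np.ones(k))},
    )
    RtR = R.T @ R
    Rtb = R.T @ b
    res = optimize.minimize(
        lambda w: 0.5 * w @ RtR @ w - Rtb @ w,
        x0=np.clip(w / max(total, 1.0), 0, None),
        jac=lambda w: RtR @ w - Rtb,
        bounds=[(0.0, None)] * k,
        constraints=cons,
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-14},
    )
    return np.clip(res.x, 0.0, None)


def build_feature_table(
    beta: BetaMatrix,
    annotation: ProbeAnnotation,
    clock: ClockModel | None = None,
    reference: CellReferenceMatrix | None = None,
) -> pd.DataFrame:
    """Assemble the per-sample feature table (means, DNAm age, cell
    fractions) from whichever inputs are supplied."""
    table = global_mean_methylation(beta, annotation)
    if clock is not None:
        table["dnam_age"] = dnam_age(beta, clock)
    if reference is not None:
        fractions = estimate_cell_proportions(beta, reference)
        for ct in fractions.columns:
            table[f"cellfrac_{ct}"] = fractions[ct]
    return table
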