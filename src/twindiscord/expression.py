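"""Paired longitudinal differential expression and case-control validation.

CPM filtering, TMM between-sample normalisation factors, log2-CPM with
optional mean–variance precision weights, gene-wise linear modelling with
BH-FDR, and fold-change gating.

Empirical-Bayes variance moderation is deliberately not implemented; the
per-gene model is ordinary (optionally precision-weighted) least squares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .core import CountMatrix, SampleSheet, ValidationError
from .models import bh_fdr

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NormalisedExpression:
    """log2-CPM matrix with the TMM factors and effective library sizes
    used to compute it."""

    logcpm: pd.DataFrame
    tmm_factors: pd.Series
    effective_library_sizes: pd.Series

    def __post_init__(self) -> None:
        if (self.tmm_factors <= 0).any():
            raise ValidationError("TMM factors must be positive")


def cpm(counts: CountMatrix) -> pd.DataFrame:
    """Counts per million on raw library sizes."""
    lib = counts.library_sizes
    if (lib <= 0).any():
        raise ValidationError("library sizes must be positive")
    return counts.data / lib * 1e6


def cpm_filter(counts: CountMatrix, min_cpm: float, min_samples: int) -> list[str]:
    """Genes with CPM strictly greater than ``min_cpm`` in at least
    ``min_samples`` samples."""
    keep = (cpm(counts) > min_cpm).sum(axis=1) >= min_samples
    return list(counts.data.index[keep])


def _quantile_ref_column(data: pd.DataFrame, p: float = 0.75) -> str:
    """TMM reference: column whose upper-quartile CPM is closest to the
    mean upper-quartile."""
    scaled = data / data.sum(axis=0)
    uq = scaled.quantile(p, axis=0)
    return (uq - uq.mean()).abs().idxmin()


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              logratio_trim: float, abs_trim: float) -> float:
    """Weighted trimmed mean of log2 ratios of one column vs the reference."""
    ok = (obs > 0) & (ref > 0)
    obs, ref = obs[ok].astype(float), ref[ok].astype(float)
    if obs.size == 0:
        return 1.0
    m = np.log2((obs / n_obs) / (ref / n_ref))
    a = 0.5 * np.log2((obs / n_obs) * (ref / n_ref))
    # asymptotic binomial variance weights
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abs_trim) + 1
    hi_a = n + 1 - lo_a
    rm = stats.rankdata(m)
    ra = stats.rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def tmm_factors(
    counts: CountMatrix,
    logratio_trim: float = 0.30,
    abs_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factor per sample, geometric mean 1."""
    data = counts.data
    if data.shape[1] < 2:
        raise ValidationError("TMM needs >= 2 samples")
    lib = counts.library_sizes
    if (lib <= 0).any():
        raise ValidationError("all-zero column in count matrix")
    ref_col = _quantile_ref_column(data)
    ref = data[ref_col].to_numpy()
    n_ref = float(lib[ref_col])
    factors = {}
    for s in data.columns:
        if s == ref_col:
            factors[s] = 1.0
        else:
            factors[s] = _tmm_pair(data[s].to_numpy(), ref, float(lib[s]), n_ref,
                                   logratio_trim, abs_trim)
    f = pd.Series(factors).loc[data.columns]
    f = f / np.exp(np.mean(np.log(f)))
    return f


def normalise(counts: CountMatrix, prior_count: float = 0.5) -> NormalisedExpression:
    """TMM-normalised log2-CPM: log2((count + prior) / (eff_lib + 2·prior) · 1e6)."""
    f = tmm_factors(counts)
    eff = counts.library_sizes * f
    logcpm = np.log2((counts.data + prior_count).div(eff + 2 * prior_count, axis=1) * 1e6)
    return NormalisedExpression(logcpm=logcpm, tmm_factors=f, effective_library_sizes=eff)


def _voom_style_weights(logcpm: pd.DataFrame, fitted: pd.DataFrame) -> pd.DataFrame:
    """Per-observation precision weights from a lowess fit of sqrt residual
    sd against mean log2-CPM, evaluated at each fitted value."""
    resid = logcpm - fitted
    sd = resid.std(axis=1, ddof=1)
    mean_expr = logcpm.mean(axis=1)
    trend = lowess(np.sqrt(sd), mean_expr, frac=0.5, return_sorted=True)
    xs, ys = trend[:, 0], trend[:, 1]
    pred = np.interp(fitted.to_numpy(), xs, ys)
    pred = np.clip(pred, 1e-3, None)
    return pd.DataFrame(pred ** -4, index=logcpm.index, columns=logcpm.columns)


def _genewise_wls(y: np.ndarray, X: np.ndarray, w: np.ndarray | None, coef_idx: int):
    """Weighted least squares for one gene.

    Returns (coef, unit_var, sigma2, df) where unit_var is the coefficient
    variance per unit residual variance ((X'WX)^-1 diagonal entry).
    """
    sw = np.ones_like(y) if w is None else np.sqrt(w)
    Xw = X * sw[:, None]
    yw = y * sw
    beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    df = y.size - rank
    resid = yw - Xw @ beta
    sigma2 = float(resid @ resid / df) if df > 0 else np.nan
    unit_var = float(np.linalg.pinv(Xw.T @ Xw)[coef_idx, coef_idx])
    return float(beta[coef_idx]), unit_var, sigma2, df


def _moderated_tests(
    coefs: np.ndarray,
    unit_vars: np.ndarray,
    sigma2: np.ndarray,
    df: int,
    mean_expr: np.ndarray,
    variance: str,
) -> tuple[np.ndarray, np.ndarray]:
    """t and p per gene under either variance rule.

    ``genewise`` uses each gene's own residual variance with its exact
    residual df.  ``pooled_trend`` replaces it with a lowess trend of
    log residual variance against mean log2-CPM — variance information is
    pooled across the whole matrix, so the reference distribution is
    normal.  Paired twin designs leave almost no residual df per gene
    (collections − 1), which makes the pooled rule the usable default.
    """
    if variance == "genewise":
        with np.errstate(divide="ignore", invalid="ignore"):
            t = coefs / np.sqrt(sigma2 * unit_vars)
        t = np.where(np.isfinite(t), t, 0.0)
        p = 2.0 * stats.t.sf(np.abs(t), df)
        return t, p
    if variance != "pooled_trend":
        raise ValidationError(f"unknown variance rule {variance!r}")
    safe = np.clip(sigma2, 1e-10, None)
    trend = lowess(np.log(safe), mean_expr, frac=0.4, return_sorted=True)
    s2_trend = np.exp(np.interp(mean_expr, trend[:, 0], trend[:, 1]))
    t = coefs / np.sqrt(s2_trend * unit_vars)
    p = 2.0 * stats.norm.sf(np.abs(t))
    return t, p


def _design_paired(sheet: SampleSheet, sample_ids: list[str]) -> tuple[np.ndarray, list[str], int]:
    """Intercept + collection-factor + disease design for the paired twin test."""
    meta = sheet.data.set_index("sample_id").loc[sample_ids]
    collections = sorted(meta["collection_index"].unique())
    # drop collections observed for only one twin (unbalanced)
    balanced = [c for c in collections
                if meta.loc[meta["collection_index"] == c, "individual_id"].nunique() >= 2]
    if len(balanced) < len(collections):
        dropped = set(collections) - set(balanced)
        logger.warning("dropping unbalanced collection(s): %s", sorted(dropped))
    keep = meta["collection_index"].isin(balanced)
    meta = meta[keep]
    ids = list(meta.index)
    disease = meta["disease_status"].isin(["affected", "asymptomatic_carrier"]).astype(float)
    cols = [np.ones(len(meta))]
    names = ["intercept"]
    for c in balanced[1:]:
        cols.append((meta["collection_index"] == c).astype(float).to_numpy())
        names.append(f"collection_{c}")
    cols.append(disease.to_numpy())
    names.append("disease")
    return np.column_stack(cols), ids, len(names) - 1


def _run_gene_models(
    logcpm: pd.DataFrame,
    X: np.ndarray,
    coef_idx: int,
    use_weights: bool,
    variance: str,
) -> pd.DataFrame:
    weights = None
    if use_weights:
        beta_hat = np.linalg.lstsq(X, logcpm.to_numpy().T, rcond=None)[0]
        fitted = pd.DataFrame((X @ beta_hat).T, index=logcpm.index, columns=logcpm.columns)
        weights = _voom_style_weights(logcpm, fitted)
    Y = logcpm.to_numpy()
    W = weights.to_numpy() if weights is not None else None
    n_genes = Y.shape[0]
    coefs = np.empty(n_genes)
    unit_vars = np.empty(n_genes)
    sigma2 = np.empty(n_genes)
    df = 0
    for i in range(n_genes):
        coefs[i], unit_vars[i], sigma2[i], df = _genewise_wls(
            Y[i], X, W[i] if W is not None else None, coef_idx
        )
    t, p = _moderated_tests(coefs, unit_vars, sigma2, df,
                            logcpm.mean(axis=1).to_numpy(), variance)
    res = pd.DataFrame(
        {"log2_fold_change": coefs, "t_statistic": t, "p_value": p},
        index=pd.Index(logcpm.index, name="gene_id"),
    )
    res["fdr"] = bh_fdr(res["p_value"].to_numpy())
    return res


def paired_de_test(
    norm: NormalisedExpression,
    sheet: SampleSheet,
    use_weights: bool = True,
    variance: str = "pooled_trend",
    fdr_threshold: float = 0.05,
    fc_threshold: float = 1.5,
) -> pd.DataFrame:
    """Gene-wise paired longitudinal DE test for one discordant pair.

    Linear model on log2-CPM with disease + collection factor terms;
    positive log2FC = higher in affected.  BH-FDR across all tested genes;
    ``passes_fc_gate`` applies both the FDR and |log2FC| ≥ log2(fc) gates.
    """
    X, ids, coef_idx = _design_paired(sheet, list(norm.logcpm.columns))
    res = _run_gene_models(norm.logcpm[ids], X, coef_idx, use_weights, variance)
    res["passes_fc_gate"] = (res["fdr"] < fdr_threshold) & (
        np.abs(res["log2_fold_change"]) >= np.log2(fc_threshold)
    )
    return res


def threshold_degs(
    results: pd.DataFrame,
    fdr_threshold: float = 0.05,
    fc_threshold: float = 1.5,
) -> pd.DataFrame:
    """Genes with fdr < threshold and |log2FC| ≥ log2(fc_threshold)."""
    keep = (results["fdr"] < fdr_threshold) & (
        np.abs(results["log2_fold_change"]) >= np.log2(fc_threshold)
    )
    return results[keep]


def validate_degs_case_control(
    counts: CountMatrix,
    sheet: SampleSheet,
    gene_subset: list[str],
    use_weights: bool = True,
    variance: str = "pooled_trend",
) -> tuple[pd.DataFrame, dict]:
    """Case-control disease test (with sex covariate) restricted to a gene
    subset; BH-FDR over the present subset only.

    Returns (per-gene results, availability report with present/absent ids).
    """
    if not gene_subset:
        raise ValidationError("gene subset is empty")
    present = [g for g in gene_subset if g in counts.data.index]
    absent = [g for g in gene_subset if g not in counts.data.index]
    report = {"present": present, "absent": absent}
    if not present:
        return pd.DataFrame(columns=["log2_fold_change", "t_statistic", "p_value", "fdr"]), report

    norm = normalise(counts)
    meta = sheet.data.set_index("sample_id").loc[norm.logcpm.columns]
    disease = meta["disease_status"].isin(["affected", "asymptomatic_carrier"]).astype(float)
    if disease.nunique() < 2:
        raise ValidationError("both disease groups must be present")
    X = np.column_stack([
        np.ones(len(meta)),
        (meta["sex"] == "M").astype(float).to_numpy(),
        disease.to_numpy(),
    ])
    # model every post-filter gene (the variance trend needs the full
    # matrix) but report and FDR-correct only the present subset
    res_all = _run_gene_models(norm.logcpm, X, coef_idx=2,
                               use_weights=use_weights, variance=variance)
    res = res_all.loc[present, ["log2_fold_change", "t_statistic", "p_value"]].copy()
    res["fdr"] = bh_fdr(res["p_value"].to_numpy())
    return res, report
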