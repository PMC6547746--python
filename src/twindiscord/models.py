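"""Discordance and case-control inference: twin-structured mixed models
with likelihood-ratio tests, proportion regression for cell fractions, and
per-probe case-control linear models with BH-FDR."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .core import (
    BetaMatrix,
    ParameterError,
    SampleSheet,
    TwindiscordError,
    ValidationError,
)


@dataclass(frozen=True)
class ModelSpec:
    """Fixed/random structure for a feature model.

    ``fixed_terms`` are drawn from {disease, age, sex, disease:age};
    random intercepts are always fitted per twin set and per individual, a
    random slope over collections per individual is optional.
    """

    response: str
    fixed_terms: tuple[str, ...] = ("disease", "age", "sex")
    random_slope_collections: bool = False
    family: str = "gaussian"

    def __post_init__(self) -> None:
        allowed = {"disease", "age", "sex", "disease:age"}
        bad = set(self.fixed_terms) - allowed
        if bad:
            raise ParameterError(f"unknown fixed term(s): {sorted(bad)}")
        if self.family not in ("gaussian", "beta"):
            raise ParameterError(f"unknown family {self.family!r}")


@dataclass
class MixedModelResult:
    term: str
    estimate: float
    lrt_statistic: float
    p_value: float
    converged: bool
    family_used: str = "gaussian"
    note: str = ""


_TERM_FORMULA = {
    "disease": "disease",
    "age": "age_at_collection",
    "sex": "C(sex)",
    "disease:age": "disease:age_at_collection",
}


def _model_frame(values: pd.Series, sheet: SampleSheet) -> pd.DataFrame:
    df = sheet.data.set_index("sample_id").copy()
    df = df.loc[values.index]
    df["y"] = values.astype(float).to_numpy()
    df["disease"] = (df["disease_status"].isin(["affected", "asymptomatic_carrier"])).astype(float)
    df = df.reset_index()
    return df


def _fit_ml(formula: str, df: pd.DataFrame, vc: dict, re_formula: str = "1"):
    # lbfgs first; fall back to powell when the boundary trips convergence
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups=df["twin_set_id"],
                            re_formula=re_formula, vc_formula=vc)
        fit = model.fit(reml=False, method="lbfgs", maxiter=500)
        if not fit.converged:
            retry = model.fit(reml=False, method="powell", maxiter=1000)
            if retry.converged:
                fit = retry
    return fit


def fit_feature_mixed_model(
    values: pd.Series,
    sheet: SampleSheet,
    spec: ModelSpec,
    test_terms: tuple[str, ...] = ("disease",),
) -> list[MixedModelResult]:
    """Twin-structured linear mixed model with ML likelihood-ratio tests.

    Fits y ~ fixed terms with a random intercept per twin set and per
    individual (optionally a random collection slope per individual); each
    term in ``test_terms`` is tested by dropping it from the fixed part and
    comparing likelihoods against χ² with df = parameters dropped.
    """
    if sheet.data["twin_set_id"].nunique() < 2:
        raise ValidationError("mixed model needs >= 2 twin sets")
    if values.nunique() < 2:
        raise ValidationError("response has zero variance")
    df = _model_frame(values, sheet)

    vc = {"individual": "0 + C(individual_id)"}
    if spec.random_slope_collections:
        vc["indiv_slope"] = "0 + C(individual_id):collection_index"
    full_terms = [_TERM_FORMULA[t] for t in spec.fixed_terms]
    full_formula = "y ~ " + " + ".join(full_terms)
    full = _fit_ml(full_formula, df, vc)

    results = []
    for term in test_terms:
        if term not in spec.fixed_terms:
            raise ParameterError(f"term {term!r} not in fixed_terms")
        reduced_terms = [_TERM_FORMULA[t] for t in spec.fixed_terms if t != term]
        reduced_formula = "y ~ " + (" + ".join(reduced_terms) if reduced_terms else "1")
        reduced = _fit_ml(reduced_formula, df, vc)
        stat = 2.0 * (full.llf - reduced.llf)
        df_diff = len(full.fe_params) - len(reduced.fe_params)
        stat = max(stat, 0.0)
        p = float(stats.chi2.sf(stat, max(int(df_diff), 1)))
        converged = bool(full.converged and reduced.converged)
        # pull the fixed-effect estimate for the tested term
        est = np.nan
        for name in full.fe_params.index:
            base = _TERM_FORMULA[term]
            if name == base or name.startswith(base) or (
                term == "disease:age" and ":" in name and "disease" in name
            ):
                est = float(full.fe_params[name])
                break
        results.append(MixedModelResult(
            term=term,
            estimate=est if converged else np.nan,
            lrt_statistic=float(stat),
            p_value=p,
            converged=converged,
        ))
    return results


def fit_cellprop_beta_regression(
    fractions: pd.DataFrame,
    sheet: SampleSheet,
    spec: ModelSpec | None = None,
) -> dict[str, MixedModelResult]:
    """Disease test per cell type on offset, logit-scale proportions.

    Every fraction is increased by 0.001 (avoids log of zero); if any value
    then reaches 1 the column is rescaled by max+0.002.  A beta-family mixed
    model is not available in the Python stack, so the documented
    approximation is a gaussian mixed model on the logit scale with random
    intercepts per individual and per twin set (no random slope); results
    are flagged ``family_used='gaussian_logit'``.
    """
    if spec is None:
        spec = ModelSpec(response="cell_fraction", fixed_terms=("disease", "age", "sex"),
                         family="beta")
    out: dict[str, MixedModelResult] = {}
    for cell in fractions.columns:
        f = fractions[cell].astype(float) + 0.001
        if (f >= 1).any():
            f = f / (f.max() + 0.002)
        y = np.log(f / (1 - f))  # logit link scale
        res = fit_feature_mixed_model(
            pd.Series(y, index=fractions.index), sheet,
            ModelSpec(response=cell, fixed_terms=spec.fixed_terms,
                      random_slope_collections=False),
            test_terms=("disease",),
        )[0]
        res.family_used = "gaussian_logit"
        res.note = "beta mixed regression approximated on logit scale"
        out[cell] = res
    return out


def case_control_probe_models(
    beta: BetaMatrix,
    sheet: SampleSheet,
    probes: list[str] | None = None,
    response_scale: str = "beta",
) -> pd.DataFrame:
    """Per-probe case-control linear model β ~ disease + age + sex.

    The disease coefficient is case − control on the response scale
    (β by default, M via ``response_scale='m'``).  BH-FDR is computed across
    exactly the selected probe set; constant probes are skipped with a flag.
    """
    from .core import beta_to_m

    probes = list(probes) if probes is not None else beta.probe_ids
    missing = [p for p in probes if p not in beta.data.index]
    if missing:
        raise ValidationError(f"probe(s) absent from matrix: {missing[:5]}")
    mat = beta if response_scale == "beta" else beta_to_m(beta)
    df = sheet.data.set_index("sample_id").loc[mat.sample_ids]
    disease = df["disease_status"].isin(["affected", "asymptomatic_carrier"]).astype(float)
    if disease.nunique() < 2:
        raise ValidationError("both disease groups must be present")
    X = pd.DataFrame({
        "const": 1.0,
        "disease": disease.to_numpy(),
        "age": df["age_at_collection"].astype(float).to_numpy(),
        "sex": (df["sex"] == "M").astype(float).to_numpy(),
    })
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValidationError("design matrix is rank deficient (collinear covariates)")
    rows = []
    for p in probes:
        y = mat.data.loc[p].to_numpy(dtype=float)
        if np.nanstd(y) == 0:
            rows.append({"probe_id": p, "estimate": np.nan, "p_value": np.nan,
                         "skipped": True})
            continue
        ok = ~np.isnan(y)
        fit = sm.OLS(y[ok], X.loc[ok].to_numpy()).fit()
        rows.append({"probe_id": p, "estimate": float(fit.params[1]),
                     "p_value": float(fit.pvalues[1]), "skipped": False})
    res = pd.DataFrame(rows).set_index("probe_id")
    tested = res.index[~res["skipped"]]
    res["fdr"] = np.nan
    if len(tested):
        res.loc[tested, "fdr"] = bh_fdr(res.loc[tested, "p_value"].to_numpy())
    return res


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ParameterError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ParameterError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]  # enforce monotonicity
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out
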