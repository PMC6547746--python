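"""Cross-platform gene-list integration, Fisher-exact gene-set enrichment,
and the clustering/PCA utilities used for disease-signature checks."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .core import ParameterError, ValidationError
from .models import bh_fdr


@dataclass(frozen=True)
class OverlapResult:
    list_a: tuple[str, ...]
    list_b: tuple[str, ...]
    universe_a: tuple[str, ...]
    universe_b: tuple[str, ...]
    a_in_b_universe: tuple[str, ...]
    b_in_a_universe: tuple[str, ...]
    intersection: tuple[str, ...]


def overlap_genes(
    dmp_genes,
    deg_genes,
    methylation_universe,
    expression_universe,
) -> OverlapResult:
    """Restrict each list to the other platform's measured universe, then
    intersect.  Order within outputs is sorted for determinism."""
    uni_m, uni_e = set(methylation_universe), set(expression_universe)
    if not uni_m or not uni_e:
        raise ValidationError("universes must be non-empty")
    a, b = set(dmp_genes), set(deg_genes)
    a_in_e = sorted(a & uni_e)
    b_in_m = sorted(b & uni_m)
    inter = sorted(set(a_in_e) & set(b_in_m))
    return OverlapResult(
        list_a=tuple(sorted(a)),
        list_b=tuple(sorted(b)),
        universe_a=tuple(sorted(uni_m)),
        universe_b=tuple(sorted(uni_e)),
        a_in_b_universe=tuple(a_in_e),
        b_in_a_universe=tuple(b_in_m),
        intersection=tuple(inter),
    )


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT: one term per line — name, description, then member genes."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def fisher_enrichment(
    gene_list,
    gene_sets: dict[str, list[str]],
    background,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Per-term Fisher exact test of the gene list against a background.

    Terms are intersected with the background; fold_enrichment =
    (k/n)/(K/N).  Direction is 'over' when fold_enrichment > 1 else
    'under'.  BH-FDR across tested terms.
    """
    bg = set(background)
    lst = set(gene_list)
    offenders = sorted(lst - bg)
    if offenders:
        raise ValidationError(f"gene list not subset of background: {offenders[:10]}")
    n, N = len(lst), len(bg)
    rows = []
    for term, members in gene_sets.items():
        in_bg = set(members) & bg
        K = len(in_bg)
        if K == 0:
            continue
        k = len(lst & in_bg)
        table = [[k, n - k], [K - k, N - n - (K - k)]]
        _, p = stats.fisher_exact(table, alternative=alternative)
        fold = (k / n) / (K / N) if n else 0.0
        rows.append({
            "term": term, "k": k, "n": n, "K": K, "N": N,
            "fold_enrichment": fold,
            "log2_fold_enrichment": np.log2(fold) if fold > 0 else -np.inf,
            "p_value": float(p),
            "direction": "over" if fold > 1 else "under",
        })
    res = pd.DataFrame(rows).set_index("term") if rows else pd.DataFrame(
        columns=["k", "n", "K", "N", "fold_enrichment", "log2_fold_enrichment",
                 "p_value", "direction"])
    if len(res):
        res["fdr"] = bh_fdr(res["p_value"].to_numpy())
    return res


def _sample_distances(matrix: pd.DataFrame, distance: str) -> np.ndarray:
    """Condensed distance vector between sample columns."""
    X = matrix.to_numpy(dtype=float).T  # samples x features
    if distance == "manhattan":
        return pdist(X, metric="cityblock")
    if distance == "spearman":
        if np.any(X.std(axis=1) == 0):
            raise ValidationError("constant sample vector: spearman distance undefined")
        rho = stats.spearmanr(X.T).statistic
        rho = np.atleast_2d(rho)
        return squareform(1.0 - rho, checks=False)
    raise ParameterError(f"unknown distance {distance!r}")


def hierarchical_cluster(
    matrix: pd.DataFrame,
    distance: str = "manhattan",
    linkage: str = "ward",
    k: int = 2,
) -> tuple[pd.Series, np.ndarray]:
    """Agglomerative clustering of sample columns; cut at ``k`` clusters.

    Labels are renumbered by first occurrence in column order so the output
    is deterministic.  Returns (labels, linkage matrix).
    """
    if matrix.shape[1] < 2:
        raise ValidationError("clustering needs >= 2 samples")
    if linkage not in ("ward", "average"):
        raise ParameterError(f"unknown linkage {linkage!r}")
    d = _sample_distances(matrix, distance)
    Z = hierarchy.linkage(d, method=linkage)
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    seen: dict[int, int] = {}
    labels = []
    for lab in raw:
        if lab not in seen:
            seen[lab] = len(seen) + 1
        labels.append(seen[lab])
    return pd.Series(labels, index=matrix.columns, name="cluster"), Z


def pca(matrix: pd.DataFrame, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of sample columns on centred features.

    Returns (samples × components coordinates, variance-explained fractions).
    """
    n_components = int(n_components)
    if n_components > min(matrix.shape):
        raise ParameterError("n_components exceeds matrix dimensions")
    X = matrix.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    coords = (Vt[:n_components].T * S[:n_components])
    total_var = (S ** 2).sum()
    var_frac = (S[:n_components] ** 2) / total_var if total_var > 0 else np.zeros(n_components)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return pd.DataFrame(coords, index=matrix.columns, columns=cols), var_frac
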