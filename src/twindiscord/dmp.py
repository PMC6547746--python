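"""Differentially methylated probe (DMP) calling.

Per-individual collapsing of longitudinal/replicate samples, the paired
test on M-values, the cross-set ranked magnitude-significance procedure
with direction-consistency truncation, within-set |Δβ| thresholding, and
gene-level aggregation with cross-set overlaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    BetaMatrix,
    ProbeAnnotation,
    SampleSheet,
    ValidationError,
    beta_to_m,
)

AFFECTED_STATUSES = ("affected", "asymptomatic_carrier")


@dataclass(frozen=True)
class CollapsedCohort:
    """One affected and one unaffected value per probe per twin set.

    Longitudinal samples and technical replicates are collapsed to a
    per-individual mean; unaffected triplet co-twins are averaged into the
    single unaffected value.  β and M variants are both held (M collapsed
    from per-sample M-values, not recomputed from collapsed β).
    Δ = affected − unaffected.
    """

    beta_affected: pd.DataFrame
    beta_unaffected: pd.DataFrame
    m_affected: pd.DataFrame
    m_unaffected: pd.DataFrame
    control_sets: tuple[str, ...] = ()

    @property
    def set_ids(self) -> list[str]:
        return list(self.beta_affected.columns)

    @property
    def n_sets(self) -> int:
        return self.beta_affected.shape[1]

    @property
    def delta_beta(self) -> pd.DataFrame:
        return self.beta_affected - self.beta_unaffected

    @property
    def delta_m(self) -> pd.DataFrame:
        return self.m_affected - self.m_unaffected


@dataclass(frozen=True)
class RankedDmpResult:
    table: pd.DataFrame  # per-probe stats + ranks, sorted by mean_rank (HC only rows flagged)
    top_list: tuple[str, ...]

    def __post_init__(self) -> None:
        top = self.table.loc[list(self.top_list)]
        assert bool(top["direction_consistent"].all())


@dataclass(frozen=True)
class WithinSetDmpResult:
    """Per twin set: DataFrame (probe_id, delta_beta, direction)."""

    per_set: dict[str, pd.DataFrame]
    threshold: float


def collapse_per_individual(
    beta: BetaMatrix,
    sheet: SampleSheet,
    affected_statuses: tuple[str, ...] = AFFECTED_STATUSES,
    sets: list[str] | None = None,
) -> CollapsedCohort:
    """Collapse to one affected / one unaffected value per twin set.

    Each individual's samples (all collections and replicates) are averaged;
    a set's unaffected value is the mean over its unaffected individuals.
    Sets whose members are all unaffected/control are treated as control
    sets: the first-listed individual stands in as the reference
    ("affected") side and is recorded in ``control_sets``.
    """
    m = beta_to_m(beta)
    meta = sheet.data[sheet.data["sample_id"].isin(beta.sample_ids)]
    meta = meta[meta["cohort"] == "twin"]
    set_ids = sets if sets is not None else list(dict.fromkeys(meta["twin_set_id"]))

    beta_aff, beta_un, m_aff, m_un = {}, {}, {}, {}
    control_sets = []
    for set_id in set_ids:
        grp = meta[meta["twin_set_id"] == set_id]
        if grp.empty:
            raise ValidationError(f"twin set {set_id!r} has no samples in the matrix")
        indiv_beta: dict[str, pd.Series] = {}
        indiv_m: dict[str, pd.Series] = {}
        indiv_status: dict[str, str] = {}
        for indiv, sub in grp.groupby("individual_id", sort=False):
            cols = list(sub["sample_id"])
            indiv_beta[indiv] = beta.data[cols].mean(axis=1)
            indiv_m[indiv] = m.data[cols].mean(axis=1)
            indiv_status[indiv] = sub["disease_status"].iloc[0]
        affected = [i for i in indiv_beta if indiv_status[i] in affected_statuses]
        unaffected = [i for i in indiv_beta if indiv_status[i] not in affected_statuses]
        if not affected:
            # control set: first-listed individual is the reference side
            ordered = list(indiv_beta)
            affected, unaffected = ordered[:1], ordered[1:]
            control_sets.append(set_id)
        if not unaffected:
            raise ValidationError(f"twin set {set_id!r} has no unaffected individual")
        beta_aff[set_id] = pd.concat([indiv_beta[i] for i in affected], axis=1).mean(axis=1)
        m_aff[set_id] = pd.concat([indiv_m[i] for i in affected], axis=1).mean(axis=1)
        beta_un[set_id] = pd.concat([indiv_beta[i] for i in unaffected], axis=1).mean(axis=1)
        m_un[set_id] = pd.concat([indiv_m[i] for i in unaffected], axis=1).mean(axis=1)

    return CollapsedCohort(
        beta_affected=pd.DataFrame(beta_aff),
        beta_unaffected=pd.DataFrame(beta_un),
        m_affected=pd.DataFrame(m_aff),
        m_unaffected=pd.DataFrame(m_un),
        control_sets=tuple(control_sets),
    )


def paired_twin_test(collapsed: CollapsedCohort, exclude_controls: bool = True) -> pd.DataFrame:
    """Classic paired t-test per probe on collapsed per-set M differences.

    df = n_sets − 1, two-sided p.  Zero-variance differences give p = 0
    (nonzero mean, flagged) or t = 0, p = 1 (all-zero differences).
    Returns columns t_statistic, p_value, zero_variance.
    """
    sets = [s for s in collapsed.set_ids
            if not (exclude_controls and s in collapsed.control_sets)]
    if len(sets) < 2:
        raise ValidationError("paired test needs >= 2 discordant sets")
    d = collapsed.delta_m[sets].to_numpy(dtype=float)
    n = d.shape[1]
    mean = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
        zero_var = sd <= 1e-12 * np.maximum(np.abs(mean), 1.0)
        zero_mean = np.abs(mean) <= 1e-12
        t = np.where(zero_var, np.where(zero_mean, 0.0, np.sign(mean) * np.inf), t)
        p = np.where(zero_var, np.where(zero_mean, 1.0, 0.0), p)
    return pd.DataFrame(
        {"t_statistic": t, "p_value": p, "zero_variance": zero_var},
        index=collapsed.delta_m.index,
    )


def rank_combine_and_truncate(
    collapsed: CollapsedCohort,
    annotation: ProbeAnnotation,
    hil_restrict: str = "HC",
    exclude_controls: bool = True,
) -> RankedDmpResult:
    """Ranked magnitude-significance DMP procedure.

    All probes are ranked by ascending paired-test p (significance, M scale)
    and by descending |mean Δβ| (magnitude, β scale), ties averaged;
    mean_rank is their average.  The list restricted to ``hil_restrict``
    probes and sorted by mean_rank (ties broken by probe id) is truncated
    immediately before the first probe whose per-set Δβ signs are not all
    identical across the discordant sets; that prefix is the top_list.
    """
    tests = paired_twin_test(collapsed, exclude_controls=exclude_controls)
    sets = [s for s in collapsed.set_ids
            if not (exclude_controls and s in collapsed.control_sets)]
    delta = collapsed.delta_beta[sets]
    mean_delta = delta.mean(axis=1)

    sig_rank = pd.Series(
        stats.rankdata(tests["p_value"].to_numpy(), method="average"),
        index=tests.index,
    )
    mag_rank = pd.Series(
        stats.rankdata(-np.abs(mean_delta.to_numpy()), method="average"),
        index=tests.index,
    )
    mean_rank = (sig_rank + mag_rank) / 2.0
    signs = np.sign(delta.to_numpy())
    consistent = (signs == 1).all(axis=1) | (signs == -1).all(axis=1)

    table = pd.DataFrame({
        "t_statistic": tests["t_statistic"],
        "p_value": tests["p_value"],
        "mean_delta_beta": mean_delta,
        "significance_rank": sig_rank,
        "magnitude_rank": mag_rank,
        "mean_rank": mean_rank,
        "direction_consistent": consistent,
    })
    for s in sets:
        table[f"delta_beta_{s}"] = delta[s]

    hil = annotation.hil_map()
    table["hil_category"] = hil.reindex(table.index)
    hc = table[table["hil_category"] == hil_restrict].copy()
    # stable sort after an index sort: mean_rank ties break by probe id
    hc = hc.sort_index(kind="mergesort").sort_values("mean_rank", kind="mergesort")

    top: list[str] = []
    for pid, row in hc.iterrows():
        if not row["direction_consistent"]:
            break
        top.append(pid)

    table = table.sort_index(kind="mergesort").sort_values("mean_rank", kind="mergesort")
    return RankedDmpResult(table=table, top_list=tuple(top))


def dmp_probe_sets(result: WithinSetDmpResult) -> dict[str, list[str]]:
    """Probe-id lists per set from a within-set DMP result."""
    return {s: list(df.index) for s, df in result.per_set.items()}


def within_set_dmps(
    collapsed: CollapsedCohort,
    threshold: float = 0.25,
    include_sets: list[str] | None = None,
) -> WithinSetDmpResult:
    """Per-set probes with |Δβ| ≥ threshold (inclusive), affected as the
    direction reference (hyper/hypo in affected).  Control sets use the
    first-listed co-twin as reference; their labels are magnitude-only."""
    sets = include_sets if include_sets is not None else collapsed.set_ids
    per_set: dict[str, pd.DataFrame] = {}
    for s in sets:
        d = collapsed.delta_beta[s]
        # tolerance keeps the inclusive boundary robust to float round-off
        hit = d[np.abs(d) >= threshold - 1e-12]
        per_set[s] = pd.DataFrame({
            "delta_beta": hit,
            "direction": np.where(hit > 0, "hyper", "hypo"),
        })
    return WithinSetDmpResult(per_set=per_set, threshold=threshold)


def aggregate_dmps_to_genes(
    dmps: dict[str, list[str]],
    annotation: ProbeAnnotation,
    min_probes_per_gene: int = 2,
    control_sets: tuple[str, ...] = (),
) -> dict:
    """Per-set gene lists plus cross-set probe/gene overlap tallies.

    A gene is listed for a set when at least ``min_probes_per_gene`` of the
    set's DMPs annotate to it (multi-gene probes count toward each symbol).
    Control sets are tallied separately from discordant sets.
    """
    gene_map = annotation.gene_map()
    genes_per_set: dict[str, list[str]] = {}
    for set_id, probes in dmps.items():
        counts: dict[str, int] = {}
        for p in probes:
            if p not in gene_map:
                raise ValidationError(f"probe {p!r} missing from annotation")
            for g in gene_map[p]:
                counts[g] = counts.get(g, 0) + 1
        genes_per_set[set_id] = sorted(g for g, c in counts.items() if c >= min_probes_per_gene)

    disc = [s for s in dmps if s not in control_sets]
    ctrl = [s for s in dmps if s in control_sets]

    def _overlaps(set_ids: list[str], item_map: dict[str, list[str]]) -> dict:
        membership: dict[str, set[str]] = {}
        for s in set_ids:
            for item in item_map[s]:
                membership.setdefault(item, set()).add(s)
        multi = {i: sorted(ss) for i, ss in membership.items() if len(ss) > 1}
        pairwise = {
            f"{a}&{b}": len(set(item_map[a]) & set(item_map[b]))
            for a, b in combinations(set_ids, 2)
        }
        return {"in_multiple_sets": multi, "pairwise_counts": pairwise}

    return {
        "genes_per_set": genes_per_set,
        "probe_overlaps": _overlaps(disc, dmps),
        "gene_overlaps": _overlaps(disc, genes_per_set),
        "control_probe_overlaps": _overlaps(ctrl, dmps) if ctrl else None,
        "control_sets": list(ctrl),
    }
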