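"""Synthetic cohorts with planted truth.

Generates MZ-twin methylome cohorts (shared baselines, individual
deviations, longitudinal collections, technical replicates, planted
disease Δβ effects), case-control cohorts, amplicon plates with structured
missingness, synthetic epigenetic clocks with an exact age embedding,
cell-type references and mixtures, and negative-binomial count matrices
with planted fold changes.  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    HIL_CATEGORIES,
    BetaMatrix,
    ClockModel,
    CountMatrix,
    DetectionPMatrix,
    ParameterError,
    ProbeAnnotation,
    SampleSheet,
    ValidationError,
)
from .epityper import EpityperPlate
from .features import DEFAULT_CELL_TYPES, CellReferenceMatrix, age_transform

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TwinSimConfig:
    """Configuration for :func:`simulate_twin_methylomes`.

    ``triplet_sets`` holds 1-based set numbers that get a second unaffected
    co-twin.  ``hil_fractions`` are proportions over (HC, IC, ICshore, LC).
    """

    n_twin_sets: int = 4
    triplet_sets: tuple[int, ...] = ()
    n_probes: int = 1000
    n_planted_dmps_shared: int = 10
    n_planted_dmps_private: int = 0
    delta_beta: float = 0.3
    n_collections: int = 1
    n_replicates: int = 1
    replicate_sd: float = 0.02
    biological_sd: float = 0.02
    hil_fractions: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    detection_fail_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.delta_beta < 1):
            raise ParameterError("delta_beta must be in (0, 1)")
        if abs(sum(self.hil_fractions) - 1.0) > 1e-9:
            raise ParameterError("hil_fractions must sum to 1")
        for name in ("n_twin_sets", "n_probes", "n_planted_dmps_shared",
                     "n_planted_dmps_private", "n_collections", "n_replicates"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        bad = [t for t in self.triplet_sets if not (1 <= t <= self.n_twin_sets)]
        if bad:
            raise ParameterError(f"triplet_sets out of range: {bad}")
        n_planted = (self.n_planted_dmps_shared
                     + self.n_planted_dmps_private * self.n_twin_sets)
        if n_planted > self.n_probes:
            raise ParameterError("planted probes exceed n_probes")


@dataclass
class SimulationTruth:
    """Planted effects keyed by the ids emitted in the matrices."""

    planted_shared_dmps: dict[str, dict[str, float]] = field(default_factory=dict)
    planted_private_dmps: dict[str, dict[str, float]] = field(default_factory=dict)
    planted_degs: dict[str, float] = field(default_factory=dict)
    true_ages: dict[str, float] = field(default_factory=dict)
    true_cell_fractions: dict[str, dict[str, float]] = field(default_factory=dict)
    clock: ClockModel | None = None
    failed_samples: list[str] = field(default_factory=list)
    failed_units: list[str] = field(default_factory=list)
    probe_effects: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        obj = {
            "planted_shared_dmps": self.planted_shared_dmps,
            "planted_private_dmps": self.planted_private_dmps,
            "planted_degs": self.planted_degs,
            "true_ages": self.true_ages,
            "true_cell_fractions": self.true_cell_fractions,
            "failed_samples": self.failed_samples,
            "failed_units": self.failed_units,
            "probe_effects": self.probe_effects,
            "clock": None if self.clock is None else {
                "intercept": self.clock.intercept,
                "coefficients": self.clock.coefficients,
                "transform": self.clock.transform,
                "adult_age": self.clock.adult_age,
            },
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)


# ---------------------------------------------------------------------------
# Synthetic clock
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticClock:
    """A clock model plus the β embedding that makes it exactly invertible.

    Each clock CpG carries β(age) = base + slope·T(age), with T the clock's
    forward age transform; the weights satisfy Σ w·slope = 1 and the
    intercept cancels Σ w·base, so the linear predictor equals T(age)
    exactly in the noiseless limit.
    """

    model: ClockModel
    base: dict[str, float]
    slope: dict[str, float]

    def embed(self, ages, rng: np.random.Generator | None = None,
              noise_sd: float = 0.0) -> pd.DataFrame:
        """Noiseless (or jittered) clock-CpG β rows for the given ages."""
        ages = np.asarray(ages, dtype=float)
        g = age_transform(ages, self.model.transform, self.model.adult_age)
        cpgs = self.model.cpg_ids
        b = np.array([self.base[c] for c in cpgs])[:, None]
        d = np.array([self.slope[c] for c in cpgs])[:, None]
        vals = b + d * g[None, :]
        if noise_sd > 0:
            if rng is None:
                rng = np.random.default_rng(0)
            vals = vals + rng.normal(0, noise_sd, vals.shape)
        return pd.DataFrame(np.clip(vals, 0.0, 1.0), index=cpgs)


def make_synthetic_clock(
    n_clock_cpgs: int,
    transform: str = "identity",
    adult_age: float = 20.0,
    seed: int = 0,
    age_span: tuple[float, float] = (0.0, 100.0),
) -> SyntheticClock:
    """Build a clock whose linear predictor recovers the transformed age
    exactly when β follows the paired embedding."""
    if n_clock_cpgs < 1:
        raise ParameterError("n_clock_cpgs must be >= 1")
    rng = np.random.default_rng(seed)
    cpgs = [f"clk{i:04d}" for i in range(1, n_clock_cpgs + 1)]
    g_lo, g_hi = (float(x) for x in age_transform(
        np.asarray(age_span), transform, adult_age))
    base, slope = {}, {}
    for c in cpgs:
        sgn = rng.choice([-1.0, 1.0])
        # slope small enough that β stays inside (0, 1) over the age span
        max_abs = 0.9 / max(abs(g_lo), abs(g_hi), 1e-9)
        d = sgn * rng.uniform(0.3 * max_abs, 0.5 * max_abs)
        lo = 0.02 + max(-d * g_lo, -d * g_hi, 0.0)
        hi = 0.98 - max(d * g_lo, d * g_hi, 0.0)
        base[c] = float(rng.uniform(lo, hi))
        slope[c] = float(d)
    weights = {c: 1.0 / (n_clock_cpgs * slope[c]) for c in cpgs}
    intercept = -sum(weights[c] * base[c] for c in cpgs)
    model = ClockModel(intercept=intercept, coefficients=weights,
                       transform=transform, adult_age=adult_age)
    return SyntheticClock(model=model, base=base, slope=slope)


# ---------------------------------------------------------------------------
# Twin methylome cohort
# ---------------------------------------------------------------------------


def _bimodal_baseline(rng: np.random.Generator, n: int) -> np.ndarray:
    """50/50 mixture of Beta(0.5, 8) and Beta(8, 0.5): a bimodal methylome."""
    low = rng.beta(0.5, 8.0, n)
    high = rng.beta(8.0, 0.5, n)
    pick = rng.random(n) < 0.5
    return np.where(pick, low, high)


def simulate_twin_methylomes(
    config: TwinSimConfig,
    clock: SyntheticClock | None = None,
) -> tuple[BetaMatrix, DetectionPMatrix, SampleSheet, ProbeAnnotation, SimulationTruth]:
    """Simulate an MZ twin cohort with planted disease effects.

    Per twin set a shared bimodal baseline; per individual a Gaussian offset
    (sd ``biological_sd``); affected individuals shifted by ±delta_beta at
    planted probes (sign fixed per probe for shared DMPs); every sample adds
    replicate noise (sd ``replicate_sd``); all β clipped to [0, 1].  When a
    :class:`SyntheticClock` is given its CpG rows are appended with a
    noiseless age embedding and sample ages recorded in the truth.
    """
    rng = np.random.default_rng(config.seed)
    n_probes = config.n_probes
    probe_ids = [f"cg{i:05d}" for i in range(1, n_probes + 1)]

    hil = rng.choice(HIL_CATEGORIES, size=n_probes, p=config.hil_fractions)
    hc_idx = np.flatnonzero(hil == "HC")
    n_private_total = config.n_planted_dmps_private * config.n_twin_sets
    need = config.n_planted_dmps_shared + n_private_total
    if need > len(hc_idx):
        # force enough HC probes for the requested planted effects
        extra = rng.choice(np.flatnonzero(hil != "HC"), need - len(hc_idx), replace=False)
        hil[extra] = "HC"
        hc_idx = np.flatnonzero(hil == "HC")
    planted_idx = rng.choice(hc_idx, size=need, replace=False)
    shared_idx = planted_idx[: config.n_planted_dmps_shared]
    private_idx = planted_idx[config.n_planted_dmps_shared:]

    baseline = _bimodal_baseline(rng, n_probes)
    shared_sign = rng.choice([-1.0, 1.0], size=len(shared_idx))
    # mid-range baselines at planted probes so the shift does not clip
    margin = 0.1
    for j, idx in enumerate(shared_idx):
        if shared_sign[j] > 0:
            baseline[idx] = rng.uniform(margin, 1 - config.delta_beta - margin)
        else:
            baseline[idx] = rng.uniform(config.delta_beta + margin, 1 - margin)

    set_ids = [f"set{i}" for i in range(1, config.n_twin_sets + 1)]
    private_map: dict[str, dict[str, float]] = {}
    pos = 0
    for i, set_id in enumerate(set_ids):
        effects: dict[str, float] = {}
        for _ in range(config.n_planted_dmps_private):
            idx = private_idx[pos]
            sgn = float(rng.choice([-1.0, 1.0]))
            if sgn > 0:
                baseline[idx] = rng.uniform(margin, 1 - config.delta_beta - margin)
            else:
                baseline[idx] = rng.uniform(config.delta_beta + margin, 1 - margin)
            effects[probe_ids[idx]] = sgn * config.delta_beta
            pos += 1
        private_map[set_id] = effects

    # cohort layout
    records = []
    columns: dict[str, np.ndarray] = {}
    truth = SimulationTruth()
    sample_counter = 0
    for i, set_id in enumerate(set_ids):
        set_no = i + 1
        n_indiv = 3 if set_no in config.triplet_sets else 2
        sex = str(rng.choice(["F", "M"]))
        base_age = float(rng.uniform(25, 65))
        for j in range(n_indiv):
            indiv = f"{set_id}_i{j + 1}"
            status = "affected" if j == 0 else "unaffected"
            offset = rng.normal(0, config.biological_sd, n_probes)
            effect = np.zeros(n_probes)
            if status == "affected":
                effect[shared_idx] = shared_sign * config.delta_beta
                for pid, d in private_map[set_id].items():
                    effect[probe_ids.index(pid)] = d
            profile = baseline + offset + effect
            for ci in range(1, config.n_collections + 1):
                age = base_age + (ci - 1) * 2.0
                rep_group = f"{indiv}_c{ci}"
                for _ in range(config.n_replicates):
                    sample_counter += 1
                    sid = f"s{sample_counter:04d}"
                    noise = rng.normal(0, config.replicate_sd, n_probes)
                    columns[sid] = np.clip(profile + noise, 0.0, 1.0)
                    records.append({
                        "sample_id": sid, "individual_id": indiv,
                        "twin_set_id": set_id, "disease_status": status,
                        "sex": sex, "age_at_collection": age,
                        "collection_index": ci, "replicate_group": rep_group,
                        "cohort": "twin",
                    })
                    truth.true_ages[sid] = age

    sheet = SampleSheet(pd.DataFrame(records))
    beta_df = pd.DataFrame(columns, index=probe_ids)

    all_probe_ids = list(probe_ids)
    if clock is not None:
        ages = [truth.true_ages[s] for s in beta_df.columns]
        clk = clock.embed(ages)
        clk.columns = beta_df.columns
        beta_df = pd.concat([beta_df, clk])
        all_probe_ids += clock.model.cpg_ids
        truth.clock = clock.model

    detp = rng.uniform(0.0, 0.01, beta_df.shape)
    if config.detection_fail_rate > 0:
        fail = rng.random(beta_df.shape) < config.detection_fail_rate
        detp[fail] = rng.uniform(0.06, 0.5, fail.sum())
    detp_df = pd.DataFrame(detp, index=beta_df.index, columns=beta_df.columns)

    gene_pool = [f"GENE{i:04d}" for i in range(1, max(n_probes // 10, 5) + 1)]
    genes = []
    for _ in all_probe_ids:
        u = rng.random()
        if u < 0.1:
            genes.append("")
        elif u < 0.9:
            genes.append(str(rng.choice(gene_pool)))
        else:
            genes.append(";".join(rng.choice(gene_pool, 2, replace=False)))
    annot = ProbeAnnotation(pd.DataFrame({
        "probe_id": all_probe_ids,
        "chromosome": "chr1",
        "position": np.arange(1, len(all_probe_ids) + 1) * 100,
        "genes": genes,
        "distance_to_tss": rng.integers(-2000, 2000, len(all_probe_ids)),
        "hil_category": list(hil) + ["LC"] * (len(all_probe_ids) - n_probes),
        "cross_hybridising": False,
        "sex_chromosome": False,
        "snp_overlap": False,
    }))

    truth.planted_shared_dmps = {
        probe_ids[idx]: {s: float(shared_sign[j] * config.delta_beta) for s in set_ids}
        for j, idx in enumerate(shared_idx)
    }
    truth.planted_private_dmps = private_map
    return (BetaMatrix(beta_df), DetectionPMatrix(detp_df), sheet, annot, truth)


# ---------------------------------------------------------------------------
# Case-control methylation cohort
# ---------------------------------------------------------------------------


def simulate_case_control(
    n_cases: int,
    n_controls: int,
    probe_effects: dict[str, float],
    age_range: tuple[float, float] = (40.0, 75.0),
    sex_imbalance: float = 0.5,
    seed: int = 0,
    n_null_probes: int = 50,
    noise_sd: float = 0.05,
) -> tuple[BetaMatrix, SampleSheet, SimulationTruth]:
    """Unrelated case-control β matrix with planted case shifts.

    Case columns are shifted by Δβ at the listed probes; values pushed
    outside [0, 1] are clipped with a warning.  ``sex_imbalance`` is the
    male fraction in both groups.
    """
    if n_cases < 2 or n_controls < 2:
        raise ParameterError("need >= 2 cases and >= 2 controls")
    rng = np.random.default_rng(seed)
    effect_probes = list(probe_effects)
    null_probes = [f"np{i:04d}" for i in range(1, n_null_probes + 1)]
    probes = effect_probes + null_probes
    baseline = np.empty(len(probes))
    for i, p in enumerate(effect_probes):
        d = probe_effects[p]
        lo = max(0.15, -d + 0.15)
        hi = min(0.85, 1 - d - 0.15)
        baseline[i] = rng.uniform(lo, hi) if lo < hi else 0.5
    baseline[len(effect_probes):] = rng.uniform(0.1, 0.9, n_null_probes)

    effect = np.zeros(len(probes))
    effect[: len(effect_probes)] = [probe_effects[p] for p in effect_probes]

    records = []
    columns = {}
    for k in range(n_cases + n_controls):
        is_case = k < n_cases
        sid = f"{'case' if is_case else 'ctrl'}{k + 1 if is_case else k - n_cases + 1:04d}"
        vals = baseline + (effect if is_case else 0.0) + rng.normal(0, noise_sd, len(probes))
        if ((vals < 0) | (vals > 1)).any():
            logger.warning("clipping %d value(s) outside [0, 1] for %s",
                           int(((vals < 0) | (vals > 1)).sum()), sid)
        columns[sid] = np.clip(vals, 0.0, 1.0)
        records.append({
            "sample_id": sid, "individual_id": sid, "twin_set_id": sid,
            "disease_status": "affected" if is_case else "control",
            "sex": "M" if rng.random() < sex_imbalance else "F",
            "age_at_collection": float(rng.uniform(*age_range)),
            "collection_index": 1, "replicate_group": sid,
            "cohort": "case_control",
        })
    sheet = SampleSheet(pd.DataFrame(records))
    beta = BetaMatrix(pd.DataFrame(columns, index=probes))
    truth = SimulationTruth(probe_effects=dict(probe_effects))
    return beta, sheet, truth


# ---------------------------------------------------------------------------
# Amplicon plate
# ---------------------------------------------------------------------------


def simulate_epityper(
    n_units: int,
    n_samples: int,
    missing_rate: float = 0.05,
    failed_samples: int = 0,
    failed_units: int = 0,
    seed: int = 0,
) -> tuple[EpityperPlate, SimulationTruth]:
    """Percent-methylation plate with structured missingness.

    Designated failed samples/units receive >= 90% missing entries (an
    exact count of ceil(0.95·dim) cells); all other cells are missing
    independently at ``missing_rate``.
    """
    if failed_samples > n_samples or failed_units > n_units:
        raise ParameterError("failure counts exceed plate dimensions")
    rng = np.random.default_rng(seed)
    units = [f"u{i:03d}" for i in range(1, n_units + 1)]
    samples = [f"e{i:03d}" for i in range(1, n_samples + 1)]
    base = rng.uniform(5, 95, n_units)
    vals = np.clip(base[:, None] + rng.normal(0, 3.0, (n_units, n_samples)), 0, 100)
    miss = rng.random((n_units, n_samples)) < missing_rate

    fail_s = list(rng.choice(n_samples, failed_samples, replace=False))
    fail_u = list(rng.choice(n_units, failed_units, replace=False))
    for j in fail_s:
        k = int(np.ceil(0.95 * n_units))
        miss[rng.choice(n_units, k, replace=False), j] = True
    for i in fail_u:
        k = int(np.ceil(0.95 * n_samples))
        miss[i, rng.choice(n_samples, k, replace=False)] = True

    vals = vals.astype(float)
    vals[miss] = np.nan
    plate = EpityperPlate(
        pd.DataFrame(vals, index=units, columns=samples),
        n_sites=pd.Series(rng.integers(1, 5, n_units), index=units),
    )
    truth = SimulationTruth(
        failed_samples=[samples[j] for j in fail_s],
        failed_units=[units[i] for i in fail_u],
    )
    return plate, truth


# ---------------------------------------------------------------------------
# Cell reference and mixtures
# ---------------------------------------------------------------------------


def make_cell_reference(
    n_probes: int = 600,
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES,
    seed: int = 0,
) -> CellReferenceMatrix:
    """Discriminating reference profiles: each probe is near-unmethylated in
    one marker cell type and higher elsewhere."""
    rng = np.random.default_rng(seed)
    k = len(cell_types)
    vals = rng.uniform(0.4, 0.9, (n_probes, k))
    marker = rng.integers(0, k, n_probes)
    vals[np.arange(n_probes), marker] = rng.uniform(0.0, 0.15, n_probes)
    probes = [f"ref{i:04d}" for i in range(1, n_probes + 1)]
    return CellReferenceMatrix(pd.DataFrame(vals, index=probes, columns=list(cell_types)))


def simulate_cell_mixtures(
    reference: CellReferenceMatrix,
    n_samples: int,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[BetaMatrix, SimulationTruth]:
    """β profiles that are exact (or noisy) convex mixtures of the reference."""
    rng = np.random.default_rng(seed)
    k = len(reference.cell_types)
    W = rng.dirichlet(np.ones(k), size=n_samples)  # rows sum to 1
    R = reference.data.to_numpy()
    B = R @ W.T
    if noise_sd > 0:
        B = B + rng.normal(0, noise_sd, B.shape)
    B = np.clip(B, 0.0, 1.0)
    samples = [f"mix{i:03d}" for i in range(1, n_samples + 1)]
    beta = BetaMatrix(pd.DataFrame(B, index=reference.probe_ids, columns=samples))
    truth = SimulationTruth(true_cell_fractions={
        s: dict(zip(reference.cell_types, map(float, W[i])))
        for i, s in enumerate(samples)
    })
    return beta, truth


# ---------------------------------------------------------------------------
# RNA-seq counts
# ---------------------------------------------------------------------------


def simulate_counts(
    n_genes: int,
    sheet: SampleSheet,
    n_planted_degs: int = 0,
    log2fc: float = 1.0,
    dispersion: float = 0.1,
    baseline_logmean_range: tuple[float, float] = (3.0, 9.0),
    seed: int = 0,
) -> tuple[CountMatrix, SimulationTruth]:
    """Negative-binomial counts over the sheet's samples.

    Planted genes are scaled by 2^log2fc in affected columns; a per-gene,
    per-collection batch factor is shared by all samples of one collection
    (so the paired design can absorb it).  ``dispersion`` 0 gives Poisson.
    """
    if n_planted_degs > n_genes:
        raise ParameterError("planted genes exceed n_genes")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(1, n_genes + 1)]
    planted = list(rng.choice(genes, n_planted_degs, replace=False))
    mu_base = 2.0 ** rng.uniform(*baseline_logmean_range, n_genes)

    meta = sheet.data
    samples = list(meta["sample_id"])
    lib_factor = rng.lognormal(0.0, 0.1, len(samples))
    collections = sorted(meta["collection_index"].unique())
    batch = {c: rng.lognormal(0.0, 0.1, n_genes) for c in collections}
    affected = meta["disease_status"].isin(["affected", "asymptomatic_carrier"]).to_numpy()
    planted_mask = np.isin(genes, planted)

    cols = {}
    for j, sid in enumerate(samples):
        mu = mu_base * batch[meta["collection_index"].iloc[j]] * lib_factor[j]
        if affected[j]:
            mu = mu * np.where(planted_mask, 2.0 ** log2fc, 1.0)
        if dispersion > 0:
            r = 1.0 / dispersion
            counts = rng.negative_binomial(r, r / (r + mu))
        else:
            counts = rng.poisson(mu)
        cols[sid] = counts
    cm = CountMatrix(pd.DataFrame(cols, index=genes, dtype=np.int64))
    truth = SimulationTruth(planted_degs={g: float(log2fc) for g in planted})
    return cm, truth
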