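import numpy as np
import pandas as pd
import pytest
from scipy import stats

from twindiscord import simulate as sim
from twindiscord.core import CountMatrix, ValidationError
from twindiscord.expression import (
    cpm,
    cpm_filter,
    normalise,
    paired_de_test,
    threshold_degs,
    tmm_factors,
    validate_degs_case_control,
)


def brute_force_tmm(counts: pd.DataFrame, logratio_trim=0.30, abs_trim=0.05):
    """Independent TMM oracle: literal loop over the published recipe."""
    lib = counts.sum(axis=0)
    scaled = counts / lib
    uq = scaled.quantile(0.75, axis=0)
    ref = (uq - uq.mean()).abs().idxmin()
    yr = counts[ref].to_numpy().astype(float)
    nr = float(lib[ref])
    factors = {}
    for s in counts.columns:
        if s == ref:
            factors[s] = 1.0
            continue
        ys = counts[s].to_numpy().astype(float)
        ns = float(lib[s])
        keep0 = (ys > 0) & (yr > 0)
        ys_, yr_ = ys[keep0], yr[keep0]
        m = np.log2((ys_ / ns) / (yr_ / nr))
        a = 0.5 * np.log2((ys_ / ns) * (yr_ / nr))
        w = (ns - ys_) / (ns * ys_) + (nr - yr_) / (nr * yr_)
        n = len(m)
        lo_m, hi_m = np.floor(n * logratio_trim) + 1, n - np.floor(n * logratio_trim)
        lo_a, hi_a = np.floor(n * abs_trim) + 1, n - np.floor(n * abs_trim)
        rm, ra = stats.rankdata(m), stats.rankdata(a)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if keep.sum() == 0:
            factors[s] = 1.0
        else:
            factors[s] = 2 ** (np.sum(m[keep] / w[keep]) / np.sum(1 / w[keep]))
    f = pd.Series(factors).loc[counts.columns]
    return f / np.exp(np.mean(np.log(f)))


def _pair_sheet(n_collections=3, seed=0):
    cfg = sim.TwinSimConfig(n_twin_sets=2, n_probes=10, n_planted_dmps_shared=0,
                            n_collections=n_collections, seed=seed)
    _, _, sheet, _, _ = sim.simulate_twin_methylomes(cfg)
    keep = sheet.data.loc[sheet.data.twin_set_id == "set1", "sample_id"]
    return sheet.subset(list(keep))


class TestCpmFilter:
    def test_cpm_definition(self):
        cm = CountMatrix(pd.DataFrame({"s1": [500, 999500]}, index=["g1", "g2"]))
        assert cpm(cm).loc["g1", "s1"] == pytest.approx(500.0)

    def test_retained_with_three_samples(self):
        lib = 1_000_000
        cm = CountMatrix(pd.DataFrame(
            {f"s{i}": [c, lib - c] for i, c in enumerate([400, 400, 400, 100])},
            index=["g1", "g2"]))
        assert "g1" in cpm_filter(cm, 0.3, 3)

    def test_boundary_strictly_greater(self):
        lib = 10_000_000  # count 3 → CPM exactly 0.3
        cm = CountMatrix(pd.DataFrame(
            {f"s{i}": [3, lib - 3] for i in range(4)}, index=["g1", "g2"]))
        assert "g1" not in cpm_filter(cm, 0.3, 3)

    def test_monotone_in_parameters(self):
        rng = np.random.default_rng(1)
        cm = CountMatrix(pd.DataFrame(
            rng.integers(0, 50, (100, 6)), index=[f"g{i}" for i in range(100)],
            columns=[f"s{i}" for i in range(6)]))
        n1 = len(cpm_filter(cm, 1.0, 2))
        n2 = len(cpm_filter(cm, 5.0, 2))
        n3 = len(cpm_filter(cm, 1.0, 4))
        assert n2 <= n1 and n3 <= n1


class TestTmm:
    def test_identical_columns_unit_factors(self):
        col = np.arange(1, 201)
        cm = CountMatrix(pd.DataFrame({"a": col, "b": col, "c": col},
                                      index=[f"g{i}" for i in range(200)]))
        np.testing.assert_allclose(tmm_factors(cm).to_numpy(), 1.0, atol=1e-12)

    def test_depth_change_invariant(self):
        rng = np.random.default_rng(2)
        col = rng.integers(1, 500, 300)
        cm = CountMatrix(pd.DataFrame({"a": col, "b": 2 * col},
                                      index=[f"g{i}" for i in range(300)]))
        np.testing.assert_allclose(tmm_factors(cm).to_numpy(), 1.0, atol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        counts = pd.DataFrame(
            rng.negative_binomial(5, 0.05, (200, 6)),
            index=[f"g{i}" for i in range(200)],
            columns=[f"s{i}" for i in range(6)])
        counts += 1  # avoid all-zero rows
        mine = tmm_factors(CountMatrix(counts))
        oracle = brute_force_tmm(counts)
        np.testing.assert_allclose(mine.to_numpy(), oracle.to_numpy(), atol=1e-8)

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(rng.integers(1, 1000, (100, 4)),
                              index=[f"g{i}" for i in range(100)],
                              columns=list("abcd"))
        f1 = tmm_factors(CountMatrix(counts))
        f2 = tmm_factors(CountMatrix(counts.sample(frac=1, random_state=7)))
        np.testing.assert_allclose(f1.to_numpy(), f2.to_numpy(), atol=1e-12)

    def test_geometric_mean_one(self):
        rng = np.random.default_rng(4)
        counts = pd.DataFrame(rng.integers(1, 1000, (150, 5)),
                              index=[f"g{i}" for i in range(150)],
                              columns=list("abcde"))
        f = tmm_factors(CountMatrix(counts))
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_column_errors(self):
        cm_df = pd.DataFrame({"a": [1, 2], "b": [0, 0]}, index=["g1", "g2"])
        with pytest.raises(ValidationError):
            tmm_factors(CountMatrix(cm_df))


class TestPairedDe:
    def test_identical_twins_null_gene(self):
        sheet = _pair_sheet()
        cm, _ = sim.simulate_counts(200, sheet, n_planted_degs=0, seed=5)
        norm = normalise(cm)
        res = paired_de_test(norm, sheet)
        assert abs(res["log2_fold_change"].mean()) < 0.05
        assert (res["fdr"] < 0.05).mean() <= 0.05

    def test_planted_gene_recovered(self):
        sheet = _pair_sheet()
        cm, truth = sim.simulate_counts(300, sheet, n_planted_degs=10, log2fc=1.0,
                                        dispersion=0.05,
                                        baseline_logmean_range=(5.0, 10.0), seed=6)
        res = paired_de_test(normalise(cm), sheet)
        planted = list(truth.planted_degs)
        assert res.loc[planted, "log2_fold_change"].mean() == pytest.approx(1.0, abs=0.3)
        assert (res.loc[planted, "fdr"] < 0.05).mean() >= 0.5

    def test_sign_convention_positive_in_affected(self):
        sheet = _pair_sheet()
        cm, truth = sim.simulate_counts(300, sheet, n_planted_degs=10, log2fc=2.0,
                                        dispersion=0.02, seed=7)
        res = paired_de_test(normalise(cm), sheet)
        assert (res.loc[list(truth.planted_degs), "log2_fold_change"] > 0).all()

    def test_genewise_variance_option(self):
        sheet = _pair_sheet()
        cm, _ = sim.simulate_counts(100, sheet, seed=8)
        res = paired_de_test(normalise(cm), sheet, variance="genewise")
        assert ((res["p_value"] >= 0) & (res["p_value"] <= 1)).all()


class TestThresholdDegs:
    def _results(self):
        return pd.DataFrame({
            "log2_fold_change": [0.8, 0.4, 2.0],
            "t_statistic": [3, 3, 3],
            "p_value": [0.001, 0.001, 0.01],
            "fdr": [0.03, 0.03, 0.06],
        }, index=["gA", "gB", "gC"])

    def test_gates(self):
        out = threshold_degs(self._results())
        assert list(out.index) == ["gA"]

    def test_fc_exactly_at_threshold_kept(self):
        res = self._results()
        res.loc["gB", "log2_fold_change"] = np.log2(1.5)
        out = threshold_degs(res)
        assert "gB" in out.index


class TestCaseControlValidation:
    def _cc(self, n_genes=300, planted=5, log2fc=0.6, seed=9, n=60):
        rows = []
        rng = np.random.default_rng(seed)
        for i in range(n):
            is_case = i < n // 2
            sid = f"cc{i:03d}"
            rows.append({"sample_id": sid, "individual_id": sid,
                         "twin_set_id": sid,
                         "disease_status": "affected" if is_case else "control",
                         "sex": "M" if rng.random() < 0.5 else "F",
                         "age_at_collection": float(rng.uniform(40, 70)),
                         "collection_index": 1, "replicate_group": sid,
                         "cohort": "case_control"})
        from twindiscord.core import SampleSheet
        sheet = SampleSheet(pd.DataFrame(rows))
        cm, truth = sim.simulate_counts(n_genes, sheet, n_planted_degs=planted,
                                        log2fc=log2fc, dispersion=0.05, seed=seed)
        return cm, sheet, truth

    def test_subset_availability_report(self):
        cm, sheet, _ = self._cc()
        subset = ["g00001", "g00002", "not_a_gene"]
        res, report = validate_degs_case_control(cm, sheet, subset)
        assert report["present"] == ["g00001", "g00002"]
        assert report["absent"] == ["not_a_gene"]
        assert set(res.index) == {"g00001", "g00002"}

    def test_fdr_divisor_is_subset_size(self):
        cm, sheet, _ = self._cc()
        subset = [f"g{i:05d}" for i in range(1, 11)]
        res, _ = validate_degs_case_control(cm, sheet, subset)
        from twindiscord.models import bh_fdr
        np.testing.assert_allclose(res["fdr"].to_numpy(),
                                   bh_fdr(res["p_value"].to_numpy()))

    def test_planted_effect_detected(self):
        cm, sheet, truth = self._cc(planted=5, log2fc=1.0, n=160)
        res, _ = validate_degs_case_control(cm, sheet, list(truth.planted_degs))
        assert (res["fdr"] < 0.05).mean() >= 0.8

    def test_empty_subset_errors(self):
        cm, sheet, _ = self._cc()
        with pytest.raises(ValidationError):
            validate_degs_case_control(cm, sheet, [])


def test_normalised_invariants():
    rng = np.random.default_rng(12)
    counts = pd.DataFrame(rng.integers(1, 2000, (200, 6)),
                          index=[f"g{i}" for i in range(200)],
                          columns=[f"s{i}" for i in range(6)])
    norm = normalise(CountMatrix(counts))
    assert (norm.tmm_factors > 0).all()
    assert np.exp(np.mean(np.log(norm.tmm_factors))) == pytest.approx(1.0, abs=1e-12)
    assert norm.logcpm.shape == counts.shape
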