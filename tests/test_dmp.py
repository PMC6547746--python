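import numpy as np
import pandas as pd
import pytest
from scipy import stats

from twindiscord import simulate as sim
from twindiscord.core import BetaMatrix, ProbeAnnotation, SampleSheet, ValidationError, beta_to_m
from twindiscord.dmp import (
    CollapsedCohort,
    aggregate_dmps_to_genes,
    collapse_per_individual,
    dmp_probe_sets,
    paired_twin_test,
    rank_combine_and_truncate,
    within_set_dmps,
)


def _sheet(rows):
    return SampleSheet(pd.DataFrame(rows))


def make_collapsed(delta_beta: pd.DataFrame, base: float = 0.4) -> CollapsedCohort:
    """Collapsed cohort whose per-set Δβ equals the given frame."""
    un = pd.DataFrame(base, index=delta_beta.index, columns=delta_beta.columns)
    aff = un + delta_beta
    to_m = lambda b: np.log2(np.clip(b, 1e-6, 1 - 1e-6) / (1 - np.clip(b, 1e-6, 1 - 1e-6)))
    return CollapsedCohort(
        beta_affected=aff, beta_unaffected=un,
        m_affected=to_m(aff), m_unaffected=to_m(un),
    )


class TestCollapse:
    def _simple(self):
        rows = []
        # set1: affected i1 with 3 longitudinal samples, unaffected i2
        for k, ci in enumerate([1, 2, 3]):
            rows.append({"sample_id": f"a{k}", "individual_id": "i1",
                         "twin_set_id": "set1", "disease_status": "affected",
                         "sex": "F", "age_at_collection": 50.0 + ci,
                         "collection_index": ci, "replicate_group": f"a{k}",
                         "cohort": "twin"})
        rows.append({"sample_id": "u0", "individual_id": "i2",
                     "twin_set_id": "set1", "disease_status": "unaffected",
                     "sex": "F", "age_at_collection": 50.0,
                     "collection_index": 1, "replicate_group": "u0", "cohort": "twin"})
        # set2 so the paired test has two sets
        for sid, ind, st in [("b0", "i3", "affected"), ("b1", "i4", "unaffected")]:
            rows.append({"sample_id": sid, "individual_id": ind,
                         "twin_set_id": "set2", "disease_status": st,
                         "sex": "M", "age_at_collection": 60.0,
                         "collection_index": 1, "replicate_group": sid,
                         "cohort": "twin"})
        sheet = _sheet(rows)
        beta = BetaMatrix(pd.DataFrame(
            {"a0": [0.4], "a1": [0.5], "a2": [0.6], "u0": [0.5],
             "b0": [0.8], "b1": [0.5]}, index=["p1"]))
        return beta, sheet

    def test_longitudinal_mean(self):
        beta, sheet = self._simple()
        col = collapse_per_individual(beta, sheet)
        assert col.beta_affected.loc["p1", "set1"] == pytest.approx(0.5)

    def test_delta_sign_convention(self):
        beta, sheet = self._simple()
        col = collapse_per_individual(beta, sheet)
        assert col.delta_beta.loc["p1", "set2"] == pytest.approx(0.3)

    def test_triplet_unaffected_averaged(self):
        rows = []
        for sid, ind, st in [("x0", "i1", "affected"), ("x1", "i2", "unaffected"),
                             ("x2", "i3", "unaffected")]:
            rows.append({"sample_id": sid, "individual_id": ind,
                         "twin_set_id": "set1", "disease_status": st,
                         "sex": "F", "age_at_collection": 40.0,
                         "collection_index": 1, "replicate_group": sid,
                         "cohort": "twin"})
        sheet = _sheet(rows)
        beta = BetaMatrix(pd.DataFrame({"x0": [0.8], "x1": [0.3], "x2": [0.5]},
                                       index=["p1"]))
        col = collapse_per_individual(beta, sheet)
        assert col.beta_unaffected.loc["p1", "set1"] == pytest.approx(0.4)
        assert col.delta_beta.loc["p1", "set1"] == pytest.approx(0.4)

    def test_control_set_uses_first_individual(self):
        rows = []
        for sid, ind, st in [("c0", "i1", "unaffected"), ("c1", "i2", "unaffected")]:
            rows.append({"sample_id": sid, "individual_id": ind,
                         "twin_set_id": "ctrl1", "disease_status": st,
                         "sex": "F", "age_at_collection": 40.0,
                         "collection_index": 1, "replicate_group": sid,
                         "cohort": "twin"})
        sheet = _sheet(rows)
        beta = BetaMatrix(pd.DataFrame({"c0": [0.6], "c1": [0.4]}, index=["p1"]))
        col = collapse_per_individual(beta, sheet)
        assert col.control_sets == ("ctrl1",)
        assert col.delta_beta.loc["p1", "ctrl1"] == pytest.approx(0.2)

    def test_m_collapsed_from_sample_m(self):
        beta, sheet = self._simple()
        col = collapse_per_individual(beta, sheet)
        m = beta_to_m(beta)
        expected = m.data[["a0", "a1", "a2"]].mean(axis=1)["p1"]
        assert col.m_affected.loc["p1", "set1"] == pytest.approx(expected)


class TestPairedTest:
    def test_symmetric_null(self):
        d = pd.DataFrame([[0.1, -0.1, 0.1, -0.1]], index=["p1"],
                         columns=["s1", "s2", "s3", "s4"])
        col = make_collapsed(d)
        # use M-scale differences directly: construct so delta_m symmetric
        res = paired_twin_test(CollapsedCohort(
            beta_affected=col.beta_affected, beta_unaffected=col.beta_unaffected,
            m_affected=d, m_unaffected=d * 0.0))
        assert res.loc["p1", "t_statistic"] == pytest.approx(0.0)
        assert res.loc["p1", "p_value"] == pytest.approx(1.0)

    def test_hand_computed_t(self):
        d = pd.DataFrame([[0.2, 0.3, 0.25, 0.25]], index=["p1"],
                         columns=list("abcd"))
        res = paired_twin_test(CollapsedCohort(
            beta_affected=d, beta_unaffected=d * 0.0,
            m_affected=d, m_unaffected=d * 0.0))
        assert res.loc["p1", "t_statistic"] == pytest.approx(12.247, abs=1e-3)

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(21)
        aff = pd.DataFrame(rng.normal(0, 1, (1000, 5)),
                           index=[f"p{i}" for i in range(1000)],
                           columns=[f"s{j}" for j in range(5)])
        un = pd.DataFrame(rng.normal(0, 1, (1000, 5)),
                          index=aff.index, columns=aff.columns)
        col = CollapsedCohort(beta_affected=aff * 0 + 0.5,
                              beta_unaffected=un * 0 + 0.5,
                              m_affected=aff, m_unaffected=un)
        res = paired_twin_test(col)
        t_oracle, p_oracle = stats.ttest_rel(aff.to_numpy(), un.to_numpy(), axis=1)
        np.testing.assert_allclose(res["t_statistic"].to_numpy(), t_oracle, atol=1e-10)
        np.testing.assert_allclose(res["p_value"].to_numpy(), p_oracle, atol=1e-10)

    def test_zero_variance_nonzero_mean(self):
        d = pd.DataFrame([[0.2, 0.2, 0.2]], index=["p1"], columns=list("abc"))
        res = paired_twin_test(CollapsedCohort(
            beta_affected=d, beta_unaffected=d * 0.0,
            m_affected=d, m_unaffected=d * 0.0))
        assert res.loc["p1", "p_value"] == 0.0
        assert bool(res.loc["p1", "zero_variance"])


def _annot_for(probes, hil):
    return ProbeAnnotation(pd.DataFrame({
        "probe_id": probes, "chromosome": "chr1",
        "position": np.arange(1, len(probes) + 1),
        "genes": "", "distance_to_tss": 0, "hil_category": hil,
        "cross_hybridising": False, "sex_chromosome": False, "snp_overlap": False,
    }))


class TestRankCombine:
    def test_mean_rank_formula(self):
        rng = np.random.default_rng(30)
        d = pd.DataFrame(rng.normal(0, 0.1, (10, 4)),
                         index=[f"p{i}" for i in range(10)], columns=list("abcd"))
        col = make_collapsed(d)
        annot = _annot_for(list(d.index), ["HC"] * 10)
        res = rank_combine_and_truncate(col, annot)
        expected = (res.table["significance_rank"] + res.table["magnitude_rank"]) / 2
        np.testing.assert_allclose(res.table["mean_rank"], expected)

    def test_truncation_fixture(self):
        """6 HC probes; the 5th by mean rank is direction-inconsistent →
        top list holds exactly the first 4."""
        # deltas: magnitude ordered p1 > p2 > ... ; p5 has a sign flip
        deltas = {
            "p1": [0.30, 0.32, 0.31, 0.29],
            "p2": [0.25, 0.26, 0.24, 0.27],
            "p3": [0.20, 0.21, 0.19, 0.22],
            "p4": [0.15, 0.16, 0.14, 0.17],
            "p5": [0.12, -0.13, 0.11, 0.12],
            "p6": [0.05, 0.06, 0.04, 0.05],
        }
        d = pd.DataFrame(deltas, index=list("abcd")).T
        col = make_collapsed(d)
        annot = _annot_for(list(d.index), ["HC"] * 6)
        res = rank_combine_and_truncate(col, annot)
        assert list(res.top_list) == ["p1", "p2", "p3", "p4"]

    def test_hil_restriction(self):
        d = pd.DataFrame({"p1": [0.3, 0.3], "p2": [0.2, 0.2]},
                         index=["a", "b"]).T
        col = make_collapsed(d)
        annot = _annot_for(["p1", "p2"], ["LC", "HC"])
        res = rank_combine_and_truncate(col, annot)
        assert list(res.top_list) == ["p2"]

    def test_input_order_invariance(self):
        rng = np.random.default_rng(31)
        d = pd.DataFrame(rng.normal(0.1, 0.1, (20, 4)),
                         index=[f"p{i:02d}" for i in range(20)], columns=list("abcd"))
        col1 = make_collapsed(d)
        perm = d.sample(frac=1, random_state=1)
        col2 = make_collapsed(perm)
        annot = _annot_for(list(d.index), ["HC"] * 20)
        r1 = rank_combine_and_truncate(col1, annot)
        r2 = rank_combine_and_truncate(col2, annot)
        assert r1.top_list == r2.top_list

    def test_top_list_all_consistent(self, small_cohort):
        beta, _, sheet, annot, truth = small_cohort
        col = collapse_per_individual(beta, sheet)
        res = rank_combine_and_truncate(col, annot)
        top = res.table.loc[list(res.top_list)]
        assert bool(top["direction_consistent"].all())

    def test_planted_recovery(self, small_cohort):
        beta, _, sheet, annot, truth = small_cohort
        col = collapse_per_individual(beta, sheet)
        res = rank_combine_and_truncate(col, annot)
        planted = set(truth.planted_shared_dmps)
        assert len(planted & set(res.top_list)) / len(planted) >= 0.9


class TestWithinSet:
    def _col(self):
        d = pd.DataFrame({"p1": [0.30], "p2": [0.20], "p3": [-0.25], "p4": [0.0]},
                         index=["set1"]).T
        return make_collapsed(d, base=0.45)

    def test_threshold_rule(self):
        res = within_set_dmps(self._col())
        hits = res.per_set["set1"]
        assert set(hits.index) == {"p1", "p3"}
        assert hits.loc["p1", "direction"] == "hyper"
        assert hits.loc["p3", "direction"] == "hypo"

    def test_boundary_inclusive(self):
        res = within_set_dmps(self._col(), threshold=0.25)
        assert "p3" in res.per_set["set1"].index  # Δβ = −0.25 exactly

    def test_threshold_zero_returns_all(self):
        res = within_set_dmps(self._col(), threshold=0.0)
        assert len(res.per_set["set1"]) == 4

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(32)
        d = pd.DataFrame(rng.normal(0, 0.2, (50, 2)),
                         index=[f"p{i}" for i in range(50)], columns=["s1", "s2"])
        col = make_collapsed(d, base=0.5)
        counts = [sum(len(v) for v in within_set_dmps(col, threshold=t).per_set.values())
                  for t in (0.0, 0.1, 0.2, 0.3)]
        assert counts == sorted(counts, reverse=True)

    def test_pure_noise_yields_none(self):
        hits = 0
        for seed in range(20):
            cfg = sim.TwinSimConfig(n_twin_sets=4, n_probes=200,
                                    n_planted_dmps_shared=0,
                                    replicate_sd=0.02, biological_sd=0.02,
                                    seed=100 + seed)
            beta, _, sheet, _, _ = sim.simulate_twin_methylomes(cfg)
            col = collapse_per_individual(beta, sheet)
            res = within_set_dmps(col, threshold=0.25)
            if any(len(v) for v in res.per_set.values()):
                hits += 1
        assert hits <= 1  # >= 95% of runs clean


class TestAggregate:
    def _annot(self):
        return ProbeAnnotation(pd.DataFrame({
            "probe_id": ["p1", "p2", "p3", "p4"],
            "chromosome": "chr1", "position": [1, 2, 3, 4],
            "genes": ["geneA", "geneA", "geneB", "geneA;geneB"],
            "distance_to_tss": 0, "hil_category": "HC",
            "cross_hybridising": False, "sex_chromosome": False,
            "snp_overlap": False,
        }))

    def test_min_two_probes(self):
        out = aggregate_dmps_to_genes({"set1": ["p1", "p2", "p3"]}, self._annot())
        assert out["genes_per_set"]["set1"] == ["geneA"]

    def test_min_one_probe(self):
        out = aggregate_dmps_to_genes({"set1": ["p1", "p2", "p3"]}, self._annot(),
                                      min_probes_per_gene=1)
        assert out["genes_per_set"]["set1"] == ["geneA", "geneB"]

    def test_multi_gene_probe_counts_both(self):
        out = aggregate_dmps_to_genes({"set1": ["p3", "p4"]}, self._annot())
        assert out["genes_per_set"]["set1"] == ["geneB"]

    def test_three_set_overlap_tallies(self):
        dmps = {"set1": ["p1", "p2"], "set2": ["p1", "p3"], "set3": ["p3"]}
        out = aggregate_dmps_to_genes(dmps, self._annot(), min_probes_per_gene=1)
        po = out["probe_overlaps"]
        assert po["in_multiple_sets"] == {"p1": ["set1", "set2"],
                                          "p3": ["set2", "set3"]}
        assert po["pairwise_counts"] == {"set1&set2": 1, "set1&set3": 0,
                                         "set2&set3": 1}

    def test_controls_reported_separately(self):
        dmps = {"set1": ["p1"], "ctrlA": ["p1"], "ctrlB": ["p1"]}
        out = aggregate_dmps_to_genes(dmps, self._annot(),
                                      control_sets=("ctrlA", "ctrlB"))
        assert out["control_sets"] == ["ctrlA", "ctrlB"]
        assert out["control_probe_overlaps"]["pairwise_counts"] == {"ctrlA&ctrlB": 1}

    def test_missing_annotation_errors(self):
        with pytest.raises(ValidationError):
            aggregate_dmps_to_genes({"set1": ["zz"]}, self._annot())


def test_dmp_probe_sets_roundtrip():
    d = pd.DataFrame({"p1": [0.3], "p2": [0.1]}, index=["set1"]).T
    res = within_set_dmps(make_collapsed(d, base=0.4))
    assert dmp_probe_sets(res) == {"set1": ["p1"]}
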