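import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact, kstest

from immunodiffnet import (
    ClusterConfig,
    ImmuneProfileMatrix,
    PlantedOutliers,
    SyntheticCohortConfig,
    associate_clusters,
    bh_fdr,
    fisher_exact_rxc,
    generate_cohort,
    hierarchical_cluster,
    log_transform,
    moderated_ttest,
    remove_outliers,
)
from immunodiffnet.cohort_io import ClinicalTable
from immunodiffnet.errors import ConfigError, SizeError, ValidationError
from immunodiffnet.profile_clustering import estimate_prior_variance


def matrix_from_array(x, prefix="m"):
    """patients x markers array -> ImmuneProfileMatrix."""
    x = np.asarray(x, dtype=float)
    markers = [f"{prefix}{i}" for i in range(x.shape[1])]
    patients = [f"P{i:03d}" for i in range(x.shape[0])]
    return ImmuneProfileMatrix(
        values=pd.DataFrame(x.T, index=markers, columns=patients),
        marker_kinds={m: "cytokine" for m in markers})


class TestHierarchicalCluster:
    def test_two_separated_blobs_recovered(self):
        rng = np.random.default_rng(42)
        a = rng.standard_normal((10, 5))
        b = rng.standard_normal((10, 5)) + 10.0
        m = matrix_from_array(np.vstack([a, b]))
        res = hierarchical_cluster(m, ClusterConfig(n_clusters=2))
        labels = np.array([res.labels[p] for p in m.patient_ids])
        truth = np.array([0] * 10 + [1] * 10)
        agree = max((labels == truth + 1).mean(), (labels == 2 - truth).mean())
        assert agree == 1.0

    def test_identical_patients_merge_at_zero(self):
        m = matrix_from_array(np.ones((5, 3)))
        res = hierarchical_cluster(m, ClusterConfig(n_clusters=2))
        assert np.allclose(res.merge_tree[:, 2], 0.0)

    def test_three_collinear_points_first_merge(self):
        # Ward on points 0, 1, 10 along one axis: closest pair merges first
        m = matrix_from_array(np.array([[0.0], [1.0], [10.0]]))
        res = hierarchical_cluster(m, ClusterConfig(n_clusters=2))
        z = res.merge_tree
        assert {int(z[0, 0]), int(z[0, 1])} == {0, 1}
        assert z[0, 2] == pytest.approx(1.0)
        # exhaustive Ward height for the second merge:
        # d({0,1},{10}) = sqrt(2*3/3 * ||centroid diff||^2 ... Ward distance
        # = sqrt(2*2*1/(2+1)) * |9.5| on the distance scale
        assert z[1, 2] == pytest.approx(np.sqrt(4.0 / 3.0) * 9.5)

    def test_heights_monotone_nondecreasing(self, planted_cohort):
        prof, _, _ = planted_cohort
        res = hierarchical_cluster(log_transform(prof),
                                   ClusterConfig(n_clusters=3))
        heights = res.merge_tree[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    def test_labels_stable_under_patient_permutation(self, planted_cohort):
        prof, _, _ = planted_cohort
        logged = log_transform(prof)
        res1 = hierarchical_cluster(logged, ClusterConfig(n_clusters=3))
        rng = np.random.default_rng(3)
        perm = list(rng.permutation(logged.patient_ids))
        res2 = hierarchical_cluster(logged.subset_patients(perm),
                                    ClusterConfig(n_clusters=3))
        # same partition up to relabelling
        part1 = {}
        for p, c in res1.labels.items():
            part1.setdefault(c, set()).add(p)
        part2 = {}
        for p, c in res2.labels.items():
            part2.setdefault(c, set()).add(p)
        assert set(map(frozenset, part1.values())) == set(
            map(frozenset, part2.values()))

    def test_more_clusters_than_patients_rejected(self, tiny_matrix):
        with pytest.raises(ConfigError):
            hierarchical_cluster(tiny_matrix, ClusterConfig(n_clusters=5))

    def test_config_requires_exactly_one_cut(self):
        with pytest.raises(ConfigError):
            ClusterConfig(n_clusters=3, cut_height=2.0)
        with pytest.raises(ConfigError):
            ClusterConfig()


class TestRemoveOutliers:
    def test_planted_outliers_removed(self):
        cfg = SyntheticCohortConfig(
            planted_outliers=PlantedOutliers(count=2, shift_sd=8.0))
        prof, _, truth = generate_cohort(cfg, seed=11)
        logged = log_transform(prof)
        # cut at a height separating the two shifted patients
        retained, outliers = remove_outliers(logged, cut_height=25.0)
        assert sorted(outliers) == truth.outlier_patients
        assert retained.n_patients == 25

    def test_cut_above_root_removes_nobody(self, planted_cohort):
        prof, _, _ = planted_cohort
        logged = log_transform(prof)
        retained, outliers = remove_outliers(logged, cut_height=1e9)
        assert outliers == []
        assert retained.n_patients == prof.n_patients

    def test_refuses_to_remove_majority(self, planted_cohort):
        prof, _, _ = planted_cohort
        logged = log_transform(prof)
        with pytest.raises(ValidationError):
            remove_outliers(logged, cut_height=1e-6)


class TestFisherExactRxc:
    def test_two_by_two_hand_enumeration(self):
        # margins (2,2)/(2,2): three tables with probs 1/6, 2/3, 1/6
        assert fisher_exact_rxc([[2, 0], [0, 2]]) == pytest.approx(1 / 3)

    def test_zero_row_gives_p_one(self):
        assert fisher_exact_rxc([[0, 0], [3, 4]]) == pytest.approx(1.0)

    @pytest.mark.parametrize("table", [
        [[3, 1], [1, 3]], [[8, 2], [1, 5]], [[10, 0], [0, 10]],
        [[2, 3], [4, 2]], [[0, 5], [5, 0]],
    ])
    def test_matches_classical_2x2_fisher(self, table):
        ours = fisher_exact_rxc(table)
        ref = fisher_exact(table).pvalue
        assert ours == pytest.approx(ref, abs=1e-10)

    def test_matches_r_fisher_test_on_3x2(self):
        """Independent oracle: R's exact r x c fisher.test on the printed
        cluster-by-performance-status grid."""
        out = subprocess.run(
            ["Rscript", "-e", textwrap.dedent("""
                cat(sprintf('%.12f', fisher.test(
                  matrix(c(0,8,6,3,7,1), nrow=2, byrow=TRUE))$p.value))
            """)],
            capture_output=True, text=True, check=True)
        r_p = float(out.stdout.strip())
        assert fisher_exact_rxc([[0, 8, 6], [3, 7, 1]]) == pytest.approx(
            r_p, rel=1e-8)

    def test_probabilities_sum_to_one_over_margins(self):
        # run enumeration with an impossible observed prob threshold by
        # checking directly that total mass is 1: p of the least probable
        # table equals its own contribution, and p of the most probable
        # table is 1.
        table = [[4, 1, 2], [2, 3, 1], [0, 2, 3]]
        assert fisher_exact_rxc(table) <= 1.0
        # the all-inclusive tail (observed = most probable table) is 1
        flat = [[3, 2, 2], [2, 2, 2], [2, 2, 1]]
        assert fisher_exact_rxc(flat) == pytest.approx(1.0, abs=1e-9)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact_rxc([[-1, 2], [3, 4]])

    def test_enumeration_budget_enforced(self):
        with pytest.raises(SizeError):
            fisher_exact_rxc([[40, 40], [40, 40]])


class TestAssociateClusters:
    def test_perfect_separation_is_extreme(self):
        table = pd.DataFrame(
            {"response": ["R"] * 10 + ["NR"] * 10,
             "performance_status": ["PS0"] * 20},
            index=pd.Index([f"P{i}" for i in range(20)], name="patient_id"))
        clin = ClinicalTable(table=table)
        labels = {f"P{i}": (1 if i < 10 else 2) for i in range(20)}
        grid, p = associate_clusters(labels, clin, "response")
        assert grid.to_numpy().tolist() in ([[0, 10], [10, 0]],
                                            [[10, 0], [0, 10]])
        assert p < 0.001

    def test_independent_labels_give_uniform_p(self):
        """Type-I simulation: p under label independence is ~uniform."""
        rng = np.random.default_rng(5)
        pvals = []
        patients = [f"P{i}" for i in range(20)]
        for _ in range(400):
            resp = np.array(["R"] * 10 + ["NR"] * 10)
            rng.shuffle(resp)
            table = pd.DataFrame(
                {"response": resp, "performance_status": ["PS0"] * 20},
                index=pd.Index(patients, name="patient_id"))
            labels = {p: (1 if i < 10 else 2)
                      for i, p in enumerate(patients)}
            _, p = associate_clusters(labels, ClinicalTable(table=table),
                                      "response")
            pvals.append(p)
        rate = np.mean(np.array(pvals) < 0.05)
        assert 0.02 <= rate <= 0.08 or rate < 0.02  # exact test is conservative
        assert rate <= 0.08

    def test_patient_mismatch_rejected(self, tiny_clinical):
        with pytest.raises(ValidationError):
            associate_clusters({"P99": 1, "P01": 2}, tiny_clinical, "response")


class TestModeratedTTest:
    @pytest.fixture()
    def two_groups(self):
        rng = np.random.default_rng(8)
        markers = [f"m{i}" for i in range(50)]
        a = pd.DataFrame(rng.standard_normal((50, 6)), index=markers)
        b = pd.DataFrame(rng.standard_normal((50, 7)), index=markers)
        return a, b

    def test_d0_zero_equals_ordinary_t(self, two_groups):
        from scipy.stats import ttest_ind
        a, b = two_groups
        res = moderated_ttest(a, b, d0=0.0)
        ref = ttest_ind(a.to_numpy(), b.to_numpy(), axis=1, equal_var=True)
        assert np.allclose(res.table["moderated_t"], ref.statistic, atol=1e-10)
        assert np.allclose(res.table["raw_p"], ref.pvalue, atol=1e-10)

    def test_d0_infinite_pools_variance(self, two_groups):
        a, b = two_groups
        res = moderated_ttest(a, b, d0=np.inf, s0_sq=2.5)
        delta = a.mean(axis=1) - b.mean(axis=1)
        expected = delta / np.sqrt(2.5 * (1 / 6 + 1 / 7))
        assert np.allclose(res.table["moderated_t"], expected, atol=1e-12)

    def test_log2_fold_change_is_mean_difference(self, two_groups):
        a, b = two_groups
        res = moderated_ttest(a, b)
        assert np.allclose(res.table["log2_fold_change"],
                           a.mean(axis=1) - b.mean(axis=1))

    def test_null_pvalues_uniform(self):
        """Moderated p-values under a global null are uniform (KS)."""
        rng = np.random.default_rng(123)
        pvals = []
        for _ in range(25):
            a = pd.DataFrame(rng.standard_normal((200, 13)))
            b = pd.DataFrame(rng.standard_normal((200, 12)))
            pvals.append(moderated_ttest(a, b).table["raw_p"].to_numpy())
        pvals = np.concatenate(pvals)
        assert pvals.size == 5000
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_fdr_control_under_null(self):
        """Average fraction of q<0.05 calls under the null stays below 5%."""
        rng = np.random.default_rng(321)
        frac = []
        for _ in range(120):
            a = pd.DataFrame(rng.standard_normal((200, 13)))
            b = pd.DataFrame(rng.standard_normal((200, 12)))
            q = moderated_ttest(a, b).table["fdr_q"].to_numpy()
            frac.append((q < 0.05).mean())
        assert np.mean(frac) <= 0.05

    def test_shrinkage_recovers_prior_on_simulated_variances(self):
        """Moment-matching estimates (d0, s0^2) near truth when variances
        are drawn from the scaled inverse-chi-square model."""
        rng = np.random.default_rng(99)
        d0_true, s0_true, dg = 8.0, 1.7, 23
        # s^2 ~ s0^2 * (chi2_dg/dg) / (chi2_d0/d0)  (scaled F)
        s2 = (s0_true * (rng.chisquare(dg, 20000) / dg)
              / (rng.chisquare(d0_true, 20000) / d0_true))
        d0_est, s0_est = estimate_prior_variance(s2, dg)
        assert d0_est == pytest.approx(d0_true, rel=0.15)
        assert s0_est == pytest.approx(s0_true, rel=0.05)

    def test_matches_r_limma_on_fixture(self, tmp_path):
        """Independent oracle: Bioconductor limma's eBayes on a small
        two-group fixture must agree with the moderated t and p."""
        rng = np.random.default_rng(2024)
        markers = [f"m{i}" for i in range(40)]
        a = pd.DataFrame(rng.standard_normal((40, 6)) * rng.uniform(
            0.5, 2.0, size=(40, 1)), index=markers)
        b = pd.DataFrame(rng.standard_normal((40, 7)) * 1.0, index=markers)
        mat = pd.concat([a, b], axis=1)
        mat.columns = [f"s{i}" for i in range(13)]
        csv = tmp_path / "expr.csv"
        mat.to_csv(csv)
        script = tmp_path / "limma.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(limma))
            x <- as.matrix(read.csv('{csv}', row.names=1))
            design <- cbind(Intercept=1, A=c(rep(1,6), rep(0,7)))
            fit <- eBayes(lmFit(x, design))
            out <- data.frame(t=fit$t[,'A'], p=fit$p.value[,'A'])
            write.csv(out, '{tmp_path / 'limma_out.csv'}')
            cat(fit$df.prior, fit$s2.prior)
        """))
        proc = subprocess.run(["Rscript", str(script)], capture_output=True,
                              text=True, check=True)
        d0_r, s0_r = map(float, proc.stdout.split())
        ref = pd.read_csv(tmp_path / "limma_out.csv", index_col=0)
        res = moderated_ttest(a, b)
        assert res.d0 == pytest.approx(d0_r, rel=1e-4)
        assert res.s0_sq == pytest.approx(s0_r, rel=1e-4)
        # limma's A coefficient is mean(A) - mean(B): same sign convention
        assert np.allclose(res.table["moderated_t"], ref["t"], atol=1e-6)
        assert np.allclose(res.table["raw_p"], ref["p"], atol=1e-8)


class TestBHFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_hand_step_up(self):
        assert np.allclose(bh_fdr([0.01, 0.04]), [0.02, 0.04])

    def test_all_ones(self):
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.5])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(17)
        p = rng.uniform(size=200)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(bh_fdr(p), ref, atol=1e-12)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_monotone_and_permutation_invariant(self, p):
        p = np.asarray(p)
        q = bh_fdr(p)
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-12).all()
        rng = np.random.default_rng(0)
        perm = rng.permutation(p.size)
        assert np.allclose(bh_fdr(p[perm]), q[perm], atol=1e-12)
        assert ((q >= p - 1e-12) & (q <= 1 + 1e-12)).all()
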