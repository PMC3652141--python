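import itertools

import numpy as np
import pytest

from nitroscreen import (
    anosim,
    bbb_table,
    cluster,
    grubbs_test,
    ols_fit,
    path_coefficients,
    pearson_matrix,
    summarize,
)
from nitroscreen.chem_io import DescriptorRecord, DescriptorTable
from nitroscreen.errors import InputError
from nitroscreen.multivariate import grubbs_critical

from conftest import make_random_table


class TestSummarize:
    def test_reference_log_p_row(self, table1):
        row = {r.property: r for r in summarize(table1)}["log_p"]
        assert round(row.mean, 3) == 2.524
        assert round(row.sd, 4) == 0.5337
        assert (row.minimum, row.maximum, row.median) == (1.537, 3.924, 2.458)

    def test_reference_fw_and_psa_rows(self, table1):
        rows = {r.property: r for r in summarize(table1)}
        assert round(rows["fw"].mean, 1) == 232.8
        assert round(rows["fw"].sd, 2) == 30.76
        assert rows["fw"].median == 225.7
        assert round(rows["psa"].mean, 2) == 62.89
        assert round(rows["volume"].sd, 2) == 23.03

    def test_constant_column_degenerates(self, table1):
        row = {r.property: r for r in summarize(table1)}["n_ro5_violations"]
        assert row.sd == 0 and row.minimum == row.maximum == row.median == row.mean

    def test_too_few_records(self, table1):
        with pytest.raises(InputError):
            summarize(DescriptorTable(table1.records[:1], "fixture"))

    def test_first_principles_re_derivation(self):
        rng = np.random.default_rng(5)
        t = make_random_table(rng, 25)
        df = t.to_frame()
        for row in summarize(t):
            x = np.sort(df[row.property].to_numpy(dtype=float))
            n = len(x)
            assert row.mean == pytest.approx(x.sum() / n, abs=1e-10)
            assert row.sd == pytest.approx(
                np.sqrt(((x - x.sum() / n) ** 2).sum() / (n - 1)), abs=1e-10
            )
            med = (x[n // 2 - 1] + x[n // 2]) / 2 if n % 2 == 0 else x[n // 2]
            assert row.median == pytest.approx(med, abs=1e-10)


class TestPearson:
    def test_reference_correlation_claims(self, table1):
        m = pearson_matrix(table1)
        assert m.loc["fw", "n_atoms"] > 0.8700
        assert m.loc["volume", "n_atoms"] > 0.8700
        assert m.loc["volume", "fw"] > 0.8700
        assert m.loc["log_p", "fw"] > 0.5000

    def test_diagonal_and_symmetry(self, table1):
        m = pearson_matrix(table1)
        assert np.allclose(np.diag(m.values), 1.0)
        assert np.allclose(m.values, m.values.T)

    def test_zero_variance_column_dropped(self, table1):
        m = pearson_matrix(table1)
        assert "n_ro5_violations" not in m.columns

    def test_all_constant_fields_error(self, table1):
        with pytest.raises(InputError):
            pearson_matrix(table1, fields=["n_ro5_violations"])

    def test_first_principles_formula(self):
        rng = np.random.default_rng(9)
        t = make_random_table(rng, 20)
        m = pearson_matrix(t, fields=["log_p", "fw", "psa"])
        df = t.to_frame()
        for a, b in itertools.combinations(["log_p", "fw", "psa"], 2):
            x, y = df[a].to_numpy(float), df[b].to_numpy(float)
            xc, yc = x - x.mean(), y - y.mean()
            r = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
            assert m.loc[a, b] == pytest.approx(r, abs=1e-10)


class TestGrubbs:
    def test_no_outliers_in_reference_properties(self, table1):
        df = table1.to_frame()
        for field in ("log_p", "fw", "volume"):
            res = grubbs_test(df[field].astype(float).tolist(), alpha=0.05)
            assert not res.outlier_flag and res.outlier_index is None

    def test_no_outlier_in_bb(self, table1):
        bbs = [p.bb for p in bbb_table(table1)]
        assert not grubbs_test(bbs, alpha=0.05).outlier_flag

    def test_gross_outlier_flagged(self):
        # n=4, mean 25, sd 50: G = 75/50 = 1.5 > G_crit(4, .05) = 1.481
        res = grubbs_test([0, 0, 0, 100], alpha=0.05)
        assert res.outlier_flag and res.outlier_index == 3
        assert res.g_statistic == pytest.approx(1.5)

    @pytest.mark.parametrize(
        "n, published", [(10, 2.290), (18, 2.651), (30, 2.908)]
    )
    def test_critical_values_match_published_tables(self, n, published):
        assert grubbs_critical(n, alpha=0.05) == pytest.approx(published, abs=0.01)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(InputError):
            grubbs_test([1.0, 2.0], alpha=0.05)
        with pytest.raises(InputError):
            grubbs_test([3.0, 3.0, 3.0], alpha=0.05)


FW_PREDICTORS = ["log_p", "psa", "n_atoms", "n_rot"]


class TestOls:
    def test_reference_fw_regression(self, table1):
        fit = ols_fit(table1, "fw", FW_PREDICTORS)
        assert round(fit.r_squared, 4) == 0.7934
        expected = {
            "log_p": 0.9578, "psa": -0.04598, "n_atoms": 19.236, "n_rot": -3.947,
        }
        assert fit.intercept == pytest.approx(-24.859, rel=0.005)
        for k, v in expected.items():
            assert fit.coefficients[k] == pytest.approx(v, rel=0.005)

    def test_fitted_plus_residual_is_observed(self, table1):
        fit = ols_fit(table1, "fw", FW_PREDICTORS)
        observed = table1.to_frame()["fw"].to_numpy(float)
        assert np.allclose(fit.fitted + fit.residuals, observed)

    def test_exact_linear_data(self):
        recs = [
            DescriptorRecord(
                agent_id=f"e{i}", log_p=float(i), psa=50.0, n_atoms=10,
                fw=2.0 * i + 1e-9, n_on=5, n_ohnh=1, n_ro5_violations=0, n_rot=3,
            )
            for i in range(1, 7)
        ]
        fit = ols_fit(DescriptorTable(recs, "synthetic"), "fw", ["log_p"])
        assert fit.intercept == pytest.approx(0.0, abs=1e-6)
        assert fit.coefficients["log_p"] == pytest.approx(2.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_normal_equations_re_derivation(self):
        rng = np.random.default_rng(3)
        t = make_random_table(rng, 30)
        fit = ols_fit(t, "fw", ["log_p", "psa", "n_rot"])
        df = t.to_frame()
        X = np.column_stack(
            [np.ones(30)] + [df[c].to_numpy(float) for c in ("log_p", "psa", "n_rot")]
        )
        beta = np.linalg.solve(X.T @ X, X.T @ df["fw"].to_numpy(float))
        assert fit.intercept == pytest.approx(beta[0], abs=1e-10)
        for b, name in zip(beta[1:], ("log_p", "psa", "n_rot")):
            assert fit.coefficients[name] == pytest.approx(b, abs=1e-10)

    def test_collinear_predictors_named(self):
        rng = np.random.default_rng(1)
        recs = []
        for i in range(10):
            fw = float(rng.uniform(150, 400))
            recs.append(
                DescriptorRecord(
                    agent_id=f"c{i}", log_p=1.0, psa=60.0, n_atoms=12, fw=fw,
                    n_on=5, n_ohnh=1, n_ro5_violations=0, n_rot=4, volume=2 * fw,
                )
            )
        t = DescriptorTable(recs, "synthetic")
        with pytest.raises(InputError, match="volume"):
            ols_fit(t, "log_p", ["fw", "volume"])

    def test_too_few_records(self, table1):
        small = DescriptorTable(table1.records[:4], "fixture")
        with pytest.raises(InputError):
            ols_fit(small, "fw", FW_PREDICTORS)


class TestPathCoefficients:
    def test_equals_ols_on_z_scored_columns(self):
        rng = np.random.default_rng(8)
        t = make_random_table(rng, 24)
        res = path_coefficients(t, "fw", ["log_p", "psa", "n_rot"])
        df = t.to_frame()[["fw", "log_p", "psa", "n_rot"]].astype(float)
        z = (df - df.mean()) / df.std(ddof=1)
        X = np.column_stack([np.ones(24)] + [z[c] for c in ("log_p", "psa", "n_rot")])
        beta = np.linalg.lstsq(X, z["fw"].to_numpy(), rcond=None)[0]
        for b, name in zip(beta[1:], ("log_p", "psa", "n_rot")):
            assert res.coefficients[name] == pytest.approx(b, abs=1e-10)

    def test_single_predictor_equals_pearson_r(self, table1):
        res = path_coefficients(table1, "fw", ["n_atoms"])
        r = pearson_matrix(table1).loc["fw", "n_atoms"]
        assert res.coefficients["n_atoms"] == pytest.approx(r, abs=1e-10)

    def test_zero_variance_predictor_rejected(self, table1):
        with pytest.raises(InputError):
            path_coefficients(table1, "fw", ["n_ro5_violations"])


def two_cluster_table(rng, n_a=5, n_b=5, gap=500.0):
    recs = []
    for i in range(n_a + n_b):
        offset = 0.0 if i < n_a else gap
        recs.append(
            DescriptorRecord(
                agent_id=f"g{i}",
                log_p=float(rng.normal(2, 0.1)) + offset / 100,
                psa=60.0 + float(rng.normal(0, 0.5)) + offset,
                n_atoms=14, fw=230.0 + offset, n_on=5, n_ohnh=1,
                n_ro5_violations=0, n_rot=5,
            )
        )
    return DescriptorTable(recs, "synthetic"), ["A"] * n_a + ["B"] * n_b


class TestAnosim:
    def test_complete_separation_gives_r_one(self):
        t, groups = two_cluster_table(np.random.default_rng(2))
        res = anosim(t, groups, n_permutations=99, seed=0)
        assert res.r_statistic == pytest.approx(1.0)
        assert res.p_value <= 0.05

    def test_single_group_rejected(self, table1):
        with pytest.raises(InputError):
            anosim(table1, ["g"] * 18, n_permutations=9, seed=0)

    def test_r_matches_scikit_bio(self):
        from scipy.spatial.distance import pdist, squareform
        from skbio import DistanceMatrix
        from skbio.stats.distance import anosim as skbio_anosim

        rng = np.random.default_rng(21)
        t = make_random_table(rng, 14)
        groups = ["A"] * 7 + ["B"] * 7
        mine = anosim(t, groups, n_permutations=99, seed=3)
        dm = DistanceMatrix(
            squareform(pdist(t.to_frame().to_numpy(float))),
            ids=[r.agent_id for r in t],
        )
        ref = skbio_anosim(dm, grouping=list(groups), permutations=0)
        assert mine.r_statistic == pytest.approx(ref["test statistic"], abs=1e-10)

    def test_null_calibration_on_exchangeable_data(self):
        """Type-I error rate at alpha=0.05 stays within binomial MC error.

        For an exactly calibrated observed-inclusive permutation test
        P(p <= 0.05) = 0.05, so over 200 repeats the rejection count is
        Binomial(200, 0.05); the 3-sigma upper bound is 10 + 3*3.08 < 20.
        """
        n_reps = 200
        rejections = 0
        for rep in range(n_reps):
            rng = np.random.default_rng(1000 + rep)
            t = make_random_table(rng, 12, with_volume=False)
            labels = rng.permutation(["A"] * 6 + ["B"] * 6)
            res = anosim(t, labels, n_permutations=199, seed=rep)
            rejections += res.p_value <= 0.05
        bound = 0.05 * n_reps + 3 * np.sqrt(n_reps * 0.05 * 0.95)
        assert rejections <= bound

    def test_seed_agreement_within_monte_carlo_error(self):
        rng = np.random.default_rng(13)
        t = make_random_table(rng, 12)
        labels = ["A"] * 6 + ["B"] * 6
        p1 = anosim(t, labels, n_permutations=1999, seed=1).p_value
        p2 = anosim(t, labels, n_permutations=1999, seed=2).p_value
        # binomial MC error on p is ~sqrt(p(1-p)/2000) <= 0.012
        assert abs(p1 - p2) < 4 * 0.012
        r1 = anosim(t, labels, n_permutations=9, seed=1).r_statistic
        r2 = anosim(t, labels, n_permutations=9, seed=2).r_statistic
        assert r1 == r2  # the statistic itself is seed-free


def brute_force_single_linkage(X, labels):
    """Exhaustive single-linkage: scan all inter-cluster pairs each step."""
    clusters = [frozenset([lab]) for lab in labels]
    pos = {lab: i for i, lab in enumerate(labels)}
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = min(
                    np.linalg.norm(X[pos[a]] - X[pos[b]])
                    for a in clusters[i]
                    for b in clusters[j]
                )
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        merges.append((clusters[i], clusters[j], d))
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return merges


class TestCluster:
    def test_reference_isolates_agent_12(self, table1):
        tree = cluster(table1, standardize=True)
        assert tree.last_merging_singleton() == "12"
        assert tree.dropped_fields == ("n_ro5_violations",)

    def test_merge_count_and_monotone_heights(self, table1):
        tree = cluster(table1, standardize=True)
        merges = tree.merges
        assert len(merges) == len(table1) - 1
        heights = [h for _, _, h in merges]
        assert heights == sorted(heights)

    def test_identical_records_merge_at_zero(self):
        recs = [
            DescriptorRecord(
                agent_id=f"t{i}", log_p=2.0, psa=60.0, n_atoms=14, fw=230.0,
                n_on=5, n_ohnh=1, n_ro5_violations=0, n_rot=5,
            )
            for i in range(2)
        ]
        tree = cluster(DescriptorTable(recs, "synthetic"), standardize=False)
        assert tree.merges[0][2] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_agrees_with_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        t = make_random_table(rng, n)
        tree = cluster(t, standardize=False)
        X = t.to_frame().to_numpy(float)
        labels = [r.agent_id for r in t]
        expected = brute_force_single_linkage(X, labels)
        got = tree.merges
        for (ea, eb, eh), (ga, gb, gh) in zip(expected, got):
            assert {ea, eb} == {ga, gb}
            assert gh == pytest.approx(eh, abs=1e-10)

    def test_newick_export_is_a_valid_tree(self, table1):
        import dendropy

        nwk = cluster(table1, standardize=True).to_newick()
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert len(tree.leaf_nodes()) == 18
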