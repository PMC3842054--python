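import numpy as np
import pytest
import scipy.stats
from scipy.optimize import minimize

from sigrank import (
    ExpressionDataset,
    RankedList,
    SyntheticSpec,
    cut_ranking,
    generate_dataset,
    rank_features,
    rank_svm_one,
    rank_svm_rfe,
    score_oner,
    score_relieff,
)
from sigrank.rankers import (
    chi2_statistic,
    gain_ratio,
    info_gain,
    oner_accuracy,
    symmetrical_uncertainty,
)


def _dataset(values, labels, gene_ids=None):
    values = np.asarray(values, float)
    return ExpressionDataset(
        sample_ids=[f"s{i}" for i in range(values.shape[0])],
        gene_ids=gene_ids or [f"g{j}" for j in range(values.shape[1])],
        values=values,
        labels=np.asarray(labels),
    )


# ---------------------------------------------------------------------------
# univariate scorers against their defining formulas

def brute_ig(table):
    table = np.asarray(table, float)
    n = table.sum()
    pc = table.sum(axis=0) / n
    hc = -sum(p * np.log2(p) for p in pc if p > 0)
    hcx = 0.0
    for row in table:
        if row.sum() == 0:
            continue
        pr = row / row.sum()
        hcx += row.sum() / n * -sum(p * np.log2(p) for p in pr if p > 0)
    return hc - hcx


def brute_hx(table):
    px = np.asarray(table, float).sum(axis=1)
    px = px[px > 0] / px.sum()
    return -sum(p * np.log2(p) for p in px)


def brute_hc(table):
    pc = np.asarray(table, float).sum(axis=0)
    pc = pc[pc > 0] / pc.sum()
    return -sum(p * np.log2(p) for p in pc)


class TestScorerFormulas:
    def test_chi2_hand_case(self):
        # 2x2 shortcut: n(ad-bc)^2 / (r1 r2 c1 c2) = 8*64/256 = 2
        assert chi2_statistic([[3, 1], [1, 3]]) == pytest.approx(2.0)

    def test_chi2_perfect_association_equals_n(self):
        assert chi2_statistic([[4, 0], [0, 4]]) == pytest.approx(8.0)

    def test_entropic_hand_case(self):
        t = [[3, 1], [1, 3]]
        assert info_gain(t) == pytest.approx(0.18872187554086717, abs=1e-12)
        # H(X) = H(C) = 1 here, so SU and GR coincide with IG
        assert symmetrical_uncertainty(t) == pytest.approx(info_gain(t))
        assert gain_ratio(t) == pytest.approx(info_gain(t))

    def test_perfect_association_maximal(self):
        t = [[4, 0], [0, 4]]
        assert info_gain(t) == pytest.approx(1.0)
        assert symmetrical_uncertainty(t) == pytest.approx(1.0)
        assert gain_ratio(t) == pytest.approx(1.0)

    def test_constant_gene_scores_zero(self):
        t = [[4, 4]]  # single bin
        assert chi2_statistic(t) == 0.0
        assert info_gain(t) == pytest.approx(0.0)
        assert symmetrical_uncertainty(t) == 0.0
        assert gain_ratio(t) == 0.0

    def test_random_tables_match_brute_force(self):
        """1000 random contingency tables: all four scorers vs. their formulas."""
        rng = np.random.default_rng(123)
        for _ in range(1000):
            rows = int(rng.integers(1, 5))
            table = rng.integers(0, 8, size=(rows, 2)).astype(float)
            if table.sum() == 0:
                table[0, 0] = 1
            ig = brute_ig(table)
            hx, hc = brute_hx(table), brute_hc(table)
            assert abs(info_gain(table) - ig) <= 1e-10
            su = 0.0 if hx + hc == 0 else 2 * ig / (hx + hc)
            assert abs(symmetrical_uncertainty(table) - su) <= 1e-10
            gr = 0.0 if hx == 0 else ig / hx
            assert abs(gain_ratio(table) - gr) <= 1e-10
            if (table.sum(axis=1) > 0).sum() >= 2 and (table.sum(axis=0) > 0).sum() >= 2:
                expected = scipy.stats.chi2_contingency(
                    table[table.sum(axis=1) > 0], correction=False
                )[0]
                assert abs(chi2_statistic(table) - expected) <= 1e-10

    def test_bounds_invariants(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            table = rng.integers(0, 6, size=(int(rng.integers(1, 4)), 2)).astype(float)
            if table.sum() == 0:
                table[0, 0] = 1
            assert chi2_statistic(table) >= 0
            assert info_gain(table) <= min(brute_hc(table), brute_hx(table)) + 1e-12
            assert 0 <= symmetrical_uncertainty(table) <= 1 + 1e-12
            assert 0 <= gain_ratio(table) <= 1 + 1e-12


# ---------------------------------------------------------------------------
# OneR

class TestOneR:
    def test_perfect_split_scores_100(self):
        v = np.concatenate([np.arange(10), np.arange(10) + 100.0])
        y = np.array([0] * 10 + [1] * 10)
        assert oner_accuracy(v, y) == pytest.approx(100.0)

    def test_constant_gene_majority_rate(self):
        v = np.zeros(10)
        y = np.array([0] * 7 + [1] * 3)
        assert oner_accuracy(v, y) == pytest.approx(70.0)

    def test_independent_gene_near_chance(self):
        # deterministic toy vector: values interleave the classes
        v = np.arange(20.0)
        y = np.tile([0, 1], 10)
        acc = oner_accuracy(v, y)
        assert 50.0 <= acc <= 65.0

    def test_score_oner_dispatch(self, toy_dataset):
        # 4+4 samples: min_bucket must be reachable for a split to form
        scores = score_oner(toy_dataset, min_bucket=2)
        assert scores[0] == pytest.approx(100.0)  # g1 separates perfectly
        assert scores.shape == (3,)

    def test_small_sample_below_bucket_size_single_bucket(self, toy_dataset):
        # 4+4 samples cannot fill a 6-member majority bucket: one bucket,
        # majority-class accuracy
        scores = score_oner(toy_dataset, min_bucket=6)
        assert scores[0] == pytest.approx(50.0)


# ---------------------------------------------------------------------------
# ReliefF

class TestReliefF:
    def test_informative_gene_outweighs_noise(self):
        # two well-separated clusters of 4+4 on gene 0; gene 1 is noise
        g0 = np.array([0.0, 0.05, 0.1, 0.15, 1.0, 1.05, 1.1, 1.15])
        g1 = np.array([0.3, 0.9, 0.1, 0.7, 0.5, 0.2, 0.8, 0.4])
        ds = _dataset(np.column_stack([g0, g1]), ["a"] * 4 + ["b"] * 4)
        w = score_relieff(ds, k_neighbors=3)
        assert w[0] > w[1]
        assert w[0] > 0

    def test_identical_instances_zero_hit_contribution(self):
        # all values equal across classes -> every diff is 0 -> weight 0
        ds = _dataset(np.ones((6, 1)), ["a", "a", "a", "b", "b", "b"])
        w = score_relieff(ds)
        assert w[0] == pytest.approx(0.0)

    def test_needs_two_per_class(self):
        ds = _dataset(np.arange(6).reshape(3, 2), ["a", "a", "b"])
        with pytest.raises(ValueError, match="2 instances"):
            score_relieff(ds)


# ---------------------------------------------------------------------------
# SVM rankers, with a quadratic-programming dual oracle

def svm_dual_weights(x, y_pm, c=1.0):
    """Solve the soft-margin linear SVM dual with SLSQP and return w."""
    n = len(y_pm)
    gram = (x @ x.T) * np.outer(y_pm, y_pm)

    def neg_obj(a):
        return 0.5 * a @ gram @ a - a.sum()

    res = minimize(
        neg_obj,
        x0=np.full(n, 0.5),
        jac=lambda a: gram @ a - 1,
        bounds=[(0, c)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a @ y_pm}],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-12},
    )
    assert res.success
    return (res.x * y_pm) @ x


class TestSvmOne:
    def test_informative_gene_ranked_first(self):
        rng = np.random.default_rng(2)
        g0 = np.array([0.0, 0.1, 0.2, 1.0, 1.1, 1.2])
        g1 = rng.normal(size=6)
        ds = _dataset(np.column_stack([g0, g1]), ["a"] * 3 + ["b"] * 3)
        assert rank_svm_one(ds).ordered_genes[0] == "g0"

    def test_duplicated_columns_tie_broken_by_index(self):
        g = np.array([0.0, 0.1, 0.2, 1.0, 1.1, 1.2])
        ds = _dataset(np.column_stack([g, g]), ["a"] * 3 + ["b"] * 3)
        ranking = rank_svm_one(ds)
        assert ranking.ordered_genes == ["g0", "g1"]
        assert ranking.scores[0] == pytest.approx(ranking.scores[1])

    def test_matches_qp_dual_solution(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(size=(6, 2))
        x[3:, 0] += 2.0
        x = (x - x.min(axis=0)) / (x.max(axis=0) - x.min(axis=0))
        y = np.array(["a"] * 3 + ["b"] * 3)
        ds = _dataset(x, y)
        w_oracle = svm_dual_weights(x, np.array([-1, -1, -1, 1, 1, 1]), c=1.0)
        oracle_order = [f"g{j}" for j in np.argsort(-(w_oracle**2), kind="stable")]
        assert rank_svm_one(ds).ordered_genes == oracle_order


class TestSvmRfe:
    def test_removal_arithmetic_one_per_round(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(12, 10))
        x[:6, 0] += 3
        ds = _dataset(x, ["a"] * 6 + ["b"] * 6)
        ranking = rank_svm_rfe(ds, removal_fraction=0.10)
        # ceil(0.1 * n) = 1 per round for n <= 10: full permutation returned
        assert len(ranking.ordered_genes) == 10
        assert set(ranking.ordered_genes) == set(ds.gene_ids)

    def test_noise_gene_eliminated_first(self):
        g0 = np.array([0.0, 0.1, 0.2, 1.0, 1.1, 1.2])
        g1 = np.array([0.5, 0.5, 0.5, 0.5, 0.5, 0.50001])
        ds = _dataset(np.column_stack([g0, g1]), ["a"] * 3 + ["b"] * 3)
        assert rank_svm_rfe(ds).ordered_genes == ["g0", "g1"]

    def test_agrees_with_svm_one_on_bottom_gene(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(16, 8))
        x[8:, :2] += 1.5
        ds = _dataset(x, ["a"] * 8 + ["b"] * 8)
        bottom_one = rank_svm_one(ds).ordered_genes[-1]
        # with 8 genes, ceil(0.1*8)=1 dropped in round 1
        bottom_rfe = rank_svm_rfe(ds).ordered_genes[-1]
        assert bottom_one == bottom_rfe

    def test_recovers_most_planted_markers_on_average(self):
        # proportional elimination trims some redundantly informative
        # markers once the noise genes are gone; the bulk still lands on top
        counts = []
        for seed in range(5):
            ds, markers = generate_dataset(SyntheticSpec(seed=seed))
            top10 = set(rank_svm_rfe(ds).ordered_genes[:10])
            counts.append(len(top10 & set(markers)))
        assert np.mean(counts) >= 7.0

    def test_planted_markers_survive_elimination(self):
        spec = SyntheticSpec(z_samples=40, n_genes=20, n_informative=3,
                             effect_size=2.5, seed=5)
        ds, markers = generate_dataset(spec)
        ranking = rank_svm_rfe(ds)
        assert set(markers) <= set(ranking.ordered_genes[:8])


# ---------------------------------------------------------------------------
# dispatch, tie rule, cutting

class TestRankFeatures:
    def test_tie_breaking_by_original_index(self):
        # craft a dataset where two genes get identical scores
        g = np.array([0.0, 0.0, 1.0, 1.0])
        ds = _dataset(np.column_stack([g * 0, g, g * 0]), ["a", "a", "b", "b"],
                      gene_ids=["a_const", "b_info", "c_const"])
        ranking = rank_features(ds, "IG")
        assert ranking.ordered_genes == ["b_info", "a_const", "c_const"]

    def test_unknown_ranker_lists_valid_names(self, toy_dataset):
        with pytest.raises(ValueError, match="CHI2.*SVM_RFE"):
            rank_features(toy_dataset, "BOGUS")

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(21)
        x = rng.normal(size=(20, 6))
        x[:10, 0] += 2
        labels = np.array(["a"] * 10 + ["b"] * 10)
        ds = _dataset(x, labels)
        perm = rng.permutation(20)
        ds_perm = ExpressionDataset(
            sample_ids=[ds.sample_ids[i] for i in perm],
            gene_ids=ds.gene_ids,
            values=x[perm],
            labels=labels[perm],
        )
        for name in ["CHI2", "IG", "SU", "GR", "ONER", "RELIEFF", "SVM_ONE"]:
            assert rank_features(ds, name).ordered_genes == \
                rank_features(ds_perm, name).ordered_genes, name

    def test_gene_permutation_invariance(self):
        """Permuting columns must permute the ranking identically (unique scores)."""
        rng = np.random.default_rng(31)
        x = rng.normal(size=(24, 8))
        x[:12] += rng.uniform(0.5, 2.5, size=8)  # distinct effect per gene
        labels = np.array(["a"] * 12 + ["b"] * 12)
        ds = _dataset(x, labels)
        perm = rng.permutation(8)
        ds_perm = _dataset(x[:, perm], labels,
                           gene_ids=[ds.gene_ids[j] for j in perm])
        for name in ["RELIEFF", "SVM_ONE"]:
            r1 = rank_features(ds, name)
            assert len(set(np.round(r1.scores, 12))) == len(r1.scores), "scores tied"
            r2 = rank_features(ds_perm, name)
            assert r1.ordered_genes == r2.ordered_genes, name

    def test_univariate_score_unaffected_by_other_genes(self, toy_dataset):
        full = rank_features(toy_dataset, "IG")
        alone = rank_features(toy_dataset.subset_genes(["g1"]), "IG")
        s_full = dict(zip(full.ordered_genes, full.scores))
        assert alone.scores[0] == pytest.approx(s_full["g1"])


class TestPlantedMarkerRecovery:
    """Each ranker should put the planted class-shifted genes on top."""

    @pytest.mark.parametrize(
        "name", ["CHI2", "IG", "SU", "GR", "ONER", "RELIEFF", "SVM_ONE"]
    )
    def test_top10_contains_planted_genes(self, name):
        hits = 0
        for seed in range(10):
            ds, markers = generate_dataset(SyntheticSpec(seed=seed))
            top10 = set(rank_features(ds, name).ordered_genes[:10])
            hits += len(top10 & set(markers)) >= 8
        assert hits >= 9


class TestCutRanking:
    def test_cut_sizes(self):
        ranking = RankedList("IG", [f"g{i}" for i in range(5)], np.arange(5)[::-1])
        assert len(cut_ranking(ranking, 1)) == 1
        assert cut_ranking(ranking, 1).genes == {"g0"}
        assert cut_ranking(ranking, 5).genes == {f"g{i}" for i in range(5)}
        with pytest.raises(ValueError):
            cut_ranking(ranking, 6)
        with pytest.raises(ValueError):
            cut_ranking(ranking, 0)
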