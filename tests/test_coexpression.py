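import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from soytol import coexpression as cx
from soytol.simulate import DEGSpec, gen_expression_study
from soytol.study import ExpressionStudy, ValidationError

NO_DEG = DEGSpec(0, 0, 0, 2.0, 0)


def frame(arr, genes=None, samples=None) -> pd.DataFrame:
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=genes, columns=samples)


def adjacency_from(a: np.ndarray) -> cx.AdjacencyMatrix:
    return cx.AdjacencyMatrix(frame(a, genes=[f"g{i}" for i in range(len(a))],
                                    samples=[f"g{i}" for i in range(len(a))]), power=1)


# ------------------------- independent oracles -------------------------

def tom_oracle(a: np.ndarray) -> np.ndarray:
    """Naive triple-loop topological overlap."""
    n = len(a)
    t = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            ki = sum(a[i, u] for u in range(n) if u != i)
            kj = sum(a[j, u] for u in range(n) if u != j)
            t[i, j] = (shared + a[i, j]) / (min(ki, kj) + 1 - a[i, j])
    return t


def k_within_oracle(a: np.ndarray, labels: np.ndarray) -> np.ndarray:
    n = len(a)
    k = np.zeros(n)
    for i in range(n):
        if labels[i] == 0:
            continue
        k[i] = sum(a[i, j] for j in range(n) if j != i and labels[j] == labels[i])
    return k


def random_adjacency(rng, n):
    a = rng.uniform(size=(n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    return a


# ------------------------------- tests ---------------------------------

class TestFilter:
    def _study(self, matrix):
        samples = pd.DataFrame(
            {"cultivar": "c", "tissue": "above",
             "condition": ["control", "control", "stress", "stress"],
             "replicate": [1, 2, 1, 2]},
            index=pd.Index([f"s{i}" for i in range(4)], name="sample"),
        )
        return ExpressionStudy(matrix, samples)

    def test_boundary_inclusive_and_zero_removed(self):
        study = self._study(frame([[0, 0, 0, 0], [2, 0, 0, 0], [1.9, 1.9, 1.9, 1.9]],
                                  samples=[f"s{i}" for i in range(4)]))
        kept = cx.filter_low_expression(study, 2.0)
        assert list(kept.matrix.index) == ["g1"]

    def test_constructed_fraction_removed_exactly(self, rng):
        arr = rng.uniform(3, 10, size=(40, 4))
        arr[:12] *= 0.1  # push 30% of genes below the threshold
        study = self._study(frame(arr, samples=[f"s{i}" for i in range(4)]))
        kept = cx.filter_low_expression(study, 2.0)
        assert set(kept.matrix.index) == {f"g{i}" for i in range(12, 40)}

    def test_all_filtered_is_an_error(self):
        study = self._study(frame(np.full((3, 4), 0.5), samples=[f"s{i}" for i in range(4)]))
        with pytest.raises(ValidationError):
            cx.filter_low_expression(study, 2.0)


class TestAdjacency:
    def test_perfect_and_partial_correlations(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        z = np.array([1.0, 1.0, -1.0, -1.0])
        y = -0.5 * x + np.sqrt(0.75) * z  # exact Pearson -0.5 with x
        adj = cx.adjacency(frame([x, 2 * x + 1, y]), power=2)
        assert adj.a.iloc[0, 1] == pytest.approx(1.0)  # |1|^beta
        assert adj.a.iloc[0, 2] == pytest.approx(0.25)  # |-0.5|^2
        signed = cx.adjacency(frame([x, y]), power=1, mode="signed")
        assert signed.a.iloc[0, 1] == pytest.approx(0.25)  # (1 - 0.5)/2

    def test_uncorrelated_pair_is_zero(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        z = np.array([1.0, 1.0, -1.0, -1.0])  # orthogonal to x
        adj = cx.adjacency(frame([x, z]), power=3)
        assert adj.a.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_constant_gene_is_an_error_naming_the_gene(self):
        with pytest.raises(ValidationError, match="g1"):
            cx.adjacency(frame([[1, 2, 3, 4], [5, 5, 5, 5]]), power=2)

    def test_power_monotonicity_of_connectivity(self, rng):
        expr = frame(rng.normal(size=(30, 10)))
        k_lo = cx.connectivity(cx.adjacency(expr, 2))
        k_hi = cx.connectivity(cx.adjacency(expr, 6))
        assert (k_hi <= k_lo + 1e-12).all()


class TestScaleFreeFit:
    def test_exact_power_law_fits_perfectly(self):
        k = np.repeat([1.0, 2.0, 4.0, 8.0], [64, 16, 4, 1])
        assert cx.scale_free_fit(k) == pytest.approx(1.0)

    def test_increasing_frequency_is_negative(self):
        k = np.repeat([1.0, 2.0, 4.0, 8.0], [1, 4, 16, 64])
        assert cx.scale_free_fit(k) < 0

    def test_flat_histogram_is_near_zero(self):
        k = np.repeat(np.linspace(1, 10, 10), 5)
        assert abs(cx.scale_free_fit(k)) < 0.1

    def test_too_few_bins_undefined(self):
        assert np.isnan(cx.scale_free_fit(np.repeat([1.0, 2.0], 5)))


class TestPickSoftThreshold:
    def test_target_zero_returns_smallest_power(self, rng):
        expr = frame(rng.normal(size=(40, 12)))
        res = cx.pick_soft_threshold(expr, range(2, 9), target=0.0)
        assert res.power == 2 and res.reached_target

    def test_first_crossing_consistent_with_own_table(self, rng):
        expr = frame(rng.normal(size=(60, 12)))
        probe = cx.pick_soft_threshold(expr, range(1, 13), target=-np.inf)
        target = np.nanpercentile(probe.table["fit_r2"], 60)
        res = cx.pick_soft_threshold(expr, range(1, 13), target=target)
        first = res.table.loc[res.table["fit_r2"] >= target, "power"].iloc[0]
        assert res.power == int(first)

    def test_fallback_warns_when_target_unreachable(self, rng):
        expr = frame(rng.normal(size=(40, 12)))
        with pytest.warns(UserWarning, match="falling back"):
            res = cx.pick_soft_threshold(expr, range(2, 6), target=0.999)
        assert not res.reached_target
        best = res.table.loc[res.table["fit_r2"].idxmax(), "power"]
        assert res.power == int(best)

    def test_powers_must_ascend(self, rng):
        expr = frame(rng.normal(size=(10, 6)))
        with pytest.raises(ValidationError):
            cx.pick_soft_threshold(expr, [5, 3, 1])


class TestTOM:
    def test_two_gene_hand_computation(self):
        a = adjacency_from(np.array([[1.0, 0.5], [0.5, 1.0]]))
        tom = cx.tom_similarity(a)
        # k1 = k2 = 0.5; t = (0 + 0.5) / (0.5 + 1 - 0.5)
        assert tom.t.iloc[0, 1] == pytest.approx(0.5)
        assert tom.t.iloc[0, 0] == 1.0

    def test_complete_graph_saturates(self):
        a = adjacency_from(np.ones((5, 5)))
        assert np.allclose(cx.tom_similarity(a).t, 1.0)

    def test_matches_triple_loop_oracle(self, rng):
        for _ in range(10):
            a = random_adjacency(rng, 20)
            tom = cx.tom_similarity(adjacency_from(a)).t.to_numpy()
            assert np.max(np.abs(tom - tom_oracle(a))) <= 1e-12

    def test_bounds_on_random_adjacencies(self, rng):
        for _ in range(20):
            a = random_adjacency(rng, 15)
            t = cx.tom_similarity(adjacency_from(a)).t.to_numpy()
            assert t.min() >= 0.0 and t.max() <= 1.0
            assert np.allclose(t, t.T)


class TestModules:
    def _block_expr(self, rng, sizes, n_samples=24, within=0.9, shared_factor=False):
        rows, labels = [], []
        base = rng.normal(size=n_samples)
        for m, size in enumerate(sizes, start=1):
            factor = base if shared_factor else rng.normal(size=n_samples)
            b = np.sqrt(within / (1 - within))
            for _ in range(size):
                rows.append(5 + b * factor + rng.normal(size=n_samples))
                labels.append(m)
        return frame(np.array(rows)), np.array(labels)

    def test_two_planted_blocks_recovered_exactly(self, rng):
        expr, truth = self._block_expr(rng, [50, 50])
        tom = cx.tom_similarity(cx.adjacency(expr, 6))
        asg = cx.detect_modules(tom, expr, min_size=30)
        assert adjusted_rand_score(truth, asg.labels.to_numpy()) == 1.0
        assert len(asg.module_sizes()) == 2

    def test_blocks_sharing_a_factor_are_merged(self, rng):
        expr, _ = self._block_expr(rng, [40, 40], shared_factor=True)
        tom = cx.tom_similarity(cx.adjacency(expr, 6))
        asg = cx.detect_modules(tom, expr, min_size=30)
        assert len(asg.module_sizes()) == 1

    def test_pure_noise_is_mostly_unassigned(self):
        study, _ = gen_expression_study(n_genes=100, module_specs=[], deg_spec=NO_DEG, seed=1)
        logm = study.log2_matrix()
        asg = cx.detect_modules(cx.tom_similarity(cx.adjacency(logm, 6)), logm)
        assert (asg.labels == 0).mean() >= 0.9

    def test_fewer_genes_than_min_size_all_unassigned(self, rng):
        expr, _ = self._block_expr(rng, [10])
        tom = cx.tom_similarity(cx.adjacency(expr, 6))
        with pytest.warns(UserWarning, match="min module size"):
            asg = cx.detect_modules(tom, expr, min_size=30)
        assert (asg.labels == 0).all()

    def test_permutation_equivariance(self, rng):
        expr, _ = self._block_expr(rng, [40, 35])
        extra = frame(5 + rng.normal(size=(20, 24)), genes=[f"n{i}" for i in range(20)])
        full = pd.concat([expr, extra])
        perm = rng.permutation(len(full))
        shuffled = full.iloc[perm]

        def run(e):
            adj = cx.adjacency(e, 6)
            asg = cx.detect_modules(cx.tom_similarity(adj), e, min_size=30)
            hubs = cx.hub_genes(adj, asg.labels, top_k=10)
            return asg.labels, hubs

        labels_a, hubs_a = run(full)
        labels_b, hubs_b = run(shuffled)
        assert labels_a.sort_index().equals(labels_b.sort_index())
        for m in hubs_a:
            assert list(hubs_a[m]["gene"]) == list(hubs_b[m]["gene"])


class TestEigengenes:
    def test_rank_one_module_reproduces_profile(self, rng):
        profile = rng.normal(size=12)
        expr = frame(np.tile(profile, (5, 1)) * rng.uniform(1, 3, size=(5, 1)))
        labels = pd.Series(1, index=expr.index)
        me = cx.module_eigengenes(expr, labels).loc[1].to_numpy()
        z = (profile - profile.mean()) / profile.std()
        assert np.allclose(me, z, atol=1e-8)

    def test_orientation_robust_to_minority_sign_flips(self, rng):
        expr, _ = TestModules()._block_expr(rng, [20], within=0.95)
        labels = pd.Series(1, index=expr.index)
        me = cx.module_eigengenes(expr, labels).loc[1]
        flipped = expr.copy()
        flipped.iloc[:5] = 10 - flipped.iloc[:5]  # flip a minority of genes
        me2 = cx.module_eigengenes(flipped, labels).loc[1]
        assert np.corrcoef(me, me2)[0, 1] > 0.99

    def test_pc1_explains_at_least_any_single_gene_share(self, rng):
        expr = frame(rng.normal(size=(8, 15)))
        labels = pd.Series(1, index=expr.index)
        me = cx.module_eigengenes(expr, labels).loc[1].to_numpy()
        z = ((expr.T - expr.mean(axis=1)) / expr.std(axis=1)).T.to_numpy()
        var_me = np.mean((z @ me / np.linalg.norm(me)) ** 2)
        for row in z:
            var_g = np.mean((z @ row / np.linalg.norm(row)) ** 2)
            assert var_me >= var_g - 1e-9

    def test_single_gene_module(self, rng):
        expr = frame(rng.normal(size=(1, 10)))
        me = cx.module_eigengenes(expr, pd.Series(1, index=expr.index)).loc[1]
        z = (expr.iloc[0] - expr.iloc[0].mean()) / expr.iloc[0].std(ddof=0)
        assert np.allclose(me, z)


class TestModuleTraits:
    def test_trait_equal_to_eigengene_has_unit_correlation(self, rng):
        mes = pd.DataFrame(rng.normal(size=(2, 12)), index=[1, 2],
                           columns=[f"s{i}" for i in range(12)])
        traits = pd.DataFrame({"T1": mes.loc[1], "T2": rng.normal(size=12)})
        res = cx.module_trait_correlations(mes, traits)
        assert res.correlation.loc[1, "T1"] == pytest.approx(1.0)
        assert res.best_module["T1"] == 1

    def test_sample_mismatch_is_an_error(self, rng):
        mes = pd.DataFrame(rng.normal(size=(1, 5)), index=[1],
                           columns=[f"s{i}" for i in range(5)])
        traits = pd.DataFrame({"T": rng.normal(size=5)},
                              index=[f"x{i}" for i in range(5)])
        with pytest.raises(ValidationError, match="mismatch"):
            cx.module_trait_correlations(mes, traits)


class TestHubsAndCandidates:
    def test_small_module_returns_all_genes(self, rng):
        a = random_adjacency(rng, 10)
        adj = adjacency_from(a)
        labels = pd.Series(1, index=adj.a.index)
        hubs = cx.hub_genes(adj, labels, top_k=30)
        assert len(hubs[1]) == 10

    def test_k_within_matches_naive_oracle(self, rng):
        a = random_adjacency(rng, 20)
        adj = adjacency_from(a)
        labels = pd.Series([1] * 8 + [2] * 7 + [0] * 5, index=adj.a.index)
        k = cx.intramodular_connectivity(adj, labels).to_numpy()
        assert np.max(np.abs(k - k_within_oracle(a, labels.to_numpy()))) <= 1e-12

    def test_tie_break_by_gene_id(self):
        a = np.full((6, 6), 0.5)
        np.fill_diagonal(a, 1.0)
        adj = adjacency_from(a)
        labels = pd.Series(1, index=adj.a.index)
        hubs = cx.hub_genes(adj, labels, top_k=3)
        assert list(hubs[1]["gene"]) == ["g0", "g1", "g2"]

    def test_candidates_disjoint_and_contained_cases(self):
        hubs = {1: pd.DataFrame({"gene": ["g1", "g2"], "k_within": [5.0, 4.0]}),
                2: pd.DataFrame({"gene": ["g9"], "k_within": [2.0]})}
        empty = cx.candidate_genes(hubs, {1, 2}, {"zz"})
        assert empty.empty
        contained = cx.candidate_genes(hubs, {1}, {"g1", "g2"})
        assert list(contained["gene"]) == ["g1", "g2"]
        # module 0 and non-trait-linked modules are never consulted
        only_m1 = cx.candidate_genes(hubs, {0, 1}, {"g1", "g9"})
        assert list(only_m1["gene"]) == ["g1"]
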