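import itertools

import numpy as np
import pytest

from scdemux import (
    FitConfig,
    GenotypePosterior,
    fit,
    genotype_concordance,
    match_donors,
    panel_table,
    select_discriminatory_variants,
)
from scdemux.matching import ConcordanceMatrix, _partition_entropy, _refine


def onehot_posterior(hard):
    return GenotypePosterior(np.eye(3)[np.asarray(hard)])


def deep(n, k):
    return np.full((n, k), 100.0)


class TestGenotypeConcordance:
    def test_self_concordance_is_one(self):
        rng = np.random.default_rng(0)
        hard = rng.integers(0, 3, size=(50, 4))
        g = onehot_posterior(hard)
        cm = genotype_concordance(g, deep(50, 4), g, deep(50, 4))
        np.testing.assert_allclose(np.diag(cm.values), 1.0)
        assert (cm.n_shared_variants == 50).all()

    def test_independent_genotypes_agree_about_a_third(self):
        rng = np.random.default_rng(1)
        a = onehot_posterior(rng.integers(0, 3, size=(3000, 2)))
        b = onehot_posterior(rng.integers(0, 3, size=(3000, 2)))
        cm = genotype_concordance(a, deep(3000, 2), b, deep(3000, 2))
        np.testing.assert_allclose(cm.values, 1 / 3, atol=0.04)

    def test_depth_gating(self):
        hard = np.array([[0], [1], [2]])
        g = onehot_posterior(hard)
        depth_a = np.array([[100.0], [100.0], [5.0]])
        depth_b = np.array([[100.0], [5.0], [100.0]])
        cm = genotype_concordance(g, depth_a, g, depth_b, min_umis=10)
        # only the first variant is well covered in both
        assert cm.n_shared_variants[0, 0] == 1
        assert cm.values[0, 0] == 1.0

    def test_no_shared_variants_is_nan(self):
        g = onehot_posterior([[0], [1]])
        cm = genotype_concordance(
            g, np.zeros((2, 1)), g, deep(2, 1), min_umis=10
        )
        assert np.isnan(cm.values[0, 0])
        assert cm.n_shared_variants[0, 0] == 0

    def test_mismatched_universe_is_error(self):
        a = onehot_posterior([[0], [1]])
        b = onehot_posterior([[0], [1], [2]])
        with pytest.raises(ValueError, match="variant universe"):
            genotype_concordance(a, deep(2, 1), b, deep(3, 1))


class TestMatchDonors:
    def test_recovers_permutation(self):
        rng = np.random.default_rng(2)
        hard = rng.integers(0, 3, size=(100, 5))
        perm = np.array([3, 0, 4, 1, 2])
        a = onehot_posterior(hard)
        b = onehot_posterior(hard[:, perm])
        cm = genotype_concordance(a, deep(100, 5), b, deep(100, 5))
        mapping, scores = match_donors(cm)
        # b's column j holds a's donor perm[j], so a's donor perm[j] -> j
        np.testing.assert_array_equal(mapping[perm], np.arange(5))
        np.testing.assert_allclose(scores, 1.0)

    def test_tie_break_prefers_low_index(self):
        cm = ConcordanceMatrix(np.full((3, 3), 0.5), np.full((3, 3), 10))
        mapping, scores = match_donors(cm)
        np.testing.assert_array_equal(mapping, [0, 1, 2])

    def test_matches_brute_force_optimum(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            vals = rng.random((6, 6))
            cm = ConcordanceMatrix(vals, np.full((6, 6), 10))
            mapping, scores = match_donors(cm)
            got = vals[np.arange(6), mapping].sum()
            best = max(
                vals[np.arange(6), list(p)].sum()
                for p in itertools.permutations(range(6))
            )
            assert got == pytest.approx(best, rel=1e-12)

    def test_rectangular_leaves_surplus_unmatched(self):
        vals = np.array([[0.9, 0.1], [0.2, 0.8], [0.5, 0.5]])
        cm = ConcordanceMatrix(vals, np.full((3, 2), 10))
        mapping, scores = match_donors(cm)
        assert (mapping == -1).sum() == 1
        assert mapping[0] == 0 and mapping[1] == 1

    def test_nan_counts_as_zero(self):
        vals = np.array([[np.nan, 0.9], [0.8, np.nan]])
        cm = ConcordanceMatrix(vals, np.zeros((2, 2), int))
        mapping, scores = match_donors(cm)
        np.testing.assert_array_equal(mapping, [1, 0])
        np.testing.assert_allclose(scores, [0.9, 0.8])

    def test_split_pool_runs_link_up(self):
        # genotype hard calls need ~20+ UMIs per (variant, donor) to be
        # reliable, so use a denser pool than the shared fixture
        from scdemux import SimConfig, filter_variants, simulate_pool

        cfg_pool = SimConfig(
            n_donors=4, cells_per_donor=150, n_variants=500,
            coverage_rate=0.15, doublet_rate=0.0, seed=17,
        )
        data, truth = simulate_pool(cfg_pool)
        data = filter_variants(data)
        rng = np.random.default_rng(5)
        idx = rng.permutation(data.n_cells)
        half = data.n_cells // 2
        sub_a = _subset_cells(data, np.sort(idx[:half]))
        sub_b = _subset_cells(data, np.sort(idx[half:]))
        cfg = FitConfig(n_init=8, warmup_iters=10, seed=1)
        fa = fit(sub_a, 4, config=cfg, with_doublets=False)
        fb = fit(sub_b, 4, config=cfg, with_doublets=False)
        cm = genotype_concordance(
            fa.genotype, fa.donor_depth(sub_a), fb.genotype, fb.donor_depth(sub_b)
        )
        mapping, scores = match_donors(cm)
        assert (scores > 0.9).all()
        # unmatched pairs are clearly worse than matched ones
        unmatched = [
            cm.values[k, l]
            for k in range(4)
            for l in range(4)
            if l != mapping[k] and np.isfinite(cm.values[k, l])
        ]
        assert max(unmatched) < 0.8


def _subset_cells(data, idx):
    from scdemux import AlleleCountData

    return AlleleCountData(
        data.A[:, idx].tocsr(),
        data.D[:, idx].tocsr(),
        [data.cells[j] for j in idx],
        data.variants,
    )


class TestPartitionHelpers:
    def test_entropy_of_even_split(self):
        assert _partition_entropy(np.array([0, 0, 1, 1])) == pytest.approx(1.0)
        assert _partition_entropy(np.array([0, 1, 2, 3])) == pytest.approx(2.0)
        assert _partition_entropy(np.zeros(4, int)) == 0.0

    def test_refine_splits_blocks(self):
        labels = np.array([0, 0, 1, 1])
        pattern = np.array([0, 1, 0, 0])
        refined = _refine(labels, pattern)
        assert len(np.unique(refined)) == 3
        assert refined[2] == refined[3] != refined[0] != refined[1]


class TestVariantPanel:
    def test_two_orthogonal_variants_suffice(self):
        hard = np.array([[0, 0, 2, 2], [0, 2, 0, 2], [1, 1, 1, 1]])
        g = onehot_posterior(hard)
        panel = select_discriminatory_variants(g, deep(3, 4))
        assert sorted(panel.variants) == [0, 1]
        assert panel.complete
        assert panel.entropy == pytest.approx(2.0)

    def test_tie_broken_by_depth_then_index(self):
        hard = np.array([[0, 2], [0, 2], [0, 2]])
        g = onehot_posterior(hard)
        depth = np.array([[30.0, 30.0], [90.0, 90.0], [30.0, 30.0]])
        panel = select_discriminatory_variants(g, depth)
        assert panel.variants == [1]  # deepest of the equal-gain trio
        hard2 = np.array([[0, 2], [0, 2]])
        panel2 = select_discriminatory_variants(
            onehot_posterior(hard2), deep(2, 2)
        )
        assert panel2.variants == [0]  # equal depth: lower index

    def test_indistinguishable_donors_warn(self):
        hard = np.array([[0, 0, 2], [1, 1, 0]])
        g = onehot_posterior(hard)
        with pytest.warns(UserWarning, match="unresolved"):
            panel = select_discriminatory_variants(g, deep(2, 3))
        assert not panel.complete
        assert [0, 1] in panel.unresolved_blocks

    def test_low_depth_variants_excluded(self):
        hard = np.array([[0, 2], [0, 2]])
        depth = np.array([[100.0, 5.0], [100.0, 100.0]])
        g = onehot_posterior(hard)
        panel = select_discriminatory_variants(g, depth)
        assert panel.variants == [1]

    def test_exclude_all_hom_alt(self):
        hard = np.array([[2, 2], [0, 2]])
        g = onehot_posterior(hard)
        panel = select_discriminatory_variants(
            g, deep(2, 2), exclude_all_hom_alt=True
        )
        assert 0 not in panel.variants

    def test_panel_actually_separates_all_pairs(self):
        rng = np.random.default_rng(8)
        for trial in range(10):
            hard = rng.integers(0, 3, size=(60, 5))
            g = onehot_posterior(hard)
            panel = select_discriminatory_variants(g, deep(60, 5))
            assert panel.complete
            sub = hard[panel.variants]
            for k, l in itertools.combinations(range(5), 2):
                assert (sub[:, k] != sub[:, l]).any()

    def test_greedy_size_near_brute_force_minimum(self):
        rng = np.random.default_rng(9)
        for trial in range(5):
            hard = rng.integers(0, 3, size=(12, 4))
            g = onehot_posterior(hard)
            panel = select_discriminatory_variants(g, deep(12, 4))
            if not panel.complete:
                continue
            minimal = None
            for size in range(1, len(panel.variants) + 1):
                for combo in itertools.combinations(range(12), size):
                    sub = hard[list(combo)]
                    if all(
                        (sub[:, k] != sub[:, l]).any()
                        for k, l in itertools.combinations(range(4), 2)
                    ):
                        minimal = size
                        break
                if minimal is not None:
                    break
            assert minimal is not None
            # greedy entropy refinement is near-optimal on small instances
            assert len(panel.variants) <= minimal + 1

    def test_needs_two_donors(self):
        g = onehot_posterior(np.zeros((3, 1), int))
        with pytest.raises(ValueError, match="two donors"):
            select_discriminatory_variants(g, deep(3, 1))

    def test_panel_table(self, small_fit):
        f, data, _ = small_fit
        panel = select_discriminatory_variants(f.genotype, f.donor_depth(data))
        table = panel_table(panel, f.genotype, data.variants)
        assert len(table) == len(panel.variants)
        assert {"variant", "donor0", "donor3"} <= set(table.columns)
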