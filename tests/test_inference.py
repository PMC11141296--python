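import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pipet.inference import (
    NullModel,
    adjust_bh,
    assign_labels,
    empirical_pvalues,
    permutation_null,
    predict,
)
from pipet.similarity import ScoreTable, score
from pipet.templates import MarkerSet, PipetError, build_templates

from .conftest import make_cells


def make_score_table(stat, polarity="higher_is_closer", metric="cosine",
                     class_names=None, degenerate=None):
    stat = np.asarray(stat, dtype=float)
    c, k = stat.shape
    return ScoreTable(
        stat=stat,
        metric_name=metric,
        polarity=polarity,
        cell_ids=[f"c{i + 1}" for i in range(c)],
        class_names=class_names or [chr(ord("A") + j) for j in range(k)],
        degenerate=degenerate,
    )


def make_null(values, metric="cosine", polarity="higher_is_closer", seed=0):
    values = np.asarray(values, dtype=float)
    return NullModel(
        permuted_stats=values, metric_name=metric, polarity=polarity,
        n_perm=values.shape[0], seed=seed,
    )


class TestPermutationNull:
    def test_single_permutation_shape(self, rng, binary_templates):
        cells = make_cells(rng.lognormal(size=(10, 4)),
                           gene_ids=[f"g{i + 1}" for i in range(10)])
        null = permutation_null(cells, binary_templates, "cosine", n_perm=1, seed=0)
        assert null.permuted_stats.shape == (1, 4, 2)

    def test_determinism(self, rng, binary_templates):
        cells = make_cells(rng.lognormal(size=(10, 4)),
                           gene_ids=[f"g{i + 1}" for i in range(10)])
        a = permutation_null(cells, binary_templates, "cosine", n_perm=20, seed=5)
        b = permutation_null(cells, binary_templates, "cosine", n_perm=20, seed=5)
        np.testing.assert_array_equal(a.permuted_stats, b.permuted_stats)
        c = permutation_null(cells, binary_templates, "cosine", n_perm=20, seed=6)
        assert not np.array_equal(a.permuted_stats, c.permuted_stats)

    def test_too_few_genes_errors(self, rng, binary_templates):
        cells = make_cells(rng.lognormal(size=(2, 3)), gene_ids=["g1", "g2"])
        with pytest.raises(PipetError, match="fewer than"):
            permutation_null(cells, binary_templates, "cosine", n_perm=5, seed=0)

    def test_observed_within_null_range_on_iid_noise(self, rng, binary_templates):
        # genes are exchangeable, so the observed statistic behaves like one
        # more draw from the null: coverage of [min, max] ~ 1 - 2/(nPerm+1)
        n_perm = 19
        inside = 0
        trials = 300
        for t in range(trials):
            vals = rng.lognormal(size=(12, 1))
            cells = make_cells(vals, gene_ids=[f"g{i + 1}" for i in range(12)])
            obs = score(cells, binary_templates, "cosine").stat[0, 0]
            null = permutation_null(
                cells, binary_templates, "cosine", n_perm=n_perm, seed=t
            ).permuted_stats[:, 0, 0]
            inside += null.min() <= obs <= null.max()
        expected = 1 - 2 / (n_perm + 1)
        assert abs(inside / trials - expected) < 0.06


class TestEmpiricalPvalues:
    def test_observed_above_all_nulls(self, rng):
        null = make_null(rng.uniform(0, 0.5, size=(1000, 1, 1)))
        obs = make_score_table([[0.9]])
        assert empirical_pvalues(obs, null)[0, 0] == pytest.approx(1 / 1001)

    def test_observed_at_null_minimum(self):
        null = make_null(np.linspace(0.1, 0.9, 100).reshape(100, 1, 1))
        obs = make_score_table([[0.1]])
        assert empirical_pvalues(obs, null)[0, 0] == pytest.approx(1.0)

    def test_95th_percentile_of_999_draws(self):
        vals = np.arange(1, 1000, dtype=float)  # 1..999
        null = make_null(vals.reshape(999, 1, 1))
        obs = make_score_table([[950.0]])
        # 50 draws are >= 950 -> (1 + 50) / 1000
        assert empirical_pvalues(obs, null)[0, 0] == pytest.approx(0.051)

    @pytest.mark.parametrize("polarity", ["higher_is_closer", "lower_is_closer"])
    def test_exhaustive_count_oracle(self, rng, polarity):
        for n_perm in (1, 2, 5, 20):
            null_vals = rng.normal(size=(n_perm, 6, 3))
            obs_vals = rng.normal(size=(6, 3))
            metric = "cosine" if polarity == "higher_is_closer" else "euclidean"
            null = make_null(null_vals, metric=metric, polarity=polarity)
            obs = make_score_table(obs_vals, polarity=polarity, metric=metric)
            p = empirical_pvalues(obs, null)
            for i in range(6):
                for j in range(3):
                    if polarity == "higher_is_closer":
                        b = sum(null_vals[r, i, j] >= obs_vals[i, j] for r in range(n_perm))
                    else:
                        b = sum(null_vals[r, i, j] <= obs_vals[i, j] for r in range(n_perm))
                    assert p[i, j] == pytest.approx((1 + b) / (n_perm + 1))

    def test_polarity_mismatch_errors(self, rng):
        null = make_null(rng.normal(size=(10, 2, 2)), metric="euclidean",
                         polarity="lower_is_closer")
        obs = make_score_table(rng.normal(size=(2, 2)))
        with pytest.raises(PipetError):
            empirical_pvalues(obs, null)

    def test_pvalues_bounded_below(self, rng, binary_templates):
        cells = make_cells(rng.lognormal(size=(30, 10)),
                           gene_ids=[f"g{i + 1}" for i in range(30)])
        obs = score(cells, binary_templates, "cosine")
        null = permutation_null(cells, binary_templates, "cosine", n_perm=50, seed=1)
        p = empirical_pvalues(obs, null)
        assert np.all(p >= 1 / 51)
        assert np.all(p <= 1.0)


class TestAdjustBH:
    def test_hand_computed_step_up(self):
        p = np.array([[0.01, 0.02, 0.03, 0.04]])
        np.testing.assert_allclose(adjust_bh(p), 0.04)

    def test_all_equal(self):
        p = np.full((3, 2), 0.2)
        np.testing.assert_allclose(adjust_bh(p), 0.2)

    def test_single_test(self):
        np.testing.assert_allclose(adjust_bh(np.array([[0.031]])), 0.031)

    def test_per_class_family(self):
        p = np.array([[0.01, 0.5], [0.02, 0.6], [0.03, 0.7], [0.04, 0.8]])
        adj = adjust_bh(p, family="per_class")
        np.testing.assert_allclose(adj[:, 0], 0.04)
        np.testing.assert_allclose(adj[:, 1], 0.8)

    def test_out_of_range_rejected(self):
        with pytest.raises(PipetError):
            adjust_bh(np.array([[0.0, 0.5]]))
        with pytest.raises(PipetError):
            adjust_bh(np.array([[1.5]]))

    @settings(max_examples=50, deadline=None)
    @given(
        ps=st.lists(st.floats(0.001, 1.0), min_size=2, max_size=12),
        idx=st.integers(0, 11),
        bump=st.floats(0.0, 0.5),
    )
    def test_monotonicity(self, ps, idx, bump):
        # raising any single input p never lowers any adjusted value
        p = np.asarray(ps).reshape(1, -1)
        i = idx % p.shape[1]
        q = p.copy()
        q[0, i] = min(1.0, q[0, i] + bump)
        assert np.all(adjust_bh(q) >= adjust_bh(p) - 1e-12)


class TestAssignLabels:
    def test_significant_best_class(self):
        obs = make_score_table([[0.9, 0.1]])
        recs = assign_labels(obs, np.array([[0.001, 0.8]]),
                             np.array([[0.01, 0.9]]), alpha=0.05, gate="p")
        assert recs[0].label == "A"
        assert recs[0].best_class == "A"

    def test_tie_breaks_to_first_class(self):
        obs = make_score_table([[0.5, 0.5]])
        recs = assign_labels(obs, np.full((1, 2), 0.001),
                             np.full((1, 2), 0.001), gate="p")
        assert recs[0].best_class == "A"
        assert recs[0].tie

    def test_gate_failure_unassigns(self):
        obs = make_score_table([[0.9, 0.1]])
        recs = assign_labels(obs, np.array([[0.2, 0.9]]),
                             np.array([[0.3, 0.9]]), gate="p")
        assert recs[0].label == "Unassigned"
        assert recs[0].best_class == "A"

    def test_gate_none_labels_everyone(self, rng):
        obs = make_score_table(rng.normal(size=(50, 3)))
        recs = assign_labels(obs, np.full((50, 3), 0.99),
                             np.full((50, 3), 0.99), gate="none")
        assert all(r.label != "Unassigned" for r in recs)

    def test_distance_polarity_uses_argmin(self):
        obs = make_score_table([[2.0, 0.5]], polarity="lower_is_closer",
                               metric="euclidean")
        recs = assign_labels(obs, np.array([[0.5, 0.001]]),
                             np.array([[0.5, 0.01]]), gate="p")
        assert recs[0].label == "B"

    def test_degenerate_cell_unassigned(self):
        obs = make_score_table([[0.0, 0.0]], degenerate=np.array([True]))
        recs = assign_labels(obs, np.array([[0.001, 0.001]]),
                             np.array([[0.001, 0.001]]), gate="p")
        assert recs[0].label == "Unassigned"
        assert recs[0].p_value == 1.0
        assert recs[0].degenerate


class TestPredict:
    def _self_match_setup(self, rng):
        markers = MarkerSet(
            class_names=["A", "B"],
            genes={"A": [f"g{i}" for i in range(1, 6)],
                   "B": [f"g{i}" for i in range(6, 11)]},
        )
        templates = build_templates(markers)
        n = 60
        gene_ids = [f"g{i}" for i in range(1, n + 1)]
        vals = rng.lognormal(mean=0.0, sigma=0.3, size=(n, 2))
        vals[:5, 0] += 5.0  # cell 1 strongly expresses A markers
        vals[5:10, 1] += 5.0  # cell 2 strongly expresses B markers
        cells = make_cells(vals, gene_ids=gene_ids, cell_ids=["cellA", "cellB"])
        return cells, templates

    def test_self_match(self, rng):
        cells, templates = self._self_match_setup(rng)
        recs, manifest = predict(cells, templates, n_perm=200, seed=3, gate="p")
        assert recs[0].label == "A"
        assert recs[1].label == "B"
        assert recs[0].p_value <= 0.05
        assert manifest["n_common_genes"] == 10

    def test_class_name_swap_symmetry(self, rng):
        cells, templates = self._self_match_setup(rng)
        swapped = build_templates(
            MarkerSet(
                class_names=["B", "A"],
                genes={"B": templates.gene_ids[:5], "A": templates.gene_ids[5:]},
            )
        )
        recs, _ = predict(cells, templates, n_perm=100, seed=3)
        recs2, _ = predict(cells, swapped, n_perm=100, seed=3)
        assert [r.best_class for r in recs] == ["A", "B"]
        # the same marker genes now carry the other class name
        assert [r.best_class for r in recs2] == ["B", "A"]

    def test_invariant_to_cell_and_gene_order(self, rng):
        cells, templates = self._self_match_setup(rng)
        recs, _ = predict(cells, templates, n_perm=50, seed=9)
        gperm = rng.permutation(cells.n_genes)
        reordered = make_cells(
            cells.values[gperm][:, ::-1],
            gene_ids=[cells.gene_ids[i] for i in gperm],
            cell_ids=list(cells.cell_ids[::-1]),
        )
        recs2, _ = predict(reordered, templates, n_perm=50, seed=9)
        by_id = {r.cell_id: r for r in recs2}
        for r in recs:
            assert by_id[r.cell_id].best_class == r.best_class
            assert by_id[r.cell_id].best_stat == pytest.approx(r.best_stat)

    def test_super_uniform_pvalues_under_null(self, rng):
        # i.i.d. noise cells: empirical CDF of p at 0.05 must stay near 0.05
        markers = MarkerSet(
            class_names=["A", "B"],
            genes={"A": [f"g{i}" for i in range(1, 11)],
                   "B": [f"g{i}" for i in range(11, 21)]},
        )
        templates = build_templates(markers)
        n_genes, n_cells = 100, 1000
        cells = make_cells(
            rng.lognormal(size=(n_genes, n_cells)),
            gene_ids=[f"g{i}" for i in range(1, n_genes + 1)],
        )
        from pipet.inference import empirical_pvalues, permutation_null
        from pipet.templates import intersect_with_cells

        t = intersect_with_cells(templates, cells.gene_ids)
        obs = score(cells, t, "cosine")
        null = permutation_null(cells, t, "cosine", n_perm=199, seed=11)
        p = empirical_pvalues(obs, null)
        assert p.size >= 2000
        assert (p <= 0.05).mean() <= 0.07
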