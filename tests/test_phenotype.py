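"""Z-score matrices, cosine similarity, clustering and matrix reordering."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from mechphen.core import control_condition, full_design
from mechphen.phenotype import (
    SimilarityMatrix,
    ZMatrix,
    cluster_similarity,
    compute_zmatrix,
    cosine_similarity_matrix,
    reorder_zmatrix,
)
from mechphen.synth import default_effect_model, make_property_table


def table_from_values(values: dict[str, dict[str, list[float]]]) -> pd.DataFrame:
    """condition -> property -> replicate values, as a long table."""
    rows = [
        {"condition_id": c, "property": p, "replicate": i, "value": v}
        for c, props in values.items()
        for p, vals in props.items()
        for i, v in enumerate(vals)
    ]
    return pd.DataFrame(rows)


def zmatrix_from_array(arr, conditions, properties, control="ctrl"):
    df = pd.DataFrame(arr, index=conditions, columns=properties)
    return ZMatrix(values=df, control_id=control)


class TestZMatrix:
    def test_hand_evaluated_score(self):
        """x_bar=5, control mean 3 and SD 2 give z = 1."""
        tbl = table_from_values(
            {"ctrl": {"p": [1.0, 3.0, 5.0]}, "cond": {"p": [5.0, 5.0, 5.0]}}
        )
        z = compute_zmatrix(tbl, "ctrl")
        assert z.values.loc["cond", "p"] == pytest.approx(1.0)

    def test_control_row_identically_zero(self):
        tbl = make_property_table(seed=1)
        z = compute_zmatrix(tbl, control_condition(24).condition_id)
        assert np.all(z.values.loc[z.control_id].to_numpy() == 0.0)

    def test_equal_means_give_zero_scores(self):
        tbl = table_from_values(
            {"ctrl": {"p": [2.0, 4.0]}, "cond": {"p": [1.0, 5.0]}}
        )
        z = compute_zmatrix(tbl, "ctrl")
        assert z.values.loc["cond", "p"] == pytest.approx(0.0)

    def test_zero_control_sd_error_names_property(self):
        tbl = table_from_values(
            {"ctrl": {"flat_prop": [3.0, 3.0]}, "cond": {"flat_prop": [4.0, 5.0]}}
        )
        with pytest.raises(ValueError, match="flat_prop"):
            compute_zmatrix(tbl, "ctrl")

    def test_missing_cell_rejected(self):
        tbl = table_from_values(
            {"ctrl": {"a": [1.0, 2.0], "b": [1.0, 2.0]}, "cond": {"a": [3.0, 4.0]}}
        )
        with pytest.raises(ValueError, match="missing"):
            compute_zmatrix(tbl, "ctrl")

    def test_missing_control_rejected(self):
        tbl = table_from_values({"cond": {"a": [1.0, 2.0]}})
        with pytest.raises(ValueError, match="control"):
            compute_zmatrix(tbl, "ctrl")


class TestCosineSimilarity:
    def test_identical_and_orthogonal_vectors(self):
        z = zmatrix_from_array(
            [[0.0, 0.0], [1.0, 0.0], [2.0, 0.0], [0.0, 1.0]],
            ["ctrl", "a", "b", "c"],
            ["p1", "p2"],
        )
        c = cosine_similarity_matrix(z, "conditions")
        assert c.values.loc["a", "b"] == pytest.approx(1.0)
        assert c.values.loc["a", "c"] == pytest.approx(0.0)

    def test_hand_evaluated_oblique_pair(self):
        """(1,1) against (1,0) has cosine 1/sqrt(2)."""
        z = zmatrix_from_array(
            [[0.0, 0.0], [1.0, 1.0], [1.0, 0.0]],
            ["ctrl", "a", "b"],
            ["p1", "p2"],
        )
        c = cosine_similarity_matrix(z, "conditions")
        assert c.values.loc["a", "b"] == pytest.approx(1.0 / np.sqrt(2.0))

    def test_control_row_excluded_by_default(self):
        z = zmatrix_from_array(
            [[0.0, 0.0], [1.0, 2.0], [2.0, 1.0]], ["ctrl", "a", "b"], ["p1", "p2"]
        )
        c = cosine_similarity_matrix(z, "conditions")
        assert "ctrl" not in c.values.index

    def test_zero_norm_vector_error_names_item(self):
        z = zmatrix_from_array(
            [[0.0, 0.0], [1.0, 2.0], [0.0, 0.0]],
            ["ctrl", "a", "dead"],
            ["p1", "p2"],
        )
        with pytest.raises(ValueError, match="dead"):
            cosine_similarity_matrix(z, "conditions")

    def test_contracts_over_random_draws(self):
        """C and P are symmetric with unit diagonal and entries in
        [-1, 1] for 1,000 random Z matrices."""
        rng = np.random.default_rng(0)
        for _ in range(1000):
            m, n = rng.integers(3, 7), rng.integers(3, 7)
            arr = rng.normal(size=(m, n))
            arr[0] = 0.0
            conds = ["ctrl"] + [f"c{i}" for i in range(m - 1)]
            z = zmatrix_from_array(arr, conds, [f"p{j}" for j in range(n)])
            for axis in ("conditions", "properties"):
                try:
                    s = cosine_similarity_matrix(z, axis)
                except ValueError:
                    continue  # a zero-norm property column: contract is an error
                v = s.values.to_numpy()
                assert np.allclose(v, v.T)
                assert np.allclose(np.diag(v), 1.0)
                assert (v <= 1.0 + 1e-12).all() and (v >= -1.0 - 1e-12).all()

    def test_row_scale_invariance(self):
        rng = np.random.default_rng(1)
        arr = rng.normal(size=(4, 5))
        arr[0] = 0.0
        conds = ["ctrl", "a", "b", "c"]
        props = [f"p{j}" for j in range(5)]
        c1 = cosine_similarity_matrix(zmatrix_from_array(arr, conds, props),
                                      "conditions")
        arr2 = arr.copy()
        arr2[2] *= 7.5
        c2 = cosine_similarity_matrix(zmatrix_from_array(arr2, conds, props),
                                      "conditions")
        assert np.allclose(c1.values.to_numpy(), c2.values.to_numpy())


def planted_similarity(sizes, within, between, noise, rng) -> SimilarityMatrix:
    n = sum(sizes)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    s = np.where(labels[:, None] == labels[None, :], within, between).astype(float)
    s += rng.uniform(-noise, noise, (n, n))
    s = (s + s.T) / 2
    np.fill_diagonal(s, 1.0)
    s = np.clip(s, -1, 1)
    names = [f"i{i}" for i in range(n)]
    return SimilarityMatrix(pd.DataFrame(s, index=names, columns=names),
                            "conditions")


class TestClustering:
    def test_planted_two_blocks_recovered_across_seeds(self):
        """Two planted blocks with a similarity gap >= 0.5 are recovered
        with ARI = 1 for 100 random instances."""
        for seed in range(100):
            rng = np.random.default_rng(seed)
            s = planted_similarity([4, 3], within=0.9, between=0.2,
                                   noise=0.1, rng=rng)
            res = cluster_similarity(s, k="auto")
            truth = [0, 0, 0, 0, 1, 1, 1]
            assert adjusted_rand_score(truth, res.labels) == 1.0

    def test_degenerate_flat_similarity_defaults_to_two_clusters(self):
        n = 5
        s = np.full((n, n), 0.5)
        np.fill_diagonal(s, 1.0)
        names = [f"i{i}" for i in range(n)]
        sm = SimilarityMatrix(pd.DataFrame(s, index=names, columns=names),
                              "conditions")
        r1 = cluster_similarity(sm, k="auto")
        r2 = cluster_similarity(sm, k="auto")
        assert r1.k == 2
        assert np.array_equal(r1.labels, r2.labels)

    def test_explicit_k_respected(self):
        rng = np.random.default_rng(0)
        s = planted_similarity([3, 3, 3], 0.9, 0.1, 0.05, rng)
        res = cluster_similarity(s, k=3)
        assert res.k == 3

    def test_auto_needs_three_items(self):
        s = planted_similarity([1, 1], 0.9, 0.1, 0.0, np.random.default_rng(0))
        with pytest.raises(ValueError, match="3 items"):
            cluster_similarity(s, k="auto")

    def test_blocks_contiguous_under_ordering(self):
        rng = np.random.default_rng(3)
        s = planted_similarity([4, 4], 0.9, 0.1, 0.1, rng)
        res = cluster_similarity(s, k="auto")
        ordered_labels = res.labels[res.ordering]
        changes = np.count_nonzero(np.diff(ordered_labels))
        assert changes == res.k - 1


class TestReorder:
    @pytest.fixture
    def z(self):
        rng = np.random.default_rng(2)
        arr = rng.normal(size=(4, 3))
        arr[0] = 0
        return zmatrix_from_array(arr, ["ctrl", "a", "b", "c"],
                                  ["p1", "p2", "p3"])

    def test_identity_permutation_is_noop(self, z):
        out = reorder_zmatrix(z, z.conditions, z.properties)
        pd.testing.assert_frame_equal(out.values, z.values)

    def test_any_permutation_preserves_entries(self, z):
        out = reorder_zmatrix(z, ["c", "ctrl", "a", "b"], ["p3", "p1", "p2"])
        assert sorted(out.values.to_numpy().ravel()) == pytest.approx(
            sorted(z.values.to_numpy().ravel())
        )

    def test_control_row_completed_when_ordering_omits_it(self, z):
        out = reorder_zmatrix(z, ["c", "b", "a"], None)
        assert out.values.index[0] == "ctrl"

    def test_invalid_permutation_rejected(self, z):
        with pytest.raises(ValueError, match="permutation"):
            reorder_zmatrix(z, ["a", "b", "x"], None)

    def test_reordered_blocks_match_cluster_labels(self, z):
        c = cosine_similarity_matrix(z, "conditions")
        res = cluster_similarity(c, k=2)
        out = reorder_zmatrix(z, res, None)
        ordered = [n for n in out.values.index if n != "ctrl"]
        labels = res.labels_of(ordered)
        assert np.count_nonzero(np.diff(labels)) == res.k - 1


class TestEndToEndEmulation:
    def test_24h_conditions_cluster_by_genotype(self):
        """At 24 h the unsupervised clustering splits the seven non-control
        conditions exactly by vimentin genotype."""
        for seed in range(5):
            tbl = make_property_table(design=full_design(24), seed=seed)
            z = compute_zmatrix(tbl, control_condition(24).condition_id)
            c = cosine_similarity_matrix(z, "conditions")
            res = cluster_similarity(c, k="auto")
            genotype = ["VimKO" in n for n in res.items]
            assert res.k == 2
            assert adjusted_rand_score(genotype, res.labels) == 1.0

    def test_48h_stiffness_rescue_moves_ko_into_wt_cluster(self):
        """At 48 h the knockout conditions on the stiff substrate join
        the wildtype cluster; only soft-substrate knockouts remain apart."""
        for seed in range(5):
            tbl = make_property_table(design=full_design(48), seed=seed)
            z = compute_zmatrix(tbl, control_condition(48).condition_id)
            c = cosine_similarity_matrix(z, "conditions")
            res = cluster_similarity(c, k="auto")
            expected = [
                0 if ("VimWT" in n or "E_H" in n) else 1 for n in res.items
            ]
            assert res.k == 2
            assert adjusted_rand_score(expected, res.labels) == 1.0
            # and the rescued conditions share a label with the wildtypes
            lab = dict(zip(res.items, res.labels))
            wt_label = lab["E_H-C_P-VimWT-48h"]
            assert lab["E_H-C_P-VimKO-48h"] == wt_label
            assert lab["E_H-C_H-VimKO-48h"] == wt_label
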