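"""Correlation, thresholding and network assembly."""

import warnings

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from traitnets import (
    TraitCorrelation,
    build_network,
    build_trait_network,
    correlate,
    threshold_adjacency,
)
from traitnets.construction import write_edge_list, write_graphml, write_node_table


def textbook_pearson(x, y):
    """Two-pass covariance/variance formula with t-distribution p-value.

    Independent oracle for the vectorized implementation.
    """
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    r = cov / (vx * vy) ** 0.5
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * ((n - 2) / (1 - r * r)) ** 0.5
    return r, 2 * stats.t.sf(abs(t), df=n - 2)


def _frame(arr):
    cols = pd.MultiIndex.from_tuples(
        [("t", f"c{j}") for j in range(arr.shape[1])], names=["trait", "level"])
    return pd.DataFrame(arr, columns=cols)


class TestCorrelate:
    def test_matches_textbook_formula_on_random_matrices(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 30))
            k = int(rng.integers(2, 8))
            arr = rng.normal(size=(n, k))
            corr = correlate(_frame(arr))
            for i in range(k):
                for j in range(i + 1, k):
                    r_ref, p_ref = textbook_pearson(arr[:, i], arr[:, j])
                    assert corr.r.iloc[i, j] == pytest.approx(r_ref, abs=1e-12)
                    assert corr.p.iloc[i, j] == pytest.approx(p_ref, abs=1e-12)

    def test_hand_picked_binary_vectors(self):
        x = np.array([1, 0, 1, 0, 1], dtype=float)
        y = np.array([1, 0, 0, 0, 1], dtype=float)
        corr = correlate(_frame(np.column_stack([x, y])))
        r_ref, p_ref = textbook_pearson(x, y)
        assert corr.r.iloc[0, 1] == pytest.approx(r_ref, abs=1e-12)
        assert corr.p.iloc[0, 1] == pytest.approx(p_ref, abs=1e-12)

    def test_identical_columns_give_r_one(self):
        x = np.array([0.1, 0.9, 0.4, 0.7])
        corr = correlate(_frame(np.column_stack([x, x])))
        assert corr.r.iloc[0, 1] == pytest.approx(1.0)
        assert corr.p.iloc[0, 1] == pytest.approx(0.0)

    def test_binary_complement_gives_r_minus_one(self):
        # the two levels of a one-hot trait are exact complements
        x = np.array([1.0, 0.0, 1.0, 0.0, 0.0])
        corr = correlate(_frame(np.column_stack([x, 1 - x])))
        assert corr.r.iloc[0, 1] == pytest.approx(-1.0)

    def test_phi_coefficient_equivalence_on_binary_columns(self, rng):
        """On 0/1 columns Pearson r equals the phi coefficient
        (ad - bc) / sqrt((a+b)(c+d)(a+c)(b+d)) from the 2x2 table."""
        for _ in range(20):
            x = rng.integers(0, 2, size=40).astype(float)
            y = (x * (rng.random(40) < 0.7) + (1 - x) * (rng.random(40) < 0.3))
            if x.std() == 0 or y.std() == 0:
                continue
            a = np.sum((x == 1) & (y == 1))
            b = np.sum((x == 1) & (y == 0))
            c = np.sum((x == 0) & (y == 1))
            d = np.sum((x == 0) & (y == 0))
            phi = (a * d - b * c) / np.sqrt((a + b) * (c + d) * (a + c) * (b + d))
            corr = correlate(_frame(np.column_stack([x, y])))
            assert corr.r.iloc[0, 1] == pytest.approx(phi, abs=1e-12)

    def test_constant_columns_dropped_with_warning(self, rng):
        arr = rng.normal(size=(10, 3))
        arr[:, 1] = 0.5
        with pytest.warns(UserWarning, match="constant"):
            corr = correlate(_frame(arr))
        assert corr.r.shape == (2, 2)
        assert ("t", "c1") in corr.dropped

    def test_too_few_observations_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 3"):
            correlate(_frame(rng.normal(size=(2, 4))))

    def test_all_constant_rejected(self):
        with pytest.raises(ValueError):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                correlate(_frame(np.ones((5, 3))))

    def test_row_permutation_leaves_correlation_unchanged(self, rng):
        arr = rng.normal(size=(15, 5))
        c1 = correlate(_frame(arr))
        c2 = correlate(_frame(arr[rng.permutation(15)]))
        np.testing.assert_allclose(c1.r.to_numpy(), c2.r.to_numpy(), atol=1e-12)


def _corr_from(r_pairs, p_pairs, k, traits=None):
    r = np.eye(k)
    p = np.zeros((k, k))
    for (i, j), val in r_pairs.items():
        r[i, j] = r[j, i] = val
    for (i, j), val in p_pairs.items():
        p[i, j] = p[j, i] = val
    if traits is None:
        traits = ["t"] * k
    cols = pd.MultiIndex.from_tuples(
        [(traits[j], f"c{j}") for j in range(k)], names=["trait", "level"])
    return TraitCorrelation(r=pd.DataFrame(r, index=cols, columns=cols),
                            p=pd.DataFrame(p, index=cols, columns=cols), n_obs=20)


class TestThresholdAdjacency:
    def test_default_rule_requires_both_p_and_r(self):
        # (r, p) = (0.25, 0.01) passes; (0.15, 0.001) fails r*; (0.6, 0.2) fails alpha
        corr = _corr_from(
            {(0, 1): 0.25, (0, 2): 0.15, (1, 2): 0.6},
            {(0, 1): 0.01, (0, 2): 0.001, (1, 2): 0.2}, 3)
        A = threshold_adjacency(corr)
        expected = np.zeros((3, 3))
        expected[0, 1] = expected[1, 0] = 1
        np.testing.assert_array_equal(A.to_numpy(), expected)

    def test_nothing_significant_gives_empty_adjacency(self):
        corr = _corr_from({(0, 1): 0.9}, {(0, 1): 0.5}, 2)
        assert threshold_adjacency(corr).to_numpy().sum() == 0

    def test_no_filtering_gives_complete_graph(self):
        corr = _corr_from({(0, 1): 0.01, (0, 2): 0.0, (1, 2): 0.5},
                          {(0, 1): 0.99, (0, 2): 0.99, (1, 2): 0.99}, 3)
        A = threshold_adjacency(corr, r_star=0.0, alpha=0.999999)
        assert np.triu(A.to_numpy(), 1).sum() == 3

    def test_monotone_in_threshold_and_alpha(self, rng):
        arr = rng.normal(size=(25, 6))
        arr[:, 1] += arr[:, 0]
        corr = correlate(_frame(arr))
        base = threshold_adjacency(corr, r_star=0.2, alpha=0.05).to_numpy()
        tighter_r = threshold_adjacency(corr, r_star=0.4, alpha=0.05).to_numpy()
        tighter_a = threshold_adjacency(corr, r_star=0.2, alpha=0.01).to_numpy()
        assert ((tighter_r == 1) <= (base == 1)).all()
        assert ((tighter_a == 1) <= (base == 1)).all()

    def test_positive_only_excludes_negative_correlations(self):
        corr = _corr_from({(0, 1): -0.9}, {(0, 1): 0.001}, 2)
        assert threshold_adjacency(corr, signed="abs").iloc[0, 1] == 1
        assert threshold_adjacency(corr, signed="positive_only").iloc[0, 1] == 0

    def test_within_trait_switch_removes_same_trait_edges(self):
        corr = _corr_from({(0, 1): -0.9, (0, 2): 0.9}, {(0, 1): 0.001, (0, 2): 0.001},
                          3, traits=["size", "size", "diet"])
        A_incl = threshold_adjacency(corr, within_trait=True)
        A_excl = threshold_adjacency(corr, within_trait=False)
        assert A_incl.iloc[0, 1] == 1 and A_excl.iloc[0, 1] == 0
        assert A_incl.iloc[0, 2] == 1 and A_excl.iloc[0, 2] == 1

    def test_bh_adjustment_is_more_conservative(self):
        corr = _corr_from(
            {(0, 1): 0.5, (0, 2): 0.5, (1, 2): 0.5},
            {(0, 1): 0.02, (0, 2): 0.2, (1, 2): 0.2}, 3)
        assert np.triu(threshold_adjacency(corr).to_numpy(), 1).sum() == 1
        # smallest p adjusts to 0.02 * 3/1 = 0.06 > alpha: no edges survive
        assert threshold_adjacency(corr, p_adjust="bh").to_numpy().sum() == 0

    def test_parameter_ranges_validated(self):
        corr = _corr_from({}, {}, 2)
        with pytest.raises(ValueError):
            threshold_adjacency(corr, r_star=1.5)
        with pytest.raises(ValueError):
            threshold_adjacency(corr, alpha=0.0)


class TestBuildNetwork:
    def test_isolated_nodes_retained(self):
        corr = _corr_from({}, {}, 5)
        A = threshold_adjacency(corr)
        G = build_network(A, corr)
        assert G.number_of_nodes() == 5
        assert G.number_of_edges() == 0

    def test_complete_adjacency_handshake_count(self):
        k = 6
        corr = _corr_from({(i, j): 0.9 for i in range(k) for j in range(i + 1, k)},
                          {(i, j): 0.0 for i in range(k) for j in range(i + 1, k)}, k)
        G = build_network(threshold_adjacency(corr), corr)
        assert G.number_of_edges() == k * (k - 1) // 2

    def test_edge_attributes_carry_r_p_sign(self):
        corr = _corr_from({(0, 1): -0.8}, {(0, 1): 0.001}, 2)
        G = build_network(threshold_adjacency(corr), corr)
        d = G.edges[("t:c0", "t:c1")]
        assert d["r"] == pytest.approx(-0.8)
        assert d["sign"] == -1

    def test_dimension_mismatch_rejected(self):
        corr3 = _corr_from({}, {}, 3)
        corr2 = _corr_from({}, {}, 2)
        A = threshold_adjacency(corr3)
        with pytest.raises(ValueError, match="different trait values"):
            build_network(A, corr2)

    def test_nodes_annotated_with_parent_trait(self):
        corr = _corr_from({(0, 1): 0.9}, {(0, 1): 0.0}, 2, traits=["size", "diet"])
        G = build_network(threshold_adjacency(corr), corr)
        assert G.nodes["size:c0"]["trait"] == "size"

    def test_column_shuffle_breaks_association(self, rng):
        """Permuting one column's entries destroys its planted edges."""
        n = 60
        x = rng.normal(size=n)
        arr = np.column_stack([x, x + 0.1 * rng.normal(size=n), rng.normal(size=n)])
        G = build_trait_network(_frame(arr))
        assert G.has_edge("t:c0", "t:c1")
        arr2 = arr.copy()
        arr2[:, 1] = arr2[rng.permutation(n), 1]
        G2 = build_trait_network(_frame(arr2))
        assert not G2.has_edge("t:c0", "t:c1")


def test_exports_round_trip(tmp_path, rng):
    arr = rng.normal(size=(20, 4))
    arr[:, 1] = arr[:, 0] + 0.1 * rng.normal(size=20)
    G = build_trait_network(_frame(arr))
    write_graphml(G, tmp_path / "net.graphml")
    back = nx.read_graphml(tmp_path / "net.graphml")
    assert set(back.nodes) == set(G.nodes)
    assert back.number_of_edges() == G.number_of_edges()
    write_edge_list(G, tmp_path / "edges.tsv")
    lines = (tmp_path / "edges.tsv").read_text().splitlines()
    assert lines[0] == "node_a\tnode_b\tr\tp"
    assert len(lines) == 1 + G.number_of_edges()
    write_node_table(G, tmp_path / "nodes.csv")
    tab = pd.read_csv(tmp_path / "nodes.csv")
    assert set(tab["trait_value"]) == set(G.nodes)
    assert tab["degree"].sum() == 2 * G.number_of_edges()
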