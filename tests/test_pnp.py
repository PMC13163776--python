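"""Network-matrix assembly, SVD projection and core extraction."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import gwgen
from gwgen.network import make_node_table
from gwgen.pnp import (
    assemble_network_matrix,
    decompose,
    extract_core,
    node_projection_values,
    projection_values,
    select_rank,
)
from gwgen.sysid import NodeModel, RealGWGEN


def _real_net(models: dict, node_classes: dict, edges=None):
    nodes = make_node_table([(n, c) for n, c in sorted(node_classes.items())])
    edf = pd.DataFrame(edges or [], columns=["source", "target", "edge_class", "weight"])
    return RealGWGEN(nodes=nodes, edges=edf, models=models, stage="q")


def _model(nid, mc, coefs, terms):
    return NodeModel(node_id=nid, model_class=mc, coefficients=coefs, terms=terms)


class TestAssemble:
    def test_single_tf_gene_edge_single_entry(self):
        net = _real_net(
            {("G1", "GRN"): _model("G1", "GRN", {"T1": 1.5}, {"T1": "linear"})},
            {"G1": "protein", "T1": "TF"})
        M = assemble_network_matrix(net)
        assert M.shape == (1, 1)
        assert M.matrix[0, 0] == 1.5
        assert M.row_index == [("G1", "GRN")]
        assert M.col_index == [("T1", "O")]

    def test_block_shape_arithmetic(self):
        # 3 PPI rows + 2 gene rows + 1 lncRNA row + 1 miRNA row;
        # 2 protein-type regulators + 1 lncRNA + 1 miRNA regulator -> 7 x 4
        classes = {"P1": "protein", "P2": "protein", "P3": "protein",
                   "G1": "protein", "G2": "protein", "H1": "lncRNA",
                   "Z1": "miRNA", "O1": "TF", "O2": "protein",
                   "U1": "lncRNA", "R1": "miRNA"}
        models = {
            ("P1", "PPIN"): _model("P1", "PPIN", {"O2": 0.1}, {"O2": "ppi"}),
            ("P2", "PPIN"): _model("P2", "PPIN", {"O2": 0.2}, {"O2": "ppi"}),
            ("P3", "PPIN"): _model("P3", "PPIN", {"O1": 0.3}, {"O1": "ppi"}),
            ("G1", "GRN"): _model("G1", "GRN", {"O1": 1.0, "U1": 0.5},
                                  {"O1": "linear", "U1": "linear"}),
            ("G2", "GRN"): _model("G2", "GRN", {"R1": 0.04}, {"R1": "repression"}),
            ("H1", "LRN"): _model("H1", "LRN", {"O1": -0.7}, {"O1": "linear"}),
            ("Z1", "MRN"): _model("Z1", "MRN", {"O1": 0.9}, {"O1": "linear"}),
        }
        M = assemble_network_matrix(_real_net(models, classes))
        assert M.shape == (7, 4)
        # repression ability enters with negative sign
        i = M.row_index.index(("G2", "GRN"))
        j = M.col_index.index(("R1", "R"))
        assert M.matrix[i, j] == -0.04
        # absent interactions are exact zeros
        assert (M.matrix == 0).sum() >= 7 * 4 - 8

    def test_pruned_edge_is_exact_zero(self):
        # regulator retained for one gene but not the other: the other's entry is 0
        models = {
            ("G1", "GRN"): _model("G1", "GRN", {"T1": 2.0}, {"T1": "linear"}),
            ("G2", "GRN"): _model("G2", "GRN", {"T2": 1.0}, {"T2": "linear"}),
        }
        M = assemble_network_matrix(_real_net(
            models, {"G1": "protein", "G2": "protein", "T1": "TF", "T2": "TF"}))
        i = M.row_index.index(("G1", "GRN"))
        j = M.col_index.index(("T2", "O"))
        assert M.matrix[i, j] == 0.0


class TestDecompose:
    def test_diagonal_singular_values_and_energy(self):
        _, d, _, e = decompose(np.diag([4.0, 3.0]))
        assert np.allclose(d, [4.0, 3.0])
        assert np.allclose(e, [0.64, 0.36])

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(0)
        m = rng.normal(size=(6, 4))
        _, d1, _, _ = decompose(m)
        _, d2, _, _ = decompose(m[rng.permutation(6)])
        assert np.allclose(d1, d2)

    def test_reconstruction_accuracy(self):
        rng = np.random.default_rng(1)
        m = rng.normal(size=(8, 5))
        u, d, v, _ = decompose(m)
        assert np.linalg.norm(u @ np.diag(d) @ v.T - m) / np.linalg.norm(m) < 1e-10

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            decompose(np.zeros((3, 3)))


class TestSelectRank:
    @pytest.mark.parametrize("e,thr,k", [
        ([0.64, 0.36], 0.85, 2),
        ([0.9, 0.1], 0.85, 1),
        ([0.5, 0.3, 0.2], 1.0, 3),
    ])
    def test_examples(self, e, thr, k):
        assert select_rank(np.array(e), thr) == k

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            select_rank(np.array([1.0]), 0.0)
        with pytest.raises(ValueError):
            select_rank(np.array([1.0]), 1.5)


class TestProjectionValues:
    def test_full_rank_projection_equals_row_norms(self):
        m = np.array([[3.0, 4.0], [1.0, 0.0]])
        _, _, v, _ = decompose(m)
        _, dvals = projection_values(m, v, 2)
        assert np.allclose(dvals, [5.0, 1.0])

    def test_rank_one_matrix_hand_svd(self):
        m = np.outer([1.0, 2.0], [1.0, 0.0])
        _, _, v, _ = decompose(m)
        _, dvals = projection_values(m, v, 1)
        assert np.allclose(dvals, [1.0, 2.0])

    def test_zero_row_projects_to_zero(self):
        m = np.array([[1.0, 2.0], [0.0, 0.0]])
        _, _, v, _ = decompose(m)
        _, dvals = projection_values(m, v, 2)
        assert dvals[1] == 0.0

    def test_k_out_of_range(self):
        m = np.eye(3)
        _, _, v, _ = decompose(m)
        with pytest.raises(ValueError):
            projection_values(m, v, 4)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_invariants_random_matrices(self, seed):
        """Energy sums to 1, D non-decreasing in K, scale equivariance."""
        rng = np.random.default_rng(seed)
        m = rng.normal(size=(rng.integers(2, 9), rng.integers(2, 6)))
        _, d, v, e = decompose(m)
        assert np.isclose(e.sum(), 1.0, atol=1e-10)
        assert np.isclose((d ** 2).sum(), np.linalg.norm(m, "fro") ** 2)
        assert (e[:-1] >= e[1:] - 1e-12).all()
        prev = np.zeros(m.shape[0])
        for k in range(1, v.shape[1] + 1):
            _, dv = projection_values(m, v, k)
            assert (dv >= prev - 1e-10).all()
            prev = dv
        assert np.allclose(prev, np.linalg.norm(m, axis=1), atol=1e-10)
        # scale equivariance
        c = 2.5
        _, d2, v2, e2 = decompose(c * m)
        assert np.allclose(e2, e, atol=1e-10)
        k = select_rank(e, 0.85)
        assert select_rank(e2, 0.85) == k
        _, dv1 = projection_values(m, v, k)
        _, dv2 = projection_values(c * m, v2, k)
        assert np.allclose(dv2, c * dv1, atol=1e-8)


class TestExtractCore:
    def _net(self):
        classes = {"A": "protein", "B": "protein", "C": "protein"}
        edges = [("A", "B", "PPI", 1.0)]
        return _real_net({}, classes, edges)

    def test_top_n_and_connectivity(self):
        vals = pd.Series({"A": 5.0, "B": 3.0, "C": 1.0})
        core = extract_core(self._net(), vals, top_n=2)
        assert core.nodes == ["A", "B"]

    def test_isolated_high_projection_node_dropped(self):
        vals = pd.Series({"A": 5.0, "B": 3.0, "C": 1.0})
        core = extract_core(self._net(), vals, top_n=3)
        assert "C" not in core.nodes
        assert core.dropped_isolated == ["C"]

    def test_tie_broken_by_node_id(self):
        vals = pd.Series({"A": 5.0, "B": 2.0, "C": 2.0})
        core = extract_core(self._net(), vals, top_n=2)
        # B wins the tie by id; it is connected to A
        assert core.nodes == ["A", "B"]

    def test_top_n_clamped_with_warning(self):
        vals = pd.Series({"A": 5.0, "B": 3.0, "C": 1.0})
        with pytest.warns(UserWarning, match="clamped"):
            extract_core(self._net(), vals, top_n=10)

    def test_monotone_before_connectivity_filter(self):
        vals = pd.Series({"A": 5.0, "B": 3.0, "C": 1.0})
        small = extract_core(self._net(), vals, top_n=1)
        big = extract_core(self._net(), vals, top_n=2)
        assert set(small.nodes) | set(small.dropped_isolated) <= \
            set(big.nodes) | set(big.dropped_isolated)


def test_pipeline_on_identified_network(small_real):
    """End-to-end PNP on an identified synthetic network."""
    res = gwgen.pnp(small_real)
    assert np.isclose(res.energy_fractions.sum(), 1.0, atol=1e-10)
    cum = np.cumsum(res.energy_fractions)
    assert cum[res.K - 1] >= 0.85 - 1e-12
    if res.K > 1:
        assert cum[res.K - 2] < 0.85
    # node aggregation covers every row node
    M = assemble_network_matrix(small_real)
    vals = node_projection_values(M, res.projection_values)
    assert set(vals.index) == {nid for nid, _ in M.row_index}
    core = extract_core(small_real, res.node_values, top_n=min(20, len(res.node_values)))
    assert all(res.node_values[n] >= 0 for n in core.nodes)
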