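"""Principal network projection (PNP) core-network extraction.

The estimated coefficients of an identified GWGEN are assembled into one
integrated network matrix M with a row per fitted model instance (protein
interaction rows, then gene, lncRNA and miRNA regulatory rows) and a column
per regulator (protein-type regulators O, lncRNA regulators U, miRNA
regulators R); pruned or absent interactions are zeros.  A singular value
decomposition M = U D V^T yields eigenexpression fractions
E_i = d_i^2 / sum d^2; the minimal rank K with cumulative fraction >= 85%
defines the principal subspace.  Each row's projection onto the top-K right
singular vectors gives its 2-norm projection value D(s); node-level values
aggregate a node's rows in the Euclidean sense.  The core network is the
subgraph induced by the top-ranked nodes after dropping isolated nodes, so
that only nodes on coherent regulatory paths are retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import PROTEIN_TYPE, induced_edges
from .sysid import RealGWGEN

ROW_BLOCK_ORDER = ("PPIN", "GRN", "LRN", "MRN")
COL_BLOCK_ORDER = ("O", "U", "R")
_COL_BLOCK_OF_CLASS = {"TF": "O", "receptor": "O", "protein": "O",
                       "lncRNA": "U", "miRNA": "R"}


@dataclass
class NetworkMatrix:
    """The integrated coefficient matrix of an identified network.

    Rows are (node_id, model_class) pairs ordered by model-class block;
    columns are (node_id, column_block) pairs with protein-type regulators
    first (block O), then lncRNA (U), then miRNA (R) regulators.  Repression
    abilities enter with a negative sign so entries carry the signed
    regulatory effect of the model equations.
    """

    matrix: np.ndarray
    row_index: list        # (node_id, model_class)
    col_index: list        # (node_id, block)
    block_map: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def row_nodes(self) -> list[str]:
        return [nid for nid, _ in self.row_index]


@dataclass
class PNPResult:
    """SVD spectrum, energy fractions, selected rank and projection values."""

    singular_values: np.ndarray
    left_vectors: np.ndarray
    right_vectors: np.ndarray
    energy_fractions: np.ndarray
    K: int
    projections: np.ndarray          # rows x K, V(s, i)
    projection_values: np.ndarray    # per-row D(s)
    row_index: list
    node_values: pd.Series           # node-level D, aggregated over rows
    ranking: list                    # node ids by descending D (id tie-break)


@dataclass
class CoreNetwork:
    """Top-projection nodes with their induced, connectivity-filtered edges."""

    nodes: list
    edges: pd.DataFrame
    projection_values: pd.Series
    dropped_isolated: list


# ---------------------------------------------------------------------------


def assemble_network_matrix(real_net: RealGWGEN) -> NetworkMatrix:
    """Place every surviving coefficient at (target-model row, regulator column)."""
    node_class = dict(zip(real_net.nodes["node_id"], real_net.nodes["node_class"]))

    rows = [key for key, model in real_net.models.items() if model.coefficients]
    rows.sort(key=lambda rm: (ROW_BLOCK_ORDER.index(rm[1]), rm[0]))

    regulators: set[tuple[str, str]] = set()
    for (nid, mc) in rows:
        for reg in real_net.models[(nid, mc)].coefficients:
            cls = node_class.get(reg)
            if cls is None:
                raise ValueError(f"regulator {reg!r} has no node-class annotation")
            regulators.add((reg, _COL_BLOCK_OF_CLASS[cls]))
    cols = sorted(regulators, key=lambda rb: (COL_BLOCK_ORDER.index(rb[1]), rb[0]))
    col_pos = {rb: j for j, rb in enumerate(cols)}

    m = np.zeros((len(rows), len(cols)))
    for i, (nid, mc) in enumerate(rows):
        model = real_net.models[(nid, mc)]
        for reg, ability in model.coefficients.items():
            block = _COL_BLOCK_OF_CLASS[node_class[reg]]
            signed = -ability if model.terms[reg] == "repression" else ability
            m[i, col_pos[(reg, block)]] = signed

    block_map = {"rows": {mc: [i for i, (_, m_) in enumerate(rows) if m_ == mc]
                          for mc in ROW_BLOCK_ORDER},
                 "cols": {b: [j for j, (_, b_) in enumerate(cols) if b_ == b]
                          for b in COL_BLOCK_ORDER}}
    return NetworkMatrix(matrix=m, row_index=rows, col_index=cols, block_map=block_map)


def decompose(M: NetworkMatrix | np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Thin SVD with descending singular values and a canonical sign convention
    (the largest-magnitude component of each right singular vector is positive).

    Returns (U, d, V, E) with M = U diag(d) V^T and eigenexpression fractions
    E_i = d_i^2 / sum_j d_j^2.
    """
    mat = M.matrix if isinstance(M, NetworkMatrix) else np.asarray(M, dtype=float)
    if not np.isfinite(mat).all():
        raise ValueError("network matrix contains non-finite entries")
    if not mat.any():
        raise ValueError("degenerate network matrix (all zero)")
    u, d, vt = np.linalg.svd(mat, full_matrices=False)
    v = vt.T
    for i in range(v.shape[1]):
        j = int(np.argmax(np.abs(v[:, i])))
        if v[j, i] < 0:
            v[:, i] *= -1
            u[:, i] *= -1
    energy = d ** 2
    e = energy / energy.sum()
    return u, d, v, e


def select_rank(energy_fractions: np.ndarray, threshold: float = 0.85) -> int:
    """Smallest K whose cumulative eigenexpression fraction reaches the threshold."""
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0, 1]")
    e = np.asarray(energy_fractions, dtype=float)
    if abs(e.sum() - 1.0) > 1e-8:
        raise ValueError("energy fractions must sum to 1")
    cum = np.cumsum(e)
    # tolerate float round-off at the top of the spectrum
    hits = np.nonzero(cum >= threshold - 1e-12)[0]
    return int(hits[0]) + 1 if len(hits) else len(e)


def projection_values(M: NetworkMatrix | np.ndarray, V: np.ndarray,
                      K: int) -> tuple[np.ndarray, np.ndarray]:
    """Row projections onto the top-K right singular vectors and their 2-norms.

    V(s, i) is the inner product of row s with the i-th right singular vector;
    D(s) is the Euclidean norm of (V(s,1), ..., V(s,K)).
    """
    mat = M.matrix if isinstance(M, NetworkMatrix) else np.asarray(M, dtype=float)
    if not (1 <= K <= V.shape[1]):
        raise ValueError(f"K={K} outside 1..{V.shape[1]}")
    proj = mat @ V[:, :K]
    return proj, np.linalg.norm(proj, axis=1)


def node_projection_values(M: NetworkMatrix, d_rows: np.ndarray) -> pd.Series:
    """Aggregate row-level projection values per node (Euclidean over rows)."""
    acc: dict[str, float] = {}
    for (nid, _), dv in zip(M.row_index, d_rows):
        acc[nid] = acc.get(nid, 0.0) + float(dv) ** 2
    s = pd.Series({k: np.sqrt(v) for k, v in acc.items()}, name="projection_value")
    s.index.name = "node_id"
    return s


def pnp(real_net: RealGWGEN, threshold: float = 0.85) -> PNPResult:
    """Full principal network projection of an identified network."""
    M = assemble_network_matrix(real_net)
    u, d, v, e = decompose(M)
    K = select_rank(e, threshold)
    proj, d_rows = projection_values(M, v, K)
    node_vals = node_projection_values(M, d_rows)
    ranking = sorted(node_vals.index, key=lambda n: (-node_vals[n], n))
    return PNPResult(singular_values=d, left_vectors=u, right_vectors=v,
                     energy_fractions=e, K=K, projections=proj,
                     projection_values=d_rows, row_index=M.row_index,
                     node_values=node_vals, ranking=ranking)


def extract_core(real_net: RealGWGEN, node_values: pd.Series,
                 top_n: int = 3000) -> CoreNetwork:
    """Top-n nodes by projection value, connectivity-filtered.

    Ties break by node id (stable across runs); nodes isolated in the induced
    subgraph are dropped, keeping only nodes on coherent regulatory paths.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if top_n > len(node_values):
        warnings.warn(f"top_n={top_n} exceeds {len(node_values)} scored nodes; clamped")
        top_n = len(node_values)
    ranked = sorted(node_values.index, key=lambda n: (-node_values[n], n))
    selected = ranked[:top_n]
    edges = induced_edges(real_net.edges, set(selected))
    touched = set(edges["source"]) | set(edges["target"])
    kept = [n for n in selected if n in touched]
    dropped = [n for n in selected if n not in touched]
    return CoreNetwork(nodes=kept,
                       edges=edges,
                       projection_values=node_values[kept],
                       dropped_isolated=dropped)


def receptor_tf_gene_paths(core: CoreNetwork, node_table: pd.DataFrame,
                           max_paths: int = 100) -> list[list[str]]:
    """Enumerate receptor -> ... -> TF -> gene directed paths in a core network."""
    import networkx as nx

    cls = dict(zip(node_table["node_id"], node_table["node_class"]))
    g = nx.DiGraph()
    for r in core.edges.itertuples(index=False):
        if r.edge_class == "PPI":
            g.add_edge(r.source, r.target)
            g.add_edge(r.target, r.source)
        else:
            g.add_edge(r.source, r.target)
    receptors = [n for n in core.nodes if cls.get(n) == "receptor"]
    genes = [n for n in core.nodes if cls.get(n) == "protein"]
    out = []
    for rec in receptors:
        for gene in genes:
            if rec == gene or not (g.has_node(rec) and g.has_node(gene)):
                continue
            try:
                path = nx.shortest_path(g, rec, gene)
            except nx.NetworkXNoPath:
                continue
            if any(cls.get(n) == "TF" for n in path[1:-1]):
                out.append(path)
                if len(out) >= max_paths:
                    return out
    return out
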