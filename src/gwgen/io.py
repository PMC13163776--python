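"""Readers, writers and preprocessing for GWGEN artifacts.

All on-disk formats are plain TSV (plus SIF / GraphML network exports for
Cytoscape-compatible viewing).  Expression matrices are assumed to arrive
already normalized (RMA-scale, log2-like values); the only preprocessing
performed here is probe-to-gene aggregation and gene-synonym unification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .network import (
    EDGE_CLASSES,
    EDGE_COLUMNS,
    CandidateNetwork,
    canonical_ppi,
    edge_class_valid,
    make_node_table,
)

# ---------------------------------------------------------------------------
# expression data


@dataclass
class ExpressionDataset:
    """A node x sample expression matrix with a disease-stage label per sample."""

    values: pd.DataFrame          # rows: node ids, columns: sample ids
    stages: pd.Series             # sample id -> stage label

    def __post_init__(self) -> None:
        self.stages = pd.Series(self.stages, index=self.values.columns, dtype=str)
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def stage_counts(self) -> pd.Series:
        return self.stages.value_counts()

    def subset_stage(self, stage: str) -> "ExpressionDataset":
        cols = self.stages[self.stages == stage].index
        if len(cols) == 0:
            raise ValueError(f"no samples with stage {stage!r}")
        return ExpressionDataset(self.values[cols], self.stages[cols])

    def concat(self, other: "ExpressionDataset") -> "ExpressionDataset":
        return ExpressionDataset(
            pd.concat([self.values, other.values], axis=1),
            pd.concat([self.stages, other.stages]),
        )


def write_expression(ds: ExpressionDataset, path: str | Path) -> None:
    """Write as TSV; a leading comment line carries the per-sample stage labels."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# stage\t" + "\t".join(ds.stages.astype(str)) + "\n")
        ds.values.to_csv(fh, sep="\t", index_label="node_id")


def read_expression(path: str | Path) -> ExpressionDataset:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# stage"):
            raise ValueError(f"{path}: missing '# stage' header line")
        stages = first.rstrip("\n").split("\t")[1:]
        values = pd.read_csv(fh, sep="\t", index_col="node_id")
    return ExpressionDataset(values, pd.Series(stages, index=values.columns))


def preprocess_expression(
    raw_matrix: pd.DataFrame,
    probe_map: dict[str, str],
    synonym_map: dict[str, str] | None = None,
    stages: pd.Series | None = None,
) -> ExpressionDataset:
    """Aggregate a probe x sample matrix to unique gene symbols.

    Probes absent from ``probe_map`` (no unique gene annotation) are dropped.
    Symbols are uppercased/stripped, synonymous symbols are unified to their
    canonical id, and per-gene values are arithmetic means over all of that
    gene's probes.  No log transform or centering is applied: the input is
    assumed to be an already-normalized expression matrix.
    """
    synonym_map = synonym_map or {}
    canon_syn = {str(k).strip().upper(): str(v).strip().upper() for k, v in synonym_map.items()}

    keep = [p for p in raw_matrix.index if p in probe_map]
    mat = raw_matrix.loc[keep]
    symbols = [str(probe_map[p]).strip().upper() for p in keep]
    symbols = [canon_syn.get(s, s) for s in symbols]
    agg = mat.groupby(pd.Index(symbols, name="node_id")).mean()
    if stages is None:
        stages = pd.Series("", index=agg.columns)
    return ExpressionDataset(agg, stages)


# ---------------------------------------------------------------------------
# candidate networks


def write_candidate_network(net: CandidateNetwork, edge_path: str | Path,
                            node_path: str | Path) -> None:
    net.edges[EDGE_COLUMNS].to_csv(edge_path, sep="\t", index=False)
    nodes = net.nodes.copy()
    nodes["function_tags"] = [";".join(t) for t in nodes["function_tags"]]
    nodes[["node_id", "node_class", "function_tags"]].to_csv(node_path, sep="\t", index=False)


def read_candidate_network(edge_path: str | Path, node_path: str | Path) -> CandidateNetwork:
    """Read and validate a candidate network from edge and node TSV files.

    Duplicate edges are collapsed and PPIs canonicalized; edges whose class is
    inconsistent with the endpoint node classes are rejected and reported via
    a warning.  Unknown edge-class tokens and dangling endpoints are errors.
    """
    ndf = pd.read_csv(node_path, sep="\t", dtype=str).fillna("")
    records = [
        (r.node_id, r.node_class,
         [t for t in str(getattr(r, "function_tags", "")).split(";") if t])
        for r in ndf.itertuples(index=False)
    ]
    nodes = make_node_table(records)

    edf = pd.read_csv(edge_path, sep="\t", dtype=str).fillna("")
    if "provenance" not in edf.columns:
        edf["provenance"] = ""
    known = set(nodes["node_id"])
    kept, rejected = [], []
    for lineno, row in enumerate(edf.itertuples(index=False), start=2):
        ec = row.edge_class
        if ec not in EDGE_CLASSES:
            raise ValueError(f"{edge_path}: line {lineno}: unknown edge class {ec!r}")
        if row.source not in known or row.target not in known:
            missing = row.source if row.source not in known else row.target
            raise ValueError(f"{edge_path}: line {lineno}: dangling endpoint {missing!r}")
        sc = nodes.at[row.source, "node_class"]
        tc = nodes.at[row.target, "node_class"]
        if not edge_class_valid(ec, sc, tc):
            rejected.append((lineno, row.source, row.target, ec))
            continue
        kept.append((row.source, row.target, ec, row.provenance))
    if rejected:
        warnings.warn(
            f"{edge_path}: rejected {len(rejected)} class-inconsistent edge(s): "
            + "; ".join(f"line {ln}: {s}-{t} [{ec}]" for ln, s, t, ec in rejected[:10])
        )
    edges = pd.DataFrame(kept, columns=EDGE_COLUMNS)
    return CandidateNetwork(nodes, edges)


def write_sif(edges: pd.DataFrame, path: str | Path) -> None:
    """SIF export: one ``source<TAB>class<TAB>target`` line per edge."""
    with open(path, "w") as fh:
        for row in edges.itertuples(index=False):
            fh.write(f"{row.source}\t{row.edge_class}\t{row.target}\n")


def write_graphml(net, path: str | Path) -> None:
    """GraphML export of a CandidateNetwork or RealGWGEN (via its graph view)."""
    g = net.to_graph()
    # GraphML cannot hold list attributes
    for _, data in g.nodes(data=True):
        data.pop("function_tags", None)
    nx.write_graphml(g, path)


# ---------------------------------------------------------------------------
# summary tables (layout mirrors the study's published count tables)

_NODE_ROW_ORDER = ["TF", "lncRNA", "miRNA", "receptor", "protein"]
_NODE_ROW_LABEL = {"TF": "TFs", "lncRNA": "lncRNAs", "miRNA": "miRNAs",
                   "receptor": "Receptors", "protein": "Proteins"}


def summarize_network(net) -> dict[str, pd.DataFrame]:
    """Node counts by class and edge counts by the 12 interaction classes.

    Accepts a CandidateNetwork or a RealGWGEN (anything with ``nodes`` and
    ``edges`` frames).  Totals equal the sum of the per-class counts.
    """
    node_counts = net.nodes["node_class"].value_counts()
    nrows = [(_NODE_ROW_LABEL[c], int(node_counts.get(c, 0))) for c in _NODE_ROW_ORDER]
    nrows.append(("Total nodes", int(sum(n for _, n in nrows))))
    ntab = pd.DataFrame(nrows, columns=["node_class", "count"])

    edge_counts = net.edges["edge_class"].value_counts()
    erows = [(c, int(edge_counts.get(c, 0))) for c in EDGE_CLASSES]
    erows.append(("Total edges", int(sum(n for _, n in erows))))
    etab = pd.DataFrame(erows, columns=["edge_class", "count"])
    return {"nodes": ntab, "edges": etab}


# ---------------------------------------------------------------------------
# packaged reference tables (transcriptions of the study's printed tables)


def _load_packaged(name: str) -> pd.DataFrame:
    with resources.files("gwgen").joinpath("data", name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_asthma_node_counts() -> pd.DataFrame:
    """Published node counts of the candidate and three stage-specific networks."""
    return _load_packaged("asthma_node_counts.tsv").set_index("node_class")


def load_asthma_edge_counts() -> pd.DataFrame:
    """Published edge counts by interaction class for candidate and real networks."""
    return _load_packaged("asthma_edge_counts.tsv").set_index("edge_class")


def load_asthma_signatures() -> pd.DataFrame:
    """Stage-specific biomarker expression signs (columns: stage, target, expression)."""
    return _load_packaged("asthma_signatures.tsv")


def load_asthma_drug_effects() -> pd.DataFrame:
    """Published per-drug signed effects on the stage biomarkers."""
    df = _load_packaged("asthma_drug_effects.tsv")
    df["effect"] = df["effect"].astype(str)
    return df


def load_asthma_final_calls() -> pd.DataFrame:
    """Published integrated (final) signs of the multi-drug combinations."""
    return _load_packaged("asthma_final_calls.tsv")


def sign_to_int(s: str) -> int:
    s = str(s).strip()
    if s in {"+", "+1", "1"}:
        return 1
    if s in {"-", "−", "-1"}:
        return -1
    if s in {"0", "", "nan"}:
        return 0
    raise ValueError(f"unrecognised sign token {s!r}")
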