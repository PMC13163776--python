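"""Typed network containers for candidate and identified GWGENs.

A genome-wide genetic and epigenetic network (GWGEN) integrates four layers
over five node classes (transcription factors, lncRNAs, miRNAs, receptors and
other proteins): protein-protein interactions (PPI, undirected), TF-mediated
transcriptional regulation (T-*), lncRNA-mediated regulation (L-*) and
miRNA-mediated post-transcriptional repression (M-*).  Twelve interaction
classes are recognised; each constrains the node classes of its endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

# The five node classes.
NODE_CLASSES = ("TF", "lncRNA", "miRNA", "receptor", "protein")

#: node classes whose products are proteins (valid PPI endpoints and, as
#: regulators, valid transcriptional sources when they are TFs)
PROTEIN_TYPE = frozenset({"TF", "receptor", "protein"})

#: the twelve interaction classes: directed classes map to
#: (source node class, allowed target node classes); PPI is undirected.
EDGE_CLASSES = (
    "T-G", "T-T", "T-R", "T-L", "T-M",
    "L-G", "L-T",
    "M-G", "M-T", "M-R", "M-L",
    "PPI",
)

_DIRECTED_RULES: dict[str, tuple[str, frozenset[str]]] = {
    "T-G": ("TF", frozenset({"protein"})),
    "T-T": ("TF", frozenset({"TF"})),
    "T-R": ("TF", frozenset({"receptor"})),
    "T-L": ("TF", frozenset({"lncRNA"})),
    "T-M": ("TF", frozenset({"miRNA"})),
    "L-G": ("lncRNA", frozenset({"protein"})),
    "L-T": ("lncRNA", frozenset({"TF"})),
    "M-G": ("miRNA", frozenset({"protein"})),
    "M-T": ("miRNA", frozenset({"TF"})),
    "M-R": ("miRNA", frozenset({"receptor"})),
    "M-L": ("miRNA", frozenset({"lncRNA"})),
}

#: directed regulation class implied by a (source class, target class) pair
CLASS_OF_PAIR = {
    (src, tgt): ec
    for ec, (src, tgts) in _DIRECTED_RULES.items()
    for tgt in tgts
}

#: miRNA-mediated classes enter the model equations as repression terms with a
#: non-negative ability coefficient (the term is subtracted).
REPRESSION_CLASSES = frozenset({"M-G", "M-T", "M-R", "M-L"})

EDGE_COLUMNS = ["source", "target", "edge_class", "provenance"]


def edge_class_valid(edge_class: str, source_class: str, target_class: str) -> bool:
    """True if an edge of ``edge_class`` may join the given node classes."""
    if edge_class == "PPI":
        return source_class in PROTEIN_TYPE and target_class in PROTEIN_TYPE
    if edge_class not in _DIRECTED_RULES:
        return False
    src, tgts = _DIRECTED_RULES[edge_class]
    return source_class == src and target_class in tgts


def canonical_ppi(source: str, target: str) -> tuple[str, str]:
    """Canonical (lexicographic) endpoint order for an undirected PPI edge."""
    return (source, target) if source <= target else (target, source)


def make_node_table(records) -> pd.DataFrame:
    """Build a validated node table from (node_id, node_class[, function_tags]) records.

    ``function_tags`` is a list of free-text annotations (e.g. "deubiquitination
    enzyme") used by the epigenetic-modification inference.
    """
    rows = []
    for rec in records:
        node_id, node_class = rec[0], rec[1]
        tags = list(rec[2]) if len(rec) > 2 and rec[2] else []
        rows.append((str(node_id).strip().upper(), node_class, tags))
    df = pd.DataFrame(rows, columns=["node_id", "node_class", "function_tags"])
    bad = set(df["node_class"]) - set(NODE_CLASSES)
    if bad:
        raise ValueError(f"unknown node classes: {sorted(bad)}")
    if df["node_id"].duplicated().any():
        dups = df.loc[df["node_id"].duplicated(), "node_id"].tolist()
        raise ValueError(f"duplicate node ids: {dups}")
    return df.set_index("node_id", drop=False)


@dataclass
class CandidateNetwork:
    """A candidate GWGEN: annotated nodes plus typed edges.

    Candidate networks mined from interaction databases are supersets of the
    biologically active network; the ``provenance`` edge column (``"truth"`` /
    ``"spurious"`` for synthetic networks, ``""`` otherwise) exists only so
    that recovery tests can score identification against a known ground truth.
    """

    nodes: pd.DataFrame
    edges: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=EDGE_COLUMNS))

    def __post_init__(self) -> None:
        e = self.edges.copy()
        if "provenance" not in e.columns:
            e["provenance"] = ""
        e = e[EDGE_COLUMNS].astype({"source": str, "target": str, "edge_class": str})
        # canonicalize undirected PPIs, then collapse duplicates
        is_ppi = e["edge_class"] == "PPI"
        if is_ppi.any():
            pairs = [canonical_ppi(s, t) for s, t in zip(e.loc[is_ppi, "source"], e.loc[is_ppi, "target"])]
            e.loc[is_ppi, ["source", "target"]] = pairs
        e = e.drop_duplicates(subset=["source", "target", "edge_class"], keep="first")
        self.edges = e.reset_index(drop=True)
        self.validate()

    # -- queries -------------------------------------------------------------

    def node_class(self, node_id: str) -> str:
        return self.nodes.at[node_id, "node_class"]

    @property
    def node_ids(self) -> list[str]:
        return list(self.nodes["node_id"])

    def ppi_partners(self, node_id: str) -> list[str]:
        e = self.edges
        ppi = e[e["edge_class"] == "PPI"]
        out = [t for s, t in zip(ppi["source"], ppi["target"]) if s == node_id]
        out += [s for s, t in zip(ppi["source"], ppi["target"]) if t == node_id]
        return sorted(set(out))

    def regulators_of(self, node_id: str) -> pd.DataFrame:
        """Directed candidate in-edges of ``node_id`` (excludes PPIs)."""
        e = self.edges
        return e[(e["target"] == node_id) & (e["edge_class"] != "PPI")]

    def validate(self) -> None:
        known = set(self.nodes["node_id"])
        for row in self.edges.itertuples(index=False):
            if row.edge_class not in EDGE_CLASSES:
                raise ValueError(f"unknown edge class {row.edge_class!r}")
            if row.source not in known or row.target not in known:
                missing = row.source if row.source not in known else row.target
                raise ValueError(f"dangling edge endpoint {missing!r}")
            sc, tc = self.node_class(row.source), self.node_class(row.target)
            if not edge_class_valid(row.edge_class, sc, tc):
                raise ValueError(
                    f"edge class {row.edge_class} inconsistent with endpoint "
                    f"classes {row.source}:{sc} -> {row.target}:{tc}"
                )

    def to_graph(self) -> nx.MultiDiGraph:
        """Directed multigraph view; PPIs appear as a single canonical arc tagged undirected."""
        g = nx.MultiDiGraph()
        for row in self.nodes.itertuples(index=False):
            g.add_node(row.node_id, node_class=row.node_class)
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.source, row.target, edge_class=row.edge_class,
                       undirected=row.edge_class == "PPI")
        return g


def induced_edges(edges: pd.DataFrame, keep: set[str]) -> pd.DataFrame:
    """Edges with both endpoints in ``keep``."""
    m = edges["source"].isin(keep) & edges["target"].isin(keep)
    return edges[m].reset_index(drop=True)
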