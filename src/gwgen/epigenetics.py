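"""Basal-level epigenetic modification calls.

The basal (intercept) term of each identified node model absorbs regulation
that the genetic interaction equations do not represent.  A node whose basal
magnitude exceeds a threshold is flagged as putatively epigenetically
modified; the kind of modification is then annotated from the network
context: a flagged protein interacting with a partner annotated as, e.g., a
deubiquitination enzyme is inferred to undergo (de)ubiquitination, while a
flagged gene is attributed to DNA methylation/demethylation.  These are
network-level associations, not biochemical measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

# enzyme-family keyword -> reported modification kind, in deterministic
# reporting order (a tag matches on substring, case-insensitive)
ENZYME_KINDS = (
    ("acetyl", "acetylation/deacetylation"),
    ("methyl", "methylation/demethylation"),
    ("phosphor", "phosphorylation/dephosphorylation"),
    ("ubiquitin", "ubiquitination/deubiquitination"),
)

GENE_KIND = "DNA methylation/demethylation"
UNSPECIFIED = "unspecified"


@dataclass
class ThresholdSpec:
    """Either a |basal| quantile within each model class, or an absolute cutoff."""

    quantile: float | None = 0.9
    absolute: float | None = None

    def cutoff(self, basals: np.ndarray) -> float:
        if self.absolute is not None:
            return float(self.absolute)
        return float(np.quantile(basals, self.quantile))


def call_modifications(real_net, node_table: pd.DataFrame,
                       threshold: ThresholdSpec | None = None) -> pd.DataFrame:
    """Flag nodes whose |basal| strictly exceeds the per-model-class threshold.

    ``real_net`` is an identified RealGWGEN (its models carry the basal
    estimates).  Returns one row per (node, model_class) with columns
    node_id, model_class, basal, threshold, flagged, inferred_kind.
    Thresholds are computed separately per model class, so protein-interaction
    basals and gene/ncRNA regulatory basals are judged against their own
    distributions.
    """
    threshold = threshold or ThresholdSpec()
    if not real_net.models:
        raise ValueError("no fitted models: empty basal table")

    frame = pd.DataFrame(
        [(nid, mc, m.basal) for (nid, mc), m in real_net.models.items()],
        columns=["node_id", "model_class", "basal"])

    tags = {r.node_id: list(r.function_tags) for r in node_table.itertuples(index=False)}
    neighbors = _ppi_neighbors(real_net.edges)

    rows = []
    for mc, grp in frame.groupby("model_class", sort=True):
        cut = threshold.cutoff(np.abs(grp["basal"].to_numpy()))
        for r in grp.itertuples(index=False):
            flagged = abs(r.basal) > cut
            kind = ""
            if flagged:
                if mc == "PPIN":
                    kind = _kind_from_neighbors(r.node_id, neighbors, tags)
                elif mc == "GRN":
                    kind = GENE_KIND
                else:
                    kind = UNSPECIFIED
            rows.append((r.node_id, mc, float(r.basal), cut, flagged, kind))
    out = pd.DataFrame(rows, columns=["node_id", "model_class", "basal",
                                      "threshold", "flagged", "inferred_kind"])
    return out.sort_values(["node_id", "model_class"]).reset_index(drop=True)


def _ppi_neighbors(edges: pd.DataFrame) -> dict[str, set]:
    nbrs: dict[str, set] = {}
    ppi = edges[edges["edge_class"] == "PPI"]
    for r in ppi.itertuples(index=False):
        nbrs.setdefault(r.source, set()).add(r.target)
        nbrs.setdefault(r.target, set()).add(r.source)
    return nbrs


def _kind_from_neighbors(node_id: str, neighbors: dict, tags: dict) -> str:
    kinds = []
    for nbr in sorted(neighbors.get(node_id, ())):
        for tag in tags.get(nbr, ()):
            low = tag.lower()
            for key, kind in ENZYME_KINDS:
                if key in low and "enzyme" in low and kind not in kinds:
                    kinds.append(kind)
    return "; ".join(sorted(kinds)) if kinds else UNSPECIFIED
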