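"""Constrained least-squares system identification with AIC order pruning.

Each node of a candidate GWGEN is fitted independently against one disease
stage's expression samples.  Four per-node regression model classes exist:

* ``PPIN`` — a protein's interaction equation; each candidate partner
  contributes a bilinear column ``target[n] * partner[n]``;
* ``GRN`` — a gene's regulatory equation; TF/protein and lncRNA regulators
  contribute plain columns, each candidate miRNA contributes a repression
  product column ``target[n] * mirna[n]`` whose fitted coefficient is
  constrained non-positive (the repression ability is non-negative);
* ``LRN`` / ``MRN`` — the analogous equations for lncRNA and miRNA targets.

Every model carries a trailing basal (intercept) column; its estimate is the
node's basal level, interpreted downstream as unmodeled (epigenetic)
regulation.  Model order is selected by minimizing

    AIC(Y) = ln(RSS / N) + 2 (Y + 1) / N

over nested models grown by forward stepwise selection (largest RSS drop
first, refitting under the sign constraints at every step); regulators outside
the minimizing order are pruned as false positives.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import lsq_linear

from .io import ExpressionDataset
from .network import (
    PROTEIN_TYPE,
    REPRESSION_CLASSES,
    CandidateNetwork,
    canonical_ppi,
)

logger = logging.getLogger(__name__)

_RSS_TOL = 1e-16      # relative to the squared response norm: "perfect fit"
_SOLVER_TOL = 1e-10

MODEL_CLASSES = ("PPIN", "GRN", "LRN", "MRN")


def model_class_for_target(node_class: str) -> str:
    """Model class of a node's directed-regulation equation."""
    return {"lncRNA": "LRN", "miRNA": "MRN"}.get(node_class, "GRN")


@dataclass
class RegressionProblem:
    """One node's regression system over N stage samples.

    ``design`` holds one column per candidate regulator plus a trailing
    all-ones basal column; ``column_meta`` lists (regulator_id, term) per
    column, term in {"ppi", "linear", "repression", "basal"}.  ``lower`` /
    ``upper`` are per-column coefficient bounds: repression columns are
    bounded above by zero, all others are free.
    """

    node_id: str
    model_class: str
    response: np.ndarray
    design: np.ndarray
    column_meta: list
    lower: np.ndarray
    upper: np.ndarray

    @property
    def n_samples(self) -> int:
        return len(self.response)

    @property
    def n_regulators(self) -> int:
        return self.design.shape[1] - 1


@dataclass
class NodeModel:
    """A node's pruned, estimated regression model for one stage.

    ``coefficients`` maps each retained regulator to its ability as written in
    the model equation: interaction abilities and transcriptional abilities
    are signed, repression abilities are non-negative (the fitted column
    coefficient is their negative).  ``terms`` records each retained
    regulator's term kind.
    """

    node_id: str
    model_class: str
    coefficients: dict = field(default_factory=dict)
    terms: dict = field(default_factory=dict)
    basal: float = 0.0
    residual_variance: float = 0.0
    aic_trace: list = field(default_factory=list)
    selected_order: int = 0
    entry_order: list = field(default_factory=list)


@dataclass
class RealGWGEN:
    """The identified (real) network of one stage: surviving weighted edges
    plus the per-node models that produced them."""

    nodes: pd.DataFrame
    edges: pd.DataFrame
    models: dict
    stage: str = ""

    def model(self, node_id: str, model_class: str) -> NodeModel | None:
        return self.models.get((node_id, model_class))

    def to_graph(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        for row in self.nodes.itertuples(index=False):
            g.add_node(row.node_id, node_class=row.node_class)
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.source, row.target, edge_class=row.edge_class,
                       weight=float(row.weight))
        return g


# ---------------------------------------------------------------------------
# problem construction


def build_regression(node_id: str, model_class: str,
                     candidate: CandidateNetwork,
                     data: ExpressionDataset) -> RegressionProblem:
    """Assemble the regression system of one node for one model class."""
    values = data.values[sorted(data.values.columns)]
    if values.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    if node_id not in values.index:
        raise KeyError(f"target {node_id!r} missing from expression matrix")
    y = values.loc[node_id].to_numpy(dtype=float)
    n = len(y)

    if model_class == "PPIN":
        regulators = [(p, "ppi") for p in candidate.ppi_partners(node_id)]
    else:
        regs = candidate.regulators_of(node_id).sort_values(["source", "edge_class"])
        regulators = [
            (r.source, "repression" if r.edge_class in REPRESSION_CLASSES else "linear")
            for r in regs.itertuples(index=False)
        ]

    cols, meta, lower, upper = [], [], [], []
    for reg, term in regulators:
        if reg not in values.index:
            raise KeyError(
                f"regulator {reg!r} of {node_id!r} missing from expression matrix")
        x = values.loc[reg].to_numpy(dtype=float)
        if term == "linear":
            cols.append(x)
            lo, hi = -np.inf, np.inf
        elif term == "ppi":
            cols.append(y * x)
            lo, hi = -np.inf, np.inf
        else:  # repression product column; coefficient = -ability <= 0
            cols.append(y * x)
            lo, hi = -np.inf, 0.0
        meta.append((reg, term))
        lower.append(lo)
        upper.append(hi)
    cols.append(np.ones(n))
    meta.append(("", "basal"))
    lower.append(-np.inf)
    upper.append(np.inf)

    return RegressionProblem(
        node_id=node_id, model_class=model_class, response=y,
        design=np.column_stack(cols), column_meta=meta,
        lower=np.array(lower), upper=np.array(upper))


# ---------------------------------------------------------------------------
# constrained least squares


def _solve(design: np.ndarray, response: np.ndarray,
           lower: np.ndarray, upper: np.ndarray) -> np.ndarray:
    if np.all(np.isinf(lower)) and np.all(np.isinf(upper)):
        theta, _, rank, _ = np.linalg.lstsq(design, response, rcond=None)
        if rank < design.shape[1]:
            logger.warning("rank-deficient design (%d < %d): minimum-norm solution",
                           rank, design.shape[1])
        return theta
    res = lsq_linear(design, response, bounds=(lower, upper),
                     method="bvls" if design.shape[0] >= design.shape[1] else "trf",
                     tol=_SOLVER_TOL)
    return res.x


def estimate_parameters(problem: RegressionProblem,
                        columns: list[int] | None = None) -> tuple[np.ndarray, float]:
    """Box-constrained least-squares estimate and residual variance RSS/N.

    ``columns`` restricts the fit to a subset of regulator columns (the basal
    column is always included); the returned vector is dense over the full
    column set with zeros for excluded columns.
    """
    n, q1 = problem.design.shape
    if columns is None:
        columns = list(range(q1 - 1))
    idx = list(columns) + [q1 - 1]
    theta_sub = _solve(problem.design[:, idx], problem.response,
                       problem.lower[idx], problem.upper[idx])
    theta = np.zeros(q1)
    theta[idx] = theta_sub
    resid = problem.response - problem.design[:, idx] @ theta_sub
    return theta, float(resid @ resid) / n


# ---------------------------------------------------------------------------
# AIC order detection


def aic_value(rss: float, n: int, order: int) -> float:
    """AIC(Y) = ln(RSS/N) + 2(Y+1)/N (natural logarithm)."""
    return float(np.log(rss / n) + 2.0 * (order + 1) / n)


def detect_order(problem: RegressionProblem) -> NodeModel:
    """Forward-stepwise nested fits scored by AIC; minimum-AIC order kept.

    At each step the regulator giving the largest residual-sum-of-squares
    decrease (refit under the sign constraints) enters the model; the AIC
    trace over orders 0..q_max is minimized, ties broken toward the smaller
    order.  A perfect fit (RSS numerically zero) receives a -inf sentinel and
    stops the search.  The search is capped at N - 2 regulators so every
    fitted model stays overdetermined.
    """
    n = problem.n_samples
    q = problem.n_regulators
    q_max = min(q, n - 2)
    y2 = float(problem.response @ problem.response)
    rss_floor = _RSS_TOL * max(1.0, y2)

    included: list[int] = []
    remaining = list(range(q))
    trace: list[tuple[int, float]] = []
    fits: dict[int, tuple[np.ndarray, float]] = {}

    theta, rv = estimate_parameters(problem, [])
    fits[0] = (theta, rv)
    rss = rv * n
    trace.append((0, -np.inf if rss < rss_floor else aic_value(rss, n, 0)))

    order = 0
    while remaining and order < q_max and trace[-1][1] != -np.inf:
        best = None
        for j in remaining:
            theta_j, rv_j = estimate_parameters(problem, included + [j])
            if best is None or rv_j < best[2] - 1e-15:
                best = (j, theta_j, rv_j)
        j, theta, rv = best
        included.append(j)
        remaining.remove(j)
        order += 1
        fits[order] = (theta, rv)
        rss = rv * n
        trace.append((order, -np.inf if rss < rss_floor else aic_value(rss, n, order)))

    best_order = min(trace, key=lambda t: (t[1], t[0]))[0]
    theta, rv = fits[best_order]

    model = NodeModel(node_id=problem.node_id, model_class=problem.model_class,
                      basal=float(theta[-1]), residual_variance=rv,
                      aic_trace=trace, selected_order=best_order)
    for j in included[:best_order]:
        reg, term = problem.column_meta[j]
        coef = float(theta[j])
        if coef == 0.0:
            continue  # clamped at its sign bound: no surviving edge
        ability = -coef if term == "repression" else coef
        model.coefficients[reg] = ability
        model.terms[reg] = term
        model.entry_order.append(reg)
    model.selected_order = len(model.coefficients)
    return model


# ---------------------------------------------------------------------------
# whole-network identification


def identify_gwgen(candidate: CandidateNetwork, data: ExpressionDataset,
                   stage: str) -> RealGWGEN:
    """Identify the real GWGEN of one stage from its candidate superset.

    Every node is fitted independently with the given stage's samples: a
    protein-type node with candidate PPI edges gets a PPIN model, any node
    with directed candidate regulators gets the regulatory model of its class.
    Edges whose coefficient is pruned by AIC order detection are removed; an
    undirected PPI edge survives if it is retained in either endpoint's model
    (its weight is the mean of the retained estimates).
    """
    if stage and (data.stages == stage).any():
        data = data.subset_stage(stage)
    elif stage and not (data.stages == stage).any():
        raise ValueError(f"no samples labelled {stage!r}")

    present = [n for n in candidate.node_ids if n in data.values.index]
    missing = sorted(set(candidate.node_ids) - set(present))
    if missing:
        warnings.warn(f"{len(missing)} network node(s) absent from expression "
                      f"data were dropped: {missing[:10]}...")
    keep = set(present)
    nodes = candidate.nodes.loc[sorted(keep)].copy()
    edges = candidate.edges
    edges = edges[edges["source"].isin(keep) & edges["target"].isin(keep)]
    pruned_net = CandidateNetwork(nodes, edges)

    models: dict = {}
    n_pruned = 0
    for node_id in sorted(keep):
        cls = pruned_net.node_class(node_id)
        if cls in PROTEIN_TYPE and pruned_net.ppi_partners(node_id):
            prob = build_regression(node_id, "PPIN", pruned_net, data)
            m = detect_order(prob)
            models[(node_id, "PPIN")] = m
            n_pruned += prob.n_regulators - m.selected_order
        if len(pruned_net.regulators_of(node_id)):
            mc = model_class_for_target(cls)
            prob = build_regression(node_id, mc, pruned_net, data)
            m = detect_order(prob)
            models[(node_id, mc)] = m
            n_pruned += prob.n_regulators - m.selected_order
    logger.info("stage %s: pruned %d candidate regulators across %d models",
                stage, n_pruned, len(models))

    # assemble surviving edges
    ppi_estimates: dict[tuple[str, str], list[float]] = {}
    rows = []
    for (node_id, mc), m in models.items():
        for reg, ability in m.coefficients.items():
            term = m.terms[reg]
            if term == "ppi":
                ppi_estimates.setdefault(canonical_ppi(node_id, reg), []).append(ability)
            else:
                ec = _edge_class_of(pruned_net, reg, node_id)
                weight = -ability if term == "repression" else ability
                rows.append((reg, node_id, ec, weight))
    for (a, b), ests in sorted(ppi_estimates.items()):
        rows.append((a, b, "PPI", float(np.mean(ests))))
    edges_out = pd.DataFrame(rows, columns=["source", "target", "edge_class", "weight"])
    edges_out["stage"] = stage
    edges_out = edges_out.sort_values(["edge_class", "source", "target"]).reset_index(drop=True)
    return RealGWGEN(nodes=nodes, edges=edges_out, models=models, stage=stage)


def _edge_class_of(net: CandidateNetwork, source: str, target: str) -> str:
    e = net.edges
    m = e[(e["source"] == source) & (e["target"] == target) & (e["edge_class"] != "PPI")]
    return m["edge_class"].iloc[0]


# ---------------------------------------------------------------------------
# ground-truth scoring (synthetic benchmarks only)


def _edge_key_set(edges: pd.DataFrame) -> set:
    keys = set()
    for r in edges.itertuples(index=False):
        if r.edge_class == "PPI":
            keys.add(("PPI",) + canonical_ppi(r.source, r.target))
        else:
            keys.add(("DIR", r.source, r.target))
    return keys


def recovery_scores(truth, real_net: RealGWGEN) -> dict:
    """Edge-level precision / recall / F1 of an identified network against a
    GroundTruth's provenance."""
    true_keys = _edge_key_set(truth.truth_network.edges)
    found_keys = _edge_key_set(real_net.edges)
    tp = len(true_keys & found_keys)
    fp = len(found_keys - true_keys)
    fn = len(true_keys - found_keys)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {"tp": tp, "fp": fp, "fn": fn,
            "precision": precision, "recall": recall, "f1": f1}


def coefficient_rmse(truth, real_net: RealGWGEN) -> dict:
    """RMSE of retained coefficient estimates against their generating values.

    Truth coefficients live in a specific generating equation; each is
    compared with the estimate of the same (target, model_class, regulator)
    term when retained.
    """
    errors = []
    for r in truth.coefficients.itertuples(index=False):
        m = real_net.model(r.target, r.model_class)
        if m is None or r.regulator not in m.coefficients:
            continue
        errors.append(m.coefficients[r.regulator] - r.value)
    rmse = float(np.sqrt(np.mean(np.square(errors)))) if errors else float("nan")
    return {"rmse": rmse, "n_matched": len(errors),
            "n_truth": len(truth.coefficients)}


def exhaustive_best_subset(problem: RegressionProblem) -> tuple[int, tuple]:
    """Best-subset AIC search (test oracle; exponential in q, use q <= 8).

    Returns (order, regulator index tuple) of the AIC-minimal subset; ties
    break toward the smaller order, then lexicographic.
    """
    from itertools import combinations

    n = problem.n_samples
    q = problem.n_regulators
    y2 = float(problem.response @ problem.response)
    rss_floor = _RSS_TOL * max(1.0, y2)
    best = None
    for k in range(min(q, n - 2) + 1):
        for subset in combinations(range(q), k):
            _, rv = estimate_parameters(problem, list(subset))
            rss = rv * n
            a = -np.inf if rss < rss_floor else aic_value(rss, n, k)
            key = (a, k, subset)
            if best is None or key < best:
                best = key
    return best[1], best[2]


# ---------------------------------------------------------------------------
# persistence (TSV round trip used by the command-line pipeline)


def save_real_gwgen(real_net: RealGWGEN, outdir, aic_trace: bool = False) -> None:
    """Write an identified network as TSV tables (edges, node models,
    coefficients and optionally the AIC traces)."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    real_net.edges.to_csv(outdir / "edges.tsv", sep="\t", index=False)
    nodes = real_net.nodes.copy()
    nodes["function_tags"] = [";".join(t) for t in nodes["function_tags"]]
    nodes[["node_id", "node_class", "function_tags"]].to_csv(
        outdir / "nodes.tsv", sep="\t", index=False)

    mrows, crows, trows = [], [], []
    for (nid, mc) in sorted(real_net.models):
        m = real_net.models[(nid, mc)]
        mrows.append((nid, mc, m.basal, m.residual_variance, m.selected_order))
        for reg in m.entry_order if m.entry_order else sorted(m.coefficients):
            if reg in m.coefficients:
                crows.append((nid, mc, reg, m.terms[reg], m.coefficients[reg]))
        for order, a in m.aic_trace:
            trows.append((nid, mc, order, a))
    pd.DataFrame(mrows, columns=["node_id", "model_class", "basal",
                                 "residual_variance", "selected_order"]
                 ).to_csv(outdir / "models.tsv", sep="\t", index=False)
    pd.DataFrame(crows, columns=["target", "model_class", "regulator",
                                 "term", "ability"]
                 ).to_csv(outdir / "coefficients.tsv", sep="\t", index=False)
    if aic_trace:
        pd.DataFrame(trows, columns=["node_id", "model_class", "order", "aic"]
                     ).to_csv(outdir / "aic_trace.tsv", sep="\t", index=False)


def load_real_gwgen(outdir) -> RealGWGEN:
    """Rebuild a RealGWGEN from the tables written by :func:`save_real_gwgen`."""
    from pathlib import Path

    from .network import make_node_table

    outdir = Path(outdir)
    edges = pd.read_csv(outdir / "edges.tsv", sep="\t").fillna({"stage": ""})
    ndf = pd.read_csv(outdir / "nodes.tsv", sep="\t", dtype=str).fillna("")
    nodes = make_node_table(
        (r.node_id, r.node_class, [t for t in str(r.function_tags).split(";") if t])
        for r in ndf.itertuples(index=False))
    mdf = pd.read_csv(outdir / "models.tsv", sep="\t")
    cdf = pd.read_csv(outdir / "coefficients.tsv", sep="\t")
    models: dict = {}
    for r in mdf.itertuples(index=False):
        models[(r.node_id, r.model_class)] = NodeModel(
            node_id=r.node_id, model_class=r.model_class, basal=float(r.basal),
            residual_variance=float(r.residual_variance),
            selected_order=int(r.selected_order))
    for r in cdf.itertuples(index=False):
        m = models[(r.target, r.model_class)]
        m.coefficients[r.regulator] = float(r.ability)
        m.terms[r.regulator] = r.term
        m.entry_order.append(r.regulator)
    stage = str(edges["stage"].iloc[0]) if len(edges) else ""
    return RealGWGEN(nodes=nodes, edges=edges, models=models, stage=stage)
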