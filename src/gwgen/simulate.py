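"""Synthetic GWGEN benchmark generator.

Emulates the structure of the study data end-to-end so every downstream stage
is testable with a known ground truth: a sparse truth network over the five
node classes, stage-labelled expression matrices generated from the four
regression model classes plus Gaussian residual noise, a corrupted candidate
network (truth plus class-respecting spurious edges, mimicking the false
positives of database mining), and a drug-effect matrix averaged over pseudo
cell lines (as perturbation compendia average over cell lines).

The generative truth is a DAG: each regulated node is produced by exactly one
model equation whose regulators precede it in a fixed topological order.  The
protein-interaction and miRNA-repression equations are implicit in the target
(the regressor contains the target itself); they are solved in closed form,

    p_x = (b_x + w) / (1 - sum_y a_xy p_y)          (PPI targets)
    g_i = (sum_o c_io p_o + sum_u d_iu l_u + b_i + w) / (1 + sum_r e_ir k_r)

and samples whose denominator magnitude falls below 0.1 are rejected and the
whole sample column redrawn (the implicit form explodes near singularity).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io import ExpressionDataset
from .network import (
    CLASS_OF_PAIR,
    PROTEIN_TYPE,
    CandidateNetwork,
    canonical_ppi,
    make_node_table,
)

#: term kinds of the model equations: a plain regressor column ("linear",
#: transcriptional abilities), a target*partner product ("ppi") and a
#: target*miRNA product with non-negative ability ("repression").
TERM_KINDS = ("ppi", "linear", "repression")

COEF_COLUMNS = ["target", "model_class", "regulator", "term", "value"]

_DENOM_GUARD = 0.1
_MAX_REDRAWS = 100

#: default per-stage sample sizes mirroring the three clinical asthma stages
DEFAULT_STAGES = {"quiet": 118, "exacerbation": 118, "follow_up": 102}


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic benchmark.

    Node counts and regulator in-degrees are scaled-down but keep the real
    network's character: proteins dominate, ncRNA layers are thin, regulated
    genes carry a handful of regulators.  Expression lives on an RMA-like
    log2 scale (source nodes ~ Normal(8, 1)); coefficient magnitudes are
    chosen so that regulated nodes keep a variance comparable to source
    nodes, as log-scale microarray genes do.
    """

    node_counts: dict = field(default_factory=lambda: {
        "TF": 30, "lncRNA": 8, "miRNA": 10, "receptor": 22, "protein": 130})
    samples_per_stage: dict = field(default_factory=lambda: dict(DEFAULT_STAGES))
    # fraction of each class generated as exogenous sources (no truth parents)
    source_fraction: dict = field(default_factory=lambda: {
        "TF": 0.4, "lncRNA": 0.3, "miRNA": 0.4, "receptor": 0.5, "protein": 0.2})
    # among regulated proteins, fraction modeled by the PPI equation
    # (the rest are transcriptionally regulated)
    ppi_fraction_of_regulated_proteins: float = 0.6
    # in-degree law: 1 + Poisson(mean), capped
    ppi_extra_partners_mean: float = 0.8
    ppi_max_partners: int = 3
    tf_extra_parents_mean: float = 1.0
    tf_max_parents: int = 4
    lnc_parent_prob: float = 0.25    # chance of one lncRNA regulator (where typed edges exist)
    mir_repressor_prob: float = 0.3  # chance of one miRNA repressor
    # coefficient magnitude ranges
    ppi_ability_range: tuple = (0.1, 0.3)       # divided by (8 * in-degree)
    linear_ability_range: tuple = (0.4, 0.9)    # divided by sqrt(in-degree)
    repression_ability_range: tuple = (0.01, 0.05)
    basal_mean: float = 8.0
    basal_sd: float = 1.0
    base_mean: float = 8.0   # source-node expression ~ Normal(base_mean, base_sd)
    base_sd: float = 1.0
    noise_sd: float = 0.1
    spurious_multiplier: float = 2.0
    n_drugs: int = 20
    n_cell_lines: int = 3
    seed: int = 0

    def validate(self) -> None:
        for cls, n in self.node_counts.items():
            if n <= 0:
                raise ValueError(f"node count for {cls} must be positive")
        for stage, n in self.samples_per_stage.items():
            if n <= 0:
                raise ValueError(f"sample count for stage {stage!r} must be positive")
        if self.spurious_multiplier < 0:
            raise ValueError("spurious multiplier must be >= 0")


@dataclass
class GroundTruth:
    """A truth network with its generating coefficients and basal levels.

    ``coefficients`` rows are (target, model_class, regulator, term, value);
    each row is one term of the target's generating equation.  ``basals`` maps
    (node_id, model_class) to the equation's basal level.  Every repression
    ability is non-negative by construction.
    """

    truth_network: CandidateNetwork
    coefficients: pd.DataFrame
    basals: dict
    noise_sd: float = 0.1
    base_mean: float = 8.0
    base_sd: float = 1.0
    seed: int = 0
    config: SimulationConfig | None = None

    def __post_init__(self) -> None:
        c = self.coefficients
        bad = c[(c["term"] == "repression") & (c["value"] < 0)]
        if len(bad):
            raise ValueError("repression abilities must be non-negative")
        models = c.groupby("target")["model_class"].nunique()
        multi = models[models > 1]
        if len(multi):
            raise ValueError(
                f"nodes with more than one generating equation: {list(multi.index)}")
        edge_keys = self._edge_keys(self.truth_network.edges)
        for row in c.itertuples(index=False):
            key = self._coef_edge_key(row.regulator, row.target, row.term)
            if key not in edge_keys:
                raise ValueError(
                    f"coefficient {row.regulator}->{row.target} has no truth edge")

    @staticmethod
    def _edge_keys(edges: pd.DataFrame) -> set:
        keys = set()
        for row in edges.itertuples(index=False):
            if row.edge_class == "PPI":
                keys.add(("PPI",) + canonical_ppi(row.source, row.target))
            else:
                keys.add(("DIR", row.source, row.target))
        return keys

    @staticmethod
    def _coef_edge_key(regulator: str, target: str, term: str):
        if term == "ppi":
            return ("PPI",) + canonical_ppi(regulator, target)
        return ("DIR", regulator, target)

    @property
    def regulated_nodes(self) -> list[str]:
        return sorted(set(self.coefficients["target"]))

    def model_of(self, node_id: str) -> str | None:
        sub = self.coefficients[self.coefficients["target"] == node_id]
        return None if sub.empty else sub["model_class"].iloc[0]

    def equation_terms(self, node_id: str) -> pd.DataFrame:
        return self.coefficients[self.coefficients["target"] == node_id]


# ---------------------------------------------------------------------------
# ground-truth generation


def _model_for_class(node_class: str) -> str:
    return {"lncRNA": "LRN", "miRNA": "MRN"}.get(node_class, "GRN")


def generate_ground_truth(config: SimulationConfig) -> GroundTruth:
    """Sample a sparse DAG truth network with coefficients and basal levels."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    prefixes = {"TF": "TF", "lncRNA": "LNC", "miRNA": "MIR",
                "receptor": "REC", "protein": "PRO"}
    nodes: list[tuple[str, str]] = []
    for cls in ("TF", "lncRNA", "miRNA", "receptor", "protein"):
        for i in range(config.node_counts.get(cls, 0)):
            nodes.append((f"{prefixes[cls]}{i + 1:04d}", cls))

    # roles: source vs regulated; regulated proteins split into PPI- vs
    # transcriptionally-modeled
    roles: dict[str, str] = {}
    for node_id, cls in nodes:
        if rng.random() < config.source_fraction.get(cls, 0.3):
            roles[node_id] = "source"
        elif cls == "protein" and rng.random() < config.ppi_fraction_of_regulated_proteins:
            roles[node_id] = "PPIN"
        else:
            roles[node_id] = _model_for_class(cls)

    # generation order: sources first, regulated nodes after, each shuffled;
    # parents are drawn from strictly earlier nodes, so the truth is a DAG
    sources = [n for n, _ in nodes if roles[n] == "source"]
    regulated = [n for n, _ in nodes if roles[n] != "source"]
    rng.shuffle(sources)
    rng.shuffle(regulated)
    order = sources + regulated
    node_class = dict(nodes)

    def _pool(upto: int, classes: frozenset | set) -> list[str]:
        return [n for n in order[:upto] if node_class[n] in classes]

    coef_rows: list[tuple] = []
    basals: dict = {}

    def _draw_linear(k: int) -> np.ndarray:
        lo, hi = config.linear_ability_range
        mags = rng.uniform(lo, hi, size=k) / np.sqrt(k)
        return mags * rng.choice([-1.0, 1.0], size=k)

    for pos, node_id in enumerate(order):
        role = roles[node_id]
        if role == "source":
            continue
        cls = node_class[node_id]
        basals[(node_id, role)] = rng.normal(config.basal_mean, config.basal_sd)

        if role == "PPIN":
            pool = [n for n in _pool(pos, PROTEIN_TYPE)]
            want = 1 + int(rng.poisson(config.ppi_extra_partners_mean))
            want = min(want, config.ppi_max_partners)
            if len(pool) < 1:
                raise ValueError(
                    "no available protein-type partners for PPI target "
                    f"{node_id} (node class protein)")
            k = min(want, len(pool))
            partners = rng.choice(pool, size=k, replace=False)
            lo, hi = config.ppi_ability_range
            mags = rng.uniform(lo, hi, size=k) / (8.0 * k)
            signs = rng.choice([-1.0, 1.0], size=k)
            for p, a in zip(partners, mags * signs):
                coef_rows.append((node_id, "PPIN", p, "ppi", a))
            continue

        # transcriptional models (GRN for protein-type, LRN/MRN for ncRNA)
        tf_pool = _pool(pos, {"TF"})
        want = 1 + int(rng.poisson(config.tf_extra_parents_mean))
        want = min(want, config.tf_max_parents)
        if len(tf_pool) < 1:
            raise ValueError(
                f"no available TF regulators for target {node_id} "
                f"(node class {cls})")
        k = min(want, len(tf_pool))
        parents = list(rng.choice(tf_pool, size=k, replace=False))

        lnc_parent = None
        # lncRNA regulation is typed only onto genes, TFs and lncRNAs
        if cls in {"protein", "TF"} and rng.random() < config.lnc_parent_prob:
            lnc_pool = _pool(pos, {"lncRNA"})
            if lnc_pool:
                lnc_parent = rng.choice(lnc_pool)
        repressor = None
        if cls != "miRNA" and rng.random() < config.mir_repressor_prob:
            mir_pool = _pool(pos, {"miRNA"})
            if mir_pool:
                repressor = rng.choice(mir_pool)

        n_linear = k + (lnc_parent is not None)
        coeffs = _draw_linear(n_linear)
        for p, cval in zip(parents, coeffs[:k]):
            coef_rows.append((node_id, role, p, "linear", cval))
        if lnc_parent is not None:
            coef_rows.append((node_id, role, lnc_parent, "linear", coeffs[-1]))
        if repressor is not None:
            lo, hi = config.repression_ability_range
            coef_rows.append((node_id, role, repressor, "repression",
                              rng.uniform(lo, hi)))

    coefficients = pd.DataFrame(coef_rows, columns=COEF_COLUMNS)
    edges = _edges_from_coefficients(coefficients, node_class)
    node_table = make_node_table([(n, c) for n, c in nodes])
    truth_net = CandidateNetwork(node_table, edges)
    return GroundTruth(
        truth_network=truth_net, coefficients=coefficients, basals=basals,
        noise_sd=config.noise_sd, base_mean=config.base_mean,
        base_sd=config.base_sd, seed=config.seed, config=config)


def _edges_from_coefficients(coefficients: pd.DataFrame,
                             node_class: dict[str, str]) -> pd.DataFrame:
    rows = []
    for r in coefficients.itertuples(index=False):
        if r.term == "ppi":
            s, t = canonical_ppi(r.regulator, r.target)
            rows.append((s, t, "PPI", "truth"))
        else:
            ec = CLASS_OF_PAIR[(node_class[r.regulator], node_class[r.target])]
            rows.append((r.regulator, r.target, ec, "truth"))
    return pd.DataFrame(rows, columns=["source", "target", "edge_class", "provenance"])


# ---------------------------------------------------------------------------
# expression simulation


def _generation_order(truth: GroundTruth) -> list[str]:
    """Topological order of the dependency DAG; raises listing any cycle."""
    g = nx.DiGraph()
    g.add_nodes_from(truth.truth_network.node_ids)
    for r in truth.coefficients.itertuples(index=False):
        g.add_edge(r.regulator, r.target)
    try:
        return list(nx.topological_sort(g))
    except nx.NetworkXUnfeasible:
        cycle = nx.find_cycle(g)
        raise ValueError(
            "cyclic dependency among regulated nodes (the simulator supports "
            f"DAG truth networks only): {cycle}") from None


def stage_seed(base_seed: int, stage_label: str) -> int:
    """Deterministic per-stage RNG seed derived from the base seed."""
    return int((base_seed + zlib.crc32(stage_label.encode())) % (2**31 - 1))


def simulate_expression(truth: GroundTruth, n_samples: int, stage_label: str,
                        seed: int | None = None) -> ExpressionDataset:
    """Generate an expression matrix for one disease stage.

    Source nodes are drawn from Normal(base_mean, base_sd); regulated nodes
    follow their generating equation plus Normal(0, noise_sd) residual noise.
    Sample columns whose implicit-equation denominator magnitude falls below
    0.1 are rejected and redrawn (at most 100 rounds, then an error).
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    order = _generation_order(truth)
    rng = np.random.default_rng(
        stage_seed(truth.seed, stage_label) if seed is None else seed)

    terms = {n: truth.equation_terms(n) for n in order if truth.model_of(n)}
    values = {n: np.empty(n_samples) for n in order}
    active = np.arange(n_samples)

    for attempt in range(_MAX_REDRAWS):
        bad = np.zeros(len(active), dtype=bool)
        for node_id in order:
            model = truth.model_of(node_id)
            if model is None:
                values[node_id][active] = truth.base_mean + \
                    truth.base_sd * rng.standard_normal(len(active))
                continue
            eq = terms[node_id]
            w = truth.noise_sd * rng.standard_normal(len(active))
            b = truth.basals[(node_id, model)]
            num = np.full(len(active), b) + w
            denom = np.ones(len(active))
            for t in eq.itertuples(index=False):
                reg = values[t.regulator][active]
                if t.term == "linear":
                    num += t.value * reg
                elif t.term == "ppi":
                    denom -= t.value * reg
                else:  # repression: -e * target * k  moves to the denominator
                    denom += t.value * reg
            bad |= np.abs(denom) < _DENOM_GUARD
            with np.errstate(divide="ignore", invalid="ignore"):
                values[node_id][active] = num / denom
        if not bad.any():
            break
        active = active[bad]
    else:
        raise RuntimeError(
            f"implicit-equation denominator guard failed for {len(active)} "
            f"sample(s) after {_MAX_REDRAWS} redraw rounds")

    ids = [f"{stage_label}_{i + 1:04d}" for i in range(n_samples)]
    mat = pd.DataFrame(np.vstack([values[n] for n in truth.truth_network.node_ids]),
                       index=pd.Index(truth.truth_network.node_ids, name="node_id"),
                       columns=ids)
    return ExpressionDataset(mat, pd.Series(stage_label, index=ids))


def model_residuals(truth: GroundTruth, data: ExpressionDataset) -> pd.DataFrame:
    """Residuals of every generating equation evaluated on simulated data.

    With ``noise_sd = 0`` these are numerically zero for every regulated node
    and sample: the model-consistency check of the generator.
    """
    rows = []
    for node_id in truth.regulated_nodes:
        model = truth.model_of(node_id)
        eq = truth.equation_terms(node_id)
        target = data.values.loc[node_id].to_numpy()
        pred = np.full(len(target), truth.basals[(node_id, model)])
        for t in eq.itertuples(index=False):
            reg = data.values.loc[t.regulator].to_numpy()
            if t.term == "linear":
                pred += t.value * reg
            elif t.term == "ppi":
                pred += t.value * target * reg
            else:
                pred -= t.value * target * reg
        rows.append((node_id, model, float(np.max(np.abs(target - pred)))))
    return pd.DataFrame(rows, columns=["node_id", "model_class", "max_abs_residual"])


# ---------------------------------------------------------------------------
# candidate-network corruption


def _class_respecting_complement(truth: GroundTruth) -> list[tuple[str, str, str]]:
    nodes = truth.truth_network.nodes
    node_class = dict(zip(nodes["node_id"], nodes["node_class"]))
    ids = list(nodes["node_id"])
    existing = GroundTruth._edge_keys(truth.truth_network.edges)
    out = []
    for u in ids:
        cu = node_class[u]
        for v in ids:
            if u == v:
                continue
            cv = node_class[v]
            ec = CLASS_OF_PAIR.get((cu, cv))
            if ec is not None and ("DIR", u, v) not in existing:
                out.append((u, v, ec))
            if cu in PROTEIN_TYPE and cv in PROTEIN_TYPE and u < v:
                if ("PPI", u, v) not in existing:
                    out.append((u, v, "PPI"))
    return out


def corrupt_candidate(truth: GroundTruth, spurious_multiplier: float,
                      seed: int) -> CandidateNetwork:
    """Truth network plus class-respecting spurious edges (the false positives
    of database mining), uniformly sampled without replacement.

    Spurious edges carry provenance ``"spurious"`` — a test oracle only; the
    identification stage never reads the provenance column.
    """
    if spurious_multiplier < 0:
        raise ValueError("spurious multiplier must be >= 0")
    n_true = len(truth.truth_network.edges)
    n_spurious = int(round(spurious_multiplier * n_true))
    complement = _class_respecting_complement(truth)
    if n_spurious > len(complement):
        raise ValueError(
            f"requested {n_spurious} spurious edges but only {len(complement)} "
            "class-respecting non-truth edges exist")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(complement), size=n_spurious, replace=False)
    spurious = pd.DataFrame(
        [complement[i] + ("spurious",) for i in sorted(idx)],
        columns=["source", "target", "edge_class", "provenance"])
    edges = pd.concat([truth.truth_network.edges, spurious], ignore_index=True)
    return CandidateNetwork(truth.truth_network.nodes.copy(), edges)


# ---------------------------------------------------------------------------
# drug-effect matrices


@dataclass
class DrugEffectMatrix:
    """Signed drug-by-gene effect tables, per pseudo cell line and averaged."""

    per_cell_line: list          # list of drugs x genes DataFrames
    averaged: pd.DataFrame       # drugs x genes

    @property
    def drugs(self) -> list[str]:
        return list(self.averaged.index)


def generate_drug_matrix(genes, n_drugs: int, n_cell_lines: int,
                         seed: int) -> DrugEffectMatrix:
    """Sparse signed effects per pseudo cell line, averaged per drug."""
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene list")
    if n_drugs < 1 or n_cell_lines < 1:
        raise ValueError("n_drugs and n_cell_lines must be >= 1")
    rng = np.random.default_rng(seed)
    drug_ids = [f"drug{i + 1:04d}" for i in range(n_drugs)]
    tables = []
    for _ in range(n_cell_lines):
        nonzero = rng.random((n_drugs, len(genes))) < 0.4
        mags = rng.uniform(0.2, 1.0, size=(n_drugs, len(genes)))
        signs = rng.choice([-1.0, 1.0], size=(n_drugs, len(genes)))
        tables.append(pd.DataFrame(np.where(nonzero, mags * signs, 0.0),
                                   index=drug_ids, columns=genes))
    averaged = sum(tables) / n_cell_lines
    return DrugEffectMatrix(per_cell_line=tables, averaged=averaged)
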