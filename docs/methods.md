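# Methods

## Model

A genome-wide genetic and epigenetic network (GWGEN) couples four layers over
five node classes — transcription factors (TFs), lncRNAs, miRNAs, receptors
and other proteins.  Each node carries one static regression equation per
applicable model class, indexed by sample `n = 1..N` within one disease
stage:

* **PPIN** (protein-type node `x` with interaction partners `y`):
  `p_x[n] = Σ_y a_xy p_x[n] p_y[n] + b_x + w_x[n]`.  The interaction term is
  bilinear in the two partners' expression; the equation is implicit in
  `p_x`.
* **GRN** (gene `i`): `g_i[n] = Σ_o c_io p_o[n] + Σ_u d_iu l_u[n]
  − Σ_r e_ir g_i[n] k_r[n] + b_i + w_i[n]` with repression abilities
  `e_ir ≥ 0`; miRNA repression is a product of target and miRNA expression.
* **LRN / MRN**: the same shape for lncRNA and miRNA targets, with abilities
  `(S_ho, Γ_hu, λ_hr)` and `(η_zo, δ_zu, σ_zr)`, `λ, σ ≥ 0`.

The basal level (intercept) of each equation absorbs regulation that the
genetic terms do not represent and is interpreted downstream as putative
epigenetic modification.  `w` is i.i.d. Gaussian residual noise.

Twelve interaction classes type the candidate edges (T-G, T-T, T-R, T-L,
T-M, L-G, L-T, M-G, M-T, M-R, M-L, PPI).  Because this typing has no
lncRNA→lncRNA, lncRNA→miRNA or miRNA→miRNA classes, the `Γ`, `δ` and `σ`
coefficient families are estimable by the machinery but never instantiated
by the synthetic generator.

## Identification

Per node and model class, candidate regulators define a linear regression
with one column per regulator (plain expression for transcriptional terms,
target×partner products for PPI and repression terms) plus a basal column.
Estimation is box-constrained least squares: repression-product columns are
bounded above by zero so abilities stay non-negative (`scipy`'s BVLS with
tolerance 1e-10; unconstrained systems use the minimum-norm `lstsq`
solution, with a logged warning when rank-deficient).

Order detection minimizes `AIC(Y) = ln(RSS/N) + 2(Y+1)/N` (natural
logarithm; base changes shift all values equally) over nested models grown
by **forward stepwise selection**: at each step the regulator whose
constrained refit drops RSS most enters the model.  Ties in AIC break toward
the smaller order; a numerically perfect fit (RSS below 1e-16 of the squared
response norm) receives a −∞ sentinel and stops the search; the order is
capped at `N − 2` so every fitted model is overdetermined.  Forward
selection was chosen over ranking the full-fit coefficients because the
bilinear PPI columns are strongly collinear (they share a large common
direction proportional to the response), which makes full-fit coefficient
magnitudes an unstable ordering; refitting at each step is O(q²) solves and
exact for the nested sweep.  For q ≤ 8 an exhaustive best-subset AIC search
is kept as a test oracle; on noiseless and null benchmarks greedy and
exhaustive selections agree in ≥ 48/50 trials.

An undirected PPI edge appears in both endpoint equations; it survives if
either endpoint retains it (union rule), and its reported edge weight is the
mean of the retained per-equation estimates.  The per-equation estimates are
kept separately in the node models, since `a_xy` and `a_yx` are distinct
parameters of distinct equations.

### Identifiability limits

Two limits are inherent to the model class and worth knowing before
interpreting recovered networks:

1. **The PPI regressor contains the response.**  On a microarray-like scale
   (values ≈ mean 8, sd 1), a product column `p_x·p_z` is approximately
   `μ_z p_x + μ_x p_z`: a copy of the response plus partner noise.  Any
   spurious PPI candidate therefore "explains" a large share of response
   variance, and least squares can average k such columns to cancel the
   partner noise, keeping marginal AIC gains above the 2/N penalty until
   roughly N/2 partners are retained.  Spurious PPI candidates are
   consequently almost never rejected when a protein has fewer than ~N/2
   candidates, and PPI support recovery is weak even though retained
   coefficient values on true terms remain accurate.  Directed regulatory
   layers do not share this pathology (their spurious retention is the usual
   ~16% of a null χ²₁ exceeding the AIC penalty); the sign constraint
   additionally rejects most spurious repression candidates, whose
   self-correlation pushes the fitted coefficient against the zero bound.
2. **Zero-noise collinearity.**  With no residual noise, a regulated node
   that itself regulates others is an exact linear function of its own
   parents, so a perfect fit of its targets exists without it and the edge
   set is not unique; exact noiseless edge-set recovery is guaranteed only
   when regulators are exogenous.

## Epigenetic calls

Basal estimates are compared per model class against a threshold — by
default the 90th percentile of |basal| within the class (absolute override
available); the flag requires a strict exceedance, and magnitude is used
because the direction of unmodeled regulation is uninformative here.
Flagged PPIN models inherit a modification kind from the function tags of
their network PPI partners (acetylation/deacetylation,
methylation/demethylation, phosphorylation/dephosphorylation,
ubiquitination/deubiquitination; multiple matches are reported joined in
deterministic order); flagged GRN models are attributed to DNA
methylation/demethylation; flagged ncRNA models are reported unspecified.
Calls are network-level associations, not biochemical measurements.

## Principal network projection

Rows of the integrated matrix `M` are fitted model instances in block order
(PPIN, GRN, LRN, MRN); columns are regulators in block order (protein-type
`O`, lncRNA `U`, miRNA `R`).  The `O` block holds every protein-type node
with a retained outgoing interaction (not only TFs, so PPIs with non-TF
partners keep their columns).  Repression abilities enter negatively, so
entries carry the signed regulatory effect; pruned or absent interactions
are exact zeros.  The thin SVD uses a canonical sign convention (the
largest-magnitude component of each right singular vector is positive) for
reproducibility.  `K` is the smallest rank whose eigenexpression fractions
accumulate ≥ 85% (threshold configurable in (0, 1]); row projection values
are `D(s) = ‖(row_s·v_1, …, row_s·v_K)‖₂`, and a node with several model
rows aggregates them in the Euclidean sense.  Core extraction keeps the
top-n nodes by projection value (n defaults to 3000, clamped with a warning;
ties break by node id), induces their subgraph in the identified network and
drops degree-0 nodes, so isolated high-projection nodes are excluded.

## Drug-signature reversal

A stage signature is its biomarker targets with dysregulation signs (±1).
Continuous drug effects are thresholded to signs at |effect| > ε (ε = 0 by
default).  A drug's reversal score counts targets whose effect sign opposes
the disease sign; zero effects never count.  Combinations integrate per
target by the majority of nonzero effect signs — exact ties and all-zero
columns give 0; blank cells in published tables read as 0 ("no detectable
effect").  This majority rule reproduces all 15 published final-result signs
across the three stages and is the default (overridable by passing
pre-thresholded effects).  `select_combination` builds a k-drug combination
greedily, maximizing the count of targets whose integrated sign reverses the
signature, with deterministic tie-breaks by drug id and a step audit trail;
an exhaustive subset search over small matrices serves as its test oracle.

## Synthetic benchmark

The generator emulates the structure of the motivating study — three
stage-labelled sample groups of 118/118/102 peripheral-blood profiles on an
RMA-like log2 scale — with defaults chosen once as study conditions:

* **Composition**: 200 nodes (30 TFs, 8 lncRNAs, 10 miRNAs, 22 receptors,
  130 proteins) — protein-dominated with thin ncRNA layers like the real
  network, with the ncRNA classes held slightly above strict proportion so
  the LRN/MRN machinery is exercised at this scale.
* **Truth topology**: a DAG; a class-specific fraction of nodes is exogenous
  (sources, drawn Normal(8, 1)); regulated proteins split 60/40 between
  PPI-modeled (1 + Poisson(0.8) partners, ≤ 3) and transcriptionally modeled
  targets (1 + Poisson(1) TF parents ≤ 4, optional lncRNA parent with
  probability 0.25 where the edge typing allows, optional miRNA repressor
  with probability 0.3).
* **Coefficients**: transcriptional abilities |U(0.4, 0.9)|/√in-degree with
  random signs, so regulated nodes keep variances comparable to sources (as
  log-scale microarray genes do); PPI abilities |U(0.1, 0.3)|/(8·in-degree)
  with random signs, keeping the implicit-equation denominator safely away
  from zero; repression abilities U(0.01, 0.05); basals Normal(8, 1);
  residual noise sd 0.1.
* **Implicit equations** are solved in closed form; sample columns whose
  denominator magnitude falls below 0.1 are rejected and redrawn (≤ 100
  rounds, then an error).
* **Corruption**: spurious edges are sampled uniformly without replacement
  from the class-respecting complement of the truth (the simplest null for
  database false positives), at a default multiplier of 2 false per true
  edge; provenance flags exist only for scoring.
* **Drug compendium**: per pseudo cell line, each drug–gene effect is
  nonzero with probability 0.4 with magnitude U(0.2, 1) and random sign;
  per-drug profiles are cell-line averages.

What the generator does **not** emulate: probe-level noise, batch effects,
correlated residuals, cyclic regulation (the static equations define no
generative order on cycles, although identification itself accepts cyclic
candidate structures), and the heavy-tailed degree distributions of real
interactomes.  Passing recovery tests on this benchmark therefore
demonstrates correctness of the estimation machinery under the model's own
assumptions, not performance on real microarray data.

Problem sizes used by the test suite and the acceptance script (200-node
networks, one 118-sample stage, 25 order-detection replicates, 100 random
PNP matrices) are scaled-down choices that keep the full suite executable in
a few seconds while preserving the study's sample-size regime.

## Determinism

All randomness flows through seeded `numpy` generators; per-stage simulation
seeds derive from the base seed and the stage label (CRC32 mix, kept below
2³¹).  Repeated runs of the full pipeline — library calls or the CLI — are
bit-identical given equal seeds; iteration orders are sorted wherever dicts
or sets could otherwise leak ordering.
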