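"""Drug-signature reversal scoring and multi-molecule combination design.

A disease stage is summarized by a signature: its biomarker target genes with
their dysregulation signs (+1 upregulated, -1 downregulated).  A drug's
perturbation profile reverses a target when its effect sign opposes the
disease sign.  Single drugs are ranked by how many targets they reverse; a
multi-molecule combination is integrated per target by the majority of the
selected drugs' nonzero effect signs (exact ties and all-zero columns give
0), and combinations are built greedily to maximize the number of targets
whose integrated sign reverses the signature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class DiseaseSignature:
    """Ordered biomarker targets of one stage with their expression signs."""

    stage: str
    targets: list                 # gene ids
    signs: np.ndarray             # +1 / -1 per target

    def __post_init__(self) -> None:
        self.signs = np.asarray(self.signs, dtype=int)
        if len(self.targets) == 0:
            raise ValueError("empty signature")
        if len(self.targets) != len(set(self.targets)):
            raise ValueError("signature genes must be unique")
        if np.any(self.signs == 0) or not np.all(np.isin(self.signs, (-1, 1))):
            raise ValueError("signature signs must be +1 or -1")


@dataclass
class CombinationResult:
    """Integrated per-target call of a drug combination."""

    signature: DiseaseSignature
    drugs: list
    integrated_signs: np.ndarray          # +1 / -1 / 0 per target
    per_drug_scores: dict = field(default_factory=dict)
    per_drug_effect_signs: dict = field(default_factory=dict)
    audit: list = field(default_factory=list)

    @property
    def n_reversed(self) -> int:
        return int(np.sum(self.integrated_signs == -self.signature.signs))

    def table(self) -> pd.DataFrame:
        """Report mirroring the published layout: one row per drug plus the
        expression and final-result rows, columns = targets."""
        rows = {"Expression": self.signature.signs}
        for d in self.drugs:
            rows[d] = self.per_drug_effect_signs[d]
        rows["Final result"] = self.integrated_signs
        df = pd.DataFrame(rows, index=self.signature.targets).T
        return df.map(lambda v: {1: "+", -1: "-", 0: "0"}[int(v)])


def signs_of_effects(effects: np.ndarray, epsilon: float = 0.0) -> np.ndarray:
    """Threshold continuous effects to signs; |effect| <= epsilon becomes 0."""
    e = np.asarray(effects, dtype=float)
    out = np.sign(e).astype(int)
    out[np.abs(e) <= epsilon] = 0
    return out


def _effect_vector(signature: DiseaseSignature, drug_effects,
                   epsilon: float = 0.0) -> np.ndarray:
    """Signed effects of one drug aligned with the signature targets.

    ``drug_effects`` is a mapping / Series gene -> signed effect; targets
    missing from it are treated as 0 with a warning.
    """
    if isinstance(drug_effects, pd.Series):
        drug_effects = drug_effects.to_dict()
    missing = [t for t in signature.targets if t not in drug_effects]
    if missing:
        warnings.warn(f"targets missing from drug profile treated as 0: {missing}")
    raw = np.array([float(drug_effects.get(t, 0.0)) for t in signature.targets])
    return signs_of_effects(raw, epsilon)


def reversal_score(signature: DiseaseSignature, drug_effects,
                   epsilon: float = 0.0) -> int:
    """Count of signature targets whose effect sign opposes the disease sign.

    Zero effects never count, in either direction.
    """
    eff = _effect_vector(signature, drug_effects, epsilon)
    return int(np.sum((eff != 0) & (eff == -signature.signs)))


def integrate_combination(signature: DiseaseSignature, drug_effects: dict,
                          epsilon: float = 0.0) -> CombinationResult:
    """Majority-of-nonzero-signs integration of several drugs' effects.

    ``drug_effects`` maps drug id -> (gene -> signed effect).  Per target the
    integrated sign is the majority sign over the drugs' nonzero effects; an
    exact tie or an all-zero column integrates to 0.
    """
    if not drug_effects:
        raise ValueError("need at least one drug")
    drugs = list(drug_effects)
    eff = {d: _effect_vector(signature, drug_effects[d], epsilon) for d in drugs}
    stacked = np.vstack([eff[d] for d in drugs])
    totals = stacked.sum(axis=0)
    integrated = np.sign(totals).astype(int)
    scores = {d: int(np.sum((eff[d] != 0) & (eff[d] == -signature.signs)))
              for d in drugs}
    return CombinationResult(signature=signature, drugs=drugs,
                             integrated_signs=integrated,
                             per_drug_scores=scores,
                             per_drug_effect_signs=eff)


def select_combination(signature: DiseaseSignature, matrix: pd.DataFrame,
                       k: int, epsilon: float = 0.0) -> CombinationResult:
    """Greedy k-drug combination maximizing reversed targets.

    ``matrix`` is a drugs x genes table of signed effects.  At each step the
    drug whose addition maximizes the number of targets whose integrated
    (majority) sign reverses the signature enters the combination; ties break
    by drug id.  Raises if no drug has any nonzero effect on the signature.
    """
    if not (1 <= k <= len(matrix)):
        raise ValueError(f"k={k} outside 1..{len(matrix)}")
    profiles = {d: matrix.loc[d] for d in matrix.index}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        any_nonzero = any(np.any(_effect_vector(signature, p, epsilon) != 0)
                          for p in profiles.values())
    if not any_nonzero:
        raise ValueError("no drug has a nonzero effect on any signature gene")

    selected: list[str] = []
    audit = []
    for step in range(k):
        best = None
        for d in sorted(set(matrix.index) - set(selected)):
            trial = {x: profiles[x] for x in selected + [d]}
            res = integrate_combination(signature, trial, epsilon)
            if best is None or res.n_reversed > best[1]:
                best = (d, res.n_reversed, res)
        d, gain, res = best
        selected.append(d)
        audit.append({"step": step + 1, "drug": d, "reversed_targets": gain})
    res.audit = audit
    return res


def signature_from_frame(df: pd.DataFrame, stage: str) -> DiseaseSignature:
    """Build a DiseaseSignature from a (stage, target, expression) sign table."""
    from .io import sign_to_int

    sub = df[df["stage"] == stage]
    if sub.empty:
        raise ValueError(f"no signature rows for stage {stage!r}")
    return DiseaseSignature(stage=stage, targets=list(sub["target"]),
                            signs=np.array([sign_to_int(s) for s in sub["expression"]]))


def effects_from_frame(df: pd.DataFrame, stage: str) -> dict:
    """Per-drug effect mappings from a long (stage, drug, target, effect) table."""
    from .io import sign_to_int

    sub = df[df["stage"] == stage]
    out: dict[str, dict] = {}
    for r in sub.itertuples(index=False):
        out.setdefault(r.drug, {})[r.target] = sign_to_int(r.effect)
    return out
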