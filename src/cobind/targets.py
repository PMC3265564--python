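"""Target prediction by leave-one-feature-out perturbation, plus validation.

A gene is a predicted target of a selected ES-up (ES-down) feature when (1)
it is an ES-up (ES-down) gene and (2) removing the feature's term from the
classifier's probability ratio decreases (increases) the ratio.  Predicted
targets are then checked against an independent two-stage expression set:
targets of an ES activator and/or DF repressor should drop after
differentiation (fold change ES over DF > 1), and conversely.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .classify import NBModel, nb_log_ratio, predictor_log_terms
from .core import ExpressionMatrix

#: Roles whose targets are expected to decrease after differentiation.
_DECREASING_ROLES = {"EA", "DR", "EA/DR"}
_INCREASING_ROLES = {"ER", "DA", "ER/DA"}


@dataclass
class TargetPrediction:
    feature: str
    gene: str
    log_ratio_with: float
    log_ratio_without: float
    rank: int = 0

    @property
    def ratio_fold_change(self) -> float:
        return float(np.exp(self.log_ratio_with - self.log_ratio_without))


def predict_targets(
    model: NBModel,
    X: pd.DataFrame,
    es_class: pd.Series,
    feature: str,
    direction: str,
) -> List[TargetPrediction]:
    """Targets of one selected feature, ranked by |log ratio fold change|.

    *X* holds the predictor columns of all the cluster's ES genes (the model
    is fitted on the same genes); *es_class* maps gene id to ES-up/ES-down.
    """
    if direction not in ("ES-up", "ES-down"):
        raise ValueError("direction must be 'ES-up' or 'ES-down'")
    names = model.predictor_names()
    if feature not in names:
        raise ValueError(f"feature {feature!r} is not among the model's predictors")
    j = names.index(feature)
    terms = predictor_log_terms(model, X)
    with_ratio = model.prior_log_ratio + terms.sum(axis=1)
    without_ratio = with_ratio - terms[:, j]

    out: List[TargetPrediction] = []
    for i, gene in enumerate(X.index):
        if es_class.get(gene) != direction:
            continue
        delta = with_ratio[i] - without_ratio[i]
        if direction == "ES-up" and delta > 0:
            out.append(TargetPrediction(feature, gene, float(with_ratio[i]), float(without_ratio[i])))
        elif direction == "ES-down" and delta < 0:
            out.append(TargetPrediction(feature, gene, float(with_ratio[i]), float(without_ratio[i])))
    out.sort(key=lambda t: -abs(t.log_ratio_with - t.log_ratio_without))
    for rank, t in enumerate(out, start=1):
        t.rank = rank
    return out


def match_status(status_primary: str, status_validation: str) -> bool:
    """Statuses match when equal or when either side is uniformly high (H)."""
    if status_primary == status_validation:
        return True
    return "H" in (status_primary, status_validation)


@dataclass
class ValidationSummary:
    feature: str
    role: str
    status_validation: str
    matched: bool
    n_b: int  # predicted targets present in the validation set
    n_e: int  # ... with usable expression
    pc: Optional[float]  # proportion with role-consistent fold change
    quartiles: Optional[tuple]  # (1Q, median, 3Q) of target fold changes


def validate_targets(
    targets: Sequence[TargetPrediction],
    role: str,
    validation_expr: ExpressionMatrix,
    status_validation: str = "",
    matched: bool = True,
    floor: float = 0.0,
) -> ValidationSummary:
    """Check predicted targets' fold-change direction in the validation set.

    The caller compares the cofactor's primary and validation statuses with
    :func:`match_status` and passes the outcome via *matched*; an unmatched
    feature is summarised but skipped (no Pc).  ``floor`` is the
    detectability threshold on the validation mean expression (both stages)
    for a target to count toward N_e.
    """
    feature = targets[0].feature if targets else ""
    if role not in _DECREASING_ROLES | _INCREASING_ROLES:
        raise ValueError(f"unknown role {role!r}")
    status_val = status_validation

    if not matched:
        return ValidationSummary(feature, role, status_val, False, 0, 0, None, None)

    mean_es = validation_expr.stage_values("ES").mean(axis=1)
    mean_df = validation_expr.stage_values("DF").mean(axis=1)

    present = [t for t in targets if t.gene in validation_expr.values.index]
    n_b = len(present)
    usable = [
        t
        for t in present
        if mean_es[t.gene] > floor and mean_df[t.gene] > floor and mean_df[t.gene] > 0
    ]
    n_e = len(usable)
    if n_e == 0:
        return ValidationSummary(feature, role, status_val, matched, n_b, 0, None, None)

    fcs = np.array([mean_es[t.gene] / mean_df[t.gene] for t in usable])
    if role in _DECREASING_ROLES:
        consistent = fcs > 1.0
    else:
        consistent = fcs < 1.0
    pc = float(consistent.mean())
    q1, med, q3 = np.percentile(fcs, [25, 50, 75])
    return ValidationSummary(
        feature, role, status_val, matched, n_b, n_e, pc, (float(q1), float(med), float(q3))
    )
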