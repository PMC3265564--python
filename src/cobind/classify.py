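"""Naive Bayes gene classification and top-(k1,k2) feature selection.

The classifier compares P(Y=1|X)/P(Y=0|X) under conditional independence.
Each predictor contributes

    P(X_j | Y) = (1 - lam_jY)^(1-I_j) * (lam_jY f_jY(x))^(I_j)

where I_j indicates score existence, lam_jY is the class-conditional
existence probability, and f_jY is a Gaussian-kernel density estimate with a
Silverman rule-of-thumb bandwidth.  Predictors derived from the proportion
test carry only the indicator; main-factor association scores are
always-present continuous.

Feature selection enumerates the 3 x 3 pairs of one ES-up and one ES-down
feature type and, for each pair, the full (k1, k2) grid with
0 <= k1, k2 <= 20 top features per type, scored by stratified ten-fold CV
with main-factor predictors always included.  k1 = k2 = 0 is the
main-factor-only baseline.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

DEFAULT_KMAX = 20
DEFAULT_FOLDS = 10
BANDWIDTH_FALLBACK = 0.1
_DENSITY_FLOOR = 1e-300  # guards log(0) from KDE underflow far in the tails


@dataclass(frozen=True)
class PredictorSpec:
    """A predictor column and how its density enters the classifier."""

    name: str
    kind: str  # 'continuous' | 'indicator' | 'always'

    def __post_init__(self):
        if self.kind not in ("continuous", "indicator", "always"):
            raise ValueError(f"unknown predictor kind {self.kind!r}")


def silverman_bandwidth(x: Sequence[float]) -> float:
    """0.9 * min(sd, IQR/1.34) * n^(-1/5), with fallback 0.1 when degenerate."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        return BANDWIDTH_FALLBACK
    sd = float(np.std(x, ddof=1))
    q75, q25 = np.percentile(x, [75, 25])
    h = 0.9 * min(sd, (q75 - q25) / 1.34) * n ** (-0.2)
    return h if h > 0 else BANDWIDTH_FALLBACK


@dataclass
class _PredictorParams:
    spec: PredictorSpec
    lam1: float
    lam0: float
    scores1: np.ndarray
    scores0: np.ndarray
    h1: float
    h0: float


@dataclass
class NBModel:
    """Fitted classifier: class prior plus per-predictor parameters."""

    p1: float
    predictors: List[_PredictorParams]

    @property
    def prior_log_ratio(self) -> float:
        return math.log(self.p1) - math.log(1.0 - self.p1)

    def predictor_names(self) -> List[str]:
        return [p.spec.name for p in self.predictors]


def _kde_log_density(xs: np.ndarray, train: np.ndarray, h: float) -> np.ndarray:
    """log of the Gaussian-kernel density of *train* evaluated at *xs*.

    A class with no training scores contributes a flat density of 1 (log 0):
    the smoothed existence probability already penalises the event, and no
    density estimate is available to sharpen it.
    """
    if train.size == 0:
        return np.zeros(xs.size)
    z = (xs[:, None] - train[None, :]) / h
    dens = np.exp(-0.5 * z * z).sum(axis=1) / (train.size * h * math.sqrt(2 * math.pi))
    return np.log(np.maximum(dens, _DENSITY_FLOOR))


def fit_nb(X: pd.DataFrame, y: Sequence[int], specs: Sequence[PredictorSpec]) -> NBModel:
    """Fit priors, existence probabilities and KDEs from labeled gene rows.

    *X* holds one column per spec (NaN = score absent); *y* holds 1 for ES-up
    and 0 for ES-down.  Priors are the plain ratio N1/N; existence
    probabilities use add-one smoothing (N_jY + 1) / (N_Y + 2) so held-out
    genes never meet a zero likelihood.
    """
    y = np.asarray(y, dtype=int)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present in the training data")
    params: List[_PredictorParams] = []
    for spec in specs:
        col = X[spec.name].to_numpy(dtype=float)
        if spec.kind == "always" and np.isnan(col).any():
            raise ValueError(f"always-present predictor {spec.name!r} has missing values")
        s1 = col[(y == 1) & ~np.isnan(col)]
        s0 = col[(y == 0) & ~np.isnan(col)]
        params.append(
            _PredictorParams(
                spec=spec,
                lam1=(s1.size + 1) / (n1 + 2),
                lam0=(s0.size + 1) / (n0 + 2),
                scores1=s1,
                scores0=s0,
                h1=silverman_bandwidth(s1),
                h0=silverman_bandwidth(s0),
            )
        )
    return NBModel(p1=n1 / (n1 + n0), predictors=params)


def predictor_log_terms(model: NBModel, X: pd.DataFrame) -> np.ndarray:
    """(n_rows, n_predictors) matrix of per-predictor log likelihood ratios."""
    out = np.empty((len(X), len(model.predictors)))
    for j, pp in enumerate(model.predictors):
        col = X[pp.spec.name].to_numpy(dtype=float)
        present = ~np.isnan(col)
        absent_term = math.log(1 - pp.lam1) - math.log(1 - pp.lam0)
        term = np.full(col.size, absent_term)
        if pp.spec.kind == "always":
            if not present.all():
                raise ValueError(f"always-present predictor {pp.spec.name!r} has missing values")
            term = _kde_log_density(col, pp.scores1, pp.h1) - _kde_log_density(
                col, pp.scores0, pp.h0
            )
        elif pp.spec.kind == "continuous":
            xs = col[present]
            term[present] = (
                math.log(pp.lam1)
                - math.log(pp.lam0)
                + _kde_log_density(xs, pp.scores1, pp.h1)
                - _kde_log_density(xs, pp.scores0, pp.h0)
            )
        else:  # indicator
            term[present] = math.log(pp.lam1) - math.log(pp.lam0)
        out[:, j] = term
    return out


def nb_log_ratio(model: NBModel, X: pd.DataFrame) -> np.ndarray:
    """Per-row log posterior-probability ratio under the fitted model."""
    return model.prior_log_ratio + predictor_log_terms(model, X).sum(axis=1)


def nb_ratio(model: NBModel, X: pd.DataFrame) -> np.ndarray:
    return np.exp(nb_log_ratio(model, X))


def classify(model: NBModel, X: pd.DataFrame) -> np.ndarray:
    """Predicted labels; ties (ratio exactly 1) resolve to ES-up (1)."""
    return (nb_log_ratio(model, X) >= 0).astype(int)


def _make_folds(y: np.ndarray, folds: int, seed: int) -> List[Tuple[np.ndarray, np.ndarray]]:
    min_class = min(int((y == 1).sum()), int((y == 0).sum()))
    eff = min(folds, min_class)
    if eff < folds:
        warnings.warn(f"reducing folds from {folds} to {eff}: smallest class has {min_class} genes")
    if eff < 2:
        raise ValueError("need at least 2 genes per class for cross-validation")
    skf = StratifiedKFold(n_splits=eff, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(y.size), y))


def cross_validate(
    X: pd.DataFrame,
    y: Sequence[int],
    specs: Sequence[PredictorSpec],
    folds: int = DEFAULT_FOLDS,
    seed: int = 0,
) -> Tuple[float, float]:
    """Class-stratified k-fold CV; returns (mean error, sd across folds / sqrt(k))."""
    y = np.asarray(y, dtype=int)
    errors = []
    for train_idx, test_idx in _make_folds(y, folds, seed):
        model = fit_nb(X.iloc[train_idx], y[train_idx], specs)
        pred = classify(model, X.iloc[test_idx])
        errors.append(float(np.mean(pred != y[test_idx])))
    errors = np.asarray(errors)
    return float(errors.mean()), float(errors.std(ddof=1) / math.sqrt(errors.size))


@dataclass
class SelectionResult:
    up_type: Optional[int]
    down_type: Optional[int]
    k1: int
    k2: int
    up_features: List[PredictorSpec]
    down_features: List[PredictorSpec]
    cv_error: float
    cv_se: float
    baseline_error: float
    baseline_se: float
    n_pairs_evaluated: int = 0

    @property
    def selected_specs(self) -> List[PredictorSpec]:
        return list(self.up_features) + list(self.down_features)


def select_features(
    ranked_up: Dict[int, List[PredictorSpec]],
    ranked_down: Dict[int, List[PredictorSpec]],
    X: pd.DataFrame,
    y: Sequence[int],
    mf_specs: Sequence[PredictorSpec],
    kmax: int = DEFAULT_KMAX,
    folds: int = DEFAULT_FOLDS,
    seed: int = 0,
    cv_fn: Optional[Callable] = None,
) -> SelectionResult:
    """Grid search over the 9 feature-type pairs and all (k1, k2) counts.

    ``ranked_up[w]`` / ``ranked_down[w]`` list candidate predictors of type w
    in increasing-p-value order; w values absent from the dicts contribute an
    empty list, so all 3 x 3 type pairs are still enumerated.  Main-factor
    predictors (*mf_specs*) are always included.  Ties on CV error break
    toward the smallest k1 + k2, then smallest k1, then the lexicographically
    first (up_type, down_type) pair.

    ``cv_fn(up_type, down_type, k1, k2, specs) -> (error, se)`` overrides the
    internal evaluator (used for instrumentation); the default evaluator
    reproduces :func:`cross_validate` on the same folds exactly, via shared
    per-fold fits.
    """
    y = np.asarray(y, dtype=int)
    up_types = sorted(set(ranked_up) | {0, 1, 2})
    down_types = sorted(set(ranked_down) | {0, 1, 2})
    mf_specs = list(mf_specs)

    best = None  # (error, k1+k2, k1, pair_rank) -> payload
    baseline: Optional[Tuple[float, float]] = None
    n_pairs = 0

    for pair_rank, (wu, wd) in enumerate(
        (wu, wd) for wu in up_types for wd in down_types
    ):
        ups = list(ranked_up.get(wu, []))[:kmax]
        downs = list(ranked_down.get(wd, []))[:kmax]
        n_pairs += 1

        if cv_fn is None:
            grids = _grid_cv(X, y, mf_specs, ups, downs, folds, seed)
        else:
            grids = None

        for k1 in range(min(kmax, len(ups)) + 1):
            for k2 in range(min(kmax, len(downs)) + 1):
                if cv_fn is None:
                    err, se = grids[0][k1, k2], grids[1][k1, k2]
                else:
                    err, se = cv_fn(wu, wd, k1, k2, mf_specs + ups[:k1] + downs[:k2])
                if k1 == 0 and k2 == 0 and baseline is None:
                    baseline = (err, se)
                key = (err, k1 + k2, k1, pair_rank)
                if best is None or key < best[0]:
                    best = (key, (wu, wd, k1, k2, ups[:k1], downs[:k2], err, se))

    assert best is not None and baseline is not None
    wu, wd, k1, k2, sel_up, sel_down, err, se = best[1]
    return SelectionResult(
        up_type=wu if k1 > 0 else None,
        down_type=wd if k2 > 0 else None,
        k1=k1,
        k2=k2,
        up_features=sel_up,
        down_features=sel_down,
        cv_error=err,
        cv_se=se,
        baseline_error=baseline[0],
        baseline_se=baseline[1],
        n_pairs_evaluated=n_pairs,
    )


def _grid_cv(
    X: pd.DataFrame,
    y: np.ndarray,
    mf_specs: List[PredictorSpec],
    ups: List[PredictorSpec],
    downs: List[PredictorSpec],
    folds: int,
    seed: int,
) -> Tuple[np.ndarray, np.ndarray]:
    """Evaluate the whole (k1, k2) grid with one fit per fold.

    Because every predictor's parameters are estimated independently, fitting
    all candidates at once and prefix-summing their per-gene log terms in
    rank order yields exactly the per-subset CV results.
    """
    cand = mf_specs + ups + downs
    n_up, n_down = len(ups), len(downs)
    fold_errors = []
    for train_idx, test_idx in _make_folds(y, folds, seed):
        model = fit_nb(X.iloc[train_idx], y[train_idx], cand)
        terms = predictor_log_terms(model, X.iloc[test_idx])
        base = model.prior_log_ratio + terms[:, : len(mf_specs)].sum(axis=1)
        t_up = terms[:, len(mf_specs): len(mf_specs) + n_up]
        t_down = terms[:, len(mf_specs) + n_up:]
        cum_up = np.concatenate(
            [np.zeros((terms.shape[0], 1)), np.cumsum(t_up, axis=1)], axis=1
        )
        cum_down = np.concatenate(
            [np.zeros((terms.shape[0], 1)), np.cumsum(t_down, axis=1)], axis=1
        )
        score = base[:, None, None] + cum_up[:, :, None] + cum_down[:, None, :]
        pred = score >= 0
        truth = (y[test_idx] == 1)[:, None, None]
        fold_errors.append((pred != truth).mean(axis=0))
    fe = np.stack(fold_errors)
    return fe.mean(axis=0), fe.std(axis=0, ddof=1) / math.sqrt(fe.shape[0])
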