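"""Feature screening: one-sided tests, BH FDR, direction labels, cofactor roles.

For every feature of every type (w), two one-sided comparisons between ES-up
and ES-down genes are run in both directions: a Wilcoxon rank-sum test on the
present feature scores, and a pooled two-sample proportion z-test on score
presence.  BH is applied within each (cluster, w, test kind, direction)
family at FDR q; a feature significant in either test kind in a direction is
labeled with that direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_Q = 0.10

ROLE_TABLE: Dict[Tuple[str, str], str] = {
    ("ES-up", "P"): "EA",
    ("ES-up", "N"): "DR",
    ("ES-up", "H"): "EA/DR",
    ("ES-down", "P"): "ER",
    ("ES-down", "N"): "DA",
    ("ES-down", "H"): "ER/DA",
}


def ranksum_test(
    scores_up: Sequence[float],
    scores_down: Sequence[float],
    direction: str,
) -> Tuple[float, bool]:
    """One-sided Wilcoxon rank-sum p-value; returns (p, testable).

    ``direction="up"`` tests whether the up-group scores are stochastically
    greater.  Exact enumeration is used when both groups have <= 10
    observations and there are no ties; otherwise the normal approximation
    with tie and continuity corrections.  An empty group yields p = 1,
    flagged untestable.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    x = np.asarray(scores_up, dtype=float)
    y = np.asarray(scores_down, dtype=float)
    if x.size == 0 or y.size == 0:
        return 1.0, False
    if direction == "down":
        x, y = y, x
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size <= 10 and y.size <= 10 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="greater", method=method)
    return float(res.pvalue), True


def proportion_test(
    k_up: int,
    n_up: int,
    k_down: int,
    n_down: int,
    direction: str,
) -> Tuple[float, bool]:
    """One-sided pooled two-sample z-test on proportions (no continuity
    correction); returns (p, testable).  Empty groups yield p = 1, untestable."""
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    if not (0 <= k_up <= n_up and 0 <= k_down <= n_down):
        raise ValueError("counts must satisfy 0 <= k <= n")
    if n_up == 0 or n_down == 0:
        return 1.0, False
    p1, n1 = k_up / n_up, n_up
    p2, n2 = k_down / n_down, n_down
    if direction == "down":
        p1, p2 = p2, p1
        n1, n2 = n2, n1
    pooled = (k_up + k_down) / (n_up + n_down)
    var = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    if var == 0:
        return 0.5, True
    z = (p1 - p2) / np.sqrt(var)
    return float(stats.norm.sf(z)), True


def bh_fdr(pvalues: Sequence[float], q: float = DEFAULT_Q) -> Tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up. Returns (rejected boolean mask, adjusted q-values)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    adj = ranked * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    qvals = np.empty(m)
    qvals[order] = adj
    reject = qvals <= q
    # step-up: everything below the largest rejected rank is rejected, which
    # the monotone adjusted values already guarantee.
    return reject, qvals


@dataclass
class FeatureTestResult:
    feature: str
    cluster: str
    w: int
    test: str  # 'ranksum' | 'proportion'
    direction: str  # 'up' | 'down'
    pvalue: float
    testable: bool
    qvalue: float = np.nan
    significant: bool = False


def test_features(
    score_matrix: pd.DataFrame,
    combo_w: Dict[str, int],
    up_genes: Sequence[str],
    down_genes: Sequence[str],
    cluster: str,
) -> List[FeatureTestResult]:
    """Run both tests in both directions for every feature of a cluster."""
    up_idx = [g for g in up_genes if g in score_matrix.index]
    down_idx = [g for g in down_genes if g in score_matrix.index]
    up = score_matrix.loc[up_idx]
    down = score_matrix.loc[down_idx]
    results: List[FeatureTestResult] = []
    for feat in score_matrix.columns:
        w = combo_w[feat]
        su = up[feat].dropna().to_numpy()
        sd = down[feat].dropna().to_numpy()
        for direction in ("up", "down"):
            p, ok = ranksum_test(su, sd, direction)
            results.append(FeatureTestResult(feat, cluster, w, "ranksum", direction, p, ok))
            p, ok = proportion_test(su.size, len(up_idx), sd.size, len(down_idx), direction)
            results.append(FeatureTestResult(feat, cluster, w, "proportion", direction, p, ok))
    return results


def label_features(
    results: List[FeatureTestResult],
    q: float = DEFAULT_Q,
) -> pd.DataFrame:
    """Apply BH within each (cluster, w, test, direction) family and label.

    Returns one row per feature with columns ``cluster``, ``w``, ``label``
    (ES-up / ES-down / none), ``best_p``, ``best_test`` (the test kind
    achieving the label's smallest p), plus per-family significance counts.
    Untestable results (p set to 1) are excluded from the BH families.
    """
    groups: Dict[Tuple[str, int, str, str], List[FeatureTestResult]] = {}
    for r in results:
        groups.setdefault((r.cluster, r.w, r.test, r.direction), []).append(r)
    for key, rs in groups.items():
        testable = [r for r in rs if r.testable]
        reject, qvals = bh_fdr([r.pvalue for r in testable], q)
        for r, rej, qv in zip(testable, reject, qvals):
            r.qvalue = float(qv)
            r.significant = bool(rej)

    rows = []
    by_feature: Dict[Tuple[str, str], List[FeatureTestResult]] = {}
    for r in results:
        by_feature.setdefault((r.cluster, r.feature), []).append(r)
    for (cluster, feat), rs in by_feature.items():
        sig_up = [r for r in rs if r.significant and r.direction == "up"]
        sig_down = [r for r in rs if r.significant and r.direction == "down"]
        if sig_up and sig_down:
            warnings.warn(f"feature {feat!r} significant in both directions; labeled none")
            label, chosen = "none", []
        elif sig_up:
            label, chosen = "ES-up", sig_up
        elif sig_down:
            label, chosen = "ES-down", sig_down
        else:
            label, chosen = "none", []
        if chosen:
            best = min(chosen, key=lambda r: r.pvalue)
            best_p, best_test = best.pvalue, best.test
        else:
            best_p, best_test = np.nan, ""
        rows.append(
            {
                "cluster": cluster,
                "feature": feat,
                "w": rs[0].w,
                "label": label,
                "best_p": best_p,
                "best_test": best_test,
            }
        )
    return pd.DataFrame(rows)


def reason_role(label: str, status: str) -> Optional[str]:
    """Map (feature direction label, cofactor expression status) to a role.

    Statuses outside {P, N, H} or an unlabeled feature yield no role.
    """
    return ROLE_TABLE.get((label, status))
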