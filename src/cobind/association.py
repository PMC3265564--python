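"""Gene x main-factor association scores, clustering, and ES gene calling.

The association score between a gene and a factor sums, over the factor's
peaks within a window of the TSS, the peak intensity weighted by an
exponential decay in the peak-to-TSS distance:

    score(g, F) = sum_i f_i * exp(-d_i / d0)

Scores are log(1+x)-transformed and quantile-normalized before k-means
clustering into five named clusters.  ES-up/ES-down gene calls combine a
fold-change threshold with a Welch t-test on log2(1+expression).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .core import ExpressionMatrix, GeneRecord, Peak

DEFAULT_D0 = 5000.0
DEFAULT_WINDOW = 1_000_000

CLUSTER_NAMES = (
    "uniformly-high",
    "Oct4",
    "Myc",
    "Oct4-moderate",
    "uniformly-low",
)


@dataclass
class ClusterAssignment:
    """Per-gene cluster membership with named clusters and factors of interest."""

    labels: pd.Series  # gene id -> cluster id (1..k)
    names: Dict[int, str]  # cluster id -> cluster name
    factors_of_interest: Dict[str, List[str]]  # cluster name -> factor list

    def genes_in(self, cluster_name: str) -> List[str]:
        ids = [cid for cid, n in self.names.items() if n == cluster_name]
        if not ids:
            return []
        return list(self.labels.index[self.labels.isin(ids)])

    @property
    def analysis_clusters(self) -> List[str]:
        """Clusters carrying main factors of interest (uniformly-low excluded)."""
        return [n for n in self.names.values() if self.factors_of_interest.get(n)]


def association_scores(
    peaks: Sequence[Peak],
    genes: Sequence[GeneRecord],
    d0: float = DEFAULT_D0,
    window: int = DEFAULT_WINDOW,
    factors: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Raw association score matrix (genes x factors).

    Genes with no peak of a factor within ``window`` bp of the TSS score 0.
    """
    if not d0 > 0:
        raise ValueError("d0 must be positive")
    if factors is None:
        factors = sorted({p.factor for p in peaks})
    gene_ids = [g.gene_id for g in genes]
    out = pd.DataFrame(0.0, index=gene_ids, columns=list(factors))

    by_factor_chrom: Dict[str, Dict[str, tuple]] = {}
    for f in factors:
        by_factor_chrom[f] = {}
    for p in peaks:
        if p.factor not in by_factor_chrom:
            continue
        by_factor_chrom[p.factor].setdefault(p.chrom, []).append(p)
    for f, per_chrom in by_factor_chrom.items():
        for chrom, plist in per_chrom.items():
            centers = np.array([p.center for p in plist], dtype=float)
            intens = np.array([p.intensity for p in plist], dtype=float)
            order = np.argsort(centers)
            centers, intens = centers[order], intens[order]
            per_chrom[chrom] = (centers, intens)

    for g in genes:
        for f in factors:
            entry = by_factor_chrom[f].get(g.chrom)
            if entry is None:
                continue
            centers, intens = entry
            lo = np.searchsorted(centers, g.tss - window, side="left")
            hi = np.searchsorted(centers, g.tss + window, side="right")
            if hi <= lo:
                continue
            d = np.abs(centers[lo:hi] - g.tss)
            out.at[g.gene_id, f] = float(np.sum(intens[lo:hi] * np.exp(-d / d0)))
    return out


def normalize_association(matrix: pd.DataFrame) -> pd.DataFrame:
    """log(1+x) transform followed by column-wise quantile normalization.

    Every column is mapped onto the mean empirical distribution (the mean of
    the column-sorted values); ties receive the mean reference value of their
    tied ranks, so within-column rank order is preserved.
    """
    if (matrix.values < 0).any():
        raise ValueError("raw association scores must be nonnegative")
    logged = np.log1p(matrix.values.astype(float))
    ref = np.sort(logged, axis=0).mean(axis=1)
    n = logged.shape[0]
    out = np.empty_like(logged)
    for j in range(logged.shape[1]):
        ranks = stats.rankdata(logged[:, j], method="average")  # 1..n, may be half-integer
        lo = np.floor(ranks).astype(int) - 1
        hi = np.ceil(ranks).astype(int) - 1
        out[:, j] = 0.5 * (ref[lo] + ref[hi])
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def _name_clusters(
    centers: pd.DataFrame,
    myc_group: Sequence[str],
    oct4_group: Sequence[str],
) -> Dict[int, str]:
    """Deterministic naming of the five k-means clusters from their mean profiles.

    uniformly-high maximizes the minimum excess over the grand mean across
    factors; uniformly-low minimizes the maximum; among the remaining three,
    Myc has the largest (Myc-group mean - Oct4-group mean), Oct4 the larger
    Oct4-group mean of the final two, Oct4-moderate the last.
    """
    grand = centers.mean(axis=0)
    excess = centers - grand
    remaining = list(centers.index)

    uh = excess.min(axis=1).idxmax()
    remaining.remove(uh)
    ul = excess.loc[remaining].max(axis=1).idxmin()
    remaining.remove(ul)
    diff = centers.loc[remaining, list(myc_group)].mean(axis=1) - centers.loc[
        remaining, list(oct4_group)
    ].mean(axis=1)
    myc = diff.idxmax()
    remaining.remove(myc)
    oct4 = centers.loc[remaining, list(oct4_group)].mean(axis=1).idxmax()
    remaining.remove(oct4)
    (oct4_mod,) = remaining
    return {
        uh: "uniformly-high",
        ul: "uniformly-low",
        myc: "Myc",
        oct4: "Oct4",
        oct4_mod: "Oct4-moderate",
    }


def cluster_genes(
    matrix: pd.DataFrame,
    myc_group: Sequence[str],
    oct4_group: Sequence[str],
    k: int = 5,
    restarts: int = 25,
    seed: int = 0,
) -> ClusterAssignment:
    """k-means (Euclidean, k-means++ init, ``restarts`` runs) plus cluster naming.

    The lowest within-cluster sum of squares over the restarts is kept.
    Factors of interest: all factors (uniformly-high), the Oct4 group (Oct4 and
    Oct4-moderate), the Myc group (Myc), none (uniformly-low).
    """
    if len(matrix) < k:
        raise ValueError(f"need at least k={k} genes, got {len(matrix)}")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    raw = km.fit_predict(matrix.values)
    labels = pd.Series(raw + 1, index=matrix.index)
    centers = pd.DataFrame(
        km.cluster_centers_, index=range(1, k + 1), columns=matrix.columns
    )
    if k == 5:
        names = _name_clusters(centers, myc_group, oct4_group)
    else:  # non-default k: keep numeric names, no factor-of-interest semantics
        names = {cid: f"cluster{cid}" for cid in range(1, k + 1)}
    all_factors = list(matrix.columns)
    foi_by_name = {
        "uniformly-high": all_factors,
        "Oct4": [f for f in all_factors if f in oct4_group],
        "Myc": [f for f in all_factors if f in myc_group],
        "Oct4-moderate": [f for f in all_factors if f in oct4_group],
        "uniformly-low": [],
    }
    factors_of_interest = {
        name: foi_by_name.get(name, []) for name in names.values()
    }
    return ClusterAssignment(labels=labels, names=names, factors_of_interest=factors_of_interest)


# ---------------------------------------------------------------------------
# ES gene calling and expression statuses

H_FLOOR = 500.0


def call_es_genes(
    expr: ExpressionMatrix,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Call ES-up/ES-down genes and P/N/H expression statuses.

    Returns a DataFrame indexed by gene with columns ``mean_es``, ``mean_df``,
    ``fc`` (ES over DF), ``pvalue`` (Welch t on log2(1+x)), ``es_class`` in
    {ES-up, ES-down, neutral} and ``status`` in {P, N, H, other}.

    ES-up requires fc > ``fc_threshold`` and p < ``alpha``; ES-down is the
    mirror image.  Status P/N use the fold-change thresholds alone (no test);
    H requires mean index > 500 at both stages and applies only when neither
    P nor N does.
    """
    es = expr.stage_values("ES").values.astype(float)
    df = expr.stage_values("DF").values.astype(float)
    mean_es = es.mean(axis=1)
    mean_df = df.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(mean_df > 0, mean_es / np.where(mean_df > 0, mean_df, 1.0), np.inf)
    if (mean_df == 0).any():
        warnings.warn("zero DF mean for some genes; fold change treated as +inf")
        fc = np.where(mean_df == 0, np.inf, fc)

    log_es = np.log2(1.0 + es)
    log_df = np.log2(1.0 + df)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(log_es, log_df, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)

    es_class = np.full(len(fc), "neutral", dtype=object)
    es_class[(fc > fc_threshold) & (p < alpha)] = "ES-up"
    with np.errstate(divide="ignore"):
        down = (np.where(fc > 0, 1.0 / fc, np.inf) > fc_threshold) & (p < alpha)
    es_class[down] = "ES-down"

    status = np.full(len(fc), "other", dtype=object)
    status[fc > fc_threshold] = "P"
    status[fc < 1.0 / fc_threshold] = "N"
    high = (status == "other") & (mean_es > H_FLOOR) & (mean_df > H_FLOOR)
    status[high] = "H"

    return pd.DataFrame(
        {
            "mean_es": mean_es,
            "mean_df": mean_df,
            "fc": fc,
            "pvalue": p,
            "es_class": es_class,
            "status": status,
        },
        index=expr.values.index,
    )
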