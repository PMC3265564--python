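"""TF-combination enumeration and gene x feature score matrices.

A feature couples w in {0,1,2} main factors of interest with one cofactor
motif.  Its score for a gene sums, over the gene's associated neighborhoods
that support the combination, the product of the geometric-mean peak
intensity, the geometric-mean motif-site score, and an exponential decay in
the average site-to-TSS distance:

    sum_k (prod_i f_ki)^(1/n_k) (prod_j g_kj)^(1/m_k)
          * exp(-(sum_i d_ki + sum_j d_kj) / ((n_k + m_k) d0))

Scores are carried in natural-log scale; a gene whose associated
neighborhoods never support the combination has no score (NaN / "NA").
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .core import GeneRecord, Neighborhood
from .io_formats import feature_name

DEFAULT_D0 = 5000.0


@dataclass(frozen=True)
class TFCombination:
    """w main factors (order-free, distinct) plus one cofactor motif."""

    mains: tuple
    motif: str

    def __post_init__(self):
        if len(set(self.mains)) != len(self.mains):
            raise ValueError("main factors in a combination must be distinct")
        if len(self.mains) > 2:
            raise ValueError("combinations carry at most 2 main factors")
        object.__setattr__(self, "mains", tuple(sorted(self.mains)))

    @property
    def w(self) -> int:
        return len(self.mains)

    @property
    def name(self) -> str:
        return feature_name(self.mains, self.motif)


def enumerate_combinations(
    main_factors: Sequence[str],
    cofactors: Sequence[str],
    w: int,
) -> List[TFCombination]:
    """All (|main_factors| choose w) x |cofactors| combinations, lexicographic."""
    if w not in (0, 1, 2):
        raise ValueError(f"w must be 0, 1 or 2, got {w}")
    mains = sorted(set(main_factors))
    if w > len(mains):
        raise ValueError(f"w={w} exceeds the {len(mains)} available main factors")
    motifs = sorted(set(cofactors))
    return [
        TFCombination(mains=combo, motif=m)
        for combo in itertools.combinations(mains, w)
        for m in motifs
    ]


def supports(nbhd: Neighborhood, combo: TFCombination) -> bool:
    """True iff the neighborhood holds >= 1 peak of every main factor of the
    combination and >= 1 site of its cofactor motif (cofactor only for w=0)."""
    present = nbhd.factors()
    if any(f not in present for f in combo.mains):
        return False
    return any(s.motif == combo.motif for s in nbhd.sites)


def feature_score(
    gene: GeneRecord,
    nbhds: Sequence[Neighborhood],
    combo: TFCombination,
    d0: float = DEFAULT_D0,
) -> Optional[float]:
    """Natural-log feature score of *combo* for *gene*, or None when absent.

    Only peaks of the combination's own main factors enter n_k / f_ki.  For
    w=0 the main-factor geometric mean is the empty product (1) and n_k = 0.
    """
    terms: List[float] = []
    for nb in nbhds:
        if not supports(nb, combo):
            continue
        sites = nb.motif_sites(combo.motif)
        fpeaks = [p for p in nb.peaks if p.factor in combo.mains]
        n_k, m_k = len(fpeaks), len(sites)
        log_f = 0.0
        dist_sum = 0.0
        for p in fpeaks:
            if not p.intensity > 0:
                raise ValueError(f"nonpositive peak intensity {p.intensity}")
            log_f += math.log(p.intensity)
            dist_sum += abs(p.center - gene.tss)
        log_g = 0.0
        for s in sites:
            if not s.score > 0:
                raise ValueError(f"nonpositive motif score {s.score}")
            log_g += math.log(s.score)
            dist_sum += abs(s.pos - gene.tss)
        log_term = (
            (log_f / n_k if n_k else 0.0)
            + log_g / m_k
            - dist_sum / ((n_k + m_k) * d0)
        )
        terms.append(log_term)
    if not terms:
        return None
    m = max(terms)
    return m + math.log(sum(math.exp(t - m) for t in terms))


def build_score_matrix(
    genes: Sequence[GeneRecord],
    nbhd_map: Dict[str, Sequence[Neighborhood]],
    combos: Sequence[TFCombination],
    d0: float = DEFAULT_D0,
) -> pd.DataFrame:
    """genes x combinations matrix of natural-log scores (NaN = absent).

    Row order follows *genes*; column order follows *combos* (the enumeration
    order), so the layout is deterministic.  Neighborhood terms are
    accumulated per supporting neighborhood across its associated genes at
    once, which matches :func:`feature_score` exactly but avoids the
    genes x combos x neighborhoods triple loop.
    """
    gene_ids = [g.gene_id for g in genes]
    row_of = {gid: i for i, gid in enumerate(gene_ids)}

    # unique neighborhoods and their associated gene rows / TSS coordinates
    nb_index: Dict[int, int] = {}
    nbhds: List[Neighborhood] = []
    nb_rows: List[List[int]] = []
    for g in genes:
        for nb in nbhd_map.get(g.gene_id, []):
            key = id(nb)
            if key not in nb_index:
                nb_index[key] = len(nbhds)
                nbhds.append(nb)
                nb_rows.append([])
            nb_rows[nb_index[key]].append(row_of[g.gene_id])
    nb_row_arr = [np.array(rows, dtype=int) for rows in nb_rows]
    nb_tss = [
        np.array([genes[r].tss for r in rows], dtype=float) for rows in nb_rows
    ]

    # per-neighborhood per-factor and per-motif summaries
    factor_stats: List[Dict[str, Tuple[int, float, np.ndarray]]] = []
    motif_stats: List[Dict[str, Tuple[int, float, np.ndarray]]] = []
    for nb in nbhds:
        fstat: Dict[str, list] = {}
        for p in nb.peaks:
            if not p.intensity > 0:
                raise ValueError(f"nonpositive peak intensity {p.intensity}")
            fstat.setdefault(p.factor, []).append((math.log(p.intensity), p.center))
        factor_stats.append(
            {
                f: (
                    len(v),
                    sum(lg for lg, _ in v),
                    np.array([pos for _, pos in v], dtype=float),
                )
                for f, v in fstat.items()
            }
        )
        mstat: Dict[str, list] = {}
        for s in nb.sites:
            if not s.score > 0:
                raise ValueError(f"nonpositive motif score {s.score}")
            mstat.setdefault(s.motif, []).append((math.log(s.score), s.pos))
        motif_stats.append(
            {
                m: (
                    len(v),
                    sum(lg for lg, _ in v),
                    np.array([pos for _, pos in v], dtype=float),
                )
                for m, v in mstat.items()
            }
        )

    acc = np.zeros((len(genes), len(combos)))
    present = np.zeros((len(genes), len(combos)), dtype=bool)
    for j, combo in enumerate(combos):
        for k, nb in enumerate(nbhds):
            ms = motif_stats[k].get(combo.motif)
            if ms is None:
                continue
            fs = [factor_stats[k].get(f) for f in combo.mains]
            if any(f is None for f in fs):
                continue
            n_k = sum(f[0] for f in fs)
            m_k = ms[0]
            log_f = sum(f[1] for f in fs)
            log_g = ms[1]
            positions = np.concatenate([f[2] for f in fs] + [ms[2]]) if fs else ms[2]
            gm = (log_f / n_k if n_k else 0.0) + log_g / m_k
            tss = nb_tss[k]
            dist = np.abs(positions[:, None] - tss[None, :]).sum(axis=0)
            rows = nb_row_arr[k]
            acc[rows, j] += np.exp(gm - dist / ((n_k + m_k) * d0))
            present[rows, j] = True

    with np.errstate(divide="ignore"):
        data = np.where(present, np.log(np.maximum(acc, 1e-320)), np.nan)
    return pd.DataFrame(data, index=gene_ids, columns=[c.name for c in combos])
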