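"""Merged genomic islands ("neighborhoods") and their gene association.

A window of +-``extend`` bp is opened around every peak center; windows whose
peak centers lie within ``merge_dist`` bp of each other are merged, the
merging applied recursively (i.e., the transitive closure of the pairwise
relation).  Only islands holding at least ``min_peaks`` peaks are retained.
"""

from __future__ import annotations

from typing import Dict, List, Sequence

from .core import GeneRecord, Neighborhood, Peak

DEFAULT_EXTEND = 500
DEFAULT_MERGE_DIST = 500
DEFAULT_MIN_PEAKS = 2
DEFAULT_ASSOC_DIST = 1_000_000


def build_neighborhoods(
    peaks: Sequence[Peak],
    extend: int = DEFAULT_EXTEND,
    merge_dist: int = DEFAULT_MERGE_DIST,
    min_peaks: int = DEFAULT_MIN_PEAKS,
) -> List[Neighborhood]:
    """Build retained neighborhoods from the given peaks.

    On a line, the transitive closure of "centers within ``merge_dist``"
    equals chaining sorted centers whose consecutive gaps are <= merge_dist,
    which makes the construction order-independent.  Peaks of the same factor
    may jointly satisfy the ``min_peaks`` minimum.
    """
    by_chrom: Dict[str, List[Peak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)

    out: List[Neighborhood] = []
    for chrom in sorted(by_chrom):
        plist = sorted(by_chrom[chrom], key=lambda p: (p.center, p.factor, p.intensity))
        run: List[Peak] = [plist[0]]
        for p in plist[1:]:
            if p.center - run[-1].center <= merge_dist:
                run.append(p)
            else:
                _emit(run, extend, min_peaks, out)
                run = [p]
        _emit(run, extend, min_peaks, out)
    return out


def _emit(run: List[Peak], extend: int, min_peaks: int, out: List[Neighborhood]) -> None:
    if len(run) < min_peaks:
        return
    centers = [p.center for p in run]
    out.append(
        Neighborhood(
            chrom=run[0].chrom,
            start=min(centers) - extend,
            end=max(centers) + extend,
            center=sum(centers) // len(centers),
            peaks=list(run),
        )
    )


def associate_neighborhoods(
    nbhds: Sequence[Neighborhood],
    genes: Sequence[GeneRecord],
    d: int = DEFAULT_ASSOC_DIST,
) -> Dict[str, List[Neighborhood]]:
    """Map each gene to the neighborhoods with |center - tss| <= d (inclusive)."""
    by_chrom: Dict[str, List[Neighborhood]] = {}
    for nb in nbhds:
        by_chrom.setdefault(nb.chrom, []).append(nb)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda nb: nb.center)

    import bisect

    mapping: Dict[str, List[Neighborhood]] = {}
    for g in genes:
        lst = by_chrom.get(g.chrom, [])
        centers = [nb.center for nb in lst]
        lo = bisect.bisect_left(centers, g.tss - d)
        hi = bisect.bisect_right(centers, g.tss + d)
        mapping[g.gene_id] = lst[lo:hi]
    return mapping
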