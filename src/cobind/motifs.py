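"""Cofactor binding-site detection inside neighborhoods.

Each w-mer of a neighborhood sequence is scored by the probability ratio

    r = P(w-mer | PWM) / P(w-mer | first-order Markov background),

on both strands, with masked (lowercase/N) positions skipped.  Score cutoffs
are calibrated per motif from a null distribution of w-mer scores over
length- and TSS-distance-matched control sequences; a site is called when its
score is strictly greater than the calibrated threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import (
    BASE_INDEX,
    GeneRecord,
    GenomeSequence,
    MotifSite,
    Neighborhood,
    PWMRecord,
)

DEFAULT_P = 9.09e-5
DEFAULT_N_CONTROLS = 20
DEFAULT_TRANSITION_PSEUDOCOUNT = 0.5
#: Sequences with fewer informative bases fall back to a pooled background.
MIN_INFORMATIVE = 200

_CODE = np.full(256, -1, dtype=np.int8)
for _b, _i in BASE_INDEX.items():
    _CODE[ord(_b)] = _i
# lowercase and N stay -1 (masked)

_COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.int8)  # A<->T, C<->G


def encode(seq: str) -> np.ndarray:
    """Encode bases as ints A=0,C=1,G=2,T=3; masked positions become -1."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class BackgroundModel:
    """First-order Markov background: 4x4 transition matrix + initial probs."""

    transition: np.ndarray
    initial: np.ndarray

    def __post_init__(self):
        self.transition = np.asarray(self.transition, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        if self.transition.shape != (4, 4) or self.initial.shape != (4,):
            raise ValueError("background model must be 4x4 transitions + 4 initial probs")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")
        with np.errstate(divide="ignore"):
            self._log_initial = np.log(self.initial)
            self._log_transition = np.log(self.transition)


class AllMaskedError(ValueError):
    """Raised when a sequence has too few informative bases for estimation."""


def _count_background(codes: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    # Counts are accumulated on both strands so that the estimate -- and hence
    # the called site set -- is invariant under reverse complementation.
    valid = codes >= 0
    fwd = np.bincount(codes[valid], minlength=4).astype(float)
    base_counts = fwd + fwd[::-1]
    a, b = codes[:-1], codes[1:]
    ok = (a >= 0) & (b >= 0)
    trans_counts = np.zeros((4, 4))
    if ok.any():
        np.add.at(trans_counts, (a[ok], b[ok]), 1.0)
        trans_counts += trans_counts[::-1, ::-1].T.copy()
    return base_counts, trans_counts


def estimate_background(
    seq: str,
    pseudocount: float = DEFAULT_TRANSITION_PSEUDOCOUNT,
) -> BackgroundModel:
    """Estimate the background from adjacent unmasked base pairs of *seq*.

    Raises :class:`AllMaskedError` when fewer than 2 informative bases are
    available; callers then substitute a pooled background.
    """
    codes = encode(seq)
    base_counts, trans_counts = _count_background(codes)
    if base_counts.sum() < 2:
        raise AllMaskedError("sequence has < 2 informative bases")
    trans = trans_counts + pseudocount
    rowsums = trans.sum(axis=1)
    if (rowsums == 0).any():  # pseudocount 0 and an unseen origin base
        trans[rowsums == 0] = 0.25
        rowsums = trans.sum(axis=1)
    init = base_counts.copy() + pseudocount
    return BackgroundModel(trans / rowsums[:, None], init / init.sum())


def pooled_background(
    seqs: Sequence[str],
    pseudocount: float = DEFAULT_TRANSITION_PSEUDOCOUNT,
) -> BackgroundModel:
    base_counts = np.zeros(4)
    trans_counts = np.zeros((4, 4))
    for s in seqs:
        b, t = _count_background(encode(s))
        base_counts += b
        trans_counts += t
    if base_counts.sum() < 2:
        raise AllMaskedError("pooled sequences have < 2 informative bases")
    trans = trans_counts + pseudocount
    init = base_counts + pseudocount
    return BackgroundModel(trans / trans.sum(axis=1, keepdims=True), init / init.sum())


def background_for(
    seq: str,
    pooled: Optional[BackgroundModel],
    pseudocount: float = DEFAULT_TRANSITION_PSEUDOCOUNT,
    min_informative: int = MIN_INFORMATIVE,
) -> BackgroundModel:
    """Per-sequence background with pooled fallback for short/masked sequences."""
    codes = encode(seq)
    n_informative = int((codes >= 0).sum())
    if n_informative >= min_informative:
        return estimate_background(seq, pseudocount)
    if pooled is None:
        if n_informative >= 2:
            return estimate_background(seq, pseudocount)
        raise AllMaskedError("sequence too masked and no pooled background supplied")
    return pooled


def _strand_scores(codes: np.ndarray, log_pwm: np.ndarray, bg: BackgroundModel) -> np.ndarray:
    """log-ratio scores for every w-mer start of an encoded strand (NaN = masked)."""
    w = log_pwm.shape[1]
    L = codes.size
    n = L - w + 1
    if n <= 0:
        return np.empty(0)
    safe = np.where(codes >= 0, codes, 0)
    log_init = bg._log_initial
    log_trans = bg._log_transition

    num = np.zeros(n)
    for j in range(w):
        num += log_pwm[safe[j:j + n], j]
    den = log_init[safe[:n]].copy()
    if w > 1:
        step = log_trans[safe[:-1], safe[1:]]  # length L-1
        csum = np.concatenate(([0.0], np.cumsum(step)))
        den += csum[w - 1:] - csum[:n]

    scores = num - den
    masked = codes < 0
    if masked.any():
        bad = np.convolve(masked.astype(np.int32), np.ones(w, dtype=np.int32), "valid") > 0
        scores[bad] = np.nan
    return scores


def _rc_codes(codes: np.ndarray) -> np.ndarray:
    rc = _COMPLEMENT[np.where(codes >= 0, codes, 0)][::-1]
    return np.where(codes[::-1] >= 0, rc, -1)


def _score_codes(
    codes: np.ndarray,
    rc_codes: np.ndarray,
    log_pwm: np.ndarray,
    bg: BackgroundModel,
) -> Tuple[np.ndarray, np.ndarray]:
    w = log_pwm.shape[1]
    if w > codes.size:
        return np.empty(0), np.empty(0)
    fwd = _strand_scores(codes, log_pwm, bg)
    rev = _strand_scores(rc_codes, log_pwm, bg)[::-1]
    return np.exp(fwd), np.exp(rev)


def score_wmers(
    seq: str,
    pwm: PWMRecord,
    bg: BackgroundModel,
) -> Tuple[np.ndarray, np.ndarray]:
    """Probability-ratio scores r for every w-mer of *seq*, both strands.

    Returns ``(forward, reverse)`` arrays of length ``L - w + 1``; entry ``i``
    of either array refers to the w-mer occupying ``seq[i:i+w]``.  The reverse
    entry scores the reverse complement of that w-mer under the same
    background.  w-mers overlapping a masked base are NaN.
    """
    codes = encode(seq)
    return _score_codes(codes, _rc_codes(codes), np.log(pwm.matrix), bg)


# ---------------------------------------------------------------------------
# matched controls


class ControlSamplingError(RuntimeError):
    pass


def _nearest_tss_distance(nbhd: Neighborhood, genes: Sequence[GeneRecord]) -> int:
    ds = [abs(nbhd.center - g.tss) for g in genes if g.chrom == nbhd.chrom]
    if not ds:
        raise ValueError(f"no gene on chromosome {nbhd.chrom}")
    return min(ds)


def sample_matched_controls(
    genome: GenomeSequence,
    genes: Sequence[GeneRecord],
    nbhd: Neighborhood,
    n: int = DEFAULT_N_CONTROLS,
    seed: int = 0,
    tolerance: float = 0.10,
    max_tries: int = 1000,
) -> List[str]:
    """Draw *n* control sequences matching the neighborhood's length and its
    center-to-nearest-TSS distance (within +-``tolerance``).

    Controls are placed on either flank of randomly chosen TSSs.  If no
    eligible position is found in ``max_tries`` draws the tolerance is relaxed
    to 25% with a warning; a second failure raises.
    """
    rng = np.random.default_rng(seed)
    length = nbhd.length
    target_d = _nearest_tss_distance(nbhd, genes)
    genes = list(genes)

    def attempt(tol: float) -> Optional[List[str]]:
        out: List[str] = []
        tries = 0
        while len(out) < n and tries < max_tries:
            tries += 1
            g = genes[rng.integers(len(genes))]
            side = 1 if rng.random() < 0.5 else -1
            d = rng.uniform(max(0.0, target_d * (1 - tol)), target_d * (1 + tol))
            center = int(round(g.tss + side * d))
            start = center - length // 2
            end = start + length
            if start < 0 or end > genome.length(g.chrom):
                continue
            out.append(genome.fetch(g.chrom, start, end))
        return out if len(out) == n else None

    result = attempt(tolerance)
    if result is None:
        warnings.warn(
            f"matched-control sampling at +-{tolerance:.0%} failed for "
            f"{nbhd.chrom}:{nbhd.start}-{nbhd.end}; relaxing to +-25%"
        )
        result = attempt(0.25)
    if result is None:
        raise ControlSamplingError(
            f"no eligible control positions for neighborhood "
            f"{nbhd.chrom}:{nbhd.start}-{nbhd.end}"
        )
    return result


# ---------------------------------------------------------------------------
# threshold calibration


@dataclass
class NullDistribution:
    """Sorted null w-mer score sample for one motif."""

    motif: str
    scores: np.ndarray

    def __post_init__(self):
        self.scores = np.sort(np.asarray(self.scores, dtype=float))

    @property
    def size(self) -> int:
        return self.scores.size


def calibrate_threshold(null: NullDistribution, p: float = DEFAULT_P) -> float:
    """Score cutoff at tail probability *p*: the ceil((1-p)*n)-th order statistic.

    A site is called iff its score is strictly greater than the threshold.
    """
    n = null.size
    if n * p < 1:
        raise ValueError(
            f"null sample of size {n} cannot calibrate p={p}; need more control sequence (>= {int(np.ceil(1 / p))} scores)"
        )
    k = int(np.ceil((1 - p) * n))  # 1-based order statistic
    k = min(max(k, 1), n)
    return float(null.scores[k - 1])


# ---------------------------------------------------------------------------
# full scanning procedure


def _finite(scores: np.ndarray) -> np.ndarray:
    return scores[np.isfinite(scores)]


def build_null_distributions(
    control_seqs: Sequence[str],
    pwms: Sequence[PWMRecord],
    pooled_bg: BackgroundModel,
    pseudocount: float = DEFAULT_TRANSITION_PSEUDOCOUNT,
) -> Dict[str, NullDistribution]:
    """Pool w-mer scores (both strands) of each motif over the control set."""
    samples: Dict[str, List[np.ndarray]] = {pwm.name: [] for pwm in pwms}
    log_pwms = {pwm.name: np.log(pwm.matrix) for pwm in pwms}
    for seq in control_seqs:
        try:
            bg = background_for(seq, pooled_bg, pseudocount)
        except AllMaskedError:
            continue
        codes = encode(seq)
        rc = _rc_codes(codes)
        for pwm in pwms:
            fwd, rev = _score_codes(codes, rc, log_pwms[pwm.name], bg)
            samples[pwm.name].append(_finite(fwd))
            samples[pwm.name].append(_finite(rev))
    return {
        name: NullDistribution(name, np.concatenate(parts) if parts else np.empty(0))
        for name, parts in samples.items()
    }


def call_sites(
    nbhds: Sequence[Neighborhood],
    pwms: Sequence[PWMRecord],
    genome: GenomeSequence,
    genes: Sequence[GeneRecord],
    p: float = DEFAULT_P,
    seed: int = 0,
    n_controls: int = DEFAULT_N_CONTROLS,
    max_null_nbhds: Optional[int] = 8,
    pseudocount: float = DEFAULT_TRANSITION_PSEUDOCOUNT,
) -> Dict[str, float]:
    """Calibrate per-motif thresholds and fill ``nbhd.sites`` in place.

    Null scores are pooled across the controls of (a seeded subsample of) the
    neighborhoods; ``max_null_nbhds`` caps how many neighborhoods contribute
    controls, which bounds runtime while keeping the null sample far larger
    than 1/p.  Returns the motif -> threshold mapping.
    """
    if not nbhds:
        return {}
    rng = np.random.default_rng(seed)
    nbhd_seqs = [genome.fetch(nb.chrom, nb.start, nb.end) for nb in nbhds]
    pooled_bg = pooled_background(nbhd_seqs, pseudocount)

    idx = np.arange(len(nbhds))
    if max_null_nbhds is not None and len(nbhds) > max_null_nbhds:
        idx = rng.choice(idx, size=max_null_nbhds, replace=False)
    control_seqs: List[str] = []
    for i in idx:
        control_seqs.extend(
            sample_matched_controls(
                genome, genes, nbhds[i], n=n_controls, seed=int(rng.integers(2**31))
            )
        )

    nulls = build_null_distributions(control_seqs, pwms, pooled_bg, pseudocount)
    thresholds = {name: calibrate_threshold(null, p) for name, null in nulls.items()}

    log_pwms = {pwm.name: np.log(pwm.matrix) for pwm in pwms}
    for nb, seq in zip(nbhds, nbhd_seqs):
        try:
            bg = background_for(seq, pooled_bg, pseudocount)
        except AllMaskedError:
            nb.sites = []
            continue
        codes = encode(seq)
        rc = _rc_codes(codes)
        sites: List[MotifSite] = []
        for pwm in pwms:
            thr = thresholds[pwm.name]
            fwd, rev = _score_codes(codes, rc, log_pwms[pwm.name], bg)
            for strand, scores in (("+", fwd), ("-", rev)):
                hits = np.flatnonzero(np.isfinite(scores) & (scores > thr))
                for i in hits:
                    sites.append(
                        MotifSite(
                            motif=pwm.name,
                            chrom=nb.chrom,
                            pos=nb.start + int(i),
                            strand=strand,
                            score=float(scores[i]),
                        )
                    )
        nb.sites = sites
    return thresholds
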