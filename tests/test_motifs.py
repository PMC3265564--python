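import math

import numpy as np
import pytest

from cobind.core import GeneRecord, GenomeSequence, PWMRecord
from cobind.motifs import (
    AllMaskedError,
    BackgroundModel,
    ControlSamplingError,
    NullDistribution,
    build_null_distributions,
    calibrate_threshold,
    call_sites,
    encode,
    estimate_background,
    pooled_background,
    sample_matched_controls,
    score_wmers,
)
from cobind.neighborhoods import build_neighborhoods
from cobind.core import Peak

UNIFORM_BG = BackgroundModel(np.full((4, 4), 0.25), np.full(4, 0.25))


def _uniform_pwm(w):
    return PWMRecord("U", np.full((4, w), 0.25))


class TestEstimateBackground:
    def test_homopolymer(self):
        bg = estimate_background("AAAA", pseudocount=0.0)
        assert bg.transition[0, 0] == pytest.approx(1.0)

    def test_alternating(self):
        bg = estimate_background("ACACAC", pseudocount=0.0)
        # A->C and C->A are the only transitions out of A and C
        assert bg.transition[0, 1] == pytest.approx(1.0)
        assert bg.transition[1, 0] == pytest.approx(1.0)

    def test_iid_uniform_concentration(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=10_000))
        bg = estimate_background(seq)
        assert (bg.transition > 0.22).all() and (bg.transition < 0.28).all()

    def test_all_masked_raises(self):
        with pytest.raises(AllMaskedError):
            estimate_background("acgtnnn" * 10)

    def test_masked_positions_skipped(self):
        # the masked run breaks the adjacency; only AA and TT pairs counted
        bg = estimate_background("AAaaTT", pseudocount=0.0)
        assert bg.transition[0, 0] == pytest.approx(1.0)

    def test_strand_symmetric_estimate(self, rng):
        seq = "".join(rng.choice(list("ACGT"), p=[0.4, 0.2, 0.1, 0.3], size=3000))
        rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        a, b = estimate_background(seq), estimate_background(rc)
        np.testing.assert_allclose(a.transition, b.transition)
        np.testing.assert_allclose(a.initial, b.initial)


class TestScoreWmers:
    def test_uniform_pwm_uniform_bg_scores_one(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=200))
        fwd, rev = score_wmers(seq, _uniform_pwm(5), UNIFORM_BG)
        np.testing.assert_allclose(fwd, 1.0, rtol=1e-12)
        np.testing.assert_allclose(rev, 1.0, rtol=1e-12)

    def test_width1_informative_column(self):
        mat = np.array([[10.0], [0.0], [0.0], [0.0]])
        mat = (mat + 0.01) / (mat + 0.01).sum()
        pwm = PWMRecord("A1", mat)
        fwd, _ = score_wmers("A", pwm, UNIFORM_BG)
        assert fwd[0] == pytest.approx((10.01 / 10.04) / 0.25, rel=1e-12)
        assert fwd[0] == pytest.approx(3.99, abs=0.01)

    def test_masked_overlap_nan(self):
        fwd, rev = score_wmers("ACGTaCGTA", _uniform_pwm(3), UNIFORM_BG)
        # w-mers covering index 4 (lowercase) are NaN
        assert np.isnan(fwd[2]) and np.isnan(fwd[3]) and np.isnan(fwd[4])
        assert np.isfinite(fwd[0]) and np.isfinite(fwd[6])
        assert np.isnan(rev[2]) and np.isfinite(rev[0])

    def test_wider_than_sequence(self):
        fwd, rev = score_wmers("ACG", _uniform_pwm(5), UNIFORM_BG)
        assert fwd.size == 0 and rev.size == 0

    def test_probability_ratio_oracle(self, rng):
        """Direct per-w-mer probability computation, no sliding-window algebra."""
        seq = "".join(rng.choice(list("ACGT"), p=[0.3, 0.25, 0.2, 0.25], size=400))
        bg = estimate_background(seq)
        mat = rng.dirichlet(np.ones(4) * 0.7, size=6).T
        pwm = PWMRecord("R", mat)
        fwd, rev = score_wmers(seq, pwm, bg)
        idx = {b: i for i, b in enumerate("ACGT")}
        comp = str.maketrans("ACGT", "TGCA")
        for i in rng.choice(len(fwd), size=60, replace=False):
            wmer = seq[i:i + 6]
            num = math.prod(mat[idx[b], j] for j, b in enumerate(wmer))
            den = bg.initial[idx[wmer[0]]] * math.prod(
                bg.transition[idx[a], idx[b]] for a, b in zip(wmer, wmer[1:])
            )
            assert fwd[i] == pytest.approx(num / den, rel=1e-12)
            rcw = wmer.translate(comp)[::-1]
            num_rc = math.prod(mat[idx[b], j] for j, b in enumerate(rcw))
            den_rc = bg.initial[idx[rcw[0]]] * math.prod(
                bg.transition[idx[a], idx[b]] for a, b in zip(rcw, rcw[1:])
            )
            assert rev[i] == pytest.approx(num_rc / den_rc, rel=1e-12)

    def test_strand_symmetry_site_set(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=500))
        rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        mat = rng.dirichlet(np.ones(4) * 0.5, size=7).T
        pwm = PWMRecord("S", mat)
        bg = estimate_background(seq)  # strand-symmetric, equal for rc
        fwd, rev = score_wmers(seq, pwm, bg)
        fwd_rc, rev_rc = score_wmers(rc, pwm, bg)
        # position i on seq maps to L - w - i on the reverse complement
        np.testing.assert_allclose(fwd, rev_rc[::-1], rtol=1e-12)
        np.testing.assert_allclose(rev, fwd_rc[::-1], rtol=1e-12)


# ---------------------------------------------------------------------------
# matched controls


def _toy_genome(rng, L=300_000):
    seq = "".join(rng.choice(list("ACGT"), size=L))
    return GenomeSequence({"chr1": seq})


def _toy_nbhd(center=150_000, half=600):
    peaks = [Peak("chr1", center - 100, "F", 1.0), Peak("chr1", center + 100, "F", 1.0)]
    (nb,) = build_neighborhoods(peaks)
    return nb


class TestMatchedControls:
    def test_lengths_and_distance_match(self, rng):
        genome = _toy_genome(rng)
        genes = [GeneRecord(f"g{i}", "chr1", int(t)) for i, t in
                 enumerate(rng.integers(20_000, 280_000, size=12))]
        nb = _toy_nbhd()
        target = min(abs(nb.center - g.tss) for g in genes)
        controls = sample_matched_controls(genome, genes, nb, n=20, seed=7)
        assert len(controls) == 20
        assert all(len(c) == nb.length for c in controls)

    def test_determinism(self, rng):
        genome = _toy_genome(rng)
        genes = [GeneRecord("g", "chr1", 100_000), GeneRecord("h", "chr1", 200_000)]
        nb = _toy_nbhd()
        a = sample_matched_controls(genome, genes, nb, seed=3)
        b = sample_matched_controls(genome, genes, nb, seed=3)
        assert a == b

    def test_impossible_raises(self, rng):
        genome = GenomeSequence({"chr1": "ACGT" * 300})
        genes = [GeneRecord("g", "chr1", 600)]
        nb = _toy_nbhd(center=600)
        nb.start, nb.end = 0, 5000  # longer than the chromosome
        with pytest.warns(UserWarning):
            with pytest.raises(ControlSamplingError):
                sample_matched_controls(genome, genes, nb, n=5, seed=0)


class TestCalibrateThreshold:
    def test_order_statistic_example(self):
        null = NullDistribution("m", np.arange(1, 101, dtype=float))
        thr = calibrate_threshold(null, p=0.05)
        assert thr == 95
        assert (null.scores > thr).sum() == 5

    def test_boundary_p_equals_one_over_n(self):
        null = NullDistribution("m", np.arange(1, 51, dtype=float))
        thr = calibrate_threshold(null, p=1 / 50)
        assert thr == 49  # second largest
        assert (null.scores > thr).sum() == 1

    def test_all_equal_nothing_passes(self):
        null = NullDistribution("m", np.full(1000, 7.0))
        thr = calibrate_threshold(null, p=0.01)
        assert (null.scores > thr).sum() == 0

    def test_insufficient_null(self):
        null = NullDistribution("m", np.arange(10, dtype=float))
        with pytest.raises(ValueError, match="more control"):
            calibrate_threshold(null, p=1e-3)


class TestCallSites:
    def test_planted_consensus_recovered_and_calibrated(self, rng):
        # one strong planted instance in an otherwise background neighborhood
        L = 400_000
        seq = rng.choice(list("ACGT"), size=L)
        w = 10
        mat = np.full((4, w), 0.1 / 3)
        cons = rng.integers(0, 4, size=w)
        mat[cons, np.arange(w)] = 0.9
        pwm = PWMRecord("P", mat)
        center = 200_000
        inst = "".join("ACGT"[c] for c in cons)
        seq[center - 30:center - 30 + w] = list(inst)
        genome = GenomeSequence({"chr1": "".join(seq)})
        genes = [GeneRecord(f"g{i}", "chr1", int(t)) for i, t in
                 enumerate(rng.integers(20_000, 380_000, size=10))]
        peaks = [Peak("chr1", center - 100, "F", 1.0), Peak("chr1", center + 100, "F", 1.0)]
        nbhds = build_neighborhoods(peaks)
        thresholds = call_sites(nbhds, [pwm], genome, genes, p=1e-3, seed=5)
        positions = [s.pos for s in nbhds[0].sites]
        assert center - 30 in positions
        assert all(s.score > thresholds["P"] for s in nbhds[0].sites)

    def test_error_message_for_insufficient_null(self, rng):
        genome = _toy_genome(rng, L=50_000)
        genes = [GeneRecord("g", "chr1", 25_000)]
        peaks = [Peak("chr1", 25_100, "F", 1.0), Peak("chr1", 25_200, "F", 1.0)]
        nbhds = build_neighborhoods(peaks)
        with pytest.raises(ValueError, match="more control"):
            call_sites(nbhds, [_uniform_pwm(4)], genome, genes, p=1e-8, seed=0, n_controls=2)


def test_pooled_background_fallback_for_short_sequence(rng):
    pooled = pooled_background(["".join(rng.choice(list("ACGT"), size=1000))])
    from cobind.motifs import background_for

    short = "ACGTACGT"
    bg = background_for(short, pooled)
    np.testing.assert_allclose(bg.transition, pooled.transition)
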