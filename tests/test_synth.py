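import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import rand_score

from cobind.association import (
    association_scores,
    call_es_genes,
    cluster_genes,
    normalize_association,
)
from cobind.core import GenomeSequence
from cobind.synth import (
    ConfigurationError,
    PlantedFeature,
    SyntheticConfig,
    design_truth,
    generate_bundle,
    generate_expression,
    generate_genome,
    generate_pwms,
    plant_cofactor_sites,
    sample_instance,
    write_bundle,
)
from conftest import small_config, tiny_config


class TestGenerateGenome:
    def test_determinism(self):
        cfg = tiny_config(seed=9)
        rng1, rng2 = np.random.default_rng(9), np.random.default_rng(9)
        g1, genes1 = generate_genome(cfg, rng1)
        g2, genes2 = generate_genome(cfg, rng2)
        assert g1.chroms == g2.chroms
        assert genes1 == genes2

    def test_repeat_fraction_zero_no_lowercase(self):
        cfg = tiny_config(repeat_fraction=0.0)
        genome, _ = generate_genome(cfg, np.random.default_rng(0))
        for seq in genome.chroms.values():
            assert seq == seq.upper()

    def test_gc_concentration(self):
        cfg = SyntheticConfig(
            seed=0, n_chromosomes=1, chrom_length=1_000_000, n_genes=20,
            gc=0.5, repeat_fraction=0.0,
        )
        genome, _ = generate_genome(cfg, np.random.default_rng(0))
        seq = genome["chr1"].upper()
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert 0.48 <= gc <= 0.52

    def test_repeat_fraction_realized(self):
        cfg = tiny_config(repeat_fraction=0.10)
        genome, _ = generate_genome(cfg, np.random.default_rng(1))
        seq = "".join(genome.chroms.values())
        frac = sum(1 for b in seq if b.islower()) / len(seq)
        # tracts may overlap, so the realized fraction can fall a little short
        assert 0.07 <= frac <= 0.12

    def test_tss_spacing(self):
        cfg = tiny_config()
        genome, genes = generate_genome(cfg, np.random.default_rng(2))
        for chrom in genome.names():
            tss = sorted(g.tss for g in genes if g.chrom == chrom)
            assert min(np.diff(tss)) >= cfg.min_tss_spacing

    def test_infeasible_spacing_error(self):
        cfg = SyntheticConfig(n_chromosomes=1, chrom_length=100_000, n_genes=50)
        with pytest.raises(ConfigurationError):
            generate_genome(cfg, np.random.default_rng(0))


class TestPeaks:
    def test_uniformly_low_rarely_bound(self, bundle):
        truth = bundle.truth
        low = truth.cluster.index[truth.cluster == "uniformly-low"]
        genes = {g.gene_id: g for g in bundle.genes}
        total = len(low) * len(bundle.config.factors)
        # a gene's own off-factor peaks appear with probability <= ~0.05; the
        # proximity check excludes neighboring genes' anchors, which always
        # fall inside the much wider 1 Mb association window
        own = sum(
            1
            for gid in low
            for f in bundle.config.factors
            if any(
                p.factor == f and p.chrom == genes[gid].chrom
                and abs(p.center - genes[gid].tss) <= 10_000
                for p in bundle.peaks
            )
        )
        assert own / total <= 0.15

    def test_myc_cluster_fully_bound(self, bundle):
        truth = bundle.truth
        genes = {g.gene_id: g for g in bundle.genes}
        for gid in truth.cluster.index[truth.cluster == "Myc"]:
            g = genes[gid]
            for f in bundle.config.myc_factors:
                n = sum(
                    1 for p in bundle.peaks
                    if p.factor == f and p.chrom == g.chrom and abs(p.center - g.tss) <= 1_000_000
                )
                assert n >= 2

    def test_cluster_recovery_rand_index(self, bundle):
        norm = normalize_association(association_scores(bundle.peaks, bundle.genes))
        ca = cluster_genes(
            norm, bundle.config.myc_factors, bundle.config.oct4_factors, seed=0
        )
        pred = ca.labels.map(ca.names)
        assert rand_score(bundle.truth.cluster[pred.index], pred) > 0.9


class TestPlanting:
    def test_most_targets_carry_instances(self, bundle):
        for fname, targets in bundle.truth.planted_targets.items():
            skips = bundle.truth.planted_skips[fname]
            assert len(targets) >= 0.875 * (len(targets) + len(skips))

    def test_empty_planted_leaves_genome_unchanged(self):
        cfg = tiny_config()
        rng = np.random.default_rng(3)
        genome, genes = generate_genome(cfg, rng)
        truth = design_truth(cfg, genes, rng)
        truth.planted = []
        pwms = generate_pwms(cfg, truth, rng)
        before = dict(genome.chroms)
        after = plant_cofactor_sites(genome, [], pwms, truth, genes, rng)
        assert after.chroms == before

    def test_instance_sampling_frequency(self, rng):
        from cobind.core import PWMRecord

        mat = np.array([[0.997], [0.001], [0.001], [0.001]])
        pwm = PWMRecord("M", mat)
        draws = [sample_instance(pwm, rng) for _ in range(4000)]
        freq = sum(1 for d in draws if d == "A") / len(draws)
        assert freq == pytest.approx(0.997, abs=0.01)

    def test_planted_instances_written_uppercase(self, bundle):
        for fname, positions in bundle.truth.planted_positions.items():
            motif = fname.split(".")[-1]
            width = next(p.width for p in bundle.pwms if p.name == motif)
            for chrom, pos in positions:
                segment = bundle.genome.fetch(chrom, pos, pos + width)
                assert segment == segment.upper()


class TestExpression:
    def test_effect_zero_few_es_calls(self):
        cfg = tiny_config(effect=0.0, planted=[])
        rng = np.random.default_rng(5)
        genome, genes = generate_genome(cfg, rng)
        truth = design_truth(cfg, genes, rng)
        expr, _ = generate_expression(cfg, truth, rng)
        out = call_es_genes(expr)
        called = (out.loc[truth.es_label.index, "es_class"] != "neutral").mean()
        assert called < 0.075

    def test_strong_effect_high_power(self, bundle):
        out = call_es_genes(bundle.expression)
        truth = bundle.truth.es_label
        up = truth.index[truth == "ES-up"]
        assert (out.loc[up, "es_class"] == "ES-up").mean() > 0.95
        down = truth.index[truth == "ES-down"]
        assert (out.loc[down, "es_class"] == "ES-down").mean() > 0.95

    def test_h_status_cofactors_above_floor(self, bundle):
        out = call_es_genes(bundle.expression)
        for motif, status in bundle.truth.cofactor_status.items():
            gene = bundle.truth.cofactor_gene[motif]
            if status == "H":
                assert out.at[gene, "mean_es"] > 500
                assert out.at[gene, "mean_df"] > 500
            assert out.at[gene, "status"] == status

    def test_validation_matrix_concordant(self, bundle):
        out = call_es_genes(bundle.validation)
        truth = bundle.truth.es_label
        up = truth.index[truth == "ES-up"]
        assert (out.loc[up, "fc"] > 1).mean() > 0.95


class TestBundle:
    def test_full_bundle_reproducible(self):
        a = generate_bundle(tiny_config(seed=11))
        b = generate_bundle(tiny_config(seed=11))
        assert a.genome.chroms == b.genome.chroms
        assert a.peaks == b.peaks
        pd.testing.assert_frame_equal(a.expression.values, b.expression.values)
        assert a.truth.planted_targets == b.truth.planted_targets

    def test_write_bundle_files(self, tmp_path):
        bundle = generate_bundle(tiny_config(seed=2))
        paths = write_bundle(bundle, str(tmp_path))
        for p in paths.values():
            assert (tmp_path / p.split("/")[-1]).exists()

    def test_write_bundle_byte_reproducible(self, tmp_path):
        for sub in ("a", "b"):
            write_bundle(generate_bundle(tiny_config(seed=4)), str(tmp_path / sub))
        for f in (tmp_path / "a").iterdir():
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()

    def test_invalid_planted_motif(self):
        cfg = tiny_config(
            planted=[PlantedFeature("Myc", (), "M99", "ES-up")]
        )
        with pytest.raises(ConfigurationError):
            generate_bundle(cfg)
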