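"""Synthetic input bundles with planted structure and a ground-truth manifest.

Generates every file the pipeline reads -- soft-masked genome, TSS
annotation, per-factor peak tables, PWMs, two-stage expression, a validation
expression set -- with designed gene clusters, planted cofactor co-binding
near chosen gene sets, and controllable expression effect sizes, so the full
analysis is testable end to end without external data.
"""

from __future__ import annotations

import dataclasses
import os
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import io_formats
from .core import (
    BASES,
    ExpressionMatrix,
    GeneRecord,
    GenomeSequence,
    Peak,
    PWMRecord,
)

CLUSTER_CYCLE = ("uniformly-high", "Oct4", "Myc", "Oct4-moderate", "uniformly-low")


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedFeature:
    """A TF combination planted near a gene set of one expression direction."""

    cluster: str
    mains: Tuple[str, ...]
    motif: str
    direction: str  # 'ES-up' | 'ES-down'
    n_targets: Optional[int] = None

    def __post_init__(self):
        if self.direction not in ("ES-up", "ES-down"):
            raise ConfigurationError("planted direction must be 'ES-up' or 'ES-down'")
        if len(self.mains) > 2:
            raise ConfigurationError("planted combinations carry at most 2 main factors")


@dataclass
class SyntheticConfig:
    seed: int = 0
    # genome
    n_chromosomes: int = 2
    chrom_length: int = 5_000_000
    gc: float = 0.42
    repeat_fraction: float = 0.05
    repeat_tract_length: int = 300
    # annotation
    n_genes: int = 400
    min_tss_spacing: int = 10_000
    # factors
    myc_factors: Tuple[str, ...] = ("E2f1", "Myc", "Mycn")
    oct4_factors: Tuple[str, ...] = ("Nanog", "Oct4", "Sox2")
    # peaks
    peaks_per_gene: Tuple[int, int] = (2, 4)
    peak_distance_mean: float = 20_000.0
    # one anchor per gene sits proximal to the TSS so the exponential decay in
    # the association score does not swamp the designed cluster contrast
    proximal_distance_mean: float = 2_000.0
    colocation_jitter: int = 150
    off_factor_prob: float = 0.05
    intensity_scale: float = 10.0
    intensity_sigma: float = 0.5
    moderate_scale: float = 0.4
    # cofactors
    n_cofactors: int = 20
    pwm_width: int = 12
    pwm_dominance: float = 0.9
    n_filtered_cofactors: int = 4  # motifs given 'other' status (dropped by selection)
    # expression
    n_es_samples: int = 8
    n_df_samples: int = 8
    effect: float = 2.0  # log2 fold change between stages for ES genes
    noise_sd: float = 0.25
    baseline_log2: float = 7.0
    up_fraction: float = 0.45
    down_fraction: float = 0.45
    # validation expression (day-0 vs day-4..6 analogue)
    n_val_es_samples: int = 3
    n_val_df_samples: int = 3
    planted: Optional[List[PlantedFeature]] = None

    @property
    def factors(self) -> List[str]:
        return list(self.myc_factors) + list(self.oct4_factors)

    def motif_names(self) -> List[str]:
        return [f"M{i + 1:02d}" for i in range(self.n_cofactors)]

    def default_planted(self) -> List[PlantedFeature]:
        myc, oct4 = self.myc_factors, self.oct4_factors
        names = self.motif_names()
        return [
            PlantedFeature("uniformly-high", (oct4[0],), names[0], "ES-up"),
            PlantedFeature("Oct4", (oct4[0], oct4[1]), names[1], "ES-down"),
            PlantedFeature("Myc", (myc[0],), names[2], "ES-down"),
            PlantedFeature("Oct4-moderate", (), names[3], "ES-up"),
        ]

    def validate(self) -> None:
        if not 0 < self.gc < 1:
            raise ConfigurationError("gc must be in (0, 1)")
        if not 0 <= self.repeat_fraction < 1:
            raise ConfigurationError("repeat fraction must be in [0, 1)")
        per_chrom = -(-self.n_genes // self.n_chromosomes)
        if self.chrom_length < (per_chrom + 1) * self.min_tss_spacing:
            raise ConfigurationError(
                f"chrom_length {self.chrom_length} cannot space {per_chrom} TSSs "
                f">= {self.min_tss_spacing} bp apart"
            )
        if self.effect < 0:
            raise ConfigurationError("effect size must be >= 0")
        planted = self.planted if self.planted is not None else self.default_planted()
        names = set(self.motif_names())
        factors = set(self.factors)
        for pf in planted:
            if pf.motif not in names:
                raise ConfigurationError(f"planted motif {pf.motif!r} not generated")
            if not set(pf.mains) <= factors:
                raise ConfigurationError(f"planted factors {pf.mains} not generated")


@dataclass
class GroundTruth:
    """What was planted, for downstream acceptance checks."""

    cluster: pd.Series  # gene id -> designed cluster name
    es_label: pd.Series  # gene id -> ES-up / ES-down / neutral
    cofactor_status: Dict[str, str]  # motif -> P / N / H / other
    cofactor_gene: Dict[str, str]  # motif -> cofactor gene id
    planted: List[PlantedFeature] = field(default_factory=list)
    planted_targets: Dict[str, List[str]] = field(default_factory=dict)  # feature name -> genes
    planted_skips: Dict[str, List[str]] = field(default_factory=dict)
    planted_positions: Dict[str, List[Tuple[str, int]]] = field(default_factory=dict)


@dataclass
class SyntheticBundle:
    config: SyntheticConfig
    genome: GenomeSequence
    genes: List[GeneRecord]
    peaks: List[Peak]
    pwms: List[PWMRecord]
    expression: ExpressionMatrix
    validation: ExpressionMatrix
    truth: GroundTruth


# ---------------------------------------------------------------------------
# genome + annotation


def generate_genome(
    config: SyntheticConfig, rng: np.random.Generator
) -> Tuple[GenomeSequence, List[GeneRecord]]:
    """I.i.d. genome at the configured GC with contiguous lowercase repeat
    tracts, and evenly spaced, jittered TSSs at least ``min_tss_spacing`` apart."""
    config.validate()
    p = np.array(
        [(1 - config.gc) / 2, config.gc / 2, config.gc / 2, (1 - config.gc) / 2]
    )
    chroms: Dict[str, str] = {}
    genes: List[GeneRecord] = []
    per_chrom = [config.n_genes // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_genes % config.n_chromosomes):
        per_chrom[i] += 1

    gene_no = 0
    base_arr = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    lower_arr = np.frombuffer("acgt".encode(), dtype=np.uint8)
    for ci in range(config.n_chromosomes):
        name = f"chr{ci + 1}"
        L = config.chrom_length
        codes = rng.choice(4, size=L, p=p)
        seq = base_arr[codes].copy()
        if config.repeat_fraction > 0:
            target = int(L * config.repeat_fraction)
            tract = config.repeat_tract_length
            n_tracts = max(1, target // tract)
            starts = rng.integers(0, L - tract, size=n_tracts)
            for s in starts:
                seq[s:s + tract] = lower_arr[codes[s:s + tract]]
        chroms[name] = seq.tobytes().decode("ascii")

        n = per_chrom[ci]
        spacing = L / (n + 1)
        # modest jitter keeps neighboring genes' peaks from leaking sizeable
        # association score across the interleaved cluster design
        jitter = max(0.0, min(spacing / 8.0, (spacing - config.min_tss_spacing) / 2.0))
        for k in range(n):
            tss = int((k + 1) * spacing + rng.uniform(-jitter, jitter))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneRecord(f"g{gene_no:04d}", name, tss, strand))
            gene_no += 1
    return GenomeSequence(chroms), genes


# ---------------------------------------------------------------------------
# design: clusters, ES labels, cofactor statuses


def design_truth(config: SyntheticConfig, genes: Sequence[GeneRecord], rng: np.random.Generator) -> GroundTruth:
    n = len(genes)
    gene_ids = [g.gene_id for g in genes]
    # interleave clusters along the genome so neighborhood association smears
    # symmetrically over clusters
    cluster = pd.Series(
        [CLUSTER_CYCLE[i % len(CLUSTER_CYCLE)] for i in range(n)], index=gene_ids
    )
    es_label = pd.Series("neutral", index=gene_ids, dtype=object)
    for cname in CLUSTER_CYCLE:
        members = list(cluster.index[cluster == cname])
        perm = rng.permutation(len(members))
        n_up = int(round(config.up_fraction * len(members)))
        n_down = int(round(config.down_fraction * len(members)))
        for i in perm[:n_up]:
            es_label[members[i]] = "ES-up"
        for i in perm[n_up:n_up + n_down]:
            es_label[members[i]] = "ES-down"

    planted = list(config.planted) if config.planted is not None else config.default_planted()
    motif_names = config.motif_names()
    planted_motifs = {pf.motif for pf in planted}
    status_cycle = ["P", "N", "H"]
    statuses: Dict[str, str] = {}
    n_other = 0
    ci = 0
    for m in motif_names:
        if m not in planted_motifs and n_other < config.n_filtered_cofactors:
            statuses[m] = "other"
            n_other += 1
        else:
            statuses[m] = status_cycle[ci % 3]
            ci += 1
    cof_gene = {m: f"cof_{m}" for m in motif_names}
    return GroundTruth(
        cluster=cluster,
        es_label=es_label,
        cofactor_status=statuses,
        cofactor_gene=cof_gene,
        planted=planted,
    )


# ---------------------------------------------------------------------------
# PWMs


def generate_pwms(config: SyntheticConfig, truth: GroundTruth, rng: np.random.Generator) -> List[PWMRecord]:
    pwms = []
    for name in config.motif_names():
        dominant = rng.integers(0, 4, size=config.pwm_width)
        mat = np.full((4, config.pwm_width), (1 - config.pwm_dominance) / 3.0)
        mat[dominant, np.arange(config.pwm_width)] = config.pwm_dominance
        pwms.append(PWMRecord(name, mat, [truth.cofactor_gene[name]]))
    return pwms


# ---------------------------------------------------------------------------
# peaks


def _cluster_profile(config: SyntheticConfig, cname: str) -> Tuple[List[str], float]:
    """(on factors, intensity scale) for a designed cluster."""
    if cname == "uniformly-high":
        return config.factors, 1.0
    if cname == "Oct4":
        return list(config.oct4_factors), 1.0
    if cname == "Myc":
        return list(config.myc_factors), 1.0
    if cname == "Oct4-moderate":
        return list(config.oct4_factors), config.moderate_scale
    return [], 1.0  # uniformly-low


def generate_peaks(
    config: SyntheticConfig,
    genes: Sequence[GeneRecord],
    truth: GroundTruth,
    genome: GenomeSequence,
    rng: np.random.Generator,
) -> List[Peak]:
    """Per-gene anchor positions at exponential distances from the TSS; every
    "on" factor drops one peak per anchor with a small jitter so that peaks of
    co-binding factors fall within the neighborhood merge distance."""
    peaks: List[Peak] = []
    lo_n, hi_n = config.peaks_per_gene
    margin = 1000
    # Cap anchor distances at a fraction of the local TSS spacing: otherwise
    # long-range anchors of one gene land next to a neighboring gene's TSS and
    # wash out the designed between-cluster association contrast.
    caps: Dict[str, float] = {}
    for chrom in {g.chrom for g in genes}:
        tss = np.sort([g.tss for g in genes if g.chrom == chrom])
        gap = float(np.median(np.diff(tss))) if tss.size > 1 else 1e9
        caps[chrom] = max(3000.0, 0.35 * gap)
    for g in genes:
        on_factors, scale = _cluster_profile(config, truth.cluster[g.gene_id])
        L = genome.length(g.chrom)
        n_anchors = int(rng.integers(lo_n, hi_n + 1))
        anchors = []
        for ai in range(n_anchors):
            mean_d = config.proximal_distance_mean if ai == 0 else config.peak_distance_mean
            d = min(rng.exponential(mean_d), caps[g.chrom])
            side = 1 if rng.random() < 0.5 else -1
            pos = int(np.clip(g.tss + side * d, margin, L - margin))
            anchors.append(pos)
        for f in config.factors:
            if f in on_factors:
                for a in anchors:
                    c = a + int(rng.integers(-config.colocation_jitter, config.colocation_jitter + 1))
                    c = int(np.clip(c, 0, L - 1))
                    intensity = float(
                        rng.lognormal(np.log(config.intensity_scale * scale), config.intensity_sigma)
                    )
                    peaks.append(Peak(chrom=g.chrom, center=c, factor=f, intensity=intensity))
            else:
                if rng.random() < config.off_factor_prob:
                    c = int(np.clip(g.tss + rng.integers(-1_000_000, 1_000_001), 0, L - 1))
                    intensity = float(
                        rng.lognormal(np.log(config.intensity_scale), config.intensity_sigma)
                    )
                    peaks.append(Peak(chrom=g.chrom, center=c, factor=f, intensity=intensity))
    peaks.sort(key=lambda p: (p.chrom, p.center, p.factor))
    return peaks


# ---------------------------------------------------------------------------
# planting motif instances


def sample_instance(pwm: PWMRecord, rng: np.random.Generator) -> str:
    """Draw one motif instance base-by-base from the PWM's column probabilities."""
    cols = [rng.choice(4, p=pwm.matrix[:, j]) for j in range(pwm.width)]
    return "".join(BASES[c] for c in cols)


def plant_cofactor_sites(
    genome: GenomeSequence,
    peaks: Sequence[Peak],
    pwms: Sequence[PWMRecord],
    truth: GroundTruth,
    genes: Sequence[GeneRecord],
    rng: np.random.Generator,
    window: int = 1_000_000,
    colocate: int = 500,
    max_offset: int = 250,
) -> GenomeSequence:
    """Write consensus-sampled motif instances near co-located peak groups of
    each planted combination's main factors, close to each target gene.

    For every target gene the eligible anchor closest to the TSS is used: a
    peak position where each required main factor (or, for w=0, at least two
    peaks of any factors) lies within ``colocate`` bp.  Genes with no eligible
    anchor are skipped with a warning and recorded in the manifest.
    """
    arrays = {name: bytearray(seq.encode("ascii")) for name, seq in genome.chroms.items()}
    pwm_by_name = {p.name: p for p in pwms}
    genes_by_id = {g.gene_id: g for g in genes}
    peaks_by_chrom: Dict[str, List[Peak]] = {}
    for p in peaks:
        peaks_by_chrom.setdefault(p.chrom, []).append(p)
    for chrom in peaks_by_chrom:
        peaks_by_chrom[chrom].sort(key=lambda p: p.center)

    for pf in truth.planted:
        pwm = pwm_by_name[pf.motif]
        members = truth.cluster.index[
            (truth.cluster == pf.cluster) & (truth.es_label == pf.direction)
        ]
        targets = list(members)
        if pf.n_targets is not None:
            targets = targets[: pf.n_targets]
        placed: List[str] = []
        skipped: List[str] = []
        positions: List[Tuple[str, int]] = []
        centers_by_chrom = {
            chrom: np.array([p.center for p in plist])
            for chrom, plist in peaks_by_chrom.items()
        }
        for gid in targets:
            g = genes_by_id[gid]
            plist = peaks_by_chrom.get(g.chrom, [])
            centers = centers_by_chrom.get(g.chrom, np.empty(0))
            lo = np.searchsorted(centers, g.tss - window)
            hi = np.searchsorted(centers, g.tss + window)
            cand = plist[lo:hi]
            cand.sort(key=lambda p: abs(p.center - g.tss))
            anchor = None
            for pivot in cand:
                nlo = np.searchsorted(centers, pivot.center - colocate)
                nhi = np.searchsorted(centers, pivot.center + colocate, side="right")
                near = plist[nlo:nhi]
                if pf.mains:
                    have = {q.factor for q in near}
                    if all(f in have for f in pf.mains):
                        anchor = pivot.center
                        break
                else:
                    if len(near) >= 2:
                        anchor = pivot.center
                        break
            if anchor is None:
                warnings.warn(
                    f"no eligible peak location for planted feature {pf.motif} near {gid}; skipped"
                )
                skipped.append(gid)
                continue
            offset = int(rng.integers(-max_offset, max_offset - pwm.width + 1))
            pos = int(np.clip(anchor + offset, 0, genome.length(g.chrom) - pwm.width))
            instance = sample_instance(pwm, rng)
            arrays[g.chrom][pos:pos + pwm.width] = instance.encode("ascii")
            placed.append(gid)
            positions.append((g.chrom, pos))
        fname = io_formats.feature_name(sorted(pf.mains), pf.motif)
        truth.planted_targets[fname] = placed
        truth.planted_skips[fname] = skipped
        truth.planted_positions[fname] = positions
    return GenomeSequence({name: arr.decode("ascii") for name, arr in arrays.items()})


# ---------------------------------------------------------------------------
# expression


_STATUS_MEANS_LOG2 = {
    # (ES mean, DF mean) on the log2 scale, chosen so raw-scale means land in
    # the intended P/N/H/other status regions
    "P": (np.log2(400.0), np.log2(100.0)),
    "N": (np.log2(100.0), np.log2(400.0)),
    "H": (np.log2(800.0), np.log2(780.0)),
    "other": (np.log2(50.0), np.log2(45.0)),
}


def _draw_matrix(
    means_es: np.ndarray,
    means_df: np.ndarray,
    index: List[str],
    n_es: int,
    n_df: int,
    noise_sd: float,
    rng: np.random.Generator,
    prefix: str,
) -> ExpressionMatrix:
    cols = [f"{prefix}ES{i + 1}" for i in range(n_es)] + [
        f"{prefix}DF{i + 1}" for i in range(n_df)
    ]
    stages = pd.Series(["ES"] * n_es + ["DF"] * n_df, index=cols)
    log2 = np.concatenate(
        [
            rng.normal(means_es[:, None], noise_sd, size=(len(index), n_es)),
            rng.normal(means_df[:, None], noise_sd, size=(len(index), n_df)),
        ],
        axis=1,
    )
    return ExpressionMatrix(pd.DataFrame(2.0 ** log2, index=index, columns=cols), stages)


def generate_expression(
    config: SyntheticConfig,
    truth: GroundTruth,
    rng: np.random.Generator,
) -> Tuple[ExpressionMatrix, ExpressionMatrix]:
    """Two-stage expression for genes + cofactor genes, and a concordant
    validation matrix (day-0-vs-later analogue).

    Regular genes sit at ``baseline_log2`` with +-effect/2 shifts by stage and
    label; cofactor genes follow their designed P/N/H/other status on the raw
    index scale.  Values are exponentiated to the raw scale for output.
    """
    gene_ids = list(truth.es_label.index)
    shift = np.zeros(len(gene_ids))
    labels = truth.es_label.to_numpy()
    shift[labels == "ES-up"] = config.effect / 2.0
    shift[labels == "ES-down"] = -config.effect / 2.0
    means_es = config.baseline_log2 + shift
    means_df = config.baseline_log2 - shift

    cof_ids = [truth.cofactor_gene[m] for m in sorted(truth.cofactor_gene)]
    cof_status = [truth.cofactor_status[m] for m in sorted(truth.cofactor_gene)]
    cof_es = np.array([_STATUS_MEANS_LOG2[s][0] for s in cof_status])
    cof_df = np.array([_STATUS_MEANS_LOG2[s][1] for s in cof_status])

    all_ids = gene_ids + cof_ids
    all_es = np.concatenate([means_es, cof_es])
    all_df = np.concatenate([means_df, cof_df])

    primary = _draw_matrix(
        all_es, all_df, all_ids, config.n_es_samples, config.n_df_samples,
        config.noise_sd, rng, prefix="",
    )
    validation = _draw_matrix(
        all_es, all_df, all_ids, config.n_val_es_samples, config.n_val_df_samples,
        config.noise_sd, rng, prefix="val_",
    )
    return primary, validation


# ---------------------------------------------------------------------------
# bundle


def generate_bundle(config: SyntheticConfig) -> SyntheticBundle:
    """Generate the full input bundle; byte-reproducible for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    genome, genes = generate_genome(config, rng)
    truth = design_truth(config, genes, rng)
    pwms = generate_pwms(config, truth, rng)
    peaks = generate_peaks(config, genes, truth, genome, rng)
    genome = plant_cofactor_sites(genome, peaks, pwms, truth, genes, rng)
    expression, validation = generate_expression(config, truth, rng)
    return SyntheticBundle(
        config=config,
        genome=genome,
        genes=genes,
        peaks=peaks,
        pwms=pwms,
        expression=expression,
        validation=validation,
        truth=truth,
    )


def write_bundle(bundle: SyntheticBundle, outdir: str) -> Dict[str, str]:
    """Write every input file plus the ground-truth manifest; returns paths."""
    io_formats.ensure_outdir(outdir)
    paths = {
        "genome": os.path.join(outdir, "genome.fa"),
        "genes": os.path.join(outdir, "genes.tsv"),
        "pwms": os.path.join(outdir, "pwms.txt"),
        "expression": os.path.join(outdir, "expression.tsv"),
        "validation": os.path.join(outdir, "validation_expression.tsv"),
        "truth": os.path.join(outdir, "ground_truth.tsv"),
        "config": os.path.join(outdir, "synth_config.yaml"),
    }
    io_formats.write_genome(bundle.genome, paths["genome"])
    io_formats.write_genes(bundle.genes, paths["genes"])
    io_formats.write_pwms(bundle.pwms, paths["pwms"])
    io_formats.write_expression(bundle.expression, paths["expression"])
    io_formats.write_expression(bundle.validation, paths["validation"])
    for factor in bundle.config.factors:
        p = os.path.join(outdir, f"peaks_{factor}.tsv")
        io_formats.write_peaks([pk for pk in bundle.peaks if pk.factor == factor], p)
        paths[f"peaks_{factor}"] = p

    truth_df = pd.DataFrame(
        {"cluster": bundle.truth.cluster, "es_label": bundle.truth.es_label}
    )
    io_formats.write_table(truth_df, paths["truth"], index_label="gene_id")
    manifest = {
        "config": _config_dict(bundle.config),
        "cofactor_status": bundle.truth.cofactor_status,
        "cofactor_gene": bundle.truth.cofactor_gene,
        "planted": [
            {
                "cluster": pf.cluster,
                "mains": list(pf.mains),
                "motif": pf.motif,
                "direction": pf.direction,
                "feature": io_formats.feature_name(sorted(pf.mains), pf.motif),
                "targets": bundle.truth.planted_targets.get(
                    io_formats.feature_name(sorted(pf.mains), pf.motif), []
                ),
                "skipped": bundle.truth.planted_skips.get(
                    io_formats.feature_name(sorted(pf.mains), pf.motif), []
                ),
            }
            for pf in bundle.truth.planted
        ],
    }
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return paths


def _config_dict(config: SyntheticConfig) -> dict:
    d = dataclasses.asdict(config)
    if d.get("planted"):
        d["planted"] = [dataclasses.asdict(pf) for pf in config.planted]
    return d
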