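"""End-to-end orchestration: synthesize/load inputs, run every analysis
stage in order, and write all result tables.

Stage order: synth -> associate -> cluster -> es_call -> neighborhoods ->
scan -> features -> tests -> classify -> targets.  Each stage writes its
outputs under the run directory; a stage-subset rerun loads the cached
outputs of earlier stages from the same directory and fails with the name of
any missing artifact.  A manifest records the configuration hash, seeds and
package versions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import association as assoc_mod
from . import io_formats
from . import synth as synth_mod
from .association import ClusterAssignment, call_es_genes, cluster_genes, normalize_association
from .classify import (
    NBModel,
    PredictorSpec,
    SelectionResult,
    fit_nb,
    select_features,
)
from .core import ExpressionMatrix, GeneRecord, GenomeSequence, MotifSite, Neighborhood, Peak, PWMRecord
from .features import TFCombination, build_score_matrix, enumerate_combinations
from .motifs import call_sites
from .neighborhoods import associate_neighborhoods, build_neighborhoods
from .significance import label_features, reason_role, test_features
from .targets import TargetPrediction, match_status, predict_targets, validate_targets

log = logging.getLogger("cobind")

STAGES = (
    "synth",
    "associate",
    "cluster",
    "es_call",
    "neighborhoods",
    "scan",
    "features",
    "tests",
    "classify",
    "targets",
)

# fixed child-seed offsets so partial reruns reproduce stage-level randomness
_SEED_OFFSETS = {"kmeans": 11, "scan": 101, "cv": 211}


@dataclass
class PipelineParams:
    """All pipeline constants (defaults are the reference values) plus inputs."""

    seed: int = 0
    d0: float = 5000.0
    assoc_window: int = 1_000_000
    extend: int = 500
    merge_dist: int = 500
    min_peaks: int = 2
    n_controls: int = 20
    motif_p: float = 9.09e-5
    fc_threshold: float = 2.0
    alpha: float = 0.05
    fdr_q: float = 0.10
    kmax: int = 20
    folds: int = 10
    kmeans_k: int = 5
    kmeans_restarts: int = 25
    max_null_nbhds: Optional[int] = 8
    target_floor: float = 0.0
    myc_factors: Tuple[str, ...] = ()
    oct4_factors: Tuple[str, ...] = ()
    # either a synthetic block ...
    synthetic: Optional[synth_mod.SyntheticConfig] = None
    # ... or explicit input paths
    genome_path: Optional[str] = None
    genes_path: Optional[str] = None
    peak_paths: Dict[str, str] = field(default_factory=dict)  # factor -> path
    pwms_path: Optional[str] = None
    expression_path: Optional[str] = None
    validation_path: Optional[str] = None

    def __post_init__(self):
        for name in (
            "d0", "assoc_window", "extend", "merge_dist", "min_peaks", "n_controls",
            "motif_p", "fc_threshold", "alpha", "fdr_q", "kmax", "folds",
            "kmeans_k", "kmeans_restarts",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"parameter {name} must be positive")

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ClusterResult:
    name: str
    factors_of_interest: List[str]
    nbhds: List[Neighborhood]
    thresholds: Dict[str, float]
    score_matrix: pd.DataFrame
    combo_w: Dict[str, int]
    labels: pd.DataFrame
    X: Optional[pd.DataFrame] = None
    y: Optional[np.ndarray] = None
    selection: Optional[SelectionResult] = None
    model: Optional[NBModel] = None
    targets: Dict[str, List[TargetPrediction]] = field(default_factory=dict)
    validation: List = field(default_factory=list)


@dataclass
class PipelineResult:
    params: PipelineParams
    genome: GenomeSequence
    genes: List[GeneRecord]
    peaks: List[Peak]
    pwms: List[PWMRecord]
    expression: ExpressionMatrix
    validation_expr: Optional[ExpressionMatrix]
    assoc_raw: pd.DataFrame
    assoc_norm: pd.DataFrame
    clustering: ClusterAssignment
    es_table: pd.DataFrame
    selected_pwms: List[PWMRecord]
    clusters: Dict[str, ClusterResult]
    truth: Optional[synth_mod.GroundTruth] = None


def _predictor_kind(test: str) -> str:
    return "continuous" if test == "ranksum" else "indicator"


def _cofactor_status(pwm: PWMRecord, es_table: pd.DataFrame) -> str:
    """Best status over the motif's mapped cofactor genes (P/N/H before other)."""
    order = {"P": 0, "N": 1, "H": 2, "other": 3}
    statuses = [
        es_table.at[g, "status"] for g in pwm.cofactor_genes if g in es_table.index
    ]
    if not statuses:
        return "other"
    return min(statuses, key=lambda s: order.get(s, 9))


def analyze_cluster(
    cluster_name: str,
    foi: List[str],
    result: PipelineResult,
    params: PipelineParams,
) -> ClusterResult:
    """Run neighborhoods -> scan -> features -> tests for one cluster."""
    t0 = time.time()
    foi_peaks = [p for p in result.peaks if p.factor in foi]
    nbhds = build_neighborhoods(
        foi_peaks, params.extend, params.merge_dist, params.min_peaks
    )
    seed = params.seed + _SEED_OFFSETS["scan"] + _stable_offset(cluster_name)
    thresholds = call_sites(
        nbhds,
        result.selected_pwms,
        result.genome,
        result.genes,
        p=params.motif_p,
        seed=seed,
        n_controls=params.n_controls,
        max_null_nbhds=params.max_null_nbhds,
    )

    cluster_genes_ids = set(result.clustering.genes_in(cluster_name))
    es_classes = result.es_table["es_class"]
    up = [g for g in result.es_table.index
          if g in cluster_genes_ids and es_classes[g] == "ES-up"]
    down = [g for g in result.es_table.index
            if g in cluster_genes_ids and es_classes[g] == "ES-down"]
    es_gene_recs = [g for g in result.genes if g.gene_id in set(up) | set(down)]

    motif_names = [p.name for p in result.selected_pwms]
    combos: List[TFCombination] = []
    for w in (0, 1, 2):
        if w <= len(foi):
            combos.extend(enumerate_combinations(foi, motif_names, w))
    combo_w = {c.name: c.w for c in combos}

    nbhd_map = associate_neighborhoods(nbhds, es_gene_recs, params.assoc_window)
    score_matrix = build_score_matrix(es_gene_recs, nbhd_map, combos, params.d0)

    results = test_features(score_matrix, combo_w, up, down, cluster_name)
    labels = label_features(results, params.fdr_q)
    log.info(
        "cluster %s: %d nbhds, %d sites, %d features, %d labeled (%.1fs)",
        cluster_name,
        len(nbhds),
        sum(len(nb.sites) for nb in nbhds),
        len(combos),
        int((labels["label"] != "none").sum()),
        time.time() - t0,
    )
    return ClusterResult(
        name=cluster_name,
        factors_of_interest=foi,
        nbhds=nbhds,
        thresholds=thresholds,
        score_matrix=score_matrix,
        combo_w=combo_w,
        labels=labels,
    )


def _stable_offset(name: str) -> int:
    return int(hashlib.sha256(name.encode()).hexdigest()[:6], 16) % 997


def classify_cluster(
    cr: ClusterResult,
    result: PipelineResult,
    params: PipelineParams,
) -> None:
    """Feature selection + final NB fit for one cluster (in place)."""
    es_classes = result.es_table["es_class"]
    genes = list(cr.score_matrix.index)
    y = np.array([1 if es_classes[g] == "ES-up" else 0 for g in genes])
    if min((y == 1).sum(), (y == 0).sum()) < 2:
        log.info("cluster %s: too few ES genes per class; classification skipped", cr.name)
        return

    mf_cols = result.assoc_norm.loc[genes, cr.factors_of_interest]
    mf_cols = mf_cols.rename(columns={f: f"assoc:{f}" for f in cr.factors_of_interest})
    X = pd.concat([mf_cols, cr.score_matrix], axis=1)
    mf_specs = [PredictorSpec(c, "always") for c in mf_cols.columns]

    ranked_up: Dict[int, List[PredictorSpec]] = {}
    ranked_down: Dict[int, List[PredictorSpec]] = {}
    lab = cr.labels[cr.labels["label"] != "none"].sort_values(
        ["best_p", "feature"], kind="stable"
    )
    for _, row in lab.iterrows():
        spec = PredictorSpec(row["feature"], _predictor_kind(row["best_test"]))
        d = ranked_up if row["label"] == "ES-up" else ranked_down
        d.setdefault(int(row["w"]), []).append(spec)

    seed = params.seed + _SEED_OFFSETS["cv"] + _stable_offset(cr.name)
    selection = select_features(
        ranked_up, ranked_down, X, y, mf_specs,
        kmax=params.kmax, folds=params.folds, seed=seed,
    )
    model = fit_nb(X, y, mf_specs + selection.selected_specs)
    cr.X, cr.y, cr.selection, cr.model = X, y, selection, model
    log.info(
        "cluster %s: selected (w_up=%s k1=%d, w_down=%s k2=%d) cv=%.3f baseline=%.3f",
        cr.name, selection.up_type, selection.k1, selection.down_type,
        selection.k2, selection.cv_error, selection.baseline_error,
    )


def target_cluster(
    cr: ClusterResult,
    result: PipelineResult,
    params: PipelineParams,
) -> None:
    """Target prediction and fold-change validation for the selected features."""
    if cr.model is None or cr.selection is None:
        return
    es_classes = result.es_table["es_class"]
    label_of = dict(zip(cr.labels["feature"], cr.labels["label"]))
    pwm_by_name = {p.name: p for p in result.pwms}
    val = result.validation_expr
    val_status = call_es_genes(val, params.fc_threshold, params.alpha) if val is not None else None

    for spec in cr.selection.selected_specs:
        direction = label_of.get(spec.name, "none")
        if direction not in ("ES-up", "ES-down"):
            continue
        targets = predict_targets(
            cr.model, cr.X, es_classes.loc[cr.X.index], spec.name, direction
        )
        cr.targets[spec.name] = targets
        motif = spec.name.split(".")[-1]
        pwm = pwm_by_name.get(motif)
        status_primary = _cofactor_status(pwm, result.es_table) if pwm else "other"
        role = reason_role(direction, status_primary)
        if role is None or val is None or val_status is None:
            continue
        status_validation = _cofactor_status(pwm, val_status)
        matched = match_status(status_primary, status_validation)
        cr.validation.append(
            validate_targets(
                targets, role, val,
                status_validation=status_validation,
                matched=matched,
                floor=params.target_floor,
            )
        )


def analyze_bundle(
    bundle: synth_mod.SyntheticBundle,
    params: Optional[PipelineParams] = None,
    stages: Sequence[str] = STAGES,
) -> PipelineResult:
    """Run the in-memory pipeline on a synthetic bundle."""
    if params is None:
        params = PipelineParams(seed=bundle.config.seed)
    params.myc_factors = tuple(bundle.config.myc_factors)
    params.oct4_factors = tuple(bundle.config.oct4_factors)
    return _analyze(
        params,
        bundle.genome,
        bundle.genes,
        bundle.peaks,
        bundle.pwms,
        bundle.expression,
        bundle.validation,
        truth=bundle.truth,
        stages=stages,
    )


def _analyze(
    params: PipelineParams,
    genome: GenomeSequence,
    genes: List[GeneRecord],
    peaks: List[Peak],
    pwms: List[PWMRecord],
    expression: ExpressionMatrix,
    validation_expr: Optional[ExpressionMatrix],
    truth: Optional[synth_mod.GroundTruth] = None,
    stages: Sequence[str] = STAGES,
) -> PipelineResult:
    factors = sorted({p.factor for p in peaks})
    assoc_raw = assoc_mod.association_scores(
        peaks, genes, params.d0, params.assoc_window, factors
    )
    assoc_norm = normalize_association(assoc_raw)
    clustering = cluster_genes(
        assoc_norm,
        params.myc_factors,
        params.oct4_factors,
        k=params.kmeans_k,
        restarts=params.kmeans_restarts,
        seed=(params.seed + _SEED_OFFSETS["kmeans"]) % (2**31),
    )
    es_table = call_es_genes(expression, params.fc_threshold, params.alpha)

    selected_pwms = [
        p for p in pwms if _cofactor_status(p, es_table) in ("P", "N", "H")
    ]
    result = PipelineResult(
        params=params,
        genome=genome,
        genes=genes,
        peaks=peaks,
        pwms=pwms,
        expression=expression,
        validation_expr=validation_expr,
        assoc_raw=assoc_raw,
        assoc_norm=assoc_norm,
        clustering=clustering,
        es_table=es_table,
        selected_pwms=selected_pwms,
        clusters={},
        truth=truth,
    )
    for cname in result.clustering.analysis_clusters:
        foi = result.clustering.factors_of_interest[cname]
        cr = analyze_cluster(cname, foi, result, params)
        if "classify" in stages or "targets" in stages:
            classify_cluster(cr, result, params)
        if "targets" in stages:
            target_cluster(cr, result, params)
        result.clusters[cname] = cr
    return result


# ---------------------------------------------------------------------------
# file-based runs with caching


def run_pipeline(
    params: PipelineParams,
    outdir: str,
    stages: Optional[Sequence[str]] = None,
) -> PipelineResult:
    """Run the pipeline from files or a synthetic block, writing all tables.

    With ``stages`` given, only those stages' outputs are recomputed; the
    synthetic bundle is reused from ``outdir/inputs`` if present (determined
    by the stored config hash).
    """
    io_formats.ensure_outdir(outdir)
    requested = set(stages) if stages is not None else set(STAGES)
    unknown = requested - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")

    truth = None
    if params.synthetic is not None:
        input_dir = os.path.join(outdir, "inputs")
        marker = os.path.join(input_dir, "synth_config.yaml")
        bundle = None
        if "synth" not in requested and os.path.exists(marker):
            pass  # reuse files below
        else:
            bundle = synth_mod.generate_bundle(params.synthetic)
            synth_mod.write_bundle(bundle, input_dir)
        if bundle is not None:
            truth = bundle.truth
        params.genome_path = os.path.join(input_dir, "genome.fa")
        params.genes_path = os.path.join(input_dir, "genes.tsv")
        params.pwms_path = os.path.join(input_dir, "pwms.txt")
        params.expression_path = os.path.join(input_dir, "expression.tsv")
        params.validation_path = os.path.join(input_dir, "validation_expression.tsv")
        params.peak_paths = {
            f: os.path.join(input_dir, f"peaks_{f}.tsv")
            for f in params.synthetic.factors
        }
        params.myc_factors = tuple(params.synthetic.myc_factors)
        params.oct4_factors = tuple(params.synthetic.oct4_factors)

    for what, path in (
        ("genome", params.genome_path),
        ("gene annotation", params.genes_path),
        ("PWMs", params.pwms_path),
        ("expression", params.expression_path),
    ):
        if path is None or not os.path.exists(path):
            raise FileNotFoundError(f"missing required input: {what} ({path})")

    genome = io_formats.read_genome(params.genome_path)
    genes = io_formats.read_genes(params.genes_path)
    peaks: List[Peak] = []
    for factor, path in sorted(params.peak_paths.items()):
        peaks.extend(io_formats.read_peaks(path, factor))
    pwms = io_formats.read_pwms(params.pwms_path)
    expression = io_formats.read_expression(params.expression_path)
    validation = (
        io_formats.read_expression(params.validation_path)
        if params.validation_path and os.path.exists(params.validation_path)
        else None
    )

    t0 = time.time()
    heavy = {"neighborhoods", "scan", "features"}
    use_cache = stages is not None and requested.isdisjoint(heavy | {"synth"})
    if use_cache:
        result = _analyze_from_cache(
            params, outdir, genome, genes, peaks, pwms, expression, validation,
            truth=truth, stages=tuple(requested),
        )
    else:
        result = _analyze(
            params, genome, genes, peaks, pwms, expression, validation, truth=truth
        )
    write_results(result, outdir)
    _write_manifest(params, outdir, time.time() - t0)
    return result


def _analyze_from_cache(
    params: PipelineParams,
    outdir: str,
    genome: GenomeSequence,
    genes: List[GeneRecord],
    peaks: List[Peak],
    pwms: List[PWMRecord],
    expression: ExpressionMatrix,
    validation_expr: Optional[ExpressionMatrix],
    truth: Optional[synth_mod.GroundTruth],
    stages: Tuple[str, ...],
) -> PipelineResult:
    """Rerun the testing/classification/target stages from cached feature
    score matrices under *outdir* (skipping neighborhoods and scanning)."""
    factors = sorted({p.factor for p in peaks})
    assoc_raw = assoc_mod.association_scores(
        peaks, genes, params.d0, params.assoc_window, factors
    )
    assoc_norm = normalize_association(assoc_raw)
    clustering = cluster_genes(
        assoc_norm, params.myc_factors, params.oct4_factors,
        k=params.kmeans_k, restarts=params.kmeans_restarts,
        seed=(params.seed + _SEED_OFFSETS["kmeans"]) % (2**31),
    )
    es_table = call_es_genes(expression, params.fc_threshold, params.alpha)
    selected_pwms = [p for p in pwms if _cofactor_status(p, es_table) in ("P", "N", "H")]
    result = PipelineResult(
        params=params, genome=genome, genes=genes, peaks=peaks, pwms=pwms,
        expression=expression, validation_expr=validation_expr,
        assoc_raw=assoc_raw, assoc_norm=assoc_norm, clustering=clustering,
        es_table=es_table, selected_pwms=selected_pwms, clusters={}, truth=truth,
    )
    es_classes = result.es_table["es_class"]
    for cname in clustering.analysis_clusters:
        tag = cname.replace(" ", "_")
        path = os.path.join(outdir, f"feature_scores_{tag}.tsv")
        if not os.path.exists(path):
            raise FileNotFoundError(
                f"stage dependency missing: cached feature score matrix {path}"
            )
        score_matrix = io_formats.read_table(path, index_col=0)
        combo_w = {c: c.count(".") for c in score_matrix.columns}
        members = set(clustering.genes_in(cname))
        up = [g for g in score_matrix.index if g in members and es_classes[g] == "ES-up"]
        down = [g for g in score_matrix.index if g in members and es_classes[g] == "ES-down"]
        labels = label_features(
            test_features(score_matrix, combo_w, up, down, cname), params.fdr_q
        )
        cr = ClusterResult(
            name=cname,
            factors_of_interest=clustering.factors_of_interest[cname],
            nbhds=[],
            thresholds={},
            score_matrix=score_matrix,
            combo_w=combo_w,
            labels=labels,
        )
        if "classify" in stages or "targets" in stages:
            classify_cluster(cr, result, params)
        if "targets" in stages:
            target_cluster(cr, result, params)
        result.clusters[cname] = cr
    return result


def _write_manifest(params: PipelineParams, outdir: str, elapsed: float) -> None:
    manifest = {
        "version": __version__,
        "config_hash": params.config_hash(),
        "seed": params.seed,
        "child_seed_offsets": dict(_SEED_OFFSETS),
        "elapsed_seconds": round(elapsed, 2),
        "parameters": {
            k: v
            for k, v in dataclasses.asdict(params).items()
            if not k.endswith("_path") and k not in ("peak_paths", "synthetic")
        },
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def write_results(result: PipelineResult, outdir: str) -> None:
    """Write every result table the pipeline produces."""
    io_formats.ensure_outdir(outdir)
    io_formats.write_table(result.assoc_raw, os.path.join(outdir, "association_scores.tsv"),
                           index_label="gene_id")
    io_formats.write_table(result.assoc_norm,
                           os.path.join(outdir, "association_scores_normalized.tsv"),
                           index_label="gene_id")
    cl = pd.DataFrame(
        {
            "cluster_id": result.clustering.labels,
            "cluster": [result.clustering.names[c] for c in result.clustering.labels],
        }
    )
    io_formats.write_table(cl, os.path.join(outdir, "clusters.tsv"), index_label="gene_id")
    io_formats.write_table(result.es_table, os.path.join(outdir, "es_genes.tsv"),
                           index_label="gene_id")

    width_of = {p.name: p.width for p in result.pwms}
    sig_rows, sel_rows, cv_rows, target_rows, val_rows = [], [], [], [], []
    pwm_by_name = {p.name: p for p in result.pwms}
    for cname, cr in result.clusters.items():
        tag = cname.replace(" ", "_")
        if cr.nbhds:  # absent on cached reruns that skipped the scan stages
            io_formats.write_neighborhoods_bed(
                cr.nbhds, os.path.join(outdir, f"neighborhoods_{tag}.bed"))
            io_formats.write_neighborhood_members(
                cr.nbhds, os.path.join(outdir, f"neighborhood_members_{tag}.tsv"))
            sites = [s for nb in cr.nbhds for s in nb.sites]
            io_formats.write_sites_bed(sites, width_of,
                                       os.path.join(outdir, f"motif_sites_{tag}.bed"))
            thr = pd.DataFrame(
                sorted(cr.thresholds.items()), columns=["motif", "threshold"]
            )
            io_formats.write_table(thr, os.path.join(outdir, f"motif_thresholds_{tag}.tsv"))
            io_formats.write_table(cr.score_matrix,
                                   os.path.join(outdir, f"feature_scores_{tag}.tsv"),
                                   index_label="gene_id")
        io_formats.write_table(cr.labels, os.path.join(outdir, f"feature_tests_{tag}.tsv"))

        for _, row in cr.labels[cr.labels["label"] != "none"].iterrows():
            motif = row["feature"].split(".")[-1]
            pwm = pwm_by_name.get(motif)
            status = _cofactor_status(pwm, result.es_table) if pwm else "other"
            role = reason_role(row["label"], status)
            for cof_gene in (pwm.cofactor_genes if pwm else [""]):
                sig_rows.append(
                    {
                        "cluster": cname,
                        "U/D": "U" if row["label"] == "ES-up" else "D",
                        "feature": row["feature"],
                        "cofactor": cof_gene,
                        "status": status,
                        "role": role if role else "",
                        "pvalue": row["best_p"],
                        "test": row["best_test"],
                    }
                )
        if cr.selection is not None:
            sel = cr.selection
            cv_rows.append(
                {
                    "cluster": cname, "method": "NB_MF",
                    "cv_error": sel.baseline_error, "cv_se": sel.baseline_se,
                }
            )
            cv_rows.append(
                {"cluster": cname, "method": "NB", "cv_error": sel.cv_error, "cv_se": sel.cv_se}
            )
            for spec in sel.selected_specs:
                sel_rows.append(
                    {
                        "cluster": cname,
                        "feature": spec.name,
                        "kind": spec.kind,
                        "k1": sel.k1,
                        "k2": sel.k2,
                        "up_type": sel.up_type,
                        "down_type": sel.down_type,
                    }
                )
        for feat, targets in cr.targets.items():
            for t in targets:
                target_rows.append(
                    {
                        "cluster": cname,
                        "feature": feat,
                        "gene": t.gene,
                        "rank": t.rank,
                        "log_ratio_with": t.log_ratio_with,
                        "log_ratio_without": t.log_ratio_without,
                        "ratio_fold_change": t.ratio_fold_change,
                    }
                )
        for vs in cr.validation:
            val_rows.append(
                {
                    "cluster": cname,
                    "feature": vs.feature,
                    "role": vs.role,
                    "status_validation": vs.status_validation,
                    "matched": vs.matched,
                    "N_b": vs.n_b,
                    "N_e": vs.n_e,
                    "Pc": vs.pc if vs.pc is not None else np.nan,
                    "fc_1Q": vs.quartiles[0] if vs.quartiles else np.nan,
                    "fc_median": vs.quartiles[1] if vs.quartiles else np.nan,
                    "fc_3Q": vs.quartiles[2] if vs.quartiles else np.nan,
                }
            )

    for rows, name, cols in (
        (sig_rows, "significant_features.tsv",
         ["cluster", "U/D", "feature", "cofactor", "status", "role", "pvalue", "test"]),
        (sel_rows, "selected_features.tsv",
         ["cluster", "feature", "kind", "k1", "k2", "up_type", "down_type"]),
        (cv_rows, "cv_report.tsv", ["cluster", "method", "cv_error", "cv_se"]),
        (target_rows, "predicted_targets.tsv",
         ["cluster", "feature", "gene", "rank", "log_ratio_with",
          "log_ratio_without", "ratio_fold_change"]),
        (val_rows, "validation_summary.tsv",
         ["cluster", "feature", "role", "status_validation", "matched",
          "N_b", "N_e", "Pc", "fc_1Q", "fc_median", "fc_3Q"]),
    ):
        df = pd.DataFrame(rows, columns=cols)
        io_formats.write_table(df, os.path.join(outdir, name))
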