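"""Readers and writers for every external file the pipeline touches.

All genomic coordinates are 0-based; interval outputs use the half-open BED
convention.  Floats are written with 12 significant digits so that read/write
round trips are value-exact.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    BASES,
    ExpressionMatrix,
    GeneRecord,
    GenomeSequence,
    MotifSite,
    Neighborhood,
    Peak,
    PWMRecord,
)

FLOAT_FMT = "%.12g"

#: Pseudocount added to every PWM cell (before normalization) when the block
#: contains a zero entry; keeps log-ratios finite.
PWM_PSEUDOCOUNT = 0.01


class ParseError(ValueError):
    """A malformed input row; the message names the offending line."""


# ---------------------------------------------------------------------------
# genome FASTA


def read_genome(path: str) -> GenomeSequence:
    """Read a (soft-masked) genome FASTA; lowercase/N are kept verbatim."""
    chroms: Dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in chroms:
            raise ParseError(f"{path}: duplicate chromosome {rec.id!r}")
        chroms[rec.id] = str(rec.seq)
    if not chroms:
        raise ParseError(f"{path}: no FASTA records found")
    return GenomeSequence(chroms)


def write_genome(genome: GenomeSequence, path: str, width: int = 80) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.chroms.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# peaks


def read_peaks(path: str, factor: str) -> List[Peak]:
    """Read a peak table for one factor.

    Two tab-separated layouts are accepted, distinguished by the header:
    ``chrom  start  end  intensity`` (BED-like, 0-based half-open; the peak
    center is ``floor((start + end) / 2)``) or ``chrom  center  intensity``.
    """
    peaks: List[Peak] = []
    with open(path) as fh:
        header = fh.readline()
        if header == "":
            raise ParseError(f"{path}: empty file (missing header)")
        cols = header.rstrip("\n").split("\t")
        if cols[:4] == ["chrom", "start", "end", "intensity"]:
            form = "interval"
        elif cols[:3] == ["chrom", "center", "intensity"]:
            form = "center"
        else:
            raise ParseError(f"{path}: line 1: unrecognized peak header {cols}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            try:
                if form == "interval":
                    chrom, start, end, intensity = (
                        parts[0],
                        int(parts[1]),
                        int(parts[2]),
                        float(parts[3]),
                    )
                    center = (start + end) // 2
                else:
                    chrom, center, intensity = parts[0], int(parts[1]), float(parts[2])
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}: line {lineno}: malformed row {line!r}") from exc
            if not intensity > 0:
                raise ParseError(
                    f"{path}: line {lineno}: nonpositive intensity {intensity}"
                )
            peaks.append(Peak(chrom=chrom, center=center, factor=factor, intensity=intensity))
    peaks.sort(key=lambda p: (p.chrom, p.center))
    return peaks


def write_peaks(peaks: Sequence[Peak], path: str) -> None:
    """Write peaks in the ``chrom  center  intensity`` layout."""
    with open(path, "w") as fh:
        fh.write("chrom\tcenter\tintensity\n")
        for p in sorted(peaks, key=lambda p: (p.chrom, p.center)):
            fh.write(f"{p.chrom}\t{p.center}\t{FLOAT_FMT % p.intensity}\n")


# ---------------------------------------------------------------------------
# gene annotation


def read_genes(path: str) -> List[GeneRecord]:
    """Read a TSS annotation table: ``gene_id  chrom  tss  strand``."""
    genes: List[GeneRecord] = []
    seen = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["gene_id", "chrom", "tss", "strand"]:
            raise ParseError(f"{path}: line 1: unrecognized gene header {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            try:
                rec = GeneRecord(parts[0], parts[1], int(parts[2]), parts[3])
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}: line {lineno}: malformed row {line!r}") from exc
            if rec.gene_id in seen:
                raise ParseError(f"{path}: line {lineno}: duplicate gene id {rec.gene_id!r}")
            seen.add(rec.gene_id)
            genes.append(rec)
    return genes


def write_genes(genes: Sequence[GeneRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\ttss\tstrand\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.tss}\t{g.strand}\n")


# ---------------------------------------------------------------------------
# PWMs


def _normalize_pwm(matrix: np.ndarray) -> np.ndarray:
    matrix = np.asarray(matrix, dtype=float)
    if (matrix < 0).any():
        raise ParseError("PWM cells must be nonnegative")
    if (matrix == 0).any():
        matrix = matrix + PWM_PSEUDOCOUNT
    return matrix / matrix.sum(axis=0, keepdims=True)


def read_pwms(path: str) -> List[PWMRecord]:
    """Read motif blocks.

    Each block starts with ``>name [genes=g1,g2]``.  The matrix may be given
    as four labelled base rows (``A: ...`` etc., each of length w) or as w
    unlabelled rows of four numbers (one position per row).  Counts or
    probabilities are both accepted; counts are normalized per column with a
    0.01 pseudocount per cell whenever the block contains a zero.
    """
    pwms: List[PWMRecord] = []
    name: Optional[str] = None
    genes: List[str] = []
    rows: List[List[float]] = []
    labels: List[Optional[str]] = []

    def flush(lineno: int) -> None:
        nonlocal name, genes, rows, labels
        if name is None:
            return
        if not rows:
            raise ParseError(f"{path}: motif {name!r} has no matrix rows")
        if all(lab is not None for lab in labels):
            order = {lab: i for i, lab in enumerate(labels)}
            if sorted(order) != list("ACGT"):
                raise ParseError(f"{path}: motif {name!r}: base rows must be A,C,G,T")
            mat = np.array([rows[order[b]] for b in BASES], dtype=float)
        else:
            widths = {len(r) for r in rows}
            if widths != {4}:
                raise ParseError(
                    f"{path}: line {lineno}: motif {name!r}: "
                    f"unlabelled rows must have exactly 4 columns"
                )
            mat = np.array(rows, dtype=float).T
        pwms.append(PWMRecord(name, _normalize_pwm(mat), list(genes)))
        name, genes, rows, labels = None, [], [], []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                flush(lineno)
                fields = line[1:].split()
                name = fields[0]
                genes = []
                for f in fields[1:]:
                    if f.startswith("genes="):
                        genes = [g for g in f[len("genes="):].split(",") if g]
                continue
            if name is None:
                raise ParseError(f"{path}: line {lineno}: matrix row before any '>' header")
            label = None
            if ":" in line.split()[0]:
                label, _, rest = line.partition(":")
                label = label.strip()
                line = rest
            try:
                row = [float(x) for x in line.split()]
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: malformed matrix row") from exc
            rows.append(row)
            labels.append(label)
        flush(-1)
    return pwms


def write_pwms(pwms: Sequence[PWMRecord], path: str) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            gene_part = f" genes={','.join(pwm.cofactor_genes)}" if pwm.cofactor_genes else ""
            fh.write(f">{pwm.name}{gene_part}\n")
            for i, base in enumerate(BASES):
                row = " ".join(FLOAT_FMT % x for x in pwm.matrix[i])
                fh.write(f"{base}: {row}\n")


# ---------------------------------------------------------------------------
# expression


def read_expression(path: str) -> ExpressionMatrix:
    """Read a TSV expression matrix with a ``#stage`` label line.

    Line 1 holds ``gene_id`` followed by sample ids; line 2 starts with
    ``#stage`` and assigns ``ES``/``DF`` per sample; remaining lines are genes.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "gene_id":
            raise ParseError(f"{path}: line 1: expected 'gene_id' header")
        samples = header[1:]
        stage_line = fh.readline().rstrip("\n").split("\t")
        if stage_line[0] != "#stage":
            raise ParseError(f"{path}: line 2: expected '#stage' label line")
        stages = stage_line[1:]
        if len(stages) != len(samples):
            raise ParseError(f"{path}: line 2: {len(stages)} labels for {len(samples)} samples")
        gene_ids: List[str] = []
        data: List[List[float]] = []
        for lineno, line in enumerate(fh, start=3):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(samples) + 1:
                raise ParseError(f"{path}: line {lineno}: wrong column count")
            try:
                data.append([float(x) for x in parts[1:]])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: malformed value") from exc
            gene_ids.append(parts[0])
    values = pd.DataFrame(data, index=gene_ids, columns=samples)
    return ExpressionMatrix(values, pd.Series(stages, index=samples))


def write_expression(expr: ExpressionMatrix, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(expr.values.columns) + "\n")
        fh.write("#stage\t" + "\t".join(expr.stages[c] for c in expr.values.columns) + "\n")
        for gid, row in expr.values.iterrows():
            fh.write(gid + "\t" + "\t".join(FLOAT_FMT % v for v in row) + "\n")


# ---------------------------------------------------------------------------
# feature naming and result tables


def feature_name(main_factors: Sequence[str], motif: str) -> str:
    """Dot-concatenated feature name; a w=0 feature is the motif name alone."""
    return ".".join(list(main_factors) + [motif])


def write_table(df: pd.DataFrame, path: str, index_label: Optional[str] = None) -> None:
    """Write a TSV with 'NA' for missing values and 12-significant-digit floats."""
    df.to_csv(
        path,
        sep="\t",
        na_rep="NA",
        float_format=FLOAT_FMT,
        index=index_label is not None,
        index_label=index_label,
    )


def read_table(path: str, index_col: Optional[int] = None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], index_col=index_col)


def write_neighborhoods_bed(nbhds: Sequence[Neighborhood], path: str) -> None:
    """Neighborhoods as BED4 (name = nbhd index) plus a membership table."""
    with open(path, "w") as fh:
        for i, nb in enumerate(nbhds):
            fh.write(f"{nb.chrom}\t{nb.start}\t{nb.end}\tnbhd{i}\n")


def write_neighborhood_members(nbhds: Sequence[Neighborhood], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("nbhd\tchrom\tcenter\tfactor\tpeak_center\tintensity\n")
        for i, nb in enumerate(nbhds):
            for p in nb.peaks:
                fh.write(
                    f"nbhd{i}\t{nb.chrom}\t{nb.center}\t{p.factor}\t"
                    f"{p.center}\t{FLOAT_FMT % p.intensity}\n"
                )


def write_sites_bed(sites: Sequence[MotifSite], width_of: Dict[str, int], path: str) -> None:
    """Motif sites as 6-column BED (name = motif, score = probability ratio)."""
    with open(path, "w") as fh:
        for s in sites:
            end = s.pos + width_of[s.motif]
            fh.write(
                f"{s.chrom}\t{s.pos}\t{end}\t{s.motif}\t{FLOAT_FMT % s.score}\t{s.strand}\n"
            )


def ensure_outdir(outdir: str) -> str:
    try:
        os.makedirs(outdir, exist_ok=True)
        probe = os.path.join(outdir, ".write_probe")
        with open(probe, "w"):
            pass
        os.remove(probe)
    except OSError as exc:
        raise OSError(f"output directory {outdir!r} is not writable: {exc}") from exc
    return outdir
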