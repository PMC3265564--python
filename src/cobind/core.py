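"""Core domain types shared across the pipeline.

Coordinates are 0-based throughout; intervals are half-open ([start, end)),
matching the BED convention.  Genome sequences keep soft masking: lowercase
bases and ``N`` mark masked positions that motif scanning must skip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

VALID_BASES = set("ACGTacgtN")

#: Canonical base ordering used for PWM rows and background models.
BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class GenomeSequence:
    """Per-chromosome base strings with soft (lowercase/N) masking."""

    def __init__(self, chroms: Dict[str, str]):
        if len(chroms) == 0:
            raise ValueError("genome must contain at least one chromosome")
        for name, seq in chroms.items():
            if len(seq) == 0:
                raise ValueError(f"chromosome {name!r} has length 0")
        self.chroms: Dict[str, str] = dict(chroms)

    def __contains__(self, name: str) -> bool:
        return name in self.chroms

    def __getitem__(self, name: str) -> str:
        return self.chroms[name]

    def length(self, name: str) -> int:
        return len(self.chroms[name])

    def names(self) -> List[str]:
        return list(self.chroms)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return ``[start, end)`` of *chrom*, clipped to chromosome bounds."""
        seq = self.chroms[chrom]
        return seq[max(0, start):min(len(seq), end)]


@dataclass(frozen=True, order=True)
class Peak:
    """A single ChIP-seq binding site summarised by its center coordinate."""

    chrom: str
    center: int
    factor: str
    intensity: float

    def __post_init__(self):
        if not self.intensity > 0:
            raise ValueError(
                f"peak intensity must be positive, got {self.intensity!r} "
                f"({self.factor} {self.chrom}:{self.center})"
            )


@dataclass(frozen=True)
class GeneRecord:
    """A gene reduced to a single TSS coordinate."""

    gene_id: str
    chrom: str
    tss: int
    strand: str = "+"

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class PWMRecord:
    """A position weight matrix over ACGT with its mapped cofactor gene(s).

    ``matrix`` has shape (4, w); rows follow :data:`BASES` order and each
    column sums to 1 after pseudocount normalization.
    """

    name: str
    matrix: np.ndarray
    cofactor_genes: List[str] = field(default_factory=list)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4:
            raise ValueError(
                f"PWM {self.name!r}: matrix must be 4 x w, got {self.matrix.shape}"
            )
        if self.matrix.shape[1] < 1:
            raise ValueError(f"PWM {self.name!r}: width must be >= 1")
        colsums = self.matrix.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise ValueError(
                f"PWM {self.name!r}: columns must sum to 1 (got {colsums})"
            )

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=0))


@dataclass
class ExpressionMatrix:
    """genes x samples expression indices with a per-sample stage label.

    ``values`` is a DataFrame indexed by gene id; ``stages`` maps each sample
    (column) to ``"ES"`` or ``"DF"``.
    """

    values: pd.DataFrame
    stages: pd.Series

    def __post_init__(self):
        self.stages = pd.Series(self.stages)
        if list(self.stages.index) != list(self.values.columns):
            raise ValueError("stage labels must be indexed by the sample columns")
        bad = set(self.stages) - {"ES", "DF"}
        if bad:
            raise ValueError(f"unknown stage labels: {sorted(bad)}")
        for stage in ("ES", "DF"):
            if (self.stages == stage).sum() < 2:
                raise ValueError(f"need >= 2 samples at stage {stage}")
        if (self.values.values < 0).any():
            raise ValueError("expression values must be nonnegative")

    def samples(self, stage: str) -> List[str]:
        return list(self.stages.index[self.stages == stage])

    def stage_values(self, stage: str) -> pd.DataFrame:
        return self.values[self.samples(stage)]


@dataclass(frozen=True)
class MotifSite:
    """A called cofactor motif site (0-based start of the w-mer)."""

    motif: str
    chrom: str
    pos: int
    strand: str
    score: float

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.score > 0:
            raise ValueError("motif score must be positive")


@dataclass
class Neighborhood:
    """A merged genomic island of main-factor peaks.

    ``start``/``end`` delimit the half-open union of the +-extend windows of
    the member peaks; ``center`` is the floor of the mean member peak center.
    Cofactor motif sites are attached later by the scanning stage.
    """

    chrom: str
    start: int
    end: int
    center: int
    peaks: List[Peak]
    sites: List[MotifSite] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start

    def factors(self) -> set:
        return {p.factor for p in self.peaks}

    def motif_sites(self, motif: str) -> List[MotifSite]:
        return [s for s in self.sites if s.motif == motif]


def distance_to_tss(pos: int, gene: GeneRecord) -> int:
    """Absolute, strand-independent bp distance from a coordinate to a TSS."""
    return abs(pos - gene.tss)
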