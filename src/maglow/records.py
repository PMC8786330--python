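"""Core record types shared across the pipeline.

Coordinates are 0-based, half-open throughout; the forward strand is the
deposited scaffold orientation.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ScaffoldRecord:
    """One assembled scaffold, optionally carrying its true genome of origin."""

    id: str
    sequence: str
    genome: str | None = None  # planted ground-truth label, if known
    start: int = 0  # offset of the scaffold within its source genome

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class GeneAnnotation:
    """An annotated feature (ORF, rRNA, tRNA) on a genome or scaffold."""

    id: str
    genome: str
    start: int
    end: int
    strand: str = "+"
    feature_type: str = "CDS"
    product: str = "hypothetical protein"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PileupSite:
    """Read observations stacked on a single genomic site.

    Observations are stored as three parallel arrays (base, mapping quality,
    base quality) so that per-site filtering stays vectorized.
    """

    genome: str
    scaffold: str
    pos: int
    ref: str
    bases: np.ndarray
    mapq: np.ndarray
    baseq: np.ndarray

    @property
    def depth(self) -> int:
        return len(self.bases)

    @property
    def observations(self) -> list[tuple[str, int, int]]:
        return list(zip(self.bases.tolist(), self.mapq.tolist(), self.baseq.tolist()))


@dataclass
class SnpCall:
    """A retained polymorphic site: major allele < 95% with >= 2 minor reads."""

    genome: str
    scaffold: str
    pos: int
    ref: str
    major: str
    major_freq: float
    minor: str
    minor_count: int
    depth: int
    substitution_class: str | None = None  # synonymous / nonsynonymous / noncoding


@dataclass
class PnpsReport:
    """Observed and expected synonymous / nonsynonymous polymorphism counts."""

    obs_n: int
    obs_s: int
    exp_n: float
    exp_s: float

    @property
    def ratio(self) -> float | None:
        """pN/pS = (obsN/expN) / (obsS/expS); None when obsS == 0."""
        if self.obs_s == 0 or self.exp_n == 0 or self.exp_s == 0:
            return None
        return (self.obs_n / self.exp_n) / (self.obs_s / self.exp_s)


@dataclass
class BinRecord:
    """A candidate MAG assembled from member scaffolds."""

    id: str
    scaffolds: list[str]
    completeness: float = 0.0
    contamination: float = 0.0
    score: float = 0.0
    size: int = 0
    n50: int = 0
    depth: float | None = None
    abundance: float | None = None
    tier: str | None = None


@dataclass
class QualityReport:
    completeness: float
    contamination: float
    score: float
    estimated_size: float
    rrna: dict[str, bool] = field(default_factory=dict)
    trna_count: int = 0
    mimag_class: str = "fail"  # high-quality / draft / fail


@dataclass
class AniResult:
    query: str
    reference: str
    ani: float
    coverage: float  # aligned fraction of the query


@dataclass
class SkewProfile:
    """Windowed GC skew and its cumulative series over one scaffold.

    ``ori_index`` is the window whose right edge is the origin estimate
    (global minimum of the cumulative series under the default convention);
    ``ter_index`` marks the terminus (global maximum).
    """

    window: int
    skew: np.ndarray
    cumulative: np.ndarray
    ori_index: int
    ter_index: int

    @property
    def n_windows(self) -> int:
        return len(self.skew)

    @property
    def ori_position(self) -> int:
        return ((self.ori_index + 1) % self.n_windows) * self.window

    @property
    def ter_position(self) -> int:
        return ((self.ter_index + 1) % self.n_windows) * self.window


@dataclass
class MgeCall:
    orf: str
    bin: str | None
    mge_class: str  # transposon / plasmid / phage / other / none
    keyword: str | None = None


@dataclass
class PathwayCall:
    pathway: str
    total: int
    present: int

    @property
    def fraction(self) -> float:
        return self.present / self.total

    @property
    def is_present(self) -> bool:
        return self.fraction > 0.66


@dataclass
class AssemblyStats:
    total: int
    n50: int
    largest: int
    n_ge_1mbp: int
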