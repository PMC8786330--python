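"""Synthetic gut-community generator with planted ground truth.

Generates a mock multi-genome community in which every quantity the
downstream estimators try to recover is planted explicitly and recorded:

* log-normally distributed relative abundances spanning the high (>1%),
  low (0.1-1%) and extra-low (<0.1%) tiers;
* a genome-specific composition signature (first-order Markov chain) plus a
  target GC content, so tetranucleotide vectors separate genomes;
* a two-segment GC-skew layout (G-rich leading replichore from a planted
  origin to a planted terminus) so the cumulative skew troughs at ori;
* one copy per genome of each single-copy marker, planted as a reserved
  unique 60-bp tag so marker detection is exact string search;
* an ori->ter log-linear coverage gradient realizing a planted
  peak-to-trough ratio (PTR);
* coding-region SNPs at a planted density whose nonsynonymous:synonymous
  mix realizes a planted dN/dS against the enumerated codon opportunities;
* annotation keywords at planted per-class mobile-genetic-element counts,
  plus configurable rRNA/tRNA features.

Everything derives from a single seed: the same spec reproduces the same
community byte for byte.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import popgen
from .abundance import classify_tier
from .records import GeneAnnotation, PileupSite, ScaffoldRecord

_BASE = np.array(["A", "C", "G", "T"])
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_OTHER = np.array([[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]])  # alt codes per ref
# ref code -> {alt base: slot in _OTHER row}
_ALT_SLOT = [
    {_BASE[code]: slot for slot, code in enumerate(row)} for row in _OTHER
]
_PHYLA = (
    "Firmicutes",
    "Bacteroidota",
    "Actinobacteriota",
    "Proteobacteria",
    "Verrucomicrobiota",
)

# Sense codons grouped by (G count, C count), used to patch in-frame stop
# codons without perturbing either the GC target or the planted GC skew.
_SENSE_BY_GC: dict[tuple[int, int], list[str]] = {}
for _codon in popgen.CODON_SUBSTITUTIONS:
    _key = (_codon.count("G"), _codon.count("C"))
    _SENSE_BY_GC.setdefault(_key, []).append(_codon)
for _v in _SENSE_BY_GC.values():
    _v.sort()

DEFAULT_MGE_PRODUCTS = {
    "transposon": (
        "IS3 family transposase",
        "Tn3 family transposase",
        "insertion sequence IS200 protein",
    ),
    "plasmid": (
        "conjugal transfer protein TraG",
        "plasmid mobilization protein MobA",
        "plasmid replication initiator RepB",
    ),
    "phage": (
        "phage major capsid protein",
        "phage terminase large subunit",
        "phage tail tape measure protein",
    ),
    "other": (
        "site-specific integrase",
        "tyrosine recombinase XerC",
        "mobile element protein",
    ),
}


@dataclass
class CommunitySpec:
    """Parameters of the planted community.

    Defaults describe the study conditions exercised by the test-suite: a
    30-genome community whose renormalized log-normal abundances span all
    three tiers, with a 10-Gbp sequencing yield.  Genome lengths are
    desk-scale (kilobases rather than megabases) so every stage runs in
    seconds; all planted signals scale per-base and are unaffected.
    """

    n_genomes: int = 30
    genome_length_range: tuple[int, int] = (60_000, 120_000)
    abundance_mu: float = 0.0
    abundance_sigma: float = 1.8
    gc_range: tuple[float, float] = (0.32, 0.62)
    n_scg: int = 123
    total_bases: float = 1.0e10
    ptr_range: tuple[float, float] = (1.2, 2.5)
    snp_density_range: tuple[float, float] = (0.5, 4.0)
    dnds_per_genome: float = 0.5
    mge_keyword_counts: dict[str, int] = field(
        default_factory=lambda: {"transposon": 4, "plasmid": 3, "phage": 3, "other": 5}
    )
    seed: int = 0
    # composition / layout knobs
    skew_amplitude: float = 0.2
    signature_strength: float = 15.0  # Dirichlet-like concentration; lower = stronger
    orf_length_range: tuple[int, int] = (150, 900)
    intergenic_mean: int = 90
    rrna_counts: dict[str, int] = field(
        default_factory=lambda: {"5S": 1, "16S": 1, "23S": 1}
    )
    trna_count: int = 20
    taxonomy_labeled_fraction: float = 0.7

    def validate(self) -> None:
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be >= 1")
        lo, hi = self.genome_length_range
        if lo <= 0 or hi < lo:
            raise ValueError("genome_length_range must be a positive interval")
        if self.abundance_sigma < 0:
            raise ValueError("abundance_sigma must be >= 0")
        glo, ghi = self.gc_range
        if not (0 < glo <= ghi < 1):
            raise ValueError("gc_range must lie inside (0, 1)")
        if self.n_scg <= 0:
            raise ValueError("n_scg must be > 0")
        if self.total_bases <= 0:
            raise ValueError("total_bases must be > 0")
        if self.ptr_range[0] < 1 or self.ptr_range[1] < self.ptr_range[0]:
            raise ValueError("ptr_range must be an interval with ptr >= 1")
        if self.snp_density_range[0] < 0:
            raise ValueError("snp_density_range must be >= 0")
        if self.dnds_per_genome <= 0:
            raise ValueError("dnds_per_genome must be > 0")


@dataclass
class GenomeTruth:
    genome_id: str
    abundance: float
    length: int
    gc: float
    ori: int
    ter: int
    ptr: float
    snp_density: float
    dnds: float
    tier: str
    phylum: str
    species: str
    scg_positions: dict[int, int]
    mge_counts: dict[str, int]
    rrna_counts: dict[str, int]
    trna_count: int
    orfs: list[GeneAnnotation] = field(default_factory=list)
    features: list[GeneAnnotation] = field(default_factory=list)


@dataclass
class CommunityTruth:
    genomes: dict[str, GenomeTruth]
    tag_catalog: dict[int, str]  # marker id -> reserved 60-bp tag
    spec: CommunitySpec

    def abundances(self) -> dict[str, float]:
        return {g: t.abundance for g, t in self.genomes.items()}

    def to_frame(self):
        import pandas as pd

        rows = []
        for t in self.genomes.values():
            rows.append(
                {
                    "genome": t.genome_id,
                    "abundance": t.abundance,
                    "length": t.length,
                    "gc": t.gc,
                    "ori": t.ori,
                    "ter": t.ter,
                    "ptr": t.ptr,
                    "snp_density": t.snp_density,
                    "dnds": t.dnds,
                    "tier": t.tier,
                    "phylum": t.phylum,
                    "species": t.species,
                    "n_scg": len(t.scg_positions),
                    "trna_count": t.trna_count,
                }
            )
        return pd.DataFrame(rows).set_index("genome")


def _draw_abundances(rng: np.random.Generator, spec: CommunitySpec) -> np.ndarray:
    # z clipped at +/-2.5 sigma: keeps the spread tier-spanning while
    # bounding the rarest genome away from zero coverage
    z = np.clip(rng.standard_normal(spec.n_genomes), -2.5, 2.5)
    w = np.exp(spec.abundance_mu + spec.abundance_sigma * z)
    return w / w.sum()


def _half_of(pos: np.ndarray | int, ori: int, length: int) -> np.ndarray | int:
    """0 for the leading (ori->ter, G-rich) replichore, 1 otherwise."""
    return (np.asarray(pos) - ori) % length >= length // 2


def _markov_background(
    rng: np.random.Generator, length: int, ori: int, gc: float, skew: float,
    signature: np.ndarray,
) -> np.ndarray:
    """Genome backbone from a genome-specific first-order Markov chain.

    The stationary base mix targets ``gc`` with a G/C imbalance of
    ``skew`` on the leading replichore (reversed on the lagging one);
    ``signature`` (4x4 positive matrix) imprints a reproducible
    genome-specific k-mer signature.
    """
    probs = []
    for half in (0, 1):
        s = skew if half == 0 else -skew
        p = np.array(
            [(1 - gc) / 2, gc * (1 - s) / 2, gc * (1 + s) / 2, (1 - gc) / 2]
        )  # A, C, G, T
        rows = p[None, :] * signature
        rows /= rows.sum(axis=1, keepdims=True)
        probs.append(np.cumsum(rows, axis=1).tolist())
    half_len = length // 2
    u = rng.random(length)
    seq = np.empty(length, dtype=np.uint8)
    prev = 0
    for x in range(length):
        h = 1 if ((x - ori) % length) >= half_len else 0
        row = probs[h][prev]
        ux = u[x]
        if ux < row[0]:
            b = 0
        elif ux < row[1]:
            b = 1
        elif ux < row[2]:
            b = 2
        else:
            b = 3
        seq[x] = b
        prev = b
    return seq


def _correct_gc(
    rng: np.random.Generator,
    seq: np.ndarray,
    ori: int,
    gc: float,
    skew: float,
    protected: np.ndarray,
) -> None:
    """Flip bases (outside protected regions) so each replichore hits its
    target G and C counts, preserving the planted skew."""
    length = len(seq)
    halves = _half_of(np.arange(length), ori, length).astype(int)
    for half in (0, 1):
        s = skew if half == 0 else -skew
        idx = np.flatnonzero((halves == half) & ~protected)
        n_half = int((halves == half).sum())
        prot_idx = np.flatnonzero((halves == half) & protected)
        for code, frac in ((2, gc * (1 + s) / 2), (1, gc * (1 - s) / 2)):
            target = int(round(frac * n_half)) - int((seq[prot_idx] == code).sum())
            current = int((seq[idx] == code).sum())
            delta = target - current
            if delta > 0:
                pool = idx[(seq[idx] == 0) | (seq[idx] == 3)]
                pick = rng.choice(pool, size=min(delta, len(pool)), replace=False)
                seq[pick] = code
            elif delta < 0:
                pool = idx[seq[idx] == code]
                pick = rng.choice(pool, size=min(-delta, len(pool)), replace=False)
                seq[pick] = np.where(rng.random(len(pick)) < 0.5, 0, 3)


def _decode(seq: np.ndarray) -> str:
    return "".join(_BASE[seq])


def _plant_orfs(
    rng: np.random.Generator,
    seq: np.ndarray,
    free_intervals: list[tuple[int, int]],
    spec: CommunitySpec,
    genome_id: str,
) -> list[GeneAnnotation]:
    """Carve forward-strand ORFs into the free intervals.

    Each ORF contains sense codons only: in-frame stop codons are patched
    with a random sense codon matching the stop's G and C counts, so
    neither the GC target nor the planted skew drifts.  The annotated
    interval is the sense-codon stretch, so downstream codon enumeration
    applies to the whole interval.
    """
    lo, hi = spec.orf_length_range
    orfs: list[GeneAnnotation] = []
    counter = 0
    for start, end in free_intervals:
        cur = start
        while True:
            gap = int(rng.integers(spec.intergenic_mean // 3, spec.intergenic_mean * 2))
            avail = end - cur - gap
            if avail < lo:
                break
            # ORFs shrink to fit the interval left between marker tags
            orf_len = min(int(rng.integers(lo // 3, hi // 3 + 1)) * 3, (avail // 3) * 3)
            a = cur + gap
            b = a + orf_len
            for cstart in range(a, b, 3):
                codon = "".join(_BASE[seq[cstart : cstart + 3]])
                if codon in popgen.STOP_CODONS:
                    pool = _SENSE_BY_GC[(codon.count("G"), codon.count("C"))]
                    repl = pool[int(rng.integers(len(pool)))]
                    seq[cstart : cstart + 3] = [_CODE[ch] for ch in repl]
            orfs.append(
                GeneAnnotation(
                    id=f"{genome_id}_orf{counter:04d}",
                    genome=genome_id,
                    start=a,
                    end=b,
                    strand="+",
                    feature_type="CDS",
                )
            )
            counter += 1
            cur = b
    return orfs


def generate_genomes(
    spec: CommunitySpec,
) -> tuple[dict[str, str], CommunityTruth]:
    """Generate the community: genome sequences plus full planted truth."""
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    rng_global = np.random.default_rng(root.spawn(1)[0])

    # community-level draws
    abundances = _draw_abundances(rng_global, spec)
    tag_catalog: dict[int, str] = {}
    seen = set()
    for marker in range(1, spec.n_scg + 1):
        while True:
            tag = "".join(rng_global.choice(_BASE, size=60))
            if tag not in seen:
                break
        seen.add(tag)
        tag_catalog[marker] = tag

    genome_seeds = root.spawn(spec.n_genomes + 1)[1:]
    genomes: dict[str, str] = {}
    truth_rows: dict[str, GenomeTruth] = {}
    lo_len, hi_len = spec.genome_length_range
    tag_bases = spec.n_scg * 60

    for i in range(spec.n_genomes):
        rng = np.random.default_rng(genome_seeds[i])
        gid = f"g{i:02d}"
        length = int(rng.integers(lo_len, hi_len + 1))
        if length < 2 * tag_bases:
            raise ValueError(
                f"genome length {length} too short to plant {spec.n_scg} markers"
            )
        gc = float(rng.uniform(*spec.gc_range))
        ori = int(rng.integers(length))
        ter = (ori + length // 2) % length
        ptr = float(rng.uniform(*spec.ptr_range))
        density = float(rng.uniform(*spec.snp_density_range))
        signature = rng.gamma(spec.signature_strength, size=(4, 4))
        signature /= spec.signature_strength

        seq = _markov_background(rng, length, ori, gc, spec.skew_amplitude, signature)

        # one marker tag per equal-width block: non-overlapping and spread
        # across the genome, so any sizeable sub-assembly keeps a
        # proportional share of markers
        block = length // spec.n_scg
        scg_positions: dict[int, int] = {}
        protected = np.zeros(length, dtype=bool)
        for marker in range(1, spec.n_scg + 1):
            bstart = (marker - 1) * block
            pos = bstart + int(rng.integers(block - 60))
            tag = tag_catalog[marker]
            seq[pos : pos + 60] = [_CODE[ch] for ch in tag]
            protected[pos : pos + 60] = True
            scg_positions[marker] = pos

        _correct_gc(rng, seq, ori, gc, spec.skew_amplitude, protected)

        # free intervals = complement of the tag slots
        tag_starts = sorted(scg_positions.values())
        free: list[tuple[int, int]] = []
        prev = 0
        for ts in tag_starts:
            if ts - prev > 0:
                free.append((prev, ts))
            prev = ts + 60
        if prev < length:
            free.append((prev, length))
        orfs = _plant_orfs(rng, seq, free, spec, gid)

        # plant MGE keywords on randomly chosen ORFs, disjoint across classes
        total_requested = sum(spec.mge_keyword_counts.values())
        if total_requested > len(orfs):
            raise ValueError(
                f"requested {total_requested} MGE keywords but only "
                f"{len(orfs)} ORFs in {gid}"
            )
        chosen = rng.choice(len(orfs), size=total_requested, replace=False)
        cursor = 0
        for mge_class, count in spec.mge_keyword_counts.items():
            phrases = DEFAULT_MGE_PRODUCTS[mge_class]
            for j in range(count):
                orfs[chosen[cursor]].product = phrases[j % len(phrases)]
                cursor += 1

        features: list[GeneAnnotation] = []
        rrna_lengths = {"5S": 120, "16S": 1550, "23S": 2900}
        fcount = 0
        for rtype, count in spec.rrna_counts.items():
            for _ in range(count):
                start = int(rng.integers(length - rrna_lengths[rtype]))
                features.append(
                    GeneAnnotation(
                        id=f"{gid}_rrna{fcount:02d}",
                        genome=gid,
                        start=start,
                        end=start + rrna_lengths[rtype],
                        feature_type=f"rRNA_{rtype}",
                        product=f"{rtype} ribosomal RNA",
                    )
                )
                fcount += 1
        for t in range(spec.trna_count):
            start = int(rng.integers(length - 75))
            features.append(
                GeneAnnotation(
                    id=f"{gid}_trna{t:02d}",
                    genome=gid,
                    start=start,
                    end=start + 75,
                    feature_type="tRNA",
                    product="tRNA",
                )
            )

        genomes[gid] = _decode(seq)
        truth_rows[gid] = GenomeTruth(
            genome_id=gid,
            abundance=float(abundances[i]),
            length=length,
            gc=gc,
            ori=ori,
            ter=ter,
            ptr=ptr,
            snp_density=density,
            dnds=spec.dnds_per_genome,
            tier=classify_tier(float(abundances[i])),
            phylum=_PHYLA[i % len(_PHYLA)],
            species=f"species_{i:02d}",
            scg_positions=scg_positions,
            mge_counts=dict(spec.mge_keyword_counts),
            rrna_counts=dict(spec.rrna_counts),
            trna_count=spec.trna_count,
            orfs=orfs,
            features=features,
        )

    return genomes, CommunityTruth(
        genomes=truth_rows, tag_catalog=tag_catalog, spec=spec
    )


def fragment_genomes(
    genomes: dict[str, str],
    truth: CommunityTruth,
    fragment_length_model: int | tuple = ("uniform", 5000, 10000),
    min_length: int = 500,
) -> list[ScaffoldRecord]:
    """Cut each genome into ordered fragments (mock scaffolds).

    ``fragment_length_model`` is either a fixed integer, ("fixed", n), or
    ("uniform", lo, hi).  A trailing remainder shorter than ``min_length``
    is absorbed into the previous fragment, so the in-order concatenation
    of a genome's fragments reproduces the genome exactly.
    """
    if isinstance(fragment_length_model, int):
        model = ("fixed", fragment_length_model)
    elif fragment_length_model[0] not in ("fixed", "uniform"):
        model = ("uniform", *fragment_length_model)
    else:
        model = tuple(fragment_length_model)
    sizes = model[1:]
    if any(s < min_length for s in sizes):
        raise ValueError(f"fragment lengths must be >= {min_length}")
    rng = np.random.default_rng([spec_seed := truth.spec.seed & 0x7FFFFFFF, 1])
    scaffolds: list[ScaffoldRecord] = []
    for gid in sorted(genomes):
        seq = genomes[gid]
        cuts = []
        pos = 0
        while pos < len(seq):
            if model[0] == "fixed":
                flen = model[1]
            else:
                flen = int(rng.integers(model[1], model[2] + 1))
            if len(seq) - pos - flen < min_length:
                flen = len(seq) - pos
            cuts.append((pos, pos + flen))
            pos += flen
        for k, (a, b) in enumerate(cuts):
            scaffolds.append(
                ScaffoldRecord(
                    id=f"{gid}_s{k:03d}", sequence=seq[a:b], genome=gid, start=a
                )
            )
    return scaffolds


def sample_taxonomy(
    scaffolds: list[ScaffoldRecord],
    truth: CommunityTruth,
    labeled_fraction: float | None = None,
    rank: str = "species",
):
    """Per-scaffold taxonomy labels standing in for homology searches.

    A configurable fraction of scaffolds receives its genome's true label
    at the requested rank; the rest stay unlabeled (None), mimicking
    scaffolds without database hits.
    """
    import pandas as pd

    frac = (
        truth.spec.taxonomy_labeled_fraction
        if labeled_fraction is None
        else labeled_fraction
    )
    rng = np.random.default_rng([truth.spec.seed & 0x7FFFFFFF, 4])
    labels = {}
    for s in scaffolds:
        t = truth.genomes[s.genome]
        label = t.species if rank == "species" else t.phylum
        labels[s.id] = label if rng.random() < frac else None
    return pd.Series(labels, name="taxonomy")


def _ptr_modulation(frac_from_ori: np.ndarray, ptr: float) -> np.ndarray:
    """Log-linear ori->ter depth modulation normalized to unit genome mean."""
    if ptr == 1.0:
        return np.ones_like(frac_from_ori)
    raw = ptr ** (0.5 - frac_from_ori)
    norm = (np.sqrt(ptr) - 1 / np.sqrt(ptr)) / np.log(ptr)
    return raw / norm


def simulate_depth(
    scaffolds: list[ScaffoldRecord],
    truth: CommunityTruth,
    total_bases: float | None = None,
    window: int = 1000,
    seed: int | None = None,
):
    """Windowed depth table with the planted abundance and PTR structure.

    Genome-average depth equals ``total_bases * abundance / length``;
    within the genome, depth is modulated log-linearly from x sqrt(PTR) at
    the origin to / sqrt(PTR) at the terminus (normalized to preserve the
    genome mean) with Poisson counting noise per window.
    """
    import pandas as pd

    if window < 100:
        raise ValueError("window must be >= 100")
    total = truth.spec.total_bases if total_bases is None else total_bases
    if total <= 0:
        raise ValueError("total_bases must be > 0")
    rng = np.random.default_rng(
        [(truth.spec.seed if seed is None else seed) & 0x7FFFFFFF, 2]
    )
    rows = []
    for s in scaffolds:
        t = truth.genomes[s.genome]
        mean_depth = total * t.abundance / t.length
        starts = np.arange(0, s.length, window)
        ends = np.minimum(starts + window, s.length)
        mids = (s.start + (starts + ends) / 2.0) % t.length
        dist = np.abs((mids - t.ori + t.length / 2) % t.length - t.length / 2)
        frac = np.minimum(dist / (t.length / 2), 1.0)
        expected = mean_depth * _ptr_modulation(frac, t.ptr)
        spans = ends - starts
        observed = rng.poisson(expected * spans) / spans
        for a, b, d in zip(starts, ends, observed):
            rows.append((s.id, int(a), int(b), float(d)))
    return pd.DataFrame(rows, columns=["scaffold", "window_start", "window_end", "depth"])


@dataclass
class PlantedVariants:
    """Planted variant sites for one genome (positions are genome coords)."""

    genome: str
    positions: np.ndarray
    alts: np.ndarray
    freqs: np.ndarray
    classes: np.ndarray  # synonymous / nonsynonymous / noncoding

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def n_nonsynonymous(self) -> int:
        return int((self.classes == "nonsynonymous").sum())

    @property
    def n_synonymous(self) -> int:
        return int((self.classes == "synonymous").sum())


class PileupSimulation:
    """Lazy per-site pileup stream plus the eagerly computed plant record."""

    def __init__(self, emitters: list[tuple], planted: dict[str, PlantedVariants]):
        self._emitters = emitters
        self.planted = planted

    def sites(self):
        for emit in self._emitters:
            yield from emit()


def _plant_variants(
    rng: np.random.Generator,
    gid: str,
    seq_codes: np.ndarray,
    orfs: list[GeneAnnotation],
    density: float,
    dnds: float,
    freq_range: tuple[float, float],
) -> PlantedVariants:
    """Choose variant substitutions by weighted sampling without replacement.

    Every possible single-nucleotide substitution gets weight 1 if
    noncoding or synonymous and ``dnds`` if nonsynonymous; sampling
    n = density * L / 1000 of them realizes the planted dN/dS against the
    opportunity counts by construction.
    """
    length = len(seq_codes)
    n_snp = int(round(density * length / 1000.0))
    if n_snp == 0:
        empty = np.array([], dtype=int)
        return PlantedVariants(
            gid, empty, empty.astype("<U1"), empty.astype(float), empty.astype("<U13")
        )
    alt_codes = _OTHER[seq_codes]  # (L, 3)
    weights = np.ones((length, 3))
    classes = np.full((length, 3), "noncoding", dtype="<U13")
    seq_str = _decode(seq_codes)
    for orf in orfs:
        for cstart in range(orf.start, orf.end, 3):
            codon = seq_str[cstart : cstart + 3]
            for offset, alt, synonymous in popgen.CODON_SUBSTITUTIONS[codon]:
                pos = cstart + offset
                slot = _ALT_SLOT[seq_codes[pos]][alt]
                if synonymous:
                    classes[pos, slot] = "synonymous"
                else:
                    classes[pos, slot] = "nonsynonymous"
                    weights[pos, slot] = dnds
    # Gumbel top-k = weighted sampling without replacement
    keys = np.log(weights) - np.log(-np.log(rng.random((length, 3))))
    flat_order = np.argsort(keys, axis=None)[::-1]
    pos_order = flat_order // 3
    slot_order = flat_order % 3
    chosen_pos: list[int] = []
    chosen_slot: list[int] = []
    used = np.zeros(length, dtype=bool)
    for p, s in zip(pos_order, slot_order):
        if used[p]:
            continue
        used[p] = True
        chosen_pos.append(int(p))
        chosen_slot.append(int(s))
        if len(chosen_pos) == n_snp:
            break
    order = np.argsort(chosen_pos)
    positions = np.array(chosen_pos)[order]
    slots = np.array(chosen_slot)[order]
    alts = _BASE[alt_codes[positions, slots]]
    freqs = rng.uniform(*freq_range, size=n_snp)
    return PlantedVariants(
        gid, positions, alts, freqs, classes[positions, slots]
    )


def simulate_pileups(
    genomes: dict[str, str],
    truth: CommunityTruth,
    mean_depth: float = 50.0,
    genome_ids: list[str] | None = None,
    *,
    low_quality_fraction: float = 0.1,
    allele_freq_range: tuple[float, float] = (0.2, 0.5),
    error_rate: float = 0.0,
    seed: int | None = None,
) -> PileupSimulation:
    """Per-site pileups with planted SNPs, qualities and optional errors.

    Minor-allele read counts are binomial at the planted frequency;
    ``low_quality_fraction`` of reads draw a mapping or base quality below
    the downstream cutoffs (split evenly between the two failure modes).
    Minor-allele frequencies default to 0.2-0.5 so planted sites remain
    detectable after the 40-read cap.
    """
    if mean_depth < 1:
        raise ValueError("mean_depth must be >= 1")
    base_seed = (truth.spec.seed if seed is None else seed) & 0x7FFFFFFF
    ids = sorted(genome_ids if genome_ids is not None else genomes)
    planted: dict[str, PlantedVariants] = {}
    emitters = []
    for gi, gid in enumerate(ids):
        t = truth.genomes[gid]
        seq = genomes[gid]
        seq_codes = np.array([_CODE[ch] for ch in seq], dtype=np.uint8)
        plant_rng = np.random.default_rng([base_seed, 3, gi])
        plants = _plant_variants(
            plant_rng,
            gid,
            seq_codes,
            t.orfs,
            t.snp_density,
            t.dnds,
            allele_freq_range,
        )
        planted[gid] = plants

        def emit(
            gid=gid,
            seq=seq,
            gi=gi,
            plants=plants,
        ):
            rng = np.random.default_rng([base_seed, 5, gi])
            length = len(seq)
            depths = rng.poisson(mean_depth, size=length)
            snp_at = dict(
                zip(plants.positions.tolist(), zip(plants.alts, plants.freqs))
            )
            q = low_quality_fraction
            for pos in range(length):
                d = int(depths[pos])
                ref = seq[pos]
                if d == 0:
                    yield PileupSite(
                        genome=gid,
                        scaffold=gid,
                        pos=pos,
                        ref=ref,
                        bases=np.array([], dtype="<U1"),
                        mapq=np.array([], dtype=int),
                        baseq=np.array([], dtype=int),
                    )
                    continue
                hit = snp_at.get(pos)
                if hit is not None:
                    alt, freq = hit
                    bases = np.where(rng.random(d) < freq, alt, ref)
                else:
                    bases = np.full(d, ref, dtype="<U1")
                if error_rate > 0:
                    err = rng.random(d) < error_rate
                    if err.any():
                        bases = bases.copy()
                        bases[err] = rng.choice(_BASE, size=int(err.sum()))
                mapq = rng.integers(20, 61, size=d)
                baseq = rng.integers(30, 42, size=d)
                fail = rng.random(d) < q
                if fail.any():
                    mode = rng.random(d) < 0.5
                    mfail = fail & mode
                    bfail = fail & ~mode
                    if mfail.any():
                        mapq[mfail] = rng.integers(0, 20, size=int(mfail.sum()))
                    if bfail.any():
                        baseq[bfail] = rng.integers(0, 30, size=int(bfail.sum()))
                yield PileupSite(
                    genome=gid,
                    scaffold=gid,
                    pos=pos,
                    ref=ref,
                    bases=bases,
                    mapq=mapq,
                    baseq=baseq,
                )

        emitters.append(emit)
    return PileupSimulation(emitters, planted)


def emit_annotations(truth: CommunityTruth, genome_ids: list[str] | None = None):
    """Materialize the planted annotations (CDS + rRNA/tRNA) as a table."""
    import pandas as pd

    ids = sorted(genome_ids if genome_ids is not None else truth.genomes)
    rows = []
    for gid in ids:
        t = truth.genomes[gid]
        for ann in list(t.orfs) + list(t.features):
            rows.append(
                {
                    "feature": ann.id,
                    "genome": ann.genome,
                    "start": ann.start,
                    "end": ann.end,
                    "strand": ann.strand,
                    "type": ann.feature_type,
                    "product": ann.product,
                }
            )
    return pd.DataFrame(rows)
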