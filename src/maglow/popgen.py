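"""Within-species polymorphism: SNP calling filters, SNP density, pN/pS.

The calling chain mirrors a conservative metagenomic workflow: per-read
quality filtering (mapping quality >= 20, base quality >= 30), capping each
site at 40 reads to equalize depth between genomes, requiring 200,000
callable sites of >= 20x depth before a genome is analyzed at all, and
retaining a site as a SNP only when the major allele frequency is below 95%
and the minor allele is supported by at least two reads.

pN/pS contrasts observed nonsynonymous/synonymous polymorphism with the
mutational opportunity counts obtained by enumerating all nine single-
nucleotide changes of every codon under the standard genetic code
(substitutions creating a stop codon count as nonsynonymous).
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy import stats

from .records import GeneAnnotation, PileupSite, PnpsReport, SnpCall

_BASES = ("A", "C", "G", "T")


def _codon_universe() -> tuple[dict[str, str], dict[str, list[tuple[int, str, bool]]]]:
    table = CodonTable.unambiguous_dna_by_id[1]
    amino = dict(table.forward_table)
    for stop in table.stop_codons:
        amino[stop] = "*"
    subs: dict[str, list[tuple[int, str, bool]]] = {}
    for codon, aa in amino.items():
        if aa == "*":
            continue
        entries = []
        for offset in range(3):
            for alt in _BASES:
                if alt == codon[offset]:
                    continue
                mutant = codon[:offset] + alt + codon[offset + 1 :]
                synonymous = amino[mutant] == aa  # stop-producing -> nonsynonymous
                entries.append((offset, alt, synonymous))
        subs[codon] = entries
    return amino, subs


AMINO_ACID, CODON_SUBSTITUTIONS = _codon_universe()
STOP_CODONS = frozenset(c for c, a in AMINO_ACID.items() if a == "*")


def codon_opportunities(orf_sequence: str) -> tuple[int, int]:
    """(nonsynonymous, synonymous) single-substitution opportunity counts.

    Every codon contributes its nine possible single-nucleotide changes;
    N + S = 3 * len(orf).  The ORF must be in frame (length divisible by 3),
    unambiguous, and free of internal stop codons.
    """
    seq = orf_sequence.upper()
    if len(seq) % 3 != 0:
        raise ValueError("ORF length must be divisible by 3")
    n = s = 0
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if codon in STOP_CODONS:
            raise ValueError(f"internal stop codon {codon} at {i}")
        try:
            entries = CODON_SUBSTITUTIONS[codon]
        except KeyError:
            raise ValueError(f"ambiguous codon {codon!r} at {i}") from None
        for _, _, synonymous in entries:
            s += synonymous
            n += not synonymous
    return n, s


def filter_observations(
    site: PileupSite, mapq_min: int = 20, baseq_min: int = 30
) -> PileupSite:
    """Keep observations with mapping quality >= 20 and base quality >= 30."""
    keep = (site.mapq >= mapq_min) & (site.baseq >= baseq_min)
    return PileupSite(
        genome=site.genome,
        scaffold=site.scaffold,
        pos=site.pos,
        ref=site.ref,
        bases=site.bases[keep],
        mapq=site.mapq[keep],
        baseq=site.baseq[keep],
    )


def _site_rng(site: PileupSite, seed: int) -> np.random.Generator:
    # keyed on (scaffold, position) so the subsample is stable across runs
    # and independent of iteration order
    key = zlib.crc32(f"{site.scaffold}:{site.pos}".encode())
    return np.random.default_rng([seed & 0x7FFFFFFF, key])


def subsample_site(site: PileupSite, cap: int = 40, seed: int = 0) -> PileupSite:
    """Subsample to at most ``cap`` reads, without replacement, seeded."""
    if site.depth <= cap:
        return site
    idx = np.sort(_site_rng(site, seed).choice(site.depth, size=cap, replace=False))
    return PileupSite(
        genome=site.genome,
        scaffold=site.scaffold,
        pos=site.pos,
        ref=site.ref,
        bases=site.bases[idx],
        mapq=site.mapq[idx],
        baseq=site.baseq[idx],
    )


def eligible_mag(site_depths, depth_min: int = 20, site_min: int = 200_000) -> bool:
    """A genome enters the analysis only with >= 200,000 sites of >= 20x depth.

    ``site_depths`` may be an iterable of per-site post-filter depths or a
    precomputed count of qualifying sites.
    """
    if np.isscalar(site_depths):
        n = int(site_depths)
    else:
        depths = np.asarray(list(site_depths))
        n = int((depths >= depth_min).sum())
    return n >= site_min


def call_snp(site: PileupSite, min_depth: int = 20) -> SnpCall | None:
    """Emit a call iff major frequency < 0.95 and minor support >= 2.

    Sites with fewer than ``min_depth`` observations are not callable.  At
    multi-allelic sites only the top minor allele is evaluated against the
    two-read support rule.  Ties are broken alphabetically.
    """
    depth = site.depth
    if depth < min_depth:
        return None
    counts = {b: 0 for b in _BASES}
    values, freqs = np.unique(site.bases, return_counts=True)
    counts.update(dict(zip(values.tolist(), freqs.tolist())))
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    major, major_count = ranked[0]
    minor, minor_count = ranked[1]
    major_freq = major_count / depth
    if major_freq >= 0.95 or minor_count < 2:
        return None
    return SnpCall(
        genome=site.genome,
        scaffold=site.scaffold,
        pos=site.pos,
        ref=site.ref,
        major=major,
        major_freq=major_freq,
        minor=minor,
        minor_count=minor_count,
        depth=depth,
    )


def snp_density(n_snps: int, n_eligible_sites: int) -> float:
    """SNPs per kilobase of callable sequence."""
    if n_eligible_sites <= 0:
        raise ValueError("snp_density requires at least one eligible site")
    return 1000.0 * n_snps / n_eligible_sites


def pnps(obs_n: int, obs_s: int, exp_n: float, exp_s: float) -> PnpsReport:
    """Pooled pN/pS report; ``ratio`` is None when obsS = 0 (undefined)."""
    return PnpsReport(obs_n=obs_n, obs_s=obs_s, exp_n=exp_n, exp_s=exp_s)


@dataclass
class PopgenResult:
    genome: str
    eligible: bool
    eligible_sites: int
    snps: list[SnpCall]
    density: float | None
    pnps: PnpsReport

    @property
    def n_snps(self) -> int:
        return len(self.snps)


class _CodingIndex:
    """Position -> (ORF, codon start, offset) lookup over forward-strand ORFs."""

    def __init__(self, orfs: list[GeneAnnotation], genome_sequence: str):
        self.seq = genome_sequence
        self.orf_at = {}
        self.orfs = [o for o in orfs if o.feature_type == "CDS"]
        for i, orf in enumerate(self.orfs):
            for pos in range(orf.start, orf.end):
                off = (pos - orf.start) % 3
                self.orf_at[pos] = (i, pos - off, off)

    def classify(self, pos: int, alt: str) -> tuple[str, int | None]:
        hit = self.orf_at.get(pos)
        if hit is None:
            return "noncoding", None
        i, codon_start, off = hit
        codon = self.seq[codon_start : codon_start + 3]
        mutant = codon[:off] + alt + codon[off + 1 :]
        if AMINO_ACID.get(mutant) == AMINO_ACID.get(codon):
            return "synonymous", i
        return "nonsynonymous", i


def analyze_genome(
    sites,
    orfs: list[GeneAnnotation],
    genome_sequence: str,
    genome_id: str | None = None,
    *,
    mapq_min: int = 20,
    baseq_min: int = 30,
    cap: int = 40,
    min_depth: int = 20,
    site_min: int = 200_000,
    seed: int = 0,
) -> PopgenResult:
    """Run the full per-genome chain: filter, cap, call, density, pN/pS.

    Eligible (denominator) sites are the sites that remain callable after
    quality filtering and capping, i.e. >= ``min_depth`` retained reads; the
    same floor gates SNP emission so numerator and denominator agree.
    Opportunity counts pool every ORF overlapping at least one eligible
    site.
    """
    eligible_sites = 0
    snps: list[SnpCall] = []
    index = _CodingIndex(orfs, genome_sequence)
    covered = np.zeros(len(index.orfs), dtype=bool)
    gid = genome_id
    for site in sites:
        gid = gid or site.genome
        filtered = filter_observations(site, mapq_min, baseq_min)
        if filtered.depth < min_depth:
            continue
        capped = subsample_site(filtered, cap=cap, seed=seed)
        eligible_sites += 1
        hit = index.orf_at.get(site.pos)
        if hit is not None:
            covered[hit[0]] = True
        call = call_snp(capped, min_depth=min_depth)
        if call is None:
            continue
        alt = call.minor if call.major == call.ref else call.major
        call.substitution_class, _ = index.classify(site.pos, alt)
        snps.append(call)
    exp_n = exp_s = 0.0
    for i, orf in enumerate(index.orfs):
        if covered[i]:
            n, s = codon_opportunities(genome_sequence[orf.start : orf.end])
            exp_n += n
            exp_s += s
    obs_n = sum(c.substitution_class == "nonsynonymous" for c in snps)
    obs_s = sum(c.substitution_class == "synonymous" for c in snps)
    density = (
        snp_density(len(snps), eligible_sites) if eligible_sites > 0 else None
    )
    return PopgenResult(
        genome=gid or "?",
        eligible=eligible_mag(eligible_sites, site_min=site_min),
        eligible_sites=eligible_sites,
        snps=snps,
        density=density,
        pnps=pnps(obs_n, obs_s, exp_n, exp_s),
    )


def feature_correlations(
    table: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rank correlations between per-genome features.

    Returns (rho, p) DataFrames.  Ties are mid-ranked; p-values come from
    the large-sample t approximation.  Constant columns yield NaN entries.
    Requires at least five complete rows.
    """
    clean = table.dropna()
    if len(clean) < 5:
        raise ValueError("feature_correlations requires >= 5 complete rows")
    cols = clean.columns
    k = len(cols)
    rho = np.ones((k, k))
    pval = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            x, y = clean.iloc[:, i], clean.iloc[:, j]
            if x.nunique() < 2 or y.nunique() < 2:
                r, p = np.nan, np.nan
            else:
                r, p = stats.spearmanr(x, y)
            rho[i, j] = rho[j, i] = r
            pval[i, j] = pval[j, i] = p
    for i in range(k):
        if clean.iloc[:, i].nunique() < 2:
            rho[i, i] = np.nan
    return (
        pd.DataFrame(rho, index=cols, columns=cols),
        pd.DataFrame(pval, index=cols, columns=cols),
    )
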