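"""Genome quality scoring, MIMAG classification, ANI and growth rate.

Completeness and contamination come from a single-copy marker-gene (SCG)
estimator over a fixed 123-marker universe: completeness is the fraction of
distinct markers present, contamination the fraction of extra copies.  The
composite quality score is percent-scale completeness minus five times
percent-scale contamination, and draft genomes must exceed completeness
80%, stay below 5% contamination, and score above 60.

ANI is fragment-based: the query is cut into fixed-size fragments, each is
seeded onto the reference with exact k-mers and scored by ungapped
identity, and ANI averages the identities of fragments that map at all.
Growth rate is summarized by the peak-to-trough ratio (PTR): the depth near
the replication origin over the depth near the terminus, with ori/ter
located from the cumulative GC skew.
"""
from __future__ import annotations

from collections import Counter, defaultdict

import numpy as np
from scipy import stats

from .records import AniResult, QualityReport, SkewProfile
from .seqfeatures import revcomp

N_MARKERS = 123


def scg_completeness(
    marker_counts, n_markers: int = N_MARKERS
) -> tuple[float, float]:
    """(completeness, contamination) from marker copy counts.

    ``marker_counts`` maps marker id -> copy number in the bin (a Counter,
    dict, or iterable of marker ids with repeats).  Completeness is
    distinct markers / universe size; contamination is extra copies beyond
    one per marker / universe size.
    """
    if not isinstance(marker_counts, dict):
        marker_counts = Counter(marker_counts)
    present = sum(1 for c in marker_counts.values() if c > 0)
    extra = sum(max(c - 1, 0) for c in marker_counts.values())
    return present / n_markers, extra / n_markers


def quality_score(completeness: float, contamination: float) -> float:
    """Percent-scale score: 100 * completeness - 5 * (100 * contamination)."""
    return 100.0 * completeness - 5.0 * (100.0 * contamination)


def estimated_genome_size(
    assembly_size: float, completeness: float, contamination: float
) -> float:
    """Assembly size adjusted for completeness and contamination (fractions).

    size / (completeness + contamination); the denominator is near 1 for a
    complete, clean genome, so the estimate reduces to the assembly size.
    """
    denom = completeness + contamination
    if denom <= 0:
        raise ValueError("completeness + contamination must be > 0")
    return assembly_size / denom


def filter_draft(
    completeness: float, contamination: float, score: float
) -> bool:
    """Draft criteria: completeness > 80%, contamination < 5%, score > 60
    (all strict)."""
    return completeness > 0.80 and contamination < 0.05 and score > 60.0


def classify_mimag(
    completeness: float,
    contamination: float,
    rrna: dict[str, bool],
    trna_count: int,
    score: float | None = None,
) -> str:
    """MIMAG class: high-quality draft requires completeness > 90%,
    contamination < 5%, 5S + 16S + 23S rRNA present and >= 18 tRNAs;
    otherwise 'draft' if the draft filter passes, else 'fail'."""
    if (
        completeness > 0.90
        and contamination < 0.05
        and all(rrna.get(r, False) for r in ("5S", "16S", "23S"))
        and trna_count >= 18
    ):
        return "high-quality"
    if score is None:
        score = quality_score(completeness, contamination)
    if filter_draft(completeness, contamination, score):
        return "draft"
    return "fail"


def quality_report(
    marker_counts,
    assembly_size: float,
    rrna: dict[str, bool],
    trna_count: int,
    n_markers: int = N_MARKERS,
) -> QualityReport:
    comp, cont = scg_completeness(marker_counts, n_markers)
    score = quality_score(comp, cont)
    return QualityReport(
        completeness=comp,
        contamination=cont,
        score=score,
        estimated_size=estimated_genome_size(assembly_size, comp, cont)
        if comp + cont > 0
        else 0.0,
        rrna=dict(rrna),
        trna_count=trna_count,
        mimag_class=classify_mimag(comp, cont, rrna, trna_count, score),
    )


def _index_kmers(sequence: str, k: int, cap: int = 4) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(sequence) - k + 1):
        hits = index[sequence[i : i + k]]
        if len(hits) < cap:
            hits.append(i)
    return index


def compute_ani(
    query: str,
    reference: str,
    fragment: int = 1000,
    *,
    k: int = 16,
    min_identity: float = 0.8,
    seed_step: int = 8,
    max_candidates: int = 50,
    query_id: str = "query",
    reference_id: str = "reference",
) -> AniResult:
    """Fragment-based average nucleotide identity.

    The query is cut into non-overlapping ``fragment``-bp pieces (the
    trailing remainder is discarded); each piece is anchored on the
    reference by exact ``k``-mer seeds tried every ``seed_step`` bp on both
    strands and scored by ungapped identity at the implied offset.  A
    fragment maps when its best identity reaches ``min_identity``; ANI is
    the mean identity of mapped fragments and coverage the mapped fraction.
    """
    if not query or not reference:
        raise ValueError("compute_ani requires non-empty sequences")
    n_frag = len(query) // fragment
    if n_frag < 2 or len(reference) < 2 * fragment:
        raise ValueError("both sequences must span >= 2 fragments")
    index = _index_kmers(reference, k)
    ref_arr = np.frombuffer(reference.encode("ascii"), dtype=np.uint8)
    identities = []
    for f in range(n_frag):
        frag = query[f * fragment : (f + 1) * fragment]
        best = 0.0
        for oriented in (frag, revcomp(frag)):
            frag_arr = np.frombuffer(oriented.encode("ascii"), dtype=np.uint8)
            tried = 0
            seen_offsets = set()
            for s in range(0, len(oriented) - k + 1, seed_step):
                for rpos in index.get(oriented[s : s + k], ()):
                    off = rpos - s
                    if off in seen_offsets:
                        continue
                    seen_offsets.add(off)
                    a = max(0, -off)
                    b = min(len(oriented), len(reference) - off)
                    if b - a < 0.9 * fragment:
                        continue
                    ident = float(
                        np.mean(frag_arr[a:b] == ref_arr[off + a : off + b])
                    )
                    best = max(best, ident)
                    tried += 1
                    if best > 0.999 or tried >= max_candidates:
                        break
                if best > 0.999 or tried >= max_candidates:
                    break
            if best > 0.999:
                break
        if best >= min_identity:
            identities.append(best)
    mapped = len(identities)
    return AniResult(
        query=query_id,
        reference=reference_id,
        ani=float(np.mean(identities)) if mapped else 0.0,
        coverage=mapped / n_frag,
    )


def classify_novelty(best_hit: AniResult | None) -> str:
    """'known' iff some reference reaches ANI >= 95% with >= 40% coverage."""
    if best_hit is None:
        return "novel"
    if best_hit.ani >= 0.95 and best_hit.coverage >= 0.40:
        return "known"
    return "novel"


def quality_improved(query_score: float, reference_score: float) -> bool:
    """A genome improves on its reference iff its score is strictly higher."""
    return query_score > reference_score


def estimate_ptr(
    window_depths,
    ori_index: int | None = None,
    ter_index: int | None = None,
    skew: SkewProfile | None = None,
    band: float = 0.05,
    trim: float = 0.1,
) -> tuple[float, str]:
    """Peak-to-trough depth ratio from a circular windowed depth profile.

    Depth is summarized by a trimmed mean over the ``band`` fraction of
    windows nearest the origin and nearest the terminus (located from the
    cumulative GC skew unless indices are given).  Returns (ptr,
    orientation); ptr >= 1 by construction, with orientation 'reversed'
    when the trough sat at the nominal origin.
    """
    depths = np.asarray(window_depths, dtype=float)
    n = len(depths)
    if n < 20:
        raise ValueError("estimate_ptr requires >= 20 windows")
    if ori_index is None or ter_index is None:
        if skew is None:
            raise ValueError("provide ori/ter indices or a SkewProfile")
        ori_index, ter_index = skew.ori_index, skew.ter_index
    half = max(1, int(round(band * n / 2)))

    def _band_mean(center: int) -> float:
        idx = (np.arange(center - half, center + half + 1)) % n
        return float(stats.trim_mean(depths[idx], trim))

    peak = _band_mean(ori_index)
    trough = _band_mean(ter_index)
    if peak == 0 and trough == 0:
        raise ValueError("zero depth at both origin and terminus")
    orientation = "forward"
    if trough > peak:
        peak, trough = trough, peak
        orientation = "reversed"
    if trough == 0:
        raise ValueError("zero trough depth")
    return peak / trough, orientation
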