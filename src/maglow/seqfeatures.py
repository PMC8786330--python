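"""Per-scaffold sequence features and assembly statistics.

Provides the signals used throughout the pipeline: the minimum-length
filter applied to raw assemblies, GC content, the canonical 136-entry
tetranucleotide frequency (TNF) signature used for binning, windowed read
depth, cumulative GC skew for locating the replication origin/terminus of
circular genomes, and standard assembly statistics (N50, largest scaffold).
"""
from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd

from .records import AssemblyStats, ScaffoldRecord, SkewProfile

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def _build_canonical_kmers() -> tuple[list[str], np.ndarray]:
    """Canonical 4-mer space: 256 4-mers collapsed by reverse complement.

    The canonical representative of a pair is the lexicographic minimum;
    palindromic 4-mers represent themselves, giving 136 entries ordered
    lexicographically.
    """
    kmers = ["".join(p) for p in product("ACGT", repeat=4)]
    canon = sorted({min(k, revcomp(k)) for k in kmers})
    index = {k: i for i, k in enumerate(canon)}
    code_to_canon = np.empty(256, dtype=np.int64)
    for code, k in enumerate(kmers):
        code_to_canon[code] = index[min(k, revcomp(k))]
    return canon, code_to_canon


CANONICAL_KMERS, _CODE_TO_CANON = _build_canonical_kmers()

# byte value -> base code (A=0, C=1, G=2, T=3, other=4)
_BYTE_CODE = np.full(256, 4, dtype=np.int64)
for _b, _c in zip(b"ACGT", range(4)):
    _BYTE_CODE[_b] = _c
for _b, _c in zip(b"acgt", range(4)):
    _BYTE_CODE[_b] = _c


def _encode(sequence: str) -> np.ndarray:
    return _BYTE_CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def filter_scaffolds(
    scaffolds: list[ScaffoldRecord], min_length: int = 2000
) -> list[ScaffoldRecord]:
    """Drop scaffolds shorter than ``min_length``; exactly 2000 bp is kept."""
    return [s for s in scaffolds if s.length >= min_length]


def compute_gc(sequence: str) -> float:
    """GC fraction over unambiguous bases; N is excluded from the denominator.

    Raises ``ValueError`` when the sequence has no unambiguous base.
    """
    codes = _encode(sequence)
    counts = np.bincount(codes, minlength=5)
    denom = counts[:4].sum()
    if denom == 0:
        raise ValueError("GC content undefined: no unambiguous bases")
    return float((counts[1] + counts[2]) / denom)


def compute_tnf(sequence: str) -> np.ndarray:
    """Canonical tetranucleotide frequency vector (136 entries, sums to 1).

    4-mers containing an ambiguous base are skipped.  Sequences shorter than
    4 bp, or with no valid 4-mer, yield an all-zero vector (flagged invalid
    by its zero sum).
    """
    out = np.zeros(len(CANONICAL_KMERS))
    if len(sequence) < 4:
        return out
    codes = _encode(sequence)
    k4 = codes[:-3] * 64 + codes[1:-2] * 16 + codes[2:-1] * 4 + codes[3:]
    valid = (
        (codes[:-3] < 4) & (codes[1:-2] < 4) & (codes[2:-1] < 4) & (codes[3:] < 4)
    )
    k4 = k4[valid]
    if k4.size == 0:
        return out
    counts = np.bincount(_CODE_TO_CANON[k4], minlength=len(CANONICAL_KMERS))
    return counts / counts.sum()


# members of each canonical 4-mer pair as base-count vectors, for the iid
# expectation used by compute_tnf_residual
_MEMBER_COUNTS = np.zeros((len(CANONICAL_KMERS), 2, 4))
_MEMBER_MASK = np.zeros((len(CANONICAL_KMERS), 2))
for _i, _k in enumerate(CANONICAL_KMERS):
    _pair = [_k] if revcomp(_k) == _k else [_k, revcomp(_k)]
    for _j, _m in enumerate(_pair):
        for _b, _code in zip("ACGT", range(4)):
            _MEMBER_COUNTS[_i, _j, _code] = _m.count(_b)
        _MEMBER_MASK[_i, _j] = 1.0


def compute_tnf_residual(sequence: str, eps: float = 1e-6) -> np.ndarray:
    """Log-ratio of observed TNF to its iid expectation from base content.

    Raw TNF vectors are dominated by GC content, so two genomes of similar
    GC correlate near 1 regardless of their actual k-mer signatures.  The
    residual log(observed / expected-under-independent-bases) removes that
    shared component and isolates the genome-specific signature; it is the
    composition feature the binner correlates.
    """
    obs = compute_tnf(sequence)
    if obs.sum() == 0:
        return obs
    codes = _encode(sequence)
    counts = np.bincount(codes, minlength=5)[:4].astype(float)
    p = counts / counts.sum()
    expected = (_MEMBER_MASK * np.prod(p[None, None, :] ** _MEMBER_COUNTS, axis=2)).sum(
        axis=1
    )
    return np.log((obs + eps) / (expected + eps))


def cumulative_gc_skew(sequence: str, window: int = 1000) -> SkewProfile:
    """Windowed GC skew (G-C)/(G+C) and its cumulative series.

    Convention: the origin of replication sits at the global *minimum* of
    the cumulative series and the terminus at the global maximum (leading
    replichore G-rich).  Windows with G+C = 0 contribute a skew of 0.  The
    first index wins ties, so a flat series reports both extremes at 0.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    codes = _encode(sequence)
    edges = np.arange(0, len(codes), window)
    g = np.add.reduceat((codes == 2).astype(np.int64), edges)
    c = np.add.reduceat((codes == 1).astype(np.int64), edges)
    denom = g + c
    skew = np.where(denom > 0, (g - c) / np.maximum(denom, 1), 0.0)
    cumulative = np.cumsum(skew)
    return SkewProfile(
        window=window,
        skew=skew,
        cumulative=cumulative,
        ori_index=int(np.argmin(cumulative)),
        ter_index=int(np.argmax(cumulative)),
    )


def assembly_stats(lengths) -> AssemblyStats:
    """Total length, N50, largest scaffold and count of scaffolds >= 1 Mbp.

    N50 is the length of the scaffold at which the cumulative sum of
    descending-sorted lengths first reaches half the total.
    """
    lengths = np.asarray(list(lengths), dtype=np.int64)
    if lengths.size == 0:
        raise ValueError("assembly_stats requires at least one scaffold")
    if (lengths <= 0).any():
        raise ValueError("scaffold lengths must be positive")
    desc = np.sort(lengths)[::-1]
    total = int(desc.sum())
    cum = np.cumsum(desc)
    n50 = int(desc[np.searchsorted(cum, total / 2)])
    return AssemblyStats(
        total=total,
        n50=n50,
        largest=int(desc[0]),
        n_ge_1mbp=int((lengths >= 1_000_000).sum()),
    )


def window_depth(per_base_depth, window: int = 1000) -> np.ndarray:
    """Mean depth per non-overlapping window.

    The final partial window is averaged over its actual span rather than
    padded.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    depth = np.asarray(per_base_depth, dtype=float)
    if (depth < 0).any():
        raise ValueError("depth values must be >= 0")
    edges = np.arange(0, len(depth), window)
    sums = np.add.reduceat(depth, edges)
    spans = np.diff(np.append(edges, len(depth)))
    return sums / spans


def scaffold_features(
    scaffolds: list[ScaffoldRecord],
    depth_table: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Feature table (length, gc, depth) plus the aligned TNF matrix.

    ``depth_table`` is the windowed depth TSV schema (scaffold,
    window_start, window_end, depth); the per-scaffold depth is the
    span-weighted mean over its windows.
    """
    rows = []
    tnfs = []
    depth_by_scaffold: dict[str, float] = {}
    if depth_table is not None:
        spans = depth_table["window_end"] - depth_table["window_start"]
        grouped = (
            pd.DataFrame(
                {
                    "scaffold": depth_table["scaffold"],
                    "bases": depth_table["depth"] * spans,
                    "span": spans,
                }
            )
            .groupby("scaffold")
            .sum()
        )
        depth_by_scaffold = (grouped["bases"] / grouped["span"]).to_dict()
    for s in scaffolds:
        rows.append(
            {
                "scaffold": s.id,
                "length": s.length,
                "gc": compute_gc(s.sequence),
                "depth": depth_by_scaffold.get(s.id, np.nan),
            }
        )
        tnfs.append(compute_tnf(s.sequence))
    frame = pd.DataFrame(rows).set_index("scaffold")
    return frame, np.vstack(tnfs) if tnfs else np.empty((0, len(CANONICAL_KMERS)))
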