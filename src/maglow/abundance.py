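"""MAG depth, relative abundance, abundance tiers and detectability.

Relative abundance is computed on the base scale: the depth of a MAG times
its length is the number of sequenced bases attributable to it, and
dividing by the total mapped bases of the sample gives the fraction of the
metagenome the MAG explains.  Tiers follow the conventional gut-metagenome
cutoffs: high-abundance above 1%, low-abundance between 0.1% and 1%
(boundaries inclusive), extra-low below 0.1%.
"""
from __future__ import annotations

import numpy as np
import pandas as pd


def mag_depth(depths, lengths) -> float:
    """Length-weighted mean depth over the member scaffolds of a MAG."""
    depths = np.asarray(depths, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if depths.size == 0:
        raise ValueError("mag_depth requires at least one scaffold")
    if depths.shape != lengths.shape:
        raise ValueError("depths and lengths must align")
    return float(np.sum(depths * lengths) / np.sum(lengths))


def relative_abundance(
    depths, lengths, total_mapped_bases: float
) -> np.ndarray:
    """Per-bin relative abundance = depth x length / total mapped bases."""
    if total_mapped_bases <= 0:
        raise ValueError("total_mapped_bases must be > 0")
    depths = np.asarray(depths, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    return depths * lengths / total_mapped_bases


def classify_tier(abundance: float) -> str:
    """high (> 1%), low (0.1-1%, boundaries inclusive), extra-low (< 0.1%)."""
    if not 0 <= abundance <= 1:
        raise ValueError("abundance must be a fraction in [0, 1]")
    if abundance > 0.01:
        return "high"
    if abundance >= 0.001:
        return "low"
    return "extra-low"


def expected_yield(
    total_bases: float, abundance: float, genome_size: float | None = None
):
    """Sequence yield attributable to a species at a given abundance.

    With 5 Gbp of data, a species at 0.1% relative abundance contributes
    only 5 Mbp.  When ``genome_size`` is given, returns (yield, coverage).
    """
    if total_bases < 0:
        raise ValueError("total_bases must be >= 0")
    if not 0 <= abundance <= 1:
        raise ValueError("abundance must be a fraction in [0, 1]")
    y = total_bases * abundance
    if genome_size is None:
        return y
    return y, y / genome_size


def rarefy_detectability(
    abundances, genome_sizes, data_amounts, min_coverage: float
) -> pd.Series:
    """Count genomes reaching ``min_coverage`` at each sequencing amount.

    A genome is detectable at data amount D iff D * abundance / size >=
    min_coverage; the resulting counts are nondecreasing step functions of
    D.
    """
    if min_coverage <= 0:
        raise ValueError("min_coverage must be > 0")
    abundances = np.asarray(abundances, dtype=float)
    sizes = np.asarray(genome_sizes, dtype=float)
    counts = {}
    for d in data_amounts:
        counts[d] = int(np.sum(d * abundances / sizes >= min_coverage))
    return pd.Series(counts, name="detectable")


def abundance_table(
    membership: dict[str, list[str]],
    depth_by_scaffold: dict[str, float],
    length_by_scaffold: dict[str, float],
    total_mapped_bases: float,
) -> pd.DataFrame:
    """Per-bin depth, relative abundance and tier in one table."""
    rows = []
    for bin_id, scaffolds in membership.items():
        d = [depth_by_scaffold[s] for s in scaffolds]
        ln = [length_by_scaffold[s] for s in scaffolds]
        depth = mag_depth(d, ln)
        size = float(np.sum(ln))
        ab = float(relative_abundance([depth], [size], total_mapped_bases)[0])
        rows.append(
            {
                "bin": bin_id,
                "depth": depth,
                "size": size,
                "abundance": ab,
                "tier": classify_tier(min(ab, 1.0)),
            }
        )
    return pd.DataFrame(rows).set_index("bin")
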