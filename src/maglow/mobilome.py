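"""Mobile genetic elements, viral/plasmid scaffolds, pathways, enrichment.

Chromosomal MGEs are classified by case-insensitive keyword search over ORF
product descriptions, in a fixed priority order (transposon -> plasmid ->
phage -> other).  The shipped keyword lists are a reconstruction of the
commonly used annotation-keyword scheme and are fully configurable.
Extrachromosomal calls follow threshold rules on external detector
evidence: viral scaffolds are >= 5 kb with a qualifying VirSorter category
(1, 2 or 4) or a VirFinder score >= 0.9 at p < 0.01; putative plasmids are
unbinned scaffolds > 10 kb that close into a circle (terminal-overlap
test).  Pathway presence requires more than 66% of a pathway's key
reactions, and tier enrichment uses one-sided Fisher tests with Hochberg
step-up adjustment.
"""
from __future__ import annotations

from collections import Counter

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .records import MgeCall, PathwayCall

# Reconstructed keyword lists, editable via the ``keywords`` argument or a
# YAML config through the CLI.  Matching is case-insensitive substring.
DEFAULT_KEYWORDS: dict[str, tuple[str, ...]] = {
    "transposon": ("transposase", "transposon", "insertion sequence", "is element"),
    "plasmid": (
        "plasmid",
        "conjugal transfer",
        "conjugative transfer",
        "mobilization protein",
        "mobilisation protein",
        "relaxase",
        "type iv secretion",
        "trag",
        "trab",
    ),
    "phage": (
        "phage",
        "capsid",
        "terminase",
        "tail protein",
        "tail tape measure",
        "portal protein",
        "baseplate",
        "holin",
        "prophage",
    ),
    "other": (
        "integrase",
        "recombinase",
        "mobile element",
        "resolvase",
        "excisionase",
    ),
}

MGE_CLASSES = ("transposon", "plasmid", "phage", "other")


def classify_cmge(
    product: str, keywords: dict[str, tuple[str, ...]] | None = None
) -> tuple[str, str | None]:
    """Classify one product description; returns (class, matched keyword).

    Classes are tried in fixed priority order so each ORF gets exactly one
    class; no match yields ("none", None).
    """
    kw = DEFAULT_KEYWORDS if keywords is None else keywords
    text = product.lower()
    for mge_class in MGE_CLASSES:
        for needle in kw.get(mge_class, ()):
            if needle in text:
                return mge_class, needle
    return "none", None


def classify_cmge_table(
    annotations: pd.DataFrame,
    keywords: dict[str, tuple[str, ...]] | None = None,
) -> list[MgeCall]:
    """Classify every CDS row of an annotation table."""
    calls = []
    cds = annotations[annotations["type"] == "CDS"]
    for _, row in cds.iterrows():
        mge_class, matched = classify_cmge(row["product"], keywords)
        calls.append(
            MgeCall(
                orf=row["feature"],
                bin=row.get("genome"),
                mge_class=mge_class,
                keyword=matched,
            )
        )
    return calls


def mge_density(calls: list[MgeCall], genome_size: float) -> dict[str, float]:
    """Per-class MGE counts normalized to elements per Mbp of genome."""
    if genome_size <= 0:
        raise ValueError("genome_size must be > 0")
    counts = Counter(c.mge_class for c in calls if c.mge_class != "none")
    return {k: counts.get(k, 0) * 1e6 / genome_size for k in MGE_CLASSES}


def rank_sum(
    x, y, *, exact_max_n: int = 20
) -> tuple[float, float]:
    """Two-sample Wilcoxon-Mann-Whitney test; exact for small samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("rank_sum requires non-empty groups")
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        return float(len(x) * len(y) / 2), 1.0  # complete tie
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (max(len(x), len(y)) <= exact_max_n and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_tiers(
    densities: pd.DataFrame, value_cols=MGE_CLASSES, tier_col: str = "tier"
) -> pd.DataFrame:
    """Pairwise rank-sum tests of per-bin MGE density between tiers.

    Requires >= 3 bins per tier; returns rows (class, tier_a, tier_b,
    statistic, p).
    """
    tiers = sorted(densities[tier_col].unique())
    for t in tiers:
        if (densities[tier_col] == t).sum() < 3:
            raise ValueError(f"tier {t!r} has fewer than 3 bins")
    rows = []
    for col in value_cols:
        for i, ta in enumerate(tiers):
            for tb in tiers[i + 1 :]:
                xa = densities.loc[densities[tier_col] == ta, col]
                xb = densities.loc[densities[tier_col] == tb, col]
                u, p = rank_sum(xa, xb)
                rows.append(
                    {"class": col, "tier_a": ta, "tier_b": tb,
                     "statistic": u, "p": p}
                )
    return pd.DataFrame(rows)


def detect_viral(
    length: int,
    virsorter_category: int | None = None,
    virfinder_score: float | None = None,
    virfinder_p: float | None = None,
    *,
    min_length: int = 5000,
    categories: frozenset[int] = frozenset({1, 2, 4}),
    combine: str = "union",
) -> bool:
    """Putative phage iff >= 5 kb and the detector evidence qualifies.

    Evidence qualifies through VirSorter (category 1, 2 or 4) or VirFinder
    (score >= 0.9 and p < 0.01); the two detectors combine as a union by
    default (configurable to intersection).
    """
    if length < min_length:
        return False
    vs = virsorter_category in categories
    vf = (
        virfinder_score is not None
        and virfinder_p is not None
        and virfinder_score >= 0.9
        and virfinder_p < 0.01
    )
    return (vs or vf) if combine == "union" else (vs and vf)


def is_circular(sequence: str, k: int = 55, max_overlap: int = 2000) -> bool:
    """Terminal-overlap circularity test.

    The scaffold closes into a circle when its k-bp prefix reappears as a
    suffix-anchored repeat within the last ``max_overlap`` bp, and the
    sequence end matches the start over that whole overlap.
    """
    if len(sequence) < 2 * k:
        return False
    prefix = sequence[:k]
    search_from = max(k, len(sequence) - max_overlap)
    idx = sequence.rfind(prefix, search_from)
    while idx != -1:
        overlap = len(sequence) - idx
        if sequence[idx:] == sequence[:overlap]:
            return True
        idx = sequence.rfind(prefix, search_from, idx + k - 1)
    return False


def detect_plasmid(
    sequence_or_length,
    binned: bool,
    circular: bool | None = None,
    *,
    min_length: int = 10_000,
    k: int = 55,
) -> bool:
    """Putative plasmid iff unbinned, > 10 kb and circular.

    Circularity may be supplied as a flag; otherwise it is derived from the
    terminal-overlap test on the sequence.
    """
    if binned:
        return False
    if isinstance(sequence_or_length, str):
        length = len(sequence_or_length)
        if circular is None:
            circular = is_circular(sequence_or_length, k=k)
    else:
        length = int(sequence_or_length)
        if circular is None:
            raise ValueError("circularity flag required when no sequence given")
    return length > min_length and bool(circular)


def assign_viral_taxonomy(
    hits: pd.DataFrame,
    n_proteins: int,
    *,
    bitscore_min: float = 50.0,
) -> str | None:
    """Majority-rule family assignment for a viral scaffold.

    ``hits`` carries (protein, family, bitscore); hits with bitscore <=
    ``bitscore_min`` are discarded, each protein keeps its best remaining
    hit, and a family is assigned only when strictly more than half of all
    predicted proteins (denominator = ``n_proteins``) agree.
    """
    if n_proteins <= 0:
        raise ValueError("n_proteins must be > 0")
    strong = hits[hits["bitscore"] > bitscore_min]
    if strong.empty:
        return None
    best = strong.loc[strong.groupby("protein")["bitscore"].idxmax()]
    counts = best["family"].value_counts()
    family, count = counts.index[0], int(counts.iloc[0])
    return family if count > 0.5 * n_proteins else None


def filter_hits(identity: float, coverage: float, database: str) -> bool:
    """Database-specific hit filters.

    KEGG: identity >= 0.30 and query coverage >= 0.70.
    CARD: identity >= 0.95 and coverage >= 0.90.
    """
    db = database.lower()
    if db == "kegg":
        return identity >= 0.30 and coverage >= 0.70
    if db == "card":
        return identity >= 0.95 and coverage >= 0.90
    raise ValueError(f"unknown database {database!r}")


def pathway_presence(
    reactions_present: set[str],
    pathway_definitions: dict[str, set[str]],
) -> list[PathwayCall]:
    """A pathway is present iff strictly more than 66% of its key reactions
    are identified in the MAG."""
    calls = []
    for pathway, reactions in sorted(pathway_definitions.items()):
        if not reactions:
            raise ValueError(f"pathway {pathway!r} has no key reactions")
        present = len(set(reactions) & reactions_present)
        calls.append(PathwayCall(pathway=pathway, total=len(reactions), present=present))
    return calls


def fisher_one_sided(table) -> float:
    """One-sided (greater) Fisher exact p for a 2x2 table."""
    table = np.asarray(table)
    if (table < 0).any():
        raise ValueError("contingency table entries must be >= 0")
    return float(stats.fisher_exact(table, alternative="greater")[1])


def enrichment(tables: dict[str, np.ndarray]) -> pd.DataFrame:
    """One-sided Fisher enrichment across pathways, Hochberg-adjusted.

    ``tables`` maps pathway id -> 2x2 contingency table of presence counts
    (rows: in-tier / out-of-tier; columns: pathway present / absent).
    Returns rows (pathway, p, p_adjusted) where adjustment is the Hochberg
    step-up procedure.
    """
    ids = sorted(tables)
    raw = [fisher_one_sided(tables[p]) for p in ids]
    if not raw:
        return pd.DataFrame(columns=["pathway", "p", "p_adjusted"])
    adjusted = multipletests(raw, method="simes-hochberg")[1]
    return pd.DataFrame({"pathway": ids, "p": raw, "p_adjusted": adjusted})
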