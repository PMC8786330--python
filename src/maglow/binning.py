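"""Marker-guided scaffold binning into MAGs.

Scaffolds are clustered by an iterative, score-based procedure over the
features that discriminate genomes in a metagenome: tetranucleotide
composition, coverage depth, and (when available) taxonomy labels.  The
composite affinity of a scaffold for a cluster is

    S = w1 * r_TNF + w2 * exp(-|log2(depth ratio)|) + w3 * tax_agreement
      + w4 * exp(-|dGC| / 0.03)

where r_TNF is the Pearson correlation between the scaffold's residual
TNF vector (log observed/expected under independent bases, which removes
the GC-driven component shared by all genomes of similar composition) and
the cluster's length-weighted centroid, and dGC the difference between
the scaffold's GC content and the cluster's length-weighted mean GC
(fragment-level GC is precise to a few tenths of a percent, so a tight
scale makes it a sharp discriminator).  Clustering is guided by
single-copy marker genes (SCGs) as a hard constraint: a scaffold may not
join a cluster if doing so would push the fraction of duplicated markers
above a small allowance, and clusters that still accumulate duplicated
markers are split by 2-means on depth + composition.  Cleanup stages
remove incompatible scaffolds from each bin (depth outliers, taxonomy
conflicts, composition outliers) and merge near-identical bins (ANI >= 95%
with >= 30% aligned coverage, keeping the larger bin as representative).
The score weights and iteration schedule are this package's own defaults;
they are configurable and not drawn from any published parameterization.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from . import quality
from .records import BinRecord, ScaffoldRecord
from .seqfeatures import assembly_stats, revcomp


def detect_scg(
    scaffolds: list[ScaffoldRecord], catalog: dict[int, str]
) -> pd.DataFrame:
    """Locate marker tags on scaffolds by exact search of both strands.

    Returns a table (scaffold, marker, position, strand) with one row per
    occurrence.  Raises on duplicate marker ids or duplicate tag sequences
    in the catalog.
    """
    if len(set(catalog.values())) != len(catalog):
        raise ValueError("duplicate tag sequences in marker catalog")
    rows = []
    for s in scaffolds:
        seq = s.sequence
        for marker, tag in catalog.items():
            for query, strand in ((tag, "+"), (revcomp(tag), "-")):
                start = seq.find(query)
                while start != -1:
                    rows.append((s.id, marker, start, strand))
                    start = seq.find(query, start + 1)
    return pd.DataFrame(rows, columns=["scaffold", "marker", "position", "strand"])


@dataclass
class _Cluster:
    members: list[str] = field(default_factory=list)
    total_bp: float = 0.0
    tnf_sum: np.ndarray | None = None
    logd_sum: float = 0.0
    gc_sum: float = 0.0
    markers: Counter = field(default_factory=Counter)
    tax: Counter = field(default_factory=Counter)

    def centroid_tnf(self) -> np.ndarray:
        return self.tnf_sum / self.total_bp

    def centroid_depth(self) -> float:
        return float(2.0 ** (self.logd_sum / self.total_bp))

    def centroid_gc(self) -> float:
        return self.gc_sum / self.total_bp

    def majority_tax(self) -> str | None:
        if not self.tax:
            return None
        return self.tax.most_common(1)[0][0]

    def dup_fraction(self, n_markers: int) -> float:
        return sum(1 for c in self.markers.values() if c >= 2) / n_markers


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


class _Binner:
    def __init__(
        self,
        features: pd.DataFrame,
        tnf: np.ndarray,
        scg: pd.DataFrame,
        taxonomy: pd.Series | None,
        weights: tuple[float, float, float],
        min_score: float,
        max_dup_frac: float,
        n_markers: int,
    ):
        self.ids = list(features.index)
        self.lengths = features["length"].to_numpy(float)
        self.depths = np.maximum(features["depth"].to_numpy(float), 1e-9)
        self.gcs = features["gc"].to_numpy(float)
        self.tnf = tnf
        self.markers = {sid: Counter() for sid in self.ids}
        for _, row in scg.iterrows():
            if row["scaffold"] in self.markers:
                self.markers[row["scaffold"]][row["marker"]] += 1
        self.tax = {}
        if taxonomy is not None:
            for sid in self.ids:
                label = taxonomy.get(sid)
                self.tax[sid] = None if pd.isna(label) else label
        else:
            self.tax = {sid: None for sid in self.ids}
        self.w1, self.w2, self.w3, self.w4 = weights
        self.min_score = min_score
        self.max_dup = max_dup_frac
        self.n_markers = n_markers
        self.pos = {sid: i for i, sid in enumerate(self.ids)}
        self.clusters: list[_Cluster] = []
        self.assign: dict[str, int | None] = {sid: None for sid in self.ids}

    GC_SCALE = 0.03

    def _score(self, sid: str, cluster: _Cluster) -> float:
        i = self.pos[sid]
        r = _pearson(self.tnf[i], cluster.centroid_tnf())
        depth_term = float(
            np.exp(-abs(np.log2(self.depths[i] / cluster.centroid_depth())))
        )
        label = self.tax[sid]
        ctax = cluster.majority_tax()
        if label is None or ctax is None:
            tax_term = 0.5
        else:
            tax_term = 1.0 if label == ctax else 0.0
        gc_term = float(
            np.exp(-abs(self.gcs[i] - cluster.centroid_gc()) / self.GC_SCALE)
        )
        return (
            self.w1 * r + self.w2 * depth_term + self.w3 * tax_term
            + self.w4 * gc_term
        )

    def _compatible(self, sid: str, cluster: _Cluster) -> bool:
        merged = cluster.markers.copy()
        merged.update(self.markers[sid])
        dup = sum(1 for c in merged.values() if c >= 2)
        return dup / self.n_markers <= self.max_dup

    def _add(self, sid: str, ci: int) -> None:
        i = self.pos[sid]
        c = self.clusters[ci]
        c.members.append(sid)
        c.total_bp += self.lengths[i]
        if c.tnf_sum is None:
            c.tnf_sum = self.lengths[i] * self.tnf[i].copy()
        else:
            c.tnf_sum = c.tnf_sum + self.lengths[i] * self.tnf[i]
        c.logd_sum += self.lengths[i] * float(np.log2(self.depths[i]))
        c.gc_sum += self.lengths[i] * self.gcs[i]
        c.markers.update(self.markers[sid])
        if self.tax[sid] is not None:
            c.tax[self.tax[sid]] += self.lengths[i]
        self.assign[sid] = ci

    def _remove(self, sid: str) -> None:
        ci = self.assign[sid]
        i = self.pos[sid]
        c = self.clusters[ci]
        c.members.remove(sid)
        c.total_bp -= self.lengths[i]
        c.tnf_sum = c.tnf_sum - self.lengths[i] * self.tnf[i]
        c.logd_sum -= self.lengths[i] * float(np.log2(self.depths[i]))
        c.gc_sum -= self.lengths[i] * self.gcs[i]
        c.markers.subtract(self.markers[sid])
        c.markers += Counter()  # drop zero/negative entries
        if self.tax[sid] is not None:
            c.tax[self.tax[sid]] -= self.lengths[i]
            if c.tax[self.tax[sid]] <= 0:
                del c.tax[self.tax[sid]]
        self.assign[sid] = None

    def _best_cluster(self, sid: str, exclude_empty: bool = True):
        best, best_score = None, -np.inf
        for ci, c in enumerate(self.clusters):
            if not c.members:
                continue
            if not self._compatible(sid, c):
                continue
            s = self._score(sid, c)
            # ties resolve to the cluster with more total bp
            if s > best_score or (s == best_score and best is not None
                                  and c.total_bp > self.clusters[best].total_bp):
                best, best_score = ci, s
        return best, best_score

    def _cluster_pair_score(self, a: _Cluster, b: _Cluster) -> float:
        r = _pearson(a.centroid_tnf(), b.centroid_tnf())
        depth_term = float(
            np.exp(-abs(np.log2(a.centroid_depth() / b.centroid_depth())))
        )
        ta, tb = a.majority_tax(), b.majority_tax()
        tax_term = 0.5 if ta is None or tb is None else float(ta == tb)
        gc_term = float(
            np.exp(-abs(a.centroid_gc() - b.centroid_gc()) / self.GC_SCALE)
        )
        return (
            self.w1 * r + self.w2 * depth_term + self.w3 * tax_term
            + self.w4 * gc_term
        )

    def _pair_compatible(
        self, a: _Cluster, b: _Cluster, allowance: float | None = None
    ) -> bool:
        merged = a.markers + b.markers
        dup = sum(1 for c in merged.values() if c >= 2)
        return dup / self.n_markers <= (
            self.max_dup if allowance is None else allowance
        )

    def merge_complementary(self, allowance: float | None = None) -> None:
        """Join cluster pairs whose union stays (close to) single-copy.

        Two clusters holding complementary halves of one genome share no
        markers, while clusters of different genomes collide on most of the
        universe, so the single-copy constraint alone separates the cases;
        ``allowance`` relaxes the duplication budget slightly so a lone
        stray scaffold cannot veto an otherwise clean merge.
        """
        while True:
            live = [c for c in self.clusters if c.members]
            best_pair, best_score = None, self.min_score
            for i, a in enumerate(live):
                for b in live[i + 1 :]:
                    if not self._pair_compatible(a, b, allowance):
                        continue
                    s = self._cluster_pair_score(a, b)
                    if s > best_score:
                        best_pair, best_score = (a, b), s
            if best_pair is None:
                return
            a, b = best_pair
            for sid in list(b.members):
                self._remove(sid)
                self._add(sid, self.clusters.index(a))

    def run(self, max_rounds: int, seed_min_score: float = 0.75) -> None:
        order = sorted(self.ids, key=lambda sid: -self.lengths[self.pos[sid]])
        # greedy seeding from the longest scaffold down; joining an existing
        # cluster takes a stricter threshold than reassignment so early
        # clusters stay pure
        for sid in order:
            best, score = self._best_cluster(sid)
            if best is not None and score >= max(self.min_score, seed_min_score):
                self._add(sid, best)
            else:
                self.clusters.append(_Cluster())
                self._add(sid, len(self.clusters) - 1)
        # iterative reassignment until stable
        for _ in range(max_rounds):
            changed = False
            for sid in order:
                current = self.assign[sid]
                self._remove(sid)
                best, score = self._best_cluster(sid)
                if best is None or score < self.min_score:
                    if self.clusters[current].members:
                        self.clusters.append(_Cluster())
                        best = len(self.clusters) - 1
                    else:
                        best = current
                self._add(sid, best)
                if best != current:
                    changed = True
            if not changed:
                break


def cluster_scaffolds(
    features: pd.DataFrame,
    tnf: np.ndarray,
    scg: pd.DataFrame,
    taxonomy: pd.Series | None = None,
    *,
    weights: tuple[float, float, float, float] = (0.3, 0.3, 0.2, 0.2),
    min_score: float = 0.5,
    max_dup_frac: float = 0.05,
    split_dup_frac: float = 0.10,
    max_rounds: int = 50,
    n_markers: int = quality.N_MARKERS,
    seed: int = 0,
) -> tuple[pd.Series, list[str]]:
    """Cluster scaffolds into candidate bins.

    ``features`` must carry columns length / gc / depth indexed by scaffold
    id, with ``tnf`` the aligned TNF matrix.  Returns (assignments: Series
    scaffold -> bin id, unassigned: scaffolds left in singleton bins).
    Deterministic for a given seed.
    """
    if len(features) < 2:
        raise ValueError("cluster_scaffolds requires at least 2 scaffolds")
    binner = _Binner(
        features, tnf, scg, taxonomy, weights, min_score, max_dup_frac, n_markers
    )
    binner.run(max_rounds)
    binner.merge_complementary()

    # SCG-constraint splitting: clusters holding two copies of a sizeable
    # share of markers are split by 2-means on depth + composition
    groups = [c.members[:] for c in binner.clusters if c.members]
    final: list[list[str]] = []
    logd = np.log2(binner.depths)
    logd_sd = logd.std() or 1.0
    queue = groups
    guard = 0
    while queue and guard < 200:
        guard += 1
        members = queue.pop()
        counts = Counter()
        for sid in members:
            counts.update(binner.markers[sid])
        dup = sum(1 for c in counts.values() if c >= 2) / n_markers
        if dup < split_dup_frac or len(members) < 2:
            final.append(members)
            continue
        idx = [binner.pos[sid] for sid in members]
        zt = binner.tnf[idx]
        zt = (zt - zt.mean(axis=0)) / (zt.std(axis=0) + 1e-12)
        x = np.column_stack(
            [3.0 * (logd[idx] - logd[idx].mean()) / logd_sd, zt / np.sqrt(zt.shape[1])]
        )
        labels = KMeans(n_clusters=2, n_init=10, random_state=seed).fit_predict(x)
        if len(set(labels)) < 2:
            final.append(members)
            continue
        queue.append([sid for sid, l in zip(members, labels) if l == 0])
        queue.append([sid for sid, l in zip(members, labels) if l == 1])

    final.sort(key=lambda m: (-sum(binner.lengths[binner.pos[s]] for s in m), m[0]))
    assignments = {}
    unassigned = []
    for bi, members in enumerate(final):
        bin_id = f"bin{bi:03d}"
        for sid in members:
            assignments[sid] = bin_id
        if len(members) == 1:
            unassigned.extend(members)
    return pd.Series(assignments, name="bin"), unassigned


def remove_incompatible(
    members: list[str],
    features: pd.DataFrame,
    tnf: np.ndarray,
    tnf_index: dict[str, int],
    taxonomy: pd.Series | None = None,
    *,
    depth_fold: float = 3.0,
    tnf_quantile: float = 0.99,
    tnf_min_dist: float = 0.60,
) -> tuple[list[str], list[str]]:
    """Prune scaffolds incompatible with the rest of their bin.

    A scaffold is removed when its depth deviates from the bin's
    length-weighted median by more than ``depth_fold``, when its taxonomy
    label conflicts with the bin's majority label, or when its TNF
    correlation distance to the bin centroid exceeds the ``tnf_quantile``
    of intra-bin distances, with an absolute floor: fragment-scale
    residual-TNF vectors are noisy (within-genome correlation ~0.6-0.8), so
    only distances beyond the floor (default 0.60, above within-genome
    sampling noise) count as outliers and homogeneous bins are never
    pruned.  Bins with fewer than 3 scaffolds pass unchanged, and
    the longest scaffold is always retained.
    """
    if len(members) < 3:
        return list(members), []
    lengths = features.loc[members, "length"].to_numpy(float)
    depths = features.loc[members, "depth"].to_numpy(float)
    order = np.argsort(depths)
    cum = np.cumsum(lengths[order])
    median_depth = depths[order][np.searchsorted(cum, cum[-1] / 2)]

    rows = np.array([tnf_index[s] for s in members])
    centroid = np.average(tnf[rows], axis=0, weights=lengths)
    dists = np.array([1.0 - _pearson(tnf[r], centroid) for r in rows])
    cut = max(float(np.quantile(dists, tnf_quantile)), tnf_min_dist)

    majority = None
    if taxonomy is not None:
        weightings = Counter()
        for sid, ln in zip(members, lengths):
            label = taxonomy.get(sid)
            if label is not None and not pd.isna(label):
                weightings[label] += ln
        if weightings:
            majority = weightings.most_common(1)[0][0]

    kept, removed = [], []
    for sid, depth, dist in zip(members, depths, dists):
        bad = (
            depth > depth_fold * median_depth
            or depth < median_depth / depth_fold
            or dist > cut
        )
        if not bad and majority is not None and taxonomy is not None:
            label = taxonomy.get(sid)
            if label is not None and not pd.isna(label) and label != majority:
                bad = True
        (removed if bad else kept).append(sid)
    if not kept:  # never empty a bin entirely
        longest = members[int(np.argmax(lengths))]
        kept = [longest]
        removed = [s for s in removed if s != longest]
    return kept, removed


def merge_bins(
    bin_sequences: dict[str, str],
    *,
    ani_min: float = 0.95,
    coverage_min: float = 0.30,
    gc_prefilter: float | None = 0.10,
    fragment: int = 1000,
) -> dict[str, str]:
    """Merge near-identical bins; returns a map bin id -> representative.

    Bins whose ANI reaches ``ani_min`` with aligned coverage (of the
    smaller bin) >= ``coverage_min`` are unioned transitively; the largest
    member of each group becomes the representative.  ``gc_prefilter``
    skips pairs whose GC differs by more (a speed heuristic; set None to
    disable).
    """
    from .seqfeatures import compute_gc

    ids = sorted(bin_sequences, key=lambda b: -len(bin_sequences[b]))
    gcs = {b: compute_gc(bin_sequences[b]) for b in ids}
    parent = {b: b for b in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if find(a) == find(b):
                continue
            if gc_prefilter is not None and abs(gcs[a] - gcs[b]) > gc_prefilter:
                continue
            small, large = (b, a) if len(bin_sequences[b]) <= len(bin_sequences[a]) else (a, b)
            if len(bin_sequences[small]) < 2 * fragment:
                continue
            res = quality.compute_ani(
                bin_sequences[small], bin_sequences[large], fragment=fragment
            )
            if res.ani >= ani_min and res.coverage >= coverage_min:
                ra, rb = find(a), find(b)
                # representative = larger bin
                keep, drop = (
                    (ra, rb)
                    if len(bin_sequences[ra]) >= len(bin_sequences[rb])
                    else (rb, ra)
                )
                parent[drop] = keep
    return {b: find(b) for b in ids}


def filter_draft(bins: list[BinRecord]) -> list[BinRecord]:
    """Retain bins passing the draft-quality criteria (strict thresholds)."""
    return [
        b
        for b in bins
        if quality.filter_draft(b.completeness, b.contamination, b.score)
    ]


def bin_community(
    scaffolds: list[ScaffoldRecord],
    depth_table: pd.DataFrame,
    catalog: dict[int, str],
    taxonomy: pd.Series | None = None,
    *,
    seed: int = 0,
    min_scaffold_length: int = 2000,
    n_markers: int = quality.N_MARKERS,
    **cluster_params,
) -> tuple[pd.Series, list[BinRecord]]:
    """End-to-end binning: features -> cluster -> prune -> merge -> score.

    Returns the final scaffold -> bin assignment and per-bin records with
    SCG completeness/contamination and the composite quality score.
    """
    from .seqfeatures import filter_scaffolds, scaffold_features

    from .seqfeatures import compute_tnf_residual

    retained = filter_scaffolds(scaffolds, min_scaffold_length)
    features, _ = scaffold_features(retained, depth_table)
    # clustering and pruning correlate residual TNF, not raw TNF
    tnf = np.vstack([compute_tnf_residual(s.sequence) for s in retained])
    scg = detect_scg(retained, catalog)
    assignments, _ = cluster_scaffolds(
        features, tnf, scg, taxonomy, seed=seed, n_markers=n_markers, **cluster_params
    )
    tnf_index = {sid: i for i, sid in enumerate(features.index)}
    seq_by_id = {s.id: s.sequence for s in retained}

    marker_by_scaffold: dict[str, Counter] = {}
    for _, row in scg.iterrows():
        marker_by_scaffold.setdefault(row["scaffold"], Counter())[row["marker"]] += 1

    def _evict_conflicts(binner: _Binner) -> None:
        # duplicated single-copy markers flag contamination directly: evict
        # the scaffold contributing most duplicates (ties -> the
        # compositionally most distant) until each cluster is single-copy
        for ci, c in enumerate(binner.clusters):
            while len(c.members) > 1:
                dup_markers = {m for m, n in c.markers.items() if n >= 2}
                if not dup_markers:
                    break

                def badness(sid):
                    overlap = sum(
                        1
                        for m in marker_by_scaffold.get(sid, {})
                        if m in dup_markers
                    )
                    dist = 1.0 - _pearson(
                        binner.tnf[binner.pos[sid]], c.centroid_tnf()
                    )
                    return (overlap, dist)

                worst = max(c.members, key=badness)
                if badness(worst)[0] == 0:
                    break
                binner._remove(worst)

    pruned: dict[str, list[str]] = {}
    for bin_id in sorted(assignments.unique()):
        members = list(assignments[assignments == bin_id].index)
        kept, _ = remove_incompatible(members, features, tnf, tnf_index, taxonomy)
        pruned[bin_id] = kept

    # with strays pruned, complementary clusters of one genome can be
    # reunited under the single-copy budget; remaining marker conflicts are
    # evicted and dropped scaffolds rescued into their best compatible bin
    merger = _Binner(
        features,
        tnf,
        scg,
        taxonomy,
        cluster_params.get("weights", (0.3, 0.3, 0.2, 0.2)),
        cluster_params.get("min_score", 0.5),
        cluster_params.get("max_dup_frac", 0.05),
        n_markers,
    )
    for members in pruned.values():
        merger.clusters.append(_Cluster())
        for sid in members:
            merger._add(sid, len(merger.clusters) - 1)
    _evict_conflicts(merger)
    merger.merge_complementary(
        allowance=cluster_params.get("split_dup_frac", 0.10) * 0.9
    )
    _evict_conflicts(merger)
    rescue_score = max(cluster_params.get("min_score", 0.5), 0.65)
    # dissolve low-completeness remnants: mixed leftovers of two genomes
    # carry disjoint marker ranges (so no internal conflict) yet block both
    # parents from merging; re-homing their members one by one resolves them
    for ci, c in enumerate(merger.clusters):
        comp = sum(1 for n in c.markers.values() if n > 0) / n_markers
        if not c.members or comp >= 0.5:
            continue
        for sid in list(c.members):
            merger._remove(sid)
            best, score = merger._best_cluster(sid)
            if best is not None and best != ci and score >= rescue_score:
                merger._add(sid, best)
            else:
                merger._add(sid, ci)
    merger.merge_complementary(
        allowance=cluster_params.get("split_dup_frac", 0.10) * 0.9
    )
    _evict_conflicts(merger)
    for sid in merger.ids:
        if merger.assign[sid] is not None:
            continue
        best, score = merger._best_cluster(sid)
        if best is not None and score >= rescue_score:
            merger._add(sid, best)
    pruned = {
        f"c{ci:03d}": list(c.members)
        for ci, c in enumerate(cl for cl in merger.clusters if cl.members)
    }

    bin_seqs = {
        b: "".join(seq_by_id[s] for s in m) for b, m in pruned.items() if m
    }
    rep = merge_bins(bin_seqs)
    merged: dict[str, list[str]] = {}
    for b, m in pruned.items():
        merged.setdefault(rep.get(b, b), []).extend(m)

    records = []
    final_assign = {}
    for bi, (b, members) in enumerate(
        sorted(merged.items(), key=lambda kv: -sum(len(seq_by_id[s]) for s in kv[1]))
    ):
        bin_id = f"MAG{bi:03d}"
        counts = Counter()
        for sid in members:
            counts.update(marker_by_scaffold.get(sid, {}))
            final_assign[sid] = bin_id
        comp, cont = quality.scg_completeness(counts, n_markers)
        lengths = [len(seq_by_id[s]) for s in members]
        st = assembly_stats(lengths)
        records.append(
            BinRecord(
                id=bin_id,
                scaffolds=sorted(members),
                completeness=comp,
                contamination=cont,
                score=quality.quality_score(comp, cont),
                size=st.total,
                n50=st.n50,
            )
        )
    return pd.Series(final_assign, name="bin"), records
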