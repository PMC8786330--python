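# Methods

This note documents the models behind `maglow`: what the synthetic
community plants and why, how each estimator works, the numerical choices,
and what the tests do and do not demonstrate about real data.

## The synthetic community

The generator builds a mock gut community in which every downstream target
is planted and recorded, so estimator error can be measured exactly.

**Scale.** Default genomes are 60–120 kb, not the 1.3–7.4 Mb of real gut
bacteria. All planted signals (GC, skew, marker spacing, coverage gradient,
SNP density) are per-base properties, so estimator behavior is
scale-invariant up to sampling noise; the small scale keeps every stage in
seconds. One consequence is inflated depth values (a 0.1-abundance genome
of 100 kb at 10 Gbp of data sits at ~10,000×); depth enters the pipeline
only through ratios and length-weighted means, which are unaffected.

**Abundances.** Relative abundances are renormalized log-normals
(`sigma = 1.8`, z-scores clipped at ±2.5). The sigma was chosen so a
30-genome community typically spans all three tiers (high > 1%, low
0.1–1%, extra-low < 0.1%); the clip bounds the rarest genome away from
zero so that, at the default 10 Gbp yield, every genome retains usable
(≥ 5×) coverage. Any particular seed may still miss a tier — the tier
counts are a draw, not a guarantee.

**Composition.** Each genome is emitted by its own first-order Markov
chain: the stationary base mix targets the genome's GC (drawn from
0.32–0.62) and the transition matrix is perturbed by a per-genome gamma
matrix (concentration 15), giving each genome a reproducible
tetranucleotide signature on top of its GC. A post-pass flips bases (never
inside marker tags) until each replichore hits its exact G and C targets,
so measured GC lands within a fraction of a percent of the target.

**GC skew.** The replichore from the planted origin to the planted
terminus (half the genome away) is G-enriched and the other half C-enriched
(|skew| = 0.2), a deliberately simple two-segment model: sufficient for the
cumulative-skew extremum convention (trough at ori, peak at ter) without
modeling real replication mutational asymmetries. Stop-codon patching in
ORFs replaces stops with sense codons matching the stop's G *and* C counts
separately; matching only G+C systematically converts G to C (stops carry
their GC exclusively as G) and visibly erodes the planted skew.

**Markers.** The 123 single-copy markers are reserved unique 60-bp random
tags, one per equal-width block of each genome, shared across genomes via a
community-level catalog. Detection downstream is exact string search on
both strands — profile-HMM search is out of scope, and exact tags make
marker truth unambiguous. Because tags sit one per block, any contiguous
sub-assembly carries a proportional share of markers, which is what makes
SCG completeness meaningful on partial bins.

**ORFs.** Forward-strand ORFs (150–900 bp, shrinking to fit between marker
tags) are carved from the background and cleared of in-frame stops, so
every annotated CDS interval is a legal sense-codon frame for the codon
machinery. Coding density lands near 50–60% on small genomes (markers and
gaps take the rest) — lower than real bacteria, which only scales the
number of coding SNPs per genome.

**Coverage.** Window depth is Poisson around
`total_bases × abundance / length`, modulated log-linearly from ×√PTR at
the origin to ÷√PTR at the terminus and renormalized to preserve the
genome mean.

**Pileups.** Variant sites are chosen by weighted sampling without
replacement over all 3L possible substitutions (Gumbel top-k): weight 1
for noncoding or synonymous changes, ω (the planted dN/dS) for
nonsynonymous ones. This construction makes the expected pN/pS against
enumerated opportunities equal ω exactly — the plant is defined by the
same accounting the estimator uses, which is the point of a recovery test.
Minor-allele frequencies are uniform on 0.2–0.5 so that planted sites
remain detectable after the 40-read cap (at a frequency of 0.1, several
percent of sites would fall under the two-read / < 95%-major rules and the
density plant would not be recoverable to its binomial error). A
configurable fraction (default 10%) of reads draws a mapping or base
quality below the filter cutoffs; sequencing error defaults to 0 so the
filter rules can be tested in isolation.

**What the generator does not emulate:** read-level errors and FASTQ
simulation, assembly artifacts (chimeras, collapsed repeats), strain
mixtures, real replichore asymmetries, rRNA/tRNA sequence content (the
features are coordinate annotations only), and horizontal transfer.
Passing recovery tests therefore demonstrates the *decision logic and
estimators* are correct, not that the pipeline is robust to assembler or
mapping artifacts.

## Binning

Scaffolds ≥ 2 kb are clustered by an iterative score-based procedure. The
affinity of scaffold *s* for cluster *c* is

    S = 0.3·r(s,c) + 0.3·exp(−|log2(depth_s/depth_c)|) + 0.2·tax + 0.2·exp(−|ΔGC|/0.03)

* `r` is the Pearson correlation of **residual TNF** vectors — the log of
  observed canonical 4-mer frequencies over their expectation from the
  scaffold's own base composition. Raw TNF vectors of two genomes with
  similar GC correlate above 0.9 regardless of their actual signatures;
  the residual removes the GC-driven component and drops cross-genome
  correlations to ≈ 0 while within-genome fragments stay at 0.6–0.8.
* the depth term uses length-weighted geometric-mean cluster depth;
* `tax` is 1 on label agreement, 0 on conflict, 0.5 when either side is
  unlabeled;
* the GC term has a deliberately tight scale (0.03) because fragment-level
  GC is precise to a few tenths of a percent.

Clusters are seeded greedily from the longest scaffold down (joining an
existing cluster requires score ≥ 0.75; reassignment later uses ≥ 0.5 —
the stricter seeding keeps early clusters pure), then reassigned
iteratively to convergence (cap 50 rounds). Single-copy markers act as a
hard constraint throughout: a scaffold may not join a cluster if the
duplicated-marker fraction would exceed 5%, and clusters that end up with
two copies of ≥ 10% of markers are split by 2-means over depth +
standardized composition.

Cleanup proceeds in marker-aware stages: per-bin incompatible-scaffold
removal (depth beyond 3× the length-weighted median; taxonomy conflicting
with the bin majority; residual-TNF distance beyond the 0.99 intra-bin
quantile with an absolute floor of 0.6 so homogeneous bins are never
pruned; the longest scaffold is always retained); eviction of scaffolds
whose markers duplicate the bin's (duplicated SCGs *are* the contamination
signal); a complementary merge that reunites cluster pairs whose union
stays essentially single-copy (two halves of one genome share no markers,
two different genomes collide on most of the universe); dissolution of
low-completeness remnants whose members are re-homed individually; and a
final ANI merge (≥ 95% identity over ≥ 30% of the smaller bin, larger bin
representative, transitive closure). Evicted scaffolds are rescued into
their best compatible bin when they score ≥ 0.65, otherwise left unbinned.

All weights and thresholds above are this package's own defaults, exposed
as parameters; none is a published value.

## Quality, ANI, growth rate

Completeness/contamination use the 123-marker universe directly (distinct
markers present; extra copies beyond one). The quality score and the draft
and MIMAG thresholds are strict inequalities on the percent scale. The
genome-size correction `size / (completeness + contamination)` takes both
terms as fractions — with percent units the estimate would shrink ~100-fold.

ANI is fragment-based: 1 kb query fragments, exact 16-mer seeds tried every
8 bp on both strands (candidate offsets capped at 50 per fragment), ungapped
identity at the implied offset, fragment accepted at identity ≥ 0.8; ANI
averages accepted fragments and coverage is the accepted fraction. This is
an analogue of mapping-based ANI estimators, adequate for the ≥ 95%
species-boundary decisions it feeds; it does not model indels, so it will
under-map across gapped divergence.

PTR is the ratio of 10%-trimmed-mean depths over the 5% of windows nearest
the origin and nearest the terminus (located at the cumulative-skew
extrema). Averaging over a band attenuates the estimate to roughly
PTR^0.95 (≈ 1.93 for a true 2.0) — well inside the ±10% recovery target,
and robust to single-window noise, which pointwise peak/trough ratios are
not. The estimate is scale-invariant and reports orientation rather than
returning ratios below 1.

## Population genetics

The per-site chain is: quality filter (mapq ≥ 20, baseq ≥ 30) → cap at 40
reads (deterministic per-site RNG keyed on scaffold and position, so
subsampling is reproducible and order-independent) → a site is *eligible*
(callable, and counted in the density denominator) iff ≥ 20 reads remain →
SNP iff the major allele is < 95% with the top minor allele supported by
≥ 2 reads. Using the same 20-read floor for callability and for the
denominator keeps SNPs/kb internally consistent. Genomes enter the analysis
only with ≥ 200,000 eligible sites.

Opportunities sum the 9 single-base changes of every codon over all ORFs
that overlap at least one eligible site; changes creating a stop codon
count as nonsynonymous. pN/pS = (obsN/expN)/(obsS/expS), reported as
undefined when obsS = 0. Feature correlations are Spearman with mid-ranked
ties and the large-sample p approximation, requiring ≥ 5 complete rows.

## Mobilome and function

Chromosomal-MGE keyword lists (transposon, plasmid, phage, other) are a
reconstruction of the commonly used annotation-keyword scheme, shipped as
an editable mapping — they are not a published inventory. Classification
is case-insensitive substring match in fixed priority order, so each ORF
gets one class. Viral detection treats the two detectors as a union
(configurable to intersection); plasmid detection (unbinned, > 10 kb,
circular by terminal k-mer overlap, k = 55) is likewise a reconstruction of
an under-specified procedure. Tier comparisons use the two-sided
Wilcoxon–Mann–Whitney test, exact for tie-free samples up to n = 20.
Enrichment uses one-sided (greater) Fisher exact tests with Hochberg
step-up adjustment.

## Verification design

Every hard threshold has an exhaustive boundary-case test. The statistics
lean on independent oracles: Fisher p-values against the closed-form
hypergeometric tail over all 2×2 tables with margins ≤ 12, Hochberg against
a direct step-up implementation, codon opportunities against translating
all nine changes of each of the 61 sense codons, N50 against a brute-force
cumulative walk, and the rank-sum test against its nominal type-I error
under 1000 null simulations. Recovery tests run the full chain on planted
communities: binning (default 30-genome community; adjusted Rand ≥ 0.9 and
≥ 90% of genomes recovered as passing drafts), SNP density (planted 2/kb,
recovered within 3 binomial SE), pN/pS (neutral within [0.9, 1.1] at
≥ 2000 SNPs; ω = 0.2 plant recovered in [0.1, 0.35]), PTR (±10% at 1.5 and
2.0 over 50 replicates), and origin recovery (within 2 windows on 20
genomes). Problem sizes — 250 kb genomes for population genetics, 100 kb
for PTR, 30 × ~90 kb for binning — were chosen as the smallest at which the
sampling error of each recovery target is comfortably inside its tolerance.

## Known limitations

* The binning score and cleanup cascade are tuned for communities with
  genuine per-genome composition signatures; two strains of one species
  (near-identical TNF, GC and taxonomy) would be separable only by depth
  and would likely co-bin, as they do for most real binners.
* ANI ignores indels and rearrangement break-points beyond fragment
  granularity.
* The PTR band estimator assumes a single circular replicon with one
  origin; multi-replicon genomes or linear scaffolds violate it.
* Pileup simulation draws read observations independently per site; linked
  haplotypes and strand bias are not modeled, so filters that would exploit
  linkage cannot be evaluated.
* `eligible_mag`'s 200,000-site rule makes the default small-genome
  community ineligible by design; population-genetic recovery runs use
  250 kb genomes instead.
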