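# Methods

## Primer matching model

Primers are degenerate oligonucleotides over the IUPAC alphabet, stored
5'→3'. Two codes match iff the base sets they encode intersect, so an
`N` (or any degenerate code) in the *subject* never counts as a
mismatch. This is the permissive convention of in-silico PCR tools; it
slightly overstates binding for databases containing many ambiguous
bases, which is why coverage numbers from such databases should be read
as upper bounds. Mismatch counting is pure Hamming distance under this
relation: no indels, no gap opening, and no special weight for
3'-terminal mismatches. Whether real polymerases forgive a 3' mismatch
as readily as an internal one is doubtful; we deliberately keep the
uniform model because it is the one under which "0–3 mismatches per
primer" sweeps are conventionally reported, and flag it as a caveat for
users ranking primer sets that differ mainly at their 3' ends. Input is
case-insensitive and `U` normalizes to `T`.

## Virtual PCR

For each record the engine computes, per primer, the mismatch count of
every window (a vectorized bitmask scan: each IUPAC code is a 4-bit set,
codes match when the masks intersect). A product is any pair of a
forward-primer site and a downstream site of the reverse-complemented
reverse primer whose full length (both footprints included) lies within
the length filter, default 100–2000 bp — the ~100–1500 bp spacer range
plus primer footprints, kept loose so the filter never hides products in
the range of interest. Both strands are searched, because public
databases store operons in arbitrary orientation; coordinates are
reported 0-based half-open on the + strand with the orientation kept in
a `strand` field. The mismatch budget applies to each primer separately
(the same value for forward and reverse), not as a summed pair budget.
All products per record are reported; the shortest full-length product
is flagged `primary` for fingerprint simulation, since shorter templates
dominate competitive PCR. Circular genomes are not modeled. A database
is scanned once per record at the largest requested budget and the hits
filtered down per budget, which makes budget nesting (hit sets at budget
*k* ⊆ budget *k*+1) structural rather than incidental.

## Coverage and specificity accounting

A taxon at any rank counts as amplified as soon as one member sequence
amplifies; no quorum is applied. Denominators are the taxa represented
in the database at that rank, read from the taxonomy table; records
unassigned at a rank are excluded from both numerator and denominator at
that rank. Taxa are keyed by their full lineage path so homonymous
labels under different parents (common in real nomenclature) never
merge. Proportions are kept at full precision internally and rounded to
one decimal on export. Note that the proportion at a shallow rank is not
mathematically forced to exceed the deep-rank proportion — what does
hold, and is asserted in tests, is that an amplified taxon implies an
amplified ancestor at every shallower rank. For databases in which many
entries simply do not span the spacer region, these denominators deflate
coverage; we keep such entries in the denominator and leave the
interpretation to the user.

The specificity screen applies the identical species-level computation
to non-target databases (chloroplast-, plant-, fungal-like), reporting
amplified/total species per phylum, primer set and budget.

## Fingerprint analysis

Peaks are binned on a fixed grid anchored at the lower end of the
instrument range (default 100–1500 bp, 2-bp window), half-open bins with
boundary peaks going up; the anchoring is arbitrary but must be fixed
for runs to be comparable, and binning conserves in-range total
abundance. Richness is the number of occupied bins; Shannon diversity is
−Σ pᵢ ln pᵢ in nats (base is an option). Bray-Curtis uses quantitative
peak heights, Jaccard presence/absence — the two views conventionally
reported side by side.

ANOSIM implements Clarke's R on the ranked upper-triangle
dissimilarities, R = (mean between-group rank − mean within-group rank)
/ (M/2) with M = n(n−1)/2. The permutation p-value uses the add-one
estimator (1 + #{R\* ≥ R}) / (1 + n\_perm), default 999 permutations,
reproducible bit-for-bit under a fixed seed; a tolerance of 1e-12 guards
the ≥ comparison against floating-point ties. An exact mode enumerates
all distinct label assignments (identity included, p = #{R\* ≥ R} /
n\_assignments) and is the reference for small n. NMDS delegates to
scikit-learn's non-metric SMACOF with several seeded random starts,
keeping the lowest Kruskal stress-1 solution and centering the
coordinates; being a stochastic optimizer, stress comparisons across
dimensionalities are only monotone up to optimizer noise. Pearson
correlations between two assays' diversity tables use two-sided t-tests
(df = n − 2) over matched samples; one-sided conventions exist in the
literature but are not assumed here.

## Synthetic data

The reference-database generator emulates the structure a spacer-
spanning database would have, not real sequence evolution: each species
gets one operon-like record — random 16S-tail flank, forward primer site
mutated at an exact planted mismatch count, random spacer of planted
length, reverse-complemented reverse site mutated likewise, random
23S-head flank. Mismatch positions are drawn only where the primer's
degenerate code does not already accept every base, and the substituted
base comes from outside the code's set, so the planted count is exact
rather than probabilistic. Flanks and spacers are rejection-resampled
until a verification scan at budget 3 (both strands, every primer set in
the plan) finds exactly the planted sites, making the analytic ground
truth exact by construction. Planting two primer sets whose motifs
cross-match within three mismatches in one record is therefore rejected
as infeasible — the bundled 23Sr and L-D-Bact-132 reverse motifs are one
such pair — and multi-assay comparisons are instead run as separate
databases over the same taxonomy and spacer lengths. Site-plan fractions
are realized as exact counts (largest-remainder rounding) and assigned
to species by a seeded permutation.

Default design choices: taxonomy of 5 phyla with branching factors
2/2/2/3 down to genus and species distributed round-robin; spacer
lengths uniform on [100, 1400] bp so full products stay inside the
default length filter; 80 bp flanks (long enough that spurious-site
rejection is rare, short enough to keep generation fast). The non-target
generator plants sites in an exact contaminated fraction of species
(default 0 mismatches — emulating the handful of genuinely amplifiable
algal/plant entries a real screen turns up) and verifies the rest
site-free; its taxonomy labels live in a non-bacterial namespace.

The community generator mirrors a paired field design: two groups of
five replicate samples (the conventional fertilized/unfertilized or
two-tree-species layout), a pool of 100 fragment-length OTUs with
fractional lengths drawn once from [100, 1500), 70% of the pool shared
between groups, per-OTU log-normal abundances (μ = 3, σ = 1 on the log
scale), a compositional group effect applied as ± effect/2 times a
per-OTU normal deviate, multiplicative log-normal noise (σ = 0.3) and
90% per-sample occupancy. These defaults produce fingerprints with
realistic richness (tens of OTUs) and clearly separable groups at effect
size 1; at effect size 0 the ANOSIM R is centered at zero. What the
generator does *not* emulate — shared 16S-anchored motifs across taxa,
length multimodality, electropherogram artifacts (shoulder peaks, size-
standard drift), chimeras, abundance-dependent detection limits — means
that passing tests certify the arithmetic of the pipeline on planted
truth, not the biological fidelity of any particular primer ranking on
real databases.

`simulate_fingerprint_from_db` links the halves: each community member
that amplified contributes a peak at its primary product length with the
member's abundance; unamplified members vanish, which is exactly the
primer-bias dropout the coverage reports quantify.

## Numerical and reproducibility choices

All generator randomness flows from a single master seed through named
substreams (numpy `default_rng` seeded with `[seed, stage, index]`), so
fixtures are byte-identical across runs and any record can be
regenerated in isolation. Verification scans cap resampling at 60
attempts before declaring a spec infeasible. Degenerate inputs raise
early with the offending identifier in the message: invalid IUPAC
characters, duplicate record ids, amplified records missing from the
taxonomy, all-zero abundance profiles, groups with fewer than two
members.

Problem sizes used by the verification script — 1000 random sequences
(200–2000 bp) for the oracle comparison, a 200-species planted database,
100-species non-target databases, 100 null-community replicates —
are comfortably larger than needed for exact planted-truth checks while
keeping the full run under a minute.

## Known limitations

* The matching model ignores annealing thermodynamics; two primer sets
  with equal mismatch counts can differ greatly in vitro.
* Quantitative amplification bias beyond presence/absence and product
  length is out of scope; simulated peak heights are community
  abundances, not PCR yields.
* Coverage against real databases inherits their taxonomic and
  spacer-coverage biases; the package reports what the database
  supports, nothing more.
* ANOSIM's exact mode enumerates label assignments and is only practical
  up to about 10 samples; beyond that, use permutations.
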