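# Methods

This note documents the models and procedures implemented in `amplicomm`,
the parameter choices that matter, what the synthetic data generator does
and does not emulate, and the numerical decisions taken where the design was
genuinely open.

## Pipeline model

The pipeline treats a multiplexed amplicon run as a fixed sequence of
filters and transforms, each with exact bookkeeping:

```
raw reads
  → demultiplex (adaptor + barcode, exact)            read_qc.demultiplex
  → quality filter (ambiguity, primer, length)        read_qc.quality_filter
  → dereplicate + precluster (denoise)                denoise.precluster
  → bimera flagging                                   denoise.flag_bimeras
  → classifier rescue of flagged reads                denoise.rescue
  → archaeal-read removal                             taxonomy.filter_domain
  → depth normalization (subsample to min)            diversity.subsample
  → OTU clustering + alpha statistics  (per cutoff)   diversity.*
  → LCA community profile → copy-number correction    taxonomy / copy_correction
```

Two invariants are enforced at every boundary: reads are partitioned, never
silently dropped (`effective + removed = post-QC`, `bacterial = post-chimera
− archaeal`), and the whole run is a pure function of the inputs and one
integer seed. Per-sample random streams are derived from the seed with
`numpy` `SeedSequence.spawn`, so adding a sample never perturbs another
sample's draws.

## Read QC

* **Ambiguity rule.** Reads with *more than one* `N` are removed; a single
  `N` is tolerated. This is the literal reading of the rule the pipeline
  models, and it matters: the stricter "any N" variant changes the
  effective-read counts.
* **Demultiplexing** requires the complete adaptor followed by an exact
  barcode at the 5′ end; no error correction is attempted. Exactness is the
  conservative interpretation of "checking completeness" of barcode and
  adaptor, and barcode edit-distance correction is deliberately out of
  scope.
* **Primer matching** honours IUPAC degeneracy position-by-position (the
  V4 forward primer `AYTGGGYDTAAAGNG` is the default). A read without the
  primer is rejected under its own reason (`no_primer`) so the three
  numbered rules keep disjoint, interpretable counts; reasons are assigned
  in rule order (ambiguous → no_primer → short). Only the forward primer is
  sought; reverse-primer read-through is not handled.
* **Length rule**: < 150 bp after stripping ⇒ rejected. With `primer=None`
  the filter skips the primer rule, which makes it idempotent on its own
  output (used by the tests).

## Denoising and chimeras

* **Pre-clustering** sorts unique sequences by abundance (descending, then
  lexicographic) and merges each into the first more-abundant unique within
  `diffs = 2` mismatches — about 1 difference per 100 bp for ~200 bp reads,
  the usual pyrosequencing-noise heuristic. Mismatches are counted
  positionally over the shared prefix (end-gap-free); amplicons from one
  primer pair share coordinates, so no alignment is needed at this stage.
* **Bimera flagging** is the abundance-based de-novo formulation: candidate
  parents must be ≥ `min_parent_fold = 2` times as abundant as the query,
  and the query is flagged when the best single-breakpoint two-parent model
  beats the best single parent by ≥ `min_score_gain = 3` matching positions
  *and* the model explains ≥ `min_model_identity = 90 %` of the query's
  positions. The identity floor is essential: without it, the sole
  representative of a divergent taxon — which has no similar parent at all —
  gets flagged whenever two unrelated sequences happen to assemble a
  slightly better mosaic, and measured false-flag rates on clean synthetic
  reads jump from ≈ 0 to ≈ 20 %. Covariance-model-guided scoring and
  three-parent chimeras (features of the original reference-based tool) are
  not reproduced.
* **Rescue.** Flagged reads are classified; those reaching genus-level
  bootstrap confidence ≥ 0.5 are merged back into the effective set. The
  0.5 threshold is the study convention this package models and is exposed
  as `rescue_confidence`.

## Naive-Bayes classifier

Word-based naive Bayes over the 4⁸ = 65 536 possible 8-mers. Training sets
P(w|G) = (m(w) + P(w)) / (M + 1) per genus, with corpus prior
P(w) = (n(w) + 0.5) / (N + 1) (add-half smoothing), where m and n count
*sequences containing* w. A query is assigned to the genus with maximal
joint log-likelihood over all of its words (ties broken by lexicographic
genus name for determinism). Confidence: 100 bootstrap replicates each
resample ⌊W/8⌋ of the query's W words with replacement; the confidence at a
rank is the fraction of replicate winners lying under the assigned taxon's
ancestor at that rank, which makes confidence non-increasing from domain to
genus by construction. Within a replicate, exact likelihood ties are broken
uniformly at random (seeded): two genera with identical references then
split genus-level confidence ≈ 50/50 while agreeing fully at family level,
as symmetry demands.

Archaeal filtering classifies each effective read (against a reference set
containing both domains) and removes reads whose maximum-likelihood winner
is archaeal — the plain winner, with no confidence threshold, since a
domain-level call on ~200 bp 16S fragments is already near-saturated.

## LCA assignment and profiles

Hits for a read (12-column tabular alignment records) are filtered at
`min_bitscore = 86` — the intermediate of the three cutoffs in published
use (35 / 86 / 250) — then restricted to hits within `top_percent = 10 %`
of the best surviving bitscore; the read is assigned to the lowest common
ancestor of the remaining hits' genera. Adding a hit can therefore only
move an assignment toward the root.

Profiles at a rank project every assignment to its ancestor-or-self at that
rank. Taxa supported by more than `min_support = 30` reads are reported
(the display rule used with such cladograms); reads of suppressed taxa are
re-attributed to their nearest reported ancestor — at a single rank this
means the explicit `unassigned` mass — so read mass is conserved and
fractions plus `unassigned` always sum to 1. Whether the original analyses
used the 30-read rule beyond the figure display is unknowable; it is a
single configurable parameter here.

## Diversity statistics

* **Distances.** Global pairwise alignment (match +1, mismatch −1, gap −2);
  distance = (mismatched + internal gap columns) / aligned columns, with
  terminal-overhang columns excluded from both counts. End gaps are
  penalised during the alignment itself (only excluded from the distance
  count afterwards): with fully free end gaps two unrelated sequences slide
  into a tiny perfect overlap and come out spuriously close, and symmetry
  breaks. The argument pair is additionally ordered canonically so
  co-optimal alignments cannot make d(a,b) ≠ d(b,a). For equal-length
  sequences `distance_matrix` uses the vectorised positional (Hamming) path,
  which coincides with the alignment definition at the small divergences
  that matter near 3–6 % cutoffs.
* **Clustering** is agglomerative complete linkage, stopping when no pair
  of clusters is within the cutoff; ties at the minimum distance are broken
  by (larger merged cluster, smallest member id). The implementation is
  checked against an exhaustive from-scratch oracle on 12-sequence inputs.
  Distance cutoffs default to 3 % and 6 %.
* **Rarefaction** uses the analytic hypergeometric expectation evaluated
  with log-gamma functions for stability; 95 % bands come from seeded
  multivariate-hypergeometric subsampling (default 100 replicates). The
  analytic mean agrees with a 2 × 10⁵-replicate Monte-Carlo mean to < 0.005
  OTUs on toy vectors.
* **Chao1** defaults to the bias-corrected form S₁ = S_obs +
  F₁(F₁−1)/(2(F₂+1)), which is defined when doubletons are absent; the
  classic F₁²/(2F₂) form is available behind a flag. Which form the original
  tables used is not stated anywhere; bias-corrected is the safer default.
* **Shannon** uses the natural logarithm — consistent with the magnitudes
  such tables report (e.g. H ≈ 6.4 for ~3 900 OTUs ≤ ln 3 902 ≈ 8.27).
* **Normalization** subsamples every sample, without replacement, to the
  smallest bacterial library (`"min"`), or to an explicit depth.

## Copy-number correction

With gene fractions p_g at genus rank and per-genus mean operon copy
numbers k_g,

  cell_g = (p_g / k_g) / Σ_h (p_h / k_h).

Genus means average the per-species values in the table (duplicate species
rows are averaged first); genera absent from the table take the table-wide
mean and are flagged `imputed`. Mass not resolved to genus rank is excluded
before renormalising — the correction is defined over genera only — and the
excluded mass is reported. The per-genus "discrepancy" is the ratio
100 × cell % / gene %; a genus sits above 100 % exactly when its copy
number is below the abundance-weighted harmonic mean of the community, so
the direction of bias is a theorem, not an observation, and is tested as a
property. A percentage-point difference is trivially derivable from the
report columns for those who prefer it. The correction is exactly scale
invariant in the copy numbers and exactly inverts the generator's
gene-fraction construction (round-trip error < 1e-9 in tests).

## Synthetic communities

The generator emulates a four-sample multiplexed wastewater-style run:

* Twelve bacterial genera in eleven families plus two archaeal contaminant
  genera. References are 207 bp of random DNA built from per-family cores;
  each genus mutates 15 % of core positions, so genera within a family
  share ≈ 72 % identity and families are unrelated (≈ 25 %). 207 bp is the
  average effective amplicon length of the sequencing technology emulated.
* Per-sample compositions mirror the study design: one diverse
  activated-sludge-like sample, one digestion sample dominated (60 % of
  cells) by a single two-operon genus, and intermediate influent/effluent
  samples. Copy numbers span 1–9 with multi-species genera averaging to
  integers so that the gene↔cell round trip is exact.
* Reads are drawn per genus in proportion to cell fraction × copy number
  (i.e. the true *gene* fractions), then assembled as adaptor + barcode +
  a realised degenerate-primer instance + amplicon.
* Noise, applied per read: substitution errors at `error_rate` (default
  0.005, matching ~99.5 % per-base accuracy); two injected `N`s with
  probability `ambig_rate = 0.2`; truncation below 150 bp with probability
  `short_rate = 0.25` (together ≈ 55 % of raw reads survive QC, inside the
  43–65 % range typical of such runs); two-parent chimeras at
  `chimera_rate = 0.1` with breakpoints uniform on 30–70 % of the read so
  both parents contribute detectable signal; archaeal contaminants at
  `archaea_fraction = 0.005`.
* The default depth is 2 000 reads per sample — deliberately smaller than a
  real pyrosequencing library, chosen so a full four-sample run with
  clustering completes in tens of seconds; every rate above is independent
  of depth.

The fabricated hit table scores each read against every reference by
positional matches (a bitscore-like integer ≈ read length for a perfect
match, so the 86 cutoff corresponds to ≈ 40 % identity), plus Gaussian
noise (σ = 2 by default); hits under 35 % of the amplicon length are
dropped except that every read keeps its best hit, leaving truly foreign
reads with only sub-threshold hits.

**What the generator does not emulate** — and what green tests therefore do
not establish about real data: flowgram/homopolymer error structure and
quality scores (errors are uniform substitutions; FASTQ output carries a
constant quality), within-genus (species-level) reference variation,
primer-dimer and off-target amplification, chimeras with more than two
parents or parents from different samples, and real reference databases
with uneven genus coverage. Classifier accuracy and chimera recall measured
here are upper bounds relative to field data, where reference mismatch
dominates.

## Known limitations

* Complete-linkage clustering materialises the dense distance matrix:
  fine to a few thousand unique sequences, not for hundreds of thousands of
  reads without prior dereplication (the pipeline always dereplicates and
  weights by abundance).
* The LCA engine consumes externally produced (or fabricated) hit tables;
  no aligner is bundled.
* Accounting identities from published per-sample counts are arithmetic
  recomputations; flagged/rescued chimera counts of the original study
  depend on its reference database and are treated as fixed inputs, not as
  reproducible outputs.
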