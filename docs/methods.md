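# Methods

## Reference model

A *hairpin* record holds the precursor sequence (uppercase DNA; RNA input is
normalized U→T and re-projected on output), its genomic span (1-based
inclusive at file interfaces, 0-based half-open internally, converted only in
readers/writers), and a 3′ *flank* of F downstream genomic bases stored in
mature orientation (minus-strand extraction reverse-complements). The flank
is what lets the caller decide whether a 3′-extended read is *templated*
(matches the genome continuation) or a *non-templated addition* (NTA).
F defaults to 10 nt and must exceed the 3′ offset cap (6), otherwise
templated additions near the hairpin end would be unresolvable; the
configuration loader enforces this.

Arms are annotated on hairpins by 1-based inclusive positions; the archetype
sequence is always re-derived from the hairpin and checked against the
stored field, so the two can never drift apart. The GFF3 reader accepts
`miRNA` features whose seqid is either a hairpin ID (hairpin-relative
coordinates — what the synthetic generator writes) or a chromosome
(genomic coordinates, resolved through the hairpin's span and strand).

## Alignment model

Reads are trimmed of their 3′ adapter natively: the earliest read position
where the remaining suffix exactly matches an adapter prefix of ≥ 3 nt — or
where a full-length adapter copy occurs with ≤ 10 % mismatches — marks the
insert end. Untrimmed reads pass through flagged. Collapsed reads are kept
when 15 ≤ length ≤ 28 (the mature-miRNA size range; the bounds are
configurable since they are a judgment call) and mean base quality ≥ 20.

Alignment is deliberately restrictive: contiguous and ungapped against
hairpin + flank, at most one substitution, and the substitution may never be
the last templated base — a 3′-terminal mismatch is indistinguishable from
an NTA and is therefore shunted into the tail. Among valid splits at one
position, fewer mismatches win before longer templated region; among
positions and hairpins, candidates rank by (mismatches, tail length), and a
read whose best rank is achieved on more than one hairpin is *ambiguous* and
excluded from quantification. Ties on one hairpin keep the placement nearest
an annotated arm start, then the smallest position, so output order is
reproducible. A candidate must explain ≥ 15 templated bases, which prevents
degenerate splits that park most of the read in the tail. Alignments are
assigned to the arm whose 5′ end is nearest the read's templated start, and
stand only if |5′ offset| ≤ 4 and |3′ offset| ≤ 6 (caps configurable);
out-of-cap placements are tallied as unassigned, never silently dropped.
Read accounting (input = kept + filtered; kept = unaligned + ambiguous +
unassigned + assigned) is asserted per sample on every run.

The pipeline aligns directly to hairpins plus flanks rather than genome-wide:
for arm-level quantification the two are equivalent at desk scale, and
genome-wide decoy mapping is out of scope.

## IsomiR nomenclature and classification

An isomiR is identified by (arm, 5′ offset, templated 3′ offset, NTA tail).
Offsets are signed, rightward (3′-ward on the hairpin) positive; the label
`s|e` prints explicit signs for nonzero values (`+1|-2`) and `0` unsigned,
with the archetype `0|0`. The aligner's tail is resolved by the
maximal-prefix rule: the longest tail prefix matching the reference
continuation is absorbed into the templated 3′ offset; the remainder is NTA.
A tail consisting solely of uridines sets the uridylation flag.

Six exclusive categories partition every record: canonical (0, 0, no tail);
5′ deletion / 5′ addition (5′ shift only); 3′ deletion / 3′ addition
(3′ change only); mixed (both termini modified, or an NTA riding on a
templated 3′ shift). Two reporting conventions exist for a pure NTA on
canonical ends (0, 0, tail): by default it is counted in the 3′-addition
column and captured by the cross-cutting uridylation percentage — the
reading under which published per-miRNA proportion rows (five exclusive
columns summing to 100 with uridylation alongside) are internally
consistent — and a configuration switch gives it its own column instead.
The proportion table emits all six exclusive columns (a 5′-addition column
appears even where published tables omitted it as empty) so the partition
always sums to 100.00 ± 0.01 at the printed 2-decimal rounding; full
precision is retained internally and rounding is applied last.

## Quantification

RPM uses the arm-aligned denominator: per sample, only reads that survived
trimming/filtering and were assigned to an arm count, so isomiR RPM columns
sum to one million and arm abundance (the sum of its isoforms' RPM) is
conserved. Whether the denominator admits one mismatch (default) or none
(strict mode) is a flag, because the underlying convention is ambiguous in
the field; the policy used is recorded in the output metadata. Proportion
tables pool replicate counts within condition by default (per-replicate
averaging is a flag) — pooling is the only convention that reproduces
single-value-per-condition published rows without a variance model.
Population doublings follow PD = (log₁₀F − log₁₀I)/log₁₀2 with cumulative
PD as the running sum.

## Count statistics

All count tests share one NB2 (variance = μ + αμ²) machinery:

* **Size factors** — median-of-ratios on the log scale (median of
  log(count) − log geometric mean over features positive in every sample),
  exponentiated and mean-centered in log space; library-size fallback when
  no feature is everywhere-positive.
* **Dispersion** — gene-wise method-of-moments from the pooled within-group
  variance of normalized counts, a mean-dispersion trend α(μ) = a/μ + b
  fitted by least squares, and log-space shrinkage of gene-wise toward trend
  with an adaptive weight: w = max(0, 1 − s²_sampling / s²_observed), where
  s²_observed is the variance of log gene-wise estimates around the trend
  and s²_sampling ≈ ψ′(df/2) (trigamma) approximates their sampling noise at
  the residual df. With three replicates per group, gene-wise estimates are
  mostly noise, w ≈ 0, and the calibrated trend is used; genuinely
  heterogeneous dispersions push w up and restore gene-wise adaptivity.
  Estimates at the floor (1e-8) take the trend value.
* **Group means** — per-feature NB score equations solved by Newton
  iteration, vectorized across features, with size factors as exposures.
* **Wald DE test** — two-sided normal test on the log-fold-change contrast
  with observed-information standard errors; features with an all-zero
  group get a half-count moderated mean for the contrast. Features that are
  all-zero overall get p = NA and leave the BH family. A feature is *called*
  at BH FDR < 0.05 and |FC| ≥ 1.5 (|log₂FC| ≥ 0.585).
* **LRT trend** — full model one mean per condition vs one shared mean,
  same dispersion, 2Δℓ against χ² with df = 2; BH across features. Shapes
  over ordered conditions: flat unless FDR < 0.05, otherwise linear when
  both transitions share direction (or one is zero), U for down-then-up,
  inverted-U for up-then-down. Classification depends only on the ordering
  of group means, so it is invariant to monotone rescaling.

Under the package's null simulation (2,000 features, NB, lognormal baseline
means, α = 0.05, 3 × 3 design) both tests hold the raw p < 0.05 fraction
inside [0.03, 0.07], and 4-fold planted effects (50 of 2,000, mean 500,
α = 0.05) are recovered at ≥ 90 % power with ≲ 0.1 % false calls — the test
suite recomputes both.

Proportion comparisons use the pooled two-proportion z-test (two-sided,
degenerate tables → p = 1), reported unadjusted per category as in published
proportion tables. The global category-distribution comparison between two
conditions is a chi-square homogeneity test by default, with a Monte-Carlo
permutation alternative behind a flag, since the identity of the published
global test is not derivable. QC computes Pearson correlations and an SVD
PCA on log₂(RPM + 1) — a pseudo-log chosen over package-specific regularized
transforms because only ordering and sign structure matter downstream.
Z-tests are delegated to statsmodels; BH is implemented natively (step-up,
NaN-aware) and its equality with statsmodels' implementation is a test.

## Targetome

The seed is mature positions 2–8 (7 nt, TargetScan convention). A 5′ offset
moves the window: positive offsets drop archetype bases, negative offsets
prepend *templated* hairpin bases — consistent with the aligner, which only
ever extends 5′ ends along the template. Site classes on the UTR strand:
7mer-m8 = reverse complement of seed positions 2–8; 7mer-A1 = reverse
complement of positions 2–7 followed by an A (the A is a UTR requirement,
not a complement); 8mer = both. 6mer sites are excluded by default
(weakest class) and switchable. Seed collisions are exact 7-mer matches
between an isomiR seed and another arm's canonical seed, self-pairs
excluded. Enrichment is a one-sided Fisher exact per gene set over a
universe defaulting to the union of all set members (an offline stand-in
for web-tool universes), BH across sets, with the reported ratio =
targeted members / set size. Venn region counts are exact set algebra for
2–3 sets; more sets fall back to a pairwise matrix.

## Synthetic data

`simulate_reads` plants per-arm spectra of (5′ offset, 3′ offset, NTA,
fraction) and writes insert + NTA + adapter at constant high quality
(threshold-based quality filtering does not need a noise model). Fractions
are allocated deterministically by largest remainder by default so recovered
proportions compare exactly; multinomial sampling is the realism option.
Substitution errors occur at a configurable per-base rate (default in the
shell pipeline: 0.005, an Illumina-like figure), at most one per read, and
by default never on the first or last templated base — a terminal
substitution is indistinguishable from an offset/NTA change and would make
truth labels ambiguous; a flag enables fully uniform errors for robustness
work. Two generator guarantees keep the ground truth honest: a planted tail
prefix that happens to match the genomic continuation is re-labeled as the
templated extension it would correctly be called as, and configurations
whose insert suffix collides with the adapter prefix (which the trimmer
would over-trim) are rejected up front. The default synthetic references pin
the bases at each arm's 3′ boundary (final arm base G, continuation A) so
planted uridine tails are genuinely non-templated.

`simulate_counts` draws NB counts for 3 conditions × 3 replicates (the
study design) with lognormal baseline means (default median 200, log-sd 1),
dispersion 0.05, and planted multiplicative effects per transition — means
(m, m·f1, m·f1·f2) with the pattern (linear-up/down, U, inverted-U) checked
for consistency against the fold changes. `simulate_utrs_and_genesets`
plants 8mer sites for assigned seeds and rejection-samples all other UTRs to
be free of any planted seed's sites (bounded retries, then a hard error).

What the generator does not emulate: PCR duplicates, UMIs, ligation bias,
indel errors (the aligner cannot represent them anyway), position-dependent
quality, multi-mapping decoys from a full genome, or A-to-I editing. Passing
tests therefore demonstrate correctness of the computational contracts —
classification, accounting, calibration — not robustness to every artifact
of real libraries.

## Determinism and problem sizes

All randomness flows from explicit integer seeds (the shell pipeline fans a
single config seed out per condition and sample by fixed derivation; no
stage reads system entropy), and identical seeds give byte-identical
artifacts — asserted by tests at the file-checksum level. Default problem
sizes are chosen as desk-scale study conditions: 9 samples × 100,000 reads
for the full synthetic run (about two minutes end to end on one CPU),
2,000-feature count matrices for the calibration suites, and hundreds of
genes for target/enrichment stages; unit and acceptance tests use smaller
slices of the same generators.

## Known limitations

* The DE/LRT machinery is a single documented NB procedure, not a
  re-implementation of any specific external package's internals; exact
  numerical concordance with such packages is a non-goal (size-factor
  equality is cross-checked against one).
* Pre-miRNA-stage vs mature-stage tailing cannot be distinguished from
  sequencing alone and is not attempted.
* Internal (non-terminal) variants are absorbed by the one-mismatch budget,
  not called; A-to-I editing detection is out of scope.
* The z-tests on proportions treat pooled replicate counts as one binomial
  sample, ignoring replicate-level overdispersion — matching the published
  table convention, but optimistic if replicates vary strongly.
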