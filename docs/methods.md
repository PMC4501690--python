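# Methods

This note describes the statistical models and procedures implemented in
`flyvirome`, the assumptions behind them, the defaults and why they were
chosen, and what the synthetic-data generators do and do not emulate.

## Background

Metagenomic virus discovery in *Drosophila* rests on two complementary
signals.  First, sequence similarity: assembled contigs with protein-level
hits to known viruses.  Second, the host's own antiviral response:
Dicer-2 processes double-stranded viral RNA into 21 nt small interfering
RNAs (viRNAs) from both strands, so a contig that attracts many 21–23 nt
small RNAs — relative to its RNAseq abundance and to 25–29 nt piRNA-like
reads — is being recognised as a replicating virus even when it resembles
nothing in the databases.  Downstream of discovery, field surveys of
individually assayed flies (and small pools of flies) give prevalence
estimates, and public sequencing archives can be screened for the same
viruses by read mapping.

## Small-read mapping

Reads of 17–29 nt are placed at every position, on either strand, where
the 5′-anchored prefix matches the reference exactly; only the last
`max_3prime_mismatch` bases (default 2) may mismatch, and each tolerated
mismatch is recorded as `(offset from 3′ end, read base, template base)`.
This asymmetric tolerance is deliberate: the biological signal of interest
at the 3′ end is *non-templated* uridylation, which must be detected
rather than discarded, while the 5′ end of a small RNA is defined by
Dicer cleavage and should match the template.  General mismatch-anywhere
alignment is out of scope; the mapper exists so profiling is testable
end-to-end without an external aligner.

Implementation: a k-mer index over each reference's exact 5′-anchor
length; correctness is asserted against a brute-force all-positions scan
in the test suite.  `N` never matches (conservative counting).  Multimapped
reads are reported at every location (policy `all`, the default) or with
weight 1/n locations (`fractional`, for sensitivity analysis).  U is
normalised to T internally; RNA outputs are rendered with U.

## Small-RNA profiling

* **Size/strand spectrum** — weighted counts over (length 17–29, strand).
* **Strand bias** — positive-strand fraction of placements; a bias far
  from 0 or 1 indicates reads from both strands, i.e. a double-stranded
  (replicative) substrate.
* **5′ and positional base composition** — frequencies of the read's own
  bases (minus-strand placements are already in read orientation).  The
  sequence-logo information content per position is `2 − H` bits with
  Shannon entropy `H` in log2 and `0·log 0 ≡ 0`; no small-sample
  correction is applied.  A deterministic position scores exactly 2 bits,
  a uniform one exactly 0.
* **Non-templated 3′ detection** — a placement's terminal base is
  non-templated when the mapper recorded a mismatch at 3′ offset 0.  The
  headline statistic is the fraction of 3′-U reads whose U is
  non-templated (the uridylation signal).  Note an identifiability limit:
  replacement of a terminal base by U is invisible when the template
  already ends in U, so on a ~uniform-composition reference only ~3/4 of
  uridylation events are detectable; recovering the underlying rate
  divides by that detectable fraction.
* **viRNA production ratio** — per virus,
  `(viRNA count / miR-34-5p count) / (virus RNAseq / non-viral RNAseq)`,
  rescaled so the lowest-producing virus is 1.  Normalising viRNAs by an
  abundant, stably expressed host miRNA and RNAseq by the non-viral total
  makes the ratio comparable across libraries of different depth.  Viruses
  with zero RNAseq reads are flagged undefined and excluded from the
  minimum.
* **Dominant-read statistics** — the share of the single most abundant
  unique sequence, plus the number of unique sequences and of those seen
  more than once.  A very high share of one exact sequence marks a
  miRNA-like species; a diverse population marks Dicer processing.

The viRNA window is 21–23 nt and the piRNA window 25–29 nt throughout;
both are configurable for sensitivity analysis.

## Sector classification of contigs

Each contig ≥200 nt gets a profile (siRNA-window count *s*, piRNA-window
count *π*, RNAseq count *r*) and coordinates

    x = log10((s + α) / (r + α)),   y = log10((s + α) / (π + α)),

with pseudocount α = 1 by default.  Per-length normalisation cancels
between numerator and denominator and is omitted.  The candidate sector is
calibrated from known-virus positive-control profiles as the axis-aligned
lower-left corner of their scores (minimum x and minimum y over controls);
comparisons are inclusive so controls always self-classify.  A contig with
at least `min_sirna_reads` (default 1) siRNA-window reads, in-sector
scores and no database hit is labelled `sirna_candidate`; in-sector
contigs *with* hits are passed through as `blast_candidate_region` for
reporting.  The package ships illustrative control profiles shaped like
the four well-characterised *Drosophila* viruses (DAV, DCV, Nora Virus,
DMelSV — siRNA-rich, piRNA-poor, moderate RNAseq); they are synthetic
stand-ins, and measured control profiles should be supplied when
available.  Sector geometry choices that were genuinely open — axis
definition, log base, pseudocount — are this package's explicit
convention and are all configurable.

BLAST itself is out of scope; `blast_hit` is an input flag, and the
taxonomy walk consumes externally supplied hit lineages, returning the
deepest rank at which ≥75% (configurable, must exceed 50%) of lineages
agree, falling back to "root".

## EVE exclusion

A virus-like sequence segregating as an endogenous viral element (EVE) in
the host genome should attract genomic reads at a per-kilobase rate
approaching that of any other locus.  The test normalises target
reads·kb⁻¹ to reads·kb⁻¹ on a single-copy host region (default 7 kbp) and
calls the sequence EVE-consistent when the ratio is ≥0.1.  The 0.1
default leaves a wide margin between a true genomic copy (≈1.0) and
mismapping/contamination levels (≲0.01); zero single-copy reads make the
verdict indeterminate rather than negative.

## Pooled-assay prevalence

A bulk assay on k flies is positive iff ≥1 fly carries the virus, so at
per-fly prevalence p the positivity probability is `1 − (1−p)^k`.  For a
set of single-fly and bulk assays (each fly's carriage assumed independent
Bernoulli(p) within a location × species stratum),

    logL(p) = Σ_positive log(1 − (1−p)^k) + Σ_negative k·log(1−p).

The MLE is found by grid search at 1e-4 resolution over [0, 1] followed by
bounded scalar refinement around the best grid point — deterministic, and
exact for the closed-form cases (singles-only: x/n; uniform bulk size k:
`1 − (1 − x/n)^(1/k)`).  The reported interval is the connected hull of
`{p : logL(p) ≥ logL(p̂) − 2}` with endpoints sharpened by root-finding;
the 2-unit drop in *natural* log corresponds to a ≈95.4% asymptotic
confidence level via the χ²(1) calibration of the likelihood-ratio
statistic.  All-negative data pin p̂ = 0 (lower bound 0); all-positive pin
p̂ = 1.  The log-likelihood is unimodal in p, so the hull is the exact
profile set.  Detection is treated as perfect, so estimates are lower
bounds on true carriage.

Supporting tests:

* **Bulks vs singles LRT** — 2·(logL̂_singles + logL̂_bulks − logL̂_pooled)
  against χ²(1); requires both strata.
* **Benjamini–Hochberg** — standard step-up FDR control (via statsmodels)
  across many location × virus tests.
* **Global means** — locations weighted equally (not by sample size),
  with a percentile bootstrap interval over locations; undetected
  locations contribute zeros.
* **Virus × Wolbachia association** — two-sided Fisher's exact test per
  location on the single-fly 2×2 table, combined by Fisher's method
  (X = −2 Σ ln pᵢ ~ χ²(2m)).  Tables with a zero margin carry no
  information about association and are excluded and reported, rather
  than assigned p = 1.
* **Prevalence correlation** — Spearman's rank correlation (average ranks
  on ties) with an OLS line for illustration; needs ≥3 locations.

## rpm screening of run tables

Counts per (sequencing run, virus) are converted to reads per million
total mappable reads; a virus is present in a run when rpm ≥ threshold
(default 100, inclusive — the threshold is a detection limit; a strict
mode is provided).  Runs with zero total reads are excluded.  Positivity
is summarised per run, per sample and per submitted project (a group is
positive when any member run is), giving fractions that are necessarily
non-decreasing up the grouping hierarchy, and as a monotone threshold
curve.  A segment-to-virus map sums multi-segment counts before
conversion, and a pairwise presence-correlation report supports merging
always-co-occurring candidates into one genome.

## Synthetic data: what it emulates, and what it does not

The generators produce every input the pipeline consumes, with ground
truth, so every statistical property above is testable end to end:

* **Small-RNA populations** — templated substrings of a reference with
  configurable length spectrum (default peaked at 21 nt), strand bias
  (default 0.6, the middle of the 50–70% positive-strand range typical of
  positive-sense RNA viruses), 5′-base composition (default with a mild
  bias against 5′ G), non-templated 3′-U replacement at a configurable
  rate, and an optional exact dominant sequence (default off; 22 nt at a
  ~40% share when emulating a miRNA-dominated population).  The 5′ bias is
  implemented by sampling start positions from per-base position pools,
  keeping every read genuinely templated.
* **Contig scenarios** — virus-like contigs draw RNAseq counts
  log-uniform in [100, 1000] with siRNA counts 10–100× higher and
  near-zero piRNA counts; transposon-like contigs are piRNA-heavy
  (piRNA log-uniform in [500, 5000], siRNA 0.03–0.3× that); mRNA-like
  contigs carry RNAseq only.  These ranges are deliberately wide and
  disjoint in sector coordinates, so classifier errors under the defaults
  indicate implementation faults, not statistical noise; narrowing the
  ranges moves errors to the sector boundary as expected.
* **Surveys** — per-fly carriage drawn individually (so bulk positivity
  is `1 − (1−p)^k` by construction, not by formula), with per-fly joint
  virus × Wolbachia status solved analytically from the margins and a
  configurable odds ratio (quadratic root in the feasible cell range).
  Bulk-size lists are caller-supplied rather than assumed, since field
  designs vary (typically 2–20 flies per bulk).
* **Run tables** — infections planted per (run, virus) at a configurable
  rate with log-uniform rpm; non-infected cells are zero or Poisson
  "mismapping" noise (default mean 0).

Not emulated: sequencing error, read quality, adapter artefacts,
ligation bias between library protocols, paired-end structure, multiple
competing virus genotypes, and spatial/temporal correlation between
survey locations.  Passing tests therefore demonstrate the correctness
and calibration of the *statistics* under their stated sampling
assumptions, not robustness to the full messiness of real libraries.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen to make sampling
bounds tight while keeping the suite fast: 10,000 reads for parameter
recovery (3 binomial/multinomial SD bounds, plus a fixed 0.01 allowance
for multimapping and finite-reference composition effects), 200 replicate
surveys of 500 singles for interval coverage (accepted band [90%, 99%]
around the 95.4% asymptotic level), 1,000 null replicates for the LRT
type-I error (accepted [3%, 7%] at α = 5%), 100 seeded scenarios for
classifier recovery, and 10,000 replicates for the χ² distribution of
Fisher's combined statistic (KS p > 0.01).  Grid resolution 1e-4 with
refinement makes MLEs exact to ~1e-6 for the closed-form cases.  Ties at
all thresholds are inclusive.  All generators take explicit seeds and use
a single `numpy` Generator per call; identical seeds give byte-identical
outputs.

## Known limitations

* The mapper is exact but not indexed for genome-scale references; it is
  intended for virus-genome-sized references.
* The sector calibration is only as good as its positive controls; the
  shipped defaults are illustrative shapes, not measurements.
* The prevalence model assumes one underlying prevalence per stratum and
  a perfectly sensitive, perfectly specific assay; violations bias
  estimates downward (assay failure) or upward (cross-amplification).
* Fisher's-method combination assumes independent per-location tests;
  Fisher's exact p-values are discrete and conservative in small tables,
  so the combined test is conservative too.
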