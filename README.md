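# flyvirome

Statistical tools for small-RNA-based virus discovery and virome surveys
in *Drosophila* (and other insects with an antiviral RNAi response).

When a virus replicates in a fly, Dicer-2 dices its double-stranded RNA
into 21 nt small interfering RNAs from both strands.  That host response
is a virus detector: a contig that attracts many 21–23 nt small RNAs
relative to its RNAseq abundance — and few 25–29 nt piRNA-like reads — is
being recognised as a replicating virus even if it resembles no known
sequence.  `flyvirome` implements the computational pipeline around that
idea, for researchers running insect virome surveys:

* **Small-RNA profiling** — size/strand spectra, 5′ and positional base
  composition (sequence-logo information content), non-templated 3′-U
  (uridylation) detection, dominant-read statistics, and the
  miRNA-normalised viRNA production ratio per virus.
* **A 5′-anchored small-read mapper** with a tolerant 3′ window, so
  non-templated 3′ additions are recorded rather than dropped.
* **siRNA-signature classification** of contigs in the
  log₁₀(siRNA:RNAseq) × log₁₀(siRNA:piRNA) plane, with the candidate
  sector calibrated from known-virus positive controls; plus an
  endogenous-viral-element (EVE) coverage test and a 75%-majority
  taxonomy walk over database-hit lineages.
* **Pooled-assay prevalence estimation** — a bulk of k flies tests
  positive with probability 1 − (1−p)^k at per-fly prevalence p; the
  package maximises the pooled binomial likelihood

      logL(p) = Σ₊ log(1 − (1−p)^k) + Σ₋ k·log(1−p)

  by grid search with refinement and reports the 2-log-likelihood
  interval (≈95% asymptotic coverage), with a bulks-vs-singles likelihood
  ratio test, Benjamini–Hochberg FDR control, equal-weight global means
  with bootstrap intervals, virus × *Wolbachia* association via Fisher's
  exact tests combined by Fisher's method, and across-location rank
  correlations.
* **rpm screening** of per-run virus read-count tables at a
  reads-per-million detection threshold, summarised per run, sample and
  project.
* **Seeded synthetic-data generators** for every input above, with ground
  truth, so the whole pipeline is testable end to end.

## Worked example

Estimating prevalence from a simulated two-location survey of single
flies and small bulks (`examples/estimate_prevalence.py`):

```
per-location ML prevalence (2-logL interval):
  Athens     LaJollaVirus: 0.238 [0.169, 0.318] from 124 assays / 150 flies (truth 0.25)
  Marrakesh  LaJollaVirus: 0.052 [0.022, 0.099] from 122 assays / 135 flies (truth 0.05)

bulks-vs-singles LRT in Athens: statistic 0.11, p = 0.735 (no real difference was simulated)
global mean prevalence across locations: 0.145 (95% bootstrap interval 0.052-0.238)
virus x Wolbachia association: combined X = 0.80 on 4 df, p = 0.939 (independence was simulated, so p should be unremarkable)
```

The point estimates recover the simulated truths inside their intervals;
the raw positive-assay fractions would not (a positive bulk of 10 flies
says only that ≥1 fly carried the virus, which is why the pooled
likelihood is needed).  The LRT and the association test are null here by
construction and behave accordingly.

The other example scripts each exercise one capability and print a line
on what the numbers mean:

* `examples/simulate_and_profile.py` — small-RNA population in, profile
  statistics out (strand bias, dominant-read share, uridylation signal).
* `examples/classify_contigs.py` — sector classification of 15 labelled
  synthetic contigs, the EVE coverage test, and the taxonomy walk.
* `examples/screen_public_runs.py` — rpm screening of a 300-run table
  with planted infections.

A thin CLI mirrors the library for shell use
(`flyvirome simulate|map|profile|classify|eve-test|taxwalk|prevalence|lrt|wolbachia|global-mean|screen`);
all tables are tab-separated text with a `#` metadata header.

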