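# Methods

This note records the models, algorithms, parameter choices and known
limitations of `premasig`, in the order the pipeline runs.

## IHC positivity and subtype rules

Marker positivity is a strict inequality against configurable thresholds
(`PositivityThresholds`): ER and PR positive above 1% stained cells, Ki67
positive above 14% (the St Gallen convention). A staining score of exactly
1% or 14% is negative. Missing Ki67 yields a missing call, never an error.

Subtype assignment applies rules in a fixed order so every marker
combination maps to exactly one label:

1. HER2 *equivocal* without confirmatory FISH → `Undetermined` (the case
   cannot be placed in the ER×HER2 grid); FISH-confirmed equivocal results
   are treated as resolved-positive.
2. ER+ → `LuminalA` (HER2−) or `LuminalB` (HER2+).
3. ER− → `HER2enriched` (HER2+), `TripleNegative` (PR− and HER2−), or
   `Undetermined` for the leftover ER−/PR+/HER2− pattern.
4. Triple-negative tumors are `basal` when EGFR+ and/or CK5/6+, else
   `non-basal`.

HER2 is consumed as a pre-scored category (negative/equivocal/positive);
raw 0/1+/2+/3+ scoring is not modeled.

## Exact contingency tests

The 2×2 two-sided Fisher p uses the probability rule — the sum of
hypergeometric probabilities of all margin-fixed tables no more probable
than the observed one, with a relative guard of 1+1e-7 against float ties —
and is served by `scipy.stats.fisher_exact`; the test suite checks it
against an independent log-factorial enumeration oracle for every table
with grand total ≤ 40. Degenerate tables (a zero margin) return p = 1.

The r×c Freeman–Halton test is implemented directly: full recursive
enumeration of margin-fixed tables when the grand total is ≤ 300 (the
observed cohort tables enumerate ~10^5 tables in well under a second), and
otherwise a Monte-Carlo estimate over Patefield-sampled tables
(`scipy.stats.random_table`) with the add-one estimator. The 2×2 case
delegates to the 2×2 path so the two functions can never disagree.

For the overall subtype × Ki67 association, the five observed subtype rows
(including `Undetermined`) reproduce the cohort's reported p ≈ 2×10⁻⁴;
restricting to the four assigned subtypes gives 1.2×10⁻⁴. Both
denominators are supported; pipelines built on `tabulate` exclude
`Undetermined` by default because subtype percentages are reported over
assigned classes.

## Somatic filtering

`filter_somatic` retains a variant for a case iff all of:

* called in both tumor duplicates (`require_both_duplicates`, default on),
  with VAF ≥ `vaf_min` (default 0.04) **in each duplicate**;
* absent from every blood sample of the whole cohort (`exclude_in_blood`);
* population allele frequency ≤ `popaf_max` (default 0.001; a variant
  absent from the table counts as frequency 0; strictly greater is
  removed);
* effect class in `effects_kept` (default: splice, indel-coding, nonsense,
  stop-loss, non-synonymous).

Retained calls are deduplicated to one record per case per variant (the
duplicate-1 call). Sequenced sources cannot be inferred from calls — a
duplicate with zero calls is legitimate data — so the caller may pass
`sequenced_sources`; without it, a case whose calls all come from one tumor
source is rejected by name when duplicate concordance is required. Because
the duplicate structure is consumed by the first pass, idempotence holds
for the source-independent rules: re-filtering retained output with the
duplicate requirement relaxed changes nothing.

Missing VAF fails the VAF threshold (a call that cannot demonstrate
sufficient allele fraction is not trusted). Multi-nucleotide substitutions
are routed to the indel/other bin throughout.

## Catalogs and spectra

Channel order is the COSMIC v2 convention: substitution classes C>A, C>G,
C>T, T>A, T>C, T>G, then the 5′ base, then the 3′ base, each alphabetical —
channel 0 is `A[C>A]A`, channel 95 `T[T>G]T`. Purine-reference
substitutions are reverse-complemented (alleles, and swapped/complemented
flanks) before classification; the test suite proves strand invariance
exhaustively over all 192 raw substitution-context combinations.
Coordinates are 1-based; the context is read from positions pos−1 and
pos+1 of the reference (pyfaidx FASTA or a plain mapping), case-insensitive;
ambiguous bases raise.

The 8-category spectrum uses purine-first labels (the style of the headline
results): `G:C>T:A` covers both G>T and C>A, and `G:C>A:T` is split at CpG
(pyrimidine-strand C immediately followed by G). The Methods-style
`C:G>A:T` labels denote the same six classes. The categories partition any
mutation list; indels and MNVs go to the `indel` bin.
`spectrum_compare` tests one category against the rest between two spectra
with the 2×2 Fisher test.

Mutation rates are count/capture-size per sample with a 47 Mb default
capture; per-sample rates and their mean are both exposed because an
averaging denominator can be ambiguous (2128 non-synonymous variants over
12 samples × 47 Mb gives 3.77/Mb, while a mean of per-sample rates weights
samples equally).

## NMF signature extraction

Objective: generalized Kullback–Leibler divergence D(V‖WH), minimized by
Brunet-style multiplicative updates (H then W per iteration); a Frobenius
objective is available behind `objective="frobenius"`. Defaults:
`max_iter=2000`, relative-change tolerance `tol=1e-6`, denominators guarded
by eps = 1e-12. Factors are initialized i.i.d. uniform(0,1) scaled by the
data mean, from a per-run generator spawned off the root seed; the same
seed is bit-reproducible. The objective trace is returned and is
non-increasing (asserted in tests); W is column-normalized on return with
the scale moved into H. All-zero sample columns are rejected with an error
directing the caller to drop the sample.

### Rank selection

Per candidate rank, `run_multistart` (default 50 restarts) computes:

* the **consensus matrix** — mean over restarts of the sample connectivity
  matrix (two samples connected when they share the arg-max signature) —
  and its **cophenetic correlation** under average-linkage clustering of
  the 1−consensus distances (defined as 1 for rank 1, a single pair, or a
  zero-variance distance vector);
* **signature stability** — the mean over restarts of the worst
  Hungarian-matched cosine between the restart's signatures and the best
  (lowest-objective) run's.

The selected rank is the *largest* one with signature stability ≥ 0.95.
Rationale: a rank below the truth merges clusters deterministically, so its
consensus is exactly as reproducible as the true rank's — the cophenetic
coefficient plateaus at ≈1 up to the true rank and cannot choose between
the tied values (simulations with 3 planted signatures show coph(2) ≈
coph(3) ≈ 1 in most replicates, and the coph ranges of the true and
over-factorized ranks overlap across replicates, so no cutoff on the curve
alone separates them). Signature-level reproducibility discriminates
sharply: spurious components of an over-factorized rank differ between
restarts (observed mean worst-matched cosine ≤ 0.85 above the true rank vs
≥ 0.97 at or below it). When no rank reaches the bar, the rank maximizing
the cophenetic coefficient is returned with ties toward the smaller rank.
The full curve (cophenetic, signature stability, best objective) is always
returned for inspection.

### Matching and exposures

Matching to a reference catalog is per-extracted-signature best cosine hit
(several extracted signatures may share a reference), flagged below a 0.75
threshold; channel orders must agree exactly, with no silent reordering. A
globally optimal one-to-one Hungarian assignment (`best_assignment`) is
provided for recovery tests. Exposures are re-estimated per sample by NNLS
against the normalized W — rather than read from the training H — so
contributions are defined for held-out samples too; percentages are
column-normalized to 100, with zero-mutation samples left all-zero and
listed in `ExposureMatrix.zero_samples`.

## Permutation association tests

The statistic is the tie-corrected Kruskal–Wallis
H = [12/(N(N+1)) Σ R²ᵢ/nᵢ − 3(N+1)]/C with mid-ranks and
C = 1 − Σ(t³−t)/(N³−N); all-tied data give H = 0 by convention. The
empirical p uses the add-one estimator p = (1 + #{H* ≥ H}) / (1 + n_perm)
(default n_perm = 2000), with a 1e-12 tolerance on the ≥ comparison.
Designs:

* **plain** — unrestricted permutations (implemented by permuting the value
  vector, which is equivalent to permuting labels under a rank statistic);
* **stratified** — permutations within strata only, so per-stratum group
  counts are preserved exactly;
* **adjusted** — Freedman–Lane: values are regressed on an indicator design
  of the nuisance covariates, residuals are permuted and re-added to the
  fit, and H is recomputed. The scheme was chosen as the standard
  permutation-valid treatment of nuisance covariates; with an empty
  covariate set it degenerates, permutation for permutation, to the plain
  design (asserted exactly in tests);
* **subset** — an inclusion mask applied before everything else, with group
  levels re-checked.

`run_panel` runs every requested design for every signature with
per-test seeds spawned from one root seed, and applies no multiplicity
adjustment by design.

## Over-representation analysis

p = P(X ≥ k), X ~ Hypergeometric(N = |universe|, K = |set ∩ universe|,
n = |query|) via `scipy.stats.hypergeom`; sets with fewer than 3
overlapping genes are removed before Benjamini–Hochberg adjustment
(statsmodels step-up), and the report keeps q < 0.05 by default. The
universe defaults to the union of all gene-set members and is logged —
an ORA p is meaningless without a stated background, and the background of
any external pathway portal is not recoverable, so numeric agreement with
portal-derived pathway lists is out of scope. Query genes outside the
universe are dropped with a logged count; gene symbols are uppercased for
matching.

## Synthetic-data generators

All generators are pure functions of `SimConfig` (seed mandatory; same
seed, byte-identical output; probability vectors validated to sum to 1
within 1e-9).

* **Cohort**: subtypes drawn from the observed cohort composition as exact
  count fractions (134/233 luminal A, 48/233 TN, 26/233 luminal B, 11/233
  HER2-enriched, 14/233 undetermined — the rounded percentages sum to
  101%, so the counts are the usable vector); marker values are drawn
  consistently with the drawn subtype, so the subtype caller recovers the
  truth for every case by construction. Per-subtype Ki67-positivity rates
  default to the observed 72/88/91/98/93%. Undetermined cases are mostly
  (13/14) equivocal-HER2-without-FISH, else ER−/PR+/HER2−; 94% of TN cases
  are basal.
* **Call sets**: gene-panel hits are per-case Bernoulli draws with
  per-subtype probabilities whose mixture approximates case-level
  frequencies near TP53 33%, PIK3CA 21%, AKT1 9%; true somatic variants
  appear in both duplicates with VAF from Beta(5, 15) truncated at the 4%
  threshold (plausible FFPE tumor fractions that respect the threshold by
  construction). Injected artifacts each violate exactly one rule
  (single-duplicate, blood-present, population AF 0.005, VAF < 0.04), at
  positions distinct from true variants so truth labels are unambiguous.
* **Catalogs**: per sample, exposures e ~ Dirichlet(α) (default α = 1),
  total n ~ Poisson(mean, default 1000), channel counts ~
  Multinomial(n, We). Default signatures are sparse Dirichlet(0.1) draws
  redrawn until pairwise cosine < 0.6, so they are recoverable.
* **TP53-like spectrum**: categories drawn from the 8-category weights
  (default G:C>T:A weight 0.27); each mutation is embedded in a synthetic
  contig whose local context realizes its category, and half the
  substitutions are emitted on the purine strand to exercise strand
  collapse.
* **Covariates**: subtype/menopausal/source columns drawn independently of
  any values, so permutation nulls hold by construction.

What the generators deliberately do **not** emulate: read-level error,
realistic genome composition (contexts are uniform), germline haplotypes,
linkage between panel genes and signature exposures, and the empirical
signature profiles of real tumors. Passing recovery tests therefore shows
the algorithms are correct on data satisfying their model assumptions, not
that real cohorts satisfy those assumptions.

## Problem sizes used in tests and the acceptance script

Signature recovery runs at 3 signatures × 30 samples × ~1000 mutations with
20 restarts over ranks 2–6; exposure recovery at 10⁴ mutations/sample;
permutation validity at 500 null cohorts of 40 samples with n_perm = 200;
the exact-test oracle sweep covers every 2×2 table with total ≤ 40. These
sizes keep a full run to a few minutes on one CPU while leaving each check
statistically sharp (3σ binomial bounds throughout).

## Known limitations

* The Freeman–Halton enumeration is exponential in rows × columns; beyond
  the 300-count cap the Monte-Carlo path must be used.
* KL-NMF multiplicative updates can converge slowly near flat optima;
  `tol=1e-6` with `max_iter=2000` is a compromise, and the stability-based
  rank selection deliberately re-runs the factorization many times.
* The signature-stability threshold (0.95) is a method constant: data whose
  true components are nearly collinear may fail the bar at the true rank
  and fall back to the cophenetic rule.
* Permutation p-values are floored at 1/(n_perm+1); reported values at the
  floor should be read as "below resolution", not as point estimates.
* Effect-class annotation, variant calling and copy number are consumed as
  inputs or out of scope.
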