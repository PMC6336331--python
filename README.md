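# premasig

Downstream tumor-genomics analysis for small breast-cancer cohorts:
immunohistochemistry (IHC) subtype classification, somatic-mutation
filtering for FFPE duplicate designs, trinucleotide mutation catalogs and
spectra, mutational-signature extraction by non-negative matrix
factorization (NMF) with stability-based rank selection, permutation
association tests of signature contributions, and gene-set
over-representation analysis — plus synthetic-data generators so every stage
can be exercised against known ground truth.

## Who it is for

Groups running pilot-scale tumor sequencing studies (tens to low hundreds of
cases, targeted panels plus a handful of exomes) who need the standard
downstream battery — subtype tables with exact tests, filtered somatic call
sets, 96-channel catalogs, de novo signatures matched to a reference, and
small-sample association tests — as reproducible, tested library code rather
than a collection of one-off scripts.

## The statistics at the core

**IHC subtyping.** ER/PR positivity is staining >1%, Ki67 positivity >14%
(strict inequalities, configurable). Subtypes: luminal A (ER+/HER2−),
luminal B (ER+/HER2+), HER2-enriched (ER−/HER2+), triple-negative
(ER−/PR−/HER2−, basal-like when EGFR+ and/or CK5/6+). Equivocal HER2 without
confirmatory FISH, and leftover patterns such as ER−/PR+/HER2−, are
*Undetermined*. Associations use Fisher's exact test: for 2×2 tables the
two-sided probability rule, for r×c tables the Freeman–Halton extension by
full enumeration of margin-fixed tables (Monte-Carlo fallback via Patefield
sampling for large tables).

**Somatic filtering.** A call is somatic when present in both FFPE tumor
duplicates with variant allele fraction ≥ 4% in each, absent from every
blood sample of the cohort, population allele frequency ≤ 0.001, and in a
potentially deleterious effect class (splice, indel, nonsense, stop-loss,
non-synonymous).

**Catalogs and spectra.** Single-base substitutions are collapsed onto the
pyrimidine strand and classified into 96 channels (6 substitution classes ×
16 flanking-base pairs, COSMIC v2 order). The coarser 8-category
strand-symmetric spectrum (G:C>A:T at CpG, G:C>A:T other, G:C>T:A, G:C>C:G,
A:T>G:C, A:T>T:A, A:T>C:G, indel) supports gene-level comparisons such as
testing one dataset's G:C>T:A excess against another's by Fisher's exact
test.

**Signatures.** A catalog V (96×S) is factorized V ≈ WH with W ≥ 0 the
signatures (columns sum to 1) and H ≥ 0 the exposures, minimizing the
generalized Kullback–Leibler divergence D(V‖WH) by multiplicative updates.
The number of signatures is chosen from the stability of repeated random
restarts: the consensus-clustering cophenetic coefficient is reported, and
the selected rank is the largest one whose signatures are reproduced across
restarts (see `docs/methods.md` for why the cophenetic coefficient alone
cannot break ties below the true rank). Extracted signatures are matched to
a reference catalog by cosine similarity; per-sample contributions are
re-estimated by non-negative least squares and reported as percentages.

**Association tests.** Signature contributions are tested against
categorical covariates with the tie-corrected Kruskal–Wallis H and an
empirical p over label permutations (default 2000; add-one estimator, so
p ≥ 1/(n_perm+1)): plain, stratified, covariate-adjusted (Freedman–Lane
residual permutation), and subset designs.

**Over-representation.** Hypergeometric upper-tail p per gene set, ≥3
overlapping genes required, Benjamini–Hochberg q < 0.05 reported, universe
explicit.

## Worked example

```python
from premasig import (SimConfig, simulate_catalog, select_rank,
                      estimate_exposures, fisher_exact_2x2, fisher_exact_rxc)
from premasig.signature_inference import (SignatureSet, ReferenceCatalog,
                                          match_signatures)

# Ki67 positivity in luminal A (96/134) vs triple-negative (47/48) cases
p = fisher_exact_2x2([[96, 38], [47, 1]])
print(f"Ki67+ luminal A vs TN: p = {p:.2e}")

# overall subtype x Ki67 association over five subtype rows
res = fisher_exact_rxc([[96, 38], [23, 3], [10, 1], [47, 1], [13, 1]])
print(f"subtype x Ki67 ({res.method}, {res.n_tables} tables): p = {res.p:.2e}")

# recover 3 signatures from a synthetic 30-sample catalog
cfg = SimConfig(seed=11, n_samples=30, n_signatures=3,
                mutations_per_sample_mean=1000)
catalog, truth = simulate_catalog(cfg)
sel = select_rank(catalog, range(2, 7), n_runs=20, seed=7, max_iter=1000)
print(sel.curve.round(4).to_string(index=False))
best = sel.results[sel.rank].best_run
sig = SignatureSet(W=best.W, labels=["Sig.A", "Sig.B", "Sig.C"])
ref = ReferenceCatalog(matrix=truth.signatures, names=["true0", "true1", "true2"])
print(match_signatures(sig, ref).round(4).to_string(index=False))
```

prints

```
Ki67+ luminal A vs TN: p = 2.85e-05
subtype x Ki67 (enumeration, 94896 tables): p = 1.92e-04
 rank  cophenetic  signature_stability  best_objective
    2      0.9279               0.8859       3896.4524
    3      1.0000               0.9998       1038.8431
    4      0.9814               0.7361        962.0334
    5      0.9362               0.5461        897.1650
    6      0.9465               0.7403        842.4791
signature best_match  cosine  below_threshold
    Sig.A      true0  0.9991            False
    Sig.B      true1  0.9967            False
    Sig.C      true2  0.9982            False
```

The two exact tests recover the cohort's printed associations (Ki67
positivity is far lower in luminal A than in triple-negative tumors, and
differs across subtypes overall). In the simulation, the stability curve
identifies the true rank 3 — ranks 2 and 3 cluster samples equally
reproducibly (cophenetic ≈ 1), but only up to rank 3 is every *signature*
reproduced across restarts — and each recovered signature matches its
generating truth at cosine > 0.99.

A command-line layer mirrors the library: `premasig simulate`, `subtype`,
`assoc-table`, `filter`, `catalog`, `spectrum`, `extract`, `match`, `assoc`,
`enrich` (see `premasig --help`).

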