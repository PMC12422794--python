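# Methods

## Overview

`agealign` scores how strongly a disease's target-gene profile aligns with
the hallmarks of aging. The pipeline per disease:

1. **Target filtering.** Keep genes with association score strictly
   greater than `min_assoc` (default 0.4), sort by score (ties broken
   alphabetically for determinism), truncate to the top `top_k` (60).
2. **Resampling.** Draw `sample_size` (50) genes without replacement from
   the pool, `n_samples` (250) times. When the pool is not larger than the
   sample size every draw is the full pool (degenerate sampling; SD and CI
   widths are reported as exactly 0).
3. **Enrichment.** Each draw is tested against every library pathway with
   the one-sided hypergeometric upper tail P(X ≥ k); pathways with raw
   p < `enrich_alpha` (0.001, strict) form the enriched set. Query genes
   outside the universe are dropped and counted.
4. **Hallmark scoring.** Per hallmark, the −log10(p) mass of its enriched
   pathways, multiplied by the density normalizer N_h and the pathway-count
   bonus 1 + log2(|R_h|+1)/4. Multi-label pathways contribute fully to
   every hallmark they carry (no fractional splitting). An optional
   gene-level term (−log10 of the sample's overlap tail against a
   hallmark's annotated gene list, weight `w_genelist` = 0.25 vs. 1.0 for
   the pathway term) is added when a gene→hallmark map is supplied; it is
   formulated as an over-representation score so the two terms are
   commensurable.
5. **Diversity and total.** D_f = (N_nz/11)·(1 + E_n) with E_n the Shannon
   entropy (base 2) of the combined score distribution normalized by
   log2(11); A_d = (Σ combined scores)·D_f. D_f is scale-invariant and
   reaches 2 exactly for eleven equal positive hallmark scores; a single
   hallmark gives 1/11; all-zero scores give 0.
6. **Significance.** Per disease × hallmark cell, a p-value for "true
   hallmark score > 0", BH-corrected jointly across all cells of the study
   (one family; per-disease families behind a flag), NS flagged at
   q ≥ `q_threshold` (0.001).
7. **Normalization.** All reported scores are scaled to 0–100 relative to
   the maximum score achieved in sampling — separate denominators for
   partial and total scores, since the two live on different scales; both
   denominators are recorded in the run metadata.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `min_assoc` | 0.4 | strict lower bound on the association score (unitless, [0,1]) |
| `top_k` / `sample_size` / `n_samples` | 60 / 50 / 250 | resampling design |
| `enrich_alpha` | 0.001 | raw-p gate for the enriched set |
| `q_threshold` | 0.001 | NS threshold on BH q |
| `w_pathway` / `w_genelist` | 1.0 / 0.25 | term weights; the gene-list term is down-weighted for its lower annotation density |
| `n_perm` | 999 | permutation count (permutation method) |
| `normalizer_strategy` | `inverse_frequency` | N_h = mean count over populated hallmarks / C_h; `uniform` sets N_h = 1 |
| `significance_method` | `permutation` | or `sign` |
| `ci_method` | `percentile` | 2.5/97.5 empirical percentiles; `normal` gives mean ± 1.96·SD |

## Open design choices and their resolution

* **N_h concrete form.** Only the purpose of the normalizer (correcting
  uneven pathway annotation density) is fixed by the method's definition;
  this implementation uses inverse frequency scaled to mean 1
  (mean C over populated hallmarks ÷ C_h), the simplest form that
  equalizes expected contribution and reduces to N_h ≡ 1 under uniform
  annotation. A `uniform` strategy is selectable.
* **Entropy normalization.** E_n = H/log2(N_t) so that "all eleven
  hallmarks, even" gives E_n = 1 and D_f = 2. Normalizing by log2(N_nz)
  instead is available via `entropy_base_total=False`. Entropy is computed
  over non-zero proportions (identical to the 0·log 0 := 0 convention);
  proportions that underflow to zero are skipped.
* **Significance construction.** The hypothesis ("true hallmark score
  greater than zero") does not determine a test. Two are provided:
  - *Permutation*: score `n_perm` random gene sets of the analysis sample
    size, drawn uniformly from the library universe (testing against
    genomic background, not the disease's own pool), through the identical
    pipeline; add-one estimate p = (1 + #{null ≥ observed mean})/(1 + n_perm).
    Note the estimate is bounded below by 1/(n_perm+1): with the default
    999 permutations the smallest attainable p is 0.001, so q < 0.001
    after BH is unreachable — at that threshold this method can only
    ever report NS. It remains the assumption-free default for
    exploratory thresholds.
  - *Sign test*: p = P(Binom(n_samples, ½) ≥ #{resamples with score > 0}).
    Under the point null (score ≡ 0) this is conservative, but it can
    reach arbitrarily small p when a hallmark scores consistently, and it
    is the construction that makes the strict q < 0.001 reporting
    threshold operational.
* **BH family.** All disease × hallmark cells of a study jointly (one
  corrected panel); per-disease families behind `bh_per_disease`.
* **Enrichment gate.** Raw (unadjusted) p-values, strict inequality.
  BH is reserved for hallmark-level significance.
* **Numbers on disk.** 6 significant digits, fixed row order, sorted JSON
  keys — identical inputs and seed give byte-identical outputs.
  Randomness flows from per-disease substreams spawned from
  (seed, disease index), so results are independent of processing order.

## Synthetic worlds

The generator emulates the three inputs at desk scale: 2,000 genes, 20
pathways per hallmark of 10–50 genes (uniformly random memberships, 10%
of pathways carrying a second random hallmark label), and an 80-target
disease. Signal is planted at the membership level: each target is, with
probability equal to the planted strength, drawn from the planted
hallmark's pathway union, else uniformly from the universe. Planted
targets get association scores on [0.5, 1.0] so the 0.4 filter retains
them; background targets on [0.2, 1.0] so the filter is non-trivial. The
default planted strength is 0.75 — strong enough to dominate the target
pool while keeping the mixture, the filter, and the sampling variability
all active.

What these worlds do **not** emulate: GO topology (term overlap and
hierarchy), gene-length and annotation-density biases, correlated pathway
memberships, or realistic association-score distributions. A green test
on synthetic worlds therefore establishes that the statistical machinery
behaves as specified under a known signal model — not that the scores on
real Open Targets exports carry the same power.

A structural property of the planted model worth knowing: the planted
pathway union spans roughly 560 of the 2,000 genes, so a 50-gene sample
overlaps any single planted pathway in only ~2–5 genes, against a
p < 0.001 gate that typically needs 6–7. Detection therefore rides the
boundary of the gate, and in roughly 5–10% of world realizations no
planted pathway is ever gated — a property of the stated world geometry,
not of the planted strength (it persists at strength 1.0).

## Numerical notes

* Hypergeometric tails come from scipy's log-space survival function,
  floored at 1e-300 to keep p strictly positive; tails for repeated
  (N, K, n) triples are memoized so resampling reduces to table lookups.
* The tails match exact rational enumeration to < 1e-12; "exact"
  assertions in the worked example use that tolerance, since the rational
  oracle and the log-space routine round differently in the last float
  digit.
* Percentile CIs use numpy's default linear interpolation; SD uses ddof=1
  (0 for a single sample, with a warning).
* Result ordering ties are broken by pathway id; target-score ties by gene
  name.

## Known limitations

* No identifier mapping: gene symbols are matched after upper-casing
  only; orthologs and aliases are the caller's responsibility.
* The permutation significance method cannot certify q below
  1/(n_perm+1) (see above).
* Scores depend on annotation density; sparsely annotated hallmarks are
  up-weighted by N_h but remain noisier.
* The gene-list component is disabled unless a gene→hallmark map is
  provided; no attempt is made to derive one from the pathway map.
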