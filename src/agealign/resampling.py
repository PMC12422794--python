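"""The sampling design around the scores: repeated subsampling of the
high-evidence target pool (50 of the top 60, 250 times by default),
empirical confidence intervals, significance of non-zero hallmark scores,
joint Benjamini-Hochberg correction across disease x hallmark cells, and
cross-disease 0-100 normalization.

Significance of "hallmark score > 0" is the one part of the design the
formulas leave open. Two constructions are provided:

* ``permutation`` (default): score random same-size gene sets drawn from
  the library universe through the identical pipeline and report the
  add-one estimate p = (1 + #{null >= observed mean}) / (1 + n_perm). Note
  the estimate is bounded below by 1/(n_perm + 1), so very small q-value
  thresholds require correspondingly many permutations.
* ``sign``: a one-sided binomial sign test on the number of resampled
  score vectors with a strictly positive hallmark score,
  p = P(Binom(n_samples, 1/2) >= #positive). Cheap and able to reach
  arbitrarily small p when the hallmark scores consistently.

Determinism: all randomness flows from per-disease substreams spawned from
(config.seed, disease index), so results do not depend on processing order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom, norm as normal_dist

from .enrichment import bh_adjust
from .errors import ValidationError
from .hallmarks import HALLMARKS, N_HALLMARKS
from .io import GeneSetLibrary, HallmarkAnnotationMap, TargetAssociationTable
from .scoring import (
    ScoringConfig,
    hallmark_normalizers,
    score_sample,
    select_targets,
)


@dataclass
class SamplingSummary:
    """Per-disease aggregation over the resampled score vectors.

    Arrays are aligned on the fixed hallmark order. ``p``/``q``/``ns`` and
    the normalized fields are None until filled by ``significance_table``
    and ``normalize_scores``.
    """

    disease_id: str
    mean: np.ndarray
    sd: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    total_mean: float
    total_sd: float
    total_ci_low: float
    total_ci_high: float
    samples_partial: np.ndarray  # (n_samples, 11) raw per-sample partial scores
    samples_total: np.ndarray  # (n_samples,)
    n_samples: int
    seed: int
    disease_index: int = 0
    # instrumentation counters (design-constant conformance)
    n_ranked: int = 0
    n_passing_filter: int = 0
    draw_sizes: tuple[int, ...] = ()
    p: np.ndarray | None = None
    q: np.ndarray | None = None
    ns: np.ndarray | None = None
    norm_mean: np.ndarray | None = None
    norm_sd: np.ndarray | None = None
    norm_ci_low: np.ndarray | None = None
    norm_ci_high: np.ndarray | None = None
    norm_total_mean: float | None = None
    norm_total_sd: float | None = None
    norm_denominators: dict | None = None

    def __post_init__(self) -> None:
        if not (np.all(self.ci_low <= self.ci_high)):
            raise ValidationError("CI lower bound exceeds upper bound")


def _disease_rngs(seed: int, disease_index: int) -> tuple[np.random.Generator, np.random.Generator]:
    """Independent (sampling, permutation) streams for one disease."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(disease_index,))
    child_sampling, child_perm = ss.spawn(2)
    return np.random.default_rng(child_sampling), np.random.default_rng(child_perm)


def sample_targets(
    ranked: list[str],
    sample_size: int,
    rng: np.random.Generator,
) -> list[str]:
    """Uniform sample without replacement of min(sample_size, |ranked|)
    genes; degenerate (full list) when the pool is not larger than the
    sample size."""
    if not ranked:
        raise ValidationError("cannot sample from an empty ranked list")
    if len(ranked) <= sample_size:
        return list(ranked)
    idx = rng.choice(len(ranked), size=sample_size, replace=False)
    return [ranked[i] for i in sorted(idx)]


def _aggregate(samples: np.ndarray, ci_method: str) -> tuple[float, float, float, float]:
    if np.ptp(samples) == 0.0:
        # degenerate sampling (identical draws): SD exactly 0, CI width 0
        v = float(samples[0])
        return v, 0.0, v, v
    mean = float(np.mean(samples))
    sd = float(np.std(samples, ddof=1)) if samples.size > 1 else 0.0
    if ci_method == "normal":
        z = float(normal_dist.ppf(0.975))
        lo, hi = mean - z * sd, mean + z * sd
    else:
        lo = float(np.percentile(samples, 2.5))
        hi = float(np.percentile(samples, 97.5))
    return mean, sd, lo, hi


def run_sampling(
    table: TargetAssociationTable,
    library: GeneSetLibrary,
    ann: HallmarkAnnotationMap,
    config: ScoringConfig,
    disease_index: int = 0,
) -> SamplingSummary:
    """Repeat sample -> enrich -> score ``config.n_samples`` times and
    aggregate mean/SD/95% CI per hallmark and for the total. Every sampled
    score vector is stored for significance testing and normalization."""
    if config.n_samples < 1:
        raise ValidationError("n_samples must be >= 1")
    norms = hallmark_normalizers(library, ann, strategy=config.normalizer_strategy)
    passing = [g for g, s in table.rows if s > config.min_assoc]
    ranked = select_targets(table, config.min_assoc, config.top_k, config.sample_size)
    rng, _ = _disease_rngs(config.seed, disease_index)

    partials = np.zeros((config.n_samples, N_HALLMARKS))
    totals = np.zeros(config.n_samples)
    draw_sizes = []
    for i in range(config.n_samples):
        draw = sample_targets(ranked, config.sample_size, rng)
        draw_sizes.append(len(draw))
        vec = score_sample(draw, library, ann, norms, config, disease_id=table.disease_id)
        partials[i] = vec.partial_array()
        totals[i] = vec.total

    if config.n_samples == 1:
        warnings.warn(
            f"{table.disease_id!r}: n_samples=1, SD reported as 0", stacklevel=2
        )

    stats = [_aggregate(partials[:, j], config.ci_method) for j in range(N_HALLMARKS)]
    t_mean, t_sd, t_lo, t_hi = _aggregate(totals, config.ci_method)
    return SamplingSummary(
        disease_id=table.disease_id,
        mean=np.array([s[0] for s in stats]),
        sd=np.array([s[1] for s in stats]),
        ci_low=np.array([s[2] for s in stats]),
        ci_high=np.array([s[3] for s in stats]),
        total_mean=t_mean,
        total_sd=t_sd,
        total_ci_low=t_lo,
        total_ci_high=t_hi,
        samples_partial=partials,
        samples_total=totals,
        n_samples=config.n_samples,
        seed=config.seed,
        disease_index=disease_index,
        n_ranked=len(ranked),
        n_passing_filter=len(passing),
        draw_sizes=tuple(draw_sizes),
    )


def permutation_null_scores(
    library: GeneSetLibrary,
    ann: HallmarkAnnotationMap,
    config: ScoringConfig,
    sample_size: int,
    rng: np.random.Generator,
    n_perm: int | None = None,
) -> np.ndarray:
    """(n_perm, 11) matrix of partial hallmark scores of random gene sets
    drawn uniformly from the library universe — the permutation null,
    testing enrichment against genomic background rather than against the
    disease's own target pool."""
    n_perm = config.n_perm if n_perm is None else n_perm
    norms = hallmark_normalizers(library, ann, strategy=config.normalizer_strategy)
    genes = library.universe.genes
    out = np.zeros((n_perm, N_HALLMARKS))
    size = min(sample_size, len(genes))
    for i in range(n_perm):
        idx = rng.choice(len(genes), size=size, replace=False)
        vec = score_sample([genes[j] for j in idx], library, ann, norms, config)
        out[i] = vec.partial_array()
    return out


def permutation_significance(
    observed_mean: float,
    null_scores: np.ndarray,
) -> float:
    """Add-one permutation p-value: (1 + #{null >= observed}) / (1 + n_perm).

    An observed mean of 0 gives p = 1 (every null score is >= 0)."""
    null_scores = np.asarray(null_scores, dtype=float)
    n_perm = null_scores.size
    if n_perm < 1:
        raise ValidationError("need at least one permutation")
    return float((1 + np.sum(null_scores >= observed_mean)) / (1 + n_perm))


def sign_test_pvalue(samples: np.ndarray) -> float:
    """One-sided sign test on a hallmark's resampled scores: p =
    P(Binom(n, 1/2) >= #{samples > 0}). All-zero samples give p = 1."""
    samples = np.asarray(samples, dtype=float)
    n = samples.size
    s = int(np.sum(samples > 0))
    return float(binom.sf(s - 1, n, 0.5))


def attach_pvalues(
    summaries: list[SamplingSummary],
    library: GeneSetLibrary,
    ann: HallmarkAnnotationMap,
    config: ScoringConfig,
) -> list[SamplingSummary]:
    """Fill per-hallmark p-values on each summary using the configured
    significance construction."""
    for s in summaries:
        if config.significance_method == "sign":
            s.p = np.array(
                [sign_test_pvalue(s.samples_partial[:, j]) for j in range(N_HALLMARKS)]
            )
        else:
            _, perm_rng = _disease_rngs(config.seed, s.disease_index)
            null = permutation_null_scores(
                library, ann, config, sample_size=config.sample_size, rng=perm_rng
            )
            s.p = np.array(
                [
                    permutation_significance(float(s.mean[j]), null[:, j])
                    for j in range(N_HALLMARKS)
                ]
            )
    return summaries


def significance_table(
    summaries: list[SamplingSummary],
    config: ScoringConfig,
) -> list[SamplingSummary]:
    """Benjamini-Hochberg across disease x hallmark cells (one joint family
    by default, per-disease families behind ``bh_per_disease``) and the NS
    flag at q >= q_threshold."""
    for s in summaries:
        if s.p is None:
            raise ValidationError(f"{s.disease_id!r}: p-values missing; run attach_pvalues first")
    if config.bh_per_disease:
        for s in summaries:
            s.q = bh_adjust(s.p)
    else:
        flat = np.concatenate([s.p for s in summaries])
        q = bh_adjust(flat)
        for i, s in enumerate(summaries):
            s.q = q[i * N_HALLMARKS: (i + 1) * N_HALLMARKS]
    for s in summaries:
        s.ns = s.q >= config.q_threshold
    return summaries


def normalize_scores(summaries: list[SamplingSummary]) -> list[SamplingSummary]:
    """Scale scores relative to the maximal score achieved in sampling:
    per-hallmark statistics by the global maximum sampled partial score,
    totals by the global maximum sampled total, both x100. The two
    denominators are separate because partial and total scores live on
    different scales; both are recorded on every summary."""
    if not summaries:
        raise ValidationError("no summaries to normalize")
    max_partial = max(float(s.samples_partial.max()) for s in summaries)
    max_total = max(float(s.samples_total.max()) for s in summaries)
    if max_partial == 0.0 or max_total == 0.0:
        warnings.warn("all sampled scores are zero; normalized scores set to 0", stacklevel=2)
    denom_p = max_partial if max_partial > 0 else 1.0
    denom_t = max_total if max_total > 0 else 1.0
    for s in summaries:
        s.norm_mean = s.mean / denom_p * 100.0
        s.norm_sd = s.sd / denom_p * 100.0
        s.norm_ci_low = s.ci_low / denom_p * 100.0
        s.norm_ci_high = s.ci_high / denom_p * 100.0
        s.norm_total_mean = s.total_mean / denom_t * 100.0
        s.norm_total_sd = s.total_sd / denom_t * 100.0
        s.norm_denominators = {"max_partial": max_partial, "max_total": max_total}
    return summaries
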