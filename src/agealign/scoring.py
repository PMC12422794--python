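"""Hallmark scoring: from one gene sample's enriched pathways to the
per-hallmark partial scores, the diversity factor, and the total
aging-alignment score.

For hallmark ``h`` with enriched, h-annotated pathways R_h:

    P_h = [sum_{p in R_h} -log10(p_p)] * N_h * (1 + log2(|R_h| + 1) / 4)

where N_h corrects for uneven pathway annotation density across hallmarks
and the final factor is a gentle bonus for hallmarks supported by several
independent pathways rather than one.

The total score is the combined hallmark mass scaled by a diversity factor

    D_f = (N_nz / N_t) * (1 + E_n),      A_d = (sum_h combined_h) * D_f

with N_nz the number of non-zero hallmark scores, N_t the vocabulary size
(11) and E_n the normalized Shannon entropy (base 2) of the hallmark score
distribution. D_f rewards diseases whose aging signal is spread across many
hallmarks over single-hallmark ones; it reaches 2 exactly when all N_t
hallmarks score equally, and 1/N_t for a single-hallmark disease.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .enrichment import EnrichedSet, hypergeometric_upper_tail
from .errors import DomainError, ValidationError
from .hallmarks import HALLMARKS, N_HALLMARKS
from .io import GeneSetLibrary, GeneUniverse, HallmarkAnnotationMap, TargetAssociationTable


@dataclass(frozen=True)
class ScoringConfig:
    """Pipeline constants. Defaults mirror the published design: strict
    association filter at 0.4, top-60 pool, 50-gene samples repeated 250
    times, enrichment gate p < 0.001, NS at q >= 0.001."""

    min_assoc: float = 0.4
    top_k: int = 60
    sample_size: int = 50
    n_samples: int = 250
    enrich_alpha: float = 0.001
    q_threshold: float = 0.001
    w_pathway: float = 1.0
    w_genelist: float = 0.25
    n_perm: int = 999
    seed: int = 0
    entropy_base_total: bool = True
    normalizer_strategy: str = "inverse_frequency"  # or "uniform"
    significance_method: str = "permutation"  # or "sign"
    ci_method: str = "percentile"  # or "normal"
    bh_per_disease: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_assoc <= 1.0):
            raise ValidationError("min_assoc outside [0, 1]")
        if self.sample_size > self.top_k:
            raise ValidationError("sample_size exceeds top_k")
        if min(self.w_pathway, self.w_genelist) < 0:
            raise ValidationError("weights must be non-negative")
        if self.normalizer_strategy not in {"inverse_frequency", "uniform"}:
            raise ValidationError(f"unknown normalizer strategy {self.normalizer_strategy!r}")
        if self.significance_method not in {"permutation", "sign"}:
            raise ValidationError(f"unknown significance method {self.significance_method!r}")
        if self.ci_method not in {"percentile", "normal"}:
            raise ValidationError(f"unknown CI method {self.ci_method!r}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class HallmarkNormalizers:
    """Per-hallmark pathway counts C_h and weights N_h.

    N_h = mean(C over populated hallmarks) / C_h, so a hallmark annotated
    to few pathways is up-weighted and all N_h equal 1 when annotation is
    uniform; N_h = 0 exactly when C_h = 0 (that hallmark can never score).
    """

    counts: dict[str, int]
    weights: dict[str, float]

    def __post_init__(self) -> None:
        for h in HALLMARKS:
            c, w = self.counts[h], self.weights[h]
            if (c == 0) != (w == 0.0):
                raise ValidationError(f"{h}: N_h must be zero exactly when C_h is zero")


@dataclass(frozen=True)
class HallmarkScoreVector:
    """Everything computed for one gene sample: P_h, |R_h|, optional
    gene-list components G_h, combined scores, D_f and the total A_d."""

    partial: dict[str, float]
    r_counts: dict[str, int]
    genelist: dict[str, float]
    combined: dict[str, float]
    d_f: float
    n_nz: int
    e_n: float
    total: float
    genelist_enabled: bool = False

    def partial_array(self) -> np.ndarray:
        return np.array([self.partial[h] for h in HALLMARKS])

    def combined_array(self) -> np.ndarray:
        return np.array([self.combined[h] for h in HALLMARKS])


def select_targets(
    table: TargetAssociationTable,
    min_assoc: float = 0.4,
    top_k: int = 60,
    sample_size: int | None = None,
) -> list[str]:
    """High-evidence target pool: strict ``score > min_assoc`` filter,
    sorted by (score descending, gene ascending), truncated to ``top_k``.

    Returns a shorter list when fewer genes pass (warning if fewer than
    ``sample_size`` remain); zero passing genes is an error.
    """
    passing = [(g, s) for g, s in table.rows if s > min_assoc]
    if not passing:
        raise ValidationError(
            f"{table.disease_id!r}: no high-evidence targets (score > {min_assoc})"
        )
    passing.sort(key=lambda gs: (-gs[1], gs[0]))
    ranked = [g for g, _ in passing[:top_k]]
    if sample_size is not None and len(ranked) < sample_size:
        warnings.warn(
            f"{table.disease_id!r}: only {len(ranked)} targets pass the filter, "
            f"fewer than the sample size {sample_size}; sampling degenerates",
            stacklevel=2,
        )
    return ranked


def hallmark_normalizers(
    library: GeneSetLibrary,
    ann: HallmarkAnnotationMap,
    strategy: str = "inverse_frequency",
) -> HallmarkNormalizers:
    """Compute C_h (library pathways annotated to h) and N_h.

    ``inverse_frequency``: N_h = mean(C over populated hallmarks) / C_h.
    ``uniform``: N_h = 1 wherever C_h > 0.
    """
    known = set(library.sets)
    counts = {h: 0 for h in HALLMARKS}
    for pid, labels in ann.pathway_map.items():
        if pid not in known:
            continue
        for h in labels:
            counts[h] += 1
    populated = [c for c in counts.values() if c > 0]
    if not populated:
        raise ValidationError("no library pathway carries a hallmark annotation")
    if strategy == "uniform":
        weights = {h: (1.0 if c > 0 else 0.0) for h, c in counts.items()}
    elif strategy == "inverse_frequency":
        mean_c = float(np.mean(populated))
        weights = {h: (mean_c / c if c > 0 else 0.0) for h, c in counts.items()}
    else:
        raise ValidationError(f"unknown normalizer strategy {strategy!r}")
    return HallmarkNormalizers(counts=counts, weights=weights)


def partial_hallmark_scores(
    enriched: EnrichedSet,
    ann: HallmarkAnnotationMap,
    norms: HallmarkNormalizers,
) -> tuple[dict[str, float], dict[str, int]]:
    """P_h and |R_h| per hallmark for one enriched set.

    A multi-label pathway contributes fully to every hallmark it carries;
    hallmarks with empty R_h score 0. Invariant under pathway relabeling
    and enumeration order (the inner sum is commutative).
    """
    neglog: dict[str, list[float]] = {h: [] for h in HALLMARKS}
    for res in enriched.results:
        labels = ann.pathway_map.get(res.pathway_id)
        if not labels:
            continue
        v = -math.log10(res.p_value)
        for h in labels:
            neglog[h].append(v)
    partial: dict[str, float] = {}
    r_counts: dict[str, int] = {}
    for h in HALLMARKS:
        r = len(neglog[h])
        r_counts[h] = r
        if r == 0:
            partial[h] = 0.0
        else:
            bonus = 1.0 + math.log2(r + 1) / 4.0
            partial[h] = sum(neglog[h]) * norms.weights[h] * bonus
    return partial, r_counts


def genelist_component(
    sample,
    ann: HallmarkAnnotationMap,
    universe: GeneUniverse,
) -> tuple[dict[str, float], bool]:
    """Optional gene-level term: G_h = -log10 of the hypergeometric upper
    tail of the sample's overlap with hallmark h's annotated gene list,
    0 when there is no overlap. Disabled (all zeros) without a gene map.
    """
    if ann.gene_map is None:
        return {h: 0.0 for h in HALLMARKS}, False
    bg = universe.as_set()
    eff = {str(g).strip().upper() for g in sample} & bg
    N = len(universe)
    n = len(eff)
    out: dict[str, float] = {}
    for h in HALLMARKS:
        genes_h = ann.genes_for(h) & bg
        K = len(genes_h)
        k = len(eff & genes_h)
        if k == 0 or K == 0 or n == 0:
            out[h] = 0.0
        else:
            out[h] = -math.log10(hypergeometric_upper_tail(k, K, n, N))
    return out, True


def diversity_factor(
    scores,
    n_t: int = N_HALLMARKS,
    entropy_base_total: bool = True,
) -> tuple[float, int, float]:
    """D_f = (N_nz / N_t) * (1 + E_n); returns (D_f, N_nz, E_n).

    E_n is the Shannon entropy (bits) of the score proportions normalized
    by log2(N_t) (default) or by log2(N_nz) when ``entropy_base_total`` is
    off. All-zero scores give D_f = 0. Scale-invariant in the scores.
    """
    s = np.asarray([scores[h] for h in HALLMARKS] if isinstance(scores, dict) else list(scores),
                   dtype=float)
    if n_t < 1:
        raise DomainError("n_t must be >= 1")
    if np.any(s < 0):
        raise DomainError("hallmark scores must be non-negative")
    nz = s[s > 0]
    n_nz = int(nz.size)
    if n_nz == 0:
        return 0.0, 0, 0.0
    q = nz / nz.sum()
    q = q[q > 0]  # guard against underflow of extreme score ratios
    h_bits = float(-(q * np.log2(q)).sum())
    denom = math.log2(n_t) if entropy_base_total else (math.log2(n_nz) if n_nz > 1 else 0.0)
    e_n = h_bits / denom if denom > 0 else 0.0
    d_f = (n_nz / n_t) * (1.0 + e_n)
    return d_f, n_nz, e_n


def total_score(
    partials: dict[str, float],
    genelists: dict[str, float] | None = None,
    config: ScoringConfig | None = None,
    genelist_enabled: bool = False,
    r_counts: dict[str, int] | None = None,
) -> HallmarkScoreVector:
    """Combine the pathway and gene-list terms, weight by the diversity
    factor and return the full score vector:

        combined_h = w_pathway * P_h + w_genelist * G_h
        A_d = (sum_h combined_h) * D_f
    """
    cfg = config or ScoringConfig()
    gl = genelists or {h: 0.0 for h in HALLMARKS}
    combined = {
        h: cfg.w_pathway * partials.get(h, 0.0) + cfg.w_genelist * gl.get(h, 0.0)
        for h in HALLMARKS
    }
    d_f, n_nz, e_n = diversity_factor(
        combined, n_t=N_HALLMARKS, entropy_base_total=cfg.entropy_base_total
    )
    total = sum(combined.values()) * d_f
    return HallmarkScoreVector(
        partial={h: partials.get(h, 0.0) for h in HALLMARKS},
        r_counts={h: (r_counts or {}).get(h, 0) for h in HALLMARKS},
        genelist={h: gl.get(h, 0.0) for h in HALLMARKS},
        combined=combined,
        d_f=d_f,
        n_nz=n_nz,
        e_n=e_n,
        total=total,
        genelist_enabled=genelist_enabled,
    )


def score_sample(
    sample,
    library: GeneSetLibrary,
    ann: HallmarkAnnotationMap,
    norms: HallmarkNormalizers,
    config: ScoringConfig,
    disease_id: str = "",
) -> HallmarkScoreVector:
    """Full single-sample pipeline: enrich -> P_h (+ optional gene-list
    component) -> D_f -> A_d. The unit of work the resampler repeats."""
    from .enrichment import enrich  # local import avoids a cycle at module load

    enriched = enrich(sample, library, alpha=config.enrich_alpha, disease_id=disease_id)
    partial, r_counts = partial_hallmark_scores(enriched, ann, norms)
    if ann.gene_map is not None and config.w_genelist > 0:
        gl, enabled = genelist_component(sample, ann, library.universe)
    else:
        gl, enabled = {h: 0.0 for h in HALLMARKS}, False
    return total_score(partial, gl, config, genelist_enabled=enabled, r_counts=r_counts)
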