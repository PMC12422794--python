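import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from agealign import (
    DomainError,
    GeneSetLibrary,
    HallmarkAnnotationMap,
    ScoringConfig,
    TargetAssociationTable,
    ValidationError,
    diversity_factor,
    genelist_component,
    hallmark_normalizers,
    partial_hallmark_scores,
    select_targets,
    total_score,
)
from agealign.enrichment import EnrichedSet, EnrichmentResult
from agealign.hallmarks import HALLMARKS

from oracles import diversity_oracle, partial_score_oracle, total_oracle

SEN = "cellular senescence"
INF = "chronic inflammation"


def _table(pairs, disease="D"):
    return TargetAssociationTable(disease_id=disease, rows=tuple(pairs))


def _enriched(pvals: dict[str, float], alpha=0.001):
    results = tuple(
        EnrichmentResult(
            pathway_id=pid, overlap_k=1, set_size_K=10, query_size_n=10,
            universe_size_N=100, p_value=p,
        )
        for pid, p in sorted(pvals.items(), key=lambda kv: kv[1])
    )
    return EnrichedSet(disease_id="D", results=results, alpha=alpha)


class TestSelectTargets:
    def test_top_k_with_alphabetical_tiebreak(self):
        t = _table((f"G{i:03d}", 0.9) for i in range(100))
        ranked = select_targets(t, 0.4, 60)
        assert len(ranked) == 60
        assert ranked == sorted(ranked)

    def test_threshold_is_strict(self):
        t = _table([("A", 0.4), ("B", 0.41)])
        assert select_targets(t, 0.4, 60) == ["B"]

    def test_fewer_than_sample_size_warns(self):
        t = _table([(f"G{i}", 0.5) for i in range(45)] + [(f"H{i}", 0.3) for i in range(10)])
        with pytest.warns(UserWarning, match="fewer than the sample size"):
            ranked = select_targets(t, 0.4, 60, sample_size=50)
        assert len(ranked) == 45

    def test_no_passing_targets_is_error(self):
        t = _table([("A", 0.1)])
        with pytest.raises(ValidationError, match="no high-evidence"):
            select_targets(t, 0.4, 60)

    def test_sorted_by_score_then_gene(self):
        t = _table([("B", 0.8), ("A", 0.9), ("C", 0.8)])
        assert select_targets(t, 0.4, 60) == ["A", "B", "C"]


class TestHallmarkNormalizers:
    def _world(self, counts):
        sets, pmap = {}, {}
        i = 0
        for h, c in counts.items():
            for _ in range(c):
                pid = f"PW{i}"
                sets[pid] = [f"G{i}a", f"G{i}b"]
                pmap[pid] = frozenset({h})
                i += 1
        lib = GeneSetLibrary.from_dict(sets)
        return lib, HallmarkAnnotationMap(pathway_map=pmap)

    def test_uniform_counts_give_unit_weights(self):
        lib, ann = self._world({h: 3 for h in HALLMARKS})
        norms = hallmark_normalizers(lib, ann)
        assert all(norms.weights[h] == pytest.approx(1.0) for h in HALLMARKS)

    def test_inverse_frequency(self):
        lib, ann = self._world({SEN: 10, INF: 30})
        norms = hallmark_normalizers(lib, ann)
        assert norms.weights[SEN] == pytest.approx(2.0)
        assert norms.weights[INF] == pytest.approx(2 / 3)

    def test_zero_count_hallmark_gets_zero_weight(self):
        lib, ann = self._world({SEN: 4})
        norms = hallmark_normalizers(lib, ann)
        assert norms.weights[INF] == 0.0 and norms.counts[INF] == 0

    def test_no_annotations_is_error(self):
        lib = GeneSetLibrary.from_dict({"PW1": ["A", "B"]})
        ann = HallmarkAnnotationMap(pathway_map={})
        with pytest.raises(ValidationError):
            hallmark_normalizers(lib, ann)


class TestPartialHallmarkScores:
    @pytest.fixture()
    def ann(self):
        return HallmarkAnnotationMap(
            pathway_map={
                "P1": frozenset({SEN}),
                "P2": frozenset({SEN}),
                "P3": frozenset({SEN, INF}),
            }
        )

    @pytest.fixture()
    def norms(self):
        from agealign import HallmarkNormalizers

        counts = {h: 0 for h in HALLMARKS}
        counts[SEN], counts[INF] = 3, 1
        weights = {h: 0.0 for h in HALLMARKS}
        weights[SEN] = weights[INF] = 1.0
        return HallmarkNormalizers(counts=counts, weights=weights)

    def test_two_pathway_example(self, ann, norms):
        partial, rc = partial_hallmark_scores(
            _enriched({"P1": 1e-4, "P2": 1e-5}), ann, norms
        )
        assert partial[SEN] == pytest.approx(9 * (1 + math.log2(3) / 4), rel=1e-12)
        assert rc[SEN] == 2 and partial[INF] == 0.0

    def test_single_pathway_closed_form(self, ann, norms):
        p = 1e-3 * (1 - 1e-9)
        partial, _ = partial_hallmark_scores(_enriched({"P1": p}), ann, norms)
        assert partial[SEN] == pytest.approx(-math.log10(p) * 1.25, rel=1e-9)

    def test_multilabel_contributes_to_every_hallmark(self, ann, norms):
        partial, rc = partial_hallmark_scores(_enriched({"P3": 1e-4}), ann, norms)
        assert partial[SEN] == partial[INF] > 0
        assert rc[SEN] == rc[INF] == 1

    def test_empty_r_h_scores_zero(self, ann, norms):
        partial, rc = partial_hallmark_scores(_enriched({}), ann, norms)
        assert all(v == 0.0 for v in partial.values())

    def test_adding_a_pathway_strictly_increases(self, ann, norms):
        p1, _ = partial_hallmark_scores(_enriched({"P1": 1e-4}), ann, norms)
        p2, _ = partial_hallmark_scores(_enriched({"P1": 1e-4, "P2": 5e-4}), ann, norms)
        assert p2[SEN] > p1[SEN]

    @given(
        st.lists(st.floats(1e-10, 9e-4), min_size=0, max_size=6),
        st.floats(0.1, 5.0),
    )
    def test_matches_oracle(self, ps, w):
        from agealign import HallmarkNormalizers

        counts = {h: 0 for h in HALLMARKS}
        weights = {h: 0.0 for h in HALLMARKS}
        counts[SEN], weights[SEN] = max(1, len(ps)), w
        norms = HallmarkNormalizers(counts=counts, weights=weights)
        ann = HallmarkAnnotationMap(
            pathway_map={f"Q{i}": frozenset({SEN}) for i in range(len(ps))}
        )
        enriched = _enriched({f"Q{i}": p for i, p in enumerate(ps)})
        partial, _ = partial_hallmark_scores(enriched, ann, norms)
        assert partial[SEN] == pytest.approx(partial_score_oracle(ps, w), rel=1e-12, abs=1e-12)


class TestGenelistComponent:
    def test_disabled_without_gene_map(self):
        ann = HallmarkAnnotationMap(pathway_map={"P1": frozenset({SEN})})
        lib = GeneSetLibrary.from_dict({"P1": [f"G{i:02d}" for i in range(20)]})
        g, enabled = genelist_component(["G00"], ann, lib.universe)
        assert not enabled and all(v == 0.0 for v in g.values())

    def test_full_containment_matches_combinatorial_oracle(self):
        genes = [f"G{i:02d}" for i in range(20)]
        ann = HallmarkAnnotationMap(
            pathway_map={"P1": frozenset({SEN})},
            gene_map={g: frozenset({SEN}) for g in genes[:5]},
        )
        lib = GeneSetLibrary.from_dict({"P1": genes})
        g, enabled = genelist_component(genes[:5], ann, lib.universe)
        assert enabled
        assert g[SEN] == pytest.approx(math.log10(15504), rel=1e-12)
        assert g[INF] == 0.0  # zero overlap -> p = 1 -> score 0


class TestDiversityFactor:
    def test_uniform_eleven_gives_two(self):
        d, n_nz, e_n = diversity_factor({h: 3.3 for h in HALLMARKS})
        assert (d, n_nz, e_n) == pytest.approx((2.0, 11, 1.0))

    def test_point_mass(self):
        scores = {h: 0.0 for h in HALLMARKS}
        scores[SEN] = 5.0
        d, n_nz, e_n = diversity_factor(scores)
        assert d == pytest.approx(1 / 11) and n_nz == 1 and e_n == 0.0

    def test_two_equal_hallmarks(self):
        scores = {h: 0.0 for h in HALLMARKS}
        scores[SEN] = scores[INF] = 9.0
        d, _, _ = diversity_factor(scores)
        assert d == pytest.approx((2 / 11) * (1 + 1 / math.log2(11)), rel=1e-12)
        assert d == pytest.approx(0.234375, abs=5e-7)

    def test_all_zero(self):
        assert diversity_factor({h: 0.0 for h in HALLMARKS}) == (0.0, 0, 0.0)

    def test_negative_scores_rejected(self):
        scores = {h: 0.0 for h in HALLMARKS}
        scores[SEN] = -1.0
        with pytest.raises(DomainError):
            diversity_factor(scores)

    @given(st.lists(st.floats(0, 100, allow_subnormal=False), min_size=11, max_size=11))
    def test_matches_oracle_and_bounds(self, scores):
        d, n_nz, _ = diversity_factor(scores)
        assert d == pytest.approx(diversity_oracle(scores), rel=1e-12, abs=1e-12)
        if any(s > 0 for s in scores):
            assert 0 < d <= 2.0 + 1e-12
        else:
            assert d == 0.0

    @given(st.lists(st.floats(1e-3, 100), min_size=1, max_size=11), st.floats(1e-3, 1e3))
    def test_scale_invariance(self, nz, c):
        scores = nz + [0.0] * (11 - len(nz))
        d1, _, _ = diversity_factor(scores)
        d2, _, _ = diversity_factor([c * s for s in scores])
        assert d1 == pytest.approx(d2, rel=1e-9)


class TestTotalScore:
    def test_two_equal_combined(self):
        partials = {h: 0.0 for h in HALLMARKS}
        partials[SEN] = partials[INF] = 9.0
        vec = total_score(partials, None, ScoringConfig(w_genelist=0.0))
        assert vec.total == pytest.approx(18 * 0.234375, abs=1e-4)
        assert vec.total == pytest.approx(total_oracle(list(vec.combined.values())), rel=1e-12)

    def test_all_zero(self):
        vec = total_score({h: 0.0 for h in HALLMARKS})
        assert vec.total == 0.0 and vec.d_f == 0.0

    def test_genelist_weighting(self):
        partials = {h: 0.0 for h in HALLMARKS}
        gl = {h: 0.0 for h in HALLMARKS}
        partials[SEN], gl[SEN] = 4.0, 2.0
        vec = total_score(partials, gl, ScoringConfig(w_pathway=1.0, w_genelist=0.25))
        assert vec.combined[SEN] == pytest.approx(4.5)

    @given(st.lists(st.floats(0, 50, allow_subnormal=False), min_size=11, max_size=11), st.floats(0.1, 10))
    def test_scaling_combined_scales_total_linearly(self, scores, c):
        partials = dict(zip(HALLMARKS, scores))
        scaled = {h: c * v for h, v in partials.items()}
        cfg = ScoringConfig(w_genelist=0.0)
        v1, v2 = total_score(partials, None, cfg), total_score(scaled, None, cfg)
        assert v2.d_f == pytest.approx(v1.d_f, rel=1e-9)
        assert v2.total == pytest.approx(c * v1.total, rel=1e-9)

    @given(st.lists(st.floats(0, 50, allow_subnormal=False), min_size=11, max_size=11))
    def test_matches_one_line_oracle(self, scores):
        partials = dict(zip(HALLMARKS, scores))
        vec = total_score(partials, None, ScoringConfig(w_genelist=0.0))
        assert vec.total == pytest.approx(
            total_oracle(scores), rel=1e-12, abs=1e-12
        )


class TestScoringConfig:
    def test_defaults_mirror_published_design(self):
        cfg = ScoringConfig()
        assert (cfg.min_assoc, cfg.top_k, cfg.sample_size, cfg.n_samples) == (0.4, 60, 50, 250)
        assert (cfg.enrich_alpha, cfg.q_threshold) == (0.001, 0.001)
        assert cfg.w_genelist < cfg.w_pathway

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValidationError):
            ScoringConfig(sample_size=70, top_k=60)
        with pytest.raises(ValidationError):
            ScoringConfig(min_assoc=1.5)
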