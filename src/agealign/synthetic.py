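"""Self-contained synthetic input worlds: a gene universe, a pathway
library, hallmark annotations and a disease target table with controlled
hallmark-specific signal.

Signal is planted at the membership level — targets are drawn from a
planted hallmark's pathway union with a given mixture probability — so the
entire statistical chain (filtering, sampling, enrichment, scoring,
significance) is exercised honestly rather than by rigging p-values.
Planted targets receive association scores on [0.5, 1.0] so the strict
0.4 evidence filter retains them; background targets draw from [0.2, 1.0]
so the filter is non-trivial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .hallmarks import HALLMARKS
from .io import (
    GeneSetLibrary,
    HallmarkAnnotationMap,
    TargetAssociationTable,
    write_gmt,
    write_target_table,
)
from .scoring import ScoringConfig

#: Default mixture probability for a planted hallmark: strong enough that
#: the planted signal dominates the target pool, weak enough that the
#: background mixture and the evidence filter still matter.
DEFAULT_PLANTED_STRENGTH = 0.75


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic world. Defaults give a desk-scale analog
    of a GO:BP slice: 2,000 genes, 20 pathways per hallmark of 10-50 genes
    each, an 80-target disease."""

    n_genes: int = 2000
    pathways_per_hallmark: int | dict[str, int] = 20
    pathway_size_range: tuple[int, int] = (10, 50)
    planted_hallmarks: dict[str, float] = field(default_factory=dict)
    n_targets: int = 80
    multi_label_fraction: float = 0.1
    background_score_range: tuple[float, float] = (0.2, 1.0)
    planted_score_range: tuple[float, float] = (0.5, 1.0)
    disease_id: str = "SYNTHETIC_DISEASE"
    seed: int = 0

    def counts(self) -> dict[str, int]:
        if isinstance(self.pathways_per_hallmark, dict):
            return {h: int(self.pathways_per_hallmark.get(h, 0)) for h in HALLMARKS}
        return {h: int(self.pathways_per_hallmark) for h in HALLMARKS}

    def __post_init__(self) -> None:
        if self.n_targets > self.n_genes:
            raise ValidationError("n_targets exceeds n_genes")
        if self.pathway_size_range[1] > self.n_genes:
            raise ValidationError(
                f"pathway size {self.pathway_size_range[1]} exceeds universe size {self.n_genes}"
            )
        if self.pathway_size_range[0] < 1:
            raise ValidationError("pathway sizes must be >= 1")
        for h, s in self.planted_hallmarks.items():
            if h not in HALLMARKS:
                raise ValidationError(f"planted hallmark {h!r} not in the vocabulary")
            if not (0.0 <= s <= 1.0):
                raise ValidationError(f"planted strength {s} outside [0, 1]")


def make_world(
    spec: FixtureSpec,
) -> tuple[GeneSetLibrary, HallmarkAnnotationMap, TargetAssociationTable]:
    """Generate a (library, annotation map, target table) triple.

    Genes are named G0001...; each pathway carries its generating hallmark
    and, with probability ``multi_label_fraction``, one extra label. Each
    target is, with probability equal to the planted strength, drawn from
    the planted hallmark's pathway union, otherwise uniformly from the
    universe. Fully deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    width = max(4, len(str(spec.n_genes)))
    genes = tuple(f"G{i + 1:0{width}d}" for i in range(spec.n_genes))

    sets: dict[str, list[str]] = {}
    pathway_map: dict[str, frozenset[str]] = {}
    lo, hi = spec.pathway_size_range
    pid_counter = 0
    for h_idx, h in enumerate(HALLMARKS):
        for _ in range(spec.counts()[h]):
            pid_counter += 1
            pid = f"PW{pid_counter:04d}"
            size = int(rng.integers(lo, hi + 1))
            members = rng.choice(spec.n_genes, size=size, replace=False)
            sets[pid] = [genes[j] for j in members]
            labels = {h}
            if rng.random() < spec.multi_label_fraction:
                extra = HALLMARKS[int(rng.integers(0, len(HALLMARKS)))]
                labels.add(extra)
            pathway_map[pid] = frozenset(labels)
    if not sets:
        raise ValidationError("spec generates no pathways")

    library = GeneSetLibrary.from_dict(sets, universe=genes)
    ann = HallmarkAnnotationMap(pathway_map=pathway_map)
    table = _draw_targets(
        library, ann, rng,
        planted_hallmarks=spec.planted_hallmarks,
        n_targets=spec.n_targets,
        background_score_range=spec.background_score_range,
        planted_score_range=spec.planted_score_range,
        disease_id=spec.disease_id,
    )
    return library, ann, table


def _draw_targets(
    library: GeneSetLibrary,
    ann: HallmarkAnnotationMap,
    rng: np.random.Generator,
    planted_hallmarks: dict[str, float],
    n_targets: int,
    background_score_range: tuple[float, float],
    planted_score_range: tuple[float, float],
    disease_id: str,
) -> TargetAssociationTable:
    genes = library.universe.genes
    # Planted-hallmark pathway unions (sorted for determinism).
    unions = {
        h: sorted(set().union(*(library.members(p) for p in ann.pathways_for(h))))
        for h in planted_hallmarks
        if ann.pathways_for(h)
    }
    planted_list = sorted(planted_hallmarks)

    chosen: dict[str, float] = {}
    b_lo, b_hi = background_score_range
    p_lo, p_hi = planted_score_range
    guard = 0
    while len(chosen) < n_targets:
        guard += 1
        if guard > 100 * n_targets:
            raise ValidationError("could not draw enough unique target genes")
        planted = False
        gene = None
        if planted_list:
            h = planted_list[int(rng.integers(0, len(planted_list)))]
            if h in unions and rng.random() < planted_hallmarks[h]:
                pool = unions[h]
                gene = pool[int(rng.integers(0, len(pool)))]
                planted = True
        if gene is None:
            gene = genes[int(rng.integers(0, len(genes)))]
        if gene in chosen:
            continue
        if planted:
            chosen[gene] = float(rng.uniform(p_lo, p_hi))
        else:
            chosen[gene] = float(rng.uniform(b_lo, b_hi))

    return TargetAssociationTable(disease_id=disease_id, rows=tuple(chosen.items()))


def make_targets(
    library: GeneSetLibrary,
    ann: HallmarkAnnotationMap,
    planted_hallmarks: dict[str, float] | None = None,
    n_targets: int = 80,
    seed: int = 0,
    disease_id: str = "SYNTHETIC_DISEASE",
    background_score_range: tuple[float, float] = (0.2, 1.0),
    planted_score_range: tuple[float, float] = (0.5, 1.0),
) -> TargetAssociationTable:
    """Draw a disease target table against an *existing* world, so several
    diseases with different planted hallmarks can share one library —
    required whenever they are to be scored in the same study."""
    rng = np.random.default_rng(seed)
    return _draw_targets(
        library, ann, rng,
        planted_hallmarks=planted_hallmarks or {},
        n_targets=n_targets,
        background_score_range=background_score_range,
        planted_score_range=planted_score_range,
        disease_id=disease_id,
    )


def planted_world(
    hallmark: str = "cellular senescence",
    strength: float = DEFAULT_PLANTED_STRENGTH,
    seed: int = 0,
    **overrides,
) -> tuple[GeneSetLibrary, HallmarkAnnotationMap, TargetAssociationTable]:
    """World with exactly one planted hallmark at the default strength."""
    spec = FixtureSpec(planted_hallmarks={hallmark: strength}, seed=seed, **overrides)
    return make_world(spec)


def null_world(
    seed: int = 0, **overrides
) -> tuple[GeneSetLibrary, HallmarkAnnotationMap, TargetAssociationTable]:
    """World with no planted signal: targets uniform over the universe."""
    spec = FixtureSpec(planted_hallmarks={}, seed=seed, **overrides)
    return make_world(spec)


def write_world(
    library: GeneSetLibrary,
    ann: HallmarkAnnotationMap,
    table: TargetAssociationTable,
    out_dir,
) -> dict[str, str]:
    """Materialize a world as the same GMT/TSV dialects the readers accept."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gmt = out_dir / "library.gmt"
    annp = out_dir / "hallmark_annotations.tsv"
    tgt = out_dir / f"targets_{table.disease_id}.tsv"
    write_gmt(library, gmt)
    with annp.open("w") as fh:
        fh.write("pathway_id\thallmark\n")
        for pid in sorted(ann.pathway_map):
            for h in sorted(ann.pathway_map[pid]):
                fh.write(f"{pid}\t{h}\n")
    write_target_table(table, tgt)
    return {"library": str(gmt), "annotations": str(annp), "targets": str(tgt)}


# ---------------------------------------------------------------------------
# The fixed micro-world behind the documented worked example
# ---------------------------------------------------------------------------

def worked_example_world() -> tuple[GeneSetLibrary, HallmarkAnnotationMap, TargetAssociationTable]:
    """Hard-coded 20-gene universe, 4 pathways across 2 hallmarks, and a
    7-target disease whose full pipeline outputs (every enrichment p, each
    P_h, D_f, A_d) are small enough to verify by exact enumeration.

    With the worked-example config (alpha = 0.1, no subsampling
    variability) the 5 high-evidence targets {G01, G02, G03, G06, G11}
    enrich PW_A (k=3, K=5, n=5, N=20; p = 1126/15504) for cellular
    senescence and PW_D (k=3, K=4; p = 496/15504) for chronic
    inflammation.
    """
    genes = [f"G{i:02d}" for i in range(1, 21)]
    sets = {
        "PW_A": [f"G{i:02d}" for i in range(1, 6)],     # G01-G05
        "PW_B": [f"G{i:02d}" for i in range(6, 11)],    # G06-G10
        "PW_C": [f"G{i:02d}" for i in range(11, 21)],   # G11-G20
        "PW_D": ["G01", "G06", "G11", "G16"],
    }
    library = GeneSetLibrary.from_dict(sets, universe=genes)
    ann = HallmarkAnnotationMap(
        pathway_map={
            "PW_A": frozenset({"cellular senescence"}),
            "PW_C": frozenset({"cellular senescence"}),
            "PW_B": frozenset({"chronic inflammation"}),
            "PW_D": frozenset({"chronic inflammation"}),
        }
    )
    table = TargetAssociationTable(
        disease_id="WORKED_EXAMPLE",
        rows=(
            ("G01", 0.90),
            ("G02", 0.85),
            ("G03", 0.80),
            ("G06", 0.70),
            ("G11", 0.60),
            ("G04", 0.40),  # exactly at the threshold: excluded (strict >)
            ("G20", 0.20),
        ),
    )
    return library, ann, table


def worked_example_config(**overrides) -> ScoringConfig:
    """Config for the micro-world: a looser enrichment gate (the 20-gene
    universe cannot reach p < 0.001) and a sample size exceeding the pool
    so every draw is the full high-evidence target list (deterministic)."""
    params = dict(
        enrich_alpha=0.1,
        sample_size=50,
        top_k=60,
        n_samples=20,
        n_perm=99,
        seed=0,
    )
    params.update(overrides)
    return ScoringConfig(**params)
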