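"""End-to-end orchestration: load inputs, score every disease, attach
significance, normalize across diseases, and write figure-ready tables.

This is the library face of the pipeline sketch: target filtering ->
subsampling -> enrichment -> hallmark scoring -> significance ->
normalization -> report. It is invoked from Python (see ``examples/``);
``RunConfig`` may also be loaded from a YAML file.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ValidationError
from .hallmarks import HALLMARKS
from .io import (
    FLOAT_FMT,
    GeneSetLibrary,
    read_gene_hallmark_map,
    read_gmt,
    read_hallmark_annotations,
    read_target_table,
    write_score_tables,
)
from .resampling import (
    attach_pvalues,
    normalize_scores,
    run_sampling,
    significance_table,
)
from .scoring import ScoringConfig
from .synthetic import FixtureSpec, make_world, write_world

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths plus scoring constants plus report options."""

    library_path: str
    annotation_path: str
    target_paths: dict[str, str]  # disease_id -> path
    out_dir: str
    gene_map_path: str | None = None
    score_column: str = "score"
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    normalize: bool = True
    keep_samples: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh)
        scoring = ScoringConfig(**raw.pop("scoring", {}))
        return cls(scoring=scoring, **raw)


def run_scoring(config: RunConfig) -> dict[str, str]:
    """Run the full pipeline for every disease table and write the long
    TSV, disease totals, heatmap matrix (diseases x 11 hallmarks of
    normalized mean scores with NS markers) and run metadata.

    Deterministic: identical inputs and seed give byte-identical tables;
    per-disease substreams make the result independent of table order.
    Returns the file manifest.
    """
    if not config.target_paths:
        raise ValidationError("no disease target tables configured")
    for label, p in [("library", config.library_path), ("annotations", config.annotation_path),
                     *[(f"targets[{d}]", p) for d, p in config.target_paths.items()]]:
        if not Path(p).exists():
            raise ValidationError(f"{label} file not found: {p}")

    library = read_gmt(config.library_path)
    ann = read_hallmark_annotations(config.annotation_path, library)
    if config.gene_map_path:
        gene_map = read_gene_hallmark_map(config.gene_map_path)
        ann = type(ann)(
            pathway_map=ann.pathway_map,
            gene_map=gene_map,
            dropped_pathways=ann.dropped_pathways,
        )

    summaries = []
    for idx, disease_id in enumerate(sorted(config.target_paths)):
        table = read_target_table(
            config.target_paths[disease_id], disease_id, config.score_column
        )
        logger.info("scoring %s (%d targets)", disease_id, len(table))
        summaries.append(
            run_sampling(table, library, ann, config.scoring, disease_index=idx)
        )

    attach_pvalues(summaries, library, ann, config.scoring)
    significance_table(summaries, config.scoring)
    if config.normalize:
        normalize_scores(summaries)

    out_dir = Path(config.out_dir)
    manifest = write_score_tables(summaries, out_dir, config=config.scoring, library=library)

    heatmap = out_dir / "heatmap_matrix.tsv"
    with heatmap.open("w") as fh:
        fh.write("disease_id\t" + "\t".join(HALLMARKS) + "\n")
        for s in summaries:
            vals = s.norm_mean if s.norm_mean is not None else s.mean
            cells = []
            for j in range(len(HALLMARKS)):
                cell = FLOAT_FMT % float(vals[j])
                if s.ns is not None and s.ns[j]:
                    cell += " (NS)"
                cells.append(cell)
            fh.write(s.disease_id + "\t" + "\t".join(cells) + "\n")
    manifest["heatmap"] = str(heatmap)

    if config.keep_samples:
        samples_dir = out_dir / "samples"
        samples_dir.mkdir(exist_ok=True)
        for s in summaries:
            path = samples_dir / f"samples_{s.disease_id}.tsv"
            with path.open("w") as fh:
                fh.write("\t".join(HALLMARKS) + "\ttotal\n")
                for i in range(s.n_samples):
                    row = [FLOAT_FMT % v for v in s.samples_partial[i]]
                    row.append(FLOAT_FMT % s.samples_total[i])
                    fh.write("\t".join(row) + "\n")
            manifest[f"samples_{s.disease_id}"] = str(path)

    logger.info("wrote %d files to %s", len(manifest), out_dir)
    return manifest


def materialize_fixtures(spec: FixtureSpec, out_dir: str | Path) -> dict[str, str]:
    """Generate a synthetic world and write it to disk in the same file
    dialects the readers accept. Prints nothing; returns the manifest."""
    world = make_world(spec)
    manifest = write_world(*world, out_dir)
    meta = Path(out_dir) / "fixture_spec.json"
    with meta.open("w") as fh:
        json.dump(
            {
                "seed": spec.seed,
                "n_genes": spec.n_genes,
                "n_targets": spec.n_targets,
                "planted_hallmarks": dict(spec.planted_hallmarks),
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    manifest["spec"] = str(meta)
    return manifest
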