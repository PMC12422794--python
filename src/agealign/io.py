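"""Input/output layer: gene-set libraries (GMT), hallmark annotation tables,
disease target-association tables, and the tabular result writers.

Gene identifiers are upper-cased strings throughout; no alias or ortholog
resolution is attempted, which keeps the tool agnostic to the data source
(Open Targets exports, hand-built tables, synthetic worlds).
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ParseError, ValidationError
from .hallmarks import HALLMARKS, normalize_hallmark

logger = logging.getLogger(__name__)

# All floating-point output is serialized with 6 significant digits so that
# re-runs are byte-identical across platforms.
FLOAT_FMT = "%.6g"


def _norm_gene(g: str) -> str:
    return g.strip().upper()


@dataclass(frozen=True)
class GeneUniverse:
    """Ordered, unique, case-normalized gene identifiers forming the
    enrichment background."""

    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError("gene universe is empty")
        if any(not g for g in self.genes):
            raise ValidationError("gene universe contains a blank identifier")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("gene universe contains duplicate identifiers")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.as_set()

    def as_set(self) -> frozenset[str]:
        return frozenset(self.genes)


@dataclass(frozen=True)
class GeneSetLibrary:
    """Named pathways over a gene universe.

    ``universe`` defaults to the union of all member sets; an explicit,
    larger background may be supplied (every member must lie inside it).
    """

    sets: Mapping[str, tuple[str, frozenset[str]]]  # id -> (description, members)
    universe: GeneUniverse

    def __post_init__(self) -> None:
        if not self.sets:
            raise ValidationError("gene-set library is empty")
        bg = self.universe.as_set()
        for pid, (_, members) in self.sets.items():
            if not members:
                raise ValidationError(f"pathway {pid!r} has no members")
            stray = members - bg
            if stray:
                raise ValidationError(
                    f"pathway {pid!r} has members outside the universe: {sorted(stray)[:5]}"
                )

    @classmethod
    def from_dict(
        cls,
        sets: Mapping[str, Iterable[str]],
        descriptions: Mapping[str, str] | None = None,
        universe: Sequence[str] | None = None,
    ) -> "GeneSetLibrary":
        norm: dict[str, tuple[str, frozenset[str]]] = {}
        for pid, genes in sets.items():
            desc = (descriptions or {}).get(pid, "")
            norm[pid] = (desc, frozenset(_norm_gene(g) for g in genes))
        if universe is None:
            union = sorted(set().union(*(m for _, m in norm.values())))
            uni = GeneUniverse(tuple(union))
        else:
            uni = GeneUniverse(tuple(dict.fromkeys(_norm_gene(g) for g in universe)))
        return cls(sets=norm, universe=uni)

    def members(self, pathway_id: str) -> frozenset[str]:
        return self.sets[pathway_id][1]

    @property
    def pathway_ids(self) -> tuple[str, ...]:
        return tuple(self.sets)

    def checksum(self) -> str:
        """Stable SHA-256 over sorted pathway content, for run metadata."""
        h = hashlib.sha256()
        for pid in sorted(self.sets):
            desc, members = self.sets[pid]
            h.update(pid.encode())
            h.update(b"\x00")
            h.update(",".join(sorted(members)).encode())
            h.update(b"\n")
        h.update(",".join(self.universe.genes).encode())
        return h.hexdigest()


@dataclass(frozen=True)
class HallmarkAnnotationMap:
    """Pathway -> hallmark (multi-label) assignments, with an optional
    gene -> hallmark map backing the gene-list score component.

    Pathways absent from ``pathway_map`` are unannotated and contribute to
    no hallmark. ``coverage`` counts annotated pathways per hallmark; for a
    multi-label map the counts sum to at least the number of annotated
    pathways, with equality exactly when every pathway is single-label.
    """

    pathway_map: Mapping[str, frozenset[str]]
    gene_map: Mapping[str, frozenset[str]] | None = None
    dropped_pathways: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        vocab = set(HALLMARKS)
        for pid, labels in self.pathway_map.items():
            if not labels:
                raise ValidationError(f"pathway {pid!r} has an empty hallmark set")
            if not labels <= vocab:
                raise ValidationError(f"pathway {pid!r} carries labels outside the vocabulary")
        if self.gene_map is not None:
            for g, labels in self.gene_map.items():
                if not labels or not labels <= vocab:
                    raise ValidationError(f"gene {g!r} has an invalid hallmark set")

    @property
    def coverage(self) -> dict[str, int]:
        counts = {h: 0 for h in HALLMARKS}
        for labels in self.pathway_map.values():
            for h in labels:
                counts[h] += 1
        return counts

    def pathways_for(self, hallmark: str) -> frozenset[str]:
        return frozenset(p for p, labels in self.pathway_map.items() if hallmark in labels)

    def genes_for(self, hallmark: str) -> frozenset[str]:
        if self.gene_map is None:
            return frozenset()
        return frozenset(g for g, labels in self.gene_map.items() if hallmark in labels)


@dataclass(frozen=True)
class TargetAssociationTable:
    """One disease's (gene, association score) rows, scores in [0, 1]."""

    disease_id: str
    rows: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        genes = [g for g, _ in self.rows]
        if len(set(genes)) != len(genes):
            raise ValidationError(f"duplicate genes in target table {self.disease_id!r}")
        for g, s in self.rows:
            if not (0.0 <= s <= 1.0):
                raise ValidationError(
                    f"association score {s} for {g!r} outside [0, 1] ({self.disease_id!r})"
                )

    def __len__(self) -> int:
        return len(self.rows)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path, universe: Sequence[str] | None = None) -> GeneSetLibrary:
    """Read a GMT gene-set library (tab-separated: id, description, genes...).

    Gene identifiers are upper-cased; duplicates within a line are
    collapsed. The universe defaults to the union of all member sets unless
    an explicit background is given.
    """
    path = Path(path)
    sets: dict[str, Iterable[str]] = {}
    descs: dict[str, str] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >=3")
            pid, desc, *genes = fields
            genes = [g for g in genes if g.strip()]
            if not genes:
                raise ParseError(f"{path}:{lineno}: GMT line has no member genes")
            if pid in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate pathway id {pid!r}")
            sets[pid] = genes
            descs[pid] = desc
    if not sets:
        raise ParseError(f"{path}: empty GMT file")
    return GeneSetLibrary.from_dict(sets, descs, universe=universe)


def write_gmt(library: GeneSetLibrary, path: str | Path) -> None:
    """Write a library in GMT dialect (members sorted for determinism)."""
    path = Path(path)
    with path.open("w") as fh:
        for pid in library.sets:
            desc, members = library.sets[pid]
            fh.write("\t".join([pid, desc, *sorted(members)]) + "\n")


def read_hallmark_annotations(
    path: str | Path, library: GeneSetLibrary
) -> HallmarkAnnotationMap:
    """Read a pathway->hallmark TSV (columns ``pathway_id``, ``hallmark``,
    one pair per row) into a multi-label map.

    Rows naming pathways absent from the library are dropped with a warning
    and recorded in ``dropped_pathways``. Hallmark strings must resolve to
    the 11-label vocabulary after case/underscore normalization.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise ValidationError(f"{path}: annotation table has no rows")
    required = {"pathway_id", "hallmark"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")

    bad_rows = []
    pathway_map: dict[str, set[str]] = {}
    dropped: list[str] = []
    known = set(library.sets)
    for idx, row in df.iterrows():
        pid = str(row["pathway_id"]).strip()
        try:
            label = normalize_hallmark(str(row["hallmark"]))
        except ValidationError:
            bad_rows.append((int(idx) + 2, str(row["hallmark"])))  # +2: header + 1-based
            continue
        if pid not in known:
            dropped.append(pid)
            continue
        pathway_map.setdefault(pid, set()).add(label)
    if bad_rows:
        raise ValidationError(
            f"{path}: unknown hallmark labels at rows {bad_rows[:10]}"
        )
    if dropped:
        warnings.warn(
            f"{path}: dropped {len(dropped)} annotation rows naming pathways "
            f"absent from the library (e.g. {dropped[:3]})",
            stacklevel=2,
        )
    ann = HallmarkAnnotationMap(
        pathway_map={p: frozenset(v) for p, v in sorted(pathway_map.items())},
        dropped_pathways=tuple(dict.fromkeys(dropped)),
    )
    logger.info("annotation coverage: %s", ann.coverage)
    return ann


def read_gene_hallmark_map(path: str | Path) -> dict[str, frozenset[str]]:
    """Read an optional gene->hallmark TSV (columns ``gene``, ``hallmark``)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene", "hallmark"} <= set(df.columns):
        raise ParseError(f"{path}: expected columns ['gene', 'hallmark']")
    gene_map: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        gene_map.setdefault(_norm_gene(str(row["gene"])), set()).add(
            normalize_hallmark(str(row["hallmark"]))
        )
    return {g: frozenset(v) for g, v in sorted(gene_map.items())}


def read_target_table(
    path: str | Path,
    disease_id: str,
    score_column: str = "score",
) -> TargetAssociationTable:
    """Read a disease target table: TSV with columns (``gene``,
    ``<score_column>``) or an Open Targets-style JSON-lines export where
    each record carries a gene symbol and a named score field.

    Duplicate genes keep the maximum association score (with a warning) —
    conservative for the downstream strict ``score > threshold`` filter.
    """
    path = Path(path)
    pairs: list[tuple[str, float]] = []
    if path.suffix in {".json", ".jsonl", ".ndjson"}:
        with path.open() as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise ParseError(f"{path}:{lineno}: bad JSON record: {exc}") from None
                gene = rec.get("gene") or rec.get("symbol") or rec.get("targetSymbol")
                if gene is None or score_column not in rec:
                    raise ParseError(
                        f"{path}:{lineno}: record lacks a gene symbol or {score_column!r}"
                    )
                pairs.append((_norm_gene(str(gene)), float(rec[score_column])))
    else:
        df = pd.read_csv(path, sep="\t")
        if "gene" not in df.columns or score_column not in df.columns:
            raise ParseError(
                f"{path}: expected columns ['gene', {score_column!r}], got {list(df.columns)}"
            )
        for _, row in df.iterrows():
            pairs.append((_norm_gene(str(row["gene"])), float(row[score_column])))

    if not pairs:
        raise ValidationError(f"{path}: target table has no rows")
    best: dict[str, float] = {}
    dup = False
    for g, s in pairs:
        if not (0.0 <= s <= 1.0):
            raise ValidationError(f"{path}: score {s} for {g!r} outside [0, 1]")
        if g in best:
            dup = True
            best[g] = max(best[g], s)
        else:
            best[g] = s
    if dup:
        warnings.warn(
            f"{path}: duplicate genes collapsed, keeping the maximum score", stacklevel=2
        )
    return TargetAssociationTable(disease_id=disease_id, rows=tuple(best.items()))


def write_target_table(table: TargetAssociationTable, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene\tscore\n")
        for g, s in table.rows:
            fh.write(f"{g}\t{FLOAT_FMT % s}\n")


# ---------------------------------------------------------------------------
# Result writers
# ---------------------------------------------------------------------------

def _fmt(x) -> str:
    if x is None:
        return "NA"
    try:
        import math

        if isinstance(x, float) and math.isnan(x):
            return "NA"
    except TypeError:  # pragma: no cover
        pass
    if isinstance(x, (int,)):
        return str(x)
    return FLOAT_FMT % x


def write_score_tables(
    summaries: Sequence,
    out_dir: str | Path,
    config=None,
    library: GeneSetLibrary | None = None,
) -> dict[str, str]:
    """Write the long-format disease x hallmark table, the disease totals
    table and the run-metadata JSON. Returns a file manifest.

    Re-running with identical inputs yields byte-identical TSVs (fixed row
    order, 6-significant-digit serialization, sorted JSON keys).
    """
    if not summaries:
        raise ValidationError("no summaries to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    long_path = out_dir / "hallmark_scores_long.tsv"
    with long_path.open("w") as fh:
        cols = [
            "disease_id", "hallmark", "mean", "sd", "ci_low", "ci_high",
            "p_value", "q_value", "ns", "norm_score",
        ]
        fh.write("\t".join(cols) + "\n")
        for s in summaries:
            for i, h in enumerate(HALLMARKS):
                ns = "NA" if s.q is None else ("NS" if s.ns[i] else "")
                row = [
                    s.disease_id, h,
                    _fmt(float(s.mean[i])), _fmt(float(s.sd[i])),
                    _fmt(float(s.ci_low[i])), _fmt(float(s.ci_high[i])),
                    _fmt(None if s.p is None else float(s.p[i])),
                    _fmt(None if s.q is None else float(s.q[i])),
                    ns,
                    _fmt(None if s.norm_mean is None else float(s.norm_mean[i])),
                ]
                fh.write("\t".join(row) + "\n")

    totals_path = out_dir / "disease_totals.tsv"
    with totals_path.open("w") as fh:
        fh.write("disease_id\ttotal_mean\ttotal_sd\ttotal_ci_low\ttotal_ci_high\tnorm_total\n")
        for s in summaries:
            fh.write("\t".join([
                s.disease_id,
                _fmt(float(s.total_mean)), _fmt(float(s.total_sd)),
                _fmt(float(s.total_ci_low)), _fmt(float(s.total_ci_high)),
                _fmt(None if s.norm_total_mean is None else float(s.norm_total_mean)),
            ]) + "\n")

    meta_path = out_dir / "run_metadata.json"
    meta = {
        "n_diseases": len(summaries),
        "hallmarks": list(HALLMARKS),
        "seed": getattr(config, "seed", None) if config is not None else None,
        "config": (config.to_dict() if hasattr(config, "to_dict") else None),
        "library_checksum": library.checksum() if library is not None else None,
        "normalization": getattr(summaries[0], "norm_denominators", None),
    }
    with meta_path.open("w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return {
        "long": str(long_path),
        "totals": str(totals_path),
        "metadata": str(meta_path),
    }
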