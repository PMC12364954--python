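"""Readers and writers for every external format the pipeline touches.

Formats
-------
* expression TSV — header row of sample ids, first column ``feature_id``.
* design TSV — columns ``kind`` (``sample`` | ``feature``), ``id``, ``label``;
  sample rows assign group labels (``groupA``/``groupB``), feature rows assign
  RNA classes. One file carries the whole experimental design, because ids
  such as ``MSTRG.244`` carry no class information on their own.
* target TSV — columns ``mirna_id``, ``target_id``, ``target_class`` and an
  optional ``sites`` count; duplicate pairs are merged with sites summed.
* GTF (1-based inclusive) / BED (0-based half-open) — normalised to 0-based
  half-open internally; only ``gene`` records with ``gene_id`` (and optional
  ``gene_biotype``) attributes are read from GTF.
* network exports — Cytoscape-importable edge TSV or SIF, plus a node
  attribute TSV with RNA class and degree.

All TSV files are tab-delimited UTF-8; lines starting with ``#`` are ignored.
Values are parsed and written at full precision (``repr`` round-trip), so a
write -> read cycle reproduces the in-memory object exactly.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    BIOTYPES,
    GROUPS,
    LONG_RNA_CLASSES,
    RNA_CLASSES,
    AnnotationIntervals,
    ExpressionMatrix,
    GeneSetAnnotation,
    LoadError,
    TargetTable,
)

log = logging.getLogger(__name__)

EDGE_COLUMNS = ["source", "interaction_type", "target", "scc", "pcc", "hypergeom_p"]
INTERACTION_TYPES = ("mirna_target", "cerna_pair")


def _rows(path) -> list[tuple[int, list[str]]]:
    """Yield (1-based line number, fields) for non-comment, non-blank lines."""
    out = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            out.append((lineno, line.rstrip("\n").split("\t")))
    return out


def _fmt(x) -> str:
    """Full-precision scalar formatting (floats via repr, ints as ints)."""
    if isinstance(x, (float, np.floating)):
        return repr(float(x))
    return str(x)


# --------------------------------------------------------------------- design
def read_design(path) -> tuple[pd.Series, pd.Series]:
    """Read a design TSV into (sample->group, feature->class) Series."""
    rows = _rows(path)
    if not rows:
        raise LoadError(f"{path}: empty design file")
    groups: dict[str, str] = {}
    classes: dict[str, str] = {}
    header = rows[0][1]
    if header[:3] != ["kind", "id", "label"]:
        raise LoadError(f"{path}: line {rows[0][0]}: expected header 'kind\\tid\\tlabel'")
    for lineno, fields in rows[1:]:
        if len(fields) != 3:
            raise LoadError(f"{path}: line {lineno}: expected 3 fields, got {len(fields)}")
        kind, ident, label = fields
        if kind == "sample":
            if label not in GROUPS:
                raise LoadError(f"{path}: line {lineno}: unknown group {label!r}")
            if ident in groups:
                raise LoadError(f"{path}: line {lineno}: duplicate sample id {ident!r}")
            groups[ident] = label
        elif kind == "feature":
            if label not in RNA_CLASSES:
                raise LoadError(f"{path}: line {lineno}: unknown RNA class {label!r}")
            if ident in classes:
                raise LoadError(f"{path}: line {lineno}: duplicate feature id {ident!r}")
            classes[ident] = label
        else:
            raise LoadError(f"{path}: line {lineno}: unknown kind {kind!r}")
    return pd.Series(groups, dtype=object), pd.Series(classes, dtype=object)


def write_design(groups: pd.Series, classes: pd.Series, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("kind\tid\tlabel\n")
        for ident, label in groups.items():
            fh.write(f"sample\t{ident}\t{label}\n")
        for ident, label in classes.items():
            fh.write(f"feature\t{ident}\t{label}\n")


# ----------------------------------------------------------------- expression
def read_expression(path, design_path) -> ExpressionMatrix:
    """Read an expression TSV plus its design file into an ExpressionMatrix.

    Errors name the file, line and offending token; the constructed matrix
    satisfies every container invariant (non-negative finite values, unique
    ids, >= 2 samples per group). Row order is preserved.
    """
    groups, classes = read_design(design_path)
    rows = _rows(path)
    if not rows:
        raise LoadError(f"{path}: empty expression file")
    header_lineno, header = rows[0]
    if header[0] != "feature_id":
        raise LoadError(
            f"{path}: line {header_lineno}: first column must be 'feature_id', "
            f"got {header[0]!r}"
        )
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        raise LoadError(f"{path}: line {header_lineno}: duplicate sample id in header")

    feature_ids: list[str] = []
    data: list[list[float]] = []
    seen: set[str] = set()
    for lineno, fields in rows[1:]:
        if len(fields) != len(header):
            raise LoadError(
                f"{path}: line {lineno}: ragged row ({len(fields)} fields, "
                f"expected {len(header)})"
            )
        fid = fields[0]
        if fid in seen:
            raise LoadError(f"{path}: line {lineno}: duplicate feature id {fid!r}")
        seen.add(fid)
        vals = []
        for sample, tok in zip(sample_ids, fields[1:]):
            try:
                v = float(tok)
            except ValueError:
                raise LoadError(
                    f"{path}: line {lineno}: non-numeric value {tok!r} "
                    f"(feature {fid!r}, sample {sample!r})"
                ) from None
            if not np.isfinite(v) or v < 0:
                raise LoadError(
                    f"{path}: line {lineno}: invalid abundance {tok!r} "
                    f"(feature {fid!r}, sample {sample!r}): values must be finite and >= 0"
                )
            vals.append(v)
        feature_ids.append(fid)
        data.append(vals)

    values = pd.DataFrame(data, index=feature_ids, columns=sample_ids, dtype=float)
    missing = values.index.difference(classes.index)
    if len(missing):
        raise LoadError(f"{path}: features missing from design file: {list(missing[:5])}")
    return ExpressionMatrix(values=values, feature_class=classes, group_of_sample=groups)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("feature_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for fid, row in matrix.values.iterrows():
            fh.write(fid + "\t" + "\t".join(_fmt(v) for v in row.to_numpy()) + "\n")


# -------------------------------------------------------------------- targets
def read_target_table(path) -> TargetTable:
    """Read a miRNA->target prediction TSV, collapsing duplicate pairs."""
    rows = _rows(path)
    if not rows:
        raise LoadError(f"{path}: empty target table")
    lineno0, header = rows[0]
    required = ["mirna_id", "target_id", "target_class"]
    if header[: len(required)] != required:
        raise LoadError(
            f"{path}: line {lineno0}: expected header starting "
            f"'mirna_id\\ttarget_id\\ttarget_class'"
        )
    has_sites = len(header) > 3 and header[3] == "sites"
    recs = []
    for lineno, fields in rows[1:]:
        if len(fields) < 3:
            raise LoadError(f"{path}: line {lineno}: expected >= 3 fields")
        mirna, target, tclass = fields[:3]
        if tclass == "miRNA":
            raise LoadError(
                f"{path}: line {lineno}: target_class 'miRNA' is unsupported "
                f"(miRNA-miRNA edges are not modelled)"
            )
        if tclass not in LONG_RNA_CLASSES:
            raise LoadError(f"{path}: line {lineno}: unknown target_class {tclass!r}")
        sites = 1
        if has_sites and len(fields) > 3 and fields[3] != "":
            try:
                sites = int(fields[3])
            except ValueError:
                raise LoadError(f"{path}: line {lineno}: non-integer sites {fields[3]!r}") from None
        recs.append((mirna, target, tclass, sites))
    if not recs:
        log.warning("%s: target table has a header but no records", path)
        return TargetTable(
            records=pd.DataFrame(columns=["mirna_id", "target_id", "target_class", "site_count"])
        )
    df = pd.DataFrame(recs, columns=["mirna_id", "target_id", "target_class", "site_count"])
    table = TargetTable.from_records(df)
    if table.n_collapsed:
        log.info("%s: collapsed %d duplicate target records", path, table.n_collapsed)
    return table


def write_target_table(table: TargetTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("mirna_id\ttarget_id\ttarget_class\tsites\n")
        for rec in table.records.itertuples(index=False):
            fh.write(f"{rec.mirna_id}\t{rec.target_id}\t{rec.target_class}\t{rec.site_count}\n")


# ------------------------------------------------------------------ intervals
_GTF_BIOTYPES = {"protein_coding": "protein_coding", "lncRNA": "lncRNA"}


def _gtf_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for chunk in text.strip().rstrip(";").split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_intervals(path, dialect: str) -> AnnotationIntervals:
    """Read gene intervals from GTF or BED, normalised to 0-based half-open.

    GTF coordinates (1-based inclusive) become ``[start-1, end)``; BED is
    stored as-is. Only GTF ``gene`` records are kept, keyed by their
    ``gene_id`` attribute; ``gene_biotype`` maps onto
    {protein_coding, lncRNA, other}.
    """
    if dialect not in ("GTF", "BED"):
        raise ValueError(f"unknown interval dialect {dialect!r}")
    recs = []
    for lineno, fields in _rows(path):
        if dialect == "GTF":
            if len(fields) < 9:
                raise LoadError(f"{path}: line {lineno}: GTF needs 9 fields, got {len(fields)}")
            chrom, _source, ftype, start, end, _score, strand, _frame, attr_text = fields[:9]
            if ftype != "gene":
                continue
            try:
                start0, end0 = int(start) - 1, int(end)
            except ValueError:
                raise LoadError(f"{path}: line {lineno}: non-integer coordinate") from None
            attrs = _gtf_attributes(attr_text)
            if "gene_id" not in attrs:
                raise LoadError(f"{path}: line {lineno}: gene record without gene_id")
            fid = attrs["gene_id"]
            biotype = _GTF_BIOTYPES.get(attrs.get("gene_biotype", ""), "other")
        else:
            if len(fields) < 4:
                raise LoadError(f"{path}: line {lineno}: BED needs >= 4 fields (chrom start end name)")
            chrom, start, end, fid = fields[:4]
            try:
                start0, end0 = int(start), int(end)
            except ValueError:
                raise LoadError(f"{path}: line {lineno}: non-integer coordinate") from None
            strand = fields[5] if len(fields) >= 6 else "."
            biotype = "other"
        if start0 >= end0:
            raise LoadError(
                f"{path}: line {lineno}: empty interval after normalisation "
                f"(start {start0} >= end {end0})"
            )
        if strand not in ("+", "-", "."):
            raise LoadError(f"{path}: line {lineno}: unknown strand {strand!r}")
        recs.append((fid, chrom, start0, end0, strand, biotype))
    df = pd.DataFrame(
        recs, columns=["feature_id", "chrom", "start", "end", "strand", "biotype"]
    )
    return AnnotationIntervals(records=df)


def write_gtf(intervals: AnnotationIntervals, path, source: str = "cernet") -> None:
    """Write intervals as GTF gene records (converting back to 1-based inclusive)."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in intervals.records.itertuples(index=False):
            biotype = rec.biotype if rec.biotype in _GTF_BIOTYPES else "misc_RNA"
            attrs = f'gene_id "{rec.feature_id}"; gene_biotype "{biotype}";'
            fh.write(
                f"{rec.chrom}\t{source}\tgene\t{rec.start + 1}\t{rec.end}\t.\t"
                f"{rec.strand}\t.\t{attrs}\n"
            )


# -------------------------------------------------------------------- network
def write_network(network, path_prefix, dialect: str = "edge-TSV") -> list[Path]:
    """Export a ceRNA network for Cytoscape import.

    Writes ``<prefix>.edges.tsv`` (or ``.sif``) plus ``<prefix>.nodes.tsv``
    with RNA class and degree. Statistics inapplicable to an edge type are
    left empty. Returns the written paths.
    """
    if dialect not in ("edge-TSV", "SIF"):
        raise ValueError(f"unknown network dialect {dialect!r}")
    prefix = Path(path_prefix)
    graph = network.graph
    edges = sorted(
        (tuple(sorted((u, v))), data) for u, v, data in graph.edges(data=True)
    )
    written = []
    if dialect == "edge-TSV":
        epath = prefix.with_suffix(".edges.tsv")
        with open(epath, "w", encoding="utf-8") as fh:
            fh.write("\t".join(EDGE_COLUMNS) + "\n")
            for (u, v), data in edges:
                scc = _fmt(data["scc"]) if data.get("scc") is not None else ""
                pcc = _fmt(data["pcc"]) if data.get("pcc") is not None else ""
                p = _fmt(data["hypergeom_p"]) if data.get("hypergeom_p") is not None else ""
                fh.write(f"{u}\t{data['interaction_type']}\t{v}\t{scc}\t{pcc}\t{p}\n")
    else:
        epath = prefix.with_suffix(".sif")
        with open(epath, "w", encoding="utf-8") as fh:
            for (u, v), data in edges:
                fh.write(f"{u}\t{data['interaction_type']}\t{v}\n")
    written.append(epath)

    npath = prefix.with_suffix(".nodes.tsv")
    with open(npath, "w", encoding="utf-8") as fh:
        fh.write("node_id\trna_class\tdegree\n")
        for node in sorted(graph.nodes):
            fh.write(f"{node}\t{graph.nodes[node]['rna_class']}\t{graph.degree[node]}\n")
    written.append(npath)
    return written


def read_network_edges(path) -> pd.DataFrame:
    """Read an edge TSV back into a DataFrame (round-trip counterpart)."""
    rows = _rows(path)
    if not rows:
        raise LoadError(f"{path}: empty edge file")
    lineno0, header = rows[0]
    if header != EDGE_COLUMNS:
        raise LoadError(f"{path}: line {lineno0}: unexpected edge header {header!r}")
    recs = []
    for lineno, fields in rows[1:]:
        if len(fields) != len(EDGE_COLUMNS):
            raise LoadError(f"{path}: line {lineno}: ragged edge row")
        src, etype, dst, scc, pcc, p = fields
        if etype not in INTERACTION_TYPES:
            raise LoadError(f"{path}: line {lineno}: unknown interaction_type {etype!r}")
        recs.append(
            (
                src,
                etype,
                dst,
                float(scc) if scc else None,
                float(pcc) if pcc else None,
                float(p) if p else None,
            )
        )
    return pd.DataFrame(recs, columns=EDGE_COLUMNS)


# ------------------------------------------------------------------ gene sets
def read_annotation(path) -> GeneSetAnnotation:
    """Read a gene->term annotation TSV (term_id, term_name, gene_id per row)."""
    rows = _rows(path)
    if not rows:
        raise LoadError(f"{path}: empty annotation file")
    lineno0, header = rows[0]
    if header[:3] != ["term_id", "term_name", "gene_id"]:
        raise LoadError(f"{path}: line {lineno0}: expected header 'term_id\\tterm_name\\tgene_id'")
    names: dict[str, str] = {}
    members: dict[str, set] = {}
    for lineno, fields in rows[1:]:
        if len(fields) < 3:
            raise LoadError(f"{path}: line {lineno}: expected 3 fields")
        term_id, term_name, gene_id = fields[:3]
        if term_id in names and names[term_id] != term_name:
            raise LoadError(f"{path}: line {lineno}: conflicting names for term {term_id!r}")
        names[term_id] = term_name
        members.setdefault(term_id, set()).add(gene_id)
    terms = pd.DataFrame(
        sorted(names.items()), columns=["term_id", "term_name"]
    )
    return GeneSetAnnotation(
        terms=terms, members={t: frozenset(m) for t, m in members.items()}
    )


def read_gene_list(path) -> list[str]:
    """Read a one-id-per-line gene list (deduplicated, order preserved)."""
    seen = []
    for _lineno, fields in _rows(path):
        gid = fields[0].strip()
        if gid and gid not in seen:
            seen.append(gid)
    return seen


def write_table(df: pd.DataFrame, path) -> None:
    """Write a result DataFrame as full-precision TSV."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(df.columns)
        for row in df.itertuples(index=False):
            writer.writerow([_fmt(v) for v in row])
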