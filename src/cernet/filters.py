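"""Correlation filters and cis/trans lncRNA target assignment.

miRNA-target edges are retained at Spearman rho < -0.7 (strict, matching the
sponge hypothesis: more miRNA, less target). Candidate ceRNA pairs — two
retained targets of a shared miRNA — are kept at Pearson r > 0.9 (strict) on
the log2 scale. lncRNA cis targets are protein-coding genes within 10 kb
(non-strict) of the lncRNA locus, gap measured between closest interval
edges, strand-agnostic; trans targets are co-expressed genes with
|Pearson r| >= 0.95 (non-strict).

Spearman is computed as Pearson on mid-ranks (exact under ties) rather than
the 6*sum(d^2) shortcut. Correlations pool both sample groups: the edge
filters describe co-variation across the whole contrast, not within-group
noise. Constant vectors have no defined correlation; such pairs are dropped
and counted rather than silently scored.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core import (
    CERNA_CLASSES,
    AnnotationIntervals,
    ExpressionMatrix,
    UndefinedCorrelationError,
)
from .de import DEFAULT_PSEUDOCOUNT, de_feature_ids

log = logging.getLogger(__name__)

EDGE_TABLE_COLUMNS = ["mirna_id", "target_id", "target_class", "scc", "passes"]
CANDIDATE_COLUMNS = ["cerna_id", "cerna_class", "mrna_id", "pcc"]


def _check_pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("correlation requires n >= 3 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    return x, y


def pearson(x, y) -> float:
    """Product-moment correlation, clipped to [-1, 1]."""
    x, y = _check_pair(x, y)
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    return float(min(1.0, max(-1.0, r)))


def spearman(x, y) -> float:
    """Rank correlation: Pearson of mid-ranks (average ranks on ties)."""
    x, y = _check_pair(x, y)
    return pearson(rankdata(x, method="average"), rankdata(y, method="average"))


def filter_mirna_targets(
    matrix: ExpressionMatrix,
    targets,
    de: pd.DataFrame | None = None,
    scc_cutoff: float = -0.7,
    require_de: bool = True,
) -> pd.DataFrame:
    """Score predicted miRNA-target pairs by Spearman correlation.

    Only pairs where both members are flagged DE are scored (the network is
    built from differentially expressed RNAs); pass ``require_de=False`` to
    score every resolvable pair. Returns one row per scored pair with its
    rho and a ``passes`` flag (rho < scc_cutoff, strict). Unresolvable ids
    and undefined (constant-vector) correlations are logged and skipped.
    """
    de_ids = de_feature_ids(de) if require_de else None
    if require_de and de is None:
        raise ValueError("require_de=True needs a call_de result")
    known = set(matrix.feature_ids)
    rows = []
    n_unresolved = n_not_de = n_undefined = 0
    for rec in targets.records.itertuples(index=False):
        if rec.mirna_id not in known or rec.target_id not in known:
            n_unresolved += 1
            continue
        if require_de and (rec.mirna_id not in de_ids or rec.target_id not in de_ids):
            n_not_de += 1
            continue
        try:
            rho = spearman(matrix.row(rec.mirna_id), matrix.row(rec.target_id))
        except UndefinedCorrelationError:
            n_undefined += 1
            continue
        rows.append((rec.mirna_id, rec.target_id, rec.target_class, rho, rho < scc_cutoff))
    if n_unresolved:
        log.info("filter_mirna_targets: %d pairs with unresolvable ids skipped", n_unresolved)
    if n_not_de:
        log.info("filter_mirna_targets: %d pairs excluded by the DE gate", n_not_de)
    if n_undefined:
        log.info("filter_mirna_targets: %d pairs with undefined correlation dropped", n_undefined)
    out = pd.DataFrame(rows, columns=EDGE_TABLE_COLUMNS).astype({"scc": float, "passes": bool})
    return out.sort_values(["mirna_id", "target_id"], kind="mergesort").reset_index(drop=True)


def retained_edges(edges: pd.DataFrame) -> pd.DataFrame:
    """Edges passing the SCC filter."""
    return edges[edges["passes"]].reset_index(drop=True)


def candidate_cerna_pairs(
    matrix: ExpressionMatrix,
    edges: pd.DataFrame,
    pcc_cutoff: float = 0.9,
    log2_scale: bool = True,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Candidate ceRNA pairs: co-expressed (lncRNA|circRNA, mRNA) sponge pairs.

    Every (ceRNA, mRNA) pair sharing at least one retained miRNA edge is
    scored by Pearson correlation (log2 scale by default) and kept at
    r > pcc_cutoff, strict. Pairs sharing no retained miRNA are never
    emitted regardless of correlation.
    """
    kept = retained_edges(edges)
    by_mirna = kept.groupby("mirna_id", sort=True)
    pair_keys: set[tuple[str, str, str]] = set()
    for _mirna, sub in by_mirna:
        cernas = sub[sub["target_class"].isin(CERNA_CLASSES)]
        mrnas = sub[sub["target_class"] == "mRNA"]["target_id"]
        for crec, mrna in itertools.product(cernas.itertuples(index=False), mrnas):
            pair_keys.add((crec.target_id, crec.target_class, mrna))

    rows = []
    n_undefined = 0
    for cerna, cclass, mrna in sorted(pair_keys):
        x = matrix.row(cerna)
        y = matrix.row(mrna)
        if log2_scale:
            x = np.log2(x + pseudocount)
            y = np.log2(y + pseudocount)
        try:
            r = pearson(x, y)
        except UndefinedCorrelationError:
            n_undefined += 1
            continue
        if r > pcc_cutoff:
            rows.append((cerna, cclass, mrna, r))
    if n_undefined:
        log.info("candidate_cerna_pairs: %d pairs with undefined correlation dropped", n_undefined)
    return pd.DataFrame(rows, columns=CANDIDATE_COLUMNS).astype({"pcc": float})


def interval_gap(start1: int, end1: int, start2: int, end2: int) -> int:
    """Gap in bp between two 0-based half-open intervals (0 if they overlap)."""
    return max(start1 - end2, start2 - end1, 0)


def cis_targets(
    lnc_intervals: AnnotationIntervals,
    gene_intervals: AnnotationIntervals,
    window_bp: int = 10_000,
) -> pd.DataFrame:
    """Protein-coding genes within ``window_bp`` of each lncRNA locus.

    Distance is the closest-edge gap on the same chromosome, strand-agnostic;
    overlapping loci have distance 0. The window is inclusive ("within 10 kb"
    admits a gap of exactly 10,000 bp).
    """
    genes = gene_intervals.records[gene_intervals.records["biotype"] == "protein_coding"]
    rows = []
    for lnc in lnc_intervals.records.itertuples(index=False):
        same_chrom = genes[genes["chrom"] == lnc.chrom]
        for gene in same_chrom.itertuples(index=False):
            if gene.feature_id == lnc.feature_id:
                continue
            gap = interval_gap(lnc.start, lnc.end, gene.start, gene.end)
            if gap <= window_bp:
                rows.append((lnc.feature_id, gene.feature_id, gap))
    return pd.DataFrame(rows, columns=["lncrna_id", "gene_id", "distance_bp"])


def trans_targets(
    matrix: ExpressionMatrix,
    lnc_ids,
    gene_ids,
    threshold: float = 0.95,
    log2_scale: bool = True,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Genome-wide co-expression targets: |Pearson r| >= threshold (non-strict)."""
    known = set(matrix.feature_ids)
    rows = []
    n_undefined = 0
    for lnc in lnc_ids:
        if lnc not in known:
            log.info("trans_targets: unknown lncRNA id %r skipped", lnc)
            continue
        x = matrix.row(lnc)
        if log2_scale:
            x = np.log2(x + pseudocount)
        for gene in gene_ids:
            if gene == lnc:
                continue
            if gene not in known:
                log.info("trans_targets: unknown gene id %r skipped", gene)
                continue
            y = matrix.row(gene)
            if log2_scale:
                y = np.log2(y + pseudocount)
            try:
                r = pearson(x, y)
            except UndefinedCorrelationError:
                n_undefined += 1
                continue
            if abs(r) >= threshold:
                rows.append((lnc, gene, r))
    if n_undefined:
        log.info("trans_targets: %d pairs with undefined correlation dropped", n_undefined)
    return pd.DataFrame(rows, columns=["lncrna_id", "gene_id", "pearson_r"])
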