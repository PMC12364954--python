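"""Shared-MRE hypergeometric test, triad assembly and ceRNA network analysis.

Two RNAs are a ceRNA pair when the overlap of their (correlation-retained)
miRNA regulator sets is larger than chance: with N miRNAs in the universe, K
targeting the ceRNA, M targeting the mRNA and s shared, significance is the
hypergeometric upper tail P(X >= s), X ~ Hypergeom(N, K, M). Each significant
pair expands into one (ceRNA, miRNA, mRNA) triad per shared miRNA; triads are
merged into a typed graph whose degree ranking identifies hub RNAs.

The universe N defaults to every expressed miRNA in the matrix. A
conservative alternative (miRNAs with at least one retained edge) collapses
to a handful of miRNAs in sparse designs, where a pair sharing its sole
regulator can never reach p < 0.05 (p = 1/N); both policies, plus "de"
(all DE miRNAs), are available and the choice is recorded in run metadata
because every p-value depends on it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .core import ExpressionMatrix, ValidationError

log = logging.getLogger(__name__)

UNIVERSE_POLICIES = ("expressed", "retained", "de")

PAIR_TEST_COLUMNS = [
    "cerna_id",
    "cerna_class",
    "mrna_id",
    "pcc",
    "N",
    "K",
    "M",
    "s",
    "p_value",
    "significant",
]

TRIAD_COLUMNS = [
    "cerna_id",
    "cerna_class",
    "mirna_id",
    "mrna_id",
    "scc_cerna_mirna",
    "scc_mirna_mrna",
    "pcc_pair",
    "pair_p_value",
]


def _log_comb(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def hypergeom_upper_tail(N: int, K: int, M: int, s: int) -> float:
    """P(X >= s) for X ~ Hypergeometric(population N, successes K, draws M).

    Summed in log space for stability; symmetric in (K, M). P(X >= 0) = 1 by
    convention.
    """
    for name, v in (("N", N), ("K", K), ("M", M), ("s", s)):
        if v != int(v) or v < 0:
            raise ValidationError(f"{name} must be a non-negative integer, got {v!r}")
    N, K, M, s = int(N), int(K), int(M), int(s)
    if N < 1:
        raise ValidationError("N must be >= 1")
    if K > N or M > N:
        raise ValidationError(f"K={K}, M={M} may not exceed N={N}")
    if s > min(K, M):
        raise ValidationError(f"s={s} exceeds min(K, M)={min(K, M)}")
    if s == 0:
        return 1.0
    log_denom = _log_comb(N, M)
    log_terms = []
    for k in range(s, min(K, M) + 1):
        if M - k > N - K:  # not enough failures to fill the draw
            continue
        log_terms.append(_log_comb(K, k) + _log_comb(N - K, M - k) - log_denom)
    if not log_terms:
        return 0.0
    peak = max(log_terms)
    total = peak + math.log(sum(math.exp(t - peak) for t in log_terms))
    return float(min(1.0, math.exp(total)))


def mirna_universe(
    policy: str,
    matrix: ExpressionMatrix | None = None,
    edges: pd.DataFrame | None = None,
    de: pd.DataFrame | None = None,
) -> frozenset:
    """Resolve the miRNA universe for the shared-MRE test under a policy."""
    if policy == "expressed":
        if matrix is None:
            raise ValueError("'expressed' universe needs the expression matrix")
        return frozenset(matrix.features_of_class("miRNA"))
    if policy == "retained":
        if edges is None:
            raise ValueError("'retained' universe needs the edge table")
        return frozenset(edges.loc[edges["passes"], "mirna_id"])
    if policy == "de":
        if de is None:
            raise ValueError("'de' universe needs a call_de result")
        sub = de[(de["feature_class"] == "miRNA") & de["is_de"]]
        return frozenset(sub["feature_id"])
    raise ValueError(f"unknown universe policy {policy!r}; choose from {UNIVERSE_POLICIES}")


def test_cerna_pairs(
    candidates: pd.DataFrame,
    edges: pd.DataFrame,
    universe: frozenset,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Score candidate pairs by shared-miRNA hypergeometric overlap.

    The targeting relation is the SCC-retained edge set restricted to the
    universe. Returns every candidate with (N, K, M, s, p) and a
    ``significant`` flag (p < alpha, strict, uncorrected — a BH column can be
    added downstream but the default mirrors a raw p < 0.05 gate).
    """
    kept = edges[edges["passes"] & edges["mirna_id"].isin(universe)]
    mirnas_of: dict[str, frozenset] = {
        t: frozenset(sub["mirna_id"]) for t, sub in kept.groupby("target_id")
    }
    N = len(universe)
    rows = []
    for cand in candidates.itertuples(index=False):
        set_c = mirnas_of.get(cand.cerna_id, frozenset())
        set_m = mirnas_of.get(cand.mrna_id, frozenset())
        K, M, s = len(set_c), len(set_m), len(set_c & set_m)
        p = hypergeom_upper_tail(N, K, M, s)
        rows.append(
            (cand.cerna_id, cand.cerna_class, cand.mrna_id, cand.pcc, N, K, M, s, p, p < alpha)
        )
    return pd.DataFrame(rows, columns=PAIR_TEST_COLUMNS).astype(
        {"pcc": float, "N": int, "K": int, "M": int, "s": int, "p_value": float, "significant": bool}
    )


def assemble_triads(tests: pd.DataFrame, edges: pd.DataFrame) -> pd.DataFrame:
    """Expand significant pairs into (ceRNA, miRNA, mRNA) triads.

    One triad per (significant pair, shared miRNA) combination, carrying both
    edge correlations and the pair statistics. Per-class counts are logged.
    """
    kept = edges[edges["passes"]]
    scc_of = {(r.mirna_id, r.target_id): r.scc for r in kept.itertuples(index=False)}
    mirnas_of: dict[str, frozenset] = {
        t: frozenset(sub["mirna_id"]) for t, sub in kept.groupby("target_id")
    }
    rows = []
    for pair in tests[tests["significant"]].itertuples(index=False):
        shared = sorted(mirnas_of.get(pair.cerna_id, frozenset()) & mirnas_of.get(pair.mrna_id, frozenset()))
        for mirna in shared:
            rows.append(
                (
                    pair.cerna_id,
                    pair.cerna_class,
                    mirna,
                    pair.mrna_id,
                    scc_of[(mirna, pair.cerna_id)],
                    scc_of[(mirna, pair.mrna_id)],
                    pair.pcc,
                    pair.p_value,
                )
            )
    out = pd.DataFrame(rows, columns=TRIAD_COLUMNS).astype(
        {"scc_cerna_mirna": float, "scc_mirna_mrna": float, "pcc_pair": float, "pair_p_value": float}
    )
    for cls in ("lncRNA", "circRNA"):
        n = int((out["cerna_class"] == cls).sum())
        log.info("assemble_triads: %d %s-miRNA-mRNA triads", n, cls)
    return out.sort_values(["cerna_id", "mirna_id", "mrna_id"], kind="mergesort").reset_index(
        drop=True
    )


@dataclass
class CeRNANetwork:
    """Typed RNA interaction graph (miRNA-target and ceRNA-ceRNA edges)."""

    graph: nx.Graph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree_of(self, node: str) -> int:
        return int(self.graph.degree[node])

    def check_invariants(self) -> None:
        if any(u == v for u, v in self.graph.edges):
            raise ValidationError("self-loop in ceRNA network")
        if sum(d for _n, d in self.graph.degree) != 2 * self.n_edges:
            raise ValidationError("degree sum != 2 * edge count")


def build_network(triads: pd.DataFrame) -> CeRNANetwork:
    """Merge triads into a deduplicated typed graph.

    Nodes carry their RNA class; edges are deduplicated across triads by
    unordered node pair (an edge shared by many triads counts once for
    degree, matching a visual reading of network connectivity).
    """
    g = nx.Graph()
    for t in triads.itertuples(index=False):
        g.add_node(t.cerna_id, rna_class=t.cerna_class)
        g.add_node(t.mirna_id, rna_class="miRNA")
        g.add_node(t.mrna_id, rna_class="mRNA")
        g.add_edge(
            t.mirna_id, t.cerna_id,
            interaction_type="mirna_target", scc=t.scc_cerna_mirna, pcc=None, hypergeom_p=None,
        )
        g.add_edge(
            t.mirna_id, t.mrna_id,
            interaction_type="mirna_target", scc=t.scc_mirna_mrna, pcc=None, hypergeom_p=None,
        )
        g.add_edge(
            t.cerna_id, t.mrna_id,
            interaction_type="cerna_pair", scc=None, pcc=t.pcc_pair, hypergeom_p=t.pair_p_value,
        )
    net = CeRNANetwork(graph=g)
    net.check_invariants()
    return net


def rank_connectivity(network: CeRNANetwork, top_k: int = 10) -> list[tuple[str, int]]:
    """Top-k nodes by degree, ties broken lexicographically by id."""
    degrees = sorted(network.graph.degree, key=lambda nd: (-nd[1], nd[0]))
    if top_k > len(degrees):
        log.info("rank_connectivity: top_k=%d exceeds %d nodes; returning all", top_k, len(degrees))
    return [(n, int(d)) for n, d in degrees[:top_k]]


def extract_subnetwork(network: CeRNANetwork, gene_set) -> CeRNANetwork:
    """Induced subnetwork around a set of mRNAs.

    Contains the listed mRNAs present in the network, every node adjacent to
    them (their miRNA regulators and ceRNA partners from retained triads) and
    all edges among those nodes. Unknown gene ids are logged and skipped.
    """
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("gene_set must be nonempty")
    g = network.graph
    seeds = []
    for gid in gene_set:
        if gid in g:
            seeds.append(gid)
        else:
            log.info("extract_subnetwork: gene %r absent from network, skipped", gid)
    nodes = set(seeds)
    for gid in seeds:
        nodes.update(g.neighbors(gid))
    sub = CeRNANetwork(graph=g.subgraph(nodes).copy())
    sub.check_invariants()
    return sub
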