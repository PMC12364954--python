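"""Hypergeometric over-representation analysis on user-supplied annotations.

A generic ORA: for a query gene set drawn from a background universe, each
annotation term is scored by the upper-tail hypergeometric probability of
observing at least the seen number of query hits (the same math core as the
shared-MRE ceRNA test), with BH-adjusted FDR alongside. No term database is
bundled — annotations are an input table.
"""

from __future__ import annotations

import logging

import pandas as pd

from .core import GeneSetAnnotation
from .de import bh_adjust
from .network import hypergeom_upper_tail

log = logging.getLogger(__name__)

ENRICHMENT_COLUMNS = [
    "term_id",
    "term_name",
    "k",
    "K",
    "n",
    "N",
    "p_value",
    "fdr",
    "significant",
]


def over_representation(
    query,
    background,
    annotation: GeneSetAnnotation,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided over-representation of annotation terms in a query set.

    Parameters follow the standard ORA contingency: N = background size,
    K = term size within the background, n = query size, k = query hits.
    Term membership is intersected with the background before testing;
    query must be a subset of background. Terms with p < alpha (strict) are
    flagged significant.
    """
    query = set(query)
    background = set(background)
    if not query or not background:
        raise ValueError("query and background must be nonempty")
    if not query <= background:
        extra = sorted(query - background)[:5]
        raise ValueError(f"query genes outside background: {extra}")
    N = len(background)
    n = len(query)
    rows = []
    for term in annotation.terms.itertuples(index=False):
        members = annotation.members[term.term_id] & background
        K = len(members)
        k = len(members & query)
        p = hypergeom_upper_tail(N=N, K=K, M=n, s=k) if K else 1.0
        rows.append((term.term_id, term.term_name, k, K, n, N, p))
    out = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS[:7])
    out["fdr"] = bh_adjust(out["p_value"].to_numpy()) if len(out) else []
    out["significant"] = out["p_value"] < alpha
    log.info(
        "over_representation: %d/%d terms at p < %g (query %d of %d genes)",
        int(out["significant"].sum()), len(out), alpha, n, N,
    )
    return out
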