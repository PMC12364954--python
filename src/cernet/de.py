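"""Differential expression with a Welch-on-log2 surrogate test.

Long RNAs (mRNA/lncRNA/circRNA) are called DE at fold change >= 2 and
BH-adjusted FDR < 0.05; miRNAs at fold change >= 2 and raw p < 0.05. The
two-group test is Welch's unequal-variance t on log2(x + pseudocount) —
a deliberately simple surrogate for count-model DE software, labelled as
such in output metadata (see ``TEST_LABEL``).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .core import ExpressionMatrix, LONG_RNA_CLASSES

log = logging.getLogger(__name__)

#: recorded in output manifests so downstream users know the DE model
TEST_LABEL = "welch_t_on_log2(surrogate)"

DEFAULT_PSEUDOCOUNT = 1e-2

DE_COLUMNS = [
    "feature_id",
    "feature_class",
    "mean_groupA",
    "mean_groupB",
    "log2fc",
    "p_value",
    "fdr",
    "direction",
    "is_de",
]


def log2_fold_change(
    matrix: ExpressionMatrix, feature: str, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> float:
    """log2((mean_B + c) / (mean_A + c)) for one feature (B over A)."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    row = matrix.row(feature)
    in_b = (matrix.group_of_sample == "groupB").to_numpy()
    mean_a = row[~in_b].mean()
    mean_b = row[in_b].mean()
    return float(np.log2((mean_b + pseudocount) / (mean_a + pseudocount)))


def _welch_log2(a: np.ndarray, b: np.ndarray, pseudocount: float) -> float:
    """Two-sided Welch p on log2(x + c); degenerate zero-variance cases handled."""
    la = np.log2(a + pseudocount)
    lb = np.log2(b + pseudocount)
    if la.var(ddof=1) == 0.0 and lb.var(ddof=1) == 0.0:
        return 1.0 if la.mean() == lb.mean() else 0.0
    p = stats.ttest_ind(la, lb, equal_var=False).pvalue
    return float(p)


def two_group_test(
    matrix: ExpressionMatrix, feature: str, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> float:
    """Welch's unequal-variance test between groups on the log2 scale."""
    row = matrix.row(feature)
    in_b = (matrix.group_of_sample == "groupB").to_numpy()
    a, b = row[~in_b], row[in_b]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("two_group_test requires >= 2 samples per group")
    return _welch_log2(a, b, pseudocount)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR, returned in input order.

    q_(i) = min_{j >= i} p_(j) * m / j over the ascending order statistics,
    capped at 1. Raises on p outside [0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if (~np.isfinite(p)).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q


def call_de(
    matrix: ExpressionMatrix,
    fc_min: float = 2.0,
    de_fdr: float = 0.05,
    mirna_de_p: float = 0.05,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Call differential expression for every feature in the matrix.

    BH adjustment runs within each RNA class separately (the classes are
    analysed as separate experiments). Long RNAs require |log2fc| >= log2(fc_min)
    and fdr < de_fdr; miRNAs |log2fc| >= log2(fc_min) and raw p < mirna_de_p.
    Fold-change gates are non-strict, significance gates strict.
    """
    if fc_min < 1:
        raise ValueError("fc_min must be >= 1 (a fold change)")
    log2fc_min = float(np.log2(fc_min))
    in_b = (matrix.group_of_sample == "groupB").to_numpy()
    vals = matrix.values.to_numpy(dtype=float)
    a, b = vals[:, ~in_b], vals[:, in_b]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    log2fc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))
    p = np.array([_welch_log2(a[i], b[i], pseudocount) for i in range(vals.shape[0])])

    out = pd.DataFrame(
        {
            "feature_id": matrix.feature_ids,
            "feature_class": matrix.feature_class.to_numpy(),
            "mean_groupA": mean_a,
            "mean_groupB": mean_b,
            "log2fc": log2fc,
            "p_value": p,
        }
    )
    fdr = np.empty(len(out), dtype=float)
    for cls, idx in out.groupby("feature_class", sort=False).groups.items():
        fdr[np.asarray(idx)] = bh_adjust(out.loc[idx, "p_value"].to_numpy())
    out["fdr"] = fdr

    fc_ok = np.abs(out["log2fc"]) >= log2fc_min
    is_mirna = out["feature_class"] == "miRNA"
    sig = np.where(is_mirna, out["p_value"] < mirna_de_p, out["fdr"] < de_fdr)
    out["is_de"] = fc_ok & sig
    out["direction"] = np.where(
        ~out["is_de"], "none", np.where(out["log2fc"] > 0, "up", "down")
    )
    out = out[DE_COLUMNS]

    for cls in list(dict.fromkeys(out["feature_class"])):
        sub = out[out["feature_class"] == cls]
        n_up = int((sub["direction"] == "up").sum())
        n_down = int((sub["direction"] == "down").sum())
        log.info(
            "DE summary [%s] %s: up=%d down=%d total=%d of %d",
            TEST_LABEL, cls, n_up, n_down, n_up + n_down, len(sub),
        )
    return out


def de_feature_ids(de: pd.DataFrame) -> frozenset:
    """Ids flagged DE in a call_de result."""
    return frozenset(de.loc[de["is_de"], "feature_id"])
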