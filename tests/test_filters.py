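"""Correlation filters, threshold semantics and cis/trans assignment."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import pearsonr, rankdata, spearmanr

from cernet.core import AnnotationIntervals, TargetTable, UndefinedCorrelationError
from cernet.filters import (
    candidate_cerna_pairs,
    cis_targets,
    filter_mirna_targets,
    interval_gap,
    pearson,
    spearman,
    trans_targets,
)
from conftest import make_matrix

# Integer-arithmetic vectors whose correlations are bit-exact floats:
# centered ranks (1..5) vs (5,2,4,3,1) give rho = -7/10; centered
# (2,-2,4,-4,0).(4,-2,2,-4,0) = 36, norms 40 -> r = 0.9; centered
# (3,-3,1,-1,0).(3,-3,1,0,-1) = 19, norms 20 -> r = 0.95.
SCC_EXACT_07 = ([1.0, 2, 3, 4, 5], [5.0, 2, 4, 3, 1])
PCC_EXACT_09 = ([7.0, 3, 9, 1, 5], [9.0, 3, 7, 1, 5])
PCC_EXACT_095 = ([8.0, 2, 6, 4, 5], [8.0, 2, 6, 5, 4])

vectors6 = st.lists(
    st.integers(min_value=0, max_value=8), min_size=6, max_size=6
).filter(lambda v: len(set(v)) > 1)


class TestCorrelations:
    def test_perfect_antimonotone_is_minus_one(self):
        assert spearman([1, 2, 3, 4, 5, 6], [6, 5, 4, 3, 2, 1]) == -1.0

    def test_monotone_transform_invariance_example(self):
        assert spearman([1, 2, 3, 4, 5, 6], [2, 4, 6, 8, 10, 12]) == 1.0

    def test_hand_ranked_oracle(self):
        # ranks (1,2,3,4) vs (1,3,2,4): d^2 = 2 -> rho = 1 - 12/60 = 0.8
        assert spearman([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_pearson_affine_invariance(self):
        x = np.array([1.0, 2, 5, 7, 9])
        assert pearson(x, 2 * x + 1) == 1.0
        assert pearson(x, -x) == -1.0

    def test_pearson_matches_textbook_formula(self):
        x, y = np.array([0.0, 1, 2]), np.array([0.0, 1, 3])
        n = 3
        oracle = (n * (x * y).sum() - x.sum() * y.sum()) / np.sqrt(
            (n * (x**2).sum() - x.sum() ** 2) * (n * (y**2).sum() - y.sum() ** 2)
        )
        assert pearson(x, y) == pytest.approx(oracle, rel=1e-14)

    def test_constant_vector_is_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])
        with pytest.raises(UndefinedCorrelationError):
            pearson([1, 2, 3, 4], [2, 2, 2, 2])

    def test_short_vectors_refused(self):
        with pytest.raises(ValueError):
            spearman([1, 2], [2, 1])

    @settings(max_examples=300, derandomize=True)
    @given(vectors6, vectors6)
    def test_spearman_is_pearson_of_midranks(self, x, y):
        assert spearman(x, y) == pytest.approx(
            pearson(rankdata(x, method="average"), rankdata(y, method="average"))
        )

    @settings(max_examples=200, derandomize=True)
    @given(vectors6, vectors6)
    def test_spearman_matches_scipy_reference(self, x, y):
        assert spearman(x, y) == pytest.approx(spearmanr(x, y).statistic, abs=1e-12)

    @settings(max_examples=200, derandomize=True)
    @given(vectors6, vectors6)
    def test_spearman_invariant_under_strictly_increasing_transforms(self, x, y):
        fx = np.exp(np.asarray(x, dtype=float) / 3.0)
        gy = np.asarray(y, dtype=float) ** 3 + 7.0
        assert spearman(fx, gy) == pytest.approx(spearman(x, y))

    def test_pearson_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            x, y = rng.normal(size=6), rng.normal(size=6)
            assert pearson(x, y) == pytest.approx(pearsonr(x, y).statistic, abs=1e-12)


def _target_table(rows):
    df = pd.DataFrame(rows, columns=["mirna_id", "target_id", "target_class"])
    return TargetTable.from_records(df)


class TestEdgeFilter:
    def test_noise_free_planted_edges_retained_with_exact_scc(self, noise_free_triad):
        matrix, targets, _i, truth = noise_free_triad
        from cernet.de import call_de

        edges = filter_mirna_targets(matrix, targets, de=call_de(matrix))
        t = truth.triads.iloc[0]
        kept = edges[edges["passes"]]
        got = set(zip(kept["mirna_id"], kept["target_id"]))
        assert {(t.mirna_id, t.cerna_id), (t.mirna_id, t.mrna_id)} <= got
        assert (kept["scc"] == -1.0).all()

    def test_scc_exactly_at_cutoff_is_dropped(self):
        x, y = SCC_EXACT_07
        assert spearman(x, y) == -0.7
        m = make_matrix({"mir": x, "tgt": y}, {"mir": "miRNA", "tgt": "mRNA"}, n_per_group=3)
        edges = filter_mirna_targets(
            m, _target_table([("mir", "tgt", "mRNA")]), require_de=False
        )
        assert len(edges) == 1 and not edges.iloc[0].passes

    def test_unresolvable_ids_are_skipped_not_fatal(self, noise_free_triad):
        matrix = noise_free_triad[0]
        edges = filter_mirna_targets(
            matrix, _target_table([("ghost_mir", "ghost_gene", "mRNA")]), require_de=False
        )
        assert len(edges) == 0

    def test_decoy_retention_matches_exhaustive_permutation_null(self):
        """For independent continuous pairs at n = 6, P(retained) equals the
        exact null P(rho < -0.7) obtained by enumerating all 720 orderings."""
        base = np.arange(1.0, 7.0)
        null_hits = sum(
            spearman(base, np.array(perm, dtype=float)) < -0.7
            for perm in itertools.permutations(base)
        )
        p_null = null_hits / 720
        rng = np.random.default_rng(3)
        n_pairs = 4000
        hits = sum(
            spearman(rng.normal(size=6), rng.normal(size=6)) < -0.7
            for _ in range(n_pairs)
        )
        se = np.sqrt(p_null * (1 - p_null) / n_pairs)
        assert abs(hits / n_pairs - p_null) <= 4 * se + 1e-9

    def test_raising_cutoff_magnitude_never_adds_edges(self, fixture_dataset):
        matrix, targets, _i, _t = fixture_dataset
        from cernet.de import call_de

        de = call_de(matrix)
        counts = [
            int(filter_mirna_targets(matrix, targets, de=de, scc_cutoff=c)["passes"].sum())
            for c in (-0.5, -0.7, -0.9, -1.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestCandidatePairs:
    def _edges(self, rows):
        return pd.DataFrame(
            rows, columns=["mirna_id", "target_id", "target_class", "scc", "passes"]
        ).astype({"scc": float, "passes": bool})

    def test_noise_free_planted_pair_retained_with_unit_pcc(self, noise_free_triad):
        matrix, targets, _i, truth = noise_free_triad
        from cernet.de import call_de

        edges = filter_mirna_targets(matrix, targets, de=call_de(matrix))
        cands = candidate_cerna_pairs(matrix, edges)
        t = truth.triads.iloc[0]
        assert (t.cerna_id, t.mrna_id) in set(zip(cands["cerna_id"], cands["mrna_id"]))
        assert (cands["pcc"] > 0.99).all()

    def test_pair_without_shared_retained_mirna_never_emitted(self):
        x = [1.0, 2, 3, 4, 5, 6]
        m = make_matrix(
            {"l1": x, "g1": x, "mir1": x[::-1], "mir2": x[::-1]},
            {"l1": "lncRNA", "g1": "mRNA", "mir1": "miRNA", "mir2": "miRNA"},
        )
        edges = self._edges(
            [("mir1", "l1", "lncRNA", -1.0, True), ("mir2", "g1", "mRNA", -1.0, True)]
        )
        assert len(candidate_cerna_pairs(m, edges)) == 0  # pcc = 1 but no shared miRNA

    def test_pcc_exactly_at_cutoff_is_dropped(self):
        x, y = PCC_EXACT_09
        assert pearson(x, y) == 0.9
        m = make_matrix(
            {"l1": x, "g1": y, "mir1": x[::-1]},
            {"l1": "lncRNA", "g1": "mRNA", "mir1": "miRNA"},
            n_per_group=3,
        )
        edges = self._edges(
            [("mir1", "l1", "lncRNA", -0.9, True), ("mir1", "g1", "mRNA", -0.9, True)]
        )
        cands = candidate_cerna_pairs(m, edges, pcc_cutoff=0.9, log2_scale=False)
        assert len(cands) == 0
        kept = candidate_cerna_pairs(m, edges, pcc_cutoff=0.89, log2_scale=False)
        assert len(kept) == 1

    def test_raising_pcc_cutoff_never_adds_pairs(self, fixture_dataset):
        matrix, targets, _i, _t = fixture_dataset
        from cernet.de import call_de

        edges = filter_mirna_targets(matrix, targets, de=call_de(matrix))
        counts = [
            len(candidate_cerna_pairs(matrix, edges, pcc_cutoff=c))
            for c in (0.5, 0.7, 0.9, 0.99)
        ]
        assert counts == sorted(counts, reverse=True)


def _intervals(rows):
    return AnnotationIntervals(
        records=pd.DataFrame(
            rows, columns=["feature_id", "chrom", "start", "end", "strand", "biotype"]
        )
    )


class TestCisTargets:
    def test_gap_of_exactly_window_is_included(self):
        lnc = _intervals([("l1", "chr1", 11_000, 11_500, "+", "lncRNA")])
        genes = _intervals([("g1", "chr1", 0, 1_000, "+", "protein_coding")])
        out = cis_targets(lnc, genes, window_bp=10_000)
        assert len(out) == 1 and out.iloc[0].distance_bp == 10_000

    def test_gap_one_past_window_is_excluded(self):
        lnc = _intervals([("l1", "chr1", 11_001, 11_500, "+", "lncRNA")])
        genes = _intervals([("g1", "chr1", 0, 1_000, "+", "protein_coding")])
        assert len(cis_targets(lnc, genes, window_bp=10_000)) == 0

    def test_overlap_has_distance_zero(self):
        lnc = _intervals([("l1", "chr1", 500, 1_500, "+", "lncRNA")])
        genes = _intervals([("g1", "chr1", 0, 1_000, "+", "protein_coding")])
        out = cis_targets(lnc, genes)
        assert out.iloc[0].distance_bp == 0

    def test_other_chromosome_and_non_coding_biotypes_ignored(self):
        lnc = _intervals([("l1", "chr1", 0, 500, "+", "lncRNA")])
        genes = _intervals(
            [
                ("g1", "chr2", 600, 1_000, "+", "protein_coding"),
                ("g2", "chr1", 600, 1_000, "+", "other"),
            ]
        )
        assert len(cis_targets(lnc, genes)) == 0

    @settings(max_examples=100, derandomize=True)
    @given(
        st.integers(0, 10**6), st.integers(1, 10**4),
        st.integers(0, 10**6), st.integers(1, 10**4),
    )
    def test_gap_is_symmetric(self, s1, w1, s2, w2):
        assert interval_gap(s1, s1 + w1, s2, s2 + w2) == interval_gap(s2, s2 + w2, s1, s1 + w1)


class TestTransTargets:
    def test_identical_profiles_included_with_unit_r(self):
        x = [1.0, 2, 3, 4, 5, 6]
        m = make_matrix({"l1": x, "g1": x}, {"l1": "lncRNA", "g1": "mRNA"})
        out = trans_targets(m, ["l1"], ["g1"], log2_scale=False)
        assert len(out) == 1 and out.iloc[0].pearson_r == 1.0

    def test_r_exactly_at_threshold_is_included(self):
        x, y = PCC_EXACT_095
        assert pearson(x, y) == 0.95
        m = make_matrix({"l1": x, "g1": y}, {"l1": "lncRNA", "g1": "mRNA"}, n_per_group=3)
        out = trans_targets(m, ["l1"], ["g1"], threshold=0.95, log2_scale=False)
        assert len(out) == 1 and out.iloc[0].pearson_r == 0.95

    def test_null_inclusion_rate_matches_analytic_null(self):
        """For independent Gaussian pairs at n = 6, P(|r| >= 0.95) has the exact
        t-distribution form; the empirical inclusion rate must agree."""
        from scipy.stats import t as tdist

        r0, n = 0.95, 6
        t0 = r0 * np.sqrt(n - 2) / np.sqrt(1 - r0**2)
        p_null = 2 * tdist.sf(t0, n - 2)
        rng = np.random.default_rng(9)
        n_pairs = 3000
        rows = {f"l{i}": rng.normal(10, 1, 6) for i in range(n_pairs)}
        hits = 0
        for i in range(0, n_pairs, 2):
            hits += abs(pearson(rows[f"l{i}"], rows[f"l{i+1}"])) >= r0
        n_tested = n_pairs // 2
        se = np.sqrt(p_null * (1 - p_null) / n_tested)
        assert abs(hits / n_tested - p_null) <= 4 * se + 2 / n_tested
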