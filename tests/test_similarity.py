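import math

import numpy as np
import pytest

from connfp.exceptions import ValidationError
from connfp.io import STRUCTURAL, ConnectomeMatrix
from connfp.similarity import (
    SimilarityMatrix,
    density_mask,
    identifiability,
    masked_spearman,
    row_max_normalize,
    similarity_matrix,
    threshold_sweep,
    zscore_rows,
)
from tests.conftest import random_connectome


def average_ranks(v: np.ndarray) -> np.ndarray:
    """Independent average-rank computation (no scipy)."""
    v = np.asarray(v, dtype=float)
    ranks = np.empty(v.size)
    order = np.argsort(v, kind="stable")
    sv = v[order]
    i = 0
    while i < v.size:
        j = i
        while j + 1 < v.size and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1  # average of 1-based ranks
        i = j + 1
    return ranks


def brute_spearman(a, b) -> float:
    """Oracle: Pearson correlation of average ranks."""
    return float(np.corrcoef(average_ranks(a), average_ranks(b))[0, 1])


def conn(w):
    return ConnectomeMatrix("s", 1, STRUCTURAL, np.asarray(w, dtype=float))


def sym(n, upper_values):
    w = np.zeros((n, n))
    w[np.triu_indices(n, 1)] = upper_values
    return w + w.T


class TestDensityMask:
    def test_full_density_keeps_every_pair(self):
        rng = np.random.default_rng(0)
        cm = random_connectome(rng, n=6)
        mask = density_mask(cm, 1.0)
        assert mask.sum() == 6 * 5  # symmetric count
        assert not mask.diagonal().any()

    def test_toy_keeps_exactly_the_largest_edges(self):
        w = sym(4, [10, 9, 8, 3, 2, 1])
        mask = density_mask(w, 0.5)
        iu = np.triu_indices(4, 1)
        kept = set(zip(*[idx[mask[iu]] for idx in iu]))
        edge_weights = {(i, j): w[i, j] for i, j in zip(*iu)}
        top3 = set(sorted(edge_weights, key=edge_weights.get, reverse=True)[:3])
        assert kept == top3 and len(kept) == 3

    def test_quarter_density_on_90_nodes_keeps_1002_pairs(self):
        rng = np.random.default_rng(1)
        cm = random_connectome(rng, n=90)
        mask = density_mask(cm, 0.25)
        assert mask.sum() // 2 == math.ceil(0.25 * 90 * 89 / 2) == 1002

    def test_ties_broken_by_lexicographic_pair_order(self):
        w = sym(4, [5, 5, 5, 5, 5, 5])
        mask = density_mask(w, 0.5)
        iu = np.triu_indices(4, 1)
        kept = [tuple(p) for p in zip(*iu) if mask[p]]
        assert kept == [(0, 1), (0, 2), (0, 3)]  # first 3 pairs in (i,j) order

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.2])
    def test_density_outside_unit_interval_rejected(self, bad):
        rng = np.random.default_rng(2)
        with pytest.raises(ValidationError):
            density_mask(random_connectome(rng, n=5), bad)


class TestMaskedSpearman:
    def test_self_identity_and_monotone_transform_give_one(self):
        rng = np.random.default_rng(3)
        cm = random_connectome(rng, n=8)
        mask = density_mask(cm, 0.5)
        assert masked_spearman(cm, cm, mask) == pytest.approx(1.0)
        cubed = conn(cm.weights**3)
        assert masked_spearman(cm, cubed, mask) == pytest.approx(1.0)

    def test_hand_ranked_vectors(self):
        # untied ranks: rho = 1 - 6*sum(d^2)/(n(n^2-1))
        a = conn(sym(4, [1, 2, 3, 4, 5, 0]))
        rev = conn(sym(4, [5, 4, 3, 2, 1, 0]))
        perm = conn(sym(4, [1, 3, 2, 5, 4, 0]))
        mask = sym(4, [1, 1, 1, 1, 1, 0]).astype(bool)
        assert masked_spearman(a, rev, mask) == pytest.approx(-1.0)
        # d^2 sums to 4 across (1,2,3,4,5) vs (1,3,2,5,4): 1 - 24/120 = 0.8
        assert masked_spearman(a, perm, mask) == pytest.approx(0.8)

    def test_agrees_with_brute_force_oracle_including_ties(self):
        rng = np.random.default_rng(4)
        for trial in range(200):
            n = rng.integers(3, 13)
            a = rng.integers(0, 6, size=n).astype(float)  # heavy ties
            b = rng.integers(0, 6, size=n).astype(float)
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                continue
            # embed the vectors as the first n upper-triangle edges of an
            # (n+1)-node graph and mask exactly those edges
            w1 = np.zeros(((n + 1), (n + 1)))
            w2 = np.zeros_like(w1)
            iu = np.triu_indices(n + 1, 1)
            w1[iu[0][:n], iu[1][:n]] = a
            w2[iu[0][:n], iu[1][:n]] = b
            w1, w2 = w1 + w1.T, w2 + w2.T
            mask = np.zeros_like(w1, dtype=bool)
            mask[iu[0][:n], iu[1][:n]] = True
            mask |= mask.T
            got = masked_spearman(w1, w2, mask)
            assert got == pytest.approx(brute_spearman(a, b), abs=1e-12)

    def test_too_few_retained_pairs_rejected(self):
        rng = np.random.default_rng(5)
        cm = random_connectome(rng, n=5)
        mask = np.zeros((5, 5), dtype=bool)
        mask[0, 1] = mask[1, 0] = True
        with pytest.raises(ValidationError, match="at least 3"):
            masked_spearman(cm, cm, mask)


class TestSimilarityMatrix:
    def test_identical_subjects_are_exchangeable(self):
        rng = np.random.default_rng(6)
        w = random_connectome(rng, n=10).weights
        tp1 = [ConnectomeMatrix(s, 1, STRUCTURAL, w) for s in ("a", "b")]
        tp2 = [ConnectomeMatrix(s, 2, STRUCTURAL, w) for s in ("a", "b")]
        sim = similarity_matrix(tp1, tp2, density=0.5)
        assert np.ptp(sim.values) == 0.0

    def test_strong_fingerprint_diagonal_dominates(self, strong_fingerprint_cohort):
        tp1, tp2 = strong_fingerprint_cohort.sc_pair()
        sim = similarity_matrix(tp1, tp2, density=0.25)
        off = sim.values - np.diagonal(sim.values)[:, None]
        assert (off[~np.eye(sim.n, dtype=bool)] < 0).all()

    def test_subject_set_mismatch_rejected(self):
        rng = np.random.default_rng(7)
        tp1 = [random_connectome(rng, subject_id="a"), random_connectome(rng, subject_id="b")]
        tp2 = [random_connectome(rng, subject_id="a"), random_connectome(rng, subject_id="c")]
        with pytest.raises(ValidationError, match="subject"):
            similarity_matrix(tp1, tp2)

    def test_invariant_to_monotone_transform_of_either_timepoint(self):
        rng = np.random.default_rng(8)
        tp1 = [random_connectome(rng, n=12, subject_id=f"s{i}") for i in range(4)]
        tp2 = [random_connectome(rng, n=12, subject_id=f"s{i}", timepoint=2)
               for i in range(4)]
        base = similarity_matrix(tp1, tp2, density=0.3)
        tp2_t = [ConnectomeMatrix(c.subject_id, 2, STRUCTURAL, np.expm1(c.weights))
                 for c in tp2]
        tp1_t = [ConnectomeMatrix(c.subject_id, 1, STRUCTURAL, c.weights**3)
                 for c in tp1]
        np.testing.assert_allclose(
            similarity_matrix(tp1, tp2_t, density=0.3).values, base.values, atol=1e-12
        )
        # monotone transform of timepoint 1 also preserves its density mask
        np.testing.assert_allclose(
            similarity_matrix(tp1_t, tp2, density=0.3).values, base.values, atol=1e-12
        )

    def test_density_none_compares_all_pairs(self):
        rng = np.random.default_rng(9)
        tp1 = [random_connectome(rng, n=8, subject_id="a")]
        tp2 = [random_connectome(rng, n=8, subject_id="a", timepoint=2)]
        sim = similarity_matrix(tp1, tp2, density=None)
        from tests.test_similarity import brute_spearman as bs
        iu = np.triu_indices(8, 1)
        assert sim.values[0, 0] == pytest.approx(
            bs(tp1[0].weights[iu], tp2[0].weights[iu]), abs=1e-12
        )

    @pytest.mark.parametrize("convention", ["row", "union", "intersection"])
    def test_mask_conventions_all_run_and_match_on_diagonal(self, convention):
        rng = np.random.default_rng(10)
        tp1 = [random_connectome(rng, n=12, subject_id=f"s{i}") for i in range(3)]
        tp2 = [random_connectome(rng, n=12, subject_id=f"s{i}", timepoint=2)
               for i in range(3)]
        sim = similarity_matrix(tp1, tp2, density=0.5, mask_convention=convention)
        row = similarity_matrix(tp1, tp2, density=0.5, mask_convention="row")
        # self-comparisons use the subject's own mask under every convention
        np.testing.assert_allclose(np.diagonal(sim.values), np.diagonal(row.values))


class TestIdentifiability:
    def test_diagonal_dominance_gives_full_rate(self):
        v = np.full((5, 5), 0.5) + 0.5 * np.eye(5)
        res = identifiability(SimilarityMatrix(v, list("abcde"), 0.25, STRUCTURAL))
        assert res.rate == 1.0 and res.n_matched == 5

    def test_ties_count_as_non_matches(self):
        v = np.full((4, 4), 0.7)
        res = identifiability(SimilarityMatrix(v, list("abcd"), 0.25, STRUCTURAL))
        assert res.rate == 0.0

    def test_matches_brute_force_row_scan(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            v = rng.uniform(-1, 1, size=(6, 6))
            res = identifiability(SimilarityMatrix(v, list("abcdef"), None, STRUCTURAL))
            expected = sum(
                all(v[i, i] > v[i, j] for j in range(6) if j != i) for i in range(6)
            )
            assert res.n_matched == expected
            assert res.rate == expected / 6


class TestRowTransforms:
    def test_row_max_normalize_example_and_idempotence(self):
        v = np.array([[0.9, 0.6, 0.3], [0.2, 0.8, 0.4], [0.1, 0.2, 0.5]])
        s = SimilarityMatrix(v, list("abc"), None, STRUCTURAL)
        norm = row_max_normalize(s)
        np.testing.assert_allclose(norm.values[0], [1.0, 2 / 3, 1 / 3])
        assert (norm.values.max(axis=1) == 1.0).all()
        np.testing.assert_allclose(row_max_normalize(norm).values, norm.values)

    def test_row_max_nonpositive_rejected(self):
        v = np.array([[-0.1, -0.5, -0.2], [0.2, 0.8, 0.4], [0.1, 0.2, 0.5]])
        with pytest.raises(ValidationError, match="maximum"):
            row_max_normalize(SimilarityMatrix(v, list("abc"), None, STRUCTURAL))

    def test_zscore_closed_form_and_moments(self):
        v = np.array([[0.1, 0.2, 0.3], [0.5, 0.5, 0.8], [0.0, 0.1, -0.1]])
        z = zscore_rows(SimilarityMatrix(v, list("abc"), None, STRUCTURAL))
        np.testing.assert_allclose(z.values[0], [-1.0, 0.0, 1.0], atol=1e-12)
        np.testing.assert_allclose(z.values.mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(z.values.std(axis=1, ddof=1), 1.0, atol=1e-10)

    def test_transforms_preserve_identifiability(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            v = rng.uniform(0.05, 1.0, size=(7, 7))
            s = SimilarityMatrix(v, list("abcdefg"), None, STRUCTURAL)
            base = identifiability(s).matched
            np.testing.assert_array_equal(
                identifiability(row_max_normalize(s)).matched, base
            )
            np.testing.assert_array_equal(
                identifiability(zscore_rows(s)).matched, base
            )


class TestThresholdSweep:
    def test_strong_fingerprint_plateaus_at_full_rate(self, strong_fingerprint_cohort):
        tp1, tp2 = strong_fingerprint_cohort.sc_pair()
        sweep = threshold_sweep(tp1, tp2, [0.1, 0.25, 0.5, 1.0])
        assert (sweep.table["rate"] == 1.0).all()
        assert sweep.best_densities == [0.1, 0.25, 0.5, 1.0]

    def test_single_density_matches_direct_computation(self, strong_fingerprint_cohort):
        tp1, tp2 = strong_fingerprint_cohort.sc_pair()
        sweep = threshold_sweep(tp1, tp2, [1.0])
        direct = identifiability(similarity_matrix(tp1, tp2, density=1.0))
        assert sweep.table.loc[0, "n_matched"] == direct.n_matched

    def test_empty_density_list_rejected(self, strong_fingerprint_cohort):
        tp1, tp2 = strong_fingerprint_cohort.sc_pair()
        with pytest.raises(ValidationError):
            threshold_sweep(tp1, tp2, [])
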