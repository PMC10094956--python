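"""Descriptor providers and the sensitivity-analysis selectors."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from haptenml.featurize import (
    DescriptorMatrix,
    FileProvider,
    RDKit2DProvider,
    cfs_merit,
    compute_descriptors,
    equal_frequency_bins,
    impute_median,
    make_input_vector,
    rank_correlation,
    rank_info_gain,
    select_cfs,
)


def matrix_from(values, names=None):
    values = np.asarray(values, dtype=float)
    return DescriptorMatrix(
        row_ids=[f"r{i}" for i in range(values.shape[0])],
        descriptor_names=names or [f"f{j}" for j in range(values.shape[1])],
        values=values,
        provider_id="test",
    )


@pytest.fixture(scope="module")
def provider():
    return RDKit2DProvider()


class TestProviders:
    def test_identical_smiles_give_identical_rows(self, provider):
        m = compute_descriptors(["CCO", "CCO"], provider, row_ids=["a", "b"])
        np.testing.assert_array_equal(m.values[0], m.values[1])

    def test_column_count_matches_declared_descriptors(self, provider):
        m = compute_descriptors(["c1ccccc1"], provider)
        assert m.values.shape == (1, len(provider.descriptor_names))

    def test_benzene_molecular_weight(self, provider):
        # independent oracle: 6 C (12.011) + 6 H (1.008)
        expected = 6 * 12.011 + 6 * 1.008
        m = compute_descriptors(["c1ccccc1"], provider)
        mw = m.values[0, m.descriptor_names.index("MolWt")]
        assert mw == pytest.approx(expected, abs=0.01)

    def test_unparseable_smiles_named_in_error(self, provider):
        with pytest.raises(ValueError, match="not-a-smiles"):
            compute_descriptors(["not-a-smiles"], provider)

    def test_file_provider_round_trip_and_missing_key(self):
        base = matrix_from([[1.0, 2.0], [3.0, 4.0]])
        fp = FileProvider(base)
        np.testing.assert_array_equal(fp.compute("r1"), [3.0, 4.0])
        with pytest.raises(ValueError, match="nope"):
            fp.compute("nope")


class TestCorrelationRanking:
    def test_label_column_scores_one_constant_scores_zero(self):
        y = [0, 1, 0, 1]
        m = matrix_from(
            np.column_stack([y, np.ones(4)]), names=["same_as_label", "const"]
        )
        r = rank_correlation(m, y)
        assert r.scores["same_as_label"] == pytest.approx(1.0)
        assert r.scores["const"] == 0.0
        assert r.order[0] == "same_as_label"

    def test_hand_computed_pearson(self):
        x = np.array([1.0, 2.0, 4.0, 5.0])
        y = np.array([0, 0, 1, 1])
        n = 4
        num = (x * y).sum() - n * x.mean() * y.mean()
        den = math.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        expected = abs(num / den)
        r = rank_correlation(matrix_from(x[:, None]), y)
        assert r.scores["f0"] == pytest.approx(expected)

    def test_too_few_rows_is_error(self):
        with pytest.raises(ValueError, match="3 rows"):
            rank_correlation(matrix_from([[1.0], [2.0]]), [0, 1])

    def test_tie_break_is_lexicographic(self):
        y = [0, 1, 0, 1]
        col = np.array(y, dtype=float)
        m = matrix_from(np.column_stack([col, col]), names=["zeta", "alpha"])
        assert rank_correlation(m, y).order == ["alpha", "zeta"]


class TestInfoGain:
    def test_perfect_predictor_scores_class_entropy(self):
        y = [0, 0, 0, 1, 1, 1]
        col = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        r = rank_info_gain(matrix_from(col[:, None]), y, n_bins=2)
        assert r.scores["f0"] == pytest.approx(1.0)  # H(Y) = 1 bit at 3:3

    def test_constant_column_scores_zero(self):
        y = [0, 0, 0, 1, 1, 1]
        r = rank_info_gain(matrix_from(np.ones((6, 1))), y, n_bins=2)
        assert r.scores["f0"] == 0.0

    def test_six_row_contingency_brute_force(self):
        y = np.array([0, 0, 1, 0, 1, 1])
        col = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        bins = equal_frequency_bins(col, 2)
        # brute-force entropy bookkeeping over the 2x2 contingency table
        def H(counts):
            tot = sum(counts)
            return -sum(c / tot * math.log2(c / tot) for c in counts if c)

        h_y = H([(y == 0).sum(), (y == 1).sum()])
        h_cond = 0.0
        for b in np.unique(bins):
            mask = bins == b
            h_cond += mask.mean() * H([(y[mask] == 0).sum(), (y[mask] == 1).sum()])
        r = rank_info_gain(matrix_from(col[:, None]), y, n_bins=2)
        assert r.scores["f0"] == pytest.approx(h_y - h_cond)

    def test_invariant_to_monotone_transform(self):
        gen = np.random.default_rng(5)
        col = gen.normal(size=30)
        y = (col + gen.normal(0, 0.5, 30) > 0).astype(int)
        a = rank_info_gain(matrix_from(col[:, None]), y, n_bins=5).scores["f0"]
        b = rank_info_gain(matrix_from(np.exp(col)[:, None]), y, n_bins=5).scores["f0"]
        assert a == pytest.approx(b)

    def test_gain_ratio_normalizes_by_bin_entropy(self):
        y = [0, 0, 0, 1, 1, 1]
        col = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        ig = rank_info_gain(matrix_from(col[:, None]), y, n_bins=2).scores["f0"]
        gr = rank_info_gain(matrix_from(col[:, None]), y, n_bins=2, gain_ratio=True).scores["f0"]
        assert gr == pytest.approx(ig / 1.0)  # equal-frequency split: H(bin) = 1

    def test_degenerate_labels_are_error(self):
        with pytest.raises(ValueError, match="constant"):
            rank_info_gain(matrix_from(np.arange(4.0)[:, None]), [1, 1, 1, 1])


def exhaustive_cfs(matrix, labels):
    """Oracle: maximize the CFS merit over all non-empty subsets."""
    y = np.asarray(labels, dtype=float)
    X = matrix.values
    d = X.shape[1]

    def absr(u, v):
        if u.std() == 0 or v.std() == 0:
            return 0.0
        return abs(float(np.corrcoef(u, v)[0, 1]))

    corr_cf = np.array([absr(X[:, j], y) for j in range(d)])
    corr_ff = np.zeros((d, d))
    for a in range(d):
        for b in range(d):
            if a != b:
                corr_ff[a, b] = absr(X[:, a], X[:, b])
    best, best_merit = None, -1.0
    for k in range(1, d + 1):
        for subset in itertools.combinations(range(d), k):
            m = cfs_merit(list(subset), corr_cf, corr_ff)
            if m > best_merit + 1e-12:
                best, best_merit = set(subset), m
    return {matrix.descriptor_names[j] for j in best}, best_merit


class TestCfs:
    def test_duplicate_informative_feature_is_penalized(self):
        gen = np.random.default_rng(0)
        y = np.tile([0, 1], 10)
        sig = y + gen.normal(0, 0.1, 20)
        m = matrix_from(np.column_stack([sig, sig]), names=["a", "a_copy"])
        assert len(select_cfs(m, y)) == 1

    def test_label_feature_beats_noise(self):
        gen = np.random.default_rng(1)
        y = np.tile([0, 1], 8)
        m = matrix_from(
            np.column_stack([y.astype(float), gen.normal(size=16), gen.normal(size=16)]),
            names=["label_copy", "n1", "n2"],
        )
        assert select_cfs(m, y)[0] == "label_copy"

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_greedy_matches_exhaustive_on_five_features(self, seed):
        gen = np.random.default_rng(seed)
        n = 40
        y = np.tile([0, 1], n // 2)
        cols = [
            y + gen.normal(0, 0.8, n),
            y + gen.normal(0, 2.0, n),
            gen.normal(size=n),
            gen.normal(size=n),
            y * 0.5 + gen.normal(0, 1.5, n),
        ]
        m = matrix_from(np.column_stack(cols))
        greedy = set(select_cfs(m, y))
        oracle, _ = exhaustive_cfs(m, y)
        assert greedy == oracle


class TestInputVector:
    def test_prefix_of_ranking(self):
        names = [f"d{i:02d}" for i in range(30)]
        assert make_input_vector(names, 24) == names[:24]

    def test_degenerate_and_oversized_requests_are_errors(self):
        with pytest.raises(ValueError):
            make_input_vector(["a", "b"], 0)
        with pytest.raises(ValueError):
            make_input_vector(["a", "b"], 3)

    def test_configured_sizes_for_both_endpoints(self):
        names = [f"d{i:02d}" for i in range(40)]
        for size in (9, 17, 24, 11, 26):
            assert len(make_input_vector(names, size)) == size


@given(st.integers(0, 2**31 - 1))
def test_rankings_are_permutation_equivariant(seed):
    gen = np.random.default_rng(seed)
    n = 16
    y = np.tile([0, 1], n // 2)
    X = np.column_stack([y + gen.normal(0, 1, n), gen.normal(size=n)])
    perm = gen.permutation(n)
    a = rank_correlation(matrix_from(X), y)
    b = rank_correlation(matrix_from(X[perm]), y[perm])
    for name in a.scores:
        assert a.scores[name] == pytest.approx(b.scores[name])
    ia = rank_info_gain(matrix_from(X), y, n_bins=4)
    ib = rank_info_gain(matrix_from(X[perm]), y[perm], n_bins=4)
    for name in ia.scores:
        assert ia.scores[name] == pytest.approx(ib.scores[name])


def test_impute_median_uses_training_medians_only():
    train = np.array([[1.0, np.nan], [3.0, 2.0], [5.0, 4.0]])
    test = np.array([[np.nan, np.nan]])
    tr, te = impute_median(train, test)
    assert tr[0, 1] == 3.0  # median of the observed column values
    np.testing.assert_array_equal(te, [[3.0, 3.0]])  # training medians, no peeking
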