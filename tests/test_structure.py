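"""Binary encoding, distances, PCoA and permutation AMOVA."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epimsap import (
    BinaryEpiMatrix,
    MSAPMatrix,
    amova,
    encode_binary,
    pairwise_distance,
    pcoa,
    select_msl,
)


def binmat(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"i{k}" for k in range(values.shape[0])]
    return BinaryEpiMatrix(ids, [f"L{j}" for j in range(values.shape[1])], values)


def centroid_ssd_phi(X, labels):
    """Independent AMOVA oracle via centroid sums of squares (not distances)."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    N = len(X)
    groups = np.unique(labels)
    G = len(groups)
    ss_total = ((X - X.mean(axis=0)) ** 2).sum()
    ss_within = sum(
        ((X[labels == g] - X[labels == g].mean(axis=0)) ** 2).sum() for g in groups
    )
    ss_among = ss_total - ss_within
    sizes = np.array([(labels == g).sum() for g in groups])
    sigma_w = ss_within / (N - G)
    n0 = (N - (sizes**2).sum() / N) / (G - 1)
    sigma_a = (ss_among / (G - 1) - sigma_w) / n0
    return sigma_a / (sigma_a + sigma_w)


class TestEncodeBinary:
    def test_restricts_to_polymorphic_msl_and_maps_states(self):
        # mono: all unmethylated (NML); rare: methylated but only one type I
        # carrier (MSL, not polymorphic); poly: polymorphic MSL
        calls = np.array(
            [
                [1, 4, 2],
                [1, 4, 3],
                [1, 4, 4],
                [1, 4, 1],
                [1, 1, 1],
            ],
            dtype=np.int8,
        )
        m = MSAPMatrix(
            individuals=list("abcde"),
            groups=["g"] * 5,
            loci=["mono", "rare", "poly"],
            calls=calls,
        )
        part = select_msl(m)
        b = encode_binary(m, part)
        assert b.loci == ["poly"]
        np.testing.assert_array_equal(b.values[:, 0], [1, 1, 1, 0, 0])

    def test_missing_propagates(self):
        calls = np.array([[2, -1], [1, 2], [1, 4], [1, 1], [1, 1]], dtype=np.int8)
        m = MSAPMatrix(list("abcde"), ["g"] * 5, ["x", "y"], calls)
        b = encode_binary(m, select_msl(m))
        col = b.values[:, b.loci.index("y")]
        assert np.isnan(col[0]) and col[1] == 1

    def test_locus_mismatch_rejected(self):
        calls = np.array([[2], [1], [1]], dtype=np.int8)
        m = MSAPMatrix(list("abc"), ["g"] * 3, ["x"], calls)
        part = select_msl(m)
        other = MSAPMatrix(list("abc"), ["g"] * 3, ["z"], calls)
        with pytest.raises(ValueError):
            encode_binary(other, part)


class TestDistances:
    def test_identical_rows_distance_zero(self):
        d = pairwise_distance(binmat([[0, 1, 0], [0, 1, 0]]))
        assert d.values[0, 1] == 0.0

    def test_opposite_rows(self):
        d = pairwise_distance(binmat([[0, 0, 0], [1, 1, 1]]))
        assert d.values[0, 1] == pytest.approx(np.sqrt(3))

    def test_single_difference(self):
        d = pairwise_distance(binmat([[0, 1], [1, 1]]))
        assert d.values[0, 1] == pytest.approx(1.0)

    def test_missing_rescaling(self):
        # one of two shared loci differs; rescale by sqrt(3/2)
        d = pairwise_distance(binmat([[0, 1, np.nan], [1, 1, 0]]))
        assert d.values[0, 1] == pytest.approx(np.sqrt(1 * 3 / 2))

    def test_no_shared_loci_errors_with_pair_names(self):
        with pytest.raises(ValueError, match="i0.*i1"):
            pairwise_distance(binmat([[np.nan, 1], [1, np.nan]]))


class TestPCoA:
    def test_identical_individuals_coincide(self):
        res = pcoa(pairwise_distance(binmat([[0, 1], [0, 1], [1, 0]])))
        np.testing.assert_allclose(
            res.coordinates.iloc[0], res.coordinates.iloc[1], atol=1e-9
        )

    def test_right_triangle_embedding_reproduces_distances(self):
        from epimsap import DistanceMatrix

        d = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0, 1, np.sqrt(2)], [1, 0, 1], [np.sqrt(2), 1, 0]]),
        )
        res = pcoa(d, n_axes=3)
        coords = res.coordinates.to_numpy()
        for i in range(3):
            for j in range(3):
                assert np.linalg.norm(coords[i] - coords[j]) == pytest.approx(
                    d.values[i, j], abs=1e-9
                )

    def test_variance_fractions_sum_to_at_most_one(self):
        rng = np.random.default_rng(7)
        X = rng.integers(0, 2, size=(10, 20)).astype(float)
        res = pcoa(pairwise_distance(binmat(X)), n_axes=5)
        assert res.proportion_explained.sum() <= 1 + 1e-12

    def test_eigenvalue_sum_equals_centered_trace(self):
        rng = np.random.default_rng(11)
        X = rng.integers(0, 2, size=(9, 15)).astype(float)
        d = pairwise_distance(binmat(X))
        res = pcoa(d)
        D2 = d.values**2
        n = D2.shape[0]
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ D2 @ J
        assert res.eigenvalues.sum() == pytest.approx(np.trace(B), abs=1e-9)

    def test_truncation_warning(self):
        with pytest.warns(UserWarning, match="positive eigenvalues"):
            pcoa(pairwise_distance(binmat([[0, 1], [1, 0], [0, 0]])), n_axes=5)

    def test_matches_scikit_bio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(3)
        X = rng.integers(0, 2, size=(12, 25)).astype(float)
        d = pairwise_distance(binmat(X))
        ours = pcoa(d, n_axes=3)
        theirs = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(d.values, ids=d.ids), number_of_dimensions=3
        )
        np.testing.assert_allclose(
            np.abs(ours.coordinates.to_numpy()),
            np.abs(theirs.samples.to_numpy()[:, :3]),
            atol=1e-8,
        )


class TestAmova:
    def test_perfect_separation_phi_one_exact_p(self):
        b = binmat([[0, 0, 0], [0, 0, 0], [1, 1, 1], [1, 1, 1]])
        res = amova(b, ["a", "a", "b", "b"], n_permutations=9999, seed=0)
        assert res.phi_st == pytest.approx(1.0)
        # 3 distinct 2+2 partitions, one achieving phi >= 1
        assert res.p_value == pytest.approx(1 / 3, abs=0.02)

    def test_matches_centroid_oracle_on_small_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(4, 9))
            labels = np.array(["a"] * (n // 2) + ["b"] * (n - n // 2))
            X = rng.integers(0, 2, size=(n, 12)).astype(float)
            res = amova(binmat(X), labels, n_permutations=10, seed=0)
            assert res.phi_st == pytest.approx(centroid_ssd_phi(X, labels), abs=1e-10)

    def test_three_group_oracle(self):
        rng = np.random.default_rng(5)
        X = rng.integers(0, 2, size=(9, 10)).astype(float)
        labels = ["a", "a", "a", "b", "b", "b", "c", "c", "c"]
        res = amova(binmat(X), labels, n_permutations=10, seed=0)
        assert res.phi_st == pytest.approx(centroid_ssd_phi(X, labels), abs=1e-10)

    def test_seed_reproducibility_and_locus_order_invariance(self):
        rng = np.random.default_rng(8)
        X = rng.integers(0, 2, size=(10, 16)).astype(float)
        labels = ["a"] * 5 + ["b"] * 5
        r1 = amova(binmat(X), labels, n_permutations=299, seed=11)
        r2 = amova(binmat(X), labels, n_permutations=299, seed=11)
        assert (r1.phi_st, r1.p_value) == (r2.phi_st, r2.p_value)
        perm = rng.permutation(16)
        r3 = amova(binmat(X[:, perm]), labels, n_permutations=299, seed=11)
        assert r3.phi_st == pytest.approx(r1.phi_st) and r3.p_value == r1.p_value

    def test_group_relabeling_invariance(self):
        rng = np.random.default_rng(9)
        X = rng.integers(0, 2, size=(8, 10)).astype(float)
        r1 = amova(binmat(X), ["a"] * 4 + ["b"] * 4, n_permutations=99, seed=2)
        r2 = amova(binmat(X), ["zzz"] * 4 + ["yyy"] * 4, n_permutations=99, seed=2)
        assert r1.phi_st == pytest.approx(r2.phi_st)

    def test_unbalanced_null_is_nonsignificant(self):
        # mirrors a 5-vs-22 comparison of groups drawn from one distribution
        rng = np.random.default_rng(1)
        X = (rng.random((27, 60)) < 0.4).astype(float)
        labels = ["ctrl"] * 5 + ["azaC"] * 22
        res = amova(binmat(X), labels, n_permutations=999, seed=4)
        assert abs(res.phi_st) < 0.1
        assert res.p_value > 0.05

    def test_small_group_rejected(self):
        b = binmat([[0, 1], [1, 0], [1, 1]])
        with pytest.raises(ValueError):
            amova(b, ["a", "b", "b"], n_permutations=9)

    def test_p_value_floor(self):
        b = binmat([[0, 0], [0, 0], [1, 1], [1, 1]])
        res = amova(b, ["a", "a", "b", "b"], n_permutations=99, seed=0)
        assert res.p_value >= 1 / 100
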