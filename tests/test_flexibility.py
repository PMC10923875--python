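import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brainflex import (
    FunctionalMatrixSequence,
    ModuleTemplate,
    WindowSpec,
    affiliation_vector,
    distance_flexibility,
    flexibility_series,
    generate_synthetic_template,
    module_strengths,
    read_template,
    template_flexibility,
)

# ---------------------------------------------------------------- oracles


def strengths_loop(A, M, K):
    """Triple-loop module-strength oracle."""
    N, P = M.shape
    H = np.zeros((N, P))
    for i in range(N):
        for j in range(P):
            H[i, j] = sum(abs(A[i, l]) * M[l, j] for l in range(N)) / K[j]
    return H


def distance_loop(A, B):
    """Element-wise two-pass Pearson-distance oracle (diagonal included)."""
    N = A.shape[0]
    ma = sum(A[i, j] for i in range(N) for j in range(N)) / N**2
    mb = sum(B[i, j] for i in range(N) for j in range(N)) / N**2
    num = sum((A[i, j] - ma) * (B[i, j] - mb) for i in range(N) for j in range(N))
    da = sum((A[i, j] - ma) ** 2 for i in range(N) for j in range(N)) ** 0.5
    db = sum((B[i, j] - mb) ** 2 for i in range(N) for j in range(N)) ** 0.5
    return 1 - num / (da * db)


def random_sym(rng, n):
    A = rng.normal(size=(n, n))
    A = (A + A.T) / 2
    np.fill_diagonal(A, 1.0)
    return A


# ---------------------------------------------------------------- template


class TestModuleTemplate:
    def test_identity_template(self):
        t = ModuleTemplate(np.eye(4))
        np.testing.assert_array_equal(t.module_sizes, 1)

    def test_rejects_empty_module_and_nonbinary(self):
        M = np.zeros((3, 2))
        M[:, 0] = 1
        with pytest.raises(ValueError, match="empty"):
            ModuleTemplate(M)
        with pytest.raises(ValueError, match="binary"):
            ModuleTemplate(np.full((2, 2), 0.5))

    def test_generator_single_membership_and_coverage(self):
        t = generate_synthetic_template(30, 5, seed=4)
        assert t.M.shape == (30, 5)
        np.testing.assert_array_equal(t.M.sum(axis=1), 1)  # one module per region
        assert np.all(t.module_sizes >= 1)
        t2 = generate_synthetic_template(30, 5, seed=4)
        np.testing.assert_array_equal(t.M, t2.M)

    def test_mapping_file_roundtrip(self, tmp_path):
        p = tmp_path / "map.tsv"
        p.write_text("1\t1\n2\t2\n3\t1\n")
        t = read_template(p)
        np.testing.assert_array_equal(t.M, [[1, 0], [0, 1], [1, 0]])

    def test_mapping_file_empty_module_errors(self, tmp_path):
        p = tmp_path / "map.tsv"
        p.write_text("1\t1\n2\t3\n3\t1\n")  # module 2 receives nothing
        with pytest.raises(ValueError, match="empty"):
            read_template(p)

    def test_binary_matrix_file(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("1,0\n0,1\n1,0\n")
        t = read_template(p)
        assert t.n_regions == 3 and t.n_modules == 2


# ---------------------------------------------------------------- operations


class TestModuleStrengths:
    def test_identity_case(self):
        H = module_strengths(np.eye(2), ModuleTemplate(np.eye(2)))
        np.testing.assert_array_equal(H, np.eye(2))

    def test_all_ones_single_module(self):
        N = 5
        A = np.ones((N, N))
        t = ModuleTemplate(np.ones((N, 1)))
        np.testing.assert_allclose(module_strengths(A, t), 1.0)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(8)
        A = random_sym(rng, 6)
        t = generate_synthetic_template(6, 3, seed=9)
        expect = strengths_loop(A, t.M, t.module_sizes)
        np.testing.assert_allclose(module_strengths(A, t), expect, atol=1e-12)


class TestAffiliation:
    def test_argmax_and_tie_rule(self):
        H = np.array([[0.2, 0.9, 0.1], [0.5, 0.5, 0.1]])
        np.testing.assert_array_equal(affiliation_vector(H), [2, 1])

    def test_matches_row_scan_oracle(self):
        rng = np.random.default_rng(10)
        H = rng.random((20, 5))
        expect = [max(range(5), key=lambda j: (H[i, j], -j)) + 1 for i in range(20)]
        np.testing.assert_array_equal(affiliation_vector(H), expect)


class TestTemplateFlexibility:
    @pytest.mark.parametrize(
        "prev,cur,expected",
        [
            ([1, 2, 3], [1, 2, 3], 0.0),
            ([1, 2, 3], [2, 3, 1], 1.0),
            ([1, 1, 1, 1], [1, 1, 1, 2], 0.25),
        ],
    )
    def test_fraction_changed(self, prev, cur, expected):
        assert template_flexibility(np.array(prev), np.array(cur)) == expected

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(11)
        prev = rng.integers(1, 5, size=30)
        cur = rng.integers(1, 5, size=30)
        relabel = {1: 3, 2: 1, 3: 4, 4: 2}
        prev2 = np.array([relabel[x] for x in prev])
        cur2 = np.array([relabel[x] for x in cur])
        assert template_flexibility(prev, cur) == template_flexibility(prev2, cur2)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            template_flexibility(np.array([1, 2]), np.array([1, 2, 3]))


class TestDistanceFlexibility:
    def test_identical_matrices(self):
        rng = np.random.default_rng(12)
        A = random_sym(rng, 5)
        assert distance_flexibility(A, A) == pytest.approx(0.0, abs=1e-12)

    def test_mirrored_matrix_gives_two(self):
        rng = np.random.default_rng(13)
        A = random_sym(rng, 5)
        B = -A + 2 * A.mean()
        assert distance_flexibility(A, B) == pytest.approx(2.0, abs=1e-9)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(14)
        A, B = random_sym(rng, 5), random_sym(rng, 5)
        assert distance_flexibility(A, B) == pytest.approx(
            distance_loop(A, B), abs=1e-10
        )

    def test_common_affine_invariance(self):
        rng = np.random.default_rng(15)
        A, B = random_sym(rng, 5), random_sym(rng, 5)
        d1 = distance_flexibility(A, B)
        d2 = distance_flexibility(1.7 * A + 0.3, 1.7 * B + 0.3)
        assert d1 == pytest.approx(d2, abs=1e-10)

    def test_diagonal_exclusion_switch(self):
        rng = np.random.default_rng(40)
        A, B = random_sym(rng, 5), random_sym(rng, 5)
        d_incl = distance_flexibility(A, B)
        mask = ~np.eye(5, dtype=bool)
        ref = 1 - np.corrcoef(A[mask], B[mask])[0, 1]
        assert distance_flexibility(A, B, include_diagonal=False) == pytest.approx(
            ref, abs=1e-12
        )
        assert d_incl != pytest.approx(ref, abs=1e-6)
        t = generate_synthetic_template(5, 2, seed=41)
        H_incl = module_strengths(A, t)
        H_excl = module_strengths(A, t, include_diagonal=False)
        A0 = np.abs(A).copy()
        np.fill_diagonal(A0, 0.0)
        np.testing.assert_allclose(H_excl, (A0 @ t.M) / t.module_sizes, atol=1e-12)
        assert not np.allclose(H_incl, H_excl)

    def test_constant_matrix_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            distance_flexibility(np.ones((3, 3)), np.eye(3))


class TestSeries:
    def make_seq(self, mats):
        mats = np.asarray(mats, dtype=float)
        starts = np.arange(mats.shape[0]) * 2.0
        return FunctionalMatrixSequence(mats, starts, WindowSpec())

    def test_identical_windows_zero_everywhere(self):
        rng = np.random.default_rng(16)
        A = random_sym(rng, 6)
        t = generate_synthetic_template(6, 2, seed=17)
        tmpl, dist = flexibility_series(self.make_seq([A, A]), t)
        assert tmpl.values[0] == 0.0
        assert dist.values[0] == pytest.approx(0.0, abs=1e-12)

    def test_series_length_contract(self):
        rng = np.random.default_rng(18)
        mats = [random_sym(rng, 4) for _ in range(5)]
        _, dist = flexibility_series(self.make_seq(mats))
        assert len(dist) == 4

    def test_series_equals_pairwise_recompute(self, small_template):
        rng = np.random.default_rng(19)
        mats = [random_sym(rng, 20) for _ in range(6)]
        seq = self.make_seq(mats)
        tmpl, dist = flexibility_series(seq, small_template)
        for t in range(5):
            assert dist.values[t] == pytest.approx(
                distance_flexibility(mats[t], mats[t + 1]), abs=1e-12
            )
            oa = affiliation_vector(module_strengths(mats[t], small_template))
            ob = affiliation_vector(module_strengths(mats[t + 1], small_template))
            assert tmpl.values[t] == template_flexibility(oa, ob)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_bounds_properties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 12))
        mats = [random_sym(rng, n) for _ in range(4)]
        t = generate_synthetic_template(n, int(rng.integers(1, min(4, n) + 1)), seed=seed)
        tmpl, dist = flexibility_series(self.make_seq(mats), t)
        # template values on the 1/N lattice in [0, 1]
        lattice = np.round(tmpl.values * n)
        np.testing.assert_allclose(tmpl.values * n, lattice, atol=1e-12)
        assert np.all(tmpl.values >= 0) and np.all(tmpl.values <= 1)
        assert np.all(dist.values >= -1e-9) and np.all(dist.values <= 2 + 1e-9)
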