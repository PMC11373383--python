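"""DAF, distance and windowing semantics of the feature representation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dafnet.representation import (
    MISSING,
    RepresentationError,
    SNPMatrix,
    center_window_start,
    compute_daf,
    compute_distances,
    extract_center_window,
    featurize,
)


def matrix_from_columns(cols, positions=None):
    a = np.asarray(cols, dtype=np.int8).T
    pos = np.linspace(0.1, 0.9, a.shape[1]) if positions is None else positions
    return SNPMatrix(alleles=a, positions=np.asarray(pos, dtype=float))


class TestComputeDaf:
    def test_simple_column(self):
        m = matrix_from_columns([[1, 1, 1, 0]])
        assert compute_daf(m) == pytest.approx([0.75])

    def test_missing_reduces_denominator(self):
        m = matrix_from_columns([[1, 1, MISSING, 0]])
        assert compute_daf(m) == pytest.approx([2 / 3])

    def test_all_missing_locus_is_an_error_naming_the_locus(self):
        m = matrix_from_columns([[1, 0], [MISSING, MISSING]])
        with pytest.raises(RepresentationError, match="locus 1"):
            compute_daf(m)

    def test_agrees_with_bruteforce_counter(self, rng):
        """Vectorized DAF equals a per-locus double-loop count."""
        for _ in range(20):
            n, w = rng.integers(1, 65), rng.integers(1, 65)
            a = rng.choice([0, 1, MISSING], size=(n, w), p=[0.5, 0.4, 0.1])
            for j in range(w):  # guard: no all-missing locus
                if np.all(a[:, j] == MISSING):
                    a[0, j] = 0
            m = SNPMatrix(alleles=a, positions=np.arange(w, dtype=float))
            expected = []
            for j in range(w):
                derived = called = 0
                for i in range(n):
                    if a[i, j] != MISSING:
                        called += 1
                        derived += a[i, j] == 1
                expected.append(derived / called)
            assert compute_daf(m) == pytest.approx(expected)


class TestComputeDistances:
    def test_neighbour_differences_with_zero_tail(self):
        assert compute_distances([10.0, 15.0, 22.0]) == pytest.approx([5, 7, 0])

    def test_single_snp(self):
        assert compute_distances([3.7]) == pytest.approx([0.0])

    def test_translation_invariance(self):
        p = np.array([0.1, 0.4, 0.45, 0.9])
        assert compute_distances(p) == pytest.approx(compute_distances(p + 1000))

    def test_decreasing_positions_rejected(self):
        with pytest.raises(RepresentationError):
            compute_distances([5.0, 2.0])


class TestFeaturize:
    def test_shape_is_sample_size_invariant(self, rng):
        pos = np.sort(rng.uniform(size=12))
        for n in (4, 64, 1000):
            a = rng.integers(0, 2, size=(n, 12), dtype=np.int8)
            a[0] = 1  # keep every locus called and polymorphic-ish
            f = featurize(SNPMatrix(alleles=a, positions=pos))
            assert f.as_array().shape == (2, 12)

    def test_equidistant_snps_give_constant_distance_row(self):
        pos = np.arange(5) * 0.1
        a = np.ones((3, 5), dtype=np.int8)
        f = featurize(SNPMatrix(alleles=a, positions=pos))
        assert f.dist == pytest.approx([0.1, 0.1, 0.1, 0.1, 0.0])

    def test_distance_scale_option(self):
        a = np.ones((2, 3), dtype=np.int8)
        f = featurize(SNPMatrix(alleles=a, positions=[100.0, 300.0, 400.0]), scale=1000)
        assert f.dist == pytest.approx([0.2, 0.1, 0.0])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_row_permutation_invariance(self, seed):
        r = np.random.default_rng(seed)
        n, w = int(r.integers(2, 20)), int(r.integers(1, 20))
        a = r.choice([0, 1, MISSING], size=(n, w), p=[0.45, 0.45, 0.1])
        a[0] = np.where(a[0] == MISSING, 0, a[0])
        m = SNPMatrix(alleles=a, positions=np.sort(r.uniform(size=w)))
        f = featurize(m)
        g = featurize(m.with_rows(r.permutation(n)))
        np.testing.assert_array_equal(f.as_array(), g.as_array())

    def test_missing_data_consistency(self, rng):
        """Deleting one derived allele moves DAF from k/n to (k-1)/(n-1)."""
        a = rng.integers(0, 2, size=(10, 4), dtype=np.int8)
        a[:, 2] = [1, 1, 1, 0, 0, 1, 0, 0, 1, 0]  # k=5 of n=10
        m = SNPMatrix(alleles=a.copy(), positions=np.arange(4, dtype=float))
        before = compute_daf(m)[2]
        a[0, 2] = MISSING
        after = compute_daf(
            SNPMatrix(alleles=a, positions=np.arange(4, dtype=float))
        )[2]
        assert before == pytest.approx(5 / 10)
        assert after == pytest.approx(4 / 9)


class TestCenterWindow:
    @pytest.mark.parametrize(
        "n_snps,width,start",
        [
            (200, 128, 36),  # tie between 36/37 resolved to the lower index
            (128, 128, 0),
            (201, 128, 37),
            (5, 1, 2),
        ],
    )
    def test_start_index(self, n_snps, width, start):
        assert center_window_start(n_snps, width) == start

    def test_bruteforce_center_rule(self):
        """Start minimizes |window centre - n/2|, ties to the lower index."""
        for n in range(1, 40):
            for w in range(1, n + 1):
                centres = np.array([s + (w - 1) / 2 for s in range(n - w + 1)])
                d = np.abs(centres - n / 2)
                assert center_window_start(n, w) == int(np.argmin(d))

    def test_identity_when_exact(self, rng):
        a = rng.integers(0, 2, size=(4, 16), dtype=np.int8)
        m = SNPMatrix(alleles=a, positions=np.sort(rng.uniform(size=16)))
        w = extract_center_window(m, 16)
        np.testing.assert_array_equal(w.alleles, m.alleles)

    def test_too_few_snps_is_an_error(self):
        a = np.ones((2, 100), dtype=np.int8)
        m = SNPMatrix(alleles=a, positions=np.arange(100, dtype=float))
        with pytest.raises(RepresentationError):
            extract_center_window(m, 128)

    def test_label_and_positions_preserved(self, rng):
        a = rng.integers(0, 2, size=(4, 30), dtype=np.int8)
        m = SNPMatrix(
            alleles=a, positions=np.arange(30, dtype=float), label="sweep"
        )
        w = extract_center_window(m, 10)
        assert w.label == "sweep"
        np.testing.assert_array_equal(w.positions, np.arange(10, 20, dtype=float))

    def test_window_cut_is_translation_invariant(self, rng):
        a = rng.integers(0, 2, size=(6, 40), dtype=np.int8)
        pos = np.sort(rng.uniform(size=40))
        f1 = featurize(extract_center_window(SNPMatrix(alleles=a, positions=pos), 20))
        f2 = featurize(
            extract_center_window(SNPMatrix(alleles=a, positions=pos + 5e6), 20)
        )
        np.testing.assert_allclose(f1.as_array(), f2.as_array(), rtol=0, atol=1e-7)
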