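"""Unit and property tests for the affine-plane partition construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pairplan import (
    PartitionDesign,
    base_matrix,
    comparison_count,
    enumerate_subsets,
    membership,
    shift_amount,
    shifted_matrix,
    smallest_admissible_prime,
)


class TestSmallestAdmissiblePrime:
    @pytest.mark.parametrize(
        "n,expected",
        [
            (435187, 661),  # UK Biobank-scale sample
            (25, 5),
            (4, 2),
            (100, 11),  # 7^2=49 < 100 <= 11^2; 8,9,10 composite
            (49, 7),
            (50, 11),  # first prime past 8
            (2000, 47),
        ],
    )
    def test_examples(self, n, expected):
        assert smallest_admissible_prime(n) == expected

    def test_square_bound_and_minimality(self):
        for n in range(4, 500):
            p = smallest_admissible_prime(n)
            assert p * p >= n
            # no smaller prime admits the sample
            smaller = [q for q in range(2, p) if all(q % d for d in range(2, q))]
            assert all(q * q < n for q in smaller)

    @pytest.mark.parametrize("n", [3, 2, 1, 0, -5])
    def test_rejects_small_n(self, n):
        with pytest.raises(ValueError, match="n must be >= 4"):
            smallest_admissible_prime(n)


class TestBaseMatrix:
    def test_column_wise_fill_25(self):
        P = base_matrix(25)
        assert P.shape == (5, 5)
        assert P[0, 0] == 1  # cell(1,1)
        assert P[4, 4] == 25  # cell(5,5)
        # column i holds (i-1)*p+1 .. i*p top to bottom
        assert list(P[:, 1]) == [6, 7, 8, 9, 10]

    def test_forced_grid_n4(self):
        assert base_matrix(4).tolist() == [[1, 3], [2, 4]]

    def test_null_cells_masked(self):
        P = base_matrix(23)
        assert (P == 0).sum() == 2  # values 24 and 25 are null
        assert P[3, 4] == 0 and P[4, 4] == 0


class TestShift:
    @pytest.mark.parametrize("i,k,p,expected", [(2, 1, 5, 1), (3, 1, 5, 2), (1, 1, 5, 0), (1, 4, 5, 0), (5, 4, 5, 1)])
    def test_shift_amount(self, i, k, p, expected):
        assert shift_amount(i, k, p) == expected

    @pytest.mark.parametrize("i,k", [(1, 0), (1, 5), (0, 1), (6, 1)])
    def test_shift_amount_bounds(self, i, k):
        with pytest.raises(ValueError):
            shift_amount(i, k, 5)

    def test_conveyor_identity(self):
        """Last element of column 2 of P_1 is the first element of column 2 of P."""
        P = base_matrix(25)
        P1 = shifted_matrix(P, 1)
        assert P1[4, 1] == P[0, 1] == 6
        # last two elements of column 3 of P_1 = first two of column 3 of P
        assert list(P1[3:, 2]) == list(P[:2, 2])

    def test_first_column_never_shifts(self):
        P = base_matrix(49)
        for k in range(1, 7):
            assert list(shifted_matrix(P, k)[:, 0]) == list(P[:, 0])

    def test_shift_is_cyclic_permutation_of_each_column(self):
        P = base_matrix(25)
        for k in range(1, 5):
            Pk = shifted_matrix(P, k)
            for i in range(5):
                assert sorted(Pk[:, i]) == sorted(P[:, i])

    @pytest.mark.parametrize("k", [0, 5, -1])
    def test_shifted_matrix_bad_k(self, k):
        with pytest.raises(ValueError):
            shifted_matrix(base_matrix(25), k)


class TestEnumerateSubsets:
    def test_worked_n4_design(self, design4):
        members = [s.members.tolist() for s in design4.subsets]
        assert members == [[1, 2], [3, 4], [1, 3], [2, 4], [1, 4], [2, 3]]
        assert [s.source for s in design4.subsets] == [
            "column-of-P", "column-of-P", "row-of-P", "row-of-P", "row-of-P_k", "row-of-P_k",
        ]

    def test_n25_structure(self, design25):
        assert design25.p == 5
        assert len(design25.subsets) == 30  # p^2 + p
        assert all(len(s) == 5 for s in design25.subsets)
        ks = sorted({s.k for s in design25.subsets if s.source == "row-of-P_k"})
        assert ks == [1, 2, 3, 4]

    def test_self_comparison_on_first_p_only(self, design25):
        flags = [s.allows_self_comparison for s in design25.subsets]
        assert flags == [True] * 5 + [False] * 25

    def test_subset_ids_are_positions(self, design25):
        assert [s.subset_id for s in design25.subsets] == list(range(30))

    def test_members_in_range_and_sorted(self):
        d = enumerate_subsets(23)
        for s in d.subsets:
            assert np.all((1 <= s.members) & (s.members <= 23))
            assert np.all(np.diff(s.members) > 0)

    def test_determinism(self):
        a, b = enumerate_subsets(137), enumerate_subsets(137)
        assert all(
            np.array_equal(x.members, y.members) and x.source == y.source
            for x, y in zip(a.subsets, b.subsets)
        )

    def test_rejects_n3(self):
        with pytest.raises(ValueError):
            enumerate_subsets(3)

    def test_empty_subsets_arise_from_full_null_columns(self):
        # n=5, p=3: column 3 of P holds 7,8,9 -- all null
        d = enumerate_subsets(5)
        assert len(d.subsets) == 12
        assert len(d.subsets[2]) == 0
        assert len(d.emitted_subsets()) < 12


class TestMembership:
    def test_n4_individual1(self, design4):
        ids = membership(1, design4)
        assert len(ids) == 3  # p + 1
        assert ids == [0, 2, 4]  # its column, its row, its shifted row

    @pytest.mark.parametrize("n", [25, 23, 49, 50])
    def test_every_individual_in_p_plus_1(self, n):
        d = enumerate_subsets(n)
        for ind in range(1, n + 1):
            ids = membership(ind, d)
            assert len(ids) == d.p + 1
            assert len(set(ids)) == len(ids)

    @pytest.mark.parametrize("bad", [0, -1, 26, 1000])
    def test_out_of_range(self, design25, bad):
        with pytest.raises(ValueError):
            membership(bad, design25)


class TestComparisonCount:
    def test_examples(self, design4, design25):
        assert comparison_count(design25, include_self=False) == 300
        assert comparison_count(design4, include_self=False) == 6
        assert comparison_count(design25, include_self=True) == 325

    def test_closed_form_when_square(self, design25):
        p = design25.p
        assert comparison_count(design25) == (p**4 - p**2) // 2 == (25 * 25 - 25) // 2

    @pytest.mark.parametrize("n", [23, 30, 50, 101, 435])
    def test_conservation_with_null_cells(self, n):
        d = enumerate_subsets(n)
        assert d.p * d.p > n  # padding present
        assert comparison_count(d) == (n * n - n) // 2
        assert comparison_count(d, include_self=True) == (n * n - n) // 2 + n


@settings(derandomize=True, deadline=None, max_examples=60)
@given(n=st.integers(min_value=4, max_value=800))
def test_design_count_invariants(n):
    """Subset count p^2+p, member ranges, per-individual membership p+1,
    and comparison conservation hold for arbitrary n."""
    d = enumerate_subsets(n)
    assert len(d.subsets) == d.p**2 + d.p
    seen = np.zeros(n + 1, dtype=int)
    for s in d.subsets:
        assert len(s) <= d.p
        if len(s):
            assert s.members.min() >= 1 and s.members.max() <= n
        np.add.at(seen, s.members, 1)
    assert np.all(seen[1:] == d.p + 1)
    assert comparison_count(d) == (n * n - n) // 2
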