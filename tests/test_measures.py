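"""Distance transform, Rao quadratic-entropy diversity, query coverage."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

import seqdiv as sd
import oracles


@pytest.fixture(scope="module")
def amino_d():
    return sd.blosum_to_distance()


@pytest.fixture(scope="module")
def full_d(amino_d):
    return sd.extend_with_special_symbols(amino_d)


class TestBlosumToDistance:
    def test_zero_diagonal(self, amino_d):
        assert np.all(np.diag(amino_d.d) == 0.0)
        for a in sd.AMINO_ACIDS:
            assert amino_d.distance(a, a) == 0.0

    def test_symmetric(self, amino_d):
        assert np.array_equal(amino_d.d, amino_d.d.T)

    def test_maximum_is_nineteen(self, amino_d):
        assert amino_d.max_distance == pytest.approx(19.0)

    def test_strictly_positive_off_diagonal(self, amino_d):
        off = amino_d.d[~np.eye(20, dtype=bool)]
        assert (off > 0).all()

    def test_bundled_matrix_matches_reference_blosum62(self):
        bundled = sd.load_blosum62()
        reference = substitution_matrices.load("BLOSUM62")
        for a in sd.AMINO_ACIDS:
            for b in sd.AMINO_ACIDS:
                assert bundled[a, b] == reference[a, b]

    def test_incomplete_matrix_rejected(self):
        tiny = substitution_matrices.Array(alphabet="AC", dims=2)
        with pytest.raises(sd.ContractViolation):
            sd.blosum_to_distance(tiny)


class TestExtendWithSpecialSymbols:
    def test_nonaligned_is_twice_gap(self, full_d):
        for a in sd.AMINO_ACIDS:
            assert full_d.distance(".", a) == 2 * full_d.distance("-", a)

    def test_gap_defaults_to_half_matrix_maximum(self, amino_d, full_d):
        assert full_d.distance("-", "A") == pytest.approx(amino_d.max_distance / 2)

    def test_special_diagonal_zero_and_symmetric(self, full_d):
        assert full_d.distance("-", "-") == 0.0
        assert full_d.distance(".", ".") == 0.0
        assert np.array_equal(full_d.d, full_d.d.T)
        assert full_d.distance("-", ".") == full_d.distance(".", "-")

    def test_nonpositive_gap_rejected(self, amino_d):
        with pytest.raises(sd.ContractViolation):
            sd.extend_with_special_symbols(amino_d, gap_distance=0.0)

    def test_custom_gap_distance(self, amino_d):
        m = sd.extend_with_special_symbols(amino_d, gap_distance=3.0)
        assert m.distance("-", "W") == 3.0
        assert m.distance(".", "W") == 6.0


class TestColumnProbability:
    def test_worked_example_column_one(self):
        assert sd.column_probability("GGG-", "G") == 0.75
        assert sd.column_probability("GGG-", "-") == 0.25

    def test_worked_example_from_rows(self, fig2_rows):
        col1 = [r[0] for r in fig2_rows]
        col3 = [r[2] for r in fig2_rows]
        col10 = [r[9] for r in fig2_rows]
        assert sd.column_probability(col1, "G") == 0.75
        assert sd.column_probability(col1, "-") == 0.25
        assert sd.column_probability(col3, "S") == 0.5
        assert sd.column_probability(col10, "A") == 1.0

    def test_uniform_column(self):
        assert sd.column_probability("AAAAA", "A") == 1.0


class TestRaoColumnEntropy:
    def test_uniform_column_is_zero(self, full_d):
        assert sd.rao_column_entropy("WWWW", full_d) == 0.0

    def test_even_split_closed_form(self, full_d):
        d = full_d.distance("A", "W")
        assert sd.rao_column_entropy("AAWW", full_d) == pytest.approx(0.5 * d)

    def test_matches_bruteforce_double_loop(self, full_d, rng):
        symbols = list(sd.AMINO_ACIDS) + ["-", "."]
        for _ in range(20):
            column = [symbols[i] for i in rng.integers(0, 22, size=7)]
            got = sd.rao_column_entropy(column, full_d)
            # one-column alignment: each column symbol is its own row
            expected = oracles.rao_brute(list(column), full_d.distance)
            assert got == pytest.approx(expected, abs=1e-9)

    def test_unknown_symbol_rejected(self, full_d):
        with pytest.raises(sd.ContractViolation):
            sd.rao_column_entropy("AB?", full_d)


class TestRaoDiversity:
    def test_identical_rows_zero(self, full_d):
        score = sd.rao_diversity(["ACDW."] * 3, full_d)
        assert score.value == 0.0
        assert score.n_rows == 3 and score.n_columns == 5

    def test_bounded_by_matrix_maximum(self, amino_d, rng):
        aas = list(sd.AMINO_ACIDS)
        for _ in range(10):
            rows = [
                "".join(aas[i] for i in rng.integers(0, 20, size=12))
                for _ in range(4)
            ]
            assert sd.rao_diversity(rows, amino_d).value <= 19.0 + 1e-12

    def test_matches_bruteforce(self, full_d, rng):
        symbols = list(sd.AMINO_ACIDS) + ["-", "."]
        for _ in range(10):
            rows = [
                "".join(symbols[i] for i in rng.integers(0, 22, size=8))
                for _ in range(3)
            ]
            got = sd.rao_diversity(rows, full_d).value
            assert got == pytest.approx(
                oracles.rao_brute(rows, full_d.distance), abs=1e-9
            )

    def test_permutation_invariance(self, full_d, rng):
        rows = ["ACDW.", "AC-W.", "GHDWY"]
        base = sd.rao_diversity(rows, full_d).value
        assert sd.rao_diversity(rows[::-1], full_d).value == pytest.approx(base)
        perm = rng.permutation(5)
        shuffled = ["".join(r[j] for j in perm) for r in rows]
        assert sd.rao_diversity(shuffled, full_d).value == pytest.approx(base)

    def test_duplicate_row_does_not_increase_diversity(self, full_d):
        fixtures = [
            ["ACDW.", "AC-W.", "GHDWY"],
            ["AAAA", "CCCC", "GGGG"],
            ["AC", "WY", "-."],
        ]
        for rows in fixtures:
            base = sd.rao_diversity(rows, full_d).value
            with_dup = sd.rao_diversity(rows + [rows[0]], full_d).value
            assert with_dup <= base + 1e-12

    def test_ragged_rows_rejected(self, full_d):
        with pytest.raises(sd.ContractViolation):
            sd.rao_diversity(["ACD", "AC"], full_d)


class TestCoverage:
    def test_disjoint_halves_cover_fully(self):
        from conftest import make_fragment

        frags = [make_fragment("1111100000", 1), make_fragment("0000011111", 2)]
        assert sd.coverage(frags) == 1.0

    def test_no_fragments(self):
        assert sd.coverage([]) == 0.0

    def test_half_cover(self):
        from conftest import make_fragment

        assert sd.coverage([make_fragment("1111100000", 1)]) == 0.5

    def test_insertion_columns_excluded(self):
        q = sd.QueryRecord("q", "ACGT")
        h1 = sd.RawHit("a", 1, 1, 2, "AC-", "ACW", 10, 1e-3)
        star = sd.build_star_alignment(q, [h1])
        # 5 columns, but coverage counts the 4 query positions only
        assert star.n_columns == 5
        assert sd.coverage(star.fragments, star) == 0.5


class TestCoverageCurve:
    def test_single_full_fragment_reaches_one_immediately(self):
        from conftest import make_fragment

        curve = sd.coverage_curve([make_fragment("1" * 10, 1)])
        assert curve[0][1] == 1.0

    def test_plateau_at_half(self):
        from conftest import make_fragment

        frags = [make_fragment("1111100000", r) for r in range(1, 4)]
        curve = sd.coverage_curve(frags)
        assert all(cov == 0.5 for _, cov in curve)

    def test_monotone_nondecreasing(self, random_star):
        star = random_star()
        curve = sd.coverage_curve(star.fragments, star)
        covs = [c for _, c in curve]
        assert all(b >= a for a, b in zip(covs, covs[1:]))

    def test_exclude_first_drops_top_hit(self):
        from conftest import make_fragment

        frags = [make_fragment("1" * 10, 1), make_fragment("1111100000", 2)]
        curve = sd.coverage_curve(frags, exclude_first=True)
        assert len(curve) == 1 and curve[0][1] == 0.5

    def test_diversified_reaches_full_coverage_no_later_than_original(self):
        spec = sd.FixtureSpec(seed=3)
        query, hits = sd.generate_fixture(spec)
        star = sd.build_star_alignment(query, hits)
        original = sd.prefixes_to_full_coverage(star.fragments, star)
        for method in ("bit", "entropy"):
            ranking = sd.diversify(star.fragments, len(star.fragments), method)
            diversified = sd.prefixes_to_full_coverage(ranking.order, star)
            assert diversified <= original
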