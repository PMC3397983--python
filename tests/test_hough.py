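"""Sinusoidal Hough transform: accumulator, gap filter, block search.

Expected values for the worked examples were frozen from the pure-
Python brute-force oracle (triple loop + exhaustive cell scan), which
the optimized path is also compared against on random inputs.
"""

import numpy as np
import pytest

from conftest import random_points
from houghsynteny import (
    HoughConfig,
    OrthologPoint,
    best_synteny,
    build_accumulator,
    cell_members,
    split_on_gaps,
    summarize_synteny,
    to_polar,
)
from houghsynteny.hough import brute_force_accumulator, brute_force_best

ANTIDIAGONAL = [
    OrthologPoint("a", 0.0, 10.0),
    OrthologPoint("b", 5.0, 5.0),
    OrthologPoint("c", 10.0, 0.0),
]
DIAGONAL = [OrthologPoint(c, k, k) for c, k in zip("abc", (1.0, 2.0, 3.0))]


class TestToPolar:
    @pytest.mark.parametrize(
        "x, y, theta, expected",
        [
            (0.0, 0.0, 37.0, 0.0),
            (3.0, 4.0, 90.0, 4.0),
            (10.0, 10.0, 45.0, 10 * np.sqrt(2)),
        ],
    )
    def test_projection(self, x, y, theta, expected):
        assert to_polar(OrthologPoint("p", x, y), theta) == pytest.approx(expected)


class TestConfig:
    def test_default_grid_is_180_by_1400(self):
        config = HoughConfig()
        assert (config.n_theta, config.n_rho) == (180, 1400)
        assert config.theta_mid(0) == 0.5
        assert config.theta_mid(45) == 45.5
        assert config.rho_mid(0) == pytest.approx(-39.95)
        assert config.rho_mid(470) == pytest.approx(7.05)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            HoughConfig(theta_bin_width=7.0)  # 180 not divisible by 7
        with pytest.raises(ValueError):
            HoughConfig(rho_bin_width=-0.1)

    def test_auto_rho_covers_data(self):
        pts = random_points(np.random.default_rng(3), 20)
        config = HoughConfig.with_auto_rho(pts)
        reach = max(np.hypot(p.x, p.y) for p in pts)
        assert config.rho_max > reach
        assert config.rho_min < -reach


class TestAccumulator:
    def test_single_point_marks_every_theta_column(self):
        grid = build_accumulator([OrthologPoint("p", 10.0, 10.0)])
        assert all(grid.counts[i].sum() >= 1 for i in range(180))

    def test_collinear_triple_shares_a_cell(self):
        config = HoughConfig()
        grid = build_accumulator(ANTIDIAGONAL, config)
        assert grid.counts[45, config.rho_bin(7.05)] == 3

    def test_counts_bounded_by_n_points(self, rng):
        pts = random_points(rng, 30)
        grid = build_accumulator(pts)
        assert grid.counts.max() <= 30
        assert grid.counts.min() >= 0

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError, match="no orthologues"):
            build_accumulator([])


class TestCellMembers:
    def test_collinear_triple_cell(self):
        config = HoughConfig()
        members = cell_members(ANTIDIAGONAL, (45, config.rho_bin(7.05)), config)
        assert sorted(p.name for p in members) == ["a", "b", "c"]

    def test_zero_count_cell_is_empty(self):
        assert cell_members(ANTIDIAGONAL, (0, 0)) == []

    def test_out_of_grid_cell_rejected(self):
        with pytest.raises(IndexError):
            cell_members(ANTIDIAGONAL, (180, 0))

    def test_member_counts_match_accumulator_everywhere(self, rng):
        pts = random_points(rng, 50)
        grid = build_accumulator(pts)
        config = grid.config
        occupied = np.argwhere(grid.counts > 0)
        idx = rng.choice(len(occupied), size=200, replace=False)
        for i, j in occupied[idx]:
            assert len(cell_members(pts, (int(i), int(j)), config)) == grid.counts[i, j]


class TestSplitOnGaps:
    @staticmethod
    def _pts(xs, ys=None):
        ys = ys if ys is not None else [0.1 * k for k in range(len(xs))]
        return [OrthologPoint(f"p{k}", x, y) for k, (x, y) in enumerate(zip(xs, ys))]

    def test_splits_at_wide_x_gap(self):
        blocks = split_on_gaps(self._pts([1, 2, 3, 10, 11]), 5.0)
        assert [b.size for b in blocks] == [3, 2]

    def test_gap_exactly_threshold_does_not_split(self):
        blocks = split_on_gaps(self._pts([0, 5, 10]), 5.0)
        assert [b.size for b in blocks] == [3]

    def test_tiny_threshold_gives_singletons(self):
        blocks = split_on_gaps(self._pts([0, 1, 2, 3]), 0.5)
        assert [b.size for b in blocks] == [1, 1, 1, 1]

    def test_y_gap_splits_under_both_axis_rule(self):
        pts = self._pts([0, 1, 2], [0, 20, 40])
        assert [b.size for b in split_on_gaps(pts, 5.0, "both")] == [1, 1, 1]
        assert [b.size for b in split_on_gaps(pts, 5.0, "x")] == [3]

    def test_sizes_partition_members(self, rng):
        pts = random_points(rng, 40)
        blocks = split_on_gaps(pts, 2.0)
        assert sum(b.size for b in blocks) == 40


class TestBestSynteny:
    def test_antidiagonal_block(self):
        result = best_synteny(ANTIDIAGONAL)
        assert (result.S, result.theta) == (3, 45.5)
        assert result.rho == pytest.approx(7.05)
        assert result.best_block.size == 3

    def test_diagonal_block_range_semantics(self):
        # under edge-range rasterisation the S=3 tie extends one theta
        # column past the exact 135-degree line; the highest column wins
        result = best_synteny(DIAGONAL)
        assert (result.S, result.theta) == (3, 136.5)
        assert result.rho == pytest.approx(-0.05)
        assert (135.5, result.rho) in [
            (pytest.approx(t), pytest.approx(r)) for t, r in result.tied_cells
        ]

    def test_diagonal_block_midpoint_semantics(self):
        result = best_synteny(DIAGONAL, HoughConfig(intersection="midpoint"))
        assert (result.S, result.theta) == (3, 135.5)
        assert result.rho == pytest.approx(-0.05)

    def test_single_point_ties_resolve_to_highest_theta(self):
        result = best_synteny([OrthologPoint("p", 10.0, 10.0)])
        assert (result.S, result.theta) == (1, 179.5)

    def test_gap_filter_limits_block(self):
        # five collinear points with a >5 Mb hole between the 3rd and 4th
        pts = [OrthologPoint(f"p{k}", x, x) for k, x in enumerate([1, 2, 3, 9, 10])]
        result = best_synteny(pts)
        assert result.S == 3

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError, match="no orthologues"):
            best_synteny([])

    @pytest.mark.parametrize("intersection", ["range", "midpoint"])
    def test_matches_bruteforce_on_random_inputs(self, rng, intersection):
        config = HoughConfig(intersection=intersection)
        for _ in range(5):
            pts = random_points(rng, int(rng.integers(3, 20)))
            fast = best_synteny(pts, config)
            slow = brute_force_best(pts, config)
            assert (fast.S, fast.theta, fast.rho) == (slow.S, slow.theta, slow.rho)
            assert fast.tied_cells == slow.tied_cells

    def test_accumulator_matches_bruteforce_matrix(self, rng):
        pts = random_points(rng, 20)
        fast = build_accumulator(pts)
        slow = brute_force_accumulator(pts)
        assert np.array_equal(fast.counts, slow.counts)

    def test_adding_a_point_never_decreases_s(self, rng):
        pts = random_points(rng, 15)
        base = best_synteny(pts).S
        for _ in range(10):
            extra = random_points(rng, 1)[0]
            assert best_synteny(pts + [extra]).S >= base

    def test_pure_noise_scatter_stays_small(self):
        # frozen regression: uniform noise must not masquerade as synteny
        pts = random_points(np.random.default_rng(42), 200)
        result = best_synteny(pts)
        assert result.S == 20  # regression value at this seed
        assert result.S < 40  # far below n = 200


class TestSummarize:
    @pytest.mark.parametrize(
        "s, n, percent", [(28, 44, 64), (11, 25, 44), (10, 10, 100), (1, 3, 33)]
    )
    def test_percent_in_block(self, s, n, percent):
        pts = [OrthologPoint(f"p{k}", float(k), float(k)) for k in range(n)]
        result = best_synteny(pts)
        summary = summarize_synteny(
            type(result)(result.theta, result.rho, s, n, result.best_block)
        )
        assert summary["percent_in_block"] == percent
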