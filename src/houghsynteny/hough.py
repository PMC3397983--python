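"""Sinusoidal Hough transform for linear synteny block detection.

Every orthologue dot-plot point (x, y) maps to the sinusoid

    rho(theta) = x * cos(theta) + y * sin(theta)

in polar (theta, rho) space. Collinear points yield sinusoids that meet
in one place, so runs of conserved gene order become peaks of an
accumulator grid over (theta, rho) cells. The default grid follows the
published procedure for ~40-Mb chromosome regions: 180 one-degree theta
bins over (0, 180) and 1400 rho bins of 0.1 Mb over (-40, 100) Mb, a
cell C[i, j] covering [i, i+1) x [-40 + 0.1 j, -39.9 + 0.1 j) with
midpoints theta_i = i + 0.5 and rho_j = -39.95 + 0.1 j.

The reported statistic S is the size of the largest accumulator-cell
cluster after splitting member runs at gaps wider than 5 Mb in either
genome; theta ties are broken toward the steepest (largest) angle bin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .gene_tables import OrthologPoint

__all__ = [
    "HoughConfig",
    "AccumulatorGrid",
    "SyntenyBlock",
    "SyntenyResult",
    "to_polar",
    "build_accumulator",
    "cell_members",
    "split_on_gaps",
    "best_synteny",
    "brute_force_best",
    "summarize_synteny",
]


@dataclass(frozen=True)
class HoughConfig:
    """Grid geometry and clustering parameters of the transform.

    All angles are degrees, all distances megabases. ``intersection``
    selects how a sinusoid is rasterised onto a theta column: "range"
    marks every rho bin between the curve's values at the column's two
    theta edges (inclusive), "midpoint" marks only the bin at the
    column's midpoint angle. ``gap_axis`` selects whether block
    splitting looks at gaps in both genomes or the query only.
    """

    theta_min: float = 0.0
    theta_max: float = 180.0
    theta_bin_width: float = 1.0
    rho_min: float = -40.0
    rho_max: float = 100.0
    rho_bin_width: float = 0.1
    gap_threshold: float = 5.0
    intersection: Literal["range", "midpoint"] = "range"
    gap_axis: Literal["both", "x"] = "both"

    def __post_init__(self) -> None:
        for w in (self.theta_bin_width, self.rho_bin_width):
            if w <= 0:
                raise ValueError("bin widths must be positive")
        if self.gap_threshold <= 0:
            raise ValueError("gap threshold must be positive")
        if abs(self.n_theta * self.theta_bin_width - (self.theta_max - self.theta_min)) > 1e-9:
            raise ValueError("theta range must be divisible by theta_bin_width")
        if abs(self.n_rho * self.rho_bin_width - (self.rho_max - self.rho_min)) > 1e-9:
            raise ValueError("rho range must be divisible by rho_bin_width")

    @property
    def n_theta(self) -> int:
        return round((self.theta_max - self.theta_min) / self.theta_bin_width)

    @property
    def n_rho(self) -> int:
        return round((self.rho_max - self.rho_min) / self.rho_bin_width)

    def theta_mid(self, i: int) -> float:
        return self.theta_min + (i + 0.5) * self.theta_bin_width

    def rho_mid(self, j: int) -> float:
        return self.rho_min + (j + 0.5) * self.rho_bin_width

    def rho_bin(self, rho: float) -> int:
        """Index of the rho bin containing rho (may fall outside the grid)."""
        return math.floor((rho - self.rho_min) / self.rho_bin_width)

    @classmethod
    def with_auto_rho(cls, points: Sequence[OrthologPoint], **kwargs) -> "HoughConfig":
        """Derive (rho_min, rho_max) from the data extent.

        |rho| never exceeds sqrt(x^2 + y^2), so the hypotenuse of the
        bounding box (rounded out to whole bins) bounds the range.
        """
        width = kwargs.get("rho_bin_width", 0.1)
        reach = max(math.hypot(p.x, p.y) for p in points) if points else 1.0
        hi = math.ceil(reach / width) * width + width
        return cls(rho_min=-hi, rho_max=hi, **kwargs)


@dataclass
class AccumulatorGrid:
    """Intersection counts O[i, j] over the (theta, rho) cells C[i, j]."""

    counts: np.ndarray
    config: HoughConfig

    def __post_init__(self) -> None:
        expected = (self.config.n_theta, self.config.n_rho)
        if self.counts.shape != expected:
            raise ValueError(f"counts shape {self.counts.shape} != grid {expected}")


@dataclass(frozen=True)
class SyntenyBlock:
    """A gap-filtered run of orthologue points; ``size`` is its S value."""

    members: tuple[OrthologPoint, ...]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class SyntenyResult:
    """The winning cell and its largest gap-filtered block.

    ``theta`` and ``rho`` are the winning cell's bin midpoints; among
    cells tied on S the largest theta bin wins, then the largest rho
    bin. All tied cells are listed so the tie-break is auditable.
    """

    theta: float
    rho: float
    S: int
    n_orthologs: int
    best_block: SyntenyBlock
    tied_cells: tuple[tuple[float, float], ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "n_orthologs": self.n_orthologs,
            "theta": round(self.theta, 2),
            "rho": round(self.rho, 2),
            "S": self.S,
            "tied_cells": [[round(t, 2), round(r, 2)] for t, r in self.tied_cells],
            "block_members": [
                {"name": p.name, "x_mb": p.x, "y_mb": p.y}
                for p in self.best_block.members
            ],
        }


def to_polar(point: OrthologPoint, theta_deg: float) -> float:
    """rho = x cos(theta) + y sin(theta), theta in degrees."""
    t = math.radians(theta_deg)
    return point.x * math.cos(t) + point.y * math.sin(t)


def _span_bins(config: HoughConfig, points_x: np.ndarray, points_y: np.ndarray,
               i: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-point inclusive rho-bin index range for theta column i.

    Under "range" semantics the sinusoid spans the bins between its
    values at the column's two theta edges; under "midpoint" both ends
    collapse onto the midpoint bin. Indices are un-clamped.
    """
    if config.intersection == "midpoint":
        t = math.radians(config.theta_mid(i))
        rho = points_x * math.cos(t) + points_y * math.sin(t)
        j = np.floor((rho - config.rho_min) / config.rho_bin_width).astype(np.int64)
        return j, j
    t0 = math.radians(config.theta_min + i * config.theta_bin_width)
    t1 = math.radians(config.theta_min + (i + 1) * config.theta_bin_width)
    r0 = points_x * math.cos(t0) + points_y * math.sin(t0)
    r1 = points_x * math.cos(t1) + points_y * math.sin(t1)
    lo = np.minimum(r0, r1)
    hi = np.maximum(r0, r1)
    j_lo = np.floor((lo - config.rho_min) / config.rho_bin_width).astype(np.int64)
    j_hi = np.floor((hi - config.rho_min) / config.rho_bin_width).astype(np.int64)
    return j_lo, j_hi


def build_accumulator(
    points: Sequence[OrthologPoint], config: HoughConfig = HoughConfig()
) -> AccumulatorGrid:
    """Rasterise every point's sinusoid into the accumulator.

    Each point increments each cell it intersects exactly once. Curve
    segments whose rho leaves the grid are clipped; a column where the
    curve lies entirely outside contributes nothing.
    """
    if not points:
        raise ValueError("no orthologues: cannot build accumulator from zero points")
    xs = np.array([p.x for p in points])
    ys = np.array([p.y for p in points])
    n_rho = config.n_rho
    counts = np.zeros((config.n_theta, n_rho), dtype=np.int64)
    # difference-array trick per theta column: +1 at j_lo, -1 after j_hi
    for i in range(config.n_theta):
        j_lo, j_hi = _span_bins(config, xs, ys, i)
        inside = (j_hi >= 0) & (j_lo < n_rho)
        if not inside.any():
            continue
        lo = np.clip(j_lo[inside], 0, n_rho - 1)
        hi = np.clip(j_hi[inside], 0, n_rho - 1)
        diff = np.zeros(n_rho + 1, dtype=np.int64)
        np.add.at(diff, lo, 1)
        np.add.at(diff, hi + 1, -1)
        counts[i] = np.cumsum(diff[:-1])
    return AccumulatorGrid(counts, config)


def cell_members(
    points: Sequence[OrthologPoint], cell: tuple[int, int],
    config: HoughConfig = HoughConfig(),
) -> list[OrthologPoint]:
    """The points whose sinusoid intersects cell (i, j).

    Consistent with :func:`build_accumulator`: the returned list has
    exactly counts[i, j] members.
    """
    i, j = cell
    if not (0 <= i < config.n_theta and 0 <= j < config.n_rho):
        raise IndexError(f"cell {cell} outside {config.n_theta} x {config.n_rho} grid")
    xs = np.array([p.x for p in points])
    ys = np.array([p.y for p in points])
    j_lo, j_hi = _span_bins(config, xs, ys, i)
    hit = (j_lo <= j) & (j <= j_hi)
    return [p for p, h in zip(points, hit) if h]


def split_on_gaps(
    members: Sequence[OrthologPoint],
    gap_threshold: float = 5.0,
    gap_axis: Literal["both", "x"] = "both",
) -> list[SyntenyBlock]:
    """Split an x-sorted run wherever consecutive points jump too far.

    A split happens between consecutive members when the distance in x
    (or, with gap_axis="both", in x or |y|) strictly exceeds the
    threshold — a conserved block must be compact in the measured
    genome(s); a gap of exactly the threshold does not split.
    """
    if not members:
        return []
    ordered = sorted(members, key=lambda p: (p.x, p.y))
    blocks: list[list[OrthologPoint]] = [[ordered[0]]]
    for prev, cur in zip(ordered, ordered[1:]):
        gap_x = cur.x - prev.x
        gap_y = abs(cur.y - prev.y)
        wide = gap_x > gap_threshold or (gap_axis == "both" and gap_y > gap_threshold)
        if wide:
            blocks.append([cur])
        else:
            blocks[-1].append(cur)
    return [SyntenyBlock(tuple(b)) for b in blocks]


def _largest_block(members: Sequence[OrthologPoint], config: HoughConfig) -> SyntenyBlock:
    blocks = split_on_gaps(members, config.gap_threshold, config.gap_axis)
    return max(blocks, key=lambda b: b.size)


def best_synteny(
    points: Sequence[OrthologPoint], config: HoughConfig = HoughConfig()
) -> SyntenyResult:
    """Find the cell whose gap-filtered member run is largest.

    For each cell the candidate score is the size of the largest block
    of its members after gap splitting; S is the maximum over cells.
    Cells are pruned by their raw count (the filtered size can only be
    smaller), scanning high counts first.
    """
    if not points:
        raise ValueError("no orthologues: cannot search an empty point set")
    grid = build_accumulator(points, config)
    counts = grid.counts
    best_s = 0
    scored: dict[tuple[int, int], int] = {}
    # raw count bounds the filtered block size, so scan count levels
    # downward and stop once the level drops below the incumbent S —
    # no cell at a lower level can win or tie
    for level in np.unique(counts)[::-1]:
        c = int(level)
        if c == 0 or c < best_s:
            break
        for flat in np.flatnonzero(counts == c):
            i, j = divmod(int(flat), config.n_rho)
            members = cell_members(points, (i, j), config)
            s = _largest_block(members, config).size
            scored[(i, j)] = s
            best_s = max(best_s, s)
    winners = [cell for cell, s in scored.items() if s == best_s]
    winners.sort()  # tie-break: largest theta bin, then largest rho bin
    win_i, win_j = winners[-1]
    block = _largest_block(cell_members(points, (win_i, win_j), config), config)
    return SyntenyResult(
        theta=config.theta_mid(win_i),
        rho=config.rho_mid(win_j),
        S=best_s,
        n_orthologs=len(points),
        best_block=block,
        tied_cells=tuple(
            (config.theta_mid(i), config.rho_mid(j)) for i, j in winners
        ),
    )


def summarize_synteny(result: SyntenyResult) -> dict:
    """Table-row style summary including the percent of orthologues in S."""
    return {
        "n_orthologs": result.n_orthologs,
        "theta": round(result.theta, 2),
        "rho": round(result.rho, 2),
        "S": result.S,
        "percent_in_block": round(100 * result.S / result.n_orthologs),
    }


# --- independent oracle -------------------------------------------------
#
# Deliberately naive re-statement of the whole pipeline in pure Python:
# triple loop over points x theta columns x spanned rho bins, then an
# exhaustive scan over every cell. Used by the test suite to check the
# vectorised path; shares no code with it beyond the config.


def _naive_span(p: OrthologPoint, i: int, config: HoughConfig) -> tuple[int, int]:
    if config.intersection == "midpoint":
        j = config.rho_bin(to_polar(p, config.theta_mid(i)))
        return j, j
    r0 = to_polar(p, config.theta_min + i * config.theta_bin_width)
    r1 = to_polar(p, config.theta_min + (i + 1) * config.theta_bin_width)
    return config.rho_bin(min(r0, r1)), config.rho_bin(max(r0, r1))


def brute_force_accumulator(
    points: Sequence[OrthologPoint], config: HoughConfig = HoughConfig()
) -> AccumulatorGrid:
    if not points:
        raise ValueError("no orthologues: cannot build accumulator from zero points")
    counts = np.zeros((config.n_theta, config.n_rho), dtype=np.int64)
    for p in points:
        for i in range(config.n_theta):
            j_lo, j_hi = _naive_span(p, i, config)
            for j in range(max(j_lo, 0), min(j_hi, config.n_rho - 1) + 1):
                counts[i, j] += 1
    return AccumulatorGrid(counts, config)


def brute_force_best(
    points: Sequence[OrthologPoint], config: HoughConfig = HoughConfig()
) -> SyntenyResult:
    """Exhaustive-scan reference implementation of :func:`best_synteny`."""
    if not points:
        raise ValueError("no orthologues: cannot search an empty point set")
    membership: dict[tuple[int, int], list[OrthologPoint]] = {}
    for p in points:
        for i in range(config.n_theta):
            j_lo, j_hi = _naive_span(p, i, config)
            for j in range(max(j_lo, 0), min(j_hi, config.n_rho - 1) + 1):
                membership.setdefault((i, j), []).append(p)
    best_s = 0
    winners: list[tuple[int, int]] = []
    for cell in sorted(membership):
        blocks = split_on_gaps(membership[cell], config.gap_threshold, config.gap_axis)
        s = max(b.size for b in blocks)
        if s > best_s:
            best_s, winners = s, [cell]
        elif s == best_s:
            winners.append(cell)
    win_i, win_j = max(winners)
    block = max(
        split_on_gaps(membership[(win_i, win_j)], config.gap_threshold, config.gap_axis),
        key=lambda b: b.size,
    )
    return SyntenyResult(
        theta=config.theta_mid(win_i),
        rho=config.rho_mid(win_j),
        S=best_s,
        n_orthologs=len(points),
        best_block=block,
        tied_cells=tuple(
            (config.theta_mid(i), config.rho_mid(j)) for i, j in sorted(winners)
        ),
    )
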