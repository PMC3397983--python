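"""Synthetic gene tables, genome layouts and peptides with known truth.

Generators for: (1) orthologue dot-plots with planted collinear blocks
on x cos(theta*) + y sin(theta*) = rho* plus uniform background pairs,
written as the same BioMart-style tables the ingestion module reads;
(2) gene placements giving a window sampler an exactly known positive-
placement probability; (3) peptide sequences realising prescribed
cysteine spacings. Everything is a pure function of its arguments and
the seed. The default layout mirrors the scales the method targets: a
~146-Mb query chromosome (a large human chromosome) against ~30-Mb
target chromosomes (medaka-sized), so the default rho range applies.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .gene_tables import BP_PER_MB, GeneRecord
from .windows import GenomeLayout, _valid_start_intervals

__all__ = [
    "PlantedBlockSpec",
    "SyntheticDataset",
    "default_layout",
    "generate_synteny_dataset",
    "generate_window_truth",
    "generate_knot_sequence",
]

_NON_CYS = "ADEFGHIKLMNPQRSTVWY"  # every standard residue except C


@dataclass(frozen=True)
class PlantedBlockSpec:
    """A collinear orthologue run to plant: n_points along the line
    x cos(theta*) + y sin(theta*) = rho*, consecutive points ``spacing``
    Mb apart along the line, each coordinate jittered uniformly within
    +/- ``jitter`` Mb."""

    theta_star: float
    rho_star: float
    n_points: int
    spacing: float = 1.0
    jitter: float = 0.0
    name_prefix: str = "blk"

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")
        if self.spacing < 0 or self.jitter < 0:
            raise ValueError("spacing and jitter must be >= 0")


@dataclass
class SyntheticDataset:
    query: list[GeneRecord]
    target: list[GeneRecord]
    layout: GenomeLayout
    blocks: list[PlantedBlockSpec]
    n_background: int
    seed: int | None
    query_chromosome: str = "q1"
    target_chromosome: str = "t1"

    def truth_json(self) -> str:
        return json.dumps(
            {
                "blocks": [
                    {
                        "theta_star": b.theta_star,
                        "rho_star": b.rho_star,
                        "n_points": b.n_points,
                        "spacing": b.spacing,
                        "jitter": b.jitter,
                        "name_prefix": b.name_prefix,
                    }
                    for b in self.blocks
                ],
                "n_background": self.n_background,
                "seed": self.seed,
            },
            indent=2,
        )


def default_layout() -> GenomeLayout:
    return GenomeLayout({"q1": 146 * BP_PER_MB, "t1": 30 * BP_PER_MB})


def _line_points(block: PlantedBlockSpec, x_max: float, y_max: float,
                 rng: np.random.Generator) -> list[tuple[float, float]]:
    """Place n points on the planted line inside [0,x_max] x [0,y_max]."""
    t = math.radians(block.theta_star)
    c, s = math.cos(t), math.sin(t)
    # line: (x, y) = rho*(c, s) + u*(-s, c); find the u interval in bounds
    lo, hi = -math.inf, math.inf
    for base, d, limit in ((block.rho_star * c, -s, x_max),
                          (block.rho_star * s, c, y_max)):
        if abs(d) < 1e-12:
            if not (0.0 <= base <= limit):
                raise ValueError("planted line lies outside the layout")
            continue
        u0, u1 = (0.0 - base) / d, (limit - base) / d
        lo, hi = max(lo, min(u0, u1)), min(hi, max(u0, u1))
    span_needed = (block.n_points - 1) * block.spacing
    if hi - lo < span_needed:
        raise ValueError(
            f"line segment inside layout ({hi - lo:.2f} Mb) too short for "
            f"{block.n_points} points spaced {block.spacing} Mb"
        )
    u_start = lo + (hi - lo - span_needed) / 2
    pts = []
    for k in range(block.n_points):
        u = u_start + k * block.spacing
        x = block.rho_star * c - u * s
        y = block.rho_star * s + u * c
        if block.jitter:
            x += rng.uniform(-block.jitter, block.jitter)
            y += rng.uniform(-block.jitter, block.jitter)
        pts.append((min(max(x, 0.0), x_max), min(max(y, 0.0), y_max)))
    return pts


def generate_synteny_dataset(
    blocks: Sequence[PlantedBlockSpec],
    n_background: int = 0,
    layout: GenomeLayout | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    query_chromosome: str = "q1",
    target_chromosome: str = "t1",
) -> SyntheticDataset:
    """Plant collinear blocks plus uniform background into gene tables.

    Every planted point appears as exactly one same-name cross pair:
    planted names are ``prefix<i>_<k>`` and background names ``bg<k>``,
    all distinct, so recovered S is attributable to geometry alone.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    layout = layout or default_layout()
    x_max = layout.lengths[query_chromosome] / BP_PER_MB
    y_max = layout.lengths[target_chromosome] / BP_PER_MB
    query: list[GeneRecord] = []
    target: list[GeneRecord] = []
    for bi, block in enumerate(blocks):
        for k, (x, y) in enumerate(_line_points(block, x_max, y_max, rng)):
            name = f"{block.name_prefix}{bi}_{k}"
            query.append(GeneRecord(query_chromosome, round(x * BP_PER_MB), name))
            target.append(GeneRecord(target_chromosome, round(y * BP_PER_MB), name))
    for k in range(n_background):
        name = f"bg{k}"
        qx = int(rng.integers(layout.lengths[query_chromosome]))
        ty = int(rng.integers(layout.lengths[target_chromosome]))
        query.append(GeneRecord(query_chromosome, qx, name))
        target.append(GeneRecord(target_chromosome, ty, name))
    return SyntheticDataset(
        query, target, layout, list(blocks), n_background, seed,
        query_chromosome, target_chromosome,
    )


def generate_window_truth(
    layout: GenomeLayout,
    window_bp: int,
    qualifying_fraction: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    reference_count: int = 5,
    target_chromosome: str = "t1",
) -> tuple[list[GeneRecord], list[GeneRecord], float]:
    """Gene tables whose positive-window probability is known exactly.

    Clusters of ``reference_count`` co-located query genes (each with a
    same-name target partner on ``target_chromosome``) are dropped onto
    the largest chromosome. A cluster at position c makes every window
    whose start lies in [c - window + 1, c] positive; clusters are
    spaced so these catchments never overlap, and one partial cluster
    near the chromosome start trims the covered-start total to the
    requested fraction exactly. The returned third element is the true
    probability (covered starts / total valid starts), equal to
    ``qualifying_fraction`` up to one-start rounding.
    """
    if not 0.0 <= qualifying_fraction <= 1.0:
        raise ValueError("qualifying_fraction must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    intervals = _valid_start_intervals(layout, window_bp, None)
    if not intervals:
        raise ValueError("window does not fit in any chromosome")
    total = sum(hi - lo for _, lo, hi in intervals)
    want = round(qualifying_fraction * total)
    chrom = max(layout.lengths, key=layout.lengths.get)
    chrom_starts = layout.lengths[chrom] - window_bp + 1
    n_full, remainder = divmod(want, window_bp)
    positions: list[tuple[int, int]] = []  # (cluster position, starts covered)
    if remainder:
        # a cluster at c = remainder - 1 is caught by starts 0..c only
        positions.append((remainder - 1, remainder))
    # full catchments tile adjacently after the partial one
    base = (remainder - 1 if remainder else -1) + window_bp
    for k in range(n_full):
        positions.append((base + window_bp * k, window_bp))
    if positions and positions[-1][0] > chrom_starts - 1:
        raise ValueError("layout too small for requested qualifying fraction")
    query: list[GeneRecord] = []
    target: list[GeneRecord] = []
    covered = 0
    for cluster, (c, take) in enumerate(positions):
        for g in range(reference_count):
            name = f"cl{cluster}_{g}"
            query.append(GeneRecord(chrom, c, name))
            target.append(
                GeneRecord(target_chromosome,
                           int(rng.integers(max(window_bp, 2))), name)
            )
        covered += take
    return query, target, covered / total


def generate_knot_sequence(
    gaps: Sequence[int],
    flank: int = 0,
    motif_inserts: Sequence[tuple[int, str]] = (),
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> str:
    """A peptide whose cysteine spacing realises ``gaps`` exactly.

    ``flank`` random non-cysteine residues are added on each side of
    the knot. ``motif_inserts`` are (offset, text) pairs overwriting
    non-cysteine positions, offsets relative to the first knot
    cysteine; colliding with a cysteine position is an error.
    """
    if any(g < 0 for g in gaps):
        raise ValueError("gaps must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)

    def rand_aa(n: int) -> list[str]:
        return [_NON_CYS[int(i)] for i in rng.integers(len(_NON_CYS), size=n)]

    knot: list[str] = ["C"]
    cys_offsets = {0}
    for g in gaps:
        knot.extend(rand_aa(g))
        knot.append("C")
        cys_offsets.add(len(knot) - 1)
    for offset, text in motif_inserts:
        for k, aa in enumerate(text):
            if offset + k in cys_offsets:
                raise ValueError(
                    f"motif {text!r} at offset {offset} collides with a cysteine"
                )
            if not 0 <= offset + k < len(knot):
                raise ValueError(f"motif {text!r} at offset {offset} leaves the knot")
            knot[offset + k] = aa
    return "".join(rand_aa(flank) + knot + rand_aa(flank))
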