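"""Randomized genomic-window background frequency estimation.

How often does a random fixed-size window of the query genome contain
as much same-name orthologue synteny with a target chromosome as a
region of interest does? Windows (default 40 Mb) are placed uniformly
over all valid start positions of a genome layout, disallowing overlap
with the reference region itself and overshoot of chromosome ends.
The positive-hit frequency f = hits / N is summarised with a 95%
confidence interval, either by the normal approximation

    f +/- z * sqrt(f (1 - f) / N),        z = 1.96

or by the Wilson score interval with continuity correction (the
interval R's one-sample ``prop.test`` reports), with Clopper-Pearson
available as a strictly exact alternative.
"""

from __future__ import annotations

import bisect
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence, TextIO

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .gene_tables import GeneRecord, Region

__all__ = [
    "GenomeLayout",
    "WindowSample",
    "ProportionCI",
    "SamplingRun",
    "StopRule",
    "sample_window",
    "window_ortholog_count",
    "classify_window",
    "normal_ci",
    "wilson_cc_ci",
    "clopper_pearson_ci",
    "run_sampling",
]


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome name -> length in bp; the space windows are drawn from."""

    lengths: dict[str, int]

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.lengths.values()):
            raise ValueError("chromosome lengths must be positive")

    @classmethod
    def from_tsv(cls, stream: TextIO) -> "GenomeLayout":
        lengths: dict[str, int] = {}
        for line in stream:
            if not line.strip():
                continue
            chrom, length = line.split("\t")[:2]
            lengths[chrom.strip()] = int(length)
        return cls(lengths)


@dataclass(frozen=True)
class WindowSample:
    chromosome: str
    start_bp: int
    end_bp: int
    count: int = -1          # orthologue count, -1 until counted
    positive: bool | None = None


@dataclass(frozen=True)
class ProportionCI:
    lower: float
    upper: float
    method: Literal["normal", "wilson_cc", "clopper_pearson"]
    confidence: float = 0.95

    def covers(self, p: float) -> bool:
        return self.lower <= p <= self.upper


@dataclass(frozen=True)
class StopRule:
    """Termination policy for sequential window sampling.

    The canonical mode is a fixed number of draws. The stability mode
    (an interpretation of "sample until the interval stabilizes", which
    has no published operational definition) additionally stops early
    once the CI half-width has changed by less than ``tolerance``
    (relative) over the last ``lookback`` draws, checked after
    ``min_n`` draws.
    """

    fixed_n: int = 100
    stability: bool = False
    lookback: int = 25
    tolerance: float = 0.10
    min_n: int = 50

    def __post_init__(self) -> None:
        if self.fixed_n < 1:
            raise ValueError("fixed_n must be >= 1")


@dataclass
class SamplingRun:
    N: int
    hits: int
    seed: int | None
    trajectory: list[tuple[int, float, ProportionCI]] = field(default_factory=list)
    windows: list[WindowSample] = field(default_factory=list)

    @property
    def f(self) -> float:
        return self.hits / self.N

    def to_dict(self) -> dict:
        ci_n = normal_ci(self.f, self.N)
        ci_w = wilson_cc_ci(self.hits, self.N)
        return {
            "N": self.N,
            "hits": self.hits,
            "f": self.f,
            "ci_normal": [ci_n.lower, ci_n.upper],
            "ci_wilson_cc": [ci_w.lower, ci_w.upper],
            "seed": self.seed,
        }


def _valid_start_intervals(
    layout: GenomeLayout, window_bp: int, excluded: Region | None
) -> list[tuple[str, int, int]]:
    """Half-open intervals [lo, hi) of valid window starts per chromosome.

    A start s on chromosome c is valid when [s, s + window) fits inside
    c and does not intersect the excluded region. Windows touching the
    excluded region at a boundary are allowed (half-open intervals).
    """
    intervals: list[tuple[str, int, int]] = []
    for chrom, length in layout.lengths.items():
        hi = length - window_bp + 1
        if hi <= 0:
            continue
        if excluded is not None and chrom == excluded.chromosome:
            # forbidden starts: s + window > excluded.start and s < excluded.end
            forb_lo = max(0, excluded.start_bp - window_bp + 1)
            forb_hi = min(hi, excluded.end_bp)
            if forb_lo < forb_hi:
                if forb_lo > 0:
                    intervals.append((chrom, 0, forb_lo))
                if forb_hi < hi:
                    intervals.append((chrom, forb_hi, hi))
                continue
        intervals.append((chrom, 0, hi))
    return intervals


def sample_window(
    layout: GenomeLayout,
    window_bp: int,
    excluded: Region | None,
    rng: np.random.Generator,
) -> WindowSample:
    """Draw one window uniformly over all valid start positions.

    Chromosomes are weighted by their number of valid starts, so the
    placement is uniform over the pooled start space.
    """
    intervals = _valid_start_intervals(layout, window_bp, excluded)
    if not intervals:
        raise ValueError("no valid window placement exists for this layout")
    sizes = np.array([hi - lo for _, lo, hi in intervals], dtype=np.int64)
    total = int(sizes.sum())
    offset = int(rng.integers(total))
    cum = np.cumsum(sizes)
    k = int(np.searchsorted(cum, offset, side="right"))
    chrom, lo, _ = intervals[k]
    start = lo + offset - (int(cum[k - 1]) if k else 0)
    return WindowSample(chrom, start, start + window_bp)


class _PairIndex:
    """Sorted query-start index over same-name cross pairs.

    Built once per sampling run so each window count is two bisects per
    chromosome rather than a nested scan.
    """

    def __init__(
        self,
        query: Sequence[GeneRecord],
        target: Sequence[GeneRecord],
        target_chromosome: str | None,
    ) -> None:
        t_names: dict[str, int] = {}
        for r in target:
            if target_chromosome is None or r.chromosome == target_chromosome:
                t_names[r.name] = t_names.get(r.name, 0) + 1
        starts: dict[str, list[int]] = {}
        for q in query:
            m = t_names.get(q.name, 0)
            if m:
                starts.setdefault(q.chromosome, []).extend([q.start] * m)
        self._starts = {c: sorted(v) for c, v in starts.items()}

    def count(self, chromosome: str, start_bp: int, end_bp: int) -> int:
        v = self._starts.get(chromosome)
        if not v:
            return 0
        return bisect.bisect_left(v, end_bp) - bisect.bisect_left(v, start_bp)


def window_ortholog_count(
    window: WindowSample,
    query: Sequence[GeneRecord],
    target: Sequence[GeneRecord],
    target_chromosome: str | None = None,
) -> int:
    """Same-name cross pairs with the query gene inside the window."""
    idx = _PairIndex(query, target, target_chromosome)
    return idx.count(window.chromosome, window.start_bp, window.end_bp)


def classify_window(
    count: int, reference_count: int, mode: Literal["ge", "gt"] = "ge"
) -> bool:
    """Positive when the window matches ("ge") or beats ("gt") the reference."""
    if count < 0 or reference_count < 0:
        raise ValueError("counts must be non-negative")
    return count >= reference_count if mode == "ge" else count > reference_count


def normal_ci(f: float, N: int, z: float = 1.96) -> ProportionCI:
    """Normal-approximation binomial CI: f +/- z sqrt(f(1-f)/N), clamped."""
    if N < 1:
        raise ValueError("N must be >= 1")
    if not 0.0 <= f <= 1.0:
        raise ValueError("f must lie in [0, 1]")
    half = z * math.sqrt(f * (1.0 - f) / N)
    if half == 0.0:
        warnings.warn(
            "normal approximation degenerates to zero width at f in {0, 1}",
            stacklevel=2,
        )
    conf = 2 * stats.norm.cdf(z) - 1
    return ProportionCI(max(0.0, f - half), min(1.0, f + half), "normal", conf)


def wilson_cc_ci(x: int, N: int, confidence: float = 0.95) -> ProportionCI:
    """Wilson score interval with continuity correction.

    This is the interval printed by R's one-sample proportions test
    (``prop.test``) with its default continuity correction; despite
    often being quoted as "exact binomial" it is not Clopper-Pearson.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if not 0 <= x <= N:
        raise ValueError("x must lie in [0, N]")
    z = stats.norm.ppf(0.5 + confidence / 2)
    p = x / N
    q = 1.0 - p
    z2 = z * z
    denom = 2 * (N + z2)
    lower = (2 * N * p + z2 - 1 - z * math.sqrt(z2 - 2 - 1 / N + 4 * p * (N * q + 1))) / denom
    upper = (2 * N * p + z2 + 1 + z * math.sqrt(z2 + 2 - 1 / N + 4 * p * (N * q - 1))) / denom
    if x == 0:
        lower = 0.0
    if x == N:
        upper = 1.0
    return ProportionCI(max(0.0, lower), min(1.0, upper), "wilson_cc", confidence)


def clopper_pearson_ci(x: int, N: int, confidence: float = 0.95) -> ProportionCI:
    """Exact (Clopper-Pearson) binomial interval, via statsmodels."""
    if N < 1:
        raise ValueError("N must be >= 1")
    lo, hi = proportion_confint(x, N, alpha=1 - confidence, method="beta")
    return ProportionCI(float(lo), float(hi), "clopper_pearson", confidence)


def run_sampling(
    layout: GenomeLayout,
    window_bp: int,
    excluded: Region | None,
    query: Sequence[GeneRecord],
    target: Sequence[GeneRecord],
    target_chromosome: str | None,
    reference_count: int,
    mode: Literal["ge", "gt"] = "ge",
    stop: StopRule = StopRule(),
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    ci_method: Literal["normal", "wilson_cc"] = "wilson_cc",
    keep_windows: bool = False,
) -> SamplingRun:
    """Sequentially draw windows, classify them, and track f with its CI.

    Fully reproducible from ``seed`` (or a caller-supplied generator).
    The trajectory records (N, f, CI) after every draw.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    idx = _PairIndex(query, target, target_chromosome)
    run = SamplingRun(N=0, hits=0, seed=seed)
    half_widths: list[float] = []
    while run.N < stop.fixed_n:
        w = sample_window(layout, window_bp, excluded, rng)
        c = idx.count(w.chromosome, w.start_bp, w.end_bp)
        pos = classify_window(c, reference_count, mode)
        run.N += 1
        run.hits += int(pos)
        f = run.hits / run.N
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ci = (
                normal_ci(f, run.N)
                if ci_method == "normal"
                else wilson_cc_ci(run.hits, run.N)
            )
        run.trajectory.append((run.N, f, ci))
        if keep_windows:
            run.windows.append(
                WindowSample(w.chromosome, w.start_bp, w.end_bp, c, pos)
            )
        half_widths.append((ci.upper - ci.lower) / 2)
        if stop.stability and run.N >= max(stop.min_n, stop.lookback + 1):
            prev = half_widths[-1 - stop.lookback]
            cur = half_widths[-1]
            if prev > 0 and abs(cur - prev) / prev < stop.tolerance:
                break
    return run


def write_trajectory_tsv(run: SamplingRun, stream: TextIO) -> None:
    stream.write("N\tf\tci_lower\tci_upper\tmethod\n")
    for n, f, ci in run.trajectory:
        stream.write(f"{n}\t{f:.6f}\t{ci.lower:.6f}\t{ci.upper:.6f}\t{ci.method}\n")
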