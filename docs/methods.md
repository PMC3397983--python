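# Methods

## Orthologue pairing

Orthology is operationalised as *same simplified name*: the first
whitespace-delimited token of the "associated gene name" column,
case-folded. Case-insensitive matching is required in practice because
human symbols are upper-case while teleost symbols are conventionally
lower-case; without it the same-name rule finds almost nothing across
species. Tokens that are empty or purely numeric are always rejected,
as are a configurable list of prefixes covering symbol classes prone to
ambiguous cross-species naming (microRNAs `MIR*`, snoRNAs
`SNORD*`/`SNORA*`, snRNAs `RNU*`, provisional `LOC*` loci, and
teleost clone-derived names `si:`/`zgc:`/`wu:`). The list is a package
default, not a community standard; reproductions of published
orthologue counts on real exports can differ by a few pairs depending
on the exclusion set in force.

A name occurring m times in one table and n in the other contributes
all m·n cross pairs. All-pairs is the only rule that is symmetric and
independent of row order; callers who prefer a conservative map can
restrict to names unique in both tables (`unique_names=True` /
`--unique-names`). Coordinates are integer base pairs (0-based)
internally and become megabases only at pairing time, so the ρ grid of
0.1 Mb below addresses dot-plot distances directly.

## The sinusoidal Hough transform

Each dot-plot point (x, y) (Mb) defines ρ(θ) = x·cos θ + y·sin θ. The
transform plane is partitioned into cells
C_ij = [i, i+1)° × [−40 + 0.1·j, −39.9 + 0.1·j) Mb for 0 ≤ i < 180,
0 ≤ j < 1400, identified by midpoints θ_i = i + 0.5 and
ρ_j = −39.95 + 0.1·j. The counter O_ij is the number of point-curves
intersecting C_ij.

Defaults and their rationale:

| parameter | default | why |
|---|---|---|
| θ bin width | 1° | small enough that a 40-Mb region's collinearity is not blurred across angles |
| ρ bin width | 0.1 Mb | a typical neighbouring-gene distance inside a conserved block |
| ρ range | (−40, 100) Mb | covers every intersection for a ≤146-Mb query against a ≤30-Mb target; segments leaving it are clipped silently, or pass `--rho-auto` to derive the range from the data's reach |
| gap threshold | 5 Mb | a hole of this size in either genome means separate blocks |

**Cell-intersection semantics.** A sinusoid "intersects" the cells of a
θ column; which ones is a genuine modelling choice. The default
(`intersection="range"`) marks every ρ bin between the curve's values
at the column's two θ edges, inclusive — correct up to the (negligible
at these amplitudes, ≤ ρ·(1−cos 0.5°)) non-monotonicity of a sinusoid
inside a 1° column. The alternative `"midpoint"` marks only the bin at
the column midpoint; it is cheaper and slightly sharper but can miss
curves crossing a cell away from the midpoint. Both are exposed for
sensitivity checks; results on tight blocks agree, but tie sets differ
(the range rule extends an S-maximal tie roughly one θ column further,
which moves the reported tie-broken θ by ±1 bin).

**Block statistic S.** For every cell, its member points (sorted by x)
are split wherever consecutive points jump strictly more than the gap
threshold in x or in |y| — a conserved block must be compact in both
genomes (restrict to x-only with `gap_axis="x"`). S is the maximum
over cells of the largest surviving block. The search prunes by raw
count (the filtered size can only be smaller), scanning count levels
downward.

**Tie-breaking.** Among cells achieving S, the largest θ bin wins
("furthest from horizontal"), then the largest ρ bin; all tied cells
are returned so the choice is auditable. Note the consequence: for
blocks lying far from their line's perpendicular foot through the
origin, the per-column curve spans are wide, many adjacent columns tie
at S, and the winning cell's ρ can sit several bins from the
geometric line's ρ. The tied-cell list always contains the geometric
cell; consumers interested in the line itself should inspect it rather
than the single tie-broken winner.

θ = 180° is excluded (it duplicates θ = 0° with negated ρ); ρ values
exactly on a bin edge belong to the upper bin (floor convention).

A deliberately naive reference implementation (`brute_force_best`:
pure-Python triple loop plus exhaustive cell scan) shares nothing with
the vectorised path except the configuration object and is held to
exact integer equality with it in the tests.

## Window-resampling significance

Windows of fixed size (default 40 Mb) are placed uniformly over the
pooled valid start positions of all chromosomes — valid meaning the
window fits inside its chromosome and does not intersect the excluded
reference region (half-open intervals; touching at a boundary is
allowed). Pooling weights chromosomes by their number of valid starts,
which is exactly the uniform distribution over placements.

A window is positive when its orthologue count reaches the reference
count. The default comparison is ≥ ("at least as many"); strict >
("exceeds") is available as `mode="gt"` since both readings are
defensible and differ when counts tie exactly.

Confidence intervals on f = hits/N:

- `normal`: f ± z·√(f(1−f)/N) with z = 1.96, clamped to [0, 1]. Width
  degenerates to zero at f ∈ {0, 1} (a warning is emitted) — do not
  use it near the extremes.
- `wilson_cc`: Wilson score with continuity correction, the interval
  printed by R's one-sample `prop.test`. Verified against R to 6
  decimals. Note this interval is conservative: its exact coverage at
  p = 0.1, N = 100 is 97.2%, not 95%.
- `clopper_pearson`: the exact tail-inversion interval (statsmodels
  `proportion_confint(method="beta")`), offered separately because
  "exact binomial" in the literature often actually denotes
  `prop.test` output.

**Stopping.** The canonical rule is a fixed N (the published analyses
terminated at N = 100 and N = 500). "Sample until the CI stabilizes"
has no published operational definition, so a clearly-labelled
non-canonical stability rule is offered: stop once the CI half-width
has changed by < 10% (relative) over the last 25 draws, after at least
50.

## Cysteine-knot module

Spacing notation lists the runs of non-cysteine residues between
consecutive cysteines: gap 0 renders `C-C`, gap 1 `C-x-C`, gap n
`C-x(n)-C`; render→parse is an exact round-trip. The knot domain of a
precursor is located positionally — the 10th cysteine counted from the
C-terminus through the last cysteine — because Agouti-family knots are
C-terminal and N-terminal regions may contain stray cysteines.

Classification rules: first two gaps (6,6) → A1, (6,5) → A2, anything
else → other (e.g. fungal `C-x(8,9)-C-C` homologues). The functional
motif is the first exact R-F-F or R-L-F triplet in the domain;
conservative substitutions are not tolerated, and the search scans the
whole domain because the motif's loop has no fixed coordinates across
family members (a positional restriction can be layered on by slicing
the domain before classification). L-F-A-R is searched in the full
precursor when supplied. Ambiguity codes (B, Z, X) count as gap
residues and never satisfy a fixed pattern position.

Pattern matching compiles PROSITE-style elements (fixed residue,
bracket set `[VI]`, wildcard `x`, repeats `x(n)` and ranges `x(n,m)`)
to a regular expression wrapped in a lookahead, so overlapping matches
are reported at every distinct start. A recursive
enumerate-all-repeat-choices oracle in the test suite pins the
semantics.

## Synthetic data

`generate_synteny_dataset` plants collinear runs on
x·cos θ* + y·sin θ* = ρ*, parameterised by along-line spacing, with
optional per-coordinate uniform jitter, centred in the portion of the
line inside the layout; background pairs are uniform over both
chromosomes. Planted and background names are disjoint and unique, so
every planted point is exactly one pair and recovered S is
attributable to geometry alone. The default layout (146-Mb query
chromosome, 30-Mb target) mirrors the chromosome scales the default ρ
range was designed for. Placement is infeasible — and an error — when
the in-quadrant segment of the line is shorter than (n−1)·spacing; at
θ* = 45.5°, ρ* = 7.05 Mb that segment is only ~14 Mb, which is why
example blocks there use 0.4-Mb spacing.

`generate_window_truth` makes the positive-window probability exactly
computable: clusters of `reference_count` co-located query genes are
placed so that the window starts they qualify tile without overlap,
one partial cluster trimming the covered-start count to the requested
fraction (achieved exactly, up to one start in granularity). The
returned probability is the constructed truth, not an estimate.

`generate_knot_sequence` realises an exact gap list with random
non-cysteine residues and optional motif insertions (colliding with a
cysteine position is an error).

All generators are pure functions of (specification, seed).

**What the synthetic data does not emulate:** gene-density
heterogeneity, assembly gaps, duplicated names, paralogy clouds around
whole-genome-duplication remnants, or inversions within blocks.
Passing the planted-recovery tests shows the transform and its
bookkeeping are correct; it does not show that a given S on real data
is biologically meaningful — that is what the window-resampling module
is for, and its uniform placement null is itself blind to gene-density
structure.

## Problem sizes used in the test suite

Randomised checks use dot-plots of ≤ 50 points against the full
180 × 1400 grid (100 replicates for the accumulator-equality check),
1,000 single-point augmentations for S monotonicity, and 500
sampling runs of N = 100 windows for CI coverage. These sizes give the
comparisons enough resolution (binomial noise on 500 replicates is
under one percentage point) while keeping the default suite fast.

## Known limitations

- Only the single largest block is reported; a second, disjoint
  synteny area is masked (by design — the statistic diagnoses presence
  of linear synteny, not its full structure).
- The uniform window null ignores gene density; regions matched on
  density would be a stricter control.
- Same-name orthology inherits every naming inconsistency of the
  underlying annotations; it finds nothing for unnamed genes.
- The continuity-corrected Wilson interval over-covers at small N;
  for calibrated coverage use Clopper–Pearson mid-P style alternatives
  outside this package.
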