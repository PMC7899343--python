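# Methods

## The analysis in one paragraph

A colony orthomosaic is partitioned into 700 × 700 px tiles; blank
(no-content) tiles are flagged and excluded from counting. Each non-blank
tile collects repeated volunteer counts per species until it retires
(15 classifications, or 7 that reported no animals). Per (tile, species)
the sorted count vector is collapsed by six order-statistic estimators —
mean and median of the full vector, of the vector minus its two smallest
values, and of the vector minus its two largest — and each consensus is
scored against the expert count: per-photo relative error, error by
number of counters, presence/absence confusion, OLS of consensus on
expert, flight totals, and a paired Wilcoxon signed-rank test.

## Tiling conventions

Pixel coordinates are 0-based; tile bounds are half-open
`[x0, x1) × [y0, y1)`, so tiles form an exact partition and a point on an
interior edge belongs to exactly one tile (the one starting there). Edge
tiles carry the remainder and are kept. An animal belongs to the tile
containing its *head* pixel — the same rule volunteers are given ("mark an
animal only where its head is visible"), which is what prevents double
counting of bodies spanning tile boundaries.

Blank filtering uses an explicit content fraction per tile (from a
boolean content mask in synthetic mode, or a supplied per-tile score in
real mode) with default threshold 0.001 — any content keeps the tile.
A compressed-file-size proxy would be codec-dependent and not
reproducible, so it is not used.

## Volunteer behavior model

The minimal model reproducing the three phenomena real count data show —
undercount bias, species confusion, and spurious marks — with one
parameter each:

| parameter | meaning | default |
|---|---|---|
| `p_detect` | per-animal detection probability (per species) | 0.85 |
| `confusion` | row-stochastic mislabel matrix over species | identity |
| `fp_rate` | expected spurious marks per classification (Poisson) | 0.05 |
| `count_jitter` | SD of extra integer count noise | 0 |
| `activity_sigma` | log-SD of log-normal volunteer effort weights | 1.5 |
| `mark_jitter_px` | SD of mark placement around the true head | 5 px |

Each volunteer detects each animal independently (Bernoulli `p_detect`),
labels each detection by a draw from the confusion row of the true
species, and adds Poisson false marks at random positions. Volunteers are
drawn per tile without replacement, weighted by log-normal effort — a
heavy-tailed activity distribution under which a handful of volunteers do
a large share of all counting, as crowd-sourced projects consistently
show. Retirement: the full limit is 15; 7 empty classifications retire a
tile early. Empties count toward the full limit (a classification is a
classification), and the default `empty_mode="total"` counts empties in
any order; a consecutive mode is provided. Exports taken before
retirement are modeled by per-tile caps on the number of counters.

Two simulation routes share this model: the mark-level route
(`simulate_classifications` → `marks_to_counts`), which produces
positioned marks and is the canonical pipeline path, and a vectorized
count-level route (`simulate_count_matrix`) that draws per-classification
counts directly and replays retirement column-wise. They are
distributionally identical (tested) ; the count-level route exists for
replicate-heavy experiments.

## True-count structure

Occupied tiles are overdispersed and low-median: defaults target means
(SDs) of 6 (12) animals per occupied tile for seals and 12 (19) for sea
lions — the per-photo structure observed in real colony counts — via a
zero-truncated negative binomial (`sample_tile_counts`). The spatial
generator (`generate_colony`) reaches the same overdispersion with a
clustered point process: log-normally weighted cluster centers inside an
occupancy-restricted habitat, Gaussian spread (default 350 px) around
each.

When both species occupy the same tiles, their counts are coupled through
a Gaussian copula with correlation 0.7 on the negative-binomial marginals
(`sample_correlated_tile_counts`): crowded ledges are crowded for both
species. Independent draws would create tiles pairing many seals with
near-zero sea lions, a configuration real colonies — where sea lions
outnumber seals nearly everywhere — do not show, and which would dominate
the sea-lion relative error through tiny denominators.

## Consensus numerics

Trimming is positional on the sorted vector, so ties need no rule. For
n ≤ 2 a trimmed variant cannot drop two values; it falls back to the
untrimmed statistic and sets `fallback_used`, keeping every photo
auditable (real exports contain photos counted by a single volunteer).
Medians of even-length vectors are midpoints; consensus values stay
fractional, since downstream comparisons use sums and errors rather than
discrete counts. The vectorized path (`aggregate_sorted_matrix`) computes
all rows at once from NaN-padded sorted matrices and is exactly equal to
the scalar definition (property-tested against an independent
sort-then-slice oracle).

## Validation metrics

Relative error |cs − e| / e is undefined (not zero) when e = 0; such
photos are classified TN/FP instead. Per-photo errors are averaged with
the arithmetic mean over photos with e > 0 (the median is reported
alongside). Flight percent error is |Σcs − Σe| / Σe × 100, undefined when
Σe = 0. The regression is ordinary least squares of consensus on expert;
combinations with fewer than 3 pairs, or constant expert counts, are
omitted with a warning. "Paired Wilcoxon" is implemented as the Wilcoxon
signed-rank test (the paired variant), two-sided, zeros dropped; when all
differences are zero the report says "no detectable difference" rather
than fabricating a p-value. Photos short of the retirement limit are
included, with their actual number of counters recorded.

## Experiment sizes

The simulation experiments run at: parameter recovery — 2,000 occupied
tiles, 15 counters; error versus counters — 200 replicates of 2,000 tiles
with per-tile counter caps uniform on 1..15 (emulating an export taken
before full retirement, which is what produces photos with few counters);
confusion injection — 100 replicates of 500 two-species tiles at mislabel
rate 0.3. The demo island is 7,000 × 4,900 px (70 tiles), chosen so the
complete pipeline runs in seconds.

## What the synthetic data does and does not show

The generator reproduces the statistical structure the analysis assumes:
overdispersed low-median tile counts, undercount bias, species confusion,
sparse false positives, heavy-tailed volunteer activity, and the
retirement rules. It does not reproduce perceptual structure — animals
are not harder to detect when clustered, camouflaged or at tile edges;
volunteer skill does not vary; the expert is error-free. Passing tests
therefore demonstrate that the pipeline's estimators and metrics behave
correctly under the stated noise model, not that any particular error
level will be attained on real imagery. Real classification exports can
be ingested directly (`read_classifications`, `read_expert_counts`) for
that purpose.

## Known limitations

- Mark positions are simulated (jitter around true heads) but no
  position-based analysis is performed; counts are marks per
  classification.
- The confusion model is label-level, independent per detection; it does
  not model context effects (e.g. mixed groups being harder).
- Anonymous volunteers are distinguished per session; the same person
  counting anonymously twice is treated as two volunteers, exactly as an
  anonymized export forces.
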