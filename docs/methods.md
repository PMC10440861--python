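# Methods

## Scope and model

`cnsv` converts catalogues of large mutational events into fixed-order
channel × sample count matrices for signature analysis. Two schemas are
implemented; both are classifications, not callers — segments and
rearrangements must already be called upstream.

### CNV48

A copy-number segment is a 1-based inclusive interval with integer
major/minor allele counts (A ≥ B ≥ 0). Classification is a pure
function of (A, B, length):

* heterozygosity state: homdel (A = B = 0), LOH (A > 0, B = 0),
  het (A > 0, B > 0);
* TCN class over A + B: {0}, {1}, {2}, {3–4}, {5–8}, {≥ 9};
* size bin: (0, 100 kb], (100 kb, 1 Mb], (1 Mb, 10 Mb], (10 Mb, 40 Mb],
  (40 Mb, ∞) for het/LOH; (0, 100 kb], (100 kb, 1 Mb], (1 Mb, ∞) for
  homdel.

The admissible combinations number exactly 48 (het: 4 TCN classes × 5
bins; LOH: 5 × 5; homdel: 3), since het forces TCN ≥ 2 and homdel
forces TCN = 0. Canonical row order is homdel block, LOH block, het
block, each by TCN class then size bin; the published schema prints no
order, so a stable one is fixed here for downstream tools.

Bin inclusivity is not printed with the schema's bin edges; left-open,
right-closed is adopted uniformly (a 100 kb segment is `0-100kb`) and
enumerated in tests. Fractional caller output (PURPLE, Battenberg)
rounds half away from zero because the schema is defined on integer
allele counts; rows with negative/non-finite copy numbers, invalid
chromosomes (outside 1–22, X, Y after stripping `chr`), or end ≤ start
are skipped with a logged warning rather than imputed. FACETS rows with
missing `lcn.em` are skipped: heterozygosity is undefined without the
minor allele. Diploid `2:het` segments are counted — the schema
includes those channels. All dialects are read as 1-based inclusive
tables; the 1-based convention only matters through length
= end − start + 1, and a uniform rule keeps the same profile identical
across dialects.

### SV32

Each rearrangement contributes two single-base breakpoints (BEDPE mate
intervals are collapsed to their midpoint, floored, after 0-based →
1-based conversion). Type comes from `svclass` (synonyms DEL/deletion,
DUP/duplication, INV/inversion, TRA/BND/translocation are accepted) or
from the mate-strand convention; inter-chromosomal events are always
translocations. Intra-chromosomal events are binned by |pos2 − pos1|
into (0, 10 kb], (10 kb, 100 kb], (100 kb, 1 Mb], (1 Mb, 10 Mb],
(10 Mb, ∞); translocations are unbinned because their net size is not
well defined. With the clustered/non-clustered split this yields 32
channels.

### Clustered annotation

Per sample:

1. Both mates of every record enter the breakpoint list of their
   chromosome (clusters are a property of breakpoints, not events).
2. Per chromosome in sorted order, IMD_i = pos_i − pos_{i−1}; the first
   breakpoint takes its successor's distance so it can join a cluster
   at a chromosome edge. A chromosome with a single breakpoint has no
   defined IMD and is excluded from all means.
3. The sample mean IMD is the mean over all defined IMDs across
   chromosomes jointly.
4. Each chromosome's log10(IMD + 1) series is segmented by exact
   piecewise-constant fitting; a segment is clustered iff it contains
   ≥ `min_breakpoints` (default 10) breakpoints and its mean **raw**
   IMD ≤ sample mean / `cluster_factor` (default 10). A record is
   clustered iff either breakpoint lies in a clustered segment.

The published description ("average distance in a segment is less than
10 times the average") is directional only after interpretation: read
literally it would mark essentially every segment clustered. It is
implemented as *ten-fold shorter than the sample average*, which
matches the published rainfall examples where dispersed chromosomes are
entirely non-clustered. Because the test is a ratio of means, clustered
flags are invariant under rescaling all coordinates by a positive
constant (checked on random fixtures).

### PCF numerical choices

The segmentation minimizes Σ within-segment SSE + γ·(#segments) exactly
by dynamic programming over cut points with prefix sums (O(n²) time,
n = breakpoints per chromosome per sample — trivially fast at realistic
densities). Ties break toward fewer segments, making output
deterministic. γ defaults to 25 on the log10 scale: the upstream
Potts-filter reference does not print a penalty, and on log10 values a
split must explain ≥ 25 units of squared deviation — roughly a
sustained ≥ 1.5-decade IMD shift over a dozen breakpoints — which keeps
uniform background unsplit while isolating kilobase-scale clusters
against megabase-scale background. γ, the 10× factor, and the
10-breakpoint minimum are all CLI-exposed so alternative conventions
can be reproduced.

The exactness of the DP is verified in tests against an independent
brute-force oracle that enumerates all 2^(n−1) segmentations for
n ≤ 12.

## Synthetic-data generator

The fixture module emits inputs with per-record ground-truth channels,
so `classify(generate(spec))` can be compared exactly. Scenarios (all
with one seeded RNG stream; identical specs give byte-identical files):

* **focal_amp / loh_heavy / wgd** — archetypal copy-number profiles:
  60% of events are drawn from the scenario's signature channels
  (TCN 5–8/9+ at ≤ 10 Mb sizes; TCN-1 LOH across all bins; TCN 3–4 at
  10 Mb–40 Mb/> 40 Mb respectively) and 40% from a diploid-range
  background pool. Segments are placed non-overlapping on chromosomes
  1–22 with real GRCh38 lengths, sizes drawn strictly inside the
  intended bin.
* **chromothripsis / mixed** — one tight cluster (≥ 10 breakpoints,
  consecutive spacing 0.8–1.2 kb, on a dedicated chromosome) plus
  sparse background spaced ≥ 10 Mb on other chromosomes; mixed adds
  translocations and a larger background share.
* **dispersed** — background only.

Two construction rules make ground-truth clustered flags provable
rather than probable: background chromosomes carry at most 8
breakpoints, so the ≥ 10-breakpoint rule alone forbids clustered
background calls; and in cluster scenarios background intra-event
sizes are ≥ 1 Mb, so with cluster spacing s ≤ 1.2 kb, n_c ≥ 10 cluster
breakpoints and n_b ≥ 4 background breakpoints of IMD ≥ 10⁶, the sample
mean is at least n_b·10⁶/(n_c + n_b) ≥ 10·s for every admissible event
count — the threshold inequality holds with two orders of magnitude of
margin. Cluster scenarios therefore require n_events ≥ 8 (a cluster
with no background has sample mean = cluster mean and could never
satisfy a relative threshold).

What the generator does **not** emulate: overlapping/subclonal
segments, caller noise in copy numbers, purity/ploidy distortion,
realistic breakpoint mechanisms (the "chromothripsis" scenario is a
spacing pattern, not an oscillating CN state), sex chromosomes in CNV
fixtures, or multi-sample cohorts. Passing end-to-end tests therefore
demonstrates correctness of classification, clustering, and I/O on
well-formed input — not robustness to caller artifacts, which is
handled separately by the readers' row-level validation tests.

## Plotting

Data assembly is separated from rendering: `profile_series` returns the
exact bar heights (the sample's matrix column in canonical order), and
tests assert on those numbers; rendering tests only check a valid
PNG/PDF is produced. The palette (one color per SV type; per-group
colors for CNV blocks) is a fixed package choice — the schema
prescribes none.

## Problem sizes used in checks

Structural checks are exhaustive enumerations of the channel grids.
Stochastic checks use 20-event fixtures across 20 seeds per scenario,
200 random series (n ≤ 12) for the PCF oracle, and 50 fixtures for
scale invariance — sizes at which the brute-force oracles are exact and
the full suite runs in seconds.

## Known limitations

* Human genome only (chromosomes 1–22, X, Y); other contigs are
  skipped with warnings.
* Battenberg input uses the clonal state columns (`nMaj1_A`,
  `nMin1_A`); subclonal fractions are ignored.
* The O(n²) DP is exact but would be slow for a sample with hundreds of
  thousands of breakpoints on one chromosome; real SV catalogues are
  orders of magnitude below that.
* Balanced vs unbalanced translocations are not distinguished, and no
  complex-event typing beyond the clustered flag is attempted.
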