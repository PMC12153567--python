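# Methods

This note records the models behind `flygroup`, the defaults that matter,
and the choices made where more than one reasonable construction exists.

## Data model

A trajectory table holds one row per (trial, individual, integer second)
with positions in mm inside a square arena of side 140 mm (configurable).
Raw video-rate streams are reduced to 1 Hz by **nearest-frame selection**
(ties toward the earlier frame), never by interpolation: interpolation
manufactures sub-pixel motion that would bias speed and pause statistics
downward and upward respectively. Tracking dropouts are forward-filled
only when a gap is at most 5 s (configurable); longer gaps split the track
into bouts and are reported, not invented.

The 24-h day is analysed in six contiguous 4-h phases: PI, PII, PIII in
the photoperiod, P-S straddling the lights-off transition, and SI, SII in
the scotoperiod. With a 14 h photoperiod the only placement in which a
4-h bin straddles lights-off (14 h) is PI = [0, 4), PII = [4, 8),
PIII = [8, 12), P-S = [12, 16), SI = [16, 20), SII = [20, 24) hours from
lights-on; that is the default. Phase intervals are half-open, so every
second belongs to exactly one phase.

## Micro-area partition

Four regions are derived from the cumulated (identity-free) movement
positions of a whole observation:

1. **food-provision** — cells of a 1 mm occupancy grid inside the central
   food circle. Pure geometry, assigned first and excluded from all other
   labels; 78.5 mm² in the grid-free limit for the 10 mm diameter.
2. **center-diffusion** — the 2-D DBSCAN cluster (eps 4 mm, min_pts 5)
   whose grid footprint contains the arena centre, minus food cells. If no
   cluster holds the centre the region is empty and a warning is raised.
3. **edge** — grid cells within a 5 mm wall band whose positions, collapsed
   to an unrolled-perimeter arclength coordinate (origin corner, up the
   left wall, then top, right, bottom), fall within eps of a 1-D DBSCAN
   cluster of the collapsed positions. The wrap-around at arclength
   0 ≡ 4·side is not stitched; a cluster spanning the origin corner is
   found as two adjacent clusters, which labels the same cells.
4. **intermediate** — every remaining cell.

Region area is footprint cell count × cell area, so the four areas close
to the arena area within one cell of rounding — a convex hull would
overstate ring-like occupancy, a kernel density would need a bandwidth the
data cannot justify. Because day-long recordings pile thousands of points
into single cells, the partition DBSCAN runs on the unique occupied cells
with occupancy counts as sample weights; at grid resolution this is
equivalent to clustering the raw points and bounds memory by the cell
count. The 5 mm band default (~two body lengths) is a parameter, not a
claim about where "the wall" ends; widening it grows the maximal possible
edge region accordingly.

## Movement parameters

All are defined on 1-s displacement units of one individual, attributed to
the micro-area of the unit's **starting** position, then averaged per
individual and (unweighted) across individuals to one value per
(trial, area, phase).

* A unit is a **pause** when its displacement is below 0.25 mm. The pause
  threshold exists because tracked centroids jitter — "no movement" is
  never literal — and the observed speed mass lies overwhelmingly below
  0.2 mm/s; every speed-dependent parameter shares this single threshold.
* **Speed** averages over all units, pauses included; the **locomotory
  rate** averages over moving units only and is therefore never smaller.
  It is reported missing when nothing moved.
* **DCR** is the absolute heading difference of consecutive moving units,
  in [0°, 180°]. Headings are undefined across sub-threshold
  displacements and such units are skipped, not zero-filled — zero-filling
  would deflate the rate during rest.
* **Sinuosity** (path length / net displacement) needs a segment
  definition. The segment used is one individual's continuous residence
  bout within one micro-area and phase; bouts shorter than 3 samples or
  with net displacement under 0.1 mm (closed loops) are skipped, and the
  cell value is the mean over bouts. Any fixed-length segmentation is
  equally defensible; residence bouts were chosen because they never span
  the area boundaries the analysis conditions on.
* **Stop number / stop time** count maximal runs of paused units and sum
  their durations; paused plus moving time equals attributed time exactly.
* **Duration rate** is the percentage of (individual, second) rows of a
  phase spent in each area; the four areas sum to 100 % by construction.

## Dispersion parameters

Computed on positions pooled over non-overlapping windows aligned to phase
starts (10–60 s by default), each window value averaged per
(trial, area, phase, setting):

* **Cluster count**: DBSCAN clusters (scikit-learn) at eps 4 mm — just
  under the closest reported inter-fly distance — with min_pts 5; noise
  belongs to no cluster.
* **I-index**: I = (N+1) Σ rᵢ⁴ / 4 (Σ rᵢ²)², rᵢ the distance from point i
  to its nearest other point. The formula is dimensionless and
  scale-invariant; it equals 0.375 for every 2-point set and (N+1)/4N when
  all rᵢ are equal. Note that a single dominant rᵢ *raises* the index —
  the implementation follows the formula as printed, and callers should
  read large values as "few isolated distances dominate", not "aggregated".
* **Mean crowding**: c = m + v/m over quadrat counts of a lattice of cell
  lengths side/{4, 6, 14, 28, 42} (cells of 1225 … 11.1 mm²), with v the
  population variance — m and v describe the realised lattice, not an
  estimate of a superpopulation; the sample estimator and Lloyd's classical
  m + v/m − 1 are available as options. Per-area values restrict both the
  points and the lattice cells to that area.
* **SSI**: first-bin minus second-bin counts, bins [0, l) and [l, 2l) at
  l = 4 mm, of nearest-neighbour distances. The point-set form
  (`dispersion.ssi`) operates on any point cloud. The windowed pipeline
  uses **per-second inter-individual distances** (`ssi_social`): in a
  pooled cloud of 1-Hz tracks, every point's nearest neighbour is its own
  previous-second position whenever per-second steps are below l, which
  saturates the cloud statistic at +N for any behaviour. Distances between
  distinct individuals at the same second measure social spacing; at or
  below 0 the index indicates no attraction at range l. Raw counts are
  used rather than percentages so areas of different occupancy compare on
  an absolute footing.

Min–max normalization is provided for display panels only; raw values are
what enters statistics.

## Statistical layer

Per-trial means are the representative values; their mean, sample SD and
CV = SD/mean summarise each (strain, area, phase, parameter) cell. The
area and phase factors are coupled in the design (every second has both an
area and a phase), so multiple comparisons release one factor at a time:
areas are compared within each phase (6 pairs, alpha 0.05/6 = 0.0083) and
phases within each area (15 pairs, alpha 0.05/15 = 0.00333), each family
screened first by a Friedman test. Strain contrasts are paired by trial
index per (area, phase) cell at 0.05, with [0.05, 0.10) flagged as a trend.

Both paired tests are exact at the study size:

* **Wilcoxon signed-rank**: zeros dropped, average ranks on tied absolute
  values, W = min(positive-rank sum, negative-rank sum). For n ≤ 12 the
  two-sided p is the exact share of the 2ⁿ sign assignments whose
  min-rank-sum is at most the observed W (the sign-flip distribution is
  symmetric, so this equals twice the one-tail mass capped at 1); beyond
  n = 12 the tie-corrected normal approximation is used. At n = 8 the
  attainable floor is p = 2/256 ≈ 0.008.
* **Paired permutation**: statistic Δμ = mean difference; p counts sign
  assignments with |mean(s·d)| ≥ |Δμ|, the observed assignment included,
  so p > 0 and the test is valid (type-I ≤ nominal). Full enumeration to
  n = 16, seeded Monte-Carlo beyond.

The cutoffs (12 and 16) keep every n = 8 analysis exact. The Friedman
statistic is tie-corrected and referred to χ²(k−1); a fully tied matrix
carries no ordering information and reports χ² = 0, p = 1. The two-way
repeated-measures ANOVA tests each effect against its own
subject-interaction error term (MS_A/MS_{A×S}, etc.); no sphericity
correction is applied by default, matching common practice for this
design, and the decomposition is verified against a brute-force
sums-of-squares oracle in the tests.

## Synthetic trajectory generator

`synth.simulate_group` is a statistical stand-in for arena recordings, not
a biomechanical fly model. Per individual and second:

* a two-state Markov chain (move → pause 0.05/s, pause → move 0.25/s,
  hence ~17 % of time paused at stationarity) gates movement; paused
  individuals displace exactly 0;
* moving individuals draw a lognormal step (median `base_step` = 0.1 mm,
  shape σ = 1.5, capped at 20 mm/s) scaled by a diel phase multiplier
  (defaults peak at 2× in P-S and stay elevated through the scotoperiod).
  The shape parameter puts ~70 % of steps below 0.2 mm yet leaves a
  few-percent tail beyond 1 mm/s — both features of observed arena speed
  histograms, and the tail is what lets a track break into separate
  density clumps rather than one continuous trail;
* heading performs a correlated random walk (persistence 0.7), biased
  toward the food circle within a 40 mm olfactory capture range (weight
  0.3) and toward the nearest neighbour within 10 mm (weight 0.5);
  without the range limit a constant centre-ward drift makes the centre
  absorbing and no fly ever reaches the wall;
* inside a 5 mm edge band, headings are projected onto the nearest wall's
  tangent with probability 0.5 per second (wall following); steps crossing
  a wall are reflected.

Randomness comes from one root seed; per-individual streams are spawned
deterministically, so runs are byte-identical given the seed and existing
tracks are unchanged when individuals are added (absent interaction).

What the generator reproduces: right-skewed speeds, diel modulation,
central and wall occupancy clusters, local aggregation with small
inter-individual distances, move/pause bout structure. What it does not:
body orientation, courtship or aggression events, identity swaps and
detection noise of real tracking, or any calibrated match to a particular
strain's numbers. Tests passing on synthetic data therefore validate the
*measurement machinery* — that the pipeline recovers the structure the
generator planted — not any biological claim.

## Problem sizes used in the tests

Unit and acceptance tests simulate 5–10 individuals for 600–1500 s per
trial and average over 5–20 seeds; the exact-test suites enumerate 2⁸
patterns per dataset and 2000 null datasets for the type-I check. These
sizes were chosen as the smallest at which the Monte-Carlo checks have
stable margins (3 SE criteria) while the whole suite stays fast enough to
run routinely.

## Known limitations

* The edge-cluster arclength does not stitch across the origin corner
  (two adjacent 1-D clusters result; cell labels are unaffected).
* The I-index's printed form rewards dominant isolated distances (see
  above); it is reported as defined, with interpretation left to the
  caller.
* The permutation test's Monte-Carlo branch (n > 16) uses the add-one
  estimator, which is slightly conservative.
* `rm_anova_two_way` requires a complete balanced design; unbalanced data
  must be completed or analysed pairwise instead.
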