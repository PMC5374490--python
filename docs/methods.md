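# Methods

## Behavior classification

The classifier operates on per-frame 3D positions `p_i` (cm) at frame rate
`f` (default 30 fps).  Speed at sample `i` is the backward difference
`v_i = f·‖p_i − p_{i−1}‖`; the turn angle `θ_i` is the unsigned angle
(0–180°) between the horizontal-plane displacement entering and leaving
sample `i`.  Vertical motion contributes to speed but not to turning:
darting is a planar swimming pattern, and vertical angles are dominated by
tracking noise.

Two boundary conventions are fixed so results are reproducible.  First,
the initial sample inherits the first computable speed (`v_0 := v_1`), so
a fish that is stationary from the very first frame yields a freezing bout
covering the whole recording rather than one starting a frame late.
Second, ties at thresholds are resolved as strict `<` for freezing and `≥`
for erratic movement.

**Freezing** is a maximal run of `v < v_freeze` that, after merging runs
separated by at most `merge_gap`, lasts at least `d_min`.
**Erratic movement** marks frames with `v ≥ v_err` whose mean turn angle
over a centered window of `w_err` seconds (valid turn samples only) is at
least `θ_err`; marked runs are merged across gaps of at most `merge_gap`.
Because `v_freeze < v_err` is enforced, the two behaviors are disjoint by
construction.

Defaults, all configurable via `ClassifierParams`:

| parameter | default | unit | rationale |
|---|---|---|---|
| `freeze_speed_max` | 0.5 | cm/s | conventional adult-zebrafish immobility criterion |
| `freeze_min_dur` | 2.0 | s | excludes momentary pauses between swim bouts |
| `erratic_speed_min` | 10.0 | cm/s | darting is several-fold faster than cruising (~3 cm/s) |
| `erratic_turn_min` | 45 | degrees | separates zig-zagging from fast straight swimming |
| `erratic_window` | 1.0 | s | turning must be sustained, not a single sharp turn |
| `merge_gap` | 0.5 | s | bridges single-frame threshold crossings and short dropouts |

Tracking dropouts are first bridged by linear interpolation when at most
`max_gap` frames long (default 5 frames ≈ 0.17 s), positions are smoothed
by a centered moving average over valid samples (default window 5 frames),
and remaining invalid samples are excluded from both the numerator and the
denominator of every percent-time computation; dropout spans longer than
`merge_gap` break bouts.  Percent time is exact interval arithmetic: each
frame occupies `[t_i, t_i + 1/f)`, and bouts straddling an interval
boundary contribute pro-rata.

Protocol intervals follow the standard design — baseline `[0, 300)` s,
onset at 300 s, first-5-min window `[300, 600)`, and three 10-min test
bins covering `[300, 2100)` s.  All are derived from the trajectory's
`protocol_onset`, so other onsets shift the whole grid.

## Observer validation

Agreement is computed at the granularity treatment effects are analyzed
at: per-fish percent freezing over the full 30-min test, automated vs.
observer, summarized by Pearson r with a two-sided p from the t transform
(n − 2 df).  Correlation of percentages is insensitive to constant
boundary biases between scorer and classifier; frame-level Cohen's κ is
provided for stricter, offset-sensitive comparison.

## qPCR relative expression

Relative quantity per (fish, nucleus) is `E^−ΔCt` with
`ΔCt = Ct(c-fos) − Ct(18s)` and amplification efficiency `E = 2.0`
(perfect doubling) by default; per-run efficiencies can be substituted.
Both plain `2^−ΔCt` and calibrator-normalized (ΔΔCt-style) modes exist
because either may be appropriate depending on whether a control treatment
is designated.  Cells missing either gene are NaN and are never imputed.

Group statistics: per-nucleus one-way ANOVA across treatments, pairwise
equal-variance t tests over a *declared* comparison family, and Holm
step-down adjustment over exactly that family.  Declaring the family
explicitly (rather than all pairs by default) keeps the correction aligned
with the planned contrasts.

## Co-activation networks

Edges are pairwise-complete Pearson correlations across fish, computed on
**log2 relative quantities**.  `2^−ΔCt` values are log-normal; correlating
them on the raw scale attenuates the underlying association (a true
log-scale correlation of 0.8 with σ = 1 log2-unit appears as ≈ 0.76 raw),
so the log scale is both the standard qPCR analysis scale and the one on
which the simulator's target structure is recovered.  Edges need at least
3 complete fish pairs and nonzero variance; otherwise they are flagged
undefined, and the summary measures refuse undefined edges rather than
silently dropping them.

**QAP.**  The observed statistic is the Pearson correlation between the
two matrices' upper-off-diagonal entries.  The null permutes one matrix's
node labels jointly over rows and columns, preserving the within-matrix
dependence that invalidates treating edges as independent observations.
With ≤ 8 nodes all `n!` permutations are enumerated (4 nuclei → 24,
always exact); larger problems fall back to seeded Monte-Carlo with the
add-one estimator `(1 + #{r_π ≥ r_obs})/(1 + n_perm)` so p never reaches
0.  The p-value is one-sided toward similarity (proportion of
permutations, identity included, with `r_π ≥ r_obs`); QAP is used here as
a similarity test, and *failure* to detect similarity (`p > α`) is the
verdict that two co-activation patterns differ.  A two-sided mode is
available.

**Density and centrality.**  Valued-graph density is the mean of |r| over
node pairs; eigenvector centrality is the principal eigenvector (symmetric
eigendecomposition, nonnegative, unit Euclidean norm) of the |r| weight
matrix with zeroed diagonal.  Absolute values keep the weight matrix
nonnegative, which Perron–Frobenius requires for a well-defined
nonnegative principal eigenvector.  A significance-filtered variant
(edges with p < α only) of both measures is available as a switch; it was
measured to be *less* reliable than raw |r| weights at recovering the
decoupled-node signature at n = 10 fish (edge-level significance is
noisy at that sample size), so |r| remains the default.

## Synthetic data generators

**Trajectories.**  Fear dynamics are a 3-state continuous-time Markov
chain over {swim, erratic, freeze} whose transition rates switch at
stimulus onset, sampled by Gillespie holding times (truncated at the
epoch boundary) and discretized to frames.  Default rates encode the
social-buffering contrast: post-onset freezing occupancy ≈ 50% for fish
tested alone vs ≈ 20% for shoal-buffered fish, with quiet baselines
(< 1% freezing) before onset.  Freezing exit rates (0.095/s alone,
0.16/s buffered) give mean bout lengths of 6–10 s, comfortably above the
2-s detection minimum.  Positions follow per-state kinematics — persistent
random walk at 3 ± 1 cm/s while swimming, 18 ± 4 cm/s with near-uniform
heading changes while erratic, a held position with 0.003 cm jitter while
freezing — folded into reflective arena walls (default 30 × 15 × 25 cm).
Tracking noise is iid Gaussian (default 0.01 cm, sub-millimetre as typical
of tracker centroid error) and dropouts iid per frame (default 1%).  The
noise magnitudes matter jointly with smoothing: after the 5-frame moving
average, position noise must contribute well under `freeze_speed_max` of
apparent speed, which 0.01 cm does (~0.2 cm/s) and 0.1 cm would not.
Cohorts add per-fish lognormal multipliers (σ = 0.3) on every transition
rate, giving the overdispersion real fish show.

What the generator does **not** emulate: burst-glide micro-structure of
swimming, thigmotaxis and wall-following, depth preferences, non-
exponential bout-length distributions, autocorrelated tracking error, and
any interaction with the stimulus shoal.  Passing tests therefore show the
pipeline recovers the *statistical* structure it assumes, not that the
thresholds are correct for any particular arena — those must be validated
against observer scoring on real recordings.

**Observer logs** are ground-truth freezing runs degraded by a miss rate
and Gaussian boundary jitter, then re-ordered to stay non-overlapping.

**Expression tables** draw per-fish log2 expression from a multivariate
normal with configurable per-nucleus means/SDs and target correlation
matrix, and emit Ct pairs against a fixed reference (`Ct(c-fos) =
Ct(18s) − log2(expression)`), so the 2^−ΔCt computation recovers the
generated quantities exactly (verified to 1e-9).  Two structure factories
encode the study's contrast: `decoupled_structure` (Dm–Vs–POA mutually
coupled, Vv independent) and `coupled_structure` (all four coupled).

## Numerical choices

- Run/merge arithmetic uses a 1e-9 s tolerance so exact-duration bouts
  (e.g. exactly 2.0 s at 30 fps) are kept regardless of float rounding.
- QAP comparisons use a 1e-12 tolerance on `r_π ≥ r_obs` so the identity
  permutation always counts, making exact p ≥ 1/n!.
- Eigenvector centrality uses `eigh` (machine precision, well below the
  1e-10 documented tolerance); the Perron vector's sign is fixed by its
  sum and rounding-level negatives are clipped.
- Zero-variance inputs raise typed errors (`ZeroVarianceError`,
  `UndefinedIntervalError`) rather than returning silent zeros.
- Percent-time denominators use valid time only; an interval with no valid
  time yields NaN plus a recorded warning.

## Problem sizes

Verification runs use cohorts of 20 fish per treatment at 30 fps for the
full 35-min protocol (the study-scale cohort), 200 replicates of 10-fish
expression cohorts for the centrality signature, and 20 replicates of
100-fish cohorts for QAP verdict rates — sizes at which every check
completes in seconds on one core.

## Known limitations

- **QAP on exchangeable structures.**  A permutation test can only single
  out the identity alignment when the population matrix has no nontrivial
  automorphism.  The idealized decoupled structure with all three
  couplings equal is invariant under the 6 permutations of Dm/Vs/POA, so
  for two independent samples of that structure the identity ranks first
  only ~1/6 of the time and the minimum 4-node p of 1/24 is rarely
  attained: QAP then cannot certify "same structure" even when it is true.
  With heterogeneous couplings (as in real data, where every pairwise r
  differs) both verdicts are recovered essentially always at large n.
  Similarly, comparing two *fully-coupled* samples is degenerate: the
  off-diagonal vector is near-constant, `r_obs` is noise-dominated, and
  the verdict is uninformative.
- **Decoupled-node centrality at small n.**  With 10 fish and couplings of
  0.7, sampling noise on the null edges gives the decoupled nucleus the
  minimum eigenvector centrality in ≈ 90% of cohorts (direct Monte-Carlo:
  0.896 ± 0.002), not always — single-cohort centrality rankings at this
  sample size should be interpreted with that in mind.
- Erratic-movement criteria are operationalized here (speed + windowed
  turning); published threshold sets vary and all parameters are exposed
  rather than asserted as canonical.
- The repeated-measures ANOVA over time bins (with sphericity
  corrections) is deliberately out of scope: the pipeline emits tidy
  per-fish binned tables consumable by any standard implementation.
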