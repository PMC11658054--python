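# Methods

This note documents the models implemented in `queenrelay`, their
assumptions, the parameters that matter, and the choices made where the
design was genuinely open.  Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Body geometry and contact detection

Each bee's outline is a trapezium centred on its tracking tag, long axis
along the body heading, wider at the head than the tail (worker defaults:
length 1.0 BL, head width 0.55 BL, tail width 0.35 BL; the queen is 1.5 BL
long and proportionally wider).  Exact tag-to-outline dimensions are not
measurable from the data this package targets, so all dimensions are
config-exposed; only the relative properties (head wider than tail, queen
longer than worker) are load-bearing.

A frame is a contact frame for a pair iff the *head half* of one bee's
trapezium (front half, split at the tag line) intersects any part of the
other's trapezium.  This implements the exclusion of transmission-irrelevant
configurations: side-by-side or tail-to-tail bees have no head-half overlap.
Per frame, bee *i* *inspects* *j* when additionally the bearing from *i* to
*j* lies strictly within ±90° of *i*'s heading (the frontal half-plane; the
boundary case — a partner exactly perpendicular — is not "facing", which is
what excludes side-by-side stances).  Consecutive contact frames merge into
contact intervals; a dropout of at most one frame (config `gap_tol_frames`)
is bridged as tracking-noise tolerance; contacts never span a change of
comb side.  Inspection flags are summarised per contact as the fraction of
contact frames, and a participant counts as inspecting when that fraction
is ≥ 1/2.  Detection uses a per-frame KD-tree centroid prefilter followed
by exact polygon intersection; the unit tests verify equivalence with a
brute-force all-pairs, all-frames oracle.

No minimum contact duration is imposed: a single overlapping frame is a
0.5 s contact.

## Queen movement states

Daily queen trajectories are decomposed into step lengths (displacement per
frame) and turn angles (signed change of the displacement direction; the
first step of a track and steps adjacent to zero-length steps have
undefined turns).  Time gaps > 1 frame and side switches split tracks.

The two-state HMM uses zero-inflated gamma step emissions (a per-state
point mass at zero handles frames with no displacement) and von Mises turn
emissions; frames with undefined turns contribute only through the step
density.  Fitting is EM with the forward–backward recursions supplied by
`hmmlearn` and custom emission M-steps: weighted gamma maximum likelihood
(shape solved from ln k − ψ(k) = ln(mean) − mean(ln) by bracketed root
finding) and the standard A1-inverse approximation for the von Mises
concentration.  Ten random restarts by default; the best log-likelihood is
kept, ties broken by the smaller stationary-state mean.  State S is always
the state with the smaller fitted step mean.  Untransformed step lengths
are fitted (square-root transforms are display conventions, not model
choices).

Bout boundaries come from the Viterbi path; bout confidence is the mean
per-frame posterior of the decoded state.  Bouts shorter than 10 s or with
confidence below 0.75 are excluded from transmission analyses, and
within-bout curves are computed only to a 305 s horizon (longer bouts are
retained but truncated).  On simulated 24-hour tracks the fitted state
step means recover the generating values within 15 % (acceptance suite).

## Transmission model

State per worker: a queen-derived surface load λ_qw(t) and a worker-derived
load λ_ww(t), both in pg; λ = λ_qw + λ_ww.  The queen is the only source
and her load is clamped at λ_Q (production balances removal).  Workers
start each simulation at zero.

Processing the time-ordered contacts:

* **Direction.**  The inspector receives.  If both inspect, the bee with
  the higher current load donates; exact ties give symmetric half-rate
  transfers in both directions.  If neither inspects, nothing happens.
* **Mode.**  Each contact is a licking contact with probability
  p(τ) = p_max / (1 + exp(−(τ − τ0)/s)) in its duration τ, otherwise
  antennation; licking extracts faster (k_lick > k_ant).  The draw is the
  model's only random element (a per-frame redraw variant is selectable).
  Crucially, the uniform deviate behind each draw is keyed by the *contact
  identity* (donor, receiver, start time) hashed with the run seed, not by
  the contact's position in the sequence.  Edited sequences (queen removal,
  direct-only) therefore share common random numbers with the full
  sequence: the queen-removal curves are bit-identical to the daily curves
  before the removal time, and edited-vs-full comparisons are free of
  Monte-Carlo re-alignment noise.
* **Extraction.**  First order in the donor's load: a worker donor yields
  removed = λ0(1 − e^{−kτ}) (diminishing returns within the contact, and a
  persistent loss to the donor, split proportionally over its λ_qw/λ_ww
  fractions); the clamped queen yields removed = k λ_Q τ.  Transfers are
  leaky: the receiver's surface gains acquired = ½ × removed, credited to
  λ_qw for queen donors and wholly to λ_ww for worker donors regardless of
  the donor's own mix.  When a worker is inspected *by the queen* the
  removed amount simply vanishes (her load is clamped; nothing is credited
  and no relay flow is recorded).
* **Decay.**  Between events each worker load decays as e^{−δΔt}.  Decay is
  applied between events only; within a contact, extraction operates on the
  undecayed load (an interacting extraction+decay ODE would change results
  by O(δτ), far below the calibration uncertainty).  Integration is
  event-driven with lazy per-bee updates and exact exponential bridging, so
  grid-sampled loads match per-frame integration to rounding error.

A worker is *informed* when λ(t) > λ_min = 9.03 pg, the established worker
sensitivity threshold; directly informed when λ_qw > λ_ww, else indirectly.
Informed status for the audience metrics is computed on the ensemble-mean
loads over the S = 100 default replicates (a per-run-majority variant would
be straightforward but is not the averaging used for the audience measures).

**Calibration.**  The numeric defaults (λ_Q = 2000 pg, k_lick = 0.05 /s,
k_ant = 0.0125 /s, δ = 2×10⁻⁴ /s, lick curve p_max = 0.8, τ0 = 20 s,
s = 8 s) are a calibrated profile, not literature measurements.  The
governing consideration: λ_min is a *detection* threshold in the pg range,
while retinue workers physically gather nanogram-scale quantities; a
calibration in which one retinue visit yields only ~λ_min would make every
worker-to-worker hop sub-threshold (acquired ≤ donor/2) and indirect relay
impossible by construction.  The defaults instead deliver tens to a hundred
λ_min per retinue visit, so acquired loads survive a few leaky hops —
the regime in which a messenger system can operate at all.  All parameters
are overridable, including from YAML profiles.

## Audience metrics and experiments

A(t) is the informed fraction of the tagged workers (optionally within a
task group); S(t) the mean pairwise distance between informed workers,
using Euclidean distance on the same comb side and the shortest
around-the-edge path (minimum over the four comb edges of the reflected
straight-line distance) for opposite sides; L(t) the mean load of informed
workers.  S is missing below two informed bees, L below one.

Within-bout runs zero all loads at the bout start and use only contacts
that start and end inside the bout, on a bout-relative clock up to the
305 s horizon.  Daily runs use the full day's contacts from zero loads.
The queen-removal experiment deletes queen↔worker contacts starting after
the removal time and reports, per group, the time for the informed count to
fall to half its value at removal (linear interpolation between grid
points; counts are step functions at frame resolution).  The direct-only
experiment deletes all worker↔worker contacts.  The forward/reverse
experiment takes, for each queen–worker encounter, the worker-to-worker
contacts in the five minutes after (forward) and the time-reversed contacts
of the five minutes before (reverse; order inverted, durations preserved —
an involution), seeding the focal worker in both runs with the expected
load from the queen encounter itself so the two runs differ only through
the worker contact sequence.  An all-zero-seed variant is available by
flag.  Aggregation across colonies always gives each colony one value
(grand mean ± SE).

## Orientation, attraction, mobility

Receiver orientation toward messengers uses the specified-direction
Rayleigh statistic ρ = Σcos(θ − μ)/n, with μ the direction from the
receiver to the nearest point of the messenger's trapezium boundary
(receivers inside the outline point at its centre).  Samples are collected
for all workers within 2 BL of a messenger on the same side, in ±5 min
windows anchored at the queen-contact start (pre) and end (post) so the
contact itself contaminates neither window; positions and orientations are
rotated into the messenger frame.  Difference maps take per-cell mean ρ
(0.2 BL cells over [−2, 2]², cells under 50 samples masked) between strata:
minute-k post minus minute-k pre (time variant) or a messenger-load decile
minus all post samples (load variant).  Angular transects bin receivers by
clockwise angle from the messenger's heading (24 bins).

Worker attraction to the queen follows the trajectory-pairing approach:
observed simultaneous worker–queen distances (restricted to the queen's
stationary bouts, since attraction to a moving queen is confounded with the
queen approaching workers) are compared with distances between all pairs of
positions irrespective of simultaneity.  The paired construction converts
each observed distance into its quantile within that frame's expected
distance distribution (queen positions sampled independently per frame —
a shared subsample would correlate the quantiles); under no attraction the
quantiles are uniform, and a one-tailed Wilcoxon signed-rank on u − ½ tests
whether observed distances sit systematically low.  Frames are subsampled
(default one per 60 s) to blunt temporal autocorrelation; the null
calibration test in the suite uses well-mixed trajectories, and strongly
autocorrelated paths at high frame rates will still be anticonservative —
an inherited property of trajectory-pairing tests generally.  An unpaired
Mann-Whitney variant is available.  The reported effect is median(observed)
− median(expected) in BL (negative = attracted).

Mobility curves align per-frame speed, unsigned turn angle and side-switch
indicator on the contact start (pre) and end (post) and report the
post-minus-pre difference at matched |t| over ±5 min windows.

## Networks, communities, hierarchy

Daily contact networks count contacts per pair.  Soft communities come from
a static per-day non-negative matrix factorisation of the symmetrised,
degree-normalised adjacency (multiplicative updates, several restarts, best
reconstruction kept), row-normalised so each bee's k = 3 scores sum to 1.
This deliberately replaces temporally-smoothed soft community detection:
the temporal-smoothness term couples days, while every metric used here is
per-day.  Labelling is deterministic: F is the community whose members
(by argmax) have the highest mean age, ties broken by entrance-corner
occupancy; N_A is the nurse community holding more occupants of broodnest
patch A.  Nurses are bees with N_A + N_B > 2/3, foragers F > 2/3.  The
bridging score renormalises (N_A, N_B) to p = N_A/(N_A + N_B) and takes the
binary entropy over its maximum, H′ = −[p ln p + (1−p) ln(1−p)]/ln 2 (the
renormalisation is what makes equal affiliations score exactly 1 regardless
of the forager share).

Relay networks carry Q(i→j) = Σ_s Σ_n q_n(i→j)/S, the simulation-averaged
sum of acquired volumes, with per-node out-degree, in-degree and
Δk = k_out − k_in.  Coarse-graining by age sums gross flows between age
cohorts (0–2 day-olds pooled as callows), keeps the positive net direction,
and ranks cohorts by David's score on dyadic win proportions
P_ab = gross(a→b)/(gross(a→b) + gross(b→a)) (DS = w + w₂ − l − l₂), ties
broken by total out-flow.

## Messaging syndrome and development

The six metrics per bee-day: m1 the signed attraction effect (negated
median distance difference, so larger = more attracted — effect sizes, not
p-values, which conflate sample size), m2 queen-contact count, m3
N_A + N_B, m4 H′, m5 k_out, m6 Δk.  Each metric is quantile-transformed
within each colony-day (rank/(n+1), mean ranks for ties, constants map to
0.5), removing between-colony and between-day level differences; the
transformed rows are pooled into a single centred PCA (complete cases; the
sign convention fixes the PC1 loading of k_out positive).  Per colony, the
mean (PC1, PC2) per age traces the developmental path; Savitzky–Golay
smoothing (window 7, order 3) is applied to PC1(age) and PC2(age) and the
*inflection age* is the interior age of maximum discrete curvature
κ = |x′y″ − y′x″|/(x′² + y′²)^{3/2}.  Ages where the path has nearly
stopped (speed below half the median) are excluded: curvature is
ill-conditioned at vanishing speed, and developmental paths plateau at old
ages, which would otherwise plant spurious corners.  On planted-switch
synthetic syndromes the inflection age is recovered within ±1 day.

## The synthetic colony generator

The generator's role is to produce tracking-shaped data whose *generating
truth is known*, with the statistical structure the analyses assume:

* **Queen**: correlated random walk with per-state gamma steps and von
  Mises turns driven by a two-state Markov chain (defaults: step means
  0.04/0.45 BL per frame, dwell 60 s/40 s giving a 60 % stationary share),
  softly tethered to the broodnest (heading redirected home beyond 16 BL —
  queens stay on the brood).
* **Workers**: staggered cohorts (defaults mirror eight cohorts of 290 at
  three-day intervals; tests use far smaller colonies), each cohort split
  between the two broodnest patches (one per comb side).  Drift mixes
  area-fidelity to the patch (age-decaying), queen attraction within a 5 BL
  sensing radius (non-volatile signal; age curve peaking at 3.5 d), and for
  workers past the 10 d transition age a drift toward the entrance corner
  with stochastic patrol excursions.  Headings follow the displacement
  direction plus von Mises noise; stationary frames keep their heading.
* **Retinue turnover**: a worker in sensing range joins the court with an
  age-weighted per-frame probability, approaches, inspects at close range
  for ~60 s (court residence; run-over bees also turn briefly to inspect a
  passing queen), then leaves *excited* — the planted messenger effect: 1.8×
  speed and straighter movement for 120 s — and is refractory to
  re-engagement for 5 min.
* **Sides**: switching is teleportation when within 1 BL of the comb
  boundary, with a per-frame probability (the two sides are 2-D planes
  joined at the frame edge).

Every stochastic stream derives from the colony seed via seed sequences,
so identical configurations are byte-identical.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: tracking error and detection dropouts beyond
1-frame gaps; comb content (cells, honey/brood structure); density-driven
congestion and collision; circadian and weather-driven activity
modulation; trophallaxis networks distinct from the geometric contact
rule; and real retinue crowding limits.  One scaled-colony consequence is
documented: with a single dense brood patch per side, the stationary
queen's *encounter rate* matches or exceeds the travelling rate (in large
uniformly-crowded hives travelling sweeps more fresh bees), although the
travelling state still shows shorter contacts, faster audience growth and
lower audience loads — the directions the acceptance suite asserts.

## Problem sizes used in the tests

The test suite and acceptance checks run on scaled-down study conditions
chosen as the package's own desk-scale standard: an 80-worker, 40-minute
synthetic day (cohorts aged 14, 8, 4, 2 days) for the directional
experiments, a 100-worker day for the structural comparisons of edited
contact sequences, 20–50 stochastic replicates per ensemble (100 where the
comparison is against the S = 100 averaging convention), and a full 24-hour
queen track for HMM parameter recovery.  The scaled 40-minute day uses a
faster decay profile (δ = 3×10⁻³ /s) so that load attrition — which shapes
the queen-removal half-lives over hours in a real day — is observable
within the shortened day; experiments probing 5-minute windows
(forward/reverse) use the default δ, under which 5-minute decay is
negligible.

## Known limitations

* The direct-only ≤ full audience comparison is a statistical property of
  colony-scale spread, not a per-bee theorem: donor depletion means a bee
  that donated heavily in the full run can transiently hold more load in
  the direct-only run.  At the 100-worker scale the ensemble-mean audience
  satisfies the inequality pointwise; at a few dozen workers single
  marginal bees can flicker.
* Transfer-rate constants are calibrated, not measured; all conclusions
  from synthetic runs are directional, never quantitative predictions for
  real colonies.
* The attraction test inherits the autocorrelation sensitivity of
  trajectory-pairing tests; subsampling mitigates but does not remove it.
* The HMM assumes within-state stationarity over a day and exactly two
  states.
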