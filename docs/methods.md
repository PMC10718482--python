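# Methods

## Problem and data model

The package analyses one-week wrist-wearable records of activity energy
expenditure (EE) from a small cohort (tens of participants) in which each
person uses their own device. Three canonical export dialects cover the
brand landscape: a per-minute kcal stream emitted while the device is worn,
and two per-activity interval formats carrying one energy value per episode
(in cal and in kcal respectively). All downstream analysis operates on the
harmonized representation: per person-day, 144 half-open ten-minute bins
anchored at local midnight (bin 36 starts at 06:00), each holding the kcal
expended in that bin.

Binning assumes a constant expenditure rate within each record and
apportions energy to bins by interval overlap. This conserves total energy
exactly (records straddling bin edges or midnight are split
proportionally) and is the conservative reading of "one value per
activity" exports; the alternative — snapping short activities into a
single bin — would not conserve energy under splitting and is not offered.
Non-wear is zero EE by definition, not missing data, so profiles are
directly comparable without imputation. Timestamps are local clock times;
no time-zone arithmetic is attempted (single-site design). The 10-hour/day
wear instruction is evaluated as a QC flag only; no day is excluded on it.
Note that interval-dialect devices leave no record outside activity
episodes, so their measured "wear time" is structurally low — the flag is
informative mainly for per-minute streams.

## Weekday/weekend profiles

Person-days split by ISO weekday (Mon–Fri vs Sat–Sun). A participant's
segment profile is the per-bin arithmetic mean over their contributing
days — averaging within the day grid rather than concatenating days, so a
profile is always one "typical day". Participants with no days in a
segment are excluded from that segment (and from weekly group assignment)
with a log entry; nothing is imputed.

## TADPole clustering

Distances are dynamic time warping with L1 local cost, symmetric
unit-slope steps, matched endpoints, and a Sakoe–Chiba band |i−j| ≤ w.
L1 cost makes w=0 reduce exactly to the Manhattan distance, which anchors
several tests. Series are not z-normalized: the absolute EE level is
meaningful here (the two chronotypes differ in level as well as phase),
and normalization would discard it.

Density-peak construction: ρ_i counts neighbours strictly closer than the
cutoff d_c; δ_i is the distance to the nearest series of higher density
(density ties broken toward the smaller index, which totalizes the order);
the globally densest series takes δ = max distance. Centers are the k
series with the largest ρ·δ (ties: larger δ, then smaller index);
non-centers inherit, in decreasing-density order, the cluster of their
nearest denser neighbour. Every tie-break in the stage is a deterministic
index rule, so clustering is reproducible without a seed.

Pruning uses two admissible bounds: LB_Keogh (envelope lower bound,
symmetrized as the max of the two one-sided bounds) and the diagonal-path
cost as upper bound. A pair is a neighbour without exact DTW when its
upper bound is strictly below d_c, a non-neighbour when its lower bound is
at or above d_c; only undecided pairs get exact DTW. Both decisions are
consistent with the strict neighbour inequality, so pruned ρ, δ and the
final partition are identical to the full-matrix computation (property-
tested against an independent density-peaks implementation). The
δ-search scans denser candidates in lower-bound order and stops when no
candidate can beat the incumbent. One numerical subtlety: the diagonal
upper bound is accumulated in the same sequential order as the DP kernel,
so that when the diagonal path is optimal the bound equals the distance
bit-for-bit and equality edge cases cannot flip a neighbour decision.
The original algorithm's interruptible "anytime" contract is not
replicated — only the pruning logic that makes it fast.

Cluster prototypes are PAM medoids (member minimizing summed within-
cluster distance, ties to the smaller index). Validity is the mean
silhouette index from the DTW matrix, with the standard s=0 convention for
singleton-cluster members; k=1 is rejected as undefined. Model selection
maximizes silhouette over a grid: k ∈ {2,…,6} and d_c over the
{0.05,…,0.50} quantiles of the pairwise upper bounds (ties: smaller k,
then smaller d_c). The band default is w=14 bins (±140 min, ~10% of the
series length) — wide enough to absorb within-chronotype onset jitter,
narrow enough not to warp a night onset onto a morning one. Selection
computes the full DTW matrix once and shares it across grid cells, since
every cell's silhouette needs it anyway; pruning pays off when fitting a
single (k, d_c) pair.

## Pattern labels and groups

A profile's activity onset is its first bin above a threshold (default 0:
any positive EE counts). Onset before bin 36 (06:00) marks a night owl;
bin 36 or later an early bird — the boundary bin itself counts as "after
6 AM". Clusters are labelled by majority vote of member onsets (ties to
early bird); labelling by the medoid's onset alone is available by
configuration. Since onset depends only on positivity at the default
threshold, labels are invariant to uniform rescaling of EE. Participants
with both segment labels are *stable* if the labels agree, else
*shifting*.

## Statistics

Categorical group comparisons dispatch on observed counts: Fisher's exact
test (two-sided, sum of tables at most as likely as observed) whenever any
cell is below 5, Pearson χ² without continuity correction otherwise.
Numerical variables use the pooled-variance two-tailed t test by default —
on the reference cohort's printed EE summaries the pooled form reproduces
the published significance pattern (weekday p < .001; the weekend row
prints .003 where recomputation from the rounded printed means/SDs gives
.0004, a discrepancy attributable to input rounding, not to the test
variant) — Welch is available by flag, and a summary-statistics entry
point accepts published mean/SD/n directly. One documented discrepancy in
the reference report itself: its results prose cites age P=.001 while its
own table and abstract print P=.004; recomputation from the table counts
gives .0037, supporting the printed .004.

Association models are maximum-likelihood logistic regressions
(Newton/IRLS, tolerance 1e-8, ≤100 iterations) with Wald 95% CIs
exp(β ± 1.96·SE). Quasi-separation is flagged when |β| > 15 (with a
gradient-method fallback when the Hessian degenerates) rather than hidden
— expected behaviour at n≈47 with three binary predictors. Diagnostics:
McFadden pseudo-R², accuracy at 0.5, Hosmer–Lemeshow over 10 risk deciles
(tied deciles merged with a warning; χ² with g−2 df), and trapezoid AUC
over the ROC sweep. The reverse-direction model (risk-factor count > 1 as
outcome, pattern group among predictors) is the same machinery with roles
swapped.

## Synthetic cohorts

The generator emulates the study frame: 47 participants × 7 consecutive
days from a Monday (329 person-days: 235 weekday, 94 weekend), ~80%
weekday early birds, ~25% shifting, covariate frequencies matching the
reference cohort's margins (49% male, 36% aged ≥40, 89% sedentary, 47%
with >1 risk factor), and an optional configured log-odds linking age to
shifting (centred so the marginal shifting rate stays at the configured
fraction). Days are built on a minute grid: the first bout starts at a
truncated-normal onset (early: mean 08:00; night: mean 04:00; SD 60 min;
truncation at the 06:00 boundary keeps the archetype constraint exact in
every generated day), later bouts fall inside the archetype's active
window (night owls wind down by ~16:00, early birds by ~20:00). Bouts are
short on weekdays (~20 min) and long on weekends (~80 min); per-bout rates
are ~0.9 kcal/min (early) and ~1.4 kcal/min (night, matching the higher
night-owl EE of the reference cohort) with lognormal jitter — scale
choices that put recorded daily totals in the 150–400 kcal range of the
reference margins, not fitted quantities. Non-wear gaps (2/day, 30–120
min) are placed outside bouts. Each participant exports in one dialect
(default: equal thirds). All randomness flows from one seed with
deterministic per-participant substreams, so cohorts are byte-reproducible
and extensible without reshuffling.

Ground-truth bin series are accumulated directly on the minute grid — an
arithmetic route independent of the ingest module's interval-overlap
apportionment — which makes export → ingest → bin round-trip tests a real
cross-check rather than a tautology.

What the generator does not emulate: accelerometer noise, device-specific
EE estimation error, within-person day-to-day autocorrelation beyond the
archetype, seasonal effects, or realistic missing-data mechanisms. Passing
recovery tests therefore demonstrates correctness of the pipeline's
algorithms under the stated generative assumptions, not validity of the
chronotype construct on real cohorts.

## Problem sizes and known limitations

Tests and the acceptance script run at the scales the analysis itself
uses: cohorts of 12–47 participants for pipeline checks, 40 participants
× 10 seeds for model selection, 100 replicates of n=500 for CI coverage,
and brute-force oracle comparisons at n ≤ 25 series / length ≤ 8 DTW
enumeration — sizes at which the oracles are exact and fast.

Cluster-archetype recovery is essentially perfect on weekday profiles
(five days averaged per participant). Weekend profiles average only two
days of long, sparse bouts; DTW distance there is dominated by energy
volume rather than timing, and recovery degrades to ~0.8–0.95 on
well-separated configurations — consistent with the reference cohort's
own lopsided weekend split. Onset-at-first-positive-bin is sensitive to
any stray positive EE when the threshold is 0; the eps parameter exists
for noisy real data. The Fisher dispatcher follows the observed-cell rule
and so differs from expected-count textbook advice on purpose. Wald CIs
(not profile likelihood) are reported, matching standard small-cohort
reporting; they are anti-conservative near separation, which is why
separation is surfaced as a flag.
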