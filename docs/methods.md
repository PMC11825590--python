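# Methods

## Measurement model and well summaries

Each well of a PM-M plate produces an optical-density time series read at
a fixed interval (canonically every 15 min from 0 to 1440 min, 97 points;
any strictly increasing grid is accepted).  Two reductions to a single
per-well energy-production value are supported:

* **AUC** (default): the trapezoidal integral of OD over time, in OD·min.
  No smoothing or baseline subtraction is applied first — the raw curves
  are integrated as read.
* **Endpoint**: the relative absorbance A590−750, the reading at the
  dye's 590 nm peak minus the 750 nm background reading.

Which of the two feeds the statistics is a required configuration choice
(`RunConfig.source`, default `auc`); both can be computed side by side.

Summaries are carried downstream as `log10(max(x, eps))` with
`eps = 1e-3` (OD·min).  The floor exists because background-subtracted
endpoint reads can be zero or negative; the choice of logarithm base is
immaterial for the rank-based group statistics (invariant under any
strictly increasing transform) and affects only the scale on which the
single-case limits are drawn, which matches the quantity that would be
plotted.

## Group comparisons

A *comparison family* is a named pair of disjoint sample selections
(group labels, explicit ids, and/or a sex filter) over a set of plates;
every annotated well of every included plate is tested once.  Per well, a
two-sided Mann–Whitney test compares the two groups' log summaries:

* U counts pairs with a > b plus half of tied pairs.
* When C(n_a + n_b, n_a) ≤ 20 000 — which covers all of this package's
  intended designs, including 2-vs-50 and 1-vs-50 — the p-value is exact:
  every assignment of the pooled (midrank-tied) values to the groups is
  enumerated, and p is the fraction of assignments whose U lies at least
  as far from the null mean n_a·n_b/2 as the observed one.  The 20 000
  bound keeps the worst enumerated case well under a second per well.
* Larger designs fall back to the normal approximation with tie
  correction and continuity correction.

Exact and approximate branches agree within 0.05 (verified exhaustively
over tie-free rank configurations) whenever both groups have at least two
members and n ≥ 6; singleton-group designs can disagree by up to ~0.13
because the two-sided tail of a very coarse discrete distribution is
poorly captured by a continuous approximation.  Since singleton designs
are always handled by the exact branch in practice, this limitation never
affects results; it is stated here because the asymptotic branch is
user-reachable through `exact_limit`.

Within one comparison family, p-values are adjusted by the
Benjamini–Hochberg step-up (delegated to statsmodels' `fdr_bh`; the
monotonized p·m/i values, capped at 1).  The family is one comparison
run — all wells of all plates included in that run — and adjustment is
never pooled across comparisons.  Both thresholds are strict: raw
significance is p < alpha and FDR significance is p_adj < q, each
defaulting to 0.05.  Direction is the sign of the difference of group
medians on the log scale, `none` on an exact tie (and `none` wells are
excluded from trend aggregation).

With n = 2 vs 50 the exact test is heavily discretized: the smallest
achievable two-sided p is 2/C(52, 2) ≈ 0.0015, and the realized type-I
rate at alpha = 0.05 is 60/1326 ≈ 0.045, slightly conservative.  A
single case against 50 controls (min p = 2/51 ≈ 0.039) can never survive
FDR control over hundreds of wells — which is exactly why the single-case
classifier below exists.

## Single-case classification

One patient's per-well log summary is classified against the control
cohort's box-and-whisker **outer limits**:

* Quartiles use linear interpolation between order statistics (position
  (n−1)·p), fixed so that limits are reproducible bit-for-bit.
* Tukey fences are Q1 − 1.5·IQR and Q3 + 1.5·IQR; whisker limits are the
  most extreme control values lying inside the fences.
* The default method is `whisker` — what a box plot visually draws —
  with `fence` available by flag; fence limits always contain the whisker
  limits, so the fence method never calls more wells.
* Boundary values classify as `within` (conservative for calling
  abnormality).  At least 4 control values are required per well; wells
  with a missing patient value are reported in a skipped-wells list, not
  an error.

Under the null (a control classified against its 49 peers) the outside
rate is the Tukey-outlier coverage of the control distribution — about
2–5% per well for the log-normal-like summaries simulated here — so
single-case calls are a screening tool, not an error-controlled test.

## Aggregation

Per-compound trends: a compound (possibly spanning several wells, e.g. a
concentration series) is *increased*/*decreased* for a group when at
least one well is called in that direction and none in the opposite;
conflicting calls yield *mixed*, which is reported but excluded from
counts and from the opposite/shared lists.  Opposite trends between two
groups are compounds with strictly opposite directions; shared trends are
compounds carrying the same direction in every group.  Cluster fractions
report k/n and a percentage for a named well set (e.g. all wells whose
compound contains "glycine"); percentages are printed to one decimal
with round-half-up, matching the convention of the reported counting
arithmetic (264/672 → 39.3, 95/672 → 14.1, 11/27 → 40.7).

## Synthetic data generator

Per-well kinetics follow a logistic colour-development curve

    od(t) = b + A / (1 + exp(−(t − m)/s)) + eps(t),  eps ~ N(0, sigma²)

with amplitude A drawn log-normally per well per sample and patient
effects expressed as shifts delta on log A.  Defaults: baseline b = 0.05
OD, median amplitude 0.5 OD with sdlog = 0.2, midpoint m = 720 min,
steepness s = 120 min, read noise sigma = 0.01 OD.  These are plausible
scales for dye-reduction assays chosen to make the power experiments
non-degenerate (on the log10 summary scale the control SD is ≈ 0.07);
they are not fitted to real OmniLog data.  Endpoint reads are derived
from the 24 h curve value plus a small simulated 750 nm background.
Cohort defaults are 50 controls (26 female, 24 male).  Each sample owns
an RNG stream derived as `SeedSequence([seed, crc32(sample_id)])`, so
adding samples never perturbs existing ones, and identical configurations
are bit-for-bit reproducible.

The emulated study conditions (`study_patients`, `study_effect_map`,
`study_sex_effects`) encode the qualitative pattern the pipeline is meant
to surface, with |delta| = 1.2 (~6 control SD on the log scale, so truly
shifted wells are essentially never missed):

* two female loss-of-function lines with a deficit on every PM-M8 well
  except G10 (TNF-alpha), on 12 glycine-containing and 11
  tyrosine-containing wells, and on five opposite-trend compounds, plus a
  surplus on five shared compounds;
* one male duplication line with surpluses on carbon-source/dipeptide
  blocks and the shared/opposite compounds, and deficits on concentrated
  ion replicates and a set of hormone wells;
* male-control heterogeneity on the affected amino-acid wells
  (`study_sex_effects`), so those deficits separate from the cohort only
  in the female-only comparison while the pooled comparison flags the
  PM-M8 block alone — the generator's device for a sex-stratified
  finding.

What passing tests on these cohorts shows is that the pipeline recovers
known effect structure under its own measurement model; it does not show
robustness to features of real plate data the generator omits (edge
effects, drift, plate-to-plate batch shifts, non-logistic kinetics,
heteroscedastic noise).

The operating-characteristics harness (`recovery_experiment`,
`fdr_experiment`) simulates log-AUC values directly from the same model,
with the trapezoidal noise propagation computed analytically — verified
against the full curve pipeline — and uses common random numbers across
effect sizes so power comparisons are paired.  Default problem sizes
(1000 wells for null/FDR checks, 400 for power curves) give Monte-Carlo
standard errors below one percentage point while keeping a full run in
seconds.

## Numerical and design choices

* Well addressing is row-major A01–H12; unpadded input ("D6") is
  accepted, output is canonical zero-padded.
* The builtin layout is synthetic (see README); `plates_present` reports
  only fully annotated (96-well) plates while partial layouts remain
  usable for fixtures.
* p-values are clipped into (0, 1]; results TSVs print floats at 6
  significant digits; percentages at one decimal, round half up.
* The minimum control count for box-whisker limits is 4 (quartiles are
  meaningless below that); zero-IQR control sets degenerate to point
  limits, classifying any distinct patient value as outside.
* Comparisons require complete data for every selected sample on every
  included well; the default comparison builder instead restricts each
  contrast to the plates where data are complete (the pattern for a
  cohort in which one group was never assayed on one plate).

## Known limitations

* Single-case calls carry no formal error control (no Crawford–Howell
  style inference); they mirror a graphical procedure.
* Per-compound direction aggregation uses the at-least-one-and-none-
  opposite rule above; with many wells per compound this is permissive.
* The Mann–Whitney asymptotic branch is inaccurate for singleton groups
  (see above) — such designs are always served by the exact branch.
* The generator's amplitude spread and noise are placeholders on
  realistic scales, not estimates from real instrument data.
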