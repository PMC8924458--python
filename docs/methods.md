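# Methods

This note documents the statistical procedures, the synthetic-data model and
the design decisions behind `intentgap`.

## Survey data model

Each participant answers 5-point Likert items coded −2..+2 (a raw 1..5 coding
is recoded by subtracting 3 on read). Items map, via a configurable layout,
to nine constructs per topic (health, sustainability): the TPB constructs
A, SN, PBC; the SDT regulations R_Ext, R_Intro, R_Id, R_Int; and the
single-item self reports I (intention) and B (behavior). The default layout
uses 3 items per multi-item construct; the exact item inventory of any given
survey can be supplied as a YAML layout, since published reports rarely
restate it.

Two sentinels are kept distinct:

* **MISSING** — no answer. Any construct touching a missing item is undefined
  for that participant; a record with any missing item is incomplete and is
  dropped by the completion filter (mirroring a survey with 176 starters and
  144 completers, where drop-out happens toward the end of the questionnaire —
  the generator's synthetic dropouts therefore answer only the first
  self-report section).
* **DONT_KNOW** — an explicit "Don't know", offered on behavior items. It
  counts as an answer for completeness but leaves B undefined, so DK
  responders are excluded *pairwise* — only from analyses involving B — not
  from the study. With 6 DK answers on the sustainability behavior item,
  analyses touching B_S use n = 138 (paired df 137, correlation df 136) while
  everything else keeps n = 144.

## Composites

* **BI = w_A·A + w_SN·SN + w_PBC·PBC** with non-negative weights, not all
  zero. Pearson correlation is invariant under positive rescaling of the
  weight vector, so only the weight *direction* is identified; weights are a
  scale class and the package reports one representative.
* **RAI = 2·R_Int + R_Id − R_Intro − 2·R_Ext**, fixed theory-given weights;
  range [−12, +12] for scores in [−2, +2].

### Weight calibration

`calibrate_weights` maximises corr(BI(w), I) over the exhaustive grid
w ∈ {0, 0.1, …, 2.0}³ \ {0}. A grid (rather than continuous optimisation) is
used so reported weights have one-decimal granularity and runs are exactly
reproducible; the correlation for every grid point is computed from the 4×4
covariance matrix of (A, SN, PBC, I), so the search is O(grid) after one pass
over the data. Ties (within 1e-9 relative tolerance, which collapses
proportional triples) break toward the smallest weight sum, then
lexicographically — the smallest representative of the winning direction.
Participants with any of A, SN, PBC, I undefined are excluded pairwise.
Calibration fails loudly when I is constant or every candidate composite is
constant.

Note that when the weights are calibrated on the same data, the BI ~ I
correlation rows of the battery are circular by construction; the report
flags this.

## Persona segmentation

Dichotomising (A, SN, PBC) as positive/negative gives 8 segments, indexed so
that attitude is the leading bit, then social-pressure awareness, then
perceived behavioral control (1 = Positive/High/High … 8 = Negative/Low/Low).
A score of exactly 0 classifies as negative/low (strict `> 0`); item-mean
Likert scores hit 0 frequently, so this choice is exposed as the
`zero_as_positive` switch and recorded in the output. Marginal tables use
pairwise inclusion (a participant undefined on one topic still counts toward
the other); the joint 8×8 table covers participants defined on both. The
low-PBC share sums personas {3, 4, 7, 8}.

## Statistical battery

All tests are two-sided with pairwise deletion.

* **Paired t**: t = mean(d) / (sd(d)/√n) on differences d, df = n − 1.
  Three effect-size variants are reported side by side — d_z = mean(d)/sd(d),
  d_pooled = (mean(x)−mean(y))/√((sd(x)²+sd(y)²)/2), and d_from_t = t/√n —
  because published paired-design "Cohen's d" values are often not
  reproducible under any single formula; the report labels each variant.
  Zero-variance differences raise by default (`zero_variance="zero"` opts
  into t = 0).
* **Pearson r** with df = n − 2; p from the exact t transform
  t = r√(n−2)/√(1−r²).
* **Wilcoxon signed-rank** on the paired raw PBC scores (not the dichotomised
  indicator). The statistic is W⁺, the sum of ranks of positive differences
  with average ranks for ties. Zero differences are discarded by default;
  the Pratt policy (rank zeros, drop them from both sums) is a switch. The
  p-value is exact — full 2ⁿ sign enumeration via convolution over the
  doubled-rank grid — for ≤ 12 retained differences, otherwise a normal
  approximation whose null moments (Σr/2, Σr²/4) are computed from the actual
  retained ranks, which makes tie and Pratt corrections automatic. The exact
  two-sided p is 2·min(lower tail, upper tail), capped at 1.
* **Benjamini–Hochberg step-up** at q = 0.05 over the whole 17-test family:
  per-rank thresholds α_i = i·q/m (reported to 3 decimals, decided unrounded),
  ranks by ascending p with ties broken by input order, rejection of all
  tests ranked ≤ max{i : p_(i) ≤ α_i}. For m = 17 the rounded thresholds are
  0.003, 0.006, …, 0.047, 0.05. The 17-test family — 6 paired t, 10 Pearson,
  1 Wilcoxon — is a reconstruction from the per-rank thresholds quoted in the
  reference survey's results, not an explicitly published list; the report
  says so.

## Synthetic cohorts

The generator exists so the full pipeline can be exercised and tested at the
reference study's scale without its deposited dataset.

**Latent model.** Participants are rows of an 18-dimensional Gaussian over
the 14 construct scores and 4 self reports. Items are emitted as
`round(clip(latent, −2, 2) + ε)` clipped to the Likert range, with iid
N(0, `item_noise_sd` = 0.4) item noise; I and B are single discretized items.
The defaults reproduce the reference cohort: 144 completers of 176 starters,
6 "Don't know" answers placed uniformly on the sustainability behavior item,
dropouts answering only the first self-report section.

**Construct-level targets.** The published summaries constrain the
self-reports directly (e.g. I_H: mean 1.38, SD 0.69) but constrain the
constructs only through the composites (BI_H: 2.33/1.45, RAI_H: 2.12/2.48,
etc.). `default_calibration` therefore derives construct-level targets by
linear-composite algebra under explicit exchangeability assumptions:

* TPB constructs of a topic share one mean (BI mean / Σw) and one SD chosen
  so that Var(BI) matches, under an exchangeable within-topic correlation
  ρ_TPB = 0.3 (a moderate positive value typical of TPB inventories).
* Regulations share one SD matched to Var(RAI) under ρ_reg = 0.2, with means
  REG_BASELINE (0.5) ± RAI mean / 6 following the sign of the RAI weight, so
  autonomous regulations sit above the controlled ones.
* Published correlations involving composites become uniform construct-level
  correlations via the same algebra. For RAI-linked pairs the correlation is
  taken proportional to the regulation weight (otherwise the ±-weighted sum
  cancels); for the cross-topic RAI link only same-regulation pairs correlate
  (motivational style is trait-like across topics).
* The two unreported cross-topic intention/behavior correlations (I_H ~ B_S,
  I_S ~ B_H) default to 0.30: a zero default contradicts the four published
  correlations in that quartet (the implied matrix is indefinite), and 0.30
  sits between the published within-topic and cross-topic links.

All remaining unspecified correlations start at 0 and the matrix is completed
to positive definite by alternating projections: eigenvalue clipping at a
1e-6 floor with re-normalised unit diagonal, re-imposing the specified
entries each pass (≤ 500 passes, then a final clip). The unspecified entries
absorb any inconsistency; if a specified entry still moves by more than 0.02
the specification is reported as contradictory with the worst deviation.

**Discretization-bias calibration.** Truncation at the scale ends shifts
means, rounding changes SDs, and both attenuate correlations. With
`calibrate_discretization` on (the default), the generator deterministically
solves, per score, for the latent (μ, σ) whose *discretized* score has the
target mean and SD — closed-form normal-bin algebra for single items,
64-node Gauss–Hermite quadrature over the latent for multi-item constructs —
and inflates each specified correlation by 1/(λ_x·λ_y), where
λ = corr(latent, observed score) is the per-variable attenuation factor
computed from the calibrated parameters (clipped at |ρ| ≤ 0.99 with a
warning). Under this calibration, 200 replicate cohorts at n = 144 recover
the target I_H mean to ≈ 0.002 and the I_H ~ B_H correlation to ≈ 0.007
(the residual reflecting the linear-attenuation approximation for coarse
5-point bins); the acceptance script recomputes both.

**What the generator does not model.** Item-level response styles
(acquiescence, straight-lining), demographic composition, non-normal latent
shapes, and any dependence of DK or drop-out on the scores. Passing tests on
synthetic cohorts therefore demonstrate the pipeline's correctness and its
behavior at the published moment structure — not robustness to real-world
response artefacts.

## Numerical choices

* Determinism: every stochastic routine takes a seed; one `default_rng`
  drives the latent draw, the item noise (in fixed layout order) and the DK
  placement, so identical (config, seed) pairs give byte-identical cohorts
  and reports. Report writers format floats explicitly (`%.10g`).
* Rounding uses `np.rint` (ties to even); ties occur with probability zero
  for continuous latents.
* The latent-parameter solve uses bounded least squares (μ ∈ [−4, 4],
  σ ∈ [0.02, 4]); a misfit above 5e-3 is logged as a warning, which flags
  targets unreachable by a discretized normal.
* Problem sizes: the acceptance script uses 200 replicate cohorts of n = 144
  (Monte-Carlo SE of the replicate-averaged mean ≈ 0.004) and grid
  enumeration at step 0.5 for the score-range checks; oracle tests enumerate
  all 2ⁿ sign assignments up to n = 12.

## Known limitations

* Construct-level moments are identified only up to the exchangeability
  assumptions above; any allocation of means/SDs consistent with the
  composite summaries would do, and real data will generally violate
  exchangeability.
* The attenuation correction is first-order; for correlations near ±1 or
  heavily saturated scales the realized correlation can deviate by a few
  hundredths.
* Calibrating BI weights on synthetic cohorts does not recover any
  particular published weight vector: the synthetic construct–intention
  correlations are exchangeable by design, so the correlation surface over
  weight directions is nearly flat. Weight-recovery behavior is instead
  tested on data generated with a known weight direction.
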