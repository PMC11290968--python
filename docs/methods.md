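# Methods

This note documents the models, parameter choices, numerical decisions
and known limitations of the package. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Consensus perturbation signature

Inputs are differential expression z-scores (genes × treated samples)
on an approximately standard-normal scale, with `cell_line` and
`timepoint` column metadata. The pipeline restricts to one timepoint
(default `"24 h"`, the modal treatment duration in large perturbation
compendia) and averages replicate columns within a cell line.

Retention rule, per gene over the n cell lines:

- `frac_up = #{z ≥ z_min} / n`, `frac_down = #{z ≤ −z_min} / n`
  (available-case counts under missing data);
- retained iff exactly one of the two fractions reaches τ;
- `consensus_z` = mean z over **all** cell lines (responders and
  non-responders), so a gene firing in a subset keeps an attenuated but
  directional value;
- `agreement` = the qualifying fraction.

Parameters: `τ = 0.30` (directional agreement across at least 30% of
lines — tolerant of cell-context-specific response while excluding
idiosyncratic hits) and `z_min = 2.0` ("changed" operationalised as
roughly a two-sided 0.05 exceedance of a standard-normal score). Both
are exposed everywhere. The "top k" restriction ranks by |consensus_z|
with lexicographic gene-id tie-break; ranking by effect magnitude is
our choice — agreement-weighted alternatives would also be defensible.

A consequence of the exclusive-or rule worth knowing: retention is not
strictly monotone in τ. A gene whose up- and down-fractions both reach
a low τ is excluded there as direction-conflicted but can be retained
at a higher τ that silences one side. The property tests assert
monotonicity up to exactly this exception.

## Disease signatures and discordance

Subgroup signatures are per-gene log₂ fold changes of the subgroup's
central expression against the whole cohort: median-based (robust
"disease signature") and mean-based ("markers") variants are separate,
explicitly named operations; the scorer accepts either. On log₂-scale
cohorts the fold change is a difference of central values; on linear
cohorts `log2((c_s + ε)/(c_all + ε))` with pseudocount `ε = 1.0`
(standard for nonnegative expression; configurable). Even-sized-group
medians are midpoints of the two central order statistics.

Discordance is Spearman's ρ (average ranks on ties) between consensus
z and subgroup log₂FC over exactly-id-matched shared genes (≥ 3
required; unmatched drug genes are reported, never imputed). The
response prediction is the bare sign test ρ < 0 — no significance
gate — because the negative correlation itself is the criterion of
interest; a permutation p-value (gene-label shuffles, default 10,000,
seeded, one-sided toward discordance, with the +1 correction) is
reported for context. The permutation null is vectorised by permuting
one rank vector and computing Pearson correlations on ranks.

## Survival stratification

Gene-set score = unweighted mean expression over the present genes of
the set (missing genes logged). Quartile assignment sorts patients
ascending by score with stable id tie-break and splits into four
contiguous rank blocks via the `numpy.array_split` convention — extra
patients go to the *lowest* quartiles, so n = 10 splits (3, 3, 2, 2);
sizes always differ by ≤ 1. The survival comparison is Q4 vs Q1 only
(Q2/Q3 excluded), using a two-group Mantel–Cox log-rank statistic
`(O_A − E_A)² / V` with hypergeometric variance summed over distinct
event times, tied deaths counted together, and p from χ²₁. Single-time
risk sets with n = 1 contribute no variance. The statistic is
implemented directly (≈ 25 lines) so its arithmetic is transparent and
testable against both a per-event-time 2×2-table oracle and the
lifelines implementation.

Patient clustering standardizes each panel gene to mean 0 / sd 1
across patients (constant genes dropped with a warning) before
agglomerative clustering, defaults euclidean distance with complete
linkage — the common heatmap-package defaults; both configurable.

## Synergy and curve fits

HSA reference: expected combination inhibition at (a, b) is
`max(single-agent A at a, single-agent B at b)`; the synergy score is
the unweighted mean of observed − expected over all combination cells,
in percentage points. Classification: score > +10 synergistic,
< −10 antagonistic, otherwise additive; the boundaries themselves are
additive. Viability surfaces are converted by `100 − v` first.

4PL fits minimise least squares of
`y = bottom + (top − bottom)/(1 + (ec50/x)^hill)` evaluated on log
dose, with EC50 optimised on the log scale (positive by construction)
and multi-start initialisation (EC50 guess at every distinct nonzero
dose × Hill ∈ {0.5, 1, 2}); the best residual sum of squares wins.
Zero-dose (vehicle) wells are included at a surrogate dose of
`min(nonzero dose)/100`, anchoring the no-effect asymptote, since the
log-dose model is undefined at 0; this introduces a relative EC50 bias
on the order of the surrogate's residual effect (≈ 1e−5 for a Hill-1
curve), negligible against assay noise. Flat responses and fits whose
asymptotes collapse are reported as `converged=False` values, never
exceptions, so batch scoring continues.

One-phase decay fits `y(t) = (y0 − plateau)·exp(−kt) + plateau` with k
optimised on the log scale; the plateau is free unless fixed (0 for
complete degradation). Half-life = ln2/k. Non-decaying data drive k
toward 0 and are flagged unconverged rather than producing a negative
half-life.

On EC50 precision: with 8 single-replicate doses, additive sd-5 noise
and all four parameters free, the Cramér–Rao bound gives
sd(log EC50) ≈ 0.22 for log-spaced designs spanning the curve, i.e. a
median relative EC50 error around 16% for any unbiased estimator. The
test suite therefore checks that the multistart fit is *near-efficient*
(within 1.5× the information bound) under noise, and exact (≤ 1e−6
relative) on noiseless data. Single-digit-percent EC50 precision at
this noise level requires replicate averaging or fixed asymptotes, not
a better optimiser.

## Synthetic data: what it emulates and what it does not

Generators are pure functions of (spec, seed).

- **Perturbation screens**: planted up/down genes receive
  z ~ N(±effect, noise_sd) in a random subset of
  `round(responder_fraction · n_lines)` lines at "24 h", noise
  elsewhere; background genes are N(0, noise_sd) throughout. Defaults
  (1000 genes, 18 lines, 50 + 50 planted, effect 4, responder fraction
  0.5, unit noise) emulate a multi-line screen with strong but
  context-dependent responses.
- **Cohorts**: baseline per-gene means N(7, 1) (log₂ microarray scale)
  plus N(0, 1) per cell; subgroups apportioned by largest remainder
  from the configured proportions (defaults WNT 10% / SHH 30% /
  G3 25% / G4 35% over 76 patients) then shuffled. Each non-discordant
  subgroup gets private markers shifted +marker_log2fc (default 2);
  the discordant subgroup's markers sit on the drug-signature genes,
  shifted against the signature's sign. Because every subgroup is
  referenced to the shared whole-cohort median, the non-discordant
  subgroups come out mildly concordant with the drug on those same
  genes — which is exactly the sign pattern the scorer must resolve.
- **Survival**: exponential times with baseline median 1825 days
  (5 years); a patient's hazard is multiplied by `HR^(q/3)` for
  0-based score-quartile q, so the planted Q4-vs-Q1 hazard ratio is HR
  exactly. Censoring is independent Bernoulli(censor_rate) with the
  censoring time drawn uniformly before the event.
- **Dependency tables**: essential genes N(−1.5, 0.3) per line, others
  N(0, 0.3) — the negative-means-required convention.
- **Combination surfaces**: exact 4PL single-agent margins; combination
  cells = max(margins) + planted excess + N(0, noise_sd), clipped to
  [0, 110]. Default grids ([0, 2.5, 5, 10, 20, 40] around EC50 = 10)
  keep single-agent inhibition in 20–80%, so planted excesses in
  [−15, +25] never touch the clip and are recovered exactly at zero
  noise.

Not emulated: probe/batch effects, expression–survival confounding
beyond the planted gene set, inter-gene correlation, dropout,
copy-number structure, non-exponential hazards, and plate/edge effects
in assays. Passing tests therefore demonstrate that the analysis
recovers planted structure under idealised noise — a necessary check of
correctness, not evidence about any specific real data set.

## Problem sizes and determinism

The test suite and acceptance script use desk-scale sizes chosen as the
smallest that make the statistical assertions stable: 20 seeds ×
(1000 × 18) for signature recovery, 100 cohorts of 76 for sign
recovery, 20/1000 cohorts of 200 for log-rank power/calibration, 500
random instances per oracle-equivalence check, 50 noisy fits per curve
model. Every stochastic path takes a seed; the pipeline forks one
master seed per stage by CRC32 of the stage name, so stage order never
perturbs another stage's stream, and a rerun with the same config is
bit-identical for all deterministic outputs.
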