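# Methods

## Problem setting

Circulating tumor DNA (ctDNA) in plasma must be detected at allele fractions
of 1e-3–1e-2 against a sequencing error background of similar magnitude.
Two measurement arms are modelled: ultra-deep targeted amplicon sequencing
(~10,000× over a small panel) with a position-specific error null, and
droplet digital PCR (dPCR) with a per-assay limit of blank. Their outputs
are merged into per-patient longitudinal timelines (baseline T0, first
evaluation E1 at 6 ± 2 weeks, time of progression ToP).

## Background error model

Errors in amplicon sequencing are strongly position- and alteration-specific
(sequence context, homopolymers, amplification artifacts), so the calling
null is calibrated per (position, alteration) pair from mutation-free
control samples.

For control *i* with depth `d_i` and count `c_i` at a pair, the smoothed
error fraction is `r_i = (c_i + c0)/(d_i + 4·c0)`. The pseudocount
`c0 = 0.5` (a Jeffreys-style half count, spread over the four possible
outcomes in the denominator) keeps the variance estimate positive at
positions where every control is error-free; its cost is a small upward bias
of ≈ c0/d ≈ 5e-5 at 10,000×, which is conservative (it can only make calling
harder). Controls shallower than `min_depth = 1000` carry too little
information and are excluded per position.

**Germline handling.** A control with `r_i > germline_cut = 0.05` at a pair
is almost certainly carrying a private germline variant, not sequencing
error; it is dropped from that pair's estimate. If more than half the
eligible controls look germline at a position, the position is masked
entirely (a common SNP site cannot provide a somatic null). Masked positions
are reported as such and never called.

The background of a pair never observed with errors in any control falls
back to the position's zero-count statistics (rates `c0/(d_i + 4·c0)` over
control depths), so the model covers the whole panel × alteration space.
Control-rate vectors are sorted before averaging so calibration is exactly
invariant to control order.

## Thresholds and the calling decision

The per-pair threshold is `τ = max(μ + k·σ, floor)` with `k = 3` and
kind-specific floors: 0.003 for substitutions and indels of ≤ 2 bp, 0.001
for indels of > 2 bp. The floors are the assay's validated detection limits;
`k`, and optionally a relaxed `hotspot_k` at recurrent driver positions, are
configuration.

A deliberate design point: the two components of τ enter the decision
differently.

* The noise bound `μ + k·σ` is compared against the *point* allele fraction —
  the sample must visibly exceed its own position's background.
* The floor is a claim about the *true* allele fraction, measured with
  binomial sampling noise (an AF of 0.003 at 10,000× is 30 ± 5.5 reads).
  Requiring the point estimate to exceed the floor would detect a variant
  truly present at the floor only ~50% of the time, contradicting the floor's
  meaning as a reliable detection limit. The caller therefore requires the
  one-sided 95% Clopper–Pearson upper bound of the measured AF to exceed τ.
  Analytically this places the effective count threshold at 10,000× near 22
  reads for SNVs (floor 0.003) and 6 reads for long indels (floor 0.001),
  giving ≥ 90% detection at the floor and < 90% one titration step below —
  exactly the intended operating point. Consequence: a passing call may have
  a point AF slightly below the floor (e.g. 0.0024); its upper bound does not.

The remaining conditions are `alt_reads ≥ 5` (single-molecule artifact
guard) and a binomial tail test `P[X ≥ alt | Bin(d, μ)]` Bonferroni-corrected
over the number of tested hypotheses M. In whole-panel screening M counts,
per testable position, the three non-reference substitutions plus any indel
hypotheses known to the model or supported by reads; in marker-tracking mode
M is the number of the patient's markers (typically 1–3), which is what makes
follow-up far more sensitive than discovery. Bonferroni was chosen over FDR
because the clinically relevant guarantee is per-sample family-wise: a
patient should not be declared ctDNA-positive by multiplicity.

Deletions are counted at every deleted reference base in the pileup (making
per-position depth and error rates well defined) but *called* once per event,
anchored at the first base of a contiguous run of the same `del:<len>` key.
Insertions are anchored to the base preceding the event. Short indels
(≤ 2 bp) are refused by default — they are outside the assay's validated
scope on this chemistry (homopolymer artifacts dominate) — with a
configuration override.

Numerical choices: `σ_min = 1e-6` floors the denominator of the reported
z-score; zero-depth positions are flagged uncallable; ties at the limit of
blank or at τ resolve to "not detected" (strict inequalities throughout).

## Digital PCR

Per-assay limits of blank follow the standard clinical-chemistry convention:
blank mutant counts normalized per 1e6 droplets, LOB = mean + 1.645·SD
(sample SD), switching to the nonparametric 95th percentile at ≥ 20 blanks.
Positivity requires strictly exceeding the LOB. Mutant fractions use Poisson
occupancy correction, `λ = −ln(1 − f)` per channel and
`MAF = λ_mut/(λ_mut + λ_wt)`; a saturated channel (all droplets positive)
raises an explicit error advising dilution. Double-positive droplets are
assumed merged into the mutant count upstream. A `raw_ratio` option
reproduces uncorrected droplet-ratio workflows.

## Absolute quantification

Total cfDNA copies in the reaction are `λ_total × N_droplets` from
mutant + wild-type droplets jointly (a `wt_only` flag gives the literal
wild-type-only reading; the difference is O(MAF)). Copies scale from the
loaded aliquot to the full extract (default 50 µL) and normalize to 1 mL
plasma (default draw 2 mL). Mass conversion uses 3.3 pg per haploid genome,
the value forced by the benchmark 7.8 ng ↔ 2,363 genome equivalents
(7.8/0.0033 = 2363.6, floored — hence floor rounding, with a 1e-9 epsilon to
keep exact multiples of 3.3 pg from flooring one unit low). The theoretical
LOD of an input of G genome equivalents is `min_molecules/G` (default 3
molecules), capped at 1; at the median clinical input this is 3/2363 ≈
0.0013, which is why sub-0.001 sensitivity is not reachable for every sample.
Concentration categories use the fixed tertile cut-offs 0.027 and 0.50
ng/mL; `tertile_cutoffs` re-estimates empirical tertiles for new cohorts.

## Longitudinal layer

A time point is positive if *either* modality detects a mutation; a patient
with neither modality measured is non-contributive and excluded from rate
denominators. T0→E1 trajectories: increase/decrease for E1-positive patients
(ties conservatively count as increase), normalized for T0-positive patients
turning negative, negative otherwise. Turnover at ToP compares ToP plasma
mutations against the marker set (tumor ∪ T0 plasma): acquired / lost /
persistent are disjoint by construction. Detection rates carry Wilson-score
95% CIs and percentages are rounded half-up to one decimal. Time to ctDNA
progression is configurable because no single operational definition is
standard: the default event is the first positive sample at/after E1 with
concentration above the running nadir; alternatives are first reappearance
after a negative sample, or first increase over the preceding sample.

## Synthetic data

The generators define the study conditions the tests run under: 1,000 panel
positions, depth ~ Poisson(10,000) (optional negative-binomial
overdispersion), per-position substitution error rates log-uniform in
[1e-5, 1e-3] (calibration-validation studies use [1e-5, 3e-4]) and indel
rates log-uniform in [1e-6, 1e-4] — plausible ranges for recalibrated
amplicon data; one error-prone substitution and one 3-bp-deletion channel
per position, i.i.d. binomial counts given the rate. Droplet runs disperse
Poisson-distributed molecules over droplets; blanks add rare false-positive
droplets (default 2 per 1e6). Cohorts plant a 71.4% detected baseline
positivity, baseline concentrations lognormal with median 0.12 ng/mL and
log-SD 3.4 (back-fitted from the tertile cut-offs, truncated above the
detection limit so the planted positivity is the detected one), exponential
clearance under response and regrowth at resistance with progression times
lognormal around a 139-day median, and acquired mutations injected at ToP in
a configurable fraction of patients.

What the simulations do **not** model: sequence-context error structure
(homopolymer runs, strand bias, batch effects between control runs),
fragment-size biology, library-preparation stochasticity beyond binomial
sampling, and inter-assay dPCR variation. Passing tests therefore establish
the statistical machinery — calibration, thresholds, multiplicity,
quantification algebra — not performance on any particular instrument's
error profile; real panels need their own control runs.

## Validation studies and problem sizes

`bper.validation` packages the analytical-validation experiments: spike-in
LOD titrations (20 calibration controls, 200 replicates per candidate AF,
marker mode, 1,000 positions), whole-panel specificity on 50 background-only
samples, and dPCR MAF/concentration recovery (50 replicates at 1e6
droplets). These sizes give binomial standard errors of ~2% on detection
fractions and sub-percent errors on recovery means, and run in seconds —
they are the same routines the acceptance script executes.

## Known limitations

* The error model is per-position Gaussian on control rates; with few
  controls the SD is noisy and k·σ is only an approximate quantile bound
  (the kind-specific floors dominate at clean positions, which limits the
  damage).
* Bonferroni M in screening mode depends mildly on the sample itself (indel
  hypotheses with supporting reads enter M), a data-dependent multiplicity
  that is conservative in the regimes tested.
* Phasing of co-occurring mutations (cis/trans) requires read-level
  haplotyping and is out of scope, as are fusions, copy-number changes and
  base-quality recalibration (assumed done upstream).
* NGS-sourced quantification borrows dPCR-measured total copies; without a
  dPCR run the input mass / 3.3 pg proxy is used.
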