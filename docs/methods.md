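# Methods

This note documents the models and procedures implemented in
`carrierscreen`, the assumptions behind them, the parameters that matter,
and what the synthetic-data generators do and do not emulate.

## The screening problem

A drug that must be carried across the plasma membrane by a specific
transporter loses much of its toxicity in a strain deleted for that
transporter's gene. `carrierscreen` implements the desk-side computations of
a chemical-genomics screen built on this logic in *S. cerevisiae*, with
three complementary platforms:

1. **Pool competitions** — all deletants co-grown in one fermenter with and
   without the drug; strain proportions read out via molecular barcodes
   hybridised to an array (arbitrary fluorescence units, AFU). Resistant
   deletants enrich in the treated arm.
2. **Robot colony arrays** — 111 plasma-membrane transporter deletants
   spotted in quadruplicate onto 768-spot agar plates with and without the
   drug; colony sizes are quantified from plate photographs.
3. **Liquid-culture validation** — growth curves in a plate reader (OD600
   every 10 minutes), dose–response profiles, IC90 estimation, and
   protection assays in which a carrier's native substrate competes with
   the drug for uptake.

## Plate layouts

The master plate is 16 × 24 (384 wells): every border well carries the
wild-type (WT) control (an *HO*-locus deletion with no growth phenotype) to
buffer edge effects, each transporter strain occupies two adjacent interior
wells, and leftover interior wells are filled with extra WT copies. The
interior holds 308 wells, so the layout accommodates at most 154 strains.

The robot spots the master twice onto one agar plate, giving a 24 × 32
(768-spot) test plate with each mutant in quadruplicate. The geometric
arrangement of the two passes is a package convention (no physical record
of the robot's path exists): master well (r, c) maps to test positions
(row = c, col = 2r) and (row = c, col = 2r + 1), i.e. the two passes form
two column-interleaved images of the master inside the test grid. This
choice preserves the two properties that matter — each mutant in exactly
four spots, and a complete WT border on the test plate.

## Colony quantification

The quantification algorithm operates on the photograph directly:

* the **blue channel** of the RGB image carries the signal;
* a **window size** is computed from the four manually identified grid
  corners as max(grid width / n_cols, grid length / n_rows), unrounded;
* the grid is partitioned into equal **diamond-shaped windows** (L1 balls
  with diagonals equal to the window size) centred on the bilinear lattice
  between the corners, one window framing each colony;
* the colony size is the count of window pixels with intensity strictly
  greater than **1.25 × the window minimum**.

Numerical choices: pixel membership is tested at pixel centres
(x + 0.5, y + 0.5) in 0-based image coordinates with a 1e-9 tolerance on
the L1 boundary, so integer translations of image and corners leave every
count unchanged. Strict inequality at the threshold makes a uniform window
score zero even when its minimum is zero. The window minimum (not a
plate-wide background) defines the threshold, which makes counts invariant
to uniform rescaling of a window's illumination. Windows that extend past
the image are clipped with a warning; a fully clipped window is a missing
measurement, not an error. JPEG input is accepted as-is; tests use lossless
PNG so oracle comparisons are exact.

## Hit calling

Border spots (the WT buffer) are excluded from all statistics: edge
colonies grow larger for lack of competition. Per strain, the median of the
four replicate spots is taken on each plate (robust to a single suppressor
colony), the drug-plate median is divided by the control-plate median, and
the ratio is multiplied by 100. Scores are z-scored against the mean and
sample SD (n − 1) of all scored strains on the plate; a strain is called
resistant when z > 3 (2.5 or 2 as documented fallbacks when extreme
outliers inflate the SD) and sensitive when z < −2.5, both strict.

Two conventions were genuinely open and are package decisions: the plate
average includes interior WT replicates (they are flagged so reports can
drop them without changing the statistics), and no multiple-testing
correction is applied — the report instead records how many strains would
be called at each threshold of the menu.

## Pool enrichment

Conditions are first put on a common scale by total-sum scaling (each
condition rescaled so its total AFU equals the across-condition mean
total); the external array-normalization protocol used on the physical
arrays is out of scope, and the substitution is declared in output
metadata. A strain is called **enriched** when both criteria hold:

* treated − untreated AFU exceeds the noise band (default ±1000 AFU, the
  half-width containing 98% of deletants when comparing untreated
  replicate pools; `estimate_noise_band` computes it from replicates as an
  exact order statistic when they are available);
* treated / untreated ratio ≥ 3 (2 as the relaxed setting).

The conjunction is a package decision: the band is a noise estimate, the
ratio an effect-size threshold, and a hit should clear both. A strain with
zero untreated AFU has an undefined ratio — it is not imputed; the band
criterion alone governs and the row is flagged. Ranking is by treated AFU
descending with lexicographic tie-break.

## Growth curves, IC90, protection

**mu_max.** The maximum specific growth rate is the steepest least-squares
slope of ln(OD) over a sliding window of 5 consecutive 10-minute readings
(50 min), in h⁻¹, with the best window and its R² reported. The blank is
subtracted first — by default the curve's first reading, matching the
generator's convention that the instrument's startup read is media-only;
an explicit numeric blank can be supplied instead. Blank-subtracted values
at or below the detection floor (1e-4 OD) are below detection and excluded
from window fitting; a curve with no usable window is a no-growth curve
(mu_max = 0). On noiseless exponentials the estimator is exact to machine
precision; on logistic curves it underestimates the instantaneous maximum
by under 5% at 10-minute sampling (the window straddles the onset of
saturation).

**Dose–response and IC90.** Per-concentration means and standard errors
over replicates (n = 3 in the validation runs) feed a Hill fit

    mu(c) = mu0 / (1 + (c / IC50)^h)

with mu0 pinned to the zero-concentration arm (not fitted) to stabilise
small panels. The IC at level L is the closed-form inversion
c = IC50 · (L/(1−L))^(1/h); IC90 = IC50 · 9^(1/h). The requested level must
be bracketed by the measured responses and the returned concentration must
lie inside the measured range — extrapolation raises an error rather than
returning a number. If the fit fails to converge the estimator falls back
to monotone interpolation of mu against log concentration and says so.

**Protection.** A native substrate sharing the carrier's binding site
competes with the drug for uptake; under classical single-site competitive
inhibition the effective drug concentration is
c_eff = c_drug / (1 + c_comp / Ks). Protection is quantified as the
recovery fraction mu(drug + competitor) / mu(untreated), which rises
monotonically to 1 as the competitor saturates the carrier. Final OD
(blank-subtracted last reading) is reported alongside, because biomass
yield can reveal protection that the growth rate misses.

## Synthetic-data generators

The generators define the study conditions under which the pipeline is
tested; all are driven by one `SimParams` record and a single seed, and
identical parameters give bit-identical outputs.

**Plate images.** Colonies are filled discs centred in their diamond
windows on a uniform agar background (blue channel 40 vs foreground 200 of
255), radius = 0.45 × window half-diagonal × growth score, where the score
is the strain's fitness, times (1 − inhibition) on drug plates. Border
spots are inflated ×1.3 (edge effect; the magnitude is a package choice —
only the direction is documented behaviour). Suppressor colonies — the
false-positive mode of agar screens — are planted as full-size discs on
Poisson(1)-many susceptible spots per treated plate. Pixel noise is
multiplicative Gaussian (sd 0.05), appropriate for a positive-valued
intensity readout. The renderer returns every disc's exact pixel count so
the quantifier can be tested against planted truth.

**Pool competitions.** Strains start at equal proportions and grow
exponentially at mu_wt × fitness (× (1 − inhibition) in the treated arm;
mu_wt = 0.35 h⁻¹, a typical yeast minimal-medium rate). Both arms are
integrated until total abundance reaches 100 × the inoculum, emulating
sampling at the exit from exponential phase; the stop time solves
Σ exp(mu_i t)/N = 100 by root finding, and proportions follow the closed
form. AFU = 1e5 × proportion × log-normal noise (sd 0.15 on the log
scale). With 112 strains this puts a typical untreated strain near 900 AFU,
so the ±1000 AFU default band sits several noise SDs from parity —
consistent with a band drawn to contain 98% of deletants.

**Growth curves.** Three phases: a media-blank startup read at t = 0
(blank OD 0.05), a 2 h lag at the inoculum OD (0.01), then logistic growth
to carrying OD 0.9 at the Hill-inhibited rate, sampled every 10 minutes for
24 h. Defaults IC50 = 10 μM and h = 2 give an IC90 of 30 μM. The
competitive-inhibition constant defaults to Ks = 2 μM: with h = 2 this is
the unique value for which 10 μM of competitor recovers 80% of the control
growth rate when the drug is at its IC90 — the protection behaviour the
screen's validation experiments document — so the default reproduces that
operating point by construction.

**What the generators do not emulate.** Illumination gradients, colony
morphology and overlap, plate-to-plate batch effects, array saturation and
probe-level noise, fermenter pH/CO₂ dynamics, solvent (DMSO) effects beyond
a scalar penalty, and strain-specific lag or yield differences. Passing
planted-truth tests therefore demonstrates that the *computations* are
correct and robust to the modelled noise modes, not that the pipeline would
be free of the systematic artefacts of real images and arrays.

## Aggregation

Per-drug records combine pool hits, robot hits (each with the SD threshold
at which it was called), indirect-effect genes, verification status,
protection outcome and the rule-of-five flag. *Direct* vs *indirect* is an
annotation-driven label: deciding that a gene acts on the drug's target
rather than its import (e.g. iron importers phenocopying resistance to a
P450-inhibiting drug) is expert curation, and the package refuses to infer
it. A drug "has an identified carrier" when the union of pool and robot
hits is non-empty — hits qualified at 2 or 2.5 SD count, indirect hits do
not. Category assignment: `none` (no hits at all), `indirect_only`,
`single_carrier` (exactly one distinct direct gene), `multiple` (two or
more). The packaged 26-drug fixture is checksum-guarded and round-trips
through serialization identically.

## Problem sizes and determinism

The replicate-recovery properties are evaluated over 200 seeded screen
replicates (a full rendered plate pair per replicate for the robot arm;
full pool simulations plus an untreated-vs-untreated null for the pool
arm), chosen to estimate a ≥95% recovery rate and a ≤1 false-positive mean
with comfortable margins. Every stochastic component consumes an explicit
seed; pipelines re-run on the same config are byte-identical, and all
outputs carry a metadata header with the tool version, seed, thresholds
and config hash.

## Known limitations

* The quantifier assumes an approximately axis-aligned grid between the
  supplied corners; severe perspective distortion is not corrected.
* The Hill fit pins mu0 to the zero-concentration arm; a biased untreated
  estimate propagates into the IC estimate.
* The pool model has no carrying-capacity interaction between strains
  beyond the shared stop time, and no barcode cross-hybridisation.
* Thresholds (3/2.5/2 SD, band 1000 AFU, ratios 3/2) are screen
  conventions, not calibrated error rates; the reports record call counts
  at every menu threshold for transparency.
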