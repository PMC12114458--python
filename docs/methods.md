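# Methods

## The assay being modelled

A label-free FCM efficacy test exposes ~10⁶ CFU/mL of bacteria to a two-fold
dilution ladder of a disinfectant for the label contact time, neutralizes,
subcultures ~1:10 into broth for a ~4 h outgrowth, and acquires each sample
volumetrically (35 µL/min, ≥25 µL, so one acquisition covers ~43 s). Intact
bacteria (0.5–1 µm) form a compact scatter cluster well above electronic
noise and debris; at bactericidal concentrations both the scatter signature
and the count rate collapse. The analysis chain is: gate bacteria-like
events, convert to counts/s, normalize against the assay's own controls,
classify each concentration against a cut-off, and call the MBC.

## Gating

Order is fixed — threshold → doublet exclusion → bacteria gate — and each
step only removes events.

- **Threshold.** Keep events with FSC-H ≥ 1000 (the instrument-style
  threshold set from control data). The comparison is inclusive: hardware
  thresholds conventionally admit the threshold value itself.
- **Doublet exclusion.** Coincident particles inflate pulse area relative to
  height. The criterion is operationalized as a robust outlier test on the
  per-event area/height ratio (default SSC-A/SSC-H): exclude events with
  ratio > median + k·1.4826·MAD, k = 3. A degenerate MAD of 0 excludes
  nothing. Zero-height events cannot be ratioed and are dropped as noise,
  counted separately. Which area/height pairing to use is configurable
  (`doublet_channels`) since both FSC and SSC pairings appear in practice.
- **Bacteria gate.** SYTO9⁺ events of the stained growth control (green
  fluorescence above the 99.5th percentile of an unstained control, or an
  absolute fallback cut when no unstained control exists) are back-gated
  onto floored-log₁₀(FSC-H, SSC-H). The gate is the convex hull of the
  smallest set of 64×64 histogram bins containing 98% (`density_mass`) of
  those events — a hull rather than a fitted ellipse because manual gates
  are irregular polygons; a log₁₀-with-floor transform rather than
  logicle/biexponential because the assay's plots are plain log scale and
  logicle would introduce parameters with no data to set them. Boundary
  points count as inside. Fewer than 100 SYTO9⁺ events is an error (the
  density estimate would be meaningless).

## Normalization and MBC calling

Rates are `n_gated / duration_s` with the duration derived from volume and
flow rate when not recorded. Normalization maps the negative control to 0
and the growth control to 1 exactly; values are clamped below at 0 (sub-NC
rates are noise) but not above 1 (super-PC rates are real growth variation).
The bactericidal cut-off (default 0.1) applies to the **normalized** scale:
counts are normalized before analysis and a raw events/s cut-off would not
transfer across instruments or samples. A raw-scale reading remains
available by skipping normalization and passing raw rates to the classifier.

Classification is strict: normalized < 0.1 ⇒ "above_or_MBC". The strict MBC
policy scans from the top of the ladder and calls the MBC at the bottom of
the contiguous killed run; an isolated killed well lower down does not move
the call (the conservative reading of "lowest concentration causing" the
collapse; a `lowest_passing` policy is available). A surviving top
concentration censors the call above the range. A fully killed ladder is
called at the lowest tested concentration with a `below_range` annotation
rather than reported as "≤ c_min", so downstream log₂ comparisons stay
well-defined; censoring flags propagate into the agreement denominators.

Log reductions use `LR = log₁₀(n₀ / max(n_d, limit))` with a censoring flag
when the surviving count is below the detection limit; LR ≥ 5 is the
bactericidal criterion.

## Agreement statistics

Categorical agreement is exact label concordance; essential agreement is
|log₂(MBC_fcm/MBC_std)| ≤ k (+1e-9 for float safety), k = 1 by default, with
censored pairs excluded from the denominator and counted separately — which
is why both the n-of-69 and n-of-70 denominators are computable. Percentages
are rounded half-up to one decimal for parity with printed tables. ROC
analysis scores each sample by its normalized count with inverted
orientation (predicted bactericidal when score ≤ t); the curve sweeps all
distinct scores with ties grouped, AUC is the trapezoid area (equal to the
normalized Mann–Whitney U, which the tests verify exhaustively at small n),
and the operating threshold maximizes Youden's J with ties broken toward
higher specificity — the selection functional is a package choice since the
cut-off was originally set empirically. Welch's t (Satterthwaite df) and
tie-corrected Kruskal–Wallis come from scipy; growth detection uses the
one-sided Welch test (direction known a priori) at α = 0.05.

## VBNC quadrant analysis

Quadrant cuts are the per-channel 99.5th-percentile of the unstained
control's log₁₀ intensities; boundary events are positive. At most 5000
events are analyzed, subsampled uniformly with a fixed seed. PI is read on
FL3 (>670 nm) and SYTO9 on FL1 (533/30), with the channel mapping
configurable. Spillover between FL1/FL3 is modelled as a 2×2 mixing matrix;
compensation multiplies by its inverse and floors negatives at 0. The
estimator takes each off-diagonal as the median background-subtracted
secondary/primary ratio among stain-positive events of the single-stain
control (≥100 positives required — an unstained sample trivially puts ~0.5%
of its own events above the quantile cut and must not pass as a control).
The double-positive quadrant is reported as "membrane-compromised /
VBNC-candidate": the dye phenotype alone, with no resuscitation claim.

## Synthetic cytometer

The generator emulates the assay, not the instrument:

- **Populations.** Intact cells: per-channel log-normal, log₁₀ FSC-H mean
  4.3 (sd 0.15), SSC-H 4.0 (sd 0.15), FSC/SSC correlation 0.6; SYTO9-bright
  (log₁₀ 4.0) when a stained role requires it. Damaged cells: FSC shifted
  −0.3 log₁₀, SSC sd ×1.5 — a qualitative realization of "altered scatter";
  the exact shift is a config placeholder, not a claim about real data.
  Debris: exponential in linear intensity, concentrated below the bacteria
  cluster. Pulse area tracks height with 5% log-normal jitter; doublets
  replace random singlet pairs with their mean scaled by separate area (×2.0)
  and height (×1.3) gains.
- **Dose response.** Survival follows a Hill curve
  `s(c) = floor + (1−floor)/(1+(c/c50)^hill)` — two interpretable parameters
  and a closed-form oracle. Killed cells split into retained damaged
  particles and lysed material (emitted as debris) via a second Hill curve
  with the same c50 and steepness: membrane-disrupting agents progressively
  lyse cells at supra-MBC doses. This is what makes a far-supra-MBC exposure
  collapse the gated count to its survivors and clear the 5-log criterion,
  while near-MBC doses still leave damaged particles in the scene.
- **Scaling.** `n0_events` (default 500) is the expected bacteria-like event
  count at the reference 25 µL volume before outgrowth; `growth_factor`
  (default 30, ~5 doublings in 4 h) multiplies it for grown samples; totals
  scale linearly with sampled volume. The no-bacteria control emits debris
  at `nc_event_rate` (default 2/s). Counts are Poisson around their
  expectations.
- **Reproducibility.** One integer seed; per-sample sub-streams derived by
  CRC-32 hashing of (role, concentration index) into a `SeedSequence` spawn
  key, so each sample is independently reproducible. Arrival times are
  uniform over the acquisition, so emitted order is an exchangeable shuffle.
- **Dual stain.** Class-conditional (FL1, FL3) log-normals: live bright
  green/background red, dead bright red/background green (PI displaces
  SYTO9), injured bright in both; the configured spillover matrix
  (default off-diagonals 0.05/0.10) mixes the pair. A heat-killed control is
  fractions (0, 1−debris, 0, debris).

**What passing tests do and do not show.** The generator reproduces the
separability, dose dependence, doublet geometry and control structure of the
assay, so recovery tests validate the pipeline's logic end to end. It does
not model fluidics artifacts, laser drift, strain-to-strain scatter
variation, partial-injury continua, or dye–disinfectant chemical
interactions — agreement on synthetic data therefore does not by itself
establish performance on instrument data.

## Problem sizes and numerical choices

- Parameter-recovery study: 200 seeded assays at n0 = 300 events,
  growth factor 12, Hill 4, c50 = 2.0 on the default six-step ladder — sizes
  chosen to make the study a routine desk run while keeping ≥3500 gated
  control events per assay.
- Fully-bactericidal log-reduction study: n0 = 100 000 events, growth factor
  10 (~10⁶ gated control events ≈ 10⁶ CFU/mL-equivalent), dose 32× c50 with
  Hill 4 (surviving fraction ≈ 9.5×10⁻⁷), detection limit 1.
- Two-fold ladder validation tolerates 1e-9 relative error; essential
  agreement adds 1e-9 to the log₂ window; quadrant fractions sum to 1 by
  construction; MAD = 0 and single-class ROC inputs are explicit degenerate
  cases (exclude nothing / error).

## Known limitations

- The FCS writer emits the single-data-segment float list-mode subset only;
  log-amplified ($PnE) and multi-dataset files are out of scope, and
  $SPILLOVER keywords are not parsed (compensation is explicit).
- MICs are inputs from the standard test, never computed.
- No AUC confidence intervals (DeLong/bootstrap) and no absolute CFU/mL
  calibration of event counts.
- The damaged-population scatter shift and the lysis-curve coupling are
  plausible defaults exposed in config, not fitted to instrument data.
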