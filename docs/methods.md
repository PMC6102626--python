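# Methods

This note records the models, defaults and numerical choices behind
`botanicad`, in the spirit of a methods appendix: what is assumed, what is
tunable, and what the synthetic benchmark does and does not demonstrate.

## Universal CAD quantitation

The charged aerosol detector is modeled as mass-proportional: every
non-volatile constituent contributes peak area `area = mass x RF` with one
response factor RF shared across chemical classes. RF is fitted by
through-origin least squares pooled over all calibration points
(`slope = sum(area x mass) / sum(mass^2)`), because aerosol signal is zero
at zero mass and the standards span more than two decades; an intercept
would be dominated by the lowest level. The reported r² is the uncentered
coefficient of determination of the through-origin fit. The universality
assumption is checked, as in practice, by calibrating the washed polymer
retentate of an MWCO filtration as a pseudo-standard and verifying its slope
against the monomer/oligomer standards (the test suite requires agreement
within 5 %).

Per-dose amounts scale the injected mass fraction to the daily dose:
`amount = (area / RF) / load x dose_mg x 1000` with
`load = conc x injection volume`. Defaults: 10 mg/mL sample, 10 uL
injection (100 ug load), 210 mg/day dose.

## TTC logic

The threshold of toxicological concern defaults to 90 ug/person/day
(Cramer Class III). Flagging compares unrounded ug/dose values, inclusive
at exactly the TTC. The derived reporting threshold
(`percent = ttc / (dose x 1000) x 100`) is floored to one significant
figure — 0.0428... % reports as 0.04 % / 400 ppm — so the printed cut-off
is always at least as strict as the exact ratio. The rounded figure is
never used for flagging.

## Chromatogram processing

* **Baseline.** Morphological opening (rolling minimum then rolling
  maximum) of a lightly pre-smoothed signal. Pre-smoothing (window/8,
  capped at 0.5 min) suppresses the downward bias a rolling minimum takes
  from noise troughs. The window must exceed the broadest genuine feature:
  the pipeline default is 40 min because the tannin hump itself is ~30 min
  wide and must *not* be treated as baseline.
* **Peak detection.** `scipy.signal.find_peaks` on the baseline-corrected
  signal; default thresholds are 10x a robust noise estimate (1.4826 x MAD
  of the pre-elution segment). Integration windows are apex ± 1.3 x FWHM
  (~±3 sigma for a Gaussian, 99.7 % of its area); windows of barely
  resolved neighbours are split at the inter-apex valley, the
  valley-to-valley convention of chromatography software. Peak areas are
  trapezoidal integrals above a local level interpolated from the smoothed
  between-peak samples, which cancels any residual global-baseline error.
* **Hump splitting.** Inside the hump window (default 15–45 min) narrow
  peaks are found on the residual above a short (0.4 min) opening, masked,
  and the hump level under each peak is re-estimated by a local polynomial
  through the flanking hump samples (quadratic when both flanks are well
  populated, linear otherwise — one-sided quadratic extrapolation has
  ruinous noise leverage). The hump area is defined as window total minus
  narrow total, so narrow + hump equals the window integral identically.
* **Integration.** Trapezoid quadrature with interpolated window endpoints,
  which makes `integrate(a,b) + integrate(b,c) = integrate(a,c)` exact for
  the fixed-zero baseline mode. Irregular time axes are linearly resampled
  to the median spacing first.
* **Dual gain.** Two CAD acquisitions (high/low gain) can be merged by
  substituting rescaled low-gain signal wherever the high-gain channel
  saturates; the rescaling factor is fitted on the unsaturated overlap.

## MS feature alignment and formula assignment

Contributor selection follows the extracted-ion-chromatogram logic: per
polarity, features around the CAD peak window (padded by 0.25 min so a
slightly delayed co-eluter is evaluated rather than silently dropped) are
referenced to the most intense in-window feature; those at >= 20 % of that
base intensity are tested for apex alignment and accepted only if
`|feature RT − CAD apex RT| <= rt_tol` (default 0.10 min, configurable and
recorded in output metadata — the underlying observation is qualitative, a
"slightly delayed" ion not aligning).

Formula search enumerates all element counts within bounds (default C<=40,
H<=60, N<=3, O<=20), solving the hydrogen count analytically from the mass
window so cost scales only with the non-hydrogen box. Candidates are kept if
|ppm error| <= 5 (default) and RDBE = C − H/2 + N/2 + 1 lies in [−0.5, 40],
and are ranked by |ppm|, ties to fewer atoms. Ion m/z values include the
electron mass (0.000549 Da); omitting it shifts fourth-decimal values (e.g.
the [M+H]+ of catechol is 111.0441, not 111.0446). Inorganic salt clusters
are represented as named records only; they are outside the CHNO search
space.

The adulterant screen treats the A-type (575.1189) and B-type (577.1345)
proanthocyanidin-dimer marker m/z values as configured literals taken from
common reference usage. Recomputing the B-type value from current constants
gives 577.1351 (~1 ppm away); the default 5 ppm screen tolerance absorbs
this, and the documented discrepancy is why the formula-search example for
this ion uses a 10 ppm tolerance.

## GC volatile fraction

Retention indexing uses the van den Dool–Kratz linear form appropriate for
temperature-programmed runs; ladders with carbon-number gaps (C7→C9)
interpolate across the gap, and retention times outside the ladder span
raise rather than extrapolate. FID quantitation pools a through-origin
response factor over the n-alkane standards exactly as the CAD calibration
does, and volatile TTC flagging reuses the same comparator. FID–MS peak
matching is greedy nearest-RI, one-to-one, within a tolerance (default 10
index units).

## MWCO tannin sizing

Loss at cutoff c is `100 x (1 − filtered/full)` integrated over the
analysis window (default 10–50 min, deliberately including the narrow
oligomer peaks — the measured quantity is overall signal loss, not
hump-only loss). Successive differences of the loss series give
mass-fraction bins `(<c1, c1–c2, …, >c_max)`; a running minimum is applied
before differencing so noise-induced non-monotonicity yields clipped,
non-negative bins (with a warning flag) that still sum to exactly 100. The
qualitative PVPP check is modeled as class-selective removal of all
polyphenolic signal.

## Safety rule engine

Ordered rules per constituent: (1) known structure, found in food, and
supplement exposure <= user-supplied dietary exposure → diet-comparable;
(2) published safety data with an adequate margin of safety → MoS-supported;
(3) amount < TTC → TTC-cleared; (4) otherwise follow-up. Dietary
comparability is implemented as a hard `<=` on ug/day numbers because the
underlying judgment ("comparable to the diet") has no published numeric
rule; annotations come from the user (food-composition databases are not
queried). Cramer classification itself is out of scope; the TTC value is
configuration.

## The synthetic benchmark

The generator emulates a tannin-dominated extract profile across all
channels. Defaults (all configurable):

* **Composition:** 16.6 % polar, 7.9 % non-tannin polyphenol, 71.9 %
  tannin, 1.0 % nonpolar, 2.6 % volatile — chosen so the CAD class split is
  ~17/82/1 (polar/polyphenol/nonpolar) and the CAD + GC mass balances close
  at 100 %. Constituents are named, real formulas of the classes found in
  grape seed extract; relative within-class weights are fixed template
  values. The smallest per-peak masses (~0.3 ug on a 100 ug load, i.e.
  several hundred ug/dose) are set so that every peak's area noise sits
  well below the 10 % recovery bar at the default noise level; real
  extracts also contain smaller peaks, for which per-peak error would be
  correspondingly larger.
* **Peak shape:** Gaussian, sigma drawn uniformly in 0.045–0.07 min;
  tailing is not modeled. Time axis 0–70 min at 0.01 min sampling.
* **Noise:** additive white Gaussian, SD = 0.2 % of the maximum clean
  signal, plus a constant 0.2 pA baseline offset.
* **Tannins:** 100 polymer members rendered as wide (1.5–2.5 min sigma)
  Gaussians between 20 and 40 min. Member molecular weights are *stratified*
  (equal-mass quantile) draws from a log-normal — median 130 kDa,
  sigma_ln = 2.0 — so the measured MWCO loss series converges to the
  closed-form survival function at O(1/n) and the >100 kDa mass fraction is
  roughly half of the in-window signal, the hallmark of a high-molecular-
  weight, broadly distributed tannin pool. (A 40 kDa median cannot put half
  the mass above 100 kDa for any log-normal width; the median was chosen to
  make the observed pattern attainable.)
* **MS features:** one adduct per permitted polarity ([M−H]⁻ / [M+H]+) at
  the constituent's RT (jitter SD 0.01 min); intensities are arbitrary-unit
  draws uncorrelated with CAD area, because the MS channel is explicitly
  non-quantitative here. Decoys are placed 0.3 min (= 3x the alignment
  tolerance) after a host peak, with clearance from all true apexes, and
  recorded as non-contributors. Tannins emit no ESI features.
* **GC:** a C6/C7/C9/C10–C25 alkane ladder with retention mildly quadratic
  in carbon number; volatile RTs are placed by inverting their template
  Kovats indexes, so re-indexing recovers the template values exactly.
  Twenty volatiles: eight above the TTC (template amounts 170–980 ug/dose)
  plus twelve minor ones, totalling 2.6 % of the load.

What passing the synthetic benchmark shows: the universal-RF arithmetic,
peak/hump separation, alignment filtering, TTC logic, MWCO inversion, and
the orchestration are correct under known ground truth at realistic
signal-to-noise. What it does not show: robustness to peak tailing,
retention drift between runs, isotope structure, co-elution closer than
~0.4 min, matrix-dependent CAD response (mobile-phase gradients are assumed
compensated), or detector saturation — real-data behaviour on those axes is
untested by design.

## Determinism

All randomness flows from one `numpy.random.Generator` seeded by the user;
stage-level generators are spawned from it. Identical (config, seed) pairs
reproduce datasets bit-for-bit, and CSV/JSON writers use fixed float
formats and sorted keys so exported files and reports are byte-identical
across reruns. Every generated file and report embeds the seed and a hash
of the configuration.
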