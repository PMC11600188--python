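# Methods

## The axial-profile measurement

A fish is imaged as a two-channel confocal z-stack: a GFP reporter labels
the pronephric duct wall, and a solvatochromic tracer dye reports plasma
protein inside the lumen.  The duct is traced once by the user as a
polyline over the GFP maximum-intensity projection, glomerular end first.

The measurement then proceeds per axis pixel:

1. **Rasterization.**  Each polyline segment is rasterized with Bresenham's
   algorithm; pixels are 8-connected, segment joints are kept once, and the
   physical step length is `pixel_size` or `√2·pixel_size`.  Cumulative
   distance is the running sum of these in-plane steps.  The z drift of
   the duct is deliberately *not* added: the distance axis is defined on
   the projection plane where the trace was drawn.  A consequence worth
   knowing: the 8-connected chain is up to ~8% longer than the smooth
   curve it approximates (exactly 8% at 22.5° incidence), so slopes
   measured against cumulative distance are commensurately shallower than
   slopes against true arc length.  This affects all profiles of a given
   trace equally and cancels out of between-group comparisons.
2. **In-focus slice.**  At each chain pixel, the mean GFP over a disk of
   diameter `D1` (chosen to cover the duct's outer circumference) is
   computed per slice; `N_max` is the argmax, ties broken toward the lower
   slice.  Disk membership uses pixel-center distance with inclusive
   boundary.
3. **Focus smoothing.**  The duct crosses the field at a slowly varying
   depth, so `N_max(x)` is fitted with an OLS cubic in the pixel x
   coordinate (numpy's scaled-basis polynomial fit for conditioning), then
   rounded half-up and clamped to the slice range to give `⟨N_max⟩`.  When
   fewer than four distinct x values exist the fit errors, directing the
   caller to an explicit lower-order fallback flag; an option fits against
   cumulative distance instead of x for strongly curved or vertical
   traces, where x is a degenerate regressor.  One global cubic is fitted
   per fish — the smoothing corrects isolated jumps in the argmax, and a
   piecewise fit would follow those jumps instead.
4. **Dye readout.**  `FI_dye` is the mean dye intensity over an inner disk
   `D2` (inside the lumen) at slice `⟨N_max⟩`.  The mean (rather than sum
   or max) is used for both channels so that values are independent of
   disk size in homogeneous regions.

Defaults `D1 = 15 px`, `D2 = 7 px` suit a larval duct at a 10× objective
with ~1.3 µm pixels; both are configurable and must be matched to the
actual duct diameter in pixels — `D1` should enclose the outer wall, `D2`
stay inside the lumen (the phantom-matched values used throughout the
tests are 21 and 7 px at 1 µm/px).

**Summary statistics.**  Each profile is reduced to the mean `⟨F.I.⟩` and
the OLS line `FI_dye ≈ intercept + slope·s`.  The intercept estimates the
dye level where filtrate enters the duct (glomerular sieve integrity); the
slope estimates net removal or accumulation along the duct (tubular
function).  The quadrant call compares a fish against healthy controls:
glomerular impaired when its intercept exceeds a chosen quantile (default:
the maximum) of control intercepts, tubular impaired when its slope
exceeds the upper bound of the control slope band.  Thresholds are
data-driven because absolute dye units depend on staining and detector
settings; they are recorded in each call.

**Spikes.**  Hematuria appears as sudden local peaks in the profile.
Flagging is advisory and off by default (spiked profiles are still valid
measurements): residuals are taken from a Theil–Sen line — an OLS baseline
would itself be dragged by a large spike and flag the entire profile — and
positions beyond `k·1.4826·MAD` are flagged, with a relative floor on the
MAD so that numerically-zero residual vectors produce no flags.

**Group testing.**  Between-group comparison of mean/intercept/slope uses
Kruskal–Wallis with tie correction followed by all pairwise two-sided
Wilcoxon rank-sum tests, Bonferroni-adjusted over the pairs of that metric
(not across metrics, matching per-panel reporting).  With the assay's
typical n ≈ 9 fish per group, pairwise p-values are exact whenever both
samples have ≤ 10 tie-free values, otherwise the tie-corrected normal
approximation is used.  A simulated exchangeable null (3 × 9, 10,000
replicates) keeps the family-wise error of the adjusted procedure at or
below the nominal 0.05 within Monte-Carlo error.

## The binding model

The dye is almost non-fluorescent free in water and brightens on binding a
plasma protein.  For a protein at total concentration `P₀` with `n`
equivalent sites of dissociation constant `K_d`, and dye at total `L_tot`:

    [PL] = n·P₀·L_f / (K_d + L_f),   L_f = L_tot − [PL]
    FI   = u·(L_f + α·[PL])

`[PL]` is obtained exactly as the physical root of the quadratic this
implies (numerically stable form `2q/(b+√(b²−4q))`), rather than by the
common approximation `L_f ≈ L_tot` — exactness costs nothing and matters
when `L_tot ≈ n·P₀`.  `u` is the fluorescence per µM of free dye and `α`
the dimensionless fold-enhancement of a bound dye molecule; the free-dye
baseline term is kept by default (solvatochromic quenching in water is
strong but not total) and can be zeroed by a flag.

* **α** is estimated operationally as the ratio of saturated to free-dye
  fluorescence at matched dye concentration: FI is measured over a range
  of protein concentrations at one fixed low dye concentration, regressed
  against `1/P₀`, and the y-intercept (the infinite-protein limit, where
  all dye is bound) is divided by the zero-protein FI.  Because
  `FI(1/P₀)` is exactly linear only asymptotically, the estimate carries a
  small positive curvature bias that vanishes as the largest `P₀/K_d`
  grows; at the grid used here (10–1000 × K_d) it is well under 1%.
* **(K_d, n)** are fitted from a vary-dye titration at fixed protein by
  least squares in log-parameters (positivity by construction), with
  multi-start initialisation — K_d starts log-spaced across the dye range
  crossed with n ∈ {0.3, 1, 3} — and tight (1e−15) convergence tolerances;
  the best of all starts is returned with residual norm and convergence
  flag.  A series with no protein response is reported with a degenerate
  flag instead of a meaningless parameter pair.
* The Scatchard transform `bound = (FI/u − L_tot)/(α − 1)` is provided for
  display and cross-checks (slope −1/K_d, bound-axis intercept n·P₀); it
  is never used for fitting.

## Electropherogram quantification

Chip-electrophoresis detectors under-report late (large) species; sizing
instruments express this per ladder peak as the ratio "time-corrected
area"/"area".  The ratio is fitted as a power law `r(t) = a·t^b` by OLS in
log-log space (exact for true power laws, deterministic), the whole trace
is multiplied pointwise by `r(t)`, and thereafter the time integral is
proportional to protein amount.  Molecular-weight windows are mapped to
time windows by piecewise-linear interpolation of log(MW) against
migration time through the ladder — the standard sizing convention; the
instrument's internal mapping is not disclosed.  A band's amount is the
trapezoidal integral of (sample − water baseline) over the window,
converted via a ladder peak of known amount:

    amount = ∫(sample − water) dt · amount_ref / corrected_area_ref

Detector gain cancels through the ladder reference.  Negative estimates
(sample below baseline) are floored at zero with a warning.  The
10–40 kDa window is exposed as a named preset because low-molecular-weight
proteins in that range are the first to appear in urine when tubular
reabsorption fails.

## The synthetic phantoms

`synthetic.generate_tube_zstack` renders a curved duct with known ground
truth.  The centerline is the graph of cubic splines `y(x)`, `z(x)`
through control points with strictly increasing x (with four control
points and not-a-knot ends, `z(x)` is a single cubic — the smooth drift
the focus fit models).  Around it:

* the **GFP channel** is an annular wall (`r_in ≤ ρ ≤ r_out`, defaults
  7/10 µm), with brightness modulated by a Gaussian of the axial offset
  from the centerline plane (`wall_focus_sigma`, 4 µm).  This emulates
  confocal axial sectioning and gives the wall an unambiguous brightness
  maximum at the in-focus slice — a uniformly painted cylindrical shell
  has a *flat* in-plane cross-section over `|dz| ≤ r_in` and no usable
  argmax;
* the **dye channel** fills the lumen (`ρ < r_in`) with the scenario's
  axial profile `entry + slope·s + baseline`, plus optional Gaussian
  spikes emulating hematuria.  `s` is the in-plane arc length, matching
  the measurement convention;
* both channels are blurred by an isotropic Gaussian PSF (1 µm default —
  a resolution proxy, not an optics model) and optionally perturbed by
  additive Gaussian noise clipped at zero.  The tube is painted with a
  one-radius extension beyond both ends so that ROI disks centered on the
  first and last axis pixels sample tube rather than background.

The four scenario presets place the quadrant taxonomy in dye units:
healthy (entry 20, slope 0), glomerular leak (200, −0.5/µm), tubular
failure (15, +0.5/µm), combined (200, +0.3/µm), all over baseline 10.
Default geometry matches the acquisition the pipeline targets: 3.947 µm
slice spacing, 1 µm pixels, 40 × 256 × 256 voxels.  `make_study_case`
randomizes per-seed lateral wiggle (±25 µm) and gentle depth drift (±15 µm
about a random mid-depth) while keeping the scenario profile fixed, so a
seed sweep emulates a cohort of fish.

What the phantom does **not** emulate: real PSF anisotropy and depth
attenuation, autofluorescence and gut accumulation of dye, body curvature
and duct-diameter variation along the axis, motion during acquisition, and
Poisson photon statistics.  Passing the recovery tests therefore
demonstrates the correctness of the measurement chain on its own model of
the data, not robustness to every confound of live imaging.

## Verification sizes and tolerances

The headline checks run on: 20-seed sweeps of all four scenarios at
40 × 256 × 256 voxels (noiseless; quadrant calls must be exact, means
within 5%); exhaustive-oracle equivalence for disk masks (diameters 1–25,
100 random centers) and focal-slice selection (50 random fixtures); cubic
smoothing exactness on integer-cubic data and ≤ 1-slice error under
0.5-slice noise at 200 positions; a 10,000-replicate null for the pairwise
testing procedure; 1%/2% recovery for ladder equalisation and band
amounts; and 1e−4 relative round-trip recovery of both published
(K_d, n, α) parameter sets.  Slope recovery on phantoms is compared in the
chain metric (ground-truth slope rescaled by true-arc/chain length) within
15%.

## Known limitations

* The cumulative-distance axis inherits the rasterization metric (see
  above); absolute slopes are trace-dependent at the few-percent level.
* `FI_dye` is reported in detector units; no absolute protein
  concentration calibration is attempted.
* The quadrant thresholds are order statistics of small control groups and
  should be treated as screening calls, not diagnoses.
* The binding model assumes one class of equivalent, independent sites; no
  cooperative (Hill) or multi-site global fitting is provided.
* Electropherogram bands are quantified by windowed integration; heavily
  overlapping bands are not deconvolved.
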