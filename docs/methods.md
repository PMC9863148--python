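# Methods

`cytoblot` re-implements, as a tested library, the semi-automatic workflow
used to quantify urinary cytokines on spotted antibody membranes (dot-blot
arrays) and to derive consensus chronic-kidney-disease (CKD) marker panels
from them. This note records the models, the numerical choices, and what
the synthetic validation does and does not demonstrate.

## The measurement model

A membrane carries a lattice of antibody spots organised in blocks separated
by alleyways, with every analyte printed in duplicate and constant-intensity
reference spots at the outermost corners. A chemiluminescence scan gives a
grayscale raster in which spot brightness reflects analyte abundance. The
quantity of interest per spot is its *integrated density*: the sum of pixel
intensities over a circular aperture centred on the spot.

### Grid inference

1. **Pre-blur.** The scan is convolved with a Gaussian of sigma 4 px
   (reflective boundaries, kernel truncated at 6 sigma so repeated blurs
   compose to machine precision). The blur exists only to stabilise
   localization; densities are always measured on the original raster.
2. **Maxima.** Strict 8-neighbourhood maxima are filtered by topographic
   prominence (the FIJI "noise tolerance": peak height above the highest
   saddle toward higher terrain), computed exactly with one grayscale
   reconstruction (h-dome). Peaks closer than half a pitch to a stronger
   accepted peak are suppressed greedily. The pipeline default prominence is
   adaptive — 20x the robust (MAD-based) noise sigma of the blurred image —
   because the appropriate noise tolerance depends on the scanner; it is a
   free parameter everywhere. On noise-free synthetic images the MAD
   degenerates to zero and an explicit prominence must be given.
3. **Corners.** Within each image quadrant, the three maxima nearest the
   image corner are shortlisted; the anchor is the *nearest* shortlisted
   point whose intensity reaches half the shortlist maximum. Preferring
   proximity with an intensity floor keeps the anchor on the corner
   reference spot even when an adjacent, strongly up-regulated analyte
   outshines it (picking the brightest outright shifts the whole grid by
   one pitch in exactly that situation), while still rejecting faint noise
   maxima closest to the corner.
4. **Interpolation.** Every layout position maps to the bilinear
   interpolation of the four corner anchors at fractional coordinates
   derived from its lattice units: a position in block column `B`, column
   `c` sits at `B*(cols_per_block + alley_col) + c` pitch units, so alley 0
   continues the lattice seamlessly and the alley value adds that many
   extra pitch units of gap between blocks. Bilinear (not projective)
   interpolation is deliberate: four anchors determine it exactly, and
   membrane scans show shear/scale but negligible perspective.
5. **Snapping.** Each interpolated position moves to the nearest unclaimed
   maximum within 0.4x pitch, matched one-to-one greedily by distance so a
   single bright maximum can never serve two positions; unmatched positions
   keep interpolated coordinates and are flagged as such. Snapping is
   idempotent.

### Densitometry

Integrated density sums original pixel intensities whose centres fall within
the layout's spot radius of the fitted position (pixel-centre-in-circle:
simple, deterministic, additive and homogeneous). Apertures cut by the
border are flagged `clipped`; fully outside, `missing`. No local background
annulus is subtracted — the detection rule below handles background
globally. Duplicates are collapsed by the arithmetic mean (n=2 duplicates
make a median pointless); the duplicate CV is kept as QC.

## Statistics

### Normalization

The robust spline normalization is implemented as a monotone quantile-curve
mapping: per sample, a strictly increasing PCHIP spline maps the sample's
log2 densities onto the across-sample mean quantile curve. Three
robustness choices matter, each motivated by a concrete failure of the
naive version:

- **Rank-invariant anchors.** The spline is fitted only on features whose
  within-sample rank varies by at most 10% of the feature count across
  samples. Differential features shift rank and stay off the curve, so
  their fold changes survive; exact full-quantile mapping instead forces
  every rank onto the reference and fabricates ratios at the tails.
- **Tail trimming.** Features in the extreme 10% of mean ranks are never
  anchors: a marker that is already the dimmest or brightest feature keeps
  its rank no matter how it changes, so rank stability is uninformative
  there, and anchoring it normalizes the effect away.
- **Few, populated knots.** Anchors are condensed to at most 8 quantile
  bins (each holding at least 3 anchors) whose means form the spline
  knots. A knot per anchor would map those features exactly onto the
  reference, silently deleting their replicate variance and corrupting the
  variance-prior estimate downstream.

Outside the anchor range the map continues with unit slope in log space,
which preserves fold changes of features brighter or dimmer than every
anchor. Zeros are offset by half the smallest positive value before the
log transform. The map is strictly increasing, so within-sample ranks are
preserved exactly; identical samples are a fixed point, and a global scale
factor between samples is removed completely.

### Background and detection

Per membrane, background spots are those whose density lies within 5% of
the dynamic range above the minimum (`min + 0.05*(max - min)`, inclusive).
Reference spots are fiducials, not measurements, and are excluded before
the range is computed. If fewer than 10% of spots fall under the threshold
the membrane has no signal range above its noise floor; the threshold is
then slicing the noise distribution itself, and keeping only its lower
tail would bias the background mean and SD downward — in that case all
spots are background (the all-values-equal degenerate case is the limit of
this rule). Densities enter per unit aperture area, because the
pixel-quantized aperture area varies by a few pixels between positions and
the `area x background` term otherwise adds fixed-pattern spread.

An analyte is *detected* (expressed) when its duplicate densities sit
significantly above the background population at one-sided p < 0.05. The
statistic is `t = (mean_a - mean_bg) / (sd_bg * sqrt(1/n_a + 1/n_bg))`
with `n_bg - 1` degrees of freedom: under the null an analyte spot is just
another background spot, so the background SD is the right noise scale.
A Welch two-sample test is available (`method="welch"`) but not the
default — with n=2 duplicates its 1-df analyte variance makes it both
liberal under the null (measured 8.2% at alpha 0.05) and underpowered
(0.80 at SNR 10, versus 1.0 for the default). With a single replicate the
statistic reduces to the classic z-score against background mean/SD; zero
background variance degenerates to an exact comparison.

### Moderated t and composite calls

Differential expression per contrast (one series, one gender; one pooled
CKD membrane against one pooled control membrane) uses the two-group
empirical-Bayes moderated t on log2 normalized densities, with duplicate
spots as technical replicates — the only available variance source in this
pooled design, a limitation inherited from it: the "replicates" do not
capture biological variation between subjects. Per analyte g the pooled
residual variance s_g^2 (d_g df) is shrunk toward a prior,

    s~_g^2 = (d0 s0^2 + d_g s_g^2) / (d0 + d_g),

with (d0, s0^2) estimated by closed-form method of moments on log s_g^2
(trigamma inversion, Newton iterations to 1e-10). The moderated t uses
s~_g and d0 + d_g degrees of freedom. If the log-variances show no excess
spread beyond chi-squared sampling noise, d0 is infinite and every
variance is the df-weighted pooled variance. `prior_df=0` reproduces the
ordinary pooled t exactly; `prior_df=inf` with a fixed `prior_var` gives
the known-variance statistic — both are tested limits.

An analyte is called **up** when: detected in at least one condition, AND
linear ratio (mean normalized CKD / mean normalized control) > 1.5, AND
moderated p < 0.05, AND Benjamini–Hochberg FDR < 0.25; **down**
symmetrically with ratio < 0.667. Ratios are computed on normalized
*linear* densities (the thresholds are linear-scale); the log2 ratio of
group means is reported alongside. FDR is computed within each contrast.
BH adjustment is delegated to statsmodels and verified exactly against a
brute-force O(n^2) step-up oracle.

### Panels and clustering

Call sets (analyte -> up/down) intersect by identical direction: across
the two experiment series per gender (cross-series consensus), or across
genders within a series (gender overlap). Analytes present with opposite
directions are reported as *discordant*, never silently dropped — the
direction flips between series are themselves informative. The bundled
machine-readable marker tables digitized from the study let the panel
logic be tested independently of the imaging pipeline. Gender-independent
calls average male and female normalized densities replicate-by-replicate
before re-running the contrast; the detection gate takes the per-condition
minimum of the two genders' detection p-values.

Sample clustering uses complete linkage on 1 - Pearson correlation
(scipy), with merge heights equal to the linkage distance; the tree is
exported as Newick with branch lengths as height differences. Tests verify
the merge sequence and heights against a naive O(n^3) agglomeration
oracle.

### Cohort screening

A subject is CKD-eligible when eGFR < 60 mL/min per 1.73 m^2 or
albumin/creatinine ratio >= 3.0 mg/mmol, control when eGFR >= 60 and
ACR < 3.0; a record whose computed label contradicts its declared group is
flagged `ineligible_conflict`. The bundled cohort fixture's ACR column is
interpreted as mg/mmol (its printed unit header is inconsistent with the
eligibility thresholds; mg/mmol is the reading consistent with both the
thresholds and the values). One record (a 22-year-old male with eGFR
157.26 and ACR 2.55 declared CKD) computes as control and is flagged.

## The synthetic study

The simulator emulates the study design: two experiment series x
{male, female} x {CKD, control}, one membrane per arm (each arm modelling a
pool of ten urine samples — pooling is implicit; per-subject simulation is
out of scope), 50 analytes in adjacent-column duplicates on a 2x2-block
10x10 layout, 600x400 px 16-bit images. Defaults: log-normal analyte
abundances (log2 mean 15, SD 1 — spanning faint-to-bright spots on the
16-bit scale), 4 up- and 4 down-regulated consensus markers at 3-fold
change shared between series, duplicate technical CV 15% (multiplicative
log-normal), Gaussian spot PSF sigma 2.5 px, corner jitter SD 2 px,
per-spot jitter SD 1 px, constant background 50, read-noise SD 10,
reference spots at 2^21 integrated mass (bright enough that no analyte
tail can outshine a corner anchor, peak still below 16-bit saturation).
Per-spot jitter models printing imprecision of physical spots; a position
with nothing printed has its true centre on the warped lattice.
Optional series-discordant markers flip direction in even series to
emulate the cross-series variability the real data show. A tabular
shortcut (`simulate_expression_table`) generates the same expression model
without imaging. Fixed seed implies byte-identical images, tables and
truth sidecars; all randomness descends from `numpy.random.SeedSequence`.

What passing the synthetic validation shows: the pipeline recovers planted
grids to ~2 px under realistic jitter and missing spots, its detection
call is calibrated (null rate ~5% at alpha 0.05) and sensitive (SNR 10
fully detected), and planted 3-fold consensus markers are recovered end to
end (typically 90–100%) with no direction errors and essentially no false
panel members. What it does not show: robustness to structured real-scan
artifacts (illumination gradients, scratches, bleed-over, saturation
smears), to rotated or warped-beyond-bilinear grids, or to biological
variance between subjects — the pooled design has no handle on the latter,
and the simulator mirrors that.

## Problem sizes in the validation experiments

The bundled test suite and `scripts/acceptance.py` size their experiments
to be decisive yet quick: 10–20 membranes for grid recovery (4 000–8 000
positions), 25–50 membranes for detection calibration (1 250–2 500 analyte
calls), and 2 full studies (16 membranes, 32 planted-marker calls, 168
non-planted analytes) for the end-to-end recovery experiment; 1 000 fuzzed
vectors for the BH oracle and 200 random matrices for the clustering
oracle. The whole suite runs in well under a minute of compute plus a few
seconds per simulated study.
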