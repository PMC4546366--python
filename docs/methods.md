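# Methods

## The measurement model

The package quantifies regional left-ventricular (LV) systolic function from
cine short-axis cavity segmentations. For each slice the cavity is divided
into six 60° angular sectors (anterior, antero-septal, septal, lateral,
posterior, inferior) about the end-diastolic cavity centroid, and the
regional fractional area change of each (slice, sector) cell is

    RFAC = (EDA − ESA) / EDA × 100 %

with EDA and ESA the sector cavity areas at end-diastole and end-systole.
End-diastole (ED) and end-systole (ES) are chosen **globally** per study as
the phases of maximal and minimal total cavity area (ties broken toward the
earlier phase). The alternative — choosing ES per sector — would bound RFAC
away from negative values and hide dyskinesis, so it is not offered.

Sector geometry: angles are measured from image "up" (decreasing row index),
increasing clockwise on screen, offset by a configurable
`reference_angle_deg` because the anatomical anchoring of the first boundary
is a per-acquisition convention, not something the data dictate. Each cavity
pixel is assigned to the sector whose half-open 60° interval contains its
center, so sector areas sum to the total cavity area exactly. The sector
origin (the per-slice centroid) is taken from the ED frame and held fixed
across phases, so RFAC measures wall motion relative to a stationary frame;
a per-phase centroid is available via `centroid_mode="per-phase"` for users
who prefer to discount bulk translation.

Hearts covered by different slice counts are compared by resampling each
sector's apex→base RFAC profile with a cubic spline to 10 equally spaced
slice positions in [0, 1]. The spline is not-a-knot by default (exact on
cubic polynomials); a natural spline is available. Slice positions are
normalized by index, not physical position, because resampling is a device
for aligning slice grids, not a geometric reconstruction. Fewer than 4
usable slices per sector falls back to linear interpolation with a warning.

Remote-wall (non-infarcted territory) summaries on the resampled grid:
iRFAC and pRFAC average the inferior and posterior sectors over resampled
slices 2–7 (1-based) — the apex slice is excluded as unreliable (through-
plane apex motion causes partial-volume artifacts) and the three basal
slices as outside the infarct's influence — and ipRFAC = (iRFAC + pRFAC)/2.

Global volumes use stacked-disk summation: EDV = Σ slices (total cavity area
at ED) × slice spacing, in μl (mm³); EF = 100 × (EDV − ESV)/EDV. With
uniform spacing this makes EF *identically* the EDA-weighted mean of the
per-cell RFACs — an internal consistency contract the test suite checks to
1e-9 on every phantom.

## The synthetic phantom

Each slice's cavity boundary is a star-convex curve

    ρ(θ, t, s) = R(s) · (1 − c(θ, s) · g(t)),

where R(s) is the end-diastolic radius (positive, nondecreasing apex→base),
c(θ, s) the radial contraction amplitude, and g(t) a periodic waveform with
g(0) = 0 and max 1 (default raised cosine; ES phase = argmax g, exported as
ground truth). Contraction acts on the **radius**, so a sector with uniform
amplitude c has closed-form RFAC = (1 − (1 − c)²)·100 — the primary
measurement oracle. Per-sector amplitudes are blended across boundaries with
a cosine taper (default 10° arc) to avoid non-physical steps; ground-truth
sector areas integrate the blended field by dense quadrature (7200 angular
points), so with the taper enabled the ground truth is the blended field's
area, which near sharp amplitude steps deviates from the per-sector closed
form by up to ~1.5 %. Recovery tests against the closed form therefore
disable the taper; recovery against the blended ground truth holds either
way. At a 256² matrix the pipeline recovers the closed form within 0.3 %
absolute per sector (tested bound: 1 %).

Boundary jitter (SD in pixels) is a smooth periodic perturbation of ρ built
from 32 angular control points, drawn independently per frame — it emulates
segmentation noise, not MR physics. There is no k-space, coil, gating, or
myocardium model; the phantom emits segmentations directly because the
measurement pipeline takes segmentations as its input contract.

### Cohort generator

The default design emulates a three-arm mouse infarct study: sham, untreated
infarct (MI), and treated infarct (MI+Val), 12 animals per arm, measured at
baseline, 24 h, 1 week and 4 weeks. Contraction targets are expressed as
mid-apical RFAC per sector and converted through c = 1 − √(1 − RFAC/100):
the anterior/antero-septal/lateral territory is severely hypokinetic
(RFAC 4–14 %), the remote inferior/posterior wall moderately depressed
(MI ≈ 17–29 %, treated ≈ 27–38 % across follow-up), the septum intermediate,
and the three basal slices ramp back toward ~55 %. Between-subject variation
is a subject-level additive offset on the whole field (SD 0.015–0.045 by
arm). Cavity radii run 0.96–1.75 mm apex→base (baseline EDV ≈ 42 μl) and
dilate by per-timepoint radius factors up to 1.67 (MI, 4 w) and 1.46
(treated), reproducing the EDV trajectory of an untreated vs treated
infarct. Mortality is exponential from randomization with per-week hazards
0 (sham), 0.07 (MI), 0.025 (MI+Val), censored at 4 weeks — a few early
deaths in the infarcted arms, none in sham. Cohort tables are filled by
running the *actual* pipeline on every generated study, never by copying
generator targets.

Atrial traces are built per subject from sampled LA Vmax and LA emptying
fraction (Vmin derived as Vmax·(1 − EF/100) so the two volumes stay
coupled), an appendage midline of target arc length, and duct diameters set
from a sampled fractional shortening. LA contours are ellipse polygons
constructed to a target Simpson volume (prolate spheroid closed form), so
the volumetric code path is exercised with known answers.

The expression generator is log-normal: intensity = exp(baseline + class
effect + β·(trait − mean) + noise), matching intensity-scale microarray data
and the log-based probe filters. Defaults: 800 genes + 10 % duplicate
probes, 15 % low-intensity (below-detection) probes, 80 class-affected genes
(MI shifted ±0.6 on the log scale, treated arm 40 % of that, alternating
sign to mimic up- and down-regulated remodeling clusters), 40 of them
additionally coupled to the remote-wall index with slope −0.03 per RFAC
point (higher expression where function is worse), noise SD 0.25. Ground
truth (affected / coupled / low probes) is attached as metadata.

What the generator does **not** emulate: probe-level normalization artifacts
(VST/RSN are upstream of this package's input contract; the default
normalization hook is log2), spatial correlation of segmentation errors,
arrhythmia/gating failures, and operator variability in echo tracing.
Passing tests therefore demonstrate correctness of the computations and
calibration of the statistics under the stated noise model, not robustness
to every artifact of real acquisitions.

## Statistics

* **Helmert contrasts** (pre-treatment): one-way ANOVA contrasting (a) sham
  vs the average of the infarcted arms and (b) MI vs MI+Val, as t-tests on
  cell means sharing the pooled error term. **Treatment contrasts**
  (post-treatment): MI vs each other arm, same machinery.
* **Repeated-measures ANOVA** (sham time-constancy) with Holm step-down
  adjusted pairwise paired t-tests; incomplete subject × timepoint grids are
  rejected rather than imputed.
* **Sector-by-sector comparison**: unpaired t-test per cell of the resampled
  10-slice grid; pooled variance by default (Welch by flag). Raw p-values by
  default — the bull's-eye display marks raw p (• 0.05<p<0.1, * p<0.05,
  ** p<0.01) — with optional Benjamini–Hochberg across the 60 cells.
* **Power**: noncentral-t with pooled SD √((s₁²+s₂²)/2), noncentrality
  δ√(n/2)/SD, df = 2n−2; one- or two-sided is explicit because published
  power statements often omit it. For the scenario n = 12/group, δ = 14.0,
  SDs 10.4 and 17.3, α = 0.05 this gives 63.2 % (two-sided) or 75.3 %
  (one-sided), values validated against a 10⁶-trial Monte-Carlo oracle in
  the test suite; the oracle, not any published figure, is the authority.
* **Survival**: Kaplan–Meier product-limit curves and the standard log-rank
  test (lifelines); the no-event case is flagged rather than given a fake p.

Type-I error of the sector t-test, both Helmert contrasts, and the log-rank
test is verified on 1000 null simulations each (nominal α = 0.05, accepted
within 3 binomial SEs).

## FDR-with-confidence permutation screens

Class-comparison and quantitative-trait screens control the false-discovery
**proportion** with stated confidence (default: FDP < 10 % with 80 %
confidence), not its expectation. Genes are ranked by p-value (one-way F
across classes, or the t-based Pearson-correlation p against the trait); for
a candidate list of size k with cutoff p(k), class labels (or trait values)
are permuted — exhaustively when the permutation space has at most `n_perm`
elements, else `n_perm` random draws — and each permutation's count of
p-values ≤ p(k) estimates the null false-discovery count. The selected list
is the largest k for which the fraction of permutations with count ≤
fdr·k is at least the confidence level. This construction is validated by
its defining property: under a simulated global null the screen returns a
non-empty list in at most 1 − conf = 20 % of replicates (200-replicate
check, binomial tolerance), and on tiny instances it coincides with full
enumeration of the permutation space. The selected set is nested: raising
the FDR bound or lowering the confidence never shrinks it.

Probe filtering applies three rules: (a) drop probes whose 33rd intensity
percentile is below 125 (below-detection); (b) drop probes whose
log2-intensity variance is not significantly above the typical probe, via a
χ² test of (n−1)s²/σ₀² against χ²(n−1) where σ₀² is the median probe
variance of the input (retain if p ≤ 0.05) — the precise form of a
"log-variation p-value" is a convention, so σ₀² is an explicit parameter and
the filter audit records the value used; (c) collapse multiple probes per
gene symbol to the max-IQR probe. Refiltering with the audit's σ₀² is a
no-op; with the default (recompute the median on the now-smaller matrix) a
second pass can drop more probes, which is why the parameter exists.
Fold-change gates use the signed linear-scale ratio of group means (negative
reciprocal below 1), requiring p < α and |FC| ≥ 1.2 in at least one of the
MI-vs-sham / MI-vs-treated comparisons.

## Numerical choices and problem sizes

* Polygon rasterization: even-odd rule sampled at pixel centers (0-based),
  implemented directly so the convention is exact and testable; boundary
  pixels follow the half-open crossing rule.
* Simpson (method-of-disks) volumes: chords measured by intersecting the
  contour with the perpendicular at each strip midpoint (shapely); 20 disks
  by default, exact for cylinders, within 0.5 % of the spherical closed form
  at 200 disks.
* Permutation p-granularity: selection operates on false-discovery counts,
  so no per-gene permutation p-value is formed; where one is reported the
  add-one convention (b+1)/(B+1) applies.
* Degenerate inputs are flagged, not silently absorbed: constant cavity
  areas (ED/ES undefined), zero EDA cells (missing, never 0 % RFAC), zero
  within-group variance (ANOVA flagged), no survival events (log-rank
  flagged).
* Routine tests run cohorts at n = 2–12 per arm on 48²–96² matrices; the
  analytic recovery check uses a single 256² jitterless phantom; null
  calibrations use 1000 replicates (tests) and the FDP checks 200 replicates
  at 60 genes × 18 samples with 300 permutations. These sizes were chosen to
  exercise every code path at full statistical fidelity while keeping the
  whole suite around a minute.

## Known limitations

* The sector origin's anatomical anchoring is configuration, not inference;
  comparing acquisitions requires a consistent `reference_angle_deg`.
* Stacked-disk volumes ignore slice-profile overlap (spacing governs volume,
  matching the 1 mm-spacing acquisition geometry the phantom emulates).
* The mono-plane disk method assumes circular cross-sections of the atrium;
  group-mean LA EF is the mean of per-subject ratios, so it will not equal
  the ratio of group-mean volumes.
* The FDP-control selection rule fixes one defensible reading of
  "confidence that the FDR is below the bound"; other order-statistic
  conventions exist and would differ at the margin. The guarantee tested is
  the distribution-level property, not agreement with any specific external
  implementation.
* Regional wall thickness, M-mode LV mass, clustering of gene lists, and GO
  enrichment are out of scope.
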