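# Methods

This note documents the models, algorithms, parameter choices, and known
limitations of `cardiopair`. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## 1. Geometries and coordinates

All lengths are micrometres. Physical x runs along image columns; fibril
angles are degrees counter-clockwise from +x with y pointing up (against
the row axis) and are π-periodic throughout, because fibrils are apolar.

* **Pattern**: a 211 μm × 15 μm rectangle (14:1), the stamp used for
  human iPSC-CM pairs — an island of ~3,200 μm² sized for two ~1,600 μm²
  cells (7:1 each) joined end to end.
* **Tissue**: a rectangular base continued by a narrower neck along +x.
  Defaults (base 2 × 2 mm, neck 0.8 × 3 mm) are our own choice of a
  realistic mm-scale micromolded construct; no construct dimensions are
  published for the experiments emulated here. Point stimulation sits at
  the centre of the base edge opposite the neck. Velocity recovery does
  not depend on these dimensions.
* **Canonical pair frame**: 64 × 512 samples over [−1, 1]² (short × long
  axis), junction plane at x = 0, bilinear resampling. The left/right
  orientation is normalized content-based: the half with greater total
  nuclei signal maps to x < 0.

## 2. Synthetic data: the stated world

The generators emulate the experimental data classes; every sample
carries its ground truth so each analysis stage is testable by parameter
recovery.

**Cell-pair images** (0.5 μm/px; resolves the 15 μm pattern width).
Four channels: nuclei (filled ellipses, default 18 μm major axis, aspect
2, centred 55% of the half-pattern length from the junction — slightly
distal of mid-cell, reflecting displacement of the nucleus away from the
junctional, myofibril-dense cell end; this also makes the perinuclear
localization centre (d ≈ 0.45) fall below the diffuse one (0.5), the
ordering expected of the disease readout); sarcomeric α-actinin and
F-actin (rendered fibril segments, 6–16 μm long, ~0.08 /μm²); and a
junction-protein channel that is a mixture with nonnegative weights
summing to one:

* *junctional* — Gaussian band across the short axis (default σ = 5 μm)
  centred at the junction plane;
* *diffuse* — uniform over the cell mask;
* *perinuclear* — 2 μm annuli hugging each nucleus.

Each component is normalized to unit total intensity before weighting, so
weights are interpretable as signal fractions. Additive Gaussian noise
(default SD 2% of the mean cell signal) is applied last.

**Fibril angles** are drawn from a von Mises distribution on the doubled
angle (so κ = 0 is uniform on [0°, 180°) and κ above 10⁶ collapses to the
director). A `zdisc_fraction` of α-actinin fibrils is drawn about the
short axis instead of the director — the transverse Z-disc mode.

**Plates** tile islands on a grid; each island is independently occupied
(Bernoulli) and occupied islands hold either a valid pair or one of the
QC-failure taxonomy: empty, single cell (half coverage, one nucleus),
three nuclei, or a close-nuclei binucleate (nuclei 40 μm apart with
explicit long-axis filaments spanning both). A no-span variant of the
binucleate exists to test the exclusion rule's conjunction. The mosaic
can be rotated to emulate plate misalignment.

**Calcium movies** (default 20 μm/px, 1 ms frames — macroscope-scale
mapping). Per pixel, F(t) = baseline·(1 + amplitude·g(t − t_act)) with
t_act = geodesic distance within the tissue mask from the stimulation
site divided by the set velocity (geodesic, not Euclidean, so waves wrap
correctly into the neck), and

    g(τ) = (e^(−τ/τ_down) − e^(−τ/τ_up)) / norm,  τ ≥ 0  (else 0)

normalized to peak 1; beats repeat at the pacing rate (previous-beat
decay tails are included). Defaults τ_up = 10 ms, τ_down = 150 ms,
amplitude 0.5 ΔF/F, baseline 100, noise SD 5 (SNR 10 on the transient):
the experiments give no transient kinetics, so values typical of
X-Rhod-1 hiPSC-CM recordings were chosen. A frame interval coarser than
τ_up records a warning in the movie. All randomness flows from one
integer seed through a named generator; identical specs regenerate
bit-identical data.

*What the generator does not emulate*: optical PSF and depth blur,
staining heterogeneity within a cell, membrane-bound vs cytosolic
partitioning, motion, photobleaching, action-potential electrophysiology.
A green recovery test therefore establishes correctness of the
measurement chain, not robustness to every property of real microscopy.

## 3. Registration and QC

Island detection thresholds the summed, smoothed channels. Otsu's
threshold always splits *something*, so a crop or plate is declared
signal-free when Otsu does not clear a robust floor (background median
plus 5 MAD·1.4826; background = crop margin outside the pattern box).
Occupied-island candidates must be ~14:1 elongated; the plate rotation is
the median candidate orientation when not supplied, and the grid offset
is refined by the median residual of candidate centroids to the nominal
pitch. Empty plates fall back to the nominal layout with a warning.

QC applies the inclusion rules in a fixed order (the rejection reason is
the first failure): α-actinin positivity (mean in-cell signal above 3×
the robust background level — no published threshold exists), coverage
≥ 0.8 of the pattern area ("covered most of the patterned area" is
unquantified; 0.8 tolerates edge retraction while excluding single
cells), exactly two nuclei (Otsu + watershed segmentation), and the
binucleate exclusion: nuclei centroids < 50 μm apart **and** long-axis
filaments spanning both nuclei. The spanning test is operationalized as
column coverage: skeletonized F-actin pixels within ±15° of the long
axis, restricted to the nuclei row band, must cover ≥ 90% of the columns
between the outer edges of the two nuclei. Coverage is used rather than
single-component span because crossing fibrils fragment any individual
skeleton branch; no published operational definition exists.

Canonicalization maps the junction plane — the transverse plane through
the midpoint of the two nuclei centroids projected onto the pattern
midline — to x = 0 and resamples bilinearly. Per-channel physical
integrals before/after are recorded in provenance (preserved to ≪ 1%).
Coincident nuclei centroids (< 1 μm apart) are a hard error.

## 4. Localization μ/σ

Profiles integrate intensity across the short axis, fold the two halves
about x = 0 by averaging I(x) and I(−x), report on d = 1 − |x| (1 = the
junction plane), and area-normalize. The centre/spread summary is a
least-squares Gaussian density (μ, σ, amplitude, baseline) with
multi-start initialization; the functional form behind the published
centre/width readout is not stated, and a unimodal Gaussian with a
moment-based fallback (μ = profile mean, σ = profile SD, flagged) is the
simplest total choice consistent with it. The fallback triggers on
optimizer failure, vanishing amplitude, or fitted σ > 1 (wider than the
domain — the Gaussian then only mimics the baseline; a flat profile
yields μ = 0.5, σ = 1/√12). μ is clipped to [0, 1]. Fits are per-pair,
then summarized as group mean ± SD (matching how cohort statistics are
reported); fitting the averaged profile instead is possible but not the
default.

Known bias: when an off-centre band's tail crosses the junction plane
(offset ≲ 3σ), folding reflects that mass and pulls μ slightly junction-
ward; recovery tests use band placements clear of the fold.

Heatmaps min–max normalize each pair to [0, 1] before pixel-wise
averaging — bounded output, robust to staining-batch intensity, and μ/σ
are scale-invariant by construction (area-normalized profiles).

## 5. Cytoskeletal order

Skeletonization: Hessian ridge (tubeness) enhancement at 0.8 μm (the
fibril diameter scale), Otsu threshold, morphological skeletonization;
per-pixel orientation from the structure tensor of the enhanced image
(gradient σ = 1 px, tensor smoothing 1.5 μm), fibril direction
perpendicular to the dominant gradient.

OOP is the largest eigenvalue of the mean tensor ⟨2 n nᵀ − I⟩ computed
over skeleton pixels (pixel-weighted, not per-component): well-defined
for branched skeletons and matching dense-orientation usage. Closed-form
checks: all-equal angles → 1; {0°, 90°} → 0; {0°, 0°, 90°} → 1/3.

Z-disc presence = fraction of α-actinin skeleton pixels within δ = 15°
(config-exposed) of the short axis. In dense fields with two orthogonal
fibril populations, structure-tensor smoothing at crossings pulls local
angles toward intermediate values and deflates pixel-weighted presence
relative to the per-fibril truth; recovery tests therefore use sparse
fields, and dense-field numbers should be compared only within a
consistent pipeline.

Nuclear morphometry uses second-order image moments (ellipse-equivalent
axes); alignment is the π-periodic angle between the nuclear major axis
and the cell long axis folded to [0°, 90°]; near-circular nuclei
(eccentricity < 0.05) report alignment 0 by convention. Components under
10 px are skipped.

## 6. Calcium mapping

ΔF/F uses a per-pixel 10th-percentile baseline; optional spatial Gaussian
(1 px) and temporal Savitzky–Golay filters are off by default and
recorded in provenance when used. Pixels with F₀ ≤ 0 are invalidated.
With short diastolic intervals the percentile baseline sits slightly
above true diastole, biasing peak ΔF/F down by a few tenths of a percent.

Beat onsets are dF/dt peaks of the tissue-mean trace separated by at
least half the pacing period and above half the maximal slope; measured
frequency is the reciprocal median inter-beat interval (requires ≥ 2
beats).

Activation time is the linearly interpolated 50% fractional-upstroke
crossing (robust at these frame rates; a dF/dt-maximum variant is
provided). Pixels with beat peak < 0.1 ΔF/F are undefined. The 50%
crossing lags true activation by a fixed transient-shape delay, a
uniform offset that cancels in every gradient-based quantity; residual
map error is bounded by half a frame interval (interpolation).

Velocity: plane fit t(x, y) = a + bx + cy over the ROI, v = 1/‖(b, c)‖
(μm/ms × 0.1 → cm/s), with r². The measurement ROI is the central 80% of
the neck, excluding entry curvature and the free end. A windowed
quadratic (`local_poly`, median of local speeds) handles curved fronts.
Whether published velocities were plane fits or local averages is not
stated; both are provided and plane-fit is the default.

## 7. Statistics

Fixed-effects OLS ANOVA (Type-II sums of squares for unbalanced two-way
layouts, interaction included) followed by Tukey HSD on the crossed
cells, annotated at p < 0.05 and p < 0.10 (both tiers reported, neither
suppressed). Batch (independent differentiation) is recorded but not
modelled as a random effect, matching fixed-effects usage; per-batch
aggregation is available upstream. Tukey adjustment applies within one
metric; no cross-metric correction. The type-I-error simulator exploits
that, for balanced layouts, "any Tukey pair flagged" is equivalent to the
studentized-range test on the extreme means; the fast vectorized path is
cross-validated decision-for-decision against `pairwise_tukeyhsd` in the
test suite. Western normalization divides per-sample signal/control
ratios by the reference-group mean ratio, making that group's mean
exactly 1 and the result invariant to global gain.

## 8. Numerical and testing notes

* Test and acceptance simulations are scaled down where resolution is
  immaterial: unit tests use a smaller tissue (1.2 × 1.2 mm base,
  0.5 × 1.5 mm neck), single-beat movies for velocity, and 40 μm/px for
  beat-frequency checks (timing is measured on the tissue-mean trace and
  is independent of pixel pitch).
* Geodesic distances use 8-connected minimum-cost paths; the test suite
  cross-checks them against an independent sparse-graph Dijkstra.
  Metrication error is negligible for axis-aligned propagation in the
  neck ROI.
* Seeded statistical tests (KS, binomial bounds) use fixed
  non-pathological seeds; hypothesis-based property tests are bounded in
  example count for runtime.
* Degenerate inputs raise typed errors (flat movies → no-beats,
  simultaneous activation → undefined velocity, zero-variance groups →
  ANOVA diagnostic, zero-mass profiles → error); QC never raises — it
  classifies with exactly one machine-readable reason.

## 9. Known limitations

* Segmentation is classical (threshold/watershed); it is tuned for the
  synthetic phantom contrast and will need parameter review on real
  stains with uneven background.
* Pixel-weighted OOP and Z-disc presence are not bias-free estimators of
  per-fibril quantities in dense crossing fields (see §5).
* The localization model assumes an (approximately) unimodal folded
  distribution; genuinely bimodal mislocalization patterns are summarized
  by their moment centre via the fallback.
* Camera pixel pitch and magnification of the mapping macroscope are
  stand-ins; all recoveries are reported in physical units so the choice
  only affects sampling density.
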