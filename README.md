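# cardiopair

Quantitative phenotyping of engineered human cardiomyocyte **cell pairs**
and **tissues** from fluorescence imaging — with a synthetic-data
generator so that every stage of the pipeline can be validated by
parameter recovery, without any external download.

## Who this is for

Groups using micropatterned substrates to study cardiomyocyte cell–cell
junction assembly (e.g. in arrhythmogenic-cardiomyopathy disease models)
and calcium optical mapping of engineered tissues. The package turns raw
multi-channel TIFFs (nuclei / sarcomeric α-actinin / junction protein /
F-actin) and paced calcium movies into the standard structural and
functional readouts of that field.

## What it computes

**Registration & QC** (`cardiopair.registration`). Rectangular 14:1 ECM
islands (211 μm × 15 μm, sized for two ~1,600 μm² cells end to end) are
detected on a plate grid; each island is screened with the cell-pair
inclusion rules: α-actinin positivity, ≥ 80% coverage of the pattern,
exactly two nuclei, and exclusion of likely binucleated single cells
(nuclei < 50 μm apart **and** long-axis filaments spanning both).
Accepted pairs are resampled to a canonical frame (long axis = x,
junction plane at x = 0, both axes normalized to [−1, 1]).

**Junction-protein localization** (`cardiopair.localization`).
Population-averaged heatmaps on the canonical grid, and per-pair
longitudinal profiles folded onto d ∈ [0, 1] (1 = junction plane). A
Gaussian-density fit yields the localization centre **μ** and spread
**σ**; junctional assembly drives μ → 1 and narrows σ, perinuclear
mislocalization lowers μ.

**Cytoskeletal order** (`cardiopair.cytoskeleton`). Tubeness-enhanced
skeletonization with structure-tensor orientations; the **orientational
order parameter**

    OOP = λ_max⟨ 2 n nᵀ − I ⟩,   n = (cos θ, sin θ)

(0 = isotropic, 1 = perfectly aligned, π-periodic angles); **Z-disc
presence** (fraction of α-actinin skeleton within 15° of the short axis);
nuclear aspect ratio and nuclear–cellular axis alignment from image
moments.

**Calcium optical mapping** (`cardiopair.calcium`). ΔF/F normalization,
beat segmentation under pacing, per-pixel activation times at 50% of the
upstroke, isochrone contours, and wavefront speed from a plane fit
t(x, y) = a + bx + cy with v = 1/‖(b, c)‖, measured in the neck of a
base-plus-neck tissue geometry.

**Statistics** (`cardiopair.stats_report`). Thin wrappers: loading-control
western normalization relative to a reference condition, one/two-way
ANOVA (Type-II SS) + Tukey HSD with p < 0.05 and p < 0.10 tiers, and
deterministic CSV/JSON export.

**Synthetic data** (`cardiopair.synthetic`). Ground-truth generators for
all of the above: cell-pair images with junctional / diffuse /
perinuclear mixtures, fibril fields of controlled angular concentration,
plate mosaics with a QC-failure taxonomy, and planar calcium waves at a
set speed with double-exponential transient kinetics.

## Worked example

```python
import numpy as np
from cardiopair.synthetic import SyntheticSpec, CalciumSpec, gen_plate, gen_calcium_movie
from cardiopair.registration import detect_islands, qc_cell_pair, to_canonical_frame
from cardiopair.localization import longitudinal_profile, fit_localization
from cardiopair.calcium import delta_f_over_f, segment_beats, activation_map, estimate_velocity

spec = SyntheticSpec(seed=7, noise_sd=0.02)          # WT-like junctional pairs
plate = gen_plate(12, 0.8, 0.7, spec, seed=7)        # 80% occupied, 70% valid
rois = detect_islands(plate.channels, spec.geometry, spec.px_size,
                      plate.layout, n_islands=12)
accepted = [r for r in rois if qc_cell_pair(r).accepted]
print(f"{len(accepted)}/{len(rois)} islands accepted as valid cell pairs")

pairs = [to_canonical_frame(r) for r in accepted]
fits = [fit_localization(longitudinal_profile(p, "junction")) for p in pairs]
print(f"junction localization: mu = {np.mean([f.mu for f in fits]):.3f}, "
      f"sigma = {np.mean([f.sigma for f in fits]):.3f}")

cs = CalciumSpec(velocity=15.4, noise_sd=0.0, n_beats=2, seed=7)
movie, truth = gen_calcium_movie(cs)
dff = delta_f_over_f(movie)
beats = segment_beats(dff)
amap = activation_map(dff, window=beats.windows[0])
est = estimate_velocity(amap, roi_mask=cs.geometry.neck_roi_mask(cs.px_size))
print(f"pacing {beats.frequency_hz:.2f} Hz; "
      f"wave speed {est.velocity_cm_s:.2f} cm/s (r^2 = {est.r_squared:.3f})")
```

Output:

```
7/12 islands accepted as valid cell pairs
junction localization: mu = 1.000, sigma = 0.047
pacing 1.00 Hz; wave speed 15.40 cm/s (r^2 = 0.995)
```

The 12-island plate contains empty islands and QC-failing configurations
by construction; the 7 accepted islands are exactly the valid pairs. The
junctional phenotype fits μ ≈ 1 (at the junction plane) with σ matching
the rendered band width (5 μm / 105.5 μm ≈ 0.047), and the optical-mapping
pipeline recovers the simulated 15.4 cm/s wave to within a fraction of a
percent.

A command-line interface mirrors the library:
`cardiopair simulate pair|plate|movie`, `cardiopair pairs`,
`cardiopair localize`, `cardiopair cytoskeleton`, `cardiopair calcium`,
`cardiopair report` (see `cardiopair --help`).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from freshly simulated data, the orientational order
parameter of perfectly aligned and isotropic fibril fields, the calcium
wave speeds recovered by the full mapping pipeline from planar waves
simulated at the group-mean velocities of healthy, diseased, and
drug-treated engineered tissues, and the measured beat frequency under
1 Hz pacing, writing one JSON entry per quantity.

## Layout

```
src/cardiopair/
  geometry.py       pattern, plate-grid, and tissue geometries
  synthetic/        ground-truth generators (images, plates, movies)
  registration.py   island detection, cell-pair QC, canonical frame
  localization.py   heatmaps, folded profiles, mu/sigma fits
  cytoskeleton.py   skeletonization, OOP, Z-disc presence, nuclei
  calcium.py        dF/F, beats, activation maps, isochrones, velocity
  stats_report.py   ANOVA + Tukey, western normalization, exports
  io.py, cli.py     TIFF/JSON/YAML round trips; typer CLI
docs/methods.md     model and algorithm notes, parameter choices, limits
```
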