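# Methods

## Dose model

Dose rates follow the TG-43U1 line-source formalism. The geometry function
is computed exactly, `G_L(r,θ) = β/(L·r·sinθ)` with `β` the angle the
active line subtends at the point, falling back to `1/(r² − L²/4)` on the
source long axis; the two branches agree continuously (checked against a
brute-force line-integration oracle to < 1e-5 relative). Radial dose
function `g(r)` is interpolated linearly in `r` and clamped to the table
ends outside its range; the anisotropy function `F(r,θ)` bilinearly with
edge clamping. Linear-vs-log-linear radial interpolation differs far below
the ~1% scale of the source-model effects this package studies, so the
simpler monotone rule is used. Source strength decays as
`S_K(t) = S_K(0)·2^(−Δt/T½)` with `T½ = 73.83 d` (Ir-192).

Points closer than 0.5 mm to an active source segment are flagged rather
than excluded: the kernel is finite off the segment, and the flag lets a
caller reproduce a validation-style exclusion when wanted.

The hot loop (points × dwells) is a numba-compiled kernel; a plain
numpy/scipy composition of the same factors serves as the reference path
in the tests (agreement to ~1e-15 relative).

### Packaged source tables

The three shipped source descriptions (mHDR-v2 / v2r / v2c style) are
**schematic**: coarse grids that satisfy the normalization identities
(g(1 cm) = 1, F(r, 90°) = 1, θ covering 0–180°) and differ from each
other by < 1% everywhere, mirroring how close the published revisions of
this source's dosimetry are. They are *not* the published consensus data;
the plain-text source format accepts full tables when the user supplies
them. Consequences: absolute doses are illustrative, but every quantity
the package reports is a ratio or a within-model difference, which the
schematic tables support.

## Organ reconstruction

An organ is a z-sorted stack of simple polygons (normalized
counter-clockwise) at 3.3 mm slice spacing. Reconstruction settings:

* **Interpolation on** inserts one midway contour per consecutive pair
  (no recursion): both signed Euclidean distance fields are sampled on a
  shared grid (default spacing 0.82 mm, ≥ 2 cells of margin), averaged,
  and the zero level set extracted by marching squares with linear edge
  interpolation. Saddle cells are resolved by the cell-corner average
  (scikit-image's rule). If several closed components arise, the
  largest-area one is kept — the organs modeled here are simply
  connected; branching organs are a documented limitation. An everywhere-
  negative averaged field means the mid-slab vanishes and contributes
  zero volume.
* **Slabs**: each contour (original or midway) fills the half-open
  interval reaching to the z-midpoints toward its neighbours —
  half-open `[z_low, z_high)` so no point is ever double-counted.
  With `outer_slab="full"` the outermost contours extend half the slice
  thickness beyond their planes; with `"partial"` the organ stops at the
  outermost contour planes. A single-contour organ under partial slabs is
  degenerate (zero volume) and warns.
* **Intersection policy** maps a host organ to organs subtracted from it
  (urethra from prostate and bladder in the "exclude" setting). The
  subtracted organ's own slab model, built with the same interpolation
  and outer-slab settings, defines the excluded region; volumes subtract
  the slab-wise polygon-intersection volume exactly (shapely).
* Boundary points count as organ members (points may lie on the surface).
* The 0.3 mm inter-slice imaging gap is not modeled; slices tile z
  contiguously at the slice thickness.

The exact Euclidean signed distance is used for interpolation (the
chamfer-distance approximation some TPS implementations use is a nearby
but different operator; exactness was preferred here).

## Point sampling and index computation

Dose-calculation points are rejection-sampled uniformly in the host
organ's bounding box until the target count of members is reached
(10⁹-draw safety budget). The generator is the Mersenne Twister 19937;
each organ draws from a substream seeded by (seed, CRC32 of the organ
name) so adding an organ never perturbs another organ's points. Two
modes: fixed count per organ, or fixed count per cm³ with
`n = max(1, round(density · volume))`, the volume taken under the active
settings (including exclusion).

Indices use no histogram: Vx% counts points at or above the threshold
(ties count as "at least"); Dxcm³ returns the dose at 1-based rank
`ceil(n·x/V)` of the descending sort — with 1,000 points in a 2.01 cm³
organ, D0.1cm³ is point 50. The ceiling rule is the conservative choice
consistent with that worked rank; the rank volume `V` is the organ volume
under the active setting. D90% (a relative-volume dose index) uses rank
`ceil(0.9·n)`. Dose indices are reported both in Gy and in % of the
planning-aim dose (13 Gy); volume indices in % of organ volume.

## Replicates, factor grid and statistics

The baseline setting is: mHDR-v2 tables, interpolation on, urethra
included in prostate and bladder, partial outer slabs. The factor grid is
the 2×2×2 cross of (interpolation, intersection, outer slab) — baseline
appears exactly once — plus two source swaps at baseline geometry.
Convergence studies double the point count (1,000 → 256,000 per organ;
10 → 2,560 per cm³ for OARs) and summarize each index over replicate
seeds (default 1..100, recorded in output) as mean, SD and CI width
2·1.96·SD, averaged arithmetically over patients. Sensitivity runs fix
256,000 points per target and 2,560 per cm³ per OAR, one sampling seed,
and report per-patient deltas against baseline with boxplot summaries
(median, quartiles, min/max whiskers); non-evaluable indices (e.g. D2cm³
of an organ smaller than 2 cm³) propagate as missing with a count.

Paired comparisons use a classical paired t test (two-sided, 95% CI of
the mean difference) when the differences look normal, otherwise the
exact binomial sign test with ties dropped; significance threshold 0.01.
Zero-variance input is returned as a degenerate-test signal rather than
NaN. Q-Q quantile pairs and five-number summaries are emitted as plot
data; the normality "advisory" flag (|skew| > 1) is explicitly a
heuristic, not a decision.

## Synthetic patients

The generator emulates the *structure* the analysis is sensitive to, not
anatomy:

* organs are superellipsoids (exponent 2.5 for the prostate) with smooth
  low-harmonic radial perturbations, sliced at 3.3 mm with a random grid
  offset; target volumes are drawn uniformly inside clinical ranges
  (prostate 20–60, bladder 60–180, rectum 35–80, vesicles 1.5–6 cm³) that
  keep reconstructed volumes inside the reported clinical min–max even
  after perturbation and slicing;
* the bladder is an ellipsoidal dome truncated at its base plane 5 mm
  above the prostate, so its most caudal contour is large and closest to
  the implant — the caudal-hotspot scenario (`caudal_bladder_hotspot`
  off gives a full ellipsoid with a small caudal cap instead);
* seminal vesicles get 2–4 near-constant-area contours starting one slice
  below the cranial prostate slice: the base is hot, the stack runs out
  of the high-dose region cranially, which is what makes V80% sensitive
  to the outer-slab mode;
* the urethra is a 6.5 mm tube through the prostate into the bladder
  (delineated-as-catheter convention, so urethra∩bladder overlap exists);
* 14–20 catheters sit on two rings (0.75/0.42 of the mid-gland radius,
  ≥ 9 mm from the urethra axis) with 2 mm dwell steps over the prostate
  ± 3 mm, giving 250–668 activated dwells across the volume range; dwell
  times carry an urethra-sparing taper (clip((d−6)/13, 0.15, 1) with d
  the distance to the urethra axis in mm) and are globally scaled so
  baseline D90% prostate = 13 Gy (32,000 points, per-patient fixed seed).
  A thinning helper keeps every k-th dwell (~50 for desk-scale replicate
  studies) and re-applies the D90 scaling.

Everything is deterministic in (config, seed); per-patient streams derive
from SeedSequence(seed, patient index).

What the phantoms do *not* capture: true anatomy and inter-patient shape
correlations, inverse-optimized dwell times, delineation variability, and
patient-specific hotspot geometry. Passing direction-of-effect checks on
these phantoms therefore demonstrates that the pipeline detects the
mechanisms (caudal bladder hotspot vs outer slab, few-contour vesicles,
urethra sparing vs exclusion), not that clinical effect sizes are
reproduced.

## Problem sizes in the shipped tests and acceptance script

The test suite exercises the study design at reduced scale — 3 phantom
patients, plans thinned to ~50–120 dwells, 8–40 replicate seeds,
≤ 256,000 points — chosen so the full suite runs in about a minute while
every bound it asserts (binomial CI widths, 3σ uniformity, χ² variance
consistency, direction medians) is computed at its stated tolerance. The
acceptance script uses 30 replicate seeds at the full 256,000-point
budget. Replicate seed lists always start at the user-supplied seed.

## Numerical choices and edge cases

* Slab intervals half-open; slab lookup by binary search on lower edges.
* Marching-squares paths that touch the grid frame are discarded (the
  ≥ 2-cell margin makes the level set closed in practice).
* Contours are implicitly closed; a repeated closing vertex is dropped;
  mixed orientations normalized to CCW before signing distances.
* `dose_index` rank is clamped to n (x = V returns the minimum dose).
* Rejection sampling raises after 10⁹ raw draws (degenerate organ).
* Polygonized circles (64–128-gon) bias areas by < 0.2%, below every
  volume tolerance asserted.
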