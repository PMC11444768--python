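# Methods

This note documents the models, parameter choices and numerical decisions in
`gelsense`, and what the synthetic-data experiments do and do not establish
about real data.

## The measurement being modelled

Cells seeded on bead-labelled PAAm hydrogels are imaged in time lapse (one
fluorescence frame per 5 min over 24 h at 10× magnification).  Bead motion
is tracked by digital image correlation on a 10 × 8 grid of cells (99
nodes); displacement increments between frames one hour apart are
accumulated per node; the 90th percentile of the cumulative displacement
across nodes summarises each hourly time point, with SD taken across
replicate gels; and the mean of the hourly p90 over an 8–24 h window gives
one number per condition.  This package implements that chain and, because
no raw videos are publicly deposited, exercises it on synthetic imagery
whose true displacement field is known exactly.

## Synthetic imagery (`synthgel`)

**Scene.** Single-channel frames, default 512 × 512 px at 0.65 µm/px (a
plausible camera/10× combination; the true pixel pitch is instrument
specific, so it is explicit everywhere).  Frame count is
`floor(duration·60/cadence) + 1` with defaults 24 h / 5 min (289 frames).
Beads are uniform sub-pixel points rendered as Gaussian spots of
σ = 1.2 px ≈ 0.8 µm — the diffraction width of a 10×/0.3 objective combined
with the 0.5 µm bead diameter.  The default of 10 000 beads per 512² field
is a deliberately thinned surrogate of the real 1 % v/v loading (which
implies ≳1 bead/µm² within a widefield depth of focus, i.e. unresolvably
dense speckle); 10 000 keeps ≈30 beads per 31 px correlation template while
remaining cheap to render.  Camera noise is additive Gaussian after spot
rendering (σ default 100 counts against a spot peak of 1000, i.e. peak SNR
10), quantized to 16 bits.  Poisson shot noise, photobleaching, stage drift,
out-of-plane motion and wrinkle morphology are *not* modelled.

**Traction surrogate.** Each cell contracts the surface radially toward its
centre:

    u(x, t) = − s · (1 − e^{−t/τ}) · (r/σ_c) · e^{−r²/(2σ_c²)} · r̂ ,   r = |x − c|.

The spatial profile is the simplest smooth field that is zero at the cell
centre, maximal at r = σ_c, integrable, and produces the inward-arrow
pattern seen around contracting cells; the exponential ramp makes
displacements grow monotonically and saturate.  Defaults: τ = 8 h (plateau
within the analysis day); σ_c = 100 µm and a per-cell plateau amplitude of
30 µm at the 1000 cells/cm² reference condition, calibrated once so that the
synthetic low-density arm lands at the tens-of-µm p90 scale the real
experiments report — elastic half-spaces couple cells over hundreds of
micrometres, which a shorter reach cannot emulate.  Superposition is linear.

**Density and the traction budget.** Density scenarios Poisson-place cells
over the field of view (seeded; truncated below at one cell) and divide the
*total* traction budget among them: per-cell strength scales as
1000/density.  This encodes the tug-of-war saturation between neighbouring
cells that the density experiments invoke.  It matters because plain
superposition of equal-strength Poisson-placed contraction fields would
*increase* the p90 with density (shot-noise variance grows linearly in the
number of sources); the observed decline is a biological saturation, not a
geometric cancellation, and the generator represents it as such.

**Thickness attenuation.** With `attenuation_mode="mechanics"`, all
displacement amplitudes are multiplied by `k_∞/k(h)` from the layer model
below — same tractions, stiffer-feeling gel, smaller displacements.

**Ground truth.** Bead displacement is the field evaluated at each bead's
t = 0 position (small-displacement Lagrangian approximation; peak synthetic
displacements of tens of µm over a 100 µm-scale field make the secondary
correction a few percent, well below tracker noise).  The recorded ground
truth is the exact field at the tracking-grid nodes, to machine precision.

**Confocal z-profiles.** A slab of thickness T starting at z = 5 µm,
error-function edges (σ default 2 µm), sampled every 2 or 10 µm with
additive noise.  The 5 µm offset keeps the sampling grid off-phase with the
slab edges, as in real stacks.

## Tracking (`dic_tracker`)

Per node: a 31 × 31 px template from the earlier frame is matched against
the later frame by zero-normalized cross-correlation over integer offsets in
[−6, 6]² (`skimage.feature.match_template`).  Ties at the peak break toward
the smallest offset, then lexicographically.  Sub-pixel refinement fits a
2-D quadratic by least squares over the 9 px peak neighbourhood, clipped
*symmetrically* at the search bounds — an asymmetric sample of the peak
biases the vertex.  The fit is performed on log-correlation weighted by
correlation squared: the speckle correlation peak is near-Gaussian, for
which the log-space fit is exact, whereas a raw-value quadratic over a 9 px
window systematically shrinks the sub-pixel fraction (we measured recovery
gains of 0.8–0.96 and uniform-shift RMSE of ≈0.3 px).  If the fitted surface
is not concave the estimate falls back to an intensity-weighted centroid
(flag `fallback`).

Validation and smoothing: a peak correlation below 0.2 (`min_corr`) marks a
speckle mismatch, and a normalized-median test (threshold 2.5 over the 8
nearest contributing neighbours, regularised by 0.1 px) rejects vectors
inconsistent with their neighbourhood — both are flagged `low_corr` and
replaced by the smoothed neighbour estimate.  Valid vectors are blended with
the Gaussian-weighted (σ = 25 px) average of their neighbours' raw vectors
as `û = (u_raw + 5·ũ)/6`; smoothness 0 disables this exactly.  Peaks on the
search border are flagged `clamped`.

Sequences track consecutive hourly pairs; in the default Lagrangian mode
each node's anchor advances by the measured displacement, following the
material point, and nodes whose window would leave the frame are frozen and
flagged.  An Eulerian mode (fixed anchors) is available.  Microns are always
pixels × pixel size.  Coordinates: origin at the top-left pixel centre,
x rightward (columns), y downward (rows).

Measured performance on the synthetic conditions (seeded): uniform sub-pixel
shift (3.30, −2.10) px at 800 beads/SNR 10 — RMSE ≈ 0.1 px across the 99
nodes; single-cell contraction — pooled interval RMSE ≈ 8–9 % of the largest
interval displacement; static scenes — noise floor ≈ 0.06 px per interval.
Accuracy degrades monotonically as SNR drops through {30, 10, 3}.

## Statistics (`cumdisp`)

Hourly pairs are chained: (0,12), (12,24), … at 5-min cadence (the interval
must be a whole number of frames).  Cumulative displacement per node is the
*path length* Σ|Δu| by default — nondecreasing in time even under
oscillatory motion, and equal to the net displacement |ΣΔu| when increments
are collinear; net mode is retained for sensitivity analysis and is
dominated by path mode pointwise (triangle inequality).  Percentiles use
linear interpolation between order statistics (the common software default;
an independent brute-force oracle agrees to 1e-15).  The p90 at each time
point pools all nodes of all replicates; the error bar is the sample SD
(n−1) across per-replicate p90s, with the across-node SD also emitted.
Window averages are unweighted means over hourly points with
`window_start ≤ t ≤ window_end`, default [8, 24] h inclusive (the plateau
region; figure-replication configs may set the last-11 h or last-12 h
windows explicitly).

## Layer mechanics (`layer_mechanics`)

The model: a rigid circular patch of radius `a` (default 25 µm, the order of
measured cell spread radii) on a linear-elastic layer (E, ν, thickness h)
perfectly bonded to a rigid base, optionally surrounded by a rigid outer
wall at `R_lateral` (the crowding surrogate).  Two loadings: *normal*
(frictionless flat punch, harmonic n = 0) and *tangential* (rigid in-plane
translation with zero normal traction, Fourier harmonic n = 1 with the axis
constraints w = 0, v = −u).  Stiffness is twice the strain energy of the
unit-displacement solution.

Discretisation: bilinear quadrilaterals on a tensor-product mesh graded
toward the contact edge (20 elements across the patch, geometric growth
1.25), with selective reduced integration (single-point quadrature on the
dilatational term) so ν → 0.5 does not lock; ν = 0.5 inputs are capped at
0.499 with a warning.  An unbounded layer is truncated traction-free at
`20a + 2h` — the thickness term matters because a net tangential load on a
domain with R < h bends like a cantilever column and fakes compliance.
Every reported value is recomputed on a nested mesh doubling; drift above
2 % raises an error.  Against the closed forms at h/a = 50 the solver is
within 2.5 % (normal) and 1.1 % (tangential); k is proportional to E, the
attenuation ratio independent of E, and k decreases strictly with h and
with R_lateral on the tested grids.

Default gel parameters: E = 5.5 kPa (soft-gel modulus measured for thick
samples), ν = 0.48 (PAAm is nearly incompressible; literature values
0.45–0.5).  The *normal* mode is the default for displacement attenuation:
with a near-incompressible bonded layer it reproduces the sharp thin-gel
stiffening the experiments imply (k(50 µm)/k(200 µm) ≈ 1.6 for a = 25 µm,
matching the ≈2× thick/thin displacement contrast), whereas the Mindlin
tangential mode stiffens appreciably only for h ≪ a.  The original
supplementary model's exact formulation is not available; this solver is
validated against the classical limits and claims only the qualitative
predictions.

## Thickness estimation (`thickness_profile`)

Baseline = median of the lowest decile of samples (tolerates
autofluorescence offsets); intensity normalised to [baseline, max]; the slab
is the single contiguous run above the threshold fraction (default 0.5),
with single-sample spikes ignored and multiple runs rejected explicitly;
thickness is the distance between the linearly interpolated first-up and
last-down crossings.  On noiseless error-function-edged slabs the estimate
is exact to ≪0.1 µm (the erf inflection sits at the crossing); at SNR 20 the
max-based normalisation biases the estimate by ≈−0.5 µm at a 2 µm step —
within half a z-step across the 27–597 µm range of gel thicknesses tested.

## Built-in scenarios and problem sizes

All built-in scenarios render one frame per hour for 24 h: the hourly-pair
analysis never reads the intermediate 5-min frames, so rendering them would
only add I/O.  Thick/thin arms use 512² fields with three fixed cells
(s = 16 µm) and differ only in h (200 vs 50 µm); density and timecourse arms
use 1024² fields (0.44 mm²) so that seeding densities of 1000–60 000
cells/cm² yield sensible cell counts (≈4–266), with the fixed traction
budget described above; `static` has no cells and measures the noise floor.
Acceptance runs use three replicates per arm (matching the triplicate
design) and complete in a few minutes on one CPU.

## What passing tests do and do not show

The synthetic experiments verify the *pipeline*: that the tracker recovers
known fields to sub-pixel accuracy, that the statistics implement their
definitions exactly, that the mechanics solver matches classical limits,
and that the qualitative orderings (thick > thin; low density > high
density; deformations declining as cultures densify) follow from the
modelled mechanisms.  They do not validate the traction surrogate against
real cells: the spatial profile, ramp, reach and budget scaling are
idealisations, real speckle contains aggregates and wrinkle artefacts the
generator omits, and absolute synthetic magnitudes match the real
experiments only to order of magnitude.  Equivalence with the original
MATLAB tracker is not claimed — parameter names follow its published
settings, but the sub-pixel estimator, validation and smoothing semantics
are this package's own, documented above.

## Known limitations

Purely 2-D surface tracking (no out-of-plane motion); linear small-strain
elasticity (no viscoelasticity, poroelasticity or large-strain effects);
additive Gaussian noise only; the tangential solver assumes a single
Fourier harmonic (exact for the axisymmetric geometry, but only the two
idealised loadings are provided); no wrinkle rendering or bead clumping,
although bead aggregation in wrinkles is a documented confound in the real
images.
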