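# Methods

## Lamella geometry and in-silico straightening

A cryo-FIB lamella is modelled per tomogram as a flat slab of constant
local thickness, tilted relative to the tomogram frame. The reference
plane `z(x, y) = a·x + b·y + c` is fitted by ordinary least squares
through *all* template-match coordinates of the tomogram — including
false positives — because the matches populate the slab roughly uniformly
and the unclassified set gives the densest support for the surfaces. No
outlier rejection is applied by default; an iteratively reweighted Huber
fit is available (`robust=True`) for tomograms with pathological match
distributions. The fit requires at least three points with non-collinear
(x, y) support and raises a degenerate-geometry error naming the tomogram
otherwise.

Subtracting the plane from each particle's Z ("flattening") centers the
slab around z = 0. Surfaces are then located on the flattened-Z histogram,
converted to nm via the per-tomogram pixel size (nm is the canonical unit
for all derived quantities; voxel coordinates are only an I/O format).
Histogram bins are `bin_width_nm` wide (default 5 nm, matching the 5-nm
granularity of the depth analysis and the size scale of a ribosome) and
anchored at integer multiples of the bin width, making the estimate
deterministic. The plateau level is the median count over occupied
interior bins (outermost occupied bins excluded, since they are partially
filled); scanning outward from the bin containing the median, the surface
is the outer edge of the last contiguous bin whose count is at least
`dropoff_fraction` (default 0.5) times the plateau. "Half the plateau"
operationalizes the sharp drop-off of particle counts at the slab
boundary: for a uniform slab the boundary bin is on average half filled,
so the rule bisects the true edge to within one bin. At least 100
particles (`min_support`) are required; fewer raise an
insufficient-support error rather than returning an unreliable surface.

Depth is `min(z_flat − z_bottom, z_top − z_flat)`, with no distinction
between top and bottom surface. Particles outside the estimated slab are
retained with negative depth and an `in_slab=False` flag rather than
dropped, so surface-estimation errors remain visible downstream.

Degenerate inputs: a histogram whose central bin already falls below the
threshold (e.g. a bimodal Z distribution) raises a degenerate-histogram
error; surfaces are never extrapolated.

## Stratification and selection rules

*Equal-count groups* are contiguous blocks of the stable-sorted key;
when the count is not divisible by k the extra particles go to the
lowest-key groups, so sizes differ by at most one. Reported boundaries
are the realized min/max of the key per group — with duplicated key values
adjacent groups can share a boundary value.

*Depth bins* take, for each center, the `per_center_n` particles with the
smallest |depth − center| (stable ties). Groups may overlap across
centers when few particles lie near the surface; the overlap fraction
with the previous center is reported.

*High-quality filter*: strict inequalities (thickness < 180 nm, depth
> 30 nm), so records exactly at a cutoff are excluded. The filter is
idempotent and monotone in its thresholds.

*Random subsets* are nested: one seeded permutation defines all subset
sizes, each smaller subset contained in the next (sequential reduction).
Each subset's thickness distribution is compared against the full table
by a two-sample Kolmogorov-Smirnov test; p < 0.01 logs a bias warning
but does not fail the run, since a biased draw is a property of the data
to be inspected, not an error of the procedure.

*Tomogram-level selection* adds whole tomograms in seeded random order
until the particle target is reached, then randomly trims the last
tomogram to hit the target exactly.

## FSC and Rosenthal-Henderson analysis

FSC uses shells one Fourier voxel wide with the frequency assigned at the
shell center, the real part of the cross-spectrum normalized by the
per-shell power product, after voxelwise multiplication by an optional
[0, 1] mask. No mask correction (phase randomization) or weighting is
applied: the module targets validation on synthetic half-maps, not map
deposition. Threshold crossings (0.143 default, 0.5 optional) are
linearly interpolated between the bracketing shells; a curve that never
crosses reports the Nyquist resolution with an explicit flag.

The B-factor fit regresses 1/d² on ln N. Points saturated at the Nyquist
ceiling (resolution within 5% of the Nyquist limit, roughly one shell at
the box sizes used here) are excluded from the default fit range, because
the band limit, not the particle statistics, sets their resolution. A
non-positive slope raises a no-valid-fit error instead of returning a
meaningless negative B — resolution series produced by multi-particle
refinement can lack a linear regime entirely, and the module flags rather
than forces a fit.

## Damage-layer estimation

The qualitative observation that normalized CC scores "level off" beyond
the damage layer is made explicit as a hinge regression:
`cc(d) = c_surface + (c_plateau − c_surface)·min(d, d_b)/d_b`. For fixed
d_b the model is linear, so the two linear parameters have closed-form
least-squares solutions; d_b is scanned on a grid (default 1-nm steps
over 5–80 nm, matching the reporting precision of the damage depth) and
the SSE-minimizing triple returned. Grid scanning is preferred over
gradient methods because the objective is only piecewise smooth in d_b.
Uncertainty comes from a seeded case-resampling bootstrap (default 200
resamples, percentile 2.5/97.5 interval). A flat profile is detected by
an F-like statistic comparing the hinge fit against a constant fit
(2 extra parameters; threshold 10, configurable — the level-off criterion
has no canonical value and the threshold is deliberately exposed); when
the hinge does not help, a no-damage flag is returned with d_b at the
grid minimum rather than a spurious breakpoint.

CC normalization divides by the per-tomogram maximum, so `cc_norm` is
invariant under per-tomogram positive rescaling and exactly one particle
per tomogram scores 1.

## Tilt schemes and exposure weighting

Dose-symmetric schemes start at the lamella pretilt and alternate sides
in blocks of `group` consecutive increments, positive branch first by
default (the branch order is not fixed by the scheme definition and is a
flag). The angle set `{pretilt + k·step}` is independent of the grouping;
only acquisition order — and therefore cumulative dose per angle —
changes. Defaults (pretilt +8°, step 2°, group 2, span ±60°) give the
61-projection scheme used for acquisition; the per-tilt dose is inferred
as total/61 from the ~120 e⁻/Å² target, since only the total is
specified. Exposure weights use the critical-exposure model
`Ne(k) = 0.245·k^(−1.665) + 2.81` (the published constants of the
critical-exposure dose-filtering method, configurable), with the weight
`exp(−D/(2Ne))` composing multiplicatively over accumulated dose.

## Synthetic data: what it emulates and what it does not

The particle generator places uniform particles inside a tilted slab
whose thickness grows linearly front to back. Defaults emulate the study
conditions: 12 tomograms spanning 43–255 nm local thickness (front
thickness 43 nm, wedge slope 0.0106 nm/nm over a 20-µm lamella), a ~5°
slab tilt in the tomogram frame, reconstruction pixel size 4.9 Å, and
~1700 particles per tomogram (Poisson), giving tertile sizes of a few
thousand at desk scale. CC scores follow either the ramp (hinge) model —
defaults c_surface 0.6, c_plateau 0.95, break 30 nm, noise sd 0.05 — or
an exponential-recovery model, so the breakpoint estimator is tested both
under its own functional form and under misspecification.

Half-map pairs are built directly in the Fourier-shell SNR domain: a
band-limited random structure plus independent unit noise, scaled so the
per-shell SNR is `scale·N·exp(−B·k²/2)`, whence the expected FSC is
SNR/(1+SNR). There is no image-formation physics — no CTF, no missing
wedge, no projection alignment — so passing tests demonstrate the
correctness of the FSC/B-factor machinery, not robustness to
reconstruction artifacts in real maps. Likewise the slab generator has no
false-positive matches outside the lamella and no density gradient near
the surfaces, so surface estimation on real template matches can behave
worse than the tests indicate.

The simulated resolution-versus-N series in the demo uses box 48, pixel
3 Å, B = 500 Å² and SNR scale 4·10⁻³, chosen so that resolutions for
N = 250–16000 fall between ~11.5 Å and the 6-Å Nyquist limit — a series
shape comparable to binned STA data, at seconds of CPU.

## Problem sizes and determinism

Test and demo problem sizes (≤64³ volumes, ≤20k particles per scenario,
200 bootstrap resamples) keep the full suite and the demo within seconds
on one CPU while leaving Monte-Carlo tolerances comfortably resolvable.
All stochastic stages take explicit seeds or `numpy.random.Generator`
instances; generator outputs are bit-reproducible for a fixed scenario
and seed, and every pipeline output file records the seed and a config
hash in its header.

## Known limitations

- The slab model assumes one flat lamella per tomogram; strongly bent
  lamellae violate the plane fit and inflate apparent thickness.
- Surface localization is bin-quantized; with 5-nm bins the thickness
  estimate is accurate to ~2 bins, and the ~1-nm positive bias of the
  demo's damage depth traces to this quantization propagating into
  depths.
- FSC is computed without mask correction, so masked FSC values on real
  maps will be slightly optimistic compared to corrected pipelines.
- The F-like flatness threshold for the damage fit is a free parameter;
  profiles with very shallow damage contrast near the threshold can flip
  between "detected" and "flat".
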