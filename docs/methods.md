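# Methods

`vascage` re-implements, as a tested library, the quantitative core of a
cerebrovascular-aging analysis: structural morphometry over 3D vascular
networks and the analysis of awake-mouse hemodynamic recordings.  Everything
is exercised end to end on synthetic data with known ground truth; this note
describes the models, the defaults and why they were chosen, and what the
synthetic validation does and does not establish about real data.

## Vessel graphs and structural metrics

The central container is a spatial graph of vessel centerlines: nodes are
branch points and endpoints (positions in µm), edges carry ordered centerline
polylines with a per-point radius.  All structural quantities are defined on
this graph within the regions of an integer label atlas:

- **Length density** (m/mm³): summed polyline segment lengths whose midpoints
  fall in the region, divided by region volume.  Midpoint assignment makes the
  measure additive over any partition of space (tested to 1e-9 relative).
- **Branching density** (1/mm³): nodes of degree ≥ 3 in the region per volume.
- **Mean radius** (µm): length-weighted mean of per-point radii.  Length
  weighting makes the average invariant to how densely a polyline is
  resampled, which an unweighted per-point mean is not.
- **Arc-chord ratio** (tortuosity): centerline path length divided by the
  endpoint-to-endpoint distance; 1 for straight vessels.  Closed loops have
  no defined ratio and raise an error.
- **Nearest-vessel distance** (µm): on a 10 µm isotropic probe grid, the
  minimum straight-line distance from each extravascular probe to the vessel
  surface, with candidates restricted to the ±100 µm Cartesian cube around
  the probe.  The vessel surface is the set of foreground voxels with at
  least one background 6-neighbor (or, in graph mode, the centerline offset
  by the local radius).  Probes inside the lumen are excluded — intravascular
  distance is not a perfusion metric.  A probe whose cube contains no vessel
  is censored at the cube half-width and flagged rather than silently
  dropped; the KD-tree search is exact (a Euclidean neighbor within the cube
  half-width is automatically inside the cube, and the corner region is
  searched explicitly otherwise).
- **Pericyte density** (1/mm³) and **coverage** (cells per mm of vessel):
  point counts per region volume and per vessel length.  With both measured
  in the same region, coverage reduces to count divided by vessel length in
  mm (100 cells on 1 mm of vessel is 100 cells/mm).

Layer profiles aggregate any per-region metric over cortical-layer tags with
region-volume weights, which for density-like metrics equals pooling the
underlying counts and lengths.

## Vessel tracing

`trace_volume` converts an intensity or binary volume into a vessel graph:
threshold binarization (fixed value or Otsu), topology-preserving 3D thinning
(scikit-image's implementation of Lee's algorithm), and conversion of the
one-voxel skeleton to a graph.  Numerical choices that matter:

- **Isotropy**: thinning assumes isotropic voxels.  Anisotropic stacks (e.g.
  1×1×5 µm serial tomography) must be linearly resampled to 1 µm first;
  the pipeline refuses to continue otherwise rather than silently producing
  a biased skeleton.
- **Length debiasing**: the polygon through raw skeleton voxel centers
  zigzags and overestimates the arc length of a digitized straight line by up
  to ~10%.  Chain interior points are smoothed with a 5-voxel moving average
  (endpoints pinned) before lengths are measured; residual bias on phantoms
  is ~2–4% (under the 5% acceptance tolerance).
- **Junction consolidation**: thinning a thick Y-junction can leave a small
  triangle or chain of junction voxels where the tubes overlap.  Junction
  nodes closer than 10 µm (Euclidean) along a connecting edge are contracted
  into one node; without this the branch count inflates on thick-vessel
  phantoms.
- **Pruning**: terminal spurs shorter than 5 µm and connected components
  totalling under 10 µm are removed; degree-2 nodes left behind are absorbed
  by joining their edges.  The more elaborate artifact reconnection used by
  full-scale tracing pipelines is out of scope; these two rules are this
  repository's choices, not claims about any published pipeline.
- **Radii**: per-point radius is the distance from the skeleton voxel center
  to the nearest background voxel, found by searching offset shells of
  increasing physical distance.  This costs O(radius³) per centerline voxel
  rather than a full-volume distance transform, which at (1 mm)³ and 1 µm
  would need tens of gigabytes.  Radius estimates on phantoms are biased low
  by roughly half a voxel (discretization), well inside the 15% tolerance.
- A perfectly voxel-grid-symmetric cylinder has its medial axis between
  voxels and can thin away entirely; generic (off-grid) geometry, which all
  generated phantoms have, is unaffected.

## Synthetic vascular networks

The generator grows a seeded forest of branching random walks until a target
total centerline length is reached.  It is a phenomenological model chosen to
make every downstream observable controllable — it does not model
angiogenesis, flow, or real branching-angle statistics (the literature the
package draws on does not publish radius or branch-angle distributions, so
the defaults here are repository choices, not anatomical claims).

Knobs and defaults:

- `target_length_density` (default 0.4 m/mm³, the order of whole-brain mouse
  values); growth stops within one 5 µm step of the implied length budget.
- `branch_rate` (default 3 branch points per mm): per-step fork probability,
  with forks suppressed within 25 µm of the previous fork so junctions stay
  resolvable at typical capillary radii.
- `radius_law`: branch order ↦ lognormal radius (default mean 3.5 µm at
  order 0, ×0.9 per order, σ = 0.08) — the capillary range.
- `tortuosity_amp`: per-step Gaussian heading jitter (40° × amp); 0 gives
  exactly straight segments, and mean arc-chord ratio increases strictly
  with the amplitude.
- `min_separation_um` (default off): a spatial-hash clearance constraint that
  terminates a branch before it approaches an unrelated vessel.  Phantoms
  used for round-trip validation set it to ~2 vessel diameters so that every
  ledger junction is unambiguously recoverable by tracing; forks look three
  steps ahead and are suppressed at dead ends, and terminal stubs shorter
  than 3 steps are retracted before the ledger is computed (a stub shorter
  than the tube radius is invisible to thinning).

Every generated object ships with a ground-truth ledger whose entries are
recomputable from the object by direct enumeration; tests enforce this.

Pericytes are placed by a Poisson process along the network (rate × vessel
length per subtype), displaced uniformly within the local vessel radius.

## Hemodynamics

Locomotion, hemodynamic forward model and HRF estimation follow the standard
linear-time-invariant treatment of neurovascular coupling:

- **Event detection**: treadmill velocity is zero-phase low-pass filtered
  (Butterworth, 10 Hz, 5th order), differentiated by central differences,
  and binarized at |a| ≥ 3 cm/s².  Runs separated by gaps under 0.5 s are
  merged (acceleration crosses zero repeatedly within a bout); the merge gap
  and the threshold are exposed parameters.  Zero-phase filtering avoids
  shifting onsets, which matters because onset alignment is the reference
  for every triggered analysis downstream.
- **Synthetic sessions**: bouts are linear velocity ramps into a plateau
  carrying a 3 Hz, 1.5 cm/s stride oscillation (a constant plateau would
  read as rest under the acceleration rule — running mice are not constant-
  velocity), plus optional Gaussian noise.  Noiseless detection recovers the
  programmed intervals within 2 samples.
- **Resting periods**: from 4 s after each bout offset to the next onset,
  kept if ≥ 60 s; the session start counts as an offset at t = 0.
- **Deconvolution**: the kernel solves min‖LH − V‖₂ where L has an all-ones
  intercept column and the binarized event vector shifted by lags 1…k
  (default k = 10 s × fs, covering evoked responses with margin).  The
  pseudo-inverse is used rather than the literal normal-equation inverse:
  identical when L has full column rank, still defined when it does not.
  L is built with one row per observed sample; the forward generator uses
  the same convention, and noiseless recovery is exact to 1e-12.
- **Gamma-variate kernel**: A(t/T)^α e^{−(t−T)/β} with α = (T/W)²·8 ln 2 and
  β = W²/(T·8 ln 2), so the kernel peaks at exactly A at time T; α·β = T is
  an algebraic identity used as a test invariant.  Fitting is Nelder–Mead on
  the sum of squared errors with T and W in log space, moment-based starts
  (peak value, peak time, half-max width), 5 jittered restarts under a fixed
  seed, and 1e-10/1e-12 simplex tolerances.  Response metrics (amplitude,
  time to peak, FWHM) are read off the fitted kernel on a 1 ms grid with
  linear interpolation of the half-maximum crossings.
- **Oxygenation regression**: per-event means of ΔHbT and ΔHbO−ΔHbR over a
  2–5 s post-onset window, fit by ordinary least squares; at least two events
  are required.

The forward generator drives ΔHbO as a scaled copy of the ΔHbT response
(gain 1.5 by default, so ΔHbR goes negative during hyperemia) and defines
ΔHbR = ΔHbT − ΔHbO, keeping the identity exact even under per-channel noise.

At 10% amplitude noise with 20 events over 600 s, deconvolution kernel RMSE
and fitted-parameter errors stay well under the frozen Monte-Carlo bounds
(0.03 signal units and 0.01 per parameter, from a 40-run oracle).

## Spectroscopy

The modified Beer–Lambert inversion solves, per sample,
ΔA_λ = −ln(I_λ/I₀) = X_λ(ε_HbO,λ ΔHbO + ε_HbR,λ ΔHbR) over the available
wavelengths (exact 2×2 at two wavelengths, least squares at three).  Natural
logarithm throughout — stated explicitly because the log₁₀ dialect differs
by a factor of 2.303.  The shipped extinction coefficients (470/530/660 nm)
come from the standard compiled hemoglobin spectra and the path lengths from
Monte-Carlo tissue models; both are user-configurable constants, and all
validation uses forward–inverse round trips, which are independent of the
chosen values.  530 nm is treated as exactly isosbestic (ε_HbO = ε_HbR), so
its absorbance change depends only on ΔHbT — a property the tests verify on
the forward model.  Baseline I₀ defaults to the mean over the full trace and
re-baselining shifts all Δ traces by a constant.

## Line scans

- **Diameter**: full width at half maximum of the across-vessel intensity
  profile, background = profile minimum (a percentile option exists),
  crossings linearly interpolated outward from the peak.  Invariant to
  affine intensity rescaling.
- **Smoothing**: Savitzky–Golay, 15 points, 3rd order; preserves cubic
  signals exactly and attenuates white noise by the filter's coefficient
  norm, both tested.
- **RBC velocity**: the streak angle of the space-time image is the Radon
  projection angle of maximum variance (1° coarse grid, refined at 0.25°);
  velocity = (dx/dt)·cot θ, signed, with θ = 90° for stationary cells.
  Projection variances are normalized by projection support, otherwise plain
  noise biases the profile toward diagonal angles; an image whose peak
  normalized variance is under 5× the median (streak phantoms exceed 30×,
  noise stays under 2×) is rejected as having no dominant angle.
- **Stalls**: inter-RBC intervals lying entirely within resting segments of
  ≥ 5 s; a stall is an interval over 1 s.  Passage times may be supplied
  directly or extracted from shadow dips by threshold crossing (the
  extraction rule is a repository choice and is kept separate from the
  counting rule).

## Region statistics

Per-region two-group comparisons are two-sided unpaired t-tests — pooled
variance by default to match the common "unpaired t-test" convention of
commercial packages, with a Welch flag — with missing values handled
complete-case within region and counted, never silently dropped.  Multiple
comparisons are corrected with the two-stage adaptive step-up procedure of
Benjamini, Krieger and Yekutieli: stage 1 runs Benjamini–Hochberg at
α′ = α/(1+α) to estimate the number of true nulls m₀, stage 2 re-runs the
step-up at α′·m/m₀.  The primary output is the discovery set; the reported
q-values are the stage-2 adjusted p-values scaled by (1+α) so that q ≤ α
exactly characterizes rejection (because m₀ < m inflates the per-test level,
q can drop below the raw p — this is expected).  The implementation is
written here and cross-checked in tests against both an independent
brute-force transcription of the two-stage rule and statsmodels'
`fdr_tsbky` on a thousand random p-vectors.

## Synthetic cohorts and what passing tests show

`simulate_aging_study` builds a two-cohort regional study: each region is an
independent simulation box, each animal draws its density and radius targets
lognormally around its group mean with a 5% coefficient of variation, and
"aged" group means in effect regions carry −10% length density, +7% radius
and a raised tortuosity amplitude.  The between-animal CV is a modeling
choice (without it group variances collapse and t-tests are degenerate); 5%
makes a 10% effect a Cohen's d of ~2 at n = 5/group, the regime in which
the upstream study designs operate.

Passing the validation suite establishes that the estimators are unbiased
and correctly calibrated **under the generator's assumptions**: tubular
vessels with piecewise-constant radii, additive Gaussian noise, Poisson cell
placement, an exactly linear-time-invariant hemodynamic response, and a
noiseless forward Beer–Lambert model.  It does not establish robustness to
imaging artifacts real pipelines face — point-spread blur, stitching seams,
segmentation errors, motion, or hemodynamic nonlinearity — all of which are
explicitly out of scope here.

## Problem sizes

Default validation sizes: structural round trip on a (1 mm)³ volume at 1 µm
(≈10⁹ voxels, ~2 minutes, ~3.5 GB); cohort simulation with 16 regions ×
10 animals in (200 µm)³ boxes; HRF recovery on 600 s sessions at 30 Hz;
FDR oracle on 1000 random p-vectors plus a 500-replicate global-null
simulation.  These sizes were chosen so the full suite runs on a laptop-class
machine in minutes while keeping every tolerance meaningfully exercised.

## Known limitations

- The tracer assumes vessels are well separated relative to their radii;
  tubes that touch are traced as connected (that is what the image shows).
  Branch-count exactness is therefore only guaranteed for phantoms generated
  with a separation constraint.
- Radius recovery is biased low by about half a voxel; sub-voxel radius
  estimation (e.g. cross-section fitting) is not implemented.
- The Radon velocity estimator assumes straight streaks (constant velocity
  within the analyzed window).
- The q-value convention for the two-stage FDR is one of several in use;
  the discovery set, which is unambiguous, is the primary output.
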