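# Methods

## Scope and model

The package reproduces, at desk scale, the computational chain used to
plan deep-target temporal-interference stimulation: a volume-conductor
model of the head, per-channel quasistatic field solves, TI envelope
dosimetry, montage scoring with threshold metrics, and synthesis and
validation of the pulsed theta-burst stimulation waveform.  Anatomical
head models and commercial FEM solvers are deliberately replaced by a
parameterized layered-sphere phantom and a compact voxel solver so that
every stage is testable from scratch on one CPU in seconds to minutes.

## Head phantom (`tidose.phantom`)

Concentric spheres on a regular isotropic grid: scalp / skull / CSF /
gray matter shells with outer radii 92 / 86 / 80 / 78 mm (adult-head
scale) and a white-matter core of radius 55 mm; a bilateral deep
spherical target (radius 12 mm, centers ±20 mm lateral, 5 mm anterior,
5 mm superior of the head center) stands in for deep gray-matter
nuclei.  Default voxel spacing is 2 mm (valid range 1–4 mm).  A voxel
belongs to the innermost shell whose radius strictly exceeds the
distance of the voxel center from the head center; strict inequalities
make ties impossible and the analytic geometry makes label volumes
resolution-consistent and exactly mirror-symmetric (the grid is
odd-sized and centered).

Default conductivities (S/m): scalp 0.4, skull 0.01, CSF 1.79, gray
0.28, white 0.13, deep target 0.28 — low-frequency literature-scale
values; all overridable per configuration, and no test depends on the
exact numbers.  Air is exactly 0 S/m.

Electrode positions come from a built-in 10-10 table constructed
analytically: midline and vertex-coronal electrodes at 18°
inclination steps, an outer ring at 72° inclination with 18° azimuth
steps, and interior rows interpolated linearly in (inclination,
azimuth) between their midline electrode and ring terminus.  This is a
placement *convention* (the mapping of 10-10 labels onto a sphere is
not uniquely defined); left/right homologs mirror exactly about the
mid-sagittal plane.  Electrode patches are the outermost scalp voxels
(scalp-labeled with an air 6-neighbor) within the electrode radius
(default 7 mm) of the radial exit point.

"Sphere under electrode" ROIs scan the electrode's inward ray in 0.1-mm
steps and return the shallowest 10-mm sphere entirely inside the brain
mask, mirroring how control spheres under stimulation electrodes are
placed by projecting scalp positions toward the brain center.

## Quasistatic solver (`tidose.solver`)

Ohmic currents dominate displacement currents at low-kHz frequencies,
so each channel solves ∇·(σ∇φ)=0.  Discretization is a 7-point
finite-volume stencil with **harmonic-mean face conductances**, which
is conservative and robust across the ~200× skull/CSF contrast; air
(σ=0) faces carry no current, so the insulating outer boundary is
automatic.  Electrode contact is ideal: Dirichlet values +0.5 / −0.5 V
on the anode/cathode patch voxels.  The SPD system is solved by
conjugate gradients with Jacobi preconditioning (default relative
residual 1e-8, iteration cap 2000·N^(1/3)); disconnected electrode
patches are rejected up front via a connected-component check.

The injected current is measured by summing ohmic face currents leaving
the anode patch; the identical sum at the cathode is an independent
conservation check (they agree to ≪0.1 %).  Fields are then rescaled
exactly (linearity) to the requested current — Dirichlet solve followed
by current normalization.  E = −∇φ uses central differences in the
tissue interior and one-sided differences at tissue/air faces; air
voxels are zero.  Because tissue properties are flat across the low-kHz
band, one solve per electrode pair serves both carriers.

Verification oracles: the parallel-plate slab closed form (|E| = V/d,
exact to 1e-6), and a Legendre-series solution for antipodal point
electrodes on a homogeneous sphere,
φ(z) = I/(2πσR) Σ_{n odd} ((2n+1)/n)(z/R)ⁿ on the axis, derived by
matching the Neumann boundary condition term by term.  The voxel solver
tracks the series within 2 % of the axis-potential scale for
|z| ≤ 0.6 R on a 92-mm sphere at 2-mm spacing; closer to the
electrodes the point-source singularity and the finite patch size
dominate, so that region is excluded by construction.

## TI envelope (`tidose.ti`)

The per-voxel dosimetric quantity is
max over unit n of 2·min(|n·E₁|, |n·E₂|).  The closed form — after
flipping the sign of E₂ if E₁·E₂ < 0 (the physical envelope is
phase-invariant) and relabeling so |E₁| ≥ |E₂| — is 2|E₂| when
|E₂| ≤ |E₁|cos α, else 2|E₂×(E₁−E₂)|/|E₁−E₂|.  Correctness is defined
by two independent oracles rather than by the formula itself:

* **Direction scan** — the maximum of the defining expression over a
  deterministic Fibonacci-sphere direction set; optionally polished by
  Nelder-Mead restarts from the best few well-separated scan directions
  (the objective carries narrow ridges when the vectors are nearly
  orthogonal with very different magnitudes; a plain scan at feasible n
  underestimates there).  The polish only ever evaluates the defining
  min-of-projections expression, so it stays independent of the closed
  form; with it, agreement is at machine precision.
* **Time-domain beat** — synthesize (n·E₁)sin(2πf₁t)+(n·E₂)sin(2πf₂t),
  take the analytic-signal envelope, and measure max−min over whole
  interior beat cycles, which equals (A₁+A₂)−|A₁−A₂| = 2·min(A₁,A₂).
  Whole-cycle windowing avoids Hilbert edge bias; agreement with the
  closed form is well within 1 %.

The map operation scales each per-mA-normalized channel field by its
current and applies the closed form voxelwise; joint current scaling is
exactly linear.  The tDCS comparator is simply |E|·I.

## Montage sweep and metrics (`tidose.sweep`)

Electrodes are grouped into left/right mirror (homolog) pairs; for each
unordered choice of two homolog pairs {L₁,R₁},{L₂,R₂} exactly three
montages exist up to channel-swap and polarity-swap symmetry —
within-hemisphere channels (parallel-sagittal paths), homolog channels
(parallel-coronal), and diagonal channels (crossing) — giving
3·C(k,2) montages for k pairs.  No claim is made to reproduce any
particular historical enumeration count; the closed form above is the
package's own rule and is asserted against brute force in tests.

Scoring uses the **98 % volumetric iso-percentile threshold**: the 98th
percentile (linear interpolation between order statistics) of the TI
map over brain voxels, with the suprathreshold set defined by strict
inequality.  Both conventions matter at small N and are therefore
fixed.  Metrics per montage: **focality** = % of suprathreshold brain
volume inside the target (undefined — NaN — when nothing is
suprathreshold), **activation** = % of the target volume that is
suprathreshold, and **target exposure strength** = median TI exposure
in the target (median rather than mean because the exposure
distributions are skewed; the mean is reported alongside).  The pareto
front is standard non-domination over the three maximized objectives;
equal rows are all flagged; failed solves mark their row and the sweep
continues.

**Arg-max depth.**  At the gray/CSF interface the conductivity contrast
makes the normal field component jump, and finite differences within
two voxels of the boundary mix the tissues, so raw brain-mask arg-max
voxels sit in a spuriously bright boundary layer (the analogous edge
voxels are conventionally omitted from exposure histograms as noise).
The depth diagnostic therefore takes the arg-max over the brain eroded
by 2 voxels.  On the default phantom with the striatal montage
(channels F3–F4 and TP7–TP8) the TI envelope arg-max then sits ~37 mm
below the scalp versus ~17 mm for either channel's own |E| arg-max.
With diagonal channel pairings (F3–TP8 / F4–TP7) no such depth
advantage appears on the layered sphere: near-surface regions where
both diagonal fields are strong always win.  The depth check is
accordingly defined on the homolog-paired striatal montage.

## Waveform (`tidose.waveform`)

The pulsed protocol keeps channel 1 at f₁ = 2 kHz while channel 2 is
frequency-shift keyed to f₁ + Δf = 2.1 kHz for 30 ms every 200 ms
within 2-s trains repeated every 10 s; amplitude is 2 mA per channel
with 5-s linear ramps, sampled at 100 kHz (≥20× carrier, integer
samples per burst period).  Δf × shift-window must be a whole number of
beat cycles (3 at the defaults), so the channels return to phase
alignment at every window end.  Switching is **phase-continuous**
(channel 2 integrates its instantaneous frequency), chosen to avoid
spectral splatter; the interburst and intertrain intervals carry
unmodulated HF current, not silence; the ramp precedes the train
schedule; both channels start at phase 0.  The HF control never shifts
and its envelope is flat to ≪1 %.

Validation works from the signals alone.  The summed-channel envelope
(analytic signal, a few carrier cycles trimmed at the edges) sits at
its plateau 2A outside bursts and dips toward zero once per beat cycle
inside them, so **pulses are counted as excursions of the AM-depth
signal** (plateau minus envelope): local maxima reaching ≥50 % of the
global depth, separated by at least half a beat period, with a 5 %
minimum modulation depth so control-condition ripple never counts.
Bursts are pulse clusters separated by less than half a burst period;
trains are burst clusters separated by more than two burst periods.
The AM frequency is the spectral peak of the envelope restricted to
burst intervals, concatenated across bursts (they are beat-phase
coherent by the whole-cycle constraint), which gives the AM line a long
integration time; a single 30-ms burst's zero-padded spectrum is
leakage-biased by ~2 %, the concatenation is exact to <0.01 %.
Session templates: experiment 1 stimulates during sixty 30-s task
repetitions (30 min total); experiment 2 during seven 90-s task blocks
(10 min 30 s).

Default synthesized session length is 35 s — ramp, three full trains,
ramp-down — long enough to measure train periodicity while keeping
memory at a few tens of MB.

## Reporting (`tidose.report`)

ROI histograms default to 50 uniform bins on [0, 1] V/m; bins are
left-closed right-open with a right-closed final bin, values above the
clip (default 1 V/m) are counted as omitted rather than binned, and
below-range values are tracked separately so counts always conserve the
ROI voxel total.  Summaries report mean, sd (n−1), median and the 99th
percentile (linear interpolation).  Condition comparisons are
descriptive only — voxels are not independent samples, so no
inferential statistics are attached.  JSON/CSV output uses sorted keys
and fixed float formatting so identical inputs give byte-identical
files.

## Pipeline (`tidose.pipeline`)

One YAML document configures every stage; validation (including
electrode-label resolution) completes before any output is written.
The run writes a manifest of every produced file with SHA-256 hashes;
identical configurations give identical manifests (volumes are written
as uncompressed NIfTI-1 so the hashes are stable).

## What the phantom does and does not show

The synthetic phantom preserves the features the method depends on —
nested conductivity contrasts, symmetric electrode geometry, a deep
target under a conductive CSF shell — and therefore supports testing
the physics (conservation, superposition, mirror symmetry), the
envelope mathematics, and the metric bookkeeping.  It has no gyri, no
skull layering, no anisotropy and no realistic striatal geometry, so
absolute exposure values, focality/activation percentages and
pareto-front membership on the phantom do **not** predict those
quantities on an anatomical head model; on the layered sphere the top
2 % of brain exposure is superficial and the deep target's focality and
activation evaluate to 0 at the 98 % threshold.  Published
anatomical-model dosimetry values are consequently not comparison
surfaces for this package.

## Problem sizes

Default test/analysis sizes: 2-mm phantom (97³ grid, ~4·10⁵ tissue
voxels; one channel solve ≈ 400–700 CG iterations, a few seconds),
4-mm phantom for sweep-backed tests, 35-s sessions at 100 kHz for
waveform measurements, 1000 seeded vector pairs for oracle-equivalence
checks.  These sizes make the full suite and the acceptance script run
in minutes on one CPU while leaving every numerical tolerance
comfortably met.
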