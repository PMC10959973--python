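# Methods

## Scope

`shoal` simulates and analyses the collective dynamics of small groups
of zebrafish (*Danio rerio*) treated as interacting active agents.  It
couples a minimal 2D agent-based model to the observable stack used to
characterise multistate shoaling: polarization and rotation order
parameters with a three-state classification, nearest-neighbour
subgroup statistics, comoving-frame pair correlations, three-fish bond
angles, and observed-versus-Kirkwood triplet correlation maps.  The
analysis side accepts any trajectory table (2D simulated or 3D
tracked); the simulator doubles as the package's realistic synthetic
data source.

## Units

Length is measured in body lengths, L = 30 mm.  Time is measured in
T = L / v_f = 0.3 s, where v_f = 100 mm/s is a typical zebrafish
cruising speed, so the dimensionless cruise speed is v0 = 1.  All
defaults below are quoted in these units.

## Order parameters and state classification

For one frame with N fish of velocity v_i and position r_i,

    O_p = |Σ_i v_i/|v_i|| / N
    O_r = |Σ_i (v_i/|v_i|) × u_i| / N,   u_i = (r_i − r_cm)/|r_i − r_cm|

with r_cm the group centre of mass.  In 2D the cross product is the
scalar z-component; in 3D a vector whose norm is taken after summing.
Frames are classified frame-by-frame: *schooling* if O_p > 0.65,
*milling* if O_r > 0.65, *swarming* if both < 0.35, otherwise
unclassified.  The (rare) region where both exceed 0.65 is resolved in
favour of the larger value; an exact tie stays unclassified.  Fish
with undefined headings (missing samples, or speed below a 10⁻⁶ L/s
floor) are dropped from that frame's sums; a frame left with no usable
fish (one for O_p, two for O_r) is unclassified with NaN order
parameters.

Local subgroups F_N^n are a focal fish plus its n − 1 nearest
neighbours by Euclidean distance at that frame, with distance ties
broken by fish index for determinism; subgroup O_r uses the subgroup's
own centre of mass.

## The agent-based model

Fish move at speed v_i along heading φ_i and can only turn
(overdamped dynamics):

    dx_i/dt = v_i cos φ_i + u_x(r_i)
    dy_i/dt = v_i sin φ_i + u_y(r_i)
    dφ_i/dt = (1/v_i)(F_wall + F_att)·e_φ + Σ_j k_al sin(φ_j − φ_i) e^{−r_ij/r_al}
              + ω(r_i)/2 + η_i

with e_φ = (−sin φ_i, cos φ_i) and η_i zero-mean Gaussian white noise,
⟨η_i(t) η_j(t′)⟩ = 2 D_φ δ_ij δ(t − t′), D_φ = 0.015.

Force channels (all strengths are model choices, see below):

* **Wall.**  A soft exponential boundary at radius R = 66.7 L:
  magnitude k_w exp(−(R − |r_i|)/λ_w) pointing inward; defaults
  k_w = 4, λ_w = 2.  The tank is simplified to a 2D circle.
* **Attraction–repulsion.**  A linear spring toward each visible
  neighbour within r_cut = 30 L: magnitude k_att (r_ij − r_eq) with
  rest separation r_eq = 1 L and k_att = 3, capped at f_max = 3.
  Below r_eq the slope steepens to k_rep = 8 (still zero at r_eq, same
  cap): because forces act only on the heading while the hydrodynamic
  flow advects positions directly, a repulsion as soft as the
  attraction lets the trio collapse into an overlapping bound state; a
  stiffer contact branch restores a physical spacing.
* **Alignment.**  A weak torque k_al sin(φ_j − φ_i) exp(−r_ij/r_al)
  toward each visible neighbour's heading; k_al = 0.12, r_al = 3.
* **Field of view.**  Attraction and alignment act only on neighbours
  within 150° of the heading (a 60° blind zone behind).  The
  hydrodynamic channel is not masked — flow does not require vision.
* **Hydrodynamics.**  Each fish sources a 2D potential (source)
  dipole of strength s_h v_j along its heading; the flow decays as
  1/r² and is regularised inside a core of radius 1.5 L.  Other fish
  are advected by the summed flow and reoriented by half the local
  vorticity.  A potential dipole is irrotational outside the core, so
  the vorticity term acts only at near-contact separations; the
  advection is the dominant coupling.  Default s_h = 0.9.

**Variable speed.**  Optionally the speed obeys
v̇_i = (v0 − v_i)/τ_v + (F_wall + F_att)·ê_i with ê_i = (cos φ_i,
sin φ_i), τ_v = 2 T, clipped below at 0.05; the heading and position
updates are unchanged with v_i in place of v0.  At the defaults this
shifts the state balance only mildly (the three states remain
occupied), consistent with speed variability being a second-order
effect for these observables.

**Integration.**  Euler–Maruyama with synchronous updates,
dt = 0.05 T; the heading is updated first and the position moves along
the new heading, so a free fish advances exactly v0·dt per step.  A
run discards 10⁴ burn-in steps.  Noise comes from one PCG64 generator
seeded from the config; per-fish increments are columns of a single
(steps × N) normal block, so identical seeds give bit-identical
trajectories.  Coincident fish are separated by a deterministic 10⁻⁶ L
offset and the spring force is capped, so the update is defined
everywhere.

**Parameter provenance.**  D_φ, v0, R, dt and the unit system are
fixed physical/tank constants of the study design.  The interaction
strengths are *calibrated model choices*: they were selected, before
freezing, as a set for which an isolated trio is tristable — it
switches intermittently between schooling, milling and swarming with
no state below a few percent occupancy — while the group stays
cohesive (median pair distance a few L).  They are shipped as the
named defaults of `SimulationConfig` and should be treated as tunable.
With them, a 5·10⁵-frame three-fish run spends roughly 46% / 15% /
13% of its time schooling / milling / swarming (the rest
unclassified), stable to the choice of seed.

**Known model feature.**  Swarming occupancy grows from N = 3 to
N = 10 to N = 20 and dominates at N = 20, but N = 5 groups
over-occupy the ordered states (milling in particular) relative to
both N = 3 and N = 10 at these defaults — the hydrodynamic coupling
strengthens with the number of near neighbours before crowding and
noise win.  The monotone-growth property is therefore asserted over
N ∈ {3, 10, 20}.

## Pair correlations

The comoving map g2(x′, y′) histograms neighbour positions in the
frame of a focal fish (x′ along its horizontal heading, y′ 90° to its
left), over all ordered pairs or focal→nearest-neighbour only,
optionally restricted to frames in one dynamical state.  Default grid:
0.2 L bins on [−5 L, 5 L]².  Maps are max-normalised; contour levels
0.1–0.9 are used for rendering.  For 3D data the frame is built from
the horizontal velocity component and vertical separation is
marginalised.  Peaks are local maxima above half the map maximum,
labelled β (front, |y′| < 0.5 L and x′ > 0), α/γ (left/right side
peaks) or "back".

The radial g2(r) divides the pair-distance histogram by the shell
measure (2πr Δr in 2D, 4πr² Δr in 3D) and is max-normalised; its
argmax r_max sets the separation window for the triplet statistics.
When the positions live in a known disc-shaped observation window
(the ideal-gas fixture; optionally the arena), `window_radius` applies
the isotropic (Ripley) edge correction — dividing by the disc's set
covariance — without which even an ideal gas shows a spurious decay
of g2 with r.

## Triplet statistics and Kirkwood superposition

Bond angles: for each frame of a trio and each vertex, the angle
between the two incident bonds, counted when both bond lengths lie in
a window (by default r_max ± 0.25 L from the state-conditioned radial
g2); histogrammed in 10° bins on [0°, 180°].

Triplet maps: for every ordered reference pair with |r_12| in the
window (optionally also satisfying an orientation condition —
side-by-side or head-to-tail within 30° tolerances), the third fish is
histogrammed in the frame with origin at the pair midpoint and x̃
along r_12.  Without an orientation condition all six ordered pairs
contribute, symmetrising the map under x̃ → −x̃; head-to-tail pairs
are oriented follower → leader.  The Kirkwood superposition predicts
this map from pair correlations alone, g3 ∝ g2(r_13) g2(r_23) with the
constant g2(r_12) factor absorbed by normalisation; g2 values are
interpolated linearly and bins needing g2 beyond its estimated support
are flagged missing.  With `window_radius` set, the observed map is
divided per-bin by the fraction of sampled pair frames for which the
bin lies inside the window (a Monte-Carlo edge correction).

The discrepancy statistic compares the two sides after rescaling each
to unit mean over interior bins (≥ 2 bins from every edge).  The
stored maps remain max-normalised for display, but the raw maximum of
a counted histogram is biased high by noise-peak selection, which
would shift every observed bin down relative to the smooth Kirkwood
side; the interior mean is an unbiased common scale.  The per-bin
sampling envelope combines the bin's counting error, the error of the
normalising mean, and a 1/c_max floor.  Reported summaries: the
maximum |g3 − g3K| over interior bins, the same maximum in units of
the envelope, and the mean difference over the central region (third
fish between the reference pair).

## Synthetic fixtures

Deterministic generators provide analytic ground truth without the
simulator: a single-file school (O_p = 1 exactly, up to float
rounding), a perfect mill of equally spaced fish with tangential
counter-clockwise velocities (O_r = 1), a random swarm (uniform
positions and headings; mean O_p follows the Rayleigh law
√(π/4N)), and ideal-gas frames (independent uniform positions in a
disc) — the exact null for Kirkwood superposition.  Fixtures carry
analytic velocity sidecars so order-parameter tests are exact; the
finite-difference path is tested separately.  The Kirkwood null is
exercised at region radius 8 L, r_12 window [2.0, 2.5] L, 1 L map bins
on [−5, 5]² (margin-2 interior) — chosen so that, at 10⁵ frames,
residual O(r/region) boundary effects stay inside the sampling
envelope of the edge-corrected estimators.

What the fixtures do *not* emulate: measurement noise, tracking
dropouts, fish-to-fish variability, or 3D structure.  Passing fixture
tests therefore validates the estimator mathematics, not robustness to
real tracking artefacts; the simulator covers realistic dynamical
structure, and 3D experimental data exercise the same code paths via
the horizontal-plane projection.

## Velocity estimation and degenerate inputs

Velocities come from central differences ((r(t+1) − r(t−1))/(2Δt),
exact for uniform motion at any frame interval); the first and last
frames use one-sided differences and are flagged.  The experimental
frame rate is dataset-specific, so `frame_interval` is a required
input of the readers, not a default.  Fish below the speed floor, or
coincident with the subgroup centre of mass, are excluded from
heading-dependent observables rather than imputed.

## Problem sizes used in the shipped checks

The reference three-fish run records 5·10⁵ frames (dt = 0.05 T,
~7 hours of fish time); group-size comparisons use 10⁵-frame runs at
N = 10 and 20; the diffusion check uses 10⁴ independent fish over 40
steps; the Kirkwood null uses 10⁵ ideal-gas frames.  These sizes give
occupancy fractions stable to ±1–2% across seeds while keeping a full
analysis run in minutes on one core.

## Known limitations

* The interaction forces are a documented stand-in family, not fitted
  to fish data; only their qualitative structure (strong short-range
  attraction, weak alignment, dipolar hydrodynamics, rear blind zone)
  is constrained.
* 2D circular arena only; no parabolic tank geometry, no inertia.
* Frame-by-frame thresholding — no temporal smoothing of state
  sequences, so occupancy counts frames, not episodes.
* The Kirkwood comparison assumes an (effectively) homogeneous
  background; the edge correction handles a known disc window but not
  an arbitrary non-uniform one-body density.
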