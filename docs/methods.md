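# Methods

## Scope and model

`pathmetad` implements the enhanced-sampling protocol used to map two-state
conformational transitions of hinged, multi-domain proteins — the
adenylate-kinase open/closed motion being the motivating case: a reference
path is built by morphing between the two endpoint structures, the progress
variable s along that path is biased with well-tempered metadynamics, the
distance-from-path z is restrained, and the converged bias (or a reweighted
projection) yields free-energy surfaces that are analyzed for basins,
lowest free-energy paths and barriers.

Explicit-solvent all-atom dynamics is out of scope.  The sampling stage is
replaced by a seedable BAOAB Langevin integrator acting on two synthetic
systems whose thermodynamics are designed analytically, so every pipeline
stage can be validated against a known answer on a desktop.

## The MSD metric and the path CVs

Distances between configurations use the mean square displacement (nm²)
after optimal rigid superposition (unweighted Kabsch with the reflection
branch removed: the smallest singular direction is sign-flipped so det R =
+1, since only proper rigid motions are physical).  The alignment subset and
the measured subset may differ, as when aligning on a stable core and
measuring a mobile domain.  A `"none"` alignment sentinel disables
superposition for systems with a fixed external frame (e.g. 1-D toys).

For a path of P frames S(l), with d²_l the metric distance of configuration
R to frame l:

    s(R) = Σ_l l·e^(−λ d²_l) / Σ_l e^(−λ d²_l)        (progress, ∈ [1, P])
    z(R) = −(1/λ) ln Σ_l e^(−λ d²_l)                  (distance, nm²)

computed with a log-sum-exp shift so no input underflows to NaN.  λ is set
to 1/mean(successive-frame MSD) after resampling, which makes
λ·mean(spacing) = 1 exactly.  Note that z is a *softmin*: it lies below
min_l d²_l and rises monotonically toward it as λ grows; near nodes it is
slightly negative (bounded below by −(ln P)/λ), and no clamping is applied.

Analytic Cartesian gradients of (s, z) follow from the envelope theorem
through the optimal superposition (the variation of the optimal rotation and
translation drops out), which is exact when the alignment and measured
subsets coincide; for distinct subsets central finite differences (step
1e−5 nm) are used instead.

## Path construction

Morphing is per-coordinate linear interpolation after superposing one
endpoint onto the other.  Equal spacing in the metric is obtained by
arc-length reparameterization: the raw frames are chain-aligned, densely
interpolated (≥20× P), and P frames are picked at equal quantiles of the
cumulative √MSD arc length, with an inner redistribution loop that
equalizes the chord MSDs of the picked frames; density is doubled and the
procedure repeated if the spacing coefficient of variation stays above the
tolerance (default 2%), and a `ResamplingError` reporting the achieved CV is
raised if it cannot be met.  Endpoints are preserved exactly.

**Path extension.** For the bead model the reference path is built between
endpoints extrapolated 25% beyond the closed and open states.  With
endpoints exactly at the metastable states the softmax saturates near the
path ends (|ds/dθ| measured ≈2.3/rad at the wells vs ≈7.4/rad mid-path),
which piles probability into the end bins and deepens the wells by ≈1.2 kBT
relative to the designed profile — an artifact of the CV, not of the
sampler, visible already in unbiased histograms.  Keeping the physical wells
at interior frames restores F(s) ≈ F(θ) + const to within ≈0.3 kBT.
Extending the reference path beyond the states of interest is standard
path-CV practice.

## Synthetic systems

**Tilted double well (1-D).**  U(ξ) = b(ξ²−1)² + (c/2)(ξ³−3ξ) with ξ = x/x₀.
The cubic tilt keeps the minima pinned exactly at ξ = ±1 while offsetting
them by exactly 2c; b is solved (Brent, |Δ| < 1e−14) so the interior saddle
sits exactly `barrier` above the lower (ξ=+1) minimum.  Requires
barrier > offset ≥ 0.  The analytic potential is exposed for oracles.

**Two-domain bead model.**  A planar 10-bead "protein": a 4-bead core
carrying two 3-bead mobile blocks ("lid-like", "nmp-like"), each hinged at a
core bead.  All intra-block pair distances and block-to-hinge distances are
restrained harmonically (default 1500 kJ/mol/nm²), so each hinge angle is
the only soft mode; the angle carries the tilted-quartic double well with
the designed barrier (default 4 kBT above the lower, open well) and
open/closed offset (default 1.5 kBT; the open state is the more stable one).
The secondary (nmp-like) hinge defaults to a milder 2 kBT/1 kBT profile.
Bead placements receive a 0.02 nm seeded jitter so different seeds give
different geometries; endpoints are built from the same jittered template
and differ only by the hinge rotations (60° per hinge, a protein-like
domain swing for which the linear morph chord stays close to the rotation
arc; larger swings make the chord-interpolated frames so distorted that
the s(θ) mapping can lose monotonicity).

The model is planar (z frozen) by design: in 2-D the orientational measure
of a hinge rotation is flat, so the free-energy profile along the hinge
angle equals the designed potential exactly in the stiff-spring limit (no
ln sin θ correction).  An unbiased 4.5-ns control run reproduces the
designed F(θ) to <0.1 kBT across the whole range.

What the generator does *not* emulate: solvent and hydrodynamics, sterics
(beads may overlap), sequence detail, multi-state kinetics beyond two wells
per hinge, and the ruggedness of a real protein FES.  Passing tests
therefore demonstrate the correctness of the machinery (metric, CVs, bias
schedule, reweighting, analysis), not force-field realism.

## Sampling and bias coupling

BAOAB Langevin splitting (good configurational accuracy at modest
timesteps); k_B = 0.0083144621 kJ/(mol·K); units nm, ps, K, kJ/mol, amu.
Initial velocities are Maxwell–Boltzmann draws from the run's single seeded
generator; no global random state is touched.  Non-finite energies or
forces abort with the step index.

Bias forces enter through the CVs: F = −dV/ds ∇s − Σ_w k_w(excess) ∇(cv_w),
with the analytic (s, z) gradients above.  During a run the accumulated
1-D bias and its derivative are also tabulated on a 4001-point grid updated
at each deposit, so per-step lookups are O(1) linear interpolations (grid
spacing ≪ hill width; interpolation error ≈1e−4 kJ/mol).  The public
`evaluate_bias` always performs the exact Gaussian sum (hills truncated at
6σ, relative error ≲1e−8).

## Well-tempered schedule and FES estimate

Hills of width σ are deposited every `pace` ps with height
w = w₀·e^(−V/(k_B ΔT)); the converged bias maps to the free energy as
F = −(T+ΔT)/ΔT · V, min-shifted to zero.  The convergence estimate averages
the FES over the bias as it stood at each deposition in the final 20% of
the run, damping the well-tempered ripples.  The "z < threshold" constraint
of the protocol is realized as a stiff upper half-harmonic wall (continuous,
C¹ at the threshold), preserving differentiable dynamics.

Defaults follow the production settings: T = 300 K, ΔT = 3300 K, pace 2 ps,
w₀ = 2 kJ/mol, σ_s = 0.03 (s-units under the s ∈ [1, P] convention),
z-wall at 1 nm² with spring 1000 kJ/mol/nm⁴.  Per-system choices:

- **Double-well benchmark**: σ = 0.08 nm (≈half the thermal width of a
  well), friction 2 ps⁻¹, dt 5 fs, 10 ns (5000 hills).  Production ΔT and
  pace are kept.
- **Two-domain pipeline**: σ_s = 0.4 (half the measured unbiased s
  fluctuation, the same criterion the protocol uses), dt 4 fs (500 steps
  per pace), friction 5 ps⁻¹, 4 ns.  ΔT = 900 K (γ = 4): ΔT should scale
  with the barriers to overcome, and the production 3300 K was set for a
  protein-scale landscape; on the ~15 kJ/mol toy landscape γ = 12 lets the
  edge bias grow so large that the system is eventually crushed against the
  hinge-extension region.  Walls confine the run to the path interior:
  z < 0.25 nm² (spring 4000) — the threshold scaled to the toy's z scale —
  and soft walls on s at both ends (spring 200), inside the extension
  margin, mirroring production path-CV setups.

## Reweighting

The weight of record i is w_i ∝ exp[(V(s_i, t_i) − c(t_i))/k_B T] with the
time-dependent offset

    c(t) = (1/β) ln [ Σ_x e^{βγ/(γ−1)·V(x,t)} / Σ_x e^{β/(γ−1)·V(x,t)} ],
    γ = (T+ΔT)/T,

evaluated on a grid over the biased CV, updated as hills accumulate
(records before the first hill get V = 0, c = 0).  Weights are normalized
to mean 1 and are invariant under a constant bias shift.  Projected FES:
F = −k_B T ln(weighted histogram) on half-open fixed-width bins, values at
bin centers, empty bins marked unvisited (NaN), min-shifted.

## FES analysis

Basins are persistent local minima: cells are flooded in ascending F with
union-find merging, and a minimum survives as a separate basin only if its
merging ridge lies ≥ depth_threshold above it (default 2.5 kJ/mol, one
contour step; configurable).  Member cells are the orthogonally connected
cells within depth_threshold of the basin minimum.  The lowest free-energy
path between basin minima is the minimax path over 4-connected visited
cells (Dijkstra on the key (max F, total F); ties by smaller total F).
Barriers are max-F-along-path minus the starting minimum (also reported in
kBT); forward and backward barriers differ by the basin offset.  Basin ΔF
uses population sums over member cells, −k_B T ln(Σ_a e^{−βF}/Σ_b e^{−βF}),
because basins of very different widths are compared; the sign is negative
when the first basin is the more populated one.  Whether a point-minimum or
population difference is wanted is analysis-dependent; both are computable
(F_min is exposed on each basin), the population form is the default.

RMSD series align each frame on a chosen subset (e.g. the core) and measure
another; RMSF aligns every frame against the time-mean structure (one
align–average–realign pass) and reports per-particle fluctuations about the
per-particle means.

## Numerical choices and degenerate inputs

- Superposition requires ≥3 non-collinear alignment points (second singular
  value > 1e−10 + 1e−8·first); degenerate sets raise.
- Identical path endpoints raise "degenerate path" (arc length ≤ 1e−8 of
  the coordinate scale).
- Hill evaluation truncated at 6σ; FES grids store unvisited cells as NaN.
- Basin flooding breaks F ties lexicographically by cell index, making the
  analysis deterministic.
- Spring forces guard against exactly coincident beads (direction undefined
  at zero separation).

## Problem sizes

The shipped tests and the acceptance script use: 10-ns double-well runs
(2M steps, 5000 hills, three seeds in the benchmark test), a 2M-step
unbiased comparison run, and a 4-ns (1M-step) two-domain pipeline on the
10-bead model with P = 16 path frames.  These sizes give metadynamics
statistical errors comfortably below the stated recovery tolerances
(≤1 kJ/mol on the double well; ≤1 kBT barrier / ≤0.5 kBT offset on the bead
model) while remaining desktop-scale.

## Known limitations

- The envelope-theorem CV gradient requires align = measure; distinct
  subsets fall back to finite differences, which is slow for large systems.
- Reweighting assumes the recorded instantaneous bias matches the hills up
  to the record time; traces assembled from other sources must respect
  this convention.
- The minimax path is grid-based (4-connectivity); it is not a string-method
  refinement and has no sub-cell resolution.
- find_minima's member sets of different basins may overlap when
  depth_threshold exceeds the separating ridge; ΔF estimates are then
  correspondingly approximate.
- HILLS files store the bias factor, not ΔT and T separately; readers
  default to the '#! SET temperature' header (or 300 K) to reconstruct ΔT.
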