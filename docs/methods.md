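# Methods

This note documents the models, conventions and numerical choices behind
`ionbind`, and what its synthetic-data validation does and does not show
about real MD data.

## Units and conventions

Lengths are in Å everywhere.  Raw frame times are ps (the unit MD engines
write); kinetic quantities (binding times, survival-curve lags) are
reported in ns, converted only at the reporting boundary.  Coordinates
are Cartesian and never wrapped on read; distance computations apply the
minimum-image convention for orthorhombic boxes whenever the trajectory
carries box lengths (a flag can force it off).  Whether contact distances
should be periodic at all is genuinely open for surface-bound ions far
from the box boundary; defaulting to minimum-image when a box is present
is the conservative choice and makes open-boundary toy systems behave
identically either way.

## Binding-event model

A binding event is a maximal run of consecutive frames whose minimum
ion-to-protein-heavy-atom distance (closest ion atom for two-atom ions;
hydrogens excluded on the protein side) is below a cutoff, 4 Å by
default.  Runs shorter than a minimum duration are discarded; the default
is two frame intervals, i.e. 0.4 ns at 0.2 ns sampling.  The minimum is
specified in time, not frames, so data sampled at 10 ps and at 200 ps are
filtered by the same physical threshold.

**Duration convention.** An event spanning *k* frames has
t_b = *k*·dt, not (*k*−1)·dt: a minimal two-frame event at 0.2 ns
sampling is reported as 0.4 ns.  This convention keeps event counts and
the duration-threshold tables mutually consistent.

**Gap tolerance** defaults to 0 (a single frame above the cutoff ends the
event), matching a strict consecutive-frames reading; a configurable gap
parameter exists for noisier data.

**Site assignment** maps an event to the binding site whose defining
residues' heavy atoms are within the site cutoff (3 Å default) for the
largest number of event frames; ties break towards the smaller mean
distance; an event touching no site stays unassigned.  A majority-frame
tally is our choice — any rule is defensible when an ion grazes two
adjacent sites, and the tally is the least sensitive to brief excursions.

**Kinetic summaries.** The mean of t_b is the maximum-likelihood estimate
of the inverse decay rate under an exponential residence-time model.  The
bound-fraction (survival) curve f(t) = #{t_b ≥ t}/N is fit with
f(t) ≈ a·e^(−t/τ_fast) + (1−a)·e^(−t/τ_slow), amplitudes constrained to
[0, 1] and summing to one.  The optimiser is deterministic multi-start
nonlinear least squares over decade-spaced (τ_fast, τ_slow) pairs
bracketing the data range with three amplitude starts; best residual
wins, ties towards smaller τ_slow.  On a mono-exponential input the
surface is degenerate (a → 1, or τ_fast ≈ τ_slow); the fit still
reproduces the curve, and the amplitude-weighted time integral remains
well determined — tests assert exactly that.

**Hydrogen bonds** use a geometric criterion: donor–acceptor distance
≤ 3.5 Å and donor–H···acceptor angle at the hydrogen ≥ 120°, both
configurable.  Hydrogens are associated to a donor by proximity
(≤ 1.25 Å in the first frame) since the topology carries no bond table.

## Occupancy maps and hotspots

Ion reference points (bond midpoint for two-atom ions, optionally per
atom) are binned on a cubic grid, 1 Å voxels by default.  In
`probability` mode a voxel stores the fraction of frames in which at
least one ion lies inside it — the "probability to contain an ion at a
random frame" reading of an iso-level; `mean_count` mode stores mean
per-frame counts and conserves the number of in-bounds ions when summed.
No Gaussian smearing is applied.  Hotspots are 26-connected components
of voxels at or above an iso-level (diagonal-adjacent density blobs are
one physical site), with occupancy-weighted centroids and residues
within 4 Å annotated.  Superposition uses the Kabsch algorithm (via
`scipy.spatial.transform.Rotation.align_vectors`, proper rotations
only); RMSF is computed per atom about the time-average structure and
averaged per residue, assuming a pre-aligned trajectory.

## Rotational correlation and spin relaxation

C(τ) = ⟨P₂(u(t)·u(t+τ))⟩ is evaluated over all time origins by FFT of
the six unique quadratic components u_i u_j, making the cost O(n log n).
τ₂ is estimated two ways and both are always reported: a
mono-exponential least-squares fit restricted to lags with C > e⁻²
(refusing to fit if C never decays below 1/e), and the trapezoidal
integral of C up to its first non-positive crossing.  The fit is the
headline estimator by default; on simulated rotational diffusion with
τ₂ = 100 ps it recovers the truth to well under 10% at 10⁶ steps, while
the integral estimator is biased slightly low when the window truncates
the tail.

Spin-rotational relaxation uses 1/T = Δg²/(9 τ₂) with
Δg² = Σ(gᵢᵢ − g_e)², g_e = 2.00231930, and the precession timescale
τ_s = 2π/(|γ_e| B) with γ_e = 1.76085963×10¹¹ rad s⁻¹ T⁻¹ (CODATA
values; both constants are used, not fitted).  Feasibility is classed by
the ratio τ_s/T: suppressed above 10, feasible below 1, marginal
between.  The thresholds are order-of-magnitude markers, not sharp
physics, and are configurable.  Δg² is treated as a single
configuration-independent input per analysis; per-snapshot quantum
tensors are upstream inputs, never computed here.  The viscosity
projection scales both τ₂ and t_b linearly with the viscosity factor —
a first-order Stokes–Einstein–Debye model that ignores any change in
binding free energy with the medium.

## Solvation analysis

Frames are classified by the ion–protein minimum distance: bound
(≤ 3 Å), bulk (≥ 10 Å), or intermediate (excluded).  g(r) is the
standard pair-distribution estimator — per-frame ion–water distance
histogram (closest ion atom per water, mirroring the contact-distance
convention) normalised by 4πr²Δr and a reference density.  The reference
density defaults to the measured mean density (waters per frame over the
box volume, or over the r_max sphere for open systems) and is
configurable because the appropriate normalisation (simulation-box vs
textbook bulk water, 0.0334 Å⁻³) is a user decision.  The cumulative
count n(r) is accumulated directly from the histogram, so n(r_max)
equals the mean in-range water count exactly regardless of the density
choice.  Bin width defaults to 0.05 Å and minima detection smooths g(r)
with a 5-bin moving average — enough to resolve first-shell structure at
the 2.4–2.9 Å scale while suppressing bin noise.  Shell boundaries are
local minima of the smoothed g(r) after the first maximum; per-shell
water counts difference n(r) at the boundaries, and "shed waters" is the
bulk-minus-bound difference per shell, reported at one decimal.

## Synthetic generators (what they emulate, and what they do not)

`simulate_markov_binding` realises each ion as an independent two-state
(free ↔ site) Markov chain discretised at the frame interval with
per-step transition probability 1 − e^(−k·dt), implemented by sampling
alternating geometric run lengths (exactly equivalent, much faster).
Bound frames place the ion at the site centre plus isotropic Gaussian
jitter (σ = 0.5 Å default, which lets the 4 Å/3 Å criteria cleanly
recover the latent state); free frames are i.i.d. uniform draws in the
box, rejection-sampled outside 6 Å spheres around sites.  Defaults
mirror the coarse-sampled bulk condition (dt = 0.2 ns); the fine-sampled
escape condition (dt = 10 ps) is exercised in tests.  One global seed
expands into per-ion substreams via `SeedSequence` spawn keys, so adding
ions never perturbs existing streams, and all generators are
bit-reproducible given (spec, seed).

What this deliberately omits: translational diffusion of free ions
(positions decorrelate in one frame), rebinding correlations, multi-ion
interactions and competition, force-field energetics, and explicit
water.  Passing the recovery tests therefore shows the *estimators* are
correct and unbiased under the assumed kinetics — it does not validate
the kinetic model itself against real MD, where residence times need not
be exponential and detection noise is correlated.

`simulate_rotational_diffusion` applies per step a Gaussian rotation
vector in the tangent plane of the current orientation with variance
2 D_r dt per transverse component (total angular variance 4 D_r dt), the
standard isotropic discretisation for which ⟨P₂(u(0)·u(t))⟩ = e^(−6 D_r t)
and hence τ₂ = 1/(6 D_r).  Steps require D_r·dt < 0.01 rad²; unit norm
is re-normalised each step and holds to 1e−12.

`generate_solvation_points` superposes a homogeneous Poisson gas
(excluded below a 1.5 Å core) with Gaussian-radius shells of prescribed
occupancy; the RDF estimator must return g ≡ 1 for the pure gas and
recover shell occupancies by integration.

`generate_decoy_protein` places single-atom residues on a sphere with
designated ARG "site anchors" — enough scaffold for distance-based
detection and site assignment, with no pretence of protein geometry.

## Problem sizes in the test-suite and acceptance runs

Statistical fixtures were sized for tight, stable recovery margins: the
binding-kinetics system uses 8 ions × 600 ns at dt = 5 ps (≈2500 events;
mean-t_b recovery and the Kolmogorov–Smirnov residence-time check at
α = 0.01), rotational diffusion uses 10⁶ steps at 1 ps (τ₂ recovery
within 10%), RDF validation pools 400 Poisson frames.  The acceptance
script scales these to 4 ions × 300 ns and 3×10⁵ steps, which leaves
recovery comfortably inside the same tolerances.  At dt = 5 ps the
geometric-residence discretisation biases the continuous-time mean by
k_off·dt/2 ≈ 0.25% and the two-frame minimum-duration filter adds about
+0.5%; both are far inside the 5% acceptance band.

## Known limitations

* The binding chain has no intermediate "near-surface" state, so
  detected and latent bound times agree almost exactly; real data show
  boundary flicker that the gap parameter only crudely models.
* The bi-exponential fit reports amplitude fractions; converting to
  event-count fractions under a different weighting is the caller's
  responsibility.
* OpenDX output writes voxel-centre grid positions; programs that treat
  DX origins as voxel corners will see a half-voxel offset.
* The PDB reader handles standard fixed-column ATOM/HETATM records only
  (no MODEL/ENDMDL multi-frame handling, no insertion-code logic beyond
  treating the (chain, resSeq, resName) triple as the residue key).
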