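# Methods

## The burst-and-coast decision model

Swimming is modelled as a marked point process of kicks.  At kick *n* the
fish located at **x**ₙ with heading φₙ instantaneously selects a new
heading φₙ₊₁ = φₙ + δφ, a peak speed vₙ and a kick length lₙ, then glides
in a straight line while its speed relaxes exponentially with dissipation
time τ₀.  The three kinematic quantities are linked by
lₙ = vₙτ₀(1 − e^(−τₙ/τ₀)); we draw (vₙ, lₙ) and invert for the duration
τₙ.  Position between decisions follows the exponential-glide
interpolation, whose endpoints reproduce the decision points exactly and
whose initial speed equals vₙ.

The heading change is the sum of a spontaneous Gaussian term, a wall term,
and (for two fish) attraction and alignment terms; all four are evaluated
at the kick instant, using the *incoming* heading, with the partner's pose
interpolated along its current glide (two-fish runs are event-driven: the
fish whose glide ends first decides next).  Moves whose endpoint, padded by
the comfort length l_c, would leave the circular arena are rejected and
redrawn; after 1000 failures the spontaneous term is drawn uniformly in
[−π, π] until a valid move exists (a hard cap of 10⁶ attempts raises an
error so that pathological configurations fail loudly).  The rejection
mechanism, not the explicit wall term, is what dominates wall avoidance at
very short range; see "Known limitations".

### Parameters and defaults

| parameter | meaning | default | unit |
|---|---|---|---|
| τ₀ | speed dissipation time | 0.80 | s |
| γ_R | spontaneous turn scale | 0.35 (1 fish), 0.45 (2 fish) | rad |
| α | turn damping at the wall | 1 − γ_R⁰/γ_R ≈ 2/3 | – |
| γ_W | wall repulsion amplitude | 0.40 / 0.12 / 0.10 / 0.15 by condition | rad |
| l_w | wall interaction range | 60 (≈ 2 BL) | mm |
| ε_w,2 | cos 2θ_w wall anisotropy | 0.7 | – |
| l_c | comfort length | 21 / 30 / 45 by arena | mm |
| d₀ | attraction zero crossing | 30 (≈ 1 BL) | mm |
| l_Att | attraction range | 200 | mm |
| d₀′ | alignment offset | 30 | mm |
| l_Ali | alignment range | 200 | mm |
| γ_Att, γ_Ali | interaction amplitudes | 0.15, 0.08 | rad |

`ModelParams.reference(n_fish, radius)` returns the measured parameter set
for each experimental condition (arena radii 176, 250, 353 mm for one
fish; 250 mm for two).  Angular shapes are cosine series around sin θ
(odd) or 1 (even): O_w ∝ sin θ_w(1 + 0.7 cos 2θ_w),
O_Att ∝ sin ψ(1 − 0.33 cos ψ), E_Att ∝ 1 + 0.48 cos Δφ − 0.31 cos 2Δφ,
O_Ali ∝ sin Δφ(1 + 0.30 cos 2Δφ), E_Ali ∝ 1 + 0.60 cos ψ − 0.32 cos 2ψ.

Two scale conventions coexist deliberately.  The *simulator's* wall term
multiplies γ_W by the raw shape sin θ_w(1+0.7 cos 2θ_w), because the
tabulated γ_W values are calibrated in that convention.  The *measured*
factors produced by the inference module are instead normalized to unit
mean square over (−π, π] — the convention in which the Fourier
coefficients above are quoted — with all remaining scale (in radians)
carried by the distance factors.  The pair amplitudes γ_Att, γ_Ali have no
published values; they multiply shape-normalized profiles
(F̂_Att(l_Att) = 1; F̂_Ali = 1 at its maximum) and were calibrated once so
that (a) alignment dominates attraction below ≈ 75 mm and attraction above
(which fixes γ_Ali/γ_Att ≈ 0.53), and (b) the simulated inter-fish
distance distribution has its mode near 75 mm while the pair stays bound
(median distance well inside the arena diameter).

### Kick kinematics

Peak speed and kick length are log-normal (a gamma family is also
available).  Nominal parameters — single fish v = 165 ± 41 mm/s,
l = 92 ± 41 mm; pair v = 140 ± 35 mm/s, l = 64 ± 29 mm — are calibrated on
the *realized* statistics of arena simulations, because rejections near
the wall truncate long kicks: realized mean inter-kick duration ≈ 0.5 s
and mean glide speed (length/duration) ≈ 140 mm/s, with slightly shorter
kicks for two fish.  Draws with undefined duration (l ≥ vτ₀) or τ > 2 s
are rejected (the τ → ∞ divergence as l → vτ₀ would otherwise dominate
the mean).  Because a kick is by definition a burst, the new peak speed is
redrawn until it exceeds the end-of-glide speed, capped at the 98th
percentile of the speed distribution (an uncapped constraint ratchets the
speed into the distribution tail during chains of very short near-wall
kicks).

### Random numbers

Each fish consumes one named `numpy` Generator spawned from the run seed,
in a fixed documented order (kinematics, then the spontaneous turn, per
proposal), so runs are bit-for-bit reproducible given (seed, parameters).
`flip_angles=True` negates every angular draw; combined with a mirrored
initial condition this produces the exact mirror run and is used by the
equivariance tests.

## What the synthetic data emulates — and what it does not

The generator reproduces the features of tracked video data the analysis
relies on: 50 Hz planar positions of 1–2 fish in a circular tank,
burst-and-coast speed profiles, isotropic Gaussian tracking noise
(default 0.5 mm), wall accumulation, and left/right statistical symmetry.
It does not emulate body bending or shape (heading is always the glide
direction), finite-duration bursts (model bursts are instantaneous, so
speed jumps discontinuously), occlusions and identity swaps between fish,
parallax (a correction utility is provided separately), pauses and
inactivity phases, or non-circular tanks.  Tests passing on these data
therefore validate the measurement chain, not the tracking stage upstream
of it.

## Segmentation

Raw speed is the centred position difference over 0.08 s (one-sided at
the record edges), smoothed by a degree-3 Savitzky–Golay filter over
0.36 s.  At 50 Hz that span is 18 frames, an even count; a centred filter
needs an odd window, so 19 frames are used.  Samples are classified
accelerating/decelerating by the sign of the smoothed forward difference
(exact zeros attach to the preceding run); decelerations shorter than
0.08 s between accelerations are merged first, then accelerations shorter
than 0.08 s are discarded; each surviving acceleration's first sample is a
kick onset.  The first and last 9 frames are never onsets.  Activity
selection labels slow intervals (fastest fish below 0.5 BL/s) as pausing
(≤ 4 s, kept) or stopping (> 4 s, removed) and cuts the active record
into 120 s sections.  Per-kick variables: length and heading from the
inter-onset vector, duration from onset times, top speed as the maximum
*smoothed* speed between onsets (the raw maximum is noise-inflated), wall
and pair frames at the onset with the incoming heading.

Resolution limit: the 0.36 s smoothing window cannot separate kicks much
shorter than itself, so at the model's kick-duration distribution roughly
a third of kicks merge into neighbours, and detected onsets lead the true
burst by ≈ 0.12 s because the centred window reacts before the jump.
Detection is precise rather than complete: ≥ 90 % of detected onsets lie
within 0.2 s of a true kick, and (l, τ, δφ) of cleanly matched consecutive
detections are accurate to a few mm / tens of ms / < 0.1 rad.  Downstream
statistics computed from segmented tables are therefore biased toward
longer kicks; the inference pipeline is insensitive to this because every
detected decision still pairs a valid stimulus with its response.

## Inference: symmetry-constrained product factorization

Kick records are first doubled by mirror symmetrization (all signed
angles negated), then binned: (r_w, θ_w) on a 40×30 mesh over
[0, R]×[−π, π] for the wall case; (d, ψ, Δφ) on a 40×30×30 mesh with
d ≤ 280 mm for the pair case, after excluding kicks closer than 2 BL
(60 mm) to the wall.  Angular meshes are symmetric about zero so
mirroring maps bins onto bins.  Cells carry their record count ε and mean
response; empty cells carry no weight; no smoothing or regularization is
applied.

The factors are updated cyclically from their weighted normal equations
(for the pair case each update subtracts the other product term as a
counter-term), damped with p = 0.25.  After every cycle the angular
factors are projected onto their parity (odd factors antisymmetrized,
even symmetrized), renormalized to unit mean square — the scale moving
into the distance factors — and sign-fixed (non-negative mean of each
angular factor over the positive half-axis).  Iteration stops when the
largest relative change of any tabulated value falls below 10⁻⁶
(typically ~10²–10³ iterations); non-convergence is flagged, not raised,
and a near-zero distance factor flags a degenerate two-term solution.
Exactly-product tables are recovered to < 10⁻⁴ relative error, and the
converged error matches a direct numerical minimizer on small meshes.

Mesh resolution must be matched to the data volume: with fewer than
~10⁵ records on the 40×30 mesh the weighted objective can be dominated by
a handful of extreme-|δφ| records (the uniform-fallback kicks at the
wall), and the iteration drifts toward a spiked angular factor fitting
them.  The `infer` CLI exposes the mesh for this reason; tests use
proportionate meshes at small n.

## Parametric fits

All fits carry a free amplitude and are invariant under rescaling of the
table.  Profile fits (Gaussian wall range; (d−d₀)/(1+(d/l)²) attraction;
(d+d₀′)e^(−(d/l)²) alignment) use `scipy.optimize.curve_fit` over
*informative* bins — those with at least 100 effective records — with
equal weights by default; inverse-variance (count) weighting is available
but chases the near-wall systematic (see below) rather than the shape of
interest.  Angular factors are fitted linearly in the Fourier basis
(sin θ · cosines for odd, cosines for even, at most two harmonics) with
count weights; coefficients are reported as ratios to the leading
amplitude, matching the unit-mean-square convention.  A declared parity
inconsistent with the data (off-parity fraction > 20 %) is an error.

## Numerical choices

- Angles live in the half-open interval (−π, π]; −π maps to +π so mirror
  images are single-valued.  `wrap_angle` uses the exactly sign-symmetric
  form a − 2π·round(a/2π), on which the simulator's bit-exact mirror
  equivariance depends.
- A fish at the exact arena centre has an undefined wall normal; the
  frame is returned with θ_w = 0 and a degenerate flag, and such records
  are excluded from binning (measure-zero case).
- Normalization constants of the angular shapes are computed by
  trapezoidal quadrature on 8193 points (exact to ≪ 10⁻⁶ for
  trigonometric polynomials) and cached.
- Binning uses `numpy.histogramdd`: bins are left-closed right-open with
  a closed last bin; out-of-range records are dropped and counted.
- Convergence is measured as max |new − old| / (|old| + 10⁻¹²) over all
  tabulated values; the damped error sequence is monitored and is
  non-increasing (after the first cycles) on symmetrized data.

## Known limitations

- **Effective wall force ≠ explicit wall term.**  The measured wall
  response of simulated data has amplitude ≈ 0.7 rad at the wall, several
  times γ_W: most of it is generated by the arena-exit rejection rule,
  whose influence extends to r_w ≈ l + l_c, beyond the 2 BL cutoff used
  for the pair analysis.  Recovered wall parameters are therefore
  slightly inflated (l_w ≈ 62–67 mm vs 60; a₂ ≈ 0.83 vs 0.7), and a small
  wall residue contaminates the pair factorization.
- **Spontaneous-turn scale under-read near the cutoff.**  The damping
  factor 1 − αf_w is still 10–25 % active at r_w = 60–120 mm, and kicks
  beyond 2 BL concentrate just past the cutoff, so the sd of δφ measured
  on r_w > 60 mm kicks is ≈ 0.31 rad rather than γ_R = 0.35 (raising the
  cutoff to 4 BL recovers 0.347).
- **Finite-sample bias of the weak term.**  With 2×10⁵ two-fish kicks,
  the 2 BL cutoff and the 36 000-cell mesh leave ~1–2 records per cell;
  the alignment term (amplitude ≈ 0.08 rad against turn noise of
  0.45 rad) is then estimated with noticeable errors-in-variables bias —
  most visibly E_Ali's first cosine coefficient (recovered ≈ 0.7–0.9 vs
  0.60) and scatter in the attraction zero-crossing d₀ (≈ 23–44 mm vs
  30).  Feeding the factorization the noise-free interaction components
  recovers every quantity to ±0.02, so the bias is a property of the
  data volume and noise level, not of the estimator's implementation.
- The speed-relaxation time must be fitted on a fixed population of kicks
  (those lasting the full fit window); averaging all kicks alive at each
  lag underestimates τ₀ by ≈ 10 % because fast kicks are short.
- N > 2 fish, hydrodynamic coupling, 3-D motion, non-circular arenas and
  video tracking are out of scope.
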