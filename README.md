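# burstcoast

Tools for measuring and modelling the swimming decisions of fish that move
in a **burst-and-coast** style — brief accelerations ("kicks") at which the
animal picks a new heading, followed by quasi-passive straight glides.
Because the behaviour is discrete in time, a trajectory can be analysed as a
sequence of stimulus–response events: *what did the fish see at the kick,
and how much did it turn?*  The package implements the full loop

```
simulate  →  resample at 50 Hz  →  segment into kicks  →  infer interaction
functions  →  fit model parameters
```

so that the measurement method can be validated end-to-end on synthetic
data whose ground truth is known.  It is aimed at researchers in collective
animal behaviour working with tracked trajectories of small fish (e.g.
rummy-nose tetra, *Hemigrammus rhodostomus*) in circular arenas.

## The model

At kick *n* a fish at **x**ₙ with heading φₙ draws a peak speed *v*ₙ and a
kick length *l*ₙ; the glide duration follows from the exponential speed
relaxation (dissipation time τ₀ ≈ 0.8 s):

    lₙ = vₙ τ₀ (1 − e^(−τₙ/τ₀)),    x(tₙ+t) = xₙ + lₙ (1−e^(−t/τ₀))/(1−e^(−τₙ/τ₀)) e(φₙ₊₁)

The heading change at a kick is a sum of four terms,

    δφ = δφ_R(r_w) + δφ_W(r_w, θ_w) + δφ_Att(d, ψ, Δφ) + δφ_Ali(d, ψ, Δφ)

- **spontaneous**: δφ_R = γ_R [1 − α f_w(r_w)] g, a Gaussian turn damped
  near the wall, with f_w(r) = exp(−(r/l_w)²);
- **wall avoidance**: δφ_W = γ_W sin θ_w [1 + 0.7 cos 2θ_w] f_w(r_w), where
  (r_w, θ_w) are the distance to the wall and the heading relative to the
  outward normal;
- **attraction**: δφ_Att = F_Att(d) · O_Att(ψ) · E_Att(Δφ), with
  F_Att(d) ∝ (d − d₀)/(1 + (d/l_Att)²) — short-range repulsion below
  d₀ ≈ 30 mm, a maximum near l_Att ≈ 200 mm, and a 1/d visual tail;
- **alignment**: δφ_Ali = F_Ali(d) · O_Ali(Δφ) · E_Ali(ψ), with
  F_Ali(d) ∝ (d + d₀′) exp(−(d/l_Ali)²).

Here (d, ψ, Δφ) are the neighbour's distance, viewing angle and heading
difference; O-factors are odd (left/right antisymmetry), E-factors even
(anisotropic perception).  Proposed kicks whose endpoint (padded by a
comfort length l_c ≈ 1 BL) would leave the arena are rejected and redrawn,
which is what concentrates trajectories along the wall.

The measurement method is the inverse problem: bin the observed (stimulus,
δφ) pairs on a mesh and minimise

    Δ = Σ ε_cell (δφ_cell − product-of-factors)²

over *tabulated* one-variable factors with imposed odd/even parity, by a
damped fixed-point iteration (damping p = 0.25, no regularization),
after doubling the data with its mirror image.  Two factors (f_w·O_w) are
used for the wall; two three-factor terms for the pair interaction.
Parametric fits then turn the tabulated factors into the named parameters
(τ₀, l_w, d₀, l_Att, l_Ali, Fourier coefficients).

## Worked example

```python
import burstcoast as bc
from burstcoast.inference import Mesh, bin_2d, factorize_2d, symmetrize

# one fish, largest arena (R = 353 mm), reference parameters
run = bc.simulate(1, 50_000, 353.0, seed=42)
stats = bc.kick_statistics(run.kicks, radius=353.0)
print(f"mean kick duration: {stats['mean_tau_s']:.3f} s")
print(f"mean kick length:   {stats['mean_l_mm']:.1f} mm")
print(f"active-phase speed: {stats['mean_glide_speed_mm_s']:.0f} mm/s")
print(f"modal wall distance: {stats['r_w'].mode:.1f} mm")

# measure the wall interaction back from the kicks
records = symmetrize(run.kicks)
mesh = Mesh.wall(353.0, 20, 15)           # mesh proportionate to 100k records
result = factorize_2d(bin_2d(records, mesh))
print(f"factorization: converged={result.converged} after {result.iterations} iterations")
lw = bc.fit_wall_range(mesh.centers(0), result.factors["f"],
                       weights=result.bin_weights["f"])
a2 = bc.fit_fourier(mesh.centers(1), result.factors["O"], parity="odd",
                    harmonics=(2,), weights=result.bin_weights["O"])
print(f"wall interaction range l_w = {lw.params['l_w']:.1f} mm")
print(f"angular anisotropy a2 = {a2.params['c2']:.2f}")
```

prints

```
mean kick duration: 0.547 s
mean kick length:   62.2 mm
active-phase speed: 133 mm/s
modal wall distance: 13.2 mm
factorization: converged=True after 243 iterations
wall interaction range l_w = 69.2 mm
angular anisotropy a2 = 0.80
```

Kicks last about half a second at an active-phase speed near 140 mm/s, the
fish accumulates within half a body length of the wall, and the closed loop
recovers the generating wall-interaction range (l_w = 60 mm) and angular
shape (a₂ = 0.7) from the kicks alone — the systematic excess in both comes
from the arena-exit rejection mechanism, which acts as additional effective
wall repulsion (see `docs/methods.md`).

The same workflow is available from the shell:

```bash
burstcoast simulate --fish 2 --radius-mm 250 --kicks 100000 --seed 1 --out kicks.csv
burstcoast infer --kicks kicks.csv --mode pair --out factors.csv --diagnostics diag.json
burstcoast fit --factors factors.csv --model attraction --out att.json
burstcoast stats --kicks kicks.csv --pair --out summary.json
```

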