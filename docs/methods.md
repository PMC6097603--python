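# Methods

## Model

Each rotor *i* (0 ≤ *i* < *N*) is a sphere of radius *a* whose centre moves
in the plane *z* = *h* parallel to a no-slip wall at *z* = 0. Its trap
prescribes a circular orbit of radius *R* about the centre
(*iℓ*, 0, *h*): a constant tangential drive of magnitude
*F<sub>i</sub>* = *F*<sub>dr</sub>·*D*<sup>*i*−0.5</sup> and a radial
harmonic restoring force −*λ*(ρ<sub>*i*</sub> − *R*). The geometric ladder
*D* > 1 makes rotor *i*+1 intrinsically faster than rotor *i* by the factor
*D*; across six rotors the spread is *D*⁵ (≈ 5% at *D* = 1.01). The state
is (φ<sub>*i*</sub>, ρ<sub>*i*</sub>) per rotor — orbital phase and radial
excursion — i.e. planar confinement: wall-normal velocity components of the
coupling flow are discarded, since the traps define a planar array of
orbits and no vertical dynamics enter the model. Thermal fluctuations are
neglected throughout; the dynamics are fully deterministic given the
initial phases.

At zero Reynolds number the force balance gives the mobility relation

v<sub>*i*</sub> = F<sub>*i*</sub><sup>ext</sup>/(ζ₀ζ<sub>w</sub>) +
Σ<sub>*j*≠*i*</sub> **G**(x<sub>*j*</sub>, x<sub>*i*</sub>)·F<sub>*j*</sub><sup>ext</sup>,

with ζ₀ = 6πμ*a*, the wall drag correction
ζ<sub>w</sub>(*h*) = 1 + (9/16)(*a*/*h*) (leading order in *a*/*h*; the
model requires *h* > *a*), and **G** the Blake Green's function: free-space
Stokeslet minus image Stokeslet plus source-doublet and Stokes-doublet
images at the mirror point. Beads are point-like for mutual coupling; the
finite radius enters only through ζ₀ζ<sub>w</sub>. No Faxén corrections,
torques, stresslets or lubrication. The instantaneous bead positions (not
the orbit centres) are used in **G**, so temporal variations of the
interparticle spacing are retained — one reason the full simulation
couples slightly more strongly than the averaged theory below. The
`nearest_neighbor` truncation restricts the coupling sum to |*i*−*j*| = 1
without moving any bead.

## Averaged pair theory

For two rotors the phase difference χ = φ₁ − φ₀ obeys, after averaging
over the fast rotation,

χ̇ = ν − *k* sin χ,  ν = (*F*₁−*F*₀)/(*R*ζ₀ζ<sub>w</sub>),
*k* = (3*a*/4*ℓ*)·*F*₀*F*₁/(*λ*ζ₀*R*²)·[2*A*(β) + *B*(β)],

where β = 2*h*/*ℓ*, *X* = 1/√(1+β²), *A* = 1 − *X* − (β²/2)*X*³,
*B* = 1 − *X*³ + (3β²/2)*X*⁵. *A*, *B* → 0 at the wall (full screening)
and → 1 in bulk. Locking is lost at |ν| = *k* (saddle-node); beyond it the
time-averaged drift is χ̇<sub>av</sub> = √(ν²−*k*²), and with the geometric
drive ladder the boundary is explicit:
*D** = ((C+√(C²+4))/2)² with
C = (3*a*/4*ℓ*)(*F*<sub>dr</sub>ζ<sub>w</sub>/(*λR*))[2*A*+*B*].
The locked branch returns drift exactly 0 (the square-root law applies only
to non-locked states).

The theory is leading order in *a*/*ℓ* and *R*/*ℓ*. At the reference
geometry (*R*/*ℓ* = 0.173) the simulated coupling is ~35–40% stronger than
*k*; the ratio falls to 1.08 when *ℓ*, *h* are scaled 3× and 1.02 at 10×.
Practical consequence: simulation and theory agree on the drift to within
10% only once *D* is above both thresholds (e.g. *D* ≥ 1.2 at
*h* = 4.2 μm); immediately above the theoretical *D** the square-root
normal form makes any relative comparison unbounded.

Neighbour-coupling fractions: the coupling of an end rotor with its *n*-th
neighbour is *k* evaluated at separation *nℓ* (β<sub>n</sub> = 2*h*/(*nℓ*)),
normalised over *n* = 1…5. Its near/far limits are the power-law fractions
*S*(*n*) = *n*<sup>−j</sup>/Σ<sub>i=1..5</sub>*i*<sup>−j</sup> with *j* = 3
(wall-screened) and *j* = 1 (bulk): *S*(1) = 0.843 and 0.438 respectively.

## Numerics

- Integrator: `scipy.integrate.solve_ivp`, DOP853, rtol 10⁻⁸, atol 10⁻¹⁰
  (validated by a tolerance-tightening invariant: 10× tighter tolerances
  change the measured drift by < 1%). For artificially rigid orbits
  (*λ* orders of magnitude above physical) the radial equation becomes
  stiff (relaxation time ζ/λ ≪ rotation period) and an implicit method
  (`method="BDF"`/`"Radau"`) must be selected.
- Sampling: uniform grid with 100 samples per nominal period 2π/⟨ω<sub>i</sub>⟩.
  The observed rotation runs a few percent faster than ω<sub>i</sub>
  (collective advection), so this keeps ≥ 50 samples per actual period, the
  minimum the metrics layer accepts for unambiguous unwrapping.
- Initial conditions: ρ<sub>*i*</sub> = *R* exactly; φ<sub>*i*</sub> uniform
  on [0, 2π) from a stored seed. Orientation is counter-clockwise for all
  rotors; no reported statistic depends on it.
- The feedback-delay factor γ = 2.21 converts an experimentally calibrated
  trap stiffness to its ideal-trap simulation equivalent
  (λ_sim = γ·λ_exp); it is applied only when a configuration is explicitly
  flagged `lambda_is_experimental`. Default stiffnesses are taken at face
  value, matching the phase-diagram axes.

## Metrics and conventions

- **Slips**: each pairwise difference χ<sub>n</sub> is referenced to its
  initial plateau; a slip is counted at every crossing of an odd multiple
  of π of the centred signal (equivalently, each completed 2π excursion
  counts once, bounded oscillations below π never do). Direction is the
  sign of the jump.
- **Wobbles**: the signal φ<sub>i</sub> − φ₀ (default *i* = 1, the
  initiating pair; configurable) is detrended by a centred rolling median
  over 20 nominal periods. A wobble is a locally peaked excursion ≥ W_min
  (default 0.5 rad — the observed events are of order 1–2 rad) that
  returns to within W_min/2 of baseline; W is the peak excursion, τ the
  time since the previous onset, and a slip anywhere in the chain within
  one baseline window marks the wobble as terminating at that position.
- **Order parameter**: *Z* = (1/(*N*−1)) Σ<sub>n=0..N−2</sub>
  e<sup>iχ<sub>n</sub></sup> over the *N*−1 neighbouring pairs (the sum
  runs over pairwise differences, hence N−1 terms to match the prefactor).
  Ā is the time-mean of |Z| and Ψ̄ the circular mean of arg Z (Ψ is an
  angle), both for *t* > 200 s.
- **Drift per beat**: net change of the unwrapped φ<sub>N−1</sub> − φ₀
  over (200 s, t_end), in units of 2π, divided by the number of *nominal*
  beats 2π/⟨ω<sub>i</sub>⟩ in the window. The nominal period is used
  rather than the trajectory-measured one so that the beat unit is fixed
  by the drive parameters and independent of the coupling-induced
  collective speed-up (~23% at *h* = 50 μm); with the observed-period
  convention every drift-per-beat figure would be ~20% smaller. The period
  is an explicit argument for callers who want the other convention.
- **Classification** (per sweep cell): |drift per beat| > 10⁻³ →
  defect-punctuated; else |Ψ̄| < 0.05 rad → chevron; else MW. Thresholds
  are configuration constants.
- Truncated-coupling runs lock completely after the initial transient at
  both *h* = 5 μm and *h* = 1000 μm; a net drift below one slip per
  analysis window (≈ 5×10⁻⁴ beats/beat over 1800 s) is reported as zero,
  and the height variation is normalised by the larger drift magnitude or
  by that resolution floor, avoiding a 0/0 comparison between two locked
  runs.

## Problem sizes and runtime

Chain statistics (drift peak, truncation comparison) use the reference
six-rotor chain over 0 ≤ *t* ≤ 2000 s (~2200 beats, burn-in 200 s), about
one minute each on one CPU. Pair-level checks use 2-rotor runs of
120–300 s. The default sweep grid is a coarse 8×8 (h log-spaced
5–1000 μm, λ 1–10 pN/μm); denser grids are opt-in via configuration.

## Scope and limitations

- The synthetic dynamics contain no thermal noise, no trap time-sharing
  artifacts and no feedback-delay dynamics (beyond the static γ factor),
  so experimental event statistics (wobble amplitudes/recurrence, measured
  synchronization boundaries) are reproduced qualitatively, not pointwise;
  passing tests validate the deterministic model, not noisy-data behaviour.
- The wall-drag correction is first order in *a*/*h*; heights within a few
  radii of the wall are outside the model's validity (and rejected).
- Planar confinement discards wall-normal motion; whether small vertical
  excursions would shift the defect statistics is untested here.
- Long chains (*N* ≫ 6) are configurable but unprofiled; cost scales as
  O(*N*²) per step with full coupling.
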