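# rotorchain

Deterministic simulation and theory of hydrodynamically coupled colloidal
rotors above a plane no-slip wall — a minimal model of a ciliated surface.

Arrays of eukaryotic cilia coordinate into metachronal waves (MWs) through
the fluid flows they generate. A tractable surrogate replaces each cilium
with a bead of radius *a* driven around a circular orbit of radius *R*
(tangential force *F<sub>i</sub> = F*<sub>dr</sub>*D*<sup>*i*−0.5</sup>,
radial spring stiffness *λ*) at height *h* above a no-slip boundary, with
centre-to-centre spacing *ℓ*. The wall screens the hydrodynamic coupling:
wall-parallel disturbances decay as *r*<sup>−3</sup> for *β* = 2*h*/*ℓ* ≪ 1
but as *r*<sup>−1</sup> for *β* ≫ 1, so the height tunes the *range* of the
interaction. Raising a mildly detuned chain (*D* = 1.01) away from the wall
destabilises its travelling wave: wobbles appear, then periodic phase
defects (2π slips), and at soft stiffness the pattern instead morphs into a
chevron profile. `rotorchain` reproduces all of this numerically and
analytically:

- **hydrodynamics** — the Blake image tensor (Stokeslet + image system) for
  point forces above a no-slip wall, wall-corrected drag
  *ζ*<sub>0</sub>*ζ*<sub>w</sub>(*h*) = 6π*μa*·(1 + (9/16)(*a*/*h*)), and the
  mobility relation *v<sub>i</sub>* = *F<sub>i</sub>*/(*ζ*<sub>0</sub>*ζ*<sub>w</sub>) +
  Σ<sub>*j*≠*i*</sub> **G**(*x<sub>j</sub>*, *x<sub>i</sub>*)·*F<sub>j</sub>*,
  with optional nearest-neighbour truncation.
- **rotor_simulator** — the 2*N*-dimensional (φ<sub>*i*</sub>, ρ<sub>*i*</sub>)
  dynamics integrated with an adaptive high-order Runge–Kutta scheme.
- **pair_theory** — the averaged two-rotor Adler equation
  χ̇ = ν − *k* sin χ with ν = (*F*<sub>1</sub>−*F*<sub>0</sub>)/(*Rζ*<sub>0</sub>*ζ*<sub>w</sub>),
  *k* = (3*a*/4*ℓ*)·*F*<sub>0</sub>*F*<sub>1</sub>/(*λζ*<sub>0</sub>*R*²)·[2*A*(β)+*B*(β)],
  its drift law χ̇<sub>av</sub> = √(ν²−*k*²), the critical detuning *D**(*h*),
  and the neighbour-coupling fractions *S*(*n*).
- **chain_metrics** — phase unwrapping, slip and wobble detection, the
  order parameter *Z* = *A*e<sup>iΨ</sup> = (1/(*N*−1)) Σ e<sup>iχ<sub>n</sub></sup>,
  end-to-end drift per beat, kymographs.
- **sweep** / **cli** — (h, λ) phase-diagram driver and the `rotorchain`
  command line (`simulate`, `pair-scan`, `sweep`, `metrics`).

## Worked example

```python
import numpy as np
from rotorchain import (PhysicalParams, simulate, critical_detuning,
                        coupling_fraction)
from rotorchain.chain_metrics import drift_per_beat, order_parameter

p2 = PhysicalParams(N=2)           # reference parameters, two rotors
print(round(critical_detuning(4.2e-6, p2), 3))   # 1.135
print(round(coupling_fraction(1, 3), 2))         # 0.84

# six-rotor chain at the defect peak: lambda = 4.5 pN/um, h = 50 um
p6 = PhysicalParams(N=6, D=1.01, h=50e-6, lambda_=4.5e-6,
                    t_end=2000.0, seed=1)
traj = simulate(p6)                # ~1 min
print(round(drift_per_beat(traj), 3))            # 0.185
print(round(order_parameter(traj).A_bar, 2))     # 0.67
```

The pair loses phase locking at *D** ≈ 1.135 at the lowest height, and 84%
of an end rotor's coupling is carried by its nearest neighbour in the
wall-screened limit. The six-rotor chain at *h* = 50 μm drifts ≈ 0.19 beats
per beat — the end rotors slip roughly one full beat in every five — with a
degraded order-parameter amplitude *Ā* ≈ 0.67, the defect-punctuated state.
The same chain simulated with coupling truncated to nearest neighbours
locks completely, at *h* = 5 μm and *h* = 1000 μm alike: the defects are a
long-range-interaction effect.

From a shell:

```sh
rotorchain simulate --config config.yaml --out run/
rotorchain metrics --traj run/trajectory.csv
rotorchain sweep --config sweep.yaml --out grid/
```

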