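# myoarch

A 2D lattice simulator of myofibrillogenesis — how a cardiac myocyte
confined to a micropatterned adhesive island builds and organizes its
contractile cytoskeleton.  The package is aimed at quantitative cell
biologists and modelers who want to ask how boundary geometry (square,
triangular, circular or stair-step islands, or an arbitrary mask) shapes
focal-adhesion placement, myofibril orientation and substrate traction.

## The model in brief

Three integrin density fields live on an area-normalized lattice Ω:
free integrin ρ_f, premyofibril-bound ρ_p and nascent-myofibril-bound
ρ_n, with Φ₀·A total integrin conserved exactly.  Every pair of mutually
visible lattice points carries a contractile fiber of weight
f_p(r)f_p(r′) + G·f_n(r)f_n(r′), where f_c = ρ_c/(ρ_c+ε) is a Langmuir
adsorption fraction; the pair tension optionally scales with fiber length
(toggle *L*).  The net force **F**(r) — the vector sum of all pair
tensions over the visibility set Λ(r) — stabilizes adhesions (binding
rate k_b + k_F|F|), matures premyofibrils into nascent myofibrils (rate
k_m|F|), and translates into substrate traction **T** = −**F**.  Nascent
fibers carve Gaussian attraction wells χ along their length; free
integrin, whose diffusion is treated as instantaneous, redistributes as
exp(−σχ) (toggle *τ*), which laterally couples adjacent bundles.

Read-outs per lattice point: fiber density p(r), director θ(r) and
orientational order parameter (OOP, 0 = isotropic to 1 = aligned) from
the Fourier modes of the directional fiber distribution, and the
parallel-coupling index ψ = (normalized nascent density) × (nascent OOP).

## Worked example

```python
import numpy as np
from myoarch import (ModelParams, Scenario, ShapeSpec, run_simulation,
                     fiber_length_field, global_orientation)

scen = Scenario(name="stair", shape=ShapeSpec("stair"), params=ModelParams())
traj = run_simulation(scen, seed=1)
print(f"conservation residual: {traj.conservation_max:.2e}")
print(f"steady psi_mean:       {traj.psi_mean[-1]:.3f}")

dom = traj.domain
field = fiber_length_field(traj.final_state, dom,
                           k=scen.params.angular_bins,
                           epsilon=scen.params.epsilon)
direction, oop = global_orientation(field, "n")
print(f"global nascent director: {np.rad2deg(direction):.0f} deg, OOP {oop:.2f}")
```

prints

```
conservation residual: 4.44e-16
steady psi_mean:       0.256
global nascent director: 135 deg, OOP 0.45
```

i.e. total integrin is conserved to machine precision, the parallel
coupling has settled near 0.26, and the nascent myofibrils bundle along
the stair island's major diagonal (135°) with substantial global order —
the architecture such stair-shaped myocytes show in culture.  Rerunning
with `ModelParams(length_dependent=False)` drops the global nascent OOP
to ≈ 0.2 and spreads the directors over several orientation bands: the
fiber length–force dependence is what selects the major diagonal.

The same loop is available from a shell:

```
myoarch run --shape stair --seed 1 --out out/
myoarch battery --seeds 1,2,3
myoarch analyze out/trajectory.h5
myoarch sarcomere profile.csv --pixel-size 0.1
```

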