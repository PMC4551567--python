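# retistim

Computational modelling of epiretinal electrical stimulation: how the
geometry of a 3-D microelectrode — its shape (flush disk, concave or
convex hemisphere, concave or convex cone), its size, and its distance
from the retina — determines which retinal ganglion cells (RGCs) it
excites, at what current, and at what electrochemical cost.

The package is aimed at neural-prosthetics modellers comparing electrode
designs.  It couples

1. a **layered volume conductor**: the quasi-static potential
   ∇·(σ∇φ) = 0 solved by axisymmetric finite volumes over vitreous +
   eight retinal layers, with the electrode metal as an equipotential
   surface rescaled to a target cathodic current;
2. a **multicompartment RGC model**: soma, 90°-bend initial segment,
   high-density sodium-channel band and 1 mm distal axon, with five
   active currents (Na, K_DR, K_A, K_Ca, Ca) plus leak,
   C_m dE/dt = −Σ Ĝ_x·gates·(E−E_x) − Ĝ_l(E−E_l), driven extracellularly
   through the axial coupling of V_m + V_e and integrated implicitly;
3. **population metrics**: threshold current TC (minimum cathodic
   amplitude activating any of 625 seeded-random RGCs in a
   400×400×50 μm patch), threshold charge density TCD = TC·width/area,
   activated RGC area (convex hull of activated somata), and
   charge-density profiles q(r) = |J|·width at the retinal surface.

See `docs/methods.md` for the model details and the design choices.

## Worked example

Threshold and charge density of a 100 μm disk electrode 20 μm from the
retina, for a 0.4 ms cathodic pulse against a seeded 625-cell population:

```python
from retistim import (ElectrodeShape, ElectrodeSpec, build_layer_stack,
                      solve_potential, generate_population,
                      population_threshold, tcd)
from retistim.rgc import StimulusPulse

spec = ElectrodeSpec(ElectrodeShape.DISK, projection_diameter=100.0, erd=20.0)
sol = solve_potential(build_layer_stack(erd=20.0), spec, current_ua=-20.0)
layout = generate_population(seed=1, n=625)
tc = population_threshold(layout, sol, StimulusPulse(width_ms=0.4))
print(f"TC  = {tc:.2f} uA")
print(f"TCD = {tcd(tc, 0.4, spec):.4f} mC/cm2")
```

prints

```
TC  = 5.09 uA
TCD = 0.0259 mC/cm2
```

i.e. the most sensitive of the 625 cells fires from a 5.09 μA cathodic
pulse, and delivering that charge over the disk's geometric surface works
out to 0.026 mC/cm² — far below the 0.1–0.35 mC/cm² electrochemical
safety limits.  The same objects expose field maps
(`field_strength_profile`), single-cell threshold-vs-position profiles
(`threshold_position_profile`), activated-area curves (`area_vs_current`)
and the edge-effect charge-density analysis
(`retistim.experiments.run_edge_effect`).

A CLI wraps the same library calls:

```bash
retistim solve --shape disk --diameter 100 --erd 40 --current -20e-6
retistim population --diameter 100 --erd 20 --seed 1
retistim sweep erd --out results/
retistim validate
```

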