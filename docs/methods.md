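# Methods

`retistim` models how three-dimensional microelectrodes placed in the
epiretinal space excite retinal ganglion cells (RGCs).  The pipeline has
three stages: a quasi-static volume-conductor solve for the extracellular
potential, a multicompartment active-membrane simulation of single RGCs
driven by that potential, and population-level metrics that summarise an
electrode design (threshold current, threshold charge density, activated
RGC area, interface charge-density profiles).

## Volume conductor

Tissue is a purely resistive layered continuum, so the extracellular
potential obeys ∇·(σ∇φ) = 0.  The domain is a cylinder of radius 1.4 mm:
an insulating polyimide substrate carrying the electrode at the bottom, a
vitreous gap whose thickness equals the electrode–retina distance (ERD),
and eight retinal layers (NFL 24 μm and GCL 49 μm at 0.0126 S/m, IPL 40 μm
at 0.0571, INL 38 μm at 0.0147, OPL 30 μm at 0.0571, ONL 91 μm at 0.0147,
photoreceptor outer segments 25 μm at 1.0309, RPE 35 μm at 0.0010 S/m;
vitreous 1.2821 S/m).  z = 0 sits at the vitreous/NFL interface with z
increasing into the retina.

The electrode metal is an ideal equipotential (Dirichlet) surface —
platinum is ~9 orders of magnitude more conductive than tissue — and the
unit solve is rescaled so the surface-integrated electrode current equals
the requested cathodic amplitude; this linear-scaling contract is exact
and is asserted in tests.  Five shapes are supported: a flush disk, and
concave/convex hemispheres and right-angle cones (apex half-angle 45°,
height = projection radius).  ERD is measured to the nearest metal point:
the rim/face plane for disk and concave shapes, the apex for convex
shapes (a rim-plane reference would push the convex apex through the
retina at small ERD); the reference is configurable.

Discretisation is cell-centred finite volumes on a graded tensor (r, z)
grid with harmonic-mean face conductivities, which keep the normal flux
continuous across the three-orders-of-magnitude conductivity jumps.
Cells are ≤1 μm over the electrode and through the NFL/GCL (≤0.5 μm
around non-planar metal, which is represented by cell masking rather than
body-fitted meshing), and coarsen geometrically away from the region of
interest with adjacent-spacing ratios ≤1.3; segment transitions use an
exact geometric bridge so the ratio bound holds across layer interfaces.
The sparse system is solved by LU factorisation; the relative residual
must be ≤1e-8 and the electrode/boundary current balance closes to ~1e-12.
A convergence helper re-solves at a ladder of resolutions and flags runs
whose GCL field maximum is not grid-independent to 1 %.

Boundary conditions: the return electrode is "at infinity", which a
1.4 mm domain cannot represent literally; we ground the lateral wall and
the surface above the RPE, and insulate the substrate underside and the
axis.  Enlarging the domain radius to 2.8 or 5 mm changes the peak GCL
field by under 1 % at ERD 20 and ~3 % at ERD 80, so the finite ground
placement is not the dominant uncertainty.

The homogeneous-medium solver is validated against Newman's equipotential
disk solution φ(z) = (2V₀/π)·arctan(a/z) with V₀ = I/(4σa) (and its
half-space point-source far field I/(2πσd)) to within 2 %.

### Interface charge density

The safety profile q(r) at the inner retinal surface is the current
density magnitude on the vitreous side of the NFL/vitreous interface
multiplied by the pulse width, reported in μC/cm².  The magnitude (not
just the normal component) is used deliberately: almost all of the
injected charge travels laterally through the thin vitreous gap, and that
tangential flow — which peaks sharply above the electrode rim — is what
produces edge-effect exposure on the scale of tens of μC/cm²; the normal
component alone is two orders of magnitude smaller because the retina is
~100× more resistive than the vitreous.  A `component="normal"` option
reports the current actually entering the tissue.

## Single-cell model

Morphology (all lengths μm): a spherical soma (diameter 24, membrane area
πd²); S1, the axon hillock/initial segment, leaves the vitread pole of
the soma with a 0.5 vertical drop, a 90° bend of radius 5 and a 40
horizontal run (path length 48.35); S2, a 40-long sodium-channel band;
S3, a 1000-long distal axon.  The axon points nasally (−x) as for
right-eye macular cells.  Compartments are ≤1 μm in S1/S2 and the
proximal 100 μm of S3, ≤5 μm distally; thresholds change <2 % when the
time step is halved and the discretisation is convergence-checked.

Channel densities (mS/cm², ordered soma/S1/S2/S3): Na 70/100/350/80 — the
band carries the peak value; K delayed-rectifier 18/45/18/18; A-type
54/54/54/0; Ca 1.5/1.5/0/0; K(Ca) 0.065 everywhere; leak 0.005
everywhere.  Reversals: E_Na +35 mV, E_K −75 mV, E_Ca +132 mV.  C_m is
1 μF/cm².  Gating follows dx/dt = α(1−x) − (α+β)x with the salamander-RGC
rate expressions; removable singularities (α_m, α_n, α_c and α_a) are
evaluated through x/(eˣ−1) with its analytic limit.  The printed α_a
variant with a mismatched exponential shift has a true pole at −40 mV; the
default uses the consistent (V+90) form, the printed one is available
behind a flag with clamped evaluation.  The K(Ca) current is gated by a
saturating function of intracellular calcium, ([Ca]/1 μM)/(1+[Ca]/1 μM);
calcium follows d[Ca]/dt = −I_Ca·(A/V)/(2F) − ([Ca]−0.1 μM)/1.5 ms.

Choices the source tables leave open, fixed here once:

- **Axial resistivity** 110 Ω·cm (the standard value of this model
  lineage; nowhere printed).
- **Resting potential** −65 mV.  The leak reversal is computed per
  compartment from the steady-state current balance so the settled rest
  sits exactly there; a 70 ms drift check guards against spontaneous
  activity.
- **Axon diameters** S1 1.0, S2 0.9, S3 1.0 μm (soma 24).  The printed
  diameter row is typographically ambiguous.  A 3 μm S1 — one plausible
  reading — loads the proximal half of the sodium band so heavily that
  the threshold-position minimum moves ~20 μm distal of the band; with a
  thin initial segment (anatomically the axon initial segment of an RGC
  is ~1 μm) the minimum sits over the band (55–80 μm) for every ERD and
  soma depth tested, matching the validation experiment this morphology
  exists to reproduce.  All diameters are constructor arguments.

Integration is backward Euler on the cable equation with
extracellular drive entering through the axial coupling of
V_i = V_m + V_e (the activating-function pathway), gates updated by the
unconditionally stable implicit rule (x + dtα)/(1 + dt(α+β)) which keeps
them in [0,1] for any trajectory, and a tridiagonal (Thomas) solve per
step; dt defaults to 5 μs.  The integrator is cross-validated against a
high-accuracy stiff ODE solution (LSODA, rtol 1e-8) of the identical
370-compartment system: maximum deviation 0.07 mV over a 3 ms stimulus.
The kernel is JIT-compiled with numba when available and runs unmodified
(slower) in pure Python otherwise.

Activation means an upward crossing of 0 mV at the distal end of S3
within 5 ms of pulse onset — a propagated spike, not a local
depolarisation.  Thresholds are found by bracket expansion and bisection
on the cathodic amplitude to 1 % relative tolerance (cap 1 mA); the
quasi-static field scales linearly with current, so one unit-current
field solution serves every amplitude.  The stimulus is a 0.4 ms
monophasic cathodic rectangular pulse unless stated.

## Population model and metrics

The synthetic population places n = 625 somata i.i.d.-uniformly (seeded
`numpy` generator; bit-reproducible) in a 400 × 400 × 50 μm box whose
depth band lies in the GCL (z ∈ [24, 74] μm), reproducing ~3906
cells/mm² — the macular density the study design calls for.  All axons
point nasally.  Cells are electrically independent, so the field is
sampled per cell (by radial symmetry) and activation is evaluated per
cell.  What this generator does *not* emulate: clustered or laminated
real somata, dendritic arbors, varying axon trajectories and diameters,
synaptic input, and ephaptic coupling; passing tests therefore validate
the stimulation model, not retinal biology beyond it.

Population threshold current (TC) is the minimum over cells of the
per-cell threshold.  Cells are ranked by an activating-function prescreen
(largest capacitance-normalised axial drive over the band/distal-axon
compartments at unit current) and the top 25 are bisected; the prescreen
is validated against full per-cell sweeps in the tests (12/12 exact
matches across shapes, ERDs and seeds), and an optional verification
sweep re-checks every remaining cell at the found minimum.  Threshold
charge density is TCD = TC × width / electrode surface area (disk πr²,
hemisphere 2πr², cone πr√(r²+h²)).  The activated RGC area is the planar
convex hull of activated somata (0 below three cells); count/density and
alpha-shape estimators are provided because the reference population
study's exact estimator is not described.

## Experiments

Four drivers sweep ERD (Φ=100 disk, ERD 20–80), disk diameter (50–200 at
ERD 40), the five shapes (100 μm projection), and the edge-effect
configurations (disks by diameter and by ERD, plus the five shapes at
50 μm projection and ERD 20, each driven at its published threshold
current or at recomputed ones).  Results are long-format pandas tables
keyed by configuration and seed, with ordinary least-squares trend fits.
Problem sizes used by the shipped tests: full 625-cell populations for
the threshold sweeps and a 100-cell scaled-down mode for the ten-seed
area-ordering study; the scaled-down mode preserves every ordering
reported here while absolute areas shrink with the cell count.

## Known limitations and observed discrepancies

- Absolute excitability sits ~1.8–2.7× above the reference values (e.g.
  population TC for the Φ=100 disk at ERD 20 computes to ≈5.1 μA against
  a published 2.61 μA), with every ordering, monotonicity and
  profile-shape result reproduced, and the field solver validated
  independently (peak GCL field for the Φ=50 disk at ERD 20 within 0.2 %
  of the published 4176 V/m).  The reference model's own threshold for
  one identical configuration is printed as both 2.46 and 3.66 μA in
  different places, so part of this gap is irreducible ambiguity in
  morphology/placement details that are not stated (axon diameters,
  resting potential, axial resistivity, soma size).  No parameter was
  adjusted toward the published thresholds.
- The concave/convex central-field ratio computes to ~2.4 (published:
  1.5) at every radius and depth in the GCL: with ERD referenced to the
  apex, a convex electrode keeps most of its metal 50+ μm farther from
  the retina and its field is uniformly weaker.  The cone/hemisphere peak
  ratio computes to 0.98–0.99 (published 1.02).
- The largest edge-effect peak at published threshold drives computes to
  ~33 μC/cm² (published bound: 30), grid-converged to ±1 %; peak values
  depend on how the reference evaluated |J| exactly at the interface.
- Capacitive/dispersive tissue, the electrode double layer, curved
  retina, and multi-electrode arrays are out of scope.
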