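# Methods

This note documents the physical model, the numerical choices, and what
the synthetic fixtures and desk-scale presets do and do not establish.

## Dynamics

Positions of filament vertices and tetramer centers evolve by explicit
Euler–Maruyama integration of the overdamped Langevin equation

    dx = μ f_tot dt + dB,    dB ~ N(0, 2 D dt),  D = μ kBT,

with `dt = 2 ms` and `kBT = 0.0042 pN·μm`. Mobilities are Stokes-like,
`μ = 1/(3π η d)`, with an effective medium viscosity `η = 1 Pa·s`
reflecting the crowded droplet interior, `d = L_seg = 0.1 μm` for filament
vertices and `d = 60 nm` for tetramers (so `D_tet ≈ 0.0074 μm²/s`). All
three are configurable (`MechParams`).

Forces are (i) discrete worm-like-chain bending,
`E = (κ/L_seg)·Σ(1 − cos θ)` with `κ = Lp·kBT` and `Lp = 17 μm` (the
accepted value for F-actin; configurable); (ii) Hookean site–anchor bond
springs; (iii) a linear soft-core repulsion between tetramer centers
(contact 60 nm) and between tetramers and filament vertices (contact
35 nm), assembled through k-d-tree neighbor lists. Filament–filament
sterics are omitted: all effective filament–filament interaction is
mediated by explicit crosslinkers.

After the unconstrained update, segment lengths are restored by Newton
iteration on the constraint Lagrange multipliers (the SHAKE linear system,
tridiagonal along each chain, solved with a banded solver); corrections
sum to zero so each filament's center of mass is preserved. Convergence
tolerance is 1e-3 relative, typically reached in 2–3 iterations. Beads
outside the boundary are then projected to the nearest boundary point
(radially for spheres; via a vectorized monotone Newton solve of the
Lagrange condition for spheroids).

A step in which any bead would move farther than one segment length
aborts the run with a diagnostic rather than silently continuing — the
displacement guard is the instability detector.

**Stability and the bond stiffness.** Explicit Euler requires
`μ_tet·k_total·dt < 1` for the stiffest bead. A tetramer can carry four
bonds plus steric contacts, so the default bond stiffness is 25 pN/μm
(`μ_tet·(4·25 + 100)·0.002 ≈ 0.7`). Stiffer springs are configurable but
demand a smaller time step. With 25 pN/μm a bond stretched by the full
60 nm tetramer diameter carries 1.5 pN — of the same order as the Bell
force scale, so slip-bond kinetics remain meaningfully force-sensitive.

**Validation.** The integrator reproduces (tests): the Einstein relation
for free tetramers (MSD slope = 6D within 5%); exponential unloaded bond
lifetimes with mean 1/k_unbind0; the doubling of the off-rate at
`F = F_bell·ln 2`; and worm-like-chain end-to-end statistics
`⟨R²⟩ = 2LpL − 2Lp²(1 − e^{−L/Lp})` within 10% for L = 1 μm chains.

## Chemistry

Each unbound site fires with probability `1 − exp(−k_bind dt)` per step;
a firing site binds one filament segment whose nearest point lies within
`r_bind = 30 nm`, chosen uniformly among candidates, and the anchor
abscissa is frozen at binding (no sliding). An optional mode scales the
propensity with the number of candidate segments (local F-actin amount);
the default is one event per site per step. Bonds rupture with
probability `1 − exp(−k_eff dt)`, `k_eff = k_unbind0·exp(|F|/F_bell)`;
`F_bell` defaults to 2 pN (configurable; no headline quantity depends on
it).

Growth appends `k_grow·dt` at the plus end along the terminal tangent.
The terminal segment extends until it would exceed `2·L_seg`, then a
vertex splits off one exact `L_seg` segment, leaving a ≈`L_seg` terminal
remainder. Splitting at exactly `L_seg` would create near-zero-length
segments whose bending gradients (∝ 1/l) destabilize the integrator;
the two-segment rule avoids that while keeping interior rest lengths
exactly `L_seg`, so contour-length bookkeeping is exact — the growth
arithmetic (0.1 μm → 2 μm at 10.3 nm/s in 184.47 s) is reproduced to one
time step. Growth stops exactly at `L_fil_max`. Optional nucleation adds
2-vertex seeds as a Poisson process proportional to nucleator
concentration and the unpolymerized fraction of a finite actin pool
(370.4 subunits/μm, i.e. a 2.7 nm monomer rise).

## Analysis conventions

* **Surface occupancy** — filaments are resampled at the 2.7 nm monomer
  rise; monomers within 100 nm of the boundary are assigned to the
  nearest triangle (by centroid distance, k-d tree; brute force is the
  test oracle) of a 4×-subdivided icosphere; the occupied-triangle
  fraction is reported. The 2.7 nm rise also drives all concentration
  conversions and reproduces the 27.67 μM reference concentration to
  within 0.02 μM.
* **Valency** — a tetramer's valency counts *distinct* filament ids among
  its bonds; two bonds to the same filament count once.
* **Gyration spans** — `2·sqrt(5·λ_i)` from the gyration tensor of the
  monomer-resampled cloud (the axis lengths of a uniform solid ellipsoid
  with the same tensor). Only ratios and orderings of spans are asserted
  in tests, since the constant is a convention.
* **End-pair PDFs** include same-filament end pairs; for ≥ 30 filaments
  cross pairs dominate (n of n(2n−1)).

## Classification

The five order parameters (area fraction, f1..f4) are z-scored per column
(constant columns dropped with a warning) and decomposed by PCA on the
correlation matrix — the parameters have heterogeneous scales, so the
correlation convention is the defensible default. Loadings of the top
three components are varimax-rotated (raw criterion, no Kaiser
normalization) and signs fixed so each column's largest-magnitude loading
is positive. K-means (k-means++, n_init = 50, tol 1e-6, ≤ 500 iterations,
seeded) partitions the scores; k is fixed per experiment (4 for the
kinetic sweep). Cluster names are rule-based on cluster-mean raw
parameters: *ring* = lowest area fraction with high f3+f4; *shell* =
highest unbound fraction among the rest; the remaining clusters split
into strong/weak bundling by f3+f4; rule collisions fall back to rank
names with a warning rather than a silent guess.

## Deformation protocol

Starting from a terminated-growth network, the droplet elongates along z
in 10 nm constant-volume steps (`b = sqrt(V/((4/3)π a))` exactly), each
followed by 1 s of relaxation dynamics with binding/unbinding active and
growth off — the quasi-static criterion under which tetramer diffusion
keeps up with the boundary. The two end caps are defined to jointly
enclose 12.5% of the volume (6.25% per cap — the joint reading of an
ambiguous convention, configurable); elongation stops when the cap actin
concentration falls below `C_bulk/3`, or at the hard geometric stop
`2a = min(L_fil_max, 2π·R_drop)`. Cap monitoring counts monomers (not
vertices) for consistency with `C_bulk`. The analytic
filament-length-limited bound is `a/b = (L_fil_max/2)^{3/2}/R_drop^{3/2}`
(`π^{3/2} ≈ 5.57` for the 2π μm reference length). The short- vs
long-filament crossover (pliant bundles sliding past the bound vs rings
kinetically trapped below it) requires full-scale equilibration times and
is exposed through the `fig7_deformation` recipe rather than asserted in
the test suite.

## Synthetic fixtures

`vaspdrop.fixtures` builds idealized terminal geometries — equatorial
rings, boundary-hugging great-circle shells (plain / weakly / strongly
bundled), linear bundles, and a uniform gas — discretized at the engine's
`L_seg` and carrying bond tables whose distinct-filament valency
histogram matches a requested profile exactly (largest-remainder
apportionment; exact whenever `profile × n_tetramers` is integral). They
exercise every analysis and classification path in milliseconds and give
the classifier a separable ground truth (100% K-means purity is asserted).

Fixtures emulate *terminal geometries only*: they contain no dynamics, no
kinetic history, and their valency profiles are imposed rather than
emergent. Tests passing on fixtures therefore validate the measurement
and classification pipeline, not the simulation physics; the engine-level
properties above and the desk-scale sweep cover the physics.

## Desk-scale conditions

The reference conditions (R_drop = 1 μm, 30 filaments, 0.40 μM tetramers,
600 s, L_fil_max = 2π μm) take hours per trajectory in an interpreted
implementation. The desk preset shrinks to R_drop = 0.5 μm, 10 filaments,
60 s while preserving the governing dimensionless groups:
`L_fil_max/R_drop = 2π` (filaments wrap one circumference), growth
completes within the run, tetramer concentration 0.40 μM, and the same
`k_bind × k_unbind` grid and `dt = 2 ms`. One desk trajectory runs in
about a minute on one core. The kinetic-corner contrast (strong binding
→ bundled, low boundary coverage; negligible binding → shell, high
coverage) is asserted on three replicates per corner at this scale.
Desk-scale coverage values are smaller than full-scale ones (fewer, shorter
filaments); only their ordering is meaningful.

## Known limitations

* No treadmilling/depolymerization, no motors, no hydrodynamic coupling,
  no deformable boundary dynamics (deformation is quasi-static).
* Tetramer orientations are frozen (no rotational diffusion); site
  geometry is a rigid tetrahedron.
* The droplet is a hard wall: wetting and surface-tension energetics are
  outside scope.
* Growth is load-independent: no stall-force scale is established for
  this system, so none is modeled.
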