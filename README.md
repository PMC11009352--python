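# vaspdrop

Agent-based simulation and shape analysis of actin networks growing inside
VASP condensate droplets.

VASP (Vasodilator-Stimulated Phosphoprotein) is a tetrameric actin-bundling
polymerase that phase-separates into liquid droplets. Actin polymerizing
inside such a droplet adopts strikingly different architectures — uniform
peripheral *shells*, bundled shells, or single equatorial *rings* — and
rings can deform the droplet into a spheroid and ultimately a rod. This
package implements a minimal physical model of that process and the
complete analysis pipeline needed to quantify and classify the resulting
network shapes, so the kinetic-trapping phenomenology (which crosslinker
kinetics produce shells vs rings, and how the maximum filament length
limits droplet elongation) can be reproduced and explored at desk scale.

## Model

* **Droplet** — a rigid sphere of radius `R_drop` (default 1 μm) with
  hard-wall boundary conditions (the high-surface-tension limit); for
  deformation studies, a prolate spheroid from the constant-volume family
  `b = sqrt(R³/a)`.
* **Filaments** — inextensible chains of `L_seg = 0.1` μm segments with
  discrete worm-like-chain bending energy `E = (κ/L_seg)·Σ(1 − cos θ)`,
  `κ = Lp·kBT`, `Lp = 17` μm. Filaments elongate deterministically at
  `k_grow` (default 10.3 nm/s) up to `L_fil_max`.
* **VASP tetramers** — spheres of radius 30 nm with four binding sites.
  A site within `r_bind = 30 nm` of a filament binds with probability
  `1 − exp(−k_bind·dt)` per step; bonds are Hookean springs that rupture
  by Bell's slip-bond law `k_eff = k_unbind0·exp(|F|/F_bell)`.
* **Dynamics** — overdamped Euler–Maruyama, `dx = μ f dt + dB` with
  `dB ~ N(0, 2 μ kBT dt)` and `dt = 2 ms`, followed by a SHAKE-style
  projection onto the segment-length constraints and the hard wall.

Per-snapshot shape descriptors: the fraction of boundary triangles (of a
4×-subdivided icosphere) occupied by actin monomers within 100 nm of the
surface, the fractions `f0..f4` of tetramers bound to 0–4 distinct
filaments, gyration-tensor ellipsoidal spans, endpoint pair-distance PDFs
and radial density profiles. Ensembles of snapshots are standardized,
reduced by correlation-matrix PCA with varimax-rotated loadings, and
partitioned by K-means into the observed morphology classes (ring, shell,
shells with weak/strong bundling).

The quasi-static deformation protocol elongates the droplet along z in
10 nm constant-volume steps with 1 s of relaxation dynamics per step, and
stops when the actin concentration in the high-curvature end caps (jointly
12.5% of the volume) falls below `C_bulk/3` — or at the geometric bound
`2a = min(L_fil_max, 2π·R_drop)`, whose analytic form is
`a/b = (L_fil_max/2)^{3/2} / R_drop^{3/2}`.

## Worked example

```python
import numpy as np
from vaspdrop import (desk_config, run_simulation, build_icosphere,
                      surface_area_fraction, valency_fractions)
from dataclasses import replace

cfg = desk_config(seed=11)                      # R = 0.5 um, 10 filaments, 60 s
cfg = replace(cfg, kin=replace(cfg.kin, k_bind=10.0, k_unbind0=1.0))
snaps = run_simulation(cfg)                     # ~1 min on one core

surf = build_icosphere(0.5, 4)
s = snaps[-1]
print(f"area fraction  {surface_area_fraction(s, surf):.3f}")
print(f"f0..f4         {np.round(valency_fractions(s), 2)}")
```

prints (seed 11):

```
area fraction  0.143
f0..f4         [0.01 0.35 0.44 0.2  0.01]
```

Strong binding (`k_bind = 10/s`) has bundled the filaments: only ~14% of
the boundary is covered, 99% of the tetramers are engaged and a fifth of
them crosslink three or more distinct filaments. Re-running with
`k_bind = 1e-4` leaves every
tetramer unbound and the growing filaments coat ~25% of the boundary —
the shell signature (coverage keeps rising with longer runs and more
filaments; the full-scale reference uses 30 filaments for 600 s).

The same library drives a CLI:

```bash
vaspdrop simulate --preset desk --seed 11 --out runs/demo
vaspdrop analyze --traj runs/demo --out runs/demo/metrics.csv
vaspdrop replicate fig7_deformation --scale desk
```

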