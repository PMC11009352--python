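"""Quasi-static droplet deformation.

The droplet is elongated along z in 10 nm constant-volume steps; after
each step the network relaxes for 1 s of Langevin dynamics with crosslink
(un)binding active and growth off.  Elongation stops when the actin
concentration inside the two high-curvature end caps falls below
C_bulk/3, or at the hard geometric stop 2a = min(L_fil_max, 2π·R_drop).
The analytic filament-length-limited bound is
a/b = (L_fil_max/2)^{3/2} / R_drop^{3/2}.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .engine import CONC_UM_TO_PER_UM3, SimState, langevin_step, binding_update, unbinding_update
from .geometry import cap_z_threshold, spheroid_from_major_axis
from .snapshots import MONOMER_RISE, Snapshot

__all__ = [
    "DeformationProtocol",
    "deform_once",
    "cap_concentration",
    "run_deformation",
    "filament_limited_aspect",
    "bulk_concentration",
]

#: Avogadro-derived factor: monomer count -> μM in a volume given in μm³
_COUNT_TO_UM = 1.0 / CONC_UM_TO_PER_UM3


@dataclass
class DeformationProtocol:
    """Protocol parameters (μm / s / dimensionless)."""

    step_da: float = 0.010  # μm increment of the major semi-axis
    equilibration_time: float = 1.0  # s of dynamics between steps
    cap_volume_fraction: float = 0.125  # joint volume of both end caps
    concentration_threshold_factor: float = 1.0 / 3.0  # stop below C_bulk/3
    max_steps: int | None = None  # safety cap, None = until a stop rule

    def __post_init__(self) -> None:
        if self.step_da <= 0:
            raise ValueError("step_da must be > 0")
        if not (0 <= self.concentration_threshold_factor < 1):
            raise ValueError("threshold factor must be in [0, 1); 0 disables the rule")


def bulk_concentration(s: Snapshot, rise: float = MONOMER_RISE) -> float:
    """C_bulk: total polymerized actin over the droplet volume, μM."""
    count = len(s.monomers(rise))
    return count * _COUNT_TO_UM / s.confinement.volume


def cap_concentration(
    s: Snapshot, protocol: DeformationProtocol, rise: float = MONOMER_RISE
) -> float:
    """Actin concentration (μM) inside the two spheroidal end caps
    {|z| > z0} jointly enclosing ``cap_volume_fraction`` of the volume."""
    conf = s.confinement
    z0 = cap_z_threshold(conf, protocol.cap_volume_fraction)
    pts = s.monomers(rise)
    count = int(np.count_nonzero(np.abs(pts[:, 2]) > z0)) if len(pts) else 0
    joint_volume = protocol.cap_volume_fraction * conf.volume
    return count * _COUNT_TO_UM / joint_volume


def deform_once(state: SimState, protocol: DeformationProtocol) -> SimState:
    """One elongation step: replace the confinement by the constant-volume
    spheroid with a + step_da, project any out-of-bounds beads onto the new
    boundary, then run ``equilibration_time`` of dynamics (binding and
    unbinding active, growth off)."""
    old = state.confinement
    new_conf = spheroid_from_major_axis(old.a + protocol.step_da, old.volume)
    state.confinement = new_conf
    for arr in (state.verts, state.tet_centers):
        if len(arr):
            out = new_conf.level(arr) > 1.0
            if out.any():
                arr[out] = new_conf.project(arr[out])
    n_steps = int(round(protocol.equilibration_time / state.mech.dt))
    for _ in range(n_steps):
        langevin_step(state)
        binding_update(state)
        unbinding_update(state)
    return state


def run_deformation(
    state: SimState, protocol: DeformationProtocol
) -> tuple[list[Snapshot], float, pd.DataFrame]:
    """Iterate deform_once until the cap-concentration rule fires or the
    hard stop 2a = min(L_fil_max, 2π·R_drop) is reached.

    Returns (snapshots at each step, final aspect ratio with both caps
    still in actin contact, per-step log with a, b, a/b and cap
    concentration)."""
    state.growing[:] = False  # the network no longer elongates
    conf = state.confinement
    R = conf.R_drop
    a_hard = min(state.kin.L_fil_max, 2.0 * np.pi * R) / 2.0
    snap0 = state.snapshot()
    c_bulk = bulk_concentration(snap0)
    threshold = c_bulk * protocol.concentration_threshold_factor
    snaps = [snap0]
    rows = []
    max_ar = conf.aspect_ratio
    k = 0
    while state.confinement.a < a_hard - 1e-12:
        if protocol.max_steps is not None and k >= protocol.max_steps:
            break
        da = min(protocol.step_da, a_hard - state.confinement.a)
        deform_once(state, replace(protocol, step_da=da))
        snap = state.snapshot()
        c_cap = cap_concentration(snap, protocol)
        conf = state.confinement
        rows.append({"a": conf.a, "b": conf.b, "aspect_ratio": conf.aspect_ratio,
                     "cap_concentration_uM": c_cap, "C_bulk_uM": c_bulk})
        snaps.append(snap)
        k += 1
        if state.n_filaments > 0 and c_cap < threshold:
            # caps lost actin contact: the previous shape was the maximum
            break
        max_ar = conf.aspect_ratio
    return snaps, float(max_ar), pd.DataFrame(rows)


def filament_limited_aspect(L_fil_max: float, R_drop: float) -> float:
    """Aspect ratio when the major axis equals the maximum filament length
    at constant volume: a = L/2, b = sqrt(R³/a) ⇒ a/b = (L/2)^{3/2}/R^{3/2}."""
    if L_fil_max < 2.0 * R_drop:
        raise ValueError(
            "filament-limited aspect undefined for L_fil_max < 2·R_drop "
            "(the sphere already exceeds the filament length)"
        )
    a = L_fil_max / 2.0
    return float((a / R_drop) ** 1.5)
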