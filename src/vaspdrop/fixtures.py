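"""Synthetic snapshot generator.

Idealized bead–bond configurations for the morphologies the simulations
produce — equatorial rings, boundary-hugging shells (plain, weakly and
strongly bundled), linear bundles, and a uniform gas — with exactly
controlled crosslinker valency profiles.  These are static geometries (no
dynamics) sharing the engine's Snapshot contract, so every analysis and
classification stage can be exercised in milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import Confinement
from .snapshots import Snapshot

__all__ = ["FixtureSpec", "make_ring", "make_shell", "make_bundled_shell",
           "make_linear_bundle", "make_gas", "make_fixture", "MORPHOLOGIES"]

MORPHOLOGIES = ("ring", "shell", "bundled_shell", "weak_bundled_shell",
                "linear_bundle", "gas")

#: default valency profiles (f0..f4) per morphology
DEFAULT_PROFILES = {
    "ring": (0.05, 0.10, 0.15, 0.30, 0.40),
    "shell": (0.70, 0.20, 0.10, 0.0, 0.0),
    "bundled_shell": (0.10, 0.10, 0.10, 0.30, 0.40),
    "weak_bundled_shell": (0.30, 0.30, 0.30, 0.10, 0.0),
    "linear_bundle": (0.05, 0.10, 0.15, 0.30, 0.40),
    "gas": (1.0, 0.0, 0.0, 0.0, 0.0),
}


@dataclass
class FixtureSpec:
    """Recipe for one synthetic snapshot."""

    morphology: str = "ring"
    R_drop: float = 1.0  # μm
    n_filaments: int = 30
    filament_length: float = 2.0 * np.pi  # μm
    bundle_thickness: float = 0.1  # μm
    n_tetramers: int = 200
    target_valency_profile: tuple = None  # f0..f4, sums to 1
    L_seg: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.morphology not in MORPHOLOGIES:
            raise ValueError(f"unknown morphology {self.morphology!r}")
        if self.target_valency_profile is None:
            self.target_valency_profile = DEFAULT_PROFILES[self.morphology]
        p = np.asarray(self.target_valency_profile, dtype=float)
        if p.shape != (5,) or not np.isclose(p.sum(), 1.0):
            raise ValueError("valency profile must be 5 fractions summing to 1")
        if self.filament_length <= 0 or self.R_drop <= 0:
            raise ValueError("lengths must be positive")


def _valency_counts(profile, n: int) -> np.ndarray:
    """Largest-remainder apportionment of n tetramers over valencies 0..4."""
    p = np.asarray(profile, dtype=float)
    raw = p * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1
    return counts


def _discretize_arc(center_fn, length: float, L_seg: float) -> np.ndarray:
    """Sample a parametric curve (arclength parameter s -> point) at the
    segment resolution; returns (n, 3) vertices."""
    s = np.arange(0.0, length, L_seg)
    if length - s[-1] > 1e-9:
        s = np.append(s, length)
    return np.array([center_fn(x) for x in s])


def _nearest_segment(verts: np.ndarray, p: np.ndarray) -> tuple[int, float]:
    """(segment index, abscissa) of the closest point on a polyline to p."""
    a = verts[:-1]
    b = verts[1:]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    t = np.clip(np.einsum("ij,ij->i", p - a, ab) / np.maximum(denom, 1e-18), 0, 1)
    near = a + t[:, None] * ab
    d = np.linalg.norm(near - p, axis=1)
    k = int(np.argmin(d))
    return k, float(t[k])


def _bond_table(
    spec: FixtureSpec,
    filaments: list[np.ndarray],
    tet_centers: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Assign bonds so the distinct-filament valency histogram equals the
    target profile (largest-remainder apportionment); each bound site links
    a different filament, anchored at the nearest segment."""
    counts = _valency_counts(spec.target_valency_profile, len(tet_centers))
    n_bonds_needed = int(np.sum(counts * np.arange(5)))
    if n_bonds_needed > 4 * len(tet_centers):
        raise ValueError("infeasible valency profile: more bonds than 4 x tetramers")
    if counts[1:].sum() > 0 and len(filaments) < 4:
        if max(v for v in range(5) if counts[v] > 0) > len(filaments):
            raise ValueError("not enough filaments for the requested valency")
    valencies = np.repeat(np.arange(5), counts)
    rows = []
    for t_idx, v in enumerate(valencies):
        if v == 0:
            continue
        # v distinct filaments, nearest-first for geometric plausibility
        d_to_fil = np.array(
            [np.min(np.linalg.norm(fv - tet_centers[t_idx], axis=1)) for fv in filaments]
        )
        chosen = np.argsort(d_to_fil)[:v]
        for site, fil in enumerate(chosen):
            seg, ab = _nearest_segment(filaments[fil], tet_centers[t_idx])
            rows.append((t_idx, site, int(fil), seg, ab))
    if not rows:
        return Snapshot.empty_bonds()
    return pd.DataFrame(rows, columns=["tetramer", "site", "filament", "segment", "abscissa"])


def _finish(spec: FixtureSpec, filaments, tet_centers, rng,
            conf: Confinement | None = None) -> Snapshot:
    if conf is None:
        conf = Confinement.sphere(spec.R_drop)
    # clip everything inside the droplet
    clipped = []
    for v in filaments:
        ins = conf.contains(v)
        if not ins.all():
            v = v.copy()
            v[~ins] = conf.project(v[~ins])
        clipped.append(v)
    filaments = clipped
    inside = conf.contains(tet_centers)
    if not inside.all():
        tet_centers = tet_centers.copy()
        tet_centers[~inside] = conf.project(tet_centers[~inside])
    bonds = _bond_table(spec, filaments, tet_centers, rng)
    return Snapshot(
        time=0.0,
        filaments=tuple(filaments),
        tetramers=tet_centers,
        bonds=bonds,
        confinement=conf,
    )


def make_ring(spec: FixtureSpec) -> Snapshot:
    """Equatorial ring: filaments as circular arcs of radius
    R_drop − bundle_thickness/2 in the z=0 plane with jitter up to the
    bundle thickness; tetramers sit on the arcs."""
    rng = np.random.default_rng(spec.seed)
    r0 = spec.R_drop - spec.bundle_thickness / 2.0
    filaments = []
    for _ in range(spec.n_filaments):
        phi0 = rng.uniform(0, 2 * np.pi)
        rj = r0 + (rng.uniform(-0.5, 0.5) * spec.bundle_thickness if spec.bundle_thickness > 0 else 0.0)
        rj = min(rj, spec.R_drop - 1e-6)
        zj = rng.uniform(-0.5, 0.5) * spec.bundle_thickness

        def curve(s, phi0=phi0, rj=rj, zj=zj):
            phi = phi0 + s / rj
            return np.array([rj * np.cos(phi), rj * np.sin(phi), zj])

        filaments.append(_discretize_arc(curve, spec.filament_length, spec.L_seg))
    tet = _tetramers_on_filaments(spec, filaments, rng)
    return _finish(spec, filaments, tet, rng)


def make_shell(spec: FixtureSpec) -> Snapshot:
    """Boundary-hugging shell: filaments as random great-circle arcs within
    100 nm of the droplet surface."""
    rng = np.random.default_rng(spec.seed)
    filaments = []
    for _ in range(spec.n_filaments):
        r0 = spec.R_drop - rng.uniform(0.02, 0.08)
        # random orthonormal frame for the circle plane
        e1 = _rand_unit(rng)
        e2 = np.cross(e1, _rand_unit(rng))
        e2 /= np.linalg.norm(e2)
        e1 = np.cross(e2, np.cross(e1, e2))
        e1 /= np.linalg.norm(e1)
        phi0 = rng.uniform(0, 2 * np.pi)

        def curve(s, r0=r0, e1=e1, e2=e2, phi0=phi0):
            phi = phi0 + s / r0
            return r0 * (np.cos(phi) * e1 + np.sin(phi) * e2)

        filaments.append(_discretize_arc(curve, spec.filament_length, spec.L_seg))
    tet = _tetramers_on_filaments(spec, filaments, rng)
    return _finish(spec, filaments, tet, rng)


def make_bundled_shell(spec: FixtureSpec) -> Snapshot:
    """Shell geometry with a bundling-weighted valency profile."""
    return make_shell(spec)


def make_linear_bundle(spec: FixtureSpec) -> Snapshot:
    """Parallel straight filaments along z inside a cylinder of diameter
    ``bundle_thickness``, with staggered ends."""
    rng = np.random.default_rng(spec.seed)
    L = spec.filament_length
    stagger = 0.25 * spec.bundle_thickness + 0.05
    filaments = []
    for _ in range(spec.n_filaments):
        if spec.bundle_thickness > 0:
            rho = 0.5 * spec.bundle_thickness * np.sqrt(rng.uniform())
            ang = rng.uniform(0, 2 * np.pi)
            x0, y0 = rho * np.cos(ang), rho * np.sin(ang)
        else:
            x0 = y0 = 0.0
        z0 = -L / 2 + rng.uniform(-0.5, 0.5) * stagger

        def curve(s, x0=x0, y0=y0, z0=z0):
            return np.array([x0, y0, z0 + s])

        filaments.append(_discretize_arc(curve, L, spec.L_seg))
    tet = _tetramers_on_filaments(spec, filaments, rng)
    # house the bundle in a constant-volume prolate spheroid long enough
    # to contain it (bundles arise from deformed droplets)
    from .geometry import spheroid_from_major_axis

    a = max(L / 2 + 0.3, spec.R_drop)
    conf = spheroid_from_major_axis(a, 4.0 / 3.0 * np.pi * spec.R_drop**3)
    return _finish(spec, filaments, tet, rng, conf=conf)


def make_gas(spec: FixtureSpec) -> Snapshot:
    """Uniform gas: short 2-vertex filaments at uniform random positions and
    orientations in the droplet, no bonds (unless the profile says so)."""
    rng = np.random.default_rng(spec.seed)
    filaments = []
    half = min(spec.filament_length, spec.L_seg) / 2
    for _ in range(spec.n_filaments):
        while True:
            p = rng.uniform(-1, 1, 3) * spec.R_drop
            if np.linalg.norm(p) <= spec.R_drop - half:
                break
        u = _rand_unit(rng)
        filaments.append(np.array([p - half * u, p + half * u]))
    tet = _uniform_ball(rng, spec.n_tetramers, spec.R_drop - 0.03)
    return _finish(spec, filaments, tet, rng)


def make_fixture(spec: FixtureSpec) -> Snapshot:
    """Dispatch on ``spec.morphology``; deterministic given ``spec.seed``."""
    return {
        "ring": make_ring,
        "shell": make_shell,
        "bundled_shell": make_bundled_shell,
        "weak_bundled_shell": make_bundled_shell,
        "linear_bundle": make_linear_bundle,
        "gas": make_gas,
    }[spec.morphology](spec)


# ---------------------------------------------------------------------------


def _rand_unit(rng) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def _uniform_ball(rng, n: int, R: float) -> np.ndarray:
    out = np.empty((n, 3))
    k = 0
    while k < n:
        p = rng.uniform(-R, R, 3)
        if np.linalg.norm(p) <= R:
            out[k] = p
            k += 1
    return out


def _tetramers_on_filaments(spec: FixtureSpec, filaments, rng) -> np.ndarray:
    """Place tetramer centers near random points of the filaments (offset by
    the 30 nm tetramer radius) so nearest-segment anchors are plausible."""
    all_verts = np.concatenate(filaments)
    idx = rng.integers(len(all_verts), size=spec.n_tetramers)
    jitter = rng.standard_normal((spec.n_tetramers, 3))
    jitter = 0.03 * jitter / np.linalg.norm(jitter, axis=1, keepdims=True)
    return all_verts[idx] + jitter
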