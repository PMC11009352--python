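"""Overdamped Langevin dynamics of growing semiflexible actin filaments
crosslinked by tetravalent VASP linkers inside a rigid droplet.

The model: filaments are inextensible chains of 0.1 μm segments with a
discrete worm-like-chain bending energy E = (κ/L_seg)·Σ(1 − cos θ); VASP
tetramers are spheres of radius 30 nm carrying four binding sites that form
Hookean bonds to nearby filament segments with mesoscopic rate ``k_bind``
and break with Bell's-law slip-bond kinetics
k_eff = k_unbind0·exp(|F|/F_bell).  Positions evolve by explicit
Euler–Maruyama,

    dx = μ·f_tot·dt + dB,   dB ~ N(0, 2·D·dt),  D = μ·kBT,

followed by iterative re-projection onto the inextensibility constraints
and a hard-wall confinement correction.  Filaments elongate
deterministically at ``k_grow`` at the plus end, capped at ``L_fil_max``.

Units: μm, s, pN (kBT = 0.0042 pN·μm at room temperature; viscosity in
pN·s/μm² ≡ Pa·s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import Confinement
from .snapshots import MONOMER_RISE, Snapshot

__all__ = [
    "MechParams",
    "KineticParams",
    "FilamentState",
    "SimState",
    "SimConfig",
    "SimulationInstability",
    "bending_forces",
    "enforce_inextensibility",
    "langevin_step",
    "binding_update",
    "unbinding_update",
    "grow_filaments",
    "steric_forces",
    "nucleation_update",
    "run_simulation",
    "init_state",
    "t_two_pi_r",
]

#: number density (μm⁻³) of a 1 μM solution
CONC_UM_TO_PER_UM3 = 602.214076
#: actin subunits per μm of filament
SUBUNITS_PER_UM = 1.0 / MONOMER_RISE


class SimulationInstability(RuntimeError):
    """A Langevin step moved some bead farther than one segment length,
    signalling numerical instability (reduce dt or stiffnesses)."""


# ---------------------------------------------------------------------------
# parameter blocks


@dataclass
class MechParams:
    """Mechanical / integration parameters."""

    dt: float = 0.002  # s
    kBT: float = 0.0042  # pN·μm
    viscosity: float = 1.0  # pN·s/μm² (effective crowded-droplet medium)
    persistence_length: float = 17.0  # μm
    L_seg: float = 0.1  # μm
    # site–anchor link stiffness; explicit Euler–Maruyama is stable only for
    # μ_tet·(4·k_bond + k_steric)·dt < 1, which bounds k_bond ≈ 35 at the
    # 2 ms step — 25 keeps a safety margin while still holding bonds to
    # within ~0.1 μm under pN-scale loads
    bond_stiffness: float = 25.0  # pN/μm
    steric_stiffness: float = 100.0  # pN/μm soft-core
    steric_range_filament: float = 0.005  # μm, filament half-thickness
    steric_range_tetramer: float = 0.03  # μm, tetramer radius
    tetramer_diameter: float = 0.06  # μm, hydrodynamic size for mobility

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.kBT < 0:
            raise ValueError("dt must be > 0 and kBT >= 0")

    @property
    def kappa(self) -> float:
        """Flexural rigidity κ = Lp·kBT, pN·μm²."""
        return self.persistence_length * self.kBT

    @property
    def mobility_filament(self) -> float:
        """Per-vertex mobility μ = 1/(3πηd) with d = L_seg, μm/(pN·s)."""
        return 1.0 / (3.0 * np.pi * self.viscosity * self.L_seg)

    @property
    def mobility_tetramer(self) -> float:
        return 1.0 / (3.0 * np.pi * self.viscosity * self.tetramer_diameter)

    @property
    def D_tetramer(self) -> float:
        """Tetramer diffusion coefficient D = μ·kBT, μm²/s."""
        return self.mobility_tetramer * self.kBT

    @property
    def D_filament_vertex(self) -> float:
        return self.mobility_filament * self.kBT


@dataclass
class KineticParams:
    """Binding / unbinding / growth / nucleation parameters."""

    k_bind: float = 1.0  # 1/s per site
    k_unbind0: float = 0.1  # 1/s unloaded
    F_bell: float = 2.0  # pN slip-bond force scale
    r_bind: float = 0.03  # μm capture radius
    k_grow: float = 0.0103  # μm/s plus-end extension
    L_fil_max: float = 2.0 * np.pi  # μm
    nucleation_rate_constant: float = 0.0  # 1/(s·nM)
    nucleator_nM: float = 0.0
    G_pool_uM: float = 0.0  # unpolymerized actin pool (0 = unlimited)
    multiple_events: bool = False  # propensity ∝ n candidate segments

    def __post_init__(self) -> None:
        for name in ("k_bind", "k_unbind0", "k_grow", "nucleation_rate_constant"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.r_bind <= 0:
            raise ValueError("r_bind must be > 0")


def t_two_pi_r(R_drop: float, L0: float = 0.1, k_grow: float = 0.0103) -> float:
    """T_2πR: time for a seed of length L0 to elongate to one droplet
    circumference 2π·R_drop at rate k_grow."""
    return (2.0 * np.pi * R_drop - L0) / k_grow


# ---------------------------------------------------------------------------
# filament container (public, single-filament view)


@dataclass
class FilamentState:
    """One filament: ordered vertex chain with per-segment rest lengths.

    Interior segments rest at ``rest_length``; the terminal (growing)
    segment rests at ``last_rest`` ∈ (0, 2·rest_length] — growth lets it
    reach 2·rest_length before a new vertex splits off one full segment.
    """

    verts: np.ndarray
    rest_length: float = 0.1
    last_rest: float = 0.1
    growing: bool = True

    @property
    def n_segments(self) -> int:
        return len(self.verts) - 1

    @property
    def contour_length(self) -> float:
        return (self.n_segments - 1) * self.rest_length + self.last_rest

    def rest_lengths(self) -> np.ndarray:
        r = np.full(self.n_segments, self.rest_length)
        r[-1] = self.last_rest
        return r


# ---------------------------------------------------------------------------
# force kernels


def bending_forces(f: FilamentState | np.ndarray, kappa: float, L_seg: float = 0.1) -> np.ndarray:
    """Per-vertex forces −∇E of the discrete bending energy
    E = (κ/L_seg)·Σ_i (1 − cos θ_i) over interior vertices.

    Accepts a FilamentState or a bare (n, 3) vertex array; returns (n, 3).
    Net force and net torque vanish (purely internal forces).
    """
    verts = f.verts if isinstance(f, FilamentState) else np.asarray(f, dtype=float)
    n = len(verts)
    out = np.zeros((n, 3))
    if n < 3:
        return out
    d = np.diff(verts, axis=0)
    l = np.linalg.norm(d, axis=1)
    u = d / l[:, None]
    c = np.einsum("ij,ij->i", u[:-1], u[1:])  # cos θ at vertices 1..n-2
    pref = kappa / L_seg
    g_prev = -pref * (u[1:] - c[:, None] * u[:-1]) / l[:-1, None]
    g_next = pref * (u[:-1] - c[:, None] * u[1:]) / l[1:, None]
    np.add.at(out, np.arange(n - 2), g_prev)
    np.add.at(out, np.arange(2, n), g_next)
    np.add.at(out, np.arange(1, n - 1), -(g_prev + g_next))
    return out


def _relax_segments(
    verts: np.ndarray,
    seg_i: np.ndarray,
    rest: np.ndarray,
    tol: float = 1e-3,
    max_iter: int = 50,
    adjacent: np.ndarray | None = None,
) -> tuple[bool, float]:
    """Constraint projection restoring |x[i+1]-x[i]| = rest for the listed
    segments by Newton iteration on the Lagrange multipliers (the
    SHAKE-style linear system is tridiagonal along each chain).  The
    correction Δx = Jᵀλ sums to zero, so the center of mass is preserved
    exactly.  Returns (converged, max relative residual)."""
    if len(seg_i) == 0:
        return True, 0.0
    from scipy.linalg import solve_banded

    j = seg_i + 1
    if adjacent is None:
        adjacent = np.ones(max(len(seg_i) - 1, 0), dtype=bool)
    err = np.inf
    n = len(seg_i)
    for _ in range(max_iter):
        d = verts[j] - verts[seg_i]
        l = np.sqrt(np.einsum("ij,ij->i", d, d))
        g = l - rest
        err = float(np.max(np.abs(g) / rest))
        if err < tol:
            return True, err
        u = d / np.maximum(l, 1e-12)[:, None]
        # Newton/Lagrange step: solve the tridiagonal (J Jᵀ) λ = −g where
        # J is the constraint Jacobian; off-diagonal coupling −û_k·û_{k+1}
        # exists only between consecutive segments of the same filament
        ab = np.zeros((3, n))
        ab[1] = 2.0
        if n > 1:
            off = np.where(adjacent, -np.einsum("ij,ij->i", u[:-1], u[1:]), 0.0)
            ab[0, 1:] = off
            ab[2, :-1] = off
        lam = solve_banded((1, 1), ab, -g)
        corr = lam[:, None] * u
        # Δx = Jᵀλ: +λû on the segment end, −λû on its start; both index
        # arrays are unique, so fancy indexing is safe
        verts[j] += corr
        verts[seg_i] -= corr
    return err < tol, err


def enforce_inextensibility(f: FilamentState, tol: float = 1e-3, max_iter: int = 500) -> FilamentState:
    """Restore segment rest lengths by minimal iterative displacement.

    Raises SimulationInstability on non-convergence (reported with the
    residual)."""
    verts = f.verts.copy()
    seg_i = np.arange(len(verts) - 1)
    ok, res = _relax_segments(verts, seg_i, f.rest_lengths(), tol=tol, max_iter=max_iter)
    if not ok:
        raise SimulationInstability(
            f"inextensibility projection did not converge (residual {res:.3g})"
        )
    return replace(f, verts=verts)


# ---------------------------------------------------------------------------
# full system state


@dataclass
class SimState:
    """Full mutable system: flat filament vertex storage, tetramer arrays,
    confinement, clock and a named RNG stream."""

    mech: MechParams
    kin: KineticParams
    confinement: Confinement | None
    verts: np.ndarray  # (Nv, 3) all filament vertices, filament-contiguous
    offsets: np.ndarray  # (F+1,) filament i occupies verts[offsets[i]:offsets[i+1]]
    last_rest: np.ndarray  # (F,) terminal segment rest length
    growing: np.ndarray  # (F,) bool
    tet_centers: np.ndarray  # (M, 3)
    site_dirs: np.ndarray  # (M, 4, 3) fixed unit directions
    bond_fil: np.ndarray  # (M, 4) filament id or -1
    bond_seg: np.ndarray  # (M, 4) segment index
    bond_abs: np.ndarray  # (M, 4) abscissa in [0, 1]
    rng: np.random.Generator
    time: float = 0.0
    pool_subunits: float = np.inf  # unpolymerized actin pool (count)
    pool_total: float = np.inf
    _cache: dict | None = field(default=None, repr=False)

    @property
    def n_filaments(self) -> int:
        return len(self.offsets) - 1

    def _invalidate(self) -> None:
        """Drop cached topology (call after any vertex insertion)."""
        self._cache = None

    def _topology(self) -> dict:
        """Cached flat-segment topology: segment starts, terminal-segment
        slots, bending-angle triplets, vertex→segment lookup, per-segment
        filament id.  Rebuilt only when vertices are inserted."""
        if self._cache is None:
            starts = []
            term = []
            fil_of = []
            n_prev = 0
            for i in range(self.n_filaments):
                o0, o1 = int(self.offsets[i]), int(self.offsets[i + 1])
                k = o1 - o0 - 1
                starts.append(np.arange(o0, o1 - 1))
                fil_of.append(np.full(k, i))
                term.append(n_prev + k - 1)
                n_prev += k
            seg_i = np.concatenate(starts) if starts else np.empty(0, dtype=int)
            seg_fil = np.concatenate(fil_of) if fil_of else np.empty(0, dtype=int)
            # angles: consecutive segment pairs within the same filament
            if len(seg_i) > 1:
                ang = np.nonzero(
                    (np.diff(seg_i) == 1) & (seg_fil[:-1] == seg_fil[1:])
                )[0]
            else:
                ang = np.empty(0, dtype=int)
            lookup = np.full(len(self.verts), -1, dtype=int)
            lookup[seg_i] = np.arange(len(seg_i))
            adj = np.zeros(max(len(seg_i) - 1, 0), dtype=bool)
            adj[ang] = True
            self._cache = {
                "adj": adj,
                "seg_i": seg_i,
                "seg_fil": seg_fil,
                "seg_local": seg_i - self.offsets[seg_fil] if len(seg_i) else seg_i,
                "term_slot": np.asarray(term, dtype=int),
                "ang": ang,
                "lookup": lookup,
            }
        return self._cache

    @property
    def n_tetramers(self) -> int:
        return len(self.tet_centers)

    def filament(self, i: int) -> FilamentState:
        return FilamentState(
            verts=self.verts[self.offsets[i] : self.offsets[i + 1]],
            rest_length=self.mech.L_seg,
            last_rest=float(self.last_rest[i]),
            growing=bool(self.growing[i]),
        )

    def contour_lengths(self) -> np.ndarray:
        nseg = np.diff(self.offsets) - 1
        return (nseg - 1) * self.mech.L_seg + self.last_rest

    def site_positions(self) -> np.ndarray:
        """(M, 4, 3) binding-site positions on the tetramer surfaces."""
        return self.tet_centers[:, None, :] + self.mech.steric_range_tetramer * self.site_dirs

    def segment_table(self) -> tuple[np.ndarray, np.ndarray]:
        """Global segment start indices and rest lengths over all filaments."""
        topo = self._topology()
        rest = np.full(len(topo["seg_i"]), self.mech.L_seg)
        if len(rest):
            rest[topo["term_slot"]] = self.last_rest
        return topo["seg_i"], rest

    def bond_anchor_positions(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Positions of bound sites and their filament anchors.

        Returns (mask (M,4) bool, site positions (K,3), anchors (K,3))."""
        mask = self.bond_fil >= 0
        if not mask.any():
            return mask, np.empty((0, 3)), np.empty((0, 3))
        fil = self.bond_fil[mask]
        seg = self.bond_seg[mask]
        ab = self.bond_abs[mask]
        gi = self.offsets[fil] + seg
        anchors = self.verts[gi] * (1.0 - ab[:, None]) + self.verts[gi + 1] * ab[:, None]
        sites = self.site_positions()[mask]
        return mask, sites, anchors

    def bond_tensions(self) -> np.ndarray:
        """(M, 4) instantaneous bond-spring tension |F|, 0 for empty sites."""
        out = np.zeros_like(self.bond_abs)
        mask, sites, anchors = self.bond_anchor_positions()
        if mask.any():
            out[mask] = self.mech.bond_stiffness * np.linalg.norm(anchors - sites, axis=1)
        return out

    def snapshot(self) -> Snapshot:
        fils = tuple(
            self.verts[self.offsets[i] : self.offsets[i + 1]].copy()
            for i in range(self.n_filaments)
        )
        ti, si = np.nonzero(self.bond_fil >= 0)
        bonds = pd.DataFrame(
            {
                "tetramer": ti.astype(np.int64),
                "site": si.astype(np.int64),
                "filament": self.bond_fil[ti, si].astype(np.int64),
                "segment": self.bond_seg[ti, si].astype(np.int64),
                "abscissa": self.bond_abs[ti, si],
            }
        )
        return Snapshot(
            time=self.time,
            filaments=fils,
            tetramers=self.tet_centers.copy(),
            bonds=bonds,
            confinement=self.confinement,
        )


# ---------------------------------------------------------------------------
# forces


def steric_forces(state: SimState) -> tuple[np.ndarray, np.ndarray]:
    """Soft-core repulsion between tetramer centers and between tetramers
    and filament vertices: linear spring below the contact distance, zero
    beyond.  Returns (vertex forces, tetramer forces); pairwise symmetric,
    so both sum to zero."""
    m = state.mech
    fv = np.zeros_like(state.verts)
    ft = np.zeros_like(state.tet_centers)
    M = state.n_tetramers
    if M == 0:
        return fv, ft
    tree_t = cKDTree(state.tet_centers)
    contact_tt = 2.0 * m.steric_range_tetramer
    pairs = tree_t.query_pairs(contact_tt, output_type="ndarray")
    if len(pairs):
        d = state.tet_centers[pairs[:, 0]] - state.tet_centers[pairs[:, 1]]
        dist = np.linalg.norm(d, axis=1)
        keep = dist > 1e-12
        pairs, d, dist = pairs[keep], d[keep], dist[keep]
        fmag = m.steric_stiffness * (contact_tt - dist)
        fvec = (fmag / dist)[:, None] * d
        np.add.at(ft, pairs[:, 0], fvec)
        np.add.at(ft, pairs[:, 1], -fvec)
    if len(state.verts):
        contact_tv = m.steric_range_tetramer + m.steric_range_filament
        tree_v = cKDTree(state.verts)
        coo = tree_t.sparse_distance_matrix(tree_v, contact_tv, output_type="coo_matrix")
        if coo.nnz:
            ti, vi, dist = coo.row, coo.col, coo.data
            keep = dist > 1e-12
            ti, vi, dist = ti[keep], vi[keep], dist[keep]
            d = state.tet_centers[ti] - state.verts[vi]
            fmag = m.steric_stiffness * (contact_tv - dist)
            fvec = (fmag / dist)[:, None] * d
            np.add.at(ft, ti, fvec)
            np.add.at(fv, vi, -fvec)
    return fv, ft


def compute_forces(state: SimState) -> tuple[np.ndarray, np.ndarray]:
    """Assemble bending + bond-spring + steric forces on all beads."""
    m = state.mech
    fv, ft = steric_forces(state)
    kappa = m.kappa
    topo = state._topology()
    seg_i, ang = topo["seg_i"], topo["ang"]
    if len(ang) and kappa > 0:
        # flat bending over all filaments at once: for the angle at the
        # shared vertex of segments k, k+1 the force stencil spans vertices
        # seg_i[k], seg_i[k]+1, seg_i[k]+2
        d = state.verts[seg_i + 1] - state.verts[seg_i]
        l = np.sqrt(np.einsum("ij,ij->i", d, d))
        u = d / l[:, None]
        c = np.einsum("ij,ij->i", u[ang], u[ang + 1])
        pref = kappa / m.L_seg
        g_prev = -pref * (u[ang + 1] - c[:, None] * u[ang]) / l[ang, None]
        g_next = pref * (u[ang] - c[:, None] * u[ang + 1]) / l[ang + 1, None]
        v0 = seg_i[ang]
        np.add.at(fv, v0, g_prev)
        np.add.at(fv, v0 + 2, g_next)
        np.add.at(fv, v0 + 1, -(g_prev + g_next))
    # bond springs: site -> anchor
    mask, sites, anchors = state.bond_anchor_positions()
    if mask.any():
        dvec = anchors - sites
        fb = m.bond_stiffness * dvec  # force on the tetramer (toward anchor)
        ti, si = np.nonzero(mask)
        np.add.at(ft, ti, fb)
        fil = state.bond_fil[mask]
        seg = state.bond_seg[mask]
        ab = state.bond_abs[mask]
        gi = state.offsets[fil] + seg
        np.add.at(fv, gi, -(1.0 - ab)[:, None] * fb)
        np.add.at(fv, gi + 1, -ab[:, None] * fb)
    return fv, ft


# ---------------------------------------------------------------------------
# integration


def langevin_step(state: SimState, rng: np.random.Generator | None = None) -> SimState:
    """One Euler–Maruyama step: forces → drift + noise → inextensibility
    projection → hard-wall confinement.  Mutates and returns ``state``.

    Raises SimulationInstability if any bead would move farther than one
    segment length in a single dt."""
    rng = rng if rng is not None else state.rng
    m = state.mech
    fv, ft = compute_forces(state)
    dt = m.dt
    sig_v = math.sqrt(2.0 * m.D_filament_vertex * dt)
    sig_t = math.sqrt(2.0 * m.D_tetramer * dt)
    disp_v = m.mobility_filament * fv * dt
    disp_t = m.mobility_tetramer * ft * dt
    if m.kBT > 0:
        if len(state.verts):
            disp_v += sig_v * rng.standard_normal(state.verts.shape)
        if len(state.tet_centers):
            disp_t += sig_t * rng.standard_normal(state.tet_centers.shape)
    max_disp = 0.0
    if len(disp_v):
        max_disp = max(max_disp, float(np.max(np.linalg.norm(disp_v, axis=1))))
    if len(disp_t):
        max_disp = max(max_disp, float(np.max(np.linalg.norm(disp_t, axis=1))))
    if max_disp > m.L_seg:
        raise SimulationInstability(
            f"bead displacement {max_disp:.3g} μm exceeds L_seg={m.L_seg} μm "
            f"in one dt at t={state.time:.4f} s"
        )
    state.verts += disp_v
    state.tet_centers += disp_t
    seg_i, rest = state.segment_table()
    ok, res = _relax_segments(state.verts, seg_i, rest,
                              adjacent=state._topology()["adj"])
    if not ok:
        raise SimulationInstability(f"constraint projection residual {res:.3g}")
    if state.confinement is not None:
        _confine_all(state)
    state.time += dt
    return state


def _confine_all(state: SimState) -> None:
    c = state.confinement
    for arr in (state.verts, state.tet_centers):
        if len(arr):
            lev = c.level(arr)
            out = lev > 1.0
            if out.any():
                arr[out] = c.project(arr[out])


# ---------------------------------------------------------------------------
# stochastic chemistry


def unbind_probability(tension: np.ndarray, kin: KineticParams, dt: float) -> np.ndarray:
    """Per-step rupture probability 1 − exp(−k_eff·dt) with Bell's law
    k_eff = k_unbind0·exp(|F|/F_bell)."""
    k_eff = kin.k_unbind0 * np.exp(np.abs(tension) / kin.F_bell)
    return -np.expm1(-k_eff * dt)


def binding_update(state: SimState, rng: np.random.Generator | None = None) -> SimState:
    """Stochastic site–filament binding.

    Each unbound site fires with probability 1 − exp(−k_bind·dt); a firing
    site binds to one candidate segment whose nearest point lies within
    r_bind (chosen uniformly at random if several).  With
    ``multiple_events`` the firing probability scales with the number of
    candidate segments, 1 − exp(−n·k_bind·dt) (propensity ∝ local F-actin)."""
    rng = rng if rng is not None else state.rng
    kin, m = state.kin, state.mech
    if kin.k_bind == 0 or state.n_tetramers == 0 or state.n_filaments == 0:
        return state
    unbound = state.bond_fil < 0
    if not unbound.any():
        return state
    p1 = -math.expm1(-kin.k_bind * m.dt)
    ti, si = np.nonzero(unbound)
    fire = rng.random(len(ti)) < p1
    if not fire.any() and not kin.multiple_events:
        return state
    sites = state.site_positions()[ti, si]
    tree_v = cKDTree(state.verts)
    topo = state._topology()
    seg_starts = topo["seg_i"]
    lookup = topo["lookup"]
    # membership: global vertex index -> segments it belongs to
    # a segment within r_bind of a point has an endpoint within r_bind + L_seg
    search_r = kin.r_bind + m.L_seg
    candidates_needed = np.nonzero(fire)[0] if not kin.multiple_events else np.arange(len(ti))
    if len(candidates_needed) == 0:
        return state
    hits = tree_v.query_ball_point(sites[candidates_needed], search_r)
    for row, idx in zip(candidates_needed, hits):
        if not idx:
            continue
        g = np.asarray(idx)
        cand = np.concatenate([lookup[g], lookup[g[g > 0] - 1]])
        segs = np.unique(cand[cand >= 0])
        if not len(segs):
            continue
        p = sites[row]
        g0 = seg_starts[segs]
        a_pt = state.verts[g0]
        b_pt = state.verts[g0 + 1]
        ab = b_pt - a_pt
        denom = np.einsum("ij,ij->i", ab, ab)
        t = np.clip(np.einsum("ij,ij->i", p - a_pt, ab) / np.maximum(denom, 1e-18), 0.0, 1.0)
        near = a_pt + t[:, None] * ab
        dist = np.linalg.norm(near - p, axis=1)
        ok = dist <= kin.r_bind
        if not ok.any():
            continue
        if kin.multiple_events:
            n_cand = int(ok.sum())
            if rng.random() >= -math.expm1(-n_cand * kin.k_bind * m.dt):
                continue
        cand = np.nonzero(ok)[0]
        pick = cand[rng.integers(len(cand))]
        gseg = segs[pick]
        fil = int(topo["seg_fil"][gseg])
        local = int(topo["seg_local"][gseg])
        tt, ss = ti[row], si[row]
        state.bond_fil[tt, ss] = fil
        state.bond_seg[tt, ss] = local
        state.bond_abs[tt, ss] = float(t[pick])
    return state


def unbinding_update(state: SimState, rng: np.random.Generator | None = None) -> SimState:
    """Slip-bond rupture: each bond breaks with probability
    1 − exp(−k_unbind0·exp(|F|/F_bell)·dt)."""
    rng = rng if rng is not None else state.rng
    mask = state.bond_fil >= 0
    if not mask.any() or state.kin.k_unbind0 == 0:
        return state
    tension = state.bond_tensions()[mask]
    p = unbind_probability(tension, state.kin, state.mech.dt)
    breaks = rng.random(len(p)) < p
    if breaks.any():
        ti, si = np.nonzero(mask)
        ti, si = ti[breaks], si[breaks]
        state.bond_fil[ti, si] = -1
        state.bond_seg[ti, si] = 0
        state.bond_abs[ti, si] = 0.0
    return state


# ---------------------------------------------------------------------------
# growth and nucleation


def grow_filaments(state: SimState) -> SimState:
    """Deterministic plus-end elongation by k_grow·dt along the terminal
    tangent; a vertex is inserted whenever the terminal segment would exceed
    L_seg; growth stops exactly at L_fil_max.  When a finite actin pool is
    enabled the rate is scaled by the unpolymerized fraction and the pool
    is decremented by the polymerized length."""
    kin, m = state.kin, state.mech
    if kin.k_grow == 0 or not state.growing.any():
        return state
    scale = 1.0
    if np.isfinite(state.pool_total) and state.pool_total > 0:
        scale = max(state.pool_subunits, 0.0) / state.pool_total
    if scale == 0.0:
        return state
    contour = state.contour_lengths()
    inserts: list[tuple[int, np.ndarray]] = []  # (global insert position, vertex)
    for i in np.nonzero(state.growing)[0]:
        dL = min(kin.k_grow * m.dt * scale, kin.L_fil_max - contour[i])
        if dL <= 0:
            state.growing[i] = False
            continue
        o0, o1 = state.offsets[i], state.offsets[i + 1]
        tip = state.verts[o1 - 1]
        prev = state.verts[o1 - 2]
        u = tip - prev
        nu = np.linalg.norm(u)
        u = u / nu if nu > 1e-12 else np.array([0.0, 0.0, 1.0])
        new_rest = state.last_rest[i] + dL
        if new_rest > 2.0 * m.L_seg:
            # split off one exact L_seg segment; the ~L_seg remainder stays
            # terminal — never creates tiny segments (whose 1/l bending
            # gradients destabilize the integrator) and keeps interior
            # rest lengths exactly L_seg
            v_new = prev + u * m.L_seg
            rem = new_rest - m.L_seg
            state.verts[o1 - 1] = v_new + u * rem
            inserts.append((int(o1 - 1), v_new))
            state.last_rest[i] = rem
        else:
            state.verts[o1 - 1] = prev + u * new_rest
            state.last_rest[i] = new_rest
        if np.isfinite(state.pool_subunits):
            state.pool_subunits -= dL * SUBUNITS_PER_UM
        if contour[i] + dL >= kin.L_fil_max - 1e-12:
            state.growing[i] = False
    if inserts:
        _insert_vertices(state, inserts)
    return state


def _insert_vertices(state: SimState, inserts: list[tuple[int, np.ndarray]]) -> None:
    """Insert new vertices at the given flat positions, updating offsets and
    bond segment indices (anchors are unaffected: insertions happen at the
    very tip, after every existing segment)."""
    inserts.sort(key=lambda x: x[0])
    pos = np.array([p for p, _ in inserts])
    vec = np.array([v for _, v in inserts])
    # filament owning each insertion, resolved against the ORIGINAL offsets
    fils = np.searchsorted(state.offsets, pos, side="right") - 1
    state.verts = np.insert(state.verts, pos, vec, axis=0)
    for fil in fils:
        state.offsets[fil + 1 :] += 1
    # local bond segment indices are unaffected: insertions happen at the
    # filament tip, after every segment that can carry an anchor
    state._invalidate()


def nucleation_update(state: SimState, rng: np.random.Generator | None = None) -> SimState:
    """New 2-vertex seed filaments appear as a Poisson process with rate
    nucleation_rate_constant × [nucleator] × unpolymerized fraction."""
    rng = rng if rng is not None else state.rng
    kin = state.kin
    if kin.nucleation_rate_constant == 0 or kin.nucleator_nM == 0:
        return state
    frac = 1.0
    if np.isfinite(state.pool_total) and state.pool_total > 0:
        frac = max(state.pool_subunits, 0.0) / state.pool_total
    rate = kin.nucleation_rate_constant * kin.nucleator_nM * frac
    n_new = rng.poisson(rate * state.mech.dt)
    for _ in range(n_new):
        seed_len = state.mech.L_seg
        if np.isfinite(state.pool_subunits):
            if state.pool_subunits < seed_len * SUBUNITS_PER_UM:
                break
            state.pool_subunits -= seed_len * SUBUNITS_PER_UM
        center = _random_point_in_confinement(state.confinement, rng, margin=0.05)
        u = _random_unit(rng)
        v0 = center - 0.5 * seed_len * u
        v1 = center + 0.5 * seed_len * u
        state.verts = np.concatenate([state.verts, [v0, v1]])
        state.offsets = np.concatenate([state.offsets, [state.offsets[-1] + 2]])
        state.last_rest = np.concatenate([state.last_rest, [seed_len]])
        state.growing = np.concatenate([state.growing, [True]])
        state._invalidate()
    return state


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def _random_point_in_confinement(
    conf: Confinement | None, rng: np.random.Generator, margin: float = 0.05
) -> np.ndarray:
    if conf is None:
        return rng.uniform(-1, 1, 3)
    a, b = conf.a - margin, conf.b - margin
    while True:
        p = rng.uniform(-1, 1, 3) * [b, b, a]
        if (p[0] ** 2 + p[1] ** 2) / b**2 + p[2] ** 2 / a**2 <= 1.0:
            return p


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class SimConfig:
    """Everything needed for a reproducible run."""

    mech: MechParams = field(default_factory=MechParams)
    kin: KineticParams = field(default_factory=KineticParams)
    confinement: Confinement = field(default_factory=lambda: Confinement.sphere(1.0))
    n_filaments: int = 30
    seed_length: float = 0.1  # μm
    tetramer_concentration_uM: float = 0.40
    n_tetramers: int | None = None  # overrides concentration when set
    duration: float = 600.0  # s
    snapshot_stride: int = 1000  # steps between recorded frames
    seed: int = 0
    nucleation: bool = False

    def tetramer_count(self) -> int:
        if self.n_tetramers is not None:
            return self.n_tetramers
        return int(round(self.tetramer_concentration_uM * CONC_UM_TO_PER_UM3 * self.confinement.volume))


#: unit site directions of a regular tetrahedron (rotated per tetramer)
_TETRA = np.array(
    [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
) / np.sqrt(3.0)


def init_state(config: SimConfig) -> SimState:
    """Seed filaments uniform in the droplet (0.05 μm margin, uniform random
    orientations); tetramers uniform with randomly rotated site frames."""
    rng = np.random.default_rng(config.seed)
    conf = config.confinement
    verts_list = []
    for _ in range(config.n_filaments):
        c = _random_point_in_confinement(conf, rng, margin=0.05)
        u = _random_unit(rng)
        verts_list.append(c - 0.5 * config.seed_length * u)
        verts_list.append(c + 0.5 * config.seed_length * u)
    verts = np.array(verts_list).reshape(-1, 3) if verts_list else np.empty((0, 3))
    offsets = np.arange(0, 2 * config.n_filaments + 1, 2)
    M = config.tetramer_count()
    centers = np.array([_random_point_in_confinement(conf, rng, 0.03) for _ in range(M)])
    centers = centers.reshape(-1, 3)
    site_dirs = np.empty((M, 4, 3))
    for i in range(M):
        # random rotation via QR of a Gaussian matrix
        q, r = np.linalg.qr(rng.standard_normal((3, 3)))
        q *= np.sign(np.diag(r))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        site_dirs[i] = _TETRA @ q.T
    kin = config.kin
    pool_total = np.inf
    if kin.G_pool_uM > 0:
        pool_total = kin.G_pool_uM * CONC_UM_TO_PER_UM3 * conf.volume
    return SimState(
        mech=config.mech,
        kin=kin,
        confinement=conf,
        verts=verts,
        offsets=offsets,
        last_rest=np.full(config.n_filaments, min(config.seed_length, config.mech.L_seg)),
        growing=np.ones(config.n_filaments, dtype=bool),
        tet_centers=centers,
        site_dirs=site_dirs,
        bond_fil=np.full((M, 4), -1, dtype=np.int64),
        bond_seg=np.zeros((M, 4), dtype=np.int64),
        bond_abs=np.zeros((M, 4)),
        rng=rng,
        time=0.0,
        pool_subunits=pool_total,
        pool_total=pool_total,
    )


def step(state: SimState) -> SimState:
    """One full step: forces → Langevin → constraints → confinement →
    binding → unbinding → growth (→ nucleation when enabled)."""
    langevin_step(state)
    binding_update(state)
    unbinding_update(state)
    grow_filaments(state)
    if state.kin.nucleation_rate_constant > 0:
        nucleation_update(state)
    if state.confinement is not None and state.n_filaments:
        # growth moved only the tip vertices; re-confine just those
        tips = state.offsets[1:] - 1
        c = state.confinement
        lev = c.level(state.verts[tips])
        out = lev > 1.0
        if out.any():
            state.verts[tips[out]] = c.project(state.verts[tips[out]])
    return state


def run_simulation(config: SimConfig) -> list[Snapshot]:
    """Run the full protocol and return recorded Snapshots (initial frame,
    every ``snapshot_stride`` steps, and the final frame).  Reproducible:
    identical (config, seed) gives identical trajectories."""
    state = init_state(config)
    n_steps = int(round(config.duration / config.mech.dt))
    snaps = [state.snapshot()]
    for k in range(n_steps):
        step(state)
        if (k + 1) % config.snapshot_stride == 0 or k == n_steps - 1:
            snaps.append(state.snapshot())
    return snaps
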