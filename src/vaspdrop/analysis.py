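"""Per-snapshot quantification of actin network shape.

Five order parameters drive the downstream classification: the fraction of
the droplet boundary covered by actin (``area_fraction``) and the fractions
of tetramers bound to exactly 1, 2, 3 or 4 *distinct* filaments
(``f1``..``f4``; the remainder ``f0`` is the unbound fraction).  Additional
descriptors: gyration-tensor ellipsoidal spans, endpoint pairwise-distance
PDFs, radial density profiles and filament-length statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import TriangulatedSurface, build_icosphere
from .snapshots import MONOMER_RISE, Snapshot

__all__ = [
    "OrderParams",
    "surface_area_fraction",
    "valency_fractions",
    "gyration_spans",
    "end_pair_distance_pdf",
    "radial_density",
    "length_stats",
    "order_params",
]


@dataclass(frozen=True)
class OrderParams:
    """The five shape order parameters of one snapshot."""

    area_fraction: float
    f1: float
    f2: float
    f3: float
    f4: float

    @property
    def f0(self) -> float:
        return 1.0 - (self.f1 + self.f2 + self.f3 + self.f4)

    def as_array(self) -> np.ndarray:
        return np.array([self.area_fraction, self.f1, self.f2, self.f3, self.f4])


COLUMNS = ["area_fraction", "f1", "f2", "f3", "f4"]


def surface_area_fraction(
    s: Snapshot,
    surf: TriangulatedSurface | None = None,
    shell_depth: float = 0.1,
    rise: float = MONOMER_RISE,
) -> float:
    """Fraction of boundary triangles occupied by actin.

    Filaments are resampled at monomer resolution (2.7 nm rise); monomers
    within ``shell_depth`` (100 nm) of the boundary are assigned to the
    nearest triangle by centroid distance, and the fraction of triangles
    hit is returned.  ``surf`` defaults to the 4×-subdivided icosphere at
    the droplet radius (spherical confinement only)."""
    if surf is None:
        if s.confinement is None or not s.confinement.is_sphere:
            raise ValueError("an explicit surface is required for non-spherical frames")
        surf = build_icosphere(s.confinement.a, 4)
    mono = s.monomers(rise)
    if len(mono) == 0:
        return 0.0
    bdist = surf.radius - np.linalg.norm(mono, axis=1)  # distance to sphere
    near = mono[np.abs(bdist) <= shell_depth]
    if len(near) == 0:
        return 0.0
    _, tri = cKDTree(surf.centroids).query(near)
    return len(np.unique(tri)) / surf.n_triangles


def valency_fractions(s: Snapshot) -> np.ndarray:
    """(f0, f1, f2, f3, f4): fractions of tetramers bound to exactly
    0..4 DISTINCT filaments.  Two bonds to the same filament count once."""
    M = s.n_tetramers
    out = np.zeros(5)
    if M == 0:
        out[0] = 1.0
        return out
    if len(s.bonds):
        val = (
            s.bonds.groupby("tetramer")["filament"].nunique().reindex(
                range(M), fill_value=0
            )
        ).to_numpy()
    else:
        val = np.zeros(M, dtype=int)
    for v in range(5):
        out[v] = np.count_nonzero(val == v) / M
    return out


def order_params(s: Snapshot, surf: TriangulatedSurface | None = None) -> OrderParams:
    f = valency_fractions(s)
    return OrderParams(
        area_fraction=surface_area_fraction(s, surf),
        f1=f[1],
        f2=f[2],
        f3=f[3],
        f4=f[4],
    )


def gyration_spans(s: Snapshot, rise: float = MONOMER_RISE) -> np.ndarray:
    """Ellipsoidal spans (descending) of the monomer-resampled actin cloud.

    Eigenvalues λ of the 3×3 gyration tensor give spans 2·sqrt(5·λ), the
    axis lengths of the uniform solid ellipsoid with the same tensor."""
    pts = s.monomers(rise)
    if len(pts) < 2:
        raise ValueError("gyration spans undefined for fewer than 2 beads")
    x = pts - pts.mean(axis=0)
    g = x.T @ x / len(x)
    lam = np.sort(np.linalg.eigvalsh(g))[::-1]
    return 2.0 * np.sqrt(5.0 * np.clip(lam, 0.0, None))


def end_pair_distance_pdf(
    s: Snapshot, bin_width: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Probability density of pairwise distances between filament ends.

    All unordered pairs of the 2n endpoints are used (n(2n−1) pairs,
    including the two ends of the same filament).  Returns (bin centers,
    density); the histogram integrates to 1."""
    if s.n_filaments < 1:
        raise ValueError("need at least one filament")
    from scipy.spatial.distance import pdist

    d = pdist(s.endpoints())
    edges = np.arange(0.0, d.max() + 2 * bin_width, bin_width)
    dens, edges = np.histogram(d, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, dens


def radial_density(
    s: Snapshot, n_bins: int = 20, rise: float = MONOMER_RISE
) -> tuple[np.ndarray, np.ndarray]:
    """Monomer number density per spherical shell, monomers/μm³.

    Only defined for spherical confinement; returns (bin centers, density)."""
    if s.confinement is None or not s.confinement.is_sphere:
        raise ValueError("radial density requires spherical confinement")
    R = s.confinement.a
    edges = np.linspace(0.0, R, n_bins + 1)
    pts = s.monomers(rise)
    if len(pts):
        r = np.linalg.norm(pts, axis=1)
        counts, _ = np.histogram(r, bins=edges)
    else:
        counts = np.zeros(n_bins)
    vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts / vol


def length_stats(s: Snapshot) -> tuple[float, float, np.ndarray]:
    """(median, max, per-filament contour lengths) in μm."""
    lengths = s.contour_lengths()
    if len(lengths) == 0:
        return 0.0, 0.0, lengths
    return float(np.median(lengths)), float(np.max(lengths)), lengths


def metrics_frame(
    snapshots, surf: TriangulatedSurface | None = None
) -> pd.DataFrame:
    """Tidy per-snapshot metrics table: time, the five order parameters,
    gyration spans and length statistics — one row per snapshot."""
    rows = []
    for s in snapshots:
        op = order_params(s, surf)
        try:
            spans = gyration_spans(s)
        except ValueError:
            spans = np.full(3, np.nan)
        med, mx, _ = length_stats(s)
        rows.append(
            {
                "time": s.time,
                "area_fraction": op.area_fraction,
                "f0": op.f0,
                "f1": op.f1,
                "f2": op.f2,
                "f3": op.f3,
                "f4": op.f4,
                "span_a": spans[0],
                "span_b": spans[1],
                "span_c": spans[2],
                "median_length": med,
                "max_length": mx,
            }
        )
    return pd.DataFrame(rows)
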