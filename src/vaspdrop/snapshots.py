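"""Immutable trajectory frames shared by the engine, the fixture generator
and the analysis pipeline, plus plain-text (CSV/JSON) serialization."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import Confinement

__all__ = ["Snapshot", "BOND_COLUMNS", "save_trajectory", "load_trajectory"]

#: bond-table schema: one row per occupied tetramer binding site
BOND_COLUMNS = ["tetramer", "site", "filament", "segment", "abscissa"]

#: monomer rise along an actin filament, μm (≈370 subunits per μm)
MONOMER_RISE = 0.0027


@dataclass(frozen=True)
class Snapshot:
    """One frame: filament vertex chains, tetramer centers, bond table and
    the confinement the frame lives in.

    ``bonds`` is a DataFrame with columns ``tetramer, site, filament,
    segment, abscissa``; the anchor point of a bond lies on the referenced
    filament segment at fractional position ``abscissa`` in [0, 1].
    """

    time: float
    filaments: tuple  # tuple of (n_i, 3) float arrays
    tetramers: np.ndarray  # (M, 3) centers
    bonds: pd.DataFrame
    confinement: Confinement | None = None

    @staticmethod
    def empty_bonds() -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tetramer": pd.Series(dtype=np.int64),
                "site": pd.Series(dtype=np.int64),
                "filament": pd.Series(dtype=np.int64),
                "segment": pd.Series(dtype=np.int64),
                "abscissa": pd.Series(dtype=float),
            }
        )

    @property
    def n_filaments(self) -> int:
        return len(self.filaments)

    @property
    def n_tetramers(self) -> int:
        return len(self.tetramers)

    def contour_lengths(self) -> np.ndarray:
        """Per-filament contour length from vertex geometry, μm."""
        return np.array(
            [np.linalg.norm(np.diff(v, axis=0), axis=1).sum() for v in self.filaments]
        )

    def endpoints(self) -> np.ndarray:
        """(2·n_filaments, 3) array of filament end positions."""
        if not self.filaments:
            return np.empty((0, 3))
        return np.concatenate([[v[0], v[-1]] for v in self.filaments])

    def monomers(self, rise: float = MONOMER_RISE) -> np.ndarray:
        """All filaments resampled at monomer spacing (centers at
        rise/2, 3·rise/2, ... along the contour)."""
        pts = [resample_polyline(v, rise) for v in self.filaments]
        pts = [p for p in pts if len(p)]
        if not pts:
            return np.empty((0, 3))
        return np.concatenate(pts)


def resample_polyline(verts: np.ndarray, spacing: float) -> np.ndarray:
    """Points along a polyline at arclength positions spacing/2, 3·spacing/2, …"""
    seg = np.linalg.norm(np.diff(verts, axis=0), axis=1)
    total = seg.sum()
    if total < spacing / 2:
        return verts[:1].copy()
    s = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.arange(spacing / 2, total, spacing)
    out = np.empty((len(targets), 3))
    for k in range(3):
        out[:, k] = np.interp(targets, s, verts[:, k])
    return out


# ---------------------------------------------------------------------------
# plain-text trajectory container: beads.csv + bonds.csv + meta.json


def save_trajectory(snapshots: Sequence[Snapshot], directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    bead_rows = []
    bond_frames = []
    times = []
    for fi, snap in enumerate(snapshots):
        times.append(snap.time)
        for j, verts in enumerate(snap.filaments):
            for k, v in enumerate(verts):
                bead_rows.append((fi, "actin", j, k, v[0], v[1], v[2]))
        for j, c in enumerate(snap.tetramers):
            bead_rows.append((fi, "tetramer", j, 0, c[0], c[1], c[2]))
        b = snap.bonds.copy()
        b.insert(0, "frame", fi)
        bond_frames.append(b)
    beads = pd.DataFrame(
        bead_rows, columns=["frame", "kind", "owner", "index", "x", "y", "z"]
    )
    beads.to_csv(directory / "beads.csv", index=False)
    pd.concat(bond_frames, ignore_index=True).to_csv(
        directory / "bonds.csv", index=False
    )
    meta = {
        "times": times,
        "confinements": [
            (s.confinement.to_dict() if s.confinement is not None else None)
            for s in snapshots
        ],
    }
    with open(directory / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)


def load_trajectory(directory) -> list[Snapshot]:
    directory = Path(directory)
    beads = pd.read_csv(directory / "beads.csv")
    bonds = pd.read_csv(directory / "bonds.csv")
    with open(directory / "meta.json") as fh:
        meta = json.load(fh)
    out = []
    for fi, t in enumerate(meta["times"]):
        fb = beads[beads["frame"] == fi]
        act = fb[fb["kind"] == "actin"]
        filaments = tuple(
            g.sort_values("index")[["x", "y", "z"]].to_numpy()
            for _, g in act.groupby("owner", sort=True)
        )
        tet = (
            fb[fb["kind"] == "tetramer"]
            .sort_values("owner")[["x", "y", "z"]]
            .to_numpy()
        )
        bt = bonds[bonds["frame"] == fi][BOND_COLUMNS].reset_index(drop=True)
        cd = meta["confinements"][fi]
        conf = None if cd is None else Confinement(a=cd["a"], b=cd["b"])
        out.append(
            Snapshot(
                time=t,
                filaments=filaments,
                tetramers=tet,
                bonds=bt,
                confinement=conf,
            )
        )
    return out
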