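"""Reproducibility shell: structured-text configs, kinetic-parameter
sweeps with resumable manifests, and bundled replication recipes at full
and desk scale.

Desk-scale presets shrink the droplet, filament count and duration while
preserving the governing dimensionless groups (L_fil_max/R_drop, the
k_bind/k_unbind grid, and growth completing within the run), so the
qualitative phase behaviour is reproduced in minutes on one CPU.
"""

from __future__ import annotations

import configparser
import dataclasses
import json
import time as _time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis
from .deformation import (DeformationProtocol, bulk_concentration,
                          filament_limited_aspect, run_deformation)
from .engine import KineticParams, MechParams, SimConfig, run_simulation
from .fixtures import FixtureSpec, make_fixture
from .geometry import Confinement, build_icosphere
from .snapshots import save_trajectory

__all__ = [
    "SweepSpec",
    "run_sweep",
    "replicate_paper",
    "desk_config",
    "full_config",
    "load_config",
    "save_config",
    "RECIPES",
]


# ---------------------------------------------------------------------------
# configuration files ([mechanics] / [kinetics] / [confinement] / [init] /
# [output] key=value sections)


def save_config(config: SimConfig, path) -> None:
    cp = configparser.ConfigParser()
    cp.optionxform = str  # keep parameter-name case
    cp["mechanics"] = {k: repr(v) for k, v in dataclasses.asdict(config.mech).items()}
    kin = {k: repr(v) for k, v in dataclasses.asdict(config.kin).items()}
    cp["kinetics"] = kin
    cp["confinement"] = {"a": repr(config.confinement.a), "b": repr(config.confinement.b)}
    cp["init"] = {
        "n_filaments": repr(config.n_filaments),
        "seed_length": repr(config.seed_length),
        "tetramer_concentration_um": repr(config.tetramer_concentration_uM),
        "n_tetramers": repr(config.n_tetramers),
        "seed": repr(config.seed),
    }
    cp["output"] = {
        "duration": repr(config.duration),
        "snapshot_stride": repr(config.snapshot_stride),
    }
    with open(path, "w") as fh:
        cp.write(fh)


def _coerce(text: str):
    t = text.strip()
    if t == "None":
        return None
    if t in ("True", "False"):
        return t == "True"
    try:
        return int(t)
    except ValueError:
        pass
    try:
        return float(t)
    except ValueError:
        return t


def load_config(path) -> SimConfig:
    cp = configparser.ConfigParser()
    cp.optionxform = str
    with open(path) as fh:
        cp.read_file(fh)
    mech = MechParams(**{k: _coerce(v) for k, v in cp["mechanics"].items()})
    kin = KineticParams(**{k: _coerce(v) for k, v in cp["kinetics"].items()})
    conf = Confinement(a=_coerce(cp["confinement"]["a"]), b=_coerce(cp["confinement"]["b"]))
    init = {k: _coerce(v) for k, v in cp["init"].items()}
    out = {k: _coerce(v) for k, v in cp["output"].items()}
    return SimConfig(
        mech=mech,
        kin=kin,
        confinement=conf,
        n_filaments=init["n_filaments"],
        seed_length=init["seed_length"],
        tetramer_concentration_uM=init["tetramer_concentration_um"],
        n_tetramers=init["n_tetramers"],
        seed=init["seed"],
        duration=out["duration"],
        snapshot_stride=out["snapshot_stride"],
    )


# ---------------------------------------------------------------------------
# presets


def full_config(seed: int = 0, **kin_overrides) -> SimConfig:
    """The study's reference conditions: R_drop = 1 μm, 30 seed filaments of
    0.1 μm, 0.40 μM tetramers, growth to 2π μm over 600 s (10.3 nm/s)."""
    kin = KineticParams(k_grow=0.0103, L_fil_max=2 * np.pi, **kin_overrides)
    return SimConfig(
        mech=MechParams(),
        kin=kin,
        confinement=Confinement.sphere(1.0),
        n_filaments=30,
        seed_length=0.1,
        tetramer_concentration_uM=0.40,
        duration=600.0,
        snapshot_stride=1500,  # 100 frames per 600 s run
        seed=seed,
    )


def desk_config(seed: int = 0, **kin_overrides) -> SimConfig:
    """Desk-scale preset: R_drop = 0.5 μm, 10 filaments, 60 s, with
    L_fil_max/R_drop = 2π and growth finishing within the run preserved."""
    R = 0.5
    L_max = 2 * np.pi * R
    kin_kwargs = dict(k_grow=(L_max - 0.1) / 60.0, L_fil_max=L_max)
    kin_kwargs.update(kin_overrides)
    kin = KineticParams(**kin_kwargs)
    return SimConfig(
        mech=MechParams(),
        kin=kin,
        confinement=Confinement.sphere(R),
        n_filaments=10,
        seed_length=0.1,
        tetramer_concentration_uM=0.40,
        duration=60.0,
        snapshot_stride=1500,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# sweeps


@dataclass
class SweepSpec:
    """Grid over crosslinker kinetics with replicate runs per cell."""

    k_bind_values: tuple = (1e-4, 1e-3, 1e-2, 1e-1, 1.0, 10.0)
    k_unbind_values: tuple = (1e-4, 1e-3, 1e-2, 1e-1, 1.0, 10.0)
    replicates: int = 3
    base: SimConfig = field(default_factory=desk_config)
    seed_root: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.k_bind_values) or any(
            v <= 0 for v in self.k_unbind_values
        ):
            raise ValueError("all grid values must be > 0")

    def cells(self):
        for kb in self.k_bind_values:
            for ku in self.k_unbind_values:
                for rep in range(self.replicates):
                    yield kb, ku, rep

    def cell_seed(self, kb: float, ku: float, rep: int) -> int:
        i = list(self.k_bind_values).index(kb)
        j = list(self.k_unbind_values).index(ku)
        ss = np.random.SeedSequence(
            [self.seed_root, i, j, rep]
        )
        return int(ss.generate_state(1)[0] % (2**31))


def run_sweep(spec: SweepSpec, out_dir) -> pd.DataFrame:
    """Run (or resume) the sweep; one trajectory + metrics CSV per
    (cell, replicate), and a manifest mapping seeds to outputs.  Cells
    already present in the manifest are skipped; per-cell failures are
    logged and the sweep continues."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.csv"
    done = set()
    records = []
    if manifest_path.exists():
        prev = pd.read_csv(manifest_path)
        records = prev.to_dict("records")
        done = {
            (r["k_bind"], r["k_unbind"], r["replicate"])
            for r in records
            if r["status"] == "ok"
        }
    surf = build_icosphere(spec.base.confinement.R_drop, 4)
    for kb, ku, rep in spec.cells():
        if (kb, ku, rep) in done:
            continue
        seed = spec.cell_seed(kb, ku, rep)
        cfg = replace(
            spec.base, kin=replace(spec.base.kin, k_bind=kb, k_unbind0=ku), seed=seed
        )
        tag = f"kb{kb:g}_ku{ku:g}_r{rep}"
        t0 = _time.perf_counter()
        try:
            save_config(cfg, out_dir / f"config_{tag}.cfg")  # parameter echo
            snaps = run_simulation(cfg)
            metrics = analysis.metrics_frame(snaps, surf)
            mpath = out_dir / f"metrics_{tag}.csv"
            metrics.to_csv(mpath, index=False)
            save_trajectory(snaps, out_dir / f"traj_{tag}")
            records.append(
                {
                    "k_bind": kb,
                    "k_unbind": ku,
                    "replicate": rep,
                    "seed": seed,
                    "metrics": mpath.name,
                    "status": "ok",
                    "wall_s": round(_time.perf_counter() - t0, 2),
                }
            )
        except Exception as exc:  # pragma: no cover - per-cell failure path
            records.append(
                {
                    "k_bind": kb,
                    "k_unbind": ku,
                    "replicate": rep,
                    "seed": seed,
                    "metrics": "",
                    "status": f"failed: {exc}",
                    "wall_s": round(_time.perf_counter() - t0, 2),
                }
            )
        pd.DataFrame(records).to_csv(manifest_path, index=False)
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# replication recipes


def _recipe_fig2_sweep(scale, out_dir, seed, replicates):
    if out_dir is None:
        import tempfile

        out_dir = tempfile.mkdtemp(prefix="vaspdrop_fig2_")
    base = desk_config(seed) if scale == "desk" else full_config(seed)
    spec = SweepSpec(
        k_bind_values=(1e-4, 10.0),
        k_unbind_values=(1.0,),
        replicates=replicates,
        base=base,
        seed_root=seed,
    )
    manifest = run_sweep(spec, out_dir)
    means = {}
    for kb in spec.k_bind_values:
        vals = []
        for rep in range(replicates):
            tag = f"kb{kb:g}_ku1_r{rep}"
            m = pd.read_csv(Path(out_dir) / f"metrics_{tag}.csv")
            vals.append(float(m["area_fraction"].iloc[-1]))
        means[kb] = float(np.mean(vals))
    return {
        "recipe": "fig2_sweep",
        "terminal_area_fraction_by_k_bind": means,
        "fast_binding_lower_than_slow": means[10.0] < means[1e-4],
    }


def _recipe_fig4_lengths(scale, out_dir, seed, replicates):
    base = desk_config(seed, k_bind=10.0, k_unbind0=1.0) if scale == "desk" else full_config(
        seed, k_bind=10.0, k_unbind0=1.0)
    R = base.confinement.R_drop
    results = {}
    for frac in (0.8, 1.6, 4.0):
        L_max = frac * R
        cfg = replace(base, kin=replace(base.kin, L_fil_max=L_max),
                      seed=seed + int(frac * 10))
        snaps = run_simulation(cfg)
        centers, dens = analysis.end_pair_distance_pdf(snaps[-1], bin_width=0.1 * R)
        results[f"L={frac:g}R"] = {
            "pdf_mode_um": float(centers[np.argmax(dens)]),
            "final_median_length_um": analysis.length_stats(snaps[-1])[0],
        }
    return {"recipe": "fig4_lengths", "droplet_diameter_um": 2 * R, "conditions": results}


def _recipe_fig5_T2piR(scale, out_dir, seed, replicates):
    base = desk_config(seed, k_bind=0.1, k_unbind0=0.1) if scale == "desk" else full_config(
        seed, k_bind=0.1, k_unbind0=0.1)
    R = base.confinement.R_drop
    results = {}
    for t_frac in (0.25, 1.0):  # T_2piR relative to the run duration
        T = t_frac * base.duration
        k_grow = (2 * np.pi * R - base.seed_length) / T
        cfg = replace(base, kin=replace(base.kin, k_grow=k_grow), seed=seed + int(t_frac * 4))
        snaps = run_simulation(cfg)
        op = analysis.order_params(snaps[-1])
        results[f"T_2piR={T:g}s"] = {
            "k_grow_um_per_s": k_grow,
            "area_fraction": op.area_fraction,
            "f3_plus_f4": op.f3 + op.f4,
        }
    return {"recipe": "fig5_T2piR", "conditions": results}


def _recipe_fig7_deformation(scale, out_dir, seed, replicates):
    R = 0.5 if scale == "desk" else 1.0
    L_max = 2 * np.pi * R
    spec = FixtureSpec(morphology="ring", R_drop=R, n_filaments=10 if scale == "desk" else 30,
                       filament_length=L_max, n_tetramers=60 if scale == "desk" else 200,
                       seed=seed)
    snap = make_fixture(spec)
    state = _state_from_snapshot(snap, k_unbind0=1.0, k_bind=10.0, L_fil_max=L_max, seed=seed)
    protocol = DeformationProtocol(
        equilibration_time=1.0 if scale == "full" else 0.2,
        max_steps=30 if scale == "desk" else None,
    )
    snaps, max_ar, log = run_deformation(state, protocol)
    bound = filament_limited_aspect(L_max, R)
    if out_dir is not None:
        log.to_csv(Path(out_dir) / "deformation_log.csv", index=False)
    return {
        "recipe": "fig7_deformation",
        "analytic_bound_a_over_b": bound,
        "measured_max_a_over_b": max_ar,
        "C_bulk_uM": bulk_concentration(snap),
        "steps": len(log),
    }


def _state_from_snapshot(snap, k_bind=10.0, k_unbind0=1.0, L_fil_max=None, seed=0):
    """Build a SimState around a fixture snapshot (terminated growth)."""
    from .engine import SimState, _TETRA

    rng = np.random.default_rng(seed)
    verts = np.concatenate(snap.filaments) if snap.filaments else np.empty((0, 3))
    offsets = np.concatenate([[0], np.cumsum([len(v) for v in snap.filaments])]).astype(int)
    M = snap.n_tetramers
    site_dirs = np.empty((M, 4, 3))
    for i in range(M):
        q, r = np.linalg.qr(rng.standard_normal((3, 3)))
        q *= np.sign(np.diag(r))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        site_dirs[i] = _TETRA @ q.T
    bond_fil = np.full((M, 4), -1, dtype=np.int64)
    bond_seg = np.zeros((M, 4), dtype=np.int64)
    bond_abs = np.zeros((M, 4))
    for row in snap.bonds.itertuples(index=False):
        bond_fil[row.tetramer, row.site] = row.filament
        bond_seg[row.tetramer, row.site] = row.segment
        bond_abs[row.tetramer, row.site] = row.abscissa
    mech = MechParams()
    kin = KineticParams(k_bind=k_bind, k_unbind0=k_unbind0,
                        L_fil_max=L_fil_max if L_fil_max is not None else 2 * np.pi)
    last_rest = np.array([
        float(np.linalg.norm(v[-1] - v[-2])) if len(v) > 1 else mech.L_seg
        for v in snap.filaments
    ])
    last_rest = np.clip(last_rest, 1e-4, mech.L_seg)
    return SimState(
        mech=mech, kin=kin, confinement=snap.confinement,
        verts=verts.copy(), offsets=offsets, last_rest=last_rest,
        growing=np.zeros(len(snap.filaments), dtype=bool),
        tet_centers=snap.tetramers.copy(), site_dirs=site_dirs,
        bond_fil=bond_fil, bond_seg=bond_seg, bond_abs=bond_abs,
        rng=rng, time=snap.time,
    )


RECIPES = {
    "fig2_sweep": _recipe_fig2_sweep,
    "fig4_lengths": _recipe_fig4_lengths,
    "fig5_T2piR": _recipe_fig5_T2piR,
    "fig7_deformation": _recipe_fig7_deformation,
}


def replicate_paper(recipe_name: str, scale: str = "desk", out_dir=None,
                    seed: int = 0, replicates: int = 3) -> dict:
    """Run a bundled replication recipe and return its report (also written
    as JSON when ``out_dir`` is given)."""
    if recipe_name not in RECIPES:
        raise KeyError(
            f"unknown recipe {recipe_name!r}; available: {sorted(RECIPES)}"
        )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
    report = RECIPES[recipe_name](scale, out_dir, seed, replicates)
    report["scale"] = scale
    report["seed"] = seed
    if out_dir is not None:
        with open(out_dir / f"report_{recipe_name}.json", "w") as fh:
            json.dump(report, fh, indent=1, default=float)
    return report
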