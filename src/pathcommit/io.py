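"""Readers and writers shared by all pipeline stages.

Formats: extended XYZ with a trailing role column for coordination-shell
configurations; an ``.npz`` array container with a JSON sidecar for
trajectories; CSV with documented column order for committor records,
histograms and free-energy profiles; JSON schema sidecars for feature
tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .committor import CommittorDistribution, CommittorRecord
from .features import FeatureSchema
from .free_energy import FreeEnergyProfile
from .toy_dynamics import SolvationConfig, Trajectory

__all__ = [
    "read_xyz", "write_xyz",
    "save_trajectory", "load_trajectory",
    "records_to_csv", "records_from_csv",
    "distribution_to_csv", "profile_to_csv",
    "write_feature_table", "read_feature_table",
]

_ROLE_ELEMENT = {
    "ion": "Mg",
    "water_O": "O",
    "water_H": "H",
    "phosphate_O1P": "O",
    "phosphate_O2P": "O",
    "phosphate_P": "P",
    "chloride": "Cl",
    "other_RNA": "N",
}


def write_xyz(configs: list[SolvationConfig], path: str | Path) -> None:
    """Extended XYZ: ``element x y z role`` per atom, coordinates in nm."""
    lines = []
    for cfg in configs:
        n = 1 + cfg.ligand_positions.shape[0]
        lines.append(str(n))
        lines.append("ion + coordination shell; columns: element x y z role")
        x, y, z = cfg.ion_position
        lines.append(f"Mg {x:.12g} {y:.12g} {z:.12g} ion")
        for pos, role in zip(cfg.ligand_positions, cfg.ligand_roles):
            el = _ROLE_ELEMENT[role]
            lines.append(f"{el} {pos[0]:.12g} {pos[1]:.12g} {pos[2]:.12g} {role}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_xyz(path: str | Path) -> list[SolvationConfig]:
    """Parse extended XYZ written by :func:`write_xyz`.

    Round-trips coordinates to full precision and roles exactly; raises
    with the line number on malformed input.  An empty file yields an
    empty list.
    """
    text = Path(path).read_text().splitlines()
    configs = []
    i = 0
    while i < len(text):
        if not text[i].strip():
            i += 1
            continue
        try:
            n = int(text[i].strip())
        except ValueError as exc:
            raise ValueError(f"line {i + 1}: expected an atom count") from exc
        if i + 1 + n >= len(text) + 1 and n > 0:
            raise ValueError(f"line {i + 1}: frame truncated ({n} atoms declared)")
        ion = None
        positions, roles = [], []
        for j in range(n):
            ln = i + 2 + j
            parts = text[ln].split()
            if len(parts) != 5:
                raise ValueError(
                    f"line {ln + 1}: expected 'element x y z role', got "
                    f"{text[ln]!r}"
                )
            try:
                xyz = [float(p) for p in parts[1:4]]
            except ValueError as exc:
                raise ValueError(f"line {ln + 1}: bad coordinate") from exc
            if parts[4] == "ion":
                if ion is not None:
                    raise ValueError(f"line {ln + 1}: second ion in frame")
                ion = xyz
            else:
                positions.append(xyz)
                roles.append(parts[4])
        if ion is None:
            raise ValueError(f"frame starting at line {i + 1} has no ion")
        configs.append(
            SolvationConfig(
                ion_position=np.array(ion),
                ligand_positions=np.array(positions).reshape(-1, 3),
                ligand_roles=roles,
            )
        )
        i += 2 + n
    return configs


# ---------------------------------------------------------------------------

def save_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Array container (.npz) plus a JSON sidecar with the metadata."""
    path = Path(path)
    np.savez_compressed(path, positions=traj.positions, velocities=traj.velocities)
    meta = {
        "timestep": traj.timestep,
        "t0": traj.t0,
        "spec_ref": traj.spec_ref,
        "rng_seed": traj.rng_seed,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_trajectory(path: str | Path) -> Trajectory:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    arrays = np.load(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return Trajectory(
        positions=arrays["positions"], velocities=arrays["velocities"],
        timestep=meta["timestep"], t0=meta["t0"], spec_ref=meta["spec_ref"],
        rng_seed=meta["rng_seed"],
    )


# ---------------------------------------------------------------------------

RECORD_COLUMNS = ["config_id", "p_A", "n_A", "n_B", "n_trials",
                  "is_transition_state"]


def records_to_csv(records: list[CommittorRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            [r.config_id, r.p_A, r.n_A, r.n_B, r.n_trials, r.is_transition_state]
            for r in records
        ],
        columns=RECORD_COLUMNS,
    )
    df.to_csv(path, index=False)


def records_from_csv(path: str | Path) -> list[CommittorRecord]:
    df = pd.read_csv(path)
    return [
        CommittorRecord(
            config_id=int(row.config_id), p_A=float(row.p_A),
            n_A=int(row.n_A), n_B=int(row.n_B), n_trials=int(row.n_trials),
        )
        for row in df.itertuples()
    ]


def distribution_to_csv(dist: CommittorDistribution, path: str | Path) -> None:
    pd.DataFrame(
        {
            "bin_left": dist.bin_edges[:-1],
            "bin_right": dist.bin_edges[1:],
            "count": dist.counts,
        }
    ).to_csv(path, index=False)


def profile_to_csv(profile: FreeEnergyProfile, path: str | Path) -> None:
    if profile.ndim == 1:
        pd.DataFrame(
            {
                "bin_center": profile.grid[0],
                "F_kBT": profile.F,
                "occupancy": profile.occupancy,
            }
        ).to_csv(path, index=False)
    else:
        gx, gy = np.meshgrid(*profile.grid, indexing="ij")
        pd.DataFrame(
            {
                "bin_center_1": gx.ravel(),
                "bin_center_2": gy.ravel(),
                "F_kBT": profile.F.ravel(),
                "occupancy": profile.occupancy.ravel(),
            }
        ).to_csv(path, index=False)


# ---------------------------------------------------------------------------

def write_feature_table(
    X: np.ndarray, schema: FeatureSchema, path: str | Path
) -> None:
    """CSV feature table with a JSON schema sidecar."""
    path = Path(path)
    pd.DataFrame(X, columns=schema.names).to_csv(path, index=False)
    sidecar = {"names": schema.names, "groups": schema.groups,
               "count": schema.count}
    path.with_suffix(".schema.json").write_text(json.dumps(sidecar, indent=1))


def read_feature_table(path: str | Path) -> tuple[np.ndarray, FeatureSchema]:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".schema.json").read_text())
    df = pd.read_csv(path)
    if list(df.columns) != sidecar["names"]:
        raise ValueError("feature table does not match its schema sidecar")
    return df.to_numpy(dtype=float), FeatureSchema(
        names=sidecar["names"], groups=sidecar["groups"]
    )
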