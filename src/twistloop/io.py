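"""Configuration, trajectory persistence and snapshot export.

Files store reduced units; the nm-per-diameter and bp-per-bead factors
travel in the metadata so conversions happen only at reporting time.

* Scenario configs round-trip through YAML (flat keys under a ``scenario``
  section).
* Trajectories persist as ``.npz`` containers: float64 arrays (lossless
  round-trip) plus a JSON metadata string.  Junction twist angles have no
  slot in standard trajectory formats, hence the native container;
  extended-XYZ export of single frames is provided for interchange and
  visualisation.
"""
from __future__ import annotations

import json
import zipfile
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml


from .chain import BeadChain, PolymerSystem
from .dynamics import SimulationBox, Trajectory
from .scenarios import ScenarioConfig

__all__ = [
    "write_config",
    "read_config",
    "write_trajectory",
    "read_trajectory",
    "write_xyz_frame",
    "RunManifest",
]

FORMAT_VERSION = 1


def _json_default(o):
    if isinstance(o, np.generic):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


class TrajectoryFormatError(IOError):
    """Corrupt, truncated or inconsistent trajectory file."""


# ---------------------------------------------------------------------------
# scenario configs
# ---------------------------------------------------------------------------

def write_config(config: ScenarioConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"scenario": asdict(config)}, fh, sort_keys=True)


def read_config(path) -> ScenarioConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or "scenario" not in data:
        raise ValueError(f"{path}: not a scenario config (missing 'scenario' section)")
    return ScenarioConfig(**data["scenario"])


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def write_trajectory(traj: Trajectory, path) -> None:
    """Lossless persistence of positions, twists, box and metadata."""
    meta = {
        "format_version": FORMAT_VERSION,
        "metadata": traj.metadata,
        "burn_index": int(traj.burn_index),
        "box": {"edge_length": traj.box.edge_length, "periodic": traj.box.periodic},
        "chains": [
            {
                "bead_diameter_nm": ch.bead_diameter_nm,
                "bp_per_bead": ch.bp_per_bead,
                "special_sites": ch.special_sites,
                "closed": ch.closed,
            }
            for ch in traj.template.chains
        ],
        "extra_bonds": [list(b) for b in traj.template.extra_bonds],
        "affinity_pairs": [list(p) for p in traj.template.affinity_pairs],
    }
    np.savez_compressed(
        path,
        times=traj.times,
        positions=traj.positions,
        twists=traj.twists,
        ring_start=traj.ring_start,
        meta=np.frombuffer(json.dumps(meta, default=_json_default).encode(),
                           dtype=np.uint8),
    )


def read_trajectory(path) -> Trajectory:
    try:
        with np.load(path) as data:
            required = {"times", "positions", "twists", "ring_start", "meta"}
            if not required.issubset(data.files):
                raise TrajectoryFormatError(
                    f"{path}: missing arrays {sorted(required - set(data.files))}"
                )
            times = data["times"]
            positions = data["positions"]
            twists = data["twists"]
            ring_start = data["ring_start"]
            meta = json.loads(bytes(data["meta"]).decode())
    except (OSError, ValueError, KeyError, zipfile.BadZipFile,
            json.JSONDecodeError) as err:
        raise TrajectoryFormatError(f"{path}: unreadable trajectory ({err})") from err
    if meta.get("format_version") != FORMAT_VERSION:
        raise TrajectoryFormatError(f"{path}: unsupported format version")
    if positions.ndim != 3 or positions.shape[0] != len(times):
        raise TrajectoryFormatError(f"{path}: frame count mismatch")
    if positions.shape[1] != ring_start[-1] or twists.shape != positions.shape[:2]:
        raise TrajectoryFormatError(f"{path}: bead count mismatch across frames")

    chains = []
    for r, chmeta in enumerate(meta["chains"]):
        lo, hi = ring_start[r], ring_start[r + 1]
        chains.append(
            BeadChain(
                positions=positions[0, lo:hi].copy(),
                twist_angles=twists[0, lo:hi].copy(),
                bead_diameter_nm=chmeta["bead_diameter_nm"],
                bp_per_bead=chmeta["bp_per_bead"],
                special_sites={k: int(v) for k, v in chmeta["special_sites"].items()},
                closed=chmeta.get("closed", True),
            )
        )
    template = PolymerSystem(
        chains=chains,
        extra_bonds=[tuple(b) for b in meta["extra_bonds"]],
        affinity_pairs=[tuple(p) for p in meta["affinity_pairs"]],
    )
    box = SimulationBox(**meta["box"])
    traj = Trajectory(times=times, positions=positions, twists=twists,
                      ring_start=ring_start, template=template, box=box,
                      metadata=meta["metadata"])
    traj.burn_index = int(meta["burn_index"])
    return traj


def write_xyz_frame(traj: Trajectory, frame: int, path) -> None:
    """Extended-XYZ snapshot: one atom record per bead, per-bead ring index
    and site label, comment line carrying box and linking difference."""
    system = traj.frame(frame)
    n = traj.positions.shape[1]
    dlk = float(np.sum(traj.twists[frame]) / (2 * np.pi))
    box = traj.box
    lattice = ""
    if box.periodic:
        L = box.edge_length
        lattice = f'Lattice="{L} 0 0 0 {L} 0 0 0 {L}" '
    with open(path, "w") as fh:
        fh.write(f"{n}\n")
        fh.write(
            f'{lattice}Properties=species:S:1:pos:R:3:ring:I:1 '
            f"time={traj.times[frame]} total_twist_plus_writhe_hint={dlk:.4f}\n"
        )
        for r, ch in enumerate(system.chains):
            labels = {v: k for k, v in ch.special_sites.items()}
            for i, p in enumerate(ch.positions):
                species = labels.get(i, "C")[0].upper()
                fh.write(f"{species} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f} {r}\n")


# ---------------------------------------------------------------------------
# run manifests
# ---------------------------------------------------------------------------

class RunManifest(dict):
    """Provenance record written next to every output file."""

    @classmethod
    def create(cls, config: ScenarioConfig, schedule, outputs: dict[str, str]):
        from . import __version__

        return cls(
            scenario=asdict(config),
            schedule={
                "n_steps": schedule.n_steps, "dt": schedule.dt,
                "sample_every": schedule.sample_every, "seed": schedule.seed,
                "equilibration_multiple": schedule.equilibration_multiple,
            },
            seed=schedule.seed,
            code_version=__version__,
            outputs=outputs,
        )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self, fh, indent=2, sort_keys=True, default=_json_default)
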