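"""Text formats: trajectories, TSV tables, run configs and manifests.

The trajectory format is a versioned plain-text format: a header block
(box, temperature, seed, sequences, chain composition) followed by one
block per frame with the MC-step stamp, the tracked energy and integer
bead coordinates.  Round-tripping is lossless.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from .mc import Frame, LatticeConfiguration, Trajectory
from .phase import Binodal, PhasePoint
from .interface import RadialProfile, InterfaceFit
from .sequences import EncodedSequence, encode_sequence

TRAJ_MAGIC = "# sticklat-trajectory v1"


def write_trajectory(path: str | Path, traj: Trajectory) -> None:
    with open(path, "w") as fh:
        fh.write(TRAJ_MAGIC + "\n")
        fh.write(f"box_side\t{traj.box_side}\n")
        fh.write(f"T\t{traj.T!r}\n")
        fh.write(f"seed\t{traj.seed}\n")
        fh.write(f"local_only\t{int(traj.local_only)}\n")
        fh.write(f"equilibrated_from\t{traj.equilibrated_from}\n")
        fh.write(f"n_sequences\t{len(traj.sequences)}\n")
        for s in traj.sequences:
            fh.write(f">{s.id}\n{s.raw_residues}\n")
        fh.write("chain_seq_index\t"
                 + " ".join(map(str, traj.chain_seq_index)) + "\n")
        fh.write("move_attempts\t" + " ".join(map(str, traj.move_attempts)) + "\n")
        fh.write("move_accepts\t" + " ".join(map(str, traj.move_accepts)) + "\n")
        for fr in traj.frames:
            fh.write(f"FRAME\t{fr.step}\t{fr.energy!r}\n")
            np.savetxt(fh, fr.positions, fmt="%d")


def read_trajectory(path: str | Path) -> Trajectory:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0] != TRAJ_MAGIC:
        raise ValueError(f"{path}: not a sticklat trajectory file")
    i = 1

    def kv(key):
        nonlocal i
        k, v = lines[i].split("\t", 1)
        if k != key:
            raise ValueError(f"{path}: expected {key!r}, found {k!r}")
        i += 1
        return v

    box = int(kv("box_side"))
    T = float(kv("T"))
    seed = int(kv("seed"))
    local_only = bool(int(kv("local_only")))
    eq_from = int(kv("equilibrated_from"))
    n_seq = int(kv("n_sequences"))
    seqs: list[EncodedSequence] = []
    for _ in range(n_seq):
        label = lines[i][1:]
        raw = lines[i + 1]
        i += 2
        seqs.append(encode_sequence(raw, id=label))
    csi = np.array(kv("chain_seq_index").split(), dtype=np.int64)
    attempts = np.array(kv("move_attempts").split(), dtype=np.int64)
    accepts = np.array(kv("move_accepts").split(), dtype=np.int64)
    chain_lens = np.array([len(seqs[s]) for s in csi], dtype=np.int64)
    n_beads = int(chain_lens.sum())
    frames = []
    while i < len(lines):
        if not lines[i].startswith("FRAME\t"):
            raise ValueError(f"{path}: malformed frame header at line {i + 1}")
        _, step, energy = lines[i].split("\t")
        i += 1
        pos = np.array(
            [row.split() for row in lines[i:i + n_beads]], dtype=np.int64
        )
        i += n_beads
        frames.append(Frame(int(step), pos, float(energy)))
    traj = Trajectory(
        box_side=box, chain_lens=chain_lens, sequences=seqs,
        chain_seq_index=csi, T=T, seed=seed, frames=frames,
        move_attempts=attempts, move_accepts=accepts,
        equilibrated_from=eq_from, local_only=local_only,
    )
    return traj


def write_xyz(path: str | Path, config: LatticeConfiguration,
              comment: str = "") -> None:
    """XYZ export for visualization (element Y for stickers, C else)."""
    with open(path, "w") as fh:
        fh.write(f"{config.n_beads}\n{comment}\n")
        for b in range(config.n_beads):
            el = "Y" if config.sticker_mask[b] else "C"
            x, y, z = config.positions[b]
            fh.write(f"{el} {x} {y} {z}\n")


# ---------------------------------------------------------------------------
# Tabular outputs
# ---------------------------------------------------------------------------

def binodal_to_tsv(path: str | Path, binodal: Binodal) -> None:
    with open(path, "w") as fh:
        fh.write("T\tc_dilute\tc_dense\tse_dilute\tse_dense\tn_replicates\tomega\n")
        for p in binodal.points:
            fh.write(f"{p.T:g}\t{p.c_dilute:.8g}\t{p.c_dense:.8g}\t"
                     f"{p.se_dilute:.4g}\t{p.se_dense:.4g}\t{p.n_replicates}\t"
                     f"{p.omega:.6g}\n")


def read_binodal_tsv(path: str | Path) -> Binodal:
    pts = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        for line in fh:
            row = dict(zip(header, line.split()))
            pts.append(PhasePoint(
                T=float(row["T"]), c_dilute=float(row["c_dilute"]),
                c_dense=float(row["c_dense"]),
                se_dilute=float(row.get("se_dilute", 0)),
                se_dense=float(row.get("se_dense", 0)),
                n_replicates=int(row.get("n_replicates", 1)),
            ))
    return Binodal(points=pts)


def read_experimental_arm(path: str | Path) -> list[tuple[float, float]]:
    """Read a (temperature, concentration) TSV arm.

    Lines starting with ``#`` are comments; an optional ``units`` line
    (``units\t<T units>\t<c units>``) is recorded but not converted —
    unit conversion constants are configuration, never computed.
    """
    arm = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("units"):
                continue
            parts = line.split()
            if parts[0].lower() in ("t", "temp", "temperature"):
                continue
            t, c = float(parts[0]), float(parts[1])
            if c <= 0:
                raise ValueError(f"{path}: non-positive concentration {c}")
            arm.append((t, c))
    if not arm:
        raise ValueError(f"{path}: no data rows")
    return arm


def profile_to_tsv(path: str | Path, profile: RadialProfile) -> None:
    with open(path, "w") as fh:
        fh.write("r\tvalue\tcount\tse\n")
        for r, v, c, s in zip(profile.centers, profile.value,
                              profile.count, profile.se):
            fh.write(f"{r:.3f}\t{v:.8g}\t{c:g}\t{s:.4g}\n")


def interface_fit_to_dict(fit: InterfaceFit) -> dict[str, float]:
    return {
        "phi_dilute": fit.phi_dilute, "phi_dense": fit.phi_dense,
        "r_mid": fit.r_mid, "delta": fit.delta,
        "residual_rms": fit.residual_rms,
        "band_lo": fit.band[0], "band_hi": fit.band[1],
    }


# ---------------------------------------------------------------------------
# Run configuration and manifest
# ---------------------------------------------------------------------------

_DEFAULTS: dict[str, Any] = {
    "box_side": 24,
    "temperatures": "40,45,50,55,60",
    "n_sweeps": 2000,
    "snapshot_interval": 100,
    "seed": 1,
    "n_replicates": 3,
    "contact_range": math.sqrt(3),
    "shell_width": 0.25,
    "top_fraction": 0.05,
    "ncpr_coefficient": 0.0,
    "reference_ncpr": 0.0,
    "start": "droplet",
    "moves": "default",
    # optional conversion constants to physical units (never computed)
    "kelvin_per_T": None,
    "molar_per_phi": None,
}


@dataclass
class RunConfig:
    """Flat key/value run configuration with include support."""

    values: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        merged = dict(_DEFAULTS)
        merged.update(self.values)
        self.values = merged

    def __getitem__(self, key):
        return self.values[key]

    def get(self, key, default=None):
        return self.values.get(key, default)

    @property
    def temperatures(self) -> list[float]:
        v = self.values["temperatures"]
        if isinstance(v, str):
            return [float(x) for x in v.replace(",", " ").split()]
        return [float(x) for x in v]

    def hash(self) -> str:
        blob = json.dumps(
            {k: v for k, v in sorted(self.values.items())}, default=str
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def read_config(path: str | Path) -> RunConfig:
    """Parse ``key = value`` lines; ``include <path>`` pulls in another
    file (relative to the including file) before local overrides."""
    path = Path(path)
    values: dict[str, Any] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line.startswith("include "):
                inc = read_config(path.parent / line.split(None, 1)[1])
                values.update(inc.values)
                continue
            if "=" not in line:
                raise ValueError(f"{path}: malformed config line {raw!r}")
            k, v = (s.strip() for s in line.split("=", 1))
            values[k] = _coerce(v)
    return RunConfig(values=values)


def _coerce(v: str):
    for cast in (int, float):
        try:
            return cast(v)
        except ValueError:
            pass
    if v.lower() in ("true", "false"):
        return v.lower() == "true"
    if v.lower() in ("none", ""):
        return None
    return v


def write_manifest(path: str | Path, config: RunConfig, seed: int,
                   extra: dict[str, Any] | None = None) -> None:
    from . import __version__
    manifest = {
        "package": "sticklat",
        "version": __version__,
        "config_hash": config.hash(),
        "seed": int(seed),
        "config": {k: v for k, v in sorted(config.values.items())},
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
        fh.write("\n")
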