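"""Trajectory ingestion and featurization.

Reads multi-frame point trajectories — either a multi-model PDB (one node per
residue at its C-alpha) or a plain per-frame coordinate table — subsamples
them to a chosen number of steps, and builds the 6-feature tensor
(position + finite-difference velocity per axis) the relational-inference
model consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TrajectoryError",
    "RawTrajectory",
    "FeatureTensor",
    "DataSplits",
    "load_coordinates",
    "write_coordinate_table",
    "subsample",
    "featurize",
    "make_windows",
    "chronological_ranges",
]

COORDINATE_COLUMNS = ["frame", "node", "x", "y", "z"]


class TrajectoryError(ValueError):
    """Raised for malformed trajectory input or invalid featurization arguments."""


@dataclass
class RawTrajectory:
    """Per-frame, per-node coordinates with constant node ordering.

    positions: array (n_frames, n_nodes, 3), length units (Angstrom for MD
    input, abstract units for synthetic data).
    frame_interval: time per stored frame.
    node_labels: residue identifiers (PDB residue numbers as strings, or
    plain indices).
    """

    positions: np.ndarray
    frame_interval: float = 1.0
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise TrajectoryError(
                f"positions must have shape (n_frames, n_nodes, 3), got {self.positions.shape}"
            )
        if self.positions.shape[0] < 2:
            raise TrajectoryError("a trajectory needs at least 2 frames")
        if not np.all(np.isfinite(self.positions)):
            raise TrajectoryError("non-finite coordinates in trajectory")
        if self.frame_interval <= 0:
            raise TrajectoryError("frame_interval must be positive")
        if not self.node_labels:
            self.node_labels = [str(i) for i in range(self.positions.shape[1])]
        if len(self.node_labels) != self.positions.shape[1]:
            raise TrajectoryError("node_labels length does not match node count")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.positions.shape[1]


@dataclass
class FeatureTensor:
    """The model input x: per-node, per-step 6-vector.

    x: array (n_nodes, T, 6) ordered (pos_x, pos_y, pos_z, vel_x, vel_y,
    vel_z).  `normalization`, when present, records the per-axis shift and
    scale applied to positions (velocities share the scale but not the
    shift) so the transform is invertible.
    """

    x: np.ndarray
    dt: float = 1.0
    normalization: dict | None = None
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        if self.x.ndim != 3 or self.x.shape[2] != 6:
            raise TrajectoryError(
                f"feature tensor must have shape (n_nodes, T, 6), got {self.x.shape}"
            )
        if self.x.shape[1] < 2:
            raise TrajectoryError("feature tensor needs T >= 2 steps")
        if not self.node_labels:
            self.node_labels = [str(i) for i in range(self.x.shape[0])]

    @property
    def n_nodes(self) -> int:
        return self.x.shape[0]

    @property
    def n_steps(self) -> int:
        return self.x.shape[1]

    @property
    def positions(self) -> np.ndarray:
        return self.x[:, :, :3]

    @property
    def velocities(self) -> np.ndarray:
        return self.x[:, :, 3:]

    def denormalize_positions(self, positions: np.ndarray) -> np.ndarray:
        """Map positions expressed in this tensor's (possibly normalized)
        frame back to raw input coordinates."""
        if self.normalization is None:
            return positions
        center = np.asarray(self.normalization["center"])
        scale = np.asarray(self.normalization["scale"])
        return positions * scale + center


@dataclass
class DataSplits:
    """Chronological train/valid/test windows cut from one trajectory.

    Window arrays have shape (n_windows, n_nodes, window_length, 6).
    Windows within a split come from disjoint frame ranges of the source.
    """

    train: np.ndarray
    valid: np.ndarray
    test: np.ndarray
    window_length: int
    stride: int
    fractions: tuple[float, float, float]
    ranges: dict[str, tuple[int, int]]
    dt: float = 1.0
    normalization: dict | None = None
    node_labels: list[str] = field(default_factory=list)
    features: np.ndarray | None = None  # full source feature array (N, T, 6)


# -- readers / writers ---------------------------------------------------------


def _load_pdb_multimodel(path: Path) -> RawTrajectory:
    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure("traj", str(path))

    models = list(structure)
    if len(models) < 2:
        raise TrajectoryError(f"{path}: a multi-model PDB needs >= 2 MODEL records")

    def residue_keys(model):
        keys = []
        for chain in model:
            for residue in chain:
                if residue.id[0] != " ":  # skip waters/heteroatoms
                    continue
                keys.append((chain.id, residue.id[1]))
        return keys

    reference = residue_keys(models[0])
    if not reference:
        raise TrajectoryError(f"{path}: no standard residues found")

    frames = []
    for model in models:
        serial = model.serial_num if model.serial_num else model.id + 1
        keys = residue_keys(model)
        if keys != reference:
            raise TrajectoryError(
                f"{path}: residue set in model {serial} differs from model "
                f"{models[0].serial_num or 1}"
            )
        coords = []
        for chain in model:
            for residue in chain:
                if residue.id[0] != " ":
                    continue
                if "CA" not in residue:
                    raise TrajectoryError(
                        f"{path}: residue {residue.id[1]} (chain {chain.id}) has no "
                        f"C-alpha atom in model {serial}"
                    )
                coords.append(residue["CA"].coord)
        frames.append(np.asarray(coords, dtype=float))

    labels = [f"{chain_id}:{resseq}" if chain_id.strip() else str(resseq)
              for chain_id, resseq in reference]
    return RawTrajectory(np.stack(frames), node_labels=labels)


def _load_coordinate_table(path: Path) -> RawTrajectory:
    table = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in COORDINATE_COLUMNS if c not in table.columns]
    if missing:
        raise TrajectoryError(f"{path}: coordinate table missing columns {missing}")
    frames = np.sort(table["frame"].unique())
    nodes = np.sort(table["node"].unique())
    pivot = table.set_index(["frame", "node"]).sort_index()
    try:
        cube = pivot.loc[:, ["x", "y", "z"]].to_numpy().reshape(
            len(frames), len(nodes), 3
        )
    except ValueError as exc:
        raise TrajectoryError(
            f"{path}: inconsistent node set across frames"
        ) from exc
    return RawTrajectory(cube, node_labels=[str(n) for n in nodes])


def load_coordinates(path: str | Path, format: str = "auto") -> RawTrajectory:
    """Read a trajectory from disk.

    format: ``pdb_multimodel`` (one node per residue at its C-alpha),
    ``coordinate_table`` (TSV with header ``frame node x y z``), or
    ``auto`` to pick by extension.
    """
    path = Path(path)
    if not path.exists():
        raise TrajectoryError(f"no such file: {path}")
    if format == "auto":
        format = "pdb_multimodel" if path.suffix.lower() in (".pdb", ".ent") \
            else "coordinate_table"
    if format == "pdb_multimodel":
        return _load_pdb_multimodel(path)
    if format == "coordinate_table":
        return _load_coordinate_table(path)
    raise TrajectoryError(f"unknown trajectory format: {format!r}")


def write_coordinate_table(raw: RawTrajectory, path: str | Path) -> None:
    """Write the TSV dialect `load_coordinates` reads (round-trip exact)."""
    n_frames, n_nodes, _ = raw.positions.shape
    frame_idx = np.repeat(np.arange(n_frames), n_nodes)
    node_idx = np.tile(np.arange(n_nodes), n_frames)
    flat = raw.positions.reshape(-1, 3)
    table = pd.DataFrame(
        {"frame": frame_idx, "node": node_idx,
         "x": flat[:, 0], "y": flat[:, 1], "z": flat[:, 2]}
    )
    table.to_csv(path, sep="\t", index=False, float_format="%.17g")


# -- subsampling and featurization --------------------------------------------


def subsample_indices(n_frames: int, n_steps: int) -> np.ndarray:
    """Nearest-uniform frame selection: index j -> round(j * n_frames / n_steps).

    Always includes frame 0; for n_frames divisible by n_steps this is every
    (n_frames / n_steps)-th frame (e.g. 5000 frames at 50 steps -> every
    100th frame).
    """
    if not 2 <= n_steps <= n_frames:
        raise TrajectoryError(
            f"n_steps must be in [2, n_frames={n_frames}], got {n_steps}"
        )
    return np.round(np.arange(n_steps) * n_frames / n_steps).astype(int)


def subsample(raw: RawTrajectory, n_steps: int) -> RawTrajectory:
    """Keep `n_steps` frames at (as near as possible) uniform spacing."""
    idx = subsample_indices(raw.n_frames, n_steps)
    interval = raw.frame_interval * (raw.n_frames / n_steps)
    return RawTrajectory(
        raw.positions[idx],
        frame_interval=interval if n_steps < raw.n_frames else raw.frame_interval,
        node_labels=list(raw.node_labels),
    )


def featurize(raw: RawTrajectory, normalize: bool = True) -> FeatureTensor:
    """Build the (n_nodes, T, 6) position+velocity tensor.

    Velocity at step t is (pos_t - pos_{t-1}) / frame_interval for t >= 1;
    the first step copies the second step's velocity rather than introducing
    a spurious rest frame.  With ``normalize``, positions are centered and
    scaled per axis into [-1, 1]; an axis whose extent is a small fraction
    of the widest axis keeps a floored scale (20% of the widest half-span)
    instead — rescaling a near-degenerate axis to full range would amplify
    pure measurement noise into order-one features.  Velocities share the
    per-axis factors (not the shift), and the transform is recorded for
    inversion.
    """
    dt = raw.frame_interval
    if dt <= 0:
        raise TrajectoryError("frame_interval must be positive")
    pos = raw.positions  # (T, N, 3)
    vel = np.empty_like(pos)
    vel[1:] = (pos[1:] - pos[:-1]) / dt
    vel[0] = vel[1]

    normalization = None
    if normalize:
        lo = pos.min(axis=(0, 1))
        hi = pos.max(axis=(0, 1))
        center = (hi + lo) / 2.0
        half_span = (hi - lo) / 2.0
        floor = 0.2 * half_span.max()
        scale = np.maximum(half_span, floor if floor > 0 else 1.0)
        pos = (pos - center) / scale
        vel = vel / scale
        normalization = {"center": center, "scale": scale}

    x = np.concatenate([pos, vel], axis=2).transpose(1, 0, 2)  # (N, T, 6)
    return FeatureTensor(x, dt=dt, normalization=normalization,
                         node_labels=list(raw.node_labels))


# -- windowing -----------------------------------------------------------------


def chronological_ranges(n_steps: int,
                         fractions: tuple[float, float, float]) -> dict[str, tuple[int, int]]:
    """Partition [0, n_steps) into contiguous train/valid/test frame ranges."""
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise TrajectoryError("fractions must be three positive numbers")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise TrajectoryError(f"fractions must sum to 1, got {sum(fractions)}")
    t1 = int(n_steps * fractions[0])
    t2 = t1 + int(n_steps * fractions[1])
    return {"train": (0, t1), "valid": (t1, t2), "test": (t2, n_steps)}


def _cut_windows(x: np.ndarray, lo: int, hi: int, length: int, stride: int) -> np.ndarray:
    starts = range(lo, hi - length + 1, stride)
    return np.stack([x[:, s:s + length, :] for s in starts]) if len(list(starts)) \
        else np.empty((0, x.shape[0], length, 6))


def make_windows(features: FeatureTensor, window_length: int, stride: int,
                 fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
                 seed: int = 0) -> DataSplits:
    """Cut fixed-length windows inside chronological train/valid/test ranges.

    Frames are autocorrelated, so splits are contiguous in time rather than
    random; the seed shuffles the order of training windows only.
    """
    T = features.n_steps
    if not 2 <= window_length <= T:
        raise TrajectoryError(f"window_length must be in [2, T={T}]")
    if stride < 1:
        raise TrajectoryError("stride must be >= 1")
    ranges = chronological_ranges(T, fractions)
    out = {}
    for name, (lo, hi) in ranges.items():
        windows = _cut_windows(features.x, lo, hi, window_length, stride)
        if windows.shape[0] == 0:
            raise TrajectoryError(
                f"split {name!r} (frames [{lo}, {hi})) yields zero windows of "
                f"length {window_length}"
            )
        out[name] = windows
    rng = np.random.default_rng(seed)
    out["train"] = out["train"][rng.permutation(out["train"].shape[0])]
    return DataSplits(
        train=out["train"], valid=out["valid"], test=out["test"],
        window_length=window_length, stride=stride,
        fractions=tuple(fractions), ranges=ranges, dt=features.dt,
        normalization=features.normalization,
        node_labels=list(features.node_labels),
        features=features.x,
    )
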