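"""Two-animal pose post-processing and invariant feature extraction.

A :class:`PoseRecording` holds two animals × six nodes (nose, forehead,
left ear, right ear, thorax, tail base) × frames of (x, y) pixel
coordinates, the reward-port landmark, and the frame rate. Missing
detections are NaN. Preprocessing linearly interpolates gaps and smooths
each node track with a Savitzky–Golay filter (window 25 frames, cubic by
default).

Seven per-frame features are computed so that they are invariant to which
animal is labeled 1 vs 2 (sums and absolute differences) and to arena
rotation (orientation angles are folded at the thorax so clockwise and
counterclockwise configurations coincide):

1. summed thorax speed of the two animals (px/frame),
2. |speed difference|,
3. summed port–nose distance,
4. |port–nose distance difference|,
5. summed port–thorax–nose orientation angle (deg, each animal in [0, 180]),
6. |orientation-angle difference|,
7. thorax–thorax distance.

For clustering, frames are subsampled (every 3rd by default), pooled
across recordings, and each feature is z-scored over the pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from domsuite.errors import ValidationError

NODE_NAMES = ("nose", "forehead", "left_ear", "right_ear", "thorax", "tail_base")
NOSE, FOREHEAD, LEFT_EAR, RIGHT_EAR, THORAX, TAIL_BASE = range(6)

FEATURE_NAMES = (
    "velocity_sum",
    "velocity_absdiff",
    "port_nose_dist_sum",
    "port_nose_dist_absdiff",
    "angle_sum",
    "angle_absdiff",
    "thorax_thorax_dist",
)


@dataclass
class PoseRecording:
    """Pose tracks for one two-animal recording.

    ``coords`` has shape (2 animals, 6 nodes, n_frames, 2); NaN marks a
    missing detection. ``port`` is the reward-port landmark in the same
    pixel frame. ``state_truth`` optionally carries per-frame ground-truth
    state labels (used by the synthetic generator).
    """

    coords: np.ndarray
    port: tuple[float, float]
    fps: float = 30.0
    recording_id: str = "rec"
    state_truth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 4 or self.coords.shape[0] != 2 or self.coords.shape[1] != 6 \
                or self.coords.shape[3] != 2:
            raise ValidationError(
                f"coords must have shape (2, 6, frames, 2), got {self.coords.shape}"
            )
        if self.fps <= 0:
            raise ValidationError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[2]


def _fill_series(track: np.ndarray) -> np.ndarray:
    """Linear interpolation over interior gaps, nearest-value fill at edges."""
    s = pd.Series(track)
    if s.notna().sum() < 2:
        raise ValidationError("node track has fewer than 2 present values")
    return s.interpolate(method="linear", limit_direction="both").to_numpy()


def interpolate_and_smooth(
    rec: PoseRecording, window: int = 25, polyorder: int = 3
) -> PoseRecording:
    """Fill missing coordinates and Savitzky–Golay-smooth every node track.

    Interpolation is linear per node and axis, with edge gaps filled by
    the nearest present value; smoothing preserves polynomials up to
    ``polyorder`` exactly. Returns a new recording; the input is untouched.
    """
    if window % 2 == 0 or window <= polyorder:
        raise ValidationError("window must be odd and greater than polyorder")
    out = rec.coords.copy()
    n = rec.n_frames
    win = min(window, n if n % 2 == 1 else n - 1)
    if win <= polyorder:
        raise ValidationError(f"recording too short ({n} frames) for smoothing")
    for animal in range(2):
        for node in range(6):
            for axis in range(2):
                track = out[animal, node, :, axis]
                if np.isnan(track).all():
                    raise ValidationError(
                        f"animal {animal} node {NODE_NAMES[node]}: all frames missing"
                    )
                filled = _fill_series(track)
                out[animal, node, :, axis] = savgol_filter(filled, win, polyorder)
    return replace(rec, coords=out)


def orientation_angle(
    port: np.ndarray, thorax: np.ndarray, nose: np.ndarray
) -> float | np.ndarray:
    """Angle (degrees, in [0, 180]) at the thorax between port and nose rays.

    0° means the animal faces the port, 180° means it faces directly away.
    Folding to [0, 180] makes clockwise and counterclockwise headings
    equivalent (rotation invariance). Degenerate geometry (thorax
    coincident with port or nose) yields NaN; callers impute from the
    nearest valid frame. Accepts stacked (..., 2) arrays.
    """
    v1 = np.asarray(port, dtype=float) - np.asarray(thorax, dtype=float)
    v2 = np.asarray(nose, dtype=float) - np.asarray(thorax, dtype=float)
    n1 = np.linalg.norm(v1, axis=-1)
    n2 = np.linalg.norm(v2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.sum(v1 * v2, axis=-1) / (n1 * n2)
    cosang = np.clip(cosang, -1.0, 1.0)
    ang = np.degrees(np.arccos(cosang))
    ang = np.where((n1 == 0) | (n2 == 0), np.nan, ang)
    return float(ang) if ang.ndim == 0 else ang


def _impute_nearest(values: np.ndarray) -> np.ndarray:
    """Replace NaNs by the nearest (in frame index) valid value."""
    if not np.isnan(values).any():
        return values
    if np.isnan(values).all():
        raise ValidationError("all frames degenerate; cannot impute angles")
    idx = np.arange(len(values))
    valid = ~np.isnan(values)
    return np.interp(idx, idx[valid], values[valid])


def compute_features(rec: PoseRecording) -> pd.DataFrame:
    """The seven invariant features per frame of a gap-free recording.

    Velocity is the Euclidean thorax displacement between consecutive
    smoothed frames, in px/frame; the first frame repeats the second
    frame's value so rows stay aligned with frames. Swapping the two
    animals in the input leaves every column unchanged.
    """
    if rec.n_frames < 2:
        raise ValidationError("need at least 2 frames to compute velocities")
    if np.isnan(rec.coords).any():
        raise ValidationError("missing coordinates: run interpolate_and_smooth first")
    port = np.asarray(rec.port, dtype=float)
    thorax = rec.coords[:, THORAX]  # (2, frames, 2)
    nose = rec.coords[:, NOSE]

    disp = np.linalg.norm(np.diff(thorax, axis=1), axis=-1)  # (2, frames-1)
    vel = np.concatenate([disp[:, :1], disp], axis=1)  # backfill first frame

    port_nose = np.linalg.norm(nose - port, axis=-1)  # (2, frames)
    angles = np.stack(
        [_impute_nearest(orientation_angle(port, thorax[a], nose[a])) for a in range(2)]
    )
    tt = np.linalg.norm(thorax[0] - thorax[1], axis=-1)

    return pd.DataFrame(
        {
            "velocity_sum": vel.sum(axis=0),
            "velocity_absdiff": np.abs(vel[0] - vel[1]),
            "port_nose_dist_sum": port_nose.sum(axis=0),
            "port_nose_dist_absdiff": np.abs(port_nose[0] - port_nose[1]),
            "angle_sum": angles.sum(axis=0),
            "angle_absdiff": np.abs(angles[0] - angles[1]),
            "thorax_thorax_dist": tt,
        }
    )


@dataclass
class FeatureMatrix:
    """Pooled, subsampled, z-scored features with row provenance.

    ``data`` columns are the seven features (z-scored over the pool);
    ``provenance`` aligns row-for-row with (recording id, frame index).
    """

    data: pd.DataFrame
    provenance: pd.DataFrame
    means: pd.Series = field(repr=False, default=None)
    stds: pd.Series = field(repr=False, default=None)

    def __len__(self) -> int:
        return len(self.data)


def pool_zscore_subsample(
    features: dict[str, pd.DataFrame], step: int = 3
) -> FeatureMatrix:
    """Subsample every ``step``-th frame per recording, pool, z-score.

    Z-scoring is over the pooled kept frames of all recordings (not per
    recording), because clustering operates on the pooled frame set. A
    zero-variance feature maps to all-zeros rather than NaN.
    """
    if not features:
        raise ValidationError("no recordings to pool")
    if step < 1:
        raise ValidationError("step must be >= 1")
    frames = []
    prov = []
    for rec_id in sorted(features):
        df = features[rec_id]
        kept = df.iloc[::step]
        frames.append(kept.reset_index(drop=True))
        prov.append(
            pd.DataFrame({"recording": rec_id, "frame": kept.index.to_numpy()})
        )
    pooled = pd.concat(frames, ignore_index=True)
    provenance = pd.concat(prov, ignore_index=True)
    means = pooled.mean()
    stds = pooled.std(ddof=0)
    safe = stds.replace(0.0, 1.0)
    z = (pooled - means) / safe
    z.loc[:, stds == 0.0] = 0.0
    return FeatureMatrix(data=z, provenance=provenance, means=means, stds=safe)


def write_pose_h5(rec: PoseRecording, path: str | Path) -> None:
    """Write a recording to HDF5: datasets ``tracks`` (2×6×frames×2),
    ``node_names``, attrs ``port``, ``fps``, ``recording_id``, and
    optionally ``state_truth``."""
    with h5py.File(path, "w") as f:
        f.create_dataset("tracks", data=rec.coords)
        f.create_dataset(
            "node_names", data=np.array(NODE_NAMES, dtype=h5py.string_dtype())
        )
        f.attrs["port"] = np.asarray(rec.port, dtype=float)
        f.attrs["fps"] = rec.fps
        f.attrs["recording_id"] = rec.recording_id
        if rec.state_truth is not None:
            f.create_dataset(
                "state_truth",
                data=np.array(rec.state_truth, dtype=h5py.string_dtype()),
            )


def read_pose_h5(path: str | Path) -> PoseRecording:
    """Read a recording written by :func:`write_pose_h5`."""
    with h5py.File(path, "r") as f:
        coords = f["tracks"][()]
        names = tuple(n.decode() for n in f["node_names"][()])
        if names != NODE_NAMES:
            raise ValidationError(f"unexpected node order {names}, need {NODE_NAMES}")
        truth = None
        if "state_truth" in f:
            truth = np.array([s.decode() for s in f["state_truth"][()]])
        return PoseRecording(
            coords=coords,
            port=tuple(float(v) for v in f.attrs["port"]),
            fps=float(f.attrs["fps"]),
            recording_id=str(f.attrs["recording_id"]),
            state_truth=truth,
        )


def read_pose_csv(
    path: str | Path, port: tuple[float, float], fps: float = 30.0
) -> PoseRecording:
    """Read long-format pose CSV (frame, animal, node, x, y); empty cells = missing."""
    df = pd.read_csv(path)
    for col in ("frame", "animal", "node", "x", "y"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    n_frames = int(df["frame"].max()) + 1
    coords = np.full((2, 6, n_frames, 2), np.nan)
    node_idx = {n: i for i, n in enumerate(NODE_NAMES)}
    for _, row in df.iterrows():
        coords[int(row["animal"]), node_idx[row["node"]], int(row["frame"])] = (
            row["x"],
            row["y"],
        )
    return PoseRecording(coords=coords, port=port, fps=fps, recording_id=Path(path).stem)
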