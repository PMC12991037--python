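"""Duplex-on-nanotube trajectory geometry.

Per frame, the tube axis is the principal eigenvector of the SWCNT-atom
covariance (sign fixed so the anchor-strand centroid projects on the negative
side: tilt angles above 90 deg then mean "leaning toward the anchor"), the
duplex axis is the principal axis of the per-base-pair centroids oriented
from the tube-proximal to the tip base pair, and the tilt angle is the
arccos of their dot product.  The 5'-tip-to-surface distance is the minimum
distance from the centroid of the flagged 5'-terminal nucleotide to any
SWCNT atom — nearest surface point, not distance-to-axis minus a nominal
radius, so it stays meaningful for non-ideal tubes.

The canonical interchange format is multi-frame XYZ (nm) plus a group-map
table; binary MD formats are reachable through the MDAnalysis adapter.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import pearsonr

from cnetvna import io as cio
from cnetvna.synthdata import SyntheticTrajectory

__all__ = [
    "TrajectoryFrameSet",
    "DuplexGeometry",
    "read_trajectory",
    "read_trajectory_mdanalysis",
    "tube_axis",
    "duplex_axis",
    "tilt_angle",
    "tip_surface_distance",
    "expected_duplex_length",
    "summarize_geometry",
    "analyze_trajectory",
]

LABEL_TO_GROUP = {"CNT": "SWCNT", "ANC": "anchor", "CAP": "capture", "CMP": "complement"}


@dataclass
class TrajectoryFrameSet:
    """Coordinates (nm) plus the atom -> group / base-pair / tip mapping."""

    frames: list[np.ndarray]
    groups: np.ndarray
    bp_index: np.ndarray
    is_tip: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.groups)
        for i, f in enumerate(self.frames):
            if f.shape != (n, 3):
                raise ValueError(f"frame {i}: shape {f.shape} != ({n}, 3)")
        if not np.any(self.groups == "SWCNT"):
            raise ValueError("trajectory has no SWCNT atoms")
        duplex = (self.groups == "capture") | (self.groups == "complement")
        if len(np.unique(self.bp_index[duplex])) < 2:
            raise ValueError("need at least 2 base-pair groups")
        if not np.any(self.is_tip):
            raise ValueError("no atom is flagged as the 5'-tip")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @classmethod
    def from_synthetic(cls, traj: SyntheticTrajectory) -> "TrajectoryFrameSet":
        return cls(
            frames=list(traj.frames),
            groups=np.asarray(traj.groups),
            bp_index=np.asarray(traj.bp_index),
            is_tip=np.asarray(traj.is_tip, dtype=bool),
        )


@dataclass
class DuplexGeometry:
    angle_deg: np.ndarray
    tip_distance_nm: np.ndarray
    summary: dict

    def __post_init__(self) -> None:
        if self.angle_deg.size != self.tip_distance_nm.size:
            raise ValueError("angle and distance series must have equal length")


def read_trajectory(xyz_path: str | Path, groups_path: str | Path) -> TrajectoryFrameSet:
    """Read a multi-frame XYZ file (nm) and its group map."""
    frames, labels = cio.read_xyz(xyz_path)
    gm = cio.read_group_map(groups_path, n_atoms=len(labels))
    return TrajectoryFrameSet(
        frames=frames,
        groups=gm["group"].to_numpy(),
        bp_index=gm["bp_index"].to_numpy(),
        is_tip=gm["is_tip"].to_numpy().astype(bool),
    )


def read_trajectory_mdanalysis(
    topology: str | Path, trajectory: str | Path, groups_path: str | Path,
    length_scale: float = 0.1,
) -> TrajectoryFrameSet:
    """Adapter for binary MD formats (e.g. PDB + DCD/XTC) via MDAnalysis.

    `length_scale` converts the file's length unit to nm (0.1 for Angstrom,
    the MDAnalysis convention).
    """
    import MDAnalysis as mda

    u = mda.Universe(str(topology), str(trajectory))
    frames = [
        u.atoms.positions.astype(float) * length_scale for _ in u.trajectory
    ]
    gm = cio.read_group_map(groups_path, n_atoms=len(u.atoms))
    return TrajectoryFrameSet(
        frames=frames,
        groups=gm["group"].to_numpy(),
        bp_index=gm["bp_index"].to_numpy(),
        is_tip=gm["is_tip"].to_numpy().astype(bool),
    )


def _principal_axis(coords: np.ndarray) -> np.ndarray:
    c = coords - coords.mean(axis=0)
    cov = c.T @ c / max(len(c) - 1, 1)
    evals, evecs = np.linalg.eigh(cov)
    if (evals[-1] - evals[-2]) <= 1e-9 * max(evals[-1], 1e-30):
        raise ValueError("degenerate covariance: no unique principal axis")
    return evecs[:, -1]


def tube_axis(
    frame: np.ndarray,
    swcnt_mask: np.ndarray,
    anchor_centroid: np.ndarray | None = None,
) -> np.ndarray:
    """Unit vector along the nanotube from SWCNT-atom PCA.

    The sign is fixed so the anchor-strand centroid projects negative along
    the axis (when an anchor centroid is supplied); otherwise the positive-z
    convention is used.
    """
    coords = np.asarray(frame, dtype=float)[np.asarray(swcnt_mask, dtype=bool)]
    if coords.shape[0] < 10:
        raise ValueError("need at least 10 SWCNT atoms for the tube axis")
    axis = _principal_axis(coords)
    if anchor_centroid is not None:
        proj = float(np.dot(np.asarray(anchor_centroid) - coords.mean(axis=0), axis))
        if proj > 0:
            axis = -axis
    elif axis[2] < 0:
        axis = -axis
    return axis


def duplex_axis(frame: np.ndarray, duplex_mask: np.ndarray,
                bp_index: np.ndarray) -> np.ndarray:
    """Unit vector along the duplex from a line fit of per-base-pair centroids.

    Oriented from the lowest base-pair index (tube-proximal) to the highest
    (tip); a per-base-pair centroid fit is more robust to end fraying than a
    first-to-last atom vector.
    """
    frame = np.asarray(frame, dtype=float)
    duplex_mask = np.asarray(duplex_mask, dtype=bool)
    bp = np.asarray(bp_index)[duplex_mask]
    coords = frame[duplex_mask]
    idx = np.unique(bp)
    if idx.size < 2:
        raise ValueError("need at least 2 base-pair centroids for the duplex axis")
    centroids = np.array([coords[bp == j].mean(axis=0) for j in np.sort(idx)])
    axis = _principal_axis(centroids)
    if np.dot(axis, centroids[-1] - centroids[0]) < 0:
        axis = -axis
    return axis


def tilt_angle(tube_axis_vec: np.ndarray, duplex_axis_vec: np.ndarray) -> float:
    """Angle (deg) between the duplex and the tube axis; 90 deg = orthogonal."""
    a = np.asarray(tube_axis_vec, dtype=float)
    b = np.asarray(duplex_axis_vec, dtype=float)
    for name, v in [("tube_axis", a), ("duplex_axis", b)]:
        if abs(np.linalg.norm(v) - 1.0) > 1e-6:
            raise ValueError(f"{name} must be a unit vector")
    return float(np.degrees(np.arccos(np.clip(np.dot(a, b), -1.0, 1.0))))


def tip_surface_distance(frame: np.ndarray, tip_mask: np.ndarray,
                         swcnt_mask: np.ndarray) -> float:
    """Minimum distance (nm) from the 5'-tip nucleotide centroid to the tube.

    The tip reference point is the centroid of all tip-flagged pseudo-atoms;
    the surface is represented by the SWCNT atoms themselves.
    """
    frame = np.asarray(frame, dtype=float)
    tip = frame[np.asarray(tip_mask, dtype=bool)]
    sw = frame[np.asarray(swcnt_mask, dtype=bool)]
    if tip.size == 0:
        raise ValueError("no tip-flagged atoms in frame")
    if sw.size == 0:
        raise ValueError("no SWCNT atoms in frame")
    centroid = tip.mean(axis=0, keepdims=True)
    return float(cdist(centroid, sw).min())


def expected_duplex_length(n_bp: int, rise: float = 0.34) -> float:
    """Nominal B-DNA duplex length: n_bp * rise (0.34 nm per base pair)."""
    if n_bp < 1:
        raise ValueError("n_bp must be >= 1")
    if rise <= 0:
        raise ValueError("rise must be positive")
    return n_bp * rise


def summarize_geometry(angle_deg: np.ndarray, tip_distance_nm: np.ndarray) -> dict:
    """Per-series summary stats plus the tilt/distance correlation.

    The correlation is Pearson's r between |theta - 90 deg| and the tip
    distance; tilting away from perpendicular lowers the tip, so the expected
    sign is negative.  Constant series leave the correlation undefined (None).
    """
    angle_deg = np.asarray(angle_deg, dtype=float)
    tip_distance_nm = np.asarray(tip_distance_nm, dtype=float)
    if angle_deg.size < 10:
        raise ValueError("need at least 10 frames to summarize")
    if np.any(tip_distance_nm <= 0):
        raise ValueError("tip distances must be positive")
    if np.any((angle_deg < 0) | (angle_deg > 180)):
        raise ValueError("angles must lie in [0, 180] degrees")

    def stats(x):
        return {
            "mean": float(np.mean(x)),
            "median": float(np.median(x)),
            "p5": float(np.percentile(x, 5)),
            "p95": float(np.percentile(x, 95)),
        }

    dev = np.abs(angle_deg - 90.0)
    if np.ptp(dev) < 1e-12 or np.ptp(tip_distance_nm) < 1e-12:
        corr = None
    else:
        corr = float(pearsonr(dev, tip_distance_nm).statistic)
    return {
        "angle_deg": stats(angle_deg),
        "tip_distance_nm": stats(tip_distance_nm),
        "tilt_distance_correlation": corr,
    }


def analyze_trajectory(traj: TrajectoryFrameSet | SyntheticTrajectory) -> DuplexGeometry:
    """Per-frame tilt angles and tip distances, plus summary statistics."""
    if isinstance(traj, SyntheticTrajectory):
        traj = TrajectoryFrameSet.from_synthetic(traj)
    sw = traj.groups == "SWCNT"
    anc = traj.groups == "anchor"
    duplex = (traj.groups == "capture") | (traj.groups == "complement")
    angles = np.empty(traj.n_frames)
    dists = np.empty(traj.n_frames)
    for i, frame in enumerate(traj.frames):
        anchor_centroid = frame[anc].mean(axis=0) if anc.any() else None
        t_axis = tube_axis(frame, sw, anchor_centroid)
        d_axis = duplex_axis(frame, duplex, traj.bp_index)
        angles[i] = tilt_angle(t_axis, d_axis)
        dists[i] = tip_surface_distance(frame, traj.is_tip, sw)
    if traj.n_frames >= 10:
        summary = summarize_geometry(angles, dists)
    else:
        summary = {}
    return DuplexGeometry(angles, dists, summary)
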