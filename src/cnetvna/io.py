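"""Plain-text interchange formats.

All tables are comma-separated text with a header row; trajectories are
multi-frame XYZ (the element field carries a pseudo-atom label) accompanied by
a group-map table ``atom_index,group,bp_index,is_tip`` with 0-based atom
indices.  Coordinates are in nm throughout.  The XYZ blocks are read and
written in float64 so that a write/read round trip preserves coordinates to
well below 1e-6 nm; binary MD formats (DCD/XTC + topology) are supported
through the MDAnalysis adapter in :func:`cnetvna.geometry.read_trajectory_mdanalysis`.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from cnetvna.synthdata import GroundTruth, PhotonStream, SpectrumTable

PHOTON_HEADER = ["molecule_id", "macro_time_s", "micro_time_ns"]
TRUTH_HEADER = [
    "molecule_id",
    "true_tau_ns",
    "population",
    "bleach_time_s",
    "true_distance_nm",
]
GROUP_HEADER = ["atom_index", "group", "bp_index", "is_tip"]
VALID_GROUPS = frozenset({"SWCNT", "capture", "complement", "anchor"})


def write_photon_table(streams: Sequence["PhotonStream"], path: str | Path) -> None:
    """Write a cohort of photon streams to one columnar text file.

    The TCSPC window and excitation period (shared across the cohort) are
    stored in ``#``-prefixed header lines so the table round-trips.
    """
    streams = list(streams)
    if not streams:
        raise ValueError("cannot write an empty cohort")
    window = streams[0].tcspc_window
    period = streams[0].excitation_period
    for s in streams:
        if s.tcspc_window != window or s.excitation_period != period:
            raise ValueError("all streams in one table must share TCSPC settings")
    with open(path, "w") as fh:
        fh.write(f"# tcspc_window_ns={window:.17g}\n")
        fh.write(f"# excitation_period_ns={period:.17g}\n")
        fh.write(",".join(PHOTON_HEADER) + "\n")
        for s in streams:
            for t, m in zip(s.macro_times, s.micro_times):
                fh.write(f"{s.molecule_id},{t:.17g},{m:.17g}\n")


def read_photon_table(path: str | Path) -> list["PhotonStream"]:
    from cnetvna.synthdata import PhotonStream

    meta: dict[str, float] = {}
    body = _io.StringIO()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = float(val)
            else:
                body.write(line)
    body.seek(0)
    df = pd.read_csv(body, float_precision="round_trip")
    missing = set(PHOTON_HEADER) - set(df.columns)
    if missing:
        raise ValueError(f"photon table missing columns: {sorted(missing)}")
    window = meta.get("tcspc_window_ns", 25.0)
    period = meta.get("excitation_period_ns", window)
    streams = []
    for mol, grp in df.groupby("molecule_id", sort=False):
        streams.append(
            PhotonStream(
                molecule_id=str(mol),
                macro_times=np.asarray(grp["macro_time_s"], dtype=float),
                micro_times=np.asarray(grp["micro_time_ns"], dtype=float),
                tcspc_window=window,
                excitation_period=period,
            )
        )
    return streams


def write_truth_table(truths: Sequence["GroundTruth"], path: str | Path) -> None:
    rows = []
    for t in truths:
        rows.append(
            {
                "molecule_id": t.molecule_id,
                "true_tau_ns": t.true_tau,
                "population": t.population_label,
                "bleach_time_s": t.bleach_time,
                "true_distance_nm": "" if t.true_distance is None else t.true_distance,
            }
        )
    pd.DataFrame(rows, columns=TRUTH_HEADER).to_csv(path, index=False)


def read_truth_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRUTH_HEADER) - set(df.columns)
    if missing:
        raise ValueError(f"ground-truth table missing columns: {sorted(missing)}")
    return df


def write_xyz(frames: Sequence[np.ndarray], labels: Sequence[str], path: str | Path,
              comment: str = "cnetvna synthetic trajectory (nm)") -> None:
    """Write a multi-frame XYZ file; the element column holds pseudo-atom labels."""
    labels = list(labels)
    with open(path, "w") as fh:
        for coords in frames:
            coords = np.asarray(coords, dtype=float)
            if coords.shape != (len(labels), 3):
                raise ValueError(
                    f"frame shape {coords.shape} does not match {len(labels)} labels"
                )
            fh.write(f"{len(labels)}\n{comment}\n")
            for lab, (x, y, z) in zip(labels, coords):
                fh.write(f"{lab} {x:.12g} {y:.12g} {z:.12g}\n")


def read_xyz(path: str | Path) -> tuple[list[np.ndarray], list[str]]:
    """Read a multi-frame XYZ file in float64.

    Returns (frames, labels); raises with the offending frame index on a
    malformed block or an atom-count mismatch between frames.
    """
    frames: list[np.ndarray] = []
    labels: list[str] | None = None
    with open(path) as fh:
        lines = fh.read().split("\n")
    i, n_lines, frame_no = 0, len(lines), 0
    while i < n_lines:
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError as exc:
            raise ValueError(f"frame {frame_no}: expected atom count, got {lines[i]!r}") from exc
        if i + 1 + natoms >= n_lines + 1:
            raise ValueError(f"frame {frame_no}: truncated block")
        block = lines[i + 2 : i + 2 + natoms]
        frame_labels, coords = [], np.empty((natoms, 3), dtype=float)
        for j, ln in enumerate(block):
            parts = ln.split()
            if len(parts) < 4:
                raise ValueError(f"frame {frame_no}, atom {j}: malformed line {ln!r}")
            frame_labels.append(parts[0])
            coords[j] = [float(p) for p in parts[1:4]]
        if labels is None:
            labels = frame_labels
        elif len(frame_labels) != len(labels):
            raise ValueError(
                f"frame {frame_no}: atom count {len(frame_labels)} != {len(labels)} in frame 0"
            )
        frames.append(coords)
        i += 2 + natoms
        frame_no += 1
    if labels is None:
        raise ValueError("empty XYZ file")
    return frames, labels


def write_group_map(groups: Sequence[str], bp_index: Sequence[int],
                    is_tip: Sequence[bool], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "atom_index": np.arange(len(groups)),
            "group": list(groups),
            "bp_index": np.asarray(bp_index, dtype=int),
            "is_tip": np.asarray(is_tip, dtype=int),
        }
    )
    df.to_csv(path, index=False)


def read_group_map(path: str | Path, n_atoms: int | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(GROUP_HEADER) - set(df.columns)
    if missing:
        raise ValueError(f"group map missing columns: {sorted(missing)}")
    bad = set(df["group"]) - VALID_GROUPS
    if bad:
        raise ValueError(f"unknown groups in map: {sorted(bad)}")
    df = df.sort_values("atom_index").reset_index(drop=True)
    if n_atoms is not None:
        covered = set(df["atom_index"])
        expected = set(range(n_atoms))
        if covered != expected:
            missing_idx = sorted(expected - covered)[:5]
            extra = sorted(covered - expected)[:5]
            raise ValueError(
                f"group map does not cover atoms exactly (missing {missing_idx}, extra {extra})"
            )
    if not bool(df["is_tip"].astype(bool).any()):
        raise ValueError("group map has no 5'-tip flag (is_tip column all zero)")
    return df


def write_spectrum(spec: "SpectrumTable", path: str | Path) -> None:
    pd.DataFrame(
        {"wavelength_nm": spec.wavelength, "value": spec.value}
    ).to_csv(path, index=False)


def read_spectrum(path: str | Path) -> "SpectrumTable":
    from cnetvna.synthdata import SpectrumTable

    df = pd.read_csv(path)
    if not {"wavelength_nm", "value"} <= set(df.columns):
        raise ValueError("spectrum table must have columns wavelength_nm,value")
    return SpectrumTable(
        wavelength=np.asarray(df["wavelength_nm"], dtype=float),
        value=np.asarray(df["value"], dtype=float),
    )
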