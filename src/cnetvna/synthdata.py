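"""Synthetic single-molecule and trajectory data with known ground truth.

Emulates the raw inputs of a dye-on-nanotube energy-transfer experiment:

* TCSPC photon streams per molecule: a Poisson signal process that switches
  off at a single exponentially distributed photobleaching time, each signal
  photon carrying a micro-time = Gaussian IRF draw + exponential decay draw,
  wrapped on the excitation period; uniform background photons over the full
  acquisition.
* Cohorts of molecules whose true lifetimes are drawn from Gaussian
  subpopulations (truncated at a 0.05 ns floor).
* A geometric forward model linking duplex tilt to dye height, quenching
  efficiency and lifetime: d = n_bp * rise * sin(theta) + linker_offset,
  eta = 1/(1 + (d/d0)^n), tau = tau0 * (1 - eta).
* Rigid duplex-on-cylinder trajectories with a helical SWCNT pseudo-atom
  lattice (multi-frame XYZ + group map), with controllable tilt distributions.
* Gaussian toy emission/extinction spectra for the overlap integral.

Every generator is deterministic for a fixed seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from cnetvna import io as cio

__all__ = [
    "PhotonStream",
    "GroundTruth",
    "SyntheticTrajectory",
    "SpectrumTable",
    "simulate_photon_stream",
    "simulate_cohort",
    "geometry_forward_model",
    "simulate_trajectory",
    "make_toy_spectra",
    "COHORT_PRESETS",
]

#: default acquisition settings; the instrument of the original experiments is
#: not parameterized anywhere public, so these are chosen to make plausible
#: single-molecule traces (20 kHz bright state, 40 MHz laser => 25 ns period).
DEFAULT_PHOTON_PARAMS = dict(
    irf_sigma=0.1,          # ns
    irf_center=2.0,         # ns, position of the IRF peak in the TCSPC window
    brightness=2.0e4,       # signal counts/s while the dye is on
    background_rate=200.0,  # counts/s over the whole acquisition
    bleach_rate=0.2,        # 1/s
    duration=30.0,          # s
    excitation_period=25.0, # ns
    tcspc_window=25.0,      # ns
)

#: cohort presets used by the pipeline examples: a single unquenched
#: population at the reference lifetime of each dye (ATTO542 ~3.0 ns,
#: ATTO643 ~3.5 ns), ~2e4 signal photons per molecule before bleaching and a
#: ~2% flat background fraction.
COHORT_PRESETS = {
    "unquenched_atto542": dict(
        populations=[(3.0, 0.1, 1.0)],
        photon_params=dict(
            brightness=2.0e4, background_rate=408.0, bleach_rate=1.0,
            duration=10.0, irf_sigma=0.1, irf_center=2.0,
            excitation_period=25.0, tcspc_window=25.0,
        ),
    ),
    "unquenched_atto643": dict(
        populations=[(3.5, 0.1, 1.0)],
        photon_params=dict(
            brightness=2.0e4, background_rate=408.0, bleach_rate=1.0,
            duration=10.0, irf_sigma=0.1, irf_center=2.0,
            excitation_period=25.0, tcspc_window=25.0,
        ),
    ),
}

TAU_FLOOR = 0.05  # ns, smallest population lifetime the generator will emit


@dataclass
class PhotonStream:
    """Detection events of one molecule.

    macro_times are arrival times in seconds (non-decreasing); micro_times are
    TCSPC delays in ns within [0, tcspc_window).
    """

    molecule_id: str
    macro_times: np.ndarray
    micro_times: np.ndarray
    tcspc_window: float
    excitation_period: float

    def __post_init__(self) -> None:
        self.macro_times = np.asarray(self.macro_times, dtype=float)
        self.micro_times = np.asarray(self.micro_times, dtype=float)
        if self.macro_times.shape != self.micro_times.shape:
            raise ValueError("macro_times and micro_times must have equal length")
        if self.tcspc_window > self.excitation_period:
            raise ValueError("tcspc_window must not exceed excitation_period")
        if self.macro_times.size:
            if np.any(np.diff(self.macro_times) < 0):
                raise ValueError("macro_times must be non-decreasing")
            if self.micro_times.min() < 0 or self.micro_times.max() >= self.tcspc_window:
                raise ValueError("micro_times must lie in [0, tcspc_window)")

    @property
    def n_photons(self) -> int:
        return int(self.macro_times.size)

    @property
    def events(self) -> list[tuple[float, float]]:
        return list(zip(self.macro_times.tolist(), self.micro_times.tolist()))


@dataclass
class GroundTruth:
    molecule_id: str
    true_tau: float
    true_background_fraction: float
    bleach_time: float
    population_label: str
    true_distance: float | None = None

    def __post_init__(self) -> None:
        if self.true_tau <= 0:
            raise ValueError("true_tau must be positive")
        if self.bleach_time < 0:
            raise ValueError("bleach_time must be >= 0")


@dataclass
class SyntheticTrajectory:
    """Pseudo-atom trajectory of a rigid duplex on a cylindrical nanotube."""

    frames: list[np.ndarray]
    groups: np.ndarray          # per-atom group label
    bp_index: np.ndarray        # base-pair index, -1 for non-duplex atoms
    is_tip: np.ndarray          # bool, 5'-terminal nucleotide of the complement
    cylinder_radius: float
    n_bp: int
    true_tilt_deg: np.ndarray = field(default=None)  # per-frame ground truth

    @property
    def labels(self) -> list[str]:
        short = {"SWCNT": "CNT", "anchor": "ANC", "capture": "CAP", "complement": "CMP"}
        return [short[g] for g in self.groups]

    def write(self, xyz_path, groups_path) -> None:
        cio.write_xyz(self.frames, self.labels, xyz_path)
        cio.write_group_map(self.groups, self.bp_index, self.is_tip, groups_path)


@dataclass
class SpectrumTable:
    """A spectrum on a strictly increasing wavelength grid (nm)."""

    wavelength: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.wavelength.size < 10:
            raise ValueError("spectrum grid needs at least 10 points")
        if np.any(np.diff(self.wavelength) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(self.value < 0):
            raise ValueError("spectral values must be non-negative")


def _check_positive(name: str, value: float) -> None:
    if not value > 0:
        raise ValueError(f"{name} must be positive, got {value}")


def _check_nonneg(name: str, value: float) -> None:
    if value < 0:
        raise ValueError(f"{name} must be non-negative, got {value}")


def simulate_photon_stream(
    true_tau: float,
    irf_sigma: float = 0.1,
    brightness: float = 2.0e4,
    background_rate: float = 200.0,
    bleach_rate: float = 0.2,
    duration: float = 30.0,
    excitation_period: float = 25.0,
    tcspc_window: float | None = None,
    irf_center: float = 2.0,
    seed: int | np.random.Generator | None = None,
    molecule_id: str = "mol",
    population_label: str = "",
    true_distance: float | None = None,
) -> tuple[PhotonStream, GroundTruth]:
    """Simulate one molecule's photon stream.

    Signal photons arrive as a Poisson process at `brightness` until the
    (exponential) bleach time; each carries micro-time
    ``(N(irf_center, irf_sigma) + Exp(true_tau)) mod excitation_period``.
    Background photons arrive uniformly over the full `duration` with uniform
    micro-times.  Photons whose wrapped micro-time falls outside the TCSPC
    window (detector gate) are discarded.
    """
    _check_positive("true_tau", true_tau)
    _check_positive("duration", duration)
    _check_nonneg("irf_sigma", irf_sigma)
    _check_nonneg("brightness", brightness)
    _check_nonneg("background_rate", background_rate)
    _check_nonneg("bleach_rate", bleach_rate)
    _check_positive("excitation_period", excitation_period)
    if tcspc_window is None:
        tcspc_window = excitation_period
    rng = np.random.default_rng(seed)

    bleach_time = rng.exponential(1.0 / bleach_rate) if bleach_rate > 0 else math.inf
    t_on = min(bleach_time, duration)

    n_sig = rng.poisson(brightness * t_on) if brightness > 0 else 0
    sig_macro = np.sort(rng.uniform(0.0, t_on, n_sig))
    sig_micro = (
        rng.normal(irf_center, irf_sigma, n_sig) + rng.exponential(true_tau, n_sig)
    ) % excitation_period

    n_bg = rng.poisson(background_rate * duration) if background_rate > 0 else 0
    bg_macro = rng.uniform(0.0, duration, n_bg)
    bg_micro = rng.uniform(0.0, tcspc_window, n_bg)

    macro = np.concatenate([sig_macro, bg_macro])
    micro = np.concatenate([sig_micro, bg_micro])
    keep = micro < tcspc_window
    macro, micro = macro[keep], micro[keep]
    order = np.argsort(macro, kind="stable")
    macro, micro = macro[order], micro[order]

    n_total = macro.size
    bg_fraction = float(n_bg) / n_total if n_total else 0.0
    stream = PhotonStream(molecule_id, macro, micro, tcspc_window, excitation_period)
    truth = GroundTruth(
        molecule_id=molecule_id,
        true_tau=true_tau,
        true_background_fraction=bg_fraction,
        bleach_time=bleach_time,
        population_label=population_label,
        true_distance=true_distance,
    )
    return stream, truth


def simulate_cohort(
    populations: Sequence[tuple[float, float, float]],
    n_molecules: int,
    photon_params: dict | None = None,
    seed: int | None = None,
    id_prefix: str = "mol",
) -> tuple[list[PhotonStream], list[GroundTruth]]:
    """Simulate a cohort whose lifetimes come from Gaussian subpopulations.

    `populations` is a list of (mean_tau_ns, sd_tau_ns, weight); weights are
    normalized internally.  Draws are truncated at tau > 0.05 ns and each
    component must satisfy mean - 3 sd > 0.
    """
    populations = list(populations)
    if not populations:
        raise ValueError("populations must not be empty")
    means = np.array([p[0] for p in populations], dtype=float)
    sds = np.array([p[1] for p in populations], dtype=float)
    weights = np.array([p[2] for p in populations], dtype=float)
    if np.any(weights <= 0):
        raise ValueError("population weights must be positive")
    if np.any(means - 3.0 * sds <= 0):
        raise ValueError("every component needs mean_tau - 3*sd_tau > 0")
    weights = weights / weights.sum()
    params = dict(DEFAULT_PHOTON_PARAMS)
    if photon_params:
        unknown = set(photon_params) - set(DEFAULT_PHOTON_PARAMS)
        if unknown:
            raise ValueError(f"unknown photon parameters: {sorted(unknown)}")
        params.update(photon_params)

    rng = np.random.default_rng(seed)
    components = rng.choice(len(populations), size=n_molecules, p=weights)
    streams, truths = [], []
    for i, comp in enumerate(components):
        tau = rng.normal(means[comp], sds[comp])
        while tau <= TAU_FLOOR:  # truncation: redraw below the floor
            tau = rng.normal(means[comp], sds[comp])
        stream, truth = simulate_photon_stream(
            true_tau=float(tau),
            seed=rng,
            molecule_id=f"{id_prefix}{i:04d}",
            population_label=f"component{comp}",
            **params,
        )
        streams.append(stream)
        truths.append(truth)
    return streams, truths


def geometry_forward_model(
    n_bp: int,
    rise: float = 0.34,
    linker_offset: float = 1.1,
    tilt_distribution: tuple[float, float] = (90.0, 10.0),
    d0: float = 7.4,
    exponent: int = 5,
    tau0: float = 3.5,
    n_molecules: int = 100,
    seed: int | None = None,
) -> list[GroundTruth]:
    """Map duplex tilt angles to dye heights, efficiencies and lifetimes.

    The dye height above the tube surface is d = n_bp*rise*sin(theta) +
    linker_offset with theta the duplex/tube-axis angle (90 deg maximizes the
    height); the linker term is the ~1.1 nm dye + C6-linker extension.  The
    quenching efficiency follows eta = 1/(1 + (d/d0)^exponent) and
    tau = tau0 * (1 - eta).
    """
    if exponent not in (3, 4, 5, 6):
        raise ValueError("exponent must be one of 3, 4, 5, 6")
    _check_positive("d0", d0)
    _check_positive("tau0", tau0)
    _check_positive("rise", rise)
    _check_nonneg("linker_offset", linker_offset)
    mean_deg, sd_deg = tilt_distribution
    rng = np.random.default_rng(seed)
    truths = []
    for i in range(n_molecules):
        if sd_deg > 0:
            theta = rng.normal(mean_deg, sd_deg)
            while not 0.0 < theta < 180.0:
                theta = rng.normal(mean_deg, sd_deg)
        else:
            theta = mean_deg
            if not 0.0 < theta < 180.0:
                raise ValueError("tilt angle must lie in (0, 180) degrees")
        d = n_bp * rise * math.sin(math.radians(theta)) + linker_offset
        eta = 1.0 / (1.0 + (d / d0) ** exponent)
        tau = tau0 * (1.0 - eta)
        truths.append(
            GroundTruth(
                molecule_id=f"fm{i:04d}",
                true_tau=tau,
                true_background_fraction=0.0,
                bleach_time=math.inf,
                population_label=f"{n_bp}bp",
                true_distance=d,
            )
        )
    return truths


def simulate_trajectory(
    n_bp: int,
    n_frames: int,
    tilt_distribution: tuple[float, float] = (90.0, 0.0),
    azimuth_distribution: tuple[float, float] = (0.0, 0.0),
    cylinder_radius: float = 0.38,
    rise: float = 0.34,
    seed: int | None = None,
    lattice_dz: float = 0.1,
    lattice_n_phi: int = 36,
) -> SyntheticTrajectory:
    """Simulate a rigid dsDNA rod anchored on a cylindrical nanotube.

    The SWCNT is a fixed helical-lattice cylinder of radius `cylinder_radius`
    along z with one lattice site exactly at the duplex anchor point.  Per
    frame the rod direction is u = cos(theta) z + sin(theta)(cos(psi) r +
    sin(psi) t) with theta drawn from `tilt_distribution` (angle to the tube
    axis, truncated to (0, 180) deg) and psi from `azimuth_distribution`.
    Base pair j places a capture pseudo-atom at j*rise (offset 0.05 nm off the
    rod line) and a complement pseudo-atom at (j+1)*rise along u from the
    anchor; the complement atom of the last base pair is the 5'-tip.  With the
    anchor on the tube surface, the tip-to-surface distance is
    n_bp*rise*sin(theta) exactly at psi=0 (no radius correction).

    The duplex curvature over the tube surface is ignored (rod length >> tube
    radius); overhang/anchor strands are represented only as a few surface
    marker atoms, their steric effect lives in the tilt distribution.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    _check_positive("cylinder_radius", cylinder_radius)
    _check_positive("rise", rise)
    if n_bp < 2:
        raise ValueError("n_bp must be >= 2")
    rng = np.random.default_rng(seed)
    r = cylinder_radius
    length = n_bp * rise

    # helical lattice: rings every lattice_dz, staggered by half a step,
    # covering the axial span the tip can reach; site (0, 0) is the anchor.
    half_span = length + 1.0
    ks = np.arange(-int(math.ceil(half_span / lattice_dz)),
                   int(math.ceil(half_span / lattice_dz)) + 1)
    phis = 2.0 * math.pi * np.arange(lattice_n_phi) / lattice_n_phi
    zz, pp = np.meshgrid(ks * lattice_dz, phis, indexing="ij")
    pp = pp + (zz / lattice_dz) * (math.pi / lattice_n_phi)  # helical stagger
    swcnt = np.column_stack(
        [r * np.cos(pp.ravel()), r * np.sin(pp.ravel()), zz.ravel()]
    )
    # guarantee an exact lattice site at the anchor (k=0 ring, phi=0 exists)
    anchor_point = np.array([r, 0.0, 0.0])

    anchor_atoms = np.array(
        [
            [r * math.cos(0.3), r * math.sin(0.3), -0.6],
            [r, 0.0, -1.1],
            [r * math.cos(-0.3), r * math.sin(-0.3), -1.6],
        ]
    )

    n_swcnt = swcnt.shape[0]
    groups = (
        ["SWCNT"] * n_swcnt + ["anchor"] * 3 + ["capture"] * n_bp + ["complement"] * n_bp
    )
    bp_index = np.concatenate(
        [np.full(n_swcnt + 3, -1, dtype=int), np.arange(n_bp), np.arange(n_bp)]
    )
    is_tip = np.zeros(len(groups), dtype=bool)
    is_tip[-1] = True  # complement atom of the last base pair

    mean_t, sd_t = tilt_distribution
    mean_a, sd_a = azimuth_distribution
    radial = np.array([1.0, 0.0, 0.0])
    tangent = np.array([0.0, 1.0, 0.0])
    axis = np.array([0.0, 0.0, 1.0])

    frames, tilts = [], np.empty(n_frames)
    for f in range(n_frames):
        if sd_t > 0:
            theta = rng.normal(mean_t, sd_t)
            while not 0.0 < theta < 180.0:
                theta = rng.normal(mean_t, sd_t)
        else:
            theta = mean_t
            if not 0.0 < theta < 180.0:
                raise ValueError("tilt angle must lie in (0, 180) degrees")
        psi = rng.normal(mean_a, sd_a) if sd_a > 0 else mean_a
        tilts[f] = theta
        th, ps = math.radians(theta), math.radians(psi)
        u = (
            math.cos(th) * axis
            + math.sin(th) * (math.cos(ps) * radial + math.sin(ps) * tangent)
        )
        # transverse offset for the capture strand, perpendicular to the rod
        w = np.cross(u, axis)
        if np.linalg.norm(w) < 1e-12:
            w = np.cross(u, radial)
        w = w / np.linalg.norm(w)
        j = np.arange(n_bp)
        capture = anchor_point + np.outer(j * rise, u) + 0.05 * w
        complement = anchor_point + np.outer((j + 1) * rise, u)
        frames.append(np.vstack([swcnt, anchor_atoms, capture, complement]))
    return SyntheticTrajectory(
        frames=frames,
        groups=np.array(groups),
        bp_index=bp_index,
        is_tip=is_tip,
        cylinder_radius=r,
        n_bp=n_bp,
        true_tilt_deg=tilts,
    )


def make_toy_spectra(
    emission_peak: float,
    emission_fwhm: float,
    absorption_peak: float,
    absorption_fwhm: float,
    grid: np.ndarray | None = None,
    extinction_scale: float = 1.0e5,
) -> tuple[SpectrumTable, SpectrumTable]:
    """Gaussian toy emission and extinction bands on a shared grid.

    The emission band is area-normalized on the grid (trapezoid rule); the
    extinction band peaks at `extinction_scale` (M^-1 cm^-1).
    """
    for name, v in [
        ("emission_peak", emission_peak), ("emission_fwhm", emission_fwhm),
        ("absorption_peak", absorption_peak), ("absorption_fwhm", absorption_fwhm),
    ]:
        _check_positive(name, v)
    if grid is None:
        lo = min(emission_peak - 3 * emission_fwhm, absorption_peak - 3 * absorption_fwhm)
        hi = max(emission_peak + 3 * emission_fwhm, absorption_peak + 3 * absorption_fwhm)
        grid = np.linspace(lo, hi, 600)
    grid = np.asarray(grid, dtype=float)
    for name, peak, fwhm in [
        ("emission", emission_peak, emission_fwhm),
        ("absorption", absorption_peak, absorption_fwhm),
    ]:
        if grid[0] > peak - 3 * fwhm or grid[-1] < peak + 3 * fwhm:
            warnings.warn(
                f"grid does not cover +/-3 FWHM of the {name} band", stacklevel=2
            )
    sig_em = emission_fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    sig_ab = absorption_fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    em = np.exp(-0.5 * ((grid - emission_peak) / sig_em) ** 2)
    area = np.trapezoid(em, grid)
    if area <= 0:
        raise ValueError("emission band has zero area on the grid")
    em = em / area
    ab = extinction_scale * np.exp(-0.5 * ((grid - absorption_peak) / sig_ab) ** 2)
    return SpectrumTable(grid, em), SpectrumTable(grid, ab)
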