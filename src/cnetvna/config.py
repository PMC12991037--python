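"""Centralized pipeline configuration and the run manifest.

The config file is a flat YAML key-value document; unknown keys are rejected
so typos fail loudly.  All stage defaults live in :data:`PIPELINE_DEFAULTS`
and are overridable per run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "RunManifest", "PIPELINE_DEFAULTS"]

PIPELINE_DEFAULTS: dict = {
    # simulation
    "seed": 0,
    "n_molecules": 300,
    "duplex_lengths_bp": [12, 15, 18, 20, 24],
    "md_mean_distances_nm": [4.6, 5.0, 5.8, 6.2, 7.7],
    "tau0_ns": 3.5,
    "d0_nm": 7.4,
    "generating_exponent": 5,
    "tilt_sd_deg": 10.0,
    "brightness": 2.0e4,
    "background_rate": 408.0,
    "bleach_rate": 1.0,
    "duration_s": 10.0,
    "irf_sigma_ns": 0.1,
    "irf_center_ns": 2.0,
    "excitation_period_ns": 25.0,
    "tcspc_window_ns": 25.0,
    # lifetimes
    "trace_bin_width_s": 0.01,
    "decay_bins": 256,
    # decomposition-grade per-molecule photon floor: tau error ~ tau/sqrt(N)
    # must stay below half a histogram bin (0.05 ns) for the mixture stage
    "min_photons": 2000,
    "fit_mode": "mle",
    # populations
    "hist_bin_width_ns": 0.1,
    "sigma_bounds_ns": [0.05, 0.5],
    "m_range": [1, 5],
    "aic_delta": 2.0,
    "tau0_tolerance_ns": 0.25,
    # scaling law
    "rise_nm": 0.34,
    "linker_offset_nm": 1.1,
    "exponents": [3, 4, 5, 6],
    "weighted_fit": False,
    # bookkeeping
    "output_dir": "cnetvna_out",
}


@dataclass
class PipelineConfig:
    """Validated flat configuration; every field has a documented default."""

    values: dict = field(default_factory=lambda: dict(PIPELINE_DEFAULTS))

    def __post_init__(self) -> None:
        unknown = set(self.values) - set(PIPELINE_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        merged = dict(PIPELINE_DEFAULTS)
        merged.update(self.values)
        self.values = merged

    def __getitem__(self, key: str):
        return self.values[key]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must be a flat key-value mapping")
        return cls(values=data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.values, fh, sort_keys=True)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record written on every pipeline run."""

    config: dict
    package_version: str
    seed: int
    input_hashes: dict = field(default_factory=dict)
    record_counts: dict = field(default_factory=dict)

    def add_input(self, name: str, path: str | Path) -> None:
        self.input_hashes[name] = _sha256(path)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
        # keep dataclass fields order-independent for the determinism check

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        with open(path) as fh:
            data = json.load(fh)
        names = {f.name for f in fields(cls)}
        return cls(**{k: v for k, v in data.items() if k in names})
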