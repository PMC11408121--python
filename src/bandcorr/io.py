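"""File formats and configuration for the simulation/fitting pipeline.

Formats are deliberately plain and diffable: m-arrays and replicate records
as CSV, fit and study summaries as JSON, study configuration as a flat YAML
document with an explicit schema version.  Year labels in file headers are
1-based (release year 1 is the first cohort).  Every output carries the
resolved configuration and seeds it was produced from.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core_model import ConstantRates
from .study import RECORD_COLUMNS
from .synthetic_data import MArray, SimulationConfig, SimulationTruth

__all__ = [
    "read_marray",
    "write_marray",
    "read_config",
    "write_config",
    "write_truth",
    "read_records",
    "write_records",
    "provenance_block",
    "StudyConfigFile",
]

SCHEMA_VERSION = 1

_CONFIG_KEYS = {
    "schema_version", "T", "releases", "mu_kappa", "mu_eta",
    "sigma_shape", "sigma_rate", "rho_lower", "rho_upper",
    "crippling_loss", "band_reporting",
}


@dataclass(frozen=True)
class StudyConfigFile:
    """Flat key-value study configuration (see :func:`read_config`)."""

    config: SimulationConfig

    def to_dict(self) -> dict:
        c = self.config
        releases = c.releases if np.isscalar(c.releases) else list(c.releases)
        return {
            "schema_version": SCHEMA_VERSION,
            "T": c.T,
            "releases": releases,
            "mu_kappa": c.mu_kappa,
            "mu_eta": c.mu_eta,
            "sigma_shape": c.sigma_hyper[0],
            "sigma_rate": c.sigma_hyper[1],
            "rho_lower": c.rho_range[0],
            "rho_upper": c.rho_range[1],
            "crippling_loss": c.rates.c,
            "band_reporting": c.rates.b,
        }


def write_config(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(StudyConfigFile(config).to_dict(), fh, sort_keys=False)


def read_config(path) -> SimulationConfig:
    """Parse a study configuration file, rejecting unknown keys.

    All keys are optional except ``schema_version``; defaults are the
    package's standard study conditions.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    version = raw.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ValueError(f"{path}: unsupported schema_version {version}")
    defaults = SimulationConfig()
    releases = raw.get("releases", defaults.releases)
    if isinstance(releases, list):
        releases = tuple(int(r) for r in releases)
    return SimulationConfig(
        T=int(raw.get("T", defaults.T)),
        releases=releases,
        mu_kappa=float(raw.get("mu_kappa", defaults.mu_kappa)),
        mu_eta=float(raw.get("mu_eta", defaults.mu_eta)),
        sigma_hyper=(
            float(raw.get("sigma_shape", defaults.sigma_hyper[0])),
            float(raw.get("sigma_rate", defaults.sigma_hyper[1])),
        ),
        rho_range=(
            float(raw.get("rho_lower", defaults.rho_range[0])),
            float(raw.get("rho_upper", defaults.rho_range[1])),
        ),
        rates=ConstantRates(
            c=float(raw.get("crippling_loss", defaults.rates.c)),
            b=float(raw.get("band_reporting", defaults.rates.b)),
        ),
    )


def _marray_columns(T: int) -> list[str]:
    return ["release_year", *[f"rec_{j}" for j in range(1, T + 1)], "never", "releases"]


def write_marray(marray: MArray, path) -> None:
    """Write an m-array as CSV: ``release_year, rec_1..rec_T, never, releases``."""
    T = marray.T
    df = pd.DataFrame(marray.counts, columns=[*[f"rec_{j}" for j in range(1, T + 1)], "never"])
    df.insert(0, "release_year", np.arange(1, T + 1))
    df["releases"] = marray.releases
    df.to_csv(path, index=False)


def read_marray(path) -> MArray:
    """Read and validate an m-array CSV; raises naming the offending row/column."""
    df = pd.read_csv(path)
    cols = list(df.columns)
    if cols[0] != "release_year" or cols[-2:] != ["never", "releases"]:
        raise ValueError(
            f"{path}: expected header release_year, rec_1..rec_T, never, releases"
        )
    T = len(cols) - 3
    if cols != _marray_columns(T):
        raise ValueError(f"{path}: recovery-year columns must be rec_1..rec_{T}")
    if len(df) != T:
        raise ValueError(f"{path}: expected {T} cohort rows, found {len(df)}")
    counts = df[[*[f"rec_{j}" for j in range(1, T + 1)], "never"]].to_numpy(dtype=np.int64)
    releases = df["releases"].to_numpy(dtype=np.int64)
    return MArray(counts=counts, releases=releases)  # validates invariants


def write_truth(truth: SimulationTruth, path, *, config: SimulationConfig | None = None,
                seed: int | None = None) -> None:
    payload = truth.to_dict()
    if config is not None or seed is not None:
        payload["provenance"] = provenance_block(config=config, seed=seed)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def write_records(records: pd.DataFrame, path) -> None:
    # the on-disk table has a fixed header; extra diagnostic columns stay in memory
    records[RECORD_COLUMNS].to_csv(path, index=False)


def read_records(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing record columns {sorted(missing)}")
    return df


def provenance_block(*, config: SimulationConfig | None = None,
                     seed: int | None = None, extra: dict | None = None) -> dict:
    """Provenance metadata echoed into every output for regenerability."""
    block: dict = {"package": "bandcorr", "version": __version__,
                   "schema_version": SCHEMA_VERSION}
    if config is not None:
        block["config"] = StudyConfigFile(config).to_dict()
    if seed is not None:
        block["seed"] = seed
    if extra:
        block.update(extra)
    return block


def write_json(payload: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=float)
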