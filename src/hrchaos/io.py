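"""Plain-text file formats and run configuration.

ISI series and spike-time files are one value per line; ``#``-prefixed
header lines carry metadata as ``# key: value`` (recognized keys include
``units``, ``seed`` and free-form provenance).  Units default to seconds
for files read from disk and model_time for simulated series.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import ISIParseError
from .hr_model import ISISeries, SpikeTrain

__all__ = [
    "read_isi_file",
    "read_spike_file",
    "write_isi_file",
    "write_spike_file",
    "RunConfig",
]


def _parse_values(path, default_units: str):
    """Shared reader: (values, units, header) from a headered text file."""
    p = Path(path)
    units = default_units
    header: dict = {}
    values: list[float] = []
    lines: list[int] = []
    with p.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            text = raw.strip()
            if not text:
                continue
            if text.startswith("#"):
                body = text.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    header[key.strip().lower()] = val.strip()
                continue
            # allow single-column CSV with an optional textual header cell
            token = text.split(",")[0].strip()
            try:
                v = float(token)
            except ValueError:
                if lineno == 1:
                    continue  # CSV column header
                raise ISIParseError(f"cannot parse value {token!r}", line=lineno)
            values.append(v)
            lines.append(lineno)
    if "units" in header:
        units = header["units"]
    if not values:
        raise ISIParseError(f"no values found in {p}")
    return np.array(values), np.array(lines), units, header


def read_isi_file(path) -> ISISeries:
    """Read an ISI series (one positive value per line, optional header)."""
    values, lines, units, _ = _parse_values(path, default_units="seconds")
    bad = np.nonzero(values <= 0)[0]
    if len(bad):
        raise ISIParseError(f"non-positive ISI {values[bad[0]]!r}",
                            line=int(lines[bad[0]]))
    return ISISeries(values, units=units)


def read_spike_file(path) -> SpikeTrain:
    """Read spike times (strictly increasing, one per line)."""
    values, lines, units, _ = _parse_values(path, default_units="seconds")
    diffs = np.diff(values)
    bad = np.nonzero(diffs <= 0)[0]
    if len(bad):
        raise ISIParseError(
            f"spike times not strictly increasing at value {values[bad[0] + 1]!r}",
            line=int(lines[bad[0] + 1]))
    return SpikeTrain(values, units=units)


def _write_values(path, values, units: str, provenance: Optional[dict]) -> None:
    p = Path(path)
    with p.open("w") as fh:
        fh.write(f"# units: {units}\n")
        for key, val in (provenance or {}).items():
            fh.write(f"# {key}: {val}\n")
        for v in values:
            fh.write(f"{v:.12g}\n")


def write_isi_file(path, series: ISISeries, provenance: Optional[dict] = None) -> None:
    _write_values(path, series.isis, series.units, provenance)


def write_spike_file(path, train: SpikeTrain, provenance: Optional[dict] = None) -> None:
    _write_values(path, train.spike_times, train.units, provenance)


@dataclass
class RunConfig:
    """Flat key-value run configuration with documented defaults.

    Unknown keys in a config file are rejected so that typos surface
    immediately.
    """

    dt: float = 0.01
    transient: float = 500.0
    spike_threshold: float = 0.0
    min_separation: float = 1.0
    rel_tol: float = 0.01
    rel_tol_noisy: float = 0.05
    k_max: int = 8
    lle_threshold: float = 0.001
    lle_t_average: float = 5000.0
    scan_points: int = 150
    map_n_I: int = 112
    map_n_r: int = 70
    embed_m: int = 4
    embed_eps: float = 0.01
    h_max: int = 10
    n_surrogates: int = 10
    window: int = 100
    seed: int = 0
    out_dir: str = "."
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load a flat ``key: value`` (YAML) config file."""
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must be a flat mapping")
        known = {f.name: f.type for f in fields(cls)}
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)
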