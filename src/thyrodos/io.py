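"""Plain-text readers and writers for the measurement file dialects.

All raw observables travel as small CSV files:

* DTOF / IRF: a metadata header line, its values, then (time_ns, counts)
  rows.
* g2 curves: a metadata header line, its values, then (tau_s, g2) rows.
* Cohort tables: ordinary CSV with one row per measurement record or
  subject.

Every writer/reader pair is a lossless round trip on valid data, and
malformed rows are reported with their line numbers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dcs import AutocorrelationCurve
from .trs import IRF, DTOFCurve


class FormatError(ValueError):
    """A file did not match its expected dialect."""


def _read_header_block(lines, expected_fields, path):
    """Parse 'name,name,...' + value line; returns (dict, next_index)."""
    i = 0
    while i < len(lines) and (not lines[i].strip() or lines[i].lstrip().startswith("#")):
        i += 1
    if i + 1 >= len(lines):
        raise FormatError(f"{path}: missing header block")
    names = [c.strip() for c in lines[i].split(",")]
    if names != list(expected_fields):
        raise FormatError(
            f"{path}: line {i + 1}: expected header {','.join(expected_fields)}, "
            f"got {lines[i].strip()!r}"
        )
    try:
        values = [float(x) for x in lines[i + 1].split(",")]
    except ValueError as exc:
        raise FormatError(f"{path}: line {i + 2}: bad header values") from exc
    if len(values) != len(names):
        raise FormatError(f"{path}: line {i + 2}: wrong number of header values")
    return dict(zip(names, values)), i + 2


def _read_data_rows(lines, start, columns, path):
    i = start
    if i >= len(lines) or [c.strip() for c in lines[i].split(",")] != list(columns):
        raise FormatError(f"{path}: line {i + 1}: expected column row {','.join(columns)}")
    rows = []
    for j in range(i + 1, len(lines)):
        line = lines[j].strip()
        if not line:
            continue
        try:
            rows.append([float(x) for x in line.split(",")])
        except ValueError as exc:
            raise FormatError(f"{path}: line {j + 1}: malformed row {line!r}") from exc
        if len(rows[-1]) != len(columns):
            raise FormatError(f"{path}: line {j + 1}: wrong number of fields")
    if not rows:
        raise FormatError(f"{path}: no data rows")
    return np.asarray(rows)


def write_dtof(curve: DTOFCurve, path) -> None:
    with open(path, "w") as fh:
        fh.write("wavelength_nm,rho_mm,bin_ns\n")
        fh.write(f"{curve.wavelength_nm},{curve.rho_mm},{curve.bin_width_ns}\n")
        fh.write("time_ns,counts\n")
        for t, c in zip(curve.time_bins_ns, curve.counts):
            fh.write(f"{t:.17g},{c:.17g}\n")


def read_dtof(path) -> DTOFCurve:
    lines = Path(path).read_text().splitlines()
    header, i = _read_header_block(lines, ("wavelength_nm", "rho_mm", "bin_ns"), path)
    data = _read_data_rows(lines, i, ("time_ns", "counts"), path)
    t, counts = data[:, 0], data[:, 1]
    dt = np.diff(t)
    if len(dt) and not np.allclose(dt, header["bin_ns"], rtol=1e-6):
        raise FormatError(f"{path}: non-uniform time bins")
    neg = np.nonzero(counts < 0)[0]
    if len(neg):
        raise FormatError(f"{path}: line {i + 2 + neg[0]}: negative count")
    return DTOFCurve(t, counts, header["wavelength_nm"], header["rho_mm"])


def write_irf(irf: IRF, path) -> None:
    with open(path, "w") as fh:
        fh.write("wavelength_nm,bin_ns,nominal_width_ps\n")
        fh.write(f"{irf.wavelength_nm},{irf.bin_width_ns},{irf.nominal_width_ps}\n")
        fh.write("time_ns,counts\n")
        for t, c in zip(irf.time_bins_ns, irf.counts):
            fh.write(f"{t:.17g},{c:.17g}\n")


def read_irf(path) -> IRF:
    lines = Path(path).read_text().splitlines()
    header, i = _read_header_block(
        lines, ("wavelength_nm", "bin_ns", "nominal_width_ps"), path
    )
    data = _read_data_rows(lines, i, ("time_ns", "counts"), path)
    t, counts = data[:, 0], data[:, 1]
    if np.any(counts < 0):
        raise FormatError(f"{path}: negative IRF values")
    return IRF(t, counts, header["wavelength_nm"], header["nominal_width_ps"])


def write_g2(curve: AutocorrelationCurve, path) -> None:
    with open(path, "w") as fh:
        fh.write("channel,rho_mm,wavelength_nm,integration_time_s\n")
        fh.write(
            f"{curve.channel_id},{curve.rho_mm},{curve.wavelength_nm},"
            f"{curve.integration_time_s}\n"
        )
        fh.write("tau_s,g2\n")
        for tau, g in zip(curve.taus_s, curve.g2):
            fh.write(f"{tau:.17g},{g:.17g}\n")


def read_g2(path) -> AutocorrelationCurve:
    lines = Path(path).read_text().splitlines()
    header, i = _read_header_block(
        lines, ("channel", "rho_mm", "wavelength_nm", "integration_time_s"), path
    )
    data = _read_data_rows(lines, i, ("tau_s", "g2"), path)
    taus, g2 = data[:, 0], data[:, 1]
    if np.any(np.diff(taus) <= 0):
        warnings.warn(f"{path}: unsorted taus; sorting", stacklevel=2)
        order = np.argsort(taus)
        taus, g2 = taus[order], g2[order]
    return AutocorrelationCurve(
        taus, g2,
        channel_id=int(header["channel"]),
        rho_mm=header["rho_mm"],
        wavelength_nm=header["wavelength_nm"],
        integration_time_s=header["integration_time_s"],
    )


MEASUREMENT_COLUMNS = (
    "subject_id", "organ", "side", "location", "sd_separation",
    "THC", "StO2", "BFI",
)


def write_cohort(measurements: pd.DataFrame, path, subjects: pd.DataFrame = None,
                 subjects_path=None) -> None:
    measurements.to_csv(path, index=False)
    if subjects is not None and subjects_path is not None:
        subjects.to_csv(subjects_path, index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required columns {sorted(missing)}")
    return df


@dataclass
class PipelineConfig:
    """Run configuration shared by the CLI subcommands."""

    seed: int = 0
    n_tissue: float = 1.4
    n_exterior: float = 1.0
    boundary: str = "extrapolated"
    extinction_table: str | None = None  # None -> shipped compilation
    water_fraction: float = 0.78
    output_dir: str = "."
    log_level: str = "INFO"
    cohort: dict = field(default_factory=dict)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    if cfg.extinction_table is not None and not Path(cfg.extinction_table).exists():
        raise FormatError(f"extinction table not found: {cfg.extinction_table}")
    return cfg
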