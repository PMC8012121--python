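"""File readers/writers, run configuration, and report assembly.

Input dialect: comma-separated text with a mandatory header row and "."
decimals. Peak tables carry ``two_theta_deg`` and ``fwhm_deg`` (optionally
``h``, ``k``, ``l``, ``intensity``); spectra carry ``absorbance`` plus either
``energy_eV`` or ``wavelength_nm``. Reports serialize to JSON with
deterministic key order, or to a plain-text grid.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .tauc import EV_NM, AbsorptionSpectrum
from .xrd import CU_KALPHA, SCHERRER_K, DiffractionPeak, MicrostructureSummary

__all__ = [
    "RunConfig",
    "AnalysisReport",
    "read_peak_table",
    "read_spectrum",
    "write_report",
    "read_report",
]

log = logging.getLogger("coordchar")


@dataclass
class RunConfig:
    """Tunable defaults shared by the CLI subcommands, loadable from YAML."""

    wavelength: float = CU_KALPHA          # A
    shape_factor: float = SCHERRER_K
    acetate_threshold: float = 200.0       # cm^-1
    assignment_tolerance: float = 1.0      # mass-loss %
    tauc_mode: str = "auto"
    tauc_min_window: int = 5
    output_format: str = "json"            # json | text
    log_level: str = "WARNING"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("wavelength", "shape_factor", "acetate_threshold", "assignment_tolerance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tauc_mode not in ("direct", "indirect", "auto"):
            raise ValueError(f"invalid tauc_mode {self.tauc_mode!r}")
        if self.output_format not in ("json", "text"):
            raise ValueError(f"invalid output_format {self.output_format!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)


def _read_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    return df


def read_peak_table(path: str | Path) -> list[DiffractionPeak]:
    """Read a diffraction peak table from delimited text.

    Requires columns ``two_theta_deg`` and ``fwhm_deg``; ``h``/``k``/``l``
    and ``intensity`` are optional, unknown columns are ignored with a
    warning. Invalid rows raise with their row number.
    """
    df = _read_csv(path)
    required = {"two_theta_deg", "fwhm_deg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    known = required | {"h", "k", "l", "intensity"}
    extra = set(df.columns) - known
    if extra:
        warnings.warn(f"{path}: ignoring unknown column(s) {sorted(extra)}", stacklevel=2)
    has_hkl = {"h", "k", "l"} <= set(df.columns)
    peaks = []
    for i, row in df.iterrows():
        try:
            tt, fw = float(row["two_theta_deg"]), float(row["fwhm_deg"])
            if not (np.isfinite(tt) and np.isfinite(fw)):
                raise ValueError("non-numeric cell")
            hkl = (int(row["h"]), int(row["k"]), int(row["l"])) if has_hkl else None
            inten = float(row["intensity"]) if "intensity" in df.columns and pd.notna(row["intensity"]) else None
            peaks.append(DiffractionPeak(two_theta=tt, fwhm=fw, hkl=hkl, intensity=inten))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: row {i + 1}: {exc}") from exc
    return peaks


def read_spectrum(path: str | Path) -> AbsorptionSpectrum:
    """Read an absorption spectrum from delimited text.

    Accepts ``energy_eV`` or ``wavelength_nm`` as the abscissa (wavelengths
    convert via E = 1239.842 / lambda) plus ``absorbance``. Rows are sorted
    ascending in energy; duplicate energies with equal absorbance collapse
    with a warning, conflicting duplicates raise.
    """
    df = _read_csv(path)
    if "absorbance" not in df.columns:
        raise ValueError(f"{path}: missing required column 'absorbance'")
    if "energy_eV" in df.columns:
        energy = df["energy_eV"].to_numpy(dtype=float)
    elif "wavelength_nm" in df.columns:
        wl = df["wavelength_nm"].to_numpy(dtype=float)
        if np.any(wl <= 0):
            raise ValueError(f"{path}: wavelengths must be positive")
        energy = EV_NM / wl
    else:
        raise ValueError(f"{path}: need an 'energy_eV' or 'wavelength_nm' column")
    absorbance = df["absorbance"].to_numpy(dtype=float)
    if np.any(absorbance < 0):
        raise ValueError(f"{path}: negative absorbance")
    order = np.argsort(energy)
    energy, absorbance = energy[order], absorbance[order]
    dup = np.isclose(np.diff(energy), 0.0)
    if np.any(dup):
        for i in np.flatnonzero(dup):
            if not np.isclose(absorbance[i], absorbance[i + 1]):
                raise ValueError(f"{path}: conflicting duplicate energies near {energy[i]:.4f} eV")
        warnings.warn(f"{path}: collapsed duplicate energy rows", stacklevel=2)
        keep = np.concatenate([[True], ~dup])
        energy, absorbance = energy[keep], absorbance[keep]
    return AbsorptionSpectrum(energy, absorbance)


@dataclass
class AnalysisReport:
    """Versioned container for per-stage results and caveats."""

    results: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)  # rule/threshold strings
    input_digest: str | None = None
    version: str = __version__

    @staticmethod
    def digest(path: str | Path) -> str:
        return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=2, default=_jsonify)

    @classmethod
    def from_json(cls, text: str) -> "AnalysisReport":
        data = json.loads(text)
        return cls(**data)

    def to_text(self) -> str:
        lines = [f"coordchar {self.version}"]
        if self.input_digest:
            lines.append(f"input sha256/16: {self.input_digest}")
        for stage in sorted(self.results):
            lines.append("")
            lines.append(f"[{stage}]")
            lines.extend(_format_stage(self.results[stage]))
        for w in self.warnings:
            lines.append(f"warning: {w}")
        for p in self.provenance:
            lines.append(f"rule: {p}")
        return "\n".join(lines) + "\n"


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "as_dict"):
        return obj.as_dict()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _format_stage(payload) -> list[str]:
    if isinstance(payload, MicrostructureSummary):
        payload = _summary_table(payload)
    if isinstance(payload, dict):
        out = []
        for k in payload:
            v = payload[k]
            if isinstance(v, float):
                out.append(f"  {k}: {v:.4f}")
            else:
                out.append(f"  {k}: {v}")
        return out
    if isinstance(payload, str):
        return [f"  {line}" for line in payload.splitlines()]
    return [f"  {payload}"]


def _summary_table(summary: MicrostructureSummary) -> str:
    df = summary.to_frame()
    avg = pd.DataFrame(
        {
            "two_theta_deg": [float("nan")],
            "fwhm_deg": [df["fwhm_deg"].mean()],
            "d_A": [df["d_A"].mean()],
            "D_nm": [summary.mean_size],
            "strain": [summary.mean_strain],
            "dislocation_nm-2": [summary.mean_dislocation],
        },
        index=["Average"],
    )
    return pd.concat([df, avg]).to_string(float_format=lambda v: f"{v:.4g}")


def write_report(report: AnalysisReport, path: str | Path, fmt: str = "json") -> None:
    """Write a report as JSON (deterministic key order) or a text grid."""
    path = Path(path)
    if fmt == "json":
        path.write_text(report.to_json() + "\n")
    elif fmt == "text":
        path.write_text(report.to_text())
    else:
        raise ValueError(f"unknown report format {fmt!r}")


def read_report(path: str | Path) -> AnalysisReport:
    return AnalysisReport.from_json(Path(path).read_text())
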