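"""Core FTIR spectrum data model, file I/O, unit conversion, and integration.

A :class:`Spectrum` stores one sample's mid-infrared absorbance trace on its
native wavenumber grid (canonically ascending, in cm^-1).  Instruments
conventionally write spectra from 4000 down to 650 cm^-1 and often in
percent-transmittance mode; loading canonicalizes the orientation and
conversion to absorbance is explicit (``A = 2 - log10(%T)``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MIN_POINTS = 16

__all__ = [
    "Spectrum",
    "SampleRecord",
    "SpectrumLoadError",
    "ConversionError",
    "WorkbookLayout",
    "read_spectrum",
    "read_workbook_spectra",
    "write_spectrum",
    "transmittance_to_absorbance",
    "absorbance_to_transmittance",
    "integrate_spectrum",
]


class SpectrumLoadError(ValueError):
    """Raised when a spectrum file cannot be parsed into a valid Spectrum."""


class ConversionError(ValueError):
    """Raised when a %-transmittance trace cannot be converted to absorbance."""


@dataclass(frozen=True)
class Spectrum:
    """One sample's FTIR trace: ascending wavenumber grid + absorbance values.

    Parameters
    ----------
    sample_id : str
        Identifier carried through measurement tables.
    wavenumbers : ndarray
        Strictly increasing grid in cm^-1 (typically ~650 to ~4000).
    absorbance : ndarray
        Unitless absorbance, one value per grid point.  Values are always
        absorbance after construction; ``mode_source`` records the original
        acquisition mode.
    mode_source : {"absorbance", "percent_transmittance"}
    resolution : float
        Nominal instrument resolution in cm^-1 (metadata only).
    """

    sample_id: str
    wavenumbers: np.ndarray
    absorbance: np.ndarray
    mode_source: str = "absorbance"
    resolution: float = 4.0

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        if w.ndim != 1 or a.ndim != 1:
            raise SpectrumLoadError("wavenumbers and absorbance must be 1-D")
        if w.size != a.size:
            raise SpectrumLoadError(
                f"{self.sample_id!r}: {w.size} wavenumbers but {a.size} absorbances"
            )
        if w.size < MIN_POINTS:
            raise SpectrumLoadError(
                f"{self.sample_id!r}: spectrum has {w.size} points; need >= {MIN_POINTS}"
            )
        if not (np.isfinite(w).all() and np.isfinite(a).all()):
            raise SpectrumLoadError(f"{self.sample_id!r}: non-finite values in spectrum")
        # canonicalize to ascending wavenumber
        if w[0] > w[-1]:
            w, a = w[::-1], a[::-1]
        d = np.diff(w)
        if (d <= 0).any():
            i = int(np.argmax(d <= 0))
            raise SpectrumLoadError(
                f"{self.sample_id!r}: wavenumbers not strictly monotone near "
                f"{w[i]:g} cm^-1 (duplicate or unsorted grid)"
            )
        if self.mode_source not in ("absorbance", "percent_transmittance"):
            raise SpectrumLoadError(f"unknown mode_source {self.mode_source!r}")
        object.__setattr__(self, "wavenumbers", w)
        object.__setattr__(self, "absorbance", a)

    def __len__(self) -> int:
        return int(self.wavenumbers.size)

    @property
    def wmin(self) -> float:
        return float(self.wavenumbers[0])

    @property
    def wmax(self) -> float:
        return float(self.wavenumbers[-1])

    def index_of(self, wavenumber: float) -> int:
        """Index of an exact grid point; raises if the value is off-grid."""
        i = int(np.searchsorted(self.wavenumbers, wavenumber))
        if i < len(self) and np.isclose(self.wavenumbers[i], wavenumber, rtol=0, atol=1e-9):
            return i
        raise ValueError(f"{wavenumber:g} cm^-1 is not on the grid of {self.sample_id!r}")

    def scaled(self, factor: float) -> "Spectrum":
        return replace(self, absorbance=self.absorbance * factor)


@dataclass
class SampleRecord:
    """Per-sample metadata: provenance, depth, climate covariates, QC flags."""

    sample_id: str
    material: str = "peat"  # peat | plant | standard
    site: str = ""
    category: str = ""
    depth_cm: float | None = None
    latitude_deg: float | None = None
    mean_annual_temp_C: float | None = None
    excluded: bool = False
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        if self.material not in ("peat", "plant", "standard"):
            raise ValueError(f"unknown material {self.material!r}")
        if self.excluded != bool(self.exclusion_reason):
            raise ValueError(
                f"{self.sample_id!r}: excluded flag must match a non-empty exclusion_reason"
            )
        if self.material == "peat":
            if self.depth_cm is None:
                raise ValueError(f"peat sample {self.sample_id!r} requires depth_cm")
            if self.depth_cm < 0:
                raise ValueError(f"{self.sample_id!r}: negative depth_cm")
        elif self.depth_cm is not None:
            raise ValueError(
                f"{self.sample_id!r}: depth_cm only applies to peat samples"
            )


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_spectrum(
    path: str | Path,
    dialect: str = "two_column_csv",
    sample_id: str | None = None,
    mode_source: str = "absorbance",
    resolution: float = 4.0,
) -> Spectrum:
    """Read one spectrum from a two-column CSV (wavenumber, absorbance).

    The file may list wavenumbers ascending or descending; the returned
    Spectrum is always canonical (ascending).  A header row is detected and
    skipped automatically.
    """
    if dialect != "two_column_csv":
        raise ValueError(
            f"dialect {dialect!r} not supported by read_spectrum; "
            "use read_workbook_spectra for workbook sheets"
        )
    path = Path(path)
    if not path.exists():
        raise SpectrumLoadError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise SpectrumLoadError(f"{path}: {exc}") from exc
    if df.shape[1] < 2:
        raise SpectrumLoadError(f"{path}: expected two columns, found {df.shape[1]}")
    df = df.iloc[:, :2]
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SpectrumLoadError(
                f"{path}: non-numeric cell in column {col!r} at data row {row}"
            )
    w = pd.to_numeric(df.iloc[:, 0]).to_numpy(float)
    a = pd.to_numeric(df.iloc[:, 1]).to_numpy(float)
    if pd.isna(w).any() or pd.isna(a).any():
        row = int(np.flatnonzero(pd.isna(w) | pd.isna(a))[0])
        raise SpectrumLoadError(f"{path}: missing value at data row {row}")
    uniq, counts = np.unique(w, return_counts=True)
    if (counts > 1).any():
        dup = uniq[counts > 1][0]
        raise SpectrumLoadError(f"{path}: duplicate wavenumber {dup:g} cm^-1")
    return Spectrum(
        sample_id=sample_id or path.stem,
        wavenumbers=w,
        absorbance=a,
        mode_source=mode_source,
        resolution=resolution,
    )


def write_spectrum(s: Spectrum, path: str | Path) -> None:
    """Write a spectrum as two-column CSV at full precision."""
    df = pd.DataFrame({"wavenumber_cm-1": s.wavenumbers, "absorbance": s.absorbance})
    df.to_csv(path, index=False)  # default str() is shortest-round-trip for float64


@dataclass
class WorkbookLayout:
    """Configurable layout of a multi-sample spectral workbook.

    One sheet holds a metadata block (leading columns) followed by the
    spectral matrix: one row per sample, one column per wavenumber, with the
    wavenumber values in the header row.
    """

    sheet: str | int = 0
    sample_id_column: str = "sample_id"
    metadata_columns: tuple[str, ...] = ()
    first_spectral_column: int | None = None  # autodetect: first numeric header


def read_workbook_spectra(
    path: str | Path,
    layout: WorkbookLayout | None = None,
    mode_source: str = "absorbance",
) -> tuple[list[Spectrum], pd.DataFrame]:
    """Read every sample row of a workbook sheet into Spectrum objects.

    Returns (spectra, metadata) where metadata holds the leading non-spectral
    columns indexed by sample_id.
    """
    layout = layout or WorkbookLayout()
    path = Path(path)
    if not path.exists():
        raise SpectrumLoadError(f"no such file: {path}")
    df = pd.read_excel(path, sheet_name=layout.sheet, engine="openpyxl")
    if layout.sample_id_column not in df.columns:
        raise SpectrumLoadError(
            f"{path}: missing sample id column {layout.sample_id_column!r}"
        )
    if layout.first_spectral_column is None:
        spectral_cols = [c for c in df.columns if _is_number(c)]
        if not spectral_cols:
            raise SpectrumLoadError(f"{path}: no numeric wavenumber columns found")
    else:
        spectral_cols = list(df.columns[layout.first_spectral_column:])
    w = np.array([float(c) for c in spectral_cols])
    meta_cols = [c for c in df.columns if c not in spectral_cols]
    spectra = []
    for _, row in df.iterrows():
        sid = str(row[layout.sample_id_column])
        vals = pd.to_numeric(row[spectral_cols], errors="coerce").to_numpy(float)
        if np.isnan(vals).any():
            raise SpectrumLoadError(f"{path}: non-numeric spectral cell in sample {sid!r}")
        spectra.append(Spectrum(sid, w.copy(), vals, mode_source=mode_source))
    meta = df[meta_cols].set_index(layout.sample_id_column)
    return spectra, meta


def _is_number(x) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False


# ---------------------------------------------------------------------------
# conversion and integration
# ---------------------------------------------------------------------------

def transmittance_to_absorbance(s: Spectrum) -> Spectrum:
    """Convert a %-transmittance trace to absorbance: ``A = 2 - log10(%T)``.

    100 %T maps to A = 0; each decade of transmittance is one absorbance unit.
    """
    t = s.absorbance
    if (t <= 0).any():
        w_bad = s.wavenumbers[t <= 0][0]
        raise ConversionError(
            f"{s.sample_id!r}: %T <= 0 at {w_bad:g} cm^-1; cannot convert to absorbance"
        )
    return replace(s, absorbance=2.0 - np.log10(t), mode_source="percent_transmittance")


def absorbance_to_transmittance(s: Spectrum) -> np.ndarray:
    """Inverse conversion, ``%T = 10**(2 - A)``; returns the %T values."""
    return 10.0 ** (2.0 - s.absorbance)


def integrate_spectrum(s: Spectrum) -> float:
    """Total integrated area (absorbance x cm^-1), composite trapezoid.

    Computed on the native (possibly non-uniform) ascending grid.  Negative
    absorbances integrate with sign; callers that normalize by the area must
    refuse non-positive totals.
    """
    if len(s) < 2:
        raise ValueError("cannot integrate a spectrum with fewer than 2 points")
    area = float(np.trapezoid(s.absorbance, s.wavenumbers))
    if area <= 0:
        logger.warning(
            "spectrum %r has non-positive total area %.4g; "
            "downstream normalization will be refused",
            s.sample_id, area,
        )
    return area
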