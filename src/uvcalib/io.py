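"""Spectral data containers and plain-text I/O.

The package works on three containers: a single :class:`Spectrum`
(wavelength grid + absorbances), a :class:`SpectraMatrix` ``X`` whose rows
are sample spectra on a shared grid, and a :class:`ConcentrationTable`
``c`` of per-sample analyte concentrations in ug/mL.

Files are delimited text: spectra files carry the wavelength grid (nm) as
the header row and one sample per data row (absorbance units);
concentration files carry component names as the header.  Single spectra
can additionally be ingested from JCAMP-DX 4.24 files restricted to the
uncompressed ``(X++(Y..Y))`` AFFN dialect, which is what bench UV
spectrophotometers typically export.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "SpectraMatrix",
    "ConcentrationTable",
    "SpectraFormatError",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_concentration_csv",
    "write_concentration_table",
    "read_jcampdx",
]

#: Wavelength range (nm) of the UV region the models operate on.
INSTRUMENT_RANGE = (210.0, 300.0)

#: Canonical acquisition grid: 210-300 nm inclusive at 1 nm steps (91 points).
DEFAULT_GRID = np.arange(210.0, 301.0)


class SpectraFormatError(ValueError):
    """Malformed spectra/concentration file or JCAMP-DX block."""


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr


@dataclass
class Spectrum:
    """One absorbance spectrum on a strictly increasing wavelength grid."""

    wavelengths: np.ndarray
    absorbances: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = _as_float_array(self.wavelengths, "wavelengths")
        self.absorbances = _as_float_array(self.absorbances, "absorbances")
        if self.wavelengths.ndim != 1 or self.absorbances.ndim != 1:
            raise ValueError("wavelengths and absorbances must be 1-D")
        if self.wavelengths.size != self.absorbances.size:
            raise ValueError(
                f"length mismatch: {self.wavelengths.size} wavelengths vs "
                f"{self.absorbances.size} absorbances"
            )
        if self.wavelengths.size and np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        lo, hi = INSTRUMENT_RANGE
        if self.wavelengths.size and (
            self.wavelengths[0] < lo or self.wavelengths[-1] > hi
        ):
            raise ValueError(
                f"wavelengths outside instrument range {lo}-{hi} nm"
            )


@dataclass
class SpectraMatrix:
    """Sample-by-wavelength absorbance matrix ``X`` (I x J, AU)."""

    samples: list[str]
    wavelengths: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.samples = [str(s) for s in self.samples]
        self.wavelengths = _as_float_array(self.wavelengths, "wavelengths")
        self.values = _as_float_array(self.values, "values")
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x wavelengths)")
        i, j = self.values.shape
        if i < 1 or j < 1:
            raise ValueError("SpectraMatrix must be non-empty")
        if len(self.samples) != i:
            raise ValueError("sample labels must match row count")
        if self.wavelengths.size != j:
            raise ValueError("wavelength grid must match column count")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.values.shape[1]

    def row(self, i: int) -> Spectrum:
        return Spectrum(self.wavelengths, self.values[i], label=self.samples[i])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.samples, columns=self.wavelengths
        )

    @classmethod
    def from_rows(cls, spectra: Sequence[Spectrum]) -> "SpectraMatrix":
        if not spectra:
            raise ValueError("need at least one spectrum")
        grid = spectra[0].wavelengths
        for s in spectra[1:]:
            if not np.array_equal(s.wavelengths, grid):
                raise ValueError("all spectra must share one wavelength grid")
        return cls(
            samples=[s.label or str(k) for k, s in enumerate(spectra)],
            wavelengths=grid.copy(),
            values=np.vstack([s.absorbances for s in spectra]),
        )


@dataclass
class ConcentrationTable:
    """Per-sample component concentrations (I x F, ug/mL)."""

    samples: list[str]
    components: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.samples = [str(s) for s in self.samples]
        self.components = [str(c) for c in self.components]
        if not self.components:
            raise ValueError("component list must be non-empty")
        self.values = _as_float_array(self.values, "values")
        if self.values.ndim == 1:
            self.values = self.values.reshape(-1, 1)
        if self.values.shape != (len(self.samples), len(self.components)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.samples)} samples x {len(self.components)} components"
            )
        if np.any(self.values < 0):
            raise ValueError("concentrations must be non-negative")

    def column(self, component: str) -> np.ndarray:
        """Concentration vector (ug/mL) of one named component."""
        try:
            j = self.components.index(component)
        except ValueError:
            raise KeyError(
                f"unknown component {component!r}; have {self.components}"
            ) from None
        return self.values[:, j]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.samples, columns=self.components
        )


# ---------------------------------------------------------------------------
# Delimited-text readers/writers
# ---------------------------------------------------------------------------

def read_spectra_csv(path, delimiter: str = ",") -> SpectraMatrix:
    """Read a spectra table: header = wavelengths (nm), rows = samples (AU).

    An optional leading non-numeric header cell labels the sample-id
    column; rows may or may not carry a leading label.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=delimiter, header=0, index_col=None,
                         float_precision="round_trip")
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise SpectraFormatError(f"{path}: {exc}") from exc
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise SpectraFormatError(f"{path}: no data rows")

    columns = list(df.columns)
    labels: list[str]
    try:
        float(str(columns[0]))
        has_label_col = False
    except ValueError:
        has_label_col = True
    if has_label_col:
        labels = [str(v) for v in df.iloc[:, 0]]
        df = df.iloc[:, 1:]
        columns = columns[1:]
    else:
        labels = [str(i) for i in range(len(df))]

    try:
        grid = np.array([float(str(c)) for c in columns])
    except ValueError as exc:
        raise SpectraFormatError(
            f"{path}: non-numeric wavelength header {exc}"
        ) from exc
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, cell in enumerate(df[col]):
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise SpectraFormatError(
                    f"{path}: non-numeric absorbance at row {i + 1}, "
                    f"column {columns[j]!r}: {cell!r}"
                ) from None
    return SpectraMatrix(samples=labels, wavelengths=grid, values=values)


def write_spectra_csv(matrix: SpectraMatrix, path, delimiter: str = ",") -> None:
    """Write a spectra table readable by :func:`read_spectra_csv`."""
    df = matrix.to_dataframe()
    df.index.name = "sample"
    # repr() emits the shortest exact decimal, so round-trips are bitwise
    df.to_csv(path, sep=delimiter, float_format=lambda v: repr(float(v)))


def read_concentration_csv(path, delimiter: str = ",") -> ConcentrationTable:
    """Read a concentration table: header = component names, values ug/mL."""
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, header=0, index_col=0,
                     float_precision="round_trip")
    if df.shape[1] == 0:
        raise SpectraFormatError(f"{path}: no component columns")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise SpectraFormatError(f"{path}: non-numeric concentration: {exc}") from exc
    return ConcentrationTable(
        samples=[str(s) for s in df.index],
        components=[str(c) for c in df.columns],
        values=values,
    )


def write_concentration_table(
    table: ConcentrationTable, path, delimiter: str = ","
) -> None:
    """Write a concentration table readable by :func:`read_concentration_csv`."""
    df = table.to_dataframe()
    df.index.name = "sample"
    df.to_csv(path, sep=delimiter, float_format=lambda v: repr(float(v)))


# ---------------------------------------------------------------------------
# JCAMP-DX (4.24 subset: single block, AFFN (X++(Y..Y)))
# ---------------------------------------------------------------------------

_LDR = re.compile(r"^##\s*([^=]+?)\s*=\s*(.*)$")

# SQZ/DIF/DUP compressed ordinates start with these marker characters
_COMPRESSED = set("@ABCDEFGHIabcdefghiJKLMNOPQRSjklmnopqrs%TUVWXYZtuvwxyz")


def read_jcampdx(path) -> Spectrum:
    """Read a single-block JCAMP-DX UV spectrum (AFFN ``(X++(Y..Y))`` only).

    FIRSTX/LASTX/NPOINTS define the abscissa; ordinates are scaled by
    YFACTOR.  Compressed dialects (SQZ/DIF/DUP) are rejected explicitly.
    """
    path = Path(path)
    text = path.read_text()
    fields: dict[str, str] = {}
    data_lines: list[str] = []
    in_data = False
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        m = _LDR.match(line)
        if m:
            key = m.group(1).upper().replace(" ", "")
            if key == "XYDATA":
                in_data = True
                fields[key] = m.group(2).strip()
                continue
            if key == "END":
                in_data = False
                continue
            in_data = False
            fields[key] = m.group(2).strip()
        elif in_data:
            data_lines.append(line)

    if "XYDATA" not in fields:
        raise SpectraFormatError(f"{path}: missing ##XYDATA record")
    form = fields["XYDATA"].replace(" ", "")
    if form not in {"(X++(Y..Y))"}:
        raise SpectraFormatError(f"{path}: unsupported XYDATA form {form!r}")

    def _need(key: str) -> float:
        if key not in fields:
            raise SpectraFormatError(f"{path}: missing ##{key}")
        return float(fields[key])

    firstx = _need("FIRSTX")
    lastx = _need("LASTX")
    npoints = int(_need("NPOINTS"))
    yfactor = float(fields.get("YFACTOR", "1"))
    xfactor = float(fields.get("XFACTOR", "1"))

    ys: list[float] = []
    for line in data_lines:
        if any(ch in _COMPRESSED for ch in line):
            raise SpectraFormatError(
                f"{path}: compressed (SQZ/DIF/DUP) ordinates are not supported"
            )
        tokens = line.replace(",", " ").split()
        if not tokens:
            continue
        # first token is the line's starting X (AFFN), remaining are Ys
        ys.extend(float(t) for t in tokens[1:])

    if len(ys) != npoints:
        raise SpectraFormatError(
            f"{path}: NPOINTS={npoints} but decoded {len(ys)} ordinates"
        )
    x = np.linspace(firstx * xfactor, lastx * xfactor, npoints)
    y = np.asarray(ys, dtype=float) * yfactor
    label = fields.get("TITLE", path.stem)
    return Spectrum(wavelengths=x, absorbances=y, label=label)
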