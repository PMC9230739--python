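"""Data model and I/O for ATR-IR spectra.

The central container is :class:`SpectrumSet`: a set of absorbance traces
sharing one wavenumber grid, optionally carrying a per-sample reference
analyte content (mg per dosage unit).  All modelling operates on this pair
(the ``X`` matrix and ``y`` vector of multivariate calibration).

Conventions
-----------
* Wavenumbers are in cm⁻¹ and stored in strictly ascending order, even
  though FTIR software usually plots them descending; readers normalize.
* No resampling is ever performed: combining spectra measured on different
  grids is an error, not an implicit interpolation.
* Interval bounds are inclusive on both ends, so a selection written
  "500–1700, 2500–4000" keeps the 1700 and 2500 cm⁻¹ points.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError, FormatError, SelectionError

__all__ = [
    "WavenumberGrid",
    "Spectrum",
    "SpectrumSet",
    "IntervalSelection",
    "read_csv_spectra",
    "write_csv_spectra",
    "read_jcamp",
    "read_reference_table",
    "select_intervals",
]

#: sanity bounds on wavenumbers, cm⁻¹ (mid-IR instruments live well inside)
_WN_LO, _WN_HI = 100.0, 8000.0

WIDE_WN_COLUMN = "wavenumber_cm-1"


@dataclass(frozen=True)
class WavenumberGrid:
    """A strictly increasing wavenumber axis in cm⁻¹."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size == 0:
            raise DataError("wavenumber grid must be a non-empty 1-D array")
        if not np.all(np.isfinite(values)):
            raise DataError("wavenumber grid contains non-finite values")
        if np.any(np.diff(values) <= 0):
            raise DataError("wavenumber grid must be strictly increasing")
        if values[0] < _WN_LO or values[-1] > _WN_HI:
            raise DataError(
                f"wavenumbers outside the sane range [{_WN_LO}, {_WN_HI}] cm-1"
            )

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def spacing(self) -> np.ndarray:
        return np.diff(self.values)

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        """True when the grid spacing is constant to relative tolerance ``rtol``."""
        d = self.spacing
        if d.size == 0:
            return True
        return bool(np.all(np.abs(d - d[0]) <= rtol * abs(d[0])))


@dataclass(frozen=True)
class Spectrum:
    """One absorbance trace with its grid and optional sample annotations."""

    sample_id: str
    grid: WavenumberGrid
    absorbance: np.ndarray
    form: str | None = None  # "tablet" | "granule"
    strength_label: float | None = None  # nominal content, mg/unit

    def __post_init__(self) -> None:
        absorbance = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "absorbance", absorbance)
        if absorbance.shape != (len(self.grid),) :
            raise DataError(
                f"spectrum {self.sample_id!r}: absorbance length "
                f"{absorbance.size} != grid length {len(self.grid)}"
            )
        if not np.all(np.isfinite(absorbance)):
            raise DataError(f"spectrum {self.sample_id!r}: non-finite intensities")


@dataclass
class SpectrumSet:
    """Samples × wavenumbers absorbance matrix on a shared grid.

    Parameters
    ----------
    grid
        Common wavenumber axis.
    matrix
        Shape ``(n_samples, len(grid))`` absorbance matrix.
    sample_ids
        Unique sample identifiers, one per row.
    reference
        Optional per-sample analyte content (mg/unit), e.g. HPLC assays.
    metadata
        Optional per-sample annotations (``form``, ``nominal_mg``,
        ``true_mg``...) indexed like ``sample_ids``.
    """

    grid: WavenumberGrid
    matrix: np.ndarray
    sample_ids: list[str]
    reference: np.ndarray | None = None
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.matrix.ndim != 2:
            raise DataError("matrix must be 2-D (samples x wavenumbers)")
        if self.matrix.shape[1] != len(self.grid):
            raise DataError(
                f"matrix has {self.matrix.shape[1]} columns but grid has "
                f"{len(self.grid)} points"
            )
        if self.matrix.shape[0] != len(self.sample_ids):
            raise DataError("one sample_id required per matrix row")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataError("sample_ids must be unique")
        if not np.all(np.isfinite(self.matrix)):
            raise DataError("matrix contains non-finite intensities")
        if self.reference is not None:
            self.reference = np.asarray(self.reference, dtype=float)
            if self.reference.shape != (self.n_samples,):
                raise DataError("reference must hold one value per sample")
            if not np.all(np.isfinite(self.reference)):
                raise DataError("reference values must be finite")
        if self.metadata is not None and len(self.metadata) != self.n_samples:
            raise DataError("metadata must hold one row per sample")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def wavenumbers(self) -> np.ndarray:
        return self.grid.values

    def with_reference(self, reference: Sequence[float]) -> "SpectrumSet":
        return replace(self, reference=np.asarray(reference, dtype=float))

    def subset(self, ids: Sequence[str]) -> "SpectrumSet":
        """Rows restricted to ``ids``, in the order given."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise DataError(f"unknown sample ids: {missing[:5]}")
        rows = [index[s] for s in ids]
        return SpectrumSet(
            grid=self.grid,
            matrix=self.matrix[rows],
            sample_ids=[self.sample_ids[i] for i in rows],
            reference=None if self.reference is None else self.reference[rows],
            metadata=None if self.metadata is None else self.metadata.iloc[rows].reset_index(drop=True),
        )


@dataclass(frozen=True)
class IntervalSelection:
    """A union of inclusive wavenumber intervals, e.g. (500, 1700) + (2500, 4000)."""

    intervals: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        pairs = tuple((float(lo), float(hi)) for lo, hi in self.intervals)
        object.__setattr__(self, "intervals", pairs)
        if not pairs:
            raise DataError("at least one interval is required")
        for lo, hi in pairs:
            if not lo < hi:
                raise DataError(f"interval ({lo}, {hi}) must satisfy lo < hi")
        ordered = sorted(pairs)
        for (_, hi_prev), (lo_next, _) in zip(ordered, ordered[1:]):
            if lo_next <= hi_prev:
                raise DataError("intervals overlap after sorting")

    def mask(self, wavenumbers: np.ndarray) -> np.ndarray:
        w = np.asarray(wavenumbers, dtype=float)
        keep = np.zeros(w.shape, dtype=bool)
        for lo, hi in self.intervals:
            keep |= (w >= lo) & (w <= hi)
        return keep

    def __str__(self) -> str:
        return ", ".join(f"{lo:g}-{hi:g}" for lo, hi in sorted(self.intervals))


def select_intervals(sset: SpectrumSet, sel: IntervalSelection) -> SpectrumSet:
    """Restrict a set to the grid points inside ``sel`` (inclusive bounds).

    Column order is preserved; the reference vector and metadata pass through
    unchanged.  Raises :class:`SelectionError` when no grid point survives.
    """
    keep = sel.mask(sset.wavenumbers)
    if not keep.any():
        raise SelectionError(f"no grid point falls inside intervals {sel}")
    return SpectrumSet(
        grid=WavenumberGrid(sset.wavenumbers[keep]),
        matrix=sset.matrix[:, keep],
        sample_ids=list(sset.sample_ids),
        reference=sset.reference,
        metadata=sset.metadata,
    )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_csv_spectra(path: str | Path, layout: str = "wide") -> SpectrumSet:
    """Read a spectrum set from CSV.

    ``wide`` layout: first column ``wavenumber_cm-1``, one column per sample.
    ``long`` layout: columns ``sample_id, wavenumber_cm-1, absorbance``.
    Descending grids are normalized to ascending with rows kept consistent.
    """
    path = Path(path)
    if layout not in ("wide", "long"):
        raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")
    try:
        frame = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"{path}: {exc}") from exc

    if layout == "long":
        required = {"sample_id", WIDE_WN_COLUMN, "absorbance"}
        if not required.issubset(frame.columns):
            raise FormatError(
                f"{path}: long layout needs columns {sorted(required)}"
            )
        try:
            wide = frame.pivot(index=WIDE_WN_COLUMN, columns="sample_id",
                               values="absorbance")
        except ValueError as exc:
            raise FormatError(f"{path}: duplicate (sample, wavenumber) pair") from exc
        if wide.isna().any().any():
            raise FormatError(f"{path}: ragged long table (missing pairs)")
        frame = wide.reset_index()
        # preserve first-appearance sample order rather than pandas' sort
        order = list(dict.fromkeys(frame.columns[1:]))
        frame = frame[[WIDE_WN_COLUMN] + order]

    if frame.shape[1] < 2:
        raise FormatError(f"{path}: need a wavenumber column plus >=1 sample")
    wn_col = frame.columns[0]
    wn = pd.to_numeric(frame[wn_col], errors="coerce")
    if wn.isna().any():
        raise FormatError(f"{path}: non-numeric wavenumber values")
    data = frame.iloc[:, 1:].apply(pd.to_numeric, errors="coerce")
    if data.isna().any().any():
        raise FormatError(f"{path}: missing or non-numeric absorbance cells")

    order = np.argsort(wn.to_numpy())
    wn_sorted = wn.to_numpy()[order]
    if np.any(np.diff(wn_sorted) <= 0):
        raise DataError(f"{path}: duplicate wavenumbers in grid")
    return SpectrumSet(
        grid=WavenumberGrid(wn_sorted),
        matrix=data.to_numpy().T[:, order],
        sample_ids=[str(c) for c in data.columns],
    )


def write_csv_spectra(sset: SpectrumSet, path: str | Path,
                      layout: str = "wide") -> None:
    """Write a spectrum set as CSV (inverse of :func:`read_csv_spectra`)."""
    path = Path(path)
    if layout == "wide":
        frame = pd.DataFrame(sset.matrix.T, columns=sset.sample_ids)
        frame.insert(0, WIDE_WN_COLUMN, sset.wavenumbers)
        frame.to_csv(path, index=False)
    elif layout == "long":
        records = pd.DataFrame({
            "sample_id": np.repeat(sset.sample_ids, len(sset.grid)),
            WIDE_WN_COLUMN: np.tile(sset.wavenumbers, sset.n_samples),
            "absorbance": sset.matrix.ravel(),
        })
        records.to_csv(path, index=False)
    else:
        raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")


def read_reference_table(path: str | Path) -> pd.DataFrame:
    """Read a reference-value table: ``sample_id, form, nominal_mg, reference_mg``."""
    frame = pd.read_csv(path)
    required = {"sample_id", "reference_mg"}
    if not required.issubset(frame.columns):
        raise FormatError(f"{path}: reference table needs columns {sorted(required)}")
    frame["sample_id"] = frame["sample_id"].astype(str)
    if frame["sample_id"].duplicated().any():
        raise DataError(f"{path}: duplicate sample ids in reference table")
    return frame


# ---------------------------------------------------------------------------
# JCAMP-DX
# ---------------------------------------------------------------------------

_AFFN_TOKEN = re.compile(r"[+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?")
# SQZ/DIF/DUP compressed ordinates use letters as pseudo-digits
_COMPRESSED = re.compile(r"[@A-DF-Za-df-z%]")


def read_jcamp(path: str | Path) -> Spectrum:
    """Read a single-spectrum JCAMP-DX file (AFFN ``##XYDATA``/``##XYPOINTS``).

    Transmittance records are converted to absorbance via ``-log10(T)``
    (percent transmittance is detected by values exceeding 1.5 and divided
    by 100 first).  Compressed ordinate dialects (SQZ/DIF/DUP) are not
    supported and raise :class:`FormatError`.
    """
    path = Path(path)
    text = path.read_text()
    labels: dict[str, str] = {}
    data_lines: list[str] = []
    mode: str | None = None
    for raw in text.splitlines():
        line = raw.split("$$")[0].rstrip()  # strip JCAMP comments
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            value = value.strip()
            if key in ("XYDATA", "XYPOINTS"):
                mode = key
                labels[key] = value
                data_lines = []
            elif key == "END":
                break
            else:
                labels[key] = value
        elif mode is not None and line.strip():
            data_lines.append(line)

    if mode is None:
        raise FormatError(f"{path}: no ##XYDATA or ##XYPOINTS record")
    body = "\n".join(data_lines)
    if _COMPRESSED.search(body):
        raise FormatError(f"{path}: compressed JCAMP ordinates (SQZ/DIF/DUP) not supported")

    xfactor = float(labels.get("XFACTOR", "1"))
    yfactor = float(labels.get("YFACTOR", "1"))

    if mode == "XYPOINTS":
        tokens = _AFFN_TOKEN.findall(body)
        if len(tokens) < 4 or len(tokens) % 2:
            raise FormatError(f"{path}: XYPOINTS needs an even number of values")
        values = np.array(tokens, dtype=float)
        x, y = values[0::2] * xfactor, values[1::2] * yfactor
    else:  # XYDATA, (X++(Y..Y)) form: first number per line is X, rest are Y
        xs: list[float] = []
        ys: list[float] = []
        per_line: list[int] = []
        for line in data_lines:
            tokens = _AFFN_TOKEN.findall(line)
            if len(tokens) < 2:
                raise FormatError(f"{path}: XYDATA line with no ordinates")
            xs.append(float(tokens[0]))
            ys.extend(float(t) for t in tokens[1:])
            per_line.append(len(tokens) - 1)
        # reconstruct the abscissa from the per-line start values
        x = np.empty(sum(per_line))
        y = np.array(ys)
        pos = 0
        for i, count in enumerate(per_line):
            x0 = xs[i] * xfactor
            if i + 1 < len(xs):
                x1 = xs[i + 1] * xfactor
                step = (x1 - x0) / count
            elif "LASTX" in labels and count > 1:
                step = (float(labels["LASTX"]) - x0) / (count - 1)
            elif "DELTAX" in labels:
                step = float(labels["DELTAX"])
            elif pos > 0:
                step = x[pos - 1] - x[pos - 2]
            else:
                step = 1.0
            x[pos:pos + count] = x0 + step * np.arange(count)
            pos += count
        y = y * yfactor

    yunits = labels.get("YUNITS", "ABSORBANCE").upper()
    if "TRANSMITTANCE" in yunits:
        if np.nanmax(y) > 1.5:  # percent transmittance
            y = y / 100.0
        if np.any(y <= 0):
            raise DataError(f"{path}: non-positive transmittance cannot convert")
        y = -np.log10(y)

    order = np.argsort(x)
    x, y = x[order], y[order]
    if np.any(np.diff(x) <= 0):
        raise DataError(f"{path}: duplicate abscissa values")
    return Spectrum(
        sample_id=labels.get("TITLE", path.stem) or path.stem,
        grid=WavenumberGrid(x),
        absorbance=y,
    )
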