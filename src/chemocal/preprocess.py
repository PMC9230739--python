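"""Spectral pretreatment operators and their ordered composition.

Three operators cover the pretreatment menu of the calibration workflow:

* **SNV** (standard normal variate): per-spectrum centering and scaling to
  unit sample standard deviation; corrects multiplicative scatter.
* **Area normalization**: division by the sum of absolute intensities, a
  discrete total-area proxy (the constant grid-spacing factor cancels in
  PLSR after centering).
* **Savitzky–Golay derivatives**: local least-squares polynomial first or
  second derivatives, scaled by the grid spacing so results are true
  d/d(cm⁻¹) and grid-independent.  Edges are handled by evaluating the
  polynomial fitted to the first/last full window, so the matrix width never
  changes and interval bookkeeping never shifts.

A :class:`PreprocessSpec` is an ordered recipe; the notation "A + B" is read
left to right (A first, then B) and serializes to strings like
``area_norm+snv`` or ``snv+d1(poly=2,window=11)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Sequence, Union

import numpy as np
from scipy.signal import savgol_filter

from .errors import DegenerateSpectrumError, GridSpacingError, ParameterError
from .spectra_core import SpectrumSet, WavenumberGrid

__all__ = [
    "AreaNorm",
    "SNV",
    "SGDerivative",
    "PreprocessSpec",
    "snv",
    "area_normalize",
    "sg_derivative",
    "apply_pipeline",
]


@dataclass(frozen=True)
class AreaNorm:
    def __str__(self) -> str:
        return "area_norm"


@dataclass(frozen=True)
class SNV:
    def __str__(self) -> str:
        return "snv"


@dataclass(frozen=True)
class SGDerivative:
    derivative_order: int
    polynomial_order: int = 2
    window_points: int = 11

    def __post_init__(self) -> None:
        if self.derivative_order not in (1, 2):
            raise ParameterError("derivative_order must be 1 or 2")
        if self.polynomial_order < self.derivative_order:
            raise ParameterError("polynomial_order must be >= derivative_order")
        if self.window_points % 2 == 0 or self.window_points <= self.polynomial_order:
            raise ParameterError(
                "window_points must be odd and exceed polynomial_order"
            )

    def __str__(self) -> str:
        return (f"d{self.derivative_order}"
                f"(poly={self.polynomial_order},window={self.window_points})")


Step = Union[AreaNorm, SNV, SGDerivative]

_STEP_RE = re.compile(
    r"^(?:(area_norm)|(snv)|d([12])(?:\(poly=(\d+),\s*window=(\d+)\))?)$"
)


@dataclass(frozen=True)
class PreprocessSpec:
    """An ordered pretreatment recipe applied row-wise to a spectrum set."""

    steps: tuple[Step, ...] = ()

    @classmethod
    def parse(cls, text: str) -> "PreprocessSpec":
        """Parse notation like ``"area_norm+snv"`` or ``"snv+d1(poly=2,window=11)"``.

        ``"original"`` (or an empty string) means no pretreatment.
        """
        text = text.strip().lower()
        if text in ("", "original", "none"):
            return cls(())
        steps: list[Step] = []
        for part in text.split("+"):
            m = _STEP_RE.match(part.strip())
            if m is None:
                raise ParameterError(f"unrecognized pretreatment step {part!r}")
            if m.group(1):
                steps.append(AreaNorm())
            elif m.group(2):
                steps.append(SNV())
            else:
                poly = int(m.group(4)) if m.group(4) else 2
                window = int(m.group(5)) if m.group(5) else 11
                steps.append(SGDerivative(int(m.group(3)), poly, window))
        return cls(tuple(steps))

    def __str__(self) -> str:
        return "+".join(str(s) for s in self.steps) if self.steps else "original"


def snv(x: np.ndarray) -> np.ndarray:
    """Standard normal variate: ``(x - mean) / sd`` with the sample (n−1) sd."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ParameterError("SNV needs at least 2 points")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateSpectrumError("constant spectrum has no variance for SNV")
    return (x - x.mean()) / sd


def area_normalize(x: np.ndarray) -> np.ndarray:
    """Divide by the sum of absolute intensities so Σ|output| = 1."""
    x = np.asarray(x, dtype=float)
    total = np.abs(x).sum()
    if total == 0:
        raise DegenerateSpectrumError("all-zero spectrum has no area")
    return x / total


def _uniform_segments(grid: WavenumberGrid, rtol: float = 1e-6
                      ) -> list[tuple[int, int]]:
    """Split the grid at spacing jumps into contiguous evenly spaced blocks.

    A grid produced by selecting disjoint wavenumber intervals from one
    instrument axis is uniform within each interval but has a jump between
    them; derivatives are taken per block.  A genuinely uneven grid (no
    uniform blocks) raises :class:`GridSpacingError`.
    """
    w = grid.values
    if len(w) == 1:
        return [(0, 1)]
    d = np.diff(w)
    base = d[0]
    segments: list[tuple[int, int]] = []
    start = 0
    for i in range(1, len(d)):
        if abs(d[i] - base) > rtol * abs(base):
            if d[i] < base * (1 - rtol):
                raise GridSpacingError(
                    "Savitzky-Golay derivatives need an evenly spaced grid"
                )
            segments.append((start, i + 1))
            start = i + 1
            if start < len(w) - 1:
                base = d[start]
    segments.append((start, len(w)))
    return segments


def sg_derivative(x: np.ndarray, grid: WavenumberGrid, derivative_order: int,
                  polynomial_order: int = 2, window_points: int = 11) -> np.ndarray:
    """Savitzky–Golay derivative per cm⁻¹ on an evenly spaced grid.

    Works on a single spectrum (1-D) or a sample-by-wavenumber matrix (2-D,
    filtered along the last axis).  A grid assembled from disjoint intervals
    of one instrument axis is differentiated per contiguous block; spacing
    that shrinks mid-grid is treated as genuinely uneven and rejected.
    """
    step = SGDerivative(derivative_order, polynomial_order, window_points)
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    segments = _uniform_segments(grid)
    for start, stop in segments:
        if stop - start < step.window_points:
            if len(segments) > 1:
                raise GridSpacingError(
                    "grid is uneven (or an interval block is shorter than "
                    f"the {step.window_points}-point filter window)"
                )
            raise ParameterError(
                f"window of {step.window_points} points exceeds spectrum "
                f"length {stop - start}"
            )
        delta = float(grid.values[start + 1] - grid.values[start]) \
            if stop - start > 1 else 1.0
        out[..., start:stop] = savgol_filter(
            x[..., start:stop],
            window_length=step.window_points,
            polyorder=step.polynomial_order,
            deriv=step.derivative_order,
            delta=delta,
            mode="interp",  # edges: re-evaluate the edge-window polynomial
            axis=-1,
        )
    return out


def _apply_step(matrix: np.ndarray, grid: WavenumberGrid, step: Step,
                sample_ids: Sequence[str]) -> np.ndarray:
    if isinstance(step, SNV):
        sd = matrix.std(axis=1, ddof=1)
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            raise DegenerateSpectrumError(
                f"sample {sample_ids[bad[0]]!r}: constant spectrum in SNV"
            )
        return (matrix - matrix.mean(axis=1, keepdims=True)) / sd[:, None]
    if isinstance(step, AreaNorm):
        total = np.abs(matrix).sum(axis=1)
        bad = np.flatnonzero(total == 0)
        if bad.size:
            raise DegenerateSpectrumError(
                f"sample {sample_ids[bad[0]]!r}: zero-area spectrum"
            )
        return matrix / total[:, None]
    return sg_derivative(matrix, grid, step.derivative_order,
                         step.polynomial_order, step.window_points)


def apply_pipeline(sset: SpectrumSet, spec: PreprocessSpec) -> SpectrumSet:
    """Apply the recipe's steps in order to every spectrum of the set.

    The grid, sample order, reference vector and metadata are unchanged; only
    intensities transform.  An empty recipe is the identity.
    """
    matrix = sset.matrix
    for step in spec.steps:
        matrix = _apply_step(matrix, sset.grid, step, sset.sample_ids)
    return replace(sset, matrix=matrix)
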