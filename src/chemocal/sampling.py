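"""Calibration/validation set construction.

Two strategies are provided, matching common chemometric practice for this
kind of calibration study:

* :func:`kennard_stone` — deterministic max–min Euclidean selection that
  spreads the calibration set over the spectral space (extremes first).
* :func:`stratified_random_split` — seeded uniform sampling without
  replacement within each concentration stratum.

:func:`ks_split_by_stratum` runs Kennard–Stone independently inside each
stratum so the per-strength calibration/validation counts come out exactly
as designed (a global run would not guarantee balance).  Distances are
computed on the raw, un-pretreated spectra by default; pass an interval
selection to restrict them to a model's wavenumber range.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .errors import DesignError, ParameterError
from .spectra_core import IntervalSelection, SpectrumSet, select_intervals

__all__ = [
    "SplitResult",
    "kennard_stone",
    "stratified_random_split",
    "ks_split_by_stratum",
]


@dataclass(frozen=True)
class SplitResult:
    """A disjoint calibration/validation partition of a sample set."""

    calibration_ids: tuple[str, ...]
    validation_ids: tuple[str, ...]
    method: str  # "kennard_stone" | "stratified_random"
    seed: int | None = None

    def __post_init__(self) -> None:
        overlap = set(self.calibration_ids) & set(self.validation_ids)
        if overlap:
            raise DesignError(f"samples in both roles: {sorted(overlap)[:5]}")

    @property
    def all_ids(self) -> tuple[str, ...]:
        return self.calibration_ids + self.validation_ids

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample_id": list(self.all_ids),
            "role": ["calibration"] * len(self.calibration_ids)
                    + ["validation"] * len(self.validation_ids),
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, method: str = "unknown",
                 seed: int | None = None) -> "SplitResult":
        frame = pd.read_csv(path)
        cal = frame.loc[frame["role"] == "calibration", "sample_id"].astype(str)
        val = frame.loc[frame["role"] == "validation", "sample_id"].astype(str)
        return cls(tuple(cal), tuple(val), method=method, seed=seed)


def kennard_stone(matrix: np.ndarray, k: int) -> list[int]:
    """Kennard–Stone selection of ``k`` rows, returned in visiting order.

    The first two selections are the pair at maximal Euclidean distance; each
    subsequent selection maximizes its minimum distance to the already
    selected rows.  Ties are broken toward the lowest row index (for the
    initial pair: the lexicographically smallest index pair), making the
    algorithm fully deterministic without a seed.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ParameterError("matrix must be 2-D")
    n = matrix.shape[0]
    if not 2 <= k <= n:
        raise ParameterError(f"need 2 <= k <= n; got k={k}, n={n}")
    if not np.all(np.isfinite(matrix)):
        raise ParameterError("matrix must be finite")

    dist = squareform(pdist(matrix))
    # initial pair: maximal distance, ties -> smallest (i, j)
    iu = np.triu_indices(n, 1)
    flat = dist[iu]
    best = int(np.argmax(flat))  # argmax returns the first (lowest (i,j)) max
    i0, j0 = int(iu[0][best]), int(iu[1][best])
    selected = [i0, j0]

    min_dist = np.minimum(dist[i0], dist[j0])
    min_dist[selected] = -np.inf
    while len(selected) < k:
        nxt = int(np.argmax(min_dist))  # first max -> lowest-index tie-break
        selected.append(nxt)
        min_dist = np.minimum(min_dist, dist[nxt])
        min_dist[nxt] = -np.inf
    return selected


def stratified_random_split(sample_ids: Sequence[str],
                            strata_labels: Sequence,
                            per_stratum_calibration: int,
                            seed: int) -> SplitResult:
    """Draw ``per_stratum_calibration`` calibration samples per stratum.

    Sampling is uniform without replacement from a :func:`numpy.random.default_rng`
    seeded generator; the remainder of every stratum goes to validation.
    """
    sample_ids = [str(s) for s in sample_ids]
    if len(sample_ids) != len(strata_labels):
        raise ParameterError("one stratum label required per sample")
    rng = np.random.default_rng(seed)
    cal: list[str] = []
    val: list[str] = []
    for label in _unique_in_order(strata_labels):
        members = [s for s, lab in zip(sample_ids, strata_labels) if lab == label]
        if len(members) < per_stratum_calibration:
            raise DesignError(
                f"stratum {label!r} has {len(members)} samples; "
                f"{per_stratum_calibration} requested for calibration"
            )
        chosen = rng.choice(len(members), size=per_stratum_calibration,
                            replace=False)
        chosen_set = set(int(i) for i in chosen)
        cal.extend(members[i] for i in sorted(chosen_set))
        val.extend(m for i, m in enumerate(members) if i not in chosen_set)
    return SplitResult(tuple(cal), tuple(val),
                       method="stratified_random", seed=seed)


def ks_split_by_stratum(sset: SpectrumSet,
                        strata_labels: Sequence,
                        per_stratum_calibration: int,
                        intervals: IntervalSelection | None = None) -> SplitResult:
    """Kennard–Stone applied independently within each stratum.

    Distances use the raw absorbance spectra (restricted to ``intervals``
    when given); the per-stratum calibration count is exact.
    """
    if len(strata_labels) != sset.n_samples:
        raise ParameterError("one stratum label required per sample")
    working = sset if intervals is None else select_intervals(sset, intervals)
    cal: list[str] = []
    val: list[str] = []
    for label in _unique_in_order(strata_labels):
        rows = [i for i, lab in enumerate(strata_labels) if lab == label]
        ids = [sset.sample_ids[i] for i in rows]
        if len(rows) < per_stratum_calibration:
            raise DesignError(
                f"stratum {label!r} has {len(rows)} samples; "
                f"{per_stratum_calibration} requested for calibration"
            )
        if per_stratum_calibration == len(rows):
            picked = list(range(len(rows)))
        else:
            picked = kennard_stone(working.matrix[rows], per_stratum_calibration)
        picked_set = set(picked)
        cal.extend(ids[i] for i in sorted(picked_set))
        val.extend(ids[i] for i in range(len(rows)) if i not in picked_set)
    return SplitResult(tuple(cal), tuple(val), method="kennard_stone")


def _unique_in_order(labels: Sequence) -> list:
    return list(dict.fromkeys(labels))
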