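"""Model-grid orchestration: enumerate, run and rank candidate calibrations.

A :class:`ModelConfig` pins one combination of spectral range, pretreatment
recipe and latent-factor search cap.  :func:`builtin_grid` returns the two
standard grids for this assay — 13 tablet configurations and 11 granule
configurations spanning full-range vs selected-interval models and the
original / derivative / SNV / area-normalized pretreatment menu.

:func:`run_grid` runs every configuration against one calibration/validation
split (interval selection → pretreatment → CV factor choice → final fit →
external validation) and :func:`select_best` ranks the metric rows by a
composite rank-sum over R²(model), R²(Pearson), RMSEP and |bias|.  The
default weights double |bias| — accuracy is the decisive criterion between
otherwise comparable models; equal weights are one argument away.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import rankdata

from .errors import ChemocalError, DesignError, ParameterError
from .evaluation import (ModelMetrics, bias, r2_model, r2_pearson, rmsep)
from .plsr_engine import (PLSRModel, cross_validate, fit_plsr, predict,
                          select_n_factors)
from .preprocess import PreprocessSpec, apply_pipeline
from .sampling import SplitResult
from .spectra_core import IntervalSelection, SpectrumSet, select_intervals

__all__ = [
    "ModelConfig",
    "GridRow",
    "GridResult",
    "builtin_grid",
    "run_grid",
    "select_best",
    "grid_to_yaml",
    "grid_from_yaml",
    "DEFAULT_RANK_WEIGHTS",
]

DEFAULT_RANK_WEIGHTS = {
    "r2_model": 1.0,
    "r2_pearson": 1.0,
    "rmsep": 1.0,
    "bias": 2.0,
}


@dataclass(frozen=True)
class ModelConfig:
    """One candidate calibration: range + pretreatment + factor policy.

    ``pinned_factors`` bypasses cross-validation with a fixed factor count
    (useful to reproduce an externally chosen complexity).
    """

    config_id: int
    intervals: IntervalSelection
    preprocess: PreprocessSpec
    max_factors: int = 12
    pinned_factors: int | None = None

    def __post_init__(self) -> None:
        if self.max_factors < 1:
            raise ParameterError("max_factors must be >= 1")
        if self.pinned_factors is not None and self.pinned_factors < 1:
            raise ParameterError("pinned_factors must be >= 1")


@dataclass(frozen=True)
class GridRow:
    config: ModelConfig
    n_factors: int | None
    metrics: ModelMetrics | None
    model: PLSRModel | None
    error: str | None = None


@dataclass(frozen=True)
class GridResult:
    rows: tuple[GridRow, ...]
    best_config_id: int

    def to_frame(self) -> pd.DataFrame:
        """Report table, one row per configuration (column order mirrors the
        conventional model-grid report: range, pretreatment, factors, R²s,
        errors, bias)."""
        records = []
        for row in self.rows:
            rec = {
                "config_id": row.config.config_id,
                "spectral_range": str(row.config.intervals),
                "pretreatment": str(row.config.preprocess),
                "latent_factors": row.n_factors,
            }
            if row.metrics is not None:
                m = row.metrics
                rec.update(r2_model=m.r2_model, r2_cv=m.r2_cv,
                           r2_pearson=m.r2_pearson, rmsec=m.rmsec,
                           rmsecv=m.rmsecv, rmsep=m.rmsep, bias=m.bias,
                           n_validation=m.n, error="")
            else:
                rec.update(r2_model=np.nan, r2_cv=np.nan, r2_pearson=np.nan,
                           rmsec=np.nan, rmsecv=np.nan, rmsep=np.nan,
                           bias=np.nan, n_validation=0, error=row.error or "")
            records.append(rec)
        return pd.DataFrame(records)

    def best_row(self) -> GridRow:
        for row in self.rows:
            if row.config.config_id == self.best_config_id:
                return row
        raise ChemocalError("best_config_id not found among rows")


def _cfg(config_id: int, intervals: list[tuple[float, float]],
         pretreat: str, max_factors: int = 12) -> ModelConfig:
    return ModelConfig(config_id=config_id,
                       intervals=IntervalSelection(tuple(intervals)),
                       preprocess=PreprocessSpec.parse(pretreat),
                       max_factors=max_factors)


def builtin_grid(form: str) -> list[ModelConfig]:
    """The standard model grids for this assay.

    Tablets: 13 configurations over ranges {400–4000, 2700–4000, 500–1700,
    2500–4000, 500–1700 + 2500–4000} and pretreatments {original, D2,
    area-normalized, area-normalized + SNV, D1, D1 + SNV} (derivatives at
    poly 2 / 11 points).  Granules: 11 configurations over {400–3700,
    400–1700 + 2800–3700} with {original, SNV, area normalization, SNV + D1}
    — the SNV + D1 rows sweep the derivative's polynomial order / window over
    (2,11), (2,21), (3,11), (3,21), (4,11), (4,21).
    """
    full_t = [(400.0, 4000.0)]
    if form == "tablet":
        return [
            _cfg(1, full_t, "original"),
            _cfg(2, full_t, "d2(poly=2,window=11)"),
            _cfg(3, full_t, "area_norm"),
            _cfg(4, full_t, "area_norm+snv"),
            _cfg(5, [(2700.0, 4000.0)], "area_norm+snv"),
            _cfg(6, full_t, "d1(poly=2,window=11)"),
            _cfg(7, full_t, "d1(poly=2,window=11)+snv"),
            _cfg(8, [(500.0, 1700.0)], "d2(poly=2,window=11)"),
            _cfg(9, [(2500.0, 4000.0)], "d2(poly=2,window=11)"),
            _cfg(10, [(500.0, 1700.0), (2500.0, 4000.0)], "d2(poly=2,window=11)"),
            _cfg(11, [(500.0, 1700.0)], "area_norm+snv"),
            _cfg(12, [(2500.0, 4000.0)], "area_norm+snv"),
            _cfg(13, [(500.0, 1700.0), (2500.0, 4000.0)], "area_norm+snv"),
        ]
    if form == "granule":
        full_g = [(400.0, 3700.0)]
        split_g = [(400.0, 1700.0), (2800.0, 3700.0)]
        configs = [
            _cfg(1, full_g, "original"),
            _cfg(2, split_g, "original"),
            _cfg(3, full_g, "snv"),
            _cfg(4, split_g, "snv"),
            _cfg(5, full_g, "area_norm"),
        ]
        for i, (poly, window) in enumerate(
                [(2, 11), (2, 21), (3, 11), (3, 21), (4, 11), (4, 21)]):
            configs.append(_cfg(6 + i, full_g,
                                f"snv+d1(poly={poly},window={window})"))
        return configs
    raise ParameterError(f"form must be 'tablet' or 'granule', got {form!r}")


def run_grid(sset: SpectrumSet, split: SplitResult,
             configs: list[ModelConfig], cv_scheme: str = "auto",
             cv_segments: int = 10, cv_seed: int = 0,
             factor_rule: str = "min_rmsecv") -> GridResult:
    """Run every configuration against one split and assemble the report.

    Per configuration: interval selection → pretreatment → cross-validated
    factor choice on the calibration samples (unless pinned) → final fit →
    external validation metrics.  A configuration that fails (e.g. a
    degenerate pretreatment) is recorded as a failed row and the grid
    continues.
    """
    if sset.reference is None:
        raise DesignError("spectrum set needs reference values to run a grid")
    known = set(sset.sample_ids)
    unknown = [s for s in split.all_ids if s not in known]
    if unknown:
        raise DesignError(f"split refers to unknown samples: {unknown[:5]}")

    rows: list[GridRow] = []
    for config in configs:
        try:
            rows.append(_run_one(sset, split, config, cv_scheme,
                                 cv_segments, cv_seed, factor_rule))
        except ChemocalError as exc:
            rows.append(GridRow(config=config, n_factors=None, metrics=None,
                                model=None, error=str(exc)))
    frame = pd.DataFrame([
        {"config_id": r.config.config_id, "n_factors": r.n_factors,
         "r2_model": r.metrics.r2_model, "r2_pearson": r.metrics.r2_pearson,
         "rmsep": r.metrics.rmsep, "bias": r.metrics.bias}
        for r in rows if r.metrics is not None
    ])
    if frame.empty:
        raise DesignError("every grid configuration failed")
    best = select_best(frame)
    return GridResult(rows=tuple(rows), best_config_id=best)


def _run_one(sset: SpectrumSet, split: SplitResult, config: ModelConfig,
             cv_scheme: str, cv_segments: int, cv_seed: int,
             factor_rule: str) -> GridRow:
    selected = select_intervals(sset, config.intervals)
    treated = apply_pipeline(selected, config.preprocess)
    cal = treated.subset(list(split.calibration_ids))
    val = treated.subset(list(split.validation_ids))
    X_cal, y_cal = cal.matrix, cal.reference
    X_val, y_val = val.matrix, val.reference

    max_factors = min(config.max_factors, X_cal.shape[0] - 1, X_cal.shape[1])
    if config.pinned_factors is not None:
        n_factors = config.pinned_factors
        rmsecv_val = None
        r2_cv_val = None
    else:
        cv = cross_validate(X_cal, y_cal, max_factors, scheme=cv_scheme,
                            n_segments=cv_segments, seed=cv_seed)
        n_factors = select_n_factors(cv, rule=factor_rule)
        rmsecv_val = float(cv.rmsecv[n_factors - 1])
        r2_cv_val = float(cv.r2_cv[n_factors - 1])

    model = fit_plsr(X_cal, y_cal, n_factors)
    model.grid = treated.wavenumbers
    model.intervals = config.intervals
    model.preprocess = config.preprocess
    fitted = predict(model, X_cal)
    pred = predict(model, X_val)
    metrics = ModelMetrics(
        r2_model=r2_model(fitted, y_cal),
        r2_cv=r2_cv_val,
        r2_pearson=r2_pearson(pred, y_val),
        rmsec=rmsep(fitted, y_cal),
        rmsecv=rmsecv_val,
        rmsep=rmsep(pred, y_val),
        bias=bias(pred, y_val),
        n=int(y_val.size),
    )
    return GridRow(config=config, n_factors=n_factors, metrics=metrics,
                   model=model)


def select_best(rows: pd.DataFrame,
                weights: dict[str, float] | None = None) -> int:
    """Composite rank-sum model selection.

    Ranks (average ties) are ascending for RMSEP and |bias| (small is good)
    and descending for R²(model) and R²(Pearson) (large is good); the
    weighted rank sum is minimized.  Ties break toward fewer latent factors,
    then the lower config_id.  Default weights double |bias|.
    """
    required = {"config_id", "r2_model", "r2_pearson", "rmsep", "bias"}
    if not required.issubset(rows.columns):
        raise ParameterError(f"rows need columns {sorted(required)}")
    rows = rows.dropna(subset=sorted(required - {"config_id"}))
    if rows.empty:
        raise DesignError("no successful rows to select from")
    w = dict(DEFAULT_RANK_WEIGHTS)
    if weights:
        w.update(weights)
    composite = (
        w["r2_model"] * rankdata(-rows["r2_model"])
        + w["r2_pearson"] * rankdata(-rows["r2_pearson"])
        + w["rmsep"] * rankdata(rows["rmsep"])
        + w["bias"] * rankdata(rows["bias"].abs())
    )
    order = np.lexsort((
        rows["config_id"].to_numpy(),
        rows["n_factors"].to_numpy() if "n_factors" in rows.columns
        else np.zeros(len(rows)),
        composite,
    ))
    return int(rows["config_id"].to_numpy()[order[0]])


# ---------------------------------------------------------------------------
# Config file round-trip
# ---------------------------------------------------------------------------

def grid_to_yaml(configs: list[ModelConfig], path: str | Path | None = None) -> str:
    doc = [
        {
            "id": c.config_id,
            "intervals": [[lo, hi] for lo, hi in c.intervals.intervals],
            "preprocess": str(c.preprocess),
            "max_factors": c.max_factors,
            **({"pinned_factors": c.pinned_factors}
               if c.pinned_factors is not None else {}),
        }
        for c in configs
    ]
    text = yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def grid_from_yaml(source: str | Path) -> list[ModelConfig]:
    text = Path(source).read_text() if Path(str(source)).is_file() else str(source)
    doc = yaml.safe_load(text)
    configs = []
    for entry in doc:
        configs.append(ModelConfig(
            config_id=int(entry["id"]),
            intervals=IntervalSelection(
                tuple((float(lo), float(hi)) for lo, hi in entry["intervals"])),
            preprocess=PreprocessSpec.parse(entry["preprocess"]),
            max_factors=int(entry.get("max_factors", 12)),
            pinned_factors=(int(entry["pinned_factors"])
                            if entry.get("pinned_factors") is not None else None),
        ))
    ids = [c.config_id for c in configs]
    if len(set(ids)) != len(ids):
        raise ParameterError("config ids must be unique within a grid")
    return configs
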