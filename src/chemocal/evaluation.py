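"""Model evaluation: prediction errors, correlation measures and diagnostics.

The two headline error statistics follow the usual multivariate-calibration
definitions, with residuals ``e_i = ŷ_i − y_i,ref``:

    RMSEP = sqrt( Σ e_i² / n )          (root-mean-square error)
    bias  = Σ e_i / n                   (mean signed error)

so that ``RMSEP² = bias² + population variance of the residuals``.  The same
formula gives RMSEC on calibration fits and RMSECV on cross-validated
predictions.  R² comes in three flavours: calibration R² (1 − SS_res/SS_tot,
reported raw, can be negative for terrible models), cross-validated R², and
the squared Pearson correlation between predictions and reference values on
the external validation set.

Method agreement against the reference assay is assessed with a two-sided
paired t-test (a seeded permutation alternative is available), and residual
heteroscedasticity — spread growing with concentration — with a Spearman
rank correlation of |residual| vs reference, p-value by permutation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DataError, ParameterError

__all__ = [
    "ModelMetrics",
    "PairedComparison",
    "ResidualDiagnostics",
    "rmsep",
    "bias",
    "r2_pearson",
    "r2_model",
    "paired_comparison",
    "residual_diagnostics",
]


@dataclass(frozen=True)
class ModelMetrics:
    """The metric row reported for one calibration model."""

    r2_model: float
    r2_cv: float | None
    r2_pearson: float
    rmsec: float
    rmsecv: float | None
    rmsep: float
    bias: float
    n: int


@dataclass(frozen=True)
class PairedComparison:
    statistic: float
    p_value: float
    alpha: float
    verdict: str  # "no significant difference" | "significant difference"
    degenerate: bool = False


@dataclass(frozen=True)
class ResidualDiagnostics:
    residuals: np.ndarray
    hetero_stat: float  # Spearman rho of |residual| vs reference
    hetero_p: float     # permutation p-value


def _paired(pred, ref) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=float).ravel()
    ref = np.asarray(ref, dtype=float).ravel()
    if pred.size != ref.size:
        raise DataError(f"length mismatch: {pred.size} vs {ref.size}")
    return pred, ref


def rmsep(pred, ref) -> float:
    """Root-mean-square prediction error, sqrt(Σ(ŷ−y_ref)²/n)."""
    pred, ref = _paired(pred, ref)
    if pred.size == 0:
        raise DataError("need at least one pair")
    return float(np.sqrt(np.mean((pred - ref) ** 2)))


def bias(pred, ref) -> float:
    """Mean signed prediction error, Σ(ŷ−y_ref)/n."""
    pred, ref = _paired(pred, ref)
    if pred.size == 0:
        raise DataError("need at least one pair")
    return float(np.mean(pred - ref))


def r2_pearson(pred, ref) -> float:
    """Squared Pearson correlation between predictions and reference values."""
    pred, ref = _paired(pred, ref)
    if np.var(pred) == 0 or np.var(ref) == 0:
        raise DataError("zero variance: Pearson correlation undefined")
    r = stats.pearsonr(pred, ref).statistic
    return float(r * r)


def r2_model(fitted, ref) -> float:
    """Coefficient of determination 1 − SS_res/SS_tot (reported raw)."""
    fitted, ref = _paired(fitted, ref)
    ss_tot = float(np.sum((ref - ref.mean()) ** 2))
    if ss_tot == 0:
        raise DataError("zero total sum of squares: R² undefined")
    ss_res = float(np.sum((ref - fitted) ** 2))
    return 1.0 - ss_res / ss_tot


def paired_comparison(pred, ref, alpha: float = 0.05,
                      method: str = "t", n_permutations: int = 9999,
                      seed: int | None = 0) -> PairedComparison:
    """Two-sided paired test of H0: mean(ŷ − y_ref) = 0.

    ``method="t"`` is the default paired t-test; ``method="permutation"``
    uses a seeded sign-flip permutation of the differences.  Zero-variance
    differences are degenerate: reported as p = 1 with a warning.
    """
    pred, ref = _paired(pred, ref)
    if pred.size < 3:
        raise ParameterError("paired comparison needs n >= 3")
    diff = pred - ref
    if np.ptp(diff) == 0:
        warnings.warn("all paired differences identical; test degenerate",
                      stacklevel=2)
        return PairedComparison(statistic=float("nan"), p_value=1.0,
                                alpha=alpha, verdict="no significant difference",
                                degenerate=True)
    if method == "t":
        res = stats.ttest_rel(pred, ref)
        stat, p = float(res.statistic), float(res.pvalue)
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        observed = diff.mean()
        signs = rng.choice((-1.0, 1.0), size=(n_permutations, diff.size))
        perm_means = (signs * diff).mean(axis=1)
        p = float((1 + np.sum(np.abs(perm_means) >= abs(observed)))
                  / (n_permutations + 1))
        stat = float(observed)
    else:
        raise ParameterError(f"unknown method {method!r}")
    verdict = ("no significant difference" if p > alpha
               else "significant difference")
    return PairedComparison(statistic=stat, p_value=p, alpha=alpha,
                            verdict=verdict)


def residual_diagnostics(pred, ref, n_permutations: int = 999,
                         seed: int | None = 0) -> ResidualDiagnostics:
    """Quantitative heteroscedasticity check on validation residuals.

    Statistic: Spearman correlation between |residual| and the reference
    value.  Its p-value comes from permuting the residual-to-sample
    assignment ``n_permutations`` times with a seeded generator (two-sided).
    """
    pred, ref = _paired(pred, ref)
    if pred.size < 5:
        raise ParameterError("residual diagnostics need n >= 5")
    residuals = pred - ref
    abs_res = np.abs(residuals)
    observed = stats.spearmanr(abs_res, ref).statistic
    rng = np.random.default_rng(seed)
    # Spearman rho = Pearson on ranks, and permuting values permutes their
    # ranks, so rank once and correlate shuffled rank vectors (vectorized).
    r_abs = stats.rankdata(abs_res)
    r_ref = stats.rankdata(ref)
    r_abs_c = r_abs - r_abs.mean()
    r_ref_c = r_ref - r_ref.mean()
    denom = np.sqrt((r_abs_c ** 2).sum() * (r_ref_c ** 2).sum())
    if denom == 0:  # constant ranks: no association measurable
        return ResidualDiagnostics(residuals=residuals,
                                   hetero_stat=0.0, hetero_p=1.0)
    idx = rng.permuted(np.tile(np.arange(pred.size), (n_permutations, 1)), axis=1)
    perm_rho = (r_abs_c[idx] @ r_ref_c) / denom
    count = int(np.sum(np.abs(perm_rho) >= abs(observed) - 1e-12))
    p = (1 + count) / (n_permutations + 1)
    return ResidualDiagnostics(residuals=residuals,
                               hetero_stat=float(observed),
                               hetero_p=float(p))
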