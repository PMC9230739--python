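"""Partial least squares regression by NIPALS, with cross-validation.

The model relates a spectral matrix ``X`` (samples × wavenumbers) to a
single response ``y`` (analyte content, mg/unit) through a small number of
latent factors.  Factors are extracted sequentially from the column-mean
centered ``X`` and centered ``y`` (no variance scaling — the pretreatments
do the scaling work):

1. weight      ``w_a ∝ X'y``, normalized to unit length,
2. score       ``t_a = X w_a``,
3. x-loading   ``p_a = X't_a / t_a't_a``,
4. y-loading   ``q_a = y't_a / t_a't_a``,
5. deflation   ``X ← X − t_a p_a'``, ``y ← y − q_a t_a``.

With a univariate response the inner NIPALS iteration converges in a single
pass; the iteration loop (tolerance 1e-12, max 500) is retained as a guard
for degenerate inputs.  The regression vector in the original (centered)
variable space is ``b = W (P'W)⁻¹ q``, so predictions are
``ŷ = ȳ + (X_new − x̄) b``.

Model complexity (the number of factors) is chosen by cross-validation:
leave-one-out for small sets, seeded random segments otherwise, minimizing
RMSECV (ties toward fewer factors) or by a parsimony rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import CompatibilityError, DesignError, ParameterError, RankError
from .preprocess import PreprocessSpec
from .spectra_core import IntervalSelection

__all__ = [
    "PLSRModel",
    "CVResult",
    "fit_plsr",
    "predict",
    "cross_validate",
    "select_n_factors",
]

_NIPALS_TOL = 1e-12
_NIPALS_MAX_ITER = 500


@dataclass
class PLSRModel:
    """A fitted PLSR calibration.

    ``weights`` (W), ``x_loadings`` (P) are (n_features × n_factors);
    ``y_loadings`` (q) is (n_factors,).  ``regression_vector`` reproduces the
    factor model's fitted values exactly.  ``grid``, ``intervals`` and
    ``preprocess`` record how prediction inputs must be prepared; they are
    optional for bare-matrix use.
    """

    n_factors: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    regression_vector: np.ndarray
    scores: np.ndarray | None = None  # calibration scores T, kept for diagnostics
    grid: np.ndarray | None = None
    intervals: IntervalSelection | None = None
    preprocess: PreprocessSpec | None = None

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        return predict(self, X_new)

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        """Serialize to a single JSON document; a reloaded model re-predicts
        bit-identically (float64 round-trips through repr)."""
        doc = {
            "n_factors": self.n_factors,
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "regression_vector": self.regression_vector.tolist(),
            "grid": None if self.grid is None else self.grid.tolist(),
            "intervals": None if self.intervals is None
                         else [list(p) for p in self.intervals.intervals],
            "preprocess": None if self.preprocess is None else str(self.preprocess),
        }
        text = json.dumps(doc)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PLSRModel":
        text = Path(source).read_text() if Path(str(source)).is_file() else str(source)
        doc = json.loads(text)
        return cls(
            n_factors=doc["n_factors"],
            x_mean=np.array(doc["x_mean"], dtype=float),
            y_mean=float(doc["y_mean"]),
            weights=np.array(doc["weights"], dtype=float),
            x_loadings=np.array(doc["x_loadings"], dtype=float),
            y_loadings=np.array(doc["y_loadings"], dtype=float),
            regression_vector=np.array(doc["regression_vector"], dtype=float),
            grid=None if doc["grid"] is None else np.array(doc["grid"], dtype=float),
            intervals=None if doc["intervals"] is None
                      else IntervalSelection(tuple(tuple(p) for p in doc["intervals"])),
            preprocess=None if doc["preprocess"] is None
                       else PreprocessSpec.parse(doc["preprocess"]),
        )


@dataclass(frozen=True)
class CVResult:
    """Per-factor-count cross-validation summary (entries for 1..max_factors)."""

    rmsecv: np.ndarray  # (max_factors,)
    r2_cv: np.ndarray   # (max_factors,) = 1 - PRESS/SS_tot
    scheme: str

    def __post_init__(self) -> None:
        if len(self.rmsecv) != len(self.r2_cv) or len(self.rmsecv) == 0:
            raise ParameterError("rmsecv and r2_cv must be non-empty, equal length")


def _nipals(Xc: np.ndarray, yc: np.ndarray, n_factors: int
            ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Extract ``n_factors`` from centered data. Returns (W, P, q, T)."""
    n, p = Xc.shape
    W = np.empty((p, n_factors))
    P = np.empty((p, n_factors))
    q = np.empty(n_factors)
    T = np.empty((n, n_factors))
    X = Xc.copy()
    y = yc.copy()
    for a in range(n_factors):
        w = X.T @ y
        norm = np.linalg.norm(w)
        if norm <= 1e-14 * max(1.0, np.abs(X).max(initial=0.0)):
            raise RankError(
                f"no covariance left for factor {a + 1}; reduce n_factors"
            )
        w /= norm
        t = X @ w
        # univariate-y NIPALS converges in one pass; iterate as a guard
        for _ in range(_NIPALS_MAX_ITER):
            tt = t @ t
            if tt == 0:
                raise RankError(f"zero score variance at factor {a + 1}")
            q_a = (y @ t) / tt
            w_new = X.T @ (y * q_a)
            w_new /= np.linalg.norm(w_new)
            if np.linalg.norm(w_new - w) < _NIPALS_TOL:
                break
            w = w_new
            t = X @ w
        tt = t @ t
        p_a = X.T @ t / tt
        q_a = (y @ t) / tt
        X = X - np.outer(t, p_a)
        y = y - q_a * t
        W[:, a], P[:, a], q[a], T[:, a] = w, p_a, q_a, t
    return W, P, q, T


def _coefficients(W: np.ndarray, P: np.ndarray, q: np.ndarray,
                  n_factors: int | None = None) -> np.ndarray:
    """Regression vector(s) b = W (P'W)⁻¹ q in centered space.

    With ``n_factors=None`` returns a (p × A) matrix whose column a-1 is the
    coefficient vector using the first a factors (used by cross-validation).
    """
    A = q.size
    R = np.empty_like(W)  # R = W (P'W)^-1, built column by column
    PtW = P.T @ W  # unit upper triangular for NIPALS (diag = t't/t't)
    for a in range(A):
        r = W[:, a] - R[:, :a] @ PtW[:a, a]
        R[:, a] = r / PtW[a, a]
    if n_factors is not None:
        return R[:, :n_factors] @ q[:n_factors]
    return np.cumsum(R * q, axis=1)


def fit_plsr(X: np.ndarray, y: np.ndarray, n_factors: int) -> PLSRModel:
    """Fit a PLSR model with ``n_factors`` latent factors.

    ``X`` is column-mean centered and ``y`` centered internally; inputs are
    left untouched.  Requires ``n_factors <= min(n_samples − 1, n_features)``
    and a response with positive variance.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ParameterError("X must be (n_samples, n_features) matching y")
    n, p = X.shape
    if not 1 <= n_factors <= min(n - 1, p):
        raise RankError(
            f"n_factors must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}]; "
            f"got {n_factors}"
        )
    if np.var(y) == 0:
        raise DesignError("response has zero variance")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, q, T = _nipals(X - x_mean, y - y_mean, n_factors)
    b = _coefficients(W, P, q)[:, -1]
    return PLSRModel(
        n_factors=n_factors, x_mean=x_mean, y_mean=y_mean,
        weights=W, x_loadings=P, y_loadings=q,
        regression_vector=b, scores=T,
    )


def predict(model: PLSRModel, X_new: np.ndarray) -> np.ndarray:
    """``ŷ = ȳ + (X_new − x̄) · b`` for rows on the model's retained grid."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.regression_vector.size:
        raise CompatibilityError(
            f"model expects {model.regression_vector.size} wavenumbers, "
            f"got {X_new.shape[1]}"
        )
    return model.y_mean + (X_new - model.x_mean) @ model.regression_vector


def _cv_folds(n: int, scheme: str, n_segments: int, seed: int | None
              ) -> tuple[list[np.ndarray], str]:
    if scheme == "auto":
        scheme = "loo" if n <= 100 else "segments"
    if scheme == "loo":
        return [np.array([i]) for i in range(n)], "loo"
    if scheme == "segments":
        if not 2 <= n_segments <= n:
            raise ParameterError(f"need 2 <= n_segments <= n; got {n_segments}")
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        return ([np.sort(fold) for fold in np.array_split(perm, n_segments)],
                f"segments({n_segments},seed={seed})")
    raise ParameterError(f"unknown CV scheme {scheme!r}")


def cross_validate(X: np.ndarray, y: np.ndarray, max_factors: int,
                   scheme: str = "auto", n_segments: int = 10,
                   seed: int | None = 0) -> CVResult:
    """Cross-validated RMSECV and R² for every factor count 1..max_factors.

    Each held-out sample/segment is predicted by a model fitted without it.
    ``scheme="auto"`` uses leave-one-out for n ≤ 100 and 10 seeded random
    segments otherwise.  R²_cv = 1 − PRESS/SS_tot with SS_tot about the
    overall mean of ``y``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    folds, scheme_desc = _cv_folds(n, scheme, n_segments, seed)
    smallest_train = n - max(len(f) for f in folds)
    if not 1 <= max_factors <= min(smallest_train - 1, X.shape[1]):
        raise ParameterError(
            f"max_factors={max_factors} invalid for the smallest training fold "
            f"({smallest_train} samples, {X.shape[1]} features)"
        )
    press = np.zeros(max_factors)
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        X_tr, y_tr = X[mask], y[mask]
        x_mean = X_tr.mean(axis=0)
        y_mean = y_tr.mean()
        W, P, q, _ = _nipals(X_tr - x_mean, y_tr - y_mean, max_factors)
        B = _coefficients(W, P, q)  # (p, max_factors), cumulative
        resid = (X[fold] - x_mean) @ B + y_mean - y[fold][:, None]
        press += (resid ** 2).sum(axis=0)
    ss_tot = ((y - y.mean()) ** 2).sum()
    return CVResult(
        rmsecv=np.sqrt(press / n),
        r2_cv=1.0 - press / ss_tot,
        scheme=scheme_desc,
    )


def select_n_factors(cv: CVResult, rule: str = "min_rmsecv",
                     tol: float = 0.05) -> int:
    """Pick the factor count from a CV curve.

    ``min_rmsecv``: argmin RMSECV, ties toward the lowest count.
    ``parsimonious``: smallest count whose RMSECV ≤ (1 + tol) · min RMSECV.
    """
    rmsecv = cv.rmsecv
    if rule == "min_rmsecv":
        return int(np.argmin(rmsecv)) + 1
    if rule == "parsimonious":
        threshold = (1.0 + tol) * rmsecv.min()
        return int(np.flatnonzero(rmsecv <= threshold)[0]) + 1
    raise ParameterError(f"unknown selection rule {rule!r}")
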