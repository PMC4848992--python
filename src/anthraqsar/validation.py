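"""Model-quality statistics: R^2, RMSE, F tests, LOO Q^2 and Y-randomization.

Conventions (these reproduce the published training/test statistics exactly
from the shipped prediction columns):

* R^2 between observed and predicted is the squared Pearson correlation.
* RMSE is the population form sqrt(SSE/n).
* Q^2_LOO = 1 - PRESS/SST with SST about the full-sample mean; leave-one-out
  predictions use the hat-matrix shortcut e_i/(1-h_i), exact for OLS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats
import statsmodels.api as sm

__all__ = [
    "ValidationReport",
    "YRandomizationResult",
    "r_squared",
    "rmse",
    "f_statistic",
    "f_critical",
    "q2_loo",
    "y_randomization",
    "validation_report",
]


def _pair(y, yhat):
    ya = np.asarray(y, dtype=float).ravel()
    ha = np.asarray(yhat, dtype=float).ravel()
    if ya.shape != ha.shape:
        raise ValueError(f"length mismatch: {ya.shape} vs {ha.shape}")
    return ya, ha


def r_squared(y, yhat) -> float:
    """Squared Pearson correlation between observed and predicted values."""
    ya, ha = _pair(y, yhat)
    if len(ya) < 3:
        raise ValueError("need at least 3 observations")
    if ya.std() == 0 or ha.std() == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(np.corrcoef(ya, ha)[0, 1] ** 2)


def rmse(y, yhat) -> float:
    """Root mean squared residual, sqrt(SSE/n)."""
    ya, ha = _pair(y, yhat)
    if len(ya) == 0:
        raise ValueError("empty input")
    return float(np.sqrt(np.mean((ya - ha) ** 2)))


def f_statistic(r2: float, n: int, p: int) -> float:
    """Overall regression F from R^2: (R^2/p) / ((1-R^2)/(n-p-1))."""
    if not 0 <= r2 <= 1:
        raise ValueError("r2 must be in [0, 1]")
    if n <= p + 1:
        raise ValueError("need n > p+1")
    if r2 == 1:
        return float("inf")
    return (r2 / p) / ((1.0 - r2) / (n - p - 1))


def f_critical(alpha: float, df1: int, df2: int) -> float:
    """Upper-tail critical value of the F(df1, df2) distribution."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be >= 1")
    return float(scipy.stats.f.isf(alpha, df1, df2))


def q2_loo(X, y) -> tuple[float, float]:
    """Leave-one-out cross-validated Q^2 and RMSE for OLS on a fixed column set.

    Uses the PRESS identity e_i/(1-h_i); equivalent to refitting with row i
    deleted.  SST is taken about the full-sample mean.
    """
    Xa = np.asarray(X, dtype=float)
    if Xa.ndim == 1:
        Xa = Xa[:, None]
    ya = np.asarray(y, dtype=float).ravel()
    n, p = Xa.shape
    if n <= p + 2:
        raise ValueError("need n > p+2 for leave-one-out")
    design = sm.add_constant(Xa, has_constant="add")
    if np.linalg.matrix_rank(design) < p + 1:
        raise np.linalg.LinAlgError("rank-deficient design")
    res = sm.OLS(ya, design).fit()
    h = res.get_influence().hat_matrix_diag
    if np.any(h >= 1 - 1e-12):
        bad = int(np.argmax(h))
        raise np.linalg.LinAlgError(
            f"row {bad} has leverage 1; deleting it makes the fit singular"
        )
    e = ya - res.fittedvalues
    press_resid = e / (1.0 - h)
    press = float(press_resid @ press_resid)
    sst = float(((ya - ya.mean()) ** 2).sum())
    return 1.0 - press / sst, float(np.sqrt(press / n))


@dataclass(frozen=True)
class YRandomizationResult:
    """Per-shuffle recall R^2 and Q^2_LOO under a permuted response."""

    runs: tuple[tuple[float, float], ...]
    seed: int

    @property
    def r2(self) -> np.ndarray:
        return np.array([r for r, _ in self.runs])

    @property
    def q2(self) -> np.ndarray:
        return np.array([q for _, q in self.runs])


def y_randomization(X, y, k: int = 10, seed: int = 0) -> YRandomizationResult:
    """Refit OLS on the fixed columns after k seeded shuffles of y.

    A model whose recall R^2 collapses to the chance level ~ p/(n-1) under
    shuffling is not a chance correlation.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    Xa = np.asarray(X, dtype=float)
    if Xa.ndim == 1:
        Xa = Xa[:, None]
    ya = np.asarray(y, dtype=float).ravel()
    if ya.std() == 0:
        raise ValueError("constant response: R^2 undefined under shuffling")
    rng = np.random.default_rng(seed)
    design = sm.add_constant(Xa, has_constant="add")
    runs = []
    for _ in range(k):
        perm = rng.permutation(len(ya))
        ys = ya[perm]
        res = sm.OLS(ys, design).fit()
        q2, _ = q2_loo(Xa, ys)
        runs.append((float(res.rsquared), float(q2)))
    return YRandomizationResult(tuple(runs), seed)


@dataclass(frozen=True)
class ValidationReport:
    r2_train: float
    rmse_train: float
    f_stat: float
    f_critical: float
    q2_loo: float | None
    rmse_loo: float | None
    r2_test: float | None
    rmse_test: float | None
    n_train: int
    n_test: int
    n_descriptors: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def validation_report(
    y_train, yhat_train, y_test=None, yhat_test=None,
    n_descriptors: int = 5, alpha: float = 0.005,
    X_train=None,
) -> ValidationReport:
    """Assemble every reported model-quality statistic in one record.

    ``X_train`` (descriptors of the training rows) is optional; when given,
    Q^2_LOO / RMSE_LOO are computed by leave-one-out OLS on those columns.
    """
    r2tr = r_squared(y_train, yhat_train)
    n_train = len(np.asarray(y_train).ravel())
    q2 = rmse_l = None
    if X_train is not None:
        q2, rmse_l = q2_loo(X_train, y_train)
    r2te = rmse_te = None
    n_test = 0
    if y_test is not None and yhat_test is not None:
        r2te = r_squared(y_test, yhat_test)
        rmse_te = rmse(y_test, yhat_test)
        n_test = len(np.asarray(y_test).ravel())
    return ValidationReport(
        r2_train=r2tr,
        rmse_train=rmse(y_train, yhat_train),
        f_stat=f_statistic(r2tr, n_train, n_descriptors),
        f_critical=f_critical(alpha, n_descriptors, n_train - n_descriptors - 1),
        q2_loo=q2, rmse_loo=rmse_l,
        r2_test=r2te, rmse_test=rmse_te,
        n_train=n_train, n_test=n_test,
        n_descriptors=n_descriptors,
    )
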