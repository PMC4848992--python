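"""Ordinary least squares, stepwise selection and collinearity diagnostics.

The 2D-QSAR model is a five-descriptor linear equation selected by classical
stepwise regression (forward entry / backward removal on partial-F p-values).
The published coefficient set is shipped as ``PUBLISHED_MLR_2016`` so activities
can be predicted from any compatible descriptor table; note that descriptor
engines differ, so predictions with externally computed descriptors are
approximate.

OLS fitting is delegated to statsmodels; RMSE uses the population convention
sqrt(SSE/n), which is the convention the published training and test errors
follow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "MLRModel",
    "CollinearityReport",
    "PUBLISHED_MLR_2016",
    "fit_ols",
    "predict_mlr",
    "stepwise_select",
    "collinearity_report",
]


@dataclass(frozen=True)
class MLRModel:
    """A fitted (or published) multiple linear regression model."""

    descriptor_names: tuple[str, ...]
    coefficients: np.ndarray
    intercept: float
    coefficient_se: np.ndarray | None = None
    intercept_se: float | None = None
    standardized_coefficients: np.ndarray | None = None
    n_train: int | None = None
    r2: float | None = None
    rmse: float | None = None
    f_stat: float | None = None

    def __post_init__(self):
        coef = np.asarray(self.coefficients, dtype=float)
        if len(coef) != len(self.descriptor_names):
            raise ValueError("one coefficient per descriptor required")
        object.__setattr__(self, "coefficients", coef)

    def predict(self, X) -> np.ndarray:
        return predict_mlr(self, X)

    def to_dict(self) -> dict:
        return {
            "descriptor_names": list(self.descriptor_names),
            "coefficients": list(map(float, self.coefficients)),
            "intercept": float(self.intercept),
            "coefficient_se": None if self.coefficient_se is None
            else list(map(float, self.coefficient_se)),
            "intercept_se": self.intercept_se,
            "standardized_coefficients": None if self.standardized_coefficients is None
            else list(map(float, self.standardized_coefficients)),
            "n_train": self.n_train,
            "r2": self.r2,
            "rmse": self.rmse,
            "f_stat": self.f_stat,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLRModel":
        return cls(
            descriptor_names=tuple(d["descriptor_names"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            intercept=float(d["intercept"]),
            coefficient_se=None if d.get("coefficient_se") is None
            else np.asarray(d["coefficient_se"], dtype=float),
            intercept_se=d.get("intercept_se"),
            standardized_coefficients=None if d.get("standardized_coefficients") is None
            else np.asarray(d["standardized_coefficients"], dtype=float),
            n_train=d.get("n_train"), r2=d.get("r2"),
            rmse=d.get("rmse"), f_stat=d.get("f_stat"),
        )


#: The published five-descriptor model ("aad-fxr-2016-mlr"):
#: pEC50 = 0.016*ASA + 14.001*RPC- - 0.049*SlogP_VSA2 + 0.362*b_rotN
#:         + 0.318*opr_leadlike - 9.717
PUBLISHED_MLR_2016 = MLRModel(
    descriptor_names=("ASA", "RPC-", "SlogP_VSA2", "b_rotN", "opr_leadlike"),
    coefficients=np.array([0.016, 14.001, -0.049, 0.362, 0.318]),
    coefficient_se=np.array([0.002, 4.041, 0.0175, 0.158, 0.276]),
    intercept=-9.717,
    intercept_se=2.221,
    standardized_coefficients=np.array([0.848, 0.393, -0.567, 0.408, 0.136]),
    n_train=31,
    r2=0.935,
    rmse=0.219,
    f_stat=72.353,
)


def _as_xy(X, y=None):
    if isinstance(X, pd.DataFrame):
        names = tuple(map(str, X.columns))
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        if Xa.ndim == 1:
            Xa = Xa[:, None]
        names = tuple(f"x{j}" for j in range(Xa.shape[1]))
    if y is None:
        return Xa, names
    ya = np.asarray(y, dtype=float).ravel()
    if len(ya) != len(Xa):
        raise ValueError("X and y lengths differ")
    return Xa, names, ya


def fit_ols(X, y) -> MLRModel:
    """OLS with intercept; raises on rank deficiency, naming dependent columns."""
    Xa, names, ya = _as_xy(X, y)
    n, p = Xa.shape
    if n <= p + 1:
        raise ValueError(f"need n > p+1 (n={n}, p={p})")
    design = sm.add_constant(Xa, has_constant="add")
    if np.linalg.matrix_rank(design) < p + 1:
        # identify columns linearly dependent on the preceding ones
        bad = []
        for j in range(1, p + 1):
            if np.linalg.matrix_rank(design[:, : j + 1]) < j + 1:
                bad.append(names[j - 1])
        raise np.linalg.LinAlgError(f"rank-deficient design; dependent columns: {bad}")
    res = sm.OLS(ya, design).fit()
    resid = ya - res.fittedvalues
    sse = float(resid @ resid)
    rmse = float(np.sqrt(sse / n))
    sy = ya.std(ddof=1)
    sx = Xa.std(axis=0, ddof=1)  # per-column sample sd
    std_coef = res.params[1:] * sx / sy if sy > 0 else np.full(p, np.nan)
    return MLRModel(
        descriptor_names=names,
        coefficients=res.params[1:],
        intercept=float(res.params[0]),
        coefficient_se=res.bse[1:],
        intercept_se=float(res.bse[0]),
        standardized_coefficients=std_coef,
        n_train=n,
        r2=float(res.rsquared),
        rmse=rmse,
        f_stat=float(res.fvalue),
    )


def predict_mlr(model: MLRModel, X) -> np.ndarray:
    """intercept + X @ coefficients, column order taken from the model.

    ``X`` may be a DataFrame (columns reordered by name) or an array whose
    columns already follow ``model.descriptor_names``.
    """
    if isinstance(X, pd.DataFrame):
        missing = set(model.descriptor_names) - set(map(str, X.columns))
        if missing:
            raise ValueError(f"missing descriptor column(s): {sorted(missing)}")
        Xa = X[list(model.descriptor_names)].to_numpy(dtype=float)
    else:
        Xa = np.atleast_2d(np.asarray(X, dtype=float))
        if Xa.shape[1] != len(model.descriptor_names):
            raise ValueError(
                f"descriptor vector length {Xa.shape[1]} != "
                f"{len(model.descriptor_names)} model coefficients"
            )
    return model.intercept + Xa @ model.coefficients


def _partial_f_pvalues(Xa: np.ndarray, ya: np.ndarray, cols: list[int]) -> np.ndarray:
    """p-value of the partial F test for dropping each included column."""
    design = sm.add_constant(Xa[:, cols], has_constant="add")
    res = sm.OLS(ya, design).fit()
    # squared t equals the partial F with 1 numerator df; p-values coincide
    return np.asarray(res.pvalues[1:], dtype=float)


def stepwise_select(
    X, y, alpha_enter: float = 0.05, alpha_remove: float = 0.10,
    max_iter: int = 100,
) -> tuple[list, MLRModel]:
    """Classical forward/backward stepwise OLS on partial-F p-values.

    Forward step: among excluded columns, add the one with the smallest
    entry p-value if it is below ``alpha_enter``.  Backward step: drop any
    included column whose p-value exceeds ``alpha_remove``.  Ties break on
    column order.  Returns (selected column labels, fitted model); an empty
    selection yields an intercept-only model.
    """
    if alpha_enter > alpha_remove:
        raise ValueError("alpha_enter must be <= alpha_remove")
    Xa, names, ya = _as_xy(X, y)
    n, p = Xa.shape
    included: list[int] = []
    for _ in range(max_iter):
        changed = False
        # forward
        candidates = [j for j in range(p) if j not in included]
        best_j, best_p = None, np.inf
        for j in candidates:
            trial = included + [j]
            if n <= len(trial) + 1:
                continue
            pv = _partial_f_pvalues(Xa, ya, trial)[-1]
            if pv < best_p - 1e-15:
                best_j, best_p = j, pv
        if best_j is not None and best_p < alpha_enter:
            included.append(best_j)
            changed = True
        # backward
        while included:
            pvals = _partial_f_pvalues(Xa, ya, included)
            worst = int(np.argmax(pvals))
            if pvals[worst] > alpha_remove:
                included.pop(worst)
                changed = True
            else:
                break
        if not changed:
            break
    included_sorted = sorted(included)
    if not included_sorted:
        model = MLRModel(
            descriptor_names=(), coefficients=np.empty(0),
            intercept=float(np.mean(ya)), n_train=n, r2=0.0,
            rmse=float(np.sqrt(np.mean((ya - ya.mean()) ** 2))),
        )
        return [], model
    sub = pd.DataFrame(Xa[:, included_sorted],
                       columns=[names[j] for j in included_sorted])
    return [names[j] for j in included_sorted], fit_ols(sub, ya)


@dataclass(frozen=True)
class CollinearityReport:
    names: tuple[str, ...]
    correlation_matrix: np.ndarray
    vif: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.correlation_matrix, index=self.names, columns=self.names)
        df["VIF"] = self.vif
        return df


def collinearity_report(X) -> CollinearityReport:
    """Pairwise Pearson correlations and VIF_j = 1/(1 - R_j^2) per column."""
    Xa, names = _as_xy(X)
    n, p = Xa.shape
    if p < 2:
        raise ValueError("need at least two columns")
    sds = Xa.std(axis=0)
    for j, s in enumerate(sds):
        if s == 0:
            raise ValueError(f"constant column: {names[j]}")
    corr = np.corrcoef(Xa, rowvar=False)
    vif = np.empty(p)
    for j in range(p):
        others = [k for k in range(p) if k != j]
        design = sm.add_constant(Xa[:, others], has_constant="add")
        r2j = sm.OLS(Xa[:, j], design).fit().rsquared
        vif[j] = 1.0 / (1.0 - r2j) if r2j < 1 else np.inf
    return CollinearityReport(names, corr, vif)
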