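"""Applicability-domain analysis: leverages, warning leverage, Williams plot.

The leverage of a descriptor vector x is h = x'(X'X)^-1 x with the intercept
included, where X is the training design matrix.  Compounds with h above the
warning leverage h* = 3(m+1)/n are structurally outside the model's domain
(X outliers); compounds whose standardized residual exceeds +-3 are response
outliers (Y outliers).  Test-compound leverages use the training (X'X)^-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LeverageRecord",
    "LeverageReport",
    "leverages",
    "warning_leverage",
    "standardized_residuals",
    "williams_report",
]


def leverages(X_train, X_query=None) -> np.ndarray:
    """h_i = x_i'(X'X)^-1 x_i with an intercept column prepended.

    With ``X_query=None`` the training self-leverages (hat-matrix diagonal)
    are returned.
    """
    Xt = np.asarray(X_train, dtype=float)
    if Xt.ndim == 1:
        Xt = Xt[:, None]
    D = np.column_stack([np.ones(len(Xt)), Xt])
    xtx = D.T @ D
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise np.linalg.LinAlgError("singular X'X: training design is rank-deficient")
    xtx_inv = np.linalg.inv(xtx)
    if X_query is None:
        Q = D
    else:
        Xq = np.asarray(X_query, dtype=float)
        if Xq.ndim == 1:
            Xq = Xq[None, :] if Xq.shape[0] == Xt.shape[1] else Xq[:, None]
        Q = np.column_stack([np.ones(len(Xq)), Xq])
    return np.einsum("ij,jk,ik->i", Q, xtx_inv, Q)


def warning_leverage(m: int, n: int) -> float:
    """h* = 3(m+1)/n where m is the number of model parameters."""
    if m < 1 or n <= m:
        raise ValueError("need m >= 1 and n > m")
    return 3.0 * (m + 1) / n


def standardized_residuals(y, yhat, s: float) -> np.ndarray:
    """(y - yhat)/s with s the training RMSE."""
    if not s > 0:
        raise ValueError("s must be positive")
    ya = np.asarray(y, dtype=float).ravel()
    ha = np.asarray(yhat, dtype=float).ravel()
    if ya.shape != ha.shape:
        raise ValueError("length mismatch")
    return (ya - ha) / s


@dataclass(frozen=True)
class LeverageRecord:
    id: str
    leverage: float
    std_residual: float
    role: str
    flags: tuple[str, ...]


@dataclass(frozen=True)
class LeverageReport:
    records: tuple[LeverageRecord, ...]
    h_star: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "leverage": [r.leverage for r in self.records],
                "std_residual": [r.std_residual for r in self.records],
                "role": [r.role for r in self.records],
                "flags": [";".join(r.flags) for r in self.records],
            }
        ).set_index("id")

    @property
    def x_outliers(self) -> list[str]:
        return [r.id for r in self.records if "x_outlier" in r.flags]

    @property
    def y_outliers(self) -> list[str]:
        return [r.id for r in self.records if "y_outlier" in r.flags]


def williams_report(
    X_train, y_train, yhat_train,
    X_test=None, y_test=None, yhat_test=None,
    ids_train=None, ids_test=None,
    plot_path=None,
) -> LeverageReport:
    """Leverage / standardized-residual record for every compound.

    Residuals for both roles are standardized by the training RMSE; test
    leverages are computed against the training (X'X)^-1.  Optionally writes
    a Williams plot to ``plot_path``.
    """
    Xt = np.asarray(X_train, dtype=float)
    if Xt.ndim == 1:
        Xt = Xt[:, None]
    yt = np.asarray(y_train, dtype=float).ravel()
    ht = np.asarray(yhat_train, dtype=float).ravel()
    n, m = Xt.shape
    s = float(np.sqrt(np.mean((yt - ht) ** 2)))
    h_star = warning_leverage(m, n)
    ids_train = list(ids_train) if ids_train is not None else [str(i + 1) for i in range(n)]

    lev_tr = leverages(Xt)
    res_tr = standardized_residuals(yt, ht, s)
    records = []
    for cid, h, r in zip(ids_train, lev_tr, res_tr):
        flags = []
        if h > h_star:
            flags.append("x_outlier")
        if abs(r) > 3:
            flags.append("y_outlier")
        records.append(LeverageRecord(str(cid), float(h), float(r), "train", tuple(flags)))

    if X_test is not None:
        Xq = np.asarray(X_test, dtype=float)
        if Xq.ndim == 1:
            Xq = Xq[:, None]
        yq = np.asarray(y_test, dtype=float).ravel()
        hq = np.asarray(yhat_test, dtype=float).ravel()
        ids_test = list(ids_test) if ids_test is not None else [
            f"t{i + 1}" for i in range(len(Xq))
        ]
        lev_te = leverages(Xt, Xq)
        res_te = standardized_residuals(yq, hq, s)
        for cid, h, r in zip(ids_test, lev_te, res_te):
            flags = []
            if h > h_star:
                flags.append("x_outlier")
            if abs(r) > 3:
                flags.append("y_outlier")
            records.append(LeverageRecord(str(cid), float(h), float(r), "test", tuple(flags)))

    report = LeverageReport(tuple(records), h_star)
    if plot_path is not None:
        _plot_williams(report, plot_path)
    return report


def _plot_williams(report: LeverageReport, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    for role, marker in (("train", "o"), ("test", "s")):
        xs = [r.leverage for r in report.records if r.role == role]
        ys = [r.std_residual for r in report.records if r.role == role]
        if xs:
            ax.scatter(xs, ys, marker=marker, label=role, alpha=0.8)
    ax.axvline(report.h_star, color="red", ls="--", label=f"h* = {report.h_star:.3f}")
    ax.axhline(3, color="gray", ls=":")
    ax.axhline(-3, color="gray", ls=":")
    ax.set_xlabel("leverage")
    ax.set_ylabel("standardized residual")
    ax.set_title("Williams plot")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
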