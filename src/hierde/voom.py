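"""Mean–variance trend estimation and per-observation precision weights.

An unweighted first-pass OLS fit (same fixed effects later used by the
mixed model, subjects pooled) yields per-gene residual standard deviations
and per-observation fitted values. A robust LOWESS smoother of sqrt-sd on
average log2 expression gives the trend; each observation's predicted
sqrt-sd is the trend evaluated at its fitted value, so the predicted
variance is trend⁴ and the precision weight is

    w_gi = trend(fitted_gi)^(-4)

i.e. the inverse of the predicted observation variance. The quarter-power
(sqrt of the standard deviation) parameterization stabilises the smoother
on the heavy right tail of gene-wise variances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "TrendFit",
    "first_pass_fit",
    "lowess_trend",
    "compute_weights",
    "VoomWeights",
    "build_design",
]


def build_design(meta: pd.DataFrame,
                 fixed_effects: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    """Fixed-effect design matrix: intercept, then one column per effect.

    ``diagnosis`` is coded AD = 1, control = 0 (so the diagnosis coefficient
    is the AD-vs-control log2 fold change); categorical effects such as
    ``region`` expand to treatment-coded dummies; numeric columns pass
    through.
    """
    cols = [np.ones(len(meta))]
    names = ["intercept"]
    for eff in fixed_effects:
        if eff not in meta.columns:
            raise ValueError(f"fixed effect {eff!r} not in metadata")
        col = meta[eff]
        if eff == "diagnosis":
            cols.append((col == "AD").to_numpy(dtype=float))
            names.append("diagnosis[AD]")
        elif col.dtype == object or str(col.dtype) == "category":
            levels = sorted(col.astype(str).unique())
            for lvl in levels[1:]:
                cols.append((col.astype(str) == lvl).to_numpy(dtype=float))
                names.append(f"{eff}[{lvl}]")
        else:
            cols.append(col.to_numpy(dtype=float))
            names.append(eff)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"singular design for fixed effects {list(fixed_effects)}")
    return X, names


@dataclass
class TrendFit:
    """Piecewise-linear mean–variance trend on the sqrt-sd scale.

    ``knots_x`` are sorted mean log2-expression values, ``knots_y`` the
    fitted sqrt-standard-deviation values. Evaluation interpolates linearly
    and clamps to the boundary value outside [min, max].
    """

    knots_x: np.ndarray
    knots_y: np.ndarray
    span: float

    def __post_init__(self) -> None:
        self.knots_x = np.asarray(self.knots_x, dtype=float)
        self.knots_y = np.asarray(self.knots_y, dtype=float)
        if not np.all(np.diff(self.knots_x) > 0):
            raise ValueError("knots_x must be strictly increasing")
        if not np.all(self.knots_y > 0):
            raise ValueError("knots_y must be strictly positive")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(x, dtype=float), self.knots_x, self.knots_y)


def first_pass_fit(
    E_log: pd.DataFrame,
    meta: pd.DataFrame,
    fixed_effects: Sequence[str] = ("diagnosis",),
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Unweighted OLS fit of every gene on the fixed-effect design.

    Returns ``(avexp, sqrt_sd, fitted, ok)`` where ``avexp`` is the row mean
    of the log2 matrix, ``sqrt_sd`` the square root of the OLS residual
    standard deviation (df = n − p), ``fitted`` the genes × samples fitted
    values, and ``ok`` flags genes with positive residual variance (genes
    with zero residual df or zero variance are excluded from trend fitting).
    """
    X, _ = build_design(meta, fixed_effects)
    E = np.asarray(E_log, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("no residual degrees of freedom in first-pass fit")
    pinv = np.linalg.pinv(X)
    coef = E @ pinv.T  # genes × p
    fitted = coef @ X.T
    resid = E - fitted
    rss = np.einsum("gn,gn->g", resid, resid)
    sd = np.sqrt(rss / (n - p))
    avexp = E.mean(axis=1)
    # relative threshold: exact fits leave rounding-level residuals
    ok = sd > 1e-8 * np.maximum(1.0, np.abs(avexp))
    return avexp, np.sqrt(sd), fitted, ok


def lowess_trend(avexp: np.ndarray, sqrt_sd: np.ndarray, span: float = 0.5,
                 iterations: int = 3) -> TrendFit:
    """Robust LOWESS smoother of sqrt-sd on mean log2 expression."""
    avexp = np.asarray(avexp, dtype=float)
    sqrt_sd = np.asarray(sqrt_sd, dtype=float)
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    if avexp.size < 50:
        raise ValueError("need at least 50 genes to estimate the trend")
    if np.ptp(avexp) == 0:
        raise ValueError("all average expressions identical; no trend estimable")
    fit = lowess(sqrt_sd, avexp, frac=span, it=iterations, return_sorted=True)
    xs, ys = fit[:, 0], fit[:, 1]
    # collapse duplicate abscissae so interpolation knots are strictly increasing
    ux, inverse = np.unique(xs, return_inverse=True)
    uy = np.zeros_like(ux)
    counts = np.bincount(inverse)
    np.add.at(uy, inverse, ys)
    uy /= counts
    uy = np.maximum(uy, 1e-6)  # trend must stay positive for the weights
    return TrendFit(knots_x=ux, knots_y=uy, span=span)


def compute_weights(fitted: np.ndarray, trend: TrendFit) -> np.ndarray:
    """Precision weights: inverse predicted observation variance.

    The trend predicts sqrt-sd, so predicted variance = trend(fitted)⁴ and
    w = trend(fitted)^(−4).
    """
    fitted = np.asarray(fitted, dtype=float)
    if not np.isfinite(fitted).all():
        raise ValueError("fitted values must be finite")
    return trend(fitted) ** -4.0


class VoomWeights(BaseEstimator):
    """Estimate the mean–variance trend and emit precision weights.

    Parameters
    ----------
    fixed_effects : sequence of str, default ("diagnosis",)
        Fixed effects of the first-pass OLS fit; should match the structure
        later used by the mixed model.
    span : float, default 0.5
        LOWESS span.
    iterations : int, default 3
        LOWESS robustness iterations.

    Attributes
    ----------
    trend_ : TrendFit
        Fitted mean–variance trend (sqrt-sd scale).
    avexp_, sqrt_sd_ : ndarray
        Per-gene mean log2 expression and sqrt residual sd.
    ok_ : ndarray of bool
        Genes that contributed to the trend; degenerate genes (zero
        residual variance) receive weight 1 everywhere and ok_ = False.
    """

    def __init__(self, fixed_effects: Sequence[str] = ("diagnosis",),
                 span: float = 0.5, iterations: int = 3):
        self.fixed_effects = fixed_effects
        self.span = span
        self.iterations = iterations

    def fit(self, E_log: pd.DataFrame, meta: pd.DataFrame) -> "VoomWeights":
        avexp, sqrt_sd, fitted, ok = first_pass_fit(E_log, meta, self.fixed_effects)
        self.avexp_ = avexp
        self.sqrt_sd_ = sqrt_sd
        self.fitted_ = fitted
        self.ok_ = ok
        self.trend_ = lowess_trend(avexp[ok], sqrt_sd[ok], self.span, self.iterations)
        return self

    def transform(self, E_log: pd.DataFrame) -> pd.DataFrame:
        W = compute_weights(self.fitted_, self.trend_)
        W[~self.ok_, :] = 1.0
        if isinstance(E_log, pd.DataFrame):
            return pd.DataFrame(W, index=E_log.index, columns=E_log.columns)
        return W

    def fit_transform(self, E_log: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
        return self.fit(E_log, meta).transform(E_log)

    def plot_trend(self, path=None):  # pragma: no cover - QC convenience
        """Scatter of mean vs sqrt-sd with the fitted trend; optional save."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        ax.plot(self.avexp_[self.ok_], self.sqrt_sd_[self.ok_], ".", ms=2,
                alpha=0.4, label="genes")
        grid = np.linspace(self.trend_.knots_x.min(), self.trend_.knots_x.max(), 200)
        ax.plot(grid, self.trend_(grid), "r-", label="LOWESS trend")
        ax.set_xlabel("average log2 expression")
        ax.set_ylabel("sqrt(residual sd)")
        ax.legend()
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig
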