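"""Per-gene weighted linear mixed models with subject random intercepts,
empirical-Bayes moderation, and multiple-testing correction.

Model
-----
For one gene, observations stacked over samples:

    y = Xβ + Z u + ε,   u ~ N(0, τ² I_S),   ε ~ N(0, σ² W⁻¹)

where ``Z`` maps samples to subjects (random intercept per subject) and
``W`` holds the per-observation precision weights. Writing λ = τ²/σ² the
marginal covariance is σ²·Ṽ(λ) with Ṽ = W⁻¹ + λZZᵀ. The REML criterion
profiled over (β, σ²),

    f(λ) = (n−p)·log RSS(λ) + log|Ṽ(λ)| + log|Xᵀ Ṽ(λ)⁻¹ X|,

is minimized over λ ≥ 0; at λ = 0 the fit is exactly weighted least
squares. Because subjects form independent blocks, Ṽ⁻¹ is available in
closed form by block-wise Sherman–Morrison updates, and the criterion is
evaluated simultaneously for all genes (the per-subject sufficient
statistics do not depend on λ).

Weights are defined up to a per-gene scale (they are normalized to mean 1
internally), so doubling all weights leaves β, τ² and σ² unchanged.

Moderation then shrinks the gene-wise residual variances s²_g (df d_g)
toward a common prior s₀² with prior df d₀ estimated by marginal method of
moments on log s²_g; the moderated t uses the posterior variance
s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g) with d₀ + d_g degrees of freedom. The
B-statistic is the posterior log-odds of differential expression under a
two-component prior on the contrast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator

from .voom import build_design

__all__ = [
    "GeneFit",
    "ModerationResult",
    "MixedDE",
    "fit_gene_lmm",
    "fit_all",
    "ebayes_moderate",
    "b_statistic",
    "estimate_v0",
    "bonferroni",
    "wilcoxon_region",
    "ols_pvalues",
]

logger = logging.getLogger(__name__)


@dataclass
class GeneFit:
    """Fixed- and variance-component estimates for one gene."""

    beta: np.ndarray            # fixed-effect estimates (intercept first)
    coef_names: list[str]
    logFC: float                # diagnosis contrast (AD − control, log2)
    se_unit: float              # unscaled standard error of the contrast
    sigma2: float               # residual variance s²_g
    df_resid: float             # residual df d_g used for moderation
    tau2: float                 # random-intercept variance
    converged: bool


@dataclass
class ModerationResult:
    """Empirical-Bayes variance moderation hyperparameters and posteriors."""

    d0: float                   # prior degrees of freedom (may be +inf)
    s0_2: float                 # prior variance
    s_tilde2: np.ndarray        # posterior variances per gene
    df_total: np.ndarray        # d0 + d_g per gene


# ---------------------------------------------------------------------------
# profiled REML, vectorized over genes
# ---------------------------------------------------------------------------

class _ProfiledREML:
    """Vectorized profiled-REML machinery for random-intercept models.

    Precomputes, per gene, the weighted cross-products and per-subject
    aggregates from which the REML criterion at any λ follows in O(G·S)
    numpy work, with no per-gene Python loop.
    """

    def __init__(self, X: np.ndarray, Y: np.ndarray, W: np.ndarray,
                 subj_codes: np.ndarray):
        G, n = Y.shape
        p = X.shape[1]
        if W.shape != Y.shape:
            raise ValueError("weight matrix shape must match expression matrix")
        if (W <= 0).any():
            raise ValueError("weights must be strictly positive")
        # weights are defined up to scale within a gene
        W = W / W.mean(axis=1, keepdims=True)
        S = subj_codes.max() + 1
        M = np.zeros((n, S))
        M[np.arange(n), subj_codes] = 1.0
        self.X, self.Y, self.W = X, Y, W
        self.n, self.p, self.G, self.S = n, p, G, S
        self.A = np.einsum("gn,np,nq->gpq", W, X, X)        # Xᵀ W X
        self.c = np.einsum("gn,np,gn->gp", W, X, Y)          # Xᵀ W y
        self.q = np.einsum("gn,gn,gn->g", W, Y, Y)           # yᵀ W y
        self.u = np.einsum("gn,ns,np->gsp", W, M, X)         # per-subject Xᵀw
        self.v = np.einsum("gn,ns,gn->gs", W, M, Y)          # per-subject yᵀw
        self.s = W @ M                                       # per-subject Σw

    def _gls_pieces(self, lam: np.ndarray):
        """XᵀṼ⁻¹X, XᵀṼ⁻¹y, yᵀṼ⁻¹y and log|Ṽ| (up to the λ-free term)."""
        lam = np.asarray(lam, dtype=float)[:, None]          # (G,1)
        f = lam / (1.0 + lam * self.s)                       # (G,S)
        XtVX = self.A - np.einsum("gs,gsp,gsq->gpq", f, self.u, self.u)
        XtVy = self.c - np.einsum("gs,gsp,gs->gp", f, self.u, self.v)
        ytVy = self.q - np.einsum("gs,gs->g", f, self.v ** 2)
        logdetV = np.log1p(lam * self.s).sum(axis=1)
        return XtVX, XtVy, ytVy, logdetV

    def objective(self, lam: np.ndarray) -> np.ndarray:
        XtVX, XtVy, ytVy, logdetV = self._gls_pieces(lam)
        sign, logdetXtVX = np.linalg.slogdet(XtVX)
        beta = np.linalg.solve(XtVX, XtVy[..., None])[..., 0]
        rss = ytVy - np.einsum("gp,gp->g", beta, XtVy)
        rss = np.maximum(rss, 1e-300)
        f = (self.n - self.p) * np.log(rss) + logdetV + logdetXtVX
        f[sign <= 0] = np.inf
        return f

    def solve(self, lam: np.ndarray, contrast_idx: int):
        """β, unscaled contrast SE, σ², τ² and RSS at the given per-gene λ."""
        XtVX, XtVy, ytVy, _ = self._gls_pieces(lam)
        beta = np.linalg.solve(XtVX, XtVy[..., None])[..., 0]
        rss = np.maximum(ytVy - np.einsum("gp,gp->g", beta, XtVy), 0.0)
        sigma2 = rss / (self.n - self.p)
        cov_unit = np.linalg.inv(XtVX)
        se_unit = np.sqrt(cov_unit[:, contrast_idx, contrast_idx])
        tau2 = lam * sigma2
        return beta, se_unit, sigma2, tau2, rss

    def optimize(self, lambda_max: float = 50.0, grid_size: int = 41,
                 iters: int = 35) -> np.ndarray:
        """Per-gene REML λ̂ by grid bracketing plus golden-section refinement.

        The grid always contains λ = 0; genes whose refined optimum does not
        beat the λ = 0 criterion are set exactly to 0, so the weighted
        least-squares identity at the boundary is exact.
        """
        grid = np.concatenate([[0.0], np.geomspace(1e-3, lambda_max, grid_size - 1)])
        F = np.stack([self.objective(np.full(self.G, lam)) for lam in grid])
        best = np.argmin(F, axis=0)
        lo = grid[np.maximum(best - 1, 0)]
        hi = grid[np.minimum(best + 1, grid.size - 1)]
        invphi = (np.sqrt(5.0) - 1.0) / 2.0
        a, b = lo.copy(), hi.copy()
        for _ in range(iters):
            c = b - invphi * (b - a)
            d = a + invphi * (b - a)
            fc = self.objective(c)
            fd = self.objective(d)
            take_left = fc < fd
            b = np.where(take_left, d, b)
            a = np.where(take_left, a, c)
        lam_hat = 0.5 * (a + b)
        f_hat = self.objective(lam_hat)
        f0 = self.objective(np.zeros(self.G))
        lam_hat = np.where(f0 <= f_hat, 0.0, lam_hat)
        return lam_hat


def _subject_codes(meta: pd.DataFrame) -> np.ndarray:
    _, codes = np.unique(meta["subject_id"].to_numpy(), return_inverse=True)
    return codes


def fit_all(
    E_adj: pd.DataFrame,
    W: pd.DataFrame | np.ndarray | None,
    meta: pd.DataFrame,
    fixed_effects: Sequence[str] = ("diagnosis",),
    lambda_max: float = 50.0,
) -> pd.DataFrame:
    """REML random-intercept fits for every gene; one row per gene.

    Degenerate genes (zero residual variance or singular fits) are retained
    with ``converged = False``, never dropped. Deterministic: no randomness
    enters the fitting.
    """
    X, names = build_design(meta, fixed_effects)
    if "diagnosis[AD]" not in names:
        raise ValueError("model must include the diagnosis fixed effect")
    contrast_idx = names.index("diagnosis[AD]")
    diag = meta["diagnosis"].to_numpy()
    for grp in ("AD", "control"):
        if meta.loc[diag == grp, "subject_id"].nunique() < 2:
            raise ValueError(f"need at least 2 subjects in group {grp!r}")
    Y = np.asarray(E_adj, dtype=float)
    if W is None:
        W = np.ones_like(Y)
    W = np.asarray(W, dtype=float)
    codes = _subject_codes(meta)
    prof = _ProfiledREML(X, Y, W, codes)
    lam = prof.optimize(lambda_max=lambda_max)
    beta, se_unit, sigma2, tau2, rss = prof.solve(lam, contrast_idx)
    n, p = prof.n, prof.p
    # df for the disease contrast: between-within convention. The contrast
    # compares subjects, so it carries subject-level information only;
    # using observation-level df (n − p) would overstate the tail precision
    # and inflate the family-wise error under Bonferroni.
    df_resid = float(prof.S - p)
    if df_resid <= 0:
        raise ValueError("need more subjects than fixed effects")
    scale = np.einsum("gn,gn->g", np.asarray(W, float), Y ** 2)
    converged = (sigma2 > 0) & (rss > 1e-12 * np.maximum(scale, 1.0)) \
        & np.isfinite(se_unit) & (se_unit > 0)
    out = pd.DataFrame({
        "gene_id": np.asarray(E_adj.index if isinstance(E_adj, pd.DataFrame)
                              else np.arange(Y.shape[0])).astype(str),
        "logFC": beta[:, contrast_idx],
        "se_unit": se_unit,
        "sigma2": sigma2,
        "df_resid": df_resid,
        "tau2": tau2,
        "lambda": lam,
        "converged": converged,
    })
    for j, name in enumerate(names):
        out[f"coef[{name}]"] = beta[:, j]
    n_bad = int((~converged).sum())
    if n_bad:
        logger.info("fit_all: %d of %d genes flagged non-converged/degenerate",
                    n_bad, len(out))
    return out


def fit_gene_lmm(
    y: np.ndarray | pd.Series,
    w: np.ndarray | None,
    meta: pd.DataFrame,
    fixed_effects: Sequence[str] = ("diagnosis",),
    lambda_max: float = 50.0,
) -> GeneFit:
    """REML random-intercept fit for a single gene's sample vector."""
    y = np.asarray(y, dtype=float)[None, :]
    W = None if w is None else np.asarray(w, dtype=float)[None, :]
    E = pd.DataFrame(y, index=["gene"], columns=meta["sample_id"].to_numpy())
    tab = fit_all(E, W, meta, fixed_effects, lambda_max=lambda_max)
    _, names = build_design(meta, fixed_effects)
    row = tab.iloc[0]
    beta = np.array([row[f"coef[{nm}]"] for nm in names])
    return GeneFit(
        beta=beta,
        coef_names=names,
        logFC=float(row["logFC"]),
        se_unit=float(row["se_unit"]),
        sigma2=float(row["sigma2"]),
        df_resid=float(row["df_resid"]),
        tau2=float(row["tau2"]),
        converged=bool(row["converged"]),
    )


# ---------------------------------------------------------------------------
# empirical-Bayes moderation
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) / x < 1e-10:
            break
    return float(x)


def ebayes_moderate(fits: pd.DataFrame) -> ModerationResult:
    """Estimate (d₀, s₀²) and squeeze the gene-wise variances.

    Marginally, s²_g ~ s₀²·F(d_g, d₀); matching the mean and variance of
    ``log s²_g`` via digamma/trigamma identities gives closed-form moment
    estimators (a trigamma inverse for d₀). A non-positive excess-variance
    moment means the spread of log-variances is no more than sampling
    noise; then d₀ = +∞ and every posterior variance equals s₀²
    (complete shrinkage).
    """
    s2 = np.asarray(fits["sigma2"], dtype=float)
    df = np.asarray(fits["df_resid"], dtype=float)
    ok = np.isfinite(s2) & (s2 > 0) & np.isfinite(df) & (df > 0)
    if ok.sum() < 20:
        raise ValueError("need at least 20 genes with positive variance to moderate")
    z = np.log(s2[ok])
    e = z - special.digamma(df[ok] / 2.0) + np.log(df[ok] / 2.0)
    e_mean = e.mean()
    excess = e.var(ddof=1) - np.mean(special.polygamma(1, df[ok] / 2.0))
    if excess > 0:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        logger.info("ebayes_moderate: no excess variability; d0 = +inf")
        d0 = np.inf
        s0_2 = float(np.mean(s2[ok]))  # degenerate spread: pool arithmetically
    if np.isfinite(d0):
        s_tilde2 = (d0 * s0_2 + df * s2) / (d0 + df)
    else:
        s_tilde2 = np.full_like(s2, s0_2)
    s_tilde2 = np.where(ok, s_tilde2, np.nan)
    return ModerationResult(d0=float(d0), s0_2=s0_2, s_tilde2=s_tilde2,
                            df_total=df + d0)


def moderated_t(fits: pd.DataFrame, moderation: ModerationResult
                ) -> tuple[np.ndarray, np.ndarray]:
    """Moderated t statistics and two-sided p-values."""
    beta1 = np.asarray(fits["logFC"], dtype=float)
    se_unit = np.asarray(fits["se_unit"], dtype=float)
    t = beta1 / (np.sqrt(moderation.s_tilde2) * se_unit)
    df = np.minimum(moderation.df_total, 1e6)  # t(df→∞) ≡ normal
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, p


def estimate_v0(t: np.ndarray, se_unit: np.ndarray, df: np.ndarray,
                proportion: float = 0.01) -> float:
    """Prior variance of the contrast under the alternative, from the top
    ranked |t| statistics.

    For each of the top ``ceil(proportion/2 · G)`` statistics the empirical
    tail probability is equated with a mixture tail to back out a variance
    inflation; the estimate is the mean of the per-gene values, floored at
    a small multiple of the unscaled variances.
    """
    t = np.abs(np.asarray(t, dtype=float))
    se_unit = np.asarray(se_unit, dtype=float)
    df = np.asarray(df, dtype=float)
    G = t.size
    ntarget = int(np.ceil(proportion / 2.0 * G))
    if ntarget < 1:
        raise ValueError("too few genes to estimate v0")
    p_top = max(ntarget / G, proportion)
    order = np.argsort(-t)[:ntarget]
    tt, vv, dd = t[order], se_unit[order] ** 2, np.minimum(df[order], 1e6)
    r = np.arange(1, ntarget + 1)
    p0 = 2.0 * stats.t.sf(tt, dd)
    ptarget = ((r - 0.5) / G - (1.0 - p_top) * p0) / p_top
    v0 = np.zeros(ntarget)
    pos = ptarget > p0
    if pos.any():
        qtarget = stats.t.isf(ptarget[pos] / 2.0, dd[pos])
        v0[pos] = vv[pos] * np.maximum((tt[pos] / qtarget) ** 2 - 1.0, 0.0)
    return float(np.mean(v0))


def b_statistic(
    t_mod: np.ndarray,
    df_total: np.ndarray,
    se_unit: np.ndarray,
    prior_prob: float = 0.01,
    v0: float | None = None,
) -> np.ndarray:
    """Posterior log-odds of differential expression (B / lods statistic).

    Under a two-component prior in which a fraction ``prior_prob`` of genes
    has a contrast with extra prior variance v₀·σ²,

        B = log(p/(1−p)) − ½·log r + ((d+1)/2)·log((t̃² + d)/(t̃²/r + d))

    with r = (v + v₀)/v, v = se_unit² and d the total (moderated) df.
    Strictly increasing in |t̃| at fixed df and se_unit.
    """
    if not 0.0 < prior_prob < 1.0:
        raise ValueError("prior_prob must lie in (0, 1)")
    t2 = np.asarray(t_mod, dtype=float) ** 2
    df = np.minimum(np.asarray(df_total, dtype=float), 1e6)
    v = np.asarray(se_unit, dtype=float) ** 2
    if v0 is None:
        v0 = estimate_v0(t_mod, se_unit, df, proportion=prior_prob)
    if v0 <= 0:
        v0 = np.median(v)  # flat-t fallback: keep the prior proper
    r = (v + v0) / v
    kernel = (df + 1.0) / 2.0 * np.log((t2 + df) / (t2 / r + df))
    return np.log(prior_prob / (1.0 - prior_prob)) - 0.5 * np.log(r) + kernel


def bonferroni(p_raw: np.ndarray | float, m: int) -> np.ndarray | float:
    """Family-wise error correction: min(1, m·p)."""
    if m < 1:
        raise ValueError("m must be at least 1")
    p = np.asarray(p_raw, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.nanmin(p, initial=0.0) < 0 or np.nanmax(p, initial=0.0) > 1:
            raise ValueError("p-values must lie in [0, 1]")
    out = np.minimum(1.0, m * p)
    return float(out) if np.isscalar(p_raw) else out


def wilcoxon_region(
    E_log: pd.DataFrame,
    meta: pd.DataFrame,
    region: str,
) -> pd.Series:
    """Two-sided Wilcoxon rank-sum p per gene, AD vs control within a region.

    Exact null distribution when the combined group size is ≤ 20 and the
    data are tie-free; otherwise the normal approximation with tie
    correction. Rank-based, hence invariant to strictly monotone transforms.
    """
    in_region = meta["region"] == region
    if not in_region.any():
        raise ValueError(f"region {region!r} absent from metadata")
    sub = meta[in_region]
    ad_ids = sub.loc[sub["diagnosis"] == "AD", "sample_id"]
    ct_ids = sub.loc[sub["diagnosis"] == "control", "sample_id"]
    if len(ad_ids) < 2 or len(ct_ids) < 2:
        raise ValueError(f"need ≥ 2 samples per group in region {region!r}")
    A = E_log[ad_ids].to_numpy(dtype=float)
    C = E_log[ct_ids].to_numpy(dtype=float)
    n_comb = A.shape[1] + C.shape[1]
    pvals = np.empty(E_log.shape[0])
    for g in range(E_log.shape[0]):
        x, y = A[g], C[g]
        pooled = np.concatenate([x, y])
        if np.ptp(pooled) == 0:
            pvals[g] = 1.0
            continue
        has_ties = np.unique(pooled).size < pooled.size
        method = "exact" if (n_comb <= 20 and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                                 use_continuity=False)
        pvals[g] = min(res.pvalue, 1.0)
    return pd.Series(pvals, index=E_log.index, name=f"wilcoxon_p[{region}]")


def ols_pvalues(
    E_adj: pd.DataFrame,
    meta: pd.DataFrame,
    fixed_effects: Sequence[str] = ("diagnosis",),
) -> np.ndarray:
    """Per-observation OLS p-values for the diagnosis contrast, ignoring
    subjects — the anti-pattern comparator for repeated-measures designs.

    Treats every sample as independent; with a positive subject variance
    this understates the standard error and inflates the type-I error,
    which is exactly what the hierarchical model is there to avoid.
    """
    X, names = build_design(meta, fixed_effects)
    j = names.index("diagnosis[AD]")
    Y = np.asarray(E_adj, dtype=float)
    n, p = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    coef = Y @ (XtX_inv @ X.T).T
    resid = Y - coef @ X.T
    s2 = np.einsum("gn,gn->g", resid, resid) / (n - p)
    se = np.sqrt(np.maximum(s2, 1e-300) * XtX_inv[j, j])
    t = coef[:, j] / se
    return 2.0 * stats.t.sf(np.abs(t), n - p)


# ---------------------------------------------------------------------------
# estimator facade
# ---------------------------------------------------------------------------

class MixedDE(BaseEstimator):
    """Hierarchical differential-expression analysis as an estimator.

    ``fit`` takes the covariate-adjusted log2 matrix, the sample metadata,
    and (optionally) a precision-weight matrix; it fits the per-gene
    random-intercept models, moderates the variances, and assembles the
    result table.

    Parameters
    ----------
    fixed_effects : sequence of str, default ("diagnosis",)
        Fixed effects; the diagnosis contrast (AD − control, log2) is the
        quantity of interest. ``region`` may be added.
    moderate : bool, default True
        Apply empirical-Bayes variance moderation.
    prior_prob : float, default 0.01
        Prior probability of differential expression for the B-statistic.
    v0 : float or None
        Prior contrast variance for the B-statistic; estimated from the
        upper tail of the moderated t when None.
    lambda_max : float, default 50.0
        Upper bound of the variance-ratio search, τ²/σ² ≤ lambda_max.

    Attributes
    ----------
    results_ : DataFrame
        One row per gene: ``gene_id, logFC, AvExp, t, P.Value, adj.P.Val,
        B, converged, tau2``. Non-converged genes keep NaN statistics but
        still count toward the Bonferroni family size.
    fits_ : DataFrame
        Raw per-gene REML estimates.
    moderation_ : ModerationResult
    """

    def __init__(self, fixed_effects: Sequence[str] = ("diagnosis",),
                 moderate: bool = True, prior_prob: float = 0.01,
                 v0: float | None = None, lambda_max: float = 50.0):
        self.fixed_effects = fixed_effects
        self.moderate = moderate
        self.prior_prob = prior_prob
        self.v0 = v0
        self.lambda_max = lambda_max

    def fit(self, E_adj: pd.DataFrame, meta: pd.DataFrame,
            weights: pd.DataFrame | np.ndarray | None = None) -> "MixedDE":
        fits = fit_all(E_adj, weights, meta, self.fixed_effects,
                       lambda_max=self.lambda_max)
        ok = fits["converged"].to_numpy()
        usable = fits[ok]
        if self.moderate:
            moderation = ebayes_moderate(usable)
        else:
            moderation = ModerationResult(
                d0=0.0, s0_2=float("nan"),
                s_tilde2=np.asarray(usable["sigma2"], dtype=float),
                df_total=np.asarray(usable["df_resid"], dtype=float),
            )
        t_ok, p_ok = moderated_t(usable, moderation)
        se_ok = usable["se_unit"].to_numpy()
        b_ok = b_statistic(t_ok, moderation.df_total, se_ok,
                           prior_prob=self.prior_prob, v0=self.v0)
        G = len(fits)
        t = np.full(G, np.nan)
        p = np.full(G, np.nan)
        B = np.full(G, np.nan)
        t[ok], p[ok], B[ok] = t_ok, p_ok, b_ok
        avexp = np.asarray(E_adj, dtype=float).mean(axis=1)
        self.fits_ = fits
        self.moderation_ = moderation
        self.results_ = pd.DataFrame({
            "gene_id": fits["gene_id"],
            "logFC": fits["logFC"],
            "AvExp": avexp,
            "t": t,
            "P.Value": p,
            "adj.P.Val": bonferroni(np.where(np.isnan(p), np.nan, p), G),
            "B": B,
            "converged": fits["converged"],
            "tau2": fits["tau2"],
        })
        return self

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        """Genes passing the Bonferroni gate at the given level."""
        res = self.results_
        return res[res["adj.P.Val"] < alpha].sort_values("P.Value")
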