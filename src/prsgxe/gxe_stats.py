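"""Interaction regression models, simple slopes, regions of significance,
susceptibility-form indices, bootstrap, and multiple-imputation pooling.

The moderated model is ``outcome ~ covariates + X + M + X:M`` where X is the
cumulative adversity score and M the standardized polygenic score. Classical
(non-robust) OLS standard errors are used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import ValidationError

GXE_COLUMNS = ["outcome", "adversity", "rprs", "sex", "pc1", "pc2", "pc3"]
X_NAME, M_NAME, XM_NAME = "adversity", "rprs", "adversity:rprs"


@dataclass
class LinearModelFit:
    """OLS fit summary: estimates, classical SEs, and coefficient covariance."""

    names: list[str]
    params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    df_resid: float
    r_squared: float
    cov: np.ndarray
    nobs: int

    def __getitem__(self, name: str) -> float:
        return float(self.params[self.names.index(name)])

    def se(self, name: str) -> float:
        return float(self.bse[self.names.index(name)])

    def var(self, name: str) -> float:
        i = self.names.index(name)
        return float(self.cov[i, i])

    def covar(self, a: str, b: str) -> float:
        return float(self.cov[self.names.index(a), self.names.index(b)])

    def p(self, name: str) -> float:
        return float(self.pvalues[self.names.index(name)])


@dataclass
class InteractionAnalysis:
    """Interaction coefficients plus conditional (simple) slopes of X at
    low/high values of the moderator M."""

    bX: float
    bM: float
    bXM: float
    var_bX: float
    var_bM: float
    var_bXM: float
    cov_bX_bXM: float
    cov_bM_bXM: float
    m_low: float
    m_high: float
    slope_low: float
    slope_low_se: float
    slope_low_p: float
    slope_high: float
    slope_high_se: float
    slope_high_p: float
    t_crit: float
    df_resid: float


@dataclass
class RoSResult:
    """Johnson-Neyman boundaries on the adversity axis for the conditional
    effect of the moderator."""

    boundaries: list[float]
    pattern: str  # 'significant everywhere' | 'nowhere' | 'inside' | 'outside' | 'above'/'below' a single root
    eval_range: tuple[float, float]
    t_crit: float
    significant_everywhere: bool = False
    significant_nowhere: bool = False


@dataclass
class SusceptibilityIndices:
    """Crossover location and interaction-form indices.

    PoI is the proportion of the area between the low/high-moderator outcome
    lines lying on the adverse side of the crossover; values near 0.5 suggest
    differential susceptibility, values near 0 or 1 a diathesis-stress /
    vantage form. PA is the fraction of observed adversity values on the
    adverse side (case counting).
    """

    crossover: float
    poi: float | None
    pa: float | None
    eval_range: tuple[float, float]
    degenerate: bool = False


@dataclass
class BootstrapResult:
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int
    n_skipped: int = 0


@dataclass
class PooledEstimates:
    """Rubin's-rules pooling over multiply imputed fits."""

    names: list[str]
    estimates: np.ndarray
    within_var: np.ndarray
    between_var: np.ndarray
    total_se: np.ndarray
    df: np.ndarray
    pvalues: np.ndarray
    m: int


def _collinear_columns(design: np.ndarray, names: list[str]) -> list[str]:
    _, r = np.linalg.qr(design)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(design.shape) * np.finfo(float).eps if diag.size else 0.0
    return [names[i] for i in np.flatnonzero(diag <= tol)]


def fit_ols(y, design, names: list[str] | None = None) -> LinearModelFit:
    """Least squares with classical SEs; the design must include any
    intercept column explicitly and be full rank."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(design, dtype=float)
    if X.ndim != 2:
        raise ValidationError("design must be 2-D")
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    if len(names) != p:
        raise ValidationError("names length must match design columns")
    if y.shape[0] != n:
        raise ValidationError("y length must match design rows")
    if n <= p:
        raise ValidationError(f"need n > p (n={n}, p={p})")
    if np.linalg.matrix_rank(X) < p:
        bad = _collinear_columns(X, names)
        raise ValidationError(f"design is rank deficient; collinear columns: {bad}")
    res = sm.OLS(y, X).fit()
    return LinearModelFit(
        names=list(names),
        params=np.asarray(res.params, dtype=float),
        bse=np.asarray(res.bse, dtype=float),
        tvalues=np.asarray(res.tvalues, dtype=float),
        pvalues=np.asarray(res.pvalues, dtype=float),
        df_resid=float(res.df_resid),
        r_squared=float(res.rsquared),
        cov=np.asarray(res.cov_params(), dtype=float),
        nobs=n,
    )


def _gxe_design(data: pd.DataFrame, terms: list[str]) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(data))]
    names = ["intercept"]
    for t in terms:
        if t == XM_NAME:
            cols.append((data[X_NAME] * data[M_NAME]).to_numpy(dtype=float))
        else:
            cols.append(data[t].to_numpy(dtype=float))
        names.append(t)
    return np.column_stack(cols), names


def fit_gxe_models(data: pd.DataFrame) -> dict[str, LinearModelFit]:
    """Fit the three pre-registered models on complete rows.

    model1: outcome ~ sex + pc1-3 + adversity
    model2: outcome ~ sex + pc1-3 + rprs
    model3: outcome ~ sex + pc1-3 + adversity + rprs + adversity:rprs
    """
    missing = [c for c in GXE_COLUMNS if c not in data.columns]
    if missing:
        raise ValidationError(f"analysis table missing columns: {missing}")
    work = data[GXE_COLUMNS].dropna()
    cov = ["sex", "pc1", "pc2", "pc3"]
    specs = {
        "model1": cov + [X_NAME],
        "model2": cov + [M_NAME],
        "model3": cov + [X_NAME, M_NAME, XM_NAME],
    }
    fits = {}
    y = work["outcome"].to_numpy(dtype=float)
    for label, terms in specs.items():
        X, names = _gxe_design(work, terms)
        fits[label] = fit_ols(y, X, names)
    return fits


def _slope_at(fit: LinearModelFit, m: float) -> tuple[float, float]:
    """Conditional slope of X at moderator value m, with its variance."""
    b = fit[X_NAME] + fit[XM_NAME] * m
    v = (
        fit.var(X_NAME)
        + m * m * fit.var(XM_NAME)
        + 2.0 * m * fit.covar(X_NAME, XM_NAME)
    )
    return b, v


def simple_slopes(
    fit: LinearModelFit,
    m_points: tuple[float, float] = (-1.0, 1.0),
    alpha: float = 0.05,
) -> InteractionAnalysis:
    """Conditional adversity slopes at low/high moderator probes.

    Default probes are the moderator mean +/- 1 SD, i.e. (-1, 1) for a
    standardized score.
    """
    for term in (X_NAME, M_NAME, XM_NAME):
        if term not in fit.names:
            raise ValidationError(f"fit lacks required term {term!r}")
    m_low, m_high = m_points
    out = {}
    for tag, m in (("low", m_low), ("high", m_high)):
        b, v = _slope_at(fit, m)
        se = float(np.sqrt(v))
        t = b / se
        p = 2.0 * stats.t.sf(abs(t), fit.df_resid)
        out[tag] = (b, se, p)
    t_crit = float(stats.t.ppf(1.0 - alpha / 2.0, fit.df_resid))
    return InteractionAnalysis(
        bX=fit[X_NAME],
        bM=fit[M_NAME],
        bXM=fit[XM_NAME],
        var_bX=fit.var(X_NAME),
        var_bM=fit.var(M_NAME),
        var_bXM=fit.var(XM_NAME),
        cov_bX_bXM=fit.covar(X_NAME, XM_NAME),
        cov_bM_bXM=fit.covar(M_NAME, XM_NAME),
        m_low=m_low,
        m_high=m_high,
        slope_low=out["low"][0],
        slope_low_se=out["low"][1],
        slope_low_p=out["low"][2],
        slope_high=out["high"][0],
        slope_high_se=out["high"][1],
        slope_high_p=out["high"][2],
        t_crit=t_crit,
        df_resid=fit.df_resid,
    )


def _moderator_t2(fit: LinearModelFit, x: np.ndarray) -> np.ndarray:
    """Squared t of the conditional moderator effect bM + bXM*x."""
    bM, bXM = fit[M_NAME], fit[XM_NAME]
    vM, vXM = fit.var(M_NAME), fit.var(XM_NAME)
    cMX = fit.covar(M_NAME, XM_NAME)
    num = (bM + bXM * x) ** 2
    den = vM + 2.0 * x * cMX + x * x * vXM
    return num / den


def jn_regions(
    fit: LinearModelFit,
    eval_range: tuple[float, float],
    alpha: float = 0.05,
) -> RoSResult:
    """Johnson-Neyman boundaries where the conditional effect of the
    moderator on the outcome crosses the significance threshold.

    Solves ``(bM + bXM*x)^2 = t_crit^2 * Var(bM + bXM*x)`` for x and
    classifies significance over ``eval_range``.
    """
    if XM_NAME not in fit.names:
        raise ValidationError("fit lacks an interaction term")
    t_crit = float(stats.t.ppf(1.0 - alpha / 2.0, fit.df_resid))
    bM, bXM = fit[M_NAME], fit[XM_NAME]
    vM, vXM = fit.var(M_NAME), fit.var(XM_NAME)
    cMX = fit.covar(M_NAME, XM_NAME)
    t2 = t_crit * t_crit
    a = bXM * bXM - t2 * vXM
    b = 2.0 * (bM * bXM - t2 * cMX)
    c = bM * bM - t2 * vM

    scale = max(abs(a), abs(b), abs(c), 1e-300)
    roots: list[float] = []
    if abs(a) / scale < 1e-12:
        if abs(b) / scale >= 1e-12:
            roots = [-c / b]
    else:
        disc = b * b - 4.0 * a * c
        if disc > 0:
            sq = np.sqrt(disc)
            roots = sorted([(-b - sq) / (2.0 * a), (-b + sq) / (2.0 * a)])
        elif disc == 0:
            roots = [-b / (2.0 * a)]

    lo, hi = eval_range
    cuts = [lo] + [r for r in roots if lo < r < hi] + [hi]
    sig_segments = []
    for i in range(len(cuts) - 1):
        mid = 0.5 * (cuts[i] + cuts[i + 1])
        sig_segments.append(bool(_moderator_t2(fit, np.array([mid]))[0] > t2))
    everywhere = all(sig_segments)
    nowhere = not any(sig_segments)
    inside_roots = [r for r in roots if lo < r < hi]
    if everywhere:
        pattern = "significant everywhere"
    elif nowhere:
        pattern = "significant nowhere"
    elif len(inside_roots) == 2:
        pattern = "significant outside boundaries" if sig_segments[0] else "significant between boundaries"
    else:
        pattern = "significant below boundary" if sig_segments[0] else "significant above boundary"
    return RoSResult(
        boundaries=sorted(roots),
        pattern=pattern,
        eval_range=(float(lo), float(hi)),
        t_crit=t_crit,
        significant_everywhere=everywhere,
        significant_nowhere=nowhere,
    )


def poi_pa(
    fit: LinearModelFit,
    x_values,
    eval_range: tuple[float, float] | None = None,
    m_points: tuple[float, float] = (-1.0, 1.0),
) -> SusceptibilityIndices:
    """Crossover point and PoI / PA interaction-form indices.

    The outcome lines at the two moderator probes intersect at
    ``x0 = -bM / bXM``. The adverse side is where the high-moderator line
    lies below the low-moderator line (higher outcome = better). PoI is the
    fraction of inter-line area on that side over the evaluation range
    (default: observed min-max of ``x_values``); PA is the fraction of
    observed adversity values on that side.
    """
    x_values = np.asarray(x_values, dtype=float)
    x_values = x_values[~np.isnan(x_values)]
    if x_values.size == 0:
        raise ValidationError("x_values is empty")
    if eval_range is None:
        eval_range = (float(x_values.min()), float(x_values.max()))
    lo, hi = eval_range
    bM, bXM = fit[M_NAME], fit[XM_NAME]
    if bXM == 0.0:
        return SusceptibilityIndices(
            crossover=float("nan"), poi=None, pa=None,
            eval_range=(lo, hi), degenerate=True,
        )
    x0 = -bM / bXM
    dm = m_points[1] - m_points[0]
    # gap(x) = y_high - y_low = (bM + bXM*x) * dm; adverse where gap < 0
    # (with dm > 0: x > x0 when bXM < 0, x < x0 when bXM > 0)
    adverse_right = (bXM * dm) < 0

    def seg_area(a: float, b: float) -> float:
        # integral of |bM + bXM*x| * |dm| over [a, b] with no sign change
        if b <= a:
            return 0.0
        mid_val = bM + bXM * 0.5 * (a + b)
        return abs(mid_val) * abs(dm) * (b - a)

    if x0 <= lo:
        poi = 1.0 if adverse_right else 0.0
    elif x0 >= hi:
        poi = 0.0 if adverse_right else 1.0
    else:
        left = seg_area(lo, x0)
        right = seg_area(x0, hi)
        total = left + right
        adverse_area = right if adverse_right else left
        poi = adverse_area / total if total > 0 else float("nan")
    pa = float(np.mean(x_values > x0)) if adverse_right else float(np.mean(x_values < x0))
    return SusceptibilityIndices(
        crossover=float(x0), poi=float(poi), pa=pa,
        eval_range=(float(lo), float(hi)), degenerate=False,
    )


def _lstsq_bxm(y: np.ndarray, X: np.ndarray) -> float | None:
    """Fast interaction-coefficient fit; None when rank deficient.
    The interaction column is assumed last."""
    if np.linalg.matrix_rank(X) < X.shape[1]:
        return None
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(beta[-1])


def bootstrap_interaction(
    data: pd.DataFrame, n_boot: int = 1000, seed: int = 0
) -> BootstrapResult:
    """Non-parametric case-resampling bootstrap of the model-3 interaction
    coefficient: SE = SD of replicates, CI = 2.5/97.5 percentiles."""
    if n_boot < 100:
        raise ValidationError("n_boot must be >= 100")
    work = data[GXE_COLUMNS].dropna().reset_index(drop=True)
    terms = ["sex", "pc1", "pc2", "pc3", X_NAME, M_NAME, XM_NAME]
    X, names = _gxe_design(work, terms)
    y = work["outcome"].to_numpy(dtype=float)
    point = _lstsq_bxm(y, X)
    if point is None:
        raise ValidationError("full-sample design is rank deficient")
    rng = np.random.default_rng(seed)
    n = len(work)
    reps: list[float] = []
    skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        b = _lstsq_bxm(y[idx], X[idx])
        if b is None:
            skipped += 1
        else:
            reps.append(b)
    if skipped > 0.1 * n_boot:
        raise ValidationError(
            f"{skipped}/{n_boot} bootstrap replicates were rank deficient"
        )
    reps_arr = np.asarray(reps)
    lo, hi = np.percentile(reps_arr, [2.5, 97.5])
    return BootstrapResult(
        estimate=point,
        se=float(reps_arr.std(ddof=1)),
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
        seed=seed,
        n_skipped=skipped,
    )


def plot_interaction(
    fit: LinearModelFit,
    x_range: tuple[float, float],
    m_points: tuple[float, float] = (-1.0, 1.0),
    path=None,
):
    """Crossover plot: predicted-outcome lines (relative to the covariate
    baseline) at the low/high moderator probes over the adversity range.
    Requires matplotlib; returns the figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xs = np.linspace(*x_range, 200)
    b0 = fit["intercept"] if "intercept" in fit.names else 0.0
    fig, ax = plt.subplots(figsize=(5, 4))
    for m, style, label in (
        (m_points[0], "--", f"low moderator (m = {m_points[0]:g})"),
        (m_points[1], "-", f"high moderator (m = {m_points[1]:g})"),
    ):
        y = b0 + fit[X_NAME] * xs + fit[M_NAME] * m + fit[XM_NAME] * xs * m
        ax.plot(xs, y, style, label=label)
    if fit[XM_NAME] != 0:
        x0 = -fit[M_NAME] / fit[XM_NAME]
        if x_range[0] <= x0 <= x_range[1]:
            ax.axvline(x0, color="red", lw=0.8, label="crossover")
    ax.set_xlabel("adversity score")
    ax.set_ylabel("predicted outcome")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def pool_estimates(fits: list[LinearModelFit]) -> PooledEstimates:
    """Combine multiply-imputed fits by Rubin's rules.

    Pooled estimate = mean; total variance = W + (1 + 1/m) B with Rubin's
    small-sample degrees of freedom (infinite when B = 0).
    """
    m = len(fits)
    if m < 2:
        raise ValidationError("pooling requires >= 2 fits")
    names = fits[0].names
    for f in fits[1:]:
        if f.names != names:
            raise ValidationError("fits have mismatched coefficient names")
    q = np.stack([f.params for f in fits])  # m x p
    u = np.stack([f.bse ** 2 for f in fits])
    qbar = q.mean(axis=0)
    w = u.mean(axis=0)
    b = q.var(axis=0, ddof=1)
    total = w + (1.0 + 1.0 / m) * b
    with np.errstate(divide="ignore"):
        df = (m - 1) * (1.0 + w / ((1.0 + 1.0 / m) * b)) ** 2
    df = np.where(b == 0, np.inf, df)
    se = np.sqrt(total)
    tstat = qbar / se
    p = np.where(
        np.isinf(df),
        2.0 * stats.norm.sf(np.abs(tstat)),
        2.0 * stats.t.sf(np.abs(tstat), np.where(np.isinf(df), 1.0, df)),
    )
    return PooledEstimates(
        names=list(names),
        estimates=qbar,
        within_var=w,
        between_var=b,
        total_se=se,
        df=df,
        pvalues=p,
        m=m,
    )
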