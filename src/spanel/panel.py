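"""Balanced panel container, within transformation, pooled and FE OLS.

The panel is stored period-major: all N regions of the first period, then
the second, and so on.  With that stacking every per-period spatial
operator is the block-diagonal ``I_T (x) W``, applied as ``W`` per period.

The fixed-effects ("within") estimator de-trends each region by its own
time mean, eliminating the constant and the region effects; both are
recovered afterwards under the normalisation that the effects sum to zero.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.stats

from .weights import SpatialWeights, spatial_lag

__all__ = [
    "PanelData",
    "FitResult",
    "WithinResult",
    "validate_panel",
    "log_outcome",
    "add_spatial_lags",
    "within_transform",
    "pooled_ols",
    "fe_ols",
]


@dataclass
class PanelData:
    """Balanced N x T panel with outcome vector and design matrix.

    ``y`` has length N*T and ``X`` shape (N*T, K), both period-major.
    """

    y: np.ndarray
    X: np.ndarray
    region_ids: list
    period_labels: list
    covariate_names: list

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        n, t = len(self.region_ids), len(self.period_labels)
        if self.y.shape[0] != n * t or self.X.shape[0] != n * t:
            raise ValueError("y and X must have N*T rows, period-major")
        if self.X.shape[1] != len(self.covariate_names):
            raise ValueError("covariate_names must match X columns")
        if t < 1 or n < 1:
            raise ValueError("need at least one region and one period")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def n_periods(self) -> int:
        return len(self.period_labels)

    @property
    def n_obs(self) -> int:
        return self.y.shape[0]

    def y_blocks(self) -> np.ndarray:
        """Outcome as a (T, N) array of per-period cross-sections."""
        return self.y.reshape(self.n_periods, self.n_regions)

    def x_blocks(self) -> np.ndarray:
        """Design as a (T, N, K) array."""
        return self.X.reshape(self.n_periods, self.n_regions, -1)

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame (region_id, period, outcome, covariates)."""
        t, n = self.n_periods, self.n_regions
        df = pd.DataFrame(self.X, columns=self.covariate_names)
        df.insert(0, "outcome", self.y)
        df.insert(0, "period", np.repeat(self.period_labels, n))
        df.insert(0, "region_id", np.tile(self.region_ids, t))
        return df


@dataclass
class FitResult:
    """Estimates and fit statistics for one panel model.

    ``beta`` excludes the constant; ``alpha`` is the recovered grand
    constant and ``mu`` the recovered region effects (sum-to-zero
    normalisation).  ``fitted``/``residuals`` are on the original outcome
    scale; ``within_fitted``/``within_residuals`` on the demeaned
    estimation scale where applicable.  ``loglik`` includes the Gaussian
    2*pi constant, ``loglik_no_constant`` drops it.
    """

    model_tag: str
    coef_names: list
    beta: np.ndarray
    std_errors: np.ndarray
    z_stats: np.ndarray
    p_values: np.ndarray
    sigma2: float
    loglik: float
    loglik_no_constant: float
    nobs: int
    df_resid: int
    alpha: float | None = None
    mu: np.ndarray | None = None
    spatial_param: float | None = None
    spatial_param_se: float | None = None
    spatial_param_p: float | None = None
    r2: float | None = None
    corr2: float | None = None
    aic: float | None = None
    fitted: np.ndarray | None = None
    residuals: np.ndarray | None = None
    within_fitted: np.ndarray | None = None
    within_residuals: np.ndarray | None = None
    n_iter: int | None = None

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.beta,
                "std_err": self.std_errors,
                "z": self.z_stats,
                "p_value": self.p_values,
            },
            index=self.coef_names,
        )


@dataclass
class WithinResult:
    """Demeaned panel plus the region means needed to recover alpha and mu."""

    panel: PanelData
    y_means: np.ndarray  # (N,)
    x_means: np.ndarray  # (N, K)
    y_grand: float = 0.0
    x_grand: np.ndarray = field(default_factory=lambda: np.empty(0))


def validate_panel(
    records,
    region_col: str = "region_id",
    period_col: str = "period",
    outcome_col: str = "outcome",
    covariates: list | None = None,
    period_order: list | None = None,
) -> PanelData:
    """Build a balanced, period-major :class:`PanelData` from long records.

    Regions are ordered by id (string sort); periods by ``period_order``
    when given, else by sorted label.  Raises on duplicated or missing
    (region, period) pairs and on non-numeric covariates, naming the
    offenders.
    """
    df = pd.DataFrame(records).copy()
    for col in (region_col, period_col, outcome_col):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    df[region_col] = df[region_col].astype(str)
    df[period_col] = df[period_col].astype(str)
    if covariates is None:
        covariates = [
            c for c in df.columns if c not in (region_col, period_col, outcome_col)
        ]
    regions = sorted(df[region_col].unique())
    if period_order is None:
        periods = sorted(df[period_col].unique())
    else:
        periods = [str(p) for p in period_order]
        extra = set(df[period_col].unique()) - set(periods)
        if extra:
            raise ValueError(f"periods not in declared order: {sorted(extra)}")
    dup = df.duplicated(subset=[region_col, period_col])
    if dup.any():
        pairs = df.loc[dup, [region_col, period_col]].apply(tuple, axis=1).tolist()
        raise ValueError(f"duplicated (region, period) pairs: {pairs[:5]}")
    expected = {(r, p) for r in regions for p in periods}
    present = set(df[[region_col, period_col]].apply(tuple, axis=1))
    missing = sorted(expected - present)
    if missing:
        raise ValueError(f"unbalanced panel, missing (region, period): {missing[:5]}")
    for col in [outcome_col] + covariates:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = df.loc[vals.isna(), [region_col, period_col]].apply(tuple, axis=1)
            raise ValueError(f"non-numeric values in {col!r} at {bad.tolist()[:5]}")
        df[col] = vals.astype(float)
    df = df.set_index([period_col, region_col]).sort_index()
    order = pd.MultiIndex.from_product([periods, regions], names=[period_col, region_col])
    df = df.loc[order]
    return PanelData(
        y=df[outcome_col].to_numpy(),
        X=df[covariates].to_numpy(),
        region_ids=regions,
        period_labels=periods,
        covariate_names=list(covariates),
    )


def log_outcome(p: PanelData, base: str | float = "e") -> PanelData:
    """Replace the outcome by its logarithm (natural log by default).

    ``base=10`` matches conventions where the logged outcome is reported
    in decimal magnitude.  Nonpositive outcomes raise, naming the rows.
    """
    bad = np.flatnonzero(p.y <= 0)
    if bad.size:
        n = p.n_regions
        where = [(p.region_ids[i % n], p.period_labels[i // n]) for i in bad[:5]]
        raise ValueError(f"nonpositive outcome at (region, period): {where}")
    if base == "e":
        y = np.log(p.y)
    elif float(base) == 10.0:
        y = np.log10(p.y)
    else:
        y = np.log(p.y) / np.log(float(base))
    return replace(p, y=y)


def add_spatial_lags(
    p: PanelData, w: SpatialWeights, variables: list
) -> PanelData:
    """Append neighbour-average columns ``W*<name>`` per period.

    Applies the row-standardised ``W`` blockwise (``I_T (x) W``): each
    period's cross-section is lagged independently.
    """
    if not w.standardized:
        raise ValueError("weights must be row-standardised for neighbour averages")
    if list(w.ids) != [str(r) for r in p.region_ids]:
        raise ValueError("weights ids do not match panel region ids")
    unknown = [v for v in variables if v not in p.covariate_names]
    if unknown:
        raise ValueError(f"unknown covariates: {unknown}")
    xb = p.x_blocks()  # (T, N, K)
    new_cols = []
    for name in variables:
        k = p.covariate_names.index(name)
        lagged = np.vstack([spatial_lag(w, xb[t, :, k]) for t in range(p.n_periods)])
        new_cols.append(lagged.ravel())
    X = np.column_stack([p.X] + new_cols)
    names = list(p.covariate_names) + [f"W*{v}" for v in variables]
    return replace(p, X=X, covariate_names=names)


def within_transform(p: PanelData) -> WithinResult:
    """Subtract each region's time mean from y and every column of X.

    Eliminates the constant and the region fixed effects; the stored
    means allow both to be recovered after estimation.  Idempotent.
    """
    if p.n_periods < 2:
        raise ValueError("within transformation requires T >= 2")
    yb = p.y_blocks()  # (T, N)
    xb = p.x_blocks()  # (T, N, K)
    y_means = yb.mean(axis=0)
    x_means = xb.mean(axis=0)
    demeaned = replace(
        p,
        y=(yb - y_means).ravel(),
        X=(xb - x_means).reshape(p.n_obs, -1),
    )
    return WithinResult(
        panel=demeaned,
        y_means=y_means,
        x_means=x_means,
        y_grand=float(p.y.mean()),
        x_grand=p.X.mean(axis=0),
    )


def _check_full_rank(X: np.ndarray, names: list) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name a minimal set of columns that cannot be added independently
        culprits, basis = [], np.empty((X.shape[0], 0))
        for j, name in enumerate(names):
            cand = np.column_stack([basis, X[:, j]])
            if np.linalg.matrix_rank(cand) == basis.shape[1]:
                culprits.append(name)
            else:
                basis = cand
        raise ValueError(f"design matrix is rank deficient; collinear: {culprits}")


def _ols(y: np.ndarray, X: np.ndarray):
    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    return beta, resid, XtX_inv


def _gaussian_loglik(sse: float, nobs: int) -> tuple[float, float]:
    """ML Gaussian loglik (with and without the 2*pi constant)."""
    sigma2_ml = sse / nobs
    core = -0.5 * nobs * np.log(sigma2_ml) - 0.5 * nobs
    return core - 0.5 * nobs * np.log(2 * np.pi), core


def _inference(beta, XtX_inv, sigma2):
    se = np.sqrt(sigma2 * np.diag(XtX_inv))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.inf)
    pvals = 2 * scipy.stats.norm.sf(np.abs(z))
    return se, z, pvals


def pooled_ols(p: PanelData) -> FitResult:
    """Pooled OLS with a common intercept and classical standard errors."""
    n, k = p.n_obs, p.X.shape[1]
    if n <= k + 1:
        raise ValueError("too few observations for pooled OLS")
    Xc = np.column_stack([np.ones(n), p.X])
    _check_full_rank(Xc, ["const"] + list(p.covariate_names))
    coef, resid, XtX_inv = _ols(p.y, Xc)
    sse = float(resid @ resid)
    sigma2 = sse / (n - k - 1)
    se, z, pvals = _inference(coef, XtX_inv, sigma2)
    fitted = p.y - resid
    sst = float(np.sum((p.y - p.y.mean()) ** 2))
    r2 = 1 - sse / sst if sst > 0 else np.nan
    loglik, loglik_nc = _gaussian_loglik(sse, n)
    n_params = k + 2  # intercept, slopes, sigma2
    corr = np.corrcoef(p.y, fitted)[0, 1] if sst > 0 else np.nan
    return FitResult(
        model_tag="pooled",
        coef_names=list(p.covariate_names),
        beta=coef[1:],
        std_errors=se[1:],
        z_stats=z[1:],
        p_values=pvals[1:],
        sigma2=sigma2,
        loglik=loglik,
        loglik_no_constant=loglik_nc,
        nobs=n,
        df_resid=n - k - 1,
        alpha=float(coef[0]),
        r2=r2,
        corr2=float(corr**2) if np.isfinite(corr) else np.nan,
        aic=-2 * loglik + 2 * n_params,
        fitted=fitted,
        residuals=resid,
    )


def fe_ols(p: PanelData) -> FitResult:
    """Fixed-effects (within) OLS.

    Identical to least squares with a dummy per region; region effects are
    recovered with the sum-to-zero normalisation and sigma2 uses the
    NT - N - K degrees of freedom of the within estimator.
    """
    if p.n_periods < 2:
        raise ValueError("fixed-effects estimation requires T >= 2")
    wres = within_transform(p)
    d = wres.panel
    within_var = d.X.var(axis=0)
    dead = [name for name, v in zip(d.covariate_names, within_var) if v <= 1e-14]
    if dead:
        raise ValueError(
            f"covariates with no within-region variation (absorbed by the "
            f"fixed effects): {dead}"
        )
    _check_full_rank(d.X, list(d.covariate_names))
    n, t, k = p.n_regions, p.n_periods, p.X.shape[1]
    beta, resid, XtX_inv = _ols(d.y, d.X)
    sse = float(resid @ resid)
    df = n * t - n - k
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    sigma2 = sse / df
    se, z, pvals = _inference(beta, XtX_inv, sigma2)
    alpha = float(wres.y_grand - wres.x_grand @ beta)
    mu = wres.y_means - wres.x_means @ beta - alpha
    fitted = alpha + np.tile(mu, t) + p.X @ beta
    residuals = p.y - fitted
    sst = float(np.sum(d.y**2))
    r2 = 1 - sse / sst if sst > 0 else np.nan
    loglik, loglik_nc = _gaussian_loglik(sse, n * t)
    corr = np.corrcoef(p.y, fitted)[0, 1]
    return FitResult(
        model_tag="fe",
        coef_names=list(p.covariate_names),
        beta=beta,
        std_errors=se,
        z_stats=z,
        p_values=pvals,
        sigma2=sigma2,
        loglik=loglik,
        loglik_no_constant=loglik_nc,
        nobs=n * t,
        df_resid=df,
        alpha=alpha,
        mu=mu,
        r2=r2,
        corr2=float(corr**2),
        aic=-2 * loglik + 2 * (k + 1),
        fitted=fitted,
        residuals=residuals,
        within_fitted=d.X @ beta,
        within_residuals=resid,
    )
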