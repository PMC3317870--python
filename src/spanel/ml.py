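"""Maximum-likelihood spatial panel estimators on within-transformed data.

Two fixed-effects models with spatial dependence are fitted:

* spatial error autocorrelation (SEA): ``y_t = X_t b + mu + phi_t`` with
  ``phi_t = rho W phi_t + eps_t`` — dependence lives in the disturbance;
* spatial autoregressive lag (SAR): ``y_t = delta W y_t + X_t b + mu + eps_t``
  — the outcome is jointly determined with its neighbours'.

Both likelihoods concentrate the regression coefficients and the variance
analytically, leaving a scalar problem in the spatial parameter whose
log-determinant term ``ln|I - rho W|`` is evaluated from the cached real
spectrum of the row-standardised weights.  The SEA model is estimated by
the classic iterative two-stage scheme (spatial GLS for beta given rho,
scalar likelihood maximisation for rho given beta), the SAR model by a
single concentrated optimisation.

Reported sigma2 and loglik follow the NT convention of the demeaned
pseudo-likelihood; standard errors come from the information matrix of the
exact likelihood of the demeaned data, which has N(T-1) effective
observations (the demeaning removes one cross-section of information).
The ``effective_df_correction`` switch also applies that correction to the
reported sigma2/loglik.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.optimize
import scipy.stats

from .panel import FitResult, PanelData, _check_full_rank, _ols, within_transform
from .weights import SpatialWeights, eigenvalues

__all__ = [
    "SpatialMLSettings",
    "ConvergenceError",
    "log_jacobian",
    "fit_fe_sea",
    "fit_fe_sar",
    "fit_statistics",
]


class ConvergenceError(RuntimeError):
    """Two-stage iteration failed to converge; carries the iterate trace."""

    def __init__(self, message: str, trace: list):
        super().__init__(message)
        self.trace = list(trace)


@dataclass
class SpatialMLSettings:
    """Tuning knobs for the spatial ML fits.

    ``param_bounds`` defaults to the open invertibility interval
    ``(1/lambda_min + 1e-6, 1 - 1e-6)`` of the standardised weights.
    ``tol`` is the convergence tolerance on the spatial parameter.
    ``se_method`` selects the analytic information matrix or a numerical
    Hessian of the exact demeaned-data likelihood.
    ``effective_df_correction`` reports sigma2 = e'e/(N(T-1)) and the
    matching likelihood instead of the NT convention.
    """

    param_bounds: tuple | None = None
    tol: float = 1e-8
    max_iter: int = 100
    se_method: str = "information_matrix"
    effective_df_correction: bool = False

    def resolve_bounds(self, spectrum: np.ndarray) -> tuple:
        if self.param_bounds is not None:
            lo, hi = self.param_bounds
        else:
            lam_min = spectrum.min()
            lo = 1.0 / lam_min + 1e-6 if lam_min < 0 else -1 + 1e-6
            hi = 1.0 - 1e-6
        for edge in (lo, hi):
            if np.any(1.0 - edge * spectrum <= 0):
                raise ValueError(
                    f"bounds ({lo}, {hi}) leave the invertibility region of W"
                )
        return float(lo), float(hi)


def log_jacobian(rho: float, spectrum: np.ndarray, n_periods: int) -> float:
    """``T * ln|I_N - rho W|`` from the eigenvalues of the standardised W.

    Raises a domain error when ``1 - rho*lambda_i <= 0`` for any i.
    """
    terms = 1.0 - rho * np.asarray(spectrum)
    if np.any(terms <= 0):
        raise ValueError(f"rho={rho} outside the invertibility region of W")
    return float(n_periods * np.log(terms).sum())


def _maximize_scalar(neg_obj, lo, hi, xatol):
    res = scipy.optimize.minimize_scalar(
        neg_obj, bounds=(lo, hi), method="bounded", options={"xatol": xatol}
    )
    return float(res.x)


def _blockwise(Wsp, v: np.ndarray, t: int) -> np.ndarray:
    """Apply ``I_T (x) W`` to a period-major stacked vector or matrix."""
    if v.ndim == 1:
        return (Wsp @ v.reshape(t, -1).T).T.ravel()
    n = v.shape[0] // t
    out = np.empty_like(v)
    for s in range(t):
        out[s * n : (s + 1) * n] = Wsp @ v[s * n : (s + 1) * n]
    return out


def _recover_effects(wres, beta, delta_Wybar=None):
    """Grand constant and sum-to-zero region effects from stored means."""
    ybar = wres.y_means if delta_Wybar is None else wres.y_means - delta_Wybar
    raw = ybar - wres.x_means @ beta
    alpha = float(raw.mean())
    return alpha, raw - alpha


def _param_inference(param, var, label):
    if var <= 0 or not np.isfinite(var):
        warnings.warn(f"non-positive variance estimate for {label}", UserWarning)
        return None, None
    se = float(np.sqrt(var))
    p = float(2 * scipy.stats.norm.sf(abs(param) / se)) if se > 0 else 0.0
    return se, p


def _report_scale(sse, n, t, eff):
    """(sigma2, loglik multiplier pair) under the chosen df convention."""
    if eff:
        nobs_eff = n * (t - 1)
        jac_mult = t - 1
    else:
        nobs_eff = n * t
        jac_mult = t
    return nobs_eff, jac_mult


def _finish_loglik(sse, n, t, jacobian_at_opt, eff):
    nobs_eff, jac_mult = _report_scale(sse, n, t, eff)
    sigma2 = sse / nobs_eff
    # jacobian_at_opt is T * ln|B|; rescale to the reporting convention
    jac = jacobian_at_opt * (jac_mult / t)
    core = -0.5 * nobs_eff * np.log(sigma2) - 0.5 * nobs_eff + jac
    return sigma2, core - 0.5 * nobs_eff * np.log(2 * np.pi), core


def fit_fe_sea(
    p: PanelData,
    w: SpatialWeights,
    settings: SpatialMLSettings | None = None,
    fix_param: float | None = None,
) -> FitResult:
    """Fixed-effects spatial-error model by iterative two-stage ML.

    Alternates spatially filtered least squares for beta given rho with a
    bounded scalar maximisation of the concentrated log-likelihood

        L(rho) = -(NT/2) ln(e(rho)'e(rho)/NT) + T ln|I - rho W|

    for rho given beta, where ``e_t = (I - rho W)(y*_t - X*_t beta)`` on the
    demeaned data, until successive rho iterates agree within ``tol``.
    ``fix_param`` skips the optimisation (rho held fixed), which nests the
    plain FE estimator at 0.
    """
    settings = settings or SpatialMLSettings()
    if not w.standardized:
        raise ValueError("weights must be row-standardised")
    wres = within_transform(p)
    d = wres.panel
    _check_full_rank(d.X, list(d.covariate_names))
    n, t, k = p.n_regions, p.n_periods, p.X.shape[1]
    lam = eigenvalues(w)
    lo, hi = settings.resolve_bounds(lam)
    Wsp = w.sparse()
    ystar, Xstar = d.y, d.X
    Wy = _blockwise(Wsp, ystar, t)
    WX = _blockwise(Wsp, Xstar, t)

    def gls_beta(rho):
        yf = ystar - rho * Wy
        Xf = Xstar - rho * WX
        return _ols(yf, Xf)

    def profile(rho, beta):
        u = ystar - Xstar @ beta
        e = u - rho * _blockwise(Wsp, u, t)
        sse = float(e @ e)
        return -0.5 * n * t * np.log(sse / (n * t)) + log_jacobian(rho, lam, t)

    trace = []
    if fix_param is not None:
        rho = float(fix_param)
        beta, _, XtX_inv = gls_beta(rho)
        n_iter = 0
    else:
        rho = 0.0
        beta, _, XtX_inv = gls_beta(rho)
        n_iter = None
        obj = -np.inf
        for it in range(settings.max_iter):
            rho_new = _maximize_scalar(
                lambda r: -profile(r, beta), lo, hi, min(settings.tol, 1e-9)
            )
            trace.append(rho_new)
            beta, _, XtX_inv = gls_beta(rho_new)
            obj_new = profile(rho_new, beta)
            # stop on the parameter change, or once the monotone block
            # ascent stops improving the objective beyond rounding noise
            # (the scalar optimiser cannot localise rho more finely than
            # the likelihood's floating-point flatness near the optimum)
            if (
                abs(rho_new - rho) < settings.tol
                or obj_new - obj < 1e-9 * (1.0 + abs(obj_new))
            ):
                rho = rho_new
                n_iter = it + 1
                break
            rho = rho_new
            obj = obj_new
        if n_iter is None:
            raise ConvergenceError(
                f"SEA two-stage loop did not converge in {settings.max_iter} "
                "iterations",
                trace,
            )
        if min(rho - lo, hi - rho) < 1e-5:
            warnings.warn(
                f"rho estimate {rho:.6f} is pinned near a bound of ({lo:.4f}, {hi:.4f})",
                UserWarning,
            )
    u = ystar - Xstar @ beta
    e = u - rho * _blockwise(Wsp, u, t)
    sse = float(e @ e)
    sigma2, loglik, loglik_nc = _finish_loglik(
        sse, n, t, log_jacobian(rho, lam, t), settings.effective_df_correction
    )
    # inference on the exact demeaned-data likelihood: N(T-1) effective obs
    sigma2_eff = sse / (n * (t - 1))
    se_beta, var_rho = _sea_inference(
        Wsp, XtX_inv, rho, sigma2_eff, n, t, settings, ystar, Xstar, lam
    )
    z = np.where(se_beta > 0, beta / se_beta, np.inf)
    pvals = 2 * scipy.stats.norm.sf(np.abs(z))
    rho_se, rho_p = _param_inference(rho, var_rho, "rho")
    alpha, mu = _recover_effects(wres, beta)
    fitted = alpha + np.tile(mu, t) + p.X @ beta
    fr = FitResult(
        model_tag="fe_sea",
        coef_names=list(p.covariate_names),
        beta=beta,
        std_errors=se_beta,
        z_stats=z,
        p_values=pvals,
        sigma2=sigma2,
        loglik=loglik,
        loglik_no_constant=loglik_nc,
        nobs=n * t,
        df_resid=n * (t - 1) - k - 2,
        alpha=alpha,
        mu=mu,
        spatial_param=rho,
        spatial_param_se=rho_se,
        spatial_param_p=rho_p,
        fitted=fitted,
        residuals=p.y - fitted,
        within_fitted=Xstar @ beta,
        within_residuals=ystar - Xstar @ beta,
        n_iter=n_iter,
    )
    return fit_statistics(fr, p.y)


def _sea_inference(Wsp, XtX_inv, rho, sigma2, n, t, settings, ystar, Xstar, lam):
    """(se_beta, var_rho) for the SEA fit.

    Information matrix of the exact demeaned-data likelihood: the beta
    block is sigma2 * (Xf'Xf)^-1 from the spatial GLS; the (rho, sigma2)
    block uses W_B = W (I - rho W)^-1 with trace terms scaled by the T-1
    effective cross-sections.
    """
    te = t - 1
    if settings.se_method == "numerical_hessian":
        return _sea_numeric(Wsp, rho, sigma2, n, t, ystar, Xstar, lam)
    se_beta = np.sqrt(sigma2 * np.diag(XtX_inv))
    B = np.eye(n) - rho * Wsp.toarray()
    WB = Wsp.toarray() @ np.linalg.inv(B)
    i_rr = te * (np.trace(WB @ WB) + np.trace(WB.T @ WB))
    i_rs = te * np.trace(WB) / sigma2
    i_ss = n * te / (2 * sigma2**2)
    var_rho = 1.0 / (i_rr - i_rs**2 / i_ss)
    return se_beta, var_rho


def _sea_numeric(Wsp, rho, sigma2, n, t, ystar, Xstar, lam):
    """Numerical-Hessian fallback on the exact (beta, rho, sigma2) loglik."""
    te = t - 1

    def negll(theta):
        b, r, s2 = theta[:-2], theta[-2], theta[-1]
        if s2 <= 0:
            return np.inf
        u = ystar - Xstar @ b
        e = u - r * _blockwise(Wsp, u, t)
        return -(
            -0.5 * n * te * np.log(s2)
            + log_jacobian(r, lam, te)
            - float(e @ e) / (2 * s2)
        )

    beta0 = _ols(ystar - rho * _blockwise(Wsp, ystar, t), Xstar - rho * _blockwise(Wsp, Xstar, t))[0]
    theta = np.concatenate([beta0, [rho, sigma2]])
    H = _numeric_hessian(negll, theta)
    cov = np.linalg.inv(H)
    return np.sqrt(np.diag(cov)[:-2]), float(cov[-2, -2])


def _numeric_hessian(f, x, h=1e-5):
    k = x.size
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h * max(1.0, abs(x[i]))
            ej[j] = h * max(1.0, abs(x[j]))
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * ei[i] * ej[j])
    return H


def fit_fe_sar(
    p: PanelData,
    w: SpatialWeights,
    settings: SpatialMLSettings | None = None,
    fix_param: float | None = None,
) -> FitResult:
    """Fixed-effects spatial-lag model by concentrated ML.

    With demeaned data, regress y* and Wy* on X* once (coefficients b0,
    b1, residuals e0, e1); the concentrated log-likelihood

        L(delta) = -(NT/2) ln((e0 - delta e1)'(e0 - delta e1)/NT)
                   + T ln|I - delta W|

    is maximised over delta by bounded scalar optimisation, after which
    ``beta = b0 - delta b1``.
    """
    settings = settings or SpatialMLSettings()
    if not w.standardized:
        raise ValueError("weights must be row-standardised")
    wres = within_transform(p)
    d = wres.panel
    _check_full_rank(d.X, list(d.covariate_names))
    n, t, k = p.n_regions, p.n_periods, p.X.shape[1]
    lam = eigenvalues(w)
    lo, hi = settings.resolve_bounds(lam)
    Wsp = w.sparse()
    ystar, Xstar = d.y, d.X
    Wy = _blockwise(Wsp, ystar, t)
    b0, e0, XtX_inv = _ols(ystar, Xstar)
    b1, e1, _ = _ols(Wy, Xstar)

    def concentrated(delta):
        e = e0 - delta * e1
        return -0.5 * n * t * np.log(float(e @ e) / (n * t)) + log_jacobian(
            delta, lam, t
        )

    if fix_param is not None:
        delta = float(fix_param)
    else:
        delta = _maximize_scalar(
            lambda dd: -concentrated(dd), lo, hi, min(settings.tol, 1e-9)
        )
        if min(delta - lo, hi - delta) < 1e-5:
            warnings.warn(
                f"delta estimate {delta:.6f} is pinned near a bound of "
                f"({lo:.4f}, {hi:.4f})",
                UserWarning,
            )
    beta = b0 - delta * b1
    e = e0 - delta * e1
    sse = float(e @ e)
    sigma2, loglik, loglik_nc = _finish_loglik(
        sse, n, t, log_jacobian(delta, lam, t), settings.effective_df_correction
    )
    sigma2_eff = sse / (n * (t - 1))
    se_beta, var_delta = _sar_inference(
        Wsp, Xstar, beta, delta, sigma2_eff, n, t, settings, ystar, lam
    )
    z = np.where(se_beta > 0, beta / se_beta, np.inf)
    pvals = 2 * scipy.stats.norm.sf(np.abs(z))
    d_se, d_p = _param_inference(delta, var_delta, "delta")
    Wybar = np.asarray(Wsp @ wres.y_means).ravel()
    alpha, mu = _recover_effects(wres, beta, delta_Wybar=delta * Wybar)
    fitted = alpha + np.tile(mu, t) + p.X @ beta + delta * _blockwise(Wsp, p.y, t)
    fr = FitResult(
        model_tag="fe_sar",
        coef_names=list(p.covariate_names),
        beta=beta,
        std_errors=se_beta,
        z_stats=z,
        p_values=pvals,
        sigma2=sigma2,
        loglik=loglik,
        loglik_no_constant=loglik_nc,
        nobs=n * t,
        df_resid=n * (t - 1) - k - 2,
        alpha=alpha,
        mu=mu,
        spatial_param=delta,
        spatial_param_se=d_se,
        spatial_param_p=d_p,
        fitted=fitted,
        residuals=p.y - fitted,
        within_fitted=Xstar @ beta + delta * Wy,
        within_residuals=ystar - Xstar @ beta - delta * Wy,
        n_iter=None,
    )
    return fit_statistics(fr, p.y)


def _sar_inference(Wsp, Xstar, beta, delta, sigma2, n, t, settings, ystar, lam):
    """Full (beta, delta, sigma2) information matrix for the SAR fit.

    Data cross-products run over the demeaned observations (which carry
    the T-1 effective cross-sections implicitly); pure trace terms are
    scaled by T-1 explicitly.
    """
    te = t - 1
    if settings.se_method == "numerical_hessian":
        return _sar_numeric(Wsp, delta, sigma2, n, t, ystar, Xstar, lam)
    k = Xstar.shape[1]
    A = np.eye(n) - delta * Wsp.toarray()
    WA = Wsp.toarray() @ np.linalg.inv(A)
    WAXb = _blockwise_dense(WA, Xstar @ beta, t)
    info = np.zeros((k + 2, k + 2))
    info[:k, :k] = Xstar.T @ Xstar / sigma2
    info[:k, k] = info[k, :k] = Xstar.T @ WAXb / sigma2
    info[k, k] = (
        te * (np.trace(WA @ WA) + np.trace(WA.T @ WA))
        + float(WAXb @ WAXb) / sigma2
    )
    info[k, k + 1] = info[k + 1, k] = te * np.trace(WA) / sigma2
    info[k + 1, k + 1] = n * te / (2 * sigma2**2)
    cov = np.linalg.inv(info)
    return np.sqrt(np.diag(cov)[:k]), float(cov[k, k])


def _blockwise_dense(M, v, t):
    return (M @ v.reshape(t, -1).T).T.ravel()


def _sar_numeric(Wsp, delta, sigma2, n, t, ystar, Xstar, lam):
    te = t - 1
    Wy = _blockwise(Wsp, ystar, t)

    def negll(theta):
        b, dd, s2 = theta[:-2], theta[-2], theta[-1]
        if s2 <= 0:
            return np.inf
        e = ystar - dd * Wy - Xstar @ b
        return -(
            -0.5 * n * te * np.log(s2)
            + log_jacobian(dd, lam, te)
            - float(e @ e) / (2 * s2)
        )

    beta0 = _ols(ystar - delta * Wy, Xstar)[0]
    theta = np.concatenate([beta0, [delta, sigma2]])
    H = _numeric_hessian(negll, theta)
    cov = np.linalg.inv(H)
    return np.sqrt(np.diag(cov)[:-2]), float(cov[-2, -2])


def fit_statistics(fr: FitResult, y_observed: np.ndarray) -> FitResult:
    """Attach R^2 (estimation scale), corr^2 (original scale) and AIC.

    ``r2 = 1 - SSE/SST`` on the scale the model was estimated on (within
    scale for FE-type fits); ``corr2`` is the squared Pearson correlation
    of observed and fitted outcomes on the original scale; ``aic`` counts
    the slopes, the spatial parameter (when present) and sigma2, with the
    fixed effects concentrated out.
    """
    y_observed = np.asarray(y_observed, dtype=float).ravel()
    if np.var(y_observed) <= 0:
        raise ValueError("observed outcome has zero variance")
    if fr.within_residuals is not None:
        resid = fr.within_residuals
        target = resid + fr.within_fitted
    else:
        resid = fr.residuals
        target = y_observed
    sse = float(resid @ resid)
    sst = float(np.sum((target - target.mean()) ** 2))
    fr.r2 = 1 - sse / sst if sst > 0 else 1.0
    if np.var(fr.fitted) > 0:
        fr.corr2 = float(np.corrcoef(y_observed, fr.fitted)[0, 1] ** 2)
    else:
        fr.corr2 = np.nan
    k = len(fr.beta) + 1 + (1 if fr.spatial_param is not None else 0)
    fr.aic = -2 * fr.loglik + 2 * k
    return fr
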