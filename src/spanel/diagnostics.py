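"""Spatial-dependence LM tests and a residual homoscedasticity check.

The Lagrange-multiplier battery is the standard score-test machinery on
least-squares residuals — LM-lag for an omitted spatially lagged outcome,
LM-error for spatially autocorrelated disturbances, plus the robust
variants that immunise each against the other alternative — applied
blockwise per period (``I_T (x) W``).  On within-demeaned residuals the
effective number of cross-sections is T-1 (demeaning removes one), and
the statistics use that count; pooled residuals use T.

Model-selection rule: when both plain LM tests reject at 5% on the FE
residuals, a spatial specification is flagged as warranted.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats
import statsmodels.api as sm
import statsmodels.stats.api as sms

from .ml import _blockwise
from .panel import FitResult, PanelData, within_transform
from .weights import SpatialWeights

__all__ = ["TestStat", "LMBattery", "lm_tests", "homoscedasticity_check",
           "spatial_model_warranted"]


@dataclass
class TestStat:
    stat: float
    p: float


@dataclass
class LMBattery:
    """Four chi-square(1) spatial-dependence statistics."""

    lm_lag: TestStat
    lm_lag_robust: TestStat
    lm_error: TestStat
    lm_error_robust: TestStat

    def as_dict(self) -> dict:
        return {
            name: {"stat": t.stat, "p": t.p}
            for name, t in (
                ("lm_lag", self.lm_lag),
                ("lm_lag_robust", self.lm_lag_robust),
                ("lm_error", self.lm_error),
                ("lm_error_robust", self.lm_error_robust),
            )
        }


def _chi2(stat: float) -> TestStat:
    stat = max(float(stat), 0.0)
    return TestStat(stat, float(scipy.stats.chi2.sf(stat, df=1)))


def lm_tests(fr: FitResult, p: PanelData, w: SpatialWeights) -> LMBattery:
    """LM-lag / LM-error battery (plain and robust) on a least-squares fit.

    ``fr`` must be a pooled or FE fit of the same panel.  Statistics are
    built from the panel quadratic forms ``e'(I_T (x) W)e`` and
    ``e'(I_T (x) W)y`` with the trace normaliser T_eff * tr(WW + W'W).
    """
    if not w.standardized:
        raise ValueError("weights must be row-standardised")
    if w.n != p.n_regions:
        raise ValueError(
            f"weights have {w.n} units but the panel has {p.n_regions} regions"
        )
    t = p.n_periods
    if fr.model_tag == "fe":
        d = within_transform(p).panel
        y, X = d.y, d.X
        coef = fr.beta
        t_eff = t - 1
    elif fr.model_tag == "pooled":
        y = p.y
        X = np.column_stack([np.ones(p.n_obs), p.X])
        coef = np.concatenate([[fr.alpha], fr.beta])
        t_eff = t
    else:
        raise ValueError("lm_tests expects a pooled or fe least-squares fit")
    e = y - X @ coef
    n = p.n_regions
    sigma2 = float(e @ e) / (n * t_eff)
    if sigma2 <= 0:
        raise ValueError("residual variance is not positive")
    Wsp = w.sparse()
    tr_w2 = float(Wsp.multiply(Wsp.T).sum())
    tr_wtw = float(Wsp.multiply(Wsp).sum())
    t_w = t_eff * (tr_w2 + tr_wtw)
    d_err = float(e @ _blockwise(Wsp, e, t)) / sigma2
    d_lag = float(e @ _blockwise(Wsp, y, t)) / sigma2
    yhat = X @ coef
    w_yhat = _blockwise(Wsp, yhat, t)
    proj = X @ np.linalg.lstsq(X, w_yhat, rcond=None)[0]
    m_wy = w_yhat - proj
    j = float(w_yhat @ m_wy) / sigma2 + t_w
    lm_err = _chi2(d_err**2 / t_w)
    lm_lag = _chi2(d_lag**2 / j)
    gap = j - t_w
    if gap > 1e-12:
        rlm_lag = _chi2((d_lag - d_err) ** 2 / gap)
        rlm_err = _chi2((d_err - (t_w / j) * d_lag) ** 2 / (t_w * (1 - t_w / j)))
    else:  # degenerate design: robust forms undefined, report 0
        rlm_lag = TestStat(0.0, 1.0)
        rlm_err = TestStat(0.0, 1.0)
    return LMBattery(lm_lag, rlm_lag, lm_err, rlm_err)


def spatial_model_warranted(battery: LMBattery, level: float = 0.05) -> bool:
    """True when both plain LM tests reject: spatial estimation is indicated."""
    return battery.lm_lag.p < level and battery.lm_error.p < level


def homoscedasticity_check(fr: FitResult, p: PanelData) -> TestStat:
    """Breusch-Pagan-type test of the fit's residuals against the covariates.

    Auxiliary regression of squared residuals on the K covariates; the
    n*R^2 statistic is chi-square(K) under homoscedasticity.  Constant
    residuals return the degenerate (0, 1).
    """
    resid = fr.within_residuals if fr.within_residuals is not None else fr.residuals
    if resid is None:
        raise ValueError("fit carries no residuals")
    if np.ptp(resid) == 0 or np.var(resid) <= 1e-30:
        return TestStat(0.0, 1.0)
    exog = sm.add_constant(p.X)
    stat, pval, _, _ = sms.het_breuschpagan(resid, exog)
    return TestStat(float(stat), float(pval))
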