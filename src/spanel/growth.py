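"""Temporal-trend (first-difference) specification.

The outcome is redefined as the change between consecutive periods while
every covariate enters at its initial-period value (suffix ``_t-1``), so
the model reads the effect of initial conditions on the subsequent change.
A panel with T periods yields T-1 difference periods; the result is an
ordinary :class:`~spanel.panel.PanelData` and flows through the same
FE/SEA/SAR machinery.  Under convergence dynamics (larger gains where
initial conditions are worse) the difference-model coefficients flip sign
relative to the levels model.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel import FitResult, PanelData

__all__ = ["build_first_difference", "SignComparison", "sign_flip_interpretation"]


def build_first_difference(p: PanelData) -> PanelData:
    """Difference the outcome, lag the covariates.

    For each region and each period t >= 2 produces one row with
    ``y_t - y_{t-1}`` and the period t-1 covariates; N*(T-1) rows in all.
    """
    t = p.n_periods
    if t < 2:
        raise ValueError("first differencing requires T >= 2")
    yb = p.y_blocks()
    xb = p.x_blocks()
    dy = yb[1:] - yb[:-1]
    x_lag = xb[:-1]
    labels = [
        f"{p.period_labels[s + 1]}-{p.period_labels[s]}" for s in range(t - 1)
    ]
    return PanelData(
        y=dy.ravel(),
        X=x_lag.reshape((t - 1) * p.n_regions, -1),
        region_ids=list(p.region_ids),
        period_labels=labels,
        covariate_names=[f"{c}_t-1" for c in p.covariate_names],
    )


@dataclass
class SignComparison:
    """Per-covariate sign agreement between levels and difference fits."""

    names: list
    sign_levels: np.ndarray
    sign_diff: np.ndarray
    opposite: np.ndarray

    @property
    def n_opposite(self) -> int:
        return int(self.opposite.sum())

    @property
    def n_common(self) -> int:
        return len(self.names)

    def rows(self) -> list:
        return [
            {
                "covariate": nm,
                "sign_levels": int(sl),
                "sign_difference": int(sd),
                "opposite": bool(op),
            }
            for nm, sl, sd, op in zip(
                self.names, self.sign_levels, self.sign_diff, self.opposite
            )
        ]


def sign_flip_interpretation(
    fit_levels: FitResult, fit_diff: FitResult
) -> SignComparison:
    """Tabulate coefficient sign oppositions between a levels fit and a
    first-difference fit on the shared covariates.

    Difference-model covariates are matched to levels covariates by
    stripping the ``_t-1`` suffix; covariates present in only one fit are
    ignored.  Purely a sign report — no magnitudes are compared.
    """
    diff_map = {}
    for i, nm in enumerate(fit_diff.coef_names):
        base = nm[:-4] if nm.endswith("_t-1") else nm
        diff_map[base] = i
    names, s_lvl, s_dif = [], [], []
    for i, nm in enumerate(fit_levels.coef_names):
        if nm in diff_map:
            names.append(nm)
            s_lvl.append(np.sign(fit_levels.beta[i]))
            s_dif.append(np.sign(fit_diff.beta[diff_map[nm]]))
    s_lvl = np.array(s_lvl)
    s_dif = np.array(s_dif)
    opposite = (s_lvl * s_dif) < 0
    return SignComparison(names, s_lvl, s_dif, opposite)
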