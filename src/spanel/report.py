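"""Regression-table report writer.

Renders the fitted models as a machine-readable JSON document and a
plain-text coefficient table with significance stars (***/**/* at the
1/5/10% levels; a p-value exactly at a threshold takes the stronger
marking, so p = 0.05 maps to **).
"""
from __future__ import annotations

import json

import numpy as np

from .diagnostics import LMBattery, spatial_model_warranted
from .panel import FitResult

__all__ = ["stars", "results_to_json", "text_table"]

_MODEL_TITLES = {
    "pooled": "Pooled model",
    "fe": "Fixed Effects",
    "fe_sea": "FE SEA model",
    "fe_sar": "FE SAR model",
}


def stars(p: float) -> str:
    if p <= 0.01:
        return "***"
    if p <= 0.05:
        return "**"
    if p <= 0.10:
        return "*"
    return ""


def _fit_to_dict(fr: FitResult) -> dict:
    d = {
        "model": fr.model_tag,
        "coefficients": {
            name: {
                "coef": float(b),
                "std_err": float(se),
                "z": float(z),
                "p_value": float(pv),
                "stars": stars(float(pv)),
            }
            for name, b, se, z, pv in zip(
                fr.coef_names, fr.beta, fr.std_errors, fr.z_stats, fr.p_values
            )
        },
        "sigma2": float(fr.sigma2),
        "loglik": float(fr.loglik),
        "loglik_no_constant": float(fr.loglik_no_constant),
        "r2": _num(fr.r2),
        "corr2": _num(fr.corr2),
        "aic": _num(fr.aic),
        "nobs": int(fr.nobs),
        "n_regions": int(fr.mu.shape[0]) if fr.mu is not None else None,
    }
    if fr.alpha is not None:
        d["constant"] = float(fr.alpha)
    if fr.spatial_param is not None:
        d["spatial_param"] = {
            "value": float(fr.spatial_param),
            "std_err": _num(fr.spatial_param_se),
            "p_value": _num(fr.spatial_param_p),
            "stars": stars(fr.spatial_param_p)
            if fr.spatial_param_p is not None
            else "",
        }
    if fr.mu is not None:
        d["fixed_effects"] = [float(v) for v in fr.mu]
    return d


def _num(v):
    if v is None:
        return None
    v = float(v)
    return v if np.isfinite(v) else None


def results_to_json(
    fits: dict, lm_batteries: dict | None = None, extra: dict | None = None
) -> str:
    """Serialize fits (and LM batteries keyed by the residual model) to JSON."""
    doc: dict = {"models": {tag: _fit_to_dict(fr) for tag, fr in fits.items()}}
    if lm_batteries:
        doc["lm_tests"] = {
            tag: dict(
                battery.as_dict(),
                spatial_model_warranted=spatial_model_warranted(battery),
            )
            for tag, battery in lm_batteries.items()
        }
    if extra:
        doc["extra"] = extra
    return json.dumps(doc, indent=1, sort_keys=True)


def text_table(fits: dict, lm_batteries: dict | None = None) -> str:
    """Plain-text coefficient table across the fitted models."""
    tags = list(fits)
    all_names: list = []
    for fr in fits.values():
        for nm in fr.coef_names:
            if nm not in all_names:
                all_names.append(nm)
    name_w = max(len(n) for n in all_names + ["Spatial parameter"]) + 2
    col_w = 18
    lines = []
    header = " " * name_w + "".join(
        _MODEL_TITLES.get(t, t).rjust(col_w) for t in tags
    )
    lines.append(header)
    lines.append("-" * len(header))

    def fmt(fr, name):
        if name not in fr.coef_names:
            return "".rjust(col_w)
        i = fr.coef_names.index(name)
        return f"{fr.beta[i]: .4f}{stars(fr.p_values[i]):<3}".rjust(col_w)

    if any(fr.alpha is not None and fr.model_tag == "pooled" for fr in fits.values()):
        row = "Constant".ljust(name_w)
        for t in tags:
            fr = fits[t]
            cell = (
                f"{fr.alpha: .4f}   " if fr.model_tag == "pooled" else ""
            )
            row += cell.rjust(col_w)
        lines.append(row)
    for name in all_names:
        lines.append(
            name.ljust(name_w) + "".join(fmt(fits[t], name) for t in tags)
        )
    row = "Spatial parameter".ljust(name_w)
    for t in tags:
        fr = fits[t]
        if fr.spatial_param is None:
            row += "".rjust(col_w)
        else:
            st = stars(fr.spatial_param_p) if fr.spatial_param_p is not None else ""
            row += f"{fr.spatial_param: .4f}{st:<3}".rjust(col_w)
    lines.append(row)
    lines.append("-" * len(header))
    for label, attr in (
        ("R2", "r2"),
        ("Corr-squared", "corr2"),
        ("sigma2_eps", "sigma2"),
        ("Loglikelihood", "loglik"),
        ("AIC", "aic"),
        ("N", "nobs"),
    ):
        row = label.ljust(name_w)
        for t in tags:
            v = getattr(fits[t], attr)
            if v is None or (isinstance(v, float) and not np.isfinite(v)):
                row += "".rjust(col_w)
            elif label == "N":
                row += f"{int(v):d}".rjust(col_w)
            else:
                row += f"{v: .4f}".rjust(col_w)
        lines.append(row)
    if lm_batteries:
        lines.append("-" * len(header))
        for label, key in (
            ("LM test - spatial lag", "lm_lag"),
            ("robust LM - spatial lag", "lm_lag_robust"),
            ("LM test - spatial error", "lm_error"),
            ("robust LM - spatial error", "lm_error_robust"),
        ):
            row = label.ljust(name_w)
            for t in tags:
                if t in lm_batteries:
                    ts = getattr(lm_batteries[t], key)
                    row += f"{ts.stat: .2f}{stars(ts.p):<3}".rjust(col_w)
                else:
                    row += "".rjust(col_w)
            lines.append(row)
    return "\n".join(lines) + "\n"
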