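"""Early- vs late-growing-period comparison of SNA traits.

Each trait is modelled with a linear mixed model: growing period as the
fixed effect of interest, pen size as a covariate, and crossed random
intercepts for pen and observation day:

    value ~ period + pen_size + (1 | pen) + (1 | day)

fitted by REML (statsmodels ``MixedLM`` with variance components carrying
the two crossed factors inside a single grouping).  Reported are the
least-square means per period (covariate held at its mean) and the
period-contrast p-value from a t reference with residual degrees of
freedom  n - p_fixed - sum(levels - 1)  over the retained random factors.
Random factors whose estimated variance collapses to ~0 (or that break
convergence) are dropped with a note, in which case the fit reduces
toward OLS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.formula.api as smf


@dataclass
class ComparisonResult:
    trait: str
    periods: tuple[str, str]
    lsmeans: dict[str, float]
    lsmean_se: dict[str, float]
    estimate: float  # second period minus first
    se: float
    df: float
    p_value: float
    dropped_terms: tuple[str, ...] = ()
    flagged: bool = False
    notes: str = ""


def _fit_mixed(df: pd.DataFrame, vc_terms: dict, use_covariate: bool):
    formula = "value ~ C(period) + pen_size" if use_covariate else "value ~ C(period)"
    if vc_terms:
        model = smf.mixedlm(formula, df, groups=np.ones(len(df)),
                            re_formula="0", vc_formula=vc_terms)
    else:
        model = smf.ols(formula, df)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if vc_terms:
            fit = model.fit(reml=True, method=["lbfgs", "powell"])
        else:
            fit = model.fit()
    return fit


def _vc_variances(fit, vc_terms) -> dict[str, float]:
    out = {}
    if not vc_terms:
        return out
    vcomp = np.asarray(fit.vcomp, dtype=float)
    for name, var in zip(fit.model.exog_vc.names, vcomp):
        out[name] = float(var)
    return out


def compare_periods(
    traits: pd.DataFrame,
    trait_name: str,
    pen_sizes: dict | pd.Series,
) -> ComparisonResult:
    """Fit the period-contrast mixed model for one trait.

    ``traits`` is the long trait table (columns pen_id, period, day, trait,
    value, optionally animal_id); ``pen_sizes`` maps pen_id -> group size.
    """
    df = traits[traits["trait"] == trait_name].copy()
    if len(df) == 0:
        raise ValueError(f"trait {trait_name!r} not present")
    periods = sorted(df["period"].unique())
    if len(periods) != 2:
        raise ValueError(f"need exactly 2 periods, found {periods}")
    if df["pen_id"].nunique() < 2:
        raise ValueError("need the trait observed across >= 2 pens")
    df["pen_size"] = df["pen_id"].map(dict(pen_sizes)).astype(float)
    if df["pen_size"].isna().any():
        raise ValueError("pen_sizes missing for some pens")
    df["period"] = pd.Categorical(df["period"], categories=periods)
    df = df.reset_index(drop=True)

    use_covariate = df["pen_size"].nunique() > 1
    dropped: list[str] = []
    if not use_covariate:
        dropped.append("pen_size")

    def _fit_ok(fit, vc):
        if fit is None:
            return False
        fe = np.asarray(fit.fe_params if vc else fit.params, dtype=float)
        cov = np.asarray(fit.cov_params(), dtype=float)[: len(fe), : len(fe)]
        return bool(np.all(np.isfinite(fe)) and np.all(np.isfinite(cov)))

    vc = {"pen": "0 + C(pen_id)", "day": "0 + C(day)"}
    fit = None
    while True:
        try:
            fit = _fit_mixed(df, vc, use_covariate)
        except Exception:
            fit = None
        if _fit_ok(fit, vc):
            variances = _vc_variances(fit, vc)
            resid_var = float(getattr(fit, "scale", np.nan))
            tiny = [k for k, v in variances.items()
                    if v <= max(1e-8, 1e-6 * max(resid_var, 1e-12))]
            if not tiny:
                break
            for k in tiny:
                vc.pop(k)
                dropped.append(k)
        else:
            if not vc:
                raise RuntimeError(f"model for {trait_name!r} failed to fit")
            k = next(iter(vc))
            vc.pop(k)
            dropped.append(k)
        fit = None
        if not vc:
            fit = _fit_mixed(df, vc, use_covariate)
            break

    is_mixed = bool(vc)
    fe_names = list(fit.model.exog_names)
    fe = np.asarray(fit.fe_params if is_mixed else fit.params, dtype=float)
    cov = np.asarray(fit.cov_params(), dtype=float)[: len(fe), : len(fe)]

    # design rows at each period with pen_size at its grand mean
    contrast_col = [i for i, nm in enumerate(fe_names) if "period" in nm]
    if len(contrast_col) != 1:
        raise RuntimeError(f"unexpected fixed-effect names {fe_names}")
    c = contrast_col[0]
    const_col = fe_names.index("Intercept")
    x0 = np.zeros(len(fe)); x0[const_col] = 1.0
    if use_covariate:
        x0[fe_names.index("pen_size")] = float(df["pen_size"].mean())
    x1 = x0.copy(); x1[c] = 1.0
    lsmeans = {periods[0]: float(x0 @ fe), periods[1]: float(x1 @ fe)}
    lsse = {
        periods[0]: float(np.sqrt(x0 @ cov @ x0)),
        periods[1]: float(np.sqrt(x1 @ cov @ x1)),
    }
    est = float(fe[c])
    se = float(np.sqrt(cov[c, c]))

    n = len(df)
    lost = 0
    if "pen" in vc:
        lost += df["pen_id"].nunique() - 1
    if "day" in vc:
        lost += df["day"].nunique() - 1
    dof = max(n - len(fe) - lost, 3)
    if se > 0:
        p = float(2.0 * stats.t.sf(abs(est) / se, dof))
        flagged = False
        notes = ""
    else:
        p = 1.0
        flagged = True
        notes = "singular fit: zero standard error"
    return ComparisonResult(
        trait=trait_name,
        periods=(periods[0], periods[1]),
        lsmeans=lsmeans,
        lsmean_se=lsse,
        estimate=est,
        se=se,
        df=float(dof),
        p_value=p,
        dropped_terms=tuple(dropped),
        flagged=flagged,
        notes=notes,
    )


def compare_all(traits: pd.DataFrame, pen_sizes) -> pd.DataFrame:
    """Run compare_periods for every trait present; one row per trait."""
    rows = []
    for trait_name in sorted(traits["trait"].unique()):
        try:
            res = compare_periods(traits, trait_name, pen_sizes)
        except ValueError:
            continue
        rows.append(
            {
                "trait": res.trait,
                "lsmean_" + res.periods[0]: res.lsmeans[res.periods[0]],
                "lsmean_" + res.periods[1]: res.lsmeans[res.periods[1]],
                "se_" + res.periods[0]: res.lsmean_se[res.periods[0]],
                "se_" + res.periods[1]: res.lsmean_se[res.periods[1]],
                "estimate": res.estimate,
                "se": res.se,
                "df": res.df,
                "p_value": res.p_value,
                "dropped_terms": ";".join(res.dropped_terms),
                "flagged": res.flagged,
            }
        )
    return pd.DataFrame(rows)
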