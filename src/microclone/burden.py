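"""Mixed-effects models of clone mutation burdens and clonality.

Clone burdens from the same biopsy share UV exposure, and biopsies from
the same patient are correlated, so burdens are modelled with linear
mixed models carrying random intercepts for patient and for biopsy
nested within patient.  Model comparisons (likelihood-ratio tests) use
maximum-likelihood fits; REML is available for final variance estimates.

Also provided: the PUVA dose–response model of psoralen-attributed
burden, the median-VAF-versus-age clonality regression with a
psoralen-indicator LRT, the basal-stem-cell count estimate from
microbiopsy surface area, and a model-based detection-sensitivity
correction for clone burdens.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import STEM_CELL_AREA

__all__ = [
    "LmmFit",
    "fit_burden_lmm",
    "lrt_nested",
    "puva_dose_model",
    "clonality_vs_age",
    "estimate_basal_stem_cells",
    "detection_sensitivity",
]

PUVA_ORDER = ["0", "1-50", "51-200", ">200"]


@dataclass
class LmmFit:
    """A fitted linear mixed model (fixed effects + nested random effects)."""

    fixed_effects: pd.Series
    conf_int: pd.DataFrame          # columns: lower, upper (95%)
    p_values: pd.Series
    variances: dict                 # patient, biopsy, residual
    llf: float
    method: str                     # "ML" or "REML"
    n_obs: int
    converged: bool
    boundary: bool                  # a variance component collapsed to ~0
    result: object = field(repr=False, default=None)

    @property
    def fixed_names(self) -> list:
        return list(self.fixed_effects.index)


def fit_burden_lmm(records: pd.DataFrame, response: str,
                   fixed_terms: list, reml: bool = False) -> LmmFit:
    """Fit ``response ~ fixed_terms`` with patient and biopsy-in-patient
    random intercepts.

    ``records`` needs columns ``patient_id`` and ``biopsy_id`` plus the
    response and covariates.  Rows with missing values in the model
    variables are dropped (duration-free models keep records with
    unknown disease duration).  Singular fits are returned with the
    ``boundary`` flag set, not silently dropped.
    """
    import statsmodels.formula.api as smf

    if records["patient_id"].nunique() < 2:
        raise ValueError("need at least two patients")
    cols = {"patient_id", "biopsy_id", response}
    for t in fixed_terms:
        for c in records.columns:
            if c in t:
                cols.add(c)
    df = records[sorted(cols)].dropna().copy()
    rhs = " + ".join(fixed_terms) if fixed_terms else "1"
    formula = f"{response} ~ {rhs}"

    import warnings

    def _try_fit(vc):
        model = smf.mixedlm(
            formula, data=df, groups=df["patient_id"], re_formula="1",
            vc_formula=vc,
        )
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return model.fit(reml=reml, method=["lbfgs", "cg"], maxiter=300)

    degenerate = False
    try:
        res = _try_fit({"biopsy": "0 + C(biopsy_id)"})
    except np.linalg.LinAlgError:
        # biopsy structure indistinguishable from residual noise (for
        # instance one clone per biopsy): refit without the nested term
        degenerate = True
        res = _try_fit(None)
    fe = res.fe_params
    ci = res.conf_int().loc[fe.index]
    ci.columns = ["lower", "upper"]
    var_patient = float(np.asarray(res.cov_re)[0, 0]) if res.cov_re.size else 0.0
    var_biopsy = float(res.vcomp[0]) if len(res.vcomp) else 0.0
    variances = {
        "patient": var_patient,
        "biopsy": var_biopsy,
        "residual": float(res.scale),
    }
    boundary = (
        degenerate
        or var_patient < 1e-8 * res.scale
        or (len(res.vcomp) > 0 and var_biopsy < 1e-8 * res.scale)
    )
    return LmmFit(
        fixed_effects=fe,
        conf_int=ci,
        p_values=res.pvalues.loc[fe.index],
        variances=variances,
        llf=float(res.llf),
        method="REML" if reml else "ML",
        n_obs=int(res.nobs),
        converged=bool(res.converged),
        boundary=bool(boundary),
        result=res,
    )


def lrt_nested(fit_full: LmmFit, fit_reduced: LmmFit) -> dict:
    """Likelihood-ratio test of nested ML fits (χ² with df = Δ parameters)."""
    if fit_full.method != "ML" or fit_reduced.method != "ML":
        raise ValueError("LRT requires maximum-likelihood fits")
    if not set(fit_reduced.fixed_names) <= set(fit_full.fixed_names):
        raise ValueError("models are not nested")
    df = len(fit_full.fixed_names) - len(fit_reduced.fixed_names)
    stat = max(2.0 * (fit_full.llf - fit_reduced.llf), 0.0)
    if df == 0:
        return {"statistic": stat, "df": 0, "p_value": 1.0}
    return {"statistic": stat, "df": df,
            "p_value": float(stats.chi2.sf(stat, df))}


def puva_dose_model(records: pd.DataFrame,
                    response: str = "psoralen") -> dict:
    """Psoralen burden regressed on ordinal PUVA band (reference: no PUVA).

    Returns the fit, per-band contrasts versus the no-PUVA group in band
    order, and the LRT against the intercept-only model.  Bands with no
    patients are omitted from the contrasts.
    """
    df = records.copy()
    present = [b for b in PUVA_ORDER if (df["puva_band"] == b).any()]
    df["puva_band"] = pd.Categorical(df["puva_band"], categories=present)
    fit = fit_burden_lmm(df, response, ["C(puva_band, Treatment('0'))"])
    null = fit_burden_lmm(df, response, [])
    contrasts = {}
    for band in present[1:]:
        name = f"C(puva_band, Treatment('0'))[T.{band}]"
        if name in fit.fixed_effects.index:
            contrasts[band] = {
                "estimate": float(fit.fixed_effects[name]),
                "lower": float(fit.conf_int.loc[name, "lower"]),
                "upper": float(fit.conf_int.loc[name, "upper"]),
                "p_value": float(fit.p_values[name]),
            }
    return {"fit": fit, "contrasts": contrasts, "lrt_vs_null": lrt_nested(fit, null)}


def clonality_vs_age(per_patient: pd.DataFrame) -> dict:
    """Median microbiopsy VAF regressed on age; LRT for a psoralen indicator.

    ``per_patient`` needs columns ``age`` and ``median_vaf`` and, for the
    indicator test, a boolean ``psoralen_positive``.
    """
    import statsmodels.api as sm

    if len(per_patient) < 3:
        raise ValueError("need at least three patients")
    x0 = sm.add_constant(per_patient[["age"]].to_numpy(dtype=float))
    y = per_patient["median_vaf"].to_numpy(dtype=float)
    base = sm.OLS(y, x0).fit()
    out = {
        "slope": float(base.params[1]),
        "intercept": float(base.params[0]),
        "slope_p": float(base.pvalues[1]),
    }
    if "psoralen_positive" in per_patient.columns:
        x1 = np.column_stack(
            [x0, per_patient["psoralen_positive"].to_numpy(dtype=float)]
        )
        full = sm.OLS(y, x1).fit()
        stat = max(2.0 * (full.llf - base.llf), 0.0)
        out["psoralen_effect"] = float(full.params[2])
        out["psoralen_lrt_p"] = float(stats.chi2.sf(stat, df=1))
    return out


def estimate_basal_stem_cells(area: float) -> int:
    """Founding basal stem cells of a microbiopsy from its surface area.

    Assumes 9-μm stem-cell diameter and vertical stratification:
    count = area / (π · 4.5²  μm²), rounded to the nearest integer.
    """
    if area <= 0:
        raise ValueError("area must be positive")
    return int(round(area / STEM_CELL_AREA))


def detection_sensitivity(vaf: float, mean_depth: float,
                          min_alt: int = 3, min_depth: int = 4) -> float:
    """P(a mutation at this VAF is genotyped) under the binomial read model.

    Depth is Poisson(mean_depth); detection requires depth ≥ ``min_depth``
    and ≥ ``min_alt`` alt reads.  Dividing an observed clone burden by
    this probability corrects for mutations missed at low VAF or depth.
    """
    if not 0.0 < vaf <= 1.0:
        raise ValueError("vaf must be in (0, 1]")
    d_max = int(mean_depth + 10.0 * np.sqrt(mean_depth) + 10)
    d = np.arange(min_depth, d_max + 1)
    pd_ = stats.poisson.pmf(d, mean_depth)
    p_detect = stats.binom.sf(min_alt - 1, d, vaf)
    return float(np.sum(pd_ * p_detect))
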