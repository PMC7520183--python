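"""REML linear mixed models on logit(PSi) and information-theoretic comparison.

The model family under comparison has fixed effects drawn from
{Sex, Month, Sex x Month} (both categorical) and crossed random intercepts
for SampleSize, Location and Year. "SampleSize" as a grouping factor means
each distinct group size is a level shared by all samples from groups of
that size — the device by which sampling-intensity bias enters the model.

Fitting delegates its optimizer to statsmodels' MixedLM in the
variance-components formulation (all observations in a single group, one
variance component per crossed factor). This module owns the model family,
the AIC convention, Akaike weights, and marginal/conditional r-squared.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

RANDOM_FACTORS = ("sample_size", "location", "year")


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect structure of one candidate model (random part is fixed)."""
    name: str
    fixed: str  # patsy right-hand side over columns sex, month

    @property
    def label(self) -> str:
        rand = " + ".join(f"(1|{f})" for f in RANDOM_FACTORS)
        return f"{self.name}: logit_psi ~ {self.fixed} + {rand}"


#: The four-candidate family compared in the source analysis.
DEFAULT_SPECS = (
    ModelSpec("Sex*Month", "C(sex) * C(month)"),
    ModelSpec("Sex+Month", "C(sex) + C(month)"),
    ModelSpec("Month", "C(month)"),
    ModelSpec("Sex", "C(sex)"),
)


@dataclass
class ModelFitResult:
    spec: ModelSpec
    loglik: float                    # REML log-likelihood
    k: int                           # fixed coefs + variance components + residual
    aic: float
    variance_components: dict        # factor -> variance
    sd_components: dict              # factor -> SD
    residual_variance: float
    fixed_effects: pd.Series
    tvalues: pd.Series
    fitted_fixed: np.ndarray = field(repr=False, default=None)
    converged: bool = True

    @property
    def r2(self) -> tuple[float, float]:
        return r2_nakagawa(self)


#: Optimizers tried in turn; the fit with the best REML log-likelihood wins.
#: Gradient methods are fast but can stall on the boundary when a variance
#: component is near zero; Powell is derivative-free and escapes that ridge.
FIT_METHODS = ("bfgs", "powell")


def fit_lmm(data: pd.DataFrame, spec: ModelSpec,
            methods=FIT_METHODS) -> ModelFitResult:
    """REML fit of one candidate on a per-sample table.

    ``data`` needs columns logit_psi, sex, month, sample_size, location,
    year. A variance component estimated at zero (singular fit) is reported
    as zero with a warning, not an error.
    """
    df = data.copy()
    vc = {f: f"0 + C({f})" for f in RANDOM_FACTORS if df[f].nunique() > 1}
    if not vc:
        return _fit_ols(df, spec)
    model = sm.MixedLM.from_formula(
        f"logit_psi ~ {spec.fixed}", data=df,
        groups=np.ones(len(df)), vc_formula=vc, re_formula="0")
    result = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in methods:
            try:
                cand = model.fit(reml=True, method=method)
            except Exception:
                continue
            if np.isfinite(cand.llf) and (result is None
                                          or cand.llf > result.llf):
                result = cand
    if result is None:
        raise RuntimeError(f"all optimizers failed for model {spec.name!r}")
    vcomp = {f: 0.0 for f in RANDOM_FACTORS}
    for name, value in zip(model.exog_vc.names, result.vcomp):
        vcomp[name] = float(value)
    if any(v <= 1e-10 for v in vcomp.values()):
        warnings.warn("singular fit: a variance component is estimated at 0",
                      stacklevel=2)
    n_fixed = len(result.fe_params)
    k = n_fixed + len(model.exog_vc.names) + 1
    loglik = float(result.llf)
    fitted_fixed = model.exog @ result.fe_params.to_numpy()
    return ModelFitResult(
        spec=spec, loglik=loglik, k=k, aic=-2.0 * loglik + 2.0 * k,
        variance_components=vcomp,
        sd_components={f: float(np.sqrt(v)) for f, v in vcomp.items()},
        residual_variance=float(result.scale),
        fixed_effects=result.fe_params, tvalues=result.tvalues[:n_fixed],
        fitted_fixed=np.asarray(fitted_fixed),
        converged=bool(result.converged))


def _fit_ols(df: pd.DataFrame, spec: ModelSpec) -> ModelFitResult:
    """Degenerate case: every grouping factor constant -> plain REML-less OLS."""
    import statsmodels.formula.api as smf
    res = smf.ols(f"logit_psi ~ {spec.fixed}", data=df).fit()
    n_fixed = len(res.params)
    resid_var = float(res.mse_resid)
    k = n_fixed + 1
    fitted = res.model.exog @ res.params.to_numpy()
    warnings.warn("no grouping factor varies: fit reduces to OLS", stacklevel=3)
    return ModelFitResult(
        spec=spec, loglik=float(res.llf), k=k,
        aic=-2.0 * float(res.llf) + 2.0 * k,
        variance_components={f: 0.0 for f in RANDOM_FACTORS},
        sd_components={f: 0.0 for f in RANDOM_FACTORS},
        residual_variance=resid_var, fixed_effects=res.params,
        tvalues=res.tvalues, fitted_fixed=np.asarray(fitted))


def akaike_weights(aic_values) -> np.ndarray:
    """Burnham-Anderson weights exp(-dAIC/2) normalized over the model set."""
    aic = np.asarray(aic_values, dtype=float)
    if aic.size < 2:
        raise ValueError("need at least two models to weight")
    rel = np.exp(-(aic - aic.min()) / 2.0)
    return rel / rel.sum()


def r2_nakagawa(fit: ModelFitResult) -> tuple[float, float]:
    """Marginal and conditional r-squared for a Gaussian mixed model.

    r2_marginal = var_fixed / total, r2_conditional adds the random-effect
    variances to the numerator; total = var_fixed + sum(vc) + residual.
    var_fixed is the population variance of the fixed-effect fitted values.
    """
    var_f = float(np.var(fit.fitted_fixed))
    var_r = float(sum(fit.variance_components.values()))
    total = var_f + var_r + fit.residual_variance
    return var_f / total, (var_f + var_r) / total


def compare_models(data: pd.DataFrame, specs=DEFAULT_SPECS) -> pd.DataFrame:
    """Fit every candidate and tabulate AIC, dAIC, weights and r-squared."""
    fits = []
    for spec in specs:
        try:
            fits.append(fit_lmm(data, spec))
        except Exception as exc:
            raise RuntimeError(f"fit failed for model {spec.name!r}") from exc
    weights = akaike_weights([f.aic for f in fits])
    rows = []
    for f, w in zip(fits, weights):
        r2m, r2c = f.r2
        rows.append({"predictors": f.spec.name, "r2_fixed": r2m, "r2": r2c,
                     "aic": f.aic, "delta_aic": 0.0, "wi": w,
                     "loglik": f.loglik, "k": f.k})
    out = pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)
    out["delta_aic"] = out["aic"] - out["aic"].min()
    return out
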