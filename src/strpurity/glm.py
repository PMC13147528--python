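"""Regression layer: Poisson and logistic GLMs over annotated locus tables.

Interruption counts are modeled with Poisson GLMs (log link) whose linear
predictor always includes motif GC fraction and motif length in bp unless
explicitly overridden, with a log-exposure offset — log allele length for
noncoding purity models, log mutational-space exposure for coding models.
Purity-as-binary outcomes use binomial GLMs with a logit link.  Wald
p-values are reported by default; likelihood-ratio tests are available
behind a flag.  Model quality is compared by AIC on an identical row set,
and families of related tests are Bonferroni-corrected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ModelSpec",
    "GLMResult",
    "DEFAULT_COVARIATES",
    "fit_glm",
    "joint_consequence_model",
    "compare_aic",
    "bonferroni",
]

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("gc_fraction", "motif_len")


@dataclass(frozen=True)
class ModelSpec:
    """Declarative GLM specification over an annotated locus table."""

    response: str
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    offset: str | None = None  # column holding log-exposure
    interactions: tuple[tuple[str, str], ...] = ()
    family: str = "poisson_log"
    name: str = ""

    def __post_init__(self) -> None:
        if self.family not in ("poisson_log", "binomial_logit"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "poisson_log" and self.offset is None:
            raise ValueError("poisson_log models require an offset column")

    @property
    def columns(self) -> list[str]:
        cols = [self.response, *self.covariates]
        if self.offset:
            cols.append(self.offset)
        for a, b in self.interactions:
            cols.extend([a, b])
        return list(dict.fromkeys(cols))


@dataclass
class GLMResult:
    spec: ModelSpec
    coefficients: pd.Series
    std_errors: pd.Series
    p_values: pd.Series
    aic: float
    n_obs: int
    converged: bool
    llf: float = float("nan")
    lrt_p_values: pd.Series | None = None
    diagnostics: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"B": self.coefficients, "SE": self.std_errors, "p": self.p_values}
        ).assign(aic=self.aic, n_obs=self.n_obs)


def _design_matrix(table: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    X = pd.DataFrame(index=table.index)
    X["const"] = 1.0
    for cov in spec.covariates:
        X[cov] = pd.to_numeric(table[cov])
    for a, b in spec.interactions:
        for col in (a, b):
            if col not in X.columns:
                X[col] = pd.to_numeric(table[col])
        X[f"{a}:{b}"] = X[a] * X[b]
    return X


def fit_glm(
    table: pd.DataFrame,
    spec: ModelSpec,
    likelihood_ratio: bool = False,
    quasi_poisson: bool = False,
) -> GLMResult:
    """Fit a GLM (IRLS) per the model specification; rows with missing values are dropped.

    Non-convergence and separation are reported through ``converged`` and
    ``diagnostics`` rather than raised.  ``quasi_poisson`` rescales the
    covariance by the Pearson dispersion for sensitivity analysis.
    """
    data = table[spec.columns].apply(pd.to_numeric, errors="coerce")
    n_before = len(data)
    data = data.dropna()
    if (dropped := n_before - len(data)):
        logger.info("model %s: dropped %d rows with missing values", spec.name, dropped)
    y = data[spec.response].to_numpy(float)
    if spec.family == "poisson_log":
        if np.any(y < 0) or np.any(y != np.round(y)):
            raise ValueError("poisson_log response must be non-negative integers")
        family = sm.families.Poisson()
    else:
        family = sm.families.Binomial()
    X = _design_matrix(data, spec)
    if len(data) <= X.shape[1]:
        raise ValueError(f"n_obs ({len(data)}) must exceed n_terms ({X.shape[1]})")
    offset = data[spec.offset].to_numpy(float) if spec.offset else None
    model = sm.GLM(y, X, family=family, offset=offset)
    try:
        scale = "X2" if quasi_poisson else None
        fit = model.fit(scale=scale, maxiter=200)
        converged = bool(fit.converged) and np.all(np.isfinite(fit.params))
        diag = "" if converged else "IRLS did not converge"
    except Exception as exc:  # separation, singular design, ...
        nan = pd.Series(np.nan, index=X.columns)
        return GLMResult(spec, nan, nan, nan, float("nan"), len(data), False,
                         diagnostics=f"{type(exc).__name__}: {exc}")
    result = GLMResult(
        spec=spec,
        coefficients=pd.Series(fit.params, index=X.columns),
        std_errors=pd.Series(fit.bse, index=X.columns),
        p_values=pd.Series(fit.pvalues, index=X.columns),
        aic=float(fit.aic),
        n_obs=len(data),
        converged=converged,
        llf=float(fit.llf),
        diagnostics=diag,
    )
    if likelihood_ratio and converged:
        lrt = {}
        for term in X.columns:
            if term == "const":
                lrt[term] = np.nan
                continue
            reduced = sm.GLM(y, X.drop(columns=term), family=family, offset=offset).fit(maxiter=200)
            from scipy.stats import chi2

            lrt[term] = float(chi2.sf(2 * (fit.llf - reduced.llf), 1))
        result.lrt_p_values = pd.Series(lrt)
    return result


def joint_consequence_model(
    coding_table: pd.DataFrame,
    constraint_col: str = "loeuf",
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> GLMResult:
    """Joint silent/missense Poisson model with a consequence interaction.

    Expects long format: one row per (locus, consequence class) with
    columns ``n_interruptions``, ``consequence`` ('silent'/'missense'),
    ``exposure`` (class mutational-opportunity exposure) and the
    constraint column.  Fits a Poisson GLM with a missense indicator, the
    constraint score, their interaction, the standard covariates, and a
    log class-exposure offset.
    """
    classes = set(coding_table["consequence"])
    if classes != {"silent", "missense"}:
        raise ValueError(f"need both consequence classes, got {sorted(classes)}")
    tab = coding_table.copy()
    tab["is_missense"] = (tab["consequence"] == "missense").astype(float)
    tab["log_exposure"] = np.log(pd.to_numeric(tab["exposure"]))
    spec = ModelSpec(
        response="n_interruptions",
        covariates=(*covariates, "is_missense", constraint_col),
        offset="log_exposure",
        interactions=(("is_missense", constraint_col),),
        family="poisson_log",
        name="joint_consequence",
    )
    return fit_glm(tab, spec)


def compare_aic(m1: GLMResult, m2: GLMResult) -> float:
    """AIC(m1) - AIC(m2); negative favors m1.  Requires identical data."""
    if m1.spec.response != m2.spec.response or m1.n_obs != m2.n_obs:
        raise ValueError("AIC is only comparable across models of the same response and rows")
    return m1.aic - m2.aic


def bonferroni(p_values: list[float], m: int | None = None) -> list[float]:
    """Bonferroni correction: min(1, p*m) elementwise; m defaults to len(p)."""
    m = len(p_values) if m is None else m
    if m < len(p_values):
        raise ValueError("family size m must be >= number of p-values")
    return [min(1.0, p * m) for p in p_values]
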