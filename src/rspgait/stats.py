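"""Symmetry indices and the study-level statistical layer.

The between-leg symmetry index for a variable x is

    SI = (x_AL - x_UL) / (0.5 * (x_AL + x_UL))

computed from trial-level per-leg means; SI = 0 is perfect symmetry,
positive means the affected leg exceeds the unaffected leg, and for
positive inputs SI is bounded in (-2, 2).  Group-level inference uses
one-sample t-tests of SI against zero with Bonferroni correction, and
linear mixed models (random subject intercept) for configuration effects
on maximum velocity and the biomechanical variables; mixed-model
estimation is delegated to statsmodels MixedLM.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as spstats

from .exceptions import DegenerateInputError, DesignError, ParameterError

__all__ = [
    "FixedEffectsResult",
    "VmaxReport",
    "symmetry_index",
    "symmetry_indices",
    "one_sample_t",
    "bonferroni",
    "percent_difference",
    "fit_lmm",
    "analyze_vmax",
]

logger = logging.getLogger(__name__)

#: Variables the symmetry analysis covers (per-leg trial means).
SYMMETRY_VARIABLES = (
    "step_frequency",
    "stance_avg_vgrf",
    "contact_length",
    "contact_time",
    "aerial_time",
    "leg_stiffness",
)


def symmetry_index(var_AL: float, var_UL: float) -> float:
    """Between-leg ratio (AL - UL) / (0.5 * (AL + UL)); 0 = perfect symmetry."""
    denom = 0.5 * (var_AL + var_UL)
    if denom == 0:
        raise DegenerateInputError("symmetry index undefined: AL + UL = 0")
    return (var_AL - var_UL) / denom


def symmetry_indices(per_leg: dict, variables=SYMMETRY_VARIABLES) -> dict:
    """SI per variable from a {leg: {variable: mean}} mapping."""
    return {
        var: symmetry_index(per_leg["AL"][var], per_leg["UL"][var])
        for var in variables
        if var in per_leg["AL"] and var in per_leg["UL"]
    }


def one_sample_t(si_values, mu0: float = 0.0) -> tuple[float, int, float]:
    """Two-sided one-sample t-test of a symmetry-index sample against mu0.

    Returns (t, df, p) with df = n - 1.
    """
    x = np.asarray(si_values, dtype=float)
    if x.size < 2:
        raise DegenerateInputError(f"t-test needs n >= 2, got n = {x.size}")
    if np.var(x, ddof=1) == 0:
        raise DegenerateInputError("t-test undefined for a zero-variance sample")
    result = spstats.ttest_1samp(x, popmean=mu0)
    return float(result.statistic), int(x.size - 1), float(result.pvalue)


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, p * m) elementwise."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ParameterError("p-values must lie in [0, 1]")
    m = p.size if m is None else int(m)
    if m < 1:
        raise ParameterError(f"number of comparisons must be >= 1, got {m}")
    return np.minimum(1.0, p * m)


def percent_difference(a: float, b: float) -> float:
    """Difference of ``a`` from reference ``b`` as a percentage of ``b``.

    Reported to one decimal, matching how between-model contrasts of group
    means are usually quoted.
    """
    if not b > 0:
        raise ParameterError(f"reference mean must be positive, got {b}")
    return round(100.0 * (a - b) / b, 1)


@dataclass(frozen=True)
class FixedEffectsResult:
    """Fixed-effect coefficients and p-values from one mixed-model fit."""

    coefficients: dict  # term -> beta
    p_values: dict  # term -> p
    intercept: float
    random_intercept_var: float
    n_obs: int
    n_subjects: int
    converged: bool = True

    def beta(self, term: str) -> float:
        return self.coefficients[term]


def _check_design(model) -> None:
    exog = model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        # name the aliased columns: those whose removal does not drop the rank
        names = list(model.exog_names)
        aliased = []
        for j in range(exog.shape[1]):
            reduced = np.delete(exog, j, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                aliased.append(names[j])
        raise DesignError(f"rank-deficient fixed-effects design; aliased term(s): {aliased}")


def fit_lmm(
    table: pd.DataFrame,
    response: str,
    fixed: list[str],
    grouping: str = "subject",
    categorical: tuple[str, ...] = ("rsp_model",),
    reference: str | None = None,
) -> FixedEffectsResult:
    """Fit a random-intercept linear mixed model and return its fixed effects.

    Prosthesis model enters as a categorical term (treatment-coded against
    ``reference``, by default the level with the slowest group-mean
    response); stiffness, height and velocity covariates enter as
    continuous.  Estimation (REML) and p-values are delegated to
    statsmodels MixedLM.
    """
    if table[grouping].nunique() < 2:
        raise DesignError("mixed model needs at least 2 subjects")
    terms = []
    for term in fixed:
        if term in categorical:
            if reference is None and term in table.columns:
                reference = str(
                    table.groupby(term)[response].mean().idxmin()
                )
            terms.append(f"C({term}, Treatment(reference={reference!r}))")
        else:
            terms.append(term)
    formula = f"{response} ~ {' + '.join(terms)}"
    model = smf.mixedlm(formula, data=table, groups=table[grouping])
    _check_design(model)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=True)
    names = result.model.exog_names
    coefs = {name: float(result.fe_params[name]) for name in names}
    pvals = {name: float(result.pvalues[name]) for name in names}
    return FixedEffectsResult(
        coefficients={k: v for k, v in coefs.items() if k != "Intercept"},
        p_values={k: v for k, v in pvals.items() if k != "Intercept"},
        intercept=coefs.get("Intercept", float("nan")),
        random_intercept_var=float(np.asarray(result.cov_re)[0, 0]),
        n_obs=int(result.nobs),
        n_subjects=int(table[grouping].nunique()),
        converged=bool(getattr(result, "converged", True)),
    )


@dataclass(frozen=True)
class VmaxReport:
    """Mixed-model report for the configuration -> maximum-velocity analysis."""

    category_model: FixedEffectsResult  # model + stiffness category + height
    actual_stiffness_model: FixedEffectsResult  # model + stiffness kN/m + height
    model_means: dict  # rsp_model -> group-mean vmax
    model_contrasts: pd.DataFrame  # pairwise percent differences + adjusted p
    biomech_models: dict = field(default_factory=dict)  # variable -> fit


def _pairwise_model_contrasts(table: pd.DataFrame, response: str, covariates: list[str],
                              grouping: str) -> tuple[dict, pd.DataFrame]:
    means = table.groupby("rsp_model")[response].mean().to_dict()
    levels = sorted(means, key=means.get, reverse=True)  # fastest first
    rows = []
    for i, fast in enumerate(levels):
        for slow in levels[i + 1 :]:
            fit = fit_lmm(
                table, response, ["rsp_model", *covariates],
                grouping=grouping, reference=slow,
            )
            term = f"C(rsp_model, Treatment(reference={slow!r}))[T.{fast}]"
            rows.append(
                {
                    "model_a": fast,
                    "model_b": slow,
                    "mean_a": means[fast],
                    "mean_b": means[slow],
                    "pct_diff": percent_difference(means[fast], means[slow]),
                    "beta": fit.coefficients[term],
                    "p_raw": fit.p_values[term],
                }
            )
    contrasts = pd.DataFrame(rows)
    if len(contrasts):
        contrasts["p_adj"] = bonferroni(contrasts["p_raw"].to_numpy())
    return means, contrasts


def analyze_vmax(
    summaries: pd.DataFrame,
    biomech_variables: tuple[str, ...] = (),
    grouping: str = "subject",
) -> VmaxReport:
    """Run the configuration -> v_max mixed models and pairwise contrasts.

    ``summaries`` is long per-trial data with one v_max row per subject and
    configuration: columns ``subject, rsp_model, stiffness_category,
    height_offset, k_rsp, vmax`` plus any requested biomechanical variables.
    Two v_max models are fitted (stiffness-category coded and actual
    stiffness in kN/m), then one model per biomechanical variable with
    v_max as covariate.  Pairwise prosthesis-model contrasts are
    Bonferroni-adjusted.  Unbalanced designs (a subject missing a
    configuration cell) are tolerated and logged.
    """
    counts = summaries.groupby([grouping, "rsp_model"]).size().unstack(fill_value=0)
    if (counts == 0).any().any():
        logger.info("unbalanced design: some subject x model cells are empty; proceeding")
    category_fit = fit_lmm(
        summaries, "vmax", ["rsp_model", "stiffness_category", "height_offset"],
        grouping=grouping,
    )
    actual_fit = fit_lmm(
        summaries, "vmax", ["rsp_model", "k_rsp", "height_offset"], grouping=grouping
    )
    means, contrasts = _pairwise_model_contrasts(
        summaries, "vmax", ["stiffness_category", "height_offset"], grouping
    )
    biomech = {}
    for var in biomech_variables:
        biomech[var] = fit_lmm(summaries, var, ["rsp_model", "vmax"], grouping=grouping)
    return VmaxReport(
        category_model=category_fit,
        actual_stiffness_model=actual_fit,
        model_means=means,
        model_contrasts=contrasts,
        biomech_models=biomech,
    )
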