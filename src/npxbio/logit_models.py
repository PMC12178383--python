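"""Age-adjusted binary logistic biomarker models.

Each candidate protein is evaluated in a model of the form

    logit P(outcome = 1) = β0 + β_age·age + β_marker·NPX

fit by plain maximum likelihood (no penalization).  Reported per
marker: β, its standard error from the observed information matrix, the
odds ratio exp(β) per +1 NPX (i.e. per doubling of concentration), the
95% CI exp(β ± 1.96·SEM), a Wald p-value, and the in-sample concordance
index (Harrell's C on predicted probabilities, ties counted one half).
Step-by-step marker addition is summarized with ΔC against the previous
model and a likelihood-ratio χ² test on the added coefficients.

Quasi-separation — plausible when one diagnosis group is very small —
is detected (diverging |β| or non-convergence) and flagged rather than
penalized away.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

_BETA_DIVERGED = 15.0  # |log-odds| beyond this on standardized-ish data ≈ separation


@dataclass
class LogitResult:
    outcome: str
    terms: list[str]                 # column names incl. covariates
    beta: dict[str, float]
    sem: dict[str, float]
    or_value: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    p_value: dict[str, float]        # Wald, per term
    c_index: float
    log_likelihood: float
    converged: bool
    n: int
    fitted_probabilities: np.ndarray


@dataclass
class ModelComparison:
    base_terms: list[str]
    extended_terms: list[str]
    delta_c: float
    lr_chi2: float
    df: int
    p_value: float


def odds_ratio_ci(beta: float, sem: float) -> tuple[float, float, float]:
    """OR = exp(β) with 95% CI exp(β ∓ 1.96·SEM)."""
    if sem < 0:
        raise ValueError("sem must be non-negative")
    return (
        float(np.exp(beta)),
        float(np.exp(beta - 1.96 * sem)),
        float(np.exp(beta + 1.96 * sem)),
    )


def concordance_index(y, risk_scores) -> float:
    """Harrell's C for a binary outcome: over all case–control pairs, the
    fraction where the case scores higher, ties counting one half.

    Computed via midranks: C = (R̄_cases − (n1+1)/2) / n0 where R̄ is the
    mean midrank of the cases — algebraically identical to exhaustive
    pair counting with the 0.5 tie convention.
    """
    y = np.asarray(y)
    s = np.asarray(risk_scores, dtype=float)
    cases = y == 1
    n1 = int(cases.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both outcome classes must be present")
    ranks = stats.rankdata(s)  # midranks
    return float((ranks[cases].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _fit_mle(X: np.ndarray, yv: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """statsmodels Logit MLE; returns (beta, sem, ll, converged)."""
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(yv, X)
        try:
            res = model.fit(disp=0, maxiter=200)
        except Exception:  # PerfectSeparationError and friends
            res = model.fit(disp=0, maxiter=200, method="bfgs")
    beta = np.asarray(res.params, dtype=float)
    sem = np.asarray(res.bse, dtype=float)
    converged = bool(res.mle_retvals.get("converged", True))
    if np.any(np.abs(beta) > _BETA_DIVERGED) or not np.all(np.isfinite(sem)):
        converged = False
    return beta, sem, float(res.llf), converged


def fit_logistic(
    y,
    data: pd.DataFrame,
    markers: list[str],
    covariates: list[str] = ["age"],
    outcome: str = "",
) -> LogitResult:
    """Fit logit(y) ~ intercept + covariates + markers by maximum likelihood.

    ``data`` holds one column per covariate/marker, aligned with ``y``
    (binary, coded 1 for the first-listed group of the contrast).
    """
    yv = np.asarray(y, dtype=float)
    classes = np.unique(yv)
    if len(classes) != 2 or not set(classes) <= {0.0, 1.0}:
        raise ValueError("y must contain exactly the classes {0, 1}")
    terms = list(covariates) + list(markers)
    X = data[terms].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("design matrix contains missing values")
    Xd = np.column_stack([np.ones(len(yv)), X])
    rank = np.linalg.matrix_rank(Xd)
    if rank < Xd.shape[1]:
        raise ValueError(f"design matrix is rank deficient (columns: {terms})")

    beta, sem, ll, converged = _fit_mle(Xd, yv)
    if not converged:
        logger.warning("logistic fit did not converge (possible quasi-separation): %s", terms)

    eta = Xd @ beta
    prob = 1.0 / (1.0 + np.exp(-eta))
    names = ["intercept"] + terms
    or_ci = {t: odds_ratio_ci(b, s) for t, b, s in zip(names, beta, sem)}
    with np.errstate(divide="ignore", invalid="ignore"):
        wald_z = np.where(sem > 0, beta / sem, np.inf)
    wald_p = 2 * stats.norm.sf(np.abs(wald_z))
    return LogitResult(
        outcome=outcome,
        terms=terms,
        beta=dict(zip(names, map(float, beta))),
        sem=dict(zip(names, map(float, sem))),
        or_value={t: v[0] for t, v in or_ci.items()},
        ci95={t: (v[1], v[2]) for t, v in or_ci.items()},
        p_value=dict(zip(names, map(float, wald_p))),
        c_index=concordance_index(yv.astype(int), prob),
        log_likelihood=ll,
        converged=converged,
        n=len(yv),
        fitted_probabilities=prob,
    )


def compare_models(base: LogitResult, extended: LogitResult, y=None) -> ModelComparison:
    """Likelihood-ratio comparison of nested fits plus the C-index change."""
    if not set(base.terms) <= set(extended.terms):
        raise ValueError("models are not nested (base terms must be a subset)")
    if base.n != extended.n:
        raise ValueError("models were fit on different sample counts")
    df = len(extended.terms) - len(base.terms)
    lr = 2.0 * (extended.log_likelihood - base.log_likelihood)
    p = float(stats.chi2.sf(max(lr, 0.0), df)) if df > 0 else 1.0
    return ModelComparison(
        base_terms=list(base.terms),
        extended_terms=list(extended.terms),
        delta_c=extended.c_index - base.c_index,
        lr_chi2=float(lr),
        df=df,
        p_value=p,
    )


def stepwise_marker_table(
    y,
    data: pd.DataFrame,
    markers: list[str],
    covariates: list[str] = ["age"],
    outcome: str = "",
) -> pd.DataFrame:
    """Exploratory biomarker table: one row per single age-adjusted marker
    model, and one row per cumulative combination of the markers in the
    given order.

    Single rows carry β, SEM, OR, 95% CI, Wald p, C, and ΔC against the
    covariate-only model.  Combined rows carry the combined C, ΔC against
    the previous combination, the LR χ² of the added marker, and its
    LR p-value.  A failing fit is recorded in its row; the table is
    still emitted.
    """
    if not markers:
        raise ValueError("need at least one marker")
    base = fit_logistic(y, data, markers=[], covariates=covariates, outcome=outcome)
    rows = []
    prev: LogitResult = None
    for i, marker in enumerate(markers):
        row = {"outcome": outcome, "model": marker, "type": "single"}
        try:
            single = fit_logistic(y, data, [marker], covariates, outcome)
            row.update(
                beta=single.beta[marker], sem=single.sem[marker],
                or_value=single.or_value[marker],
                ci_low=single.ci95[marker][0], ci_high=single.ci95[marker][1],
                p=single.p_value[marker], c_index=single.c_index,
                delta_c=single.c_index - base.c_index,
                converged=single.converged,
            )
        except Exception as exc:  # rank deficiency etc.
            row.update(error=str(exc), converged=False)
        rows.append(row)

        if i == 0:
            try:
                prev = fit_logistic(y, data, markers[:1], covariates, outcome)
            except Exception:
                prev = None
            continue
        combo_name = " + ".join(markers[: i + 1])
        row = {"outcome": outcome, "model": combo_name, "type": "combined"}
        try:
            combo = fit_logistic(y, data, markers[: i + 1], covariates, outcome)
            if prev is not None:
                cmp_res = compare_models(prev, combo)
                row.update(
                    c_index=combo.c_index, delta_c=cmp_res.delta_c,
                    lr_chi2=cmp_res.lr_chi2, lr_p=cmp_res.p_value,
                    converged=combo.converged,
                )
            else:
                row.update(c_index=combo.c_index, converged=combo.converged)
            prev = combo
        except Exception as exc:
            row.update(error=str(exc), converged=False)
            prev = None
        rows.append(row)
    return pd.DataFrame(rows)
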