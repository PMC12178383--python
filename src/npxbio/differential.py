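"""Per-protein differential abundance and cohort demographic tests.

Each protein is compared between two diagnosis groups with a Welch
two-sample t-test (unequal variances; sample sizes differ markedly
between groups) and the p-values are adjusted across all proteins of
the contrast with the Benjamini–Hochberg step-up.  Because NPX is a
log2-scale unit, the mean NPX difference IS the log2 fold change, so a
volcano classification (up in either group at q < 0.05, otherwise ns)
falls straight out of the estimate's sign and the q-value.

Demographics are compared with the χ² test of independence (categorical,
no continuity correction) and the Kruskal–Wallis H test (continuous).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .npx_core import NpxMatrix, SampleInfo

logger = logging.getLogger(__name__)


@dataclass
class DiffResult:
    assay: str
    estimate: float          # mean(group2) − mean(group1), NPX = log2 FC
    t_stat: float
    df: float
    p_value: float
    q_value: float
    direction_class: str     # up_in_group1 | up_in_group2 | ns
    flagged_low_detection: bool
    n1: int
    n2: int


def welch_test(x, y) -> tuple[float, float, float, float]:
    """Welch two-sample t-test.

    Returns (estimate, t, df, p) with estimate = mean(y) − mean(x),
    Welch–Satterthwaite degrees of freedom, and a two-sided p from the
    t distribution.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 non-missing values")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = len(x), len(y)
    se2 = vx / nx + vy / ny
    estimate = my - mx
    if se2 == 0:
        return estimate, 0.0 if estimate == 0 else math.inf * np.sign(estimate), float(nx + ny - 2), 1.0 if estimate == 0 else 0.0
    t = estimate / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return float(estimate), float(t), float(df), float(p)


def adjust_fdr_bh(p_values) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (q-values), capped at 1.

    NaN inputs propagate to NaN outputs and do not count toward the
    family size.
    """
    p = np.asarray(p_values, dtype=float)
    obs = ~np.isnan(p)
    if ((p[obs] < 0) | (p[obs] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    if obs.any():
        q[obs] = multipletests(p[obs], method="fdr_bh")[1]
    return q


def volcano_table(
    m: NpxMatrix,
    labels,
    group1: str,
    group2: str,
    q_threshold: float = 0.05,
) -> list[DiffResult]:
    """One Welch test per assay for the group2-vs-group1 contrast.

    The BH family is all assays tested within this contrast.  Assays
    with fewer than 2 observed values in either group are skipped with a
    warning.  ‡ (low-detection) flags are copied through so downstream
    tables can annotate them.
    """
    labels = np.asarray(labels)
    data = m.to_frame()
    mask1 = labels == group1
    mask2 = labels == group2
    if not mask1.any() or not mask2.any():
        raise ValueError("both contrast groups must be present")

    rows: list[DiffResult] = []
    pvals: list[float] = []
    for name in data.columns:
        x = data.loc[mask1, name].to_numpy()
        y = data.loc[mask2, name].to_numpy()
        n1 = int(np.sum(~np.isnan(x)))
        n2 = int(np.sum(~np.isnan(y)))
        try:
            est, t, df, p = welch_test(x, y)
        except ValueError:
            logger.warning("assay %s skipped: <2 observed values in a group", name)
            continue
        rows.append(
            DiffResult(
                assay=name, estimate=est, t_stat=t, df=df, p_value=p,
                q_value=np.nan, direction_class="ns",
                flagged_low_detection=name in m.low_detection_flagged,
                n1=n1, n2=n2,
            )
        )
        pvals.append(p)

    q = adjust_fdr_bh(pvals)
    for r, qi in zip(rows, q):
        r.q_value = float(qi)
        if qi < q_threshold:
            r.direction_class = "up_in_group2" if r.estimate > 0 else "up_in_group1"
    return rows


def volcano_frame(results: list[DiffResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "assay": [r.assay for r in results],
            "estimate": [r.estimate for r in results],
            "t": [r.t_stat for r in results],
            "df": [r.df for r in results],
            "p": [r.p_value for r in results],
            "q": [r.q_value for r in results],
            "class": [r.direction_class for r in results],
            "flagged_low_detection": [r.flagged_low_detection for r in results],
        }
    )


def compare_demographics(
    info: list[SampleInfo],
    continuous: dict[str, dict[str, float]] | None = None,
    categorical: tuple[str, ...] = ("sex",),
) -> pd.DataFrame:
    """Cohort-level tests: χ² independence for categorical variables,
    Kruskal–Wallis H for continuous ones (age always; extra continuous
    variables may be supplied as ``{var: {sample_id: value}}``).

    Returns one row per variable with the statistic, df and p, plus
    per-group medians and ranges for continuous variables.
    """
    df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in info],
            "diagnosis": [s.diagnosis for s in info],
            "age": [s.age for s in info],
            "sex": [s.sex for s in info],
        }
    ).set_index("sample_id")
    groups = list(pd.unique(df["diagnosis"]))
    if len(groups) < 2:
        raise ValueError("need at least 2 diagnosis groups")

    rows = []
    for var in categorical:
        table = pd.crosstab(df[var], df["diagnosis"])
        if (table.to_numpy() == 0).any():
            logger.warning("χ² for %s: contingency table has empty cells", var)
        chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
        rows.append({"variable": var, "test": "chi2", "statistic": float(chi2),
                     "df": int(dof), "p": float(p), "per_group": None})

    cont_vars: dict[str, pd.Series] = {"age": df["age"]}
    for var, mapping in (continuous or {}).items():
        cont_vars[var] = pd.Series(mapping).reindex(df.index)
    for var, series in cont_vars.items():
        samples = [series[df["diagnosis"] == g].dropna().to_numpy() for g in groups]
        used = [(g, s) for g, s in zip(groups, samples) if len(s) > 0]
        if len(used) < 2:
            logger.warning("Kruskal–Wallis for %s: fewer than 2 groups with data", var)
            continue
        h, p = stats.kruskal(*[s for _, s in used])
        summary = {
            g: {"median": float(np.median(s)), "min": float(s.min()), "max": float(s.max())}
            for g, s in used
        }
        rows.append({"variable": var, "test": "kruskal", "statistic": float(h),
                     "df": len(used) - 1, "p": float(p), "per_group": summary})
    return pd.DataFrame(rows)
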