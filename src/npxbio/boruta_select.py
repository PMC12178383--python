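"""All-relevant feature selection with shadow attributes (Boruta).

The procedure asks, for every protein, whether it carries *any* signal
about a binary diagnosis label — not merely whether it belongs to some
minimal predictive subset.  Each iteration:

1. every undecided real feature gets a "shadow": a copy with its values
   independently permuted, i.e. provably pure noise with the same
   marginal distribution (padded to at least 5 shadows);
2. a random-forest classifier is fit on [real ∪ shadow] features;
3. each feature's importance Z-score = mean per-tree out-of-bag
   permutation importance (mean decrease in accuracy) divided by its
   standard error over trees;
4. a real feature scores a *hit* when its Z exceeds the best shadow Z;
5. each feature's hit count is referred to Binomial(n_iter, 1/2):
   one-sided binomial tests, Bonferroni-corrected over the undecided
   features, classify features as Confirmed (significantly more hits
   than coin-flipping against noise), Rejected (significantly fewer),
   or Tentative.

Rejected features are dropped from later iterations; Confirmed features
stay in the forest (they keep absorbing the signal they carry, which
protects weakly chance-correlated noise features from inheriting their
importance) but are no longer tested.  The loop stops
when nothing is Tentative or after ``max_runs`` iterations; Tentative
features are reported as such, never forced to a side.

Upstream of selection the protein matrix is adjusted for age and sex by
per-assay OLS residualization, and remaining missing values are
replaced by per-assay medians (the random-forest "rough fix").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .npx_core import NpxMatrix, SampleInfo

logger = logging.getLogger(__name__)

CONFIRMED = "Confirmed"
TENTATIVE = "Tentative"
REJECTED = "Rejected"

MIN_SHADOWS = 5


@dataclass
class BorutaState:
    feature_names: list[str]
    hit_counts: dict[str, int]
    n_completed_iterations: int
    decisions: dict[str, str]
    importance_history: dict[str, list[float]]    # NaN after a feature is decided
    shadow_history: list[tuple[float, float, float]]  # (min, mean, max) shadow Z
    alpha: float
    max_runs: int
    seed: int | None

    @property
    def confirmed(self) -> list[str]:
        return [f for f in self.feature_names if self.decisions[f] == CONFIRMED]

    @property
    def rejected(self) -> list[str]:
        return [f for f in self.feature_names if self.decisions[f] == REJECTED]

    @property
    def tentative(self) -> list[str]:
        return [f for f in self.feature_names if self.decisions[f] == TENTATIVE]


def residualize_covariates(
    m: NpxMatrix, info: list[SampleInfo], covariates: tuple[str, ...] = ("age", "sex")
) -> NpxMatrix:
    """Replace each assay's NPX values by OLS residuals on the covariates.

    The design is intercept + age (years) + sex (indicator, F=1), fit per
    assay over that assay's non-missing samples; missing stays missing.
    A covariate constant over the cohort is dropped with a warning.
    """
    by_id = {s.sample_id: s for s in info}
    missing_meta = [sid for sid in m.sample_ids if sid not in by_id]
    if missing_meta:
        raise ValueError(f"no metadata for samples: {missing_meta[:5]}")

    cols = {}
    for cov in covariates:
        if cov == "age":
            cols["age"] = np.array([by_id[sid].age for sid in m.sample_ids])
        elif cov == "sex":
            cols["sex"] = np.array([1.0 if by_id[sid].sex == "F" else 0.0
                                    for sid in m.sample_ids])
        else:
            raise ValueError(f"unknown covariate {cov!r}")
    keep = []
    for name, v in cols.items():
        if np.ptp(v) == 0:
            logger.warning("covariate %s is constant; dropped from the design", name)
        else:
            keep.append(v)
    X = np.column_stack([np.ones(m.n_samples)] + keep)

    out = m.copy()
    V = out.values.to_numpy()
    for j in range(V.shape[1]):
        y = V[:, j]
        obs = ~np.isnan(y)
        if obs.sum() <= X.shape[1]:
            continue
        beta, *_ = np.linalg.lstsq(X[obs], y[obs], rcond=None)
        V[obs, j] = y[obs] - X[obs] @ beta
    out.values = pd.DataFrame(V, index=m.values.index, columns=m.values.columns)
    return out


def roughfix_missing(m: NpxMatrix) -> NpxMatrix:
    """Replace missing entries by the per-assay median of observed values."""
    V = m.values.to_numpy().copy()
    all_missing = np.isnan(V).all(axis=0)
    if all_missing.any():
        bad = m.assay_names[int(np.flatnonzero(all_missing)[0])]
        raise ValueError(f"assay {bad!r} has no observed values")
    med = np.nanmedian(V, axis=0)
    idx = np.nonzero(np.isnan(V))
    V[idx] = med[idx[1]]
    out = m.copy()
    out.values = pd.DataFrame(V, index=m.values.index, columns=m.values.columns)
    return out


def _oob_importance_z(forest: RandomForestClassifier, X: np.ndarray,
                      y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Per-feature Z of the per-tree out-of-bag permutation importance.

    For each tree: accuracy on its OOB samples minus accuracy after
    permuting one feature's OOB values, for every feature.  Z = mean
    over trees / (SD over trees / sqrt(n_trees)); zero-SD features get
    Z = 0.
    """
    n, p = X.shape
    n_trees = len(forest.estimators_)
    imp = np.zeros((n_trees, p))
    inbag_sets = forest.estimators_samples_
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    for t, tree in enumerate(forest.estimators_):
        oob = np.ones(n, dtype=bool)
        oob[inbag_sets[t]] = False
        m = int(oob.sum())
        if m == 0:
            continue
        Xo = X32[oob]
        yo = y[oob]
        # one stacked low-level prediction per tree: the unpermuted OOB
        # block followed by p single-column-permuted copies
        stacked = np.empty(((p + 1) * m, p), dtype=np.float32)
        stacked[:m] = Xo
        for j in range(p):
            block = stacked[(j + 1) * m:(j + 2) * m]
            block[:] = Xo
            block[:, j] = Xo[rng.permutation(m), j]
        votes = tree.tree_.predict(stacked)          # (rows[, 1], n_classes)
        if votes.ndim == 3:
            votes = votes[:, 0, :]
        pred = np.argmax(votes, axis=1).reshape(p + 1, m)
        correct = (pred == yo[None, :]).mean(axis=1)
        imp[t] = correct[0] - correct[1:]
    mean = imp.mean(axis=0)
    sd = imp.std(axis=0, ddof=1)
    se = sd / np.sqrt(n_trees)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(se > 0, mean / se, 0.0)
    return z


def boruta(
    X: pd.DataFrame,
    y,
    max_runs: int = 500,
    alpha: float = 0.01,
    rf_params: dict | None = None,
    seed: int | None = None,
) -> BorutaState:
    """Run the shadow-feature all-relevant selection on a complete matrix.

    ``X`` is samples × features with no missing values; ``y`` is a
    binary label vector.  ``rf_params`` overrides the forest defaults
    (500 trees, sqrt(p) features per split, unlimited depth).
    """
    if max_runs < 8:
        raise ValueError("max_runs must be >= 8 for binomial decisions to be possible")
    ydata = pd.Series(y).to_numpy()
    classes = pd.unique(ydata)
    if len(classes) != 2:
        raise ValueError(f"y must be binary; got classes {list(classes)}")
    counts = [(ydata == c).sum() for c in classes]
    if min(counts) < 2:
        raise ValueError("each class needs at least 2 samples")
    if X.isna().to_numpy().any():
        raise ValueError("X contains missing values; rough-fix first")

    features = [str(c) for c in X.columns]
    Xv = X.to_numpy(dtype=float)
    ybin = (ydata == classes[0]).astype(int)
    rng = np.random.default_rng(seed)

    params = dict(n_estimators=500, max_features="sqrt", max_depth=None)
    params.update(rf_params or {})

    decisions = {f: TENTATIVE for f in features}
    hit_counts = {f: 0 for f in features}
    history: dict[str, list[float]] = {f: [] for f in features}
    shadow_history: list[tuple[float, float, float]] = []

    n_iter = 0
    for n_iter in range(1, max_runs + 1):
        undecided = [f for f in features if decisions[f] == TENTATIVE]
        if not undecided:
            n_iter -= 1
            break
        active = [f for f in features if decisions[f] != REJECTED]
        idx = [features.index(f) for f in active]
        Xr = Xv[:, idx]

        # fresh shadows: independent permutation of each active column,
        # padded to MIN_SHADOWS by recycling columns
        shadow_cols = list(range(len(idx)))
        while len(shadow_cols) < MIN_SHADOWS:
            shadow_cols.append(int(rng.integers(len(idx))))
        Xs = np.column_stack(
            [Xr[rng.permutation(Xr.shape[0]), j] for j in shadow_cols]
        )
        design = np.hstack([Xr, Xs])

        forest = RandomForestClassifier(
            random_state=int(rng.integers(2**31 - 1)), **params
        )
        forest.fit(design, ybin)
        z = _oob_importance_z(forest, design, ybin, rng)
        z_real = z[: len(idx)]
        z_shadow = z[len(idx):]
        shadow_max = float(z_shadow.max())
        shadow_history.append(
            (float(z_shadow.min()), float(z_shadow.mean()), shadow_max)
        )
        undecided_set = set(undecided)
        for f, zf in zip(active, z_real):
            history[f].append(float(zf))
            if f in undecided_set and zf > shadow_max:
                hit_counts[f] += 1
        active_set = set(active)
        for f in features:
            if f not in active_set:
                history[f].append(float("nan"))

        # one-sided binomial tests vs. 1/2, Bonferroni over undecided
        m_tests = len(undecided)
        thr = alpha / m_tests
        newly_decided = []
        for f in undecided:
            h = hit_counts[f]
            p_hi = stats.binom.sf(h - 1, n_iter, 0.5)
            p_lo = stats.binom.cdf(h, n_iter, 0.5)
            if p_hi < thr:
                decisions[f] = CONFIRMED
                newly_decided.append((f, CONFIRMED))
            elif p_lo < thr:
                decisions[f] = REJECTED
                newly_decided.append((f, REJECTED))
        if newly_decided:
            logger.info(
                "iteration %d: %s", n_iter,
                ", ".join(f"{f}→{d}" for f, d in newly_decided),
            )
        logger.info(
            "iteration %d: confirmed %d, tentative %d, rejected %d",
            n_iter,
            sum(d == CONFIRMED for d in decisions.values()),
            sum(d == TENTATIVE for d in decisions.values()),
            sum(d == REJECTED for d in decisions.values()),
        )

    return BorutaState(
        feature_names=features,
        hit_counts=hit_counts,
        n_completed_iterations=n_iter,
        decisions=decisions,
        importance_history=history,
        shadow_history=shadow_history,
        alpha=alpha,
        max_runs=max_runs,
        seed=seed,
    )


def importance_chart_table(state: BorutaState) -> pd.DataFrame:
    """Per-feature (min, mean, max) importance Z plus decision, sorted by
    mean Z descending, with one appended summary row for the shadows."""
    if state.n_completed_iterations < 1:
        raise ValueError("no completed iterations")
    rows = []
    for f in state.feature_names:
        zs = np.array([z for z in state.importance_history[f] if not np.isnan(z)])
        rows.append(
            {
                "feature": f,
                "min_z": float(zs.min()) if zs.size else np.nan,
                "mean_z": float(zs.mean()) if zs.size else np.nan,
                "max_z": float(zs.max()) if zs.size else np.nan,
                "decision": state.decisions[f],
                "hit_count": state.hit_counts[f],
            }
        )
    out = pd.DataFrame(rows).sort_values("mean_z", ascending=False, kind="mergesort")
    sh = np.array(state.shadow_history)
    shadow_row = pd.DataFrame(
        [{
            "feature": "shadow", "min_z": float(sh[:, 0].min()),
            "mean_z": float(sh[:, 1].mean()), "max_z": float(sh[:, 2].max()),
            "decision": "shadow", "hit_count": 0,
        }]
    )
    return pd.concat([out, shadow_row], ignore_index=True)


def cleveland_summary(
    m: NpxMatrix,
    labels,
    confirmed: list[str],
    q_values: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-group mean raw NPX of the confirmed features, one row per
    (feature, group), optionally annotated with the contrast's q-values."""
    if not confirmed:
        return pd.DataFrame(columns=["feature", "group", "mean_npx", "q"])
    data = m.to_frame()
    labels = np.asarray(labels)
    rows = []
    for f in confirmed:
        if f not in data.columns:
            raise ValueError(f"confirmed feature {f!r} not in matrix")
        for g in pd.unique(labels):
            vals = data.loc[labels == g, f]
            rows.append(
                {
                    "feature": f,
                    "group": str(g),
                    "mean_npx": float(vals.mean()),
                    "q": (q_values or {}).get(f, np.nan),
                }
            )
    return pd.DataFrame(rows)
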