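"""Chained-equation imputation of the filtered cohort table.

Numeric variables are imputed by predictive mean matching (PMM): a linear
regression of the observed target on the other analysis features predicts
every row, and each missing cell receives the observed value of one of its
k nearest donors in predicted space.  Categorical/boolean variables are
imputed by the most frequent observed class within the leaf a shallow
decision tree predicts for the row.  Variables are swept in order of
ascending missingness; one completed table is produced (the downstream PCA
consumes a single completed dataset).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .cohort_data import ANALYSIS_FEATURES, CohortTable


class UnimputableError(ValueError):
    """A feature has no observed values to learn from."""


@dataclass
class ImputationReport:
    imputed_counts: dict[str, int]
    sweeps_run: int
    convergence: float  # max relative change in imputed-cell means
    seed: int


def impute_cohort(table: CohortTable,
                  features: list[str] | None = None,
                  n_sweeps: int = 10,
                  k_donors: int = 5,
                  seed: int = 0,
                  ) -> tuple[CohortTable, ImputationReport]:
    """Complete the analysis features of ``table`` by chained equations.

    Observed cells are returned bit-identical; imputations are
    deterministic given ``seed``.  PMM donations always come from the
    observed values of the target, so imputed numerics stay within the
    observed range.
    """
    feats = [f for f in (features or ANALYSIS_FEATURES)
             if f in table.df.columns]
    df = table.df
    rng = np.random.default_rng(seed)

    kinds = {f: table.schema.get(f, ("numeric", None))[0] for f in feats}
    miss = {f: df[f].isna().to_numpy() for f in feats}
    for f in feats:
        if miss[f].all():
            raise UnimputableError(
                f"feature {f!r} has no observed values")

    # encode a working numeric matrix; categoricals -> integer codes
    levels: dict[str, list] = {}
    work = pd.DataFrame(index=df.index)
    for f in feats:
        if kinds[f] in ("categorical", "bool"):
            lv = sorted(df[f].dropna().unique(), key=str)
            levels[f] = lv
            work[f] = df[f].map({v: float(i) for i, v in enumerate(lv)})
        else:
            work[f] = df[f].astype(float)

    # initial fill: mean / mode of observed values
    for f in feats:
        col = work[f]
        if col.isna().any():
            if kinds[f] in ("categorical", "bool"):
                fill = col.mode().iloc[0]
            else:
                fill = col.mean()
            work[f] = col.fillna(fill)

    order = sorted((f for f in feats if miss[f].any()),
                   key=lambda f: miss[f].sum())
    prev_means: dict[str, float] = {}
    convergence = 0.0
    sweeps_run = 0
    for sweep in range(n_sweeps):
        sweeps_run = sweep + 1
        for f in order:
            m = miss[f]
            others = [g for g in feats if g != f]
            X = work[others].to_numpy(dtype=float)
            # z-scale predictors for numerical stability
            mu, sd = X.mean(axis=0), X.std(axis=0)
            sd[sd == 0] = 1.0
            X = (X - mu) / sd
            y_obs = work.loc[~m, f].to_numpy(dtype=float)
            if kinds[f] in ("categorical", "bool"):
                work.loc[m, f] = _impute_categorical(
                    X[~m], y_obs, X[m], rng)
            else:
                work.loc[m, f] = _impute_pmm(
                    X[~m], y_obs, X[m], k_donors, rng)
        new_means = {f: float(work.loc[miss[f], f].mean()) for f in order}
        if prev_means:
            convergence = max(
                (abs(new_means[f] - prev_means[f])
                 / max(abs(prev_means[f]), 1e-12) for f in order),
                default=0.0)
        prev_means = new_means
        if sweep > 0 and convergence < 1e-3:
            break

    out = table.copy()
    for f in feats:
        m = miss[f]
        if not m.any():
            continue
        if kinds[f] in ("categorical", "bool"):
            decoded = work.loc[m, f].round().astype(int).map(
                dict(enumerate(levels[f])))
            out.df.loc[m, f] = decoded.to_numpy()
        else:
            out.df.loc[m, f] = work.loc[m, f].to_numpy()
    report = ImputationReport(
        {f: int(miss[f].sum()) for f in feats}, sweeps_run,
        float(convergence), seed)
    return out, report


def _impute_pmm(X_obs, y_obs, X_mis, k, rng):
    """Predictive mean matching: OLS predictions, donate the observed
    value of one of the k nearest observed predictions."""
    if len(X_mis) == 0:
        return np.array([])
    A = np.column_stack([np.ones(len(X_obs)), X_obs])
    coef, *_ = np.linalg.lstsq(A, y_obs, rcond=None)
    pred_obs = A @ coef
    pred_mis = np.column_stack([np.ones(len(X_mis)), X_mis]) @ coef
    k_eff = min(k, len(y_obs))
    out = np.empty(len(X_mis))
    for i, p in enumerate(pred_mis):
        d = np.abs(pred_obs - p)
        donors = np.argpartition(d, k_eff - 1)[:k_eff]
        out[i] = y_obs[donors[rng.integers(k_eff)]]
    return out


def _impute_categorical(X_obs, y_obs, X_mis, rng):
    """Most frequent observed class within the decision-tree leaf
    predicted for each missing row."""
    if len(X_mis) == 0:
        return np.array([])
    y = y_obs.astype(int)
    if len(np.unique(y)) == 1:
        return np.full(len(X_mis), float(y[0]))
    tree = DecisionTreeClassifier(
        max_depth=4, min_samples_leaf=5,
        random_state=int(rng.integers(2 ** 31)))
    tree.fit(X_obs, y)
    leaf_obs = tree.apply(X_obs)
    leaf_mis = tree.apply(X_mis)
    out = np.empty(len(X_mis))
    overall_mode = np.bincount(y).argmax()
    for i, leaf in enumerate(leaf_mis):
        members = y[leaf_obs == leaf]
        out[i] = np.bincount(members).argmax() if len(members) else \
            overall_mode
    return out.astype(float)
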