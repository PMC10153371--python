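"""Correlation-matrix PCA with eigenvector (biplot) interpretation.

Clinical features carry incommensurate units, so every feature is z-scored
(population SD) before the singular value decomposition; loadings are the
unit-norm eigenvectors of the correlation matrix.  On the biplot, the
angle between two feature vectors encodes their correlation: same
direction = direct relationship, opposite = inverse, near-90 degrees = no
relationship.  Feature contributions (squared-loading shares) drive the
arrow coloring and the low-contribution display floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


@dataclass
class PCAResult:
    """Loadings (features x components, orthonormal columns), scores
    (patients x components), explained-variance ratios and the
    centering/scaling used."""

    loadings: np.ndarray
    scores: np.ndarray
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    feature_names: list[str]
    center: np.ndarray
    scale: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def contributions_frame(self) -> pd.DataFrame:
        contrib = 100.0 * self.loadings ** 2
        return pd.DataFrame(
            contrib, index=self.feature_names,
            columns=[f"PC{k + 1}" for k in range(self.n_components)])


def fit_pca(data, feature_names: list[str] | None = None) -> PCAResult:
    """PCA of the z-scored data matrix via SVD.

    Component signs are fixed so the largest-magnitude loading of each
    component is positive, making the fit bit-reproducible.  A
    zero-variance feature is an error (drop it upstream).
    """
    if isinstance(data, pd.DataFrame):
        feature_names = feature_names or list(data.columns)
        X = data.to_numpy(dtype=float)
    else:
        X = np.asarray(data, dtype=float)
        feature_names = feature_names or [f"f{j}" for j in
                                          range(X.shape[1])]
    if np.isnan(X).any():
        raise ValueError("input contains missing cells; impute first")
    n, p = X.shape
    if p < 2:
        raise ValueError("need at least two features")
    center = X.mean(axis=0)
    scale = X.std(axis=0)  # population SD
    dead = np.flatnonzero(scale == 0)
    if dead.size:
        raise ValueError(
            f"zero-variance feature(s): "
            f"{[feature_names[j] for j in dead]}; drop before PCA")
    Z = (X - center) / scale
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    loadings = Vt.T
    # sign fix: largest-|loading| entry of each component positive
    for k in range(loadings.shape[1]):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            U[:, k] *= -1
    eigvals = s ** 2 / n  # eigenvalues of the correlation matrix
    ratio = eigvals / eigvals.sum()
    scores = Z @ loadings
    return PCAResult(loadings, scores, eigvals, ratio, list(feature_names),
                     center, scale)


def feature_contributions(result: PCAResult,
                          dims: tuple[int, int] = (1, 2)) -> pd.DataFrame:
    """Percent contribution of each feature to the two displayed
    components and their eigenvalue-weighted combination.

    Contribution of feature j to component k is 100 * loading[j,k]^2 (the
    loadings are unit vectors, so these sum to 100 per component).
    """
    d1, d2 = _check_dims(result, dims)
    c1 = 100.0 * result.loadings[:, d1] ** 2
    c2 = 100.0 * result.loadings[:, d2] ** 2
    ev1, ev2 = result.explained_variance[[d1, d2]]
    pair = (ev1 * c1 + ev2 * c2) / (ev1 + ev2)
    return pd.DataFrame({f"PC{dims[0]}": c1, f"PC{dims[1]}": c2,
                         "pair": pair}, index=result.feature_names)


def vector_relationship(result: PCAResult, feat_a: str, feat_b: str,
                        dims: tuple[int, int] = (1, 2),
                        tau: float = 0.5,
                        ) -> tuple[str, float]:
    """Classify the biplot relationship of two features in the displayed
    plane by the cosine of the angle between their loading vectors.

    cosine >= +tau -> "direct", <= -tau -> "inverse", else "orthogonal";
    a near-zero projected vector yields "indeterminate".  The numeric
    cosine is returned alongside.
    """
    d1, d2 = _check_dims(result, dims)
    names = result.feature_names
    va = result.loadings[names.index(feat_a)][[d1, d2]]
    vb = result.loadings[names.index(feat_b)][[d1, d2]]
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na < 1e-12 or nb < 1e-12:
        return "indeterminate", float("nan")
    cos = float(va @ vb / (na * nb))
    if cos >= tau:
        return "direct", cos
    if cos <= -tau:
        return "inverse", cos
    return "orthogonal", cos


def render_biplot(result: PCAResult, out_path,
                  dims: tuple[int, int] = (1, 2),
                  contribution_floor: float = 0.0,
                  cmap: str = "viridis") -> int:
    """Draw the eigenvector plot: one arrow per feature from the origin,
    length = loading magnitude, color = pair contribution.

    Features whose pair contribution falls below ``contribution_floor``
    (percent) are omitted.  Returns the number of arrows drawn.
    """
    d1, d2 = _check_dims(result, dims)
    contrib = feature_contributions(result, dims)["pair"]
    keep = contrib >= contribution_floor
    fig, ax = plt.subplots(figsize=(7, 6))
    norm = matplotlib.colors.Normalize(vmin=0,
                                       vmax=max(contrib.max(), 1e-9))
    cm = matplotlib.colormaps[cmap]
    drawn = 0
    for j, name in enumerate(result.feature_names):
        if not keep.iloc[j]:
            continue
        x, y = result.loadings[j, d1], result.loadings[j, d2]
        color = cm(norm(contrib.iloc[j]))
        ax.annotate("", xy=(x, y), xytext=(0, 0),
                    arrowprops=dict(arrowstyle="->", color=color, lw=1.5))
        ax.text(x * 1.07, y * 1.07, name, fontsize=8, ha="center",
                color=color)
        drawn += 1
    lim = 1.05 * max(np.abs(result.loadings[:, [d1, d2]]).max(), 0.1)
    ax.set_xlim(-lim, lim)
    ax.set_ylim(-lim, lim)
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    r1 = 100 * result.explained_variance_ratio[d1]
    r2 = 100 * result.explained_variance_ratio[d2]
    ax.set_xlabel(f"PC{dims[0]} ({r1:.1f}%)")
    ax.set_ylabel(f"PC{dims[1]} ({r2:.1f}%)")
    fig.colorbar(matplotlib.cm.ScalarMappable(norm=norm, cmap=cm), ax=ax,
                 label="contribution (%)")
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return drawn


def encode_for_pca(df: pd.DataFrame, schema) -> pd.DataFrame:
    """Numeric encoding for PCA: booleans and two-level categoricals to
    0/1; categoricals with more than two levels are dropped (the encoding
    map is returned implicitly by the surviving columns)."""
    out = {}
    for col in df.columns:
        kind, vocab = schema.get(col, ("numeric", None))
        if kind == "bool":
            out[col] = df[col].astype("boolean").astype("Float64"
                                                        ).astype(float)
        elif kind == "categorical":
            levels = list(vocab) if vocab else sorted(df[col].dropna()
                                                      .unique())
            if len(levels) == 2:
                out[col] = df[col].map({levels[0]: 0.0, levels[1]: 1.0})
        elif kind in ("numeric", "int"):
            out[col] = df[col].astype(float)
    return pd.DataFrame(out, index=df.index)


def _check_dims(result: PCAResult, dims) -> tuple[int, int]:
    d1, d2 = dims
    if not (1 <= d1 <= result.n_components
            and 1 <= d2 <= result.n_components) or d1 == d2:
        raise ValueError(f"invalid component pair {dims}")
    return d1 - 1, d2 - 1
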