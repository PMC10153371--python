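"""PDL-1 quantification on H-DAB immunohistochemistry tiles.

Pipeline: RGB -> optical density (Beer–Lambert) -> least-squares stain
unmixing into hematoxylin and DAB concentration maps -> Otsu thresholding
per stain channel -> connected-component segmentation with morphology
features -> random-forest stain-class filtering (no/low/medium/high, "no"
regions removed) -> the PDL-1 score, the ratio of DAB-stained to
hematoxylin-stained pixel area.  Normalizing DAB area by hematoxylin
(nuclear) area controls for tissue cellularity; membranous PDL-1 staining
makes the two stain compartments spatially distinct.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage import measure
from sklearn.ensemble import RandomForestClassifier

log = logging.getLogger(__name__)

STAIN_CLASSES = ("no", "low", "medium", "high")

#: unit-norm optical-density absorbance vectors (R, G, B) for the standard
#: H-DAB pair (Ruifrok–Johnston calibration).
HEMATOXYLIN_OD = np.array([0.650, 0.704, 0.286])
DAB_OD = np.array([0.268, 0.570, 0.776])
DEFAULT_STAIN_MATRIX = np.column_stack([
    HEMATOXYLIN_OD / np.linalg.norm(HEMATOXYLIN_OD),
    DAB_OD / np.linalg.norm(DAB_OD),
])

MORPHOLOGY_FEATURES = ("area", "mean_intensity", "max_intensity",
                       "perimeter", "eccentricity", "solidity")


@dataclass
class StainPair:
    """Deconvolved hematoxylin and DAB concentration maps plus the stain
    matrix used and the count of negative concentrations clipped."""

    hematoxylin: np.ndarray
    dab: np.ndarray
    stain_matrix: np.ndarray
    clipped: int


@dataclass
class PDL1Score:
    dab_pixels: int
    hema_pixels: int

    @property
    def ratio(self) -> float:
        if self.hema_pixels == 0:
            return float("nan")
        return self.dab_pixels / self.hema_pixels

    @property
    def undefined(self) -> bool:
        return self.hema_pixels == 0


@dataclass
class StainClassModel:
    forest: RandomForestClassifier
    classes: tuple[str, ...]
    features: tuple[str, ...]
    oob_accuracy: float
    seed: int


def rgb_to_od(tile: np.ndarray, i0: int = 255) -> np.ndarray:
    """Optical density OD = -log10((I+1)/(i0+1)); pure white maps to 0.

    The +1 guards the logarithm at zero intensity.
    """
    tile = np.asarray(tile, dtype=float)
    return -np.log10((tile + 1.0) / (i0 + 1.0))


def od_to_rgb(od: np.ndarray, i0: int = 255) -> np.ndarray:
    """Exact inverse of :func:`rgb_to_od` (before integer quantization)."""
    return (i0 + 1.0) * np.power(10.0, -np.asarray(od, dtype=float)) - 1.0


def deconvolve_stains(od: np.ndarray,
                      stain_matrix: np.ndarray | None = None) -> StainPair:
    """Unmix a 3-channel OD image into hematoxylin and DAB concentrations
    by per-pixel least squares OD = M @ c.

    Negative concentrations are clipped to zero (count logged in the
    result).  Collinear stain vectors are rejected.
    """
    M = DEFAULT_STAIN_MATRIX if stain_matrix is None else \
        np.asarray(stain_matrix, dtype=float)
    if M.shape != (3, 2):
        raise ValueError("stain matrix must be 3x2 (one column per stain)")
    cos = abs(M[:, 0] @ M[:, 1]
              / (np.linalg.norm(M[:, 0]) * np.linalg.norm(M[:, 1])))
    if cos > 1 - 1e-6:
        raise ValueError("stain vectors are collinear; cannot unmix")
    pinv = np.linalg.pinv(M)  # 2x3
    flat = od.reshape(-1, 3)
    conc = flat @ pinv.T
    clipped = int((conc < -1e-12).sum())
    conc = np.clip(conc, 0.0, None)
    h, w = od.shape[:2]
    return StainPair(conc[:, 0].reshape(h, w), conc[:, 1].reshape(h, w),
                     M, clipped)


def otsu_threshold(channel: np.ndarray, n_bins: int = 256) -> float:
    """Otsu's threshold on a histogram over [min, max] of the channel.

    Returns the interior bin edge maximizing the between-class variance;
    ties resolve to the lowest threshold.  A constant channel is a
    degenerate input.
    """
    x = np.asarray(channel, dtype=float).ravel()
    lo, hi = x.min(), x.max()
    if lo == hi:
        raise ValueError("constant channel: Otsu threshold undefined")
    counts, edges = np.histogram(x, bins=n_bins, range=(lo, hi))
    total = counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(counts)                     # pixels at or below bin k
    m0 = np.cumsum(counts * centers)
    w1 = total - w0
    mu_total = m0[-1] / total
    with np.errstate(divide="ignore", invalid="ignore"):
        mean0 = m0 / w0
        mean1 = (m0[-1] - m0) / w1
        between = w0 / total * w1 / total * (mean0 - mean1) ** 2
    between = np.nan_to_num(between[:-1])      # split after bin k -> edge k+1
    best = int(np.argmax(between))             # argmax returns first (lowest)
    return float(edges[best + 1])


def segment_channel(channel: np.ndarray, threshold: float,
                    min_area: int = 20) -> pd.DataFrame:
    """8-connected components of (channel >= threshold) with morphology
    features; regions smaller than ``min_area`` pixels are discarded."""
    mask = np.asarray(channel) >= threshold
    labels = measure.label(mask, connectivity=2)
    rows = []
    for rp in measure.regionprops(labels, intensity_image=channel):
        if rp.area < min_area:
            continue
        rows.append({
            "label": rp.label, "area": int(rp.area),
            "centroid_row": rp.centroid[0], "centroid_col": rp.centroid[1],
            "mean_intensity": float(rp.intensity_mean),
            "max_intensity": float(rp.intensity_max),
            "perimeter": float(rp.perimeter),
            "eccentricity": float(rp.eccentricity),
            "solidity": float(rp.solidity),
        })
    cols = ["label", "area", "centroid_row", "centroid_col",
            "mean_intensity", "max_intensity", "perimeter",
            "eccentricity", "solidity"]
    return pd.DataFrame(rows, columns=cols)


def train_stain_classifier(labeled: pd.DataFrame, seed: int = 0,
                           n_trees: int = 200) -> StainClassModel:
    """Random forest over the morphology feature vector, predicting stain
    class (no/low/medium/high).  Requires >= 4 examples of every class;
    out-of-bag accuracy is reported."""
    missing = [c for c in STAIN_CLASSES
               if (labeled["stain_class"] == c).sum() < 4]
    if missing:
        raise ValueError(
            f"need >= 4 training examples per class; short: {missing}")
    X = labeled[list(MORPHOLOGY_FEATURES)].to_numpy(dtype=float)
    y = labeled["stain_class"].to_numpy()
    forest = RandomForestClassifier(n_estimators=n_trees, oob_score=True,
                                    random_state=seed, n_jobs=1)
    forest.fit(X, y)
    return StainClassModel(forest, STAIN_CLASSES, MORPHOLOGY_FEATURES,
                           float(forest.oob_score_), seed)


def classify_and_filter(segs: pd.DataFrame,
                        model: StainClassModel) -> pd.DataFrame:
    """Assign a stain class to every region and drop the "no stain"
    regions (artifact filtration)."""
    missing = [c for c in model.features if c not in segs.columns]
    if missing:
        raise ValueError(f"segment table lacks model features {missing}")
    out = segs.copy()
    if len(out) == 0:
        out["stain_class"] = pd.Series([], dtype="string")
        return out
    X = out[list(model.features)].to_numpy(dtype=float)
    out["stain_class"] = model.forest.predict(X)
    removed = int((out["stain_class"] == "no").sum())
    if removed:
        log.info("filtered %d no-stain regions of %d", removed, len(out))
    return out[out["stain_class"] != "no"].reset_index(drop=True)


def score_pdl1(dab_segs: pd.DataFrame,
               hema_segs: pd.DataFrame) -> PDL1Score:
    """DAB:hematoxylin pixel ratio from post-filter segmentation areas."""
    dab = int(dab_segs["area"].sum()) if len(dab_segs) else 0
    hema = int(hema_segs["area"].sum()) if len(hema_segs) else 0
    return PDL1Score(dab, hema)


def score_tile(tile: np.ndarray,
               stain_matrix: np.ndarray | None = None,
               model: StainClassModel | None = None,
               min_area: int = 20, n_bins: int = 256) -> PDL1Score:
    """Run the full per-tile pipeline: OD, unmixing, per-channel Otsu,
    segmentation, optional classifier filtration, ratio."""
    od = rgb_to_od(tile)
    pair = deconvolve_stains(od, stain_matrix)
    tables = {}
    for name, ch in (("hematoxylin", pair.hematoxylin), ("dab", pair.dab)):
        if np.ptp(ch) == 0:
            tables[name] = segment_channel(ch, np.inf, min_area)
            continue
        thr = otsu_threshold(ch, n_bins)
        segs = segment_channel(ch, thr, min_area)
        if model is not None:
            segs = classify_and_filter(segs, model)
        tables[name] = segs
    return score_pdl1(tables["dab"], tables["hematoxylin"])


def compare_score_groups(scores_a, scores_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum comparison of per-patient PDL-1 scores
    between stratified groups.

    Exact null distribution for combined n <= 20 without ties, otherwise
    the tie-corrected normal approximation.  Returns (statistic, p).
    All-tied inputs give p = 1 with a warning.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need >= 3 patients per group")
    if np.ptp(np.concatenate([a, b])) == 0:
        log.warning("all scores tied; comparison degenerate")
        return 0.0, 1.0
    pooled = np.concatenate([a, b])
    exact = len(pooled) <= 20 and len(np.unique(pooled)) == len(pooled)
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="exact" if exact else "asymptotic")
    return float(res.statistic), float(res.pvalue)
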