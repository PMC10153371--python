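"""Synthetic H-DAB tile renderer with exact ground truth.

Tiles emulate hematoxylin-stained nuclei (filled ellipses) and membranous
PDL-1 staining (DAB annular rings around a configurable fraction of
cells).  Rings and nuclei are spatially disjoint, so the true DAB and
hematoxylin pixel areas — and their ratio, the quantity the scoring
pipeline estimates — are unambiguous.  Concentration fields are rendered
to RGB through the same Beer–Lambert stain matrix the pipeline inverts
(a mismatched matrix can be supplied to probe robustness), Gaussian noise
is added in 8-bit intensity space, and the pre-noise rendered areas are
returned as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from skimage import measure

from .ihc_pipeline import (DEFAULT_STAIN_MATRIX, STAIN_CLASSES,
                           deconvolve_stains, rgb_to_od)


class PackingError(RuntimeError):
    """Nuclei could not be placed without overlap within the attempt
    budget."""


class CoverageError(ValueError):
    """A requested stain class received no training segments."""


@dataclass
class TileGeneratorConfig:
    """Geometry, staining and noise parameters for one tile."""

    height: int = 192
    width: int = 192
    n_nuclei: int = 40
    radius_mean: float = 7.0
    radius_sd: float = 1.2
    axis_ratio_range: tuple[float, float] = (0.7, 1.0)
    hema_conc_range: tuple[float, float] = (0.45, 0.85)
    dab_positive_fraction: float = 0.4
    ring_thickness: float = 2.5
    dab_conc_range: tuple[float, float] = (0.45, 0.85)
    artifact_count: int = 0
    artifact_radius_range: tuple[float, float] = (2.5, 4.0)
    artifact_conc_range: tuple[float, float] = (0.03, 0.12)
    background_intensity: int = 255
    noise_sd: float = 0.0
    seed: int = 0
    max_attempts: int = 1000

    def __post_init__(self):
        if not 0 <= self.dab_positive_fraction <= 1:
            raise ValueError("dab_positive_fraction must lie in [0, 1]")
        if self.radius_mean <= 0 or self.ring_thickness < 0:
            raise ValueError("radii must be positive")
        if min(self.height, self.width) < 32:
            raise ValueError("tiles must be at least 32x32")


@dataclass
class TileGroundTruth:
    """Per-cell geometry, pre-noise rendered stain areas, and the true
    DAB:hematoxylin area ratio the pipeline should recover."""

    cells: pd.DataFrame          # center_row, center_col, radius, has_dab
    hema_area: int
    dab_area: int
    hema_concentration: np.ndarray = field(repr=False)
    dab_concentration: np.ndarray = field(repr=False)
    config: dict = field(repr=False, default_factory=dict)

    @property
    def true_ratio(self) -> float:
        return self.dab_area / self.hema_area if self.hema_area else \
            float("nan")


def generate_tile(config: TileGeneratorConfig,
                  stain_matrix: np.ndarray | None = None,
                  ) -> tuple[np.ndarray, TileGroundTruth]:
    """Render one RGB tile and its ground truth, reproducibly per seed.

    Cells are placed by rejection sampling so that the outer radius
    (nucleus + DAB ring) of no two cells overlaps; exceeding the attempt
    budget raises :class:`PackingError`.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    M = DEFAULT_STAIN_MATRIX if stain_matrix is None else stain_matrix
    H, W = cfg.height, cfg.width
    hema = np.zeros((H, W))
    dab = np.zeros((H, W))
    rows_grid, cols_grid = np.mgrid[0:H, 0:W]

    placed: list[tuple[float, float, float]] = []  # row, col, outer radius
    cells = []
    n_pos = int(round(cfg.n_nuclei * cfg.dab_positive_fraction))
    for i in range(cfg.n_nuclei):
        radius = max(2.0, rng.normal(cfg.radius_mean, cfg.radius_sd))
        has_dab = i < n_pos
        outer = radius + (cfg.ring_thickness if has_dab else 0.0)
        for _ in range(cfg.max_attempts):
            r = rng.uniform(outer + 1, H - outer - 1)
            c = rng.uniform(outer + 1, W - outer - 1)
            if all((r - pr) ** 2 + (c - pc) ** 2 >= (outer + po) ** 2
                   for pr, pc, po in placed):
                break
        else:
            raise PackingError(
                f"could not place nucleus {i + 1}/{cfg.n_nuclei}; "
                "reduce n_nuclei or radii")
        placed.append((r, c, outer))
        ratio = rng.uniform(*cfg.axis_ratio_range)
        theta = rng.uniform(0, np.pi)
        conc_h = rng.uniform(*cfg.hema_conc_range)
        dr, dc = rows_grid - r, cols_grid - c
        u = dr * np.cos(theta) + dc * np.sin(theta)
        v = -dr * np.sin(theta) + dc * np.cos(theta)
        a, b = radius, radius * ratio
        q = (u / a) ** 2 + (v / b) ** 2
        hema[q <= 1.0] = conc_h
        if has_dab:
            conc_d = rng.uniform(*cfg.dab_conc_range)
            s = 1.0 + cfg.ring_thickness / radius
            ring = (q > 1.0) & ((u / (a * s)) ** 2
                                + (v / (b * s)) ** 2 <= 1.0)
            dab[ring] = conc_d

    artifacts = []
    for _ in range(cfg.artifact_count):
        ar = rng.uniform(*cfg.artifact_radius_range)
        r = rng.uniform(ar + 1, H - ar - 1)
        c = rng.uniform(ar + 1, W - ar - 1)
        conc = rng.uniform(*cfg.artifact_conc_range)
        spot = ((rows_grid - r) ** 2 + (cols_grid - c) ** 2 <= ar ** 2)
        spot &= (hema == 0) & (dab == 0)
        hema[spot] = conc
        artifacts.append((r, c, ar))

    hema_area = int((hema > _artifact_ceiling(cfg)).sum())
    dab_area = int((dab > 0).sum())

    od = hema[..., None] * M[:, 0] + dab[..., None] * M[:, 1]
    intensity = (cfg.background_intensity + 1.0) * 10.0 ** (-od) - 1.0
    if cfg.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, cfg.noise_sd,
                                           intensity.shape)
    tile = np.clip(np.round(intensity), 0, 255).astype(np.uint8)

    cells_df = pd.DataFrame(
        [(r, c, o, i < n_pos) for i, (r, c, o) in enumerate(placed)],
        columns=["center_row", "center_col", "outer_radius", "has_dab"])
    truth = TileGroundTruth(cells_df, hema_area, dab_area, hema, dab,
                            asdict(cfg))
    return tile, truth


def _artifact_ceiling(cfg: TileGeneratorConfig) -> float:
    """Concentration separating artifact specks from real nuclei."""
    if cfg.artifact_count == 0:
        return 0.0
    return (cfg.artifact_conc_range[1] + cfg.hema_conc_range[0]) / 2.0


def generate_training_segments(config: TileGeneratorConfig | None = None,
                               n_tiles: int = 20,
                               cut_points: tuple[float, float, float]
                               = (0.15, 0.45, 0.80),
                               seed: int = 0,
                               min_area: int = 20,
                               capture_threshold: float = 0.02,
                               ) -> pd.DataFrame:
    """Build a labeled segment table for stain-classifier training.

    Tiles are rendered, deconvolved, and segmented at a low capture
    threshold so that dim artifact specks are included; each region is
    labeled by its mean *true* concentration binned against
    ``cut_points`` into no/low/medium/high.  An empty class raises
    :class:`CoverageError` (adjust config or cuts).
    """
    if config is None:
        # training default: artifact specks give the "no" class exemplars
        # and wide concentration ranges cover low/medium/high
        config = TileGeneratorConfig(artifact_count=6,
                                     hema_conc_range=(0.1, 1.2),
                                     dab_conc_range=(0.1, 1.2))
    lo, mid, hi = cut_points
    if not lo < mid < hi:
        raise ValueError("cut points must be strictly increasing")
    rng = np.random.default_rng(seed)
    frames = []
    for t in range(n_tiles):
        cfg = TileGeneratorConfig(**{**asdict(config),
                                     "seed": int(rng.integers(2 ** 31))})
        tile, truth = generate_tile(cfg)
        pair = deconvolve_stains(rgb_to_od(tile))
        for channel, measured, true_map in (
                ("hematoxylin", pair.hematoxylin,
                 truth.hema_concentration),
                ("dab", pair.dab, truth.dab_concentration)):
            labels = measure.label(measured >= capture_threshold,
                                   connectivity=2)
            for rp in measure.regionprops(labels,
                                          intensity_image=measured):
                if rp.area < min_area:
                    continue
                mask = labels == rp.label
                true_mean = float(true_map[mask].mean())
                cls = ("no" if true_mean < lo else
                       "low" if true_mean < mid else
                       "medium" if true_mean < hi else "high")
                frames.append({
                    "tile": t, "channel": channel, "label": rp.label,
                    "area": int(rp.area),
                    "mean_intensity": float(rp.intensity_mean),
                    "max_intensity": float(rp.intensity_max),
                    "perimeter": float(rp.perimeter),
                    "eccentricity": float(rp.eccentricity),
                    "solidity": float(rp.solidity),
                    "true_mean_concentration": true_mean,
                    "stain_class": cls,
                })
    table = pd.DataFrame(frames)
    counts = table["stain_class"].value_counts() if len(table) else {}
    empty = [c for c in STAIN_CLASSES
             if c not in counts or counts[c] == 0]
    if empty:
        raise CoverageError(
            f"classes {empty} received no segments; widen concentration "
            "ranges, add artifacts, or move the cut points")
    return table
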