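"""Soma segmentation, neuron counting and survival normalization.

Counts marker-positive cell bodies per field and converts raw dose-series
counts into survival normalized to each population's untreated (dose-0)
mean, the per-well quantity used by all downstream survival statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from skimage.filters import median as median_filter
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import disk, opening, remove_small_holes, remove_small_objects

from .core import ImageField
from .synthetic import GroundTruth

#: Doses (uM hydrogen peroxide) of the survival assay.
H2O2_DOSES_UM: tuple[int, ...] = (0, 100, 150, 200)

DEFAULT_MIN_SOMA_AREA_UM2 = 30.0
DEFAULT_OPENING_RADIUS_UM = 1.5
DEFAULT_MATCH_RADIUS_UM = 5.0


@dataclass
class SomaMask:
    """Labeled soma raster with per-label geometry in physical units."""

    labels: np.ndarray  # integer labels, 0 = background
    pixel_size_um: float
    centroids_um: list[tuple[float, float]] = field(default_factory=list)
    areas_um2: list[float] = field(default_factory=list)

    @classmethod
    def from_labels(cls, labels: np.ndarray, pixel_size_um: float) -> "SomaMask":
        props = regionprops(labels)
        cents = [
            (p.centroid[1] * pixel_size_um, p.centroid[0] * pixel_size_um)
            for p in props
        ]  # (x, y)
        areas = [p.area * pixel_size_um**2 for p in props]
        return cls(labels, pixel_size_um, cents, areas)

    @property
    def count(self) -> int:
        return len(self.areas_um2)


def segment_somata(
    field: ImageField,
    channel: str = "marker",
    min_soma_area_um2: float = DEFAULT_MIN_SOMA_AREA_UM2,
    intensity_quantile: float | None = None,
    opening_radius_um: float = DEFAULT_OPENING_RADIUS_UM,
) -> SomaMask:
    """Segment bright compact cell bodies in one channel.

    Median-filtered image is thresholded (Otsu by default, or at
    ``intensity_quantile`` of the intensity distribution when given), thin
    neurite pixels are removed by a morphological opening of radius
    ``opening_radius_um``, holes are filled, and regions smaller than
    ``min_soma_area_um2`` are dropped.  A constant image yields an empty
    mask rather than an error.
    """
    img = field.channel(channel).astype(float)
    px = field.pixel_size_um
    if img.max() == img.min():
        return SomaMask.from_labels(np.zeros(img.shape, int), px)
    smooth = median_filter(img, disk(1))
    if intensity_quantile is not None:
        thresh = float(np.quantile(smooth, intensity_quantile))
    else:
        thresh = threshold_otsu(smooth)
    binary = smooth > thresh
    radius_px = max(int(round(opening_radius_um / px)), 1)
    binary = opening(binary, disk(radius_px))
    min_px = max(int(round(min_soma_area_um2 / px**2)), 1)
    binary = remove_small_holes(binary, max_size=min_px)
    binary = remove_small_objects(binary, max_size=min_px - 1)
    return SomaMask.from_labels(cc_label(binary), px)


def count_neurons(mask: SomaMask) -> int:
    """Number of labeled somata."""
    return mask.count


def evaluate_census(
    mask: SomaMask,
    truth: GroundTruth,
    match_radius_um: float = DEFAULT_MATCH_RADIUS_UM,
) -> float:
    """Counting accuracy against generator truth.

    Greedy nearest-pair one-to-one matching of predicted centroids to true
    soma centers within ``match_radius_um``;
    accuracy = matches / max(n_true, n_predicted).  Both empty -> 1.0.
    """
    if match_radius_um <= 0:
        raise ValueError("match_radius_um must be > 0")
    pred = np.asarray(mask.centroids_um, float).reshape(-1, 2)
    true = np.asarray(truth.soma_centers_um, float).reshape(-1, 2)
    n_pred, n_true = len(pred), len(true)
    if n_pred == 0 and n_true == 0:
        return 1.0
    if n_pred == 0 or n_true == 0:
        return 0.0
    dists = cdist(pred, true)
    order = np.argsort(dists, axis=None)
    used_p: set[int] = set()
    used_t: set[int] = set()
    matches = 0
    for flat in order:
        i, j = divmod(int(flat), n_true)
        if dists[i, j] > match_radius_um:
            break
        if i in used_p or j in used_t:
            continue
        used_p.add(i)
        used_t.add(j)
        matches += 1
    return matches / max(n_true, n_pred)


def normalize_survival(counts: pd.DataFrame, pool_populations: bool = False) -> pd.DataFrame:
    """Normalize per-well raw counts to the dose-0 mean of each population.

    ``counts`` needs columns ``population``, ``dose_um``, ``well_id``,
    ``count``.  Returns the table with ``normalized`` and
    ``normalization_defined`` columns; a population whose dose-0 mean is
    zero (or that has no dose-0 wells) is flagged undefined (NaN).

    ``pool_populations`` normalizes every well by the global dose-0 mean
    instead (off by default; wells are normalized within their population).
    """
    required = {"population", "dose_um", "well_id", "count"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    out = counts.copy()
    out["normalized"] = np.nan
    out["normalization_defined"] = False
    if pool_populations:
        baselines = {None: counts.loc[counts["dose_um"] == 0, "count"].mean()}
        keys = [None] * len(out)
    else:
        base = counts[counts["dose_um"] == 0].groupby("population")["count"].mean()
        baselines = base.to_dict()
        keys = out["population"].tolist()
    for idx, key in zip(out.index, keys):
        b = baselines.get(key, np.nan)
        if np.isfinite(b) and b > 0:
            out.loc[idx, "normalized"] = out.loc[idx, "count"] / b
            out.loc[idx, "normalization_defined"] = True
    return out
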