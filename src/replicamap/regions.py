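"""Region discovery and differential lipid analysis.

Tissue pixels are grouped by hierarchical cluster analysis (HCA) of their
feature vectors; clusters are interpreted as tissue regions (grey matter
GM, white matter WM, tumour T, infiltrated I, necrosis N) by the
concordance of their mean spectra with known marker ions. Differential
abundance between two pixel groups is scored per feature with a
two-tailed Student's t-test and a pseudocounted log2 fold change
(volcano analysis). Overlay maps, region areas and along-axis abundance
profiles are pure reads of the representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import AgglomerativeClustering

from .core import CommonRepresentation, TissueMask
from .errors import ParameterError
from .preprocess import resolve_feature

__all__ = [
    "RegionLabels",
    "DifferentialResult",
    "AxisProfile",
    "hca_regions",
    "name_clusters",
    "volcano",
    "overlay_map",
    "region_areas",
    "axis_profile",
    "DEFAULT_REGION_MARKERS",
]

#: marker ions used to name clusters: region -> m/z values expected to peak there
DEFAULT_REGION_MARKERS = {
    "WM": (888.62,),
    "GM": (834.53,),
    "T": (682.59, 736.65),
}

P_FLOOR = 1e-300  # p-values are reported in (0, 1]


@dataclass
class RegionLabels:
    """Per-pixel cluster assignment over tissue pixels.

    ``labels`` holds one integer cluster id per representation row, with
    -1 for background (non-tissue) pixels. ``region_names`` optionally
    maps cluster ids to region names (GM/WM/T/I/N).
    """

    labels: np.ndarray
    coords: np.ndarray
    pixel_size: float
    cluster_means: pd.DataFrame | None = None
    region_names: dict[int, str] = field(default_factory=dict)

    @property
    def cluster_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids >= 0]

    def pixels_of(self, cluster) -> np.ndarray:
        """Row indices of a cluster, by id or by region name."""
        if isinstance(cluster, str):
            matches = [k for k, v in self.region_names.items() if v == cluster]
            if not matches:
                raise ParameterError(f"no cluster named {cluster!r}")
            return np.flatnonzero(np.isin(self.labels, matches))
        return np.flatnonzero(self.labels == cluster)

    def to_image(self) -> np.ndarray:
        ny = int(self.coords[:, 1].max()) + 1
        nx = int(self.coords[:, 0].max()) + 1
        img = np.full((ny, nx), -1, dtype=int)
        img[self.coords[:, 1], self.coords[:, 0]] = self.labels
        return img


def hca_regions(
    representation: CommonRepresentation,
    mask: TissueMask,
    k: int,
    pixel_budget: int = 20000,
    subsample_seed: int = 0,
) -> RegionLabels:
    """Agglomerative (Ward/Euclidean) clustering of tissue-pixel spectra.

    The dendrogram is cut at ``k`` clusters. Above ``pixel_budget``
    tissue pixels, clustering runs on a uniformly seeded subsample and
    the remaining pixels are assigned to the nearest cluster centroid;
    the procedure is deterministic given its inputs.

    Returns labels plus the per-cluster mean spectrum (on the scale of
    the input representation).
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    is_tissue = mask.pixel_flags(representation.coords)
    tissue_idx = np.flatnonzero(is_tissue)
    if tissue_idx.size < k:
        raise ParameterError(
            f"k={k} exceeds the {tissue_idx.size} available tissue pixels"
        )
    X = representation.matrix[tissue_idx]

    if tissue_idx.size > pixel_budget:
        rng = np.random.default_rng(subsample_seed)
        chosen = np.sort(rng.choice(tissue_idx.size, size=pixel_budget, replace=False))
    else:
        chosen = np.arange(tissue_idx.size)
    model = AgglomerativeClustering(n_clusters=k, linkage="ward")
    sub_labels = model.fit_predict(X[chosen])

    # relabel clusters by decreasing size so ids are stable and ordered
    order = np.argsort(-np.bincount(sub_labels, minlength=k), kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    sub_labels = remap[sub_labels]

    centroids = np.stack([X[chosen][sub_labels == c].mean(axis=0) for c in range(k)])
    labels_tissue = np.empty(tissue_idx.size, dtype=int)
    labels_tissue[chosen] = sub_labels
    rest = np.setdiff1d(np.arange(tissue_idx.size), chosen)
    if rest.size:
        d2 = ((X[rest, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        labels_tissue[rest] = np.argmin(d2, axis=1)

    labels = np.full(representation.n_pixels, -1, dtype=int)
    labels[tissue_idx] = labels_tissue
    cluster_means = pd.DataFrame(
        np.stack(
            [representation.matrix[labels == c].mean(axis=0) for c in range(k)]
        ),
        index=pd.Index(range(k), name="cluster"),
        columns=representation.feature_mz,
    )
    return RegionLabels(
        labels=labels,
        coords=representation.coords.copy(),
        pixel_size=representation.pixel_size,
        cluster_means=cluster_means,
    )


def name_clusters(
    labels: RegionLabels,
    representation: CommonRepresentation,
    markers: dict[str, tuple] = None,
) -> RegionLabels:
    """Name clusters by marker concordance.

    Each region in ``markers`` claims the (unclaimed) cluster whose mean
    marker intensity is highest; regions are processed in the given
    order. Defaults: WM by m/z 888.62, GM by 834.53, T by 682.59+736.65.
    """
    if markers is None:
        markers = DEFAULT_REGION_MARKERS
    names: dict[int, str] = {}
    taken: set[int] = set()
    for region, mzs in markers.items():
        cols = [resolve_feature(representation, mz) for mz in mzs]
        best, best_val = None, -np.inf
        for c in labels.cluster_ids:
            if int(c) in taken:
                continue
            val = representation.matrix[labels.labels == c][:, cols].mean()
            if val > best_val:
                best, best_val = int(c), val
        if best is not None:
            names[best] = region
            taken.add(best)
    labels.region_names = names
    return labels


@dataclass
class DifferentialResult:
    """Per-feature volcano table between two pixel groups.

    ``log2_fold_change`` is log2((mean_b + ε)/(mean_a + ε)); positive
    values mean higher abundance in group b.
    """

    table: pd.DataFrame  # columns: mz, p_value, log2_fold_change, significant, flat
    lfc_threshold: float
    neg_log10_p_threshold: float

    @property
    def significant_mz(self) -> np.ndarray:
        return self.table.loc[self.table.significant, "mz"].to_numpy()


def volcano(
    representation: CommonRepresentation,
    group_a: np.ndarray,
    group_b: np.ndarray,
    lfc_threshold: float = 1.0,
    neg_log10_p_threshold: float = 5.0,
) -> DifferentialResult:
    """Two-group differential abundance per feature.

    Student's t-test (two-tailed, equal-variance) between the pixel
    groups, with a pseudocount ε = (smallest positive matrix value) ×
    1e-3 in the fold change. A feature is significant when
    ``-log10(p) > neg_log10_p_threshold`` and
    ``|log2FC| > lfc_threshold``. Features with zero variance in both
    groups get p = 1 and are flagged ``flat``.
    """
    group_a = np.asarray(group_a)
    group_b = np.asarray(group_b)
    if group_a.size < 2 or group_b.size < 2:
        raise ParameterError("each group needs at least two pixels")
    A = representation.matrix[group_a]
    B = representation.matrix[group_b]
    positive = representation.matrix[representation.matrix > 0]
    eps = (positive.min() if positive.size else 1.0) * 1e-3

    mean_a, mean_b = A.mean(axis=0), B.mean(axis=0)
    lfc = np.log2((mean_b + eps) / (mean_a + eps))
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(A, B, axis=0, equal_var=True)
    flat = (A.std(axis=0) == 0) & (B.std(axis=0) == 0)
    p = np.where(np.isnan(p) | flat, 1.0, p)
    p = np.clip(p, P_FLOOR, 1.0)
    significant = (-np.log10(p) > neg_log10_p_threshold) & (np.abs(lfc) > lfc_threshold)
    table = pd.DataFrame(
        {
            "mz": representation.feature_mz,
            "p_value": p,
            "log2_fold_change": lfc,
            "significant": significant,
            "flat": flat,
        }
    )
    return DifferentialResult(table, lfc_threshold, neg_log10_p_threshold)


def overlay_map(
    representation: CommonRepresentation,
    channels: dict[str, list[float]],
    mask: TissueMask | None = None,
    percentile: float = 99.5,
) -> dict[str, np.ndarray]:
    """Per-channel intensity images for overlay figures.

    ``channels`` maps a colour role (e.g. "blue") to one or more m/z
    values; several features per channel are summed (cumulative mode).
    Each channel image is scaled to its own [0, ``percentile``-th
    percentile] and clipped to [0, 1]. Off-tissue pixels are zeroed when
    a mask is given.
    """
    ny, nx = representation.grid_shape
    out: dict[str, np.ndarray] = {}
    tissue = mask.pixel_flags(representation.coords) if mask is not None else None
    for role, mzs in channels.items():
        cols = [resolve_feature(representation, mz) for mz in np.atleast_1d(mzs)]
        values = representation.matrix[:, cols].sum(axis=1)
        if tissue is not None:
            values = np.where(tissue, values, 0.0)
        img = np.zeros((ny, nx))
        img[representation.coords[:, 1], representation.coords[:, 0]] = values
        top = np.percentile(img, percentile)
        if top > 0:
            img = np.clip(img / top, 0.0, 1.0)
        out[role] = img
    return out


def region_areas(labels: RegionLabels, pixel_size: float | None = None) -> pd.DataFrame:
    """Region areas in mm²: pixel count × (pixel_size/1000)²."""
    if pixel_size is None:
        pixel_size = labels.pixel_size
    mm2_per_pixel = (pixel_size / 1000.0) ** 2
    rows = []
    for c in labels.cluster_ids:
        n = int((labels.labels == c).sum())
        rows.append(
            {
                "cluster": int(c),
                "region": labels.region_names.get(int(c), str(c)),
                "n_pixels": n,
                "area_mm2": n * mm2_per_pixel,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class AxisProfile:
    """Mean feature abundance along the major axis of a rectangular box."""

    box: tuple[int, int, int, int]  # x0, y0, x1, y1 inclusive pixel coords
    distance_mm: np.ndarray
    abundance: pd.DataFrame  # index: feature m/z, columns: positions


def axis_profile(
    representation: CommonRepresentation,
    box: tuple[int, int, int, int],
    features: list[float],
) -> AxisProfile:
    """Profile feature abundance along the long side of a box.

    Pixels inside the box are grouped by their coordinate along the
    box's major (longer) axis at one-pixel resolution; per position the
    mean over the minor-axis extent is reported. Distances are mm from
    the box edge.
    """
    x0, y0, x1, y1 = box
    if x1 < x0 or y1 < y0:
        raise ParameterError("box must have non-negative extent")
    ny, nx = representation.grid_shape
    if x0 < 0 or y0 < 0 or x1 >= nx or y1 >= ny:
        raise ParameterError("box exceeds the pixel grid")
    if x1 == x0 and y1 == y0:
        raise ParameterError("box has zero extent")
    cols = [resolve_feature(representation, mz) for mz in features]
    cx, cy = representation.coords[:, 0], representation.coords[:, 1]
    inside = (cx >= x0) & (cx <= x1) & (cy >= y0) & (cy <= y1)
    major_is_x = (x1 - x0) >= (y1 - y0)
    pos = (cx - x0) if major_is_x else (cy - y0)
    length = (x1 - x0 if major_is_x else y1 - y0) + 1

    profile = np.full((len(cols), length), np.nan)
    for p in range(length):
        rows = np.flatnonzero(inside & (pos == p))
        if rows.size:
            profile[:, p] = representation.matrix[np.ix_(rows, cols)].mean(axis=0)
    distance_mm = np.arange(length) * representation.pixel_size / 1000.0
    abundance = pd.DataFrame(
        profile,
        index=pd.Index([representation.feature_mz[c] for c in cols], name="mz"),
        columns=np.arange(length),
    )
    return AxisProfile(box=(x0, y0, x1, y1), distance_mm=distance_mm, abundance=abundance)
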