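"""Radiomic features: first-order, GLCM / GLRLM / GLSZM texture, and shape.

Texture features are computed on a gray-level discretization of the masked
intensities (equal-width bins, Ng = 32 by default, recomputed per filtered
channel since filter responses are unbounded).  Matrix conventions:

* GLCM — distance-1 co-occurrence, 13 unique 3D directions, symmetrized and
  normalized per direction; features averaged over directions.
* GLRLM — maximal collinear runs of equal gray level within the mask, same
  13 directions, feature-level averaging.
* GLSZM — connected zones of equal gray level under 26-connectivity;
  direction-free single matrix.

Shape features use physical units: volume from voxel counts, surface area
from a triangulated isosurface of the binary mask (marching cubes), and the
maximum axial diameter as the largest in-plane distance between foreground
voxel centers over axial (z) slices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import marching_cubes, mesh_surface_area

from .filters import CHANNEL_LABELS, get_channel
from .imaging import DegenerateInputError, SegmentationMask, VolumeImage

#: 13 unique distance-1 directions in 3D (one representative per +/- pair).
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)

DEFAULT_N_BINS = 32

#: The 15-feature analysis panel, in reporting order.
DEFAULT_PANEL: tuple[str, ...] = (
    "HHL Skewness",
    "HLH Median",
    "LoG5 Low Intensity Small Area Emp.",
    "LLH Short Run Low Gray Level Emp.",
    "Difference Entropy",
    "HHH Mean",
    "LoG4 High Intensity Large Area Emp.",
    "HLL Cluster Prominence",
    "Spherical Disproportion",
    "LoG5 Inv. Diff. Normalized",
    "HLH Low Intensity Large Area Emp.",
    "HHL Mean",
    "Run Length Non-uniformity",
    "Minimum",
    "HHH High Intensity Large Area Emp.",
)


class CatalogueError(KeyError):
    """A feature name does not resolve to a known (channel, feature) pair."""


@dataclass
class DiscretizedVolume:
    """Gray-level volume: levels 1..Ng inside the mask, 0 outside."""

    levels: np.ndarray
    ng: int
    bin_edges: np.ndarray
    mask: np.ndarray


def discretize(img: VolumeImage, mask: SegmentationMask, n_bins: int = DEFAULT_N_BINS) -> DiscretizedVolume:
    """Equal-width discretization of masked intensities into levels 1..n_bins.

    The bin grid spans [min, max] of the foreground; a constant foreground
    maps wholly to level 1.  Background voxels carry level 0 and are
    excluded from every texture count.
    """
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    mask.check_aligned(img)
    fg = mask.values
    vals = img.values[fg]
    vmin, vmax = float(vals.min()), float(vals.max())
    levels = np.zeros(img.shape, dtype=np.int32)
    if vmax > vmin:
        width = (vmax - vmin) / n_bins
        lv = np.floor((img.values[fg] - vmin) / width).astype(np.int32) + 1
        levels[fg] = np.clip(lv, 1, n_bins)
        edges = np.linspace(vmin, vmax, n_bins + 1)
    else:
        levels[fg] = 1
        edges = np.array([vmin, vmax])
    return DiscretizedVolume(levels=levels, ng=n_bins, bin_edges=edges, mask=fg)


# ---------------------------------------------------------------------------
# First-order statistics


def first_order(img: VolumeImage, mask: SegmentationMask) -> dict[str, float]:
    """Median, mean, minimum and (population) skewness of masked intensities."""
    mask.check_aligned(img)
    vals = img.values[mask.values]
    if vals.size < 2:
        raise DegenerateInputError("skewness needs >= 2 foreground voxels")
    m = vals.mean()
    m2 = np.mean((vals - m) ** 2)
    m3 = np.mean((vals - m) ** 3)
    skew = 0.0 if m2 == 0 else float(m3 / m2**1.5)
    return {
        "Median": float(np.median(vals)),
        "Mean": float(m),
        "Minimum": float(vals.min()),
        "Skewness": skew,
    }


# ---------------------------------------------------------------------------
# GLCM


def cooccurrence_matrix(disc: DiscretizedVolume, direction: tuple[int, int, int]) -> np.ndarray:
    """Symmetrized, normalized distance-1 co-occurrence matrix for one direction."""
    lv = disc.levels
    dx, dy, dz = direction

    def sl(d, n):
        if d == 0:
            return slice(None), slice(None)
        if d > 0:
            return slice(0, n - d), slice(d, n)
        return slice(-d, n), slice(0, n + d)

    (ax0, ax1), (ay0, ay1), (az0, az1) = (sl(d, n) for d, n in zip(direction, lv.shape))
    a = lv[ax0, ay0, az0]
    b = lv[ax1, ay1, az1]
    valid = (a > 0) & (b > 0)
    ng = disc.ng
    counts = np.zeros((ng, ng), dtype=np.float64)
    if valid.any():
        idx = a[valid] * ng + b[valid] - ng - 1  # (a-1)*ng + (b-1)
        np.add.at(counts.ravel(), idx, 1.0)
    counts = counts + counts.T
    total = counts.sum()
    if total > 0:
        counts /= total
    return counts


def glcm_features(disc: DiscretizedVolume) -> dict[str, float]:
    """Cluster prominence, difference entropy and IDN, averaged over 13 directions.

    CP  = sum_ij (i + j - mu_x - mu_y)^4 p(i,j)
    DE  = -sum_k p_{x-y}(k) log2 p_{x-y}(k),  p_{x-y}(k) = sum_{|i-j|=k} p(i,j)
    IDN = sum_ij p(i,j) / (1 + |i-j| / Ng)
    """
    if not disc.mask.any():
        raise DegenerateInputError("all-background discretized volume")
    ng = disc.ng
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    absdiff = np.abs(ii - jj)
    cp_list, de_list, idn_list = [], [], []
    for d in DIRECTIONS_3D:
        p = cooccurrence_matrix(disc, d)
        if p.sum() == 0:  # no voxel pairs along this direction
            continue
        px = p.sum(axis=1)
        py = p.sum(axis=0)
        mux = float((i * px).sum())
        muy = float((i * py).sum())
        cp_list.append(float((((ii + jj) - mux - muy) ** 4 * p).sum()))
        pxy = np.array([p[absdiff == k].sum() for k in range(ng)])
        nz = pxy[pxy > 0]
        de_list.append(float(-(nz * np.log2(nz)).sum()))
        idn_list.append(float((p / (1.0 + absdiff / ng)).sum()))
    if not cp_list:
        raise DegenerateInputError("no voxel pairs in any direction")
    return {
        "Cluster Prominence": float(np.mean(cp_list)),
        "Difference Entropy": float(np.mean(de_list)),
        "Inv. Diff. Normalized": float(np.mean(idn_list)),
    }


# ---------------------------------------------------------------------------
# GLRLM


def run_length_matrix(disc: DiscretizedVolume, direction: tuple[int, int, int]) -> np.ndarray:
    """R(i, j): maximal runs of gray level i (rows) and length j (cols, 1-based).

    Runs are maximal collinear sequences of equal nonzero level along the
    direction; mask boundaries terminate runs.
    """
    lv = disc.levels
    pos = np.indices(lv.shape).reshape(3, -1)
    d = np.asarray(direction)
    a0 = int(np.nonzero(d)[0][0])
    t = pos[a0] * int(np.sign(d[a0]))
    anchors = pos - t[None, :] * d[:, None]
    order = np.lexsort((t, anchors[2], anchors[1], anchors[0]))
    lv_s = lv.reshape(-1)[order]
    anc_s = anchors[:, order]
    new_line = np.ones(lv_s.size, dtype=bool)
    new_line[1:] = np.any(anc_s[:, 1:] != anc_s[:, :-1], axis=0)
    breaks = new_line.copy()
    breaks[1:] |= lv_s[1:] != lv_s[:-1]
    starts = np.flatnonzero(breaks)
    lengths = np.diff(np.append(starts, lv_s.size))
    run_levels = lv_s[starts]
    keep = run_levels > 0
    run_levels, lengths = run_levels[keep], lengths[keep]
    max_len = int(lengths.max()) if lengths.size else 1
    R = np.zeros((disc.ng, max_len), dtype=np.float64)
    np.add.at(R, (run_levels - 1, lengths - 1), 1.0)
    return R


def glrlm_features(disc: DiscretizedVolume) -> dict[str, float]:
    """RLN and SRLGLE, averaged over the 13 directions.

    RLN    = sum_j (sum_i R(i,j))^2 / Nr
    SRLGLE = [sum_ij R(i,j) / (i^2 j^2)] / Nr
    """
    if not disc.mask.any():
        raise DegenerateInputError("all-background discretized volume")
    rln_list, srlgle_list = [], []
    for d in DIRECTIONS_3D:
        R = run_length_matrix(disc, d)
        nr = R.sum()
        if nr == 0:
            continue
        i = np.arange(1, R.shape[0] + 1)[:, None]
        j = np.arange(1, R.shape[1] + 1)[None, :]
        rln_list.append(float((R.sum(axis=0) ** 2).sum() / nr))
        srlgle_list.append(float((R / (i**2 * j**2)).sum() / nr))
    return {
        "Run Length Non-uniformity": float(np.mean(rln_list)),
        "Short Run Low Gray Level Emp.": float(np.mean(srlgle_list)),
    }


# ---------------------------------------------------------------------------
# GLSZM

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def size_zone_matrix(disc: DiscretizedVolume) -> np.ndarray:
    """S(i, j): connected zones (26-connectivity) of level i and size j (1-based)."""
    lv = disc.levels
    zones: list[tuple[int, int]] = []
    for level in np.unique(lv[disc.mask]):
        lab, nlab = ndimage.label(lv == level, structure=_STRUCT_26)
        sizes = np.bincount(lab.ravel())[1:]
        zones.extend((int(level), int(s)) for s in sizes)
    max_size = max(s for _, s in zones)
    S = np.zeros((disc.ng, max_size), dtype=np.float64)
    for level, size in zones:
        S[level - 1, size - 1] += 1.0
    return S


def glszm_features(disc: DiscretizedVolume) -> dict[str, float]:
    """HILAE, LILAE and LISAE from the size-zone matrix.

    HILAE = [sum i^2 j^2 S(i,j)] / Nz   (large bright zones, e.g. hemorrhage)
    LILAE = [sum (j^2 / i^2) S(i,j)] / Nz  (large dark zones, e.g. necrosis)
    LISAE = [sum S(i,j) / (i^2 j^2)] / Nz  (small dark zones)
    """
    if not disc.mask.any():
        raise DegenerateInputError("all-background discretized volume")
    S = size_zone_matrix(disc)
    nz = S.sum()
    i = np.arange(1, S.shape[0] + 1)[:, None].astype(np.float64)
    j = np.arange(1, S.shape[1] + 1)[None, :].astype(np.float64)
    return {
        "High Intensity Large Area Emp.": float((i**2 * j**2 * S).sum() / nz),
        "Low Intensity Large Area Emp.": float((j**2 / i**2 * S).sum() / nz),
        "Low Intensity Small Area Emp.": float((S / (i**2 * j**2)).sum() / nz),
    }


# ---------------------------------------------------------------------------
# Shape


def shape_features(mask: SegmentationMask) -> dict[str, float]:
    """Volume (mm^3), spherical disproportion, and maximum axial diameter (mm).

    SD = A / (4 pi r^2) with r the radius of the sphere of equal volume; 1
    for a perfect ball, > 1 for any other shape (up to mesh discretization).
    """
    fg = mask.values
    n_fg = int(fg.sum())
    volume = n_fg * mask.voxel_volume
    padded = np.pad(fg.astype(np.float64), 1)
    if n_fg == 1 or all(dim_extent(fg, a) == 1 for a in range(3)):
        # no isosurface for sub-voxel bodies: fall back to the voxel box area
        sx, sy, sz = mask.spacing
        area = 2 * (sx * sy + sx * sz + sy * sz) * n_fg  # upper bound, degenerate case
    else:
        verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=mask.spacing)
        area = float(mesh_surface_area(verts, faces))
    r = (3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    sd = area / (4.0 * np.pi * r**2)
    sx, sy, _ = mask.spacing
    max_diam = 0.0
    for z in range(fg.shape[2]):
        xs, ys = np.nonzero(fg[:, :, z])
        if xs.size < 2:
            continue
        pts = np.column_stack([xs * sx, ys * sy])
        if pts.shape[0] > 3:
            try:
                from scipy.spatial import ConvexHull

                pts = pts[ConvexHull(pts).vertices]
            except Exception:
                pass  # collinear slice: brute force below
        dists = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        max_diam = max(max_diam, float(dists.max()))
    return {
        "Volume": float(volume),
        "Spherical Disproportion": float(sd),
        "Maximum Axial Diameter": max_diam,
    }


def dim_extent(fg: np.ndarray, axis: int) -> int:
    idx = np.nonzero(fg.any(axis=tuple(a for a in range(3) if a != axis)))[0]
    return int(idx.max() - idx.min() + 1)


# ---------------------------------------------------------------------------
# Panel extraction and catalogue

_FEATURE_FAMILY = {
    "Median": "first_order",
    "Mean": "first_order",
    "Minimum": "first_order",
    "Skewness": "first_order",
    "Cluster Prominence": "glcm",
    "Difference Entropy": "glcm",
    "Inv. Diff. Normalized": "glcm",
    "Run Length Non-uniformity": "glrlm",
    "Short Run Low Gray Level Emp.": "glrlm",
    "High Intensity Large Area Emp.": "glszm",
    "Low Intensity Large Area Emp.": "glszm",
    "Low Intensity Small Area Emp.": "glszm",
    "Volume": "shape",
    "Spherical Disproportion": "shape",
    "Maximum Axial Diameter": "shape",
}
_FEATURE_CANON = {k.lower(): k for k in _FEATURE_FAMILY}


def parse_feature_name(name: str) -> tuple[str, str]:
    """Split '<channel> <feature>' into (channel, canonical feature name).

    A missing channel prefix means the original (unfiltered) channel; shape
    features are channel-free and always resolve to channel 'shape'.
    """
    tokens = name.split(" ", 1)
    if tokens[0] in CHANNEL_LABELS and len(tokens) == 2:
        channel, feat = tokens[0], tokens[1]
    else:
        channel, feat = "original", name
    canon = _FEATURE_CANON.get(feat.strip().lower())
    if canon is None:
        raise CatalogueError(f"unknown feature name {name!r}")
    if _FEATURE_FAMILY[canon] == "shape":
        if channel != "original":
            raise CatalogueError(f"shape feature {canon!r} takes no channel prefix: {name!r}")
        return "shape", canon
    return channel, canon


def extract_panel(
    img: VolumeImage,
    mask: SegmentationMask,
    panel: tuple[str, ...] = DEFAULT_PANEL,
    n_bins: int = DEFAULT_N_BINS,
) -> dict[str, float]:
    """Compute a named feature panel on (preprocessed) image + mask.

    Each panel entry names a filter channel and a feature; the channel is
    computed once, re-discretized within the mask (filtered responses have
    their own ranges), and the feature evaluated.  Returns features keyed by
    the original panel names, in panel order.
    """
    mask.check_aligned(img)
    parsed = [(name, *parse_feature_name(name)) for name in panel]
    by_channel: dict[str, list[tuple[str, str]]] = {}
    for name, channel, feat in parsed:
        by_channel.setdefault(channel, []).append((name, feat))

    out: dict[str, float] = {}
    for channel, items in by_channel.items():
        if channel == "shape":
            vals = shape_features(mask)
            for name, feat in items:
                out[name] = vals[feat]
            continue
        ch_img = get_channel(img, channel).image
        families = {_FEATURE_FAMILY[feat] for _, feat in items}
        computed: dict[str, float] = {}
        if "first_order" in families:
            computed.update(first_order(ch_img, mask))
        if families & {"glcm", "glrlm", "glszm"}:
            disc = discretize(ch_img, mask, n_bins)
            if "glcm" in families:
                computed.update(glcm_features(disc))
            if "glrlm" in families:
                computed.update(glrlm_features(disc))
            if "glszm" in families:
                computed.update(glszm_features(disc))
        for name, feat in items:
            out[name] = computed[feat]
    return {name: out[name] for name in panel}


# Catalogue composition: 55 intensity/texture features per channel across the
# 19 channels, plus 10 global shape/size features (1,055 names total).  Only
# the panel features above are computed analytically; the full catalogue is
# the feature-space inventory the panel was selected from.
_CATALOGUE_FIRST_ORDER = (
    "Mean", "Median", "Minimum", "Maximum", "Range", "Variance",
    "Standard Deviation", "Skewness", "Kurtosis", "Energy", "Entropy",
    "Root Mean Square", "Mean Absolute Deviation", "Uniformity",
    "Interquartile Range",
)
_CATALOGUE_GLCM = (
    "Autocorrelation", "Cluster Prominence", "Cluster Shade",
    "Cluster Tendency", "Contrast", "Correlation", "Difference Entropy",
    "Dissimilarity", "Joint Energy", "Joint Entropy", "Homogeneity",
    "Informational Measure of Correlation 1",
    "Informational Measure of Correlation 2", "Inverse Difference Moment",
    "Inv. Diff. Normalized", "Inverse Difference Moment Normalized",
    "Maximum Probability", "Sum Entropy",
)
_CATALOGUE_GLRLM = (
    "Short Run Emphasis", "Long Run Emphasis", "Gray Level Non-uniformity",
    "Run Length Non-uniformity", "Run Percentage",
    "Low Gray Level Run Emphasis", "High Gray Level Run Emphasis",
    "Short Run Low Gray Level Emp.", "Short Run High Gray Level Emp.",
    "Long Run Low Gray Level Emp.", "Long Run High Gray Level Emp.",
)
_CATALOGUE_GLSZM = (
    "Small Area Emphasis", "Large Area Emphasis",
    "Gray Level Zone Non-uniformity", "Size Zone Non-uniformity",
    "Zone Percentage", "Low Intensity Emphasis", "High Intensity Emphasis",
    "Low Intensity Small Area Emp.", "High Intensity Small Area Emp.",
    "Low Intensity Large Area Emp.", "High Intensity Large Area Emp.",
)
_CATALOGUE_SHAPE = (
    "Volume", "Surface Area", "Surface-to-Volume Ratio", "Sphericity",
    "Spherical Disproportion", "Compactness 1", "Compactness 2",
    "Maximum Axial Diameter", "Maximum 3D Diameter",
    "Equivalent Sphere Radius",
)


def enumerate_catalogue(channels: tuple[str, ...] = CHANNEL_LABELS) -> list[str]:
    """All names of the default radiomic feature space (1,055 for all channels).

    Intensity and texture names are '<channel> <feature>' (no prefix for the
    original channel); the 10 shape/size names are global.
    """
    per_channel = (
        _CATALOGUE_FIRST_ORDER + _CATALOGUE_GLCM + _CATALOGUE_GLRLM + _CATALOGUE_GLSZM
    )
    names: list[str] = []
    for ch in channels:
        prefix = "" if ch == "original" else ch + " "
        names.extend(prefix + f for f in per_channel)
    if "original" in channels or set(channels) == set(CHANNEL_LABELS):
        names.extend(_CATALOGUE_SHAPE)
    return names
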