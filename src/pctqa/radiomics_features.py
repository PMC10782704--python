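"""The 107 "original image" radiomic features, and paired CT-vs-pCT
feature comparison.

Seven families on the untransformed image — 18 first-order, 14 3-D shape,
24 GLCM, 16 GLRLM, 16 GLSZM, 5 NGTDM and 14 GLDM features — following the
IBSI-consistent definitions of the standard reference feature set.  Grey
levels are discretized with a fixed bin width (default 25 HU) relative to
the masked minimum; texture matrices use the 13 unique 3-D directions at
distance 1, GLCM symmetric, with per-direction features averaged.

Structures that are too small or constant-valued produce degenerate texture
matrices; the affected features are flagged (never silently dropped) and the
paired comparison removes flagged features before testing — the outlier
handling that, on real data, strikes the NGTDM and GLCM families for tiny
organs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .core_volumes import ImageVolume, StructureMask

__all__ = [
    "DiscretizationConfig",
    "FeatureVector",
    "FAMILY_COUNTS",
    "discretize",
    "extract_features",
    "compare_features",
]

FAMILY_COUNTS = {
    "firstorder": 18,
    "shape": 14,
    "glcm": 24,
    "glrlm": 16,
    "glszm": 16,
    "ngtdm": 5,
    "gldm": 14,
}

#: the 13 unique direction vectors of a 26-neighbourhood (distance 1)
DIRECTIONS_13 = (
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)


@dataclass(frozen=True)
class DiscretizationConfig:
    """Fixed-bin-width grey-level discretization (no resampling by default)."""

    bin_width: float = 25.0
    resample_spacing_mm: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin width must be positive")


@dataclass
class FeatureVector:
    """107 named feature values plus per-feature degeneracy flags."""

    values: dict[str, float]
    degenerate: dict[str, bool]
    role: str = ""
    image: str = ""

    def __post_init__(self) -> None:
        if len(self.values) != sum(FAMILY_COUNTS.values()):
            raise ValueError(f"expected 107 features, got {len(self.values)}")

    def family(self, name: str) -> dict[str, float]:
        prefix = name + "_"
        return {k: v for k, v in self.values.items() if k.startswith(prefix)}


def discretize(
    volume: ImageVolume, mask: StructureMask, cfg: DiscretizationConfig | None = None
) -> tuple[np.ndarray, int]:
    """Integer grey levels inside the mask: level = floor((v - min)/W) + 1.

    Returns (level grid with 0 outside the mask, level count).  A constant
    region yields a single level.
    """
    cfg = cfg or DiscretizationConfig()
    if not mask.voxels.any():
        raise ValueError("empty mask")
    vals = volume.values[mask.voxels]
    lo = vals.min()
    levels = np.zeros(mask.geometry.shape, dtype=np.int64)
    levels[mask.voxels] = np.floor((vals - lo) / cfg.bin_width).astype(np.int64) + 1
    return levels, int(levels.max())


def _crop(levels: np.ndarray, mask: np.ndarray, pad: int = 1):
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + pad + 1, mask.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return levels[sl], mask[sl]


# ---------------------------------------------------------------------------
# first order
# ---------------------------------------------------------------------------

def _firstorder(vals: np.ndarray, voxel_mm3: float, bin_width: float) -> dict[str, float]:
    n = vals.size
    mean = vals.mean()
    m2 = ((vals - mean) ** 2).mean()
    p10, p25, p75, p90 = np.percentile(vals, [10, 25, 75, 90])
    robust = vals[(vals >= p10) & (vals <= p90)]
    counts = np.bincount(np.floor((vals - vals.min()) / bin_width).astype(int))
    p = counts[counts > 0] / n
    if m2 > 0:
        skew = ((vals - mean) ** 3).mean() / m2**1.5
        kurt = ((vals - mean) ** 4).mean() / m2**2
    else:
        skew, kurt = 0.0, 0.0
    return {
        "Energy": float((vals**2).sum()),
        "TotalEnergy": float(voxel_mm3 * (vals**2).sum()),
        "Entropy": float(-(p * np.log2(p)).sum()),
        "Minimum": float(vals.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(vals.max()),
        "Mean": float(mean),
        "Median": float(np.median(vals)),
        "InterquartileRange": float(p75 - p25),
        "Range": float(vals.max() - vals.min()),
        "MeanAbsoluteDeviation": float(np.abs(vals - mean).mean()),
        "RobustMeanAbsoluteDeviation": float(
            np.abs(robust - robust.mean()).mean() if robust.size else 0.0
        ),
        "RootMeanSquared": float(np.sqrt((vals**2).mean())),
        "Skewness": float(skew),
        "Kurtosis": float(kurt),
        "Variance": float(m2),
        "Uniformity": float((p**2).sum()),
    }


# ---------------------------------------------------------------------------
# shape (mesh-based)
# ---------------------------------------------------------------------------

def _shape(mask: np.ndarray, spacing) -> dict[str, float]:
    padded = np.pad(mask.astype(float), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=spacing)
    v0, v1, v2 = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    mesh_volume = abs(np.einsum("ij,ij->", v0, np.cross(v1, v2)) / 6.0)
    area = measure.mesh_surface_area(verts, faces)
    voxel_volume = mask.sum() * float(np.prod(spacing))

    # pairwise diameters over convex-hull vertices of the surface mesh
    try:
        from scipy.spatial import ConvexHull

        hull_pts = verts[ConvexHull(verts).vertices]
    except Exception:  # degenerate (flat) meshes
        hull_pts = verts

    def max_dist(pts: np.ndarray) -> float:
        if len(pts) < 2:
            return 0.0
        d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
        return float(np.sqrt(d2.max()))

    # principal axes from physical voxel-centre coordinates
    coords = np.argwhere(mask) * np.asarray(spacing, dtype=float)
    if len(coords) > 1:
        eig = np.sort(np.linalg.eigvalsh(np.cov(coords.T)))[::-1]
        eig = np.clip(eig, 0.0, None)
    else:
        eig = np.zeros(3)
    major, minor, least = (4.0 * np.sqrt(eig)).tolist()

    return {
        "MeshVolume": float(mesh_volume),
        "VoxelVolume": float(voxel_volume),
        "SurfaceArea": float(area),
        "SurfaceVolumeRatio": float(area / mesh_volume) if mesh_volume > 0 else math.nan,
        "Sphericity": float((36.0 * np.pi * mesh_volume**2) ** (1.0 / 3.0) / area)
        if area > 0
        else math.nan,
        "Maximum3DDiameter": max_dist(hull_pts),
        "Maximum2DDiameterSlice": max_dist(hull_pts[:, :2]),
        "Maximum2DDiameterColumn": max_dist(hull_pts[:, [0, 2]]),
        "Maximum2DDiameterRow": max_dist(hull_pts[:, 1:]),
        "MajorAxisLength": major,
        "MinorAxisLength": minor,
        "LeastAxisLength": least,
        "Elongation": float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else math.nan,
        "Flatness": float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else math.nan,
    }


# ---------------------------------------------------------------------------
# grey-level co-occurrence matrix
# ---------------------------------------------------------------------------

def glcm_matrices(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> list[np.ndarray]:
    """One symmetric, normalized co-occurrence matrix per direction."""
    mats = []
    for d in DIRECTIONS_13:
        src = [slice(max(-o, 0), levels.shape[a] - max(o, 0)) for a, o in enumerate(d)]
        dst = [slice(max(o, 0), levels.shape[a] + min(o, 0)) for a, o in enumerate(d)]
        a = levels[tuple(src)]
        b = levels[tuple(dst)]
        valid = mask[tuple(src)] & mask[tuple(dst)]
        i, j = a[valid] - 1, b[valid] - 1
        m = np.zeros((n_levels, n_levels))
        np.add.at(m, (i, j), 1.0)
        m = m + m.T  # symmetric accumulation
        total = m.sum()
        mats.append(m / total if total > 0 else m)
    return mats


def _glcm_features(mats: list[np.ndarray], n_levels: int) -> dict[str, float]:
    iv = np.arange(1, n_levels + 1, dtype=float)
    ii, jj = np.meshgrid(iv, iv, indexing="ij")
    per_dir: dict[str, list[float]] = {}

    for p in mats:
        if p.sum() <= 0:
            continue
        px = p.sum(axis=1)
        mu = float((px * iv).sum())
        sigma2 = float((px * (iv - mu) ** 2).sum())
        sigma = math.sqrt(sigma2)
        # sum / difference distributions
        k_sum = np.arange(2, 2 * n_levels + 1, dtype=float)
        p_sum = np.array([p[ii + jj == k].sum() for k in k_sum])
        k_diff = np.arange(0, n_levels, dtype=float)
        p_diff = np.array([p[np.abs(ii - jj) == k].sum() for k in k_diff])
        da = float((k_diff * p_diff).sum())

        nz = p > 0
        hxy = float(-(p[nz] * np.log2(p[nz])).sum())
        pxy = px[:, None] * px[None, :]
        nz2 = pxy > 0
        hxy1 = float(-(p[nz2] * np.log2(pxy[nz2])).sum())
        hxy2 = float(-(pxy[nz2] * np.log2(pxy[nz2])).sum())
        hx = float(-(px[px > 0] * np.log2(px[px > 0])).sum())

        corr = (
            float(((ii * jj * p).sum() - mu * mu) / sigma2) if sigma2 > 0 else 1.0
        )
        imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
        imc2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))

        # MCC: second largest eigenvalue of Q over levels with px > 0
        obs = px > 0
        if obs.sum() > 1:
            psub = p[np.ix_(obs, obs)]
            pxs = px[obs]
            q = (psub / pxs[:, None]) @ (psub / pxs[None, :]).T
            ev = np.sort(np.abs(np.linalg.eigvals(q)))
            mcc = float(math.sqrt(max(0.0, ev[-2].real)))
        else:
            mcc = 1.0

        inv_var_mask = ii != jj
        vals = {
            "Autocorrelation": float((ii * jj * p).sum()),
            "JointAverage": mu,
            "ClusterProminence": float((((ii + jj - 2 * mu) ** 4) * p).sum()),
            "ClusterShade": float((((ii + jj - 2 * mu) ** 3) * p).sum()),
            "ClusterTendency": float((((ii + jj - 2 * mu) ** 2) * p).sum()),
            "Contrast": float((((ii - jj) ** 2) * p).sum()),
            "Correlation": corr,
            "DifferenceAverage": da,
            "DifferenceEntropy": float(
                -(p_diff[p_diff > 0] * np.log2(p_diff[p_diff > 0])).sum()
            ),
            "DifferenceVariance": float((p_diff * (k_diff - da) ** 2).sum()),
            "JointEnergy": float((p**2).sum()),
            "JointEntropy": hxy,
            "Imc1": imc1,
            "Imc2": imc2,
            "Idm": float((p / (1.0 + (ii - jj) ** 2)).sum()),
            "Idmn": float((p / (1.0 + ((ii - jj) / n_levels) ** 2)).sum()),
            "Id": float((p / (1.0 + np.abs(ii - jj))).sum()),
            "Idn": float((p / (1.0 + np.abs(ii - jj) / n_levels)).sum()),
            "InverseVariance": float(
                (p[inv_var_mask] / (ii - jj)[inv_var_mask] ** 2).sum()
            ),
            "MaximumProbability": float(p.max()),
            "SumAverage": float((k_sum * p_sum).sum()),
            "SumEntropy": float(-(p_sum[p_sum > 0] * np.log2(p_sum[p_sum > 0])).sum()),
            "SumSquares": sigma2,
            "MCC": mcc,
        }
        for k, v in vals.items():
            per_dir.setdefault(k, []).append(v)
    return {k: float(np.mean(v)) for k, v in per_dir.items()}


# ---------------------------------------------------------------------------
# grey-level run length matrix
# ---------------------------------------------------------------------------

def glrlm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int, direction) -> np.ndarray:
    """Run-length matrix P[i-1, l-1] for one direction: maximal runs of equal
    grey level along the direction, runs broken by the mask boundary."""
    lv = np.where(mask, levels, 0)
    d = np.asarray(direction)
    shape = np.asarray(lv.shape)

    coords = np.argwhere(lv > 0)
    if coords.size == 0:
        return np.zeros((n_levels, 1))
    prev = coords - d
    inb = np.all((prev >= 0) & (prev < shape), axis=1)
    prev_lv = np.zeros(len(coords), dtype=lv.dtype)
    prev_lv[inb] = lv[tuple(prev[inb].T)]
    here_lv = lv[tuple(coords.T)]
    starts = coords[prev_lv != here_lv]

    max_len = int(np.abs(shape * d).max()) + 1
    counts = np.zeros((n_levels, max_len))
    cur = starts
    cur_lv = lv[tuple(starts.T)]
    length = 1
    while len(cur):
        nxt = cur + d
        inb = np.all((nxt >= 0) & (nxt < shape), axis=1)
        cont = np.zeros(len(cur), dtype=bool)
        cont[inb] = lv[tuple(nxt[inb].T)] == cur_lv[inb]
        ended_lv = cur_lv[~cont]
        np.add.at(counts, (ended_lv - 1, length - 1), 1.0)
        cur, cur_lv = nxt[cont], cur_lv[cont]
        length += 1
    last = np.max(np.nonzero(counts.sum(axis=0))[0]) if counts.any() else 0
    return counts[:, : last + 1]


def _glrlm_features(levels, mask, n_levels, n_voxels) -> dict[str, float]:
    per_dir: dict[str, list[float]] = {}
    for d in DIRECTIONS_13:
        P = glrlm_matrix(levels, mask, n_levels, d)
        nr = P.sum()
        if nr <= 0:
            continue
        iv = np.arange(1, P.shape[0] + 1, dtype=float)[:, None]
        jv = np.arange(1, P.shape[1] + 1, dtype=float)[None, :]
        pr = P / nr
        ri = P.sum(axis=1)  # per-level
        rj = P.sum(axis=0)  # per-length
        mu_i = float((pr * iv).sum())
        mu_j = float((pr * jv).sum())
        vals = {
            "ShortRunEmphasis": float((P / jv**2).sum() / nr),
            "LongRunEmphasis": float((P * jv**2).sum() / nr),
            "GrayLevelNonUniformity": float((ri**2).sum() / nr),
            "GrayLevelNonUniformityNormalized": float((ri**2).sum() / nr**2),
            "RunLengthNonUniformity": float((rj**2).sum() / nr),
            "RunLengthNonUniformityNormalized": float((rj**2).sum() / nr**2),
            "RunPercentage": float(nr / n_voxels),
            "GrayLevelVariance": float((pr * (iv - mu_i) ** 2).sum()),
            "RunVariance": float((pr * (jv - mu_j) ** 2).sum()),
            "RunEntropy": float(-(pr[pr > 0] * np.log2(pr[pr > 0])).sum()),
            "LowGrayLevelRunEmphasis": float((P / iv**2).sum() / nr),
            "HighGrayLevelRunEmphasis": float((P * iv**2).sum() / nr),
            "ShortRunLowGrayLevelEmphasis": float((P / (iv**2 * jv**2)).sum() / nr),
            "ShortRunHighGrayLevelEmphasis": float((P * iv**2 / jv**2).sum() / nr),
            "LongRunLowGrayLevelEmphasis": float((P * jv**2 / iv**2).sum() / nr),
            "LongRunHighGrayLevelEmphasis": float((P * iv**2 * jv**2).sum() / nr),
        }
        for k, v in vals.items():
            per_dir.setdefault(k, []).append(v)
    return {k: float(np.mean(v)) for k, v in per_dir.items()}


# ---------------------------------------------------------------------------
# grey-level size zone matrix
# ---------------------------------------------------------------------------

def glszm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Size-zone matrix: 26-connected zones of equal grey level."""
    structure = np.ones((3, 3, 3), dtype=int)
    zone_counts: dict[int, dict[int, int]] = {}
    max_size = 1
    for level in range(1, n_levels + 1):
        sel = mask & (levels == level)
        if not sel.any():
            continue
        labelled, n = ndimage.label(sel, structure=structure)
        sizes = np.bincount(labelled.ravel())[1:]
        zone_counts[level] = dict(zip(*np.unique(sizes, return_counts=True)))
        max_size = max(max_size, int(sizes.max()))
    P = np.zeros((n_levels, max_size))
    for level, sized in zone_counts.items():
        for size, cnt in sized.items():
            P[level - 1, size - 1] = cnt
    return P


def _glszm_features(P: np.ndarray, n_voxels: int) -> dict[str, float]:
    nz = P.sum()
    if nz <= 0:
        return {}
    iv = np.arange(1, P.shape[0] + 1, dtype=float)[:, None]
    jv = np.arange(1, P.shape[1] + 1, dtype=float)[None, :]
    pr = P / nz
    si = P.sum(axis=1)
    sj = P.sum(axis=0)
    mu_i = float((pr * iv).sum())
    mu_j = float((pr * jv).sum())
    return {
        "SmallAreaEmphasis": float((P / jv**2).sum() / nz),
        "LargeAreaEmphasis": float((P * jv**2).sum() / nz),
        "GrayLevelNonUniformity": float((si**2).sum() / nz),
        "GrayLevelNonUniformityNormalized": float((si**2).sum() / nz**2),
        "SizeZoneNonUniformity": float((sj**2).sum() / nz),
        "SizeZoneNonUniformityNormalized": float((sj**2).sum() / nz**2),
        "ZonePercentage": float(nz / n_voxels),
        "GrayLevelVariance": float((pr * (iv - mu_i) ** 2).sum()),
        "ZoneVariance": float((pr * (jv - mu_j) ** 2).sum()),
        "ZoneEntropy": float(-(pr[pr > 0] * np.log2(pr[pr > 0])).sum()),
        "LowGrayLevelZoneEmphasis": float((P / iv**2).sum() / nz),
        "HighGrayLevelZoneEmphasis": float((P * iv**2).sum() / nz),
        "SmallAreaLowGrayLevelEmphasis": float((P / (iv**2 * jv**2)).sum() / nz),
        "SmallAreaHighGrayLevelEmphasis": float((P * iv**2 / jv**2).sum() / nz),
        "LargeAreaLowGrayLevelEmphasis": float((P * jv**2 / iv**2).sum() / nz),
        "LargeAreaHighGrayLevelEmphasis": float((P * iv**2 * jv**2).sum() / nz),
    }


# ---------------------------------------------------------------------------
# neighbouring grey tone difference matrix
# ---------------------------------------------------------------------------

def ngtdm_table(levels: np.ndarray, mask: np.ndarray, n_levels: int):
    """Per-level (n_i, p_i, s_i): occurrence count, probability and summed
    absolute difference from the mean of the 26-neighbourhood (neighbours
    outside the mask ignored; voxels with no valid neighbour excluded)."""
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    lv = np.where(mask, levels, 0).astype(float)
    msk = mask.astype(float)
    nb_sum = ndimage.correlate(lv, kernel, mode="constant", cval=0.0)
    nb_cnt = ndimage.correlate(msk, kernel, mode="constant", cval=0.0)
    valid = mask & (nb_cnt > 0)
    mean_nb = np.zeros_like(lv)
    mean_nb[valid] = nb_sum[valid] / nb_cnt[valid]
    diff = np.abs(lv - mean_nb)
    n_i = np.zeros(n_levels)
    s_i = np.zeros(n_levels)
    for level in range(1, n_levels + 1):
        sel = valid & (levels == level)
        n_i[level - 1] = sel.sum()
        s_i[level - 1] = diff[sel].sum()
    nvp = n_i.sum()
    p_i = n_i / nvp if nvp > 0 else n_i
    return n_i, p_i, s_i, int(nvp)


def _ngtdm_features(n_i, p_i, s_i, nvp) -> dict[str, float]:
    iv = np.arange(1, len(p_i) + 1, dtype=float)
    present = p_i > 0
    ngp = int(present.sum())
    ps = float((p_i * s_i).sum())
    coarseness = 1.0 / ps if ps > 0 else 1e6

    if ngp > 1:
        pi, pj = np.meshgrid(p_i, p_i, indexing="ij")
        ivi, ivj = np.meshgrid(iv, iv, indexing="ij")
        both = (pi > 0) & (pj > 0)
        contrast = float(
            (pi[both] * pj[both] * (ivi[both] - ivj[both]) ** 2).sum()
            / (ngp * (ngp - 1))
            * s_i.sum()
            / nvp
        )
        denom = float(np.abs(ivi[both] * pi[both] - ivj[both] * pj[both]).sum())
        busyness = ps / denom if denom > 0 else 0.0
        complexity = float(
            (
                np.abs(ivi[both] - ivj[both])
                * (pi[both] * s_i[np.where(both)[0]] + pj[both] * s_i[np.where(both)[1]])
                / (pi[both] + pj[both])
            ).sum()
            / nvp
        )
        s_total = float(s_i.sum())
        strength = (
            float(((pi[both] + pj[both]) * (ivi[both] - ivj[both]) ** 2).sum()) / s_total
            if s_total > 0
            else 0.0
        )
    else:
        contrast, busyness, complexity, strength = 0.0, 0.0, 0.0, 0.0
    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


# ---------------------------------------------------------------------------
# grey-level dependence matrix
# ---------------------------------------------------------------------------

def gldm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int, alpha: int = 0) -> np.ndarray:
    """Dependence matrix P[i-1, j-1]: grey level i, dependence j = 1 + number
    of 26-neighbours within alpha grey levels of the centre."""
    lv = np.where(mask, levels, 0)
    dep = np.zeros(lv.shape, dtype=np.int64)
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    for d in offsets:
        src = [slice(max(-o, 0), lv.shape[a] - max(o, 0)) for a, o in enumerate(d)]
        dst = [slice(max(o, 0), lv.shape[a] + min(o, 0)) for a, o in enumerate(d)]
        a = lv[tuple(src)]
        b = lv[tuple(dst)]
        ok = mask[tuple(src)] & mask[tuple(dst)] & (np.abs(a - b) <= alpha)
        dep[tuple(src)] += ok
    dep = dep + 1  # include the centre voxel
    P = np.zeros((n_levels, 27))
    sel = mask
    np.add.at(P, (lv[sel] - 1, dep[sel] - 1), 1.0)
    last = np.max(np.nonzero(P.sum(axis=0))[0])
    return P[:, : last + 1]


def _gldm_features(P: np.ndarray, n_voxels: int) -> dict[str, float]:
    nz = P.sum()
    iv = np.arange(1, P.shape[0] + 1, dtype=float)[:, None]
    jv = np.arange(1, P.shape[1] + 1, dtype=float)[None, :]
    pr = P / nz
    si = P.sum(axis=1)
    sj = P.sum(axis=0)
    mu_i = float((pr * iv).sum())
    mu_j = float((pr * jv).sum())
    return {
        "SmallDependenceEmphasis": float((P / jv**2).sum() / nz),
        "LargeDependenceEmphasis": float((P * jv**2).sum() / nz),
        "GrayLevelNonUniformity": float((si**2).sum() / nz),
        "DependenceNonUniformity": float((sj**2).sum() / nz),
        "DependenceNonUniformityNormalized": float((sj**2).sum() / nz**2),
        "GrayLevelVariance": float((pr * (iv - mu_i) ** 2).sum()),
        "DependenceVariance": float((pr * (jv - mu_j) ** 2).sum()),
        "DependenceEntropy": float(-(pr[pr > 0] * np.log2(pr[pr > 0])).sum()),
        "LowGrayLevelEmphasis": float((P / iv**2).sum() / nz),
        "HighGrayLevelEmphasis": float((P * iv**2).sum() / nz),
        "SmallDependenceLowGrayLevelEmphasis": float((P / (iv**2 * jv**2)).sum() / nz),
        "SmallDependenceHighGrayLevelEmphasis": float((P * iv**2 / jv**2).sum() / nz),
        "LargeDependenceLowGrayLevelEmphasis": float((P * jv**2 / iv**2).sum() / nz),
        "LargeDependenceHighGrayLevelEmphasis": float((P * iv**2 * jv**2).sum() / nz),
    }


# ---------------------------------------------------------------------------
# extraction driver
# ---------------------------------------------------------------------------

_FEATURE_NAMES: dict[str, tuple[str, ...]] = {
    "firstorder": (
        "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile",
        "90Percentile", "Maximum", "Mean", "Median", "InterquartileRange",
        "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
        "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
    ),
    "shape": (
        "MeshVolume", "VoxelVolume", "SurfaceArea", "SurfaceVolumeRatio",
        "Sphericity", "Maximum3DDiameter", "Maximum2DDiameterSlice",
        "Maximum2DDiameterColumn", "Maximum2DDiameterRow", "MajorAxisLength",
        "MinorAxisLength", "LeastAxisLength", "Elongation", "Flatness",
    ),
    "glcm": (
        "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
        "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
        "DifferenceEntropy", "DifferenceVariance", "JointEnergy",
        "JointEntropy", "Imc1", "Imc2", "Idm", "Idmn", "Id", "Idn",
        "InverseVariance", "MaximumProbability", "SumAverage", "SumEntropy",
        "SumSquares", "MCC",
    ),
    "glrlm": (
        "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
        "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
        "RunLengthNonUniformityNormalized", "RunPercentage",
        "GrayLevelVariance", "RunVariance", "RunEntropy",
        "LowGrayLevelRunEmphasis", "HighGrayLevelRunEmphasis",
        "ShortRunLowGrayLevelEmphasis", "ShortRunHighGrayLevelEmphasis",
        "LongRunLowGrayLevelEmphasis", "LongRunHighGrayLevelEmphasis",
    ),
    "glszm": (
        "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
        "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
        "SizeZoneNonUniformityNormalized", "ZonePercentage",
        "GrayLevelVariance", "ZoneVariance", "ZoneEntropy",
        "LowGrayLevelZoneEmphasis", "HighGrayLevelZoneEmphasis",
        "SmallAreaLowGrayLevelEmphasis", "SmallAreaHighGrayLevelEmphasis",
        "LargeAreaLowGrayLevelEmphasis", "LargeAreaHighGrayLevelEmphasis",
    ),
    "ngtdm": ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength"),
    "gldm": (
        "SmallDependenceEmphasis", "LargeDependenceEmphasis",
        "GrayLevelNonUniformity", "DependenceNonUniformity",
        "DependenceNonUniformityNormalized", "GrayLevelVariance",
        "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
        "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
        "SmallDependenceHighGrayLevelEmphasis",
        "LargeDependenceLowGrayLevelEmphasis",
        "LargeDependenceHighGrayLevelEmphasis",
    ),
}


def extract_features(
    volume: ImageVolume,
    mask: StructureMask,
    cfg: DiscretizationConfig | None = None,
    image_tag: str = "",
) -> FeatureVector:
    """Extract the full 107-feature original-image set for one structure.

    Degenerate inputs (single grey level, or fewer than 2 voxels for the
    texture families) yield NaN values flagged ``degenerate`` rather than
    errors.
    """
    cfg = cfg or DiscretizationConfig()
    if not mask.voxels.any():
        raise ValueError("empty mask")
    if not mask.geometry.approx_equal(volume.geometry):
        raise ValueError("mask and volume geometries differ; resample first")

    levels_full, n_levels = discretize(volume, mask, cfg)
    levels, cmask = _crop(levels_full, mask.voxels)
    vals = volume.values[mask.voxels]
    n_vox = int(cmask.sum())
    voxel_mm3 = mask.geometry.voxel_volume_mm3

    values: dict[str, float] = {}
    degenerate: dict[str, bool] = {}

    def put(family: str, feats: dict[str, float], is_degenerate: bool = False) -> None:
        for name in _FEATURE_NAMES[family]:
            key = f"{family}_{name}"
            v = feats.get(name, math.nan)
            values[key] = float(v) if v is not None and np.isfinite(v) else math.nan
            degenerate[key] = is_degenerate or not np.isfinite(values[key])

    put("firstorder", _firstorder(vals, voxel_mm3, cfg.bin_width))
    put("shape", _shape(cmask, mask.geometry.spacing))

    texture_ok = n_levels >= 2 and n_vox >= 2
    if texture_ok:
        put("glcm", _glcm_features(glcm_matrices(levels, cmask, n_levels), n_levels))
        put("glrlm", _glrlm_features(levels, cmask, n_levels, n_vox))
        put("glszm", _glszm_features(glszm_matrix(levels, cmask, n_levels), n_vox))
        put("ngtdm", _ngtdm_features(*ngtdm_table(levels, cmask, n_levels)))
        put("gldm", _gldm_features(gldm_matrix(levels, cmask, n_levels), n_vox))
    else:
        for family in ("glcm", "glrlm", "glszm", "ngtdm", "gldm"):
            put(family, {}, is_degenerate=True)

    return FeatureVector(values, degenerate, role=mask.role, image=image_tag)


# ---------------------------------------------------------------------------
# paired comparison with outlier handling
# ---------------------------------------------------------------------------

def compare_features(
    a: dict[str, FeatureVector],
    b: dict[str, FeatureVector],
    outlier_rule: str = "degenerate",
    iqr_k: float = 3.0,
) -> pd.DataFrame:
    """Per-feature paired Wilcoxon comparison of two matched feature sets.

    ``a`` and ``b`` map case id -> FeatureVector for the same structure on
    the two images.  A feature is removed ("outlier") when — rule
    ``degenerate`` — any case yields a non-finite or degenerate value in
    either set, or — rule ``iqr`` — any value falls outside
    median +/- ``iqr_k`` * IQR across cases.  Removed features carry no
    p-value.  Returns a long-format table ready for a p-value heatmap.
    """
    from .stats_reporting import PairedSample, wilcoxon_signed_rank

    if set(a) != set(b):
        raise ValueError("case sets of the two feature collections differ")
    if outlier_rule not in ("degenerate", "iqr"):
        raise ValueError(f"unknown outlier rule {outlier_rule!r}")
    case_ids = sorted(a)
    names = list(next(iter(a.values())).values)
    rows = []
    for name in names:
        xs = np.array([a[c].values[name] for c in case_ids])
        ys = np.array([b[c].values[name] for c in case_ids])
        flagged = any(a[c].degenerate[name] or b[c].degenerate[name] for c in case_ids)
        removed = flagged or not (np.all(np.isfinite(xs)) and np.all(np.isfinite(ys)))
        if outlier_rule == "iqr" and not removed:
            for arr in (xs, ys):
                med = np.median(arr)
                iqr = np.subtract(*np.percentile(arr, [75, 25]))
                if iqr > 0 and np.any(np.abs(arr - med) > iqr_k * iqr):
                    removed = True
        family = name.split("_", 1)[0]
        row = {"feature": name, "family": family, "removed": removed, "n": len(case_ids)}
        if not removed:
            res = wilcoxon_signed_rank(PairedSample(xs, ys))
            row["p_value"] = res.p_value
            row["statistic"] = res.statistic
            row["significant"] = res.p_value < 0.05
        else:
            row["p_value"] = math.nan
            row["statistic"] = math.nan
            row["significant"] = False
        rows.append(row)
    return pd.DataFrame(rows)
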