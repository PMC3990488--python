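"""Searchlight mapping: model-RDM correlation at every voxel of a masked
volume, plus group-level signed-rank/FDR inference on the resulting maps.

Group inference reuses the signed-rank and Benjamini-Hochberg operations of
:mod:`rsatools.inference` (single implementation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from .compare import kendall_tau_a
from .inference import adjust_multiple, signed_rank_p
from .rdm import RDM, PatternSet, compute_rdm

__all__ = [
    "Volume",
    "SearchlightMap",
    "spherical_neighborhoods",
    "searchlight_map",
    "group_inference",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Volume:
    """4D voxel data (one 3D map per condition) plus a binary brain mask."""

    data: np.ndarray  # X x Y x Z x N
    mask: np.ndarray  # X x Y x Z boolean
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    condition_labels: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        mask = np.asarray(self.mask).astype(bool)
        if data.ndim != 4:
            raise ValueError(f"data must be X x Y x Z x N, got shape {data.shape}")
        if mask.shape != data.shape[:3]:
            raise ValueError(
                f"mask shape {mask.shape} does not match data spatial shape "
                f"{data.shape[:3]}"
            )
        if data.shape[3] < 2:
            raise ValueError("need at least 2 conditions")
        if not np.all(np.isfinite(data[mask])):
            raise ValueError("non-finite values inside the mask")
        labels = self.condition_labels or tuple(
            f"cond{i + 1:03d}" for i in range(data.shape[3])
        )
        if len(labels) != data.shape[3]:
            raise ValueError("one condition label per volume required")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "condition_labels", tuple(labels))

    @property
    def n_conditions(self) -> int:
        return self.data.shape[3]


@dataclass(frozen=True)
class SearchlightMap:
    """Group searchlight result: p-map and FDR-thresholded survivor mask."""

    p_map: np.ndarray
    threshold_mask: np.ndarray
    alpha: float


def spherical_neighborhoods(
    mask: np.ndarray,
    voxel_size_mm: Sequence[float],
    radius_mm: float,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """In-mask spherical neighborhoods around every in-mask voxel.

    Membership uses center-to-center Euclidean distance in millimetres with
    anisotropic voxel dimensions honored; the center always belongs to its
    own neighborhood and out-of-mask voxels are clipped.

    Returns ``(centers, neighborhoods)``: an (K, 3) array of in-mask center
    coordinates and, per center, the flat (raveled) indices of its member
    voxels.
    """
    mask = np.asarray(mask).astype(bool)
    if radius_mm < 0:
        raise ValueError("radius_mm must be >= 0")
    if not mask.any():
        raise ValueError("mask is empty")
    vs = np.asarray(voxel_size_mm, dtype=float)
    if vs.shape != (3,) or np.any(vs <= 0):
        raise ValueError("voxel_size_mm must be three positive values")

    reach = np.floor(radius_mm / vs).astype(int)
    offsets = []
    for dx in range(-reach[0], reach[0] + 1):
        for dy in range(-reach[1], reach[1] + 1):
            for dz in range(-reach[2], reach[2] + 1):
                if (dx * vs[0]) ** 2 + (dy * vs[1]) ** 2 + (dz * vs[2]) ** 2 <= radius_mm**2:
                    offsets.append((dx, dy, dz))
    offsets = np.array(offsets, dtype=int)  # always contains (0, 0, 0)

    centers = np.argwhere(mask)
    shape = mask.shape
    neighborhoods = []
    for center in centers:
        pts = center[None, :] + offsets
        inside = np.all((pts >= 0) & (pts < np.array(shape)), axis=1)
        pts = pts[inside]
        in_mask = mask[pts[:, 0], pts[:, 1], pts[:, 2]]
        pts = pts[in_mask]
        neighborhoods.append(np.ravel_multi_index(pts.T, shape))
    return centers, neighborhoods


def _rank_standardize(v: np.ndarray) -> np.ndarray:
    r = rankdata(v)
    return (r - r.mean()) / r.std()


def searchlight_map(
    volume: Volume,
    model: RDM,
    radius_mm: float,
    dissimilarity: str = "correlation",
    comparison: str = "spearman",
    min_neighborhood: int = 10,
) -> np.ndarray:
    """Model-RDM correlation at every in-mask voxel (one subject).

    Returns an ``r_map`` that is NaN outside the mask, at centers whose
    clipped neighborhood is smaller than ``min_neighborhood`` voxels, and at
    centers whose patterns make the dissimilarity undefined (counted and
    logged).
    """
    if model.n_conditions != volume.n_conditions:
        raise ValueError(
            f"model has {model.n_conditions} conditions but the volume has "
            f"{volume.n_conditions}"
        )
    centers, neighborhoods = spherical_neighborhoods(
        volume.mask, volume.voxel_size_mm, radius_mm
    )
    flat = volume.data.reshape(-1, volume.n_conditions)
    r_map = np.full(volume.mask.shape, np.nan)

    model_vec = model.dissimilarities
    if comparison in ("spearman", "pearson"):
        model_z = (
            _rank_standardize(model_vec)
            if comparison == "spearman"
            else (model_vec - model_vec.mean()) / model_vec.std()
        )
    elif comparison != "kendall_tau_a":
        raise ValueError(f"unknown comparison {comparison!r}")

    n_undefined = 0
    n_small = 0
    labels = volume.condition_labels
    for center, neigh in zip(centers, neighborhoods):
        if neigh.size < min_neighborhood:
            n_small += 1
            continue
        patterns = flat[neigh].T  # conditions x voxels
        if np.any(patterns.std(axis=1) == 0) and dissimilarity == "correlation":
            n_undefined += 1
            continue
        rdm_vec = compute_rdm(
            PatternSet(labels, patterns), dissimilarity
        ).dissimilarities
        if comparison == "kendall_tau_a":
            r = kendall_tau_a(rdm_vec, model_vec)
        else:
            sd = rdm_vec.std() if comparison == "pearson" else None
            if comparison == "pearson" and sd == 0:
                n_undefined += 1
                continue
            v = (
                _rank_standardize(rdm_vec)
                if comparison == "spearman"
                else (rdm_vec - rdm_vec.mean()) / rdm_vec.std()
            )
            r = float(v @ model_z) / v.size
        r_map[tuple(center)] = r
    if n_undefined or n_small:
        logger.info(
            "searchlight: %d centers undefined (constant patterns), "
            "%d skipped (neighborhood < %d voxels)",
            n_undefined,
            n_small,
            min_neighborhood,
        )
    return r_map


def group_inference(
    r_maps: Sequence[np.ndarray],
    alpha: float = 0.05,
    procedure: str = "fdr_bh",
) -> SearchlightMap:
    """Voxelwise one-sided signed-rank test across subjects, FDR thresholded.

    Voxels undefined (NaN) in any subject are excluded from the test family
    rather than assigned p = 1.
    """
    maps = np.stack([np.asarray(m, dtype=float) for m in r_maps])
    if maps.shape[0] < 4:
        raise ValueError(f"group inference needs >= 4 subjects, got {maps.shape[0]}")
    defined = np.all(np.isfinite(maps), axis=0)
    p_map = np.full(maps.shape[1:], np.nan)
    coords = np.argwhere(defined)
    pvals = np.empty(coords.shape[0])
    for k, c in enumerate(coords):
        pvals[k] = signed_rank_p(maps[(slice(None), *c)], alternative="greater")
        p_map[tuple(c)] = pvals[k]
    reject, _ = adjust_multiple(pvals, procedure=procedure, alpha=alpha)
    threshold_mask = np.zeros(maps.shape[1:], dtype=bool)
    threshold_mask[tuple(coords[reject].T)] = True
    return SearchlightMap(p_map=p_map, threshold_mask=threshold_mask, alpha=alpha)
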