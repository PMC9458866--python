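"""Annotated anatomical volumes and binary region masks.

An annotated volume assigns an integer label to every voxel (FreeSurfer
aseg-style segmentations or the synthetic phantom's labels).  Selected
label sets are binarized, downsampled onto the functional-tomogram grid
(presence rule: a tomogram cell is inside the region if any contributing
native voxel is), and made pairwise disjoint by removing voxels shared
between regions from all of them.  The surviving cells, in flat C-order
ordinal form, are what frequency classification looks matched sources up
against.

All affines map voxel indices to head-frame coordinates in meters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .forward import GridSpec

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotatedVolume",
    "BinaryMask",
    "binarize_labels",
    "resample_mask",
    "remove_overlap",
]


@dataclass(frozen=True)
class AnnotatedVolume:
    """Integer label volume with a voxel -> head-frame (meters) affine."""

    labels: np.ndarray      # (nx, ny, nz) int
    affine: np.ndarray      # (4, 4)

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 3 or np.any(lab < 0):
            raise ValueError("labels must be a 3-D array of codes >= 0")
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4) or abs(np.linalg.det(aff[:3, :3])) < 1e-30:
            raise ValueError("affine must be an invertible 4x4 matrix")
        object.__setattr__(self, "labels", lab)
        object.__setattr__(self, "affine", aff)

    def voxel_centers(self, mask: np.ndarray | None = None) -> np.ndarray:
        """World coordinates (meters) of voxel centers, optionally masked."""
        if mask is None:
            idx = np.indices(self.labels.shape).reshape(3, -1).T
        else:
            idx = np.argwhere(mask)
        homo = np.column_stack([idx, np.ones(len(idx))])
        return (homo @ self.affine.T)[:, :3]


@dataclass(frozen=True)
class BinaryMask:
    """Boolean region volume plus its voxel -> world affine.

    ``grid`` is set once the mask lives on the tomogram grid; the index
    set is the flat C-order ordinals of the true voxels.
    """

    volume: np.ndarray
    name: str
    affine: np.ndarray
    grid: GridSpec | None = None

    def __post_init__(self) -> None:
        vol = np.asarray(self.volume, dtype=bool)
        if vol.ndim != 3:
            raise ValueError("mask volume must be 3-D")
        object.__setattr__(self, "volume", vol)
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))
        if self.grid is not None and tuple(self.grid.shape) != vol.shape:
            raise ValueError("mask volume shape does not match its grid")

    @property
    def index_set(self) -> np.ndarray:
        """Ordinal numbers (flat C-order) of the true voxels."""
        return np.flatnonzero(self.volume.ravel())

    @property
    def n_voxels(self) -> int:
        return int(self.volume.sum())

    def voxel_centers(self) -> np.ndarray:
        """World coordinates (meters) of the true voxel centers -> (n, 3)."""
        idx = np.argwhere(self.volume)
        homo = np.column_stack([idx, np.ones(len(idx))])
        return (homo @ self.affine.T)[:, :3]

    def contains_cell(self, ijs: tuple[int, int, int]) -> bool:
        i, j, s = ijs
        if not all(0 <= v < n for v, n in zip((i, j, s), self.volume.shape)):
            return False
        return bool(self.volume[i, j, s])

    @classmethod
    def from_indices(
        cls, indices: np.ndarray, grid: GridSpec, name: str
    ) -> "BinaryMask":
        """Rebuild a tomogram-grid mask from its ordinal index set."""
        vol = np.zeros(grid.n_cells, dtype=bool)
        vol[np.asarray(indices, dtype=np.int64)] = True
        return cls(
            volume=vol.reshape(grid.shape),
            name=name,
            affine=grid.affine("m"),
            grid=grid,
        )


def binarize_labels(
    annotated: AnnotatedVolume, label_set, name: str = "region"
) -> BinaryMask:
    """Native-resolution mask: voxel true iff its label is in ``label_set``.

    Labels requested but absent from the volume are ignored with a warning.
    """
    wanted = set(int(v) for v in label_set)
    if not wanted:
        raise ValueError("label_set must be non-empty")
    present = set(int(v) for v in np.unique(annotated.labels))
    unknown = wanted - present
    if unknown:
        logger.warning("labels %s not present in the annotated volume", sorted(unknown))
    vol = np.isin(annotated.labels, sorted(wanted))
    return BinaryMask(volume=vol, name=name, affine=annotated.affine)


def resample_mask(
    mask: BinaryMask,
    grid: GridSpec,
    min_fraction: float | None = None,
) -> BinaryMask:
    """Downsample a native mask onto the tomogram grid.

    Default is the presence rule: a grid cell is true as soon as one true
    native voxel center falls inside it.  With ``min_fraction`` set, a cell
    must instead collect at least that fraction of true voxels among all
    native voxels mapping into it.

    Raises
    ------
    ValueError
        If no native voxel falls inside the tomogram grid at all.
    """
    src = AnnotatedVolume(
        labels=mask.volume.astype(np.int64), affine=mask.affine
    )
    centers = src.voxel_centers()                       # all voxels
    ijs = grid.index_of(centers)
    inside = np.all((ijs >= 0) & (ijs < np.asarray(grid.shape)), axis=1)
    if not np.any(inside):
        raise ValueError("mask volume does not overlap the tomogram grid")
    flat = np.ravel_multi_index(ijs[inside].T, grid.shape)
    truth = mask.volume.ravel()[inside]
    true_counts = np.bincount(flat[truth], minlength=grid.n_cells)
    if min_fraction is None:
        out = true_counts > 0
    else:
        all_counts = np.bincount(flat, minlength=grid.n_cells)
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(all_counts > 0, true_counts / all_counts, 0.0)
        out = frac >= min_fraction
    return BinaryMask(
        volume=out.reshape(grid.shape),
        name=mask.name,
        affine=grid.affine("m"),
        grid=grid,
    )


def remove_overlap(masks: list[BinaryMask]) -> list[BinaryMask]:
    """Make masks pairwise disjoint: shared voxels are dropped from all.

    A voxel present in two or more input masks belongs to none of the
    outputs.
    """
    if not masks:
        return []
    shape = masks[0].volume.shape
    if any(m.volume.shape != shape for m in masks):
        raise ValueError("all masks must share one grid")
    counts = np.zeros(shape, dtype=np.int64)
    for m in masks:
        counts += m.volume
    shared = counts >= 2
    return [
        BinaryMask(
            volume=m.volume & ~shared,
            name=m.name,
            affine=m.affine,
            grid=m.grid,
        )
        for m in masks
    ]
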