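"""Searchlight sphere enumeration and feature extraction.

Sphere membership uses the strict inequality ||d||^2 < radius^2 in voxel
units: at the default radius of 4 this yields 251 voxels (the closed ball
would include 6 extra lattice points at exactly distance 4, giving 257).
Spheres truncated at the mask or grid boundary keep all available voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SphereSpec", "sphere_offsets", "iterate_centers",
           "extract_features"]


def sphere_offsets(radius: float) -> np.ndarray:
    """Integer offsets with squared norm strictly below radius^2.

    Returned in lexicographic order; includes the origin for radius >= 1.
    """
    if radius < 1:
        raise ValueError("radius must be at least 1 voxel")
    r = int(np.ceil(radius))
    grid = np.arange(-r, r + 1)
    i, j, k = np.meshgrid(grid, grid, grid, indexing="ij")
    offsets = np.column_stack([i.ravel(), j.ravel(), k.ravel()])
    keep = (offsets ** 2).sum(axis=1) < radius ** 2
    out = offsets[keep]
    order = np.lexsort((out[:, 2], out[:, 1], out[:, 0]))
    return out[order]


@dataclass(frozen=True)
class SphereSpec:
    """Searchlight sphere: radius in voxel units plus its offset list."""

    radius: float = 4.0
    offsets: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.offsets is None:
            object.__setattr__(self, "offsets", sphere_offsets(self.radius))

    @property
    def n_voxels(self) -> int:
        return len(self.offsets)


def iterate_centers(mask: np.ndarray) -> np.ndarray:
    """All in-mask voxel indices, in C order; (n, 3) array."""
    if not mask.any():
        raise ValueError("mask is empty")
    return np.argwhere(mask)


def extract_features(betas, center, spec: SphereSpec) -> np.ndarray:
    """Trials x sphere-voxels feature matrix at one searchlight center.

    Offsets falling outside the grid or the mask are dropped; column order
    follows the (lexicographic) offset order.
    """
    mask = betas.mask
    center = np.asarray(center)
    if not mask[tuple(center)]:
        raise ValueError(f"center {tuple(center)} is outside the mask")
    pts = center + spec.offsets
    ok = np.all((pts >= 0) & (pts < np.array(mask.shape)), axis=1)
    pts = pts[ok]
    pts = pts[mask[tuple(pts.T)]]
    if len(pts) == 0:
        raise ValueError("no sphere voxels retained")
    return betas.data[:, pts[:, 0], pts[:, 1], pts[:, 2]]
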