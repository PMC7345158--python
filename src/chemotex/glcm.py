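"""Gray-level co-occurrence matrices and the four texture features.

A GLCM at offset (d, theta) tabulates, over all pixel pairs separated by
that displacement, the joint probability C(i, j) of observing gray level i
at one end and j at the other.  Four scalar statistics summarize it:

    contrast    = sum_ij C(i,j) (i - j)^2          local intensity variation
    energy      = sum_ij C(i,j)^2                  orderliness
    homogeneity = sum_ij C(i,j) / (1 + |i - j|)    smoothness
    entropy     = -sum_ij C(i,j) log C(i,j)        disorder (log base 2 here)

Rough, three-dimensional cell layers raise contrast and entropy and lower
energy and homogeneity relative to flat, smooth monolayers; that contrast
is the basis of the downstream chemoresistance score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .image_io import GrayPatch

__all__ = [
    "Offset",
    "GLCMatrix",
    "TextureFeatures",
    "FEATURE_NAMES",
    "compute_glcm",
    "compute_features",
    "patch_features",
    "feature_table",
]

FEATURE_NAMES = ("contrast", "entropy", "energy", "homogeneity")

# Displacement (row, col) for one step at each angle.  0 deg points right
# along a row; 90 deg points up a column (image rows grow downward, hence
# the negative row step).  Only these four Haralick angles are defined.
_ANGLE_STEPS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass(frozen=True)
class Offset:
    """GLCM sampling offset: interpixel distance, angle, symmetry."""

    distance: int = 10
    angle: int = 0
    symmetric: bool = True

    def __post_init__(self) -> None:
        if self.distance < 1:
            raise ValueError(f"distance must be >= 1, got {self.distance}")
        if self.angle not in _ANGLE_STEPS:
            raise ValueError(
                f"angle must be one of {sorted(_ANGLE_STEPS)}, got {self.angle}"
            )

    @property
    def displacement(self) -> tuple[int, int]:
        dr, dc = _ANGLE_STEPS[self.angle]
        return dr * self.distance, dc * self.distance


@dataclass(frozen=True)
class GLCMatrix:
    """Normalized co-occurrence probability table for one patch and offset."""

    C: np.ndarray
    gray_levels: int
    offset: Offset
    pair_count: int


class DegenerateInputError(ValueError):
    """Raised when an operation receives input it cannot meaningfully process."""


def compute_glcm(patch: GrayPatch, offset: Offset) -> GLCMatrix:
    """Build the normalized GLCM of a patch at one offset.

    Ordered pixel pairs (p, q) with q displaced from p by the offset are
    counted; with ``offset.symmetric`` the reverse displacement is counted
    too, making the matrix symmetric.  Counts are divided by the realized
    pair count — which shrinks as the distance grows — never by a fixed
    constant, so probabilities always sum to 1 and features stay comparable
    across distances.
    """
    G = patch.gray_levels
    dr, dc = offset.displacement
    px = patch.pixels.astype(np.int64)
    n = patch.side
    if abs(dr) >= n or abs(dc) >= n:
        raise DegenerateInputError(
            f"offset displacement ({dr}, {dc}) leaves no valid pairs in a "
            f"{n}x{n} patch"
        )
    # Slice the overlap of the patch with itself shifted by (dr, dc).
    r0, r1 = max(0, -dr), min(n, n - dr)
    c0, c1 = max(0, -dc), min(n, n - dc)
    a = px[r0:r1, c0:c1]
    b = px[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    counts = np.bincount((a * G + b).ravel(), minlength=G * G).reshape(G, G)
    if offset.symmetric:
        counts = counts + counts.T
    pair_count = int(counts.sum())
    return GLCMatrix(
        C=counts / pair_count, gray_levels=G, offset=offset, pair_count=pair_count
    )


@dataclass(frozen=True)
class TextureFeatures:
    contrast: float
    energy: float
    homogeneity: float
    entropy: float

    def as_dict(self) -> dict[str, float]:
        return {
            "contrast": self.contrast,
            "entropy": self.entropy,
            "energy": self.energy,
            "homogeneity": self.homogeneity,
        }


def compute_features(glcm: GLCMatrix, entropy_base: float = 2.0) -> TextureFeatures:
    """Evaluate contrast, energy, homogeneity and entropy of a GLCM.

    Entropy uses the 0 log 0 = 0 convention and log base 2 (bits) by
    default; pass ``entropy_base=np.e`` for nats.
    """
    C = glcm.C
    G = glcm.gray_levels
    i = np.arange(G)
    diff = i[:, None] - i[None, :]
    contrast = float((C * diff**2).sum())
    energy = float((C**2).sum())
    homogeneity = float((C / (1.0 + np.abs(diff))).sum())
    nz = C[C > 0]
    entropy = float(-(nz * (np.log(nz) / np.log(entropy_base))).sum())
    return TextureFeatures(
        contrast=contrast, energy=energy, homogeneity=homogeneity, entropy=entropy
    )


def patch_features(
    patch: GrayPatch, offset: Offset, entropy_base: float = 2.0
) -> TextureFeatures:
    """GLCM + feature evaluation in one call."""
    return compute_features(compute_glcm(patch, offset), entropy_base=entropy_base)


def feature_table(
    patches: list[GrayPatch],
    offset: Offset,
    entropy_base: float = 2.0,
    labels: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Tabulate the four features for a list of patches.

    Returns one row per patch with columns ``patch_id, source_image,
    distance, angle, contrast, entropy, energy, homogeneity`` (plus
    ``group`` when ``labels`` maps source names to group names).
    """
    rows = []
    for p in patches:
        f = patch_features(p, offset, entropy_base=entropy_base)
        row = {
            "patch_id": f"{p.source}_r{p.origin[0]}_c{p.origin[1]}",
            "source_image": p.source,
            "distance": offset.distance,
            "angle": offset.angle,
            **f.as_dict(),
        }
        if labels is not None:
            row["group"] = labels.get(p.source, "")
        rows.append(row)
    cols = ["patch_id", "source_image", "distance", "angle", *FEATURE_NAMES]
    if labels is not None:
        cols.append("group")
    return pd.DataFrame(rows, columns=cols)
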