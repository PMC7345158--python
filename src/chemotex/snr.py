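"""Taguchi signal-to-noise composite scoring of texture features.

The four GLCM features respond to chemoresistant morphology in known
directions — rough, scattering, three-dimensional cell layers have higher
contrast and entropy and lower energy and homogeneity than flat wild-type
monolayers.  The Taguchi quality-engineering S/N ratios turn that into a
single score in decibels:

    smaller-is-better:  S/N = -10 log10( (1/n) sum y_i^2 )
    larger-is-better:   S/N = -10 log10( (1/n) sum 1/y_i^2 )

Energy and homogeneity enter as smaller-is-better, contrast and entropy as
larger-is-better, so a *higher* combined S/N marks a group of images as
more resistant-like.

The default combiner pools the raw values of the two larger-is-better
features into one larger-is-better evaluation, the two smaller-is-better
features into one smaller-is-better evaluation, and averages the two
components.  An alternative combiner (``combiner="per_feature"``) averages
four per-feature S/N values instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .glcm import TextureFeatures

__all__ = [
    "FeatureDirection",
    "DEFAULT_DIRECTIONS",
    "SNRResult",
    "snr_smaller_is_better",
    "snr_larger_is_better",
    "combined_snr",
    "jackknife_sd",
    "per_image_snr",
]


@dataclass(frozen=True)
class FeatureDirection:
    feature_name: str
    direction: Literal["larger_is_better", "smaller_is_better"]


DEFAULT_DIRECTIONS: tuple[FeatureDirection, ...] = (
    FeatureDirection("contrast", "larger_is_better"),
    FeatureDirection("entropy", "larger_is_better"),
    FeatureDirection("energy", "smaller_is_better"),
    FeatureDirection("homogeneity", "smaller_is_better"),
)


@dataclass(frozen=True)
class SNRResult:
    """Composite score for one group of patches, in decibels."""

    snr_combined: float
    snr_larger: float
    snr_smaller: float
    n_patches: int
    group_label: str = ""
    n_excluded: int = 0


def _check_values(values: Sequence[float]) -> np.ndarray:
    y = np.asarray(values, dtype=np.float64)
    if y.size == 0:
        raise ValueError("S/N ratio of an empty value list is undefined")
    if np.any(y <= 0):
        raise ValueError("S/N ratios are defined for strictly positive values only")
    return y


def snr_smaller_is_better(values: Sequence[float]) -> float:
    """-10 log10 of the mean squared value; large when all values are small."""
    y = _check_values(values)
    return float(-10.0 * np.log10(np.mean(y**2)))


def snr_larger_is_better(values: Sequence[float]) -> float:
    """-10 log10 of the mean squared reciprocal; large when all values are large."""
    y = _check_values(values)
    return float(-10.0 * np.log10(np.mean(1.0 / y**2)))


def _pools(
    records: pd.DataFrame, directions: Iterable[FeatureDirection]
) -> tuple[np.ndarray, np.ndarray, int]:
    """Split feature columns into the larger/smaller pools.

    Non-positive values cannot enter either pool (the logarithm is
    undefined); a constant patch has zero contrast and entropy, so such
    values are dropped and the number of affected patches is reported.
    """
    larger_cols = [d.feature_name for d in directions if d.direction == "larger_is_better"]
    smaller_cols = [d.feature_name for d in directions if d.direction == "smaller_is_better"]
    larger_vals = records[larger_cols].to_numpy(dtype=np.float64)
    smaller_vals = records[smaller_cols].to_numpy(dtype=np.float64)
    excluded_rows = int(((larger_vals <= 0) | (smaller_vals <= 0)).any(axis=1).sum())
    return (
        larger_vals[larger_vals > 0],
        smaller_vals[smaller_vals > 0],
        excluded_rows,
    )


def _as_frame(
    features: pd.DataFrame | Sequence[TextureFeatures],
) -> pd.DataFrame:
    if isinstance(features, pd.DataFrame):
        return features
    return pd.DataFrame([f.as_dict() for f in features])


def combined_snr(
    features: pd.DataFrame | Sequence[TextureFeatures],
    directions: Iterable[FeatureDirection] = DEFAULT_DIRECTIONS,
    combiner: Literal["pooled", "per_feature"] = "pooled",
    group_label: str = "",
) -> SNRResult:
    """Reduce a group of per-patch feature records to one composite S/N.

    ``pooled`` (default): one larger-is-better evaluation of the pooled
    {contrast_i} u {entropy_i} multiset, one smaller-is-better evaluation of
    {energy_i} u {homogeneity_i}, combined as their arithmetic mean.

    ``per_feature``: one S/N per feature in its own direction, combined as
    the mean of the four; the larger/smaller components reported are then
    the means of each direction's per-feature values.
    """
    df = _as_frame(features)
    if len(df) == 0:
        raise ValueError("cannot score an empty feature table")
    if combiner == "pooled":
        larger_pool, smaller_pool, n_excl = _pools(df, directions)
        if larger_pool.size == 0 or smaller_pool.size == 0:
            raise ValueError(
                "all patches were excluded from an S/N pool (non-positive values)"
            )
        snr_l = snr_larger_is_better(larger_pool)
        snr_s = snr_smaller_is_better(smaller_pool)
    elif combiner == "per_feature":
        per_l, per_s = [], []
        n_excl = 0
        for d in directions:
            vals = df[d.feature_name].to_numpy(dtype=np.float64)
            n_excl = max(n_excl, int((vals <= 0).sum()))
            vals = vals[vals > 0]
            if vals.size == 0:
                raise ValueError(f"all {d.feature_name} values were excluded")
            if d.direction == "larger_is_better":
                per_l.append(snr_larger_is_better(vals))
            else:
                per_s.append(snr_smaller_is_better(vals))
        snr_l = float(np.mean(per_l))
        snr_s = float(np.mean(per_s))
    else:
        raise ValueError(f"unknown combiner {combiner!r}")
    return SNRResult(
        snr_combined=0.5 * (snr_l + snr_s),
        snr_larger=snr_l,
        snr_smaller=snr_s,
        n_patches=len(df),
        group_label=group_label,
        n_excluded=n_excl,
    )


def jackknife_sd(
    features: pd.DataFrame,
    directions: Iterable[FeatureDirection] = DEFAULT_DIRECTIONS,
    combiner: Literal["pooled", "per_feature"] = "pooled",
) -> float:
    """Leave-one-patch-out jackknife standard error of the combined S/N."""
    df = _as_frame(features).reset_index(drop=True)
    n = len(df)
    if n < 2:
        raise ValueError("jackknife needs at least 2 patches")
    loo = np.array(
        [
            combined_snr(df.drop(index=k), directions, combiner).snr_combined
            for k in range(n)
        ]
    )
    return float(np.sqrt((n - 1) / n * ((loo - loo.mean()) ** 2).sum()))


def per_image_snr(
    feature_table: pd.DataFrame,
    directions: Iterable[FeatureDirection] = DEFAULT_DIRECTIONS,
    combiner: Literal["pooled", "per_feature"] = "pooled",
    image_column: str = "source_image",
) -> pd.Series:
    """Combined S/N of each source image's own patches.

    Returns a Series indexed by image name, in first-appearance order —
    the per-image scores that group-level significance tests operate on.
    """
    order = feature_table[image_column].drop_duplicates().tolist()
    scores = {
        img: combined_snr(
            feature_table[feature_table[image_column] == img], directions, combiner
        ).snr_combined
        for img in order
    }
    return pd.Series(scores, name="snr_combined").loc[order]
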