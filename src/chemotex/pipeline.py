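"""End-to-end driver: synthetic study -> patches -> features -> comparison.

The analysis scripts, the command-line interface and the acceptance checks
all run the same few calls collected here, so a whole study is one
function call with one master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import group_stats, snr, synth
from .glcm import Offset, feature_table
from .image_io import GrayImage, extract_patches, quantize

__all__ = ["StudyConfig", "study_feature_table", "run_synthetic_study"]


@dataclass(frozen=True)
class StudyConfig:
    """Settings of one analysis run; defaults are the workflow's standard
    convention (150 x 150 patches, 256 gray levels, offset (10, 0))."""

    gray_levels: int = 256
    patch_side: int = 150
    distance: int = 10
    angle: int = 0
    symmetric: bool = True
    entropy_base: float = 2.0
    min_foreground_fraction: float = 0.0
    foreground_threshold: int = 5
    combiner: str = "pooled"

    @property
    def offset(self) -> Offset:
        return Offset(distance=self.distance, angle=self.angle, symmetric=self.symmetric)


def study_feature_table(
    images: list[GrayImage],
    labels: list[str] | None = None,
    names: list[str] | None = None,
    config: StudyConfig = StudyConfig(),
) -> pd.DataFrame:
    """Quantize, tile and featurize a list of images into one table."""
    if names is None:
        names = [f"img_{k:03d}" for k in range(len(images))]
    label_map = dict(zip(names, labels)) if labels is not None else None
    patches = []
    for name, img in zip(names, images):
        q = quantize(img, config.gray_levels)
        patches.extend(
            extract_patches(
                q,
                side=config.patch_side,
                min_foreground_fraction=config.min_foreground_fraction,
                threshold=config.foreground_threshold,
                source=name,
            )
        )
    return feature_table(
        patches, config.offset, entropy_base=config.entropy_base, labels=label_map
    )


@dataclass(frozen=True)
class StudyResult:
    features: pd.DataFrame         # per-patch feature table with group labels
    per_image_snr: pd.DataFrame    # columns group, source_image, snr_combined
    summary: pd.DataFrame          # feature rows + S/N row with ANOVA p and stars


def run_synthetic_study(
    n_images_per_group: int = 20,
    seed: int = 1,
    height: int = 300,
    width: int = 300,
    config: StudyConfig = StudyConfig(),
) -> StudyResult:
    """Simulate both phenotypes and push them through the full pipeline."""
    ds = synth.generate_study(
        n_images_per_group,
        wt_params=synth.wt_preset(height, width),
        cp_params=synth.cp_preset(height, width),
        seed=seed,
        height=height,
        width=width,
    )
    names = [f"{lab.lower()}_{k % n_images_per_group:03d}" for k, lab in enumerate(ds.labels)]
    feats = study_feature_table(ds.images, labels=ds.labels, names=names, config=config)
    per_image = (
        feats.groupby("source_image", sort=False)
        .first()["group"]
        .rename("group")
        .to_frame()
        .assign(
            snr_combined=snr.per_image_snr(feats, combiner=config.combiner)
        )
        .reset_index()
    )
    summary = group_stats.summarize_groups(feats, combiner=config.combiner)
    return StudyResult(features=feats, per_image_snr=per_image, summary=summary)
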