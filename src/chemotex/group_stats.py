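"""Group comparisons: one-way ANOVA with the significance-star convention.

Feature-by-feature and S/N-score comparisons between a wild-type-like
benchmark group and a resistant-like group, reported in the layout of the
standard two-column summary table: mean +/- sd per group, the ANOVA F and
p, and stars at the 0.05 / 0.01 / 0.001 ladder.  No multiple-testing
correction is applied — the stars are raw per-quantity p values, and the
documentation notes this.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .glcm import FEATURE_NAMES
from .snr import DEFAULT_DIRECTIONS, FeatureDirection, combined_snr, jackknife_sd, per_image_snr

__all__ = ["GroupComparison", "stars_for_p", "anova_compare", "summarize_groups", "render_report"]

_STAR_LADDER = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass(frozen=True)
class GroupComparison:
    quantity_name: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    f_statistic: float
    p_value: float
    stars: str


def stars_for_p(p: float) -> str:
    """Significance stars: *** p<0.001, ** p<0.01, * p<0.05, else ns."""
    for cut, mark in _STAR_LADDER:
        if p < cut:
            return mark
    return "ns"


def anova_compare(
    values_a: Sequence[float], values_b: Sequence[float], quantity_name: str = ""
) -> GroupComparison:
    """Two-group one-way (equal-variance) ANOVA.

    For two groups F equals the square of the pooled-variance t statistic,
    which the test suite uses as an algebraic cross-check.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if np.ptp(np.concatenate([a, b])) == 0:
        raise ValueError("total variance is zero; ANOVA is undefined")
    f, p = stats.f_oneway(a, b)
    return GroupComparison(
        quantity_name=quantity_name,
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        f_statistic=float(f),
        p_value=float(p),
        stars=stars_for_p(float(p)),
    )


def summarize_groups(
    feature_table: pd.DataFrame,
    directions: Iterable[FeatureDirection] = DEFAULT_DIRECTIONS,
    combiner: str = "pooled",
    group_column: str = "group",
    image_column: str = "source_image",
) -> pd.DataFrame:
    """Feature-wise and S/N-wise comparison of every pair of groups.

    For each ordered group pair (first-appearance order), emits one row per
    feature — contrast, entropy, energy, homogeneity — comparing per-patch
    feature values, then one S/N row comparing per-image combined scores.
    The S/N row's means are each group's whole-group pooled score with a
    leave-one-patch-out jackknife standard error.
    """
    groups = feature_table[group_column].drop_duplicates().tolist()
    if len(groups) < 2:
        raise ValueError("group comparison needs at least 2 groups")
    rows = []
    for ia in range(len(groups)):
        for ib in range(ia + 1, len(groups)):
            ga, gb = groups[ia], groups[ib]
            sub_a = feature_table[feature_table[group_column] == ga]
            sub_b = feature_table[feature_table[group_column] == gb]
            for feat in FEATURE_NAMES:
                cmp = anova_compare(sub_a[feat], sub_b[feat], quantity_name=feat)
                rows.append(
                    {
                        "group_a": ga,
                        "group_b": gb,
                        "quantity": feat,
                        "mean_a": cmp.mean_a,
                        "sd_a": cmp.sd_a,
                        "mean_b": cmp.mean_b,
                        "sd_b": cmp.sd_b,
                        "f_statistic": cmp.f_statistic,
                        "p_value": cmp.p_value,
                        "stars": cmp.stars,
                    }
                )
            snr_a = combined_snr(sub_a, directions, combiner, group_label=ga)
            snr_b = combined_snr(sub_b, directions, combiner, group_label=gb)
            per_img_a = per_image_snr(sub_a, directions, combiner, image_column)
            per_img_b = per_image_snr(sub_b, directions, combiner, image_column)
            cmp = anova_compare(per_img_a, per_img_b, quantity_name="snr_combined")
            rows.append(
                {
                    "group_a": ga,
                    "group_b": gb,
                    "quantity": "snr_combined",
                    "mean_a": snr_a.snr_combined,
                    "sd_a": jackknife_sd(sub_a, directions, combiner),
                    "mean_b": snr_b.snr_combined,
                    "sd_b": jackknife_sd(sub_b, directions, combiner),
                    "f_statistic": cmp.f_statistic,
                    "p_value": cmp.p_value,
                    "stars": cmp.stars,
                }
            )
    return pd.DataFrame(rows)


def render_report(
    summary: pd.DataFrame, offset_distance: int = 10, offset_angle: int = 0
) -> str:
    """Plain-text rendering of a group-comparison summary table."""
    lines = []
    header = f"{'quantity':<14}{'group A (mean±sd)':<24}{'group B (mean±sd)':<24}{'p':>12}  stars"
    for (ga, gb), block in summary.groupby(["group_a", "group_b"], sort=False):
        lines.append(f"Comparison: {ga} (A) vs {gb} (B)")
        lines.append(header)
        lines.append("-" * len(header))
        for _, r in block.iterrows():
            col_a = f"{r['mean_a']:.4g} ± {r['sd_a']:.3g}"
            col_b = f"{r['mean_b']:.4g} ± {r['sd_b']:.3g}"
            lines.append(
                f"{r['quantity']:<14}{col_a:<24}{col_b:<24}"
                f"{r['p_value']:>12.3g}  {r['stars']}"
            )
        lines.append("")
    lines.append(
        f"GLCM sampling offset was ({offset_distance}, {offset_angle}); "
        "* p < 0.05, ** p < 0.01, *** p < 0.001."
    )
    return "\n".join(lines)
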