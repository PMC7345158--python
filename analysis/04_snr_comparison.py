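"""Score both phenotype groups with the Taguchi S/N composite and compare.

From results/features.csv: computes each group's pooled combined S/N (with
a leave-one-patch-out jackknife spread), the per-image scores, and the
feature-wise + S/N-wise one-way ANOVA comparison with significance stars.
Writes results/snr.csv and results/comparison.csv and prints the
plain-text report.  A higher combined S/N marks the group as more
resistant-like; the gap between the groups is what the headline
significance claim rests on.
"""

from pathlib import Path

import pandas as pd

from chemotex import combined_snr, jackknife_sd, per_image_snr, render_report, summarize_groups

ROOT = Path(__file__).resolve().parents[1]
FEATURES = ROOT / "results" / "features.csv"


def main() -> None:
    feats = pd.read_csv(FEATURES)
    rows = []
    for group, sub in feats.groupby("group", sort=False):
        r = combined_snr(sub, group_label=group)
        rows.append(
            {
                "group": group,
                "n_patches": r.n_patches,
                "snr_larger": r.snr_larger,
                "snr_smaller": r.snr_smaller,
                "snr_combined": r.snr_combined,
                "snr_sd": jackknife_sd(sub),
            }
        )
    snr_table = pd.DataFrame(rows)
    snr_table.to_csv(ROOT / "results" / "snr.csv", index=False)
    print("Group S/N scores (dB):")
    print(snr_table.to_string(index=False))

    per_image = per_image_snr(feats)
    print(f"\nPer-image S/N spread: {per_image.groupby(feats.groupby('source_image').first()['group']).std().to_dict()}")

    summary = summarize_groups(feats)
    summary.to_csv(ROOT / "results" / "comparison.csv", index=False)
    print()
    print(render_report(summary, offset_distance=10, offset_angle=0))


if __name__ == "__main__":
    main()
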