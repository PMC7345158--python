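"""Render the synthetic two-phenotype study used by the downstream steps.

Writes 20 wild-type-like and 20 resistant-like monolayer images (300 x 300
px, master seed 1) plus labels.csv and a parameter manifest to
results/dataset/.  The wild-type preset is flat and smooth; the resistant
preset has rough speckled interiors and bright scattering rims.
"""

from pathlib import Path

from chemotex import generate_study, save_dataset, wt_preset, cp_preset

N_PER_GROUP = 20
SEED = 1
HEIGHT = WIDTH = 300
OUT = Path(__file__).resolve().parents[1] / "results" / "dataset"


def main() -> None:
    ds = generate_study(
        N_PER_GROUP,
        wt_params=wt_preset(HEIGHT, WIDTH),
        cp_params=cp_preset(HEIGHT, WIDTH),
        seed=SEED,
        height=HEIGHT,
        width=WIDTH,
    )
    out = save_dataset(ds, OUT)
    print(f"Wrote {len(ds.images)} images ({N_PER_GROUP} per phenotype, seed {SEED}) to {out}")
    wt, cp = ds.params_used["WT"], ds.params_used["CP"]
    print(f"WT preset: roughness {wt.roughness_amplitude}, halo {wt.halo_gain}")
    print(f"CP preset: roughness {cp.roughness_amplitude}, halo {cp.halo_gain}")


if __name__ == "__main__":
    main()
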