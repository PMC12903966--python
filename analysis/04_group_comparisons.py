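"""Treatment comparisons: ANOVA + Tukey letters for stocks, fractions, CUE, angle.

Writes results/summaries.csv and prints the compact letter display per depth.
The expected picture: active restoration separates from degraded for SOC
stock, POC and MAOC; passive restoration shares the degraded letters.
"""

from pathlib import Path

import pandas as pd

from stoichlim import (GeneratorConfig, RunConfig, augmented_cohort,
                       generate_cohort, group_compare, read_cohort, write_cohort)

OUT = Path(__file__).resolve().parents[1] / "results"
VARIABLES = ("soc_stock_kg_m2", "poc", "maoc", "cue_st", "angle_deg", "length")


def load_cohort():
    path = OUT / "cohort.csv"
    if not path.exists():
        OUT.mkdir(exist_ok=True)
        write_cohort(generate_cohort(GeneratorConfig()), path)
    return read_cohort(path)


def main() -> None:
    full = augmented_cohort(load_cohort(), RunConfig())
    frames = []
    for depth in ("0-15", "15-30"):
        print(f"\ndepth {depth} cm  (mean +/- SE, Tukey letters, % vs degraded)")
        for variable in VARIABLES:
            comp = group_compare(full, variable, depth=depth)
            frames.append(comp.summary)
            note = " [sqrt-transformed]" if comp.sqrt_transformed else ""
            print(f"  {variable} (ANOVA p = {comp.anova_p:.3g}){note}")
            for row in comp.summary.itertuples():
                print(f"    {row.treatment:9s} {row.mean:10.4g} +/- {row.se:.3g} "
                      f"[{row.letter_group}]  {row.pct_change_vs_degraded:+d}%")
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(OUT / "summaries.csv", index=False, float_format="%.6g")
    print(f"\nwrote {len(table)} summary rows to {OUT / 'summaries.csv'}")


if __name__ == "__main__":
    main()
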