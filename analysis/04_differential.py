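"""Differential abundance (volcano tables) and cohort demographics.

Per contrast, Welch two-sample t-tests on every protein with BH FDR
across the contrast's family; classification up/down at q < 0.05.  Also
the cohort demographic tests (χ² for sex, Kruskal–Wallis for age).
"""

import pathlib

import numpy as np

from npxbio import differential, npx_core

OUT = pathlib.Path(__file__).resolve().parents[1] / "results" / "analysis"
CONTRASTS = [("ISM", "AdvSM"), ("ISM", "PCV"), ("AdvSM", "PCV")]


def main() -> None:
    m = npx_core.read_npx_long(OUT / "npx_long.csv")
    m = npx_core.resolve_duplicate_assays(m)
    npx_core.flag_low_detection(m)
    info = npx_core.read_sample_info(OUT / "sample_info.csv")
    labels = np.array([s.diagnosis for s in info])

    demo = differential.compare_demographics(info)
    demo.to_json(OUT / "demographics.json", orient="records", indent=2)
    for _, row in demo.iterrows():
        print(f"demographics {row.variable}: {row.test} statistic "
              f"{row.statistic:.2f}, p = {row.p:.3g}")

    for a, b in CONTRASTS:
        results = differential.volcano_table(m, labels, a, b)
        frame = differential.volcano_frame(results)
        frame.to_csv(OUT / f"volcano_{a}_vs_{b}.csv", index=False)
        up2 = (frame["class"] == "up_in_group2").sum()
        up1 = (frame["class"] == "up_in_group1").sum()
        print(f"{a} vs {b}: {len(frame)} proteins tested, "
              f"{up2} up in {b}, {up1} up in {a} (q < 0.05)")


if __name__ == "__main__":
    main()
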