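"""Age-adjusted logistic biomarker models for ISM vs AdvSM.

Takes the five top-confirmed proteins from the selection stage (by mean
importance Z) and builds the exploratory biomarker table: per marker an
age-adjusted single model (β, SEM, OR per +1 NPX, 95% CI, Wald p,
in-sample C-index, ΔC vs the age-only model), plus cumulative
combinations with ΔC against the previous combination and the
likelihood-ratio test of each addition.
"""

import pathlib

import numpy as np
import pandas as pd

from npxbio import logit_models, npx_core

OUT = pathlib.Path(__file__).resolve().parents[1] / "results" / "analysis"


def main() -> None:
    chart = pd.read_csv(OUT / "boruta_ISM_vs_AdvSM.csv")
    markers = list(chart[chart.decision == "Confirmed"].feature.head(5))
    if not markers:
        print("no confirmed markers; nothing to model")
        return
    print(f"top confirmed markers (by mean Z): {markers}")

    data = pd.read_csv(OUT / "npx_imputed.csv", index_col=0)
    info = npx_core.read_sample_info(OUT / "sample_info.csv")
    by_id = {s.sample_id: s for s in info}
    labels = np.array([s.diagnosis for s in info])
    mask = (labels == "ISM") | (labels == "AdvSM")

    frame = data.loc[mask, markers].copy()
    frame["age"] = [by_id[sid].age for sid in frame.index]
    y = (labels[mask] == "ISM").astype(int)  # first-listed group = 1

    table = logit_models.stepwise_marker_table(
        y, frame, markers, outcome="ISM (vs AdvSM)"
    )
    table.to_csv(OUT / "logit_ISM_vs_AdvSM.csv", index=False)

    for _, row in table[table.type == "single"].iterrows():
        if row.get("converged", False):
            print(f"  {row.model}: OR {row.or_value:.3f} "
                  f"[{row.ci_low:.3f}, {row.ci_high:.3f}], C {row.c_index:.3f}")
        else:
            print(f"  {row.model}: did not converge (possible separation)")
    combined = table[table.type == "combined"]
    if not combined.empty:
        last = combined.iloc[-1]
        print(f"full combination C-index: {last.c_index:.3f}")


if __name__ == "__main__":
    main()
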