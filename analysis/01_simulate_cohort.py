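"""Simulate the study cohort.

Generates a synthetic plasma-proteomics cohort with the structure of the
mastocytosis study — 168 samples (CM 16, ISM 80, AdvSM 12, PCV 60),
three 92-assay panels with IL6 duplicated across two panels, below-LOD
censoring, ~1% missingness, 5 QC-failed-but-retained samples, older
AdvSM/PCV groups — plus a planted AdvSM signature (+1.5 NPX on 20
proteins) and a weaker PCV signature, so the downstream stages have
something to find.  Writes the long-format NPX CSV and the metadata CSV
under results/analysis/.
"""

import pathlib

from npxbio import npx_core
from npxbio.synthetic_data import CohortConfig, generate_cohort

OUT = pathlib.Path(__file__).resolve().parents[1] / "results" / "analysis"
SEED = 20240901

ADVSM_SIGNATURE = {(f"P{i:04d}", "AdvSM"): 1.5 for i in range(1, 21)}
PCV_SIGNATURE = {(f"P{i:04d}", "PCV"): -1.0 for i in range(30, 45)}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = CohortConfig(seed=SEED,
                          effect_table={**ADVSM_SIGNATURE, **PCV_SIGNATURE})
    matrix, info = generate_cohort(config)
    npx_core.write_npx_long(matrix, OUT / "npx_long.csv", seed=SEED)
    npx_core.write_sample_info(info, OUT / "sample_info.csv", seed=SEED)
    n_fail = sum(not s.qc_pass for s in info)
    print(f"simulated {matrix.n_samples} samples × {matrix.n_assays} assays "
          f"({n_fail} QC-fail, retained)")
    print(f"planted: +1.5 NPX on 20 proteins in AdvSM, -1.0 NPX on 15 in PCV")
    print(f"wrote {OUT/'npx_long.csv'} and {OUT/'sample_info.csv'}")


if __name__ == "__main__":
    main()
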