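"""Preprocess the NPX table.

Resolves the cross-panel duplicate (276 → 275 assays, keeping the copy
with less below-LOD censoring), flags assays with >20% of values below
LOD (retained, ‡), and completes missing values by iterative-PCA
imputation for the ordination stage.  Writes the deduplicated wide
matrix and the imputed matrix.
"""

import pathlib

from npxbio import npx_core

OUT = pathlib.Path(__file__).resolve().parents[1] / "results" / "analysis"


def main() -> None:
    m = npx_core.read_npx_long(OUT / "npx_long.csv")
    n_before = m.n_assays
    m = npx_core.resolve_duplicate_assays(m)
    flagged = npx_core.flag_low_detection(m)
    print(f"duplicate resolution: {n_before} → {m.n_assays} assays")
    print(f"‡ flagged (>20% below LOD, retained): {sorted(flagged)}")

    m.to_frame().to_csv(OUT / "npx_wide.csv")
    complete, converged = npx_core.impute_iterative_pca(m, ncp=2)
    print(f"iterative-PCA imputation (ncp=2) converged: {converged}")
    complete.to_frame().to_csv(OUT / "npx_imputed.csv")
    print(f"wrote {OUT/'npx_wide.csv'} and {OUT/'npx_imputed.csv'}")


if __name__ == "__main__":
    main()
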