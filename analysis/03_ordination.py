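"""PCA and permutation tests of group separation.

Runs prcomp-style PCA on the scaled, imputed 275-protein matrix, then,
for each pairwise contrast (ISM–AdvSM, ISM–PCV, AdvSM–PCV), refits PCA
on the two-group subset and tests the PC1/PC2 centroid distance against
a label-permutation null (9999 permutations, add-one p).  CM is carried
in the cohort-wide PCA but not contrasted.
"""

import json
import pathlib

import numpy as np
import pandas as pd

from npxbio import npx_core, ordination

OUT = pathlib.Path(__file__).resolve().parents[1] / "results" / "analysis"
CONTRASTS = [("ISM", "AdvSM"), ("ISM", "PCV"), ("AdvSM", "PCV")]
SEED = 77


def main() -> None:
    data = pd.read_csv(OUT / "npx_imputed.csv", index_col=0)
    info = npx_core.read_sample_info(OUT / "sample_info.csv")
    labels = np.array([s.diagnosis for s in info])

    model = ordination.run_pca(data)
    evr = model.explained_variance_ratio[:2]
    print(f"cohort PCA: PC1 {evr[0]:.1%}, PC2 {evr[1]:.1%} of variance")
    model.scores.iloc[:, :5].to_csv(OUT / "pca_scores.csv")

    results = {}
    for a, b in CONTRASTS:
        mask = (labels == a) | (labels == b)
        sub = ordination.run_pca(data.loc[mask])
        res = ordination.permutation_centroid_test(
            sub, labels[mask], a, b, n_perm=9999, dims=[1, 2], seed=SEED
        )
        results[f"{a}_vs_{b}"] = {
            "observed_distance": res.observed_distance,
            "p_value": res.p_value,
            "n_perm": res.n_perm,
        }
        print(f"{a} vs {b}: centroid distance {res.observed_distance:.2f} "
              f"(PC1/PC2), permutation p = {res.p_value:.4g}")

    with open(OUT / "permutation_tests.json", "w") as fh:
        json.dump(results, fh, indent=2)


if __name__ == "__main__":
    main()
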