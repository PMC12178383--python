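"""End-to-end orchestration: import → preprocessing → PCA/permutation →
volcano → shadow-feature selection → logistic table → single-cell linkage.

``run_full_analysis`` drives the whole workflow from one ``RunConfig``
and writes plain CSV/JSON artifacts plus a reproducibility manifest
(seeds, config hash, warnings, package versions).  CM samples are
carried through import and the cohort-wide PCA but excluded from the
default pairwise contrasts, which compare the systemic-mastocytosis
subtypes with each other and with the polycythemia-vera reference
group.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import boruta_select, differential, logit_models, npx_core, ordination
from .npx_core import NpxMatrix, SampleInfo
from .synthetic_data import CohortConfig, generate_cohort

logger = logging.getLogger(__name__)

DEFAULT_CONTRASTS = (("ISM", "AdvSM"), ("ISM", "PCV"), ("AdvSM", "PCV"))


@dataclass
class RunConfig:
    npx_path: str | None = None
    meta_path: str | None = None
    synthetic: CohortConfig | None = None
    sc_matrix_path: str | None = None
    sc_annotation_path: str | None = None
    contrasts: tuple[tuple[str, str], ...] = DEFAULT_CONTRASTS
    q_threshold: float = 0.05
    n_perm: int = 9999
    pca_dims: tuple[int, int] = (1, 2)
    impute_ncp: int = 2
    boruta_max_runs: int = 500
    boruta_alpha: float = 0.01
    rf_params: dict = field(default_factory=dict)
    marker_lists: dict[str, list[str]] = field(default_factory=dict)
    n_markers_logit: int = 5
    seed: int = 0

    def validate(self) -> None:
        vocab = set(npx_core.DIAGNOSES)
        for a, b in self.contrasts:
            if a not in vocab or b not in vocab:
                raise ValueError(f"contrast ({a}, {b}) not in {sorted(vocab)}")
        if self.npx_path is None and self.synthetic is None:
            raise ValueError("either input paths or a synthetic config is required")

    def content_hash(self) -> str:
        def canon(o):
            if isinstance(o, dict):
                return sorted((repr(k), canon(v)) for k, v in o.items())
            if isinstance(o, (list, tuple, set)):
                return sorted(map(canon, o)) if isinstance(o, set) else [canon(v) for v in o]
            return repr(o)

        blob = repr(canon(dataclasses.asdict(self)))
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_inputs(config: RunConfig) -> tuple[NpxMatrix, list[SampleInfo]]:
    if config.npx_path is not None:
        m = npx_core.read_npx_long(config.npx_path)
        info = npx_core.read_sample_info(config.meta_path)
        return m, info
    return generate_cohort(config.synthetic)


def run_full_analysis(config: RunConfig, out_dir: str) -> dict:
    """Run the whole workflow; returns the manifest (also written to
    ``out_dir/manifest.json``).  A stage failure preserves the artifacts
    produced so far and records the failed stage in the manifest."""
    config.validate()
    os.makedirs(out_dir, exist_ok=True)
    manifest: dict = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "stages": [],
        "warnings": [],
        "versions": _versions(),
    }
    rng = np.random.default_rng(config.seed)

    try:
        _run_stages(config, out_dir, manifest, rng)
    except Exception as exc:
        manifest["failed_stage"] = manifest["stages"][-1] if manifest["stages"] else "import"
        manifest["error"] = str(exc)
        logger.exception("pipeline failed")
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _run_stages(config: RunConfig, out_dir: str, manifest: dict, rng) -> None:
    manifest["stages"].append("import")
    m, info = _load_inputs(config)
    labels = np.array([s.diagnosis for s in info])
    n_qc_fail = sum(not s.qc_pass for s in info)
    if n_qc_fail:
        manifest["warnings"].append(f"{n_qc_fail} samples failed QC and were retained")

    manifest["stages"].append("preprocess")
    m = npx_core.resolve_duplicate_assays(m)
    flagged = npx_core.flag_low_detection(m)
    if flagged:
        manifest["warnings"].append(
            f"{len(flagged)} assays flagged >20% below LOD (retained): {sorted(flagged)[:10]}"
        )
    manifest["n_samples"] = m.n_samples
    manifest["n_assays"] = m.n_assays

    manifest["stages"].append("impute")
    m_complete, converged = npx_core.impute_iterative_pca(m, ncp=config.impute_ncp)
    if not converged:
        manifest["warnings"].append("iterative PCA imputation did not converge")

    manifest["stages"].append("demographics")
    differential.compare_demographics(info).to_json(
        os.path.join(out_dir, "demographics.json"), orient="records", indent=2
    )

    manifest["stages"].append("pca")
    data = m_complete.to_frame()
    model = ordination.run_pca(data)
    model.scores.iloc[:, :10].to_csv(os.path.join(out_dir, "pca_scores.csv"))

    for group_a, group_b in config.contrasts:
        tag = f"{group_a}_vs_{group_b}"
        manifest["stages"].append(f"permutation:{tag}")
        # refit PCA on the two-group subset (the pairwise score plot)
        pair_mask = (labels == group_a) | (labels == group_b)
        sub_model = ordination.run_pca(data.loc[pair_mask])
        perm = ordination.permutation_centroid_test(
            sub_model, labels[pair_mask], group_a, group_b,
            n_perm=config.n_perm, dims=list(config.pca_dims),
            seed=int(rng.integers(2**31 - 1)),
        )
        cents = ordination.group_centroids(sub_model, labels[pair_mask],
                                           list(config.pca_dims))
        with open(os.path.join(out_dir, f"permutation_{tag}.json"), "w") as fh:
            json.dump(
                {
                    "group_a": group_a, "group_b": group_b,
                    "observed_distance": perm.observed_distance,
                    "p_value": perm.p_value, "n_perm": perm.n_perm,
                    "dims": perm.dims,
                    "centroids": {g: list(map(float, c)) for g, c in cents.items()},
                },
                fh, indent=2,
            )

        manifest["stages"].append(f"volcano:{tag}")
        results = differential.volcano_table(m, labels, group_a, group_b,
                                             q_threshold=config.q_threshold)
        vframe = differential.volcano_frame(results)
        vframe.to_csv(os.path.join(out_dir, f"volcano_{tag}.csv"), index=False)

        manifest["stages"].append(f"boruta:{tag}")
        adjusted = boruta_select.residualize_covariates(m, info)
        fixed = boruta_select.roughfix_missing(adjusted)
        X = fixed.to_frame().loc[pair_mask]
        state = boruta_select.boruta(
            X, labels[pair_mask], max_runs=config.boruta_max_runs,
            alpha=config.boruta_alpha, rf_params=config.rf_params,
            seed=int(rng.integers(2**31 - 1)),
        )
        chart = boruta_select.importance_chart_table(state)
        chart.to_csv(os.path.join(out_dir, f"boruta_{tag}.csv"), index=False)
        qmap = dict(zip(vframe["assay"], vframe["q"]))
        boruta_select.cleveland_summary(
            npx_core.subset_samples(m, list(np.array(m.sample_ids)[pair_mask])),
            labels[pair_mask], state.confirmed, qmap,
        ).to_csv(os.path.join(out_dir, f"cleveland_{tag}.csv"), index=False)

        manifest["stages"].append(f"logit:{tag}")
        markers = config.marker_lists.get(tag)
        if markers is None:
            ranked = chart[chart["decision"] == boruta_select.CONFIRMED]
            markers = list(ranked["feature"].head(config.n_markers_logit))
        if markers:
            by_id = {s.sample_id: s for s in info}
            frame = m_complete.to_frame().loc[pair_mask].copy()
            frame["age"] = [by_id[sid].age for sid in frame.index]
            y = (labels[pair_mask] == group_a).astype(int)
            table = logit_models.stepwise_marker_table(
                y, frame, markers, outcome=f"{group_a} (vs {group_b})"
            )
            table.to_csv(os.path.join(out_dir, f"logit_{tag}.csv"), index=False)
        else:
            manifest["warnings"].append(f"no confirmed markers for {tag}; logit skipped")

    if config.sc_matrix_path:
        manifest["stages"].append("sc_linkage")
        from . import sc_linkage

        expr, cell_labels = sc_linkage.read_annotated_expression(
            config.sc_matrix_path, config.sc_annotation_path
        )
        summary = sc_linkage.celltype_dot_stats(expr, cell_labels)
        summary.mean_expression.to_csv(os.path.join(out_dir, "sc_mean_expression.csv"))
        summary.z_mean.to_csv(os.path.join(out_dir, "sc_z_mean.csv"))
        summary.pct_expressing.to_csv(os.path.join(out_dir, "sc_pct_expressing.csv"))

    manifest["stages"].append("done")


def _versions() -> dict:
    import numpy
    import pandas
    import scipy
    import sklearn
    import statsmodels

    return {
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "scikit-learn": sklearn.__version__,
        "statsmodels": statsmodels.__version__,
    }
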