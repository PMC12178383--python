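"""Synthetic NPX cohorts and annotated single-cell matrices.

The cohort generator emulates the statistical structure of a targeted
plasma-proteomics case–control study of mastocytosis subtypes: four
diagnosis groups (CM, ISM, AdvSM, and a polycythemia-vera reference
group, default sizes 16/80/12/60), three 92-assay panels with one
protein duplicated across two panels, Gaussian baseline NPX on the log2
scale with per-(assay, group) mean shifts, below-LOD censoring flags,
MCAR missingness, a handful of QC-failed-but-retained samples, and
age/sex distributions that confound diagnosis with age (the advanced
and reference groups are older).

The single-cell generator emulates a normalized, log-transformed bone
marrow mononuclear-cell expression matrix with annotated cell types and
planted marker genes, for exercising the dot-plot summarization stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .npx_core import AssayDefinition, NpxMatrix, SampleInfo

DEFAULT_GROUP_SIZES = {"CM": 16, "ISM": 80, "AdvSM": 12, "PCV": 60}

# median, min, max in years (older advanced/reference groups confound age)
DEFAULT_AGE_PARAMS = {
    "CM": (45.0, 24.0, 78.0),
    "ISM": (59.0, 25.0, 89.0),
    "AdvSM": (72.0, 49.0, 76.0),
    "PCV": (72.0, 34.0, 90.0),
}

# fraction female per group
DEFAULT_SEX_RATIO = {"CM": 9 / 16, "ISM": 54 / 80, "AdvSM": 5 / 12, "PCV": 39 / 60}

DEFAULT_PANELS = ("CardioII", "CardioIII", "ImmuneResponse")


class ConfigError(ValueError):
    """A generator configuration field is invalid."""


@dataclass
class CohortConfig:
    """Parameters of one synthetic NPX cohort.

    ``effect_table`` maps ``(assay, diagnosis)`` to an additive mean
    shift in NPX units on top of the assay's baseline mean.
    ``lod_quantile`` places each assay's LOD at that quantile of its
    baseline Gaussian, so roughly that fraction of unshifted values
    falls below LOD.  Heavier per-assay censoring (for exercising the
    >20% ‡ rule) is set via ``censored_assays``.
    """

    group_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    n_panels: int = 3
    assays_per_panel: int = 92
    duplicated_assay: str = "IL6"
    effect_table: dict[tuple[str, str], float] = field(default_factory=dict)
    baseline_mean_sd: tuple[float, float] = (5.0, 1.0)
    lod_quantile: float = 0.02
    censored_assays: dict[str, float] = field(
        default_factory=lambda: {"P0012": 0.30, "P0120": 0.25}
    )
    missing_rate: float = 0.01
    qc_fail_count: int = 5
    age_params: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_AGE_PARAMS)
    )
    sex_ratio: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SEX_RATIO))
    correlation_block: tuple[list[str], float] | None = None
    seed: int = 0

    def validate(self) -> None:
        for g, n in self.group_sizes.items():
            if n < 1:
                raise ConfigError(f"group_sizes[{g!r}] must be >= 1, got {n}")
        if self.n_panels < 1:
            raise ConfigError("n_panels must be >= 1")
        if self.assays_per_panel < 1:
            raise ConfigError("assays_per_panel must be >= 1")
        for key, shift in self.effect_table.items():
            if not np.isfinite(shift):
                raise ConfigError(f"effect_table[{key!r}] must be finite")
        if not 0 <= self.lod_quantile < 1:
            raise ConfigError("lod_quantile must be in [0, 1)")
        for name, q in self.censored_assays.items():
            if not 0 <= q < 1:
                raise ConfigError(f"censored_assays[{name!r}] must be in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ConfigError("missing_rate must be in [0, 1)")
        if self.qc_fail_count < 0:
            raise ConfigError("qc_fail_count must be >= 0")
        if self.qc_fail_count > sum(self.group_sizes.values()):
            raise ConfigError("qc_fail_count exceeds the cohort size")
        for g, (med, lo, hi) in self.age_params.items():
            if not (0 < lo <= med <= hi):
                raise ConfigError(f"age_params[{g!r}] must satisfy 0 < min <= median <= max")
        for g, f in self.sex_ratio.items():
            if not 0 <= f <= 1:
                raise ConfigError(f"sex_ratio[{g!r}] must be in [0, 1]")


def _panel_names(n_panels: int) -> list[str]:
    names = list(DEFAULT_PANELS[:n_panels])
    while len(names) < n_panels:
        names.append(f"Panel{len(names) + 1}")
    return names


def make_assay_definitions(config: CohortConfig) -> list[AssayDefinition]:
    """Panel manifest: ``n_panels × assays_per_panel`` assays with the
    duplicated protein present on the first two panels (when n_panels >= 2)."""
    panels = _panel_names(config.n_panels)
    assays: list[AssayDefinition] = []
    counter = 0
    for pi, panel in enumerate(panels):
        for k in range(config.assays_per_panel):
            dup_slot = k == 0 and pi in (0, 1) and config.n_panels >= 2
            if dup_slot:
                name = config.duplicated_assay
            else:
                counter += 1
                name = f"P{counter:04d}"
            assays.append(AssayDefinition(name=name, panel=panel))
    return assays


def _triangular_ages(rng, med: float, lo: float, hi: float, n: int) -> np.ndarray:
    if lo == hi:
        return np.full(n, lo)
    return rng.triangular(lo, med, hi, size=n)


def generate_cohort(config: CohortConfig) -> tuple[NpxMatrix, list[SampleInfo]]:
    """Draw one synthetic cohort.

    NPX values are baseline Gaussian (per-assay mean drawn once from
    ``baseline_mean_sd``, unit SD) plus the configured group shifts.
    Values below an assay's LOD are retained but flagged.  Missingness
    is MCAR at ``missing_rate``.  Exactly ``qc_fail_count`` samples are
    marked QC-fail but kept.  The two copies of the duplicated assay are
    guaranteed to differ in below-LOD fraction: the second panel's copy
    is censored at a strictly higher quantile, so the resolver must drop
    it.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    assays = make_assay_definitions(config)
    n_assays = len(assays)

    groups = list(config.group_sizes)
    labels = [g for g in groups for _ in range(config.group_sizes[g])]
    n = len(labels)
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]

    base_mu, base_sd = config.baseline_mean_sd
    assay_means = rng.normal(base_mu, base_sd, size=n_assays)
    X = assay_means[None, :] + rng.standard_normal((n, n_assays))

    if config.correlation_block is not None:
        block_names, rho = config.correlation_block
        cols = [j for j, a in enumerate(assays) if a.name in set(block_names)]
        if cols:
            shared = rng.standard_normal(n)
            w = np.sqrt(max(min(rho, 0.999), 0.0))
            for j in cols:
                X[:, j] = assay_means[j] + w * shared + np.sqrt(1 - w**2) * (
                    X[:, j] - assay_means[j]
                )

    for (assay_name, diag), shift in config.effect_table.items():
        cols = [j for j, a in enumerate(assays) if a.name == assay_name]
        if not cols:
            raise ConfigError(f"effect_table names unknown assay {assay_name!r}")
        if diag not in config.group_sizes:
            raise ConfigError(f"effect_table names unknown diagnosis {diag!r}")
        rows = [i for i, g in enumerate(labels) if g == diag]
        for j in cols:
            X[np.ix_(rows, [j])] += shift

    # per-assay LOD from the baseline distribution; duplicated assay's
    # second copy censored strictly harder so the resolver has a target
    from scipy.stats import norm

    lod_q = np.full(n_assays, config.lod_quantile)
    seen_dup = False
    for j, a in enumerate(assays):
        if a.name in config.censored_assays:
            lod_q[j] = config.censored_assays[a.name]
        if a.name == config.duplicated_assay:
            if seen_dup:
                lod_q[j] = max(0.30, min(0.95, lod_q[j] + 0.25))
            seen_dup = True
    with np.errstate(divide="ignore"):
        lods = np.where(
            lod_q > 0, assay_means + norm.ppf(lod_q), -np.inf
        )
    assays = [
        AssayDefinition(name=a.name, panel=a.panel, lod=float(lods[j]))
        for j, a in enumerate(assays)
    ]
    below = X < lods[None, :]

    miss = rng.random((n, n_assays)) < config.missing_rate
    X = np.where(miss, np.nan, X)
    below &= ~miss

    qc_fail = set(rng.choice(n, size=config.qc_fail_count, replace=False).tolist())
    info = []
    for g in groups:
        rows = [i for i, lab in enumerate(labels) if lab == g]
        med, lo, hi = config.age_params.get(g, (60.0, 20.0, 90.0))
        ages = _triangular_ages(rng, med, lo, hi, len(rows))
        frac_f = config.sex_ratio.get(g, 0.5)
        sexes = np.where(rng.random(len(rows)) < frac_f, "F", "M")
        for r, age, sex in zip(rows, ages, sexes):
            info.append(
                SampleInfo(
                    sample_id=sample_ids[r],
                    diagnosis=g,
                    age=float(age),
                    sex=str(sex),
                    qc_pass=r not in qc_fail,
                )
            )
    info.sort(key=lambda s: s.sample_id)

    matrix = NpxMatrix(
        assays=assays,
        values=pd.DataFrame(X, index=pd.Index(sample_ids, name="SampleID")),
        below_lod=pd.DataFrame(below, index=pd.Index(sample_ids, name="SampleID")),
    )
    return matrix, info


@dataclass
class SingleCellConfig:
    """Parameters of one synthetic annotated single-cell matrix.

    ``marker_plan`` maps gene name → (cell type, fold elevation of mean
    expression in that type).  Expression is on a non-negative
    normalized-log-like scale; ``dropout_rate`` zeroes entries at random.
    """

    cell_types: list[str] = field(
        default_factory=lambda: [
            "mast cells", "basophils", "monocytes", "neutrophils",
            "NK/T cells", "B cells/progenitors",
        ]
    )
    cells_per_type: int = 50
    n_genes: int = 30
    marker_plan: dict[str, tuple[str, float]] = field(default_factory=dict)
    dropout_rate: float = 0.3
    base_mean: float = 0.5
    seed: int = 0

    def gene_names(self) -> list[str]:
        planted = list(self.marker_plan)
        fillers = [f"G{k + 1:03d}" for k in range(self.n_genes - len(planted))]
        return planted + fillers

    def validate(self) -> None:
        if self.cells_per_type < 1:
            raise ConfigError("cells_per_type must be >= 1")
        if len(self.marker_plan) > self.n_genes:
            raise ConfigError("more marker genes than n_genes")
        for gene, (ct, fold) in self.marker_plan.items():
            if ct not in self.cell_types:
                raise ConfigError(f"marker {gene!r} targets unknown cell type {ct!r}")
            if fold <= 0:
                raise ConfigError(f"marker {gene!r} fold must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise ConfigError("dropout_rate must be in [0, 1)")


def generate_single_cell(config: SingleCellConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Draw a genes × cells expression matrix plus a cell-type label vector.

    Non-marker expression is exponential with mean ``base_mean``;
    a planted marker's mean is multiplied by its fold in its designated
    cell type.  Dropout zeros are injected independently at
    ``dropout_rate``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = config.gene_names()
    labels = [ct for ct in config.cell_types for _ in range(config.cells_per_type)]
    n_cells = len(labels)
    barcodes = [f"cell{c + 1:04d}" for c in range(n_cells)]

    mean = np.full((len(genes), n_cells), config.base_mean)
    for gi, gene in enumerate(genes):
        plan = config.marker_plan.get(gene)
        if plan is None:
            continue
        ct, fold = plan
        cols = [c for c, lab in enumerate(labels) if lab == ct]
        mean[gi, cols] *= fold

    expr = rng.exponential(mean)
    expr[rng.random(expr.shape) < config.dropout_rate] = 0.0

    matrix = pd.DataFrame(expr, index=pd.Index(genes, name="gene"),
                          columns=pd.Index(barcodes, name="barcode"))
    return matrix, pd.Series(labels, index=matrix.columns, name="cell_type")


def write_single_cell_dense(matrix: pd.DataFrame, labels: pd.Series,
                            matrix_path, annotation_path) -> None:
    """Write a dense genes × cells CSV and a barcode→cell-type TSV."""
    matrix.to_csv(matrix_path)
    labels.rename("cell_type").to_csv(annotation_path, sep="\t",
                                      index_label="barcode")


def write_single_cell_mtx(matrix: pd.DataFrame, labels: pd.Series, out_dir) -> None:
    """Write MatrixMarket triplet files (matrix.mtx, genes.tsv, barcodes.tsv)
    plus the annotation TSV, mirroring the usual 10x-style layout."""
    import os

    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    os.makedirs(out_dir, exist_ok=True)
    mmwrite(os.path.join(out_dir, "matrix.mtx"), csr_matrix(matrix.to_numpy()))
    with open(os.path.join(out_dir, "genes.tsv"), "w") as fh:
        fh.write("\n".join(matrix.index) + "\n")
    with open(os.path.join(out_dir, "barcodes.tsv"), "w") as fh:
        fh.write("\n".join(matrix.columns) + "\n")
    labels.rename("cell_type").to_csv(
        os.path.join(out_dir, "annotation.tsv"), sep="\t", index_label="barcode"
    )
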