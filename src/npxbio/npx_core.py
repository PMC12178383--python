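"""Data model, I/O and preprocessing for Olink-style NPX protein panels.

NPX (Normalized Protein eXpression) is a relative abundance unit on the
log2 scale: a difference of +1 NPX corresponds roughly to a doubling of
plasma concentration.  The preprocessing rules implemented here are the
conservative ones used in targeted-panel biomarker studies:

* a protein assayed on more than one panel is deduplicated by keeping the
  copy with the smaller fraction of below-LOD values;
* assays with >20% of values below the limit of detection are flagged
  (the "‡" set) but their values are retained as reported;
* samples with QC warnings are flagged, never dropped;
* missing values are completed, when a complete matrix is required, by
  iterative (EM) PCA imputation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DIAGNOSES = ("CM", "ISM", "AdvSM", "PCV")

NPX_LONG_COLUMNS = ("SampleID", "Assay", "Panel", "NPX", "BelowLOD", "QC_Warning")


class NpxParseError(ValueError):
    """Raised when an NPX CSV cannot be interpreted."""


@dataclass(frozen=True)
class AssayDefinition:
    """One targeted protein assay: short protein name, panel, and its LOD (NPX units)."""

    name: str
    panel: str
    lod: float = float("-inf")

    def __post_init__(self) -> None:
        if not np.isfinite(self.lod) and self.lod != float("-inf"):
            raise ValueError(f"LOD for assay {self.name!r} must be finite or -inf")


@dataclass(frozen=True)
class SampleInfo:
    """Per-sample metadata: diagnosis, age (years), sex, QC status."""

    sample_id: str
    diagnosis: str
    age: float
    sex: str
    qc_pass: bool = True

    def __post_init__(self) -> None:
        if self.diagnosis not in DIAGNOSES:
            raise ValueError(
                f"diagnosis {self.diagnosis!r} not in {DIAGNOSES} (sample {self.sample_id})"
            )
        if not self.age > 0:
            raise ValueError(f"age must be positive (sample {self.sample_id})")
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M' (sample {self.sample_id})")


@dataclass
class NpxMatrix:
    """Samples × assays NPX table with missingness and below-LOD masks.

    ``values`` is a DataFrame indexed by sample ID; its columns are
    positional (one per entry of ``assays``) and NaN marks a missing
    measurement.  ``below_lod`` is a boolean mask of identical shape;
    missing entries are never below-LOD-flagged.
    """

    assays: list[AssayDefinition]
    values: pd.DataFrame
    below_lod: pd.DataFrame
    low_detection_flagged: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.values.shape != self.below_lod.shape:
            raise ValueError("values and below_lod must have identical shape")
        if self.values.shape[1] != len(self.assays):
            raise ValueError("number of assay definitions must match the column count")
        if bool((self.below_lod.to_numpy() & self.values.isna().to_numpy()).any()):
            raise ValueError("missing entries cannot carry a below-LOD flag")
        names = [(a.name, a.panel) for a in self.assays]
        if len(set(names)) != len(names):
            raise ValueError("(name, panel) pairs must be unique")
        unknown = self.low_detection_flagged - {a.name for a in self.assays}
        if unknown:
            raise ValueError(f"flagged assays not present in matrix: {sorted(unknown)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def assay_names(self) -> list[str]:
        return [a.name for a in self.assays]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_assays(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "NpxMatrix":
        return NpxMatrix(
            assays=list(self.assays),
            values=self.values.copy(),
            below_lod=self.below_lod.copy(),
            low_detection_flagged=set(self.low_detection_flagged),
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame with unique assay names as columns.

        Valid only after duplicate resolution (unique names).
        """
        names = self.assay_names
        if len(set(names)) != len(names):
            raise ValueError("assay names are not unique; resolve duplicates first")
        out = self.values.copy()
        out.columns = names
        return out


def _as_bool(series: pd.Series, column: str) -> pd.Series:
    if series.dtype == bool:
        return series
    mapping = {
        "true": True, "false": False, "1": True, "0": False,
        "yes": True, "no": False, "pass": False, "warn": True, "fail": True,
    }
    out = series.astype(str).str.strip().str.lower().map(mapping)
    if out.isna().any():
        bad = series[out.isna()].iloc[0]
        raise NpxParseError(f"cannot interpret {column} value {bad!r} as boolean")
    return out.astype(bool)


def read_npx_long(path) -> NpxMatrix:
    """Read a long-format NPX CSV into a wide :class:`NpxMatrix`.

    Expected columns: SampleID, Assay, Panel, NPX, and either BelowLOD
    (boolean) or LOD (numeric, per-assay; the flag is derived as
    NPX < LOD).  A QC_Warning column, if present, is ignored here — QC
    status lives in the sample metadata (see :func:`read_sample_info`).
    (Sample, assay) pairs absent from the file become missing cells.
    """
    df = pd.read_csv(path, comment="#")
    required = {"SampleID", "Assay", "Panel", "NPX"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise NpxParseError(f"missing required columns: {sorted(missing_cols)}")
    known = required | {"BelowLOD", "LOD", "QC_Warning"}
    unknown = set(df.columns) - known
    if unknown:
        raise NpxParseError(f"unknown columns: {sorted(unknown)}")
    if "BelowLOD" not in df.columns and "LOD" not in df.columns:
        raise NpxParseError("need a BelowLOD or LOD column")

    dup = df.duplicated(subset=["SampleID", "Assay", "Panel"], keep=False)
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0]) + 2  # 1-based + header
        raise NpxParseError(f"duplicate (sample, assay, panel) row at line {row}")

    df = df.copy()
    df["SampleID"] = df["SampleID"].astype(str)
    if "BelowLOD" in df.columns:
        df["BelowLOD"] = _as_bool(df["BelowLOD"], "BelowLOD")
    else:
        df["BelowLOD"] = df["NPX"] < df["LOD"].astype(float)

    # preserve first-appearance order of samples and (assay, panel) pairs
    sample_ids = list(dict.fromkeys(df["SampleID"]))
    pairs = list(dict.fromkeys(zip(df["Assay"], df["Panel"])))
    lods: dict[tuple[str, str], float] = {}
    if "LOD" in df.columns:
        lods = df.groupby(["Assay", "Panel"])["LOD"].first().to_dict()
    assays = [
        AssayDefinition(name=a, panel=p, lod=float(lods.get((a, p), float("-inf"))))
        for a, p in pairs
    ]

    col_of = {pair: j for j, pair in enumerate(pairs)}
    row_of = {s: i for i, s in enumerate(sample_ids)}
    values = np.full((len(sample_ids), len(pairs)), np.nan)
    below = np.zeros_like(values, dtype=bool)
    rows = df["SampleID"].map(row_of).to_numpy()
    cols = [col_of[pair] for pair in zip(df["Assay"], df["Panel"])]
    values[rows, cols] = df["NPX"].to_numpy(dtype=float)
    below[rows, cols] = df["BelowLOD"].to_numpy()
    below &= ~np.isnan(values)

    return NpxMatrix(
        assays=assays,
        values=pd.DataFrame(values, index=pd.Index(sample_ids, name="SampleID")),
        below_lod=pd.DataFrame(below, index=pd.Index(sample_ids, name="SampleID")),
    )


def read_npx_wide(path) -> NpxMatrix:
    """Read a wide NPX CSV (first column SampleID, assay names as columns).

    The wide dialect carries no panel or LOD information; all assays get
    panel ``"wide"`` and an empty below-LOD mask.
    """
    df = pd.read_csv(path, comment="#", index_col=0)
    df.index = df.index.astype(str)
    assays = [AssayDefinition(name=str(c), panel="wide") for c in df.columns]
    values = df.astype(float)
    values.columns = range(len(assays))
    below = pd.DataFrame(False, index=values.index, columns=values.columns)
    return NpxMatrix(assays=assays, values=values, below_lod=below)


def write_npx_long(m: NpxMatrix, path, seed: int | None = None) -> None:
    """Write the canonical long-format CSV (round-trips with read_npx_long)."""
    records = []
    vals = m.values.to_numpy()
    below = m.below_lod.to_numpy()
    for i, sid in enumerate(m.sample_ids):
        for j, assay in enumerate(m.assays):
            if np.isnan(vals[i, j]):
                continue
            records.append((sid, assay.name, assay.panel, vals[i, j], below[i, j]))
    out = pd.DataFrame.from_records(
        records, columns=["SampleID", "Assay", "Panel", "NPX", "BelowLOD"]
    )
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        out.to_csv(fh, index=False)


def read_sample_info(path) -> list[SampleInfo]:
    """Read the metadata CSV: SampleID, Diagnosis, Age, Sex, QC_Pass."""
    df = pd.read_csv(path, comment="#")
    required = {"SampleID", "Diagnosis", "Age", "Sex"}
    missing = required - set(df.columns)
    if missing:
        raise NpxParseError(f"metadata missing columns: {sorted(missing)}")
    qc = (
        _as_bool(df["QC_Pass"], "QC_Pass")
        if "QC_Pass" in df.columns
        else pd.Series(True, index=df.index)
    )
    return [
        SampleInfo(
            sample_id=str(r.SampleID),
            diagnosis=str(r.Diagnosis),
            age=float(r.Age),
            sex=str(r.Sex),
            qc_pass=bool(q),
        )
        for r, q in zip(df.itertuples(index=False), qc)
    ]


def write_sample_info(info: list[SampleInfo], path, seed: int | None = None) -> None:
    out = pd.DataFrame(
        {
            "SampleID": [s.sample_id for s in info],
            "Diagnosis": [s.diagnosis for s in info],
            "Age": [s.age for s in info],
            "Sex": [s.sex for s in info],
            "QC_Pass": [s.qc_pass for s in info],
        }
    )
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        out.to_csv(fh, index=False)


def resolve_duplicate_assays(m: NpxMatrix) -> NpxMatrix:
    """Deduplicate proteins measured on more than one panel.

    For each assay name appearing on multiple panels, the copy with the
    smaller fraction of below-LOD values (over non-missing entries) is
    kept and the others are dropped.  An exact tie keeps the copy from
    the lexicographically first panel, with a warning.
    """
    by_name: dict[str, list[int]] = {}
    for j, a in enumerate(m.assays):
        by_name.setdefault(a.name, []).append(j)

    keep: list[int] = []
    for name, cols in by_name.items():
        if len(cols) == 1:
            keep.append(cols[0])
            continue
        fracs = []
        for j in cols:
            obs = m.values.iloc[:, j].notna().to_numpy()
            n_obs = int(obs.sum())
            frac = m.below_lod.iloc[:, j].to_numpy()[obs].mean() if n_obs else 1.0
            fracs.append((frac, m.assays[j].panel, j))
        fracs.sort()
        if len(fracs) > 1 and fracs[0][0] == fracs[1][0]:
            logger.warning(
                "assay %s: below-LOD fractions tie; keeping panel %s",
                name, fracs[0][1],
            )
        keep.append(fracs[0][2])
        for frac, panel, j in fracs[1:]:
            logger.info(
                "dropping duplicate assay %s from panel %s (below-LOD %.3f > %.3f)",
                name, panel, frac, fracs[0][0],
            )

    keep.sort()
    values = m.values.iloc[:, keep].copy()
    below = m.below_lod.iloc[:, keep].copy()
    values.columns = range(len(keep))
    below.columns = range(len(keep))
    return NpxMatrix(
        assays=[m.assays[j] for j in keep],
        values=values,
        below_lod=below,
        low_detection_flagged=set(m.low_detection_flagged),
    )


def flag_low_detection(m: NpxMatrix, threshold: float = 0.20) -> set[str]:
    """Return assays with a below-LOD fraction strictly above ``threshold``.

    The fraction is taken over non-missing values.  The flagged set is
    also stored on the matrix (``low_detection_flagged``, the ‡ set);
    the values themselves are kept untouched.
    """
    flagged: set[str] = set()
    vals = m.values.to_numpy()
    below = m.below_lod.to_numpy()
    for j, assay in enumerate(m.assays):
        obs = ~np.isnan(vals[:, j])
        if not obs.any():
            logger.warning("assay %s has no observed values; not flagged", assay.name)
            continue
        if below[obs, j].mean() > threshold:
            flagged.add(assay.name)
    m.low_detection_flagged = flagged
    return flagged


def impute_iterative_pca(
    m: NpxMatrix,
    ncp: int = 2,
    max_iter: int = 1000,
    tol: float = 1e-12,
    scale: bool = True,
    regularized: bool = False,
) -> tuple[NpxMatrix, bool]:
    """Complete a matrix by iterative (EM) PCA imputation.

    Missing cells are initialised with column means and then repeatedly
    overwritten by a rank-``ncp`` SVD reconstruction of the
    centred (and optionally unit-scaled) completed matrix, until the sum
    of squared change in the imputed cells falls below ``tol``.  Observed
    cells are never altered.  With ``regularized=True`` the reconstruction
    shrinks each retained singular value toward the mean residual
    variance, trading bias for stability on noisy data.

    Returns the completed matrix and a convergence flag.
    """
    if ncp < 1:
        raise ValueError("ncp must be >= 1")
    X = m.values.to_numpy(dtype=float).copy()
    miss = np.isnan(X)
    if not miss.any():
        return m.copy(), True

    n, p = X.shape
    if np.isnan(X).all(axis=0).any():
        bad = m.assay_names[int(np.flatnonzero(np.isnan(X).all(axis=0))[0])]
        raise ValueError(f"assay {bad!r} has no observed values; cannot impute")

    col_means = np.nanmean(X, axis=0)
    X[miss] = np.take(col_means, np.nonzero(miss)[1])

    converged = False
    for _ in range(max_iter):
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1) if scale else np.ones(p)
        sd = np.where(sd > 0, sd, 1.0)
        Z = (X - mu) / sd
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        if regularized and len(s) > ncp:
            sigma2 = float(np.mean(s[ncp:] ** 2)) / max(n * p - 1, 1)
            shrink = np.maximum(s[:ncp] - n * sigma2 / np.maximum(s[:ncp], 1e-12), 0.0)
        else:
            shrink = s[:ncp]
        recon = (U[:, :ncp] * shrink) @ Vt[:ncp] * sd + mu
        delta = float(np.sum((recon[miss] - X[miss]) ** 2))
        X[miss] = recon[miss]
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn("iterative PCA imputation did not converge", RuntimeWarning)

    out = m.copy()
    out.values = pd.DataFrame(X, index=m.values.index, columns=m.values.columns)
    return out, converged


def subset_samples(m: NpxMatrix, sample_ids: list[str]) -> NpxMatrix:
    """Restrict the matrix to the given samples, preserving their order."""
    values = m.values.loc[sample_ids]
    below = m.below_lod.loc[sample_ids]
    return NpxMatrix(
        assays=list(m.assays),
        values=values.copy(),
        below_lod=below.copy(),
        low_detection_flagged=set(m.low_detection_flagged),
    )
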