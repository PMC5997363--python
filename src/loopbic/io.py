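"""Delimited-text readers/writers, synthetic fixtures, and run reports.

The canonical interchange is tab-separated text: the data matrix has column
identifiers in the header and patient identifiers in the first column; the
label and covariate tables are keyed by the same patient identifiers. All
readers align by identifier and report mismatches by name.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import derive_rng
from .corrections import CategoricalDesign, ContinuousCovariates
from .planted import _planted_block
from .preprocess import RawMatrix, SignMatrix

__all__ = [
    "write_matrix",
    "read_matrix",
    "write_labels",
    "read_labels",
    "write_covariates",
    "read_covariates",
    "read_dataset",
    "generate_fixture",
    "write_run_report",
]

ID_COL = "id"


def write_matrix(path, matrix) -> None:
    """Write a matrix as TSV: header of column ids, first column patient ids."""
    vals = np.asarray(matrix.values if hasattr(matrix, "values") else matrix)
    rids = getattr(matrix, "row_ids", None) or [f"p{i}" for i in range(vals.shape[0])]
    cids = getattr(matrix, "col_ids", None) or [f"g{i}" for i in range(vals.shape[1])]
    df = pd.DataFrame(vals, index=pd.Index(rids, name=ID_COL), columns=cids)
    df.to_csv(path, sep="\t")


def read_matrix(path) -> RawMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate patient ids in {path}: {dups}")
    try:
        vals = df.to_numpy(dtype=np.float64)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cells in {path}: {exc}") from None
    return RawMatrix(vals, [str(i) for i in df.index], [str(c) for c in df.columns])


def write_labels(path, row_ids, labels, categories=None) -> None:
    """Write a per-patient table with a ``label`` column (case/control) and an
    optional ``category`` column."""
    df = pd.DataFrame({"label": list(labels)}, index=pd.Index(row_ids, name=ID_COL))
    if categories is not None:
        df["category"] = list(categories)
    df.to_csv(path, sep="\t")


def read_labels(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    if "label" not in df.columns:
        raise ValueError(f"labels file {path} must have a 'label' column")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate patient ids in {path}: {dups}")
    return df


def write_covariates(path, row_ids, T) -> None:
    T = np.asarray(T, dtype=np.float64)
    cols = [f"t{t}" for t in range(T.shape[1])]
    pd.DataFrame(T, index=pd.Index(row_ids, name=ID_COL), columns=cols).to_csv(path, sep="\t")


def read_covariates(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    try:
        df.astype(np.float64)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric covariates in {path}: {exc}") from None
    return df


def _align(ids_matrix: list[str], ids_table, what: str, path) -> np.ndarray:
    missing = [i for i in ids_matrix if i not in set(ids_table)]
    extra = [i for i in ids_table if i not in set(ids_matrix)]
    if missing or extra:
        parts = []
        if missing:
            parts.append(f"ids missing from {what}: {missing[:10]}")
        if extra:
            parts.append(f"ids in {what} absent from the matrix: {extra[:10]}")
        raise ValueError(f"{path}: " + "; ".join(parts))
    pos = {i: k for k, i in enumerate(ids_table)}
    return np.array([pos[i] for i in ids_matrix])


def read_dataset(matrix_path, labels_path=None, covariates_path=None):
    """Read and align a matrix, optional labels, and optional covariates.

    Returns (RawMatrix, labels array | None, CategoricalDesign | None,
    ContinuousCovariates | None), everything row-aligned to the matrix.
    Mismatched or duplicate identifiers raise errors naming the offenders.
    """
    mat = read_matrix(matrix_path)
    labels = design = cov = None
    if labels_path is not None:
        lab = read_labels(labels_path)
        order = _align(mat.row_ids, list(lab.index), "labels", labels_path)
        labels = lab["label"].to_numpy()[order]
        if "category" in lab.columns:
            design = CategoricalDesign(lab["category"].to_numpy()[order])
    if covariates_path is not None:
        cv = read_covariates(covariates_path)
        order = _align(mat.row_ids, list(cv.index), "covariates", covariates_path)
        cov = ContinuousCovariates(cv.to_numpy(dtype=np.float64)[order])
    return mat, labels, design, cov


# ------------------------------------------------------------------ fixtures


def _fixture_params(scenario: str) -> dict:
    if scenario == "example_a_mini":
        return dict(m_case=120, m_ctrl=60, n=600, m_b=20, n_b=80, l=1, epsilon=0.0,
                    covariates=True, sparsity=False)
    if scenario == "null":
        return dict(m_case=60, m_ctrl=30, n=200, m_b=0, n_b=0, l=1, epsilon=0.0,
                    covariates=True, sparsity=False)
    if scenario == "gwas_mini":
        return dict(m_case=80, m_ctrl=40, n=300, m_b=16, n_b=40, l=1, epsilon=0.0,
                    covariates=True, sparsity=True)
    raise ValueError(f"unknown scenario {scenario!r}; "
                     "choose from example_a_mini, null, gwas_mini")


def generate_fixture(scenario: str, outdir, seed: int = 0) -> dict:
    """Write a synthetic case/control dataset with a planted case-specific
    bicluster (scenarios ``example_a_mini``, ``gwas_mini``) or none (``null``).

    Files written: matrix.tsv, labels.tsv (label + category columns),
    covariates.tsv, truth.json (planted membership and all parameters).
    Byte-identical for identical seeds. Returns the truth dictionary.
    """
    p = _fixture_params(scenario)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = derive_rng(seed, 0xF1)
    m = p["m_case"] + p["m_ctrl"]
    n = p["n"]

    if p["sparsity"]:
        # per-column +1 fraction mimicking a minor-allele-frequency spectrum
        maf = rng.uniform(0.05, 0.5, size=n)
        vals = np.where(rng.uniform(size=(m, n)) < maf, 1.0, -1.0)
    else:
        vals = rng.choice(np.array([-1.0, 1.0]), size=(m, n))

    rows = cols = np.empty(0, dtype=int)
    if p["m_b"] >= 2 and p["n_b"] >= 2:
        rows = np.sort(rng.choice(p["m_case"], size=p["m_b"], replace=False))
        cols = np.sort(rng.choice(n, size=p["n_b"], replace=False))
        B = _planted_block(max(p["m_b"], p["n_b"]), p["l"], p["epsilon"], rng)
        vals[np.ix_(rows, cols)] = B[: p["m_b"], : p["n_b"]]

    labels = np.array(["case"] * p["m_case"] + ["control"] * p["m_ctrl"])
    categories = rng.choice(["a", "b"], size=m)
    T = rng.standard_normal((m, 2))
    row_ids = [f"p{i:04d}" for i in range(m)]
    col_ids = [f"g{k:04d}" for k in range(n)]

    write_matrix(outdir / "matrix.tsv", SignMatrix(vals.astype(np.int8), row_ids, col_ids))
    write_labels(outdir / "labels.tsv", row_ids, labels, categories)
    write_covariates(outdir / "covariates.tsv", row_ids, T)
    truth = {
        "scenario": scenario,
        "seed": int(seed),
        "params": {k: (float(v) if isinstance(v, float) else v) for k, v in p.items()},
        "planted_rows": [row_ids[i] for i in rows],
        "planted_cols": [col_ids[k] for k in cols],
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return truth


def write_run_report(path, *, seed: int, config: dict, **sections) -> None:
    """Write a JSON run report with the master seed and the full resolved
    configuration (sufficient to reproduce the run), plus arbitrary result
    sections (numpy arrays are converted to lists)."""

    def conv(x):
        if isinstance(x, np.ndarray):
            return x.tolist()
        if isinstance(x, (np.integer,)):
            return int(x)
        if isinstance(x, (np.floating,)):
            return float(x)
        if isinstance(x, dict):
            return {k: conv(v) for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [conv(v) for v in x]
        return x

    report = {"seed": int(seed), "config": conv(config)}
    report.update({k: conv(v) for k, v in sections.items()})
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
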