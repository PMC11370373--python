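"""Orchestration and I/O for the differential-state tests.

Reads a cells x features expression matrix with per-cell (subject,
cluster) and per-subject (group, covariates) metadata, splits it into
per-(feature, cluster) test units, applies the minimum-nonzero-cells
filter, dispatches each retained unit to the requested test variant,
adjusts p-values for multiple testing and writes a tidy results table.

Supported input layouts: Matrix Market triplet in the 10x convention
(features x cells, with ``features.tsv`` / ``barcodes.tsv``) or dense
delimited text (cells x features with a header row).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as sio
from scipy import sparse
from statsmodels.stats.multitest import multipletests

from .density import TestUnit
from .kernels import gower_center
from .mdmr import parametric_bootstrap_test
from .score import run_score_test
from .density import pairwise_distance_matrix
from .simulate import unit_seed_for

logger = logging.getLogger(__name__)

__all__ = [
    "SingleCellDataset",
    "PipelineConfig",
    "read_dataset",
    "write_dataset",
    "filter_units",
    "adjust_pvalues",
    "run_pipeline",
    "write_results",
]

VARIANTS = ("psrF", "score-sc", "score-pb")


@dataclass
class SingleCellDataset:
    """In-memory cells x features matrix with cell and subject metadata."""

    matrix: np.ndarray | sparse.spmatrix
    cell_meta: pd.DataFrame  # columns: barcode, subject, cluster
    subject_meta: pd.DataFrame  # columns: subject, group, optional covariates
    feature_ids: list[str]

    def __post_init__(self) -> None:
        n_cells = self.matrix.shape[0]
        if len(self.cell_meta) != n_cells:
            raise ValueError(
                f"matrix has {n_cells} cells but cell_meta has {len(self.cell_meta)} rows"
            )
        if self.matrix.shape[1] != len(self.feature_ids):
            raise ValueError("feature_ids must match matrix columns")
        for col in ("subject", "cluster"):
            if col not in self.cell_meta.columns:
                raise ValueError(f"cell_meta must contain a '{col}' column")
        for col in ("subject", "group"):
            if col not in self.subject_meta.columns:
                raise ValueError(f"subject_meta must contain a '{col}' column")
        groups = set(pd.unique(self.subject_meta["group"]))
        if not groups <= {0, 1} or len(groups) != 2:
            raise ValueError("subject group must be binary 0/1 with both levels present")
        known = set(self.subject_meta["subject"])
        missing = set(self.cell_meta["subject"]) - known
        if missing:
            raise ValueError(f"cells reference unknown subjects: {sorted(missing)[:5]}")

    @property
    def subjects(self) -> list[str]:
        return list(self.subject_meta["subject"])

    @property
    def covariate_columns(self) -> list[str]:
        return [c for c in self.subject_meta.columns if c not in ("subject", "group")]

    def covariate_design(self, columns: list[str] | None = None) -> np.ndarray:
        """n x q design with an intercept plus the requested covariates."""
        cols = self.covariate_columns if columns is None else columns
        unknown = set(cols) - set(self.subject_meta.columns)
        if unknown:
            raise ValueError(f"unknown covariate columns: {sorted(unknown)}")
        n = len(self.subject_meta)
        parts = [np.ones((n, 1))]
        for c in cols:
            parts.append(np.asarray(self.subject_meta[c], dtype=float)[:, None])
        return np.hstack(parts)


@dataclass
class PipelineConfig:
    variant: str = "psrF"
    pb_method: str = "mean"
    n_resamples: int = 999
    seed: int = 0
    min_nonzero: int = 20
    fdr_method: str = "by"
    grid_size: int = 1024
    covariates: list[str] | None = None
    flag_threshold: float = 0.1

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.fdr_method not in ("bh", "by"):
            raise ValueError("fdr_method must be 'bh' or 'by'")


def read_dataset(
    matrix_path: str | Path,
    cell_meta_path: str | Path,
    subject_meta_path: str | Path,
    fmt: str = "auto",
    features_path: str | Path | None = None,
    barcodes_path: str | Path | None = None,
) -> SingleCellDataset:
    """Load a dataset from Matrix Market (10x layout) or dense delimited text.

    Matrix Market files are features x cells (10x convention) and are
    transposed on load; dense text is cells x features with a header row
    of feature names.  Cells whose subject or cluster label is missing
    are dropped with a logged count.
    """
    matrix_path = Path(matrix_path)
    if fmt == "auto":
        fmt = "mtx" if matrix_path.suffix in (".mtx", ".gz") else "dense"
    if fmt == "mtx":
        mat = sio.mmread(str(matrix_path)).tocsr().T.tocsr()  # -> cells x features
        if features_path is None:
            features_path = matrix_path.parent / "features.tsv"
        features = pd.read_csv(features_path, sep="\t", header=None)
        feature_ids = list(features[0].astype(str))
        matrix = mat
    else:
        sep = "," if matrix_path.suffix == ".csv" else "\t"
        df = pd.read_csv(matrix_path, sep=sep, index_col=0)
        feature_ids = list(df.columns.astype(str))
        matrix = df.to_numpy(dtype=float)

    cell_meta = pd.read_csv(cell_meta_path, sep="\t")
    subject_meta = pd.read_csv(subject_meta_path, sep="\t")
    if matrix.shape[0] != len(cell_meta):
        raise ValueError(
            f"matrix has {matrix.shape[0]} cells but cell metadata has "
            f"{len(cell_meta)} rows; check the matrix orientation"
        )
    keep = cell_meta["subject"].notna() & cell_meta["cluster"].notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropping %d cells with missing subject/cluster labels", n_dropped)
        cell_meta = cell_meta.loc[keep].reset_index(drop=True)
        matrix = matrix[keep.to_numpy()]
    return SingleCellDataset(
        matrix=matrix,
        cell_meta=cell_meta,
        subject_meta=subject_meta,
        feature_ids=feature_ids,
    )


def write_dataset(dataset: SingleCellDataset, out_dir: str | Path, fmt: str = "mtx") -> None:
    """Write a dataset in the layout :func:`read_dataset` understands."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if fmt == "mtx":
        mat = sparse.csr_matrix(dataset.matrix)
        sio.mmwrite(str(out / "matrix.mtx"), mat.T.tocoo())  # features x cells
        pd.DataFrame({0: dataset.feature_ids}).to_csv(
            out / "features.tsv", sep="\t", header=False, index=False
        )
        pd.DataFrame({0: dataset.cell_meta["barcode"]}).to_csv(
            out / "barcodes.tsv", sep="\t", header=False, index=False
        )
    elif fmt == "dense":
        dense = np.asarray(
            dataset.matrix.todense() if sparse.issparse(dataset.matrix) else dataset.matrix
        )
        df = pd.DataFrame(dense, columns=dataset.feature_ids,
                          index=dataset.cell_meta["barcode"])
        df.to_csv(out / "matrix.tsv", sep="\t")
    else:
        raise ValueError("fmt must be 'mtx' or 'dense'")
    dataset.cell_meta.to_csv(out / "cell_meta.tsv", sep="\t", index=False)
    dataset.subject_meta.to_csv(out / "subject_meta.tsv", sep="\t", index=False)


def filter_units(
    dataset: SingleCellDataset,
    min_nonzero: int = 20,
    covariates: list[str] | None = None,
) -> tuple[list[TestUnit], pd.DataFrame]:
    """Split the dataset into per-(feature, cluster) units and filter them.

    A unit is retained only when *every* subject contributes at least
    ``min_nonzero`` cells with non-zero expression for that feature in
    that cluster.  Zero-valued cells stay inside retained units — they
    shape the distribution; only the filter looks at the non-zero count.
    Returns the retained units and an exclusion log with one row per
    (feature, cluster) pair.
    """
    matrix = dataset.matrix
    dense = np.asarray(matrix.todense()) if sparse.issparse(matrix) else np.asarray(matrix)
    subjects = dataset.subjects
    outcome = np.asarray(dataset.subject_meta["group"], dtype=float)
    X = dataset.covariate_design(covariates)
    units: list[TestUnit] = []
    log_rows = []
    cell_subject = dataset.cell_meta["subject"].to_numpy()
    cell_cluster = dataset.cell_meta["cluster"].to_numpy()
    for cluster in pd.unique(cell_cluster):
        in_cluster = cell_cluster == cluster
        subj_masks = {s: in_cluster & (cell_subject == s) for s in subjects}
        for j, feature in enumerate(dataset.feature_ids):
            col = dense[:, j]
            values = [col[subj_masks[s]] for s in subjects]
            nonzero = np.array([int(np.count_nonzero(v)) for v in values])
            if np.all(nonzero >= min_nonzero) and all(v.size > 0 for v in values):
                units.append(
                    TestUnit(
                        feature_id=str(feature),
                        cluster_id=str(cluster),
                        subject_ids=list(subjects),
                        values=values,
                        outcome=outcome,
                        covariates=X,
                    )
                )
                log_rows.append({"feature": feature, "cluster": cluster,
                                 "retained": True, "reason": ""})
            else:
                worst = int(nonzero.min())
                log_rows.append(
                    {"feature": feature, "cluster": cluster, "retained": False,
                     "reason": f"min nonzero cells per subject {worst} < {min_nonzero}"}
                )
    return units, pd.DataFrame(log_rows)


def adjust_pvalues(p: np.ndarray, method: str = "by") -> np.ndarray:
    """Benjamini-Hochberg or Benjamini-Yekutieli step-up adjustment."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    key = {"bh": "fdr_bh", "by": "fdr_by"}[method]
    return multipletests(p, method=key)[1]


def _test_unit(unit: TestUnit, config: PipelineConfig) -> dict:
    seed_seq = unit_seed_for(config.seed, unit.feature_id, unit.cluster_id)
    seed = int(seed_seq.generate_state(1)[0] % (2**31))
    flags = []
    if config.variant == "psrF":
        D = pairwise_distance_matrix(unit, config.grid_size)
        if D.degenerate:
            return {"statistic": np.nan, "p_value": 1.0, "flags": ["degenerate"]}
        G = gower_center(D)
        res = parametric_bootstrap_test(
            G, unit.outcome, unit.covariates,
            B=config.n_resamples, seed=seed, variant="sqrtF",
        )
        if res.degenerate:
            flags.append("degenerate")
        return {"statistic": res.statistic, "p_value": res.p_value, "flags": flags}
    variant = "sc" if config.variant == "score-sc" else "pb"
    res = run_score_test(unit, variant=variant, pb_method=config.pb_method,
                         grid_size=config.grid_size)
    if res.degenerate:
        flags.append("degenerate")
    return {"statistic": res.statistic, "p_value": res.p_value, "flags": flags}


def run_pipeline(dataset: SingleCellDataset, config: PipelineConfig) -> pd.DataFrame:
    """Test every retained (feature, cluster) unit and adjust p-values.

    Returns one row per retained unit with the statistic, raw and
    adjusted p-value and a significance flag at the configured adjusted
    threshold (default 0.1).  Failures inside one unit never abort the
    others; they surface as flags with a missing statistic.
    """
    units, filter_log = filter_units(dataset, config.min_nonzero, config.covariates)
    n_subjects = len(dataset.subjects)
    rows = []
    for unit in units:
        try:
            out = _test_unit(unit, config)
        except Exception as exc:  # keep going; the flag records the failure
            logger.warning("unit (%s, %s) failed: %s", unit.feature_id, unit.cluster_id, exc)
            out = {"statistic": np.nan, "p_value": np.nan, "flags": [f"error:{exc}"]}
        rows.append(
            {"feature": unit.feature_id, "cluster": unit.cluster_id,
             "variant": config.variant, "statistic": out["statistic"],
             "p_value": out["p_value"], "n_subjects": n_subjects,
             "flags": ";".join(out["flags"])}
        )
    result = pd.DataFrame(
        rows, columns=["feature", "cluster", "variant", "statistic",
                       "p_value", "n_subjects", "flags"],
    )
    if len(result):
        ok = result["p_value"].notna()
        adjusted = np.full(len(result), np.nan)
        if ok.any():
            adjusted[ok.to_numpy()] = adjust_pvalues(
                result.loc[ok, "p_value"].to_numpy(), config.fdr_method
            )
        result["p_adjusted"] = adjusted
        result["significant"] = result["p_adjusted"] < config.flag_threshold
    else:
        logger.warning("no units passed filtering; empty result")
        result["p_adjusted"] = pd.Series(dtype=float)
        result["significant"] = pd.Series(dtype=bool)
    n_total = len(filter_log)
    logger.info("tested %d of %d units", len(units), n_total)
    return result


def write_results(
    result: pd.DataFrame,
    out_path: str | Path,
    config: PipelineConfig | None = None,
    extra_manifest: dict | None = None,
) -> None:
    """Write the results TSV plus a JSON run manifest next to it."""
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    result.to_csv(out_path, sep="\t", index=False)
    manifest = {
        "n_units": int(len(result)),
        "columns": list(result.columns),
    }
    if config is not None:
        manifest["config"] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()
        }
    if extra_manifest:
        manifest.update(extra_manifest)
    with open(out_path.with_suffix(out_path.suffix + ".manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
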