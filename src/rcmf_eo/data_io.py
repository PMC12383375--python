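"""Reading and writing expression datasets, run configuration and results.

The canonical on-disk format is delimited text (CSV, or TSV for ``.tsv`` /
``.txt`` extensions): one header row of gene identifiers, one row per
sample.  Class labels come either from a designated column of the same
file or from a separate single-column file.  Files with genes in rows can
be loaded with ``transpose=True``.

Missing values are rejected by default; mean imputation is an explicit
opt-in so it can never silently change results.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = ["LabeledDataset", "RunConfig", "load_dataset", "write_result", "load_config"]


@dataclass
class LabeledDataset:
    """A samples x genes expression matrix with per-sample class labels.

    ``labels`` are contiguous integer codes 0..k-1; ``label_names`` maps a
    code back to the original class name.  The encoding is stable: names
    are assigned codes in sorted order, so the same file always yields the
    same coding.
    """

    values: np.ndarray
    labels: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    label_names: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples x genes matrix")
        n, g = self.values.shape
        if self.labels.shape != (n,):
            raise ValueError("labels length must equal the number of samples")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length must equal the number of samples")
        if len(self.gene_ids) != g:
            raise ValueError("gene_ids length must equal the number of genes")
        if len(set(self.gene_ids)) != g:
            raise ValueError("gene_ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains missing or non-finite values")
        if not self.label_names:
            names = np.unique(self.labels).tolist()
            self.label_names = names
        codes, counts = np.unique(self.labels, return_counts=True)
        if len(codes) < 2:
            raise ValueError("dataset must contain at least 2 classes")
        if not np.array_equal(codes, np.arange(len(codes))):
            raise ValueError("labels must be contiguous integer codes 0..k-1")
        if counts.min() < 2:
            raise ValueError("class with fewer than 2 samples")
        self.labels = self.labels.astype(np.int64)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1


@dataclass
class RunConfig:
    """All tunable parameters of the two-stage pipeline.

    Optimizer constants default to the published GBGPSEO settings:
    a1=2, a2=1, GP=0.5, CRmax=1, CRmin=0, GPP=0.4, population 10,
    100 iterations, fitness weight alpha=0.9 with 5-NN 10-fold CV.
    """

    population_size: int = 10
    max_iter: int = 100
    filter_top_n: int = 100
    alpha: float = 0.9
    knn_k: int = 5
    cv_folds: int = 10
    a1: float = 2.0
    a2: float = 1.0
    GP: float = 0.5
    CRmax: float = 1.0
    CRmin: float = 0.0
    GPP: float = 0.4
    rng_seed: int = 0
    n_replicates: int = 20
    # stage-1 knobs
    n_bins: int = 5
    relieff_k: int = 10
    nca_reg: float = 0.01
    nca_max_iter: int = 50
    complementarity_mode: str = "interaction_gain"
    complementarity_eps: float = 0.0
    prune_order: str = "input"  # "input" (pseudocode order) or "relevance"
    # stage-2 knobs
    binarize_threshold: float = 0.5
    # mutation-rate schedule direction: "increasing" makes the Cauchy branch
    # dominate early and the Gaussian branch late (exploration -> exploitation),
    # which is what makes the enhanced wrapper beat plain EO; "decreasing"
    # applies the printed linear decay as-is.
    cr_direction: str = "increasing"
    prune_accept_ties: bool = True
    standardize: str = "zscore"  # KNN distance scaling: "zscore" or "none"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        for name in ("population_size", "max_iter", "filter_top_n", "knn_k",
                     "cv_folds", "n_replicates"):
            if getattr(self, name) < 1 and not (name == "max_iter" and self.max_iter == 0):
                raise ValueError(f"{name} must be a positive integer")
        if self.CRmin > self.CRmax:
            raise ValueError("CRmin must not exceed CRmax")
        if not (0 <= self.GP <= 1 and 0 <= self.GPP <= 1):
            raise ValueError("GP and GPP must lie in [0, 1]")
        if self.complementarity_mode not in ("interaction_gain", "literal"):
            raise ValueError("complementarity_mode must be 'interaction_gain' or 'literal'")
        if self.prune_order not in ("input", "relevance"):
            raise ValueError("prune_order must be 'input' or 'relevance'")
        if self.standardize not in ("zscore", "none"):
            raise ValueError("standardize must be 'zscore' or 'none'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _read_table(path: Path, sep: str | None) -> pd.DataFrame:
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    return pd.read_csv(path, sep=sep)


def _encode_labels(raw: Sequence) -> tuple[np.ndarray, list]:
    raw = np.asarray(raw)
    names, codes = np.unique(raw, return_inverse=True)
    return codes.astype(np.int64), names.tolist()


def load_dataset(
    path: str | Path,
    label_col: str | None = None,
    labels_path: str | Path | None = None,
    transpose: bool = False,
    impute: str = "none",
    sep: str | None = None,
) -> LabeledDataset:
    """Load an expression matrix plus class labels from delimited text.

    Exactly one of ``label_col`` (a column of the matrix file) or
    ``labels_path`` (a one-column file, optionally with a header) must be
    given.  With ``transpose=True`` the file is read as genes-in-rows
    (first column gene identifiers, header row of sample identifiers).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if (label_col is None) == (labels_path is None):
        raise ValueError("give exactly one of label_col or labels_path")

    frame = _read_table(path, sep)
    if transpose:
        frame = frame.set_index(frame.columns[0]).T.reset_index(drop=True)
        frame.columns = [str(c) for c in frame.columns]

    label_raw = None
    if label_col is not None:
        if label_col not in frame.columns:
            raise ValueError(f"label column {label_col!r} not found")
        label_raw = frame.pop(label_col).to_numpy()

    gene_ids = [str(c) for c in frame.columns]
    try:
        values = frame.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric expression cell: {exc}") from exc

    if labels_path is not None:
        lab_path = Path(labels_path)
        if not lab_path.exists():
            raise FileNotFoundError(lab_path)
        lab = pd.read_csv(lab_path, sep=r"[,\t]", engine="python", header=None)
        col = lab.iloc[:, -1]
        # tolerate a header row in the label file
        if len(col) == values.shape[0] + 1:
            col = col.iloc[1:]
        if len(col) != values.shape[0]:
            raise ValueError("label file length does not match the sample count")
        label_raw = col.to_numpy()

    if np.isnan(values).any():
        if impute == "mean":
            col_mean = np.nanmean(values, axis=0)
            idx = np.where(np.isnan(values))
            values[idx] = np.take(col_mean, idx[1])
        else:
            raise ValueError("missing values present; pass impute='mean' to impute")

    labels, label_names = _encode_labels(label_raw)
    sample_ids = [f"s{i:04d}" for i in range(values.shape[0])]
    return LabeledDataset(values=values, labels=labels, gene_ids=gene_ids,
                          sample_ids=sample_ids, label_names=label_names)


def write_result(result, out_dir: str | Path, gene_ids: Sequence[str],
                 config: RunConfig | None = None) -> dict[str, Path]:
    """Write a RunResult to ``out_dir`` as three text artifacts.

    ``subset.txt`` — one selected gene identifier per line;
    ``summary.json`` — MeanA/MeanS/MeanF with std, seed and config echo;
    ``trace.tsv`` — two-column (iteration, best fitness) convergence trace.
    """
    if not getattr(result, "trace", None):
        raise ValueError("trace missing")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    subset_path = out_dir / "subset.txt"
    subset_path.write_text(
        "".join(f"{gene_ids[g]}\n" for g in result.best_subset), encoding="utf-8"
    )

    summary = {
        "best_fitness": result.best_fitness,
        "n_selected": len(result.best_subset),
        **{k: float(v) for k, v in result.summary.items()},
        "seed": getattr(result, "seed", None),
        "config": config.to_dict() if config is not None else None,
    }
    summary_path = out_dir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, default=float), encoding="utf-8")

    trace_path = out_dir / "trace.tsv"
    trace_path.write_text(
        "".join(f"{i}\t{f!r}\n" for i, f in enumerate(result.trace)), encoding="utf-8"
    )
    return {"subset": subset_path, "summary": summary_path, "trace": trace_path}


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML config file whose keys mirror the RunConfig fields."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)
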