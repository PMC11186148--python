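"""Dataset readers and optional external-data adapters.

CSV tasks are (SMILES, label) tables for single tasks or a SMILES column
followed by binary descriptor columns for multi-label work.  The external
benchmark adapter (Therapeutics Data Commons ADMET group) is import-guarded
so the core suite runs fully offline; it maps each of the 22 task names to
its task type and headline metric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

logger = logging.getLogger("molenc")

__all__ = ["TaskDataset", "read_task_csv", "filter_labels",
           "tdc_adapter", "ADMET_TASKS"]


@dataclass
class TaskDataset:
    """SMILES with aligned labels for one prediction task."""

    smiles: List[str]
    labels: np.ndarray
    task: str                      # binary | regression | multilabel
    metric: str = ""
    label_names: List[str] = field(default_factory=list)
    # optional plumbing for the non-pretrained baseline / hash guard
    vocab: object = None
    encoder_config: object = None
    vocab_hash: str = ""

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if len(self.smiles) != self.labels.shape[0]:
            raise ValueError("labels must align with smiles")
        if self.task not in ("binary", "regression", "multilabel"):
            raise ValueError(f"unknown task type {self.task!r}")
        if self.task in ("binary", "multilabel"):
            vals = np.unique(self.labels)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError("classification labels must be 0/1")

    def __len__(self) -> int:
        return len(self.smiles)


def read_task_csv(path, smiles_column: str, label_columns: Sequence[str],
                  task: str) -> TaskDataset:
    """Load a task table, dropping rows with empty/whitespace SMILES.

    Dropped-row counts are logged; missing columns raise a format error
    naming the column.
    """
    import pandas as pd

    df = pd.read_csv(path)
    for col in [smiles_column, *label_columns]:
        if col not in df.columns:
            raise ValueError(f"column {col!r} missing from {path}")
    smiles_raw = df[smiles_column].astype(str)
    keep = smiles_raw.str.strip().replace("nan", "").astype(bool)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropped %d rows with empty SMILES from %s", n_dropped, path)
    df = df[keep]
    labels = df[list(label_columns)].to_numpy()
    if task in ("binary", "multilabel"):
        labels = labels.astype(np.int64)
    else:
        labels = labels.astype(np.float64)
    if task != "multilabel":
        labels = labels.reshape(-1)
    return TaskDataset(list(df[smiles_column]), labels, task,
                       label_names=list(label_columns))


def filter_labels(dataset: TaskDataset, min_positives: int = 50) -> TaskDataset:
    """Keep multi-label columns with strictly more than ``min_positives``
    positive samples, preserving column order."""
    if dataset.task != "multilabel":
        raise ValueError("filter_labels expects a multilabel dataset")
    counts = dataset.labels.sum(axis=0)
    keep = np.where(counts > min_positives)[0]
    if len(keep) == 0:
        raise ValueError(
            f"no label has more than {min_positives} positive samples")
    names = [dataset.label_names[i] for i in keep] if dataset.label_names else []
    return TaskDataset(dataset.smiles, dataset.labels[:, keep], "multilabel",
                       metric=dataset.metric, label_names=names)


#: The 22 ADMET benchmark tasks with task type and headline metric.
ADMET_TASKS = {
    "caco2_wang": ("regression", "MAE"),
    "bioavailability_ma": ("binary", "AUROC"),
    "lipophilicity_astrazeneca": ("regression", "MAE"),
    "solubility_aqsoldb": ("regression", "MAE"),
    "hia_hou": ("binary", "AUROC"),
    "pgp_broccatelli": ("binary", "AUROC"),
    "bbb_martins": ("binary", "AUROC"),
    "ppbr_az": ("regression", "MAE"),
    "vdss_lombardo": ("regression", "Spearman"),
    "cyp2c9_veith": ("binary", "AUPRC"),
    "cyp2d6_veith": ("binary", "AUPRC"),
    "cyp3a4_veith": ("binary", "AUPRC"),
    "cyp2c9_substrate_carbonmangels": ("binary", "AUPRC"),
    "cyp2d6_substrate_carbonmangels": ("binary", "AUPRC"),
    "cyp3a4_substrate_carbonmangels": ("binary", "AUROC"),
    "half_life_obach": ("regression", "Spearman"),
    "clearance_hepatocyte_az": ("regression", "Spearman"),
    "clearance_microsome_az": ("regression", "Spearman"),
    "ld50_zhu": ("regression", "MAE"),
    "herg": ("binary", "AUROC"),
    "ames": ("binary", "AUROC"),
    "dili": ("binary", "AUROC"),
}


def tdc_adapter(task_name: str) -> TaskDataset:
    """Load one ADMET benchmark task through the TDC package.

    Requires the external ``PyTDC`` package and a network-fetched cache;
    raises a clear error when unavailable rather than failing tests.
    """
    if task_name not in ADMET_TASKS:
        raise ValueError(
            f"unknown task {task_name!r}; valid names: {sorted(ADMET_TASKS)}")
    task, metric = ADMET_TASKS[task_name]
    try:
        from tdc.benchmark_group import admet_group
    except ImportError as exc:
        raise RuntimeError(
            "external data required: install PyTDC and allow network access "
            "to use the ADMET benchmark adapter") from exc
    group = admet_group(path="data/")
    benchmark = group.get(task_name)
    df = benchmark["train_val"]
    labels = df["Y"].to_numpy()
    if task == "binary":
        labels = labels.astype(np.int64)
    return TaskDataset(list(df["Drug"]), labels, task, metric=metric)
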