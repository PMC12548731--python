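"""Labeled collections of haplotype matrices, with on-disk layout.

A :class:`LabeledDataset` pairs fixed-shape haplotype matrices with either
categorical class labels (e.g. neutral / moderate sweep / strong sweep) or
real-valued parameter vectors (e.g. demographic model parameters), plus
free-form provenance metadata.

The on-disk layout of a dataset directory is entirely plain text:

    mat_00000.txt, mat_00001.txt, ...   matrices in the text dialect
    labels.tsv                          index + label column(s)
    meta.yaml                           provenance metadata
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .matrix import HaplotypeMatrix, read_matrix_text, write_matrix_text

__all__ = ["LabeledDataset", "write_dataset", "read_dataset"]

Label = Union[str, np.ndarray]


@dataclass
class LabeledDataset:
    """Matrices plus one label each; all matrices share (n_hap, width).

    ``task`` is ``"classification"`` (labels are strings drawn from
    ``label_names``) or ``"regression"`` (labels are vectors whose named
    components are ``label_names``).
    """

    matrices: list[HaplotypeMatrix]
    labels: list[Label]
    label_names: list[str]
    task: str = "classification"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.matrices) != len(self.labels):
            raise ValueError("one label per matrix required")
        if self.task not in ("classification", "regression"):
            raise ValueError(f"unknown task {self.task!r}")
        shapes = {(m.n_hap, m.width) for m in self.matrices}
        if len(shapes) > 1:
            raise ValueError(f"matrices do not share a common shape: {sorted(shapes)}")
        if self.task == "regression":
            self.labels = [np.asarray(l, dtype=float) for l in self.labels]
            for l in self.labels:
                if l.shape != (len(self.label_names),):
                    raise ValueError("regression label length must match label_names")
        else:
            unknown = set(map(str, self.labels)) - set(self.label_names)
            if unknown:
                raise ValueError(f"labels not in label_names: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.matrices)

    @property
    def n_hap(self) -> int:
        return self.matrices[0].n_hap

    @property
    def width(self) -> int:
        return self.matrices[0].width

    def label_array(self) -> np.ndarray:
        if self.task == "regression":
            return np.stack(self.labels)
        return np.asarray(self.labels, dtype=object)


def write_dataset(dataset: LabeledDataset, directory: Union[str, Path]) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, m in enumerate(dataset.matrices):
        with open(directory / f"mat_{i:05d}.txt", "w") as fh:
            write_matrix_text(m, fh)
    if dataset.task == "regression":
        df = pd.DataFrame(np.stack(dataset.labels), columns=dataset.label_names)
    else:
        df = pd.DataFrame({"label": list(map(str, dataset.labels))})
    df.insert(0, "index", range(len(dataset)))
    df.to_csv(directory / "labels.tsv", sep="\t", index=False)
    meta = dict(dataset.meta)
    meta.update(task=dataset.task, label_names=list(dataset.label_names))
    with open(directory / "meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def read_dataset(directory: Union[str, Path]) -> LabeledDataset:
    directory = Path(directory)
    with open(directory / "meta.yaml") as fh:
        meta = yaml.safe_load(fh)
    task = meta.pop("task")
    label_names = [str(x) for x in meta.pop("label_names")]
    df = pd.read_csv(directory / "labels.tsv", sep="\t")
    matrices = []
    for i in df["index"]:
        with open(directory / f"mat_{int(i):05d}.txt") as fh:
            matrices.append(read_matrix_text(fh))
    if task == "regression":
        labels: list[Label] = [row for row in df[label_names].to_numpy(dtype=float)]
    else:
        labels = [str(x) for x in df["label"]]
    return LabeledDataset(
        matrices=matrices, labels=labels, label_names=label_names, task=task, meta=meta
    )
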