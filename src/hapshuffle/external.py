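"""Subprocess contract for profiling external models.

An external model is any executable that reads haplotype matrices in the
text dialect on standard input (concatenated, one after another) and
writes exactly one prediction line per matrix on standard output: a single
real number for classification scores, or whitespace-separated reals for
a regression parameter vector.
"""

from __future__ import annotations

import io
import subprocess
from typing import Sequence

import numpy as np

from .dataset import LabeledDataset
from .evaluate import ModelAdapter, _threshold_model
from .matrix import HaplotypeMatrix, write_matrix_text

__all__ = ["subprocess_model"]


def _run(command: str, matrices: Sequence[HaplotypeMatrix]) -> list[list[float]]:
    buf = io.StringIO()
    for m in matrices:
        write_matrix_text(m, buf)
    proc = subprocess.run(
        command, shell=True, input=buf.getvalue(), capture_output=True, text=True
    )
    if proc.returncode != 0:
        raise RuntimeError(f"external model failed ({proc.returncode}): {proc.stderr}")
    lines = [l for l in proc.stdout.splitlines() if l.strip()]
    if len(lines) != len(matrices):
        raise ValueError(
            f"external model wrote {len(lines)} predictions for {len(matrices)} matrices"
        )
    return [[float(tok) for tok in line.split()] for line in lines]


def subprocess_model(command: str, dataset: LabeledDataset) -> ModelAdapter:
    """Wrap a shell command as a ModelAdapter for ``dataset``'s task.

    Classification commands must emit one scalar score per matrix
    (monotone in class index); thresholds are calibrated on the original
    dataset just as for the built-in toy models.  Regression commands
    emit one parameter vector per line.
    """
    if dataset.task == "classification":
        def score_fn(matrices: Sequence[HaplotypeMatrix]) -> np.ndarray:
            return np.array([row[0] for row in _run(command, matrices)])

        return _threshold_model(f"external:{command}", dataset, score_fn)

    def predict(matrices: Sequence[HaplotypeMatrix]) -> np.ndarray:
        return np.array(_run(command, matrices), dtype=float)

    return ModelAdapter(name=f"external:{command}", task="regression", score_fn=predict)
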