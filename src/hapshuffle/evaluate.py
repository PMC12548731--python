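"""Degrade-and-compare harness: score a model across the permutation ladder.

The harness applies every permutation level to a labeled test set, calls a
user-supplied predictor (the trained model is never changed), and collects
per-level, per-seed metrics into a degradation profile.  A sharp
performance drop at a level indicates that the features destroyed by that
level were driving the model's predictions.

Three training-free toy reference models with analytically known
sensitivities are provided for calibration and testing:

* a *count* classifier scoring by the (negated) total number of 1s — by
  construction invariant to every permutation level, since all levels
  conserve the grand total of 1s;
* a *Garud-H1* classifier — invariant to column shuffling, destroyed as
  soon as haplotypes are disrupted, and driven toward the
  strongest-selection call by allele grouping (which collapses haplotype
  diversity);
* an *AFS-moment* demographic regressor estimating epoch sizes from
  frequency-binned Fu-style theta estimators i * xi_i — invariant to
  anything that preserves column sums, destroyed when the allele frequency
  spectrum is disrupted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dataset import LabeledDataset
from .matrix import HaplotypeMatrix
from .permute import PermutationLevel, apply_to_dataset
from .sumstats import StatisticUndefinedError, afs, garud_h
from .synthdata import DEFAULT_PRIORS

__all__ = [
    "ModelAdapter",
    "PerformanceProfile",
    "roc_auc",
    "confusion",
    "spearman_rho",
    "rmse",
    "run_suite",
    "make_count_model",
    "make_h1_model",
    "make_afs_model",
    "toy_models",
]


# --- metrics ------------------------------------------------------------


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve via the Mann-Whitney statistic.

    Equals P(score+ > score-) + 0.5 * P(tie) over all positive/negative
    pairs, computed from mid-ranks.  Raises
    :class:`~hapshuffle.sumstats.StatisticUndefinedError` if only one
    class is present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise StatisticUndefinedError("AUC requires both classes present")
    ranks = sps.rankdata(scores)  # mid-ranks
    return (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def confusion(
    predicted: Sequence[str], true: Sequence[str], label_names: Sequence[str]
) -> np.ndarray:
    """Count matrix: entry (i, j) = items of true class i predicted as j."""
    index = {name: i for i, name in enumerate(label_names)}
    out = np.zeros((len(label_names), len(label_names)), dtype=np.int64)
    for t, p in zip(true, predicted, strict=True):
        if t not in index or p not in index:
            raise ValueError(f"label not in label_names: {t!r} / {p!r}")
        out[index[t], index[p]] += 1
    return out


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (Pearson correlation of mid-ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise StatisticUndefinedError("Spearman's rho undefined for a constant vector")
    return float(sps.spearmanr(x, y).statistic)


def rmse(estimates: Sequence[float], truths: Sequence[float]) -> float:
    estimates = np.asarray(estimates, dtype=float)
    truths = np.asarray(truths, dtype=float)
    if estimates.shape != truths.shape:
        raise ValueError("length mismatch")
    return float(np.sqrt(np.mean((estimates - truths) ** 2)))


# --- model adapters -----------------------------------------------------


@dataclass
class ModelAdapter:
    """Contract a predictor must satisfy to be profiled.

    Classification adapters expose a scalar *selection-intensity* score
    per matrix (monotone in class index) plus fixed thresholds that
    convert scores into class labels; ties at a threshold go to the lower
    class index.  Regression adapters return one parameter-vector
    estimate per matrix.
    """

    name: str
    task: str  # "classification" | "regression"
    score_fn: Callable[[Sequence[HaplotypeMatrix]], np.ndarray]
    class_names: Optional[list[str]] = None
    thresholds: Optional[np.ndarray] = None  # len(class_names) - 1, ascending

    def predict_scores(self, matrices: Sequence[HaplotypeMatrix]) -> np.ndarray:
        out = np.asarray(self.score_fn(matrices), dtype=float)
        if out.shape[0] != len(matrices):
            raise ValueError("model returned wrong number of predictions")
        if self.task == "classification" and not np.isfinite(out).all():
            raise ValueError("classification scores must be finite")
        return out

    def predict_labels(self, matrices: Sequence[HaplotypeMatrix]) -> list[str]:
        if self.task != "classification":
            raise ValueError("labels only defined for classification adapters")
        scores = self.predict_scores(matrices)
        idx = np.searchsorted(self.thresholds, scores, side="left")
        return [self.class_names[int(i)] for i in idx]


def make_count_model(dataset: LabeledDataset) -> ModelAdapter:
    """Classifier scoring by the negated total count of 1s.

    Sweeps drastically lower the minor-allele load, so fewer 1s means more
    sweep-like; the score is therefore -(total 1s).  Thresholds are the
    training-free balanced quantiles of the scores on the original
    dataset.  Because every permutation level conserves the grand total of
    1s, this model is provably insensitive to the whole ladder.
    """
    return _threshold_model("count", dataset, _neg_total_scores)


def make_h1_model(dataset: LabeledDataset) -> ModelAdapter:
    """Classifier scoring by Garud's H1 (haplotype homozygosity)."""
    return _threshold_model("h1", dataset, _h1_scores)


def _neg_total_scores(matrices: Sequence[HaplotypeMatrix]) -> np.ndarray:
    return np.array([-float(m.region.sum(dtype=np.int64)) for m in matrices])


def _h1_scores(matrices: Sequence[HaplotypeMatrix]) -> np.ndarray:
    return np.array([garud_h(m)[0] for m in matrices])


def _threshold_model(
    name: str, dataset: LabeledDataset, score_fn: Callable
) -> ModelAdapter:
    if dataset.task != "classification":
        raise ValueError("count/h1 models require a classification dataset")
    scores = np.asarray(score_fn(dataset.matrices), dtype=float)
    k = len(dataset.label_names)
    qs = [i / k for i in range(1, k)]
    thresholds = np.quantile(scores, qs)
    return ModelAdapter(
        name=name,
        task="classification",
        score_fn=score_fn,
        class_names=list(dataset.label_names),
        thresholds=np.asarray(thresholds, dtype=float),
    )


def make_afs_model(dataset: LabeledDataset) -> ModelAdapter:
    """Method-of-moments demographic regressor on the frequency spectrum.

    Under neutrality E[xi_i] = theta / i, so i * xi_i is an unbiased theta
    estimator per frequency class.  Rare variants reflect recent history
    and common variants older history, so the adapter maps the
    singleton-class estimator to N0, the mid-frequency average to N1 and
    the high-frequency average to N2 (each divided by the reference
    theta).  The epoch times carry little moment information at this
    scale; the adapter reports the prior midpoints, a constant.
    """
    if dataset.task != "regression":
        raise ValueError("afs model requires a regression dataset")
    theta_ref = float(dataset.meta.get("theta_ref", 1.0))
    priors = dataset.meta.get("priors") or {
        k: list(v) for k, v in DEFAULT_PRIORS.items()
    }
    t_mid = [
        (float(priors[k][0]) + float(priors[k][1])) / 2 for k in ("T1", "T2")
    ]

    def predict(matrices: Sequence[HaplotypeMatrix]) -> np.ndarray:
        out = np.empty((len(matrices), 5))
        for r, m in enumerate(matrices):
            n = m.n_hap
            xi = afs(m).counts  # length n + 1
            i = np.arange(1, n)
            theta_i = i * xi[1:n].astype(float)
            mid_hi = max(2, (n - 1) // 2 + 1)  # split interior classes in two
            theta_recent = theta_i[0]
            theta_mid = float(theta_i[1 : mid_hi - 1].mean()) if mid_hi > 2 else theta_i[0]
            theta_anc = float(theta_i[mid_hi - 1 :].mean())
            out[r] = [
                theta_recent / theta_ref,
                theta_mid / theta_ref,
                theta_anc / theta_ref,
                t_mid[0],
                t_mid[1],
            ]
        return out

    return ModelAdapter(name="afs", task="regression", score_fn=predict)


def toy_models(
    classification_dataset: Optional[LabeledDataset] = None,
    regression_dataset: Optional[LabeledDataset] = None,
) -> list[ModelAdapter]:
    """The three reference models, calibrated on the supplied original data."""
    out = []
    if classification_dataset is not None:
        out.append(make_count_model(classification_dataset))
        out.append(make_h1_model(classification_dataset))
    if regression_dataset is not None:
        out.append(make_afs_model(regression_dataset))
    return out


# --- the degradation profile --------------------------------------------


@dataclass
class PerformanceProfile:
    """Per-(level, seed, metric) values of the degradation report.

    ``table`` has columns (level, seed, metric, parameter_or_class,
    value); undefined metrics are recorded as NaN, never silently as 0.
    """

    table: pd.DataFrame
    model_name: str = ""

    def value(
        self,
        level: PermutationLevel,
        metric: str,
        parameter: str = "",
        seed: Optional[int] = None,
    ) -> float:
        t = self.table
        sel = (t["level"] == PermutationLevel(level).value) & (t["metric"] == metric)
        if parameter:
            sel &= t["parameter_or_class"] == parameter
        if seed is not None:
            sel &= t["seed"] == seed
        vals = t.loc[sel, "value"]
        if vals.empty:
            raise KeyError(f"no entries for {level}, {metric!r}, {parameter!r}")
        return float(vals.mean())

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _class_metrics(
    model: ModelAdapter, dataset: LabeledDataset
) -> list[tuple[str, str, float]]:
    rows: list[tuple[str, str, float]] = []
    scores = model.predict_scores(dataset.matrices)
    predicted = model.predict_labels(dataset.matrices)
    true = [str(l) for l in dataset.labels]
    names = dataset.label_names
    # binary AUC: first class (neutral baseline) versus everything else
    is_selected = np.array([t != names[0] for t in true])
    try:
        rows.append(("auc", "", roc_auc(scores, is_selected)))
    except StatisticUndefinedError:
        rows.append(("auc", "", math.nan))
    cm = confusion(predicted, true, names)
    rows.append(("accuracy", "", float(np.trace(cm)) / len(true)))
    index = {name: i for i, name in enumerate(names)}
    rows.append(
        ("mean_predicted_class", "", float(np.mean([index[p] for p in predicted])))
    )
    for i, ti in enumerate(names):
        for j, pj in enumerate(names):
            rows.append(("confusion", f"{ti}->{pj}", float(cm[i, j])))
    return rows


def _regression_metrics(
    model: ModelAdapter, dataset: LabeledDataset
) -> list[tuple[str, str, float]]:
    rows: list[tuple[str, str, float]] = []
    est = model.predict_scores(dataset.matrices)
    truth = dataset.label_array()
    for j, name in enumerate(dataset.label_names):
        try:
            rho = spearman_rho(est[:, j], truth[:, j])
        except StatisticUndefinedError:
            rho = math.nan
        rows.append(("spearman_rho", name, rho))
        rows.append(("rmse", name, rmse(est[:, j], truth[:, j])))
    return rows


def run_suite(
    model: ModelAdapter,
    dataset: LabeledDataset,
    levels: Sequence[PermutationLevel] = tuple(PermutationLevel),
    seeds: Sequence[int] = (0,),
) -> PerformanceProfile:
    """Profile a model across permutation levels and replicate seeds.

    For each base seed and level the dataset is permuted (labels never
    move), the model predicts once, and the metrics are recorded.  The
    replicate axis is the permutation seed on a fixed model — the model is
    never retrained.  Deterministic given (model, dataset, seeds).
    """
    if dataset.task != model.task:
        raise ValueError(
            f"dataset task {dataset.task!r} does not match model task {model.task!r}"
        )
    levels = [PermutationLevel(l) for l in levels]
    if PermutationLevel.ORIGINAL not in levels:
        levels = [PermutationLevel.ORIGINAL] + levels
    records = []
    for seed in seeds:
        for level in levels:
            permuted = apply_to_dataset(dataset, level, seed)
            if model.task == "classification":
                rows = _class_metrics(model, permuted)
            else:
                rows = _regression_metrics(model, permuted)
            for metric, param, value in rows:
                records.append(
                    {
                        "level": level.value,
                        "seed": int(seed),
                        "metric": metric,
                        "parameter_or_class": param,
                        "value": value,
                    }
                )
    return PerformanceProfile(table=pd.DataFrame.from_records(records), model_name=model.name)
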