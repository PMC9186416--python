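"""Task classification from stage-2 loadings, and the ROA analysis.

Each (subject, task) pair yields one sample: the k2 x k1 loading block
flattened component-major into a feature vector.  A linear-kernel SVM
(one-vs-one multiclass, toolkit defaults otherwise) is trained on training
subjects and evaluated on held-out subjects.

The ratio-of-activation (ROA) score ranks components by how
task-specifically their loading-row support is distributed: for row i,
count the nonzero entries falling in each task's columns (plus a
pseudocount), then take the absolute mean of log count-ratios over all
task pairs.  Uniformly supported rows score 0; rows active in a single
task score high.  Sorting rows by ROA and retraining on growing prefixes
produces the incremental accuracy curve; category ablations and the
per-component capacity-vs-overlap regression reuse the same machinery.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.svm import SVC

from .blocks import BlockIndex
from .sparse import SUPPORT_TOLERANCE, SparseCodes


@dataclass(frozen=True)
class SampleFeatures:
    """One classification sample: a flattened loading block."""

    subject_id: str
    task_label: str
    features: np.ndarray = field(repr=False)  # k2*k1, component-major


@dataclass(frozen=True)
class RoaVector:
    """Per-component ROA scores with their support counts."""

    values: np.ndarray = field(repr=False)  # k2, nonnegative
    counts: np.ndarray = field(repr=False)  # k2 x n_tasks, pseudocounted
    pseudocount: float
    rank_order: np.ndarray = field(repr=False)  # descending, ties by index

    @property
    def k(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class TrainedClassifier:
    model: SVC
    feature_length: int
    classes: tuple[str, ...]
    manifest_hash: str = ""


def build_samples(
    alpha2: SparseCodes, index: BlockIndex
) -> list[SampleFeatures]:
    """One sample per (subject, task): the k2 x k1 block, component-major."""
    samples = []
    for sub in index.subjects:
        for task in index.tasks:
            block = alpha2.coefficients[:, index.block(sub, task)]
            samples.append(
                SampleFeatures(
                    subject_id=sub,
                    task_label=task,
                    features=np.ascontiguousarray(block).ravel(),
                )
            )
    return samples


def samples_to_arrays(samples: Sequence[SampleFeatures]) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([s.features for s in samples])
    y = np.array([s.task_label for s in samples])
    return X, y


def train_svm(
    samples: Sequence[SampleFeatures], manifest: dict | None = None
) -> TrainedClassifier:
    """Fit a linear-kernel one-vs-one SVM on training samples only."""
    X, y = samples_to_arrays(samples)
    classes = tuple(sorted(set(y)))
    if len(classes) < 2:
        raise ValueError("need at least two classes to train a classifier")
    model = SVC(kernel="linear")
    model.fit(X, y)
    mhash = ""
    if manifest is not None:
        mhash = hashlib.sha256(
            json.dumps(manifest, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
    return TrainedClassifier(
        model=model, feature_length=X.shape[1], classes=classes, manifest_hash=mhash
    )


def evaluate_accuracy(
    clf: TrainedClassifier, samples: Sequence[SampleFeatures]
) -> tuple[float, np.ndarray]:
    """Accuracy and confusion matrix (rows = true labels, canonical order)."""
    X, y = samples_to_arrays(samples)
    if X.shape[1] != clf.feature_length:
        raise ValueError(
            f"feature length {X.shape[1]} does not match the trained model "
            f"({clf.feature_length})"
        )
    pred = clf.model.predict(X)
    labels = list(dict.fromkeys(list(clf.classes) + sorted(set(y))))
    lut = {l: i for i, l in enumerate(labels)}
    confusion = np.zeros((len(labels), len(labels)), dtype=int)
    for yt, yp in zip(y, pred):
        confusion[lut[yt], lut[yp]] += 1
    accuracy = float((pred == y).mean())
    return accuracy, confusion


def compute_roa(
    alpha2: SparseCodes,
    index: BlockIndex,
    pseudocount: float = 1.0,
    support_tolerance: float = SUPPORT_TOLERANCE,
    convention: str = "pair_mean",
) -> RoaVector:
    """ROA score per loading row from task-wise nonzero-support counts.

    ``c[i, t]`` counts entries of row i with magnitude above the support
    tolerance among the columns of task t (over all training subjects),
    plus the pseudocount.  Under the default pair-mean convention,
    ``ROA_i = | mean_{t<k} log(c[i,t] / c[i,k]) |``; the alternative
    ``literal`` convention normalizes the pair sum by the task count T
    instead of the number of pairs.
    """
    if convention not in ("pair_mean", "literal"):
        raise ValueError(f"unknown convention {convention!r}")
    nz = np.abs(alpha2.coefficients) > support_tolerance
    T = index.n_tasks
    counts = np.empty((alpha2.k, T))
    for t in range(T):
        cols = index.task_columns(t)
        counts[:, t] = nz[:, cols].sum(axis=1) + pseudocount
    if np.any(counts <= 0):
        raise ValueError("nonpositive counts; use a positive pseudocount")
    logc = np.log(counts)
    pair_sum = np.zeros(alpha2.k)
    for t, k in combinations(range(T), 2):
        pair_sum += logc[:, t] - logc[:, k]
    denom = T * (T - 1) / 2 if convention == "pair_mean" else T
    values = np.abs(pair_sum / denom)
    rank_order = np.lexsort((np.arange(values.size), -values))
    return RoaVector(
        values=values,
        counts=counts,
        pseudocount=float(pseudocount),
        rank_order=rank_order,
    )


def _restrict(samples: Sequence[SampleFeatures], k2: int, rows: np.ndarray) -> list[SampleFeatures]:
    """Samples restricted to a subset of loading rows (components).

    Rows are applied in ascending order, so selecting all rows reproduces
    the full feature vector bit-for-bit.
    """
    rows = np.sort(np.asarray(rows))
    out = []
    for s in samples:
        block = s.features.reshape(k2, -1)
        out.append(
            SampleFeatures(
                subject_id=s.subject_id,
                task_label=s.task_label,
                features=np.ascontiguousarray(block[rows]).ravel(),
            )
        )
    return out


def roa_incremental_classification(
    train: Sequence[SampleFeatures],
    test: Sequence[SampleFeatures],
    roa: RoaVector,
    step: int = 1,
    ms: Sequence[int] | None = None,
) -> list[tuple[int, float]]:
    """Accuracy as a function of the number of top-ROA components used.

    For each m, restrict features to the m highest-ROA rows, retrain the
    SVM and evaluate; m = k2 reproduces the full-feature model exactly.
    """
    k2 = roa.k
    if ms is None:
        ms = list(range(step, k2, step))
        if not ms or ms[-1] != k2:
            ms.append(k2)
    curve = []
    for m in ms:
        if not (1 <= m <= k2):
            raise ValueError(f"m={m} out of range [1, {k2}]")
        rows = roa.rank_order[:m]
        clf = train_svm(_restrict(train, k2, rows))
        acc, _ = evaluate_accuracy(clf, _restrict(test, k2, rows))
        curve.append((int(m), acc))
    return curve


def ablation_experiment(
    train: Sequence[SampleFeatures],
    test: Sequence[SampleFeatures],
    categories: Sequence[str],
) -> dict[str, float]:
    """Accuracy for the four component groups used in the ablation.

    Groups: all components; excluding artifact; excluding resting-state;
    excluding both.  A group that would exclude every component is refused.
    """
    categories = list(categories)
    k2 = len(categories)
    groups = {
        "all": set(),
        "excl_artifact": {"artifact"},
        "excl_resting": {"resting-state"},
        "excl_both": {"artifact", "resting-state"},
    }
    results = {}
    for name, excluded in groups.items():
        rows = np.array([j for j, c in enumerate(categories) if c not in excluded])
        if rows.size == 0:
            raise ValueError(f"group {name!r} excludes every component")
        clf = train_svm(_restrict(train, k2, rows))
        acc, _ = evaluate_accuracy(clf, _restrict(test, k2, rows))
        results[name] = acc
    return results


@dataclass(frozen=True)
class CapacityOverlapResult:
    """Per-component classification capacity vs template overlap."""

    accuracy: np.ndarray = field(repr=False)  # per component
    overlap: np.ndarray = field(repr=False)  # best template overlap per component
    slope: float
    intercept: float
    r_squared: float
    p_value: float


def capacity_vs_overlap(
    train: Sequence[SampleFeatures],
    test: Sequence[SampleFeatures],
    component_masks: Sequence[np.ndarray],
    templates: Sequence,
    k2: int | None = None,
) -> CapacityOverlapResult:
    """Regress single-component accuracy on best template overlap.

    Component j's capacity is the held-out accuracy of an SVM trained on
    its k1 features alone; its overlap is the best overlap rate of its
    thresholded map against the reference templates.  An ordinary
    least-squares line summarizes the relation (slope, R^2, two-sided p).
    """
    from .features import overlap_rate

    if k2 is None:
        k2 = len(component_masks)
    if k2 < 3:
        raise ValueError("need at least three components for a regression")
    accuracy = np.empty(k2)
    overlap = np.empty(k2)
    for j in range(k2):
        clf = train_svm(_restrict(train, k2, np.array([j])))
        accuracy[j], _ = evaluate_accuracy(clf, _restrict(test, k2, np.array([j])))
        overlap[j] = max(
            (overlap_rate(component_masks[j], t.binary_mask) for t in templates),
            default=0.0,
        )
    if np.allclose(overlap, overlap[0]):
        return CapacityOverlapResult(
            accuracy=accuracy, overlap=overlap,
            slope=float("nan"), intercept=float("nan"),
            r_squared=float("nan"), p_value=float("nan"),
        )
    fit = stats.linregress(overlap, accuracy)
    return CapacityOverlapResult(
        accuracy=accuracy,
        overlap=overlap,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
    )
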