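"""Temporal courses, spatial maps, reference templates, and categorization.

After the two-stage fit, each spatial component j (an atom of D2) has a
per-task temporal course: the group average of the stage-2 loading blocks
mapped back through the temporal dictionary,
``D_t = D1 . mean_i (alpha2_{i,t})^T``.  Correlating a component's course
with the task's HRF-convolved paradigm, and overlapping its thresholded
spatial map with reference activation templates, lets components be
categorized as task-evoked, resting-state, integrated or artifact.

Reference templates can come from real GLM software output, or from the
minimal mass-univariate GLM implemented here (per-voxel OLS against the
event regressors, one-sample t across subjects, z-thresholded).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .blocks import BlockIndex
from .dataio import BoldMatrix, VoxelSampling
from .pipeline import SsrResult, TsrResult, alpha2_block
from .sparse import Dictionary, SparseCodes


@dataclass(frozen=True)
class TaskTemporalCourses:
    """Per-component temporal courses of one task (t x k2)."""

    task_id: str
    courses: np.ndarray = field(repr=False)
    p_corr: np.ndarray | None = None  # per-component Pearson r with paradigm

    @property
    def k2(self) -> int:
        return self.courses.shape[1]


@dataclass(frozen=True)
class SpatialMap:
    """One spatial-dictionary atom placed back into the 3D grid."""

    component_id: int
    values: np.ndarray = field(repr=False)  # per-sampled-voxel atom entries
    volume: np.ndarray = field(repr=False)  # 3D, unsampled voxels = 0
    zmap: np.ndarray = field(repr=False)  # 3D standardized values
    binary_mask: np.ndarray = field(repr=False)  # 3D thresholded support
    sampled_mask: np.ndarray = field(repr=False)  # 3D validity of sampled voxels

    def flat_mask(self) -> np.ndarray:
        """Thresholded support restricted to the sampled voxels (1D)."""
        return self.binary_mask.ravel()[self.sampled_mask.ravel()]


@dataclass(frozen=True)
class ReferenceTemplate:
    """A named binary activation template on the sampled-voxel space."""

    label: str
    binary_mask: np.ndarray = field(repr=False)  # 1D over sampled voxels
    zmap: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.binary_mask.sum() == 0:
            raise ValueError(f"template {self.label!r} has an empty mask")


def task_temporal_courses(
    D1: Dictionary,
    alpha2: SparseCodes,
    index: BlockIndex,
    task: str | int,
    regressor: np.ndarray | None = None,
) -> TaskTemporalCourses:
    """Group-average temporal course of every component under one task.

    ``D_t = D1 . (1/p) sum_i (alpha2_{i,t})^T`` — a t x k2 matrix whose
    column j is component j's course.  If the task's paradigm regressor is
    given, per-component Pearson correlations are attached.
    """
    p = index.n_subjects
    blocks = [alpha2_block(alpha2, index, i, task) for i in range(p)]
    mean_bt = np.mean([b.T for b in blocks], axis=0)  # k1 x k2
    courses = D1.atoms @ mean_bt
    task_label = task if isinstance(task, str) else index.tasks[task]
    p_corr = None
    if regressor is not None:
        p_corr = np.array(
            [paradigm_correlation(courses[:, j], regressor) for j in range(courses.shape[1])]
        )
    return TaskTemporalCourses(task_id=task_label, courses=courses, p_corr=p_corr)


def paradigm_correlation(course: np.ndarray, regressor: np.ndarray) -> float:
    """Pearson correlation between a temporal course and a task paradigm.

    Constant inputs have no defined correlation and yield NaN rather than 0.
    """
    course = np.asarray(course, dtype=float)
    regressor = np.asarray(regressor, dtype=float)
    if course.shape != regressor.shape:
        raise ValueError("course and regressor must have equal length")
    x = course - course.mean()
    y = regressor - regressor.mean()
    denom = np.linalg.norm(x) * np.linalg.norm(y)
    if denom == 0:
        return float("nan")
    return float(np.clip(x @ y / denom, -1.0, 1.0))


def component_spectrum(course: np.ndarray, tr: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided magnitude spectrum of a temporal course (frequencies in Hz)."""
    course = np.asarray(course, dtype=float)
    if course.size < 8:
        raise ValueError("need at least 8 frames for a spectrum")
    freqs = np.fft.rfftfreq(course.size, d=tr)
    mag = np.abs(np.fft.rfft(course)) / course.size
    return freqs, mag


def extract_spatial_map(
    D2: Dictionary,
    component_id: int,
    sampling: VoxelSampling,
    threshold: float = 2.3,
) -> SpatialMap:
    """Place one spatial atom back on the grid and threshold it.

    The atom is z-standardized across its own entries; the binary mask is
    ``|z| > threshold`` and is necessarily a subset of the sampled voxels.
    """
    if not (0 <= component_id < D2.k):
        raise IndexError(f"component {component_id} out of range [0, {D2.k})")
    values = D2.atoms[:, component_id]
    sd = values.std()
    z = (values - values.mean()) / sd if sd > 0 else np.zeros_like(values)

    shape = sampling.mask_shape
    volume = np.zeros(shape)
    zvol = np.zeros(shape)
    sampled = np.zeros(shape, dtype=bool)
    flat = sampling.sampled_indices
    volume.ravel()[flat] = values
    zvol.ravel()[flat] = z
    sampled.ravel()[flat] = True
    binary = np.zeros(shape, dtype=bool)
    binary.ravel()[flat] = np.abs(z) > threshold
    return SpatialMap(
        component_id=component_id,
        values=values,
        volume=volume,
        zmap=zvol,
        binary_mask=binary,
        sampled_mask=sampled,
    )


def glm_reference_maps(
    bolds: Sequence[np.ndarray],
    regressors: Mapping[str, np.ndarray],
    threshold: float = 2.3,
) -> list[ReferenceTemplate]:
    """Minimal mass-univariate GLM producing group activation templates.

    Per subject, each voxel's time series is regressed on the event
    regressors plus an intercept (ordinary least squares); the group map is
    a one-sample t-test across subjects on the per-subject effect sizes,
    converted to z.  The binary template is ``z > threshold``.

    ``bolds`` are frames x voxels arrays on a common voxel space (e.g. the
    sampled voxels); templates are returned on that same space.
    """
    labels = list(regressors.keys())
    X = np.column_stack([regressors[l] for l in labels] + [np.ones(len(next(iter(regressors.values()))))])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (constant or collinear regressors)")
    effects = []  # subject x event x voxel
    for Y in bolds:
        Y = np.asarray(Y, dtype=float)
        if Y.shape[0] != X.shape[0]:
            raise ValueError("run length does not match regressor length")
        beta = np.linalg.lstsq(X, Y, rcond=None)[0]
        effects.append(beta[: len(labels)])
    B = np.stack(effects)  # n_subj x n_event x n_vox
    n_subj = B.shape[0]
    if n_subj < 2:
        raise ValueError("group map needs at least two subjects")
    mean = B.mean(axis=0)
    sd = B.std(axis=0, ddof=1)
    se = sd / np.sqrt(n_subj)
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, mean / se, 0.0)
    # t -> z through matched tail probabilities
    pz = stats.t.sf(tval, df=n_subj - 1)
    z = stats.norm.isf(np.clip(pz, 1e-300, 1 - 1e-16))
    templates = []
    for e, label in enumerate(labels):
        mask = z[e] > threshold
        if mask.sum() == 0:
            continue
        templates.append(ReferenceTemplate(label=label, binary_mask=mask, zmap=z[e]))
    return templates


def overlap_rate(X: np.ndarray, T: np.ndarray) -> float:
    """|X ∩ T| / |T| between two binary masks on the same voxel space."""
    X = np.asarray(X).astype(bool).ravel()
    T = np.asarray(T).astype(bool).ravel()
    if X.shape != T.shape:
        raise ValueError("masks must live on the same voxel space")
    nT = T.sum()
    if nT == 0:
        raise ValueError("reference template is empty")
    return float((X & T).sum() / nT)


def categorize_components(
    component_masks: Sequence[np.ndarray],
    paradigm_corrs: np.ndarray,
    templates: Sequence[ReferenceTemplate],
    r_task: float = 0.4,
    o_rsn: float = 0.3,
    o_int: float = 0.25,
) -> list[str]:
    """Assign each component to task-evoked / resting-state / integrated / artifact.

    A component is task-evoked when some task's course correlates with its
    paradigm at |r| >= ``r_task``; otherwise resting-state when its best
    template overlap reaches ``o_rsn``; otherwise integrated when at least
    two templates each overlap at ``o_int``; otherwise artifact.

    ``paradigm_corrs`` is k2 x n_tasks (course-vs-paradigm Pearson r).
    """
    paradigm_corrs = np.asarray(paradigm_corrs)
    labels = []
    for j, mask in enumerate(component_masks):
        overlaps = (
            np.array([overlap_rate(mask, t.binary_mask) for t in templates])
            if len(templates)
            else np.zeros(0)
        )
        max_r = np.nanmax(np.abs(paradigm_corrs[j])) if paradigm_corrs.size else 0.0
        if max_r >= r_task:
            labels.append("task-evoked")
        elif overlaps.size and overlaps.max() >= o_rsn:
            labels.append("resting-state")
        elif overlaps.size and (overlaps >= o_int).sum() >= 2:
            labels.append("integrated")
        else:
            labels.append("artifact")
    return labels


def all_task_courses(
    tsr: TsrResult,
    ssr: SsrResult,
    paradigm_regressors: Mapping[str, np.ndarray],
) -> dict[str, TaskTemporalCourses]:
    """Temporal courses (with paradigm correlations) for every task."""
    return {
        task: task_temporal_courses(
            tsr.D1, ssr.alpha2, ssr.index, task, paradigm_regressors.get(task)
        )
        for task in ssr.index.tasks
    }
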