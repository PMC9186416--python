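"""Reproducible end-to-end experiment driver.

``run_experiment`` wires the whole chain together — simulate (or load),
split subjects, sample voxels, fit the two dictionary stages on training
subjects, code held-out subjects with frozen dictionaries, classify, and
optionally run the post-hoc analyses (temporal/spatial feature recovery,
ROA curve, category ablation, capacity-vs-overlap regression) — repeated
``n_repeats`` times with a fresh subject split and a fresh voxel sample
per repeat, aggregating mean +/- SD accuracy.

Every random choice derives from the single config seed, and the manifest
written with the report suffices to re-run bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .blocks import TASKS
from . import classify as cls
from . import features as feat
from .dataio import group_matrix_from_dataset, sample_voxels
from .pipeline import (
    DEFAULT_K1,
    DEFAULT_K2,
    DEFAULT_LAMBDA1,
    DEFAULT_LAMBDA2,
    PipelineModel,
    fit_pipeline,
)
from .synthetic import SyntheticDataset, make_ground_truth, synthesize_dataset


@dataclass
class ExperimentConfig:
    """All knobs of one experiment; round-trips through YAML unchanged."""

    # sparse-representation stages
    k1: int = DEFAULT_K1
    lambda1: float = DEFAULT_LAMBDA1
    k2: int = DEFAULT_K2
    lambda2: float = DEFAULT_LAMBDA2
    n_iterations: int = 200
    batch_size: int = 256
    normalize_s2: bool = False
    # sampling / split / protocol
    voxel_fraction: float = 0.1
    n_train_subjects: int = 30
    n_repeats: int = 10
    seed: int = 0
    # thresholds for maps and categorization
    map_z_threshold: float = 2.3
    r_task: float = 0.4
    o_rsn: float = 0.3
    o_int: float = 0.25
    # synthetic-data section
    grid_shape: tuple[int, int, int] = (16, 16, 16)
    n_subjects: int = 60
    t: int = 176
    tr: float = 0.72
    n_task_components: int = 7
    n_rsn: int = 3
    n_artifact: int = 2
    noise_sigma: float = 0.05
    jitter_sd: float = 0.1
    task_lengths: dict[str, int] | None = None
    # which post-hoc analyses to run per repeat
    analyses: tuple[str, ...] = ()

    def validate(self) -> None:
        if not (0 < self.voxel_fraction <= 1):
            raise ValueError("voxel_fraction must be in (0, 1]")
        if self.n_train_subjects >= self.n_subjects:
            raise ValueError("need at least one held-out subject")
        for name in ("k1", "k2", "n_repeats", "n_iterations", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.lambda1 <= 0 or self.lambda2 <= 0:
            raise ValueError("lambdas must be positive")

    def to_yaml(self, path: str | Path | None = None) -> str:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["analyses"] = list(self.analyses)
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "ExperimentConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = yaml.safe_load(text)
        d["grid_shape"] = tuple(d.get("grid_shape", (16, 16, 16)))
        d["analyses"] = tuple(d.get("analyses", ()))
        return cls(**d)


def desk_scale_config(seed: int = 0, analyses: Sequence[str] = ()) -> ExperimentConfig:
    """The desk-scale synthetic study conditions.

    A 10x10x10 grid (1000 voxels, 10% sampled), 12 subjects split 8/4,
    seven unequal-length tasks truncated to 120 frames at TR 0.72 s,
    k1=24 temporal and k2=16 spatial atoms with the canonical penalties
    (0.05, 0.1), moderate noise (sigma 0.05 against unit-norm atoms with
    task gains of 3) and 10% spatial-map jitter.
    """
    return ExperimentConfig(
        k1=24,
        k2=16,
        n_iterations=30,
        voxel_fraction=0.1,
        n_train_subjects=8,
        n_repeats=3,
        seed=seed,
        grid_shape=(10, 10, 10),
        n_subjects=12,
        t=176,
        task_lengths={
            "emotion": 120,
            "motor": 150,
            "gambling": 135,
            "language": 160,
            "relational": 128,
            "social": 145,
            "wm": 176,
        },
        analyses=tuple(analyses),
    )


@dataclass(frozen=True)
class RepeatResult:
    """Everything one train/test repeat produced."""

    repeat: int
    accuracy: float
    confusion: np.ndarray = field(repr=False)
    train_subjects: tuple[str, ...]
    test_subjects: tuple[str, ...]
    sampling_seed: int
    model: PipelineModel | None = None
    task_pcorr: dict[str, float] | None = None  # best |r| per task
    map_overlap: dict[str, float] | None = None  # best overlap per planted task atom
    categories: list[str] | None = None
    roa_values: np.ndarray | None = None
    roa_curve: list[tuple[int, float]] | None = None
    ablation: dict[str, float] | None = None
    capacity: cls.CapacityOverlapResult | None = None


@dataclass(frozen=True)
class ExperimentReport:
    config: ExperimentConfig
    repeats: list[RepeatResult]

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([r.accuracy for r in self.repeats])

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def sd_accuracy(self) -> float:
        return float(self.accuracies.std(ddof=1)) if len(self.repeats) > 1 else 0.0

    def write(self, outdir: str | Path) -> Path:
        """TSV tables plus a JSON manifest sufficient to re-run."""
        import pandas as pd

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rows = []
        for r in self.repeats:
            row = {"repeat": r.repeat, "accuracy": r.accuracy,
                   "train_subjects": ",".join(r.train_subjects),
                   "test_subjects": ",".join(r.test_subjects)}
            if r.task_pcorr:
                row.update({f"pcorr_{k}": v for k, v in r.task_pcorr.items()})
            if r.map_overlap:
                row.update({f"overlap_{k}": v for k, v in r.map_overlap.items()})
            rows.append(row)
        pd.DataFrame(rows).to_csv(outdir / "accuracy.tsv", sep="\t", index=False)
        for r in self.repeats:
            if r.roa_curve is not None:
                pd.DataFrame(r.roa_curve, columns=["n_components", "accuracy"]).to_csv(
                    outdir / f"roa_curve_rep{r.repeat}.tsv", sep="\t", index=False
                )
        manifest = {
            "config": yaml.safe_load(self.config.to_yaml()),
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return outdir


def simulate_dataset(config: ExperimentConfig) -> SyntheticDataset:
    """Ground truth + noisy dataset from the config's synthetic section."""
    rng = np.random.default_rng([config.seed, 0xDA7A])
    gt = make_ground_truth(
        n_task_components=config.n_task_components,
        n_rsn=config.n_rsn,
        n_artifact=config.n_artifact,
        grid_shape=config.grid_shape,
        t=config.t,
        tr=config.tr,
        seed=int(rng.integers(2**31)),
        noise_sigma=config.noise_sigma,
    )
    return synthesize_dataset(
        gt,
        n_subjects=config.n_subjects,
        task_lengths=config.task_lengths,
        noise_sigma=config.noise_sigma,
        jitter_sd=config.jitter_sd,
        seed=int(rng.integers(2**31)),
    )


def planted_templates(
    dataset: SyntheticDataset, sampling, groups: Sequence[str]
) -> list[feat.ReferenceTemplate]:
    """Planted-map supports restricted to the sampled voxels, as templates.

    Synthetic stand-ins for reference activation/RSN templates.
    """
    gt = dataset.gt
    flat = sampling.sampled_indices
    templates = []
    for j in range(gt.n_atoms):
        if gt.atom_group(j) not in groups:
            continue
        mask = gt.map_mask(j)[flat]
        if mask.sum() == 0:
            continue
        templates.append(
            feat.ReferenceTemplate(label=gt.atom_labels[j], binary_mask=mask)
        )
    return templates


def run_repeat(
    dataset: SyntheticDataset,
    config: ExperimentConfig,
    repeat: int,
    keep_model: bool = False,
) -> RepeatResult:
    """One split/sample/fit/transform/classify pass plus requested analyses."""
    rng = np.random.default_rng([config.seed, repeat, 0x5EED])
    subjects = list(dataset.subjects)
    perm = rng.permutation(len(subjects))
    train_subjects = tuple(subjects[i] for i in sorted(perm[: config.n_train_subjects]))
    test_subjects = tuple(subjects[i] for i in sorted(perm[config.n_train_subjects:]))
    sampling_seed = int(rng.integers(2**31))
    sampling = sample_voxels(dataset.mask, config.voxel_fraction, sampling_seed)

    S1_train = group_matrix_from_dataset(dataset, train_subjects, sampling)
    S1_test = group_matrix_from_dataset(dataset, test_subjects, sampling)

    model = fit_pipeline(
        S1_train,
        k1=config.k1, lambda1=config.lambda1,
        k2=config.k2, lambda2=config.lambda2,
        seed=int(rng.integers(2**31)),
        n_iterations=config.n_iterations,
        batch_size=config.batch_size,
        normalize_s2=config.normalize_s2,
    )
    test_codes = model.transform(S1_test)

    train_samples = cls.build_samples(model.ssr.alpha2, model.ssr.index)
    test_samples = cls.build_samples(test_codes.alpha2, test_codes.index2)
    clf = cls.train_svm(train_samples, manifest=model.manifest)
    accuracy, confusion = cls.evaluate_accuracy(clf, test_samples)

    extras: dict = {}
    t_min = S1_train.t
    gt = dataset.gt

    if "features" in config.analyses or "categories" in config.analyses:
        regressors = {
            task: gt.paradigms[task].truncated(t_min).regressor for task in TASKS
        }
        courses = feat.all_task_courses(model.tsr, model.ssr, regressors)
        extras["task_pcorr"] = {
            task: float(np.nanmax(np.abs(c.p_corr))) for task, c in courses.items()
        }
        comp_maps = [
            feat.extract_spatial_map(model.ssr.D2, j, sampling, config.map_z_threshold)
            for j in range(config.k2)
        ]
        comp_masks = [m.flat_mask() for m in comp_maps]
        flat = sampling.sampled_indices
        overlaps = {}
        for j in gt.atoms_in_group("task"):
            planted = gt.map_mask(j)[flat]
            if planted.sum() == 0:
                continue
            overlaps[gt.atom_labels[j]] = max(
                feat.overlap_rate(m, planted) for m in comp_masks
            )
        extras["map_overlap"] = overlaps
        if "categories" in config.analyses:
            pcorr_matrix = np.column_stack(
                [courses[task].p_corr for task in TASKS]
            )  # k2 x 7
            templates = planted_templates(dataset, sampling, ("resting",))
            extras["categories"] = feat.categorize_components(
                comp_masks, pcorr_matrix, templates,
                r_task=config.r_task, o_rsn=config.o_rsn, o_int=config.o_int,
            )

    if "roa" in config.analyses:
        roa = cls.compute_roa(model.ssr.alpha2, model.ssr.index)
        extras["roa_values"] = roa.values
        extras["roa_curve"] = cls.roa_incremental_classification(
            train_samples, test_samples, roa
        )

    if "ablation" in config.analyses and "categories" in extras:
        extras["ablation"] = cls.ablation_experiment(
            train_samples, test_samples, extras["categories"]
        )

    if "capacity" in config.analyses and "features" in config.analyses:
        comp_maps = [
            feat.extract_spatial_map(model.ssr.D2, j, sampling, config.map_z_threshold)
            for j in range(config.k2)
        ]
        templates = planted_templates(dataset, sampling, ("task", "resting"))
        extras["capacity"] = cls.capacity_vs_overlap(
            train_samples, test_samples,
            [m.flat_mask() for m in comp_maps], templates, k2=config.k2,
        )

    return RepeatResult(
        repeat=repeat,
        accuracy=accuracy,
        confusion=confusion,
        train_subjects=train_subjects,
        test_subjects=test_subjects,
        sampling_seed=sampling_seed,
        model=model if keep_model else None,
        **extras,
    )


def run_experiment(
    config: ExperimentConfig,
    dataset: SyntheticDataset | None = None,
    keep_models: bool = False,
) -> ExperimentReport:
    """The full protocol: n_repeats fresh splits and voxel samples."""
    config.validate()
    if dataset is None:
        dataset = simulate_dataset(config)
    repeats = [
        run_repeat(dataset, config, r, keep_model=keep_models)
        for r in range(config.n_repeats)
    ]
    return ExperimentReport(config=config, repeats=repeats)


def sweep_lambdas(
    config: ExperimentConfig,
    lambda1_grid: Sequence[float],
    lambda2_grid: Sequence[float],
    dataset: SyntheticDataset | None = None,
) -> dict[tuple[float, float], float]:
    """One train/test evaluation per (lambda1, lambda2) cell on a fixed split.

    Cell failures are recorded as NaN without aborting the sweep.
    """
    if not len(lambda1_grid) or not len(lambda2_grid):
        raise ValueError("lambda grids must be non-empty")
    config.validate()
    if dataset is None:
        dataset = simulate_dataset(config)
    results: dict[tuple[float, float], float] = {}
    for l1 in lambda1_grid:
        for l2 in lambda2_grid:
            cell = dataclasses.replace(
                config, lambda1=float(l1), lambda2=float(l2), analyses=()
            )
            try:
                rep = run_repeat(dataset, cell, repeat=0)
                results[(float(l1), float(l2))] = rep.accuracy
            except Exception:
                results[(float(l1), float(l2))] = float("nan")
    return results
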