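"""Synthetic multitask BOLD generator with planted ground truth.

Emulates the structure of a seven-task block-design fMRI study: every
(subject, task) run is a low-rank product of planted temporal atoms and
nonnegative spatial blob maps, plus Gaussian noise.  Atoms come in three
groups — task-evoked (HRF-convolved block designs, one per task),
resting-state (slow smooth oscillations present in every task) and
artifact (drifts, spikes, steps) — so that every downstream stage of the
pipeline has a known answer to recover: temporal courses, spatial maps,
task-discriminative loading patterns, and component categories.

Tasks have unequal numbers of frames (exercising truncation), subjects get
a small multiplicative jitter on their spatial maps (interindividual
variability), and everything is deterministic given a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .blocks import TASKS
from .hrf import convolve_boxcar

# Block design table, seconds: (onset, duration) per block at the longest
# supported run (176 frames at TR 0.72 s).  Onsets are jittered rather than
# periodic: the seven HRF-convolved regressors are pairwise decorrelated
# (|r| < 0.3) both at full length and after truncation to 120 frames, which
# strictly periodic designs cannot achieve.  Blocks beyond a shorter run's
# window are simply dropped.
_BLOCK_DESIGNS: dict[str, tuple[tuple[float, float], ...]] = {
    "emotion": ((7.3, 9.5), (50.4, 12.4), (84.3, 7.6)),
    "motor": ((2.5, 10.6), (36.8, 10.2), (85.0, 12.4)),
    "gambling": ((8.2, 12.4), (40.4, 11.9), (69.7, 13.2), (104.6, 12.6)),
    "language": ((30.2, 11.0), (75.2, 14.7)),
    "relational": ((11.6, 6.0), (62.8, 8.6), (89.3, 8.7)),
    "social": ((2.9, 9.8), (22.6, 7.5), (46.8, 6.9), (80.7, 11.7), (101.8, 8.7)),
    "wm": ((14.1, 14.9), (37.8, 8.7), (81.6, 9.9)),
}

# Relative run lengths mirroring a seven-task protocol with unequal
# durations (longest task = 1).
_RELATIVE_LENGTHS: dict[str, float] = {
    "emotion": 176 / 405,
    "motor": 284 / 405,
    "gambling": 253 / 405,
    "language": 316 / 405,
    "relational": 232 / 405,
    "social": 274 / 405,
    "wm": 405 / 405,
}


@dataclass(frozen=True)
class TaskParadigm:
    """Block design of one task: events plus derived per-frame curves."""

    task_id: str
    onsets: np.ndarray  # seconds
    durations: np.ndarray  # seconds
    amplitudes: np.ndarray  # unitless
    tr: float  # seconds
    n_frames: int
    boxcar: np.ndarray = field(repr=False)  # per-frame stimulus indicator
    regressor: np.ndarray = field(repr=False)  # HRF-convolved curve

    def truncated(self, n_frames: int) -> "TaskParadigm":
        """The same design evaluated on the first ``n_frames`` frames.

        Events that no longer fit the shorter window are dropped.
        """
        keep = self.onsets < n_frames * self.tr
        return make_task_paradigm(
            n_frames,
            self.tr,
            [
                (float(o), float(min(d, n_frames * self.tr - o)), float(a))
                for o, d, a in zip(
                    self.onsets[keep], self.durations[keep], self.amplitudes[keep]
                )
            ],
            task_id=self.task_id,
        )


def make_task_paradigm(
    n_frames: int,
    tr: float,
    blocks: list[tuple[float, float] | tuple[float, float, float]],
    task_id: str = "task",
) -> TaskParadigm:
    """Build a paradigm from (onset, duration[, amplitude]) blocks.

    Every block must lie inside the scan window ``n_frames * tr``; the
    boxcar takes the block amplitude on frames whose acquisition time falls
    within the block, and the regressor is the boxcar convolved with the
    canonical double-gamma HRF.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    if n_frames <= 0:
        raise ValueError("n_frames must be positive")
    window = n_frames * tr
    onsets, durations, amplitudes = [], [], []
    for b in blocks:
        onset, duration = float(b[0]), float(b[1])
        amplitude = float(b[2]) if len(b) > 2 else 1.0
        if onset < 0 or duration <= 0 or onset + duration > window:
            raise ValueError(
                f"block (onset={onset}, duration={duration}) exceeds the "
                f"{window:.2f} s scan window"
            )
        onsets.append(onset)
        durations.append(duration)
        amplitudes.append(amplitude)
    onsets_a = np.asarray(onsets)
    durations_a = np.asarray(durations)
    amplitudes_a = np.asarray(amplitudes)
    frame_times = np.arange(n_frames) * tr
    boxcar = np.zeros(n_frames)
    for o, d, a in zip(onsets_a, durations_a, amplitudes_a):
        boxcar[(frame_times >= o) & (frame_times < o + d)] = a
    regressor = convolve_boxcar(boxcar, tr)
    return TaskParadigm(
        task_id=task_id,
        onsets=onsets_a,
        durations=durations_a,
        amplitudes=amplitudes_a,
        tr=tr,
        n_frames=n_frames,
        boxcar=boxcar,
        regressor=regressor,
    )


def default_task_paradigm(task: str, n_frames: int, tr: float) -> TaskParadigm:
    """Canonical block design for one of the seven tasks.

    Blocks that do not fit the scan window are dropped; the window must at
    least hold the task's first block.
    """
    all_blocks = _BLOCK_DESIGNS[task]
    window = n_frames * tr
    onset0, dur0 = all_blocks[0]
    if onset0 + dur0 > window:
        raise ValueError(
            f"{n_frames} frames at tr={tr} is too short for the first "
            f"{task} block (onset {onset0} s, duration {dur0} s)"
        )
    blocks = [(o, d) for o, d in all_blocks if o + d <= window]
    return make_task_paradigm(n_frames, tr, blocks, task_id=task)


def default_task_lengths(t_max: int) -> dict[str, int]:
    """Unequal per-task frame counts scaled so the longest task has t_max."""
    return {task: int(round(_RELATIVE_LENGTHS[task] * t_max)) for task in TASKS}


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    denom = np.linalg.norm(x) * np.linalg.norm(y)
    if denom == 0:
        return np.nan
    return float(x @ y / denom)


@dataclass(frozen=True)
class SyntheticGroundTruth:
    """Planted factors behind a synthetic multitask dataset.

    ``temporal_atoms`` (t x K, unit l2 columns) and ``spatial_maps`` (K x n)
    generate the signal; ``task_gain`` (n_tasks x K) scales each atom per
    task, with every task's own evoked component strictly dominant in that
    task.  ``atom_labels`` partition the K atoms into the groups
    ``task:<name>``, ``resting:<i>`` and ``artifact:<kind>``.
    """

    grid_shape: tuple[int, int, int]
    t: int
    tr: float
    temporal_atoms: np.ndarray = field(repr=False)
    atom_labels: tuple[str, ...]
    spatial_maps: np.ndarray = field(repr=False)
    task_gain: np.ndarray = field(repr=False)
    noise_sigma: float
    seed: int
    paradigms: dict[str, TaskParadigm] = field(repr=False)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_shape))

    @property
    def n_atoms(self) -> int:
        return self.temporal_atoms.shape[1]

    def atom_group(self, j: int) -> str:
        return self.atom_labels[j].split(":", 1)[0]

    def atoms_in_group(self, group: str) -> list[int]:
        return [j for j in range(self.n_atoms) if self.atom_group(j) == group]

    def map_mask(self, j: int, rel_threshold: float = 0.3) -> np.ndarray:
        """Binary support of a planted map (values above a fraction of peak)."""
        m = self.spatial_maps[j]
        return m > rel_threshold * m.max()


def _resting_atom(rng: np.random.Generator, t: int, tr: float) -> np.ndarray:
    """Slow smooth oscillation: 2-3 sinusoids in the 0.008-0.03 Hz band."""
    times = np.arange(t) * tr
    n_comp = int(rng.integers(2, 4))
    x = np.zeros(t)
    for _ in range(n_comp):
        f = rng.uniform(0.008, 0.03)
        a = rng.uniform(0.5, 1.0)
        phi = rng.uniform(0, 2 * np.pi)
        x += a * np.sin(2 * np.pi * f * times + phi)
    return x


def _artifact_atom(rng: np.random.Generator, t: int, kind: int) -> np.ndarray:
    """Scanner/motion-like nuisance course: drift, spike train, or step."""
    if kind % 3 == 0:  # slow scanner drift: random low-order polynomial
        u = np.linspace(-1, 1, t)
        c = rng.uniform(-1, 1, size=3)
        return c[0] * u + c[1] * u**2 + c[2] * u**3
    if kind % 3 == 1:  # sparse large spikes (sudden motion)
        x = np.zeros(t)
        n_spk = int(rng.integers(3, 7))
        pos = rng.choice(t, size=n_spk, replace=False)
        x[pos] = rng.choice([-1.0, 1.0], size=n_spk) * rng.uniform(0.8, 1.2, size=n_spk)
        return ndimage.gaussian_filter1d(x, 0.8)
    # abrupt baseline step
    x = np.zeros(t)
    x[int(rng.integers(t // 4, 3 * t // 4)):] = 1.0
    return x


def _blob_maps(
    rng: np.random.Generator, k: int, grid_shape: tuple[int, int, int]
) -> np.ndarray:
    """K distinct Gaussian blobs on the grid, peak 1, flattened C-order."""
    dims = np.asarray(grid_shape, dtype=float)
    margin = 0.15 * dims
    centers: list[np.ndarray] = []
    min_sep = 0.25 * dims.min()
    for _ in range(k):
        for _ in range(200):
            c = rng.uniform(margin, dims - margin)
            if all(np.linalg.norm(c - c0) >= min_sep for c0 in centers):
                break
        centers.append(c)
    coords = np.stack(
        np.meshgrid(*[np.arange(d) for d in grid_shape], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    maps = np.empty((k, coords.shape[0]))
    for j, c in enumerate(centers):
        sigma = rng.uniform(0.08, 0.14) * dims.min()
        d2 = ((coords - c) ** 2).sum(axis=1)
        maps[j] = np.exp(-d2 / (2 * sigma**2))
    return maps


def make_ground_truth(
    n_task_components: int = 7,
    n_rsn: int = 3,
    n_artifact: int = 2,
    grid_shape: tuple[int, int, int] = (16, 16, 16),
    t: int = 176,
    tr: float = 0.72,
    seed: int = 0,
    noise_sigma: float = 0.05,
    task_gain_hi: float = 3.0,
    rsn_gain: float = 1.5,
    artifact_gain: float = 1.0,
    max_draws: int = 200,
) -> SyntheticGroundTruth:
    """Plant temporal atoms, spatial maps and per-task gains.

    Task-evoked atoms are the HRF-convolved canonical block designs
    (assigned to the seven tasks cyclically if more than seven are asked
    for); resting and artifact atoms are drawn randomly and redrawn — up
    to ``max_draws`` times each, deterministically — until all planted
    atoms are mutually decorrelated (pairwise |r| < 0.6) and, like the
    task regressors between themselves, every shared atom is
    near-orthogonal (|r| < 0.3) to every task paradigm: paradigm
    independence is what makes a planted component genuinely shared.
    """
    if n_task_components < 1:
        raise ValueError("need at least one task component")
    if int(np.prod(grid_shape)) < 50:
        raise ValueError("grid must contain at least 50 voxels")

    paradigms = {task: default_task_paradigm(task, t, tr) for task in TASKS}

    task_atoms, task_labels = [], []
    for c in range(n_task_components):
        task = TASKS[c % len(TASKS)]
        reg = paradigms[task].regressor.copy()
        task_atoms.append(reg / np.linalg.norm(reg))
        task_labels.append(f"task:{task}")

    # regressor cross-correlation is fixed by the design table; fail loudly
    for a in range(len(TASKS)):
        for b in range(a + 1, len(TASKS)):
            r = _pearson(paradigms[TASKS[a]].regressor, paradigms[TASKS[b]].regressor)
            if abs(r) >= 0.3:
                raise RuntimeError(
                    f"task designs {TASKS[a]}/{TASKS[b]} too correlated (r={r:.2f})"
                )

    rng = np.random.default_rng(seed)
    regs = np.column_stack([paradigms[task].regressor for task in TASKS])
    atoms = list(task_atoms)
    labels = list(task_labels)

    def _accept(x: np.ndarray) -> bool:
        # shared (resting/artifact) atoms must not track any task paradigm
        # — paradigm independence is what makes them shared components —
        # and all planted atoms stay pairwise decorrelated
        if max(abs(_pearson(x, regs[:, c])) for c in range(regs.shape[1])) >= 0.3:
            return False
        return all(abs(_pearson(x, a)) < 0.6 for a in atoms)

    for i in range(n_rsn + n_artifact):
        is_rsn = i < n_rsn
        for _ in range(max_draws):
            x = _resting_atom(rng, t, tr) if is_rsn else _artifact_atom(rng, t, i - n_rsn)
            x = x / np.linalg.norm(x)
            if _accept(x):
                break
        else:
            raise RuntimeError("could not decorrelate planted atoms; adjust the design")
        atoms.append(x)
        labels.append(f"resting:{i}" if is_rsn else f"artifact:{i - n_rsn}")
    A = np.column_stack(atoms)

    # sign convention: largest-magnitude entry positive
    flips = np.sign(A[np.abs(A).argmax(axis=0), np.arange(A.shape[1])])
    A = A * np.where(flips == 0, 1.0, flips)

    k = A.shape[1]
    maps = _blob_maps(rng, k, grid_shape)

    gains = np.zeros((len(TASKS), k))
    for j, label in enumerate(labels):
        group, name = label.split(":", 1)
        if group == "task":
            gains[TASKS.index(name), j] = task_gain_hi
        elif group == "resting":
            gains[:, j] = rsn_gain
        else:
            gains[:, j] = artifact_gain

    return SyntheticGroundTruth(
        grid_shape=tuple(grid_shape),
        t=t,
        tr=tr,
        temporal_atoms=A,
        atom_labels=tuple(labels),
        spatial_maps=maps,
        task_gain=gains,
        noise_sigma=noise_sigma,
        seed=seed,
        paradigms=paradigms,
    )


@dataclass(frozen=True)
class SyntheticDataset:
    """Per-(subject, task) BOLD runs generated from a ground truth."""

    gt: SyntheticGroundTruth
    subjects: tuple[str, ...]
    task_lengths: dict[str, int]
    signals: dict[tuple[str, str], np.ndarray] = field(repr=False)
    noise_sigma: float
    jitter_sd: float
    seed: int

    @property
    def mask(self) -> np.ndarray:
        return np.ones(self.gt.grid_shape, dtype=bool)

    def clean_signal(self, subject: str, task: str) -> np.ndarray:
        """Noise-free, jitter-free planted signal for one run (oracle use)."""
        gt = self.gt
        length = self.task_lengths[task]
        gains = gt.task_gain[TASKS.index(task)]
        return (gt.temporal_atoms[:length] * gains) @ gt.spatial_maps

    def manifest(self) -> dict:
        gt = self.gt
        return {
            "seed": self.seed,
            "ground_truth_seed": gt.seed,
            "tr": gt.tr,
            "grid_shape": list(gt.grid_shape),
            "atom_labels": list(gt.atom_labels),
            "task_gain": gt.task_gain.tolist(),
            "noise_sigma": self.noise_sigma,
            "jitter_sd": self.jitter_sd,
            "subjects": list(self.subjects),
            "task_lengths": dict(self.task_lengths),
        }

    def write(self, outdir: str | Path) -> Path:
        """Write NIfTI volumes, mask, FSL-style 3-column event files, manifest."""
        import nibabel as nib

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        affine = np.eye(4)
        nib.save(
            nib.Nifti1Image(self.mask.astype(np.uint8), affine),
            outdir / "mask.nii.gz",
        )
        files: dict[str, dict[str, str]] = {}
        for (sub, task), sig in self.signals.items():
            vol = np.zeros(self.gt.grid_shape + (sig.shape[0],), dtype=np.float32)
            vol.reshape(-1, sig.shape[0])[:] = sig.T
            name = f"{sub}_task-{task}_bold.nii.gz"
            nib.save(nib.Nifti1Image(vol, affine), outdir / name)
            files.setdefault(sub, {})[task] = name
        for task in TASKS:
            par = self.gt.paradigms[task]
            with open(outdir / f"task-{task}_events.txt", "w") as fh:
                for o, d, a in zip(par.onsets, par.durations, par.amplitudes):
                    fh.write(f"{o:.3f}\t{d:.3f}\t{a:g}\n")
        man = self.manifest()
        man["bold_files"] = files
        man["mask_file"] = "mask.nii.gz"
        man["event_files"] = {task: f"task-{task}_events.txt" for task in TASKS}
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(man, fh, indent=1)
        return outdir


def synthesize_dataset(
    gt: SyntheticGroundTruth,
    n_subjects: int = 12,
    task_lengths: dict[str, int] | None = None,
    noise_sigma: float | None = None,
    jitter_sd: float = 0.1,
    seed: int = 0,
) -> SyntheticDataset:
    """Generate noisy per-(subject, task) runs from planted factors.

    Each run is ``temporal_atoms[:L] @ diag(task_gain) @ maps_i`` plus iid
    Gaussian noise, where ``maps_i`` are the planted spatial maps modulated
    by a smooth per-subject multiplicative field of SD ``jitter_sd``.
    """
    if noise_sigma is None:
        noise_sigma = gt.noise_sigma
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be nonnegative")
    if task_lengths is None:
        task_lengths = default_task_lengths(gt.t)
    for task, length in task_lengths.items():
        if length > gt.t:
            raise ValueError(f"task {task}: length {length} exceeds planted t={gt.t}")
        onset0, dur = _BLOCK_DESIGNS[task][0]
        if length * gt.tr < onset0 + dur:
            raise ValueError(f"task {task}: {length} frames holds no complete block")

    rng = np.random.default_rng(seed)
    subjects = tuple(f"sub-{i + 1:02d}" for i in range(n_subjects))
    signals: dict[tuple[str, str], np.ndarray] = {}
    for sub in subjects:
        if jitter_sd > 0:
            field3d = rng.standard_normal(gt.grid_shape)
            field3d = ndimage.gaussian_filter(field3d, sigma=2.0)
            field3d /= max(field3d.std(), 1e-12)
            maps_i = gt.spatial_maps * (1.0 + jitter_sd * field3d.ravel())
        else:
            maps_i = gt.spatial_maps
        for task in TASKS:
            length = task_lengths[task]
            gains = gt.task_gain[TASKS.index(task)]
            clean = (gt.temporal_atoms[:length] * gains) @ maps_i
            noise = noise_sigma * rng.standard_normal(clean.shape) if noise_sigma else 0.0
            signals[(sub, task)] = clean + noise
    return SyntheticDataset(
        gt=gt,
        subjects=subjects,
        task_lengths=dict(task_lengths),
        signals=signals,
        noise_sigma=float(noise_sigma),
        jitter_sd=float(jitter_sd),
        seed=seed,
    )
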