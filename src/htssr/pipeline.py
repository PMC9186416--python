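"""The two-stage group-wise sparse representation pipeline.

Stage 1 (temporal sparse representation, TSR) factorizes the group signal
matrix S1 (frames x voxels*tasks*subjects) into a shared temporal
dictionary D1 and loadings alpha1.  The per-(subject, task) blocks of
alpha1 are transposed and restacked into S2 (voxels x k1*tasks*subjects),
which stage 2 (spatial sparse representation, SSR) factorizes into a
shared spatial dictionary D2 and loadings alpha2.  Held-out subjects are
coded against the *frozen* dictionaries with the training lambdas — no
test value ever updates a dictionary or a normalization statistic.

The chain gives the reconstruction identity
``S1_{i,t} ~= D1 (alpha2_{i,t})^T (D2)^T`` per subject and task, so the
task-discriminative information is concentrated in the alpha2 blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .blocks import BlockIndex
from .dataio import GroupSignalMatrix, normalize_columns
from .sparse import Dictionary, SparseCodes, lasso_code, learn_dictionary

# Canonical protocol-scale defaults for the two stages.
DEFAULT_K1 = 200
DEFAULT_LAMBDA1 = 0.05
DEFAULT_K2 = 50
DEFAULT_LAMBDA2 = 0.1


@dataclass(frozen=True)
class TsrResult:
    """Stage-1 output: temporal dictionary and voxel-wise loadings."""

    D1: Dictionary
    alpha1: SparseCodes
    index: BlockIndex  # inherited from S1 (inner axis = sampled voxels)

    @property
    def k1(self) -> int:
        return self.D1.k

    @property
    def lambda1(self) -> float:
        return self.D1.lambda_used


@dataclass(frozen=True)
class SsrResult:
    """Stage-2 output: spatial dictionary and atom-wise loadings."""

    D2: Dictionary
    alpha2: SparseCodes
    index: BlockIndex  # inner axis = k1 temporal atoms
    normalized: bool

    @property
    def k2(self) -> int:
        return self.D2.k

    @property
    def lambda2(self) -> float:
        return self.D2.lambda_used


@dataclass(frozen=True)
class TestCodes:
    """Held-out loadings obtained with frozen dictionaries."""

    alpha1: SparseCodes
    alpha2: SparseCodes
    index1: BlockIndex
    index2: BlockIndex


def fit_tsr(
    S1: GroupSignalMatrix,
    k1: int = DEFAULT_K1,
    lambda1: float = DEFAULT_LAMBDA1,
    seed: int = 0,
    n_iterations: int = 200,
    batch_size: int = 256,
    coding_algorithm: str = "lasso_cd",
) -> TsrResult:
    """Learn the shared temporal dictionary on the group matrix."""
    D1, alpha1 = learn_dictionary(
        S1.data,
        k=k1,
        lam=lambda1,
        n_iterations=n_iterations,
        batch_size=batch_size,
        seed=seed,
        domain_tag="temporal",
        coding_algorithm=coding_algorithm,
    )
    return TsrResult(D1=D1, alpha1=alpha1, index=S1.index)


def build_ssr_input(tsr: TsrResult) -> tuple[np.ndarray, BlockIndex]:
    """Restack stage-1 loadings into the stage-2 input matrix.

    For each (subject, task), the k1 x n loading block is transposed to
    n x k1 and the blocks are column-stacked subject-major, task-major,
    atom-minor: ``S2[v, col(i, t, j)] = alpha1[j, col(i, t, v)]``.
    """
    idx1 = tsr.index
    k1, n = tsr.k1, idx1.n_inner
    p, T = idx1.n_subjects, idx1.n_tasks
    A = tsr.alpha1.coefficients.reshape(k1, p, T, n)
    S2 = np.ascontiguousarray(A.transpose(3, 1, 2, 0).reshape(n, p * T * k1))
    idx2 = BlockIndex(subjects=idx1.subjects, tasks=idx1.tasks, n_inner=k1)
    return S2, idx2


def invert_ssr_input(S2: np.ndarray, idx2: BlockIndex, n: int) -> np.ndarray:
    """Recover the stage-1 loading matrix from the stage-2 stacking."""
    p, T, k1 = idx2.n_subjects, idx2.n_tasks, idx2.n_inner
    B = S2.reshape(n, p, T, k1)
    return np.ascontiguousarray(B.transpose(3, 1, 2, 0).reshape(k1, p * T * n))


def fit_ssr(
    S2: np.ndarray,
    index: BlockIndex,
    k2: int = DEFAULT_K2,
    lambda2: float = DEFAULT_LAMBDA2,
    seed: int = 0,
    n_iterations: int = 200,
    batch_size: int = 256,
    normalize: bool = False,
    coding_algorithm: str = "lasso_cd",
) -> SsrResult:
    """Learn the shared spatial dictionary on the restacked loadings.

    ``normalize=True`` applies the stage-1 column normalization to S2
    first.  Off by default: a loading column of a temporal atom unused in
    some task is near zero, and rescaling it to unit norm turns it into
    pure noise — which blurs the task-specific support structure the ROA
    analysis counts and degrades spatial-map recovery.
    """
    if normalize:
        S2 = normalize_columns(S2)[0]
    D2, alpha2 = learn_dictionary(
        S2,
        k=k2,
        lam=lambda2,
        n_iterations=n_iterations,
        batch_size=batch_size,
        seed=seed,
        domain_tag="spatial",
        coding_algorithm=coding_algorithm,
    )
    return SsrResult(D2=D2, alpha2=alpha2, index=index, normalized=normalize)


def transform_test(
    S1_test: GroupSignalMatrix,
    tsr: TsrResult,
    ssr: SsrResult,
    lambda1: float | None = None,
    lambda2: float | None = None,
    coding_algorithm: str = "lasso_cd",
) -> TestCodes:
    """Code held-out subjects with the frozen training dictionaries.

    The lambdas are taken from the training results; passing explicit
    values that disagree is refused, as re-tuning the penalty on test data
    would leak information.
    """
    if lambda1 is not None and lambda1 != tsr.lambda1:
        raise ValueError(
            f"lambda1={lambda1} differs from the training value {tsr.lambda1}; "
            "test coding must reuse the training penalty"
        )
    if lambda2 is not None and lambda2 != ssr.lambda2:
        raise ValueError(
            f"lambda2={lambda2} differs from the training value {ssr.lambda2}; "
            "test coding must reuse the training penalty"
        )
    if S1_test.index.n_inner != tsr.index.n_inner:
        raise ValueError("test subjects must use the same voxel sampling as training")

    alpha1_test = lasso_code(S1_test.data, tsr.D1, tsr.lambda1, algorithm=coding_algorithm)
    tsr_test = TsrResult(D1=tsr.D1, alpha1=alpha1_test, index=S1_test.index)
    S2_test, idx2_test = build_ssr_input(tsr_test)
    if ssr.normalized:
        S2_test = normalize_columns(S2_test)[0]
    alpha2_test = lasso_code(S2_test, ssr.D2, ssr.lambda2, algorithm=coding_algorithm)
    return TestCodes(
        alpha1=alpha1_test,
        alpha2=alpha2_test,
        index1=S1_test.index,
        index2=idx2_test,
    )


def alpha2_block(
    codes: SparseCodes, index: BlockIndex, subject: str | int, task: str | int
) -> np.ndarray:
    """The k2 x k1 loading block of one (subject, task)."""
    return codes.coefficients[:, index.block(subject, task)]


def reconstruct(
    D1: Dictionary | np.ndarray,
    D2: Dictionary | np.ndarray,
    alpha2_block: np.ndarray,
) -> np.ndarray:
    """Two-stage reconstruction of one run: ``D1 (alpha2)^T (D2)^T``."""
    A1 = D1.atoms if isinstance(D1, Dictionary) else np.asarray(D1)
    A2 = D2.atoms if isinstance(D2, Dictionary) else np.asarray(D2)
    if alpha2_block.shape[0] != A2.shape[1] or alpha2_block.shape[1] != A1.shape[1]:
        raise ValueError(
            f"alpha2 block {alpha2_block.shape} does not conform with "
            f"D1 {A1.shape} and D2 {A2.shape}"
        )
    return A1 @ alpha2_block.T @ A2.T


@dataclass(frozen=True)
class PipelineModel:
    """A fitted two-stage model plus the settings needed to reuse it."""

    tsr: TsrResult
    ssr: SsrResult
    manifest: dict = field(default_factory=dict)

    def transform(self, S1_test: GroupSignalMatrix) -> TestCodes:
        return transform_test(S1_test, self.tsr, self.ssr)


def fit_pipeline(
    S1: GroupSignalMatrix,
    k1: int = DEFAULT_K1,
    lambda1: float = DEFAULT_LAMBDA1,
    k2: int = DEFAULT_K2,
    lambda2: float = DEFAULT_LAMBDA2,
    seed: int = 0,
    n_iterations: int = 200,
    batch_size: int = 256,
    normalize_s2: bool = False,
    coding_algorithm: str = "lasso_cd",
) -> PipelineModel:
    """Run both training stages on the group matrix."""
    tsr = fit_tsr(
        S1, k1=k1, lambda1=lambda1, seed=seed,
        n_iterations=n_iterations, batch_size=batch_size,
        coding_algorithm=coding_algorithm,
    )
    S2, idx2 = build_ssr_input(tsr)
    ssr = fit_ssr(
        S2, idx2, k2=k2, lambda2=lambda2, seed=seed + 1,
        n_iterations=n_iterations, batch_size=batch_size, normalize=normalize_s2,
        coding_algorithm=coding_algorithm,
    )
    manifest = {
        "k1": k1, "lambda1": lambda1, "k2": k2, "lambda2": lambda2,
        "seed": seed, "n_iterations": n_iterations, "batch_size": batch_size,
        "normalize_s2": normalize_s2,
        "train_subjects": list(S1.index.subjects),
        "n_voxels": S1.n, "t": S1.t,
    }
    return PipelineModel(tsr=tsr, ssr=ssr, manifest=manifest)
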