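"""Shared numerical scaffolding for multi-subject blind source separation.

Holds the data containers used throughout the package (multi-subject data
blocks, demixing-matrix sets, optimizer state) and the low-level numerics
every solver relies on: subject-level PCA with whitening, the decoupling
trick that turns matrix demixing updates into row-wise vector updates,
sign-invariant convergence checks, and multiplicative step-size control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MultiSubjectData",
    "DemixingSet",
    "OptimState",
    "PCAResult",
    "DegenerateMatrixError",
    "pca_reduce",
    "decouple_vector",
    "check_convergence",
    "adapt_step",
    "STEP_FLOOR",
    "STEP_DECAY",
]

#: Multiplicative decay applied to the step size when the objective fails
#: to decrease, and the floor below which a row is frozen.
STEP_DECAY = 0.95
STEP_FLOOR = 1e-8


class DegenerateMatrixError(np.linalg.LinAlgError):
    """Raised when a demixing matrix (or a row-deleted submatrix) is rank-deficient."""


@dataclass
class MultiSubjectData:
    """K aligned per-subject data blocks plus subject metadata.

    Each block is ``rows x V`` where rows are raw time points (``reduced=False``)
    or whitened principal components (``reduced=True``).  When PCA has been
    applied, ``bases[k]`` (T x N) maps the reduced space back to the time
    domain and ``whiteners[k]`` (N x T) is the forward projection, so that
    ``blocks[k] = whiteners[k] @ (raw_k - mean_k)``.
    """

    blocks: list[np.ndarray]
    groups: np.ndarray | None = None
    sites: np.ndarray | None = None
    reduced: bool = False
    bases: list[np.ndarray] | None = None
    whiteners: list[np.ndarray] | None = None
    means: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        vs = {b.shape[1] for b in self.blocks}
        if len(vs) != 1:
            raise ValueError(f"all subject blocks must share V; got widths {sorted(vs)}")
        if self.groups is not None:
            self.groups = np.asarray(self.groups)
            if self.groups.shape[0] != len(self.blocks):
                raise ValueError("groups must have one label per subject")

    @property
    def n_subjects(self) -> int:
        return len(self.blocks)

    @property
    def n_samples(self) -> int:
        return self.blocks[0].shape[1]


@dataclass
class DemixingSet:
    """K demixing matrices, each N x N; the object every solver updates."""

    W: list[np.ndarray]

    def copy(self) -> "DemixingSet":
        return DemixingSet([w.copy() for w in self.W])

    def __len__(self) -> int:
        return len(self.W)

    def __getitem__(self, k: int) -> np.ndarray:
        return self.W[k]


@dataclass
class OptimState:
    """Book-keeping for the decoupled row-wise descent.

    ``step`` holds one step size per (component, subject) row; rows whose
    step decays below :data:`STEP_FLOOR` are frozen and no longer updated.
    """

    step: np.ndarray
    iteration: int = 0
    cost_trace: list[float] = field(default_factory=list)
    max_row_change: float = np.inf

    @property
    def frozen(self) -> np.ndarray:
        return self.step < STEP_FLOOR

    @property
    def all_frozen(self) -> bool:
        return bool(np.all(self.frozen))


@dataclass
class PCAResult:
    """Whitened reduction of one subject's raw block.

    ``reduced`` (N x V) has identity row covariance (``reduced @ reduced.T / V
    = I``); ``basis`` (T x N) back-projects so ``basis @ reduced`` is the best
    rank-N approximation of the row-centered raw data; ``whitener`` (N x T)
    is the forward map and ``mean`` the per-row means that were removed.
    """

    reduced: np.ndarray
    basis: np.ndarray
    whitener: np.ndarray
    mean: np.ndarray


def pca_reduce(raw: np.ndarray, n_components: int) -> PCAResult:
    """Subject-level PCA with whitening.

    Rows of ``raw`` (T x V) are centered, then projected onto the top
    ``n_components`` principal directions and rescaled to unit variance.

    Raises
    ------
    ValueError
        If ``n_components`` exceeds ``min(T, V)`` or the data does not
        support the requested rank.
    """
    raw = np.asarray(raw, dtype=float)
    T, V = raw.shape
    N = int(n_components)
    if N > min(T, V):
        raise ValueError(f"cannot extract {N} components from a {T} x {V} block")
    mean = raw.mean(axis=1)
    centered = raw - mean[:, None]
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    if s[N - 1] <= 1e-12 * max(s[0], 1.0):
        raise ValueError(f"data rank below requested {N} components")
    scale = np.sqrt(V)
    reduced = scale * Vt[:N]
    basis = U[:, :N] * (s[:N] / scale)
    whitener = (scale / s[:N])[:, None] * U[:, :N].T
    return PCAResult(reduced=reduced, basis=basis, whitener=whitener, mean=mean)


def decouple_vector(W: np.ndarray, n: int) -> np.ndarray:
    """Unit vector orthogonal to every row of ``W`` except row ``n``.

    With ``h = decouple_vector(W, n)``, ``det W = c * (w_n @ h)`` for a
    constant ``c`` that does not depend on row ``n``, so the gradient of
    ``log |det W|`` with respect to ``w_n`` is ``h / (w_n @ h)``.  This is
    what lets the solvers update demixing rows one at a time.
    """
    W = np.asarray(W, dtype=float)
    N = W.shape[0]
    B = np.delete(W, n, axis=0)
    sv = np.linalg.svd(B, compute_uv=False)
    if sv.size and sv[-1] <= 1e-12 * max(sv[0], 1.0):
        raise DegenerateMatrixError(
            f"rows other than {n} are rank-deficient; cannot decouple"
        )
    try:
        h = np.linalg.inv(W)[:, n]
    except np.linalg.LinAlgError:
        # W singular through row n only: h is the null direction of B.
        _, _, Vt = np.linalg.svd(B)
        h = Vt[-1]
    nrm = np.linalg.norm(h)
    if nrm == 0.0 or not np.isfinite(nrm):
        _, _, Vt = np.linalg.svd(B)
        h = Vt[-1]
        nrm = np.linalg.norm(h)
    return h / nrm


def _unit_rows(W: np.ndarray) -> np.ndarray:
    nrm = np.linalg.norm(W, axis=1, keepdims=True)
    nrm[nrm == 0] = 1.0
    return W / nrm


def check_convergence(prev: DemixingSet, cur: DemixingSet, tol: float) -> bool:
    """Sign-invariant convergence test on normalized demixing rows.

    True iff ``max_{n,k} min(|w - w'|, |w + w'|) < tol`` after normalizing
    every row to unit norm; a sign flip of a row is not a change, matching
    the inherent sign ambiguity of blind source separation.
    """
    worst = max_row_change(prev, cur)
    return bool(worst < tol)


def max_row_change(prev: DemixingSet, cur: DemixingSet) -> float:
    """Maximum sign-invariant change between corresponding unit-norm rows."""
    worst = 0.0
    for wp, wc in zip(prev.W, cur.W):
        a = _unit_rows(np.asarray(wp, dtype=float))
        b = _unit_rows(np.asarray(wc, dtype=float))
        d = np.minimum(
            np.linalg.norm(a - b, axis=1), np.linalg.norm(a + b, axis=1)
        )
        worst = max(worst, float(d.max()))
    return worst


def adapt_step(state: OptimState, cost_decreased: bool) -> OptimState:
    """Multiplicative step-size control.

    Steps are untouched when the objective decreased; otherwise every
    non-frozen row's step is multiplied by :data:`STEP_DECAY`.  A row whose
    step falls below :data:`STEP_FLOOR` is frozen, which guarantees
    termination even on pathological objectives.
    """
    if not cost_decreased:
        live = ~state.frozen
        state.step[live] *= STEP_DECAY
    return state
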