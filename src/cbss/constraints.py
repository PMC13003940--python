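"""Constraint machinery shared by the three constrained solvers.

Three mechanisms live here: the absolute-correlation similarity measure
between a component map and a reference template; the adaptive-reverse
threshold selection with its augmented-Lagrangian penalty (used by ar-cIVA
and ar-cEBM); and the threshold-free regularization term of tf-cIVA that
rewards similarity to the matching reference while penalizing similarity to
all the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ReferenceSet",
    "ThresholdGrid",
    "ConstraintState",
    "TfConfig",
    "similarity",
    "select_assertive",
    "select_conservative",
    "lagrangian_terms",
    "update_multiplier",
    "maybe_switch_mode",
    "tf_reg_term",
    "tf_cost",
    "similarity_tensor",
    "ASSERTIVE",
    "CONSERVATIVE",
    "MU_ZERO_TOL",
]

ASSERTIVE = 0
CONSERVATIVE = 1

#: Operationalizes "the multiplier approaches zero": below this the
#: adaptive-reverse scheme returns to the assertive threshold pick.
MU_ZERO_TOL = 1e-6


@dataclass
class ReferenceSet:
    """M spatial templates, one per constrained component (positional)."""

    refs: np.ndarray  # M x V

    def __post_init__(self) -> None:
        self.refs = np.atleast_2d(np.asarray(self.refs, dtype=float))
        sd = self.refs.std(axis=1)
        if np.any(sd < 1e-12):
            bad = int(np.argmin(sd))
            raise ValueError(f"reference {bad} has (near-)zero variance")

    @property
    def M(self) -> int:
        return self.refs.shape[0]

    @property
    def V(self) -> int:
        return self.refs.shape[1]


def default_grid() -> np.ndarray:
    return np.round(np.arange(1, 100) / 100.0, 2)


@dataclass
class ThresholdGrid:
    """Sorted candidate thresholds for the adaptive-reverse scheme."""

    values: np.ndarray = field(default_factory=default_grid)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("threshold grid must be a non-empty 1-D array")
        if np.any(np.diff(self.values) <= 0):
            raise ValueError("threshold grid must be strictly increasing")
        if self.values[0] <= 0 or self.values[-1] >= 1:
            raise ValueError("threshold grid values must lie in (0, 1)")


@dataclass
class TfConfig:
    """Weight of the threshold-free regularization term."""

    lam: float = 100.0

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lambda must be positive")


@dataclass
class ConstraintState:
    """Per-(component, subject) adaptive-reverse state.

    ``rho`` are the active thresholds, ``mu`` the Lagrange multipliers and
    ``mode`` the current scheme (assertive/conservative) for each of the
    M x K constraints.  ``gamma`` is the penalty parameter and ``mu_max``
    the multiplier level at which a constraint switches to the conservative
    scheme.
    """

    rho: np.ndarray
    mu: np.ndarray
    mode: np.ndarray
    gamma: float = 100.0
    mu_max: float = 1.0
    grid: ThresholdGrid = field(default_factory=ThresholdGrid)

    @classmethod
    def initial(
        cls,
        M: int,
        K: int,
        gamma: float = 100.0,
        mu_max: float = 1.0,
        grid: ThresholdGrid | None = None,
    ) -> "ConstraintState":
        grid = grid or ThresholdGrid()
        if gamma <= 0:
            raise ValueError("gamma must be positive")
        return cls(
            rho=np.full((M, K), grid.values[0]),
            mu=np.zeros((M, K)),
            mode=np.full((M, K), ASSERTIVE, dtype=int),
            gamma=gamma,
            mu_max=mu_max,
            grid=grid,
        )


def similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Absolute Pearson correlation between two maps, in [0, 1].

    Both vectors are mean-centered before the normalized inner product, so
    the cosine form and the "absolute Pearson correlation" reading coincide.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a - a.mean()
    b = b - b.mean()
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na < 1e-12 or nb < 1e-12:
        raise ValueError("similarity undefined for (near-)constant input")
    return float(abs(a @ b) / (na * nb))


def select_assertive(eps: float, grid: ThresholdGrid) -> float:
    """Smallest grid threshold strictly above the current similarity.

    Forces the similarity to keep increasing; falls back to the grid
    maximum when the similarity already exceeds every candidate.
    """
    v = grid.values
    idx = int(np.searchsorted(v, eps, side="right"))
    return float(v[idx]) if idx < v.size else float(v[-1])


def select_conservative(eps: float, grid: ThresholdGrid) -> float:
    """Largest grid threshold the current similarity already satisfies.

    Falls back to the grid minimum when no candidate is satisfied.
    """
    v = grid.values
    idx = int(np.searchsorted(v, eps, side="right")) - 1
    return float(v[idx]) if idx >= 0 else float(v[0])


def lagrangian_terms(
    eps: np.ndarray, state: ConstraintState
) -> tuple[float, np.ndarray]:
    """Augmented-Lagrangian penalty and per-constraint gradient weights.

    ``penalty = (1 / 2 gamma) * sum max(0, mu + gamma (rho - eps))^2 - mu^2``;
    the returned weights ``max(0, mu + gamma (rho - eps))`` multiply
    ``-d eps / d w`` in the solvers' row gradients.
    """
    if state.gamma <= 0:
        raise ValueError("gamma must be positive")
    t = np.maximum(0.0, state.mu + state.gamma * (state.rho - eps))
    penalty = float((t**2 - state.mu**2).sum() / (2.0 * state.gamma))
    return penalty, t


def update_multiplier(
    mu: np.ndarray | float,
    eps: np.ndarray | float,
    rho: np.ndarray | float,
    gamma: float,
) -> np.ndarray | float:
    """Projected ascent on the Lagrange multipliers: ``max(0, mu + gamma (rho - eps))``."""
    out = np.maximum(0.0, np.asarray(mu, dtype=float) + gamma * (np.asarray(rho) - np.asarray(eps)))
    return float(out) if out.ndim == 0 else out


def maybe_switch_mode(state: ConstraintState) -> ConstraintState:
    """Adaptive-reverse mode alternation, evaluated once per outer iteration.

    A constraint switches to the conservative scheme when its multiplier
    exceeds ``mu_max`` (the assertive target proved too ambitious) and back
    to the assertive scheme when the multiplier returns to (near) zero; in
    the hysteresis band in between the mode is left unchanged.
    """
    state.mode = np.where(state.mu > state.mu_max, CONSERVATIVE, state.mode)
    state.mode = np.where(state.mu < MU_ZERO_TOL, ASSERTIVE, state.mode)
    return state


def refresh_thresholds(state: ConstraintState, eps: np.ndarray) -> ConstraintState:
    """Re-pick every threshold from the grid according to its current mode."""
    M, K = state.rho.shape
    for n in range(M):
        for k in range(K):
            if state.mode[n, k] == ASSERTIVE:
                state.rho[n, k] = select_assertive(eps[n, k], state.grid)
            else:
                state.rho[n, k] = select_conservative(eps[n, k], state.grid)
    return state


def similarity_tensor(W, blocks, refs: "ReferenceSet") -> np.ndarray:
    """eps[n, m, k] = similarity(reference n, component m of subject k)."""
    M = refs.M
    K = len(blocks)
    eps = np.empty((M, M, K))
    for k in range(K):
        Y = np.asarray(W[k]) @ np.asarray(blocks[k])
        for n in range(M):
            for m in range(M):
                eps[n, m, k] = similarity(refs.refs[n], Y[m])
    return eps


def tf_cost(W, X, refs: "ReferenceSet", cfg: TfConfig | float = 100.0) -> float:
    """Threshold-free constrained IVA objective: IVA-G cost + (lam/2) * regularizer.

    Reference implementation used for checks and diagnostics; the solver
    evaluates the same quantity through its precomputed geometry.
    """
    from .iva_g import iva_g_cost

    lam = cfg.lam if isinstance(cfg, TfConfig) else float(cfg)
    blocks = X.blocks if hasattr(X, "blocks") else X
    eps = similarity_tensor(W, blocks, refs)
    return float(iva_g_cost(W, blocks) + 0.5 * lam * tf_reg_term(eps))


def tf_reg_term(eps: np.ndarray) -> float:
    """Threshold-free regularizer from the M x M x K similarity tensor.

    ``eps[n, m, k]`` is the similarity between reference n and estimated
    component m of subject k; the term sums ``eps^2`` over mismatched pairs
    and subtracts it over matched ones, so minimizing it steers component n
    toward reference n and away from all the others.  Bounded in
    ``[-M K, M K (M - 1)]``.
    """
    eps = np.asarray(eps, dtype=float)
    if eps.ndim != 3 or eps.shape[0] != eps.shape[1]:
        raise ValueError("expected an M x M x K similarity tensor")
    sq = eps**2
    diag = np.einsum("nnk->nk", sq)
    return float(sq.sum() - 2.0 * diag.sum())
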