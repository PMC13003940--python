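"""The three end-to-end constrained solvers.

* ``ar-civa``  — IVA-G with per-(component, subject) adaptive-reverse
  thresholds enforced through an augmented Lagrangian.
* ``tf-civa``  — IVA-G plus a threshold-free regularizer that rewards
  similarity to the matching reference and penalizes similarity to all
  other references.
* ``ar-cebm``  — subject-wise ICA by entropy bound minimization with the
  adaptive-reverse constraint applied independently per subject (the
  threshold is indexed by component only and reset between subjects).

All three share the decoupled row-wise descent skeleton: rows are updated
sequentially (components outer, subjects inner for the IVA methods), each
step moves against the row gradient and renormalizes to unit norm, the
objective is evaluated once per outer sweep, and a sweep that fails to
decrease it is reverted with the step sizes decayed by 0.95.  They also
share the random initializer, so runs with the same seed start from
identical demixing matrices regardless of the algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import constraints as cn
from .core import (
    DemixingSet,
    adapt_step,
    MultiSubjectData,
    OptimState,
    decouple_vector,
    max_row_change,
    pca_reduce,
)
from .constraints import ConstraintState, ReferenceSet, ThresholdGrid
from .ica_ebm import EbmModel
from .iva_g import IvaGModel

__all__ = [
    "RunConfig",
    "RunResult",
    "run",
    "run_ar_civa",
    "run_tf_civa",
    "run_ar_cebm",
    "finalize",
    "initial_demixing",
    "reduce_cohort",
]

ALGORITHMS = ("ar-civa", "tf-civa", "ar-cebm")

#: Relative cost improvement below which an accepted sweep still counts as
#: "failed to decrease" for step adaptation; lets the steps decay on a
#: plateau so the sign-invariant row-change test can terminate the run.
STAGNATION_RTOL = 1e-9


@dataclass
class RunConfig:
    """Solver configuration; defaults follow the common fMRI practice.

    ``gamma`` (penalty), ``mu_max`` (multiplier switch level) and the
    threshold grid drive the adaptive-reverse methods; ``lam`` weights the
    threshold-free regularizer.  ``step_init`` is the initial per-row step
    of the decoupled descent.
    """

    algorithm: str = "ar-civa"
    max_iter: int = 1024
    tol: float = 1e-6
    step_init: float = 0.1
    seed: int = 0
    gamma: float = 100.0
    mu_max: float = 1.0
    lam: float = 100.0
    grid: ThresholdGrid = field(default_factory=ThresholdGrid)

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}")
        if self.tol <= 0 or self.max_iter < 1:
            raise ValueError("tol must be positive and max_iter >= 1")


@dataclass
class RunResult:
    """Everything a solver run produces.

    The first M components are the constrained ones, in reference order,
    with signs flipped so the centered inner product with the matching
    reference is nonnegative.  ``eps`` holds the final matched similarities
    (M x K); ``diagnostics`` carries the constraint state (rho, mu, mode)
    or the final regularizer value.
    """

    W: DemixingSet
    Y: np.ndarray                    # K x N x V
    eps: np.ndarray                  # M x K
    cost_trace: list[float]
    converged: bool
    n_iter: int
    diagnostics: dict
    timecourses: list[np.ndarray] | None = None


# ---------------------------------------------------------------------------
# shared plumbing


def initial_demixing(N: int, K: int, seed: int) -> DemixingSet:
    """Shared random initializer: unit-norm standard-normal rows.

    Subject ``k`` draws from the kth spawned child of ``SeedSequence(seed)``,
    so the initialization of a given subject position depends only on
    (seed, k) — identical across algorithms and across batch compositions
    that preserve subject order.
    """
    children = np.random.SeedSequence(seed).spawn(K)
    W = []
    for k in range(K):
        rng = np.random.default_rng(children[k])
        w = rng.standard_normal((N, N))
        w /= np.linalg.norm(w, axis=1, keepdims=True)
        W.append(w)
    return DemixingSet(W)


def reduce_cohort(data: MultiSubjectData, n_components: int) -> MultiSubjectData:
    """Subject-level PCA/whitening of every block of a cohort."""
    results = [pca_reduce(b, n_components) for b in data.blocks]
    return MultiSubjectData(
        blocks=[r.reduced for r in results],
        groups=None if data.groups is None else data.groups.copy(),
        sites=None if data.sites is None else np.asarray(data.sites).copy(),
        reduced=True,
        bases=[r.basis for r in results],
        whiteners=[r.whitener for r in results],
        means=[r.mean for r in results],
    )


class _RefGeometry:
    """Precomputed reference geometry for one subject block.

    Stores ``q[n] = Xc r_n / |r_n|`` and ``C = Xc Xc'`` so that the
    similarity between reference n and component ``w' X`` and its gradient
    are O(N) per evaluation:

        eps = |w' q| / sqrt(w' C w)
        d eps / d w = sign(w' q) q / sqrt(w' C w) - eps C w / (w' C w)
    """

    def __init__(self, X: np.ndarray, refs: ReferenceSet):
        Xc = X - X.mean(axis=1, keepdims=True)
        R = refs.refs - refs.refs.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(R, axis=1)
        self.q = (Xc @ R.T / norms).T      # M x N
        self.C = Xc @ Xc.T                 # N x N

    def eps(self, w: np.ndarray, n: int) -> float:
        return float(abs(w @ self.q[n]) / np.sqrt(w @ self.C @ w))

    def eps_grad(self, w: np.ndarray, n: int) -> tuple[float, np.ndarray]:
        Cw = self.C @ w
        s2 = float(w @ Cw)
        num = float(w @ self.q[n])
        e = abs(num) / np.sqrt(s2)
        de = np.sign(num) * self.q[n] / np.sqrt(s2) - e * Cw / s2
        return e, de

    def eps_rows(self, W: np.ndarray, rows: np.ndarray | None = None) -> np.ndarray:
        """Similarities of each reference with each listed row (M x len(rows))."""
        rows = np.arange(W.shape[0]) if rows is None else rows
        Wr = W[rows]
        denom = np.sqrt(np.einsum("ri,ij,rj->r", Wr, self.C, Wr))
        return np.abs(self.q @ Wr.T) / denom[None, :]


def _check_inputs(X: MultiSubjectData, refs: ReferenceSet) -> None:
    if not X.reduced:
        raise ValueError("solvers require PCA-reduced (whitened) data; see reduce_cohort")
    N = X.blocks[0].shape[0]
    if refs.M > N:
        raise ValueError(f"more references ({refs.M}) than components ({N})")
    if refs.V != X.n_samples:
        raise ValueError(
            f"reference length {refs.V} does not match data sample count {X.n_samples}"
        )


def _matched_eps(geoms: list[_RefGeometry], W: DemixingSet, M: int) -> np.ndarray:
    """eps[n, k] = similarity(reference n, component n of subject k)."""
    K = len(W)
    eps = np.empty((M, K))
    for k in range(K):
        eps[:, k] = np.diag(geoms[k].eps_rows(W[k], np.arange(M)))
    return eps


# ---------------------------------------------------------------------------
# ar-cIVA


def run_ar_civa(X: MultiSubjectData, refs: ReferenceSet, cfg: RunConfig) -> RunResult:
    """Adaptive-reverse constrained IVA (augmented Lagrangian on IVA-G).

    Per outer sweep: all demixing rows are updated by decoupled gradient
    descent on the augmented Lagrangian, then (if the sweep is accepted)
    the similarities, multipliers, scheme modes and grid thresholds are
    refreshed in that order.
    """
    _check_inputs(X, refs)
    model = IvaGModel(X.blocks)
    geoms = [_RefGeometry(b, refs) for b in X.blocks]
    N, K, M = model.N, model.K, refs.M
    W = initial_demixing(N, K, cfg.seed)

    state = ConstraintState.initial(M, K, cfg.gamma, cfg.mu_max, cfg.grid)
    eps = _matched_eps(geoms, W, M)
    cn.refresh_thresholds(state, eps)
    opt = OptimState(step=np.full((N, K), cfg.step_init))

    def objective(eps_now: np.ndarray) -> float:
        return model.cost(W) + cn.lagrangian_terms(eps_now, state)[0]

    prev_cost = objective(eps)
    opt.cost_trace.append(prev_cost)
    converged = False

    for it in range(cfg.max_iter):
        W_prev = W.copy()
        for n in range(N):
            for k in range(K):
                if opt.frozen[n, k]:
                    continue
                h = decouple_vector(W[k], n)
                g = model.grad_row(W, n, k, h)
                if n < M:
                    e_nk, de = geoms[k].eps_grad(W[k][n], n)
                    wgt = max(
                        0.0,
                        state.mu[n, k] + state.gamma * (state.rho[n, k] - e_nk),
                    )
                    g = g - wgt * de
                w_new = W[k][n] - opt.step[n, k] * g
                nrm = np.linalg.norm(w_new)
                if nrm > 1e-12:
                    W.W[k][n] = w_new / nrm
        eps_new = _matched_eps(geoms, W, M)
        cost = model.cost(W) + cn.lagrangian_terms(eps_new, state)[0]
        if cost <= prev_cost:
            adapt_step(opt, cost < prev_cost - STAGNATION_RTOL * (1.0 + abs(prev_cost)))
            delta = max_row_change(W_prev, W)
            opt.cost_trace.append(cost)
            eps = eps_new
            state.mu = cn.update_multiplier(state.mu, eps, state.rho, state.gamma)
            cn.maybe_switch_mode(state)
            cn.refresh_thresholds(state, eps)
            prev_cost = objective(eps)
            opt.iteration = it + 1
            if delta < cfg.tol:
                converged = True
                break
        else:
            W = W_prev
            adapt_step(opt, False)
        if opt.all_frozen:
            break

    diagnostics = {
        "rho": state.rho.copy(),
        "mu": state.mu.copy(),
        "mode": state.mode.copy(),
    }
    return _package(W, X, refs, geoms, opt, converged, diagnostics)


# ---------------------------------------------------------------------------
# tf-cIVA


def run_tf_civa(X: MultiSubjectData, refs: ReferenceSet, cfg: RunConfig) -> RunResult:
    """Threshold-free constrained IVA.

    Minimizes the IVA-G cost plus ``lam / 2`` times the regularizer that
    rewards the matched reference similarity and penalizes all mismatched
    ones; no thresholds or multipliers are involved.
    """
    _check_inputs(X, refs)
    model = IvaGModel(X.blocks)
    geoms = [_RefGeometry(b, refs) for b in X.blocks]
    N, K, M = model.N, model.K, refs.M
    W = initial_demixing(N, K, cfg.seed)
    opt = OptimState(step=np.full((N, K), cfg.step_init))

    def reg_tensor() -> np.ndarray:
        eps = np.empty((M, M, K))
        for k in range(K):
            eps[:, :, k] = geoms[k].eps_rows(W[k], np.arange(M))
        return eps

    def objective() -> float:
        return model.cost(W) + 0.5 * cfg.lam * cn.tf_reg_term(reg_tensor())

    prev_cost = objective()
    opt.cost_trace.append(prev_cost)
    converged = False

    for it in range(cfg.max_iter):
        W_prev = W.copy()
        for n in range(N):
            for k in range(K):
                if opt.frozen[n, k]:
                    continue
                h = decouple_vector(W[k], n)
                g = model.grad_row(W, n, k, h)
                if n < M:
                    # regularizer couples row n with every reference
                    acc = np.zeros(N)
                    for r in range(M):
                        e, de = geoms[k].eps_grad(W[k][n], r)
                        acc += (-e * de) if r == n else (e * de)
                    g = g + cfg.lam * acc
                w_new = W[k][n] - opt.step[n, k] * g
                nrm = np.linalg.norm(w_new)
                if nrm > 1e-12:
                    W.W[k][n] = w_new / nrm
        cost = objective()
        if cost <= prev_cost:
            adapt_step(opt, cost < prev_cost - STAGNATION_RTOL * (1.0 + abs(prev_cost)))
            delta = max_row_change(W_prev, W)
            opt.cost_trace.append(cost)
            prev_cost = cost
            opt.iteration = it + 1
            if delta < cfg.tol:
                converged = True
                break
        else:
            W = W_prev
            adapt_step(opt, False)
        if opt.all_frozen:
            break

    diagnostics = {"tf_reg": cn.tf_reg_term(reg_tensor())}
    return _package(W, X, refs, geoms, opt, converged, diagnostics)


# ---------------------------------------------------------------------------
# ar-cEBM


def run_ar_cebm(X: MultiSubjectData, refs: ReferenceSet, cfg: RunConfig) -> RunResult:
    """Adaptive-reverse constrained ICA-EBM, one subject at a time.

    Each subject is an independent constrained ICA problem: the EBM cost
    plus the augmented-Lagrangian penalty with a per-component threshold
    ``rho_n`` (no subject index) that the adaptive-reverse scheme adjusts
    during that subject's optimization and resets before the next one.
    Results for a subject do not depend on which other subjects are in the
    batch.
    """
    _check_inputs(X, refs)
    K = X.n_subjects
    N = X.blocks[0].shape[0]
    M = refs.M
    W_init = initial_demixing(N, K, cfg.seed)

    W_out, traces, diag_rho, diag_mu, diag_mode = [], [], [], [], []
    converged_all = True
    iters = 0
    geoms = [_RefGeometry(b, refs) for b in X.blocks]
    for k in range(K):
        model = EbmModel(X.blocks[k])
        geom = geoms[k]
        W = W_init[k].copy()
        state = ConstraintState.initial(M, 1, cfg.gamma, cfg.mu_max, cfg.grid)
        eps = geom.eps_rows(W, np.arange(M)).diagonal().reshape(M, 1).copy()
        cn.refresh_thresholds(state, eps)
        opt = OptimState(step=np.full((N, 1), cfg.step_init))

        # per-row entropies cached across sweeps: a row's entropy only
        # changes when that row is updated
        ents = np.array([model.row_entropy(w).selected for w in W])

        def ebm_total() -> float:
            _, logdet = np.linalg.slogdet(W)
            return float(ents.sum() - logdet)

        prev_cost = ebm_total() + cn.lagrangian_terms(eps, state)[0]
        opt.cost_trace.append(prev_cost)
        converged = False
        for it in range(cfg.max_iter):
            W_prev = W.copy()
            ents_prev = ents.copy()
            for n in range(N):
                if opt.frozen[n, 0]:
                    continue
                h = decouple_vector(W, n)
                g = model.grad_row(W, n, h)
                if n < M:
                    e_n, de = geom.eps_grad(W[n], n)
                    wgt = max(
                        0.0, state.mu[n, 0] + state.gamma * (state.rho[n, 0] - e_n)
                    )
                    g = g - wgt * de
                w_new = W[n] - opt.step[n, 0] * g
                nrm = np.linalg.norm(w_new)
                if nrm > 1e-12:
                    W[n] = w_new / nrm
                    ents[n] = model.row_entropy(W[n]).selected
            eps_new = geom.eps_rows(W, np.arange(M)).diagonal().reshape(M, 1).copy()
            cost = ebm_total() + cn.lagrangian_terms(eps_new, state)[0]
            if cost <= prev_cost:
                adapt_step(opt, cost < prev_cost - STAGNATION_RTOL * (1.0 + abs(prev_cost)))
                delta = max_row_change(
                    DemixingSet([W_prev]), DemixingSet([W])
                )
                opt.cost_trace.append(cost)
                eps = eps_new
                state.mu = cn.update_multiplier(state.mu, eps, state.rho, state.gamma)
                cn.maybe_switch_mode(state)
                cn.refresh_thresholds(state, eps)
                prev_cost = ebm_total() + cn.lagrangian_terms(eps, state)[0]
                opt.iteration = it + 1
                if delta < cfg.tol:
                    converged = True
                    break
            else:
                W = W_prev
                ents = ents_prev
                adapt_step(opt, False)
            if opt.all_frozen:
                break
        W_out.append(W)
        traces.append(opt.cost_trace)
        diag_rho.append(state.rho[:, 0].copy())
        diag_mu.append(state.mu[:, 0].copy())
        diag_mode.append(state.mode[:, 0].copy())
        converged_all = converged_all and converged
        iters = max(iters, opt.iteration)

    W = DemixingSet(W_out)
    opt = OptimState(step=np.full((N, K), cfg.step_init))
    opt.iteration = iters
    opt.cost_trace = [float(sum(t[0] for t in traces)), float(sum(t[-1] for t in traces))]
    diagnostics = {
        "rho": np.stack(diag_rho, axis=1),
        "mu": np.stack(diag_mu, axis=1),
        "mode": np.stack(diag_mode, axis=1),
        "per_subject_traces": traces,
    }
    return _package(W, X, refs, geoms, opt, converged_all, diagnostics)


# ---------------------------------------------------------------------------
# finalization


def _package(
    W: DemixingSet,
    X: MultiSubjectData,
    refs: ReferenceSet,
    geoms: list[_RefGeometry],
    opt: OptimState,
    converged: bool,
    diagnostics: dict,
) -> RunResult:
    result = RunResult(
        W=W,
        Y=np.stack([W[k] @ X.blocks[k] for k in range(len(W))]),
        eps=_matched_eps(geoms, W, refs.M),
        cost_trace=list(opt.cost_trace),
        converged=converged,
        n_iter=opt.iteration,
        diagnostics=diagnostics,
    )
    return finalize(result, X, refs)


def finalize(result: RunResult, X: MultiSubjectData, refs: ReferenceSet) -> RunResult:
    """Canonicalize a run: component order, signs, time courses.

    Constrained components stay in reference order 1..M with signs flipped
    so the centered inner product with the matching reference is
    nonnegative; free components are reordered by descending mean variance
    of their maps.  When PCA bases are available the subject time courses
    are back-reconstructed as the columns of ``basis_k inv(W_k)``.
    """
    K, N, V = result.Y.shape
    M = refs.M
    R = refs.refs - refs.refs.mean(axis=1, keepdims=True)
    for k in range(K):
        Yk = result.Y[k]
        for n in range(M):
            yc = Yk[n] - Yk[n].mean()
            if yc @ R[n] < 0:
                result.Y[k, n] *= -1.0
                result.W.W[k][n] *= -1.0
    if N > M:
        var_free = result.Y[:, M:, :].var(axis=2).mean(axis=0)
        order = np.concatenate([np.arange(M), M + np.argsort(-var_free, kind="stable")])
        result.Y = result.Y[:, order, :]
        for k in range(K):
            result.W.W[k] = result.W.W[k][order]
    if X.bases is not None:
        tcs = []
        for k in range(K):
            Winv = np.linalg.inv(result.W[k])
            tcs.append(X.bases[k] @ Winv)
        result.timecourses = tcs
    return result


_RUNNERS = {"ar-civa": run_ar_civa, "tf-civa": run_tf_civa, "ar-cebm": run_ar_cebm}


def run(X: MultiSubjectData, refs: ReferenceSet, cfg: RunConfig) -> RunResult:
    """Dispatch to the solver named by ``cfg.algorithm``."""
    return _RUNNERS[cfg.algorithm](X, refs, cfg)
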