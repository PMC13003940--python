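"""Synthetic multi-subject cohorts with known ground truth.

Generates K subjects whose nth sources form a source component vector (SCV)
with controlled cross-subject correlation, mixes them through random
invertible matrices, derives noisy reference templates, and optionally
injects a localized spatial group effect — everything the solvers and the
evaluation stack need to be exercised without external data.

The marginal source law is a Gaussian scale mixture (a correlated Gaussian
vector multiplied by a shared random scale per voxel), which yields
heavy-tailed, sparse-looking spatial maps while preserving the target
Pearson correlation of the underlying Gaussian exactly.  The per-SCV
cross-subject correlation is spread multiplicatively around the configured
target so that no two SCVs share an identical covariance profile; identical
Gaussian SCV covariances would make the pair unidentifiable for any
second-order joint separation method, and identical Gaussian marginals
would do the same for subject-wise ICA.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .core import MultiSubjectData

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_scv_sources",
    "make_mixings",
    "make_references",
    "make_mixed_data",
    "simulate_cohort",
    "scv_correlations",
]

#: Relative half-width of the multiplicative spread of per-SCV correlations
#: around ``scv_corr`` (SCV n gets scv_corr * (1 + SPREAD * u_n), u_n
#: equispaced in [-1, 1]).  Keeps the Gaussian SCV covariances pairwise
#: distinct, hence identifiable, while the across-SCV mean stays on target.
CORR_SPREAD = 0.2

#: Maximum mixing-matrix condition number accepted before resampling.
MAX_CONDITION = 1e3


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one synthetic cohort.

    Parameters
    ----------
    K, N, V : int
        Subjects, components per subject, and samples (voxels) per map.
    M : int
        Number of referenced (constrained) components, ``M <= N``.
    scv_corr : float
        Target cross-subject correlation within an SCV, in ``[0, 1)``.
    ref_corr : float
        Correlation between each reference template and the subject-mean of
        its ground-truth source, in ``(0, 1]``.
    group_effect : float
        Amplitude of the additive localized spatial effect applied to the
        listed components of group-2 subjects (units of source SD).
    effect_components : tuple[int, ...]
        Component indices receiving the group effect.
    seed : int
        RNG seed; identical configs produce bitwise-identical cohorts.
    """

    K: int = 10
    N: int = 8
    V: int = 5000
    M: int = 6
    scv_corr: float = 0.5
    ref_corr: float = 0.9
    group_effect: float = 0.0
    effect_components: tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.M <= self.N):
            raise ValueError(f"need 0 < M <= N, got M={self.M}, N={self.N}")
        if not (0.0 <= self.scv_corr < 1.0):
            raise ValueError(f"scv_corr must be in [0, 1), got {self.scv_corr}")
        if not (0.0 < self.ref_corr <= 1.0):
            raise ValueError(f"ref_corr must be in (0, 1], got {self.ref_corr}")
        if self.V <= self.N:
            raise ValueError("need more samples than components (V > N)")
        if any(not 0 <= c < self.N for c in self.effect_components):
            raise ValueError("effect_components out of range")


@dataclass
class GroundTruth:
    """Everything the generator knows and the solvers must recover."""

    sources: np.ndarray          # K x N x V, zero-mean unit-variance rows
    mixings: np.ndarray          # K x N x N invertible
    references: np.ndarray       # M x V
    group_labels: np.ndarray     # length K, values in {1, 2}
    config: SimConfig | None = None


def scv_correlations(cfg: SimConfig) -> np.ndarray:
    """Per-SCV cross-subject correlation targets.

    SCV ``n`` gets ``scv_corr * (1 + CORR_SPREAD * u_n)`` with ``u_n``
    equispaced in ``[-1, 1]``, clipped to ``[0, 0.98]``.  The mean over SCVs
    equals ``scv_corr`` (up to clipping) and all values are distinct
    whenever ``scv_corr > 0``.
    """
    if cfg.N == 1:
        u = np.zeros(1)
    else:
        u = np.linspace(-1.0, 1.0, cfg.N)
    return np.clip(cfg.scv_corr * (1.0 + CORR_SPREAD * u), 0.0, 0.98)


def simulate_scv_sources(cfg: SimConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw the K x N x V ground-truth sources.

    For each SCV the K rows are i.i.d. draws (across samples) of a
    K-variate Gaussian scale mixture: ``s(v) = g(v) * z(v)`` where ``z(v)``
    is K-variate Gaussian with compound-symmetric correlation and ``g(v)``
    is a shared random scale with ``g^2 ~ Exp(1)``.  The shared scale makes
    the marginals Laplacian-like (excess kurtosis 3) — heavy-tailed, as
    fMRI spatial maps are — without altering the Pearson correlation.
    Distinct SCVs are generated independently.  Rows are standardized to
    exact zero mean and unit variance.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    rhos = scv_correlations(cfg)
    K, N, V = cfg.K, cfg.N, cfg.V
    sources = np.empty((K, N, V))
    for n in range(N):
        rho = rhos[n]
        C = np.full((K, K), rho) + (1.0 - rho) * np.eye(K)
        L = np.linalg.cholesky(C)
        z = L @ rng.standard_normal((K, V))
        g = np.sqrt(rng.exponential(1.0, size=V))
        s = z * g[None, :]
        s -= s.mean(axis=1, keepdims=True)
        s /= s.std(axis=1, keepdims=True)
        sources[:, n, :] = s
    return sources


def make_mixings(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """K invertible N x N mixing matrices from a standard normal ensemble.

    Matrices with condition number above :data:`MAX_CONDITION` are
    resampled, so every mixing is comfortably invertible by construction.
    """
    A = np.empty((cfg.K, cfg.N, cfg.N))
    for k in range(cfg.K):
        while True:
            cand = rng.standard_normal((cfg.N, cfg.N))
            if np.linalg.cond(cand) <= MAX_CONDITION:
                A[k] = cand
                break
    return A


def make_references(
    gt_sources: np.ndarray, cfg: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Noisy templates correlated with the subject-mean ground-truth sources.

    Reference ``n`` is built as ``ref_corr * t_hat + sqrt(1 - ref_corr^2) *
    e_hat`` where ``t_hat`` is the unit-norm centered subject-mean of source
    ``n`` and ``e_hat`` is unit-norm centered noise orthogonalized against
    ``t_hat``, so the similarity with the mean source is ``ref_corr``
    exactly.  References are rescaled to unit sample variance.
    """
    if not (0.0 < cfg.ref_corr <= 1.0):
        raise ValueError("ref_corr must be in (0, 1]; 0 would be uninformative")
    M, V = cfg.M, cfg.V
    refs = np.empty((M, V))
    for n in range(M):
        t = gt_sources[:, n, :].mean(axis=0)
        t = t - t.mean()
        t_hat = t / np.linalg.norm(t)
        e = rng.standard_normal(V)
        e -= e.mean()
        e -= (e @ t_hat) * t_hat
        e_hat = e / np.linalg.norm(e)
        r = cfg.ref_corr * t_hat + np.sqrt(1.0 - cfg.ref_corr**2) * e_hat
        refs[n] = r / r.std()
    return refs


def _group_bump(n: int, V: int) -> np.ndarray:
    """Deterministic localized spatial profile for component ``n``.

    A Hann window covering 5% of the samples, positioned by component index
    so effects on different components do not overlap; unit sample SD over
    its support region scaled to unit SD over the full map.
    """
    width = max(V // 20, 4)
    start = (n * (V // 10) + V // 7) % max(V - width, 1)
    bump = np.zeros(V)
    bump[start : start + width] = np.hanning(width)
    return bump / bump.std()


def make_mixed_data(gt: GroundTruth, cfg: SimConfig | None = None) -> MultiSubjectData:
    """Mix the ground-truth sources: ``x_k = A_k s_k``.

    Group-2 subjects receive the configured additive spatial effect on the
    listed components' source maps *before* mixing, emulating a localized
    group difference in the underlying networks.
    """
    cfg = cfg or gt.config
    K, N, _ = gt.sources.shape
    if gt.mixings.shape != (K, N, N):
        raise ValueError(
            f"mixing shape {gt.mixings.shape} does not match sources {gt.sources.shape}"
        )
    blocks = []
    V = gt.sources.shape[2]
    for k in range(K):
        s = gt.sources[k]
        if (
            cfg is not None
            and cfg.group_effect != 0.0
            and gt.group_labels[k] == 2
            and cfg.effect_components
        ):
            s = s.copy()
            for n in cfg.effect_components:
                s[n] = s[n] + cfg.group_effect * _group_bump(n, V)
        blocks.append(gt.mixings[k] @ s)
    return MultiSubjectData(blocks=blocks, groups=gt.group_labels.copy(), reduced=False)


def simulate_cohort(cfg: SimConfig) -> tuple[GroundTruth, MultiSubjectData]:
    """Full cohort: sources, mixings, references, labels, and mixed data.

    All randomness flows from ``cfg.seed`` through a single generator, so
    identical configs give bitwise-identical outputs.  Subjects are split
    into group 1 (first half, rounded up) and group 2 (rest).
    """
    rng = np.random.default_rng(cfg.seed)
    sources = simulate_scv_sources(cfg, rng)
    mixings = make_mixings(cfg, rng)
    references = make_references(sources, cfg, rng)
    labels = np.ones(cfg.K, dtype=int)
    labels[(cfg.K + 1) // 2 :] = 2
    gt = GroundTruth(
        sources=sources,
        mixings=mixings,
        references=references,
        group_labels=labels,
        config=cfg,
    )
    data = make_mixed_data(gt, cfg)
    return gt, data


def config_to_dict(cfg: SimConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["effect_components"] = list(d["effect_components"])
    return d
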