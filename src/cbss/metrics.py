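"""Evaluation stack for constrained joint blind source separation.

Permutation-invariant separation scores (ISI, joint-ISI across subjects,
cross-joint-ISI across repeated runs), temporal and spatial functional
network connectivity with Fisher z-transform, graph modularity with
link-density thresholding, the two-sample Kolmogorov-Smirnov statistic,
one-/two-sample and paired t-tests with Benjamini-Hochberg FDR control,
and voxel-wise one-sample t-maps.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ISIReport",
    "FNCMatrix",
    "ModularityResult",
    "GroupTestResult",
    "isi",
    "joint_isi",
    "cross_joint_isi",
    "global_matrices",
    "detrend_despike",
    "temporal_fnc",
    "spatial_fnc",
    "binarize_by_density",
    "modularity_q",
    "best_partition",
    "exhaustive_partition",
    "modularity_over_density",
    "ks_statistic",
    "group_tests",
    "tmap",
    "tmap_summary",
]


# ---------------------------------------------------------------------------
# ISI family


def isi(G: np.ndarray) -> float:
    """Inter-symbol-interference score of a global (demixing x mixing) matrix.

    Zero iff ``|G|`` is a scaled permutation (perfect separation up to the
    inherent scale/order ambiguities), at most one (reached by an all-ones
    matrix); rows and columns are normalized by their largest entry.
    """
    G = np.abs(np.asarray(G, dtype=float))
    N = G.shape[0]
    if G.shape != (N, N):
        raise ValueError("ISI needs a square matrix")
    row_max = G.max(axis=1)
    col_max = G.max(axis=0)
    if np.any(row_max <= 0) or np.any(col_max <= 0):
        raise ValueError("ISI undefined for a matrix with an all-zero row or column")
    rows = (G / row_max[:, None]).sum(axis=1) - 1.0
    cols = (G / col_max[None, :]).sum(axis=0) - 1.0
    return float((rows.sum() + cols.sum()) / (2.0 * N * (N - 1)))


def joint_isi(G_list) -> float:
    """ISI of the mean absolute global matrix across subjects."""
    mats = [np.abs(np.asarray(g, dtype=float)) for g in G_list]
    if not mats:
        raise ValueError("joint ISI needs at least one matrix")
    return isi(np.mean(mats, axis=0))


def global_matrices(W: list[np.ndarray], mixings: np.ndarray,
                    whiteners: list[np.ndarray] | None = None) -> list[np.ndarray]:
    """Global matrices ``G_k = W_k (P_k A_k)`` against known ground truth.

    ``whiteners`` (the PCA forward maps) are composed with the true mixing
    so the comparison happens in the space the solver worked in.
    """
    out = []
    for k, w in enumerate(W):
        A = mixings[k]
        if whiteners is not None:
            A = whiteners[k] @ A
        out.append(np.asarray(w) @ A)
    return out


@dataclass
class ISIReport:
    """Cross-run reproducibility report.

    ``pairwise[i, j]`` is the joint-ISI between runs i and j over the
    performance matrices ``P_ij_k = inv(W_i_k) W_j_k``; ``per_run`` are the
    row means over ``j != i``; ``partial_*`` restrict the mean absolute
    performance matrix to its leading M x M (constrained) block.
    """

    pairwise: np.ndarray
    per_run: np.ndarray
    partial_pairwise: np.ndarray | None = None
    partial_per_run: np.ndarray | None = None

    @property
    def mean(self) -> float:
        return float(self.per_run.mean())

    @property
    def partial_mean(self) -> float | None:
        return None if self.partial_per_run is None else float(self.partial_per_run.mean())


def cross_joint_isi(W_runs: list[list[np.ndarray]], n_constrained: int | None = None) -> ISIReport:
    """Run-to-run consistency of R repeated decompositions.

    ``W_runs[i][k]`` is the demixing matrix of subject k in run i.  The
    performance matrix of runs (i, j) for subject k treats run i's
    estimated mixing ``inv(W_i_k)`` as the reference: ``P_ij_k = W_j_k
    inv(W_i_k)``, a scaled permutation when the runs are equivalent.  The
    partial variant (computed when ``n_constrained`` is given) applies the
    ISI to the leading M x M block of the mean absolute performance matrix,
    i.e. only the constrained components.
    """
    R = len(W_runs)
    if R < 2:
        raise ValueError("cross-joint ISI needs at least two runs")
    K = len(W_runs[0])
    pair = np.zeros((R, R))
    part = np.zeros((R, R)) if n_constrained else None
    inv_runs = [[np.linalg.inv(np.asarray(w)) for w in run] for run in W_runs]
    for i, j in itertools.combinations(range(R), 2):
        Ps = [np.abs(np.asarray(W_runs[j][k]) @ inv_runs[i][k]) for k in range(K)]
        mean_abs = np.mean(Ps, axis=0)
        pair[i, j] = pair[j, i] = isi(mean_abs)
        if part is not None:
            M = n_constrained
            part[i, j] = part[j, i] = isi(mean_abs[:M, :M])
    mask = ~np.eye(R, dtype=bool)
    per_run = pair.sum(axis=1) / (R - 1)
    report = ISIReport(pairwise=pair, per_run=per_run)
    if part is not None:
        report.partial_pairwise = part
        report.partial_per_run = part.sum(axis=1) / (R - 1)
    return report


# ---------------------------------------------------------------------------
# time-course cleaning and FNC


def detrend_despike(tc: np.ndarray) -> np.ndarray:
    """Linear detrend then clip spikes to a running-median MAD fence.

    The least-squares linear trend is removed; samples deviating from a
    7-point running median by more than 3 normal-consistent MADs (median
    absolute deviation x 1.4826) are clipped to that fence.
    """
    tc = np.asarray(tc, dtype=float)
    T = tc.shape[0]
    if T < 8:
        raise ValueError("need at least 8 time points")
    t = np.arange(T, dtype=float)
    design = np.column_stack([np.ones(T), t])
    beta, *_ = np.linalg.lstsq(design, tc, rcond=None)
    x = tc - design @ beta
    med = ndimage.median_filter(x, size=7, mode="nearest")
    resid = x - med
    mad = 1.4826 * np.median(np.abs(resid))
    fence = 3.0 * mad
    return np.clip(x, med - fence, med + fence)


@dataclass
class FNCMatrix:
    """Symmetric component-by-component connectivity matrix."""

    values: np.ndarray
    kind: str                      # 'temporal' or 'spatial'
    transform: str = "r"           # 'r' or 'fisher_z'
    excluded: np.ndarray | None = None  # components without valid entries

    @property
    def N(self) -> int:
        return self.values.shape[0]


_R_CLIP = 1.0 - 1e-12


def fisher_z(r: np.ndarray) -> np.ndarray:
    """Variance-stabilizing atanh, with r clipped to keep z finite."""
    return np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP))


def temporal_fnc(timecourses: np.ndarray, fisher: bool = False,
                 preprocess: bool = True) -> FNCMatrix:
    """Pairwise Pearson correlation between component time courses (T x N)."""
    tc = np.asarray(timecourses, dtype=float)
    if preprocess:
        tc = np.column_stack([detrend_despike(tc[:, j]) for j in range(tc.shape[1])])
    sd = tc.std(axis=0)
    bad = sd < 1e-12
    tc = tc.copy()
    tc[:, bad] = np.nan
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(tc.T)
    r = np.clip(r, -_R_CLIP, _R_CLIP)
    np.fill_diagonal(r, 1.0)
    if fisher:
        z = fisher_z(r)
        np.fill_diagonal(z, 0.0)
        return FNCMatrix(values=z, kind="temporal", transform="fisher_z", excluded=bad)
    return FNCMatrix(values=r, kind="temporal", transform="r", excluded=bad)


def spatial_fnc(maps: np.ndarray, z_thresh: float = 2.0) -> FNCMatrix:
    """Correlation between z-scored, activation-thresholded spatial maps.

    Each map (row of the N x V input) is z-scored over voxels; entries with
    ``|z| < z_thresh`` are set to zero to retain only high-activation
    voxels, then plain Pearson correlations are computed between the
    thresholded maps.  Maps left entirely sub-threshold are flagged in
    ``excluded`` and their correlations set to NaN.
    """
    maps = np.asarray(maps, dtype=float)
    mu = maps.mean(axis=1, keepdims=True)
    sd = maps.std(axis=1, keepdims=True)
    if np.any(sd < 1e-12):
        raise ValueError("spatial FNC undefined for a constant map")
    z = (maps - mu) / sd
    z[np.abs(z) < z_thresh] = 0.0
    alive = z.std(axis=1) > 0
    r = np.full((maps.shape[0],) * 2, np.nan)
    if alive.any():
        sub = np.corrcoef(z[alive])
        r[np.ix_(alive, alive)] = np.atleast_2d(sub)
    r = np.clip(r, -_R_CLIP, _R_CLIP)
    np.fill_diagonal(r, 1.0)
    return FNCMatrix(values=r, kind="spatial", transform="r", excluded=~alive)


# ---------------------------------------------------------------------------
# graph construction and modularity


def binarize_by_density(F: FNCMatrix | np.ndarray, density: float) -> np.ndarray:
    """Keep the strongest positive connections up to the requested density.

    Negative values and self-connections are removed first; the
    ``ceil(density * N (N-1) / 2)`` largest positive off-diagonal entries
    become edges (ties broken by (row, col) index order).  If there are too
    few positive entries, all of them are kept.
    """
    vals = F.values if isinstance(F, FNCMatrix) else np.asarray(F, dtype=float)
    N = vals.shape[0]
    if not 0.0 < density <= 1.0:
        raise ValueError("density must be in (0, 1]")
    iu, ju = np.triu_indices(N, k=1)
    w = vals[iu, ju]
    pos = np.nan_to_num(w, nan=-np.inf) > 0
    target = int(np.ceil(density * N * (N - 1) / 2))
    order = np.lexsort((ju, iu, -np.nan_to_num(w, nan=-np.inf)))
    order = order[pos[order]][:target]
    A = np.zeros((N, N), dtype=int)
    A[iu[order], ju[order]] = 1
    return A + A.T


@dataclass
class ModularityResult:
    """Best partition found, its Q, and the graph density that produced it."""

    partition: np.ndarray
    Q: float
    link_density: float | None = None
    threshold: float | None = None


def modularity_q(A: np.ndarray, partition) -> float:
    """Newman modularity with the degree-product (configuration) null.

    ``Q = (1 / 2m) sum_ij (A_ij - d_i d_j / 2m) delta(m_i, m_j)`` with
    ``2m`` the total number of edge endpoints — the normalization under
    which two disjoint triangles score 0.5 and a complete graph scores 0.
    """
    A = np.asarray(A, dtype=float)
    part = np.asarray(partition)
    two_m = A.sum()
    if two_m <= 0:
        raise ValueError("modularity undefined for an edgeless graph")
    d = A.sum(axis=1)
    same = part[:, None] == part[None, :]
    return float(((A - np.outer(d, d) / two_m) * same).sum() / two_m)


def _labels_from_communities(comms, N: int) -> np.ndarray:
    lab = np.empty(N, dtype=int)
    for i, c in enumerate(comms):
        for v in c:
            lab[v] = i
    return lab


def _refine_partition(A: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, float]:
    """Single-node-move hill climbing until no move improves Q."""
    labels = labels.copy()
    N = labels.size
    q = modularity_q(A, labels)
    improved = True
    while improved:
        improved = False
        for v in range(N):
            current = labels[v]
            candidates = set(labels.tolist())
            candidates.add(labels.max() + 1)  # allow splitting off
            candidates.discard(current)
            for c in candidates:
                labels[v] = c
                qc = modularity_q(A, labels)
                if qc > q + 1e-13:
                    q = qc
                    current = c
                    improved = True
            labels[v] = current
    return labels, q


def best_partition(A: np.ndarray, seed: int = 0, n_restarts: int = 20) -> ModularityResult:
    """Seeded multi-level (Louvain) modularity maximization.

    Runs the greedy multi-level search from ``n_restarts`` different
    sub-seeds, plus the same number of seeded random-label starts, and
    polishes every candidate with single-node-move hill climbing.  The
    landscape of small graphs is rugged relative to Louvain's coarsening,
    so the random starts and the refinement pass regularly rescue optima
    the multi-level greedy alone misses.
    """
    A = np.asarray(A)
    if A.sum() <= 0:
        raise ValueError("best_partition needs at least one edge")
    N = A.shape[0]
    G = nx.from_numpy_array(A)
    rng = np.random.default_rng(seed)
    best_lab, best_q = None, -np.inf
    for r in range(2 * n_restarts):
        if r % 2 == 0:
            comms = nx.community.louvain_communities(G, seed=seed + r)
            lab = _labels_from_communities(comms, N)
        else:
            lab = rng.integers(0, max(2, N // 2), N)
        lab, q = _refine_partition(A, lab)
        if q > best_q:
            best_q, best_lab = q, lab
    return ModularityResult(partition=best_lab, Q=float(best_q))


def exhaustive_partition(A: np.ndarray) -> ModularityResult:
    """Brute-force modularity maximum over all partitions (tiny graphs only)."""
    A = np.asarray(A)
    N = A.shape[0]
    if N > 10:
        raise ValueError("exhaustive search is only meant for graphs with <= 10 nodes")

    best_lab, best_q = None, -np.inf
    lab = np.zeros(N, dtype=int)

    def rec(i: int, n_used: int):
        nonlocal best_lab, best_q
        if i == N:
            q = modularity_q(A, lab)
            if q > best_q:
                best_q, best_lab = q, lab.copy()
            return
        for c in range(n_used + 1):
            lab[i] = c
            rec(i + 1, max(n_used, c + 1))

    rec(0, 0)
    return ModularityResult(partition=best_lab, Q=float(best_q))


def modularity_over_density(
    F: FNCMatrix | np.ndarray,
    densities: np.ndarray | None = None,
    seed: int = 0,
) -> ModularityResult:
    """Maximum modularity over a link-density grid (default 20%..70%).

    For each density the FNC matrix is binarized and the best partition
    searched; the result with the highest Q is reported together with the
    density (and edge-weight threshold) that produced it.
    """
    if densities is None:
        densities = np.round(np.arange(0.20, 0.7001, 0.05), 2)
    vals = F.values if isinstance(F, FNCMatrix) else np.asarray(F, dtype=float)
    best: ModularityResult | None = None
    for d in np.atleast_1d(densities):
        A = binarize_by_density(vals, float(d))
        if A.sum() == 0:
            continue
        res = best_partition(A, seed=seed)
        if best is None or res.Q > best.Q:
            kept = vals[np.triu_indices_from(vals, k=1)][
                A[np.triu_indices_from(A, k=1)] > 0
            ]
            best = ModularityResult(
                partition=res.partition,
                Q=res.Q,
                link_density=float(d),
                threshold=float(kept.min()) if kept.size else None,
            )
    if best is None:
        raise ValueError("no density produced a graph with edges")
    return best


# ---------------------------------------------------------------------------
# statistics


def ks_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sample Kolmogorov-Smirnov statistic (sup distance between ECDFs)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    return float(stats.ks_2samp(x, y, method="asymp").statistic)


@dataclass
class GroupTestResult:
    """Entry-wise t statistics, raw p-values and the BH-FDR rejection mask."""

    t: np.ndarray
    p: np.ndarray
    mask: np.ndarray
    kind: str
    q: float = 0.05

    @property
    def n_significant(self) -> int:
        return int(self.mask.sum())


def bh_fdr(p: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at level ``q``."""
    p = np.asarray(p, dtype=float)
    flat = p.ravel()
    ok = np.isfinite(flat)
    mask = np.zeros(flat.size, dtype=bool)
    if ok.any():
        mask[ok] = multipletests(flat[ok], alpha=q, method="fdr_bh")[0]
    return mask.reshape(p.shape)


def group_tests(
    values: np.ndarray,
    labels: np.ndarray | None = None,
    kind: str = "two-sample",
    q: float = 0.05,
) -> GroupTestResult:
    """Entry-wise t-tests with Benjamini-Hochberg FDR control.

    ``values`` is subjects x entries (entries can be vectorized FNC cells,
    per-component similarities, ...).  ``kind`` selects a pooled-variance
    two-sample test between the two label groups, a paired test (labels
    split the subjects into two matched halves in order), or a one-sample
    test against zero.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if kind == "two-sample":
        labels = np.asarray(labels)
        g = np.unique(labels)
        if g.size != 2:
            raise ValueError("two-sample test needs exactly two groups")
        a, b = values[labels == g[0]], values[labels == g[1]]
        if min(len(a), len(b)) < 2:
            raise ValueError("each group needs at least two subjects")
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=True)
    elif kind == "paired":
        labels = np.asarray(labels)
        g = np.unique(labels)
        a, b = values[labels == g[0]], values[labels == g[1]]
        if len(a) != len(b) or len(a) < 2:
            raise ValueError("paired test needs two equal-size matched groups")
        t, p = stats.ttest_rel(a, b, axis=0)
    elif kind == "one-sample":
        if values.shape[0] < 2:
            raise ValueError("one-sample test needs at least two subjects")
        t, p = stats.ttest_1samp(values, 0.0, axis=0)
    else:
        raise ValueError(f"unknown test kind {kind!r}")
    t = np.atleast_1d(np.asarray(t, dtype=float))
    p = np.atleast_1d(np.asarray(p, dtype=float))
    return GroupTestResult(t=t, p=p, mask=bh_fdr(p, q), kind=kind, q=q)


_T_CAP = 1e6


def tmap(maps: np.ndarray) -> np.ndarray:
    """Voxel-wise one-sample t statistics across subjects (K x V input).

    Zero-variance voxels get t = 0 when the common value is zero and are
    capped at +/-1e6 otherwise (all subjects identical and non-zero).
    """
    maps = np.asarray(maps, dtype=float)
    K = maps.shape[0]
    if K < 2:
        raise ValueError("t-map needs at least two subjects")
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    t = np.zeros_like(mean)
    ok = sd > 0
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(K))
    degenerate = (~ok) & (mean != 0)
    t[degenerate] = np.sign(mean[degenerate]) * _T_CAP
    return np.clip(t, -_T_CAP, _T_CAP)


def tmap_summary(t: np.ndarray, thresholds) -> dict[float, float]:
    """Mean |t| over voxels whose z-scored |t| exceeds each threshold.

    The t-map is standardized (z-scored over voxels) and, for each listed
    threshold, the mean absolute raw t is taken over the surviving non-zero
    voxels; NaN when no voxel survives.
    """
    t = np.asarray(t, dtype=float).ravel()
    z = (t - t.mean()) / t.std() if t.std() > 0 else np.zeros_like(t)
    out = {}
    for thr in np.atleast_1d(thresholds):
        sel = (np.abs(z) > thr) & (t != 0)
        out[float(thr)] = float(np.abs(t[sel]).mean()) if sel.any() else float("nan")
    return out
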