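"""IVA cost and gradients under the multivariate-Gaussian SCV model (IVA-G).

The source component vector (SCV) formed by the nth component across all K
subjects is modeled as K-variate Gaussian, so only second-order
cross-subject statistics drive the cost:

    J(W) = sum_n 1/2 log((2 pi e)^K det Sigma_n) - sum_k log |det W_k|,

where ``Sigma_n[k, l] = w_n_k' R_kl w_n_l`` and ``R_kl = X_k X_l' / V`` are
the cross-subject data covariances (the constant data-entropy term is
dropped; it does not depend on W).  :class:`IvaGModel` precomputes the
``R_kl`` once so that the decoupled row-wise updates never touch the
V-dimensional data again.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import DemixingSet, decouple_vector

__all__ = ["SCVCovariance", "IvaGModel", "scv_covariance", "iva_g_cost", "iva_g_grad_row"]

LOG_2PIE = float(np.log(2.0 * np.pi * np.e))


@dataclass
class SCVCovariance:
    """Empirical K x K covariance of each of the N SCVs (ridge-stabilized)."""

    sigma: np.ndarray  # N x K x K


def scv_covariance(Y: np.ndarray) -> SCVCovariance:
    """Empirical SCV covariances from K x N x V source estimates.

    Rows are centered internally; a relative ridge ``delta * I`` with
    ``delta = 1e-12 * trace / K`` keeps near-singular SCVs (which occur at
    small V or perfect cross-subject dependence) invertible.  When V < K
    the covariance is rank-deficient by construction and a larger ridge
    (1e-6) is applied.
    """
    Y = np.asarray(Y, dtype=float)
    K, N, V = Y.shape
    if V < K:
        warnings.warn(
            f"fewer samples ({V}) than subjects ({K}): SCV covariances are "
            "rank-deficient; applying a larger ridge",
            stacklevel=2,
        )
    Yc = Y - Y.mean(axis=2, keepdims=True)
    sigma = np.einsum("knv,lnv->nkl", Yc, Yc) / V
    rel = 1e-6 if V < K else 1e-12
    tr = np.trace(sigma, axis1=1, axis2=2) / K
    sigma = sigma + (rel * np.maximum(tr, 1e-300))[:, None, None] * np.eye(K)
    return SCVCovariance(sigma=sigma)


class IvaGModel:
    """Precomputed second-order model of one multi-subject dataset.

    Parameters
    ----------
    blocks : list of K arrays, N x V each
        Reduced (whitened) per-subject data.
    """

    def __init__(self, blocks: list[np.ndarray]):
        blocks = [np.asarray(b, dtype=float) for b in blocks]
        self.K = len(blocks)
        self.N, self.V = blocks[0].shape
        Xc = np.stack([b - b.mean(axis=1, keepdims=True) for b in blocks])
        # cross-subject data covariances R[k, l] = X_k X_l' / V
        self.R = np.einsum("kiv,ljv->klij", Xc, Xc) / self.V

    # -- SCV covariance from demixing rows, without touching the data -----
    def scv_sigma(self, W: DemixingSet, n: int) -> np.ndarray:
        rows = np.stack([W[k][n] for k in range(self.K)])  # K x N
        sigma = np.einsum("ki,klij,lj->kl", rows, self.R, rows)
        tr = np.trace(sigma) / self.K
        return sigma + 1e-12 * max(tr, 1e-300) * np.eye(self.K)

    def all_sigma(self, W: DemixingSet) -> np.ndarray:
        Wa = np.stack(W.W)  # K x N x N
        sigma = np.einsum("kni,klij,lnj->nkl", Wa, self.R, Wa)
        tr = np.trace(sigma, axis1=1, axis2=2) / self.K
        return sigma + (1e-12 * np.maximum(tr, 1e-300))[:, None, None] * np.eye(self.K)

    def cost(self, W: DemixingSet) -> float:
        """IVA-G cost (data-entropy constant dropped)."""
        sigma = self.all_sigma(W)
        sign, logdet = np.linalg.slogdet(sigma)
        if np.any(sign <= 0):
            raise np.linalg.LinAlgError("non-PD SCV covariance")
        entropy = 0.5 * (self.K * LOG_2PIE + logdet).sum()
        det_term = 0.0
        for k in range(self.K):
            s, ld = np.linalg.slogdet(W[k])
            if s == 0:
                raise np.linalg.LinAlgError(f"singular demixing matrix for subject {k}")
            det_term += ld
        return float(entropy - det_term)

    def grad_row(
        self, W: DemixingSet, n: int, k: int, h: np.ndarray | None = None
    ) -> np.ndarray:
        """Gradient of the IVA-G cost with respect to demixing row ``w_n_k``.

        ``sum_l inv(Sigma_n)[k, l] R_kl w_n_l - h / (w' h)`` with ``h`` the
        decoupling vector for row n of subject k.
        """
        if h is None:
            h = decouple_vector(W[k], n)
        sigma = self.scv_sigma(W, n)
        Sinv = np.linalg.inv(sigma)
        rows = np.stack([W[l][n] for l in range(self.K)])  # K x N
        ent = np.einsum("l,lij,lj->i", Sinv[k], self.R[k], rows)
        w = W[k][n]
        denom = float(w @ h)
        return ent - h / denom


def iva_g_cost(W: DemixingSet | list[np.ndarray], X) -> float:
    """Convenience wrapper: IVA-G cost of ``W`` on data blocks ``X``."""
    W = W if isinstance(W, DemixingSet) else DemixingSet(list(W))
    blocks = X.blocks if hasattr(X, "blocks") else X
    return IvaGModel(blocks).cost(W)


def iva_g_grad_row(W: DemixingSet | list[np.ndarray], X, n: int, k: int) -> np.ndarray:
    """Convenience wrapper: IVA-G gradient for row ``n`` of subject ``k``."""
    W = W if isinstance(W, DemixingSet) else DemixingSet(list(W))
    blocks = X.blocks if hasattr(X, "blocks") else X
    return IvaGModel(blocks).grad_row(W, n, k)
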