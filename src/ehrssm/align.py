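"""Latent relabelling: the model is identified only up to permutation and
sign of the latent dimensions, so fitted factors are matched to reference
factors by Hungarian assignment on |H| column similarity before any
entry-wise comparison."""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = ["align_latent", "apply_alignment"]


def align_latent(H_fit: np.ndarray, H_ref: np.ndarray):
    """Match fitted latent columns to reference columns.

    Returns ``(perm, signs)`` such that column ``perm[j]`` of the fit,
    multiplied by ``signs[j]``, corresponds to reference column ``j``.
    Similarity is the inner product of normalized |H| columns.
    """
    p = H_ref.shape[1]

    def unit_abs(M):
        a = np.abs(M)
        norms = np.linalg.norm(a, axis=0)
        norms[norms == 0] = 1.0
        return a / norms

    sim = unit_abs(H_ref).T @ unit_abs(H_fit)  # (p_ref, p_fit)
    ref_idx, fit_idx = linear_sum_assignment(-sim)
    perm = np.empty(p, dtype=int)
    signs = np.empty(p)
    for r, f in zip(ref_idx, fit_idx):
        perm[r] = f
        dot = H_ref[:, r] @ H_fit[:, f]
        signs[r] = 1.0 if dot >= 0 else -1.0
    return perm, signs


def apply_alignment(A, G, H, perm, signs):
    """Relabel (A, G, H) jointly so they are comparable with the reference
    ordering: x -> S P' x leaves the likelihood invariant."""
    S = np.diag(signs)
    A2 = S @ A[np.ix_(perm, perm)] @ S
    G2 = S @ G[perm, :]
    H2 = H[:, perm] @ S
    return A2, G2, H2
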