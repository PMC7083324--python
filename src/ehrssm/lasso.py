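"""Row-wise lasso solver for the penalized M-step.

Solves  min_x  ½ x'Sx − s'x + λ‖x‖₁  (S ⪰ 0 Gram matrix from E-step
sufficient statistics) by cyclic coordinate descent with soft-thresholding
and an active-set outer loop: sweep all coordinates, iterate the non-zero
set to convergence, and re-sweep until the active set is stable.  One
coordinate may carry a box constraint (the diagonal transition weight,
bounded below 0.8 in absolute value), enforced by clipping the
soft-threshold solution — exact for the convex one-dimensional subproblem.
"""

from __future__ import annotations

import numpy as np

__all__ = ["lasso_cd", "kkt_violation", "soft_threshold"]


def soft_threshold(v: float, lam: float) -> float:
    if v > lam:
        return v - lam
    if v < -lam:
        return v + lam
    return 0.0


def _sweep(S, s, lam, x, coords, box_idx, box_lo, box_hi) -> float:
    max_delta = 0.0
    for j in coords:
        Sjj = S[j, j]
        if Sjj <= 1e-14:
            continue
        # gradient of the smooth part with x_j removed
        g = s[j] - S[j] @ x + Sjj * x[j]
        new = soft_threshold(g, lam) / Sjj
        if j == box_idx:
            new = min(max(new, box_lo), box_hi)
        delta = abs(new - x[j])
        if delta > max_delta:
            max_delta = delta
        x[j] = new
    return max_delta


def lasso_cd(
    S: np.ndarray,
    s: np.ndarray,
    lam: float,
    x0: np.ndarray | None = None,
    box: tuple | None = None,
    tol: float = 1e-10,
    max_sweeps: int = 10_000,
) -> np.ndarray:
    """Minimize ½ x'Sx − s'x + λ‖x‖₁, optionally with one boxed coordinate.

    ``box`` is ``(index, lo, hi)``.  Raises on non-convergence.
    """
    n = s.size
    x = np.zeros(n) if x0 is None else np.asarray(x0, dtype=float).copy()
    box_idx, box_lo, box_hi = (-1, 0.0, 0.0) if box is None else box
    if box is not None:
        x[box_idx] = min(max(x[box_idx], box_lo), box_hi)
    all_coords = np.arange(n)
    sweeps = 0
    while True:
        # full sweep over every coordinate
        _sweep(S, s, lam, x, all_coords, box_idx, box_lo, box_hi)
        sweeps += 1
        support = frozenset(np.flatnonzero(x).tolist())
        # iterate the active set to convergence
        active = np.fromiter(support, dtype=int) if support else np.empty(0, dtype=int)
        while active.size:
            delta = _sweep(S, s, lam, x, active, box_idx, box_lo, box_hi)
            sweeps += 1
            if sweeps > max_sweeps:
                raise RuntimeError("coordinate descent did not converge")
            if delta < tol:
                break
        # re-sweep: stop when the support is stable and nothing moved
        delta = _sweep(S, s, lam, x, all_coords, box_idx, box_lo, box_hi)
        sweeps += 1
        if sweeps > max_sweeps:
            raise RuntimeError("coordinate descent did not converge")
        if delta < tol and frozenset(np.flatnonzero(x).tolist()) == support:
            return x


def kkt_violation(S: np.ndarray, s: np.ndarray, lam: float, x: np.ndarray,
                  box: tuple | None = None) -> float:
    """Max KKT violation of the lasso problem at ``x`` (0 at an optimum).

    For a boxed coordinate sitting on its bound, only the inward gradient
    direction counts.
    """
    grad = S @ x - s  # gradient of smooth part
    viol = 0.0
    box_idx = -1 if box is None else box[0]
    for j in range(s.size):
        gj = grad[j]
        if j == box_idx:
            _, lo, hi = box
            sign = np.sign(x[j]) if x[j] != 0 else 0.0
            if x[j] >= hi - 1e-12:
                # at the upper bound, moving down must not decrease the objective
                v = max(0.0, gj + lam * (sign if sign else 1.0))
            elif x[j] <= lo + 1e-12:
                # at the lower bound, moving up must not decrease the objective
                v = max(0.0, -(gj + lam * (sign if sign else -1.0)))
            elif x[j] != 0:
                v = abs(gj + lam * sign)
            else:
                v = max(0.0, abs(gj) - lam)
            viol = max(viol, v)
            continue
        if x[j] != 0:
            viol = max(viol, abs(gj + lam * np.sign(x[j])))
        else:
            viol = max(viol, max(0.0, abs(gj) - lam))
    return viol
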