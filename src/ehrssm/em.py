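"""L1-regularized maximum likelihood for the sparse state-space model.

The penalized log-likelihood

    log L(Y | θ) − Σ_i λ_i^(s) (‖a_i‖₁ + ‖g_i‖₁) − Σ_{i'} λ_{i'}^(o) ‖h_{i'}‖₁

is maximized by EM.  The E-step is exact (Kalman smoother moments); the
M-step solves one lasso per row of [A | G] and per row of H by active-set
coordinate descent, weighting each row's quadratic form by the previous
iterate's noise variance so the rows stay separable, then updates the Q and
R diagonals and the per-participant initial means in closed form.  Each
M-step block maximizes the penalized expected complete-data log-likelihood
given the others, so the generalized-EM monotonicity guarantee holds for
the penalized objective; the |A_ii| < 0.8 box is part of the feasible set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import CohortDataset, StackedCohort
from .kalman import A_DIAG_BOUND, SSMParameters, filter_cohort, smooth_cohort
from .lasso import lasso_cd

__all__ = [
    "PenaltyConfig",
    "EStepStats",
    "FitResult",
    "InitSpec",
    "EMMonotonicityError",
    "e_step",
    "m_step_l1",
    "fit_em",
    "initial_parameters",
    "penalty_value",
]

_A_EPS = 1e-6  # the diagonal box is closed at ±(0.8 − eps)
_VAR_FLOOR = 1e-10


class EMMonotonicityError(RuntimeError):
    """Raised when an EM iteration decreases the penalized objective."""

    def __init__(self, message, before=None, after=None):
        super().__init__(message)
        self.before = before
        self.after = after


@dataclass
class PenaltyConfig:
    """Per-row L1 penalties: λ_i^(s) for rows of [A | G], λ_{i'}^(o) for
    rows of H.  Scalars broadcast to all rows."""

    lambda_sys: float | np.ndarray = 0.0
    lambda_obs: float | np.ndarray = 0.0

    def sys_rows(self, p: int) -> np.ndarray:
        out = np.broadcast_to(np.asarray(self.lambda_sys, dtype=float), (p,)).copy()
        if (out < 0).any():
            raise ValueError("penalties must be non-negative")
        return out

    def obs_rows(self, q: int) -> np.ndarray:
        out = np.broadcast_to(np.asarray(self.lambda_obs, dtype=float), (q,)).copy()
        if (out < 0).any():
            raise ValueError("penalties must be non-negative")
        return out


def penalty_value(params: SSMParameters, penalty: PenaltyConfig) -> float:
    lam_s = penalty.sys_rows(params.p)
    lam_o = penalty.obs_rows(params.q)
    return float(
        (lam_s * (np.abs(params.A).sum(axis=1) + np.abs(params.G).sum(axis=1))).sum()
        + (lam_o * np.abs(params.H).sum(axis=1)).sum()
    )


@dataclass
class EStepStats:
    """Pooled smoothed sufficient statistics of the complete-data
    log-likelihood.  ``u_{t-1} = [x_{t-1}; z_{t-1}]`` stacks state and
    covariate; observation blocks are kept per trait because element-wise
    masks make each trait's observed set different."""

    S_uu: np.ndarray        # (p+m, p+m)  Σ E[u u']
    S_xu: np.ndarray        # (p, p+m)    Σ E[x_t u']
    S_xx: np.ndarray        # (p, p)      Σ E[x_t x_t'] over transitions
    n_trans: int
    S_obs_xx: np.ndarray    # (q, p, p)   per-trait Σ E[x x'] at observed cells
    s_obs: np.ndarray       # (q, p)      per-trait Σ y E[x]
    syy: np.ndarray         # (q,)        per-trait Σ y²
    n_obs: np.ndarray       # (q,)        per-trait observed-cell counts
    m0: np.ndarray          # (K, p)      smoothed initial means E[x_0 | Y]
    loglik: float           # marginal log-likelihood of the producing params


def e_step(params: SSMParameters, ds: CohortDataset | StackedCohort) -> EStepStats:
    """Exact E-step: assemble pooled moments from the batched smoother."""
    stacked = ds if isinstance(ds, StackedCohort) else ds.to_stacked()
    filt = filter_cohort(params, stacked)
    sm = smooth_cohort(params, stacked, filt)
    p, m = params.p, stacked.m
    tmask = stacked.transition_mask.astype(float)  # (K, T)

    ms = sm.m_smooth  # (K, T+1, p), index 0 is x_0
    Ps = sm.P_smooth
    Ex_t = ms[:, 1:]       # states at t = 1..T
    Ex_prev = ms[:, :-1]   # states at t-1 = 0..T-1
    Exx_t = Ps[:, 1:] + Ex_t[..., :, None] * Ex_t[..., None, :]
    Exx_prev = Ps[:, :-1] + Ex_prev[..., :, None] * Ex_prev[..., None, :]
    Exx_cross = sm.C_cross + Ex_t[..., :, None] * Ex_prev[..., None, :]

    z = stacked.z_drive
    w_x_t = (tmask[..., None] * Ex_t).reshape(-1, p)
    x_prev_flat = Ex_prev.reshape(-1, p)
    z_flat = z.reshape(-1, m)
    S_x1x1 = np.tensordot(tmask, Exx_prev, axes=([0, 1], [0, 1]))
    S_xx = np.tensordot(tmask, Exx_t, axes=([0, 1], [0, 1]))
    S_xx1 = np.tensordot(tmask, Exx_cross, axes=([0, 1], [0, 1]))
    S_xz = w_x_t.T @ z_flat
    S_x1z = (tmask[..., None] * Ex_prev).reshape(-1, p).T @ z_flat
    S_zz = (tmask.reshape(-1, 1) * z_flat).T @ z_flat

    S_uu = np.empty((p + m, p + m))
    S_uu[:p, :p] = (S_x1x1 + S_x1x1.T) / 2
    S_uu[:p, p:] = S_x1z
    S_uu[p:, :p] = S_x1z.T
    S_uu[p:, p:] = (S_zz + S_zz.T) / 2
    S_xu = np.concatenate([S_xx1, S_xz], axis=1)

    mask = stacked.mask.astype(float)
    y0 = np.where(stacked.mask, stacked.y, 0.0)
    q = y0.shape[2]
    S_obs_xx = np.tensordot(
        mask.reshape(-1, q), Exx_t.reshape(-1, p * p), axes=(0, 0)
    ).reshape(q, p, p)
    s_obs = np.tensordot(y0.reshape(-1, q), Ex_t.reshape(-1, p), axes=(0, 0))
    syy = (y0 * y0).sum(axis=(0, 1))
    n_obs = mask.sum(axis=(0, 1))

    return EStepStats(
        S_uu=S_uu,
        S_xu=S_xu,
        S_xx=(S_xx + S_xx.T) / 2,
        n_trans=int(tmask.sum()),
        S_obs_xx=S_obs_xx,
        s_obs=s_obs,
        syy=syy,
        n_obs=n_obs,
        m0=ms[:, 0],
        loglik=filt.loglik,
    )


def m_step_l1(
    stats: EStepStats,
    penalty: PenaltyConfig,
    prev: SSMParameters,
    a_lower_bound: bool = True,
    cd_tol: float = 1e-10,
) -> SSMParameters:
    """Penalized M-step: row-wise lasso for [A | G] and H, closed-form Q, R,
    and μ_{k,0} updates.

    Row i of [A | G] minimizes (1/(2 Q_ii)) of its expected squared residual
    plus λ_i^(s) times its L1 norm; multiplying through by the previous
    iterate's Q_ii turns this into a standard lasso with effective penalty
    λ_i^(s) Q_ii.  The diagonal transition coefficient is box-constrained to
    |A_ii| ≤ 0.8 − 1e-6 inside coordinate descent.
    """
    p, q, m = prev.p, prev.q, prev.m
    lam_s = penalty.sys_rows(p)
    lam_o = penalty.obs_rows(q)

    hi = A_DIAG_BOUND - _A_EPS
    lo = -hi if a_lower_bound else -np.inf
    B = np.empty((p, p + m))
    Qnew = np.empty(p)
    for i in range(p):
        x0 = np.concatenate([prev.A[i], prev.G[i]])
        b = lasso_cd(
            stats.S_uu,
            stats.S_xu[i],
            lam=lam_s[i] * prev.Q[i],
            x0=x0,
            box=(i, lo, hi),
            tol=cd_tol,
        )
        B[i] = b
        resid = stats.S_xx[i, i] - 2.0 * b @ stats.S_xu[i] + b @ stats.S_uu @ b
        Qnew[i] = max(resid / stats.n_trans, _VAR_FLOOR)

    Hnew = np.empty((q, p))
    Rnew = np.empty(q)
    for i in range(q):
        if stats.n_obs[i] == 0:
            Hnew[i] = prev.H[i]
            Rnew[i] = prev.R[i]
            continue
        h = lasso_cd(
            stats.S_obs_xx[i],
            stats.s_obs[i],
            lam=lam_o[i] * prev.R[i],
            x0=prev.H[i].copy(),
            tol=cd_tol,
        )
        Hnew[i] = h
        resid = stats.syy[i] - 2.0 * h @ stats.s_obs[i] + h @ stats.S_obs_xx[i] @ h
        Rnew[i] = max(resid / stats.n_obs[i], _VAR_FLOOR)

    return SSMParameters(
        A=B[:, :p],
        G=B[:, p:],
        H=Hnew,
        Q=Qnew,
        R=Rnew,
        mu0=stats.m0.copy(),
        Sigma0=prev.Sigma0.copy(),
    )


# ---------------------------------------------------------------------------
# Initialization


@dataclass
class InitSpec:
    """Deterministic base initialization plus seeded Gaussian perturbation
    for random restarts."""

    a_diag: float = 0.5
    noise_scale: float = 0.5
    perturb: float = 0.1
    seed: int | None = None

    def describe(self) -> str:
        return f"a_diag={self.a_diag},noise={self.noise_scale},perturb={self.perturb},seed={self.seed}"


def initial_parameters(stacked: StackedCohort, p: int, init: InitSpec) -> SSMParameters:
    """A = scaled identity, H = top-p principal directions of pooled y
    (mean-filled, sign-fixed), G = 0, Q = R = scaled identity, μ_{k,0} = 0;
    a seeded Gaussian perturbation of A, G, H produces restarts."""
    q, m, K = stacked.q, stacked.m, stacked.K
    y = np.where(stacked.mask, stacked.y, np.nan).reshape(-1, q)
    y = y[np.isfinite(y).any(axis=1)]
    y = np.nan_to_num(y, nan=0.0)  # standardized scale: mean-fill with 0
    # principal directions of the pooled panel
    ncomp = min(p, q, max(1, y.shape[0] - 1))
    _, _, Vt = np.linalg.svd(y - y.mean(axis=0), full_matrices=False)
    H = np.zeros((q, p))
    for j in range(ncomp):
        v = Vt[j]
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        H[:, j] = v
    A = np.eye(p) * init.a_diag
    G = np.zeros((p, m))
    if init.seed is not None and init.perturb > 0:
        rng = np.random.default_rng(init.seed)
        A = A + rng.normal(0.0, init.perturb, A.shape)
        np.fill_diagonal(A, np.clip(np.diag(A), -(A_DIAG_BOUND - _A_EPS), A_DIAG_BOUND - _A_EPS))
        G = G + rng.normal(0.0, init.perturb, G.shape)
        H = H + rng.normal(0.0, init.perturb, H.shape)
    params = SSMParameters(
        A=A,
        G=G,
        H=H,
        Q=np.full(p, init.noise_scale),
        R=np.full(q, init.noise_scale),
        mu0=np.zeros((K, p)),
        Sigma0=np.eye(p),
    )
    params.validate()
    return params


# ---------------------------------------------------------------------------
# EM driver


@dataclass
class FitResult:
    """Outcome of one EM run: final parameters, penalized-objective trace,
    convergence state and the non-zero parameter count used by BIC."""

    params: SSMParameters
    trace: list
    n_iter: int
    converged: bool
    df: int
    seed: int | None = None
    init_descriptor: str = ""
    penalty: PenaltyConfig = field(default_factory=PenaltyConfig)

    @property
    def objective(self) -> float:
        return self.trace[-1]


def count_df(params: SSMParameters, include_mu0: bool = True) -> int:
    """Non-zero entries of A, G, H plus the Q and R diagonals plus, by
    default, the K·p per-participant initial means (they are free
    parameters of θ; a flag excludes them)."""
    df = params.nonzero_count() + params.p + params.q
    if include_mu0:
        df += params.mu0.size
    return df


def fit_em(
    ds: CohortDataset | StackedCohort,
    p: int,
    penalty: PenaltyConfig | None = None,
    init: InitSpec | SSMParameters | None = None,
    max_iter: int = 200,
    tol: float = 1e-6,
    a_lower_bound: bool = True,
    include_mu0_in_df: bool = True,
    monotone_tol: float = 1e-6,
) -> FitResult:
    """Run EM to a local maximum of the penalized log-likelihood.

    ``tol`` is relative: iteration stops when the objective improves by less
    than ``tol * (1 + |objective|)``.  A decrease beyond ``monotone_tol``
    raises :class:`EMMonotonicityError` carrying both iterates.
    """
    if p < 1:
        raise ValueError("latent dimension p must be >= 1")
    stacked = ds if isinstance(ds, StackedCohort) else ds.to_stacked()
    penalty = penalty or PenaltyConfig()
    if isinstance(init, SSMParameters):
        params = init
        descriptor, seed = "user-supplied", None
    else:
        init = init or InitSpec()
        params = initial_parameters(stacked, p, init)
        descriptor, seed = init.describe(), init.seed

    stats = e_step(params, stacked)
    obj = stats.loglik - penalty_value(params, penalty)
    trace = [obj]
    converged = False
    for _ in range(max_iter):
        new_params = m_step_l1(stats, penalty, params, a_lower_bound=a_lower_bound)
        new_stats = e_step(new_params, stacked)
        new_obj = new_stats.loglik - penalty_value(new_params, penalty)
        trace.append(new_obj)
        if new_obj < obj - monotone_tol:
            raise EMMonotonicityError(
                f"penalized objective decreased from {obj:.10g} to {new_obj:.10g}",
                before=params,
                after=new_params,
            )
        improved = new_obj - obj
        params, stats, obj = new_params, new_stats, new_obj
        if improved < tol * (1.0 + abs(obj)):
            converged = True
            break
    return FitResult(
        params=params,
        trace=trace,
        n_iter=len(trace) - 1,
        converged=converged,
        df=count_df(params, include_mu0_in_df),
        seed=seed,
        init_descriptor=descriptor,
        penalty=penalty,
    )
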