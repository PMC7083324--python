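"""Linear Gaussian state-space core: exact filtering and smoothing.

The model per participant k is

    x_{k,t} = A x_{k,t-1} + G z_{k,t-1} + v_{k,t},   v ~ N(0, Q)
    y_{k,t} = H x_{k,t} + w_{k,t},                   w ~ N(0, R)
    x_{k,0} ~ N(mu_{k,0}, Sigma_0)

with diagonal Q, R.  Missing visits are skipped: when a visit carries no
observation the filtered posterior equals the predicted one, and only the
observed rows of H and R enter the update when a panel is partial (valid
because R is diagonal, so marginalizing unobserved components drops rows).

All recursions are batched over participants with einsum; participants are
grouped per time step by their observation mask so each group shares one
innovation factorization.  Covariances are propagated in Joseph form and
re-symmetrized, and innovations are handled through Cholesky solves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .cohort import CohortDataset, ParticipantSeries, StackedCohort

__all__ = [
    "SSMParameters",
    "StatePosterior",
    "kalman_filter",
    "kalman_smoother",
    "filter_cohort",
    "smooth_cohort",
    "log_likelihood",
]

A_DIAG_BOUND = 0.8  # diagonal transition weights are restricted below 0.8
_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class SSMParameters:
    """Full model parameterization θ = {A, G, Q, H, R, μ_{k,0}, Σ_0}.

    ``Q`` and ``R`` hold the diagonals of the (diagonal) noise covariances.
    ``mu0`` is ``(K, p)``: one initial latent mean per participant, aligned
    with the cohort's participant order.
    """

    A: np.ndarray
    G: np.ndarray
    H: np.ndarray
    Q: np.ndarray
    R: np.ndarray
    mu0: np.ndarray
    Sigma0: np.ndarray

    @property
    def p(self) -> int:
        return self.A.shape[0]

    @property
    def q(self) -> int:
        return self.H.shape[0]

    @property
    def m(self) -> int:
        return self.G.shape[1]

    @property
    def K(self) -> int:
        return self.mu0.shape[0]

    def validate(self) -> None:
        p, q, m = self.p, self.q, self.m
        if self.A.shape != (p, p) or self.G.shape != (p, m) or self.H.shape != (q, p):
            raise ValueError("A/G/H dimensions inconsistent")
        if self.Q.shape != (p,) or self.R.shape != (q,):
            raise ValueError("Q and R must be diagonal vectors of length p and q")
        if (self.Q <= 0).any() or (self.R <= 0).any():
            raise ValueError("Q and R diagonals must be strictly positive")
        if self.mu0.ndim != 2 or self.mu0.shape[1] != p:
            raise ValueError("mu0 must be (K, p)")
        if self.Sigma0.shape != (p, p):
            raise ValueError("Sigma0 must be (p, p)")
        if not np.allclose(self.Sigma0, self.Sigma0.T, atol=1e-10):
            raise ValueError("Sigma0 must be symmetric")
        if np.linalg.eigvalsh((self.Sigma0 + self.Sigma0.T) / 2).min() < -1e-10:
            raise ValueError("Sigma0 must be positive semi-definite")
        if (np.abs(np.diag(self.A)) >= A_DIAG_BOUND).any():
            raise ValueError(f"|diag(A)| must be < {A_DIAG_BOUND}")

    def nonzero_count(self) -> int:
        return int((self.A != 0).sum() + (self.G != 0).sum() + (self.H != 0).sum())

    def to_json(self, path) -> None:
        doc = {
            "p": self.p,
            "q": self.q,
            "m": self.m,
            "A": self.A.tolist(),
            "G": self.G.tolist(),
            "H": self.H.tolist(),
            "Q": self.Q.tolist(),
            "R": self.R.tolist(),
            "mu0": self.mu0.tolist(),
            "Sigma0": self.Sigma0.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path) -> "SSMParameters":
        with open(path) as fh:
            d = json.load(fh)
        par = cls(
            A=np.asarray(d["A"], dtype=float),
            G=np.asarray(d["G"], dtype=float),
            H=np.asarray(d["H"], dtype=float),
            Q=np.asarray(d["Q"], dtype=float),
            R=np.asarray(d["R"], dtype=float),
            mu0=np.asarray(d["mu0"], dtype=float),
            Sigma0=np.asarray(d["Sigma0"], dtype=float),
        )
        par.validate()
        return par


@dataclass
class StatePosterior:
    """Latent-state posteriors for one participant (1-based t = 1..T_k).

    ``m_smooth``/``P_smooth`` have a leading t = 0 entry for the initial
    state; ``C_cross[t-1]`` is Cov(x_t, x_{t-1} | Y).  ``loglik_t`` holds the
    predictive log-density increment at observed visits and NaN elsewhere.
    """

    m_pred: np.ndarray
    P_pred: np.ndarray
    m_filt: np.ndarray
    P_filt: np.ndarray
    loglik_t: np.ndarray
    m_smooth: np.ndarray | None = None
    P_smooth: np.ndarray | None = None
    C_cross: np.ndarray | None = None

    @property
    def loglik(self) -> float:
        return float(np.nansum(self.loglik_t))


def _sym(P: np.ndarray) -> np.ndarray:
    return (P + np.swapaxes(P, -1, -2)) / 2.0


class FilterResult:
    """Batched filter output over a :class:`StackedCohort` (internal)."""

    __slots__ = ("m_pred", "P_pred", "m_filt", "P_filt", "loglik_kt")

    def __init__(self, m_pred, P_pred, m_filt, P_filt, loglik_kt):
        self.m_pred = m_pred
        self.P_pred = P_pred
        self.m_filt = m_filt
        self.P_filt = P_filt
        self.loglik_kt = loglik_kt

    def loglik_per_participant(self) -> np.ndarray:
        return np.nansum(self.loglik_kt, axis=1)

    @property
    def loglik(self) -> float:
        return float(np.nansum(self.loglik_kt))


def filter_cohort(params: SSMParameters, stacked: StackedCohort) -> FilterResult:
    """Batched Kalman filter over all participants (t = 1..T padded)."""
    K, T, q = stacked.K, stacked.T, stacked.q
    p = params.p
    A, G, H = params.A, params.G, params.H
    Qd, Rd = params.Q, params.R
    y = np.where(stacked.mask, stacked.y, 0.0)
    mask = stacked.mask

    m_pred = np.empty((K, T, p))
    P_pred = np.empty((K, T, p, p))
    m_filt = np.empty((K, T, p))
    P_filt = np.empty((K, T, p, p))
    loglik_kt = np.full((K, T), np.nan)

    m_prev = params.mu0.copy()
    P_prev = np.broadcast_to(params.Sigma0, (K, p, p)).copy()
    eye_p = np.eye(p)
    diag_idx = np.arange(p)
    groups = stacked.mask_groups()

    for s in range(T):
        # predict into visit t = s + 1
        mp = m_prev @ A.T + stacked.z_drive[:, s] @ G.T
        Pp = _sym(A @ P_prev @ A.T)
        Pp[:, diag_idx, diag_idx] += Qd
        m_pred[:, s] = mp
        P_pred[:, s] = Pp

        mf = mp.copy()
        Pf = Pp.copy()
        for obs, kk in groups[s]:
            Ho = H[obs]  # (qo, p)
            Ro = Rd[obs]
            qo = obs.size
            Pg = Pp[kk]
            PHt = Pg @ Ho.T  # (n, p, qo)
            S = _sym(Ho @ PHt)
            S[:, np.arange(qo), np.arange(qo)] += Ro
            try:
                L = np.linalg.cholesky(S)
            except np.linalg.LinAlgError as err:
                raise np.linalg.LinAlgError(
                    f"innovation covariance not PD at visit t={s + 1}"
                ) from err
            innov = y[kk, s][:, obs] - mp[kk] @ Ho.T  # (n, qo)
            sol = np.linalg.solve(S, innov[:, :, None])  # (n, qo, 1)
            Kg = np.swapaxes(np.linalg.solve(S, np.swapaxes(PHt, 1, 2)), 1, 2)
            mf[kk] = mp[kk] + (Kg @ innov[:, :, None])[:, :, 0]
            IKH = eye_p - Kg @ Ho  # (n, p, p)
            Pf_g = IKH @ Pg @ np.swapaxes(IKH, 1, 2)
            Pf_g += (Kg * Ro) @ np.swapaxes(Kg, 1, 2)
            Pf[kk] = _sym(Pf_g)
            logdet = 2.0 * np.log(np.abs(L[:, np.arange(qo), np.arange(qo)])).sum(axis=1)
            quad = (innov[:, None, :] @ sol)[:, 0, 0]
            loglik_kt[kk, s] = -0.5 * (qo * _LOG2PI + logdet + quad)
        m_filt[:, s] = mf
        P_filt[:, s] = Pf
        m_prev, P_prev = mf, Pf

    return FilterResult(m_pred, P_pred, m_filt, P_filt, loglik_kt)


class SmootherResult:
    """Batched RTS smoother output (t = 0..T for means/covs; internal)."""

    __slots__ = ("m_smooth", "P_smooth", "C_cross")

    def __init__(self, m_smooth, P_smooth, C_cross):
        self.m_smooth = m_smooth
        self.P_smooth = P_smooth
        self.C_cross = C_cross


def smooth_cohort(
    params: SSMParameters, stacked: StackedCohort, filt: FilterResult | None = None
) -> SmootherResult:
    """Fixed-interval smoother with lag-one cross-covariances.

    Uses the identity Cov(x_t, x_{t-1} | Y) = P_{t|T} J_{t-1}' with
    J_{t-1} = P_{t-1|t-1} A' P_{t|t-1}^{-1}.  Index 0 of the outputs is the
    pre-observation state x_{k,0}.
    """
    if filt is None:
        filt = filter_cohort(params, stacked)
    K, T = stacked.K, stacked.T
    p = params.p
    A = params.A

    m_all_f = np.concatenate([params.mu0[:, None, :], filt.m_filt], axis=1)  # (K,T+1,p)
    P_all_f = np.concatenate(
        [np.broadcast_to(params.Sigma0, (K, p, p))[:, None], filt.P_filt], axis=1
    )

    m_sm = np.empty((K, T + 1, p))
    P_sm = np.empty((K, T + 1, p, p))
    C_cr = np.empty((K, T, p, p))
    m_sm[:, T] = m_all_f[:, T]
    P_sm[:, T] = P_all_f[:, T]

    for t in range(T, 0, -1):  # smooth state t-1 using t
        Pf = P_all_f[:, t - 1]
        Pp = filt.P_pred[:, t - 1]  # P_{t|t-1}
        # J = Pf A' Pp^{-1}  ->  J' = Pp^{-1} A Pf
        Jt = np.linalg.solve(Pp, A @ Pf)  # (K, p, p) = J'
        J = np.swapaxes(Jt, 1, 2)
        diff_m = m_sm[:, t] - filt.m_pred[:, t - 1]
        m_sm[:, t - 1] = m_all_f[:, t - 1] + (J @ diff_m[:, :, None])[:, :, 0]
        diff_P = P_sm[:, t] - Pp
        P_sm[:, t - 1] = _sym(Pf + J @ diff_P @ Jt)
        C_cr[:, t - 1] = P_sm[:, t] @ Jt  # Cov(x_t, x_{t-1} | Y)

    return SmootherResult(m_sm, P_sm, C_cr)


# ---------------------------------------------------------------------------
# Per-participant spec API


def _single_stack(params: SSMParameters, series: ParticipantSeries, k: int) -> tuple:
    ds = CohortDataset([series], [f"y{i}" for i in range(series.y.shape[1])],
                       [f"z{j}" for j in range(series.z.shape[1])])
    stacked = ds.to_stacked()
    single = SSMParameters(
        A=params.A, G=params.G, H=params.H, Q=params.Q, R=params.R,
        mu0=params.mu0[k : k + 1], Sigma0=params.Sigma0,
    )
    return single, stacked


def kalman_filter(params: SSMParameters, series: ParticipantSeries, k: int = 0) -> StatePosterior:
    """Filter one participant; ``k`` picks the row of ``params.mu0``."""
    single, stacked = _single_stack(params, series, k)
    f = filter_cohort(single, stacked)
    return StatePosterior(
        m_pred=f.m_pred[0], P_pred=f.P_pred[0],
        m_filt=f.m_filt[0], P_filt=f.P_filt[0],
        loglik_t=f.loglik_kt[0],
    )


def kalman_smoother(params: SSMParameters, series: ParticipantSeries, k: int = 0) -> StatePosterior:
    """Filter + RTS smoother for one participant (complete posterior)."""
    single, stacked = _single_stack(params, series, k)
    f = filter_cohort(single, stacked)
    s = smooth_cohort(single, stacked, f)
    return StatePosterior(
        m_pred=f.m_pred[0], P_pred=f.P_pred[0],
        m_filt=f.m_filt[0], P_filt=f.P_filt[0],
        loglik_t=f.loglik_kt[0],
        m_smooth=s.m_smooth[0], P_smooth=s.P_smooth[0], C_cross=s.C_cross[0],
    )


def log_likelihood(params: SSMParameters, ds: CohortDataset | StackedCohort) -> float:
    """Marginal log-likelihood of all observed visits under the model."""
    stacked = ds if isinstance(ds, StackedCohort) else ds.to_stacked()
    return filter_cohort(params, stacked).loglik
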