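"""Ground-truth models and synthetic check-up cohorts.

Generates sparse state-space parameters with a block observation structure
(each latent factor drives one cluster of traits, the way lipid-panel or
red-cell items move together), simulates annual-grid cohorts with irregular
attendance and slow-moving covariates, and optionally plants SNP effects on
observation residuals so the association machinery can be exercised without
any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import CohortDataset, ParticipantSeries
from .genetics import GenotypeTable, encode_genotype
from .kalman import A_DIAG_BOUND, SSMParameters

__all__ = [
    "TruthConfig",
    "SNPPlantConfig",
    "generate_truth",
    "simulate_cohort",
    "inject_genetic_effects",
]


@dataclass
class TruthConfig:
    """Study conditions for the generator.

    Defaults mirror a small but realistic check-up panel: three latent
    processes each driving a three-trait cluster, five environmental
    factors (one binary), annual visits over eight years with 80%
    attendance in between the forced first and last visits.
    """

    p: int = 3
    q: int = 9
    m: int = 5
    K: int = 150
    T_max: int = 8
    a_diag_range: tuple = (0.3, 0.7)
    a_offdiag_density: float = 0.15
    a_offdiag_scale: float = 0.15
    h_loading_range: tuple = (0.7, 1.3)
    h_cross_density: float = 0.0
    g_density: float = 0.25
    g_effect_range: tuple = (0.5, 1.0)
    attendance: float = 0.8
    y_missing: float = 0.0
    q_scale: float = 0.1
    r_scale: float = 0.1
    z_ar: float = 0.9
    n_binary: int = 1
    spectral_cap: float = 0.95
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.attendance <= 1 and 0 <= self.y_missing <= 1):
            raise ValueError("probabilities must be in [0, 1]")
        if self.p > self.q:
            raise ValueError("latent dimension p must not exceed trait count q")
        for frac in (self.a_offdiag_density, self.h_cross_density, self.g_density):
            if not 0 <= frac <= 1:
                raise ValueError("density fractions must be in [0, 1]")


def _signed_uniform(rng, lo, hi, size):
    mag = rng.uniform(lo, hi, size)
    return mag * rng.choice([-1.0, 1.0], size=size)


def generate_truth(cfg: TruthConfig) -> SSMParameters:
    """Draw sparse ground-truth parameters, deterministic given the seed.

    A has diagonals inside (±0.8) and sparse off-diagonal couplings,
    rejection-sampled until the spectral radius is below ``spectral_cap``;
    H assigns each latent factor a contiguous block of traits with loadings
    in ``h_loading_range`` (plus optional cross-loadings); G is sparse with
    planted effects of at least 0.5 on the standardized scale.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    p, q, m = cfg.p, cfg.q, cfg.m

    A = None
    for _ in range(1000):
        cand = np.zeros((p, p))
        np.fill_diagonal(cand, rng.uniform(*cfg.a_diag_range, p))
        off = (rng.random((p, p)) < cfg.a_offdiag_density) & ~np.eye(p, dtype=bool)
        cand[off] = _signed_uniform(rng, 0.5 * cfg.a_offdiag_scale, cfg.a_offdiag_scale,
                                    int(off.sum()))
        np.fill_diagonal(
            cand, np.clip(np.diag(cand), -(A_DIAG_BOUND - 1e-6), A_DIAG_BOUND - 1e-6)
        )
        if np.max(np.abs(np.linalg.eigvals(cand))) < cfg.spectral_cap:
            A = cand
            break
    if A is None:
        raise RuntimeError(
            "rejection sampling of A failed; lower a_offdiag_scale or spectral_cap"
        )

    # block observation map: trait cluster j loads on latent factor j
    H = np.zeros((q, p))
    bounds = np.linspace(0, q, p + 1).astype(int)
    for j in range(p):
        rows = np.arange(bounds[j], bounds[j + 1])
        H[rows, j] = rng.uniform(*cfg.h_loading_range, rows.size)
    if cfg.h_cross_density > 0:
        cross = (rng.random((q, p)) < cfg.h_cross_density) & (H == 0)
        H[cross] = _signed_uniform(rng, 0.2, 0.5, int(cross.sum()))

    G = np.zeros((p, m))
    nz = rng.random((p, m)) < cfg.g_density
    G[nz] = _signed_uniform(rng, *cfg.g_effect_range, int(nz.sum()))

    params = SSMParameters(
        A=A,
        G=G,
        H=H,
        Q=np.full(p, cfg.q_scale),
        R=np.full(q, cfg.r_scale),
        mu0=rng.standard_normal((cfg.K, p)),
        Sigma0=np.eye(p),
    )
    params.validate()
    return params


def _simulate_z(rng, cfg: TruthConfig) -> np.ndarray:
    """Slow AR(1) covariates (stationary unit variance) plus sticky
    Bernoulli binaries occupying the last ``n_binary`` columns."""
    K, T, m = cfg.K, cfg.T_max, cfg.m
    n_bin = min(cfg.n_binary, m)
    n_cont = m - n_bin
    z = np.empty((K, T, m))
    innov_sd = np.sqrt(1.0 - cfg.z_ar**2)
    z[:, 0, :n_cont] = rng.standard_normal((K, n_cont))
    for t in range(1, T):
        z[:, t, :n_cont] = cfg.z_ar * z[:, t - 1, :n_cont] + innov_sd * rng.standard_normal(
            (K, n_cont)
        )
    if n_bin:
        state = (rng.random((K, n_bin)) < 0.3).astype(float)
        z[:, 0, n_cont:] = state
        for t in range(1, T):
            flip = rng.random((K, n_bin)) < 0.05
            state = np.where(flip, 1.0 - state, state)
            z[:, t, n_cont:] = state
    return z


def simulate_cohort(params: SSMParameters, cfg: TruthConfig, seed: int | None = None):
    """Simulate a cohort from the generative equations.

    Returns ``(CohortDataset, truth)`` where ``truth`` records the latent
    paths, full noise-free observations and masks so oracle tests never
    re-derive them.  The transition into visit 1 is driven by the visit-1
    covariate (the same backfill convention the filter uses), visits between
    the forced first and last are thinned by the attendance probability, and
    element-wise dropout is applied on top.
    """
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    p, q, m, K, T = params.p, params.q, params.m, cfg.K, cfg.T_max
    z = _simulate_z(rng, cfg)

    x = np.empty((K, T + 1, p))
    x[:, 0] = params.mu0 + rng.standard_normal((K, p)) @ np.linalg.cholesky(
        params.Sigma0 + 1e-12 * np.eye(p)
    ).T
    sd_q = np.sqrt(params.Q)
    sd_r = np.sqrt(params.R)
    for t in range(1, T + 1):
        drive = z[:, t - 2] if t >= 2 else z[:, 0]
        x[:, t] = (
            x[:, t - 1] @ params.A.T
            + drive @ params.G.T
            + rng.standard_normal((K, p)) * sd_q
        )
    y_clean = np.einsum("ktp,qp->ktq", x[:, 1:], params.H, optimize=True)
    y = y_clean + rng.standard_normal((K, T, q)) * sd_r

    attended = rng.random((K, T)) < cfg.attendance
    attended[:, 0] = True
    attended[:, T - 1] = True
    cell_kept = rng.random((K, T, q)) >= cfg.y_missing

    participants = []
    for k in range(K):
        yk = np.where(attended[k][:, None] & cell_kept[k], y[k], np.nan)
        # guarantee the forced visits carry at least one observed trait
        for t in (0, T - 1):
            if not np.isfinite(yk[t]).any():
                yk[t, 0] = y[k, t, 0]
        zk = np.where(attended[k][:, None], z[k], np.nan)
        participants.append(
            ParticipantSeries(
                pid=f"P{k:04d}",
                first_year=2007,
                T_k=T,
                obs_times=frozenset(int(t + 1) for t in np.flatnonzero(attended[k])),
                y=yk,
                z=zk,
                age_at_first=float(rng.uniform(55, 75)),
                sex="M" if k % 2 == 0 else "F",
            )
        )
    ds = CohortDataset(
        participants,
        [f"trait_{i + 1}" for i in range(q)],
        [f"factor_{j + 1}" for j in range(m)],
        ["continuous"] * (m - min(cfg.n_binary, m)) + ["binary"] * min(cfg.n_binary, m),
    )
    ds.validate()
    truth = {
        "x": x,
        "z": z,
        "y_clean": y_clean,
        "y_full": y,
        "attended": attended,
        "params": params,
    }
    return ds, truth


@dataclass
class SNPPlantConfig:
    """Genotypes under Hardy–Weinberg with optional planted causal effects
    on observation residuals: snp index -> (trait index, effect size on the
    standardized residual, MAF, inheritance model)."""

    n_snps: int = 100
    mafs: np.ndarray | float = 0.3
    causal: dict = field(default_factory=dict)
    seed: int = 0

    def maf_array(self) -> np.ndarray:
        mafs = np.broadcast_to(np.asarray(self.mafs, dtype=float), (self.n_snps,))
        if ((mafs <= 0) | (mafs > 0.5)).any():
            raise ValueError("MAF must lie in (0, 0.5]")
        return mafs


def inject_genetic_effects(ds: CohortDataset, cfg: SNPPlantConfig):
    """Draw genotypes binomial(2, MAF) per SNP and add coded-dose × effect
    to each causal SNP's trait at every observed visit.

    Returns the modified cohort and the :class:`GenotypeTable`; non-causal
    SNPs are independent of every trait.
    """
    rng = np.random.default_rng(cfg.seed)
    mafs = cfg.maf_array()
    K = ds.K
    genotypes = rng.binomial(2, mafs[:, None], size=(cfg.n_snps, K)).astype(float)
    table = GenotypeTable(
        snp_ids=[f"rs{i + 1:06d}" for i in range(cfg.n_snps)],
        participants=ds.pids,
        genotypes=genotypes,
    )
    new_participants = []
    for k, s in enumerate(ds.participants):
        y = s.y.copy()
        for snp_idx, (trait_idx, effect, _maf, model) in cfg.causal.items():
            dose = encode_genotype(genotypes[snp_idx, k], model)
            y[:, trait_idx] += effect * dose
        new_participants.append(
            ParticipantSeries(
                pid=s.pid, first_year=s.first_year, T_k=s.T_k,
                obs_times=s.obs_times, y=y, z=s.z.copy(),
                age_at_first=s.age_at_first, sex=s.sex, medication=s.medication,
            )
        )
    out = CohortDataset(new_participants, list(ds.blood_names), list(ds.env_names),
                        list(ds.env_kinds))
    return out, table
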