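"""Shared fixtures and independent oracles.

The oracles here never call the package's recursive filter/smoother: they
build the exact joint Gaussian distribution of (states, observed cells) by
explicit linear-map construction, so filtering, smoothing and likelihood
values can be checked against direct dense conditioning.
"""

import numpy as np
import pytest

from ehrssm import (
    CohortDataset,
    ParticipantSeries,
    SSMParameters,
    TruthConfig,
    generate_truth,
    simulate_cohort,
    standardize,
)


# ---------------------------------------------------------------------------
# Dense joint-Gaussian oracle


def joint_gaussian_moments(params, series, z_drive, k=0):
    """Mean/linear-map representation of (x_0..x_T, observed y cells).

    Returns ``(X_mean, X_map, obs_vals, obs_mu, Y_map, R_diag, rows)`` where
    every x_t and observed y cell is an affine function of the standard
    normal noise vector [e_0, v_1..v_T] plus independent observation noise.
    """
    p, q = params.p, params.q
    T = series.T_k
    A, G, H = params.A, params.G, params.H
    n_noise = p * (T + 1)
    means = [params.mu0[k].copy()]
    maps = [np.zeros((p, n_noise))]
    maps[0][:, :p] = np.linalg.cholesky(params.Sigma0 + 1e-15 * np.eye(p))
    for t in range(1, T + 1):
        means.append(A @ means[t - 1] + G @ z_drive[t - 1])
        M = (A @ maps[t - 1]).copy()
        M[:, p * t : p * (t + 1)] += np.diag(np.sqrt(params.Q))
        maps.append(M)
    rows, obs_vals, obs_mu = [], [], []
    for t in range(1, T + 1):
        for j in range(q):
            if np.isfinite(series.y[t - 1, j]):
                rows.append((t, j))
                obs_vals.append(series.y[t - 1, j])
                obs_mu.append(H[j] @ means[t])
    X_mean = np.concatenate(means)
    X_map = np.vstack(maps)
    Y_map = (
        np.array([H[j] @ maps[t] for (t, j) in rows])
        if rows
        else np.zeros((0, n_noise))
    )
    R_diag = np.array([params.R[j] for (_, j) in rows])
    return X_mean, X_map, np.array(obs_vals), np.array(obs_mu), Y_map, R_diag, rows


def oracle_loglik(params, series, z_drive, k=0):
    """Log-density of the observed cells under the dense joint Gaussian."""
    _, _, obs, mu, Y_map, R_diag, _ = joint_gaussian_moments(params, series, z_drive, k)
    if obs.size == 0:
        return 0.0
    cov = Y_map @ Y_map.T + np.diag(R_diag)
    resid = obs - mu
    _, logdet = np.linalg.slogdet(cov)
    return float(
        -0.5 * (obs.size * np.log(2 * np.pi) + logdet + resid @ np.linalg.solve(cov, resid))
    )


def oracle_posterior(params, series, z_drive, k=0):
    """Conditional mean/cov of (x_0..x_T) given the observed cells."""
    X_mean, X_map, obs, mu, Y_map, R_diag, _ = joint_gaussian_moments(
        params, series, z_drive, k
    )
    S_xx = X_map @ X_map.T
    if obs.size == 0:
        return X_mean, S_xx
    S_xy = X_map @ Y_map.T
    S_yy = Y_map @ Y_map.T + np.diag(R_diag)
    resid = obs - mu
    cond_mean = X_mean + S_xy @ np.linalg.solve(S_yy, resid)
    cond_cov = S_xx - S_xy @ np.linalg.solve(S_yy, S_xy.T)
    return cond_mean, cond_cov


def random_instance(rng, K=1, allow_missing=True, T_max=5, p_max=3, q_max=4):
    """A random small model + cohort with arbitrary missing patterns."""
    p = int(rng.integers(1, p_max + 1))
    q = int(rng.integers(1, q_max + 1))
    m = int(rng.integers(1, 3))
    T = int(rng.integers(1, T_max + 1))
    A = rng.normal(0, 0.3, (p, p))
    np.fill_diagonal(A, rng.uniform(-0.7, 0.7, p))
    params = SSMParameters(
        A=A,
        G=rng.normal(0, 0.5, (p, m)),
        H=rng.normal(0, 1.0, (q, p)),
        Q=rng.uniform(0.2, 1.0, p),
        R=rng.uniform(0.2, 1.0, q),
        mu0=rng.normal(0, 1.0, (K, p)),
        Sigma0=np.eye(p) * rng.uniform(0.5, 2.0),
    )
    participants = []
    for k in range(K):
        y = rng.normal(0, 1, (T, q))
        if allow_missing:
            y[rng.random((T, q)) < 0.3] = np.nan
        if not np.isfinite(y[0]).any():
            y[0, 0] = rng.normal()
        if not np.isfinite(y[T - 1]).any():
            y[T - 1, 0] = rng.normal()
        z = rng.normal(0, 1, (T, m))
        obs_times = frozenset(
            int(t + 1) for t in range(T) if np.isfinite(y[t]).any()
        )
        participants.append(
            ParticipantSeries(f"P{k}", 2007, T, obs_times, y, z)
        )
    ds = CohortDataset(
        participants,
        [f"y{i}" for i in range(q)],
        [f"z{j}" for j in range(m)],
    )
    ds.validate()
    return params, ds


# ---------------------------------------------------------------------------
# Fixtures


@pytest.fixture(scope="session")
def small_synthetic():
    """One modest synthetic cohort with its ground truth, standardized."""
    cfg = TruthConfig(seed=11, K=80, T_max=8)
    truth_params = generate_truth(cfg)
    ds_raw, truth = simulate_cohort(truth_params, cfg, seed=12)
    ds, norm = standardize(ds_raw)
    return {
        "cfg": cfg,
        "truth_params": truth_params,
        "truth": truth,
        "raw": ds_raw,
        "cohort": ds,
        "norm": norm,
    }
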