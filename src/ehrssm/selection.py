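"""BIC scoring and multi-restart search over the latent dimension.

BIC = −2 log L(Y | θ) + df(θ) log ν, where L is the *unpenalized* marginal
likelihood, df counts the non-zero parameters and ν the observed
participant-visits.  Because EM only finds local maxima, each candidate
dimension is fitted from several randomly perturbed initializations and the
best (lowest-BIC) fit per dimension is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import CohortDataset, StackedCohort
from .em import EMMonotonicityError, FitResult, InitSpec, PenaltyConfig, fit_em
from .kalman import log_likelihood

__all__ = ["bic", "search", "SearchResult", "RestartRecord"]


def bic(fit: FitResult, ds: CohortDataset | StackedCohort) -> float:
    """BIC of a fitted model on a cohort (lower is better)."""
    if isinstance(ds, StackedCohort):
        nu = int(ds.mask.any(axis=2).sum())
    else:
        nu = ds.n_observed_visits
    if nu == 0:
        raise ValueError("no observed visits: BIC undefined")
    llf = log_likelihood(fit.params, ds)
    return float(-2.0 * llf + fit.df * np.log(nu))


@dataclass
class RestartRecord:
    p: int
    restart: int
    seed: int
    bic: float
    objective: float
    df: int
    n_iter: int
    converged: bool
    failure: str | None = None


@dataclass
class SearchResult:
    records: list
    best_per_p: dict
    selected_p: int
    best_fit: FitResult

    def bic_table(self):
        """Lowest BIC per candidate dimension, as (p, bic) rows."""
        return sorted(self.best_per_p.items())


def _restart_seed(master_seed: int, p: int, restart: int) -> int:
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(p, restart))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def search(
    ds: CohortDataset | StackedCohort,
    p_grid,
    n_restarts: int = 50,
    penalty: PenaltyConfig | None = None,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-6,
    perturb: float = 0.1,
) -> SearchResult:
    """Fit every latent dimension in ``p_grid`` from ``n_restarts`` seeded
    initializations and select the dimension with the lowest BIC.

    Deterministic given ``seed`` (restart seeds are derived by counter).
    Numerically failed restarts are recorded with a reason and excluded from
    the minimum; ties break on (BIC, restart seed) lexicographic order.
    """
    p_grid = list(p_grid)
    if not p_grid:
        raise ValueError("p_grid must be non-empty")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    stacked = ds if isinstance(ds, StackedCohort) else ds.to_stacked()

    records = []
    best_per_p: dict = {}
    best_key = None
    best_fit = None
    selected_p = None
    for p in p_grid:
        for r in range(n_restarts):
            rseed = _restart_seed(seed, p, r)
            init = InitSpec(perturb=perturb if r > 0 else 0.0, seed=rseed)
            try:
                fit = fit_em(stacked, p, penalty=penalty, init=init,
                             max_iter=max_iter, tol=tol)
                score = bic(fit, stacked)
            except (np.linalg.LinAlgError, EMMonotonicityError, RuntimeError) as err:
                records.append(RestartRecord(p, r, rseed, np.nan, np.nan, 0, 0,
                                             False, failure=str(err)))
                continue
            records.append(
                RestartRecord(p, r, rseed, score, fit.objective, fit.df,
                              fit.n_iter, fit.converged)
            )
            if p not in best_per_p or score < best_per_p[p]:
                best_per_p[p] = score
            key = (score, rseed)
            if best_key is None or key < best_key:
                best_key, best_fit, selected_p = key, fit, p
    if best_fit is None:
        raise RuntimeError("every restart failed for every candidate dimension")
    return SearchResult(records=records, best_per_p=best_per_p,
                        selected_p=selected_p, best_fit=best_fit)
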