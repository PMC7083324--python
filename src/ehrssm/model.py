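"""Model/Results front end for the sparse state-space model.

``SparseSSM`` binds a standardized cohort to a latent dimension and penalty
configuration; ``fit()`` runs the L1-regularized EM and returns a
``SparseSSMResults`` carrying the estimates, the objective trace, BIC, and
scenario/prediction utilities.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .cohort import CohortDataset, NormalizationState, load_cohort
from .em import FitResult, InitSpec, PenaltyConfig, fit_em
from .kalman import SSMParameters, log_likelihood
from .scenario import (
    ScenarioSpec,
    Trajectory,
    build_scenario,
    predict_trajectory,
    prediction_errors,
    spectral_radius,
)
from .selection import bic as _bic

__all__ = ["SparseSSM", "SparseSSMResults"]


class SparseSSM:
    """Sparse linear Gaussian state-space model for a check-up cohort.

    Parameters
    ----------
    cohort : CohortDataset
        Standardized cohort (pooled mean 0, variance 1 per column).
    p : int
        Latent dimension.
    penalty : PenaltyConfig, optional
        L1 penalties for the system rows ([A | G]) and observation rows (H).
    norm : NormalizationState, optional
        Kept so predictions can be reported in raw units.
    """

    def __init__(self, cohort: CohortDataset, p: int,
                 penalty: PenaltyConfig | None = None,
                 norm: NormalizationState | None = None):
        cohort.validate()
        self.cohort = cohort
        self.p = int(p)
        self.penalty = penalty or PenaltyConfig()
        self.norm = norm
        self._stacked = cohort.to_stacked()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, schema: dict, p: int,
                       penalty: PenaltyConfig | None = None,
                       standardize_data: bool = True) -> "SparseSSM":
        """Build from a long-format visit table (see ``cohort.load_cohort``)."""
        from .cohort import standardize

        ds = load_cohort(df, schema)
        norm = None
        if standardize_data:
            ds, norm = standardize(ds)
        return cls(ds, p, penalty=penalty, norm=norm)

    def fit(self, init: InitSpec | SSMParameters | None = None, seed: int | None = None,
            max_iter: int = 200, tol: float = 1e-6) -> "SparseSSMResults":
        if init is None and seed is not None:
            init = InitSpec(seed=seed)
        result = fit_em(self._stacked, self.p, penalty=self.penalty, init=init,
                        max_iter=max_iter, tol=tol)
        return SparseSSMResults(self, result)


class SparseSSMResults:
    """Estimation results: parameter estimates, fit diagnostics, BIC, and
    simulation entry points."""

    def __init__(self, model: SparseSSM, fit: FitResult):
        self.model = model
        self.fit_result = fit

    # -- estimates -----------------------------------------------------
    @property
    def params(self) -> SSMParameters:
        return self.fit_result.params

    @property
    def trace(self) -> list:
        return self.fit_result.trace

    @property
    def converged(self) -> bool:
        return self.fit_result.converged

    @property
    def df(self) -> int:
        return self.fit_result.df

    @property
    def llf(self) -> float:
        """Unpenalized marginal log-likelihood at the estimates."""
        return log_likelihood(self.params, self.model._stacked)

    @property
    def bic(self) -> float:
        return _bic(self.fit_result, self.model._stacked)

    # -- simulation ----------------------------------------------------
    def predict_trajectory(self, pid: str, scenario: ScenarioSpec | None = None,
                           raw_units: bool = True) -> Trajectory:
        """Mean-propagated trajectory for one participant, optionally under
        a counterfactual scenario (no data assimilation)."""
        ds = self.model.cohort
        series = ds.participant(pid)
        k = ds.index_of(pid)
        spec = scenario or ScenarioSpec(label="actual")
        if scenario is not None and self.model.norm is None:
            raise ValueError("scenario overrides need the NormalizationState")
        if self.model.norm is not None:
            z = build_scenario(series, spec, self.model.norm, ds.env_names)
        else:
            from .cohort import _ffill_bfill

            z = _ffill_bfill(series.z)
        rho = spectral_radius(self.params.A)
        if rho >= 1.0:
            import warnings

            warnings.warn(f"spectral radius of A is {rho:.3f} >= 1; "
                          "propagated trajectories may diverge")
        return predict_trajectory(
            self.params, series, z, k=k,
            norm=self.model.norm if raw_units else None, label=spec.label,
        )

    def prediction_errors(self) -> pd.DataFrame:
        """Observed − predicted (standardized scale) at observed cells."""
        return prediction_errors(self.params, self.model.cohort)

    # -- reporting -----------------------------------------------------
    def summary(self) -> str:
        par = self.params
        ds = self.model.cohort
        nz = lambda M: int((M != 0).sum())
        lines = [
            "Sparse linear state-space model (L1-regularized EM)",
            "=" * 55,
            f"participants:        {ds.K}",
            f"observed visits:     {ds.n_observed_visits}",
            f"traits (q):          {par.q}",
            f"factors (m):         {par.m}",
            f"latent dim (p):      {par.p}",
            f"lambda (sys, obs):   {self.fit_result.penalty.lambda_sys}, "
            f"{self.fit_result.penalty.lambda_obs}",
            "-" * 55,
            f"EM iterations:       {self.fit_result.n_iter} "
            f"({'converged' if self.converged else 'not converged'})",
            f"penalized objective: {self.fit_result.objective:.4f}",
            f"log-likelihood:      {self.llf:.4f}",
            f"df (non-zero):       {self.df}",
            f"BIC:                 {self.bic:.4f}",
            "-" * 55,
            f"non-zeros  A: {nz(par.A)}/{par.A.size}   G: {nz(par.G)}/{par.G.size}"
            f"   H: {nz(par.H)}/{par.H.size}",
            f"spectral radius(A):  {spectral_radius(par.A):.4f}",
        ]
        return "\n".join(lines)

    def save(self, path) -> None:
        doc = {
            "trace": [float(v) for v in self.trace],
            "n_iter": self.fit_result.n_iter,
            "converged": self.converged,
            "df": self.df,
            "bic": self.bic,
            "llf": self.llf,
            "init": self.fit_result.init_descriptor,
            "params": {
                "A": self.params.A.tolist(),
                "G": self.params.G.tolist(),
                "H": self.params.H.tolist(),
                "Q": self.params.Q.tolist(),
                "R": self.params.R.tolist(),
                "mu0": self.params.mu0.tolist(),
                "Sigma0": self.params.Sigma0.tolist(),
            },
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @staticmethod
    def load_params(path) -> SSMParameters:
        with open(path) as fh:
            doc = json.load(fh)
        d = doc["params"]
        return SSMParameters(
            A=np.asarray(d["A"], float), G=np.asarray(d["G"], float),
            H=np.asarray(d["H"], float), Q=np.asarray(d["Q"], float),
            R=np.asarray(d["R"], float), mu0=np.asarray(d["mu0"], float),
            Sigma0=np.asarray(d["Sigma0"], float),
        )
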