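"""Counterfactual scenario simulation and prediction errors.

Predictions are pure mean propagation "without filtering steps": starting
from the fitted initial mean μ_{k,0}, the latent state is rolled forward
through x̂_t = A x̂_{t-1} + G z_{t-1} and mapped to ŷ_t = H x̂_t, with no
data assimilation.  A scenario overrides selected environmental factors
(in raw units, standardized through the cohort's NormalizationState) over a
time window; prediction errors are observed − predicted at observed visits
under the participant's actual covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortDataset, NormalizationState, ParticipantSeries, _ffill_bfill
from .kalman import SSMParameters

__all__ = [
    "ScenarioSpec",
    "Trajectory",
    "build_scenario",
    "predict_trajectory",
    "prediction_errors",
    "load_preset",
    "PRESET_NAMES",
]

PRESET_NAMES = (
    "male_unhealthy",
    "male_healthy",
    "female_unhealthy",
    "female_healthy",
)


@dataclass
class ScenarioSpec:
    """Overrides of environmental factors in raw units over [start, end]
    (1-based visit indices, inclusive; end=None runs to the horizon)."""

    overrides: dict = field(default_factory=dict)  # name -> (value, start, end|None)
    label: str = "scenario"
    base: str = "actual"  # or "flat-last-observed"

    @classmethod
    def from_yaml(cls, path_or_stream) -> "ScenarioSpec":
        if hasattr(path_or_stream, "read"):
            doc = yaml.safe_load(path_or_stream)
        else:
            with open(path_or_stream) as fh:
                doc = yaml.safe_load(fh)
        overrides = {
            name: (float(spec["value"]), int(spec.get("start", 1)),
                   None if spec.get("end") is None else int(spec["end"]))
            for name, spec in doc.get("overrides", {}).items()
        }
        return cls(overrides=overrides, label=doc.get("label", "scenario"),
                   base=doc.get("base", "actual"))


def load_preset(name: str) -> ScenarioSpec:
    """Load one of the shipped lifestyle presets (healthy/unhealthy by sex)."""
    if name not in PRESET_NAMES:
        raise KeyError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    ref = resources.files("ehrssm").joinpath(f"presets/{name}.yaml")
    with ref.open() as fh:
        return ScenarioSpec.from_yaml(fh)


def build_scenario(
    series: ParticipantSeries,
    spec: ScenarioSpec,
    norm: NormalizationState,
    env_names: list,
) -> np.ndarray:
    """Standardized covariate sequence (T_k, m) under a scenario.

    Actual z is carried forward over gaps (backfilled at the head); each
    overridden factor is replaced by its standardized override value over
    the window.  With ``base="flat-last-observed"`` the non-overridden
    factors are frozen at their first-visit values.
    """
    for name in spec.overrides:
        if name not in env_names:
            raise KeyError(f"unknown environmental factor {name!r}")
    z = _ffill_bfill(series.z)
    if spec.base == "flat-last-observed":
        z = np.tile(z[0], (z.shape[0], 1))
    for name, (value, start, end) in spec.overrides.items():
        j = env_names.index(name)
        std_value = norm.standardize_env_value(name, value)
        end_t = series.T_k if end is None else min(end, series.T_k)
        z[start - 1 : end_t, j] = std_value
    return z


@dataclass
class Trajectory:
    """Mean-propagated prediction for one participant.

    ``y_hat_std`` is on the standardized scale, ``y_hat`` de-standardized to
    raw units when a NormalizationState is supplied.  ``observed`` flags the
    cells actually measured (for overlay against the prediction).
    """

    t: np.ndarray            # 1-based visit indices 1..T_k
    x_hat: np.ndarray        # (T_k+1, p), index 0 = μ_{k,0}
    y_hat_std: np.ndarray    # (T_k, q)
    y_hat: np.ndarray        # (T_k, q) raw units (== std if no norm given)
    observed: np.ndarray     # (T_k, q) bool
    label: str = ""


def predict_trajectory(
    params: SSMParameters,
    series: ParticipantSeries,
    z_seq: np.ndarray,
    k: int | None = None,
    norm: NormalizationState | None = None,
    label: str = "",
    cold_start: bool = False,
) -> Trajectory:
    """Roll the fitted model forward under a covariate sequence.

    ``k`` indexes the participant's row of ``params.mu0``; for a
    participant outside the fit pass ``cold_start=True`` to anchor at
    x̂_0 = 0.  The drive into visit t is ``z_seq[t-2]`` for t ≥ 2 and
    ``z_seq[0]`` for the initial transition (same convention as the filter).
    """
    T = series.T_k
    p = params.p
    if cold_start:
        x0 = np.zeros(p)
    else:
        if k is None:
            if params.mu0.shape[0] != 1:
                raise ValueError(
                    "participant index k is required (or use cold_start=True "
                    "for an out-of-fit participant, anchoring at x0 = 0)"
                )
            k = 0
        x0 = params.mu0[k]
    x_hat = np.empty((T + 1, p))
    x_hat[0] = x0
    for t in range(1, T + 1):
        drive = z_seq[t - 2] if t >= 2 else z_seq[0]
        x_hat[t] = params.A @ x_hat[t - 1] + params.G @ drive
    y_std = x_hat[1:] @ params.H.T
    y_raw = norm.invert_y(y_std) if norm is not None else y_std.copy()
    return Trajectory(
        t=np.arange(1, T + 1),
        x_hat=x_hat,
        y_hat_std=y_std,
        y_hat=y_raw,
        observed=np.isfinite(series.y),
        label=label,
    )


def prediction_errors(params: SSMParameters, ds: CohortDataset) -> pd.DataFrame:
    """Observed − predicted at every observed cell, on the standardized
    scale, under each participant's actual covariates (no filtering).

    Returns a long DataFrame with columns pid, t, trait, observed,
    predicted, error.
    """
    rows = []
    for k, s in enumerate(ds.participants):
        z = _ffill_bfill(s.z)
        traj = predict_trajectory(params, s, z, k=k)
        obs_mask = np.isfinite(s.y)
        tt, jj = np.nonzero(obs_mask)
        for t_idx, j in zip(tt, jj):
            rows.append(
                (
                    s.pid,
                    int(t_idx + 1),
                    ds.blood_names[j],
                    float(s.y[t_idx, j]),
                    float(traj.y_hat_std[t_idx, j]),
                    float(s.y[t_idx, j] - traj.y_hat_std[t_idx, j]),
                )
            )
    return pd.DataFrame(rows, columns=["pid", "t", "trait", "observed", "predicted", "error"])


def spectral_radius(A: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(A))))
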