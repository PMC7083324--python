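"""Longitudinal check-up panels on an annual visit grid.

A cohort is a set of participants, each with blood-test vectors ``y`` (q
traits) and environmental-factor vectors ``z`` (m factors: body
composition, lifestyle, social status) observed at a subset of annual
visits.  Visit index ``t`` starts at 1 at each participant's first attended
check-up; a participant who attended the 2009, 2010, 2013 and 2014
check-ups has observed times {1, 2, 5, 6} and T_k = 6.  Missingness is
two-level: whole visits may be skipped, and individual panel items may be
absent within an attended visit (element-wise masks, NaN-encoded).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sstats

__all__ = [
    "ParticipantSeries",
    "CohortDataset",
    "NormalizationState",
    "ExclusionCriteria",
    "ExclusionReport",
    "StackedCohort",
    "load_cohort",
    "apply_exclusions",
    "baseline_comparison",
    "standardize",
    "spearman_matrices",
    "save_cohort",
    "read_cohort",
]


@dataclass
class ParticipantSeries:
    """One participant's visit series on the annual grid.

    ``y`` and ``z`` are dense ``(T_k, q)`` / ``(T_k, m)`` arrays with NaN
    marking missing entries; rows for skipped visits are all-NaN.
    ``obs_times`` are the 1-based attended visit indices.
    """

    pid: str
    first_year: int
    T_k: int
    obs_times: frozenset
    y: np.ndarray
    z: np.ndarray
    age_at_first: float = np.nan
    sex: str = ""
    medication: bool = False

    def validate(self, q: int, m: int) -> None:
        if self.T_k < 1:
            raise ValueError(f"participant {self.pid}: T_k must be >= 1")
        if not self.obs_times:
            raise ValueError(f"participant {self.pid}: no observed visits")
        if not self.obs_times <= set(range(1, self.T_k + 1)):
            raise ValueError(f"participant {self.pid}: obs_times outside 1..T_k")
        if 1 not in self.obs_times or self.T_k not in self.obs_times:
            raise ValueError(
                f"participant {self.pid}: first and last visits must be observed"
            )
        if self.y.shape != (self.T_k, q) or self.z.shape != (self.T_k, m):
            raise ValueError(f"participant {self.pid}: y/z shape mismatch")

    def y_at(self, t: int) -> np.ndarray:
        """Blood-test vector at 1-based visit index ``t`` (NaN = missing)."""
        return self.y[t - 1]

    def z_at(self, t: int) -> np.ndarray:
        return self.z[t - 1]


@dataclass
class CohortDataset:
    """A cohort of :class:`ParticipantSeries` sharing trait/factor panels."""

    participants: list
    blood_names: list
    env_names: list
    env_kinds: list = field(default_factory=list)  # continuous/binary/ordinal

    def __post_init__(self):
        if not self.env_kinds:
            self.env_kinds = ["continuous"] * len(self.env_names)

    @property
    def q(self) -> int:
        return len(self.blood_names)

    @property
    def m(self) -> int:
        return len(self.env_names)

    @property
    def K(self) -> int:
        return len(self.participants)

    @property
    def pids(self) -> list:
        return [s.pid for s in self.participants]

    @property
    def n_observed_visits(self) -> int:
        """Total attended visits over the cohort (the BIC sample size ν)."""
        return sum(len(s.obs_times) for s in self.participants)

    def validate(self) -> None:
        for s in self.participants:
            s.validate(self.q, self.m)

    def participant(self, pid: str) -> ParticipantSeries:
        for s in self.participants:
            if s.pid == pid:
                return s
        raise KeyError(f"unknown participant id {pid!r}")

    def index_of(self, pid: str) -> int:
        for i, s in enumerate(self.participants):
            if s.pid == pid:
                return i
        raise KeyError(f"unknown participant id {pid!r}")

    def to_stacked(self) -> "StackedCohort":
        return StackedCohort.from_cohort(self)

    def subset(self, keep: list) -> "CohortDataset":
        return CohortDataset(
            [s for s in self.participants if s.pid in set(keep)],
            list(self.blood_names),
            list(self.env_names),
            list(self.env_kinds),
        )


def _ffill_bfill(arr: np.ndarray) -> np.ndarray:
    """Carry forward the last observed row element-wise; backfill the head."""
    out = pd.DataFrame(arr).ffill().bfill().to_numpy(dtype=float)
    return np.nan_to_num(out, nan=0.0)


@dataclass
class StackedCohort:
    """Padded array view of a cohort for batched filtering.

    ``y`` is ``(K, T, q)`` with NaN at missing cells and at t > T_k; ``mask``
    its boolean observed indicator.  ``z_drive[:, s]`` is the covariate
    vector driving the transition into visit ``t = s + 1`` (i.e. z_{t-1},
    with the initial transition backfilled from the first observed z, and
    gaps carried forward).
    """

    y: np.ndarray
    mask: np.ndarray
    z_drive: np.ndarray
    T_k: np.ndarray
    pids: list
    _mask_groups: list = field(default=None, repr=False, compare=False)

    def mask_groups(self) -> list:
        """Per time step, the unique observation patterns and the
        participants sharing each: ``[(obs_cols, participant_idx), ...]``.
        Cached — masks never change while a cohort is being fitted."""
        if self._mask_groups is None:
            groups = []
            for s in range(self.T):
                step = self.mask[:, s]
                any_obs = step.any(axis=1)
                per_t = []
                if any_obs.any():
                    idx = np.flatnonzero(any_obs)
                    patterns, inv = np.unique(step[idx], axis=0, return_inverse=True)
                    for gi in range(patterns.shape[0]):
                        per_t.append(
                            (np.flatnonzero(patterns[gi]), idx[inv == gi])
                        )
                groups.append(per_t)
            self._mask_groups = groups
        return self._mask_groups

    @property
    def K(self) -> int:
        return self.y.shape[0]

    @property
    def T(self) -> int:
        return self.y.shape[1]

    @property
    def q(self) -> int:
        return self.y.shape[2]

    @property
    def m(self) -> int:
        return self.z_drive.shape[2]

    @property
    def transition_mask(self) -> np.ndarray:
        """(K, T) indicator of transitions t = 1..T_k that the model owns."""
        return np.arange(1, self.T + 1)[None, :] <= self.T_k[:, None]

    @classmethod
    def from_cohort(cls, ds: CohortDataset) -> "StackedCohort":
        K, q, m = ds.K, ds.q, ds.m
        T = max(s.T_k for s in ds.participants)
        y = np.full((K, T, q), np.nan)
        z_filled = np.zeros((K, T, m))
        T_k = np.zeros(K, dtype=int)
        for k, s in enumerate(ds.participants):
            y[k, : s.T_k] = s.y
            zf = _ffill_bfill(s.z)
            z_filled[k, : s.T_k] = zf
            if s.T_k < T:  # pad trailing years with the last carried value
                z_filled[k, s.T_k :] = zf[-1]
            T_k[k] = s.T_k
        mask = np.isfinite(y)
        z_drive = np.empty_like(z_filled)
        z_drive[:, 0] = z_filled[:, 0]  # z_0 backfilled from first visit
        z_drive[:, 1:] = z_filled[:, :-1]
        return cls(y=y, mask=mask, z_drive=z_drive, T_k=T_k, pids=ds.pids)


# ---------------------------------------------------------------------------
# Loading


def _read_table(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep)


def load_cohort(path, schema) -> CohortDataset:
    """Read a long-format visit table into a :class:`CohortDataset`.

    ``schema`` maps roles to columns: keys ``pid``, ``year``, ``blood``
    (list), ``env`` (list) and optionally ``medication``, ``sex``, ``age``,
    ``env_kinds``.  May be a dict or a path to a YAML file.  Each row is one
    participant-visit; missing cells are empty.  Visit ``t = 1`` is assigned
    to each participant's first calendar year on file and later years map to
    ``t = year - first_year + 1``, so skipped years become missing visits.
    """
    if not isinstance(schema, dict):
        with open(schema) as fh:
            schema = yaml.safe_load(fh)
    df = _read_table(path) if not isinstance(path, pd.DataFrame) else path
    pid_col, year_col = schema["pid"], schema["year"]
    blood, env = list(schema["blood"]), list(schema["env"])
    for col in [pid_col, year_col] + blood + env:
        if col not in df.columns:
            raise ValueError(f"column {col!r} declared in schema but absent")
    dup = df.duplicated(subset=[pid_col, year_col])
    if dup.any():
        bad = df.loc[dup, pid_col].iloc[0]
        raise ValueError(f"duplicate (pid, year) rows for participant {bad!r}")
    for col in blood + env:
        coerced = pd.to_numeric(df[col], errors="coerce")
        newly_bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if newly_bad.any():
            row = int(np.flatnonzero(newly_bad.to_numpy())[0])
            raise ValueError(f"non-numeric value in column {col!r} at row {row}")
        df[col] = coerced

    participants = []
    for pid, grp in df.groupby(pid_col, sort=True):
        grp = grp.sort_values(year_col)
        years = grp[year_col].astype(int).to_numpy()
        first = int(years[0])
        t_idx = years - first + 1
        T_k = int(t_idx[-1])
        y = np.full((T_k, len(blood)), np.nan)
        z = np.full((T_k, len(env)), np.nan)
        y[t_idx - 1] = grp[blood].to_numpy(dtype=float)
        z[t_idx - 1] = grp[env].to_numpy(dtype=float)
        first_row = grp.iloc[0]
        med = False
        if "medication" in schema and schema["medication"] in grp.columns:
            med = bool(pd.to_numeric(grp[schema["medication"]], errors="coerce").fillna(0).max() > 0)
        age = float(first_row[schema["age"]]) if schema.get("age") in grp.columns else np.nan
        sex = str(first_row[schema["sex"]]) if schema.get("sex") in grp.columns else ""
        participants.append(
            ParticipantSeries(
                pid=str(pid),
                first_year=first,
                T_k=T_k,
                obs_times=frozenset(int(t) for t in t_idx),
                y=y,
                z=z,
                age_at_first=age,
                sex=sex,
                medication=med,
            )
        )
    ds = CohortDataset(participants, blood, env, list(schema.get("env_kinds", [])))
    ds.validate()
    return ds


# ---------------------------------------------------------------------------
# Exclusions and QC


@dataclass
class ExclusionCriteria:
    """Sequential cohort exclusion rules: age window at first visit, a
    medication-use flag, and a minimum attended-visit count."""

    age_range: tuple | None = None
    exclude_medication: bool = False
    min_visits: int | None = None


@dataclass
class ExclusionReport:
    n_input: int
    n_excluded_age: int = 0
    n_excluded_medication: int = 0
    n_excluded_few_visits: int = 0
    n_retained: int = 0

    @property
    def retained_fraction(self) -> float:
        return self.n_retained / self.n_input

    @property
    def retained_percent(self) -> float:
        return 100.0 * self.n_retained / self.n_input

    def check(self) -> None:
        total = (
            self.n_excluded_age
            + self.n_excluded_medication
            + self.n_excluded_few_visits
            + self.n_retained
        )
        if total != self.n_input:
            raise ValueError("exclusion counts do not sum to the input size")


def apply_exclusions(ds: CohortDataset, criteria: ExclusionCriteria):
    """Apply exclusions in order age-window → medication → visit-count.

    Returns the filtered cohort and an :class:`ExclusionReport` with
    per-rule counts (each rule counts only participants surviving the
    previous ones).
    """
    report = ExclusionReport(n_input=ds.K)
    current = list(ds.participants)
    if criteria.age_range is not None:
        lo, hi = criteria.age_range
        kept = [s for s in current if np.isfinite(s.age_at_first) and lo <= s.age_at_first <= hi]
        report.n_excluded_age = len(current) - len(kept)
        current = kept
    if criteria.exclude_medication:
        kept = [s for s in current if not s.medication]
        report.n_excluded_medication = len(current) - len(kept)
        current = kept
    if criteria.min_visits is not None:
        kept = [s for s in current if len(s.obs_times) >= criteria.min_visits]
        report.n_excluded_few_visits = len(current) - len(kept)
        current = kept
    report.n_retained = len(current)
    report.check()
    out = CohortDataset(current, list(ds.blood_names), list(ds.env_names), list(ds.env_kinds))
    return out, report


def _first_visit_values(ds: CohortDataset, feature: str) -> np.ndarray:
    if feature == "age":
        return np.array([s.age_at_first for s in ds.participants], dtype=float)
    j = ds.blood_names.index(feature)
    return np.array([s.y[0, j] for s in ds.participants], dtype=float)


def baseline_comparison(
    included: CohortDataset,
    excluded: CohortDataset,
    features: list,
    alpha: float = 0.05,
    n_comparison_groups: int = 2,
) -> pd.DataFrame:
    """Per-feature two-sided Wilcoxon rank-sum test on first-visit values.

    The Bonferroni threshold is ``alpha / (n_features * n_comparison_groups)``
    — e.g. 39 features compared for two exclusion groups gives
    0.05 / 78 = 6.41e-4.  Features with fewer than two non-missing values in
    either group get an undefined (NaN) p-value.
    """
    if included.K == 0 or excluded.K == 0:
        raise ValueError("both cohorts must be non-empty")
    threshold = alpha / (len(features) * n_comparison_groups)
    rows = []
    for feat in features:
        a = _first_visit_values(included, feat)
        b = _first_visit_values(excluded, feat)
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if a.size < 2 or b.size < 2:
            p = np.nan
        else:
            p = float(sstats.mannwhitneyu(a, b, alternative="two-sided", method="auto").pvalue)
        rows.append(
            {
                "feature": feat,
                "p_value": p,
                "n_included": int(a.size),
                "n_excluded": int(b.size),
                "significant": bool(np.isfinite(p) and p < threshold),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["bonferroni_threshold"] = threshold
    return out


# ---------------------------------------------------------------------------
# Standardization


@dataclass
class NormalizationState:
    """Per-column location/scale for y and z (pooled over all visits)."""

    blood_names: list
    env_names: list
    y_loc: np.ndarray
    y_scale: np.ndarray
    z_loc: np.ndarray
    z_scale: np.ndarray

    def transform_y(self, y: np.ndarray) -> np.ndarray:
        return (y - self.y_loc) / self.y_scale

    def invert_y(self, y: np.ndarray) -> np.ndarray:
        return y * self.y_scale + self.y_loc

    def transform_z(self, z: np.ndarray) -> np.ndarray:
        return (z - self.z_loc) / self.z_scale

    def invert_z(self, z: np.ndarray) -> np.ndarray:
        return z * self.z_scale + self.z_loc

    def standardize_env_value(self, name: str, value: float) -> float:
        j = self.env_names.index(name)
        return (value - self.z_loc[j]) / self.z_scale[j]

    def to_dict(self) -> dict:
        return {
            "blood_names": list(self.blood_names),
            "env_names": list(self.env_names),
            "y_loc": self.y_loc.tolist(),
            "y_scale": self.y_scale.tolist(),
            "z_loc": self.z_loc.tolist(),
            "z_scale": self.z_scale.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationState":
        return cls(
            blood_names=list(d["blood_names"]),
            env_names=list(d["env_names"]),
            y_loc=np.asarray(d["y_loc"], dtype=float),
            y_scale=np.asarray(d["y_scale"], dtype=float),
            z_loc=np.asarray(d["z_loc"], dtype=float),
            z_scale=np.asarray(d["z_scale"], dtype=float),
        )


def _pooled(ds: CohortDataset, which: str) -> np.ndarray:
    return np.concatenate([getattr(s, which) for s in ds.participants], axis=0)


def standardize(ds: CohortDataset):
    """Standardize every y and z column to pooled mean 0, sample variance 1.

    Moments pool all participants and visits, ignoring missing cells
    (masks are preserved).  Binary and ordinal factors are standardized like
    continuous ones, so a raw-unit scenario override lands on the same scale
    the model was fitted on.  Returns the transformed cohort and the
    invertible :class:`NormalizationState`.
    """
    ys, zs = _pooled(ds, "y"), _pooled(ds, "z")

    def moments(block: np.ndarray, names: list):
        n = np.isfinite(block).sum(axis=0)
        if (n < 2).any():
            bad = names[int(np.argmax(n < 2))]
            raise ValueError(f"column {bad!r} has fewer than 2 non-missing values")
        loc = np.nanmean(block, axis=0)
        scale = np.nanstd(block, axis=0, ddof=1)
        if (scale <= 0).any():
            bad = names[int(np.argmax(scale <= 0))]
            raise ValueError(f"column {bad!r} has zero variance")
        return loc, scale

    y_loc, y_scale = moments(ys, ds.blood_names)
    z_loc, z_scale = moments(zs, ds.env_names)
    norm = NormalizationState(list(ds.blood_names), list(ds.env_names), y_loc, y_scale, z_loc, z_scale)
    new = [
        replace(s, y=norm.transform_y(s.y), z=norm.transform_z(s.z))
        for s in ds.participants
    ]
    return CohortDataset(new, list(ds.blood_names), list(ds.env_names), list(ds.env_kinds)), norm


# ---------------------------------------------------------------------------
# Descriptive correlation screens


def spearman_matrices(ds: CohortDataset, min_pairs: int = 3):
    """Spearman correlations of pooled levels and of year-differences.

    Levels pool every attended visit's ``(y, z)``; differences pool
    ``(y_t - y_{t-1}, z_t - z_{t-1})`` over pairs of *consecutive* attended
    visits only (a participant observed at {1, 3} contributes no pair).
    Cells with fewer than ``min_pairs`` complete pairs are NaN.  Ties get
    average ranks.  Returns two labelled (q+m)×(q+m) DataFrames.
    """
    cols = list(ds.blood_names) + list(ds.env_names)
    level_rows, diff_rows = [], []
    for s in ds.participants:
        obs = sorted(s.obs_times)
        for t in obs:
            level_rows.append(np.concatenate([s.y[t - 1], s.z[t - 1]]))
        for t in obs:
            if t - 1 in s.obs_times:
                diff_rows.append(
                    np.concatenate([s.y[t - 1] - s.y[t - 2], s.z[t - 1] - s.z[t - 2]])
                )
    levels = pd.DataFrame(np.asarray(level_rows), columns=cols)
    levels_corr = levels.corr(method="spearman", min_periods=min_pairs)
    if diff_rows:
        diffs = pd.DataFrame(np.asarray(diff_rows), columns=cols)
        diff_corr = diffs.corr(method="spearman", min_periods=min_pairs)
    else:
        diff_corr = pd.DataFrame(np.nan, index=cols, columns=cols)
    np.fill_diagonal(levels_corr.values, 1.0)
    np.fill_diagonal(diff_corr.values, 1.0)
    return levels_corr, diff_corr


# ---------------------------------------------------------------------------
# Serialization (single JSON archive)


def save_cohort(ds: CohortDataset, path, norm: NormalizationState | None = None) -> None:
    def ser(a: np.ndarray):
        return [[None if not np.isfinite(v) else float(v) for v in row] for row in a]

    doc = {
        "blood_names": list(ds.blood_names),
        "env_names": list(ds.env_names),
        "env_kinds": list(ds.env_kinds),
        "normalization": norm.to_dict() if norm is not None else None,
        "participants": [
            {
                "pid": s.pid,
                "first_year": s.first_year,
                "T_k": s.T_k,
                "obs_times": sorted(s.obs_times),
                "y": ser(s.y),
                "z": ser(s.z),
                "age_at_first": None if not np.isfinite(s.age_at_first) else float(s.age_at_first),
                "sex": s.sex,
                "medication": bool(s.medication),
            }
            for s in ds.participants
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_cohort(path):
    """Load a cohort archive written by :func:`save_cohort`.

    Returns ``(CohortDataset, NormalizationState | None)``.
    """
    with open(path) as fh:
        doc = json.load(fh)

    def arr(rows):
        return np.array(
            [[np.nan if v is None else float(v) for v in row] for row in rows], dtype=float
        )

    participants = [
        ParticipantSeries(
            pid=d["pid"],
            first_year=int(d["first_year"]),
            T_k=int(d["T_k"]),
            obs_times=frozenset(d["obs_times"]),
            y=arr(d["y"]),
            z=arr(d["z"]),
            age_at_first=np.nan if d["age_at_first"] is None else float(d["age_at_first"]),
            sex=d.get("sex", ""),
            medication=bool(d.get("medication", False)),
        )
        for d in doc["participants"]
    ]
    ds = CohortDataset(participants, doc["blood_names"], doc["env_names"], doc.get("env_kinds", []))
    norm = NormalizationState.from_dict(doc["normalization"]) if doc.get("normalization") else None
    ds.validate()
    return ds, norm
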