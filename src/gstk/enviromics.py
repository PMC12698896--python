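"""Environmental covariates and the enviromic relationship kernel.

A multi-environment trial is characterized by daily weather series per
location (e.g. from the NASA POWER database).  This module summarizes the
daily series over a growth window into an environments x covariates matrix
``W``, z-standardizes the columns, and turns ``W`` into an environmental
kinship ("enviromic") kernel — either a linear kernel ``W W' / q`` or a
Gaussian kernel on the Euclidean distances between environment rows.

The tested path is offline: daily covariates come from a cached long-format
comma-separated table with columns ``env_id, date, covariate, value``.  A
live fetch from a weather database can be plugged in as a loader callable
but is never required.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

__all__ = [
    "EnvSpec",
    "EnvCovariateMatrix",
    "EnvKernel",
    "POWER_COVARIATES",
    "load_daily_covariates",
    "build_env_matrix",
    "env_kernel",
]

#: Daily weather covariates pulled for each trial location: temperature
#: (mean/max/min/dewpoint), long/shortwave and photosynthetically active
#: radiation, precipitation, wind speed, relative humidity, and
#: evapotranspiration.  Duplicate names in a request are collapsed.
POWER_COVARIATES: tuple[str, ...] = (
    "T2M",
    "T2M_MAX",
    "T2M_MIN",
    "T2MDEW",
    "ALLSKY_SFC_LW_DWN",
    "ALLSKY_SFC_SW_DWN",
    "ALLSKY_SFC_SW_DNI",
    "ALLSKY_SFC_PAR_TOT",
    "ALLSKY_SFC_PAR_UVA",
    "ALLSKY_SFC_PAR_UVB",
    "PRECTOT",
    "WS2M",
    "RH2M",
    "EVPTRNS",
)


@dataclass
class EnvSpec:
    """A trial environment: identifier, coordinates, and growth window."""

    env_id: str
    latitude: float
    longitude: float
    window_start: date
    window_end: date

    def __post_init__(self) -> None:
        if isinstance(self.window_start, str):
            self.window_start = date.fromisoformat(self.window_start)
        if isinstance(self.window_end, str):
            self.window_end = date.fromisoformat(self.window_end)
        if self.window_start > self.window_end:
            raise ValueError(f"{self.env_id}: window_start after window_end")
        if abs(self.latitude) > 90 or abs(self.longitude) > 180:
            raise ValueError(f"{self.env_id}: coordinates out of range")

    @property
    def n_days(self) -> int:
        return (self.window_end - self.window_start).days + 1


@dataclass
class EnvCovariateMatrix:
    """Environments x summarized-covariates matrix."""

    env_ids: list[str]
    covariates: list[str]
    values: np.ndarray
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        assert self.values.shape == (len(self.env_ids), len(self.covariates))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.env_ids, columns=self.covariates)


@dataclass
class EnvKernel:
    """Symmetric PSD environmental relationship matrix."""

    env_ids: list[str]
    omega: np.ndarray
    kind: str
    bandwidth: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.omega, index=self.env_ids, columns=self.env_ids)


class MissingEnvironmentError(KeyError):
    pass


def load_daily_covariates(
    source,
    envs: list[EnvSpec],
    covariates: tuple[str, ...] = POWER_COVARIATES,
    fetcher=None,
) -> pd.DataFrame:
    """Assemble per-environment daily series over each growth window.

    Parameters
    ----------
    source
        Path to a cached long-format CSV (``env_id, date, covariate,
        value``) or an equivalent DataFrame. ``None`` is allowed when a
        ``fetcher`` is supplied.
    envs
        Environments to cover; each defines its own window.
    covariates
        Requested covariate names; duplicates are collapsed preserving
        first occurrence.
    fetcher
        Optional callable ``fetcher(env_spec, covariate) -> DataFrame``
        used for environments absent from the cache (a live database
        adapter). Without it, a missing environment is an error.

    Returns
    -------
    DataFrame with columns ``env_id, date, covariate, value`` restricted to
    the requested windows, plus an attached gap report in
    ``.attrs["gaps"]`` listing (env_id, covariate, n_missing_days).
    """
    covariates = list(dict.fromkeys(covariates))  # dedupe, order-preserving
    if source is None:
        cache = pd.DataFrame(columns=["env_id", "date", "covariate", "value"])
    elif isinstance(source, pd.DataFrame):
        cache = source.copy()
    else:
        cache = pd.read_csv(source)
    required = {"env_id", "date", "covariate", "value"}
    if not required.issubset(cache.columns):
        raise ValueError(f"covariate cache needs columns {sorted(required)}")
    cache["date"] = pd.to_datetime(cache["date"]).dt.date

    cached_envs = set(cache["env_id"].unique())
    missing_envs = [e.env_id for e in envs if e.env_id not in cached_envs]
    if missing_envs and fetcher is None:
        raise MissingEnvironmentError(
            f"environments absent from cache and no fetcher given: {missing_envs}"
        )
    frames = []
    gaps = []
    for env in envs:
        days = pd.date_range(env.window_start, env.window_end).date
        if env.env_id in cached_envs:
            sub = cache[cache["env_id"] == env.env_id]
        else:
            sub = pd.concat(
                [fetcher(env, cov).assign(env_id=env.env_id, covariate=cov) for cov in covariates]
            )
            sub["date"] = pd.to_datetime(sub["date"]).dt.date
        for cov in covariates:
            series = sub[(sub["covariate"] == cov) & sub["date"].isin(days)]
            n_gap = len(days) - series["date"].nunique()
            if n_gap:
                gaps.append({"env_id": env.env_id, "covariate": cov, "n_missing_days": n_gap})
            frames.append(series[["env_id", "date", "covariate", "value"]])
    out = pd.concat(frames, ignore_index=True) if frames else cache.iloc[:0]
    out.attrs["gaps"] = gaps
    return out


def build_env_matrix(
    series: pd.DataFrame,
    summarizer: str | dict = "mean",
    standardize: bool = True,
    gap_policy: str = "error",
) -> EnvCovariateMatrix:
    """Summarize daily series into an environments x covariates matrix.

    Each (env, covariate) cell is the window summary of the daily values
    (default: mean; a dict maps covariate names to "mean"/"sum" for
    per-covariate choices such as summing precipitation).  Columns are then
    z-standardized across environments; zero-variance columns are dropped
    with a warning.
    """
    gaps = series.attrs.get("gaps", [])
    if gaps and gap_policy == "error":
        raise ValueError(
            f"daily series has gaps for {len(gaps)} (env, covariate) pairs; "
            "fill the cache or set gap_policy='skip'"
        )
    env_ids = list(pd.unique(series["env_id"]))
    if len(env_ids) < 2:
        raise ValueError("need at least 2 environments to build a kernel-ready matrix")

    def _agg(cov_name: str):
        if isinstance(summarizer, dict):
            return summarizer.get(cov_name, "mean")
        return summarizer

    wide = series.pivot_table(
        index="env_id", columns="covariate", values="value", aggfunc="mean"
    )
    # re-aggregate any "sum" covariates
    if isinstance(summarizer, dict) or summarizer != "mean":
        for cov in wide.columns:
            if _agg(cov) == "sum":
                sums = series[series["covariate"] == cov].groupby("env_id")["value"].sum()
                wide[cov] = sums
    wide = wide.loc[env_ids]
    if wide.isna().any().any():
        raise ValueError("summarized matrix has absent cells; check gap policy")
    values = wide.to_numpy(dtype=float)
    names = list(wide.columns)
    if standardize:
        sd = values.std(axis=0, ddof=0)
        keep = sd > 0
        if not keep.all():
            import warnings

            dropped = [n for n, k in zip(names, keep) if not k]
            warnings.warn(f"dropping zero-variance covariates: {dropped}", stacklevel=2)
        values = values[:, keep]
        names = [n for n, k in zip(names, keep) if k]
        values = (values - values.mean(axis=0)) / values.std(axis=0, ddof=0)
    return EnvCovariateMatrix(
        env_ids=env_ids, covariates=names, values=values, standardized=standardize
    )


def env_kernel(w: EnvCovariateMatrix, kind: str = "gaussian", theta: float = 1.0) -> EnvKernel:
    """Environmental relationship kernel from a standardized covariate matrix.

    linear
        ``Omega = W W' / q`` with ``q`` the number of covariates.
    gaussian
        ``Omega_ij = exp(-theta * d2_ij / q_med)`` with ``d2`` the squared
        Euclidean distance between environment rows and ``q_med`` the
        median off-diagonal ``d2`` (1 if all distances are zero).  The
        median heuristic makes ``theta`` a unitless multiplier with
        default 1.
    """
    if len(w.env_ids) < 2:
        raise ValueError("kernel needs at least 2 environments")
    if theta <= 0:
        raise ValueError("theta must be positive")
    x = w.values
    if kind == "linear":
        omega = x @ x.T / x.shape[1]
        bw = {"n_covariates": x.shape[1]}
    elif kind == "gaussian":
        sq = (x[:, None, :] - x[None, :, :]) ** 2
        d2 = sq.sum(axis=2)
        off = d2[~np.eye(len(x), dtype=bool)]
        q_med = float(np.median(off)) if off.size and off.max() > 0 else 1.0
        omega = np.exp(-theta * d2 / q_med)
        bw = {"theta": theta, "median_d2": q_med}
    else:
        raise ValueError(f"unknown kernel kind {kind!r} (use 'linear' or 'gaussian')")
    omega = (omega + omega.T) / 2.0
    return EnvKernel(env_ids=list(w.env_ids), omega=omega, kind=kind, bandwidth=bw)
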