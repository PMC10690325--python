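"""Pleiotropy by gene age: per-branch organ-system counts, median trends,
and the constrained logistic growth fit.

A disease gene's pleiotropy m is the number of distinct organ systems whose
abnormalities its defects produce.  Across branches the median m grows with
gene age; the growth is modelled with a logistic law in evolutionary time t
(measured from the youngest branch's origin, in 100-My units):

    P(t) = P_max / (1 + ((P_max - P_0) / P_0) * exp(-k * t))

with P(0) = P_0 exactly and P(t) -> P_max as t -> inf.  P_max and P_0 are
fixed to the empirical extreme medians (defaults 10 and 4); only the growth
rate k is fitted, by bounded scalar nonlinear least squares (Brent-class,
deterministic, no random initialisation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .age_framework import AgeFramework

logger = logging.getLogger(__name__)

DEFAULT_P_MAX = 10.0
DEFAULT_P_0 = 4.0
#: k search interval (per 100 My); tolerance of the bounded scalar solver.
K_BOUNDS = (1e-9, 100.0)
K_XATOL = 1e-12


@dataclass
class PleiotropySeries:
    """Per-branch m distributions with medians and time coordinates.

    ``t`` is in 100-My units from the youngest branch's origin; branches
    are ordered oldest first (``orientation`` records this so downstream
    consumers never guess the direction).
    """

    branches: list[str]
    origin_ages_my: list[float]
    t: np.ndarray
    medians: np.ndarray
    counts: list[int]
    values: list[np.ndarray]
    orientation: str = "oldest_first"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "branch": self.branches,
            "origin_age_my": self.origin_ages_my,
            "t_100my": self.t,
            "n_genes": self.counts,
            "median_m": self.medians,
        })


@dataclass
class LogisticFit:
    """Result of the constrained logistic NLS fit (k is the only free
    parameter)."""

    k: float
    p_max: float
    p_0: float
    rss: float
    n_points: int
    converged: bool
    at_boundary: bool

    def to_dict(self) -> dict:
        return {"k": self.k, "P_max": self.p_max, "P_0": self.p_0,
                "rss": self.rss, "n_points": self.n_points,
                "converged": self.converged, "at_boundary": self.at_boundary}


def op_counts_by_branch(profiles: pd.DataFrame, framework: AgeFramework,
                        unit_my: float = 100.0) -> PleiotropySeries:
    """Per-branch m distributions and medians.

    The median of an even-sized set is the mean of the central pair.
    Branches with no profiles get a NaN median (flagged in the log).
    """
    groups = profiles.groupby("branch")["m"]
    branches, ages, ts, medians, counts, values = [], [], [], [], [], []
    for b in framework.labels:
        vals = (np.sort(groups.get_group(b).to_numpy())
                if b in groups.groups else np.array([], dtype=float))
        branches.append(b)
        ages.append(framework.origin_age(b))
        ts.append(framework.t_since_youngest(b, unit_my))
        counts.append(len(vals))
        values.append(vals)
        if len(vals) == 0:
            logger.warning("branch %s has no profiles; median undefined", b)
            medians.append(np.nan)
        else:
            medians.append(float(np.median(vals)))
    return PleiotropySeries(branches, ages, np.asarray(ts, dtype=float),
                            np.asarray(medians, dtype=float), counts, values)


def delta_op_rate(series: PleiotropySeries,
                  intervals: list[tuple[str, str]]) -> pd.DataFrame:
    """Finite-difference increase rate of the median m, in systems per My.

    Parameters
    ----------
    intervals
        Pairs ``(older_branch, younger_branch)``; for each, the rate is
        (median(younger) - median(older)) / (origin(older) - origin(younger)).

    Raises
    ------
    ValueError
        If an interval has zero elapsed time.
    """
    idx = {b: i for i, b in enumerate(series.branches)}
    rows = []
    for older, younger in intervals:
        io, iy = idx[older], idx[younger]
        dt = series.origin_ages_my[io] - series.origin_ages_my[iy]
        if dt == 0:
            raise ValueError(f"zero elapsed time between {older} and {younger}")
        dm = series.medians[iy] - series.medians[io]
        rows.append({"older": older, "younger": younger,
                     "delta_median": dm, "delta_t_my": dt,
                     "rate_per_my": dm / dt})
    return pd.DataFrame(rows)


def epoch_intervals(framework: AgeFramework) -> list[tuple[str, str, str]]:
    """Per-epoch (epoch, older branch, younger branch) comparison intervals.

    Multi-branch epochs span their own oldest-to-youngest branches; a
    single-branch epoch is compared against the oldest branch of the next
    younger epoch (so the rate covers the interval the epoch boundary
    closes).  The youngest epoch, if single-branch, has no interval.
    """
    out = []
    for i, epoch in enumerate(framework.epochs):
        members = framework.epoch_branches(epoch)
        if not members:
            continue
        if len(members) >= 2:
            out.append((epoch, members[0], members[-1]))
        else:
            younger = None
            for nxt in framework.epochs[i + 1:]:
                nxt_members = framework.epoch_branches(nxt)
                if nxt_members:
                    younger = nxt_members[0]
                    break
            if younger is not None:
                out.append((epoch, members[0], younger))
    return out


def logistic_predict(t, k: float, p_max: float = DEFAULT_P_MAX,
                     p_0: float = DEFAULT_P_0):
    """Initial-condition logistic P(t) = P_max / (1 + ((P_max-P_0)/P_0) e^{-kt}).

    P(0) = P_0 exactly; P(t) -> P_max for t -> inf (k > 0).
    """
    if not (p_max > p_0 > 0):
        raise ValueError("need P_max > P_0 > 0")
    t = np.asarray(t, dtype=float)
    c = (p_max - p_0) / p_0
    out = p_max / (1.0 + c * np.exp(-k * t))
    return float(out) if out.ndim == 0 else out


def fit_logistic_k(t, medians, p_max: float = DEFAULT_P_MAX,
                   p_0: float = DEFAULT_P_0) -> LogisticFit:
    """Fit the growth rate k by bounded scalar least squares.

    Parameters
    ----------
    t, medians
        Time coordinates (100-My units) and per-branch median m values;
        NaN medians are dropped.  At least 3 points are required.

    Raises
    ------
    ValueError
        Under-determined data (< 3 points) or solver failure.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(medians, dtype=float)
    keep = ~np.isnan(y)
    t, y = t[keep], y[keep]
    if len(t) < 3:
        raise ValueError(f"need >= 3 (t, median) points, got {len(t)}")

    def sse(k: float) -> float:
        resid = logistic_predict(t, k, p_max, p_0) - y
        return float(np.dot(resid, resid))

    res = optimize.minimize_scalar(sse, bounds=K_BOUNDS, method="bounded",
                                   options={"xatol": K_XATOL})
    if not res.success:
        raise ValueError(f"logistic fit did not converge: {res.message}")
    k_hat = float(res.x)
    at_boundary = (k_hat <= K_BOUNDS[0] * 10) or (k_hat >= K_BOUNDS[1] * 0.999)
    if at_boundary:
        logger.warning("fitted k = %.3g sits at the search boundary "
                       "(flat or degenerate data?)", k_hat)
    return LogisticFit(k=k_hat, p_max=p_max, p_0=p_0, rss=float(res.fun),
                       n_points=len(t), converged=bool(res.success),
                       at_boundary=at_boundary)


def fit_series(series: PleiotropySeries, p_max: float | None = None,
               p_0: float | None = None,
               from_data: bool = False) -> LogisticFit:
    """Fit k to a branch series.

    With ``from_data=True`` the asymptote constants are recomputed from the
    series itself (P_max = oldest-end extreme median, P_0 = youngest);
    otherwise the defaults (or explicit values) are used.
    """
    if from_data:
        finite = series.medians[~np.isnan(series.medians)]
        if len(finite) < 2:
            raise ValueError("not enough medians to set P_max/P_0 from data")
        p_max = float(np.max(finite))
        p_0 = float(np.min(finite))
        if p_max <= p_0:
            p_max = p_0 + 1e-6
    return fit_logistic_k(series.t, series.medians,
                          p_max if p_max is not None else DEFAULT_P_MAX,
                          p_0 if p_0 is not None else DEFAULT_P_0)
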