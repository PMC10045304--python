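"""Nonparametric survival estimators and rank-based metrics.

Kaplan–Meier (product-limit) and Nelson–Aalen step estimators, the
multi-group Mantel log-rank test, and the Harrell concordance index with
the tie/censoring credit rules of Ishwaran et al.'s survival-forest
formulation.  These primitives back both the parametric (Weibull AFT)
and machine-learning (random survival forest) model tracks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cohort import CohortDataset, CohortError

SURVIVAL = "survival"
CUMULATIVE_HAZARD = "cumulative_hazard"


@dataclass
class StepEstimate:
    """Right-continuous step function over distinct event times.

    ``kind`` is ``"survival"`` (nonincreasing, values in [0, 1], baseline 1
    before the first step) or ``"cumulative_hazard"`` (nondecreasing,
    nonnegative, baseline 0).  ``at_risk``/``deaths`` carry the n_j and d_j
    risk-set counts when the estimate comes from data; derived curves (e.g.
    ensemble averages) may leave them ``None``.
    """

    times: np.ndarray
    values: np.ndarray
    at_risk: np.ndarray | None
    deaths: np.ndarray | None
    kind: str

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in (SURVIVAL, CUMULATIVE_HAZARD):
            raise ValueError(f"unknown step-estimate kind {self.kind!r}")
        if self.times.ndim != 1 or self.values.shape != self.times.shape:
            raise ValueError("times and values must be equal-length 1-d arrays")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("step times must be strictly increasing")
        for name in ("at_risk", "deaths"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr)
                if arr.shape != self.times.shape:
                    raise ValueError(f"{name} must match the step-time grid")
                setattr(self, name, arr)
        if self.kind == SURVIVAL:
            if self.values.size and (np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12)):
                raise ValueError("survival values must lie in [0, 1]")
            if np.any(np.diff(self.values) > 1e-12):
                raise ValueError("survival estimate must be nonincreasing")
        else:
            if self.values.size and np.any(self.values < -1e-12):
                raise ValueError("cumulative hazard must be nonnegative")
            if np.any(np.diff(self.values) < -1e-12):
                raise ValueError("cumulative hazard must be nondecreasing")

    @property
    def baseline(self) -> float:
        return 1.0 if self.kind == SURVIVAL else 0.0

    def evaluate(self, t) -> np.ndarray | float:
        """Right-continuous evaluation: value of the largest step time <= t."""
        t_arr = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t_arr, side="right") - 1
        padded = np.concatenate(([self.baseline], self.values))
        out = padded[idx + 1]
        return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


@dataclass
class TestResult:
    """Chi-square test outcome: statistic, degrees of freedom, upper-tail p."""

    statistic: float
    df: int
    p_value: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.statistic < 0:
            raise ValueError("chi-square statistic must be nonnegative")
        if self.df < 0:
            raise ValueError("degrees of freedom must be nonnegative")
        if self.p_value is None:
            self.p_value = 1.0 if self.df == 0 else float(stats.chi2.sf(self.statistic, self.df))


def _risk_table(times: np.ndarray, events: np.ndarray):
    """Distinct death times with at-risk and death counts.

    Ties between a death and a censoring at the same time follow the
    standard convention that censoring occurs immediately after the death,
    so censored records still count in the risk set at that time.
    """
    death_times = np.unique(times[events == 1])
    n_at_risk = (times[:, None] >= death_times[None, :]).sum(axis=0)
    d = ((times[:, None] == death_times[None, :]) & (events[:, None] == 1)).sum(axis=0)
    return death_times, n_at_risk.astype(np.int64), d.astype(np.int64)


def _km_arrays(times: np.ndarray, events: np.ndarray) -> StepEstimate:
    death_times, n, d = _risk_table(times, events)
    values = np.cumprod(1.0 - d / n) if death_times.size else np.empty(0)
    return StepEstimate(death_times, values, n, d, kind=SURVIVAL)


def _na_arrays(times: np.ndarray, events: np.ndarray) -> StepEstimate:
    death_times, n, d = _risk_table(times, events)
    values = np.cumsum(d / n) if death_times.size else np.empty(0)
    return StepEstimate(death_times, values, n, d, kind=CUMULATIVE_HAZARD)


def kaplan_meier(data: CohortDataset) -> StepEstimate:
    """Product-limit estimator S^(t) = prod_{j: t_j <= t} (1 - d_j / n_j).

    Steps occur at distinct death times only; censored records contribute to
    the risk sets n_j but create no step.  With no deaths at all the step
    list is empty and S is identically 1.
    """
    return _km_arrays(data.times, data.events)


def nelson_aalen(data: CohortDataset) -> StepEstimate:
    """Nelson–Aalen cumulative hazard H^(t) = sum_{j: t_j <= t} d_j / n_j.

    The companion survival estimate is S~(t) = exp(-H^(t)).
    """
    return _na_arrays(data.times, data.events)


def log_rank_test(data: CohortDataset, group: str) -> TestResult:
    """Multi-group Mantel log-rank test for equality of survival curves.

    ``group`` must name a categorical covariate; with r nonempty levels the
    statistic is referred to a chi-square with r - 1 degrees of freedom
    (large-sample reference, no continuity correction).  Pairwise tests are
    obtained by subsetting the cohort to two levels.
    """
    if group not in data.schema.names:
        raise CohortError(f"unknown covariate {group!r}")
    if data.schema.is_numeric(group):
        raise CohortError(
            f"covariate {group!r} is numeric; discretize it before a log-rank comparison"
        )
    labels = data.covariates[group].to_numpy()
    present = [lv for lv in data.schema.levels(group) if np.any(labels == lv)]
    r = len(present)
    if r < 2:
        raise CohortError(f"log-rank test needs >=2 nonempty levels of {group!r}, found {r}")

    times, events = data.times, data.events
    death_times, n_tot, d_tot = _risk_table(times, events)
    if death_times.size == 0:
        return TestResult(statistic=0.0, df=r - 1)

    # per-group at-risk and death counts at every distinct death time
    at_risk = times[:, None] >= death_times[None, :]
    dead = (times[:, None] == death_times[None, :]) & (events[:, None] == 1)
    observed = np.empty(r)
    expected = np.empty(r)
    n_g = np.empty((r, death_times.size))
    for gi, lv in enumerate(present):
        mask = labels == lv
        n_g[gi] = at_risk[mask].sum(axis=0)
        observed[gi] = dead[mask].sum()
        expected[gi] = (n_g[gi] * d_tot / n_tot).sum()

    # hypergeometric covariance of the per-time death counts, summed over times
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(n_tot > 1, d_tot * (n_tot - d_tot) / (n_tot - 1.0), 0.0)
    p_g = n_g / n_tot
    cov = np.zeros((r, r))
    for gi in range(r):
        for gj in range(r):
            delta = 1.0 if gi == gj else 0.0
            cov[gi, gj] = (scale * p_g[gi] * (delta - p_g[gj])).sum()

    u = (observed - expected)[:-1]
    v = cov[:-1, :-1]
    try:
        statistic = float(u @ np.linalg.solve(v, u))
    except np.linalg.LinAlgError:
        statistic = float(u @ np.linalg.pinv(v) @ u)
    statistic = max(statistic, 0.0)
    return TestResult(statistic=statistic, df=r - 1)


def concordance_index(mortality, data: CohortDataset) -> float:
    """Harrell concordance index with survival-forest tie handling.

    ``mortality`` is one score per record; a higher score means a predicted
    worse outcome (shorter time).  Permissible pairs exclude those whose
    shorter time is censored and equal-time pairs with both members
    censored.  Credit: 1 when the worse-scored member has the shorter time,
    0.5 for score ties; for equal-time pairs, both deaths score 1 if their
    scores are equal else 0.5, and a death/censoring pair scores 1 if the
    death has the higher score else 0.5.
    """
    scores = np.asarray(mortality, dtype=float)
    if scores.shape != data.times.shape:
        raise ValueError("need exactly one mortality score per record")
    t = data.times
    d = data.events.astype(bool)

    ti, tj = t[:, None], t[None, :]
    di, dj = d[:, None], d[None, :]
    si, sj = scores[:, None], scores[None, :]
    upper = np.triu(np.ones((len(t), len(t)), dtype=bool), k=1)

    unequal = ti != tj
    # orient unequal-time pairs: "short" is the record with the smaller time
    i_short = ti < tj
    short_death = np.where(i_short, di, dj)
    perm_unequal = upper & unequal & short_death
    s_short = np.where(i_short, si, sj)
    s_long = np.where(i_short, sj, si)
    credit_unequal = np.where(s_short > s_long, 1.0, np.where(s_short == s_long, 0.5, 0.0))

    equal = ~unequal
    both_death = di & dj
    one_death = di ^ dj
    perm_equal = upper & equal & (both_death | one_death)
    credit_both = np.where(si == sj, 1.0, 0.5)
    s_death = np.where(di, si, sj)
    s_other = np.where(di, sj, si)
    credit_one = np.where(s_death > s_other, 1.0, 0.5)
    credit_equal = np.where(both_death, credit_both, credit_one)

    permissible = perm_unequal.sum() + perm_equal.sum()
    if permissible == 0:
        raise CohortError("concordance index undefined: no permissible pairs")
    credit = credit_unequal[perm_unequal].sum() + credit_equal[perm_equal].sum()
    return float(credit / permissible)
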