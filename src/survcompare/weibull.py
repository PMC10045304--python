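"""Censored Weibull accelerated-failure-time (AFT) regression.

Model: Y_i = log(T_i) = x_i' beta + sigma * nu_i with nu_i standard
Gumbel-minimum, equivalently T_i Weibull with shape gamma = 1/sigma and
characteristic life exp(x_i' beta).  Right-censored maximum likelihood is
carried out over (beta, tau = log sigma); inference uses the inverse
observed information (numerical Hessian at the optimum).  The module also
provides likelihood-ratio tests for nested fits, Cox–Snell / martingale /
deviance residuals, case-deletion influence refits, and median-time-ratio
effect interpretation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort import CohortDataset, CohortError, CovariateSchema, validate_pattern
from .survival_core import StepEstimate, TestResult, _km_arrays

logger = logging.getLogger(__name__)

INTERCEPT = "intercept"

# guard for exp(z) in the Gumbel-minimum log-likelihood; hit only far from
# any optimum, where the exact magnitude of the penalty is irrelevant
_Z_CLIP = 500.0

_TAU_BOUNDS = (-12.0, 12.0)


class ConvergenceError(RuntimeError):
    """Optimization failed; carries the last parameter state."""

    def __init__(self, message: str, last_state=None):
        super().__init__(message)
        self.last_state = last_state


def column_name(covariate: str, level: str | None = None) -> str:
    """Design-column label: ``name`` for numerics, ``name[level]`` for indicators."""
    return covariate if level is None else f"{covariate}[{level}]"


@dataclass
class DesignMatrix:
    """Reference-coded model matrix: intercept, numerics, level indicators."""

    matrix: np.ndarray
    column_names: list[str]
    covariate_of: list[str | None]  # parent covariate per column (None = intercept)
    schema: CovariateSchema = field(repr=False)
    covariates_used: tuple[str, ...] = ()

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]


def build_design_matrix(
    data: CohortDataset, covariates: Sequence[str] | None = None
) -> DesignMatrix:
    """Intercept + numeric columns + reference-skipping 0/1 level indicators.

    Column order is deterministic: intercept first, then covariates in schema
    order (restricted to ``covariates`` when given), categorical levels in
    declared order skipping the reference level.
    """
    schema = data.schema
    use = list(schema.names) if covariates is None else list(covariates)
    for name in use:
        if name not in schema.names:
            raise CohortError(f"unknown covariate {name!r}")
    use = [name for name in schema.names if name in use]

    n = len(data)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = [INTERCEPT]
    parents: list[str | None] = [None]
    for name in use:
        if schema.is_numeric(name):
            cols.append(data.covariates[name].to_numpy(dtype=float))
            names.append(column_name(name))
            parents.append(name)
        else:
            values = data.covariates[name].to_numpy()
            for level in schema.levels(name)[1:]:
                cols.append((values == level).astype(float))
                names.append(column_name(name, level))
                parents.append(name)
    return DesignMatrix(
        matrix=np.column_stack(cols),
        column_names=names,
        covariate_of=parents,
        schema=schema,
        covariates_used=tuple(use),
    )


def encode_pattern(design: DesignMatrix, covariates: Mapping[str, object]) -> np.ndarray:
    """Encode one covariate pattern as a design row matching ``design``'s columns."""
    pattern = validate_pattern(design.schema, covariates)
    row = np.zeros(design.n_columns)
    row[0] = 1.0
    for j, (name, parent) in enumerate(zip(design.column_names, design.covariate_of)):
        if parent is None:
            continue
        if design.schema.is_numeric(parent):
            row[j] = float(pattern[parent])  # type: ignore[arg-type]
        else:
            level = name[len(parent) + 1 : -1]
            row[j] = 1.0 if pattern[parent] == level else 0.0
    return row


def censored_loglik(
    beta: np.ndarray,
    tau: float,
    design: DesignMatrix | np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
) -> float:
    """Right-censored Gumbel-minimum log-likelihood on the log-time scale.

    With z_i = (log t_i - x_i' beta) / sigma, sigma = exp(tau), returns
    sum_i [ delta_i (-tau + z_i - e^{z_i}) + (1 - delta_i)(-e^{z_i}) ]:
    deaths contribute the log-density, censored records the log-survival.
    """
    X = design.matrix if isinstance(design, DesignMatrix) else np.asarray(design)
    beta = np.asarray(beta, dtype=float)
    sigma = np.exp(tau)
    z = (np.log(times) - X @ beta) / sigma
    clipped = np.minimum(z, _Z_CLIP)
    if np.any(z > _Z_CLIP):
        logger.debug("censored_loglik: clipped %d z-values at %g", int((z > _Z_CLIP).sum()), _Z_CLIP)
    ez = np.exp(clipped)
    ll = float(np.sum(events * (-tau + z) - ez))
    if not np.isfinite(ll):
        raise FloatingPointError("censored log-likelihood is not finite")
    return ll


def _loglik_and_grad(theta, X, logt, events, fixed_tau):
    """(negative loglik, gradient) over the free parameters."""
    if fixed_tau is None:
        beta, tau = theta[:-1], theta[-1]
    else:
        beta, tau = theta, fixed_tau
    sigma = np.exp(tau)
    z = (logt - X @ beta) / sigma
    ez = np.exp(np.minimum(z, _Z_CLIP))
    ll = np.sum(events * (-tau + z) - ez)
    w = events - ez  # d loglik / d z_i times sigma... see below
    grad_beta = -(X.T @ w) / sigma
    if fixed_tau is None:
        grad_tau = np.sum(-events - z * w)
        grad = np.concatenate([grad_beta, [grad_tau]])
    else:
        grad = grad_beta
    return -ll, -grad


def _numerical_hessian(fun, theta, step_scale=1e-5):
    """Central-difference Hessian with per-parameter step 1e-5 * (1 + |theta_k|)."""
    p = len(theta)
    steps = step_scale * (1.0 + np.abs(theta))
    hess = np.zeros((p, p))
    for i in range(p):
        for j in range(i, p):
            hi, hj = steps[i], steps[j]
            tpp = theta.copy(); tpp[i] += hi; tpp[j] += hj
            tpm = theta.copy(); tpm[i] += hi; tpm[j] -= hj
            tmp = theta.copy(); tmp[i] -= hi; tmp[j] += hj
            tmm = theta.copy(); tmm[i] -= hi; tmm[j] -= hj
            hess[i, j] = hess[j, i] = (fun(tpp) - fun(tpm) - fun(tmp) + fun(tmm)) / (4 * hi * hj)
    return hess


@dataclass
class WeibullAFTFit:
    """Fitted censored Weibull AFT regression.

    ``beta`` lives on the log-time scale; ``sigma = exp(tau)`` is the
    Gumbel scale and ``gamma = 1/sigma`` the Weibull shape.  ``covariance``
    covers the free parameters (beta, tau) from the inverse observed
    information; fits built directly from published coefficients carry NaN
    uncertainty.
    """

    beta: pd.Series
    tau: float
    covariance: pd.DataFrame | None
    loglik: float
    design: DesignMatrix = field(repr=False)
    n: int = 0
    n_events: int = 0
    fixed_scale: float | None = None
    converged: bool = True
    boundary: bool = False

    @property
    def sigma(self) -> float:
        return float(np.exp(self.tau))

    @property
    def gamma(self) -> float:
        return 1.0 / self.sigma

    @property
    def parameter_names(self) -> list[str]:
        names = list(self.beta.index)
        if self.fixed_scale is None:
            names.append("tau")
        return names

    @property
    def n_free_parameters(self) -> int:
        return len(self.parameter_names)

    @property
    def standard_errors(self) -> pd.Series:
        if self.covariance is None:
            return pd.Series(np.nan, index=self.parameter_names)
        return pd.Series(np.sqrt(np.diag(self.covariance)), index=self.covariance.index)

    @property
    def wald_p(self) -> pd.Series:
        """Two-sided normal-reference p-values for each free parameter."""
        est = pd.Series(
            list(self.beta) + ([] if self.fixed_scale is not None else [self.tau]),
            index=self.parameter_names,
        )
        se = self.standard_errors
        z = est / se
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=est.index)

    def summary(self) -> pd.DataFrame:
        se = self.standard_errors
        p = self.wald_p
        est = pd.Series(
            list(self.beta) + ([] if self.fixed_scale is not None else [self.tau]),
            index=self.parameter_names,
        )
        return pd.DataFrame({"estimate": est, "std_error": se, "p_value": p})

    def linear_predictor(self, covariates: Mapping[str, object]) -> float:
        row = encode_pattern(self.design, covariates)
        return float(row @ self.beta.to_numpy())

    @classmethod
    def from_parameters(
        cls,
        coefficients: Mapping[str, float],
        sigma: float,
        schema: CovariateSchema,
        covariates: Sequence[str] | None = None,
    ) -> "WeibullAFTFit":
        """Assemble a fit from externally given coefficients (no uncertainty).

        Useful for scoring published model tables; coefficient keys must use
        design-column names (``intercept``, ``age``, ``protocol[fast-track]``).
        """
        use = tuple(covariates) if covariates is not None else schema.names
        names = [INTERCEPT]
        parents: list[str | None] = [None]
        for name in schema.names:
            if name not in use:
                continue
            if schema.is_numeric(name):
                names.append(column_name(name))
                parents.append(name)
            else:
                for level in schema.levels(name)[1:]:
                    names.append(column_name(name, level))
                    parents.append(name)
        unknown = set(coefficients) - set(names)
        if unknown:
            raise CohortError(f"unknown coefficient name(s) {sorted(unknown)}")
        beta = pd.Series([float(coefficients.get(nm, 0.0)) for nm in names], index=names)
        design = DesignMatrix(
            matrix=np.ones((0, len(names))),
            column_names=names,
            covariate_of=parents,
            schema=schema,
            covariates_used=use,
        )
        return cls(
            beta=beta,
            tau=float(np.log(sigma)),
            covariance=None,
            loglik=np.nan,
            design=design,
        )


def _check_full_rank(design: DesignMatrix) -> None:
    X = design.matrix
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns involved in the deficiency via QR pivoting
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = [design.column_names[j] for j in np.flatnonzero(diag < 1e-8 * max(diag.max(), 1.0))]
        raise CohortError(f"design matrix is rank deficient; collinear column(s): {bad or 'unknown'}")


def fit_weibull_aft(
    data: CohortDataset,
    covariates: Sequence[str] | None = None,
    init: np.ndarray | None = None,
    tol: float = 1e-8,
    fix_scale: float | None = None,
    max_iter: int = 500,
) -> WeibullAFTFit:
    """Maximum-likelihood censored Weibull AFT fit.

    Optimizes the censored Gumbel-minimum log-likelihood over
    (beta, tau = log sigma); ``fix_scale`` pins sigma (1.0 gives the
    censored-exponential sub-model).  Initialization: least squares of
    log t on the design (censored records included as-is), tau = 0.
    ``tol`` is the gradient-norm convergence criterion.
    """
    design = build_design_matrix(data, covariates)
    _check_full_rank(design)
    if data.n_events == 0:
        raise CohortError("cannot fit: the cohort contains no deaths")

    X = design.matrix
    logt = np.log(data.times)
    events = data.events.astype(float)
    p = X.shape[1]
    fixed_tau = None if fix_scale is None else float(np.log(fix_scale))

    if init is not None:
        theta0 = np.asarray(init, dtype=float)
    else:
        beta0 = np.linalg.lstsq(X, logt, rcond=None)[0]
        theta0 = beta0 if fixed_tau is not None else np.concatenate([beta0, [0.0]])

    def objective(theta):
        return _loglik_and_grad(theta, X, logt, events, fixed_tau)

    bounds = None
    if fixed_tau is None:
        bounds = [(None, None)] * p + [_TAU_BOUNDS]
    result = optimize.minimize(
        objective,
        theta0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-12},
    )
    theta = result.x

    # Newton polish: converge on gradient norm or on the Newton decrement
    # g' H^-1 g (the attainable log-likelihood gain, robust to float noise)
    def negll(th):
        return objective(th)[0]

    converged = False
    for _ in range(60):
        f, g = objective(theta)
        if np.linalg.norm(g) <= tol * (1.0 + abs(f)):
            converged = True
            break
        H = _numerical_hessian(negll, theta)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        decrement = float(g @ step)
        if 0.0 <= decrement < 1e-12 * (1.0 + abs(f)):
            converged = True
            break
        alpha = 1.0
        accepted = False
        for _ in range(40):
            candidate = theta - alpha * step
            if fixed_tau is None:
                candidate[-1] = np.clip(candidate[-1], *_TAU_BOUNDS)
            try:
                f_new = negll(candidate)
            except FloatingPointError:
                f_new = np.inf
            if f_new <= f + 1e-12 * (1.0 + abs(f)):
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            break
        theta = candidate

    f, g = objective(theta)
    tau = fixed_tau if fixed_tau is not None else float(theta[-1])
    boundary = fixed_tau is None and (
        tau <= _TAU_BOUNDS[0] + 1e-6 or tau >= _TAU_BOUNDS[1] - 1e-6
    )
    grad_norm = float(np.linalg.norm(g))
    converged = converged or grad_norm <= max(tol * (1.0 + abs(f)), 1e-5)
    if not converged and not boundary:
        raise ConvergenceError(
            f"Weibull AFT fit did not converge (gradient norm {grad_norm:.3g})",
            last_state=theta,
        )
    if boundary:
        logger.warning(
            "scale parameter hit its optimization boundary (tau=%.3f); "
            "the data may be degenerate (e.g. all times equal)",
            tau,
        )

    beta = theta[:p] if fixed_tau is None else theta
    loglik = censored_loglik(beta, tau, design, data.times, data.events)

    covariance = None
    if not boundary:
        H = _numerical_hessian(negll, theta)  # Hessian of the NEGATIVE loglik
        try:
            cov = np.linalg.inv(H)
            if np.any(np.diag(cov) <= 0):
                raise np.linalg.LinAlgError
            names = design.column_names + ([] if fixed_tau is not None else ["tau"])
            covariance = pd.DataFrame(cov, index=names, columns=names)
        except np.linalg.LinAlgError:
            logger.warning("observed information not invertible; standard errors unavailable")

    return WeibullAFTFit(
        beta=pd.Series(beta, index=design.column_names),
        tau=tau,
        covariance=covariance,
        loglik=loglik,
        design=design,
        n=len(data),
        n_events=data.n_events,
        fixed_scale=fix_scale,
        converged=converged,
        boundary=boundary,
    )


def likelihood_ratio_test(full: WeibullAFTFit, nested: WeibullAFTFit) -> TestResult:
    """LR test for nested fits: 2 (ll_full - ll_nested) ~ chi-square(df).

    ``df`` is the free-parameter count difference; supports the
    exponential-vs-Weibull comparison (nested fit with sigma fixed at 1).
    """
    if not set(nested.beta.index) <= set(full.beta.index):
        raise CohortError("nested model's coefficients are not a subset of the full model's")
    df = full.n_free_parameters - nested.n_free_parameters
    if df < 0:
        raise CohortError("nested model has more free parameters than the full model")
    statistic = 2.0 * (full.loglik - nested.loglik)
    if statistic < -1e-6 * (1.0 + abs(full.loglik)):
        raise ConvergenceError(
            f"full-model log-likelihood ({full.loglik:.6f}) is below the nested one "
            f"({nested.loglik:.6f}): optimization failure"
        )
    statistic = max(statistic, 0.0)
    if df == 0:
        return TestResult(statistic=statistic, df=0, p_value=1.0)
    return TestResult(statistic=statistic, df=df)


def predict_time(
    fit: WeibullAFTFit, covariates: Mapping[str, object], quantile: float | None = None
) -> float:
    """Predicted stay length exp(x' beta) for a covariate pattern (hours).

    The default is the Weibull characteristic life exp(x' beta); pass
    ``quantile=q`` for the model q-quantile exp(x' beta) (-log(1-q))^sigma
    (``q=0.5`` gives the median).
    """
    mu = fit.linear_predictor(covariates)
    if quantile is None:
        return float(np.exp(mu))
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must lie in (0, 1)")
    return float(np.exp(mu) * (-np.log1p(-quantile)) ** fit.sigma)


def median_time_ratio(fit: WeibullAFTFit, coefficient: str) -> float:
    """exp(beta_j): multiplicative change in median (any quantile) time.

    For a unit increase of a numeric covariate or switching an indicator on,
    every quantile of the survival-time distribution scales by exp(beta_j).
    """
    if coefficient not in fit.beta.index:
        raise CohortError(f"unknown coefficient {coefficient!r}")
    return float(np.exp(fit.beta[coefficient]))


@dataclass
class ResidualSet:
    """Cox–Snell, martingale and deviance residuals of an AFT fit."""

    cox_snell: np.ndarray
    martingale: np.ndarray
    deviance: np.ndarray
    events: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cox_snell": self.cox_snell,
                "martingale": self.martingale,
                "deviance": self.deviance,
                "event": self.events,
            }
        )


def residuals(fit: WeibullAFTFit, data: CohortDataset) -> ResidualSet:
    """Residual triple for every record.

    Cox–Snell: e_i = (t_i exp(-mu_i))^{1/sigma}, with +1 added for censored
    records so they can be treated as uncensored exponential draws.
    Martingale: m_i = delta_i - e_i (censored records thus fall at or below
    -1).  Deviance: sign(m_i) sqrt(-2 (m_i + delta_i log(delta_i - m_i))),
    with the log term dropped when delta_i = 0.
    """
    design = build_design_matrix(data, fit.design.covariates_used)
    if design.column_names != fit.design.column_names:
        raise CohortError("dataset schema is incompatible with the fitted design")
    mu = design.matrix @ fit.beta.to_numpy()
    base = (data.times * np.exp(-mu)) ** (1.0 / fit.sigma)
    delta = data.events.astype(float)
    cox_snell = base + (1.0 - delta)  # +1 adjustment for censored records
    martingale = delta - cox_snell
    inner = delta - martingale  # equals the (adjusted) Cox–Snell residual
    if np.any((delta == 1) & (inner <= 0)):
        raise RuntimeError("internal inconsistency: nonpositive Cox–Snell at a death")
    log_term = np.where(delta == 1, delta * np.log(np.where(inner > 0, inner, 1.0)), 0.0)
    deviance = np.sign(martingale) * np.sqrt(-2.0 * (martingale + log_term))
    return ResidualSet(cox_snell, martingale, deviance, data.events.copy())


@dataclass
class GoodnessOfFitCurve:
    """KM survival of Cox–Snell residuals next to the unit-exponential reference."""

    km: StepEstimate
    reference: np.ndarray  # exp(-e) at the KM step times

    def max_discrepancy(self) -> float:
        if self.km.times.size == 0:
            return 0.0
        return float(np.max(np.abs(self.km.values - self.reference)))


def cox_snell_gof(resid: ResidualSet, events: np.ndarray | None = None) -> GoodnessOfFitCurve:
    """Goodness-of-fit check: Cox–Snell residuals vs. standard exponential.

    If the model fits, the residuals (with their original censoring status)
    behave like a unit-exponential sample, so their KM survival curve should
    track exp(-e).  Returns both curves on the KM step grid.
    """
    ev = resid.events if events is None else np.asarray(events)
    km = _km_arrays(np.asarray(resid.cox_snell, dtype=float), ev.astype(np.int8))
    return GoodnessOfFitCurve(km=km, reference=np.exp(-km.times))


def case_deletion_refit(
    data: CohortDataset,
    deletion_sets: Iterable[Iterable[int]],
    covariates: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Confirmatory influence analysis: refit after deleting record sets.

    One row per deletion set (the empty set reproduces the full fit), with
    each coefficient estimate and Wald p-value, plus ``significance_changed``
    flagging any coefficient crossing the ``alpha`` threshold relative to
    the full fit.  Record indices are 0-based positions in ``data``.
    """
    full = fit_weibull_aft(data, covariates)
    full_sig = full.wald_p < alpha
    rows = []
    index = []
    for dropset in deletion_sets:
        drop = sorted(int(i) for i in dropset)
        label = "{}" if not drop else "{" + ",".join(f"#{i}" for i in drop) + "}"
        subset = data if not drop else data.drop(drop)
        if subset.n_events == 0:
            raise CohortError(f"deletion set {label} leaves no deaths")
        try:
            fit = full if not drop else fit_weibull_aft(subset, covariates)
        except CohortError as exc:
            raise CohortError(f"deletion set {label}: {exc}") from exc
        row: dict[str, float | bool] = {}
        for name in fit.parameter_names:
            est = fit.beta[name] if name in fit.beta.index else fit.tau
            row[name] = float(est)
            row[f"p[{name}]"] = float(fit.wald_p[name])
        row["significance_changed"] = bool(((fit.wald_p < alpha) != full_sig).any())
        rows.append(row)
        index.append(label)
    return pd.DataFrame(rows, index=index)
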