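"""Coefficient estimation from used-available and case-control data.

Three estimators are provided, all returning a :class:`FitResult`:

``fit_rsf_logistic``
    The standard used-available trick: a binomial GLM (logistic link,
    fitted by IRLS) of the used/available indicator on the expanded
    design matrix.  Its slope estimates are consistent for the
    exponential-RSF selection coefficients; the intercept absorbs the
    sampling fractions and the non-identifiable normalising constant and
    is therefore excluded from the reported parameter table.

``fit_weighted_ml``
    The weighted-distribution maximum likelihood for used-available
    data: the availability sample is treated as an i.i.d. draw from the
    availability distribution, and the used sample as draws tilted by
    the selection function, giving

        l(theta) = sum_used ln w(x_i) - n_used * ln( mean_avail w(x_j) ).

    For the exponential form the intercept cancels from this likelihood
    and is not estimated; for the logistic RSPF the intercept is a real,
    identifiable parameter.  AIC values from two such fits on the same
    data (e.g. exponential vs logistic) are mutually comparable.

``fit_conditional_logistic``
    Step-selection (case-control) estimation: each stratum contains one
    used step and its matched available steps, and the conditional
    likelihood sum_s [eta_used - ln sum_{j in s} exp(eta_j)] is
    maximised by Newton-Raphson with step-halving.

Standard errors come from the inverse observed information; Wald
z = estimate / SE with two-sided normal p-values, unadjusted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
from scipy.special import expit, log_expit, logsumexp
from scipy.stats import norm

from .errors import EstimationError, InputError, NumericalError
from .model import ModelSpec, design_matrix

__all__ = [
    "UsedAvailableTable",
    "FitResult",
    "fit_rsf_logistic",
    "fit_weighted_ml",
    "fit_conditional_logistic",
    "summary_table",
]

# Convergence controls shared by the in-house optimisers.
MAX_ITER = 100
LL_RTOL = 1e-10
GRAD_TOL = 1e-8
SEPARATION_BOUND = 15.0  # |beta| on the standardised scale beyond which the
# binomial likelihood is flat to machine precision


@dataclass
class UsedAvailableTable:
    """Rows of covariate values with a used flag and optional stratum id.

    Backed by a :class:`pandas.DataFrame` with a ``used`` column of 0/1,
    an optional ``stratum`` column, an optional ``point_id`` column, and
    the remaining columns treated as numeric covariates.
    """

    data: pd.DataFrame

    RESERVED = ("used", "stratum", "point_id")

    def __post_init__(self) -> None:
        df = self.data
        if "used" not in df.columns:
            raise InputError("table is missing the required 'used' column")
        used = df["used"].to_numpy()
        bad = ~np.isin(used, (0, 1, True, False))
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise InputError(f"'used' must be 0/1; bad value at row {row + 1}")
        for col in df.columns:
            if col in ("stratum", "point_id"):
                continue
            values = pd.to_numeric(df[col], errors="coerce")
            nan_new = values.isna() & df[col].notna()
            if nan_new.any():
                row = int(np.flatnonzero(nan_new.to_numpy())[0])
                raise InputError(
                    f"non-numeric value in covariate column '{col}' at row {row + 1}"
                )
            if values.isna().any():
                row = int(np.flatnonzero(values.isna().to_numpy())[0])
                raise InputError(f"missing value in column '{col}' at row {row + 1}")
        self.data = df.reset_index(drop=True)

    @property
    def covariate_names(self) -> tuple[str, ...]:
        return tuple(c for c in self.data.columns if c not in self.RESERVED)

    @property
    def used_mask(self) -> np.ndarray:
        return self.data["used"].to_numpy().astype(bool)

    @property
    def n_used(self) -> int:
        return int(self.used_mask.sum())

    @property
    def n_avail(self) -> int:
        return int((~self.used_mask).sum())

    @property
    def has_strata(self) -> bool:
        return "stratum" in self.data.columns

    def used_rows(self) -> pd.DataFrame:
        return self.data[self.used_mask]

    def available_rows(self) -> pd.DataFrame:
        return self.data[~self.used_mask]

    def validate_for_fitting(self) -> None:
        if self.n_used < 1 or self.n_avail < 1:
            raise InputError(
                f"fitting needs at least one used and one available row "
                f"(got {self.n_used} used, {self.n_avail} available)"
            )

    def validate_strata(self) -> None:
        if not self.has_strata:
            raise InputError("table has no 'stratum' column")
        used = self.used_mask.astype(int)
        counts = pd.Series(used).groupby(self.data["stratum"]).agg(["sum", "size"])
        bad = counts[counts["sum"] != 1]
        if len(bad):
            sid = bad.index[0]
            raise InputError(
                f"stratum {sid!r} has {int(bad['sum'].iloc[0])} used rows; "
                "each stratum needs exactly one"
            )
        if (counts["size"] < 2).any():
            sid = counts.index[counts["size"] < 2][0]
            raise InputError(f"stratum {sid!r} has no available rows")


@dataclass
class FitResult:
    """Estimates, uncertainty and diagnostics from one model fit.

    ``params``/``se``/``vcov`` cover the identifiable parameter vector in
    the order of ``param_names`` (intercept first when it is a real
    parameter, i.e. for the logistic RSPF).  For exponential-form GLM
    fits the intercept is stored on ``model.intercept`` with its SE in
    ``intercept_se`` but flagged non-identifiable and kept out of the
    parameter table.
    """

    model: ModelSpec
    param_names: tuple[str, ...]
    params: np.ndarray
    se: np.ndarray
    vcov: np.ndarray
    loglik: float
    aic: float
    n_used: int
    n_avail: int
    estimator: str
    converged: bool
    iterations: int
    intercept_se: float | None = None
    intercept_identifiable: bool = False
    warnings: list[str] = field(default_factory=list)
    loglik_path: tuple[float, ...] = ()

    @property
    def z(self) -> np.ndarray:
        return self.params / self.se

    @property
    def p_values(self) -> np.ndarray:
        return 2.0 * norm.sf(np.abs(self.z))


def _check_full_rank(X: np.ndarray, labels: list[str]) -> None:
    """Raise naming the offending columns if X is rank deficient."""
    if X.shape[1] == 0:
        raise InputError("empty design matrix (no terms)")
    norms = np.linalg.norm(X, axis=0)
    zero = norms < 1e-12
    if zero.any():
        bad = [labels[i] for i in np.flatnonzero(zero)]
        raise EstimationError(f"inestimable (identically zero) terms: {bad}")
    Xs = X / norms
    _, r, piv = scipy.linalg.qr(Xs, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag[0] * max(X.shape) * np.finfo(float).eps * 100
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        bad = [labels[i] for i in piv[rank:]]
        raise EstimationError(
            f"design matrix is rank deficient; collinear or constant terms: {sorted(bad)}"
        )


def fit_rsf_logistic(
    data: UsedAvailableTable,
    spec: ModelSpec,
    *,
    separation_bound: float = SEPARATION_BOUND,
) -> FitResult:
    """Exponential-RSF slopes via the used-available binomial GLM (IRLS)."""
    import statsmodels.api as sm

    if spec.form != "exponential":
        raise InputError("fit_rsf_logistic estimates exponential-form models")
    data.validate_for_fitting()
    df = data.data
    T = design_matrix(spec, df)
    labels = list(spec.term_labels)
    X = np.column_stack([np.ones(len(df)), T])
    _check_full_rank(X, ["(intercept)"] + labels)
    y = data.used_mask.astype(float)

    glm = sm.GLM(y, X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = glm.fit(maxiter=MAX_ITER, tol=LL_RTOL)

    params = np.asarray(res.params)
    cov = np.asarray(res.cov_params())
    beta = params[1:]
    fit_warnings: list[str] = []
    sd = T.std(axis=0)
    sep = np.abs(beta) * np.where(sd > 0, sd, 1.0) > separation_bound
    if sep.any():
        names = [labels[i] for i in np.flatnonzero(sep)]
        fit_warnings.append(
            f"possible quasi-complete separation (standardised |beta| > "
            f"{separation_bound:g}): {names}"
        )
    converged = bool(getattr(res, "converged", True))
    iterations = len(res.fit_history.get("deviance", [])) if res.fit_history else 0

    model = spec.with_beta(beta)
    model.intercept = float(params[0])
    return FitResult(
        model=model,
        param_names=tuple(labels),
        params=beta,
        se=np.sqrt(np.diag(cov))[1:],
        vcov=cov[1:, 1:],
        loglik=float(res.llf),
        aic=float(res.aic),
        n_used=data.n_used,
        n_avail=data.n_avail,
        estimator="logistic_glm",
        converged=converged,
        iterations=iterations,
        intercept_se=float(np.sqrt(cov[0, 0])),
        intercept_identifiable=False,
        warnings=fit_warnings,
    )


def _weighted_ml_negloglik(theta, Xu, Xa, n_used, logistic):
    """Negative weighted-distribution log-likelihood and its gradient."""
    if logistic:
        b0, beta = theta[0], theta[1:]
        zu = b0 + Xu @ beta
        za = b0 + Xa @ beta
        wu_log = log_expit(zu)
        wa = expit(za)
        sum_wa = wa.sum()
        if sum_wa <= 0.0:
            raise NumericalError("all availability weights underflowed to zero")
        ll = wu_log.sum() - n_used * (np.log(sum_wa) - np.log(len(za)))
        Xu1 = np.column_stack([np.ones(len(Xu)), Xu])
        Xa1 = np.column_stack([np.ones(len(Xa)), Xa])
        gu = Xu1.T @ (1.0 - expit(zu))
        ga = Xa1.T @ (wa * (1.0 - wa)) / sum_wa
        grad = gu - n_used * ga
    else:
        eta_u = Xu @ theta
        eta_a = Xa @ theta
        lse = logsumexp(eta_a)
        ll = eta_u.sum() - n_used * (lse - np.log(len(eta_a)))
        p = np.exp(eta_a - lse)
        grad = Xu.sum(axis=0) - n_used * (Xa.T @ p)
    return -ll, -grad


def _numeric_information(fun_grad, theta, args) -> np.ndarray:
    """Observed information (Hessian of the negative log-likelihood) by
    central differences of the analytic gradient."""
    k = len(theta)
    H = np.empty((k, k))
    for i in range(k):
        h = 1e-5 * (1.0 + abs(theta[i]))
        tp = theta.copy()
        tp[i] += h
        tm = theta.copy()
        tm[i] -= h
        _, gp = fun_grad(tp, *args)
        _, gm = fun_grad(tm, *args)
        H[i] = (gp - gm) / (2.0 * h)
    return 0.5 * (H + H.T)


def fit_weighted_ml(data: UsedAvailableTable, spec: ModelSpec) -> FitResult:
    """Weighted-distribution maximum likelihood for RSF/RSPF models."""
    data.validate_for_fitting()
    logistic = spec.form == "logistic"
    df = data.data
    T = design_matrix(spec, df)
    labels = list(spec.term_labels)
    if logistic:
        _check_full_rank(
            np.column_stack([np.ones(len(df)), T]), ["(intercept)"] + labels
        )
    else:
        _check_full_rank(T, labels)
    used = data.used_mask
    Xu, Xa = T[used], T[~used]
    n_used = used.sum()

    k = T.shape[1] + (1 if logistic else 0)
    theta0 = np.zeros(k)
    args = (Xu, Xa, n_used, logistic)
    res = scipy.optimize.minimize(
        _weighted_ml_negloglik,
        theta0,
        args=args,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-13, "gtol": 1e-9},
    )
    theta = res.x
    negll, grad = _weighted_ml_negloglik(theta, *args)
    converged = bool(res.success) or float(np.max(np.abs(grad))) < 1e-5

    info = _numeric_information(_weighted_ml_negloglik, theta, args)
    fit_warnings: list[str] = []
    try:
        vcov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        vcov = np.linalg.pinv(info)
        fit_warnings.append("observed information is singular; vcov is a pseudo-inverse")
    diag = np.diag(vcov).copy()
    if (diag < 0).any():
        fit_warnings.append("negative variance estimates truncated to zero")
        diag = np.maximum(diag, 0.0)
    se = np.sqrt(diag)

    loglik = -float(negll)
    aic = 2.0 * k - 2.0 * loglik
    if logistic:
        model = spec.with_beta(theta[1:], intercept=theta[0])
        names = ("(intercept)",) + tuple(labels)
        intercept_se = float(se[0])
    else:
        model = spec.with_beta(theta)
        names = tuple(labels)
        intercept_se = None
    return FitResult(
        model=model,
        param_names=names,
        params=theta,
        se=se,
        vcov=vcov,
        loglik=loglik,
        aic=aic,
        n_used=int(n_used),
        n_avail=data.n_avail,
        estimator="weighted_ml",
        converged=converged,
        iterations=int(res.nit),
        intercept_se=intercept_se,
        intercept_identifiable=logistic,
        warnings=fit_warnings,
    )


def fit_conditional_logistic(data: UsedAvailableTable, spec: ModelSpec) -> FitResult:
    """Conditional logistic regression over strata (step-selection fits).

    Newton-Raphson with step-halving on the stratified conditional
    likelihood; no intercept (it cancels within strata).
    """
    if spec.form != "exponential":
        raise InputError("fit_conditional_logistic estimates exponential-form models")
    data.validate_for_fitting()
    data.validate_strata()
    df = data.data
    codes, _ = pd.factorize(df["stratum"], sort=True)
    order = np.argsort(codes, kind="stable")
    codes = codes[order]
    X = design_matrix(spec, df)[order]
    y = data.used_mask[order]
    labels = list(spec.term_labels)

    n_strata = codes.max() + 1
    starts = np.searchsorted(codes, np.arange(n_strata))
    # within-stratum centred design: columns with no contrast are inestimable
    group_sums = np.add.reduceat(X, starts, axis=0)
    group_sizes = np.add.reduceat(np.ones(len(X)), starts)
    Xc = X - (group_sums / group_sizes[:, None])[codes]
    flat = np.max(np.abs(Xc), axis=0) < 1e-12
    if flat.any():
        bad = [labels[i] for i in np.flatnonzero(flat)]
        raise EstimationError(
            f"no within-stratum variation for terms {bad}; "
            "the conditional likelihood is flat"
        )
    _check_full_rank(Xc, labels)

    used_idx = np.flatnonzero(y)
    k = X.shape[1]
    beta = np.zeros(k)

    def loglik_parts(b):
        eta = X @ b
        m = np.maximum.reduceat(eta, starts)
        e = np.exp(eta - m[codes])
        denom = np.add.reduceat(e, starts)
        ll = float(eta[used_idx].sum() - (m + np.log(denom)).sum())
        p = e / denom[codes]
        return ll, p

    ll, p = loglik_parts(beta)
    path = [ll]
    converged = False
    iterations = 0
    for iterations in range(1, MAX_ITER + 1):
        S = np.add.reduceat(X * p[:, None], starts, axis=0)  # per-stratum E[x]
        grad = X[used_idx].sum(axis=0) - S.sum(axis=0)
        info = (X * p[:, None]).T @ X - S.T @ S  # observed information
        try:
            delta = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            raise EstimationError("singular information matrix in conditional fit")
        step = 1.0
        for _ in range(40):
            new_beta = beta + step * delta
            new_ll, new_p = loglik_parts(new_beta)
            if new_ll >= ll - 1e-12:
                break
            step *= 0.5
        else:
            break
        beta, p = new_beta, new_p
        path.append(new_ll)
        rel = abs(new_ll - ll) / (abs(ll) + 1.0)
        ll = new_ll
        if rel < LL_RTOL or np.max(np.abs(grad)) < GRAD_TOL:
            converged = True
            break

    S = np.add.reduceat(X * p[:, None], starts, axis=0)
    info = (X * p[:, None]).T @ X - S.T @ S
    vcov = np.linalg.inv(info)
    se = np.sqrt(np.diag(vcov))
    aic = 2.0 * k - 2.0 * ll
    model = spec.with_beta(beta)
    return FitResult(
        model=model,
        param_names=tuple(labels),
        params=beta,
        se=se,
        vcov=vcov,
        loglik=ll,
        aic=aic,
        n_used=data.n_used,
        n_avail=data.n_avail,
        estimator="conditional_logistic",
        converged=converged,
        iterations=iterations,
        loglik_path=tuple(path),
    )


def summary_table(fit: FitResult) -> pd.DataFrame:
    """Parameter table: term, estimate, SE, Wald z, two-sided p."""
    if not fit.converged:
        raise NumericalError("fit did not converge; no summary table")
    return pd.DataFrame(
        {
            "term": list(fit.param_names),
            "estimate": fit.params,
            "se": fit.se,
            "z": fit.z,
            "p": fit.p_values,
        }
    )
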