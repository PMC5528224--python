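"""Average-effect and preference curves.

The conditional RSS answers "what if one covariate changes and nothing
else does".  To describe the *average* change in space use across a
study area, the average-effect curve evaluates the fitted selection
weight w at every available location, pairs it with the focal
covariate's value there, and smooths the scatter with a Nadaraya-Watson
kernel regression.  Each point on the curve is the average fitted
w (probability of use for a logistic RSPF; relative probability for an
exponential RSF) at a given focal value, averaged over the availability
distribution of every other covariate — so the curve changes when the
availability distribution changes, even with coefficients held fixed.

A preference curve is the same construction under an artificial uniform
availability distribution over resource *types*: every covariate is
given a uniform grid over its range, which makes use and selection
coincide and isolates the selection mechanism itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .errors import InputError
from .fitting import FitResult, UsedAvailableTable
from .model import ModelSpec, evaluate_w_array

__all__ = [
    "EffectCurve",
    "CIConfig",
    "nadaraya_watson",
    "average_effect_curve",
    "preference_curve",
    "plot_curve",
]

# R's ksmooth convention: kernels are scaled so that their quartiles sit
# at +/- 0.25 * bandwidth.  For the normal kernel sd = 0.25/qnorm(0.75).
KSMOOTH_NORMAL_SD = 0.25 / ndtri(0.75)  # 0.3706506...
DEFAULT_BANDWIDTH_FRACTION = 0.2
DEFAULT_GRID_SIZE = 100


def nadaraya_watson(x, y, query, bandwidth, kernel: str = "normal") -> np.ndarray:
    """Kernel-weighted local average of y at the query points.

    Kernels follow the ksmooth scaling: ``normal`` uses a Gaussian with
    sd = 0.3706506 * bandwidth; ``box`` averages over
    |x - q| <= 0.5 * bandwidth.  Query points where every kernel weight
    is zero (possible with the box kernel) return NaN with a warning
    rather than a silent 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    query = np.atleast_1d(np.asarray(query, dtype=float))
    if x.shape != y.shape or x.ndim != 1 or x.size < 1:
        raise InputError("x and y must be equal-length 1-D arrays with >= 1 point")
    if not bandwidth > 0:
        raise InputError("bandwidth must be positive")
    d = query[:, None] - x[None, :]
    if kernel == "normal":
        s = KSMOOTH_NORMAL_SD * bandwidth
        logK = -0.5 * (d / s) ** 2
        # NW is invariant to per-query weight scaling; shifting by the row
        # max keeps far-from-data queries from underflowing to 0/0
        K = np.exp(logK - logK.max(axis=1, keepdims=True))
    elif kernel == "box":
        K = (np.abs(d) <= 0.5 * bandwidth).astype(float)
    else:
        raise InputError(f"unknown kernel {kernel!r}; expected 'normal' or 'box'")
    den = K.sum(axis=1)
    empty = den == 0
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} query point(s) have an empty smoothing window; "
            "returning NaN there",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (K @ y) / den
    out[empty] = np.nan
    return out


def _running_quantile(x, y, query, bandwidth, q) -> np.ndarray:
    out = np.empty(len(query))
    for i, g in enumerate(query):
        sel = np.abs(x - g) <= 0.5 * bandwidth
        if not sel.any():
            out[i] = np.nan
        else:
            out[i] = np.quantile(y[sel], q)
    if np.isnan(out).any():
        warnings.warn(
            "some query points have an empty quantile window; returning NaN there",
            RuntimeWarning,
            stacklevel=2,
        )
    return out


@dataclass(frozen=True)
class CIConfig:
    """Bootstrap confidence-band settings.

    ``method='rows'`` resamples availability rows with replacement
    (nonparametric bootstrap); ``method='beta'`` instead draws
    coefficient vectors from the fit's asymptotic normal and requires
    the curve to be built from a :class:`FitResult`.
    """

    level: float = 0.95
    n_boot: int = 500
    seed: int | None = None
    method: str = "rows"

    def __post_init__(self) -> None:
        if not 0 < self.level < 1:
            raise InputError("CI level must be in (0, 1)")
        if self.n_boot < 2:
            raise InputError("n_boot must be >= 2")
        if self.seed is None:
            raise InputError("bootstrap confidence bands require a seed")
        if self.method not in ("rows", "beta"):
            raise InputError("CI method must be 'rows' or 'beta'")


@dataclass
class EffectCurve:
    """A smoothed average-effect (or preference) curve.

    ``relative`` is True for exponential-form models, whose curve is a
    *relative* probability of use; logistic curves are absolute
    probabilities and stay in [0, 1].
    """

    focal: str
    grid: np.ndarray
    estimate: np.ndarray
    lower: np.ndarray | None
    upper: np.ndarray | None
    statistic: str
    n_points: int
    relative: bool
    kind: str = "average_effect"  # or "preference"

    def to_frame(self) -> pd.DataFrame:
        cols = {self.focal: self.grid, "estimate": self.estimate}
        if self.lower is not None:
            cols["lower"] = self.lower
            cols["upper"] = self.upper
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _curve_values(w, x, grid, bandwidth, statistic, q):
    if statistic == "mean":
        return nadaraya_watson(x, w, grid, bandwidth, kernel="normal")
    if statistic == "quantile":
        return _running_quantile(x, w, grid, bandwidth, q)
    raise InputError(f"unknown statistic {statistic!r}; expected 'mean' or 'quantile'")


def average_effect_curve(
    model,
    availability: UsedAvailableTable,
    focal: str,
    *,
    grid_size: int = DEFAULT_GRID_SIZE,
    bandwidth: float | None = None,
    statistic: str = "mean",
    q: float | None = None,
    ci: CIConfig | None = None,
) -> EffectCurve:
    """Smoothed average fitted selection weight against one covariate.

    Steps: evaluate w at every available location; pair each value with
    the focal covariate there; smooth the pairs over an equally spaced
    grid spanning the focal covariate's observed range (Nadaraya-Watson
    for ``statistic='mean'``; a running quantile in a sliding window of
    width ``bandwidth`` for ``statistic='quantile'`` with ``q``).

    ``model`` may be a :class:`ModelSpec` with coefficients or a
    :class:`FitResult` (required for ``ci.method='beta'``).
    """
    fit: FitResult | None = None
    if isinstance(model, FitResult):
        fit = model
        model = fit.model
    if not isinstance(model, ModelSpec):
        raise InputError("model must be a ModelSpec or FitResult")
    model._require_beta()
    if grid_size < 2:
        raise InputError("grid_size must be >= 2")
    if statistic == "quantile" and q is None:
        raise InputError("statistic='quantile' requires q")

    df = availability.available_rows()
    if len(df) == 0:
        raise InputError("availability table has no available (used=0) rows")
    if focal not in df.columns:
        raise InputError(f"focal covariate '{focal}' is not in the table")

    x = df[focal].to_numpy(dtype=float)
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        raise InputError(f"focal covariate '{focal}' is constant; no range to span")
    if bandwidth is None:
        bandwidth = DEFAULT_BANDWIDTH_FRACTION * (hi - lo)
    grid = np.linspace(lo, hi, grid_size)

    w = evaluate_w_array(model, df)
    est = _curve_values(w, x, grid, bandwidth, statistic, q)

    lower = upper = None
    if ci is not None:
        rng = np.random.default_rng(ci.seed)
        boots = np.empty((ci.n_boot, grid_size))
        if ci.method == "rows":
            n = len(df)
            for b in range(ci.n_boot):
                idx = rng.integers(0, n, n)
                boots[b] = _curve_values(w[idx], x[idx], grid, bandwidth, statistic, q)
        else:
            if fit is None:
                raise InputError("ci.method='beta' requires a FitResult")
            draws = rng.multivariate_normal(fit.params, fit.vcov, size=ci.n_boot)
            for b in range(ci.n_boot):
                theta = draws[b]
                if fit.intercept_identifiable:
                    m_b = fit.model.with_beta(theta[1:], intercept=theta[0])
                else:
                    m_b = fit.model.with_beta(theta)
                w_b = evaluate_w_array(m_b, df)
                boots[b] = _curve_values(w_b, x, grid, bandwidth, statistic, q)
        alpha = 1.0 - ci.level
        lower = np.nanquantile(boots, alpha / 2, axis=0)
        upper = np.nanquantile(boots, 1 - alpha / 2, axis=0)
        # percentile envelopes can miss the point estimate at extreme grid
        # points; clamp so lower <= estimate <= upper holds by construction
        lower = np.fmin(lower, est)
        upper = np.fmax(upper, est)

    stat_label = "mean" if statistic == "mean" else f"quantile({q})"
    return EffectCurve(
        focal=focal,
        grid=grid,
        estimate=est,
        lower=lower,
        upper=upper,
        statistic=stat_label,
        n_points=len(df),
        relative=model.form == "exponential",
    )


def preference_curve(
    model,
    ranges: Mapping[str, tuple[float, float]],
    focal: str,
    *,
    n_grid_focal: int = DEFAULT_GRID_SIZE,
    n_grid_other: int = 21,
    bandwidth: float | None = None,
    ci: CIConfig | None = None,
    max_factorial: int = 1_000_000,
    n_monte_carlo: int = 200_000,
    seed: int | None = None,
    **kwargs,
) -> EffectCurve:
    """Average-effect curve under uniform availability of resource types.

    Builds a synthetic availability table with every model covariate
    uniform over its range — a full factorial grid when its size does
    not exceed ``max_factorial``, otherwise a uniform Monte Carlo sample
    of ``n_monte_carlo`` points (``seed`` then required) — and delegates
    to :func:`average_effect_curve`.
    """
    spec = model.model if isinstance(model, FitResult) else model
    covs = spec.covariates
    missing = [c for c in covs if c not in ranges]
    if missing:
        raise InputError(f"missing ranges for model covariates: {missing}")
    for name, (lo, hi) in ranges.items():
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise InputError(f"range for '{name}' must be finite with low < high")
    if focal not in covs:
        raise InputError(f"focal covariate '{focal}' is not in the model")

    sizes = {c: (n_grid_focal if c == focal else n_grid_other) for c in covs}
    total = int(np.prod([sizes[c] for c in covs], dtype=float))
    if total <= max_factorial:
        axes = [np.linspace(*ranges[c], sizes[c]) for c in covs]
        mesh = np.meshgrid(*axes, indexing="ij")
        table = pd.DataFrame({c: m.ravel() for c, m in zip(covs, mesh)})
    else:
        if seed is None:
            raise InputError(
                "factorial grid would exceed max_factorial; a seed is required "
                "for the Monte Carlo sample"
            )
        rng = np.random.default_rng(seed)
        table = pd.DataFrame(
            {c: rng.uniform(*ranges[c], n_monte_carlo) for c in covs}
        )
    table["used"] = 0
    avail = UsedAvailableTable(table)
    curve = average_effect_curve(
        model,
        avail,
        focal,
        grid_size=n_grid_focal,
        bandwidth=bandwidth,
        ci=ci,
        **kwargs,
    )
    curve.kind = "preference"
    return curve


def plot_curve(curve: EffectCurve, path, *, title: str | None = None) -> None:
    """Write a simple static plot of the curve (with CI band if present)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    if curve.lower is not None:
        ax.fill_between(curve.grid, curve.lower, curve.upper, color="0.8", label="CI")
    ax.plot(curve.grid, curve.estimate, color="k")
    ax.set_xlabel(curve.focal)
    ylabel = "relative probability of use" if curve.relative else "probability of use"
    if curve.kind == "preference":
        ylabel = ylabel.replace("use", "selection")
    ax.set_ylabel(ylabel)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
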