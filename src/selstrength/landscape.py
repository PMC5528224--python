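"""RSS maps and utilization distributions on covariate rasters.

A habitat-selection map assigns each pixel exp(sum beta_i h_i(x)) — the
RSS of that pixel relative to a reference pixel where every habitat
value is zero.  ``rss_map`` makes the reference explicit (zero, the
per-layer median "typical" pixel, or a custom habitat vector).

For a step-selection model the long-run utilization distribution is the
stationary distribution of the pixel-to-pixel transition chain with
P(i -> j) proportional to w(x_j) * phi(d_ij), where phi is a fixed
selection-free movement kernel truncated at its radius (and at the
raster edge).  ``stationary_distribution`` solves the chain exactly by
power iteration; ``monte_carlo_ud`` approximates it by simulating
trajectories, which also works on rasters too large to enumerate.

Movement is first-order Markov only: kernels depend on the current
pixel, never on previous headings or speeds.
"""

from __future__ import annotations

from dataclasses import dataclass
from bisect import bisect_left

import numpy as np
import scipy.sparse
import scipy.sparse.csgraph

from .errors import InputError, NumericalError
from .model import ModelSpec, evaluate_w_array
from .raster import RasterStack

__all__ = [
    "MovementKernel",
    "TransitionMatrix",
    "rss_map",
    "step_transition_matrix",
    "stationary_distribution",
    "monte_carlo_ud",
]

TRANSITION_GUARD = 10_000  # max enumerable pixels for an explicit matrix


@dataclass(frozen=True)
class MovementKernel:
    """Selection-free movement kernel: a disc of given radius (map units)
    with uniform or exponential-decay weighting of the displacement."""

    radius: float
    decay: str = "uniform"
    rate: float | None = None  # decay rate per map unit when exponential

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise InputError("kernel radius must be positive")
        if self.decay == "exponential":
            if self.rate is None or not self.rate > 0:
                raise InputError("exponential decay requires rate > 0")
        elif self.decay != "uniform":
            raise InputError(f"unknown decay {self.decay!r}")

    def weight(self, d: np.ndarray) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        if self.decay == "uniform":
            return np.ones_like(d)
        return np.exp(-self.rate * d)


@dataclass
class TransitionMatrix:
    """Row-stochastic pixel-to-pixel transition matrix over the active
    (non-NODATA) pixels of a raster."""

    P: scipy.sparse.csr_matrix
    rows: np.ndarray  # raster row per state
    cols: np.ndarray  # raster col per state
    shape: tuple[int, int]  # raster shape

    @property
    def n(self) -> int:
        return self.P.shape[0]

    def row_sums(self) -> np.ndarray:
        return np.asarray(self.P.sum(axis=1)).ravel()


def _pixel_weights(raster: RasterStack, model: ModelSpec) -> np.ndarray:
    """Selection weight w at every active pixel (order: active scan)."""
    missing = [c for c in model.covariates if c not in raster.layers]
    if missing:
        raise InputError(f"raster is missing covariate layers: {missing}")
    active = ~raster.mask
    r, c = np.nonzero(active)
    return evaluate_w_array(model, raster.table(r, c)), r, c


def rss_map(
    model: ModelSpec,
    raster: RasterStack,
    reference: str | dict = "zero",
) -> RasterStack:
    """Map of RSS(pixel, reference) for an exponential model.

    ``reference`` is ``'zero'`` (all habitat values zero: the map equals
    exp(sum beta_i h_i)), ``'typical'`` (per-layer median over active
    pixels), or a custom habitat-vector mapping.  NODATA propagates.
    """
    if model.form != "exponential":
        raise InputError("rss_map is defined for exponential-form models")
    beta = model._require_beta()
    missing = [c for c in model.covariates if c not in raster.layers]
    if missing:
        raise InputError(f"raster is missing covariate layers: {missing}")

    active = ~raster.mask
    r, c = np.nonzero(active)
    table = raster.table(r, c)
    from .model import linear_predictor_array, linear_predictor

    lp = linear_predictor_array(model, table)
    if reference == "zero":
        lp_ref = 0.0
    elif reference == "typical":
        typical = {name: float(np.nanmedian(arr)) for name, arr in raster.layers.items()}
        lp_ref = linear_predictor(model, typical)
    elif isinstance(reference, dict):
        lp_ref = linear_predictor(model, reference)
    else:
        raise InputError(
            "reference must be 'zero', 'typical' or a habitat-vector mapping"
        )
    out = np.full((raster.n_rows, raster.n_cols), np.nan)
    out[r, c] = np.exp(lp - lp_ref)
    return RasterStack(
        layers={"rss": out},
        cell_size=raster.cell_size,
        xllcorner=raster.xllcorner,
        yllcorner=raster.yllcorner,
        nodata=raster.nodata,
    )


def _neighbor_graph(raster: RasterStack, kernel: MovementKernel):
    """Edges (src_state, dst_state, distance) between active pixels whose
    centre-to-centre distance is within the kernel radius (self included)."""
    if kernel.radius < raster.cell_size:
        raise InputError(
            f"kernel radius {kernel.radius} is below the cell size "
            f"{raster.cell_size}; every pixel would be trapped"
        )
    active = ~raster.mask
    n = int(active.sum())
    if n == 0:
        raise InputError("raster has no active (non-NODATA) pixels")
    state = np.full(active.shape, -1, dtype=int)
    rows, cols = np.nonzero(active)
    state[rows, cols] = np.arange(n)

    cell = raster.cell_size
    reach = int(np.floor(kernel.radius / cell + 1e-9))
    src_list, dst_list, dist_list = [], [], []
    for di in range(-reach, reach + 1):
        for dj in range(-reach, reach + 1):
            d = cell * float(np.hypot(di, dj))
            if d > kernel.radius + 1e-12:
                continue
            r2, c2 = rows + di, cols + dj
            ok = (
                (r2 >= 0)
                & (r2 < active.shape[0])
                & (c2 >= 0)
                & (c2 < active.shape[1])
            )
            ok[ok] &= active[r2[ok], c2[ok]]
            src_list.append(state[rows[ok], cols[ok]])
            dst_list.append(state[r2[ok], c2[ok]])
            dist_list.append(np.full(ok.sum(), d))
    src = np.concatenate(src_list)
    dst = np.concatenate(dst_list)
    dist = np.concatenate(dist_list)
    order = np.argsort(src, kind="stable")
    return n, rows, cols, src[order], dst[order], dist[order]


def _row_slices(src: np.ndarray, n: int) -> np.ndarray:
    return np.searchsorted(src, np.arange(n + 1))


def step_transition_matrix(
    raster: RasterStack, model: ModelSpec, kernel: MovementKernel
) -> TransitionMatrix:
    """Explicit transition matrix P(i -> j) ~ w(x_j) * phi(d_ij)."""
    active = ~raster.mask
    n_active = int(active.sum())
    if n_active > TRANSITION_GUARD:
        raise InputError(
            f"{n_active} active pixels exceed the {TRANSITION_GUARD}-pixel guard "
            "for an explicit transition matrix; use monte_carlo_ud instead"
        )
    w, _, _ = _pixel_weights(raster, model)
    n, rows, cols, src, dst, dist = _neighbor_graph(raster, kernel)
    weight = w[dst] * kernel.weight(dist)
    bounds = _row_slices(src, n)
    totals = np.add.reduceat(weight, bounds[:-1])
    counts = np.diff(bounds)
    if (counts == 0).any() or (totals <= 0).any():
        bad = int(np.flatnonzero((counts == 0) | (totals <= 0))[0])
        raise NumericalError(
            f"pixel ({rows[bad]}, {cols[bad]}) has no reachable pixel with "
            "positive weight; the kernel radius is too small"
        )
    prob = weight / np.repeat(totals, counts)
    P = scipy.sparse.csr_matrix((prob, (src, dst)), shape=(n, n))
    return TransitionMatrix(P=P, rows=rows, cols=cols, shape=active.shape)


def stationary_distribution(
    tm: TransitionMatrix, tol: float = 1e-12, max_iter: int = 1_000_000
) -> np.ndarray:
    """Steady state pi of the chain (pi P = pi) by power iteration.

    Self-transitions make the chain aperiodic; irreducibility is checked
    by a strong-connectivity scan and a reducible chain is rejected with
    the component structure listed.
    """
    n = tm.n
    ncomp, labels = scipy.sparse.csgraph.connected_components(
        tm.P, directed=True, connection="strong"
    )
    if ncomp > 1:
        sizes = np.bincount(labels)
        raise NumericalError(
            f"transition chain is reducible: {ncomp} strongly connected "
            f"components with sizes {sizes.tolist()}"
        )
    PT = tm.P.T.tocsr()
    pi = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        new = PT @ pi
        new /= new.sum()
        if np.max(np.abs(new - pi)) < tol:
            pi = new
            break
        pi = new
    else:
        raise NumericalError("power iteration did not converge")
    return pi


def _sampling_tables(raster: RasterStack, model: ModelSpec, kernel: MovementKernel):
    """Per-state neighbor target lists and cumulative probabilities for
    trajectory simulation."""
    w, _, _ = _pixel_weights(raster, model)
    n, rows, cols, src, dst, dist = _neighbor_graph(raster, kernel)
    weight = w[dst] * kernel.weight(dist)
    bounds = _row_slices(src, n)
    targets, cums = [], []
    for i in range(n):
        lo, hi = bounds[i], bounds[i + 1]
        wt = weight[lo:hi]
        total = wt.sum()
        if hi == lo or total <= 0:
            raise NumericalError(
                f"pixel ({rows[i]}, {cols[i]}) has no reachable pixel with "
                "positive weight; trajectory would be trapped"
            )
        targets.append(dst[lo:hi].tolist())
        cums.append((np.cumsum(wt) / total).tolist())
    return n, rows, cols, targets, cums


def _simulate_path(targets, cums, start: int, n_steps: int, rng) -> list[int]:
    path = [start]
    s = start
    rand = rng.random
    for _ in range(n_steps):
        u = rand()
        cu = cums[s]
        s = targets[s][bisect_left(cu, u)]
        path.append(s)
    return path


def monte_carlo_ud(
    raster: RasterStack,
    model: ModelSpec,
    kernel: MovementKernel,
    n_steps: int,
    burn_in: int = 0,
    n_reps: int = 1,
    seed: int | None = None,
) -> RasterStack:
    """Utilization distribution by simulated trajectories.

    Runs ``n_reps`` trajectories of ``n_steps`` pixel-to-pixel moves
    (next pixel sampled with probability proportional to
    w(x_j) * phi(d_ij)), discards the first ``burn_in`` positions of
    each, and returns post-burn-in visit frequencies normalised to sum
    to 1, as a single-layer raster.
    """
    if seed is None:
        raise InputError("monte_carlo_ud requires a seed")
    if n_steps <= burn_in:
        raise InputError("n_steps must exceed burn_in")
    if n_reps < 1:
        raise InputError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    n, rows, cols, targets, cums = _sampling_tables(raster, model, kernel)
    counts = np.zeros(n)
    for _ in range(n_reps):
        start = int(rng.integers(n))
        path = _simulate_path(targets, cums, start, n_steps, rng)
        visited = np.asarray(path[burn_in + 1 :], dtype=int)
        counts += np.bincount(visited, minlength=n)
    freq = counts / counts.sum()
    out = np.full(raster.mask.shape, np.nan)
    out[rows, cols] = freq
    return RasterStack(
        layers={"ud": out},
        cell_size=raster.cell_size,
        xllcorner=raster.xllcorner,
        yllcorner=raster.yllcorner,
        nodata=raster.nodata,
    )
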