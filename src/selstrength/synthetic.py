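"""Synthetic landscapes, used-available samples and step-selection
tracks with known ground truth.

The generators stand in for telemetry data: every fitting, effect-curve
and mapping routine in the package can be exercised against known
coefficients.  Two study-area recipes are built in:

``hypothetical_study_area``
    Habitat suitability ~ Uniform(0, 1) and road distance (km) ~
    Exponential(mean 1) truncated at 3, independent — a landscape where
    habitat quality carries no information about road proximity.

``roadside_study_area``
    An availability sample concentrated near roads (road distance ~
    truncated Exponential with mean 0.6 km) in which habitat suitability
    improves with distance from the road (suitability = u^(1/(1+d)),
    u ~ Uniform(0,1), so its mean rises from 0.5 at the road to 0.8 at
    3 km).  The positive suitability-distance association emulates a
    disturbed roadside landscape and makes average-effect curves
    steeper in road distance than under the hypothetical area, for the
    same coefficients.

``elk_rsf_truth`` / ``elk_rspf_truth`` provide ground-truth coefficient
sets (suitability, road distance and their interaction) of the
magnitude reported in elk road-avoidance analyses during hunting
season, for use as generator truth in recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import InputError, NumericalError
from .fitting import UsedAvailableTable
from .landscape import MovementKernel, _sampling_tables, _simulate_path, _neighbor_graph, _row_slices
from .model import ModelSpec, Term, evaluate_w_array
from .raster import RasterStack

__all__ = [
    "CovariateLaw",
    "simulate_availability",
    "simulate_used_available",
    "simulate_ssa_tracks",
    "build_case_control",
    "hypothetical_study_area",
    "roadside_study_area",
    "elk_rsf_truth",
    "elk_rspf_truth",
]

# Default sample sizes for the emulated telemetry design: number of
# animal relocations (used) and random availability points.
DEFAULT_N_USED = 5686
DEFAULT_N_AVAIL = 13652


@dataclass(frozen=True)
class CovariateLaw:
    """Marginal sampling law for one covariate.

    Kinds: ``uniform(low, high)``, ``truncated_exponential(mean, upper)``,
    ``constant(value)``, ``raster_layer`` (values read at uniformly drawn
    active pixels of a raster; all raster-backed laws sharing the same
    raster object share one pixel draw, preserving cross-layer
    correlation).
    """

    name: str
    kind: str
    low: float = 0.0
    high: float = 1.0
    mean: float = 1.0
    upper: float = 1.0
    value: float = 0.0
    raster: RasterStack | None = None
    layer: str | None = None

    def __post_init__(self) -> None:
        if self.kind == "uniform":
            if not self.low < self.high:
                raise InputError(f"uniform law for '{self.name}': low must be < high")
        elif self.kind == "truncated_exponential":
            if not (self.mean > 0 and self.upper > 0):
                raise InputError(
                    f"truncated_exponential law for '{self.name}': mean and "
                    "upper must be positive"
                )
        elif self.kind == "raster_layer":
            if self.raster is None:
                raise InputError(f"raster_layer law for '{self.name}' needs a raster")
        elif self.kind != "constant":
            raise InputError(f"unknown law kind {self.kind!r}")

    @classmethod
    def uniform(cls, name, low, high):
        return cls(name=name, kind="uniform", low=low, high=high)

    @classmethod
    def truncated_exponential(cls, name, mean, upper):
        return cls(name=name, kind="truncated_exponential", mean=mean, upper=upper)

    @classmethod
    def constant(cls, name, value):
        return cls(name=name, kind="constant", value=value)

    @classmethod
    def raster_layer(cls, name, raster, layer=None):
        return cls(name=name, kind="raster_layer", raster=raster, layer=layer)


def sample_truncated_exponential(rng, n, mean, upper) -> np.ndarray:
    """Inverse-CDF draw from Exponential(mean) truncated at ``upper``:
    h = -mean * ln(1 - u * (1 - exp(-upper/mean)))."""
    u = rng.random(n)
    return -mean * np.log1p(-u * (1.0 - np.exp(-upper / mean)))


def simulate_availability(
    laws: Sequence[CovariateLaw], n: int, seed: int
) -> UsedAvailableTable:
    """i.i.d. availability sample of size n from the given laws."""
    if n < 1:
        raise InputError("n must be >= 1")
    if seed is None:
        raise InputError("simulate_availability requires a seed")
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    raster_pixels: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for law in laws:
        if law.kind == "uniform":
            cols[law.name] = rng.uniform(law.low, law.high, n)
        elif law.kind == "truncated_exponential":
            cols[law.name] = sample_truncated_exponential(rng, n, law.mean, law.upper)
        elif law.kind == "constant":
            cols[law.name] = np.full(n, float(law.value))
        else:  # raster_layer
            key = id(law.raster)
            if key not in raster_pixels:
                active = ~law.raster.mask
                r, c = np.nonzero(active)
                if len(r) == 0:
                    raise InputError("raster has no active pixels to sample")
                idx = rng.integers(0, len(r), n)
                raster_pixels[key] = (r[idx], c[idx])
            r, c = raster_pixels[key]
            cols[law.name] = law.raster.layer(law.layer or law.name)[r, c]
    df = pd.DataFrame(cols)
    df.insert(0, "used", 0)
    df.insert(0, "point_id", np.arange(n))
    return UsedAvailableTable(df)


def simulate_used_available(
    model: ModelSpec,
    availability: UsedAvailableTable,
    n_used: int,
    seed: int,
    pool: UsedAvailableTable | None = None,
) -> UsedAvailableTable:
    """Draw used points under a known model and attach the availability
    sample.

    Exponential form: used points are availability draws resampled with
    probability proportional to w (relative-selection semantics).
    Logistic form: candidate draws are accepted as used with probability
    expit(intercept + eta) until ``n_used`` accumulate (Bernoulli
    thinning, honouring the RSPF's absolute-probability semantics).

    ``pool`` optionally supplies a separate (usually larger) sample of
    the same availability distribution from which the used points are
    drawn; by default the availability rows themselves are the pool.
    """
    if seed is None:
        raise InputError("simulate_used_available requires a seed")
    rng = np.random.default_rng(seed)
    model._require_beta()
    source = pool if pool is not None else availability
    src_df = source.available_rows() if source.n_avail else source.data
    src_df = src_df.drop(columns=[c for c in ("used", "point_id", "stratum") if c in src_df],
                         errors="ignore").reset_index(drop=True)
    n_pool = len(src_df)
    if n_pool == 0:
        raise InputError("empty availability pool")

    if model.form == "exponential":
        w = evaluate_w_array(model, src_df)
        total = w.sum()
        if not np.isfinite(total) or total <= 0:
            raise NumericalError("all selection weights are zero or non-finite")
        idx = rng.choice(n_pool, size=n_used, replace=True, p=w / total)
    else:
        p_sel = evaluate_w_array(model, src_df)
        if p_sel.max() <= 0:
            raise NumericalError("all selection probabilities are zero")
        chosen: list[np.ndarray] = []
        got = 0
        while got < n_used:
            batch = max(1024, 4 * (n_used - got))
            cand = rng.integers(0, n_pool, batch)
            keep = cand[rng.random(batch) < p_sel[cand]]
            chosen.append(keep)
            got += len(keep)
        idx = np.concatenate(chosen)[:n_used]

    used_df = src_df.iloc[idx].reset_index(drop=True)
    used_df.insert(0, "used", 1)
    avail_df = availability.available_rows().drop(
        columns=[c for c in ("point_id", "stratum") if c in availability.data],
        errors="ignore",
    ).reset_index(drop=True)
    out = pd.concat([used_df, avail_df], ignore_index=True)
    out.insert(0, "point_id", np.arange(len(out)))
    return UsedAvailableTable(out)


def simulate_ssa_tracks(
    raster: RasterStack,
    model: ModelSpec,
    kernel: MovementKernel,
    n_steps: int,
    start: tuple[int, int] | None = None,
    seed: int | None = None,
) -> list[tuple[int, int]]:
    """One movement trajectory of ``n_steps`` steps; each next pixel is
    sampled with probability proportional to w(x_j) * phi(d_ij).
    Returns the ordered pixel list ((row, col), length n_steps + 1)."""
    if seed is None:
        raise InputError("simulate_ssa_tracks requires a seed")
    rng = np.random.default_rng(seed)
    n, rows, cols, targets, cums = _sampling_tables(raster, model, kernel)
    if start is None:
        s0 = int(rng.integers(n))
    else:
        r0, c0 = start
        match = np.flatnonzero((rows == r0) & (cols == c0))
        if len(match) == 0:
            raise InputError(f"start pixel {start} is NODATA or out of range")
        s0 = int(match[0])
    path = _simulate_path(targets, cums, s0, n_steps, rng)
    return [(int(rows[s]), int(cols[s])) for s in path]


def build_case_control(
    track: Sequence[tuple[int, int]],
    raster: RasterStack,
    kernel: MovementKernel,
    k_available: int,
    seed: int,
) -> UsedAvailableTable:
    """Stratified case-control table from an observed track.

    Each observed step becomes one stratum holding the used end pixel
    plus ``k_available`` end pixels sampled (selection-free, with
    probability proportional to phi(d) only) from the kernel around the
    step's start.  Rows carry the end-pixel covariates.
    """
    if len(track) < 2:
        raise InputError("track needs at least 2 positions (1 step)")
    if k_available < 1:
        raise InputError("k_available must be >= 1")
    if seed is None:
        raise InputError("build_case_control requires a seed")
    rng = np.random.default_rng(seed)

    active = ~raster.mask
    n = int(active.sum())
    state = np.full(active.shape, -1, dtype=int)
    rows, cols = np.nonzero(active)
    state[rows, cols] = np.arange(n)
    _, _, _, src, dst, dist = _neighbor_graph(raster, kernel)
    phi = kernel.weight(dist)
    bounds = _row_slices(src, n)

    records = []
    for t in range(len(track) - 1):
        r0, c0 = track[t]
        r1, c1 = track[t + 1]
        s0 = state[r0, c0]
        if s0 < 0:
            raise InputError(f"track position {track[t]} is NODATA")
        lo, hi = bounds[s0], bounds[s0 + 1]
        if hi <= lo:
            raise InputError(
                f"kernel admits no candidate end pixels around {track[t]}"
            )
        cand = dst[lo:hi]
        p = phi[lo:hi] / phi[lo:hi].sum()
        picks = rng.choice(cand, size=k_available, replace=True, p=p)
        records.append((t, 1, int(state[r1, c1])))
        records.extend((t, 0, int(s)) for s in picks)

    strata = np.array([rec[0] for rec in records])
    used = np.array([rec[1] for rec in records])
    states = np.array([rec[2] for rec in records])
    df = raster.table(rows[states], cols[states])
    df.insert(0, "stratum", strata)
    df.insert(0, "used", used)
    df.insert(0, "point_id", np.arange(len(df)))
    return UsedAvailableTable(df)


# ---------------------------------------------------------------------------
# Study-area recipes and ground-truth models
# ---------------------------------------------------------------------------


def hypothetical_study_area(n: int = DEFAULT_N_AVAIL, seed: int = 0) -> UsedAvailableTable:
    """Suitability ~ U(0,1); road distance (km) ~ Exp(mean 1) truncated
    at 3; independent."""
    laws = [
        CovariateLaw.uniform("suitability", 0.0, 1.0),
        CovariateLaw.truncated_exponential("road_dist", 1.0, 3.0),
    ]
    return simulate_availability(laws, n, seed)


def roadside_study_area(n: int = DEFAULT_N_AVAIL, seed: int = 0) -> UsedAvailableTable:
    """Availability concentrated near roads with suitability improving
    away from them (see module docstring)."""
    if n < 1:
        raise InputError("n must be >= 1")
    rng = np.random.default_rng(seed)
    road = sample_truncated_exponential(rng, n, 0.6, 3.0)
    u = rng.random(n)
    suit = u ** (1.0 / (1.0 + road))
    df = pd.DataFrame({"suitability": suit, "road_dist": road})
    df.insert(0, "used", 0)
    df.insert(0, "point_id", np.arange(n))
    return UsedAvailableTable(df)


_ELK_TERMS = ("suitability", "road_dist", "suitability*road_dist")


def elk_rsf_truth() -> ModelSpec:
    """Exponential-RSF ground truth: suitability, road distance (km) and
    their interaction."""
    return ModelSpec(
        form="exponential",
        terms=tuple(Term.parse(t) for t in _ELK_TERMS),
        beta=np.array([3.135, 0.428, -0.406]),
    )


def elk_rspf_truth() -> ModelSpec:
    """Logistic-RSPF ground truth with the same three terms plus an
    intercept."""
    return ModelSpec(
        form="logistic",
        terms=tuple(Term.parse(t) for t in _ELK_TERMS),
        intercept=-3.016,
        beta=np.array([4.591, 0.039, 3.030]),
    )
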