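"""Selection-function models and the relative-selection-strength calculus.

A habitat- (or step-) selection model assigns each resource unit ``x`` a
selection weight

    w(x) = c * exp(sum_i beta_i * t_i(h(x)))          (exponential RSF)
    w(x) = expit(beta_0 + sum_i beta_i * t_i(h(x)))   (logistic RSPF)

where ``h(x)`` is the vector of habitat covariates at ``x`` and the
``t_i`` are the model terms: transformed covariates (identity, log,
square) and pairwise products of transformed covariates.  Under the
used-available design the exponential normalising constant ``c`` is not
identifiable, so the library fixes ``c = 1`` and every quantity derived
from the exponential form is *relative*.

The relative selection strength between two locations is the ratio of
their selection weights,

    RSS(x1, x2) = w(x1) / w(x2),

the habitat-selection analogue of the epidemiological risk ratio.  The
argument order reads "selection for x1 relative to x2"; ``log_rss`` is
its natural logarithm, which for the exponential form reduces to the
difference of linear predictors and does not depend on any intercept.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import log_expit, expit

from .errors import DomainError, InputError

__all__ = [
    "Factor",
    "Term",
    "ModelSpec",
    "term",
    "design_matrix",
    "linear_predictor",
    "linear_predictor_array",
    "evaluate_w",
    "evaluate_w_array",
    "log_rss",
    "rss",
    "read_model",
    "write_model",
    "model_from_text",
    "model_to_text",
]

_TRANSFORMS = ("identity", "log", "square")


@dataclass(frozen=True)
class Factor:
    """One covariate inside a term, with its transform."""

    name: str
    transform: str = "identity"

    def __post_init__(self) -> None:
        if self.transform not in _TRANSFORMS:
            raise InputError(
                f"unknown transform {self.transform!r}; expected one of {_TRANSFORMS}"
            )
        if not self.name:
            raise InputError("factor name must be non-empty")

    @property
    def label(self) -> str:
        if self.transform == "log":
            return f"log({self.name})"
        if self.transform == "square":
            return f"{self.name}^2"
        return self.name

    def apply(self, values):
        """Apply the transform to scalar or array covariate values."""
        v = np.asarray(values, dtype=float)
        if self.transform == "log":
            if np.any(v <= 0):
                raise DomainError(
                    f"log transform of covariate '{self.name}' requires "
                    "strictly positive values"
                )
            return np.log(v)
        if self.transform == "square":
            return v * v
        return v


_FACTOR_RE_LOG = re.compile(r"log\(\s*([A-Za-z_]\w*)\s*\)")
_FACTOR_RE_SQ = re.compile(r"([A-Za-z_]\w*)\s*\^\s*2")
_FACTOR_RE_ID = re.compile(r"([A-Za-z_]\w*)")


def _parse_factor(token: str, transform: str | None = None) -> Factor:
    token = token.strip()
    if transform is not None and transform != "identity":
        m = _FACTOR_RE_ID.fullmatch(token)
        if not m:
            raise InputError(f"cannot parse factor {token!r}")
        return Factor(m.group(1), transform)
    for regex, tr in (
        (_FACTOR_RE_LOG, "log"),
        (_FACTOR_RE_SQ, "square"),
        (_FACTOR_RE_ID, "identity"),
    ):
        m = regex.fullmatch(token)
        if m:
            return Factor(m.group(1), tr)
    raise InputError(f"cannot parse factor {token!r}")


@dataclass(frozen=True)
class Term:
    """A model term: a transformed covariate or a product of them.

    ``factors`` of length >= 2 mark a product (interaction) term.  The
    ``square`` transform is only allowed in single-factor terms; inside
    products each factor carries its own transform (e.g. ``log(d)*forest``).
    """

    factors: tuple[Factor, ...]

    def __post_init__(self) -> None:
        if not self.factors:
            raise InputError("a term needs at least one factor")
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise InputError(f"duplicate covariate in term {'*'.join(names)}")
        if len(self.factors) > 1 and any(f.transform == "square" for f in self.factors):
            raise InputError(
                "the square transform applies to single-factor terms only"
            )

    @classmethod
    def parse(cls, text: str) -> "Term":
        """Parse ``elevation``, ``elevation : log``, ``log(d)*forest``,
        ``forest*elevation : identity`` or ``elevation^2``."""
        transform = None
        if ":" in text:
            expr, _, tr = text.partition(":")
            transform = tr.strip()
            if transform not in _TRANSFORMS:
                raise InputError(f"unknown transform {transform!r} in {text!r}")
            text = expr
        tokens = [t for t in text.split("*")]
        return cls(tuple(_parse_factor(t, transform) for t in tokens))

    @property
    def label(self) -> str:
        return "*".join(f.label for f in self.factors)

    @property
    def covariates(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors)

    def value(self, h: Mapping[str, float]) -> float:
        out = 1.0
        for f in self.factors:
            if f.name not in h:
                raise InputError(f"missing covariate '{f.name}'")
            out *= float(f.apply(h[f.name]))
        return out

    def column(self, data: pd.DataFrame) -> np.ndarray:
        out = np.ones(len(data), dtype=float)
        for f in self.factors:
            if f.name not in data.columns:
                raise InputError(f"missing covariate '{f.name}'")
            out *= np.asarray(f.apply(data[f.name].to_numpy(dtype=float)))
        return out


def term(text: str) -> Term:
    """Shorthand for :meth:`Term.parse`."""
    return Term.parse(text)


@dataclass
class ModelSpec:
    """A selection model: functional form, terms and (optionally)
    coefficients.

    For the exponential form the intercept, if present, is carried but
    non-identifiable from used-available data and is ignored by
    ``evaluate_w`` (the normalisation ``c`` is fixed at 1).  The logistic
    form requires an intercept.
    """

    form: str
    terms: tuple[Term, ...]
    intercept: float | None = None
    beta: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.form not in ("exponential", "logistic"):
            raise InputError(
                f"unknown model form {self.form!r}; expected 'exponential' or 'logistic'"
            )
        self.terms = tuple(
            Term.parse(t) if isinstance(t, str) else t for t in self.terms
        )
        labels = [t.label for t in self.terms]
        if len(set(labels)) != len(labels):
            raise InputError("duplicate terms in model specification")
        if self.beta is not None:
            self.beta = np.asarray(self.beta, dtype=float)
            if self.beta.shape != (len(self.terms),):
                raise InputError(
                    f"beta has length {self.beta.size} but the model has "
                    f"{len(self.terms)} terms"
                )

    @property
    def covariates(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for t in self.terms:
            for name in t.covariates:
                seen.setdefault(name)
        return tuple(seen)

    @property
    def term_labels(self) -> tuple[str, ...]:
        return tuple(t.label for t in self.terms)

    @property
    def n_params(self) -> int:
        return len(self.terms) + (1 if self.form == "logistic" else 0)

    def with_beta(self, beta, intercept: float | None = None) -> "ModelSpec":
        new = replace(self, beta=np.asarray(beta, dtype=float))
        if intercept is not None:
            new.intercept = float(intercept)
        return new

    def _require_beta(self) -> np.ndarray:
        if self.beta is None:
            raise InputError("model has no coefficients (beta is unset)")
        return self.beta


def design_matrix(model: ModelSpec, data: pd.DataFrame) -> np.ndarray:
    """Expand a covariate table into the model's term matrix (n x k)."""
    if len(model.terms) == 0:
        return np.empty((len(data), 0))
    return np.column_stack([t.column(data) for t in model.terms])


def linear_predictor(model: ModelSpec, h: Mapping[str, float]) -> float:
    """sum_i beta_i * t_i(h); excludes any intercept."""
    beta = model._require_beta()
    return float(sum(b * t.value(h) for b, t in zip(beta, model.terms)))


def linear_predictor_array(model: ModelSpec, data: pd.DataFrame) -> np.ndarray:
    beta = model._require_beta()
    return design_matrix(model, data) @ beta


def evaluate_w(model: ModelSpec, h: Mapping[str, float]) -> float:
    """Selection weight at one habitat vector.

    Exponential form: ``exp(linear_predictor)`` (unnormalised, c = 1).
    Logistic form: ``expit(intercept + linear_predictor)``.
    """
    lp = linear_predictor(model, h)
    if model.form == "exponential":
        return float(np.exp(lp))
    if model.intercept is None:
        raise InputError("a logistic model requires an intercept")
    return float(expit(model.intercept + lp))


def evaluate_w_array(model: ModelSpec, data: pd.DataFrame) -> np.ndarray:
    lp = linear_predictor_array(model, data)
    if model.form == "exponential":
        return np.exp(lp)
    if model.intercept is None:
        raise InputError("a logistic model requires an intercept")
    return expit(model.intercept + lp)


def log_rss(model: ModelSpec, x1: Mapping[str, float], x2: Mapping[str, float]) -> float:
    """ln RSS(x1, x2) = ln w(x1) - ln w(x2).

    Reads "log strength of selection for x1 relative to x2".  For the
    exponential form this is exactly the difference of linear predictors
    and is independent of any intercept / normalising constant.
    """
    if model.form == "exponential":
        return linear_predictor(model, x1) - linear_predictor(model, x2)
    if model.intercept is None:
        raise InputError("a logistic model requires an intercept")
    z1 = model.intercept + linear_predictor(model, x1)
    z2 = model.intercept + linear_predictor(model, x2)
    return float(log_expit(z1) - log_expit(z2))


def rss(model: ModelSpec, x1: Mapping[str, float], x2: Mapping[str, float]) -> float:
    """RSS(x1, x2) = w(x1)/w(x2); strictly positive."""
    return float(np.exp(log_rss(model, x1, x2)))


# ---------------------------------------------------------------------------
# Flat key-value serialisation
#
#   form = exponential
#   term = suitability
#   term = road_dist
#   term = suitability*road_dist
#   beta = 3.135, 0.428, -0.406
#   intercept = -3.016        (optional)
# ---------------------------------------------------------------------------


def model_to_text(model: ModelSpec) -> str:
    lines = [f"form = {model.form}"]
    lines += [f"term = {t.label}" for t in model.terms]
    if model.beta is not None:
        lines.append("beta = " + ", ".join(repr(float(b)) for b in model.beta))
    if model.intercept is not None:
        lines.append(f"intercept = {model.intercept!r}")
    return "\n".join(lines) + "\n"


def model_from_text(text: str) -> ModelSpec:
    form = None
    terms: list[Term] = []
    beta = None
    intercept = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        key, sep, value = line.partition("=")
        if not sep:
            raise InputError(f"model spec line {lineno}: expected 'key = value'")
        key, value = key.strip(), value.strip()
        if key == "form":
            form = value
        elif key == "term":
            terms.append(Term.parse(value))
        elif key == "beta":
            try:
                beta = [float(v) for v in value.split(",")]
            except ValueError as exc:
                raise InputError(f"model spec line {lineno}: bad beta: {exc}") from None
        elif key == "intercept":
            try:
                intercept = float(value)
            except ValueError:
                raise InputError(f"model spec line {lineno}: bad intercept {value!r}") from None
        else:
            raise InputError(f"model spec line {lineno}: unknown key {key!r}")
    if form is None:
        raise InputError("model spec is missing 'form'")
    if not terms:
        raise InputError("model spec has no terms")
    return ModelSpec(form=form, terms=tuple(terms), intercept=intercept, beta=beta)


def read_model(path) -> ModelSpec:
    with open(path, "r", encoding="utf-8") as fh:
        return model_from_text(fh.read())


def write_model(model: ModelSpec, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(model_to_text(model))
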