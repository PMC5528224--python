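"""Closed-form log-RSS expressions for common exponential-model structures.

Each case gives ln RSS(x1, x2) when the two locations differ in one
focal covariate h_i (by dh_i = h_i(x1) - h_i(x2)) while every covariate
not explicitly mentioned is held constant.  The formulas are algebraic
consequences of the exponential linear predictor and are therefore not
applicable to the logistic form (pass ``model=`` to have that checked).

Cases and their required keyword parameters:

==========================  =====================================================
linear                      beta_i, dh_i
interaction                 beta_i, beta_ij, dh_i, h_j1
quadratic                   beta_i, beta_i2, dh_i, h_i1
quadratic_interaction       beta_i, beta_i2, beta_ij, dh_i, h_i1, h_j1
log                         beta_i, h_i1, dh_i
log_interaction             beta_i, beta_ij, h_i1, dh_i, h_j1
log_log                     beta_i, beta_j, h_i1, dh_i, h_j1, dh_j
==========================  =====================================================

``h_i1`` is the focal covariate's value at x1 and ``h_j1`` the second
covariate's value at x1 (equal at both locations for the interaction
cases).  The log cases read the covariate on its original (pre-log)
scale and require h_i(x1) > 0 and h_i(x2) = h_i(x1) - dh_i > 0: with a
log-transformed covariate the RSS depends on the *ratio* of habitat
values rather than their difference.
"""

from __future__ import annotations

import math

from .errors import DomainError, InputError
from .model import ModelSpec

__all__ = ["closed_form_log_rss", "CLOSED_FORM_CASES"]

CLOSED_FORM_CASES: dict[str, tuple[str, ...]] = {
    "linear": ("beta_i", "dh_i"),
    "interaction": ("beta_i", "beta_ij", "dh_i", "h_j1"),
    "quadratic": ("beta_i", "beta_i2", "dh_i", "h_i1"),
    "quadratic_interaction": ("beta_i", "beta_i2", "beta_ij", "dh_i", "h_i1", "h_j1"),
    "log": ("beta_i", "h_i1", "dh_i"),
    "log_interaction": ("beta_i", "beta_ij", "h_i1", "dh_i", "h_j1"),
    "log_log": ("beta_i", "beta_j", "h_i1", "dh_i", "h_j1", "dh_j"),
}


def _log_ratio(h1: float, dh: float, name: str) -> float:
    h2 = h1 - dh
    if h1 <= 0 or h2 <= 0:
        raise DomainError(
            f"log case requires {name}(x1) > 0 and {name}(x2) > 0 "
            f"(got {name}(x1)={h1}, {name}(x2)={h2})"
        )
    return math.log(h1 / h2)


def closed_form_log_rss(case: str, *, model: ModelSpec | None = None, **params) -> float:
    """Evaluate one of the tabulated log-RSS expressions.

    Parameters are the coefficients and habitat values named in the
    module docstring.  ``model`` is optional and only used to reject
    logistic models, for which these exponential-form identities do not
    hold.
    """
    if model is not None and model.form != "exponential":
        raise InputError(
            "closed-form log-RSS expressions apply to the exponential form "
            "only; use log_rss() for a logistic model"
        )
    if case not in CLOSED_FORM_CASES:
        raise InputError(
            f"unknown closed-form case {case!r}; expected one of "
            f"{sorted(CLOSED_FORM_CASES)}"
        )
    required = CLOSED_FORM_CASES[case]
    missing = [p for p in required if p not in params]
    if missing:
        raise InputError(f"case {case!r} is missing parameters: {missing}")
    extra = [p for p in params if p not in required]
    if extra:
        raise InputError(f"case {case!r} got unexpected parameters: {extra}")
    p = {k: float(v) for k, v in params.items()}

    if case == "linear":
        return p["beta_i"] * p["dh_i"]
    if case == "interaction":
        return p["dh_i"] * (p["beta_i"] + p["beta_ij"] * p["h_j1"])
    if case == "quadratic":
        return p["dh_i"] * (p["beta_i"] + p["beta_i2"] * (2.0 * p["h_i1"] - p["dh_i"]))
    if case == "quadratic_interaction":
        return p["dh_i"] * (
            p["beta_i"]
            + p["beta_i2"] * (2.0 * p["h_i1"] - p["dh_i"])
            + p["beta_ij"] * p["h_j1"]
        )
    if case == "log":
        return _log_ratio(p["h_i1"], p["dh_i"], "h_i") * p["beta_i"]
    if case == "log_interaction":
        return _log_ratio(p["h_i1"], p["dh_i"], "h_i") * (
            p["beta_i"] + p["beta_ij"] * p["h_j1"]
        )
    # log_log
    return _log_ratio(p["h_i1"], p["dh_i"], "h_i") * p["beta_i"] + _log_ratio(
        p["h_j1"], p["dh_j"], "h_j"
    ) * p["beta_j"]
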