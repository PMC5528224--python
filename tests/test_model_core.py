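"""Model evaluation and the RSS calculus: worked examples, closed forms
against the generic ln-w-ratio oracle, and algebraic invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from selstrength import (
    CLOSED_FORM_CASES,
    DomainError,
    InputError,
    ModelSpec,
    Term,
    closed_form_log_rss,
    evaluate_w,
    linear_predictor,
    log_rss,
    model_from_text,
    model_to_text,
    rss,
)

FOREST_600 = {"forest": 1, "elevation": 600}
MEADOW_500 = {"forest": 0, "elevation": 500}


class TestLinearPredictor:
    @pytest.mark.parametrize(
        "h, expected",
        [
            (MEADOW_500, 5.0),  # 0.01*500
            (FOREST_600, 13.0),  # 1 + 0.01*600 + 0.01*600
            ({"forest": 0, "elevation": 0}, 0.0),
        ],
    )
    def test_worked_examples(self, figure1_model, h, expected):
        assert linear_predictor(figure1_model, h) == pytest.approx(expected, abs=1e-12)

    def test_missing_covariate_is_named(self, figure1_model):
        with pytest.raises(InputError, match="elevation"):
            linear_predictor(figure1_model, {"forest": 1})

    def test_log_transform_rejects_nonpositive(self):
        m = ModelSpec("exponential", ("x : log",), beta=[1.0])
        with pytest.raises(DomainError):
            linear_predictor(m, {"x": 0.0})

    def test_transforms_expand(self):
        m = ModelSpec("exponential", ("x : log", "y^2", "log(x)*z"), beta=[1.0, 2.0, 3.0])
        h = {"x": math.e, "y": 3.0, "z": 0.5}
        assert linear_predictor(m, h) == pytest.approx(1.0 + 18.0 + 1.5, abs=1e-12)


class TestEvaluateW:
    def test_exponential_zero_lp(self):
        m = ModelSpec("exponential", ("x",), beta=[0.0])
        assert evaluate_w(m, {"x": 3.0}) == 1.0

    def test_logistic_zero_is_half(self):
        m = ModelSpec("logistic", ("x",), intercept=0.0, beta=[0.0])
        assert evaluate_w(m, {"x": 3.0}) == 0.5

    def test_figure1_meadow(self, figure1_model):
        assert evaluate_w(figure1_model, MEADOW_500) == pytest.approx(
            math.exp(5.0), rel=1e-12
        )

    def test_logistic_requires_intercept(self):
        m = ModelSpec("logistic", ("x",), beta=[1.0])
        with pytest.raises(InputError, match="intercept"):
            evaluate_w(m, {"x": 1.0})


class TestRSS:
    def test_worked_forest_vs_meadow(self, figure1_model):
        assert log_rss(figure1_model, FOREST_600, MEADOW_500) == pytest.approx(
            8.0, abs=1e-12
        )

    @pytest.mark.parametrize("w1, w2", [(0.90, 0.18), (0.005, 0.001)])
    def test_five_fold_selection(self, w1, w2):
        # degenerate single-covariate model reproducing the given weights
        m = ModelSpec("exponential", ("h",), beta=[1.0])
        value = rss(m, {"h": math.log(w1)}, {"h": math.log(w2)})
        assert value == pytest.approx(5.0, rel=1e-12)

    def test_identity(self, figure1_model):
        assert log_rss(figure1_model, MEADOW_500, MEADOW_500) == 0.0
        assert rss(figure1_model, FOREST_600, FOREST_600) == 1.0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-3, 3), min_size=6, max_size=6),
        st.floats(-2, 2),
    )
    def test_antisymmetry_and_transitivity(self, vals, beta2):
        m = ModelSpec("exponential", ("a", "b"), beta=[1.3, beta2])
        x1 = {"a": vals[0], "b": vals[1]}
        x2 = {"a": vals[2], "b": vals[3]}
        x3 = {"a": vals[4], "b": vals[5]}
        assert log_rss(m, x1, x2) == pytest.approx(-log_rss(m, x2, x1), abs=1e-10)
        assert log_rss(m, x1, x2) + log_rss(m, x2, x3) == pytest.approx(
            log_rss(m, x1, x3), abs=1e-10
        )

    def test_exponential_intercept_invariance(self, figure1_model):
        with_c = ModelSpec(
            "exponential",
            figure1_model.terms,
            intercept=42.0,
            beta=figure1_model.beta,
        )
        assert log_rss(with_c, FOREST_600, MEADOW_500) == log_rss(
            figure1_model, FOREST_600, MEADOW_500
        )

    def test_rss_positive(self, figure1_model):
        assert rss(figure1_model, MEADOW_500, FOREST_600) > 0

    def test_logistic_log_rss_matches_weight_ratio(self):
        m = ModelSpec("logistic", ("x",), intercept=-1.0, beta=[2.0])
        x1, x2 = {"x": 0.7}, {"x": 0.2}
        expected = math.log(evaluate_w(m, x1) / evaluate_w(m, x2))
        assert log_rss(m, x1, x2) == pytest.approx(expected, abs=1e-12)


def _random_case(case, rng):
    """Random parameters for a closed-form case plus the equivalent
    exponential model and habitat pair for the generic oracle."""
    b = rng.uniform(-2, 2, size=4)  # beta_i, beta_i2/beta_j, beta_ij, spare
    if case in ("log", "log_interaction", "log_log"):
        h_i1 = rng.uniform(0.1, 5.0)
        h_i2 = rng.uniform(0.1, 5.0)
        dh_i = h_i1 - h_i2
    else:
        h_i1 = rng.uniform(-3, 3)
        dh_i = rng.uniform(-2, 2)
        h_i2 = h_i1 - dh_i
    h_j1 = rng.uniform(-3, 3)

    if case == "linear":
        params = {"beta_i": b[0], "dh_i": dh_i}
        model = ModelSpec("exponential", ("hi",), beta=[b[0]])
        x1, x2 = {"hi": h_i1}, {"hi": h_i2}
    elif case == "interaction":
        params = {"beta_i": b[0], "beta_ij": b[2], "dh_i": dh_i, "h_j1": h_j1}
        model = ModelSpec(
            "exponential", ("hi", "hj", "hi*hj"), beta=[b[0], b[3], b[2]]
        )
        x1 = {"hi": h_i1, "hj": h_j1}
        x2 = {"hi": h_i2, "hj": h_j1}
    elif case == "quadratic":
        params = {"beta_i": b[0], "beta_i2": b[1], "dh_i": dh_i, "h_i1": h_i1}
        model = ModelSpec("exponential", ("hi", "hi^2"), beta=[b[0], b[1]])
        x1, x2 = {"hi": h_i1}, {"hi": h_i2}
    elif case == "quadratic_interaction":
        params = {
            "beta_i": b[0], "beta_i2": b[1], "beta_ij": b[2],
            "dh_i": dh_i, "h_i1": h_i1, "h_j1": h_j1,
        }
        model = ModelSpec(
            "exponential",
            ("hi", "hi^2", "hj", "hi*hj"),
            beta=[b[0], b[1], b[3], b[2]],
        )
        x1 = {"hi": h_i1, "hj": h_j1}
        x2 = {"hi": h_i2, "hj": h_j1}
    elif case == "log":
        params = {"beta_i": b[0], "h_i1": h_i1, "dh_i": dh_i}
        model = ModelSpec("exponential", ("hi : log",), beta=[b[0]])
        x1, x2 = {"hi": h_i1}, {"hi": h_i2}
    elif case == "log_interaction":
        params = {
            "beta_i": b[0], "beta_ij": b[2],
            "h_i1": h_i1, "dh_i": dh_i, "h_j1": h_j1,
        }
        model = ModelSpec(
            "exponential", ("hi : log", "hj", "log(hi)*hj"), beta=[b[0], b[3], b[2]]
        )
        x1 = {"hi": h_i1, "hj": h_j1}
        x2 = {"hi": h_i2, "hj": h_j1}
    else:  # log_log
        h_j1p = rng.uniform(0.1, 5.0)
        h_j2p = rng.uniform(0.1, 5.0)
        params = {
            "beta_i": b[0], "beta_j": b[1],
            "h_i1": h_i1, "dh_i": dh_i,
            "h_j1": h_j1p, "dh_j": h_j1p - h_j2p,
        }
        model = ModelSpec("exponential", ("hi : log", "hj : log"), beta=[b[0], b[1]])
        x1 = {"hi": h_i1, "hj": h_j1p}
        x2 = {"hi": h_i2, "hj": h_j2p}
    return params, model, x1, x2


class TestClosedForms:
    @pytest.mark.parametrize(
        "case, params, expected",
        [
            ("linear", {"beta_i": 0.3, "dh_i": 0.0}, 0.0),
            # brute-force oracle: 0.2*(5-3) + (-0.01)*(25-9)
            ("quadratic", {"beta_i": 0.2, "beta_i2": -0.01, "h_i1": 5, "dh_i": 2}, 0.24),
            # 100*(0.01 + 0.01*1): forest at x1, elevation +100 m
            ("interaction", {"beta_i": 0.01, "beta_ij": 0.01, "h_j1": 1, "dh_i": 100}, 2.0),
            # beta_i * ln(h1/h2) with h2 = 1
            ("log", {"beta_i": 2, "h_i1": 4, "dh_i": 3}, 2 * math.log(4)),
        ],
    )
    def test_worked_examples(self, case, params, expected):
        assert closed_form_log_rss(case, **params) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("case", sorted(CLOSED_FORM_CASES))
    def test_agrees_with_generic_oracle(self, case):
        rng = np.random.default_rng(hash(case) % 2**32)
        for _ in range(1500):
            params, model, x1, x2 = _random_case(case, rng)
            assert closed_form_log_rss(case, **params) == pytest.approx(
                log_rss(model, x1, x2), abs=1e-10
            )

    def test_rejects_logistic_models(self):
        m = ModelSpec("logistic", ("x",), intercept=0.0, beta=[1.0])
        with pytest.raises(InputError, match="exponential"):
            closed_form_log_rss("linear", model=m, beta_i=1.0, dh_i=1.0)

    def test_missing_and_extra_parameters(self):
        with pytest.raises(InputError, match="missing"):
            closed_form_log_rss("interaction", beta_i=1.0, dh_i=1.0)
        with pytest.raises(InputError, match="unexpected"):
            closed_form_log_rss("linear", beta_i=1.0, dh_i=1.0, h_j1=0.0)

    def test_log_case_domain_error(self):
        with pytest.raises(DomainError):
            closed_form_log_rss("log", beta_i=1.0, h_i1=1.0, dh_i=2.0)


class TestSerialization:
    def test_round_trip(self, figure1_model):
        text = model_to_text(figure1_model)
        back = model_from_text(text)
        assert back.form == figure1_model.form
        assert back.term_labels == figure1_model.term_labels
        assert np.allclose(back.beta, figure1_model.beta)

    def test_round_trip_with_transforms_and_intercept(self):
        m = ModelSpec(
            "logistic", ("x : log", "y^2", "log(x)*y"), intercept=-3.0, beta=[1, 2, 3]
        )
        back = model_from_text(model_to_text(m))
        assert back.term_labels == ("log(x)", "y^2", "log(x)*y")
        assert back.intercept == -3.0

    def test_colon_style_terms_parse(self):
        m = model_from_text(
            "form = exponential\nterm = elevation : identity\n"
            "term = forest*elevation : identity\nbeta = 0.01, 0.001\n"
        )
        assert m.term_labels == ("elevation", "forest*elevation")

    def test_bad_spec_lines(self):
        with pytest.raises(InputError):
            model_from_text("form = exponential\nterm elevation\n")
        with pytest.raises(InputError, match="form"):
            model_from_text("term = elevation\n")


class TestTermValidation:
    def test_square_in_product_rejected(self):
        with pytest.raises(InputError, match="square"):
            Term.parse("x^2*y")

    def test_duplicate_factor_rejected(self):
        with pytest.raises(InputError, match="duplicate"):
            Term.parse("x*x")

    def test_beta_length_must_match(self):
        with pytest.raises(InputError, match="length"):
            ModelSpec("exponential", ("x", "y"), beta=[1.0])
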