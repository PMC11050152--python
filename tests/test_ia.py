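from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pahmix.dose_response import FittedCurve
from pahmix.errors import ConfigurationError
from pahmix.ia import (
    IndependentActionModel,
    build_context,
    curve_from_truth,
    ia_predict,
    ia_predict_from_truth,
)
from pahmix.mixtures import ComponentSpec, MixtureDefinition
from pahmix.simulate import TrueCurveSpec


def _ll4(d, e, b=-1.5, c=0.0, direction=None, dose_max=10.0, **meta):
    return FittedCurve(
        family="LL.4", params={"b": b, "c": c, "d": d, "e": e},
        rss=0.0, n_obs=8, aic=0.0, dose_min=0.0, dose_max=dose_max,
        direction=direction or ("up" if d > 0 else "down"), **meta,
    )


def _mix(n, tefs=None, total=10.0):
    props = np.full(n, 1.0 / n)
    return MixtureDefinition(
        "m",
        [
            ComponentSpec(f"c{i}", float(p), tef=None if tefs is None else tefs[i])
            for i, p in enumerate(props)
        ],
        full_strength_total=total,
    )


def _ie_up_term(U, max_up):
    """Inclusion-exclusion oracle for (1 - prod(1 - u_i)) * max_up."""
    n = U.shape[0]
    total = np.zeros(U.shape[1])
    for k in range(1, n + 1):
        for subset in combinations(range(n), k):
            total += (-1) ** (k + 1) * np.prod(U[list(subset)], axis=0)
    return total * max_up


@settings(deadline=None, max_examples=40)
@given(
    d=st.floats(0.5, 5.0),
    e=st.floats(0.05, 5.0),
    b=st.floats(-4.0, -0.3),
    dose=st.floats(0.001, 10.0),
)
def test_single_component_identity(d, e, b, dose):
    """With one component the IA prediction IS that component's curve."""
    mix = _mix(1)
    curve = _ll4(d, e, b=b)
    ctx = build_context("g", {"c0": curve}, None, mix, dose_range=(0.01, 10.0))
    pred = ia_predict(ctx, [dose]).predicted[0]
    expected = curve(np.array([1.0 * dose]))[0]  # proportion 1
    assert pred == pytest.approx(expected, abs=1e-12, rel=1e-12)


def test_hand_example_two_up_components():
    """u1 = u2 = 0.5 with max_up = 2 combines to (1 - 0.25) x 2 = 1.5."""
    up = _ie_up_term(np.array([[0.5], [0.5]]), 2.0)
    assert up[0] == pytest.approx(1.5, rel=1e-12)


def test_hand_example_mixed_directions():
    """Saturated up (E = max_up = 1) plus saturated down (E = max_down = -2)."""
    up = _ie_up_term(np.array([[1.0]]), 1.0)
    down = _ie_up_term(np.array([[1.0]]), -2.0)
    assert up[0] + down[0] == pytest.approx(-1.0, rel=1e-12)


@pytest.mark.parametrize("n_comp", [2, 3, 4])
def test_matches_inclusion_exclusion_oracle(n_comp):
    rng = np.random.default_rng(100 + n_comp)
    mix = _mix(n_comp)
    curves = {
        f"c{i}": _ll4(
            d=float(rng.uniform(0.5, 4.0)),
            e=float(rng.uniform(0.05, 2.0)),
            b=float(rng.uniform(-3.0, -0.5)),
        )
        for i in range(n_comp)
    }
    ctx = build_context("g", curves, None, mix, dose_range=(0.01, 10.0))
    doses = np.geomspace(0.01, 10.0, 25)
    pred = ia_predict(ctx, doses)
    spec = {c.name: c for c in mix.components}
    U = np.vstack(
        [
            np.clip(
                ctx.component_effect(spec[name], curves[name], doses) / ctx.max_up,
                0.0, 1.0,
            )
            for name in ctx.up_set
        ]
    )
    oracle = _ie_up_term(U, ctx.max_up)
    np.testing.assert_allclose(pred.predicted, oracle, atol=1e-12)
    np.testing.assert_allclose(pred.up_term, oracle, atol=1e-12)


def test_direction_terms_respect_bounds():
    rng = np.random.default_rng(9)
    mix = _mix(4)
    curves = {}
    for i in range(4):
        sign = 1.0 if i < 2 else -1.0
        curves[f"c{i}"] = _ll4(
            d=sign * float(rng.uniform(0.5, 4.0)),
            e=float(rng.uniform(0.05, 2.0)),
        )
    ctx = build_context("g", curves, None, mix, dose_range=(0.01, 10.0))
    pred = ia_predict(ctx, np.geomspace(1e-3, 10, 50))
    assert np.all(pred.up_term >= -1e-12) and np.all(pred.up_term <= ctx.max_up + 1e-12)
    assert np.all(pred.down_term <= 1e-12) and np.all(pred.down_term >= ctx.max_down - 1e-12)
    np.testing.assert_allclose(pred.predicted, pred.up_term + pred.down_term)


def test_monotone_in_single_component_effect():
    """Scaling one up component's curve upward never decreases the up term."""
    mix = _mix(2)
    doses = np.geomspace(0.01, 10, 20)
    base = {"c0": _ll4(2.0, 0.5), "c1": _ll4(1.0, 0.3)}
    bigger = {"c0": _ll4(2.0, 0.5), "c1": _ll4(1.8, 0.3)}
    p0 = ia_predict(build_context("g", base, None, mix, dose_range=(0.01, 10)), doses)
    p1 = ia_predict(build_context("g", bigger, None, mix, dose_range=(0.01, 10)), doses)
    assert np.all(p1.up_term >= p0.up_term - 1e-12)


def test_all_nonsignificant_context_is_empty_and_zero():
    mix = _mix(3)
    curves = {f"c{i}": _ll4(2.0, 0.5) for i in range(3)}
    ctx = build_context("g", curves, significant=[], mix=mix, dose_range=(0.01, 10))
    assert ctx.is_empty and ctx.max_up == 0.0 and ctx.max_down == 0.0
    pred = ia_predict(ctx, [0.1, 1.0])
    np.testing.assert_array_equal(pred.predicted, 0.0)


def test_max_up_is_cross_component_maximum():
    mix = _mix(2)
    curves = {"c0": _ll4(3.0, 0.01, b=-5.0), "c1": _ll4(1.0, 0.01, b=-5.0)}
    ctx = build_context("g", curves, None, mix, dose_range=(0.01, 10.0))
    assert ctx.n_up == 2
    assert ctx.max_up == pytest.approx(3.0, rel=1e-3)  # saturates well below top dose


def test_zero_maximum_direction_contributes_nothing():
    mix = _mix(1)
    # an "up" labelled curve whose effects are all negative over the range
    odd = _ll4(-0.5, 0.5, direction="up")
    ctx = build_context("g", {"c0": odd}, None, mix, dose_range=(0.01, 10))
    with pytest.warns(UserWarning, match="zero maximum"):
        pred = ia_predict(ctx, [1.0])
    assert pred.predicted[0] == 0.0


def test_literal_form_breaks_single_component_identity():
    """The complement-free variant returns max - E, not E: kept only for
    comparison."""
    mix = _mix(1)
    curve = _ll4(2.0, 0.5)
    ctx = build_context("g", {"c0": curve}, None, mix, dose_range=(0.01, 10))
    dose = np.array([0.3])
    e_val = curve(dose * 1.0)[0]
    literal = ia_predict(ctx, dose, literal_form=True).predicted[0]
    assert literal == pytest.approx(ctx.max_up - e_val, rel=1e-9)


def test_truth_and_fitted_kernels_agree_bitwise():
    mix = _mix(3)
    doses = np.geomspace(0.05, 10, 30)
    truth = {
        f"c{i}": TrueCurveSpec(
            gene="g", treatment=f"c{i}", family="LL.4",
            params={"b": -1.5, "c": 0.0, "d": 1.0 + i, "e": 0.4},
            direction="up",
        )
        for i in range(3)
    }
    via_truth = ia_predict_from_truth(truth, mix, doses, axis="uM", gene="g")
    fitted = {
        name: curve_from_truth(t, dose_max=mix.component(name).proportion * doses.max())
        for name, t in truth.items()
    }
    ctx = build_context(
        "g", fitted, None, mix, dose_range=(doses.max() * 1e-3, doses.max())
    )
    via_fit = ia_predict(ctx, doses)
    np.testing.assert_array_equal(via_truth.predicted, via_fit.predicted)


def test_empty_truth_predicts_zero():
    mix = _mix(2)
    pred = ia_predict_from_truth({"c0": None, "c1": None}, mix, [0.1, 1.0])
    np.testing.assert_array_equal(pred.predicted, 0.0)


def test_bep_axis_follows_highest_tef_component():
    """With TEFs spanning three orders of magnitude, the BeP-equivalent
    prediction's shape tracks the highest-TEF component's curve."""
    tefs = [1.0, 0.01, 0.001]
    mix = _mix(3, tefs=tefs, total=100.0)
    # low-TEF components sit on their plateaus (below the cross-component
    # maximum) over the BeP-equivalent grid; only the TEF = 1 curve varies
    curves = {
        "c0": _ll4(3.0, 0.5, b=-2.0, dose_max=50.0),
        "c1": _ll4(1.5, 0.5, b=-2.0, dose_max=50.0),
        "c2": _ll4(1.5, 0.5, b=-2.0, dose_max=50.0),
    }
    ctx = build_context("g", curves, None, mix, axis="bep", dose_range=(0.05, 1.0))
    grid = np.geomspace(0.05, 1.0, 80)
    pred = ia_predict(ctx, grid).predicted
    specs = {c.name: c for c in mix.components}
    cors = {
        name: np.corrcoef(
            pred, ctx.component_effect(specs[name], curves[name], grid)
        )[0, 1]
        for name in curves
    }
    assert max(cors, key=cors.get) == "c0"  # the TEF = 1 component


def test_bep_axis_requires_tefs():
    mix = _mix(2)  # no TEFs
    curves = {"c0": _ll4(2.0, 0.5), "c1": _ll4(1.0, 0.5)}
    with pytest.raises(ConfigurationError, match="TEF"):
        build_context("g", curves, None, mix, axis="bep", dose_range=(0.01, 10))


class TestIndependentActionModel:
    def test_fit_predict_roundtrip(self, simple_mixture):
        import pandas as pd

        rng = np.random.default_rng(3)
        rows = []
        for spec, d in zip(simple_mixture.components, (2.0, 1.0)):
            for r in (0.0, 0.005, 0.01, 0.05, 0.1):
                dose = r * simple_mixture.full_strength_total * spec.proportion
                mean = 0.0 if r == 0 else d * dose / (0.05 + dose)
                for rep in range(4):
                    rows.append(
                        {"gene": "g", "treatment": spec.name, "rel_conc": r,
                         "log2fc": mean + 0.01 * rng.standard_normal()}
                    )
        model = IndependentActionModel(mixture=simple_mixture).fit(pd.DataFrame(rows))
        assert set(model.curves_) == {"alpha", "beta"}
        assert model.context_.n_up == 2
        pred = model.predict([0.5, 1.0])
        assert pred.shape == (2,) and np.all(pred > 0)

    def test_sklearn_params_roundtrip(self, simple_mixture):
        from sklearn.base import clone

        model = IndependentActionModel(mixture=simple_mixture, axis="bep")
        again = clone(model)
        assert again.get_params()["axis"] == "bep"
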