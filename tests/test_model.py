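"""Model specification, marginal likelihood, fitting, and comparison."""

import math

import numpy as np
import pandas as pd
import pytest

from recalldecay import (
    ModelSpec,
    PersonTimeTable,
    RecallDecayModel,
    SimConfig,
    build_design,
    build_person_time,
    count_parameters,
    generate_cohort,
    lrt,
    month12_model,
)
from recalldecay.decay import DecayCurve

from conftest import TERTILE_COEFFS


# -- specification and design ---------------------------------------------


@pytest.mark.parametrize(
    "spec,expected",
    [
        (ModelSpec(time_effect="categorical"), 21),
        (ModelSpec(time_effect="polynomial", degree=2), 13),
        (ModelSpec(time_modifier="ses_tertile"), 17),
        (
            ModelSpec(
                time_effect="piecewise",
                time_modifier="ses_tertile",
                piecewise_degrees={"lower": 2, "middle": 1, "upper": 1},
            ),
            15,
        ),
        (ModelSpec(time_effect="none", random_household=False), 10),
    ],
)
def test_count_parameters(spec, expected):
    assert count_parameters(spec) == expected


def test_invalid_specs_rejected():
    with pytest.raises(ValueError):
        ModelSpec(degree=4)
    with pytest.raises(ValueError):
        ModelSpec(time_effect="piecewise", time_modifier="ses_tertile")
    with pytest.raises(ValueError):
        ModelSpec(time_effect="categorical", time_modifier="sex")
    with pytest.raises(ValueError):
        ModelSpec(months=frozenset())


def test_spec_dict_round_trip():
    spec = ModelSpec(
        time_effect="piecewise",
        time_modifier="ses_tertile",
        piecewise_degrees={"lower": 2, "middle": 1, "upper": 1},
        months=frozenset({1, 2, 3}),
    )
    assert ModelSpec.from_dict(spec.to_dict()) == spec


def test_design_month1_has_zero_time_columns(toy_household_table):
    spec = ModelSpec(
        main_effects=(), random_household=False, months=frozenset({1, 2, 3, 4})
    )
    d = build_design(spec, toy_household_table)
    assert d.names == ["intercept", "t", "t2"]
    m1 = d.frame["month"].to_numpy() == 1
    np.testing.assert_array_equal(d.X[m1, 1:], 0.0)  # t = month - 1 = 0
    np.testing.assert_allclose(d.offset, np.log(d.exposure))


def test_design_no_time_effect_has_no_time_columns(toy_household_table):
    spec = ModelSpec(time_effect="none", main_effects=("sex",), random_household=False)
    d = build_design(spec, toy_household_table)
    assert d.names == ["intercept", "sex[male]"]


def test_non_hierarchical_design_is_valid(toy_household_table):
    """Interaction columns without the modifier's main effect: meaningful
    because main effects act at t=0 (true rates) and the modifier may affect
    recall only."""
    spec = ModelSpec(
        main_effects=("sex",), time_modifier="ses_tertile", random_household=False
    )
    d = build_design(spec, toy_household_table)
    assert "ses_tertile[lower]" not in d.names
    assert "t:ses_tertile[middle]" in d.names and "t2:ses_tertile[upper]" in d.names
    assert count_parameters(spec) == len(d.names)


def test_rank_deficient_design_names_columns(toy_household_table):
    # all toy rows are urban, so the rural dummy is identically zero
    spec = ModelSpec(main_effects=("location",), random_household=False)
    with pytest.raises(ValueError, match="location\\[rural\\]"):
        build_design(spec, toy_household_table)


# -- marginal likelihood --------------------------------------------------


def test_single_cell_poisson_loglik_closed_form(single_cell_table):
    # events=2 with mean exposure*exp(eta)=2 at eta coefficients (0):
    # log(2^2 e^-2 / 2!) = log 2 - 2
    spec = ModelSpec(time_effect="none", main_effects=(), random_household=False)
    model = RecallDecayModel(single_cell_table, spec)
    assert model.loglike([0.0]) == pytest.approx(math.log(2.0) - 2.0)


def test_sigma_zero_reduces_to_poisson_loglik(toy_household_table):
    months = frozenset({1, 2, 3, 4})
    m_r = RecallDecayModel(
        toy_household_table, ModelSpec(main_effects=(), degree=1, months=months)
    )
    m_f = RecallDecayModel(
        toy_household_table,
        ModelSpec(main_effects=(), degree=1, months=months, random_household=False),
    )
    beta = np.array([0.3, -0.2])
    assert m_r.loglike(np.r_[beta, 0.0]) == pytest.approx(m_f.loglike(beta), abs=1e-8)


def test_marginal_loglik_matches_fine_grid_integration(toy_household_table):
    """Gauss-Hermite vs brute-force trapezoid integration of the household
    random effect (10,000 nodes over +/- 8 sigma), sigma^2 = 0.5."""
    from scipy.special import gammaln

    months = frozenset({1, 2, 3, 4})
    spec = ModelSpec(main_effects=(), degree=1, months=months)
    model = RecallDecayModel(toy_household_table, spec, quad_nodes=40)
    beta = np.array([-0.1, -0.3])
    sigma = math.sqrt(0.5)

    d = model.design
    eta = d.X @ beta + d.offset
    df = d.frame
    u = np.linspace(-8 * sigma, 8 * sigma, 10_001)
    phi = np.exp(-0.5 * (u / sigma) ** 2) / (sigma * math.sqrt(2 * math.pi))
    oracle = 0.0
    for hh in df["household_id"].unique():
        idx = (df["household_id"] == hh).to_numpy()
        y, e = d.y[idx], eta[idx]
        ll_u = (
            y[:, None] * (e[:, None] + u[None, :])
            - np.exp(e[:, None] + u[None, :])
            - gammaln(y + 1)[:, None]
        ).sum(axis=0)
        oracle += math.log(np.trapezoid(np.exp(ll_u) * phi, u))
    assert model.loglike(np.r_[beta, sigma]) == pytest.approx(oracle, abs=1e-6)


def test_score_matches_finite_differences(toy_household_table):
    spec = ModelSpec(main_effects=(), degree=1, months=frozenset({1, 2, 3, 4}))
    model = RecallDecayModel(toy_household_table, spec)
    params = np.array([-0.2, -0.1, 0.4])
    g = model.score(params)
    for j in range(len(params)):
        h = 1e-6
        up, dn = params.copy(), params.copy()
        up[j] += h
        dn[j] -= h
        fd = (model.loglike(up) - model.loglike(dn)) / (2 * h)
        assert g[j] == pytest.approx(fd, abs=1e-5)


def test_non_finite_predictor_identifies_cell(single_cell_table):
    spec = ModelSpec(time_effect="none", main_effects=(), random_household=False)
    model = RecallDecayModel(single_cell_table, spec)
    with pytest.raises(ValueError, match="non-finite linear predictor"):
        model.loglike([np.inf])


# -- fitting --------------------------------------------------------------


def test_glm_special_case_matches_statsmodels_irls(lower_decay_cohort):
    import statsmodels.api as sm

    _, _, table = lower_decay_cohort
    spec = ModelSpec(main_effects=("sex",), random_household=False)
    model = RecallDecayModel(table, spec)
    res = model.fit()
    d = model.design
    oracle = sm.GLM(d.y, d.X, family=sm.families.Poisson(), offset=d.offset).fit()
    np.testing.assert_allclose(res.params.to_numpy(), oracle.params, atol=1e-6)
    np.testing.assert_allclose(res.llf, oracle.llf, atol=1e-6)
    np.testing.assert_allclose(res.bse.to_numpy(), oracle.bse, atol=1e-5)


def test_degree2_fit_recovers_generator_coefficients(lower_decay_cohort):
    """Single-replicate recovery: fitted (b1, b2) within 3 Wald SEs of truth."""
    _, _, table = lower_decay_cohort
    res = RecallDecayModel(
        table, ModelSpec(main_effects=(), random_household=False)
    ).fit()
    assert res.converged
    for name, truth in [("t", -0.527), ("t2", 0.036)]:
        assert abs(res.params[name] - truth) < 3 * res.bse[name]


def test_random_intercept_variance_recovery():
    cfg = SimConfig(
        n_households=300,
        baseline_rate=0.323,
        decay=DecayCurve(TERTILE_COEFFS["lower"]),
        frailty_sd=0.6,
        seed=3,
    )
    table = build_person_time(generate_cohort(cfg))
    res = RecallDecayModel(table, ModelSpec(main_effects=())).fit()
    assert res.converged
    assert res.sigma2 == pytest.approx(0.36, abs=0.25)
    # doubling the quadrature nodes barely moves the optimum loglik
    model40 = RecallDecayModel(table, ModelSpec(main_effects=()), quad_nodes=40)
    assert abs(model40.loglike(res.params.to_numpy()) - res.llf) < 1e-6


def test_all_zero_event_table_flagged_nonconverged(toy_household_table):
    df = toy_household_table.data.copy()
    df["events"] = 0
    spec = ModelSpec(
        time_effect="none", main_effects=(), random_household=False,
        months=frozenset({1, 2, 3, 4}),
    )
    with pytest.warns(UserWarning, match="all-zero"):
        res = RecallDecayModel(PersonTimeTable(df), spec).fit()
    assert not res.converged
    assert res.llf == -math.inf


def test_aic_identity_and_nested_loglik_monotonicity(lower_decay_cohort):
    _, _, table = lower_decay_cohort
    fits = {}
    for deg in (1, 2):
        res = RecallDecayModel(
            table, ModelSpec(degree=deg, main_effects=(), random_household=False)
        ).fit()
        assert res.aic == pytest.approx(2 * res.n_params - 2 * res.llf)
        fits[deg] = res
    assert fits[2].llf >= fits[1].llf - 1e-9
    chi2, df = lrt(fits[1], fits[2])
    assert df == 1 and chi2 >= 0


def test_lrt_identical_models_and_df_arithmetic(lower_decay_cohort):
    _, _, table = lower_decay_cohort
    mk = lambda **kw: RecallDecayModel(
        table, ModelSpec(main_effects=("sex",), random_household=False, **kw)
    ).fit()
    none = mk(time_effect="none")
    cat = mk(time_effect="categorical")
    quad = mk(time_effect="polynomial", degree=2)

    assert lrt(none, none) == (0.0, 0)
    chi2, df = lrt(none, cat)
    assert df == 10  # categorical months 1-11 vs no time effect
    assert chi2 > 0
    chi2, df = lrt(quad, cat)  # polynomial is in the categorical span
    assert df == 8
    with pytest.raises(ValueError, match="not nested"):
        lrt(mk(time_effect="polynomial", degree=1), quad_modified(table))


def quad_modified(table):
    return RecallDecayModel(
        table,
        ModelSpec(main_effects=(), time_modifier="sex", random_household=False),
    ).fit()


def test_predicted_rates_invariant_to_reference_level(lower_decay_cohort):
    _, _, table = lower_decay_cohort
    frame = pd.DataFrame(
        {
            "sex": ["female", "male"],
            "age_group": ["16-44", "0-15"],
            "education": ["none", "secondary"],
            "location": ["urban", "rural"],
            "ses_tertile": ["middle", "lower"],
            "month": [1, 4],
        }
    )
    base = ModelSpec(main_effects=("sex",), random_household=False)
    alt = ModelSpec(
        main_effects=("sex",),
        random_household=False,
        reference_levels={"sex": "male"},
    )
    r1 = RecallDecayModel(table, base).fit().predict_rate(frame)
    r2 = RecallDecayModel(table, alt).fit().predict_rate(frame)
    np.testing.assert_allclose(r1, r2, rtol=1e-6)


def test_fit_json_round_trip(tmp_path, lower_decay_cohort):
    from recalldecay.model import load_fit_json

    _, _, table = lower_decay_cohort
    res = RecallDecayModel(
        table, ModelSpec(main_effects=(), random_household=False)
    ).fit()
    path = tmp_path / "fit.json"
    res.to_json(path)
    back = load_fit_json(path)
    assert back["spec"] == res.spec
    assert back["aic"] == pytest.approx(res.aic)
    assert back["coefficients"]["t"] == pytest.approx(res.params["t"])
    assert "coef" in res.summary() and "log-quadratic" in res.summary()


# -- month 12 vs month 1 --------------------------------------------------


def _month12_table(py1, ev1, py12, ev12, n_households=5):
    rows = []
    for h in range(n_households):
        for month, py, ev in [(1, py1, ev1), (12, py12, ev12)]:
            rows.append(
                dict(
                    sex="female", age_group="16-44", education="none",
                    location="urban", ses_tertile="middle",
                    household_id=f"h{h}", month=month,
                    person_years=py, events=ev,
                )
            )
    return PersonTimeTable(pd.DataFrame(rows))


def test_month12_offset_handles_unequal_exposure():
    # equal rates, doubled exposure in month 12: ratio exactly 1
    table = _month12_table(py1=10.0, ev1=5, py12=20.0, ev12=10)
    res = month12_model(table, main_effects=(), random_household=False)
    ratio, lo, hi = res.rate_ratio_for("month[12]")
    assert ratio == pytest.approx(1.0, abs=1e-8)


def test_month12_null_simulation_ratio_near_one():
    cfg = SimConfig(n_households=600, baseline_rate=0.4, seed=21)
    table = build_person_time(generate_cohort(cfg))
    res = month12_model(table, main_effects=(), random_household=False)
    ratio, lo, hi = res.rate_ratio_for("month[12]")
    assert lo < 1.0 < hi


def test_month12_ratio_increases_with_telescoping():
    ratios = []
    for tp in (0.0, 0.1, 0.25):
        cfg = SimConfig(n_households=600, baseline_rate=0.4, telescope_prob=tp, seed=9)
        table = build_person_time(generate_cohort(cfg))
        res = month12_model(table, main_effects=(), random_household=False)
        ratios.append(res.rate_ratio_for("month[12]")[0])
    assert ratios[0] < ratios[1] < ratios[2]
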