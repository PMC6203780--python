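"""Published-style base models: rate-table absolute risk and Cox predictor."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from crcgrs.base_models import (
    AgeRateTable,
    CoxCovariate,
    CoxModelSpec,
    FamilyHistoryRR,
    cox_absolute_risk,
    cox_linear_predictor,
    remove_covariate_effect,
    taylor_absolute_risk,
)


@pytest.fixture
def rates():
    return AgeRateTable(
        pd.DataFrame(
            {
                "age_lower": [40, 50, 60],
                "age_upper": [50, 60, 70],
                "rate": [0.0005, 0.001, 0.002],
            }
        )
    )


@pytest.fixture
def constant_rates():
    return AgeRateTable(
        pd.DataFrame({"age_lower": [40], "age_upper": [80], "rate": [0.001]})
    )


@pytest.fixture
def fh_rr():
    return FamilyHistoryRR({0: 1.0, 1: 2.0, 2: 4.0})


class TestAgeRateTable:
    def test_non_contiguous_bands_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            AgeRateTable(
                pd.DataFrame(
                    {"age_lower": [40, 55], "age_upper": [50, 60], "rate": [1e-3, 1e-3]}
                )
            )

    def test_uncovered_age_range_names_gap(self, rates):
        with pytest.raises(ValueError, match="not covered"):
            rates.cumulative_hazard(65.0, 72.0)

    def test_band_overlap_equals_quadrature(self, rates):
        def step_rate(a):
            if a < 50:
                return 0.0005
            if a < 60:
                return 0.001
            return 0.002

        for lo, hi in [(42.3, 47.1), (48.5, 63.2), (40.0, 70.0), (55.0, 55.0)]:
            quad, _ = integrate.quad(
                step_rate, lo, hi, points=[50, 60], limit=200, epsabs=1e-13
            )
            assert rates.cumulative_hazard(lo, hi) == pytest.approx(quad, abs=1e-10)


class TestTaylorAbsoluteRisk:
    def test_zero_rates_give_zero_risk(self, fh_rr):
        zero = AgeRateTable(
            pd.DataFrame({"age_lower": [40], "age_upper": [80], "rate": [0.0]})
        )
        pred = taylor_absolute_risk(50.0, 1, zero, fh_rr)
        assert pred.risk[0] == 0.0

    def test_closed_form_constant_rate(self, constant_rates, fh_rr):
        pred = taylor_absolute_risk(50.0, 1, constant_rates, fh_rr, horizon=5.0)
        assert pred.risk[0] == pytest.approx(1.0 - np.exp(-2 * 0.001 * 5))
        assert pred.log_hazard_ratio[0] == pytest.approx(np.log(2.0))

    def test_reference_category_is_baseline(self, constant_rates, fh_rr):
        pred = taylor_absolute_risk(50.0, 0, constant_rates, fh_rr, horizon=5.0)
        assert pred.risk[0] == pytest.approx(1.0 - np.exp(-0.001 * 5))
        assert pred.log_hazard_ratio[0] == 0.0

    def test_monotone_in_horizon_rr_and_rate(self, rates, fh_rr):
        r1 = taylor_absolute_risk(45.0, 0, rates, fh_rr, horizon=3.0).risk[0]
        r2 = taylor_absolute_risk(45.0, 0, rates, fh_rr, horizon=10.0).risk[0]
        assert r2 >= r1
        r3 = taylor_absolute_risk(45.0, 2, rates, fh_rr, horizon=3.0).risk[0]
        assert r3 >= r1
        hot = AgeRateTable(
            pd.DataFrame({"age_lower": [40], "age_upper": [80], "rate": [0.01]})
        )
        cold = AgeRateTable(
            pd.DataFrame({"age_lower": [40], "age_upper": [80], "rate": [0.001]})
        )
        assert (
            taylor_absolute_risk(45.0, 0, hot, fh_rr).risk[0]
            >= taylor_absolute_risk(45.0, 0, cold, fh_rr).risk[0]
        )

    def test_small_hazard_first_order_bound(self, fh_rr):
        lam = 2e-4 * 5  # small cumulative hazard
        tab = AgeRateTable(
            pd.DataFrame({"age_lower": [40], "age_upper": [80], "rate": [2e-4]})
        )
        risk = taylor_absolute_risk(50.0, 0, tab, fh_rr, horizon=5.0).risk[0]
        assert abs(risk - lam) <= lam**2 / 2


@pytest.fixture
def cox_spec():
    return CoxModelSpec(
        covariates=[
            CoxCovariate(name="age", coef=0.05, reference=55.0),
            CoxCovariate(name="bmi", coef=0.3, reference=27.0, per_unit=1.0),
            CoxCovariate(
                name="oestrogen", coef=-0.2, sex_mask="F"
            ),
            CoxCovariate(
                name="fh_category", kind="categorical",
                levels={0: 0.0, 1: 0.4, 2: 0.8},
            ),
        ],
        baseline_survival=0.99,
    )


class TestCoxLinearPredictor:
    def test_reference_profile_gives_zero(self, cox_spec):
        row = pd.DataFrame(
            {"age": [55.0], "bmi": [27.0], "oestrogen": [0], "fh_category": [0],
             "sex": ["F"]}
        )
        assert cox_linear_predictor(row, cox_spec)[0] == 0.0

    def test_single_covariate_two_units(self, cox_spec):
        row = pd.DataFrame(
            {"age": [55.0], "bmi": [29.0], "oestrogen": [0], "fh_category": [0],
             "sex": ["F"]}
        )
        assert cox_linear_predictor(row, cox_spec)[0] == pytest.approx(0.6)

    def test_sex_mask_matches_loop_oracle(self, cox_spec):
        rng = np.random.default_rng(6)
        n = 50
        df = pd.DataFrame(
            {
                "age": rng.uniform(40, 70, n),
                "bmi": rng.uniform(20, 35, n),
                "oestrogen": rng.integers(0, 2, n),
                "fh_category": rng.integers(0, 3, n),
                "sex": rng.choice(["F", "M"], n),
            }
        )
        eta = cox_linear_predictor(df, cox_spec)
        for i in range(n):
            expected = (
                0.05 * (df.loc[i, "age"] - 55.0)
                + 0.3 * (df.loc[i, "bmi"] - 27.0)
                + {0: 0.0, 1: 0.4, 2: 0.8}[df.loc[i, "fh_category"]]
            )
            if df.loc[i, "sex"] == "F":
                expected += -0.2 * df.loc[i, "oestrogen"]
            assert eta[i] == pytest.approx(expected, abs=1e-12)

    def test_missing_covariate_named(self, cox_spec):
        row = pd.DataFrame({"age": [55.0], "sex": ["F"]})
        with pytest.raises(ValueError, match="bmi"):
            cox_linear_predictor(row, cox_spec)


class TestCoxAbsoluteRisk:
    def test_reference_risk(self, cox_spec):
        pred = cox_absolute_risk(np.array([0.0]), cox_spec)
        assert pred.risk[0] == pytest.approx(1.0 - 0.99)

    def test_unit_baseline_survival_gives_zero_risk(self):
        spec = CoxModelSpec(covariates=[], baseline_survival=1.0)
        assert cox_absolute_risk(np.array([3.0]), spec).risk[0] == 0.0

    def test_hand_computed_risk(self):
        spec = CoxModelSpec(covariates=[], baseline_survival=0.99)
        pred = cox_absolute_risk(np.array([np.log(2.0)]), spec)
        assert pred.risk[0] == pytest.approx(1.0 - 0.99**2)

    def test_strictly_increasing_in_eta(self, cox_spec):
        etas = np.linspace(-2, 2, 30)
        risks = cox_absolute_risk(etas, cox_spec).risk
        assert np.all(np.diff(risks) > 0)

    def test_invalid_baseline_survival_rejected(self):
        with pytest.raises(ValueError):
            CoxModelSpec(covariates=[], baseline_survival=0.0)


class TestRemoveCovariateEffect:
    def test_remove_nothing_is_identity(self, cox_spec):
        out = remove_covariate_effect(cox_spec, [])
        row = pd.DataFrame(
            {"age": [60.0], "bmi": [30.0], "oestrogen": [1], "fh_category": [1],
             "sex": ["F"]}
        )
        assert cox_linear_predictor(row, out)[0] == cox_linear_predictor(row, cox_spec)[0]

    def test_removing_age_zeroes_age_differences(self, cox_spec):
        out = remove_covariate_effect(cox_spec, ["age"])
        base = {"bmi": [27.0], "oestrogen": [0], "fh_category": [0], "sex": ["M"]}
        young = pd.DataFrame({"age": [40.0], **base})
        old = pd.DataFrame({"age": [69.0], **base})
        assert cox_linear_predictor(young, out)[0] == cox_linear_predictor(old, out)[0]
        # the original spec is untouched
        assert cox_spec.covariates[0].coef == 0.05

    def test_categorical_levels_zeroed(self, cox_spec):
        out = remove_covariate_effect(cox_spec, ["fh_category"])
        assert all(v == 0.0 for v in out.covariates[3].levels.values())

    def test_unknown_name_rejected(self, cox_spec):
        with pytest.raises(ValueError, match="nope"):
            remove_covariate_effect(cox_spec, ["nope"])


def test_fixture_model_spec_loads():
    from crcgrs.pipeline import _FIXTURES

    spec = CoxModelSpec.from_yaml(_FIXTURES / "wells_style_model.yaml")
    assert "age" in spec.covariate_names
    assert 0.0 < spec.baseline_survival < 1.0
    rates = AgeRateTable.from_tsv(_FIXTURES / "crc_age_rates.tsv")
    rr = FamilyHistoryRR.from_tsv(_FIXTURES / "fh_relative_risk.tsv")
    pred = taylor_absolute_risk(55.0, 1, rates, rr)
    assert 0.0 < pred.risk[0] < 0.05
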