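import numpy as np
import pandas as pd
import pytest
from scipy.stats import skew

from tricomp import stats
from tricomp.anthropometry import augment_cohort
from tricomp.stats import (
    AssociationModel,
    association_grid,
    build_three_compartments,
    lnskew0,
    residualize,
    sensitivity_exclude,
    significance_mark,
    standardized_association,
)
from tricomp.synthetic import CohortSpec, default_effects, generate_cohort


class TestLnskew0:
    def test_known_shift_recovered(self):
        rng = np.random.default_rng(0)
        x = 5.0 + rng.lognormal(0.0, 1.0, 100_000)
        k, y = lnskew0(x)
        assert abs(skew(y, bias=True)) < 1e-6
        assert k == pytest.approx(5.0, abs=0.1)
        assert k < x.min()

    def test_zero_skew_sample_stays_zero_skew(self):
        rng = np.random.default_rng(1)
        x = 10.0 + rng.lognormal(0.0, 0.8, 20_000)
        _, y = lnskew0(x)
        # transforming an already-zero-skew sample leaves skewness at zero
        k2, y2 = lnskew0(np.exp(y))  # exp(y) has ln-shift root at k=0-ish
        assert abs(skew(y2, bias=True)) < 1e-6

    def test_negative_skew_handled(self):
        rng = np.random.default_rng(2)
        x = 50.0 - rng.lognormal(0.0, 0.8, 20_000)
        k, y = lnskew0(x)
        assert abs(skew(y, bias=True)) < 1e-6

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            lnskew0(np.full(100, 3.0))

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            lnskew0(np.arange(5.0))


class TestResidualize:
    def test_residual_orthogonal_to_covariate(self, rng):
        x = rng.normal(size=500)
        y = 3.0 + 2.0 * x + rng.normal(size=500)
        res = residualize(y, x[:, None])
        assert abs(np.corrcoef(res, x)[0, 1]) < 1e-12
        assert abs(res.mean()) < 1e-12

    def test_orthogonal_input_returns_centered_y(self, rng):
        x = rng.normal(size=400)
        y = rng.normal(size=400)
        y_orth = y - np.polyval(np.polyfit(x, y, 1), x)  # strip x-component
        res = residualize(y_orth, x[:, None])
        np.testing.assert_allclose(res, y_orth - y_orth.mean(), atol=1e-10)

    def test_exact_fit_gives_zero_residuals(self, rng):
        x = rng.normal(size=200)
        res = residualize(x, x[:, None])
        np.testing.assert_allclose(res, 0.0, atol=1e-12)

    def test_rank_deficiency_names_columns(self, rng):
        x = rng.normal(size=100)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="b"):
            residualize(rng.normal(size=100), X)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            residualize(np.arange(2.0), np.arange(2.0)[:, None])


class TestBuildThreeCompartments:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_pairwise_orthogonality(self, seed):
        cohort, _ = generate_cohort(CohortSpec(n=200, seed=seed))
        rc = build_three_compartments(cohort["nat"], cohort["sat"], cohort["vat"])
        assert rc.max_abs_correlation() < 1e-10
        assert abs(rc.rsat.mean()) < 1e-10
        assert abs(rc.rvat.mean()) < 1e-10

    def test_proportional_sat_flagged_degenerate(self, rng):
        nat = rng.normal(35.0, 5.0, 100)
        rc = build_three_compartments(nat, 0.5 * nat, rng.lognormal(0, 0.4, 100))
        assert "degenerate_rsat" in rc.flags
        np.testing.assert_allclose(rc.rsat, 0.0, atol=1e-8)

    def test_matches_gram_schmidt_oracle(self, rng):
        n = 300
        nat = rng.normal(35, 6, n)
        sat = 0.6 * nat + rng.lognormal(1.5, 0.5, n)
        vat = 0.02 * nat + 0.05 * sat + rng.lognormal(-0.5, 0.5, n)
        rc = build_three_compartments(nat, sat, vat)

        # oracle: classical Gram-Schmidt on centered vectors
        def proj(u, v):
            return (u @ v) / (u @ u) * u

        one = np.ones(n)
        c_nat = nat - nat.mean()
        g_sat = sat - sat.mean() - proj(c_nat, sat - sat.mean())
        c_vat = vat - vat.mean()
        g_vat = c_vat - proj(c_nat, c_vat) - proj(g_sat, c_vat)
        np.testing.assert_allclose(rc.rsat, g_sat, atol=1e-8)
        np.testing.assert_allclose(rc.rvat, g_vat, atol=1e-8)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            build_three_compartments(np.ones(10), np.ones(10), np.ones(9))

    def test_extra_covariates_sensitivity_variant(self, rng):
        n = 150
        age = rng.uniform(13, 18, n)
        nat = rng.normal(35, 6, n) + 1.5 * age
        sat = 0.5 * nat + 0.8 * age + rng.lognormal(1.5, 0.4, n)
        vat = 0.05 * sat + rng.lognormal(-0.5, 0.5, n)
        rc = build_three_compartments(nat, sat, vat, extra_covariates=age[:, None])
        assert abs(np.corrcoef(rc.rsat, age)[0, 1]) < 1e-10
        assert abs(np.corrcoef(rc.rvat, age)[0, 1]) < 1e-10
        assert abs(np.corrcoef(rc.rsat, rc.rvat)[0, 1]) < 1e-10


class TestStandardizedAssociation:
    def test_predictor_identical_to_outcome(self, rng):
        y = rng.normal(size=300)
        data = pd.DataFrame({"y": y, "x": y})
        out = standardized_association(
            data, "y", ["x"], AssociationModel(covariates=(), transform_skewed=False)
        )
        assert out["r"].iloc[0] == pytest.approx(1.0, abs=1e-10)
        assert out["p"].iloc[0] < 1e-100

    def test_frisch_waugh_equivalence(self, rng):
        # single predictor + covariates: standardized slope equals the
        # correlation of residualized outcome with residualized predictor
        n = 400
        age = rng.uniform(13, 18, n)
        sex = (rng.uniform(size=n) > 0.5).astype(float)
        x = rng.normal(size=n) + 0.3 * age
        y = 0.4 * x + 0.2 * age + 0.5 * sex + rng.normal(size=n)
        data = pd.DataFrame({"y": y, "x": x, "age": age, "sex": sex})
        out = standardized_association(
            data, "y", ["x"], AssociationModel(transform_skewed=False)
        )
        Z = np.column_stack([age, sex])
        ry = residualize((y - y.mean()) / y.std(ddof=1), Z)
        rx = residualize((x - x.mean()) / x.std(ddof=1), Z)
        expected = (ry @ rx) / (rx @ rx)
        assert out["r"].iloc[0] == pytest.approx(expected, abs=1e-10)

    def test_zero_variance_rejected(self, rng):
        data = pd.DataFrame(
            {"y": rng.normal(size=50), "x": np.ones(50), "age": rng.uniform(13, 18, 50),
             "sex": rng.integers(0, 2, 50)}
        )
        with pytest.raises(ValueError):
            standardized_association(data, "y", ["x"])

    def test_skew_transform_applied_when_triggered(self, rng):
        n = 500
        y = np.exp(rng.normal(size=n))  # heavily skewed, positive
        data = pd.DataFrame({"y": y, "x": rng.normal(size=n),
                             "age": rng.uniform(13, 18, n),
                             "sex": rng.integers(0, 2, n)})
        out = standardized_association(data, "y", ["x"])
        assert bool(out["transformed"].iloc[0])


@pytest.fixture(scope="module")
def grid_cohort():
    frame, _ = generate_cohort(CohortSpec(n=120, seed=6))
    return augment_cohort(frame)


@pytest.fixture(scope="module")
def clinic_cohort():
    frame, _ = generate_cohort(CohortSpec(n=82, clinic_count=3, seed=7))
    return augment_cohort(frame)


class TestAssociationGrid:
    def test_three_comp_arity(self, grid_cohort):
        grid = association_grid(grid_cohort, "three-comp")
        assert len(grid) == 18 * 3
        assert set(grid["predictor"]) == {"nat", "rsat", "rvat"}

    def test_anthro_arity(self, grid_cohort):
        grid = association_grid(grid_cohort, "anthro")
        assert len(grid) == 18 * 3
        assert set(grid["predictor"]) == {"bmi_z", "waist_z", "waist_height_z"}

    def test_bmi_adj_nat_arity(self, grid_cohort):
        grid = association_grid(grid_cohort, "bmi-adj-nat")
        assert len(grid) == 18
        assert set(grid["predictor"]) == {"bmi_z_adj_nat"}

    def test_determinism(self, grid_cohort):
        g1 = association_grid(grid_cohort, "three-comp")
        g2 = association_grid(grid_cohort, "three-comp")
        pd.testing.assert_frame_equal(g1, g2)

    def test_unknown_model_spec_rejected(self, grid_cohort):
        with pytest.raises(ValueError, match="unknown model_spec"):
            association_grid(grid_cohort, "nope")

    def test_coefficients_bounded(self, grid_cohort):
        grid = association_grid(grid_cohort, "three-comp")
        assert (grid["r"].abs() <= 1.0 + 1e-9).all()
        assert grid["p"].between(0, 1).all()

    def test_planted_sign_pattern(self):
        # NAT drives LV mass up, SAT drives E/A down: the grid must assign
        # the positive LV-mass column to nat and the negative E/A column to rsat
        eff = default_effects() * 0.0
        eff.loc["lv_mass", "nat"] = 0.8
        eff.loc["e_a", "sat"] = -0.5
        cohort, _ = generate_cohort(CohortSpec(n=400, effects=eff, seed=12))
        grid = association_grid(
            cohort, "three-comp", model=AssociationModel(transform_skewed=False)
        )
        lv_nat = grid[(grid.outcome == "lv_mass") & (grid.predictor == "nat")].iloc[0]
        ea_rsat = grid[(grid.outcome == "e_a") & (grid.predictor == "rsat")].iloc[0]
        assert lv_nat["r"] > 0 and lv_nat["significant"] == "significant"
        assert ea_rsat["r"] < 0 and ea_rsat["significant"] == "significant"


class TestSensitivityExclude:
    def test_excluded_run_n(self, clinic_cohort):
        full, excl, comparison = sensitivity_exclude(clinic_cohort, "three-comp")
        assert full["n"].eq(82).all()
        assert excl["n"].eq(79).all()
        assert {"r_full", "r_excl", "r_delta"} <= set(comparison.columns)

    def test_no_flagged_subjects_tables_identical(self):
        frame, _ = generate_cohort(CohortSpec(n=60, clinic_count=0, seed=8))
        cohort = augment_cohort(frame)
        full, excl, _ = sensitivity_exclude(cohort, "three-comp")
        pd.testing.assert_frame_equal(full, excl)

    def test_all_flagged_rejected(self, clinic_cohort):
        allflag = clinic_cohort.copy()
        allflag["clinic_recruit"] = True
        with pytest.raises(ValueError, match="empties"):
            sensitivity_exclude(allflag, "three-comp")

    def test_missing_flag_column_rejected(self, clinic_cohort):
        with pytest.raises(ValueError, match="not present"):
            sensitivity_exclude(clinic_cohort.drop(columns=["clinic_recruit"]), "three-comp")


class TestSignificanceMark:
    @pytest.mark.parametrize(
        "p,expected",
        [(0.005, "significant"), (0.0099, "significant"), (0.01, "trend"),
         (0.017, "trend"), (0.0499, "trend"), (0.05, "ns"), (0.5, "ns")],
    )
    def test_thresholds(self, p, expected):
        assert significance_mark(p) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            significance_mark(1.5)
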