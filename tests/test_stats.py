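"""Age mapping, trajectory models, cross-species model, factorial ANOVA."""

import numpy as np
import pandas as pd
import pytest

from segtraj import (
    AgeMapping,
    cross_species_model,
    factorial_anova,
    fit_age_trajectory,
    map_mouse_age,
)


class TestAgeMapping:
    def test_anchor_ages_map_exactly(self):
        assert map_mouse_age(3.0) == pytest.approx(18.0)
        assert map_mouse_age(20.0) == pytest.approx(70.0)

    def test_midpoint_maps_linearly(self):
        assert map_mouse_age(11.5) == pytest.approx(44.0)

    def test_affine_preserves_difference_ratios(self, rng):
        a, b, c = rng.uniform(3, 20, size=3)
        ya, yb, yc = map_mouse_age(a), map_mouse_age(b), map_mouse_age(c)
        assert (yb - ya) / (yc - ya) == pytest.approx((b - a) / (c - a))

    def test_extrapolation_warns(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="segtraj.stats"):
            map_mouse_age(25.0)
        assert any("extrapolating" in r.message for r in caplog.records)

    def test_degenerate_anchors_rejected(self):
        with pytest.raises(ValueError):
            AgeMapping(mouse_anchor_young=5, mouse_anchor_old=5)


def cohort_frame(n=40, slope=0.0, sessions=1, noise=0.05, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    ages0 = np.linspace(3, 20, n)
    for i, a0 in enumerate(ages0):
        subj_re = rng.normal(0, 0.02) if sessions > 1 else 0.0
        for s in range(sessions):
            age = a0 + 3 * s
            rows.append(
                dict(
                    subject_id=f"s{i}",
                    age=age,
                    sex="F" if i % 2 == 0 else "M",
                    session=s + 1,
                    segregation=0.7 + slope * age + subj_re + rng.normal(0, noise),
                )
            )
    return pd.DataFrame(rows)


class TestFitAgeTrajectory:
    def test_constant_response_gives_zero_slope(self):
        df = cohort_frame(noise=0.0, slope=0.0)
        df["segregation"] = 0.5
        fit = fit_age_trajectory(df)
        assert fit["beta_age"] == 0.0

    def test_cross_sectional_equals_closed_form_ols(self):
        df = cohort_frame(slope=-0.004, seed=3)
        fit = fit_age_trajectory(df)
        # independent oracle: normal equations solved directly
        sex = df["sex"].map({"F": -0.5, "M": 0.5}).to_numpy()
        X = np.column_stack([np.ones(len(df)), df["age"], sex - sex.mean()])
        beta = np.linalg.solve(X.T @ X, X.T @ df["segregation"].to_numpy())
        assert fit["beta_age"] == pytest.approx(beta[1], abs=1e-6)
        assert fit["model"] == "ols"

    def test_longitudinal_uses_random_intercept(self):
        df = cohort_frame(slope=-0.004, sessions=3, seed=4)
        fit = fit_age_trajectory(df)
        assert fit["model"] == "mixed"
        assert fit["beta_age"] < 0
        assert fit["beta_age"] == pytest.approx(-0.004, abs=0.002)

    def test_planted_negative_slope_detected(self):
        df = cohort_frame(slope=-0.005, noise=0.02, seed=5)
        fit = fit_age_trajectory(df)
        assert fit["beta_age"] < 0
        assert fit["terms"]["age"]["p"] < 0.01

    def test_slope_invariant_to_response_offset_and_scales_linearly(self):
        df = cohort_frame(slope=-0.004, seed=6)
        base = fit_age_trajectory(df)["beta_age"]
        shifted = df.copy()
        shifted["segregation"] += 5.0
        assert fit_age_trajectory(shifted)["beta_age"] == pytest.approx(base, abs=1e-10)
        scaled = df.copy()
        scaled["segregation"] *= 3.0
        assert fit_age_trajectory(scaled)["beta_age"] == pytest.approx(3 * base, abs=1e-10)

    def test_requires_age_variation(self):
        df = cohort_frame(n=5)
        df["age"] = 7.0
        with pytest.raises(ValueError, match="distinct ages"):
            fit_age_trajectory(df)


class TestCrossSpeciesModel:
    @staticmethod
    def _tables(seed=0, mouse_slope=-0.3, human_slope=-0.5, n=60):
        rng = np.random.default_rng(seed)
        mouse = cohort_frame(n=n, seed=seed)
        mouse["species"] = "mouse"
        mouse["segregation"] = 0.8 + mouse_slope * (
            (map_mouse_age(mouse["age"].to_numpy()) - 44) / 20
        ) * 0.1 + rng.normal(0, 0.03, len(mouse))
        human = cohort_frame(n=n, seed=seed + 1)
        human["age"] = np.linspace(18, 88, len(human))
        human["species"] = "human"
        human["segregation"] = 0.6 + human_slope * ((human["age"] - 53) / 20) * 0.1 + rng.normal(
            0, 0.03, len(human)
        )
        return mouse, human

    def test_label_swap_flips_species_and_interaction_signs(self):
        mouse, human = self._tables(seed=11)
        identity = AgeMapping(18.0, 18.0, 88.0, 88.0)  # mouse ages already in years
        mouse = mouse.assign(age=map_mouse_age(mouse["age"].to_numpy()))
        res = cross_species_model(mouse, human, mapping=identity)
        swapped = cross_species_model(human, mouse, mapping=identity)
        assert swapped["main_species"]["beta"] == pytest.approx(
            -res["main_species"]["beta"], abs=1e-8
        )
        assert swapped["interaction"]["beta"] == pytest.approx(
            -res["interaction"]["beta"], abs=1e-8
        )
        assert swapped["main_age"]["beta"] == pytest.approx(res["main_age"]["beta"], abs=1e-8)

    def test_identical_species_data_yields_zero_species_terms(self):
        _, human = self._tables(seed=2)
        identity = AgeMapping(18.0, 18.0, 88.0, 88.0)
        res = cross_species_model(human, human.copy(), mapping=identity)
        assert res["main_species"]["beta"] == pytest.approx(0.0, abs=1e-10)
        assert res["interaction"]["beta"] == pytest.approx(0.0, abs=1e-10)

    def test_steeper_human_slope_detected(self):
        mouse, human = self._tables(seed=3, mouse_slope=-0.2, human_slope=-0.6, n=100)
        res = cross_species_model(mouse, human)
        assert res["beta_human_std"] < res["beta_mouse_std"]
        assert res["interaction"]["p"] < 0.05

    def test_requires_age_variation_per_species(self):
        mouse, human = self._tables()
        human["age"] = 50.0
        with pytest.raises(ValueError, match="age variation"):
            cross_species_model(mouse, human)


class TestFactorialAnova:
    @staticmethod
    def _balanced(seed=0, effect_a=0.0, effect_b=0.0, interaction=0.0, n=20):
        rng = np.random.default_rng(seed)
        rows = []
        for a in (0, 1):
            for b in (0, 1):
                mu = effect_a * a + effect_b * b + interaction * a * b
                for _ in range(n):
                    rows.append((mu + rng.normal(), a, b))
        arr = np.array(rows)
        return arr[:, 0], arr[:, 1].astype(int), arr[:, 2].astype(int)

    def test_equal_cell_means_give_zero_f(self):
        y = np.array([1.0, 2.0] * 4)  # identical distribution in every cell
        a = np.repeat([0, 0, 1, 1], 2)
        b = np.tile([0, 0, 1, 1], 2)
        res = factorial_anova(y, a, b)
        for term in ("A", "B", "A_x_B"):
            assert res[term]["F"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_computed_sums_of_squares(self):
        # fixed 2 x 2 x (n=3) table
        y = np.array([2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 1.0, 2.0, 3.0, 8.0, 9.0, 13.0])
        a = np.repeat([0, 0, 1, 1], 3)
        b = np.tile([0, 1], 6).repeat(1)
        b = np.array([0, 0, 0, 1, 1, 1, 0, 0, 0, 1, 1, 1])
        res = factorial_anova(y, a, b)
        # independent oracle: explicit balanced two-way decomposition
        cells = {(i, j): y[(a == i) & (b == j)] for i in (0, 1) for j in (0, 1)}
        grand = y.mean()
        ma = {i: y[a == i].mean() for i in (0, 1)}
        mb = {j: y[b == j].mean() for j in (0, 1)}
        n_cell = 3
        ss_a = 2 * n_cell * sum((ma[i] - grand) ** 2 for i in (0, 1))
        ss_b = 2 * n_cell * sum((mb[j] - grand) ** 2 for j in (0, 1))
        ss_ab = n_cell * sum(
            (cells[(i, j)].mean() - ma[i] - mb[j] + grand) ** 2 for i in (0, 1) for j in (0, 1)
        )
        ss_err = sum(((cells[c] - cells[c].mean()) ** 2).sum() for c in cells)
        ms_err = ss_err / 8
        assert res["A"]["F"] == pytest.approx(ss_a / ms_err, rel=1e-10)
        assert res["B"]["F"] == pytest.approx(ss_b / ms_err, rel=1e-10)
        assert res["A_x_B"]["F"] == pytest.approx(ss_ab / ms_err, rel=1e-10)
        assert res["A"]["df"] == (1, 8)

    def test_null_interaction_p_uniform(self):
        # additive cell means: interaction p should be U(0,1)
        from scipy.stats import kstest

        ps = []
        for rep in range(200):
            y, a, b = self._balanced(seed=rep, effect_a=1.0, effect_b=0.5, n=15)
            ps.append(factorial_anova(y, a, b)["A_x_B"]["p"])
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_repeated_design_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        n_subj = 12
        rows = []
        for s in range(n_subj):
            base = rng.normal()
            for a in (0, 1):
                for b in (0, 1):
                    rows.append((base + 0.4 * a + 0.2 * a * b + rng.normal(0, 0.5), a, b, s))
        arr = np.array(rows)
        res = factorial_anova(
            arr[:, 0], arr[:, 1].astype(int), arr[:, 2].astype(int),
            design="repeated", subject=arr[:, 3].astype(int),
        )
        df = pd.DataFrame({"y": arr[:, 0], "A": arr[:, 1], "B": arr[:, 2], "subj": arr[:, 3]})
        pg = pingouin.rm_anova(dv="y", within=["A", "B"], subject="subj", data=df, detailed=True)
        pg = pg.set_index("Source")
        assert res["A"]["F"] == pytest.approx(float(pg.loc["A", "F"]), rel=1e-6)
        assert res["B"]["F"] == pytest.approx(float(pg.loc["B", "F"]), rel=1e-6)
        assert res["A_x_B"]["F"] == pytest.approx(float(pg.loc["A * B", "F"]), rel=1e-6)

    def test_validation(self):
        with pytest.raises(ValueError, match="2 levels"):
            factorial_anova([1, 2, 3], [0, 1, 2], [0, 0, 1])
        with pytest.raises(ValueError, match="cells"):
            factorial_anova([1, 2, 3, 4], [0, 0, 1, 1], [0, 1, 0, 1])
        with pytest.raises(ValueError, match="subject"):
            y, a, b = self._balanced()
            factorial_anova(y, a, b, design="repeated")
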