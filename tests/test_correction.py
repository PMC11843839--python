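"""Correction equations, published-grid parity, adjusted scores."""

import numpy as np
import pytest

import demnorms as dn
from demnorms.correction import ExtrapolationWarning, round_half_up
from demnorms.exceptions import ConfigurationError, DomainError, InvalidParameterError

AGES = list(range(20, 80, 5))

# Published correction grids (education x age for the timed scores, a single
# age row for Ratio, education x sex for errors), in score units.
VT_GRID = {
    8: [-0.2, -0.29, -0.42, -0.61, -0.87, -1.19, -1.6, -2.1, -2.69, -3.39, -4.22, -5.16],
    13: [2.12, 2.02, 1.89, 1.7, 1.44, 1.12, 0.71, 0.22, -0.38, -1.08, -1.9, -2.85],
    16: [2.81, 2.72, 2.58, 2.39, 2.14, 1.81, 1.41, 0.91, 0.31, -0.39, -1.21, -2.16],
    18: [3.14, 3.05, 2.92, 2.72, 2.47, 2.15, 1.74, 1.24, 0.65, -0.06, -0.88, -1.82],
    21: [3.52, 3.43, 3.3, 3.11, 2.85, 2.53, 2.12, 1.62, 1.03, 0.33, -0.5, -1.44],
}
AHT_GRID = {
    8: [0.14, 0.01, -0.18, -0.45, -0.81, -1.27, -1.85, -2.55, -3.39, -4.39, -5.55, -6.89],
    13: [2.91, 2.78, 2.58, 2.31, 1.96, 1.49, 0.92, 0.22, -0.63, -1.62, -2.79, -4.13],
    16: [3.74, 3.61, 3.41, 3.14, 2.79, 2.32, 1.75, 1.04, 0.2, -0.8, -1.96, -3.3],
    18: [4.14, 4.01, 3.81, 3.54, 3.18, 2.72, 2.15, 1.44, 0.6, -0.4, -1.56, -2.9],
    21: [4.59, 4.46, 4.27, 4.0, 3.64, 3.18, 2.6, 1.9, 1.06, 0.06, -1.1, -2.44],
}
RATIO_GRID = [0.02, 0.02, 0.02, 0.02, 0.01, 0.01, 0.0, 0.0, -0.01, -0.02, -0.03, -0.04]
ERRORS_GRID = {8: (-0.3, 0.0), 13: (-0.1, 0.2), 16: (-0.1, 0.2), 18: (-0.1, 0.2), 21: (0.0, 0.3)}


def test_published_timed_grids_cell_for_cell(published_norms):
    for sub, grid in (("vt", VT_GRID), ("aht", AHT_GRID)):
        eq = published_norms.equations[sub]
        for edu, row in grid.items():
            got = eq.values(AGES, [edu] * len(AGES), ["F"] * len(AGES))
            for age, printed, value in zip(AGES, row, got):
                assert round_half_up(value, 2) == pytest.approx(printed, abs=0.0101), (sub, age, edu)


def test_published_ratio_and_errors_grids(published_norms):
    ratio_eq = published_norms.equations["ratio"]
    for age, printed in zip(AGES, RATIO_GRID):
        got = dn.correction_value(ratio_eq, dn.Demographics(age, 13, "F"))
        assert round_half_up(got, 2) == pytest.approx(printed, abs=0.0101)
    err_eq = published_norms.equations["errors"]
    for edu, (male, female) in ERRORS_GRID.items():
        gm = dn.correction_value(err_eq, dn.Demographics(50, edu, "M"))
        gf = dn.correction_value(err_eq, dn.Demographics(50, edu, "F"))
        assert round_half_up(gm, 1) == pytest.approx(male, abs=0.0501)
        assert round_half_up(gf, 1) == pytest.approx(female, abs=0.0501)


def test_emit_grid_matches_published_tables(published_norms):
    grid = dn.emit_grid(published_norms.equations["vt"], list(VT_GRID), AGES, precision=2)
    for edu, row in VT_GRID.items():
        assert np.allclose(grid.table.loc[edu].to_numpy(), row, atol=0.0101)
    single = dn.emit_grid(published_norms.equations["vt"], [8], [75])
    assert single.table.iloc[0, 0] == pytest.approx(-5.16, abs=0.0101)
    with pytest.raises(InvalidParameterError):
        dn.emit_grid(published_norms.equations["vt"], [], AGES)


def test_correction_zero_at_centering_constants(published_norms):
    """At the stored sample means the correction vanishes by construction."""
    eq = published_norms.equations["vt"]
    age_center = 150382.9 ** (1 / 3)
    edu_center = 1 / 0.0854
    v = dn.correction_value(eq, dn.Demographics(age_center, edu_center, "F"))
    assert abs(v) < 1e-9


def test_correction_monotonicity_over_anchor_ranges(published_norms):
    for sub in ("vt", "aht"):
        eq = published_norms.equations[sub]
        for edu in (8, 13, 16, 18, 21):
            vals = eq.values(AGES, [edu] * len(AGES), ["F"] * len(AGES))
            assert (np.diff(vals) < 0).all()  # strictly decreasing in age
        for age in AGES:
            vals = eq.values([age] * 5, [8, 13, 16, 18, 21], ["F"] * 5)
            assert (np.diff(vals) > 0).all()  # strictly increasing in education


def test_correction_domain_and_extrapolation(published_norms):
    eq = published_norms.equations["vt"]
    with pytest.raises(DomainError):
        eq.values([50.0], [0.5], ["F"])  # education below one year
    with pytest.warns(ExtrapolationWarning):
        dn.correction_value(eq, dn.Demographics(85, 13, "F"))


def test_derive_correction_centering(default_cohort):
    """Derived equations store the cohort means and null out at them."""
    best = dn.select_best_model(default_cohort, "vt")
    eq = dn.derive_correction(default_cohort, best)
    frame = default_cohort.frame
    centers = {t.predictor: t.center for t in eq.terms}
    assert centers["age"] == pytest.approx((frame["age"] ** 3).mean())
    assert centers["education"] == pytest.approx((1 / frame["education_years"]).mean())
    corr = eq.values(frame["age"], frame["education_years"], frame["sex"].to_numpy())
    assert float(np.mean(corr)) == pytest.approx(0.0, abs=1e-9)


def test_derived_sex_centering_is_male_share():
    params = dn.GenerativeParams(
        errors=dn.SubtestEffects(intercept=0.2, sex_male=0.4), errors_zero_inflation=0.3
    )
    demos = dn.sample_demographics(521, seed=61)
    cohort = dn.generate_scores(demos, params, seed=62)
    best = dn.select_best_model(cohort, "errors")
    assert best is not None and "sex" in best.params
    eq = dn.derive_correction(cohort, best)
    sex_term = next(t for t in eq.terms if t.predictor == "sex")
    male_share = (cohort.frame["sex"] == "M").mean()
    assert sex_term.center == pytest.approx(male_share)


def test_adjustment_removes_modeled_age_effect(large_cohort, published_norms):
    """Adjusted VT should be nearly uncorrelated with age."""
    from demnorms.correction import adjust_cohort

    # derive the correction from the cohort itself (true model form)
    best = dn.select_best_model(large_cohort, "vt")
    eq = dn.derive_correction(large_cohort, best)
    adjusted = adjust_cohort(large_cohort, {"vt": eq})["vt"]
    r = np.corrcoef(large_cohort.frame["age"], adjusted)[0, 1]
    assert abs(r) < 0.05


def test_adjust_scores_examples(published_norms):
    eqs = published_norms.equations
    adj = dn.adjust_scores(
        dn.RawScores(vt=30.0), dn.Demographics(75, 8, "F"), eqs
    )
    assert adj.vt == pytest.approx(24.84, abs=0.005)
    adj2 = dn.adjust_scores(
        dn.RawScores(errors=0.0), dn.Demographics(50, 21, "F"), eqs
    )
    assert round_half_up(adj2.errors, 1) == pytest.approx(0.3, abs=1e-9)
    with pytest.raises(ConfigurationError):
        dn.adjust_scores(dn.RawScores(vt=30.0), dn.Demographics(50, 13, "F"), {})
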