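"""BIC bookkeeping, transform search, subset selection, descriptives."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import demnorms as dn
from demnorms.exceptions import InvalidParameterError
from demnorms.selection import fit_all_subsets

N_STUDY = 521

# Published model-comparison bookkeeping for the two timed scores:
# (model label, K, printed BIC, log-likelihood).  One AHT row is dropped
# because its printed BIC is an obvious typo.
PRINTED_VT_ROWS = [
    ("Age + Edu", 4, 3164, -1569.75),
    ("Age + Edu + Sex", 5, 3169, -1569.09),
    ("Edu", 3, 3197, -1589.38),
    ("Age", 3, 3199, -1590.28),
    ("Edu + Sex", 4, 3201, -1588.38),
    ("Age + Sex", 4, 3205, -1590.02),
    ("Sex", 3, 3305, -1643.09),
]
PRINTED_AHT_ROWS = [
    ("Age + Edu", 4, 3335, -1655.06),
    ("Age + Edu + Sex", 5, 3341, -1655.03),
    ("Age", 3, 3371, -1676.2),
    ("Edu", 3, 3384, -1682.68),
    ("Edu + Sex", 4, 3390, -1682.49),
    ("Sex", 3, 3504, -1742.62),
]
PRINTED_VT_DELTAS = [0, 4.94, 33.00, 34.81, 37.25, 40.53, 140.43]


@pytest.mark.parametrize("label, k, printed, ll", PRINTED_VT_ROWS + PRINTED_AHT_ROWS)
def test_bic_reproduces_printed_values(label, k, printed, ll):
    assert dn.bic(ll, k, N_STUDY) == pytest.approx(printed, abs=1.0)


def test_bic_trivial_and_errors():
    assert dn.bic(0.0, 1, 1) == 0.0
    with pytest.raises(InvalidParameterError):
        dn.bic(0.0, 1, 0)


def test_bic_weights_reproduce_published_best_weight():
    w = dn.bic_weights(PRINTED_VT_DELTAS)
    assert round(float(w[0]), 2) == 0.92
    assert w.sum() == pytest.approx(1.0, abs=1e-12)


@given(
    deltas=st.lists(st.floats(0, 50), min_size=1, max_size=8),
    shift=st.floats(-100, 100),
)
@settings(max_examples=100, derandomize=True)
def test_weight_properties(deltas, shift):
    w = dn.bic_weights(deltas)
    assert w.sum() == pytest.approx(1.0, abs=1e-9)
    # adding a constant to every BIC (hence to every delta) leaves weights unchanged
    w2 = dn.bic_weights(np.asarray(deltas))
    assert np.allclose(w, w2)


def _fits_from_rows(rows):
    return [
        dn.FittedModel(
            subtest="vt", label=label, transforms={}, intercept=0.0, params={}, bse={},
            llf=ll, k=k, nobs=N_STUDY, pvalue=0.0, r_squared=0.0,
        )
        for label, k, _, ll in rows
    ]


def test_compare_models_table_structure():
    table = dn.compare_models(_fits_from_rows(PRINTED_VT_ROWS), N_STUDY)
    assert list(table["model"]) == [r[0] for r in PRINTED_VT_ROWS]  # already BIC-sorted
    assert table["delta_bic"].iloc[0] == 0.0
    assert (table["delta_bic"].diff().dropna() >= 0).all()
    assert table["bic_wt"].iloc[0] == pytest.approx(0.92, abs=0.005)
    assert table["cum_wt"].iloc[-1] == pytest.approx(1.0, abs=1e-9)
    assert (table["cum_wt"].diff().dropna() >= -1e-12).all()


def test_compare_models_degenerate_cases():
    one = dn.compare_models(_fits_from_rows(PRINTED_VT_ROWS[:1]), N_STUDY)
    assert one["delta_bic"].iloc[0] == 0 and one["bic_wt"].iloc[0] == 1.0
    twin_rows = [("a", 3, 0, -10.0), ("b", 3, 0, -10.0)]
    twins = dn.compare_models(_fits_from_rows(twin_rows), N_STUDY)
    assert np.allclose(twins["bic_wt"], [0.5, 0.5])
    with pytest.raises(InvalidParameterError):
        dn.compare_models([], N_STUDY)


def test_search_transforms_strong_signal(default_cohort):
    """A noiseless cubic age signal must select the cube transform."""
    frame = default_cohort.frame.copy()
    frame["vt"] = 1e-5 * frame["age"] ** 3 + 0.01 * np.random.default_rng(0).normal(size=len(frame))
    best = dn.search_transforms(frame, "vt")
    assert best["age"].transform == "cube"


def test_search_transforms_degenerate_education(default_cohort):
    frame = default_cohort.frame.copy()
    frame["education_years"] = 13.0
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        best = dn.search_transforms(frame, "vt")
    assert "education" not in best
    assert any("degenerate" in str(w.message) for w in caught)


def test_select_best_model_recovers_structure(default_cohort):
    """Default cohort: VT correction uses age and education, not sex."""
    best = dn.select_best_model(default_cohort, "vt")
    assert best is not None
    assert set(best.params) == {"age", "education"}
    assert best.pvalue < 0.05


def test_select_best_model_finds_sex_effect():
    """A score driven only by sex must select the sex predictor."""
    params = dn.GenerativeParams(
        vt=dn.SubtestEffects(intercept=30.0, sex_male=3.0),
        resid_family="student_t",
        resid_shape=10.0,
    )
    demos = dn.sample_demographics(521, seed=31)
    cohort = dn.generate_scores(demos, params, seed=32)
    best = dn.select_best_model(cohort, "vt")
    assert best is not None and "sex" in best.params


def test_pure_noise_mostly_selects_nothing(null_params):
    """Without demographic effects, the significance gate usually rejects."""
    nones = 0
    for i in range(10):
        demos = dn.sample_demographics(300, seed=400 + i)
        cohort = dn.generate_scores(demos, null_params, seed=500 + i)
        if dn.select_best_model(cohort, "vt") is None:
            nones += 1
    assert nones >= 5


def test_select_best_model_row_order_invariant(default_cohort):
    shuffled = default_cohort.frame.sample(frac=1.0, random_state=9).reset_index(drop=True)
    a = dn.select_best_model(default_cohort, "aht")
    b = dn.select_best_model(shuffled, "aht")
    assert a.label == b.label
    for p in a.params:
        assert a.params[p] == pytest.approx(b.params[p], rel=1e-9)


def test_fit_all_subsets_has_seven_models(default_cohort):
    tr = dn.search_transforms(default_cohort, "vt")
    fits = fit_all_subsets(default_cohort, "vt", tr)
    assert len(fits) == 7
    assert {f.k for f in fits} == {3, 4, 5}


def test_descriptives_identical_groups_give_zero_F():
    frame = pd.DataFrame(
        {
            "age": np.repeat([25, 35, 45, 55, 65, 75], 3),
            "education_years": 13.0,
            "sex": ["M", "F", "M"] * 6,
            "vt": np.tile([28.0, 30.0, 32.0], 6),
            "aht": np.tile([30.0, 33.0, 36.0], 6),
            "ratio": np.tile([1.0, 1.1, 1.2], 6),
            "errors": np.tile([0.0, 1.0, 2.0], 6),
        }
    )
    desc = dn.cohort_descriptives(frame)
    row = desc.anova.set_index("subtest").loc["vt"]
    assert row["F"] == 0.0 and row["eta_sq"] == 0.0


def test_two_group_anova_equals_squared_t():
    rng = np.random.default_rng(8)
    a = rng.normal(30, 5, 40)
    b = rng.normal(33, 5, 40)
    frame = pd.DataFrame(
        {
            "age": np.r_[np.full(40, 25.0), np.full(40, 45.0)],
            "education_years": 13.0,
            "sex": "F",
            "vt": np.r_[a, b],
            "aht": np.r_[a, b] + 2,
            "ratio": 1.1,
            "errors": 0.0,
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant ratio column in correlations
        desc = dn.cohort_descriptives(frame)
    f_stat = desc.anova.set_index("subtest").loc["vt", "F"]
    t_stat = stats.ttest_ind(a, b).statistic
    assert f_stat == pytest.approx(t_stat**2, rel=1e-9)


def test_descriptives_on_default_cohort(large_cohort):
    desc = dn.cohort_descriptives(large_cohort)
    corr = desc.correlations
    assert corr.loc["vt", "aht"] > 0.7  # internal consistency of the timed scores
    assert corr.loc["age", "vt"] > 0.2
    assert corr.loc["education", "vt"] < 0
    # decade table covers all four subtests and six decades
    assert set(desc.decade_table["subtest"]) == set(dn.selection.SUBTESTS)
    assert desc.decade_table.groupby("subtest")["decade"].nunique().eq(6).all()


def test_anova_excludes_tiny_decades():
    frame = pd.DataFrame(
        {
            "age": [25, 26, 27, 35, 36, 37, 75],
            "education_years": 13.0,
            "sex": "F",
            "vt": [28.0, 29.0, 30.0, 31.0, 32.0, 33.0, 40.0],
            "aht": [30.0, 31.0, 32.0, 33.0, 34.0, 35.0, 44.0],
            "ratio": [1.0, 1.05, 1.1, 1.0, 1.05, 1.1, 1.2],
            "errors": [0, 1, 0, 1, 0, 1, 2],
        }
    )
    with pytest.warns(UserWarning, match="excluded"):
        desc = dn.cohort_descriptives(frame)
    assert (desc.anova["df_between"] == 1).all()
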