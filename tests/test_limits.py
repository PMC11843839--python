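"""Normality gate, tolerance limits, equivalent scores, percentiles."""

import numpy as np
import pytest
from scipy import stats

import demnorms as dn
from demnorms.exceptions import (
    DegenerateInputError,
    InsufficientSampleError,
    InvalidParameterError,
)
from demnorms.limits import minimal_n


def test_normality_check_cases():
    rng = np.random.default_rng(17)
    normal = dn.normality_check(rng.normal(size=5000))
    assert normal.verdict == "normal"
    skewed = dn.normality_check(rng.exponential(size=5000))  # population skew 2
    assert skewed.skew_flag and skewed.verdict == "non-normal"
    with pytest.raises(DegenerateInputError):
        dn.normality_check(np.full(100, 3.0))
    with pytest.raises(InvalidParameterError):
        dn.normality_check([1.0, 2.0])


def test_tolerance_ranks_published_and_closed_form():
    assert dn.tolerance_ranks(521) == (488, 504)
    # closed form at the boundary: OTL exists iff 1 - p^n >= gamma
    assert dn.tolerance_ranks(59)[1] == 59
    with pytest.raises(InsufficientSampleError) as err:
        dn.tolerance_ranks(58)
    assert err.value.min_n == 59


@pytest.mark.parametrize("p", [0.9, 0.95, 0.99])
@pytest.mark.parametrize("gamma", [0.9, 0.95])
def test_tolerance_ranks_against_bruteforce(p, gamma):
    """Sparse brute-force scan of the exact binomial conditions."""
    spec = dn.ToleranceSpec(coverage=p, confidence=gamma)
    for n in list(range(20, 200, 13)) + list(range(200, 2001, 97)):
        pmf = stats.binom.pmf(np.arange(n + 1), n, p)
        cum = np.cumsum(pmf)
        otl = next((k for k in range(1, n + 1) if cum[k - 1] >= gamma - 1e-12), None)
        itl = next((k for k in range(1, n + 1) if cum[k - 1] > 1 - gamma + 1e-12), None)
        if otl is None:
            with pytest.raises(InsufficientSampleError):
                dn.tolerance_ranks(n, spec)
        else:
            assert dn.tolerance_ranks(n, spec) == (itl, otl), (n, p, gamma)


def test_tolerance_limits_identity_and_permutation(rng):
    values = np.arange(1, 522, dtype=float)
    res = dn.tolerance_limits(values)
    assert (res.itl_value, res.otl_value) == (488.0, 504.0)
    shuffled = rng.permutation(values)
    res2 = dn.tolerance_limits(shuffled)
    assert (res2.itl_rank, res2.otl_rank, res2.itl_value, res2.otl_value) == (
        res.itl_rank, res.otl_rank, res.itl_value, res.otl_value,
    )


def test_otl_tracks_generative_quantile():
    """Across replicates the OTL hovers around the true 95th percentile."""
    rng = np.random.default_rng(99)
    q95 = stats.norm.ppf(0.95)
    excess = []
    for _ in range(200):
        sample = rng.normal(size=521)
        excess.append(dn.tolerance_limits(sample).otl_value - q95)
    # conservative limit: usually above the quantile, but not by much
    assert 0 < np.mean(excess) < 0.4
    assert np.mean(np.array(excess) > 0) > 0.85


def test_build_norm_table_uniform_ranks():
    table = dn.build_norm_table(np.arange(1, 522, dtype=float))
    assert table.percentile_values[table.percentile_levels.index(50)] == 261.0
    assert table.es_bounds[0] == 504.0  # ES0 boundary is the OTL
    assert table.es_bounds[3] == 261.0  # ES4 boundary is the median
    # percentile grid monotone: better score at higher level
    assert (np.diff(table.percentile_values) > 0).all()


def test_small_sample_norm_table_raises():
    with pytest.raises((InsufficientSampleError, DegenerateInputError)):
        dn.build_norm_table(np.arange(1, 41, dtype=float))


def _published_vt_table(published_norms):
    return published_norms.tables["vt"]


def test_es_assignment_published_bounds(published_norms):
    vt = published_norms.tables["vt"]
    assert vt.assign_es(41.0)[0] == 0
    assert vt.assign_es(30.0)[0] == 3
    ratio = published_norms.tables["ratio"]
    assert ratio.assign_es(1.05)[0] == 4
    errors = published_norms.tables["errors"]
    es, flags = errors.assign_es(0.5)  # inside the duplicated printed band
    assert es == 2 and "es_ambiguous" in flags
    assert errors.assign_es(1.5) == (1, [])


def test_es_assignment_monotone(published_norms):
    for table in published_norms.tables.values():
        grid = np.linspace(table.es_bounds[3] - 5, table.es_bounds[0] + 5, 200)
        es = [table.assign_es(x)[0] for x in grid]  # worse scores, lower ES
        assert (np.diff(es) <= 0).all()


def test_assign_percentile_published_rows(published_norms):
    vt = published_norms.tables["vt"]
    assert dn.assign_percentile(vt, 29.9) == (50, False)
    aht = published_norms.tables["aht"]
    assert dn.assign_percentile(aht, 43.4) == (5, False)
    assert dn.assign_percentile(vt, 15.0) == (99, True)  # better than the table
    assert dn.assign_percentile(vt, 60.0) == (1, True)  # worse than the table


def test_percentile_grids_monotone(published_norms):
    for sub, table in published_norms.tables.items():
        diffs = np.diff(table.percentile_values)
        assert (diffs >= 0).all(), sub  # worse values at worse levels


def test_tolerance_spec_validation():
    with pytest.raises(InvalidParameterError):
        dn.ToleranceSpec(coverage=1.5)
    with pytest.raises(InvalidParameterError):
        dn.ToleranceSpec(confidence=0.0)
    assert minimal_n(dn.ToleranceSpec()) == 59
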