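import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from navlearn.circular import (
    bias_screen,
    chance_level_abs_error,
    monte_carlo_chance_level,
    watson_williams,
    wrap_signed_error,
)
from navlearn.cohort import behavioral_schedule, simulate_cohort


# ---------------------------------------------------------------------------
# wrapping and chance level
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("response,target,expected",
                         [(10.0, 350.0, 20.0), (0.0, 0.0, 0.0),
                          (-170.0, 175.0, 15.0), (180.0, 0.0, 180.0),
                          (0.0, 180.0, 180.0)])
def test_wrap_signed_error_examples(response, target, expected):
    assert wrap_signed_error(response, target) == pytest.approx(expected)


@settings(max_examples=300, deadline=None)
@given(st.floats(-1e4, 1e4), st.floats(-1e4, 1e4))
def test_wrapped_error_always_in_half_open_range(response, target):
    w = wrap_signed_error(response, target)
    assert -180.0 < w <= 180.0
    assert abs(w) <= 180.0


def test_uniform_pointing_has_90_degree_expected_error():
    assert chance_level_abs_error() == 90.0
    assert abs(monte_carlo_chance_level(200_000, seed=0) - 90.0) < 0.5


# ---------------------------------------------------------------------------
# Watson-Williams test
# ---------------------------------------------------------------------------


def test_identical_samples_give_zero_f_and_unit_p():
    a = np.array([12.0, -5.0, 30.0, 8.0, -14.0])
    res = watson_williams(a, a.copy())
    assert res.F == 0.0
    assert res.pvalue == 1.0


def test_common_rotation_leaves_statistic_unchanged():
    rng = np.random.default_rng(0)
    a = np.degrees(rng.vonmises(0.1, 5.0, 20))
    b = np.degrees(rng.vonmises(0.5, 5.0, 20))
    base = watson_williams(a, b)
    for rot in (33.0, -118.0, 540.0):
        r = watson_williams((a + rot + 180) % 360 - 180,
                            (b + rot + 180) % 360 - 180)
        assert r.F == pytest.approx(base.F, abs=1e-9)
        assert r.pvalue == pytest.approx(base.pvalue, abs=1e-9)


def test_agrees_with_hand_computed_two_group_example():
    """Independent in-test computation of the classical two-sample formula
    on a fixed 2 x 5 example."""
    g1 = np.array([-20.0, -10.0, 0.0, 10.0, 20.0])
    g2 = np.array([25.0, 35.0, 45.0, 55.0, 65.0])
    res = watson_williams(g1, g2)

    def resultant(deg):
        r = np.radians(deg)
        return math.hypot(np.cos(r).sum(), np.sin(r).sum())

    R1, R2 = resultant(g1), resultant(g2)
    R = resultant(np.concatenate([g1, g2]))
    N, k = 10, 2
    rbar = (R1 + R2) / N
    kappa = -0.4 + 1.39 * rbar + 0.43 / (1 - rbar)  # 0.53 <= rbar < 0.85
    if rbar < 0.53:
        kappa = 2 * rbar + rbar**3 + 5 * rbar**5 / 6
    elif rbar >= 0.85:
        kappa = 1 / (rbar**3 - 4 * rbar**2 + 3 * rbar)
    K = 1 + 3 / (8 * kappa)
    F = K * ((N - k) * (R1 + R2 - R)) / ((k - 1) * (N - R1 - R2))
    p = stats.f.sf(F, k - 1, N - k)
    assert res.F == pytest.approx(F, abs=1e-6)
    assert res.pvalue == pytest.approx(p, abs=1e-6)


def test_type_one_error_calibrated_under_the_null():
    """Equal-mean von Mises groups: rejection rate near the nominal 5%."""
    rng = np.random.default_rng(1)
    n_sim = 2000
    rejections = 0
    for _ in range(n_sim):
        a = np.degrees(rng.vonmises(0.3, 5.0, 17))
        b = np.degrees(rng.vonmises(0.3, 5.0, 17))
        rejections += watson_williams(a, b).pvalue < 0.05
    assert 0.03 <= rejections / n_sim <= 0.07


def test_planted_mean_shift_detected():
    """40-degree shift between groups (kappa=5, n=17): detected at raw
    alpha in at least 90% of simulations."""
    rng = np.random.default_rng(2)
    hits = 0
    for _ in range(100):
        a = np.degrees(rng.vonmises(0.0, 5.0, 17))
        b = np.degrees(rng.vonmises(math.radians(40.0), 5.0, 17))
        hits += watson_williams(a, b).pvalue < 0.05
    assert hits >= 90


def test_small_groups_rejected_and_low_concentration_warns():
    with pytest.raises(ValueError):
        watson_williams(np.array([1.0]), np.array([2.0, 3.0]))
    rng = np.random.default_rng(3)
    with pytest.warns(UserWarning, match="doubtful"):
        res = watson_williams(rng.uniform(-180, 180, 30),
                              rng.uniform(-180, 180, 30))
    assert not res.valid


# ---------------------------------------------------------------------------
# cohort-level bias screen
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def cohort_trials():
    trials, _ = simulate_cohort(n_young=17, n_old=17, seed=8,
                                spec=behavioral_schedule())
    return trials


def test_screen_covers_all_32_design_cells(cohort_trials):
    table = bias_screen(cohort_trials, alpha=0.05)
    assert len(table) == 32
    assert table.attrs["n_tests"] == 32
    assert set(zip(table["intersection"], table["direction"], table["target"])) \
        == {(i, d, t) for i in ("I1", "I2", "I3", "I4")
            for d in ("D1", "D2", "D3", "D4") for t in ("T1", "T2")}


def test_identical_groups_never_flagged(cohort_trials):
    """When the two age groups' responses are literally identical in every
    cell, no comparison is significant even before correction."""
    young = cohort_trials[cohort_trials["age_group"] == "young"]
    clone = young.copy()
    clone["age_group"] = "old"
    clone["subject_id"] = "X" + clone["subject_id"].astype(str)
    table = bias_screen(pd.concat([young, clone], ignore_index=True),
                        alpha=0.05)
    assert (table["F"] == 0.0).all()
    assert int(table["significant_raw"].sum()) == 0
    assert int(table["significant_bonferroni"].sum()) == 0


def test_planted_cell_shift_flagged_before_correction(cohort_trials):
    shifted = cohort_trials.copy()
    cell = ((shifted["intersection"] == "I1") & (shifted["direction"] == "D1")
            & (shifted["target"] == "T1") & (shifted["age_group"] == "old")
            & ~shifted["missing"])
    rng = np.random.default_rng(4)
    # replace the old group's responses in one cell by a tight 60-deg bias
    shifted.loc[cell, "signed_error"] = np.degrees(
        rng.vonmises(math.radians(60.0), 8.0, int(cell.sum())))
    shifted.loc[cell, "abs_error"] = shifted.loc[cell, "signed_error"].abs()
    young_cell = ((shifted["intersection"] == "I1")
                  & (shifted["direction"] == "D1")
                  & (shifted["target"] == "T1")
                  & (shifted["age_group"] == "young") & ~shifted["missing"])
    shifted.loc[young_cell, "signed_error"] = np.degrees(
        rng.vonmises(0.0, 8.0, int(young_cell.sum())))
    shifted.loc[young_cell, "abs_error"] = \
        shifted.loc[young_cell, "signed_error"].abs()
    table = bias_screen(shifted, alpha=0.05)
    row = table[(table["intersection"] == "I1") & (table["direction"] == "D1")
                & (table["target"] == "T1")]
    assert bool(row["significant_raw"].iloc[0])
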