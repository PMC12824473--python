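"""Unit and property tests for nAUC phenotyping and the physics utilities."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from yprofiler import dose_response as dr


# --- normalization ---------------------------------------------------------


def test_normalize_divides_by_untreated_control(tidy_viability):
    out = dr.normalize_viability(tidy_viability)
    sub = out[(out.cell_line == "L1") & (out.replicate == 1)].sort_values(
        "activity_mbq_per_ml"
    )
    assert sub["fraction"].tolist() == [1.0, 0.5, 0.25]


def test_normalize_is_scale_invariant(tidy_viability):
    scaled = tidy_viability.assign(readout=tidy_viability.readout * 37.5)
    a = dr.normalize_viability(tidy_viability)["fraction"]
    b = dr.normalize_viability(scaled)["fraction"]
    np.testing.assert_allclose(a, b)


@pytest.mark.parametrize(
    "mutate, match",
    [
        (lambda df: df[df.activity_mbq_per_ml > 0], "no activity-0 control"),
        (lambda df: df.assign(readout=np.where(df.activity_mbq_per_ml == 0, 0.0, df.readout)),
         "non-positive activity-0 control"),
    ],
)
def test_normalize_errors_name_the_offender(tidy_viability, mutate, match):
    with pytest.raises(ValueError, match=match) as exc:
        dr.normalize_viability(mutate(tidy_viability))
    assert "L1" in str(exc.value)


# --- trapezoid AUC and nAUC ------------------------------------------------


@pytest.mark.parametrize(
    "acts, fracs, expected",
    [
        ([0, 20], [1.0, 1.0], 20.0),
        ([0, 10, 20], [1.0, 0.5, 0.5], 12.5),  # hand trapezoids: 7.5 + 5.0
        ([0, 5, 10, 20], [1.0, 0.75, 0.5, 0.0], 10.0),  # linear 1 - A/20
    ],
)
def test_trapezoid_auc_known_areas(acts, fracs, expected):
    assert dr.trapezoid_auc(np.array(acts, float), np.array(fracs, float)) == pytest.approx(
        expected
    )


@settings(max_examples=50, deadline=None)
@given(
    knots=st.lists(
        st.floats(0.1, 19.9, allow_nan=False), min_size=0, max_size=5, unique=True
    ),
    slope=st.floats(-0.05, 0.0),
)
def test_trapezoid_exact_for_linear_curves(knots, slope):
    """A linear survival curve integrates exactly on any grid with endpoints."""
    acts = np.array(sorted({0.0, 20.0, *knots}))
    fracs = 1.0 + slope * acts
    analytic = 20.0 + slope * 200.0
    assert dr.trapezoid_auc(acts, fracs) == pytest.approx(analytic, abs=1e-12)


def test_trapezoid_rejects_bad_grids():
    with pytest.raises(ValueError):
        dr.trapezoid_auc(np.array([0.0]), np.array([1.0]))
    with pytest.raises(ValueError):
        dr.trapezoid_auc(np.array([0.0, 5.0, 5.0]), np.array([1.0, 0.5, 0.4]))


def test_nauc_flat_curve_is_exactly_one():
    area = dr.trapezoid_auc(np.array([0.0, 0.1, 0.5, 1, 2, 4, 10, 20]), np.ones(8))
    assert dr.nauc(area, 20.0) == 1.0


def test_nauc_is_ratio_of_areas():
    assert dr.nauc(12.5, 20.0) == pytest.approx(0.625)
    with pytest.raises(ValueError):
        dr.nauc(1.0, 0.0)


@settings(max_examples=50, deadline=None)
@given(
    fracs=st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=8, max_size=8)
)
def test_nauc_bounded_by_one_when_fractions_are(fracs):
    acts = np.array([0.0, 0.1, 0.5, 1, 2, 4, 10, 20])
    f = np.array(fracs)
    f[0] = 1.0
    value = dr.nauc(dr.trapezoid_auc(acts, f), 20.0)
    assert value <= 1.0 + 1e-12


# --- replicate summaries and grouping --------------------------------------


def test_summarize_nauc_mean_and_sem():
    reps = pd.DataFrame(
        {"cell_line": ["A"] * 2 + ["B"] * 3, "replicate": [1, 2, 1, 2, 3],
         "nauc": [0.4, 0.6, 0.5, 0.5, 0.5]}
    )
    out = dr.summarize_nauc(reps).set_index("cell_line")
    assert out.loc["A", "mean_nauc"] == pytest.approx(0.5)
    assert out.loc["A", "sem"] == pytest.approx(0.1)  # SD 0.1414 / sqrt(2)
    assert out.loc["B", "sem"] == 0.0


def test_summarize_single_replicate_warns():
    reps = pd.DataFrame({"cell_line": ["A"], "replicate": [1], "nauc": [0.7]})
    with pytest.warns(UserWarning, match="single replicate"):
        out = dr.summarize_nauc(reps)
    assert out.loc[0, "sem"] == 0.0
    assert out.loc[0, "mean_nauc"] == pytest.approx(0.7)


def test_assign_groups_two_lines_symmetric():
    prof = pd.DataFrame({"cell_line": ["A", "B"], "mean_nauc": [1.0, 0.0]})
    out = dr.assign_groups(prof).set_index("cell_line")
    # sample-SD convention: SD of {0,1} is 0.7071, so z = +/-0.7071
    assert out.loc["A", "z_score"] == pytest.approx(math.sqrt(0.5))
    assert out.loc["B", "z_score"] == pytest.approx(-math.sqrt(0.5))
    assert out.loc["A", "group"] == "resistant"
    assert out.loc["B", "group"] == "sensitive"


def test_assign_groups_zero_variance_errors():
    prof = pd.DataFrame({"cell_line": list("ABC"), "mean_nauc": [0.5, 0.5, 0.5]})
    with pytest.raises(ValueError, match="zero variance"):
        dr.assign_groups(prof)


def test_zscores_have_mean_zero_sd_one(small_cohort):
    prof = dr.summarize_nauc(dr.replicate_naucs(dr.normalize_viability(small_cohort.viability)))
    out = dr.assign_groups(prof)
    z = out["z_score"].to_numpy()
    assert z.mean() == pytest.approx(0.0, abs=1e-12)
    assert z.std(ddof=1) == pytest.approx(1.0)


# --- ANOVA / Tukey ---------------------------------------------------------


def _anova_oracle(groups):
    """Textbook one-way ANOVA sum-of-squares decomposition."""
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    f = (ss_between / df_b) / (ss_within / df_w)
    p = stats.f.sf(f, df_b, df_w)
    return f, p


def test_anova_identical_groups_f_zero():
    res = dr.compare_lines_anova({"a": np.array([1.0, 2, 3]), "b": np.array([1.0, 2, 3])})
    assert res["f_statistic"] == pytest.approx(0.0, abs=1e-12)
    assert res["p_value"] == pytest.approx(1.0)


def test_anova_degenerate_within_variance():
    res = dr.compare_lines_anova({"a": np.array([0.0, 0, 0]), "b": np.array([1.0, 1, 1])})
    assert res["p_value"] <= 1e-12
    assert math.isinf(res["f_statistic"])


def test_anova_matches_sum_of_squares_oracle(rng):
    for _ in range(20):
        k = rng.integers(2, 5)
        groups = {
            f"g{i}": rng.normal(rng.normal(), 1.0, size=rng.integers(3, 7))
            for i in range(k)
        }
        res = dr.compare_lines_anova(groups)
        f, p = _anova_oracle([groups[k_] for k_ in sorted(groups)])
        assert res["f_statistic"] == pytest.approx(f, rel=1e-8)
        assert res["p_value"] == pytest.approx(p, rel=1e-8)


def test_tukey_matches_studentized_range_oracle(rng):
    groups = {f"g{i}": rng.normal(i * 0.5, 1.0, size=5) for i in range(3)}
    res = dr.compare_lines_anova(groups)
    arrays = [groups[k] for k in sorted(groups)]
    n_total = sum(len(a) for a in arrays)
    df_w = n_total - len(arrays)
    msw = sum(((a - a.mean()) ** 2).sum() for a in arrays) / df_w
    for pair in res["pairwise"]:
        i = int(pair["line_a"][1])
        j = int(pair["line_b"][1])
        se = math.sqrt(msw / 2 * (1 / len(arrays[i]) + 1 / len(arrays[j])))
        q = abs(arrays[i].mean() - arrays[j].mean()) / se
        p_oracle = stats.studentized_range.sf(q, len(arrays), df_w)
        assert pair["p_adj"] == pytest.approx(p_oracle, rel=1e-6, abs=1e-10)


def test_anova_rejects_single_replicate_group():
    with pytest.raises(ValueError, match="fewer than 2"):
        dr.compare_lines_anova({"a": np.array([1.0]), "b": np.array([1.0, 2.0])})


# --- physics ---------------------------------------------------------------


def test_mird_dose_zero_and_linearity(rng):
    assert dr.mird_dose(0.0) == 0.0
    a = float(rng.uniform(0.1, 30))
    assert dr.mird_dose(2 * a) == pytest.approx(2 * dr.mird_dose(a))


def test_mird_dose_top_of_ladder_near_1000_gy():
    assert dr.mird_dose(20.0) == pytest.approx(993, abs=2)


def test_decay_halving_and_direct_factor():
    assert dr.decay_activity(10.0, 64.2, 64.2) == pytest.approx(5.0)
    assert dr.decay_activity(1.0, 120.0, 64.2) == pytest.approx(2 ** (-120 / 64.2))
    assert dr.decay_activity(7.0, 0.0, 64.2) == 7.0


@settings(max_examples=50, deadline=None)
@given(
    a0=st.floats(0.01, 1e6),
    t1=st.floats(0, 300, allow_nan=False),
    t2=st.floats(0, 300, allow_nan=False),
)
def test_decay_semigroup_property(a0, t1, t2):
    two_step = dr.decay_activity(dr.decay_activity(a0, t1), t2)
    one_step = dr.decay_activity(a0, t1 + t2)
    assert two_step == pytest.approx(one_step, rel=1e-12)


def test_half_lives_elapsed():
    assert dr.half_lives_elapsed(240.0, 64.2) == pytest.approx(240 / 64.2)
    assert dr.half_lives_elapsed(240.0, 64.2) > 3
    assert dr.half_lives_elapsed(64.2) == 1.0
    assert dr.half_lives_elapsed(0.0) == 0.0


def test_physics_params_validated():
    with pytest.raises(ValueError):
        dr.DosePhysicsParams(half_life_hours=-1)
    with pytest.raises(ValueError):
        dr.mird_dose(-1.0)


# --- qPCR ------------------------------------------------------------------


def test_relative_expression_powers_of_two():
    assert dr.relative_expression(20.0, 20.0) == 1.0
    assert dr.relative_expression(25.0, 20.0) == pytest.approx(0.03125)
    with pytest.raises(ValueError):
        dr.relative_expression(float("nan"), 20.0)


def test_ddct_log2fc():
    assert dr.ddct_log2fc(5.0, 5.0) == 0.0
    assert dr.ddct_log2fc(3.0, 5.0) == 2.0  # 2 cycles earlier -> 4-fold up
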