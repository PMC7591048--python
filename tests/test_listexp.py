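"""List-experiment estimators, SDB, and design-effect / balance diagnostics."""

import numpy as np
import pandas as pd
import pytest

from econstress import listexp
from econstress.simulate import generate

from conftest import small_config


def _toy_frame(control_counts, treat_counts, arm="T1"):
    rows = [{"country": "IT", "arm": "control", "item_count": c} for c in control_counts]
    rows += [{"country": "IT", "arm": arm, "item_count": c} for c in treat_counts]
    return pd.DataFrame(rows)


def test_diff_means_four_point_arithmetic():
    est = listexp.estimate_support_diff_means(_toy_frame([2, 2, 2, 2], [3, 2, 3, 2]), 1)
    assert est.support_hat == pytest.approx(0.5)
    assert (est.n_control, est.n_treat) == (4, 4)


def test_diff_means_identical_samples_zero():
    est = listexp.estimate_support_diff_means(_toy_frame([1, 2, 3], [1, 2, 3]), 1)
    assert est.support_hat == pytest.approx(0.0)


def test_empty_arm_error_names_the_arm():
    data = _toy_frame([1, 2], [], arm="T1")
    with pytest.raises(listexp.EstimationError, match="T1"):
        listexp.estimate_support_diff_means(data, 1)


def test_regression_no_covariates_equals_diff_means(small_data):
    """OLS on intercept + treatment dummy is algebraically the mean difference."""
    for statement in (1, 2):
        dm = listexp.estimate_support_diff_means(small_data, statement)
        reg = listexp.estimate_support_regression(small_data, statement, covariates=())
        assert reg.support_hat == pytest.approx(dm.support_hat, abs=1e-10)


def test_regression_with_covariates_close_to_diff_means(default_data):
    """Randomization makes covariate adjustment an o(1) correction."""
    dm = listexp.estimate_support_diff_means(default_data, 1)
    reg = listexp.estimate_support_regression(default_data, 1)
    assert reg.support_hat == pytest.approx(dm.support_hat, abs=3 * dm.se)


def test_collinear_covariate_raises(small_data):
    data = small_data.copy()
    data["treat_copy"] = (data["arm"] == "T1").astype(float)
    with pytest.raises(listexp.EstimationError, match="collinear"):
        listexp.estimate_support_regression(data, 1, covariates=("treat_copy",))


def test_direct_share_examples():
    rows = [{"country": "IT", "arm": "direct", "direct_stmt1": v}
            for v in [1] * 7 + [0] * 3]
    est = listexp.estimate_direct(pd.DataFrame(rows), 1)
    assert est.share == pytest.approx(0.7)
    all_agree = pd.DataFrame(
        [{"country": "IT", "arm": "direct", "direct_stmt1": 1.0}] * 5
    )
    est = listexp.estimate_direct(all_agree, 1)
    assert (est.share, est.se) == (1.0, 0.0)


def test_sdb_subtraction_and_scope_mismatch():
    lst = listexp.ListEstimate(1, "pooled", "diff_means", 0.62, 0.02, 31.0, 100, 100)
    direct = listexp.DirectEstimate(1, "pooled", 0.56, 0.01, 50)
    res = listexp.estimate_sdb(lst, direct)
    assert res.sdb == pytest.approx(0.06)
    assert res.se == pytest.approx(np.sqrt(0.02**2 + 0.01**2))
    other = listexp.DirectEstimate(1, "IT", 0.56, 0.01, 50)
    with pytest.raises(listexp.EstimationError):
        listexp.estimate_sdb(lst, other)


def test_sdb_recovered_on_synthetic_data():
    """lambda * p is the social-desirability gap the estimator should find."""
    cfg = small_config(
        n_per_country={"IT": 4000, "ES": 4000, "UK": 4000},
        true_support=(0.6, 0.6),
        liar_rates=(0.15, 0.15),
        seed=17,
    )
    d = generate(cfg)
    lst = listexp.estimate_support_diff_means(d, 1)
    direct = listexp.estimate_direct(d, 1)
    res = listexp.estimate_sdb(lst, direct)
    assert res.sdb == pytest.approx(0.15 * 0.6, abs=3 * res.se)


def test_design_effect_interior_case_p_value_one():
    """Treatment counts = control counts + 1 leave every pi_hat >= 0."""
    rng = np.random.default_rng(3)
    ctrl = rng.integers(0, 5, 800)
    data = _toy_frame(list(ctrl), list(ctrl + 1))
    res = listexp.design_effect_test(data, 1)
    assert (res.pi_table["pi_hat"] >= -1e-12).all()
    assert res.p_value == 1.0
    assert not res.reject


def test_design_effect_pi_sums_to_one(default_data):
    for statement in (1, 2):
        res = listexp.design_effect_test(default_data, statement)
        assert res.pi_table["pi_hat"].sum() == pytest.approx(1.0, abs=1e-10)
        assert 0.0 <= res.p_value <= 1.0
        assert res.pi_table["testable"].sum() == 8  # 2(J+1) - 2 with J = 4


def test_design_effect_detects_injected_shift():
    base = dict(n_per_country={"IT": 4000, "ES": 4000, "UK": 4000}, seed=19)
    clean = generate(small_config(**base))
    assert not listexp.design_effect_test(clean, 1).reject
    shifted = generate(small_config(design_effect_shift=0.3, **base))
    assert listexp.design_effect_test(shifted, 1).reject


def test_design_effect_low_power_flag():
    data = _toy_frame([1, 2, 3] * 4, [2, 3, 4] * 4)
    assert listexp.design_effect_test(data, 1).low_power


def test_balance_randomized_and_rigged(small_data):
    table = listexp.balance_tests(small_data)
    assert set(table["covariate"]) == set(listexp.BALANCE_COVARIATES)
    assert table.loc[table["test"] != "skipped", "p_value"].between(0, 1).all()
    # a covariate deterministically tied to arm is flagged at p ~ 0
    rigged = small_data.copy()
    rigged["rigged"] = rigged["arm"].map(
        {"control": 0, "T1": 1, "T2": 2, "direct": 3}
    ).astype(float)
    out = listexp.balance_tests(rigged, covariates=("rigged",))
    assert out.loc[0, "p_value"] < 1e-10


def test_balance_constant_covariate_skipped(small_data):
    data = small_data.copy()
    data["const"] = 1.0
    out = listexp.balance_tests(data, covariates=("const",))
    assert out.loc[0, "test"] == "skipped"
    assert "constant" in out.loc[0, "note"]


def test_balance_null_rejection_rate():
    """Under randomization roughly 5% of covariate tests reject at 5%."""
    pvals = []
    for seed in range(40):
        d = generate(small_config(seed=1000 + seed))
        tab = listexp.balance_tests(d)
        pvals.extend(tab.loc[tab["test"] != "skipped", "p_value"])
    rate = float(np.mean(np.asarray(pvals) < 0.05))
    assert 0.0 <= rate < 0.12
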