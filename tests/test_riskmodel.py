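"""Risk forest, post-stratification weights and population projection."""

import numpy as np
import pandas as pd
import pytest

from econstress import mhealth, riskmodel
from econstress.simulate import generate, margins_from_sample, write_margins_fixture

from conftest import small_config


@pytest.fixture(scope="module")
def signal_data():
    """Moderate-size dataset with a strong vulnerability signal."""
    return generate(small_config(
        n_per_country={"IT": 1200, "ES": 1200, "UK": 1200},
        vulnerability_loading=2.0,
        seed=41,
    ))


@pytest.fixture(scope="module")
def signal_model(signal_data):
    return riskmodel.fit_risk_model(signal_data, n_trees=120, seed=41)


def test_refuses_tiny_training_sets(signal_data):
    with pytest.raises(riskmodel.ProjectionError):
        riskmodel.fit_risk_model(signal_data.head(50), n_trees=10, seed=0)


def test_oob_reconstruction_matches_sklearn(signal_data):
    """Recomputed bootstrap membership reproduces sklearn's OOB predictions."""
    model = riskmodel.fit_risk_model(signal_data.head(800), n_trees=60, seed=3)
    forest = model.forest
    X = signal_data.head(800).loc[:, list(model.predictors)].to_numpy(float)
    y = mhealth.score_index(signal_data.head(800)).to_numpy()
    n = len(y)
    pred_sum, pred_cnt = np.zeros(n), np.zeros(n)
    for tree in forest.estimators_:
        oob = np.ones(n, dtype=bool)
        oob[riskmodel._bootstrap_indices(tree.random_state, n)] = False
        pred_sum[oob] += tree.predict(X[oob])
        pred_cnt[oob] += 1
    seen = pred_cnt > 0
    assert np.allclose(pred_sum[seen] / pred_cnt[seen], forest.oob_prediction_[seen])
    # the recorded final-curve MSE is the OOB MSE of the full ensemble
    final = model.oob_curve.iloc[-1]
    mse = np.mean((forest.oob_prediction_[seen] - y[seen]) ** 2)
    assert final["oob_mse"] == pytest.approx(mse, rel=1e-9)


def test_signal_recovery_and_oob_curve(signal_model):
    assert signal_model.fit_spearman > 0.6
    curve = signal_model.oob_curve["oob_mse"].to_numpy()
    assert curve[-1] <= curve[0]  # non-increasing in trend
    assert signal_model.importances.sum() == pytest.approx(1.0)


def test_pure_noise_has_no_oob_skill():
    d = generate(small_config(
        n_per_country={"IT": 1000, "ES": 1000, "UK": 1000},
        vulnerability_loading=0.0,
        seed=43,
    ))
    model = riskmodel.fit_risk_model(d, n_trees=120, seed=43)
    assert model.forest.oob_score_ < 0.05  # OOB R^2 ~ 0


def test_predictions_within_index_range(signal_model, signal_data):
    pred = signal_model.predict(signal_data)
    assert pred.between(0.25, 1.0).all()


def test_high_risk_threshold_boundaries(signal_model, signal_data):
    pred = signal_model.predict(signal_data)
    # inclusive threshold: a respondent predicted exactly at t is high risk
    t = float(pred.iloc[0])
    flags = riskmodel.classify_high_risk(signal_model, signal_data, threshold=t)
    assert bool(flags.iloc[0])
    assert not riskmodel.classify_high_risk(signal_model, signal_data, 1.01).any()
    assert riskmodel.classify_high_risk(signal_model, signal_data, 0.25).all()


def test_fit_is_deterministic(signal_data):
    a = riskmodel.fit_risk_model(signal_data, n_trees=40, seed=7).predict(signal_data)
    b = riskmodel.fit_risk_model(signal_data, n_trees=40, seed=7).predict(signal_data)
    pd.testing.assert_series_equal(a, b)


def test_poststratify_identity_weights(small_data):
    margins = margins_from_sample(small_data, {"IT": 1e6, "ES": 2e6, "UK": 3e6})
    w = riskmodel.poststratify(small_data, margins)
    assert np.allclose(w, 1.0, atol=1e-10)


def test_poststratify_calibration_identity(small_data):
    """Weighted sample cell shares reproduce the population cell shares."""
    cfg = small_config()
    margins = write_margins_fixture(cfg)
    w = riskmodel.poststratify(small_data, margins)
    cells = small_data.loc[:, ["country", "gender", "region"]].copy()
    cells["age_band"] = riskmodel.age_band(small_data["age"]).to_numpy()
    cells["w"] = w
    for country in ("IT", "ES", "UK"):
        sub = cells[cells["country"] == country]
        m = margins[margins["country"] == country]
        pop_share = m.set_index(["gender", "age_band", "region"])["count"]
        pop_share = pop_share / pop_share.sum()
        got = sub.groupby(["gender", "age_band", "region"], observed=True)["w"].sum() / sub["w"].sum()
        joined = pd.concat([pop_share, got], axis=1, keys=["pop", "got"]).dropna()
        assert np.allclose(joined["pop"], joined["got"], atol=1e-10)
        assert w[small_data["country"] == country].mean() == pytest.approx(1.0)


def test_poststratify_undersampled_cell_weight_ratio():
    """A cell sampled at half its population share gets double weight."""
    data = pd.DataFrame({
        "country": "IT",
        "gender": ["F"] * 2 + ["M"] * 6,
        "age": [25] * 8,
        "region": "North",
    })
    margins = pd.DataFrame({
        "country": "IT",
        "gender": ["F", "M"],
        "age_band": "18-35",
        "region": "North",
        "count": [50, 50],  # F population share 1/2, sampled at 1/4
    })
    w = riskmodel.poststratify(data, margins)
    w_f, w_m = w.iloc[0], w.iloc[-1]
    assert w_f / w_m == pytest.approx((0.5 / 0.25) / (0.5 / 0.75))


def test_poststratify_collapses_or_reports_empty_cells(small_data):
    tiny = small_data[small_data["region"] != "North"]  # empty region cells
    cfg = small_config()
    margins = write_margins_fixture(cfg)
    w = riskmodel.poststratify(tiny, margins)  # collapses regions
    assert w.notna().all()
    with pytest.raises(riskmodel.ProjectionError, match="cells"):
        riskmodel.poststratify(tiny, margins, collapse_regions=False)


def test_project_share_arithmetic():
    ind = pd.Series([1.0, 0.0, 1.0, 0.0, 1.0, 1.0])
    w = pd.Series([1.0] * 6)
    countries = pd.Series(["IT", "IT", "ES", "ES", "UK", "UK"])
    pops = {"IT": 1.0, "ES": 1.0, "UK": 1.0}
    shares = riskmodel.project_high_risk_share(ind, w, countries, pops)
    assert shares["IT"] == pytest.approx(0.5)
    # country shares (0.5, 0.5, 1.0) with equal populations pool to 2/3
    assert shares["pooled"] == pytest.approx(2 / 3)
    # all-one indicators give share one regardless of weights
    ones = riskmodel.project_high_risk_share(
        pd.Series([1.0] * 6), pd.Series([0.1, 5, 2, 1, 9, 3]), countries, pops
    )
    assert all(v == pytest.approx(1.0) for v in ones.values())


def test_project_share_invariant_to_weight_rescaling():
    rng = np.random.default_rng(5)
    ind = pd.Series(rng.integers(0, 2, 90).astype(float))
    w = pd.Series(rng.random(90) + 0.1)
    countries = pd.Series(np.repeat(["IT", "ES", "UK"], 30))
    pops = {"IT": 4.3e7, "ES": 3.4e7, "UK": 4.8e7}
    a = riskmodel.project_high_risk_share(ind, w, countries, pops)
    b = riskmodel.project_high_risk_share(ind, w * 17.0, countries, pops)
    for k in a:
        assert a[k] == pytest.approx(b[k], abs=1e-12)


def test_holdout_stability_strong_signal(signal_data):
    out = riskmodel.holdout_stability(
        signal_data, learn_fractions=(0.5,), n_trees=80, seed=11
    )
    assert out.loc[0, "spearman"] > 0.8
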