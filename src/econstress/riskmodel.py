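"""Tree-ensemble prediction of mental-health risk and population projection.

A random-forest regression (bagged regression trees, 550 by default) maps nine
economic-vulnerability predictors onto the stress/anxiety/depression index.
Respondents whose predicted index is at least 0.5 are classified as being at
high risk; the high-risk share is projected to the population by
post-stratifying on gender, age band (18-35 / 36-55 / 56-75) and macro-region
against external population margins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.utils import check_random_state

from . import mhealth
from .simulate import age_band

#: The nine economic-vulnerability predictors.
PREDICTORS: tuple[str, ...] = (
    "income_category",
    "unemployed",
    "homeowner",
    "living_area",
    "household_size",
    "children_school",
    "buffer_stock",
    "stress_events",
    "income_loss",
)

INDEX_RANGE: tuple[float, float] = (0.25, 1.0)


class ProjectionError(ValueError):
    """Raised for unusable training data or post-stratification cells."""


@dataclass
class RiskModel:
    forest: RandomForestRegressor
    predictors: tuple[str, ...]
    #: Out-of-bag mean-squared error evaluated at increasing tree counts.
    oob_curve: pd.DataFrame
    importances: pd.Series
    #: Spearman rank correlation between in-sample predictions and the outcome.
    fit_spearman: float

    def predict(self, data: pd.DataFrame) -> pd.Series:
        X = data.loc[:, list(self.predictors)].to_numpy(dtype=float)
        pred = np.clip(self.forest.predict(X), *INDEX_RANGE)
        return pd.Series(pred, index=data.index, name="predicted_index")


def _bootstrap_indices(tree_random_state, n: int) -> np.ndarray:
    """Bootstrap sample indices for one tree, replicating the fitting draw."""
    rs = check_random_state(tree_random_state)
    return rs.randint(0, n, n, dtype=np.int32)


def _oob_curve(
    forest: RandomForestRegressor, X: np.ndarray, y: np.ndarray, step: int
) -> pd.DataFrame:
    """OOB mean-squared error as a function of the number of trees."""
    n = len(y)
    pred_sum = np.zeros(n)
    pred_cnt = np.zeros(n, dtype=np.int64)
    rows = []
    checkpoints = set(range(step, len(forest.estimators_) + 1, step))
    checkpoints.add(len(forest.estimators_))
    for t, tree in enumerate(forest.estimators_, start=1):
        oob = np.ones(n, dtype=bool)
        oob[_bootstrap_indices(tree.random_state, n)] = False
        if oob.any():
            pred_sum[oob] += tree.predict(X[oob])
            pred_cnt[oob] += 1
        if t in checkpoints:
            seen = pred_cnt > 0
            mse = float(np.mean((pred_sum[seen] / pred_cnt[seen] - y[seen]) ** 2))
            rows.append({"n_trees": t, "oob_mse": mse, "n_oob": int(seen.sum())})
    return pd.DataFrame(rows)


def fit_risk_model(
    data: pd.DataFrame,
    predictors: Sequence[str] = PREDICTORS,
    n_trees: int = 550,
    seed: int = 0,
    outcome: pd.Series | None = None,
    oob_curve_step: int = 25,
) -> RiskModel:
    """Fit the bagged regression-tree ensemble of the index on the predictors.

    ``outcome`` defaults to the scored stress index; rows with a missing
    outcome or predictor are dropped. Trees are grown on bootstrap samples of
    size n with one third of the predictors considered per split; the
    out-of-bag error curve and impurity-based variable importances are
    recorded as fit diagnostics.
    """
    predictors = tuple(predictors)
    if outcome is None:
        outcome = mhealth.score_index(data)
    frame = data.loc[:, list(predictors)].astype(float)
    frame["__y"] = outcome.to_numpy(dtype=float)
    frame = frame.dropna()
    if len(frame) < 100:
        raise ProjectionError(f"only {len(frame)} complete training rows (< 100)")
    X = frame[list(predictors)].to_numpy()
    y = frame["__y"].to_numpy()
    forest = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=1.0 / 3.0,
        bootstrap=True,
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    in_sample = forest.predict(X)
    rho = float(stats.spearmanr(in_sample, y).statistic)
    return RiskModel(
        forest=forest,
        predictors=predictors,
        oob_curve=_oob_curve(forest, X, y, oob_curve_step),
        importances=pd.Series(forest.feature_importances_, index=predictors,
                              name="importance"),
        fit_spearman=rho,
    )


def classify_high_risk(
    model: RiskModel, data: pd.DataFrame, threshold: float = 0.5
) -> pd.Series:
    """High-risk indicator: predicted index greater than or equal to threshold."""
    return (model.predict(data) >= threshold).rename("high_risk")


def _cells(data: pd.DataFrame) -> pd.DataFrame:
    out = data.loc[:, ["country", "gender", "region"]].copy()
    out["age_band"] = age_band(data["age"]).to_numpy()
    return out


def poststratify(
    data: pd.DataFrame, margins: pd.DataFrame, collapse_regions: bool = True
) -> pd.Series:
    """Post-stratification weights against gender x age-band x region margins.

    Within each country, a respondent's raw weight is the ratio of the
    population share of their cell to its sample share; weights are then
    normalized to mean 1 within country. Population cells with no sampled
    respondent trigger a collapse of the region dimension (gender x age-band
    cells only) before raising an error.
    """
    if (margins["count"] <= 0).any():
        raise ProjectionError("margins must have positive counts")
    cells = _cells(data)
    weights = pd.Series(np.nan, index=data.index, name="weight")
    for country, sub in cells.groupby("country", sort=False):
        m = margins[margins["country"] == country]
        if m.empty:
            raise ProjectionError(f"no margins for country {country!r}")
        keys = ["gender", "age_band", "region"]
        pop = m.groupby(keys, observed=True)["count"].sum()
        samp = sub.groupby(keys, observed=True).size()
        missing = pop.index.difference(samp.index)
        if len(missing) > 0 and collapse_regions:
            keys = ["gender", "age_band"]
            pop = m.groupby(keys, observed=True)["count"].sum()
            samp = sub.groupby(keys, observed=True).size()
            missing = pop.index.difference(samp.index)
        if len(missing) > 0:
            raise ProjectionError(
                f"population cells with no sampled respondent in {country}: "
                f"{list(missing)}"
            )
        pop_share = pop / pop.sum()
        samp_share = samp / len(sub)
        ratio = (pop_share / samp_share).dropna()
        w = pd.MultiIndex.from_frame(sub[keys]).map(ratio).to_numpy(dtype=float)
        w = w / w.mean()
        weights.loc[sub.index] = w
    return weights


def project_high_risk_share(
    indicators: pd.Series,
    weights: pd.Series,
    countries: pd.Series,
    country_populations: Mapping[str, float],
) -> dict[str, float]:
    """Weighted per-country high-risk shares and the population-weighted pool.

    The pooled share is the mean of the country shares weighted by each
    country's population total.
    """
    if not (len(indicators) == len(weights) == len(countries)):
        raise ProjectionError("indicators, weights and countries must align")
    shares: dict[str, float] = {}
    for country in pd.unique(countries):
        mask = (countries == country).to_numpy()
        w = weights.to_numpy(dtype=float)[mask]
        z = indicators.to_numpy(dtype=float)[mask]
        shares[str(country)] = float(np.sum(w * z) / np.sum(w))
    pops = np.array([country_populations[c] for c in shares], dtype=float)
    vals = np.array(list(shares.values()))
    shares["pooled"] = float(np.sum(pops * vals) / pops.sum())
    return shares


def holdout_stability(
    data: pd.DataFrame,
    learn_fractions: Sequence[float] = (0.15, 0.25, 0.33, 0.50),
    n_trees: int = 550,
    seed: int = 0,
    outcome: pd.Series | None = None,
) -> pd.DataFrame:
    """Stability of predictions under training on a subsample.

    For each learning fraction, a model trained on that fraction predicts the
    held-out remainder; the rank correlation of those predictions with the
    full-sample model's predictions on the same respondents measures how much
    the classification depends on the training split.
    """
    if outcome is None:
        outcome = mhealth.score_index(data)
    full = fit_risk_model(data, n_trees=n_trees, seed=seed, outcome=outcome)
    rng = np.random.default_rng(seed)
    rows = []
    for frac in learn_fractions:
        n_learn = max(100, int(round(frac * len(data))))
        idx = rng.permutation(len(data))
        learn = data.iloc[idx[:n_learn]]
        hold = data.iloc[idx[n_learn:]]
        sub_model = fit_risk_model(
            learn, n_trees=n_trees, seed=seed, outcome=outcome.iloc[idx[:n_learn]]
        )
        rho = float(
            stats.spearmanr(sub_model.predict(hold), full.predict(hold)).statistic
        )
        rows.append({"learn_fraction": frac, "n_learn": n_learn, "spearman": rho})
    return pd.DataFrame(rows)
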