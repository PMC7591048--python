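"""Scoring of the eight-item stress/anxiety/depression scale.

The instrument is an eight-item adaptation of the DASS-21 and SASRQ scales:
each item asks how often a symptom was felt in the previous week on a 1-4
frequency scale (less than one day / 1-2 days / 3-4 days / 5-7 days). The
respondent-level index is the item mean divided by 4, so it lives on
[0.25, 1]: 0.25 means no symptom was felt even one day, 1 means every symptom
most or all of the time.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import MH_COLUMNS

logger = logging.getLogger(__name__)

#: Human-readable labels for the eight items (prevalence-table rows).
ITEM_LABELS: dict[str, str] = {
    "mh1": "Felt down, depressed or hopeless about the future",
    "mh2": "Felt little interest or pleasure in doing things",
    "mh3": "Felt nervous, anxious or on the edge",
    "mh4": "Had trouble falling or staying asleep, or sleeping too much",
    "mh5": "Felt bad about yourself or that you are a failure",
    "mh6": "Had troubles concentrating on things",
    "mh7": "Had a physical reaction when thinking about the outbreak",
    "mh8": "Feeling tired or having little energy",
}

#: The nine socio-economic predictors of the correlation table, keyed by the
#: label they are reported under.
PREDICTOR_LABELS: dict[str, str] = {
    "income_category": "Household income",
    "unemployed": "Unemployed",
    "homeowner": "Home ownership",
    "living_area": "Living area",
    "household_size": "People in home",
    "children_school": "Children in school",
    "buffer_stock": "Cover the bills",
    "stress_events": "Stress events",
    "income_loss": "Income loss",
}


def score_index(
    data: pd.DataFrame,
    items: Sequence[str] = MH_COLUMNS,
    min_items: int = 6,
) -> pd.Series:
    """Per-respondent stress/anxiety/depression index on [0.25, 1].

    index = mean(items) / 4. Respondents missing up to ``8 - min_items`` items
    get a prorated mean over their answered items; respondents with fewer
    answered items are excluded (logged) and returned as NaN so callers can
    drop or track them.
    """
    block = data.loc[:, list(items)]
    arr = block.to_numpy(dtype=float)
    if np.nanmin(arr[~np.isnan(arr)]) < 1 or np.nanmax(arr[~np.isnan(arr)]) > 4:
        raise ValueError("mental-health items must lie in {1, 2, 3, 4}")
    n_used = block.notna().sum(axis=1)
    index = block.mean(axis=1, skipna=True) / 4.0
    excluded = n_used < min_items
    if excluded.any():
        ids = data.loc[excluded, "id"].tolist() if "id" in data else list(data.index[excluded])
        logger.info("score_index: excluded %d respondents with <%d items: %s",
                    int(excluded.sum()), min_items, ids[:20])
        index[excluded] = np.nan
    return index.rename("stress_index")


def prevalence_table(
    data: pd.DataFrame,
    scopes: Sequence[str] = ("ES", "UK", "IT", "pooled"),
    threshold: int = 2,
) -> pd.DataFrame:
    """Share of respondents reporting each symptom at least 1-2 days.

    One row per item, one column per scope; an entry is the share of
    respondents whose item response is >= ``threshold`` (default 2, i.e. the
    symptom was felt on at least one or two days of the previous week).
    """
    out = {}
    for scope in scopes:
        sub = data if scope == "pooled" else data[data["country"] == scope]
        out[scope] = [
            float((sub[item] >= threshold).mean()) for item in MH_COLUMNS
        ]
    table = pd.DataFrame(out, index=[ITEM_LABELS[i] for i in MH_COLUMNS])
    table.index.name = "item"
    return table


def cronbach_alpha(items: pd.DataFrame) -> float:
    """Cronbach's alpha internal-consistency coefficient.

    alpha = J/(J-1) * (1 - sum_j var(item_j) / var(total)), computed over
    complete cases with sample (ddof=1) variances.
    """
    block = items.dropna()
    J = block.shape[1]
    if J < 2:
        raise ValueError("Cronbach's alpha needs at least two items")
    if len(block) < 2:
        raise ValueError("Cronbach's alpha needs at least two complete respondents")
    total_var = block.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero total variance: alpha undefined")
    item_var = block.var(ddof=1).sum()
    return float(J / (J - 1) * (1.0 - item_var / total_var))


def spearman_correlates(index: pd.Series, predictors: pd.DataFrame) -> pd.DataFrame:
    """Spearman rank correlations of the index with each predictor.

    Rank correlation is preferred to Pearson to capture monotone non-linear
    association and damp the influence of outlying responses. Ties get average
    ranks; p-values use the large-sample t approximation. Constant predictors
    are reported as undefined with a note.
    """
    rows = []
    for col in predictors.columns:
        pair = pd.concat([index, predictors[col]], axis=1).dropna()
        label = PREDICTOR_LABELS.get(col, col)
        if pair[col].nunique() <= 1:
            rows.append({"predictor": label, "column": col, "rho": np.nan,
                         "p_value": np.nan, "n": len(pair), "note": "constant predictor"})
            continue
        rho, p = stats.spearmanr(pair.iloc[:, 0], pair.iloc[:, 1])
        rows.append({"predictor": label, "column": col, "rho": float(rho),
                     "p_value": float(p), "n": len(pair), "note": ""})
    return pd.DataFrame(rows)
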