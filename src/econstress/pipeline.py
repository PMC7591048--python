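"""End-to-end analysis pipeline over a survey dataset.

Runs, in order: list-experiment support / SDB estimation with balance and
design-effect diagnostics; mental-health index scoring with reliability,
prevalence and correlation tables; the random-forest risk model with
post-stratified population projection; exposure PCA; and the stochastic-
dominance comparison of the four indices. Results come back as a plain dict
of scalars and DataFrames, with an optional tidy-CSV dump for reproducibility.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd

from . import dominance, exposure, listexp, mhealth, riskmodel
from .simulate import COUNTRIES, MH_COLUMNS, GeneratorConfig, generate, write_margins_fixture

SCOPES: tuple[str, ...] = ("pooled",) + COUNTRIES


def run_pipeline(
    config: GeneratorConfig | None = None,
    data: pd.DataFrame | None = None,
    margins: pd.DataFrame | None = None,
    n_trees: int = 550,
    seed: int | None = None,
) -> dict:
    """Run every analysis stage; returns a dict of results keyed by stage.

    Either pass a ``GeneratorConfig`` (synthetic data are generated) or an
    explicit dataset and margins table. ``seed`` feeds the forest fit and
    defaults to the generator seed.
    """
    if data is None:
        config = config or GeneratorConfig()
        data = generate(config)
    if margins is None:
        margins = write_margins_fixture(config or GeneratorConfig())
    if seed is None:
        seed = config.seed if config is not None else 0

    # --- list experiment ---------------------------------------------------
    estimates = []
    sdb = []
    for statement in (1, 2):
        for scope in SCOPES:
            dm = listexp.estimate_support_diff_means(data, statement, scope)
            reg = listexp.estimate_support_regression(data, statement, scope)
            direct = listexp.estimate_direct(data, statement, scope)
            estimates.extend([dm, reg])
            sdb.append(listexp.estimate_sdb(reg, direct))
    est_table = pd.DataFrame([dataclasses.asdict(e) for e in estimates])
    sdb_table = pd.DataFrame([dataclasses.asdict(s) for s in sdb])
    design_tests = {s: listexp.design_effect_test(data, s) for s in (1, 2)}
    balance = listexp.balance_tests(data)

    # --- mental health ------------------------------------------------------
    index = mhealth.score_index(data)
    alpha = mhealth.cronbach_alpha(data.loc[:, list(MH_COLUMNS)])
    prevalence = mhealth.prevalence_table(data)
    correlates = mhealth.spearman_correlates(
        index, data.loc[:, list(riskmodel.PREDICTORS)]
    )

    # --- risk projection ----------------------------------------------------
    model = riskmodel.fit_risk_model(data, n_trees=n_trees, seed=seed, outcome=index)
    high_risk = riskmodel.classify_high_risk(model, data)
    weights = riskmodel.poststratify(data, margins)
    populations = margins.groupby("country")["count"].sum().to_dict()
    shares = riskmodel.project_high_risk_share(
        high_risk, weights, data["country"], populations
    )

    # --- exposure + dominance ----------------------------------------------
    exposure_scores = exposure.score_all(data)
    predicted = model.predict(data)
    dominance_results = {
        dim: dominance.fosd_check(
            predicted.to_numpy(), sc.scores.to_numpy(), names=("predicted_stress", dim)
        )
        for dim, sc in exposure_scores.items()
    }

    return {
        "data": data,
        "margins": margins,
        "estimates": est_table,
        "sdb": sdb_table,
        "design_tests": design_tests,
        "balance": balance,
        "stress_index": index,
        "cronbach_alpha": alpha,
        "prevalence": prevalence,
        "correlates": correlates,
        "risk_model": model,
        "high_risk": high_risk,
        "weights": weights,
        "high_risk_shares": shares,
        "exposure": exposure_scores,
        "dominance": dominance_results,
    }


def write_results(results: dict, outdir: str | Path) -> list[Path]:
    """Serialize the tabular pipeline results as tidy CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def dump(df: pd.DataFrame, name: str, index: bool = False) -> None:
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=index)
        written.append(p)

    dump(results["estimates"], "support_estimates")
    dump(results["sdb"], "sdb_estimates")
    dump(results["balance"], "balance_tests")
    dump(results["prevalence"], "prevalence", index=True)
    dump(results["correlates"], "spearman_correlates")
    for s, res in results["design_tests"].items():
        dump(res.pi_table, f"design_effect_stmt{s}")
    dump(results["risk_model"].oob_curve, "oob_curve")
    dump(results["risk_model"].importances.rename_axis("predictor").reset_index(),
         "variable_importance")
    shares = pd.DataFrame(
        [{"scope": k, "high_risk_share": v} for k, v in results["high_risk_shares"].items()]
    )
    dump(shares, "high_risk_shares")
    scored = pd.DataFrame({
        "id": results["data"]["id"],
        "stress_index": results["stress_index"],
        "predicted_index": results["risk_model"].predict(results["data"]),
        "high_risk": results["high_risk"].astype(int),
        "weight": results["weights"],
    })
    for dim, sc in results["exposure"].items():
        scored[f"{dim}_score"] = sc.scores
    dump(scored, "scores")
    dom = pd.DataFrame(
        [
            {"a": r.pair[0], "b": r.pair[1], "holds": r.holds,
             "max_violation": r.max_violation, "eps": r.eps}
            for r in results["dominance"].values()
        ]
    )
    dump(dom, "dominance")
    return written
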