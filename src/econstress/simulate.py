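"""Synthetic multi-country survey generator.

Emulates a three-country (Italy, Spain, United Kingdom) online-panel survey
with a four-arm list-experiment design, an eight-item stress/anxiety/depression
scale on a 1-4 Likert response format, a socio-economic covariate block driven
by a latent economic-vulnerability factor, and three COVID-exposure item blocks
(susceptibility, quarantine-compliance vulnerability, behavioural response).

The generative contract, in brief:

* latent vulnerability ``V ~ N(0, 1)`` per respondent;
* covariates are monotone in ``V`` (higher vulnerability implies lower income,
  education and financial buffer, higher unemployment / stress-event /
  income-loss probability, smaller living area);
* a mental-health latent ``M = beta * V + eps`` with ``eps ~ N(0, noise_sd)``;
  each Likert item discretizes ``M`` plus independent item noise at three
  fixed thresholds (the 25/50/75 percentiles of the item-latent marginal);
* agreement with sensitive statement k is Bernoulli(logistic(logit(p_k) +
  gamma * V)); the four uncontroversial control items are independent
  Bernoullis with configured prevalences;
* the reported item count is the sum of agreements over the items shown to the
  respondent's arm; in the direct arm an agreeing respondent admits agreement
  with probability ``1 - liar_rate_k`` (the social-desirability mechanism).

Everything is deterministic given ``GeneratorConfig.seed``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit
from scipy.stats import norm

COUNTRIES: tuple[str, ...] = ("IT", "ES", "UK")

#: Macro-regions used for post-stratification (4 for Italy, 5 each for Spain/UK).
REGIONS: dict[str, list[str]] = {
    "IT": ["North", "Centre", "South", "Isles"],
    "ES": ["Madrid-Centre", "Barcelona-West", "North", "Centre-East", "South"],
    "UK": ["East-Midlands", "London", "South", "North", "Scotland-Wales-NI"],
}

AGE_BANDS: tuple[str, ...] = ("18-35", "36-55", "56-75")

ARMS: tuple[str, ...] = ("control", "T1", "T2", "direct")

CONTROL_ITEM_NAMES: tuple[str, ...] = (
    "globalization",
    "immigration",
    "health_workers",
    "experts",
)

MH_COLUMNS: tuple[str, ...] = tuple(f"mh{i}" for i in range(1, 9))

COMORBIDITY_COLUMNS: tuple[str, ...] = (
    "diabetes",
    "hypertension",
    "asthma",
    "cardio",
    "cancer",
)

VULNERABILITY_COLUMNS: tuple[str, ...] = (
    "vuln_work",
    "vuln_care",
    "vuln_shop",
    "vuln_crowding",
    "vuln_transport",
)

BEHAVIOUR_COLUMNS: tuple[str, ...] = (
    "contacted_doctor",
    "contacted_authority",
    "sought_test",
    "got_tested",
)


class ConfigurationError(ValueError):
    """Raised when a GeneratorConfig carries invalid parameters."""


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic survey data-generating process.

    Defaults reproduce the study design: per-country sample sizes
    3,504 / 3,524 / 3,523 and a 30/30/30/10 randomized split into control,
    two list-treatment arms and a direct-questioning arm.
    """

    n_per_country: Mapping[str, int] = field(
        default_factory=lambda: {"IT": 3504, "ES": 3524, "UK": 3523}
    )
    #: (control, T1, T2, direct) assignment shares; must sum to 1.
    arm_shares: tuple[float, float, float, float] = (0.30, 0.30, 0.30, 0.10)
    #: True population agreement with the two sensitive statements.
    true_support: tuple[float, float] = (0.62, 0.70)
    #: Prevalence of agreement with each of the four uncontroversial items.
    control_item_prevalences: tuple[float, ...] = (0.35, 0.45, 0.90, 0.55)
    #: Probability that an agreeing respondent denies agreement when asked directly.
    liar_rates: tuple[float, float] = (0.09, 0.05)
    #: beta — effect of latent vulnerability V on the mental-health latent.
    vulnerability_loading: float = 1.0
    #: gamma — effect of V on the log-odds of agreeing with a sensitive statement.
    sensitivity_loading: float = 0.0
    #: sigma — sd of the respondent-level mental-health noise.
    noise_sd: float = 1.0
    #: tau — sd of the per-item noise added before Likert discretization.
    item_noise_sd: float = 1.0
    #: Latent-percentile cut points mapping the item latent into {1, 2, 3, 4}.
    mh_threshold_quantiles: tuple[float, float, float] = (0.25, 0.50, 0.75)
    #: Drop in control-item prevalence within the treatment arms (0 = no design
    #: effect, the identifying assumption of the list experiment).
    design_effect_shift: float = 0.0
    #: 18-75 population totals used by the margins fixture.
    population_totals: Mapping[str, float] = field(
        default_factory=lambda: {"IT": 43_000_000, "ES": 34_000_000, "UK": 48_000_000}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for c in COUNTRIES:
            if c not in self.n_per_country:
                raise ConfigurationError(f"missing sample size for country {c!r}")
            if int(self.n_per_country[c]) <= 0:
                raise ConfigurationError(f"n_per_country[{c!r}] must be positive")
        if len(self.arm_shares) != 4:
            raise ConfigurationError("arm_shares must have four entries")
        if any(s < 0 for s in self.arm_shares):
            raise ConfigurationError("arm shares must be non-negative")
        if abs(sum(self.arm_shares) - 1.0) > 1e-9:
            raise ConfigurationError("arm_shares must sum to 1")
        for name, probs in (
            ("true_support", self.true_support),
            ("liar_rates", self.liar_rates),
            ("control_item_prevalences", self.control_item_prevalences),
        ):
            if any(not 0.0 <= p <= 1.0 for p in probs):
                raise ConfigurationError(f"{name} entries must lie in [0, 1]")
        if len(self.control_item_prevalences) != 4:
            raise ConfigurationError("exactly four control items are required")
        if self.noise_sd <= 0 or self.item_noise_sd < 0:
            raise ConfigurationError("noise sds must be positive")
        if self.vulnerability_loading < 0:
            raise ConfigurationError("vulnerability_loading must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("arm_shares", "true_support", "control_item_prevalences",
                    "liar_rates", "mh_threshold_quantiles"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def age_band(age: "pd.Series | np.ndarray") -> pd.Series:
    """Map integer ages onto the 18-35 / 36-55 / 56-75 post-stratification bands."""
    age = pd.Series(np.asarray(age))
    return pd.cut(
        age, bins=[17, 35, 55, 75], labels=list(AGE_BANDS), right=True
    ).astype(str)


def _arm_vector(n: int, shares: Sequence[float], rng: np.random.Generator) -> np.ndarray:
    """Exact-count randomized assignment (largest-remainder apportionment)."""
    raw = np.asarray(shares) * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:remainder]] += 1
    labels = np.repeat(np.array(ARMS, dtype=object), counts)
    return rng.permutation(labels)


def _ordinal_from_latent(
    latent: np.ndarray, noise_sd: float, n_cats: int, rng: np.random.Generator
) -> np.ndarray:
    """Discretize latent + noise into 1..n_cats equal-probability categories."""
    u = latent + rng.normal(0.0, noise_sd, latent.shape[0])
    marginal_sd = float(np.sqrt(np.var(latent) + noise_sd**2)) or 1.0
    cuts = norm.ppf(np.arange(1, n_cats) / n_cats, scale=marginal_sd)
    return 1 + np.searchsorted(cuts, u, side="right").astype(np.int64)


def _generate_country(
    country: str, cfg: GeneratorConfig, rng: np.random.Generator, id_offset: int
) -> pd.DataFrame:
    n = int(cfg.n_per_country[country])
    beta = cfg.vulnerability_loading
    gamma = cfg.sensitivity_loading

    arm = _arm_vector(n, cfg.arm_shares, rng)
    gender = rng.choice(np.array(["F", "M"], dtype=object), size=n)
    age = rng.integers(18, 76, size=n)
    region = rng.choice(np.array(REGIONS[country], dtype=object), size=n)

    # Latent economic vulnerability and its monotone covariate links.
    V = rng.standard_normal(n)
    income_category = _ordinal_from_latent(-0.8 * V, 0.6, 7, rng)
    education = _ordinal_from_latent(-0.4 * V, 0.9, 5, rng)
    buffer_stock = _ordinal_from_latent(-0.9 * V, 0.5, 5, rng)
    unemployed = (rng.random(n) < expit(-2.0 + 0.8 * V)).astype(np.int64)
    married = (rng.random(n) < 0.55).astype(np.int64)
    homeowner = (rng.random(n) < expit(0.6 - 0.6 * V)).astype(np.int64)
    living_area = np.round(np.exp(4.3 - 0.18 * V + rng.normal(0, 0.35, n))).astype(np.int64)
    household_size = 1 + rng.poisson(np.exp(0.45 + 0.12 * V))
    children_school = rng.poisson(np.exp(-0.7 + 0.15 * V))
    stress_events = rng.binomial(8, expit(-1.3 + 0.7 * V))
    income_loss = (rng.random(n) < expit(-0.4 + 0.7 * V)).astype(np.int64)

    # Mental-health block: shared latent plus independent item noise,
    # discretized at fixed thresholds (25/50/75 percentile cut points).
    M = beta * V + rng.normal(0.0, cfg.noise_sd, n)
    marginal_sd = np.sqrt(beta**2 + cfg.noise_sd**2 + cfg.item_noise_sd**2)
    cuts = norm.ppf(cfg.mh_threshold_quantiles, scale=marginal_sd)
    mh = {}
    for col in MH_COLUMNS:
        latent = M + rng.normal(0.0, cfg.item_noise_sd, n)
        mh[col] = 1 + np.searchsorted(cuts, latent, side="right").astype(np.int64)

    # Sensitive-statement agreement (latent truth, independent of arm).
    agree = {}
    for k, p_k in enumerate(cfg.true_support, start=1):
        eta = logit(np.clip(p_k, 1e-12, 1 - 1e-12)) + gamma * V
        agree[k] = rng.random(n) < expit(eta)

    # Control items: independent Bernoullis; under an injected design effect the
    # prevalence drops by design_effect_shift in the two list-treatment arms.
    in_treatment = np.isin(arm, ("T1", "T2"))
    ctrl = np.empty((n, 4), dtype=bool)
    for j, p in enumerate(cfg.control_item_prevalences):
        p_row = np.full(n, p)
        p_row[in_treatment] = np.clip(p - cfg.design_effect_shift, 0.0, 1.0)
        ctrl[:, j] = rng.random(n) < p_row
    ctrl_total = ctrl.sum(axis=1)

    item_count = np.full(n, -1, dtype=np.int64)
    item_count[arm == "control"] = ctrl_total[arm == "control"]
    item_count[arm == "T1"] = (ctrl_total + agree[1])[arm == "T1"]
    item_count[arm == "T2"] = (ctrl_total + agree[2])[arm == "T2"]

    # Direct arm: control items reported truthfully; an agreeing respondent
    # admits agreement with the sensitive statement w.p. 1 - liar_rate.
    is_direct = arm == "direct"
    direct_cols: dict[str, np.ndarray] = {}
    for j, name in enumerate(CONTROL_ITEM_NAMES):
        col = np.where(is_direct, ctrl[:, j].astype(float), np.nan)
        direct_cols[f"direct_{name}"] = col
    for k, lam in enumerate(cfg.liar_rates, start=1):
        admits = agree[k] & (rng.random(n) >= lam)
        direct_cols[f"direct_stmt{k}"] = np.where(is_direct, admits.astype(float), np.nan)

    # Susceptibility block: age plus a health frailty factor drives comorbidity
    # flags and self-rated poor health, giving the one-factor structure PCA expects.
    frailty = rng.standard_normal(n)
    age_z = (age - 46.5) / 16.7
    susceptibility = {}
    for col, intercept in zip(COMORBIDITY_COLUMNS, (-2.4, -1.6, -2.1, -2.2, -2.9)):
        p = expit(intercept + 0.6 * age_z + 0.9 * frailty)
        susceptibility[col] = (rng.random(n) < p).astype(np.int64)
    susceptibility["poor_health"] = _ordinal_from_latent(0.5 * age_z + 0.9 * frailty, 0.8, 5, rng)

    # Vulnerability block: factors preventing full quarantine compliance.
    compliance = rng.standard_normal(n)
    vulnerability = {
        col: _ordinal_from_latent(0.9 * compliance, 1.0, 4, rng)
        for col in VULNERABILITY_COLUMNS
    }

    # Behavioural-response block: contacting doctors/authorities, seeking tests.
    care_seeking = rng.standard_normal(n)
    behaviour = {}
    for col, intercept in zip(BEHAVIOUR_COLUMNS, (-1.0, -1.4, -1.2, -1.8)):
        p = expit(intercept + 1.2 * care_seeking)
        behaviour[col] = (rng.random(n) < p).astype(np.int64)

    df = pd.DataFrame(
        {
            "id": np.arange(id_offset, id_offset + n, dtype=np.int64),
            "country": country,
            "gender": gender,
            "age": age,
            "region": region,
            "arm": arm,
            "item_count": item_count,
            **direct_cols,
            "income_category": income_category,
            "unemployed": unemployed,
            "married": married,
            "homeowner": homeowner,
            "living_area": living_area,
            "household_size": household_size,
            "children_school": children_school,
            "education": education,
            "buffer_stock": buffer_stock,
            "stress_events": stress_events,
            "income_loss": income_loss,
            **mh,
            **susceptibility,
            **vulnerability,
            **behaviour,
        }
    )
    df["item_count"] = df["item_count"].astype("Int64")
    df.loc[df["arm"] == "direct", "item_count"] = pd.NA
    return df


def generate(config: GeneratorConfig) -> pd.DataFrame:
    """Generate the pooled respondent-level table for the three countries.

    Returns one row per respondent with arm assignment, the list-experiment
    item count (missing in the direct arm), the six direct answers (direct arm
    only), socio-economic covariates, the eight mental-health items, and the
    exposure item blocks. Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    frames = []
    offset = 0
    for country in COUNTRIES:
        frames.append(_generate_country(country, config, rng, offset))
        offset += int(config.n_per_country[country])
    return pd.concat(frames, ignore_index=True)


def write_margins_fixture(config: GeneratorConfig) -> pd.DataFrame:
    """Population margins table: gender x age-band x macro-region per country.

    Cell counts default to a uniform split of each country's configured 18-75
    population total (the last cell absorbs the rounding remainder so counts
    sum exactly to the total).
    """
    rows = []
    for country in COUNTRIES:
        total = float(config.population_totals[country])
        cells = [
            (g, b, r)
            for g in ("F", "M")
            for b in AGE_BANDS
            for r in REGIONS[country]
        ]
        base = np.floor(total / len(cells))
        for i, (g, b, r) in enumerate(cells):
            count = base if i < len(cells) - 1 else total - base * (len(cells) - 1)
            rows.append(
                {"country": country, "gender": g, "age_band": b, "region": r, "count": count}
            )
    return pd.DataFrame(rows)


def margins_from_sample(data: pd.DataFrame, population_totals: Mapping[str, float]) -> pd.DataFrame:
    """Margins proportional to the sample's own cell composition.

    Useful as the identity case: post-stratifying against these margins gives
    unit weights for every respondent.
    """
    work = data.loc[:, ["country", "gender", "region"]].copy()
    work["age_band"] = age_band(data["age"])
    rows = []
    for country, sub in work.groupby("country", sort=False):
        counts = sub.groupby(["gender", "age_band", "region"], observed=True).size()
        total = float(population_totals[country])
        for (g, b, r), c in counts.items():
            rows.append(
                {
                    "country": country,
                    "gender": g,
                    "age_band": b,
                    "region": r,
                    "count": total * c / len(sub),
                }
            )
    return pd.DataFrame(rows)


def write_dataset(data: pd.DataFrame, outdir: str | Path) -> list[Path]:
    """Write one CSV per country plus the pooled CSV; returns paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for country, sub in data.groupby("country", sort=False):
        p = outdir / f"survey_{country}.csv"
        sub.to_csv(p, index=False)
        paths.append(p)
    pooled = outdir / "survey_pooled.csv"
    data.to_csv(pooled, index=False)
    paths.append(pooled)
    return paths
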