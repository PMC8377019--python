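"""Synthetic study generator: participants, 3AFC choices, ratings, country table.

Emulates the design of a cross-cultural facial-preference study: raters
nested in countries complete, for each of two judgements (attractiveness,
femininity) and five fertility-cue prototype sets, a three-alternative
forced choice among low/medium/high-cue composite faces and 1-7 ratings of
each composite.  Country-level demographic indicators are generated from two
latent factors (health/development and inequality) so the factor-analysis
stage has a known ground truth.

Generative model
----------------
Choices: rater i picks level j with probability proportional to
``exp(delta_i * x_j)`` where ``x = (-1, 0, +1)`` for (low, medium, high) and

    delta_i = delta0[cue_set] + sum_k slope_k * z_k(i)
              + country_effect + participant_effect,

with independent normal country and participant effects per judgement x
cue-set cell and ``z_k`` standardised moderators (participant covariates or
latent country factor scores).

Ratings: the latent value of level x in {-1/2, 0, +1/2} (low, medium, high) is

    y* = mu + (rating_effect[cue_set] + b_i) * x
         + participant_intercept + country_intercept + noise,

rounded to the nearest integer and clipped to 1..7.  The optional
per-participant cue-effect slope ``b_i`` may be correlated (``task_coupling``)
with the participant's choice preference deviation, so that the same latent
taste can drive both tasks; with the default SD of 0 the rating model reduces
to a pure random-intercept model.

One integer seed drives everything through named ``SeedSequence`` substreams
(participants, latents, choices, ratings, indicators, country factors), so a
subset of tables can be regenerated bit-identically.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "JUDGEMENTS",
    "CUE_SETS",
    "LEVELS",
    "INDICATOR_NAMES",
    "GeneratorConfig",
    "generate_participants",
    "generate_choices",
    "generate_ratings",
    "generate_country_indicators",
    "country_factor_latents",
    "generate_dataset",
    "write_dataset",
]

JUDGEMENTS = ("attractiveness", "femininity")
CUE_SETS = ("all_cycles", "textbook", "E", "P", "EP_ratio")
LEVELS = ("low", "medium", "high")
LEVEL_SCORE = {"low": -1.0, "medium": 0.0, "high": 1.0}

INDICATOR_NAMES = (
    "HDI",
    "life_expectancy",
    "years_lost_to_disease",
    "fertility_rate",
    "GII",
    "urbanisation",
    "pathogen_prevalence",
    "mortality_rate",
    "homicide_rate",
    "gini",
    "GDP",
)

# substream layout of the master SeedSequence; fixed so any table can be
# regenerated alone
_STREAMS = {
    "participants": 0,
    "latents": 1,
    "choices": 2,
    "ratings": 3,
    "indicators": 4,
    "country_factors": 5,
}


def _default_delta0() -> dict[str, float]:
    # preference strengths implied by the published attractiveness choice
    # proportions at n=1371: delta = log(p_high / p_low) / 2
    return {
        "all_cycles": 0.016,
        "textbook": 0.142,
        "E": -0.039,
        "P": -0.042,
        "EP_ratio": -0.034,
    }


def _default_rating_effect() -> dict[str, float]:
    # high-minus-low latent rating shifts of the order reported for the
    # rating task (small fractions of a scale point)
    return {
        "all_cycles": -0.08,
        "textbook": 0.08,
        "E": 0.22,
        "P": 0.10,
        "EP_ratio": 0.10,
    }


def _default_loadings() -> np.ndarray:
    """Plausible 11 x 2 loading pattern: health/development, inequality."""
    return np.array(
        [
            # health/dev, inequality
            [0.90, -0.10],  # HDI
            [0.90, -0.05],  # life_expectancy
            [-0.80, 0.10],  # years_lost_to_disease
            [-0.70, 0.20],  # fertility_rate
            [-0.50, 0.60],  # GII
            [0.60, -0.10],  # urbanisation
            [-0.70, 0.10],  # pathogen_prevalence
            [-0.80, 0.10],  # mortality_rate
            [0.00, 0.80],   # homicide_rate
            [0.00, 0.90],   # gini
            [0.80, -0.20],  # GDP
        ]
    )


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic study; defaults mirror the emulated design.

    ``delta0`` and ``rating_effect`` accept a scalar (applied to every cue
    set) or a mapping cue-set name -> value.  All standard deviations must be
    nonnegative.  A fixed ``seed`` makes every generated table bit-identical
    across runs.
    """

    n_countries: int = 12
    participants_per_country: int | Sequence[int] = 114
    seed: int = 0
    # 3AFC preference model
    delta0: float | Mapping[str, float] = field(default_factory=_default_delta0)
    delta_sd_participant: float = 0.3
    delta_sd_country: float = 0.1
    # rating model
    rating_mu: float = 4.0
    rating_effect: float | Mapping[str, float] = field(default_factory=_default_rating_effect)
    rating_sd_participant: float = 0.5
    rating_sd_country: float = 0.2
    rating_sd_residual: float = 1.0
    rating_slope_sd_participant: float = 0.0
    task_coupling: float = 0.0
    # moderators: name -> slope on delta_i; names are participant covariate
    # columns or the latent country factors "health_development"/"inequality"
    moderator_slopes: Mapping[str, float] = field(default_factory=dict)
    # country indicators
    factor_loadings: np.ndarray = field(default_factory=_default_loadings)
    indicator_noise_sd: float = 0.3
    # participant covariates
    age_mean: float = 29.59
    age_sd: float = 9.72
    age_min: float = 18.0
    age_max: float = 70.0
    kinsey_high_mass: float = 0.09
    sex_probs: tuple[float, float, float] = (0.447, 0.545, 0.008)  # female, male, other
    soi_missing_rate: float = 0.15
    covariate_missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_countries < 1:
            raise ValueError("n_countries must be >= 1")
        sizes = self.country_sizes()
        if any(s < 1 for s in sizes):
            raise ValueError("participants_per_country entries must be >= 1")
        for name in (
            "delta_sd_participant",
            "delta_sd_country",
            "rating_sd_participant",
            "rating_sd_country",
            "rating_sd_residual",
            "rating_slope_sd_participant",
            "indicator_noise_sd",
            "age_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not -1.0 <= self.task_coupling <= 1.0:
            raise ValueError("task_coupling must lie in [-1, 1]")
        if not 0.0 <= self.kinsey_high_mass <= 1.0:
            raise ValueError("kinsey_high_mass must lie in [0, 1]")
        if not np.isclose(sum(self.sex_probs), 1.0):
            raise ValueError("sex_probs must sum to 1")
        if not self.age_min < self.age_max:
            raise ValueError("age_min must be below age_max")
        L = np.asarray(self.factor_loadings, dtype=float)
        if L.shape != (len(INDICATOR_NAMES), 2):
            raise ValueError(
                f"factor_loadings must be {len(INDICATOR_NAMES)}x2, got {L.shape}"
            )
        self.factor_loadings = L
        for rate in (self.soi_missing_rate, self.covariate_missing_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("missing rates must lie in [0, 1]")

    def country_sizes(self) -> np.ndarray:
        if np.isscalar(self.participants_per_country):
            return np.full(self.n_countries, int(self.participants_per_country))
        sizes = np.asarray(self.participants_per_country, dtype=int)
        if len(sizes) != self.n_countries:
            raise ValueError(
                "participants_per_country sequence length must equal n_countries"
            )
        return sizes

    def n_participants(self) -> int:
        return int(self.country_sizes().sum())

    def delta0_for(self, cue_set: str) -> float:
        if isinstance(self.delta0, Mapping):
            return float(self.delta0[cue_set])
        return float(self.delta0)

    def rating_effect_for(self, cue_set: str) -> float:
        if isinstance(self.rating_effect, Mapping):
            return float(self.rating_effect[cue_set])
        return float(self.rating_effect)

    def replace(self, **changes) -> "GeneratorConfig":
        return dataclasses.replace(self, **changes)


def _stream(config: GeneratorConfig, name: str) -> np.random.Generator:
    children = np.random.SeedSequence(config.seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS[name]])


def generate_participants(config: GeneratorConfig) -> pd.DataFrame:
    """Generate the participant table (one row per rater).

    Covariate conventions: age is truncated-normal on [age_min, age_max];
    kinsey places ``kinsey_high_mass`` probability on {4,5,6} (uniform
    within) and the rest on 0-3 concentrated on 0-1; the 1-7 self-rating
    scales and 1-9 SOI items are uniform integers.  The SOI composite is the
    mean of the nine items; SOI carries extra missingness, mirroring its
    lower completion rate in survey data.
    """
    rng = _stream(config, "participants")
    sizes = config.country_sizes()
    n = int(sizes.sum())
    country_ids = np.repeat([f"C{c:02d}" for c in range(config.n_countries)], sizes)

    sex = rng.choice(["female", "male", "other"], size=n, p=config.sex_probs)
    a, b = (
        (config.age_min - config.age_mean) / config.age_sd,
        (config.age_max - config.age_mean) / config.age_sd,
    )
    age = stats.truncnorm.rvs(
        a, b, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng
    )

    high = rng.random(n) < config.kinsey_high_mass
    kinsey = np.where(
        high,
        rng.integers(4, 7, size=n),
        rng.choice([0, 1, 2, 3], size=n, p=[0.55, 0.25, 0.12, 0.08]),
    )

    def scale7() -> np.ndarray:
        return rng.integers(1, 8, size=n)

    soi_items = rng.integers(1, 10, size=(n, 9))
    df = pd.DataFrame(
        {
            "participant_id": np.arange(n),
            "country_id": country_ids,
            "sex": sex,
            "age": np.round(age, 1),
            "kinsey": kinsey.astype(float),
            "self_attractiveness": scale7().astype(float),
            "self_health": scale7().astype(float),
            "financial_difficulties": scale7().astype(float),
        }
    )
    for j in range(9):
        df[f"soi_{j + 1}"] = soi_items[:, j].astype(float)
    df["soi_score"] = soi_items.mean(axis=1)

    if config.covariate_missing_rate > 0:
        for col in ("self_attractiveness", "self_health", "financial_difficulties"):
            df.loc[rng.random(n) < config.covariate_missing_rate, col] = np.nan
    if config.soi_missing_rate > 0:
        miss = rng.random(n) < config.soi_missing_rate
        df.loc[miss, [f"soi_{j + 1}" for j in range(9)] + ["soi_score"]] = np.nan
    return df


def _cells() -> list[tuple[str, str]]:
    return [(j, cs) for j in JUDGEMENTS for cs in CUE_SETS]


def _preference_latents(config: GeneratorConfig):
    """Country and participant preference deviations per judgement x cue set.

    Drawn from a dedicated substream so that choices and ratings can share
    them (task coupling) while each table remains independently regenerable.
    """
    rng = _stream(config, "latents")
    n = config.n_participants()
    cells = _cells()
    country_dev = rng.normal(0.0, 1.0, size=(config.n_countries, len(cells)))
    participant_dev = rng.normal(0.0, 1.0, size=(n, len(cells)))
    return country_dev, participant_dev


def _standardised_moderators(
    config: GeneratorConfig, participants: pd.DataFrame
) -> np.ndarray:
    """Sum of slope * z(moderator) per participant; missing values drop out."""
    n = len(participants)
    total = np.zeros(n)
    if not config.moderator_slopes:
        return total
    country_z: pd.Series | None = None
    for name, slope in config.moderator_slopes.items():
        if name in ("health_development", "inequality"):
            latents = country_factor_latents(config)
            col = latents[name]
            z = (col - col.mean()) / col.std(ddof=1) if col.std(ddof=1) > 0 else col * 0.0
            vals = participants["country_id"].map(z).to_numpy()
        else:
            col = participants[name].astype(float)
            sd = col.std(ddof=1)
            z = (col - col.mean()) / sd if sd > 0 else col * 0.0
            vals = z.fillna(0.0).to_numpy()
        total = total + float(slope) * vals
    return total


def generate_choices(
    config: GeneratorConfig, participants: pd.DataFrame
) -> pd.DataFrame:
    """Generate one 3AFC choice per participant x judgement x cue set."""
    if len(participants) == 0:
        raise ValueError("participants table is empty")
    rng = _stream(config, "choices")
    country_dev, participant_dev = _preference_latents(config)
    country_index = (
        participants["country_id"].str.removeprefix("C").astype(int).to_numpy()
    )
    pid_index = np.arange(len(participants))
    mod = _standardised_moderators(config, participants)
    x = np.array([LEVEL_SCORE[lv] for lv in LEVELS])

    frames = []
    for k, (judgement, cue_set) in enumerate(_cells()):
        delta = (
            config.delta0_for(cue_set)
            + mod
            + config.delta_sd_country * country_dev[country_index, k]
            + config.delta_sd_participant * participant_dev[pid_index, k]
        )
        logits = np.outer(delta, x)
        logits -= logits.max(axis=1, keepdims=True)
        probs = np.exp(logits)
        probs /= probs.sum(axis=1, keepdims=True)
        u = rng.random(len(participants))
        idx = np.minimum((u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1), 2)
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": participants["participant_id"].to_numpy(),
                    "judgement": judgement,
                    "cue_set": cue_set,
                    "chosen_level": np.array(LEVELS)[idx],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def generate_ratings(
    config: GeneratorConfig, participants: pd.DataFrame
) -> pd.DataFrame:
    """Generate 1-7 ratings: one per participant x judgement x cue set x level."""
    if len(participants) == 0:
        raise ValueError("participants table is empty")
    rng = _stream(config, "ratings")
    n = len(participants)
    country_index = (
        participants["country_id"].str.removeprefix("C").astype(int).to_numpy()
    )

    p_int = rng.normal(0.0, 1.0, size=n) * config.rating_sd_participant
    c_int = rng.normal(0.0, 1.0, size=config.n_countries) * config.rating_sd_country
    own_slope_z = rng.normal(0.0, 1.0, size=(n, len(_cells())))

    _, participant_dev = _preference_latents(config)
    rho = config.task_coupling
    slope_dev = config.rating_slope_sd_participant * (
        rho * participant_dev + np.sqrt(max(0.0, 1.0 - rho**2)) * own_slope_z
    )

    x_level = {"low": -0.5, "medium": 0.0, "high": 0.5}
    frames = []
    for k, (judgement, cue_set) in enumerate(_cells()):
        effect = config.rating_effect_for(cue_set) + slope_dev[:, k]
        for level in LEVELS:
            x = x_level[level]
            noise = rng.normal(0.0, 1.0, size=n) * config.rating_sd_residual
            y = config.rating_mu + effect * x + p_int + c_int[country_index] + noise
            rating = np.clip(np.rint(y), 1, 7).astype(int)
            frames.append(
                pd.DataFrame(
                    {
                        "participant_id": participants["participant_id"].to_numpy(),
                        "judgement": judgement,
                        "cue_set": cue_set,
                        "level": level,
                        "rating": rating,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def country_factor_latents(config: GeneratorConfig) -> pd.DataFrame:
    """Latent two-factor scores per country (ground truth for recovery)."""
    rng = _stream(config, "country_factors")
    scores = rng.normal(0.0, 1.0, size=(config.n_countries, 2))
    return pd.DataFrame(
        scores,
        columns=["health_development", "inequality"],
        index=pd.Index([f"C{c:02d}" for c in range(config.n_countries)], name="country_id"),
    )


def generate_country_indicators(config: GeneratorConfig) -> pd.DataFrame:
    """Generate the country-by-indicator table from the two latent factors."""
    rng = _stream(config, "indicators")
    latents = country_factor_latents(config)
    X = latents.to_numpy() @ config.factor_loadings.T
    if config.indicator_noise_sd > 0:
        X = X + rng.normal(0.0, config.indicator_noise_sd, size=X.shape)
    df = pd.DataFrame(X, columns=list(INDICATOR_NAMES), index=latents.index)
    return df.reset_index()


def generate_dataset(config: GeneratorConfig) -> dict[str, pd.DataFrame]:
    """Generate all four tables (plus latent country factors) in one call."""
    participants = generate_participants(config)
    return {
        "participants": participants,
        "choices": generate_choices(config, participants),
        "ratings": generate_ratings(config, participants),
        "indicators": generate_country_indicators(config),
        "country_latents": country_factor_latents(config).reset_index(),
    }


def write_dataset(dataset: Mapping[str, pd.DataFrame], out_dir: str | Path) -> dict[str, Path]:
    """Write participants/choices/ratings/indicators CSVs (UTF-8, headered)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in ("participants", "choices", "ratings", "indicators"):
        path = out / f"{name}.csv"
        dataset[name].to_csv(path, index=False)
        paths[name] = path
    return paths
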