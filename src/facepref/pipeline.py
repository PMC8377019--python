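"""End-to-end orchestration: ten-cell 3AFC reports, model batteries, power.

``run_full_analysis`` reproduces the published analysis scheme on a dataset
(real or synthetic): exclusions, the ten 3AFC centroid randomisation tests,
the ten rating models, the ten cross-task consistency models, the
twenty moderation model cells (individual-difference and SOI batteries for
each task x judgement x cue set), and the country-factor moderation models.
Every artefact is written with the seed and a hash of the configuration, so
each number in the bundle is re-derivable from (inputs, config, seed).

``reproduce_table1`` re-runs the randomisation tests from *printed* choice
percentages: the percentages are converted to counts summing to n by
largest-remainder rounding (ties broken by column order low, medium, high)
and each row is tested against the uniform null.

``power_study`` simulates the 3AFC preference model over a grid of
preference strengths and sample sizes and reports the rejection rate of the
randomisation test at alpha = .05.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import studydata
from .datagen import CUE_SETS, JUDGEMENTS, GeneratorConfig, generate_dataset
from .preprocessing import apply_exclusions
from .ternary import TernaryComposition, mc_randomisation_test, tally_choices
from .models import (
    INDIVIDUAL_DIFFERENCE_MODERATORS,
    SOI_MODERATORS,
    ModelFit,
    difference_scores,
    fit_consistency_model,
    fit_choice_moderation_model,
    fit_rating_model,
    fit_rating_moderation_model,
)
from .country_factors import fit_country_moderation, fit_two_factor_model

__all__ = [
    "RunConfig",
    "SchemaError",
    "largest_remainder_counts",
    "reproduce_table1",
    "table1_from_choices",
    "power_study",
    "run_full_analysis",
    "load_tables",
]

_ALL_STAGES = ("table1", "ratings", "consistency", "moderation", "country")


class SchemaError(ValueError):
    """An input table violates its schema (bad columns or cell values)."""


@dataclass
class RunConfig:
    """Settings of a full analysis run."""

    data_dir: str | None = None
    out_dir: str = "facepref_out"
    seed: int = 0
    n_sim: int = 10_000
    tie_rule: str = "geq"
    apply_exclusions: bool = True
    min_country_size: int = 10
    stages: tuple[str, ...] = _ALL_STAGES
    log_level: str = "INFO"

    def config_hash(self) -> str:
        """Hash of the analysis-relevant settings (not output locations)."""
        payload = asdict(self)
        for key in ("out_dir", "log_level"):
            payload.pop(key, None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


_SCHEMAS = {
    "participants": ["participant_id", "country_id", "sex", "age", "kinsey"],
    "choices": ["participant_id", "judgement", "cue_set", "chosen_level"],
    "ratings": ["participant_id", "judgement", "cue_set", "level", "rating"],
    "indicators": ["country_id"],
}


def _validate_tables(tables: dict[str, pd.DataFrame]) -> None:
    for name, required in _SCHEMAS.items():
        if name not in tables:
            continue
        df = tables[name]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"{name}: missing columns {missing}")
    if "ratings" in tables:
        bad = tables["ratings"].index[
            ~tables["ratings"]["rating"].between(1, 7)
        ].tolist()
        if bad:
            raise SchemaError(f"ratings: values outside 1..7 at rows {bad[:20]}")
    if "choices" in tables:
        bad = tables["choices"].index[
            ~tables["choices"]["chosen_level"].isin(["low", "medium", "high"])
        ].tolist()
        if bad:
            raise SchemaError(f"choices: invalid chosen_level at rows {bad[:20]}")


def load_tables(data_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Load the four CSV tables from a directory and validate their schemas."""
    data_dir = Path(data_dir)
    tables = {}
    for name in ("participants", "choices", "ratings", "indicators"):
        path = data_dir / f"{name}.csv"
        if path.exists():
            tables[name] = pd.read_csv(path)
    if "participants" not in tables:
        raise SchemaError(f"participants.csv not found in {data_dir}")
    _validate_tables(tables)
    return tables


# ---------------------------------------------------------------------------
# reproduction of printed choice tables


def largest_remainder_counts(percentages, n: int) -> np.ndarray:
    """Integer counts summing to n from percentages, by largest remainder.

    Each percentage maps to ``pct/100 * n``; integer parts are kept and the
    leftover units go to the cells with the largest fractional remainders.
    Ties in the remainders are broken by column position (low, medium, high),
    making the rounding deterministic.
    """
    pct = np.asarray(percentages, dtype=float)
    if pct.min() < 0:
        raise ValueError("percentages must be nonnegative")
    target = pct / 100.0 * n
    base = np.floor(target).astype(int)
    shortfall = int(n - base.sum())
    if shortfall < 0:
        raise ValueError("percentages exceed 100%")
    remainders = target - base
    # stable sort: equal remainders awarded in column order
    order = np.argsort(-remainders, kind="stable")
    base[order[:shortfall]] += 1
    return base


def reproduce_table1(
    proportions: pd.DataFrame | None = None,
    n: int = studydata.FINAL_SAMPLE_SIZE,
    n_sim: int = 10_000,
    seed: int = 0,
    tie_rule: str = "geq",
) -> pd.DataFrame:
    """Re-run the ten randomisation tests from printed choice percentages.

    Parameters
    ----------
    proportions
        Table with columns ``judgement, cue_set, low_pct, medium_pct,
        high_pct`` (percentages per row summing to ~100).  Defaults to the
        published proportions in :mod:`facepref.studydata`.
    n
        Sample size used to reconstitute counts (final analysed sample).
    n_sim, seed, tie_rule
        Monte Carlo settings; each row uses an independent substream of
        ``seed``.

    Returns
    -------
    DataFrame with the reconstituted counts, proportions, observed centroid
    magnitude and Monte Carlo p-value per judgement x cue-set row.
    """
    if proportions is None:
        proportions = studydata.REPORTED_CHOICE_PROPORTIONS
    rows = []
    streams = np.random.SeedSequence(seed).spawn(len(proportions))
    for i, rec in enumerate(proportions.itertuples(index=False)):
        pcts = (rec.low_pct, rec.medium_pct, rec.high_pct)
        total = sum(pcts)
        if not 99.9 <= total <= 100.1:
            raise ValueError(
                f"row {rec.judgement}/{rec.cue_set}: percentages sum to {total:.2f}, "
                "outside [99.9, 100.1]"
            )
        counts = largest_remainder_counts(pcts, n)
        comp = TernaryComposition(*counts)
        res = mc_randomisation_test(
            comp, n_sim=n_sim, seed=np.random.default_rng(streams[i]),
            tie_rule=tie_rule,
        )
        rows.append(
            {
                "judgement": rec.judgement,
                "cue_set": rec.cue_set,
                "n_low": counts[0],
                "n_medium": counts[1],
                "n_high": counts[2],
                "low_pct": 100 * counts[0] / n,
                "medium_pct": 100 * counts[1] / n,
                "high_pct": 100 * counts[2] / n,
                "n": n,
                "magnitude": res.observed_magnitude,
                "p_value": res.p_value,
                "n_sim": n_sim,
                "tie_rule": tie_rule,
                "seed": seed,
            }
        )
    return pd.DataFrame(rows)


def table1_from_choices(
    choices: pd.DataFrame, n_sim: int = 10_000, seed: int = 0, tie_rule: str = "geq"
) -> pd.DataFrame:
    """Tally and test every judgement x cue-set cell of a choices table."""
    rows = []
    streams = np.random.SeedSequence(seed).spawn(len(JUDGEMENTS) * len(CUE_SETS))
    k = 0
    for judgement in JUDGEMENTS:
        for cue_set in CUE_SETS:
            comp = tally_choices(choices, judgement, cue_set)
            res = mc_randomisation_test(
                comp, n_sim=n_sim, seed=np.random.default_rng(streams[k]),
                tie_rule=tie_rule,
            )
            rows.append(
                {
                    "judgement": judgement,
                    "cue_set": cue_set,
                    "n_low": comp.n_low,
                    "n_medium": comp.n_medium,
                    "n_high": comp.n_high,
                    "low_pct": 100 * comp.n_low / comp.n,
                    "medium_pct": 100 * comp.n_medium / comp.n,
                    "high_pct": 100 * comp.n_high / comp.n,
                    "n": comp.n,
                    "magnitude": res.observed_magnitude,
                    "p_value": res.p_value,
                    "n_sim": n_sim,
                    "tie_rule": tie_rule,
                    "seed": seed,
                }
            )
            k += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# simulation studies


def power_study(
    delta0_grid=(0.0, 0.1, 0.2),
    n_grid=(200, 1371),
    replicates: int = 200,
    n_sim: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Rejection rate of the randomisation test over an effect x n grid.

    For each (delta0, n) cell, ``replicates`` choice compositions are drawn
    from the preference model P(j) proportional to exp(delta0 * x_j) (no
    heterogeneity) and tested with ``n_sim`` Monte Carlo samples; power is
    the fraction with p < alpha.  At delta0 = 0 this measures the type-I
    error rate.
    """
    x = np.array([-1.0, 0.0, 1.0])
    rows = []
    streams = np.random.SeedSequence(seed).spawn(len(delta0_grid) * len(n_grid))
    k = 0
    for delta0 in delta0_grid:
        probs = np.exp(delta0 * x)
        probs = probs / probs.sum()
        for n in n_grid:
            rng = np.random.default_rng(streams[k])
            k += 1
            rejections = 0
            for _ in range(replicates):
                counts = rng.multinomial(n, probs)
                res = mc_randomisation_test(
                    TernaryComposition(*counts), n_sim=n_sim, seed=rng
                )
                rejections += res.p_value < alpha
            rows.append(
                {
                    "delta0": delta0,
                    "n": int(n),
                    "replicates": replicates,
                    "n_sim": n_sim,
                    "alpha": alpha,
                    "power": rejections / replicates,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full analysis


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def run_full_analysis(
    config: RunConfig,
    tables: dict[str, pd.DataFrame] | None = None,
    generator_config: GeneratorConfig | None = None,
) -> dict:
    """Run the complete analysis scheme and write the report bundle.

    Inputs come from, in order of precedence: ``tables`` (in-memory),
    ``config.data_dir`` (CSV files), or a synthetic dataset generated from
    ``generator_config`` (default configuration with ``config.seed`` if not
    given).  Returns a summary dict with the bundle location, per-stage
    artefacts, and the list of model failures (never silently skipped).

    The report bundle under ``<out_dir>/report`` is a pure function of
    (inputs, config, seed); wall-clock timings go to ``<out_dir>/logs``.
    """
    out_dir = Path(config.out_dir)
    report_dir = out_dir / "report"
    log_dir = out_dir / "logs"
    report_dir.mkdir(parents=True, exist_ok=True)
    log_dir.mkdir(parents=True, exist_ok=True)
    log_path = log_dir / "run.jsonl"
    log_entries: list[dict] = []

    def log(stage: str, **kw) -> None:
        log_entries.append({"stage": stage, "time": time.time(), **kw})

    if tables is None:
        if config.data_dir is not None:
            tables = load_tables(config.data_dir)
        else:
            gen = generator_config or GeneratorConfig(seed=config.seed)
            tables = generate_dataset(gen)
    _validate_tables(tables)

    failures: list[dict] = []
    bundle: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": list(config.stages),
    }

    participants = tables["participants"]
    if config.apply_exclusions:
        participants, report = apply_exclusions(
            participants, min_country_size=config.min_country_size
        )
        _write_json(report_dir / "exclusion_report.json", report.to_dict())
        bundle["exclusions"] = report.to_dict()
        log("exclusions", **report.to_dict())
    retained = set(participants["participant_id"])
    choices = tables.get("choices")
    ratings = tables.get("ratings")
    if choices is not None:
        choices = choices[choices["participant_id"].isin(retained)]
    if ratings is not None:
        ratings = ratings[ratings["participant_id"].isin(retained)]

    def attempt(model_id: str, fn):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return fn()
        except Exception as exc:
            failures.append({"model_id": model_id, "error": str(exc)})
            log("failure", model_id=model_id, error=str(exc))
            return None

    fits: list[ModelFit] = []
    cells = [(j, cs) for j in JUDGEMENTS for cs in CUE_SETS]

    if "table1" in config.stages and choices is not None:
        t1 = table1_from_choices(
            choices, n_sim=config.n_sim, seed=config.seed, tie_rule=config.tie_rule
        )
        t1.to_csv(report_dir / "table1.csv", index=False)
        bundle["table1"] = t1.to_dict(orient="records")
        log("table1", rows=len(t1))

    if "ratings" in config.stages and ratings is not None:
        for j, cs in cells:
            fit = attempt(
                f"rating~level::{j}::{cs}",
                lambda j=j, cs=cs: fit_rating_model(ratings, participants, j, cs),
            )
            if fit:
                fits.append(fit)
        log("ratings", models=len(cells))

    diffs = None
    if "consistency" in config.stages and ratings is not None and choices is not None:
        diffs = difference_scores(ratings)
        for j, cs in cells:
            fit = attempt(
                f"consistency::{j}::{cs}",
                lambda j=j, cs=cs: fit_consistency_model(
                    diffs, choices, participants, j, cs
                ),
            )
            if fit:
                fits.append(fit)
        log("consistency", models=len(cells))

    if "moderation" in config.stages:
        batteries = {
            "individual_differences": INDIVIDUAL_DIFFERENCE_MODERATORS,
            "soi": SOI_MODERATORS,
        }
        for battery, moderators in batteries.items():
            for j, cs in cells:
                if choices is not None:
                    fit = attempt(
                        f"choice-moderation::{battery}::{j}::{cs}",
                        lambda j=j, cs=cs, m=moderators: fit_choice_moderation_model(
                            choices, participants, m, j, cs
                        ),
                    )
                    if fit:
                        fit.model_id = f"{fit.model_id}::{battery}"
                        fits.append(fit)
                if ratings is not None:
                    fit = attempt(
                        f"rating-moderation::{battery}::{j}::{cs}",
                        lambda j=j, cs=cs, m=moderators: fit_rating_moderation_model(
                            ratings, participants, m, j, cs
                        ),
                    )
                    if fit:
                        fit.model_id = f"{fit.model_id}::{battery}"
                        fits.append(fit)
        log("moderation", batteries=len(batteries))

    if "country" in config.stages and "indicators" in tables:
        factor_fit = attempt(
            "country-factors",
            lambda: fit_two_factor_model(
                tables["indicators"], score_countries=participants["country_id"].unique().tolist()
            ),
        )
        if factor_fit is not None:
            factor_fit.scores.to_csv(report_dir / "factor_scores.csv", index=False)
            factor_fit.loadings.to_csv(report_dir / "loadings.csv")
            for j, cs in cells:
                if choices is not None:
                    fit = attempt(
                        f"country-moderation::choices::{j}::{cs}",
                        lambda j=j, cs=cs: fit_country_moderation(
                            choices, participants, factor_fit.scores, j, cs
                        ),
                    )
                    if fit:
                        fits.append(fit)
                if ratings is not None:
                    fit = attempt(
                        f"country-moderation::ratings::{j}::{cs}",
                        lambda j=j, cs=cs: fit_country_moderation(
                            ratings, participants, factor_fit.scores, j, cs
                        ),
                    )
                    if fit:
                        fits.append(fit)
        log("country", fitted=factor_fit is not None)

    models_dir = report_dir / "models"
    models_dir.mkdir(exist_ok=True)
    summary_rows = []
    for fit in fits:
        safe = fit.model_id.replace("::", "__").replace("~", "_").replace("*", "x")
        safe = safe.replace("+", "-").replace(" ", "")
        _write_json(models_dir / f"{safe}.json", fit.to_dict())
        for term in fit.headline_terms:
            try:
                row = fit.term(term)
            except KeyError:
                continue
            summary_rows.append(
                {
                    "model_id": fit.model_id,
                    "term": term,
                    "estimate": row["estimate"],
                    "se": row["se"],
                    "p": row["p"],
                    "converged": fit.converged,
                    "pruned": "; ".join(fit.pruned),
                }
            )
    summary_cols = ["model_id", "term", "estimate", "se", "p", "converged", "pruned"]
    pd.DataFrame(summary_rows, columns=summary_cols).to_csv(
        report_dir / "model_summary.csv", index=False
    )

    bundle["n_models"] = len(fits)
    bundle["failures"] = failures
    problems = _self_validate(report_dir)
    bundle["validation_problems"] = problems
    _write_json(report_dir / "bundle.json", bundle)
    log_path.write_text("\n".join(json.dumps(e) for e in log_entries) + "\n")
    return bundle


def _self_validate(report_dir: Path) -> list[str]:
    """Sanity pass over the written bundle: p in [0,1], row sums, schemas."""
    problems = []
    t1_path = report_dir / "table1.csv"
    if t1_path.exists():
        t1 = pd.read_csv(t1_path)
        if not t1["p_value"].between(0, 1).all():
            problems.append("table1: p_value outside [0, 1]")
        sums = t1[["low_pct", "medium_pct", "high_pct"]].sum(axis=1)
        if not np.allclose(sums, 100, atol=0.1):
            problems.append("table1: row percentages do not sum to 100")
    summary_path = report_dir / "model_summary.csv"
    if summary_path.exists():
        summ = pd.read_csv(summary_path)
        if len(summ) and not summ["p"].dropna().between(0, 1).all():
            problems.append("model_summary: p outside [0, 1]")
    return problems
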