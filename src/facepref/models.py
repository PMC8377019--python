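"""Rating, consistency and moderation models for the two judgement tasks.

The rating task is analysed with linear mixed models: the fertility-cue
level of the prototype (low vs high) predicts the 1-7 rating with participant
age and sex as covariates, random intercepts for participant and country and
a random level slope for country.  Cross-task consistency regresses each
rater's high-minus-low rating difference score on their 3AFC choice (coded
-1/0/+1).  Moderation models add individual-difference predictors: for the
rating task as level x moderator interactions, for the 3AFC task as main
effects in an ordinal model of the chosen level.

The level term in the rating models is coded +1/2 (high) vs -1/2 (low), so
its coefficient equals the high-minus-low difference on the rating scale.

Mixed-model estimation is delegated to statsmodels ``MixedLM``; participants
are nested in countries, so the country is the grouping factor and the
participant intercepts enter as variance components.  Random-effect
structures start maximal and are pruned (slopes before intercepts) when a
fit is singular or fails to converge; every prune is recorded on the
returned :class:`ModelFit`.

No cumulative-link model with random effects exists in the Python
ecosystem, so the ordinal choice models come in two flavours: the default
``link="cumulative"`` fits a population-averaged cumulative logit by GEE
with the country as the cluster, and ``link="adjacent"`` fits an
adjacent-categories logit by maximum likelihood — the parameterisation under
which the synthetic generator's preference strength is directly the slope,
used for parameter-recovery validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .datagen import CUE_SETS, JUDGEMENTS
from .preprocessing import effect_code, standardise, winsorise

__all__ = [
    "ModelFit",
    "difference_scores",
    "fit_rating_model",
    "fit_consistency_model",
    "fit_choice_moderation_model",
    "fit_rating_moderation_model",
    "RatingCueModel",
    "ConsistencyModel",
    "ChoiceModerationModel",
    "RatingModerationModel",
    "INDIVIDUAL_DIFFERENCE_MODERATORS",
    "SOI_MODERATORS",
]

#: the two moderation batteries run per task and judgement
INDIVIDUAL_DIFFERENCE_MODERATORS = (
    "age",
    "sex",
    "self_attractiveness",
    "self_health",
    "financial_difficulties",
)
SOI_MODERATORS = ("age", "sex", "soi_score")

_SEPARATION_BOUND = 30.0


@dataclass
class ModelFit:
    """Uniform container for one fitted model of the analysis scheme."""

    model_id: str
    formula: str
    fixed_effects: pd.DataFrame  # term, estimate, se, p, ci_low, ci_high
    random_effects: pd.DataFrame  # name, variance
    n_obs: int
    n_participants: int
    n_countries: int
    converged: bool
    headline_terms: list[str] = field(default_factory=list)
    pruned: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def term(self, name: str) -> pd.Series:
        """Row of the fixed-effect table for one term."""
        rows = self.fixed_effects[self.fixed_effects["term"] == name]
        if len(rows) != 1:
            raise KeyError(f"term {name!r} not in model {self.model_id}")
        return rows.iloc[0]

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "formula": self.formula,
            "fixed_effects": self.fixed_effects.to_dict(orient="records"),
            "random_effects": self.random_effects.to_dict(orient="records"),
            "n_obs": self.n_obs,
            "n_participants": self.n_participants,
            "n_countries": self.n_countries,
            "converged": self.converged,
            "headline_terms": self.headline_terms,
            "pruned": self.pruned,
            "notes": self.notes,
        }


# ---------------------------------------------------------------------------
# shared design helpers


def _participant_covariates(participants: pd.DataFrame) -> pd.DataFrame:
    """Winsorised, standardised age and effect-coded sex per participant."""
    cov = participants[["participant_id", "country_id"]].copy()
    cov["age_z"] = standardise(winsorise(participants["age"].astype(float)))
    cov["sex_ec"] = effect_code(participants["sex"], "sex", strict=False)
    return cov


def _moderator_columns(
    participants: pd.DataFrame,
    moderators: tuple[str, ...] | list[str],
    raw: tuple[str, ...] = (),
) -> tuple[pd.DataFrame, list[str]]:
    """Design columns for a moderator battery.

    Continuous moderators are winsorised to +/- 3 SD and standardised at the
    participant level; ``sex`` is effect coded.  Moderators named in ``raw``
    (e.g. country factor scores already standardised at the country level)
    are passed through unchanged.  Returns the per-participant frame and the
    design column names (``<name>_z`` / ``sex_ec`` / raw names).
    """
    out = participants[["participant_id", "country_id"]].copy()
    cols: list[str] = []
    for name in moderators:
        if name in raw:
            out[name] = participants[name].astype(float)
            cols.append(name)
        elif name == "sex":
            out["sex_ec"] = effect_code(participants["sex"], "sex", strict=False)
            cols.append("sex_ec")
        else:
            vals = participants[name].astype(float)
            col = f"{name}_z"
            if vals.notna().sum() >= 2 and vals.std(ddof=1) > 0:
                out[col] = standardise(winsorise(vals))
            else:
                out[col] = np.nan  # constant or near-empty: flagged downstream
            cols.append(col)
    return out, cols


def _fixed_effects_table(result, rename: dict[str, str] | None = None) -> pd.DataFrame:
    params = result.params
    ci = result.conf_int()
    fe_names = getattr(result.model, "exog_names", list(params.index))
    rows = []
    for name in fe_names:
        if name not in params.index:
            continue
        label = (rename or {}).get(name, name)
        rows.append(
            {
                "term": label,
                "estimate": float(params[name]),
                "se": float(result.bse[name]),
                "p": float(result.pvalues[name]),
                "ci_low": float(ci.loc[name, 0]),
                "ci_high": float(ci.loc[name, 1]),
            }
        )
    return pd.DataFrame(rows)


def _fit_mixedlm(
    df: pd.DataFrame,
    formula: str,
    slope_term: str | None,
    participant_vc: bool,
    reml: bool = True,
):
    """Fit a country-grouped MixedLM with prune-on-singularity cascade.

    Starts from the maximal requested structure (country intercept + country
    slope on ``slope_term`` + participant variance components), prunes the
    slope and then the participant intercepts if the fit is singular or does
    not converge, and falls back to OLS as a last resort.  Returns
    ``(result, random_effects, pruned, converged)``.
    """
    df = df.copy()
    if participant_vc:
        # relabel participants within country: keeps the vc design narrow
        df["_pidx"] = df.groupby("country_id")["participant_id"].transform(
            lambda s: pd.factorize(s)[0]
        )
    structures = []
    if slope_term is not None:
        structures.append((f"~{slope_term}", participant_vc, f"country slope on {slope_term}"))
    structures.append(("1", participant_vc, "country intercept"))
    if participant_vc:
        structures.append(("1", False, "country intercept only"))

    pruned: list[str] = []
    last_error: Exception | None = None
    for i, (re_formula, use_vc, label) in enumerate(structures):
        vc = {"participant": "0 + C(_pidx)"} if use_vc else None
        best = None
        for method in (None, "lbfgs", "powell"):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model = smf.mixedlm(
                        formula, df, groups="country_id", re_formula=re_formula,
                        vc_formula=vc,
                    )
                    res = model.fit(reml=reml, method=method, maxiter=200)
            except (np.linalg.LinAlgError, ValueError) as exc:
                last_error = exc
                continue
            ok = bool(res.converged) and np.isfinite(res.params).all()
            singular = False
            if ok and res.cov_re.size:
                eigs = np.linalg.eigvalsh(np.asarray(res.cov_re, dtype=float))
                singular = bool(eigs.min() < 1e-6 * max(1.0, res.scale))
            if ok and not singular:
                best = res
                break
            if ok and best is None:
                best = res  # keep a converged-but-singular fit as fallback
        if best is not None:
            singular = False
            if best.cov_re.size:
                eigs = np.linalg.eigvalsh(np.asarray(best.cov_re, dtype=float))
                singular = bool(eigs.min() < 1e-6 * max(1.0, best.scale))
            if singular and i + 1 < len(structures):
                pruned.append(label)
                continue
            re_rows = []
            cov_re = np.asarray(best.cov_re, dtype=float)
            re_names = list(best.cov_re.index) if best.cov_re.size else []
            for j, name in enumerate(re_names):
                re_rows.append({"name": f"country {name}", "variance": float(cov_re[j, j])})
            for name, v in zip(model.exog_vc.names if vc else [], np.atleast_1d(best.vcomp)):
                re_rows.append({"name": name, "variance": float(v)})
            re_rows.append({"name": "residual", "variance": float(best.scale)})
            return best, pd.DataFrame(re_rows), pruned, bool(best.converged)
        pruned.append(label)

    # every mixed structure failed: ordinary least squares keeps the analysis
    # alive with a note rather than dying on a degenerate cell
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = smf.ols(formula, df).fit()
    except Exception as exc:  # pragma: no cover - pathological inputs
        raise RuntimeError(f"model could not be fitted: {last_error or exc}") from exc
    re_tab = pd.DataFrame([{"name": "residual", "variance": float(res.mse_resid)}])
    pruned.append("all random effects (OLS fallback)")
    return res, re_tab, pruned, True


# ---------------------------------------------------------------------------
# rating model


class RatingCueModel(BaseEstimator):
    """Linear mixed model: cue level (low vs high) predicts ratings.

    Parameters
    ----------
    judgement, cue_set
        Which judgement x prototype-set cell to analyse.
    reml : bool, default True

    Attributes
    ----------
    result_ : ModelFit
    level_effect_ : float
        Estimated high-minus-low rating difference (the headline term).
    """

    def __init__(self, judgement: str = "attractiveness", cue_set: str = "all_cycles",
                 reml: bool = True):
        self.judgement = judgement
        self.cue_set = cue_set
        self.reml = reml

    def _design(self, ratings: pd.DataFrame, participants: pd.DataFrame) -> pd.DataFrame:
        sub = ratings[
            (ratings["judgement"] == self.judgement)
            & (ratings["cue_set"] == self.cue_set)
            & (ratings["level"].isin(["low", "high"]))
        ].copy()
        if len(sub) == 0:
            raise ValueError(
                f"no low/high ratings for judgement={self.judgement!r}, "
                f"cue_set={self.cue_set!r}"
            )
        # +1/2 vs -1/2: the coefficient is the high-minus-low difference
        sub["level_x"] = effect_code(sub["level"], "level") / 2.0
        cov = _participant_covariates(participants)
        df = sub.merge(cov, on="participant_id", how="inner")
        return df.dropna(subset=["rating", "level_x", "age_z", "sex_ec"])

    def fit(self, ratings: pd.DataFrame, participants: pd.DataFrame):
        df = self._design(ratings, participants)
        if df["rating"].nunique() <= 1:
            raise ValueError(
                "degenerate fit: all ratings identical in "
                f"{self.judgement}/{self.cue_set}"
            )
        formula = "rating ~ level_x + age_z + sex_ec"
        res, re_tab, pruned, converged = _fit_mixedlm(
            df, formula, slope_term="level_x", participant_vc=True, reml=self.reml
        )
        fe = _fixed_effects_table(res, rename={"level_x": "level (high-low)"})
        self.result_ = ModelFit(
            model_id=f"rating~level::{self.judgement}::{self.cue_set}",
            formula=formula
            + " + (1 + level_x | country) + (1 | participant)",
            fixed_effects=fe,
            random_effects=re_tab,
            n_obs=len(df),
            n_participants=df["participant_id"].nunique(),
            n_countries=df["country_id"].nunique(),
            converged=converged,
            headline_terms=["level (high-low)"],
            pruned=pruned,
        )
        self.level_effect_ = float(self.result_.term("level (high-low)")["estimate"])
        return self


def fit_rating_model(
    ratings: pd.DataFrame,
    participants: pd.DataFrame,
    judgement: str = "attractiveness",
    cue_set: str = "all_cycles",
) -> ModelFit:
    """Fit the rating-task mixed model for one judgement x cue-set cell."""
    return RatingCueModel(judgement, cue_set).fit(ratings, participants).result_


# ---------------------------------------------------------------------------
# difference scores and consistency model


def difference_scores(ratings: pd.DataFrame) -> pd.DataFrame:
    """High-minus-low rating difference per participant x judgement x cue set.

    Positive scores mean the high-fertility-cue prototype was rated higher.
    Participants missing either the low or the high rating for a cell are
    omitted from that cell.
    """
    sub = ratings[ratings["level"].isin(["low", "high"])]
    wide = sub.pivot_table(
        index=["participant_id", "judgement", "cue_set"],
        columns="level",
        values="rating",
        aggfunc="first",
    )
    wide = wide.dropna(subset=["low", "high"])
    out = wide.reset_index()
    out["diff"] = out["high"] - out["low"]
    return out[["participant_id", "judgement", "cue_set", "diff"]]


class ConsistencyModel(BaseEstimator):
    """Do raters who *choose* the high-cue face also *rate* it higher?

    Mixed model of the high-minus-low difference score on the 3AFC choice
    coded -1/0/+1 (low/medium/high), with age and sex covariates and a
    country random intercept.  A positive choice coefficient indicates
    cross-task consistency.
    """

    def __init__(self, judgement: str = "attractiveness", cue_set: str = "all_cycles"):
        self.judgement = judgement
        self.cue_set = cue_set

    def fit(self, diff_scores: pd.DataFrame, choices: pd.DataFrame,
            participants: pd.DataFrame):
        ds = diff_scores[
            (diff_scores["judgement"] == self.judgement)
            & (diff_scores["cue_set"] == self.cue_set)
        ]
        ch = choices[
            (choices["judgement"] == self.judgement)
            & (choices["cue_set"] == self.cue_set)
        ][["participant_id", "chosen_level"]]
        df = ds.merge(ch, on="participant_id", how="inner")
        if len(df) == 0:
            raise ValueError(
                "no overlap between difference scores and choices for "
                f"{self.judgement}/{self.cue_set}"
            )
        df["choice_score"] = effect_code(df["chosen_level"], "chosen_level")
        cov = _participant_covariates(participants)
        df = df.merge(cov, on="participant_id", how="inner").dropna(
            subset=["diff", "choice_score", "age_z", "sex_ec"]
        )
        formula = "diff ~ choice_score + age_z + sex_ec"
        notes: list[str] = []
        if df["diff"].nunique() <= 1 or df["choice_score"].nunique() <= 1:
            # degenerate: no outcome or predictor variance; coefficient 0
            fe = pd.DataFrame(
                [
                    {"term": "choice_score", "estimate": 0.0, "se": np.nan,
                     "p": np.nan, "ci_low": np.nan, "ci_high": np.nan}
                ]
            )
            self.result_ = ModelFit(
                model_id=f"consistency::{self.judgement}::{self.cue_set}",
                formula=formula + " + (1 | country)",
                fixed_effects=fe,
                random_effects=pd.DataFrame(columns=["name", "variance"]),
                n_obs=len(df),
                n_participants=df["participant_id"].nunique(),
                n_countries=df["country_id"].nunique(),
                converged=False,
                headline_terms=["choice_score"],
                notes=["degenerate: outcome or predictor constant"],
            )
            self.choice_effect_ = 0.0
            return self
        res, re_tab, pruned, converged = _fit_mixedlm(
            df, formula, slope_term=None, participant_vc=False
        )
        fe = _fixed_effects_table(res)
        self.result_ = ModelFit(
            model_id=f"consistency::{self.judgement}::{self.cue_set}",
            formula=formula + " + (1 | country)",
            fixed_effects=fe,
            random_effects=re_tab,
            n_obs=len(df),
            n_participants=df["participant_id"].nunique(),
            n_countries=df["country_id"].nunique(),
            converged=converged,
            headline_terms=["choice_score"],
            pruned=pruned,
            notes=notes,
        )
        self.choice_effect_ = float(self.result_.term("choice_score")["estimate"])
        return self


def fit_consistency_model(
    diff_scores: pd.DataFrame,
    choices: pd.DataFrame,
    participants: pd.DataFrame,
    judgement: str = "attractiveness",
    cue_set: str = "all_cycles",
) -> ModelFit:
    """Cross-task consistency model for one judgement x cue-set cell."""
    return (
        ConsistencyModel(judgement, cue_set)
        .fit(diff_scores, choices, participants)
        .result_
    )


# ---------------------------------------------------------------------------
# ordinal choice moderation models


def _adjacent_categories_mle(y_idx: np.ndarray, Z: np.ndarray):
    """ML fit of the adjacent-categories logit P(j) ~ exp(delta_i * x_j).

    ``delta_i = b0 + Z_i @ gamma`` with level scores x = (-1, 0, +1); the
    slope gamma is on the same scale as the generator's preference strength.
    Returns (params, se, converged); SEs from the analytic observed
    information.
    """
    x = np.array([-1.0, 0.0, 1.0])
    X1 = np.column_stack([np.ones(len(Z)), Z])

    def negll_grad(theta):
        delta = X1 @ theta
        L = delta[:, None] * x[None, :]
        M = L.max(axis=1, keepdims=True)
        logZ = M[:, 0] + np.log(np.exp(L - M).sum(axis=1))
        ll = delta * x[y_idx] - logZ
        P = np.exp(L - logZ[:, None])
        resid = x[y_idx] - P @ x
        return -ll.sum(), -(X1.T @ resid)

    opt = optimize.minimize(
        negll_grad, np.zeros(X1.shape[1]), jac=True, method="BFGS",
        options={"maxiter": 500},
    )
    theta = opt.x
    delta = X1 @ theta
    L = delta[:, None] * x[None, :]
    M = L.max(axis=1, keepdims=True)
    P = np.exp(L - M)
    P /= P.sum(axis=1, keepdims=True)
    var_x = P @ x**2 - (P @ x) ** 2
    info = (X1 * var_x[:, None]).T @ X1
    separated = (not np.isfinite(theta).all()) or np.abs(theta).max() > _SEPARATION_BOUND
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full_like(theta, np.nan)
        separated = True
    return theta, se, bool(opt.success) and not separated


class ChoiceModerationModel(BaseEstimator):
    """Ordinal model of the chosen cue level on individual differences.

    The chosen level is treated as ordered low < medium < high.  Continuous
    moderators are winsorised and standardised at the participant level, sex
    is effect coded, and rows with missing values on any moderator are
    dropped for this model only.

    Parameters
    ----------
    moderators : sequence of str
        Participant covariates (the individual-differences battery or the
        SOI battery).
    link : {"cumulative", "adjacent"}, default "cumulative"
        ``"cumulative"`` fits a population-averaged cumulative logit via GEE
        clustered on country; ``"adjacent"`` fits the adjacent-categories
        logit whose slope is the generator's preference-strength scale.

    Positive coefficients always mean the moderator shifts choices toward
    the high-cue prototype.
    """

    def __init__(
        self,
        judgement: str = "attractiveness",
        cue_set: str = "all_cycles",
        moderators: tuple[str, ...] = INDIVIDUAL_DIFFERENCE_MODERATORS,
        link: str = "cumulative",
        raw_moderators: tuple[str, ...] = (),
    ):
        self.judgement = judgement
        self.cue_set = cue_set
        self.moderators = moderators
        self.link = link
        self.raw_moderators = raw_moderators

    def fit(self, choices: pd.DataFrame, participants: pd.DataFrame):
        if self.link not in ("cumulative", "adjacent"):
            raise ValueError(f"link must be 'cumulative' or 'adjacent', got {self.link!r}")
        ch = choices[
            (choices["judgement"] == self.judgement)
            & (choices["cue_set"] == self.cue_set)
        ][["participant_id", "chosen_level"]]
        if len(ch) == 0:
            raise ValueError(
                f"no choices for {self.judgement}/{self.cue_set}"
            )
        mod_frame, cols = _moderator_columns(
            participants, self.moderators, raw=self.raw_moderators
        )
        df = ch.merge(mod_frame, on="participant_id", how="inner")
        notes: list[str] = []
        usable = []
        for col in cols:
            if df[col].notna().sum() >= 2 and df[col].std(ddof=1) > 0:
                usable.append(col)
            else:
                notes.append(f"{col}: non-estimable (constant or missing)")
        df = df.dropna(subset=usable + ["chosen_level"])
        y = pd.Categorical(
            df["chosen_level"], categories=["low", "medium", "high"], ordered=True
        ).codes.astype(int)
        Z = df[usable].to_numpy(dtype=float)

        rows = []
        if self.link == "adjacent":
            theta, se, converged = _adjacent_categories_mle(y, Z)
            for i, col in enumerate(usable, start=1):
                est, s = theta[i], se[i]
                rows.append(
                    {
                        "term": col,
                        "estimate": float(est),
                        "se": float(s),
                        "p": float(2 * stats.norm.sf(abs(est / s))) if s > 0 else np.nan,
                        "ci_low": float(est - 1.959963984540054 * s),
                        "ci_high": float(est + 1.959963984540054 * s),
                    }
                )
            re_tab = pd.DataFrame(columns=["name", "variance"])
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.OrdinalGEE(
                    y, Z, groups=df["country_id"].to_numpy(),
                    cov_struct=sm.cov_struct.Exchangeable(),
                )
                res = model.fit()
            converged = bool(np.isfinite(np.asarray(res.params)).all())
            ci = res.conf_int()
            for i, col in enumerate(usable):
                # OrdinalGEE models P(Y > j): positive slope = toward high
                name = f"x{i + 1}"
                if name not in res.params.index:
                    continue
                rows.append(
                    {
                        "term": col,
                        "estimate": float(res.params[name]),
                        "se": float(res.bse[name]),
                        "p": float(res.pvalues[name]),
                        "ci_low": float(ci.loc[name, 0]),
                        "ci_high": float(ci.loc[name, 1]),
                    }
                )
            re_tab = pd.DataFrame(
                [{"name": "country (exchangeable corr.)",
                  "variance": float(res.cov_struct.dep_params)}]
            )
        for note_col in [c for c in cols if c not in usable]:
            rows.append(
                {"term": note_col, "estimate": np.nan, "se": np.nan, "p": np.nan,
                 "ci_low": np.nan, "ci_high": np.nan}
            )
        fe = pd.DataFrame(rows)
        if fe["estimate"].abs().max() > _SEPARATION_BOUND:
            converged = False
            notes.append("possible complete separation: extreme coefficient")
        self.result_ = ModelFit(
            model_id=(
                f"choice~{'+'.join(self.moderators)}::{self.judgement}::{self.cue_set}"
                f"::{self.link}"
            ),
            formula=f"ordered(chosen_level) ~ {' + '.join(usable)} [{self.link}]",
            fixed_effects=fe,
            random_effects=re_tab,
            n_obs=len(df),
            n_participants=df["participant_id"].nunique(),
            n_countries=df["country_id"].nunique(),
            converged=bool(converged),
            headline_terms=usable,
            notes=notes,
        )
        return self


def fit_choice_moderation_model(
    choices: pd.DataFrame,
    participants: pd.DataFrame,
    moderators: tuple[str, ...] = INDIVIDUAL_DIFFERENCE_MODERATORS,
    judgement: str = "attractiveness",
    cue_set: str = "all_cycles",
    link: str = "cumulative",
) -> ModelFit:
    """Ordinal moderation model of 3AFC choice for one cell."""
    return (
        ChoiceModerationModel(judgement, cue_set, moderators, link)
        .fit(choices, participants)
        .result_
    )


# ---------------------------------------------------------------------------
# rating moderation models


class RatingModerationModel(BaseEstimator):
    """Rating mixed model with level x moderator interactions.

    Extends the rating model with one interaction per moderator; the
    interaction coefficients — does the moderator change the high-minus-low
    rating gap? — are the headline terms.  Constant moderators are flagged
    non-estimable and excluded from the design.
    """

    def __init__(
        self,
        judgement: str = "attractiveness",
        cue_set: str = "all_cycles",
        moderators: tuple[str, ...] = INDIVIDUAL_DIFFERENCE_MODERATORS,
        raw_moderators: tuple[str, ...] = (),
    ):
        self.judgement = judgement
        self.cue_set = cue_set
        self.moderators = moderators
        self.raw_moderators = raw_moderators

    def fit(self, ratings: pd.DataFrame, participants: pd.DataFrame):
        sub = ratings[
            (ratings["judgement"] == self.judgement)
            & (ratings["cue_set"] == self.cue_set)
            & (ratings["level"].isin(["low", "high"]))
        ].copy()
        if len(sub) == 0:
            raise ValueError(f"no low/high ratings for {self.judgement}/{self.cue_set}")
        sub["level_x"] = effect_code(sub["level"], "level") / 2.0
        mod_frame, cols = _moderator_columns(
            participants, self.moderators, raw=self.raw_moderators
        )
        df = sub.merge(mod_frame, on="participant_id", how="inner")
        notes: list[str] = []
        usable = []
        for col in cols:
            if df[col].notna().sum() >= 2 and df[col].std(ddof=1) > 0:
                usable.append(col)
            else:
                notes.append(f"level_x:{col}: non-estimable (moderator constant)")
        df = df.dropna(subset=usable + ["rating"])
        terms = " + ".join([f"level_x*{c}" for c in usable]) or "level_x"
        formula = f"rating ~ {terms}"
        res, re_tab, pruned, converged = _fit_mixedlm(
            df, formula, slope_term="level_x", participant_vc=True
        )
        fe = _fixed_effects_table(res)
        headline = [t for t in fe["term"] if ":" in t]
        for col in [c for c in cols if c not in usable]:
            fe = pd.concat(
                [fe, pd.DataFrame([{"term": f"level_x:{col}", "estimate": np.nan,
                                    "se": np.nan, "p": np.nan,
                                    "ci_low": np.nan, "ci_high": np.nan}])],
                ignore_index=True,
            )
        self.result_ = ModelFit(
            model_id=(
                f"rating~level*{'+'.join(self.moderators)}"
                f"::{self.judgement}::{self.cue_set}"
            ),
            formula=formula + " + (1 + level_x | country) + (1 | participant)",
            fixed_effects=fe,
            random_effects=re_tab,
            n_obs=len(df),
            n_participants=df["participant_id"].nunique(),
            n_countries=df["country_id"].nunique(),
            converged=converged,
            headline_terms=headline,
            pruned=pruned,
            notes=notes,
        )
        return self


def fit_rating_moderation_model(
    ratings: pd.DataFrame,
    participants: pd.DataFrame,
    moderators: tuple[str, ...] = INDIVIDUAL_DIFFERENCE_MODERATORS,
    judgement: str = "attractiveness",
    cue_set: str = "all_cycles",
) -> ModelFit:
    """Rating moderation model (level x moderator interactions) for one cell."""
    return (
        RatingModerationModel(judgement, cue_set, moderators)
        .fit(ratings, participants)
        .result_
    )
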