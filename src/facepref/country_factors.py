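"""Two-factor analysis of country indicators and country-level moderation.

Eleven national demographic statistics (HDI, life expectancy, years lost to
disease, fertility rate, the Gender Inequality Index, urbanisation,
historical pathogen prevalence, mortality rate, homicide rate, Gini
coefficient, GDP) are reduced to two interpretable factors — a
health/development factor and an inequality factor — by exploratory factor
analysis (maximum-likelihood extraction, varimax rotation, regression-method
scores).  The factor model is fitted on every country supplied (typically
many more than appear in the response data); scores for the study countries
are then extracted and standardised across those countries, which is the
country-level standardisation the moderation models expect.

Factor labelling is automatic: the factor loading most heavily on HDI and
life expectancy is called ``health_development``, the one loading on Gini,
GII and homicide rate is ``inequality``; signs are oriented so those marker
loadings are positive.  Both are conventions — a factor model is only
identified up to sign and rotation — and can be overridden.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.decomposition import FactorAnalysis

from .datagen import INDICATOR_NAMES
from .models import (
    ChoiceModerationModel,
    ModelFit,
    RatingModerationModel,
)
from .preprocessing import standardise

__all__ = [
    "CountryFactorScores",
    "CountryFactorModel",
    "fit_two_factor_model",
    "tucker_congruence",
    "align_loadings",
    "fit_country_moderation",
]

_HEALTH_MARKERS = ("HDI", "life_expectancy")
_INEQUALITY_MARKERS = ("gini", "GII", "homicide_rate")


@dataclass
class CountryFactorScores:
    """Scores, loadings and variance shares from the two-factor model."""

    scores: pd.DataFrame  # country_id, health_development, inequality (z-scores)
    loadings: pd.DataFrame  # indicator x (health_development, inequality)
    variance_explained: pd.Series  # share of total variance per factor


class CountryFactorModel(BaseEstimator):
    """EFA of the country indicator table into two named factors.

    Parameters
    ----------
    n_factors : int, default 2
    rotation : {"varimax", None}, default "varimax"
    labels : tuple of str or None
        Override the automatic (marker-based) factor labelling; given in
        extracted-factor order.

    Attributes
    ----------
    loadings_ : DataFrame of shape (11, 2)
        Rotated loadings, columns named by factor label.
    noise_variance_ : ndarray
        Indicator-specific variances from the ML fit.
    variance_explained_ : Series
        Sum of squared loadings per factor over the number of indicators.
    indicator_names_ : list of str
    """

    def __init__(self, n_factors: int = 2, rotation: str | None = "varimax",
                 labels: tuple[str, ...] | None = None):
        self.n_factors = n_factors
        self.rotation = rotation
        self.labels = labels

    def _prepare(self, indicators: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
        df = indicators.set_index("country_id") if "country_id" in indicators else indicators
        df = df.apply(pd.to_numeric)
        if df.isna().any().any():
            warnings.warn(
                "missing indicator cells mean-imputed before factor analysis",
                stacklevel=3,
            )
            df = df.fillna(df.mean())
        sds = df.std(ddof=1)
        zero = sds[~(sds > 0)].index.tolist()
        if zero:
            raise ValueError(f"zero-variance indicators: {zero}")
        X = ((df - df.mean()) / sds).to_numpy()
        return df, X

    def fit(self, indicators: pd.DataFrame, y=None):
        df, X = self._prepare(indicators)
        if len(df) <= self.n_factors:
            raise ValueError(
                f"need more countries ({len(df)}) than factors ({self.n_factors})"
            )
        corr = np.corrcoef(X, rowvar=False)
        cond = np.linalg.cond(corr)
        if len(df) <= X.shape[1] and (not np.isfinite(cond) or cond > 1e12):
            # too few countries to support the indicator table: the sample
            # correlation matrix is singular for lack of data, not because
            # the indicators share a low-rank signal
            raise ValueError(
                f"indicator correlation matrix is non-invertible (condition "
                f"number {cond:.3g}) with only {len(df)} countries for "
                f"{X.shape[1]} indicators; supply more countries"
            )
        fa = FactorAnalysis(n_components=self.n_factors, rotation=self.rotation,
                            random_state=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fa.fit(X)
        loadings = fa.components_.T  # (n_indicators, n_factors)

        names = list(df.columns)
        labels, signs = self._label(loadings, names)
        loadings = loadings * signs  # orient marker loadings positive
        self.loadings_ = pd.DataFrame(loadings, index=names, columns=labels)
        # canonical column order where both canonical names are present
        want = ["health_development", "inequality"]
        if set(want) <= set(labels):
            self.loadings_ = self.loadings_[want + [l for l in labels if l not in want]]
        self._signs = signs
        self._fa = fa
        self._fit_columns = names
        self._fit_means = df.mean()
        self._fit_sds = df.std(ddof=1)
        self.noise_variance_ = fa.noise_variance_
        ssq = (self.loadings_**2).sum(axis=0)
        self.variance_explained_ = ssq / len(names)
        self.indicator_names_ = names
        self.n_countries_fit_ = len(df)
        return self

    def _label(self, loadings: np.ndarray, names: list[str]):
        """Assign factor labels and orienting signs from marker loadings."""
        if self.labels is not None:
            if len(self.labels) != loadings.shape[1]:
                raise ValueError("labels length must equal n_factors")
            signs = np.ones(loadings.shape[1])
            return list(self.labels), signs
        idx = {n: i for i, n in enumerate(names)}
        health_w = np.array(
            [loadings[idx[m]] for m in _HEALTH_MARKERS if m in idx]
        ).sum(axis=0)
        ineq_w = np.array(
            [loadings[idx[m]] for m in _INEQUALITY_MARKERS if m in idx]
        ).sum(axis=0)
        health_f = int(np.argmax(np.abs(health_w)))
        ineq_f = int(np.argmax(np.abs(ineq_w)))
        if health_f == ineq_f:
            # markers agree on one factor: give the other factor to the
            # weaker claim
            if abs(health_w[health_f]) >= abs(ineq_w[ineq_f]):
                ineq_f = 1 - health_f if loadings.shape[1] == 2 else ineq_f
            else:
                health_f = 1 - ineq_f if loadings.shape[1] == 2 else health_f
        labels = [f"factor_{k + 1}" for k in range(loadings.shape[1])]
        labels[health_f] = "health_development"
        labels[ineq_f] = "inequality"
        signs = np.ones(loadings.shape[1])
        signs[health_f] = np.sign(health_w[health_f]) or 1.0
        signs[ineq_f] = np.sign(ineq_w[ineq_f]) or 1.0
        return labels, signs

    def transform(self, indicators: pd.DataFrame, standardise_scores: bool = True
                  ) -> pd.DataFrame:
        """Regression-method factor scores for the given countries.

        Scores are z-standardised *across the given countries* (the
        country-level standardisation used by the moderation models); pass
        ``standardise_scores=False`` for raw regression scores on the
        fitting sample's scale.
        """
        has_id = "country_id" in indicators
        df = indicators.set_index("country_id") if has_id else indicators.copy()
        df = df[self._fit_columns].apply(pd.to_numeric)
        if df.isna().any().any():
            df = df.fillna(self._fit_means)
        X = ((df - self._fit_means) / self._fit_sds).to_numpy()
        raw = self._fa.transform(X) * self._signs
        out = pd.DataFrame(raw, index=df.index, columns=list(self.loadings_.columns)
                           if raw.shape[1] == self.loadings_.shape[1]
                           else None)
        out = out[self.loadings_.columns]
        if standardise_scores:
            for col in out.columns:
                out[col] = standardise(out[col])
        return out.reset_index() if has_id else out


def fit_two_factor_model(
    indicators: pd.DataFrame,
    score_countries: pd.DataFrame | list[str] | None = None,
) -> CountryFactorScores:
    """Fit the two-factor model and score (a subset of) countries.

    Parameters
    ----------
    indicators
        Country-by-indicator table; ``country_id`` plus the 11 indicators.
        Fit on *all* supplied countries.
    score_countries
        Countries to score (list of ids or a table with ``country_id``);
        defaults to all fitted countries.  Scores are standardised across
        the scored set.
    """
    model = CountryFactorModel().fit(indicators)
    if score_countries is None:
        subset = indicators
    else:
        ids = (
            list(score_countries["country_id"])
            if isinstance(score_countries, pd.DataFrame)
            else list(score_countries)
        )
        subset = indicators[indicators["country_id"].isin(ids)]
        if len(subset) == 0:
            raise ValueError("none of the requested countries are in the indicator table")
    scores = model.transform(subset)
    return CountryFactorScores(
        scores=scores,
        loadings=model.loadings_.copy(),
        variance_explained=model.variance_explained_.copy(),
    )


def align_loadings(estimated: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Orthogonally rotate estimated loadings onto a reference (procrustes).

    Factor solutions are identified only up to orthogonal rotation and sign,
    so recovery is judged after the best rotation of the estimate onto the
    reference pattern.
    """
    A = np.asarray(estimated, dtype=float)
    B = np.asarray(reference, dtype=float)
    U, _, Vt = np.linalg.svd(A.T @ B)
    return A @ (U @ Vt)


def tucker_congruence(estimated, reference, align: bool = True) -> np.ndarray:
    """Tucker's congruence coefficient per factor (after optional alignment).

    phi(x, y) = sum(x*y) / sqrt(sum(x^2) * sum(y^2)); values >= 0.95 are
    conventionally read as factor equality.
    """
    A = np.asarray(estimated, dtype=float)
    B = np.asarray(reference, dtype=float)
    if align:
        A = align_loadings(A, B)
    num = (A * B).sum(axis=0)
    den = np.sqrt((A**2).sum(axis=0) * (B**2).sum(axis=0))
    return num / den


def fit_country_moderation(
    data: pd.DataFrame,
    participants: pd.DataFrame,
    factor_scores: pd.DataFrame,
    judgement: str = "attractiveness",
    cue_set: str = "all_cycles",
    task: str | None = None,
    link: str = "cumulative",
) -> ModelFit:
    """Moderation by country factors, for either task.

    Attaches the (country-standardised) health/development and inequality
    scores to each participant and fits the same model shell as the
    individual-difference moderation: main effects in the ordinal choice
    model (``task="choices"``), level x factor interactions in the rating
    model (``task="ratings"``).  ``task`` is inferred from the columns of
    ``data`` when not given.

    With a single country the factors carry no between-country variance and
    the model is returned flagged non-estimable rather than raised.
    """
    if task is None:
        task = "ratings" if "rating" in data.columns else "choices"
    scores = factor_scores.copy()
    factor_cols = [c for c in ("health_development", "inequality") if c in scores]
    if not factor_cols:
        raise ValueError("factor_scores must contain health_development/inequality")
    aug = participants.merge(scores[["country_id"] + factor_cols], on="country_id",
                             how="left")
    single = aug["country_id"].nunique() <= 1
    if single:
        for col in factor_cols:
            aug[col] = np.nan  # no between-country variance: flag, don't fit
    moderators = tuple(factor_cols)
    if task == "choices":
        fit = ChoiceModerationModel(
            judgement, cue_set, moderators, link=link, raw_moderators=moderators
        ).fit(data, aug)
    elif task == "ratings":
        fit = RatingModerationModel(
            judgement, cue_set, moderators, raw_moderators=moderators
        ).fit(data, aug)
    else:
        raise ValueError(f"task must be 'choices' or 'ratings', got {task!r}")
    result = fit.result_
    result.model_id = f"country-moderation::{task}::{judgement}::{cue_set}"
    if single:
        result.notes.append("single country: factor predictors non-estimable")
        result.converged = False
    return result
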