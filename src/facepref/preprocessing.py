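"""Participant exclusions, winsorisation, standardisation and effect coding.

The exclusion rules mirror the study's sample construction: predominantly
homosexual raters (Kinsey 4-6) and raters identifying as neither male nor
female are removed, then countries that retain fewer than 10 raters are
dropped entirely.  Rules are applied in that order and each participant is
counted against the first rule that removes them, so the report's counts
reconcile exactly with the input size.

Continuous covariates are winsorised at +/- k standard deviations (single
pass, bounds from the raw values) and z-scored at the appropriate unit of
analysis: participant-level covariates over participants, country-level
factors over countries.  Two-level categorical predictors are effect coded
(-1/+1) so coefficients read as deviations from the grand mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "ExclusionReport",
    "apply_exclusions",
    "winsorise",
    "Winsorizer",
    "Standardizer",
    "standardise",
    "effect_code",
    "EFFECT_CODES",
]

MIN_COUNTRY_SIZE = 10

#: documented level orders for effect coding
EFFECT_CODES = {
    "sex": {"female": -1.0, "male": 1.0},
    "level": {"low": -1.0, "high": 1.0},
    "chosen_level": {"low": -1.0, "medium": 0.0, "high": 1.0},
}


@dataclass
class ExclusionReport:
    """Bookkeeping of the exclusion cascade; counts reconcile exactly."""

    n_input: int
    n_removed_kinsey: int
    n_removed_sex_other: int
    n_removed_small_country: int
    n_retained: int
    retained_country_list: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        total = (
            self.n_removed_kinsey
            + self.n_removed_sex_other
            + self.n_removed_small_country
            + self.n_retained
        )
        if total != self.n_input:
            raise ValueError(
                f"exclusion counts do not reconcile: {total} != n_input {self.n_input}"
            )

    def to_dict(self) -> dict:
        return asdict(self)


def apply_exclusions(
    participants: pd.DataFrame, min_country_size: int = MIN_COUNTRY_SIZE
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the sample-construction rules, in order.

    1. Remove raters with Kinsey score in {4, 5, 6} (predominantly
       homosexual); missing Kinsey scores are retained.
    2. Remove raters whose sex is neither female nor male.
    3. Remove every rater from countries with fewer than ``min_country_size``
       raters remaining after steps 1-2.

    Returns the retained table and an :class:`ExclusionReport`.  Idempotent:
    re-running on the output removes nobody.
    """
    if len(participants) == 0:
        raise ValueError("cannot apply exclusions to an empty participant table")
    n_input = len(participants)

    kinsey = pd.to_numeric(participants["kinsey"], errors="coerce")
    kinsey_mask = kinsey.isin([4, 5, 6])
    step1 = participants.loc[~kinsey_mask]

    sex_mask = ~step1["sex"].isin(["female", "male"])
    step2 = step1.loc[~sex_mask]

    sizes = step2["country_id"].value_counts()
    keep_countries = sizes.index[sizes >= min_country_size]
    retained = step2[step2["country_id"].isin(keep_countries)]

    report = ExclusionReport(
        n_input=n_input,
        n_removed_kinsey=int(kinsey_mask.sum()),
        n_removed_sex_other=int(sex_mask.sum()),
        n_removed_small_country=len(step2) - len(retained),
        n_retained=len(retained),
        retained_country_list=sorted(keep_countries.tolist()),
    )
    return retained.reset_index(drop=True), report


def winsorise(values, k: float = 3.0):
    """Clip values beyond ``mean +/- k * SD`` to that bound (single pass).

    Mean and sample SD (n-1 denominator) are computed once on the raw
    non-missing input; values exactly at a bound are untouched and missing
    values pass through.  A zero-variance vector is returned unchanged.
    """
    arr = np.asarray(values, dtype=float)
    finite = arr[~np.isnan(arr)]
    if finite.size < 2:
        raise ValueError("winsorise needs at least 2 non-missing values")
    mean = finite.mean()
    sd = finite.std(ddof=1)
    if sd == 0:
        out = arr
    else:
        lo, hi = mean - k * sd, mean + k * sd
        out = np.clip(arr, lo, hi)
        out[np.isnan(arr)] = np.nan
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out


class Winsorizer(BaseEstimator, TransformerMixin):
    """Column-wise +/- k SD winsorising transformer.

    Bounds are learned on ``fit`` (mean and sample SD per column of the raw
    data) and applied on ``transform``, so the same clipping can be reused on
    new data.  Zero-variance columns pass through unchanged.

    Attributes
    ----------
    lower_, upper_ : ndarray of shape (n_features,)
        Clipping bounds per column (NaN for zero-variance columns).
    """

    def __init__(self, k: float = 3.0):
        self.k = k

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if np.sum(~np.isnan(X), axis=0).min() < 2:
            raise ValueError("each column needs at least 2 non-missing values")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(X, axis=0)
            sd = np.nanstd(X, axis=0, ddof=1)
        self.mean_ = mean
        self.sd_ = sd
        self.lower_ = np.where(sd > 0, mean - self.k * sd, np.nan)
        self.upper_ = np.where(sd > 0, mean + self.k * sd, np.nan)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        arr = np.asarray(X, dtype=float)
        squeeze = arr.ndim == 1
        if squeeze:
            arr = arr[:, None]
        out = arr.copy()
        for j in range(arr.shape[1]):
            if np.isnan(self.lower_[j]):
                continue
            col = arr[:, j]
            clipped = np.clip(col, self.lower_[j], self.upper_[j])
            clipped[np.isnan(col)] = np.nan
            out[:, j] = clipped
        return out[:, 0] if squeeze else out


class Standardizer(BaseEstimator, TransformerMixin):
    """Column-wise z-scoring transformer (sample-SD convention).

    Means and SDs are learned on ``fit`` and reused on ``transform``, so
    held-out data is expressed on the training scale.  Zero-variance columns
    transform to zeros.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            self.mean_ = np.nanmean(X, axis=0)
            self.sd_ = np.nanstd(X, axis=0, ddof=1)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        arr = np.asarray(X, dtype=float)
        squeeze = arr.ndim == 1
        if squeeze:
            arr = arr[:, None]
        sd = np.where(self.sd_ > 0, self.sd_, 1.0)
        out = (arr - self.mean_) / sd
        out[:, ~(self.sd_ > 0)] = 0.0
        return out[:, 0] if squeeze else out


def standardise(values, by=None):
    """Z-score with sample SD, optionally at a coarser unit of analysis.

    Parameters
    ----------
    values
        Vector to standardise (array or Series); missing values pass through.
    by
        Optional vector of unit labels of the same length (e.g. country of
        each row).  When given, the mean and SD are computed over the
        *unit-level* values — one value per unique unit — so a covariate
        constant within countries is standardised across countries no matter
        how many rows each country contributes.

    A zero-variance input yields an all-zero output with a warning.
    """
    ser = pd.Series(np.asarray(values, dtype=float))
    if by is not None:
        units = pd.DataFrame({"by": np.asarray(by), "v": ser.to_numpy()})
        unit_vals = units.groupby("by")["v"].first()
        mean, sd = unit_vals.mean(), unit_vals.std(ddof=1)
    else:
        mean, sd = ser.mean(), ser.std(ddof=1)
    if not sd > 0:
        warnings.warn("zero variance in standardise; returning zeros", stacklevel=2)
        out = ser * 0.0
    else:
        out = (ser - mean) / sd
    arr = out.to_numpy()
    if isinstance(values, pd.Series):
        return pd.Series(arr, index=values.index, name=values.name)
    return arr


def effect_code(values, variable: str | None = None, codes: dict | None = None,
                strict: bool = True):
    """Numerically code a categorical predictor with the declared conventions.

    Two-level factors map to -1/+1 (``female=-1, male=+1``; ``low=-1,
    high=+1``); the three-level chosen level maps to (-1, 0, +1).  Unknown
    categories raise when ``strict`` (default) and map to NaN otherwise —
    the non-strict form feeds model designs, where categories outside the
    coding (e.g. sex "other") are removed listwise.  Pass ``codes`` to
    override, or ``variable`` to select one of the documented conventions
    by name.
    """
    if codes is None:
        if variable is None:
            raise ValueError("provide either `variable` or an explicit `codes` mapping")
        try:
            codes = EFFECT_CODES[variable]
        except KeyError:
            raise ValueError(
                f"no documented coding for {variable!r}; known: {sorted(EFFECT_CODES)}"
            ) from None
    ser = pd.Series(values)
    unknown = set(ser.dropna().unique()) - set(codes)
    if unknown and strict:
        raise ValueError(f"categories {sorted(unknown)} not in coding {codes}")
    out = ser.map(codes).astype(float)
    if isinstance(values, pd.Series):
        out.index = values.index
        return out
    return out.to_numpy()
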