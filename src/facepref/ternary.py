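"""Centroid-distance statistic and randomisation test for 3AFC compositions.

A three-alternative forced-choice (3AFC) cell is a composition of counts
``(n_low, n_medium, n_high)``: how many raters picked the low-, medium- and
high-fertility-cue prototype as the most attractive (or most feminine) face.
Under the null hypothesis of random choice every rater picks uniformly, so the
expected proportions sit at the centroid (1/3, 1/3, 1/3) of the ternary
simplex.  The test statistic is the Euclidean distance of the observed
proportion point from that centroid in the unit-edge equilateral-triangle
embedding; its null distribution is obtained by Monte Carlo simulation of
uniform multinomial samples of the same size.

Three routes to a p-value are provided:

``mc_randomisation_test``
    the Monte Carlo test used for reported results;
``exact_multinomial_p``
    full enumeration of the multinomial(n; 1/3,1/3,1/3) distribution, an
    exact oracle feasible for n up to a few hundred;
``chi_square_p``
    the large-n closed form: the centroid distance is a monotone function of
    the equal-expectation chi-square statistic with 2 df, whose survival
    function is exp(-X^2/2).

All exceedance comparisons use the integer statistic ``T = sum((3 c_i - n)^2)``,
which is strictly monotone in the centroid distance; this keeps ties exact
(no floating-point equality tests on simulated magnitudes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "TernaryComposition",
    "MCTestResult",
    "tally_choices",
    "centroid_vector",
    "mc_randomisation_test",
    "exact_multinomial_p",
    "chi_square_p",
    "TernaryRandomisationTest",
]

# vertices of the unit-edge equilateral triangle; centroid = mean of vertices
_V_LOW = np.array([0.0, 0.0])
_V_MED = np.array([1.0, 0.0])
_V_HIGH = np.array([0.5, np.sqrt(3.0) / 2.0])
_CENTROID = (_V_LOW + _V_MED + _V_HIGH) / 3.0

_EXACT_N_MAX = 200


@dataclass(frozen=True)
class TernaryComposition:
    """Counts of low/medium/high choices for one judgement x cue-set cell."""

    n_low: int
    n_medium: int
    n_high: int

    def __post_init__(self) -> None:
        counts = (self.n_low, self.n_medium, self.n_high)
        if any(int(c) != c or c < 0 for c in counts):
            raise ValueError(f"counts must be nonnegative integers, got {counts}")
        if self.n < 1:
            raise ValueError("composition must contain at least one choice")

    @property
    def n(self) -> int:
        return self.n_low + self.n_medium + self.n_high

    @property
    def counts(self) -> np.ndarray:
        return np.array([self.n_low, self.n_medium, self.n_high], dtype=np.int64)

    @property
    def proportions(self) -> np.ndarray:
        return self.counts / self.n

    def __iter__(self):
        return iter((self.n_low, self.n_medium, self.n_high))


@dataclass(frozen=True)
class MCTestResult:
    """Result of a centroid-distance randomisation test."""

    observed_magnitude: float
    p_value: float
    n_sim: int
    seed: int | None
    tie_rule: str
    n: int
    exceedances: int = 0
    method: str = "mc"
    p_value_smoothed: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


def _as_composition(composition) -> TernaryComposition:
    if isinstance(composition, TernaryComposition):
        return composition
    return TernaryComposition(*(int(c) for c in composition))


def _check_tie_rule(tie_rule: str) -> str:
    if tie_rule not in ("geq", "gt"):
        raise ValueError(f"tie_rule must be 'geq' or 'gt', got {tie_rule!r}")
    return tie_rule


def _int_statistic(counts: np.ndarray, n: int) -> np.ndarray:
    """Integer statistic T = sum((3 c_i - n)^2), monotone in centroid distance."""
    dev = 3 * counts.astype(np.int64) - n
    return np.sum(dev * dev, axis=-1)


def _magnitude_from_T(T, n: int):
    """Centroid distance in the unit-edge triangle: sqrt(T) / (3 n sqrt(2))."""
    return np.sqrt(T) / (3.0 * n * np.sqrt(2.0))


def tally_choices(choices: pd.DataFrame, judgement: str, cue_set: str) -> TernaryComposition:
    """Tally chosen levels for one judgement x cue-set cell of a choices table.

    Parameters
    ----------
    choices
        Long-format table with columns ``participant_id``, ``judgement``,
        ``cue_set``, ``chosen_level``.
    judgement, cue_set
        Cell selector, e.g. ``("attractiveness", "textbook")``.

    Raises
    ------
    ValueError
        If no records match, or a participant has more than one record in
        the cell (each rater chooses exactly once per task).
    """
    sub = choices[(choices["judgement"] == judgement) & (choices["cue_set"] == cue_set)]
    if len(sub) == 0:
        raise ValueError(f"no choice records for judgement={judgement!r}, cue_set={cue_set!r}")
    if sub["participant_id"].duplicated().any():
        dup = sub.loc[sub["participant_id"].duplicated(), "participant_id"].iloc[0]
        raise ValueError(
            f"duplicate choice for participant {dup!r} in judgement={judgement!r}, "
            f"cue_set={cue_set!r}: one record per participant x judgement x cue_set"
        )
    counts = sub["chosen_level"].value_counts()
    return TernaryComposition(
        int(counts.get("low", 0)), int(counts.get("medium", 0)), int(counts.get("high", 0))
    )


def centroid_vector(composition) -> tuple[float, np.ndarray]:
    """Centroid-distance magnitude and 2-D coordinates of a composition.

    The proportions are embedded in the plane via the unit-edge equilateral
    triangle with vertices low=(0,0), medium=(1,0), high=(1/2, sqrt(3)/2);
    the returned magnitude is the Euclidean distance of the embedded point
    from the centroid (1/2, sqrt(3)/6) and equals
    ``(1/sqrt(2)) * sqrt(sum_i (p_i - 1/3)^2)``.
    """
    comp = _as_composition(composition)
    p = comp.proportions
    point = p[0] * _V_LOW + p[1] * _V_MED + p[2] * _V_HIGH
    magnitude = float(np.linalg.norm(point - _CENTROID))
    return magnitude, point


def mc_randomisation_test(
    composition,
    n_sim: int = 10_000,
    seed: int | np.random.Generator | None = None,
    tie_rule: str = "geq",
) -> MCTestResult:
    """Monte Carlo centroid randomisation test for non-random 3AFC choice.

    Simulates ``n_sim`` samples of ``n`` raters each choosing one of the three
    faces uniformly at random (one multinomial(n; 1/3,1/3,1/3) draw per
    sample), computes each sample's centroid distance, and reports the
    proportion of simulated samples whose distance exceeds the observed one.
    A large observed distance — few exceedances — is evidence of non-random
    choice in either direction.

    Parameters
    ----------
    composition
        ``TernaryComposition`` or a (low, medium, high) count triple.
    n_sim
        Number of simulated samples.
    seed
        Seed or ``numpy.random.Generator`` for the simulation.
    tie_rule
        ``"geq"`` counts simulated distances >= observed (conservative
        default: p never understated); ``"gt"`` counts strict exceedances.

    Returns
    -------
    MCTestResult
        With ``p_value = exceedances / n_sim`` and the add-one smoothed
        variant ``(exceedances + 1) / (n_sim + 1)`` alongside.
    """
    comp = _as_composition(composition)
    _check_tie_rule(tie_rule)
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    rng = np.random.default_rng(seed)
    n = comp.n
    obs_T = int(_int_statistic(comp.counts, n))
    sims = rng.multinomial(n, [1 / 3, 1 / 3, 1 / 3], size=n_sim)
    sim_T = _int_statistic(sims, n)
    exceed = int(np.sum(sim_T >= obs_T) if tie_rule == "geq" else np.sum(sim_T > obs_T))
    return MCTestResult(
        observed_magnitude=float(_magnitude_from_T(obs_T, n)),
        p_value=exceed / n_sim,
        n_sim=n_sim,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
        tie_rule=tie_rule,
        n=n,
        exceedances=exceed,
        method="mc",
        p_value_smoothed=(exceed + 1) / (n_sim + 1),
    )


def _enumerate_compositions(n: int) -> np.ndarray:
    """All (a, b, c) with a+b+c = n, as an array of shape (m, 3)."""
    a = np.repeat(np.arange(n + 1), np.arange(n + 1, 0, -1))
    b = np.concatenate([np.arange(n - i + 1) for i in range(n + 1)])
    c = n - a - b
    return np.stack([a, b, c], axis=1)


def exact_multinomial_p(composition, tie_rule: str = "geq") -> float:
    """Exact null p-value by enumeration of multinomial(n; 1/3,1/3,1/3).

    Sums the multinomial probability of every outcome whose centroid distance
    exceeds (``tie_rule="gt"``) or equals-or-exceeds (``"geq"``) the observed
    distance.  Enumeration is over the O(n^2) compositions of n, feasible for
    n <= 200; beyond that use :func:`mc_randomisation_test`.
    """
    comp = _as_composition(composition)
    _check_tie_rule(tie_rule)
    n = comp.n
    if n > _EXACT_N_MAX:
        raise ValueError(
            f"exact enumeration supports n <= {_EXACT_N_MAX} (got n={n}); "
            "use mc_randomisation_test for larger samples"
        )
    outcomes = _enumerate_compositions(n)
    T = _int_statistic(outcomes, n)
    obs_T = int(_int_statistic(comp.counts, n))
    mask = T >= obs_T if tie_rule == "geq" else T > obs_T
    if not mask.any():
        return 0.0
    pmf = stats.multinomial(n, [1 / 3, 1 / 3, 1 / 3]).pmf(outcomes[mask])
    return float(np.sum(pmf))


def chi_square_p(composition) -> float:
    """Closed-form large-n p-value via the equal-expectation chi-square.

    The centroid distance is monotone in X^2 = sum_i (O_i - n/3)^2 / (n/3),
    which is asymptotically chi-square with 2 df under the uniform null, so
    p = P(X^2_2 >= x) = exp(-x/2).
    """
    comp = _as_composition(composition)
    n = comp.n
    x2 = float(_int_statistic(comp.counts, n)) / (3.0 * n)
    return float(stats.chi2.sf(x2, df=2))


class TernaryRandomisationTest(BaseEstimator):
    """Centroid-distance test for a 3AFC composition, estimator-style.

    Parameters
    ----------
    n_sim : int, default 10000
        Monte Carlo sample count (``method="mc"``).
    seed : int or None
        RNG seed for the Monte Carlo route.
    tie_rule : {"geq", "gt"}, default "geq"
        Whether simulated/enumerated distances equal to the observed one
        count as exceedances.
    method : {"mc", "exact", "chisq"}, default "mc"
        Monte Carlo simulation, exact multinomial enumeration (n <= 200),
        or the 2-df chi-square closed form.

    Attributes
    ----------
    magnitude_ : float
        Observed centroid distance in the unit-edge triangle embedding.
    coordinates_ : ndarray of shape (2,)
        Embedded (x, y) point of the observed proportions.
    p_value_ : float
    result_ : MCTestResult
    """

    def __init__(
        self,
        n_sim: int = 10_000,
        seed: int | None = None,
        tie_rule: str = "geq",
        method: str = "mc",
    ):
        self.n_sim = n_sim
        self.seed = seed
        self.tie_rule = tie_rule
        self.method = method

    def fit(self, composition, y=None):
        comp = _as_composition(composition)
        _check_tie_rule(self.tie_rule)
        if self.method == "mc":
            res = mc_randomisation_test(comp, self.n_sim, self.seed, self.tie_rule)
        elif self.method == "exact":
            p = exact_multinomial_p(comp, self.tie_rule)
            res = MCTestResult(
                observed_magnitude=centroid_vector(comp)[0],
                p_value=p,
                n_sim=0,
                seed=None,
                tie_rule=self.tie_rule,
                n=comp.n,
                method="exact",
            )
        elif self.method == "chisq":
            res = MCTestResult(
                observed_magnitude=centroid_vector(comp)[0],
                p_value=chi_square_p(comp),
                n_sim=0,
                seed=None,
                tie_rule="geq",
                n=comp.n,
                method="chisq",
            )
        else:
            raise ValueError(f"method must be 'mc', 'exact' or 'chisq', got {self.method!r}")
        self.magnitude_, self.coordinates_ = centroid_vector(comp)
        self.p_value_ = res.p_value
        self.result_ = res
        self.composition_ = comp
        return self
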