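"""Two-sample test statistics t(y, z) for use inside the permutation engine.

Every statistic is a pure function of an outcome vector ``y`` (NaN = missing,
excluded available-case) and a boolean assignment mask ``z`` (True = treated).
A statistic carries its own orientation — whether smaller or larger values
favor treatment — so callers never juggle signs when an adaptation rule swaps
statistics mid-analysis.

Statistics that are monotone increasing functions of ``sum over treated
subjects of a fixed weight vector w(y)`` additionally expose those weights;
the engine exploits this to compute exact null distributions by subset-sum
convolution and to vectorize Monte-Carlo sampling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.stats import rankdata

#: Smaller statistic values are evidence in favor of treatment.
SMALLER = "smaller"
#: Larger statistic values are evidence in favor of treatment.
LARGER = "larger"


class EvaluationError(ValueError):
    """An arm has no non-missing values, so the statistic is undefined."""


class DegenerateStatistic(Exception):
    """The data admit no informative statistic value (e.g. all paired
    differences are zero).  Distinct from an evaluation error: the engine
    converts it into p = 1 with a warning flag."""


def _split(y: np.ndarray, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=bool)
    ok = ~np.isnan(y)
    y_t, y_c = y[ok & z], y[ok & ~z]
    if y_t.size == 0 or y_c.size == 0:
        raise EvaluationError("an arm has zero non-missing values")
    return y_t, y_c


def available_counts(y: np.ndarray, z: np.ndarray) -> tuple[int, int]:
    """Non-missing sample sizes (treated, control) after available-case
    exclusion; surfaced so callers can report how many subjects were used."""
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=bool)
    ok = ~np.isnan(y)
    return int((ok & z).sum()), int((ok & ~z).sum())


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


def diff_means(y: np.ndarray, z: np.ndarray) -> float:
    """mean(treated) − mean(control), missing values excluded pairwise."""
    y_t, y_c = _split(y, z)
    return float(y_t.mean() - y_c.mean())


def diff_props(y: np.ndarray, z: np.ndarray) -> float:
    """Event-rate difference treated − control for a {0,1} outcome."""
    y_arr = np.asarray(y, dtype=float)
    ok = ~np.isnan(y_arr)
    if not np.isin(y_arr[ok], (0.0, 1.0)).all():
        raise EvaluationError("diff_props requires a binary outcome")
    return diff_means(y, z)


def wilcoxon_rank_sum(y: np.ndarray, z: np.ndarray) -> float:
    """Sum of mid-ranks of the treated arm among all non-missing values."""
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=bool)
    ok = ~np.isnan(y)
    if not (ok & z).any() or not (ok & ~z).any():
        raise EvaluationError("an arm has zero non-missing values")
    ranks = rankdata(y[ok])  # mid-ranks for ties
    return float(ranks[z[ok]].sum())


def signed_rank_paired(d: np.ndarray) -> float:
    """Wilcoxon signed-rank statistic for paired (crossover) differences.

    Exact zero differences are excluded before ranking |d|; if every
    difference is zero the data carry no paired information and a
    `DegenerateStatistic` is raised — a signal, not an error, since such a
    trial has essentially answered its own question.
    """
    d = np.asarray(d, dtype=float)
    d = d[~np.isnan(d)]
    d = d[d != 0.0]
    if d.size == 0:
        raise DegenerateStatistic("all paired differences are zero")
    ranks = rankdata(np.abs(d))
    return float(ranks[d > 0].sum())


# ---------------------------------------------------------------------------
# Statistic objects and registry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TestStatistic:
    """A named two-sample statistic with a declared orientation.

    ``weights``, when present, maps ``y`` to a vector ``w`` such that
    ``t(y, z)`` is a strictly increasing function of ``sum(w[z])`` for every
    assignment with the same arm counts; it must only be used on complete
    (no-missing) data.
    """

    name: str
    direction: str  # SMALLER or LARGER favors treatment
    evaluate: Callable[[np.ndarray, np.ndarray], float]
    weights: Optional[Callable[[np.ndarray], np.ndarray]] = None

    def __post_init__(self):
        if self.direction not in (SMALLER, LARGER):
            raise ValueError(f"direction must be {SMALLER!r} or {LARGER!r}")


def _identity_weights(y: np.ndarray) -> np.ndarray:
    return np.asarray(y, dtype=float)


def _rank_weights(y: np.ndarray) -> np.ndarray:
    return rankdata(np.asarray(y, dtype=float))


def _abs_diff_means(y: np.ndarray, z: np.ndarray) -> float:
    return abs(diff_means(y, z))


_REGISTRY: dict[str, dict] = {
    "diff_means": dict(evaluate=diff_means, weights=_identity_weights),
    "diff_props": dict(evaluate=diff_props, weights=_identity_weights),
    "wilcoxon": dict(evaluate=wilcoxon_rank_sum, weights=_rank_weights),
    "signed_rank": dict(evaluate=lambda y, z: signed_rank_paired(y), weights=None),
    # two-sided variant: direction-free magnitude, always LARGER-is-extreme
    "abs_diff_means": dict(evaluate=_abs_diff_means, weights=None),
}


def get_statistic(name: str, direction: str = SMALLER) -> TestStatistic:
    """Look up a statistic by its config name.

    Names: ``diff_means``, ``diff_props``, ``wilcoxon``, ``signed_rank``,
    ``abs_diff_means`` (two-sided magnitude; its direction is forced to
    LARGER because bigger magnitudes are always the extreme ones).
    """
    try:
        entry = _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown statistic {name!r}; choose from {sorted(_REGISTRY)}"
        ) from None
    if name == "abs_diff_means":
        direction = LARGER
    return TestStatistic(name=name, direction=direction, **entry)


def statistic_names() -> tuple[str, ...]:
    return tuple(sorted(_REGISTRY))
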