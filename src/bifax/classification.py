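"""True scores, grade classification, and classification accuracy.

A *true score* is the model-expected observed score at a given ability:
the expected number correct on the MC section, the expected summed category
score on the CR section, and their weighted composite

    tau = w_mc * tau_MC + w_cr * tau_CR,

with default weights (1.125, 2.75) — the operational composite weights of a
large mixed-format examination program.  Simulees are then classified into
five ordered grade categories (I..V) by empirical quantiles of each score
vector, and the accuracy of an estimated score vector is the percentage of
simulees whose category matches the category implied by the truth vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .irt_models import (
    cr_probs_bifactor,
    cr_probs_unidim,
    mc_probs_bifactor,
    mc_probs_unidim,
    ThetaTriple,
)

__all__ = [
    "DEFAULT_WEIGHTS",
    "TrueScoreSet",
    "ClassificationSpec",
    "AccuracyResult",
    "true_scores",
    "true_score_components",
    "classify",
    "category_counts",
    "cross_accuracy",
    "improvement",
]

#: Composite weights (w_mc, w_cr) applied to the MC and CR true scores.
DEFAULT_WEIGHTS = (1.125, 2.75)


@dataclass(frozen=True)
class TrueScoreSet:
    """Expected MC, CR and composite scores at one ability point."""

    tau_mc: float
    tau_cr: float
    tau: float


@dataclass(frozen=True)
class ClassificationSpec:
    """Fractions of simulees assigned to grade categories I..V (low to high)."""

    proportions: tuple[float, ...] = (0.216, 0.258, 0.228, 0.188, 0.11)

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if p.ndim != 1 or len(p) < 2:
            raise ValueError("need at least two category proportions")
        if np.any(p <= 0):
            raise ValueError(f"all proportions must be positive, got {self.proportions}")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError(f"proportions must sum to 1, got sum {p.sum()!r}")

    @property
    def n_categories(self) -> int:
        return len(self.proportions)


@dataclass(frozen=True)
class AccuracyResult:
    """Classification accuracy of both scoring approaches on one replication."""

    accuracy_bifactor: float  # percent
    accuracy_unidim: float  # percent
    improvement: float  # percentage points, bifactor - unidim
    table_bifactor: np.ndarray  # 5x5 counts, rows = truth, cols = estimate
    table_unidim: np.ndarray
    seed: int | None = None
    replication: int | None = None

    def __post_init__(self) -> None:
        for acc in (self.accuracy_bifactor, self.accuracy_unidim):
            if not (0.0 <= acc <= 100.0):
                raise ValueError(f"accuracy must lie in [0, 100], got {acc}")


def _split_theta(theta):
    if isinstance(theta, ThetaTriple):
        return theta.as_array()[None, :], True
    arr = np.asarray(theta, dtype=float)
    if arr.ndim == 0:
        return arr.reshape(1), True
    return arr, False


def true_score_components(theta, items, weights=DEFAULT_WEIGHTS):
    """Vectorised (tau_mc, tau_cr, tau) for abilities ``theta``.

    ``items`` is any object with ``mc_items`` and ``cr_items`` attributes —
    a bi-factor :class:`~bifax.synthetic_data.ItemPool` with (n, 3) abilities
    or a unidimensional item set with (n,) abilities.
    """
    weights = tuple(float(w) for w in weights)
    if len(weights) != 2:
        raise ValueError(f"weights must be (w_mc, w_cr), got {weights}")
    theta, scalar = _split_theta(theta)
    bifactor = theta.ndim == 2
    if bifactor:
        p_mc = mc_probs_bifactor(items.mc_items, theta)
        p_cr = cr_probs_bifactor(items.cr_items, theta)
    else:
        p_mc = mc_probs_unidim(items.mc_items, theta)
        p_cr = cr_probs_unidim(items.cr_items, theta)
    tau_mc = p_mc.sum(axis=1)
    cats = np.arange(p_cr.shape[-1], dtype=float)
    tau_cr = (p_cr * cats).sum(axis=(1, 2))
    tau = weights[0] * tau_mc + weights[1] * tau_cr
    if scalar:
        return float(tau_mc[0]), float(tau_cr[0]), float(tau[0])
    return tau_mc, tau_cr, tau


def true_scores(theta, items, weights=DEFAULT_WEIGHTS) -> TrueScoreSet:
    """True-score set at a single ability point (ThetaTriple or scalar)."""
    tau_mc, tau_cr, tau = true_score_components(theta, items, weights)
    if isinstance(tau_mc, np.ndarray):
        raise ValueError("true_scores takes one ability point; use "
                         "true_score_components for batches")
    return TrueScoreSet(tau_mc=tau_mc, tau_cr=tau_cr, tau=tau)


def category_counts(n: int, spec: ClassificationSpec) -> np.ndarray:
    """Category sizes by largest-remainder rounding of n * proportions.

    Ties in the remainders are broken toward the lower category, so the
    result is fully deterministic.
    """
    if n < spec.n_categories:
        raise ValueError(f"need at least {spec.n_categories} scores, got {n}")
    quota = n * np.asarray(spec.proportions, dtype=float)
    counts = np.floor(quota).astype(int)
    short = n - counts.sum()
    remainders = quota - np.floor(quota)
    # stable sort descending on remainder; ties resolved by category index
    order = np.argsort(-remainders, kind="stable")
    counts[order[:short]] += 1
    return counts


def classify(scores, spec: ClassificationSpec | None = None) -> np.ndarray:
    """Rank-based grade assignment: lowest scores -> category 1 (I), ...,
    highest ``spec.proportions[-1]`` fraction -> category 5 (V).

    Returns integer labels 1..K.  Ties are broken by stable person order.
    """
    spec = spec or ClassificationSpec()
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 1:
        raise ValueError("scores must be a 1-D vector")
    if np.any(~np.isfinite(scores)):
        raise ValueError("scores contain NaN or infinite values")
    counts = category_counts(len(scores), spec)
    order = np.argsort(scores, kind="stable")
    labels = np.empty(len(scores), dtype=int)
    labels[order] = np.repeat(np.arange(1, spec.n_categories + 1), counts)
    return labels


def cross_accuracy(true_cats, est_cats) -> tuple[float, np.ndarray]:
    """Percent agreement and the K x K cross-classification table.

    Table cell (r, c) counts simulees with truth category r+1 and estimated
    category c+1.
    """
    true_cats = np.asarray(true_cats, dtype=int)
    est_cats = np.asarray(est_cats, dtype=int)
    if true_cats.shape != est_cats.shape or true_cats.ndim != 1:
        raise ValueError("category vectors must be 1-D and of equal length")
    k = int(max(true_cats.max(), est_cats.max()))
    table = np.zeros((k, k), dtype=int)
    np.add.at(table, (true_cats - 1, est_cats - 1), 1)
    accuracy = 100.0 * np.trace(table) / len(true_cats)
    return accuracy, table


def improvement(result: AccuracyResult | tuple[float, float]) -> float:
    """Accuracy gain of bi-factor over unidimensional scoring, in points."""
    if isinstance(result, AccuracyResult):
        return result.accuracy_bifactor - result.accuracy_unidim
    acc_bi, acc_uni = result
    return acc_bi - acc_uni
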