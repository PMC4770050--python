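"""Synthetic mixed-format test data with a controllable degree of
multidimensionality.

This module plays the role of the (proprietary) operational data: it draws
orthogonal standard-normal abilities, builds bi-factor item pools whose
model-implied *disattenuated correlation* between the MC and CR true scores
hits a requested target, simulates complete response matrices, collapses CR
score categories, and computes the classical disattenuation index from
observed responses.

The disattenuated correlation — the observed MC/CR subscore correlation
divided by the square root of the product of the subscore reliabilities —
is the index of dimensionality used throughout: 1.0 means the two formats
measure the same trait; operational mixed-format forms span roughly
0.77-0.96.  The generator reaches a target by scaling all format-specific
loadings by a common factor lambda, found by bisection on the implied
true-score correlation (lambda = 0 recovers an exactly unidimensional pool).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classification import true_score_components
from .irt_models import (
    BifactorCRItem,
    BifactorMCItem,
    UnidimCRItem,
    UnidimMCItem,
    cr_probs_bifactor,
    cr_probs_unidim,
    mc_probs_bifactor,
    mc_probs_unidim,
)

__all__ = [
    "ItemPool",
    "UnidimItemSet",
    "GeneratorConfig",
    "ResponseMatrix",
    "sample_thetas",
    "generate_item_pool",
    "implied_disattenuated_correlation",
    "simulate_responses",
    "recode_categories",
    "observed_disattenuated_correlation",
    "cronbach_alpha",
    "write_response_csv",
    "read_response_csv",
]


@dataclass(frozen=True)
class ItemPool:
    """A bi-factor item pool: MC block plus CR block."""

    mc_items: tuple[BifactorMCItem, ...]
    cr_items: tuple[BifactorCRItem, ...]
    n_categories: int = 5

    def __post_init__(self) -> None:
        object.__setattr__(self, "mc_items", tuple(self.mc_items))
        object.__setattr__(self, "cr_items", tuple(self.cr_items))
        if len(self.mc_items) < 1 or len(self.cr_items) < 1:
            raise ValueError("pool needs at least one MC and one CR item")
        for it in self.cr_items:
            if it.n_categories != self.n_categories:
                raise ValueError(
                    f"CR item has {it.n_categories} categories, pool declares "
                    f"{self.n_categories}"
                )

    @property
    def n_mc(self) -> int:
        return len(self.mc_items)

    @property
    def n_cr(self) -> int:
        return len(self.cr_items)


@dataclass(frozen=True)
class UnidimItemSet:
    """A unidimensional (3PL + GRM) item set matching a pool's layout."""

    mc_items: tuple[UnidimMCItem, ...]
    cr_items: tuple[UnidimCRItem, ...]
    n_categories: int = 5

    def __post_init__(self) -> None:
        object.__setattr__(self, "mc_items", tuple(self.mc_items))
        object.__setattr__(self, "cr_items", tuple(self.cr_items))

    @property
    def n_mc(self) -> int:
        return len(self.mc_items)

    @property
    def n_cr(self) -> int:
        return len(self.cr_items)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition settings for one synthetic test form.

    Defaults mirror the mixed-format design studied throughout: 55 MC items,
    3 CR items with C = 5 ordered categories.  ``target_rho`` is the desired
    model-implied disattenuated MC-CR correlation.  Base item-parameter
    ranges (typical of operational MC/CR calibrations) are configurable.
    """

    target_rho: float
    n_mc: int = 55
    n_cr: int = 3
    n_categories: int = 5
    n_persons: int = 10_000
    seed: int = 0
    a_g_range: tuple[float, float] = (0.8, 2.0)
    a_spec_range: tuple[float, float] = (0.8, 2.0)
    d_mc_loc: float = 0.0
    d_mc_scale: float = 1.0
    d_cr_loc: float = -1.25
    d_cr_scale: float = 0.6
    g_range: tuple[float, float] = (0.05, 0.35)
    offset_gap_range: tuple[float, float] = (0.6, 1.05)

    def __post_init__(self) -> None:
        if not (0.0 < self.target_rho <= 1.0):
            raise ValueError(f"target_rho must lie in (0, 1], got {self.target_rho}")
        for name in ("n_mc", "n_cr", "n_persons"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_categories < 2:
            raise ValueError("n_categories must be at least 2")


@dataclass
class ResponseMatrix:
    """Complete persons x items score matrix with per-item format labels."""

    values: np.ndarray
    format_labels: np.ndarray
    n_categories: int = 5
    item_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.issubdtype(self.values.dtype, np.integer):
            if np.any(self.values != np.round(self.values)):
                raise ValueError("responses must be integers")
            self.values = self.values.astype(int)
        if self.values.ndim != 2:
            raise ValueError("values must be persons x items")
        self.format_labels = np.asarray(self.format_labels)
        if len(self.format_labels) != self.values.shape[1]:
            raise ValueError("one format label per item is required")
        bad = set(self.format_labels) - {"MC", "CR"}
        if bad:
            raise ValueError(f"unknown format labels {bad}")
        mc = self.values[:, self.format_labels == "MC"]
        cr = self.values[:, self.format_labels == "CR"]
        if mc.size and (mc.min() < 0 or mc.max() > 1):
            raise ValueError("MC responses must lie in {0, 1}")
        if cr.size and (cr.min() < 0 or cr.max() > self.n_categories - 1):
            raise ValueError(f"CR responses must lie in 0..{self.n_categories - 1}")
        if self.item_ids is None:
            n_mc = n_cr = 0
            ids = []
            for lab in self.format_labels:
                if lab == "MC":
                    n_mc += 1
                    ids.append(f"MC{n_mc:03d}")
                else:
                    n_cr += 1
                    ids.append(f"CR{n_cr:03d}")
            self.item_ids = tuple(ids)
        else:
            self.item_ids = tuple(self.item_ids)
            if len(self.item_ids) != self.values.shape[1]:
                raise ValueError("one item_id per item is required")

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    @property
    def mc_values(self) -> np.ndarray:
        return self.values[:, self.format_labels == "MC"]

    @property
    def cr_values(self) -> np.ndarray:
        return self.values[:, self.format_labels == "CR"]


# ---------------------------------------------------------------------------
# Abilities
# ---------------------------------------------------------------------------


def sample_thetas(n: int, seed) -> np.ndarray:
    """Draw n orthogonal ability triples (theta_g, theta_mc, theta_cr).

    Each coordinate is i.i.d. standard normal; returns an (n, 3) array.
    ``seed`` may be an int, a Generator or a SeedSequence.
    """
    if n < 1:
        raise ValueError(f"n must be positive, got {n}")
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n, 3))


# ---------------------------------------------------------------------------
# Item-pool generation
# ---------------------------------------------------------------------------


def implied_disattenuated_correlation(pool: ItemPool, n: int = 200_000,
                                      seed=0, thetas: np.ndarray | None = None) -> float:
    """Model-implied true-score correlation between the MC and CR subtests.

    Monte Carlo Pearson correlation of tau_MC(theta) and tau_CR(theta) over
    standard-normal ability triples — by construction the quantity the
    classical disattenuation formula estimates from observed scores.
    """
    if thetas is None:
        thetas = sample_thetas(n, seed)
    tau_mc, tau_cr, _ = true_score_components(thetas, pool)
    if tau_mc.std() < 1e-12 or tau_cr.std() < 1e-12:
        raise ValueError("degenerate (zero-variance) true scores")
    return float(np.corrcoef(tau_mc, tau_cr)[0, 1])


def _build_pool(base: dict, lam: float, n_categories: int) -> ItemPool:
    mc = tuple(
        BifactorMCItem(a_g=ag, a_mc=lam * am, d=d, g=g)
        for ag, am, d, g in zip(base["mc_a_g"], base["mc_a_spec"],
                                base["mc_d"], base["mc_g"])
    )
    cr = tuple(
        BifactorCRItem(a_g=ag, a_cr=lam * ac, d=d, offsets=tuple(off))
        for ag, ac, d, off in zip(base["cr_a_g"], base["cr_a_spec"],
                                  base["cr_d"], base["cr_offsets"])
    )
    return ItemPool(mc_items=mc, cr_items=cr, n_categories=n_categories)


def generate_item_pool(config: GeneratorConfig, rho_tol: float = 0.004,
                       max_iter: int = 40, n_rho: int = 80_000) -> ItemPool:
    """Draw a bi-factor pool whose implied disattenuated correlation matches
    ``config.target_rho`` within +/- 0.01.

    Base parameters are drawn once; a single non-negative scale ``lambda``
    multiplying every format-specific loading is then found by bisection on
    the implied correlation (which decreases monotonically in lambda).
    Raises ``ValueError`` with diagnostics when the target is unreachable.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 2024]))
    C = config.n_categories
    base = {
        "mc_a_g": rng.uniform(*config.a_g_range, config.n_mc),
        "mc_a_spec": rng.uniform(*config.a_spec_range, config.n_mc),
        "mc_d": rng.normal(config.d_mc_loc, config.d_mc_scale, config.n_mc),
        "mc_g": rng.uniform(*config.g_range, config.n_mc),
        "cr_a_g": rng.uniform(*config.a_g_range, config.n_cr),
        "cr_a_spec": rng.uniform(*config.a_spec_range, config.n_cr),
        "cr_d": rng.normal(config.d_cr_loc, config.d_cr_scale, config.n_cr),
        "cr_offsets": np.cumsum(
            rng.uniform(*config.offset_gap_range, (config.n_cr, C - 2)), axis=1
        ),
    }
    if config.target_rho == 1.0:
        return _build_pool(base, 0.0, C)

    # One fixed ability sample keeps rho(lambda) smooth for the bisection.
    thetas = sample_thetas(n_rho, np.random.SeedSequence([int(config.seed), 4049]))

    def rho_at(lam: float) -> float:
        return implied_disattenuated_correlation(
            _build_pool(base, lam, C), thetas=thetas
        )

    lo, hi = 0.0, 1.0
    rho_hi = rho_at(hi)
    while rho_hi > config.target_rho and hi < 8.0:
        lo, hi = hi, hi * 2.0
        rho_hi = rho_at(hi)
    if rho_hi > config.target_rho:
        raise ValueError(
            f"target_rho={config.target_rho} unreachable: implied correlation "
            f"is still {rho_hi:.4f} at specific-loading scale lambda={hi} "
            f"(base a_g range {config.a_g_range}, a_spec range {config.a_spec_range})"
        )
    lam, rho = hi, rho_hi
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        rho_mid = rho_at(mid)
        if abs(rho_mid - config.target_rho) <= rho_tol:
            lam, rho = mid, rho_mid
            break
        if rho_mid > config.target_rho:
            lo = mid
        else:
            hi = mid
        lam, rho = mid, rho_mid
    if abs(rho - config.target_rho) > 2 * rho_tol:
        raise ValueError(
            f"bisection failed to reach target_rho={config.target_rho}: "
            f"closest implied correlation {rho:.4f} at lambda={lam:.4f}"
        )
    return _build_pool(base, lam, C)


# ---------------------------------------------------------------------------
# Response simulation
# ---------------------------------------------------------------------------


def simulate_responses(items, thetas, seed) -> ResponseMatrix:
    """Simulate a complete response matrix (MC block first, then CR block).

    One uniform draw per person-item: an MC response is 1 when the model
    probability exceeds the draw; a CR response is the position of the draw
    on the cumulative category-probability vector.
    """
    thetas = np.asarray(thetas, dtype=float)
    if isinstance(items, ItemPool):
        if thetas.ndim != 2 or thetas.shape[1] != 3:
            raise ValueError("bi-factor simulation needs (n, 3) abilities")
        p_mc = mc_probs_bifactor(items.mc_items, thetas)
        p_cr = cr_probs_bifactor(items.cr_items, thetas)
    elif isinstance(items, UnidimItemSet):
        if thetas.ndim != 1:
            raise ValueError("unidimensional simulation needs (n,) abilities")
        p_mc = mc_probs_unidim(items.mc_items, thetas)
        p_cr = cr_probs_unidim(items.cr_items, thetas)
    else:
        raise TypeError(f"items must be ItemPool or UnidimItemSet, got {type(items)!r}")
    rng = np.random.default_rng(seed)
    u_mc = rng.random(p_mc.shape)
    y_mc = (p_mc > u_mc).astype(int)
    u_cr = rng.random(p_cr.shape[:2])
    cum = np.cumsum(p_cr, axis=2)
    y_cr = (u_cr[:, :, None] >= cum[:, :, :-1]).sum(axis=2)
    values = np.hstack([y_mc, y_cr])
    labels = np.array(["MC"] * p_mc.shape[1] + ["CR"] * p_cr.shape[1])
    return ResponseMatrix(values=values, format_labels=labels,
                          n_categories=items.n_categories)


# ---------------------------------------------------------------------------
# CR category recoding
# ---------------------------------------------------------------------------


def _collapse_map(counts: np.ndarray, target_c: int) -> np.ndarray:
    """Monotone surjective map from raw categories onto 0..target_c-1.

    Equal-count (quantile) collapsing on the observed marginal: a raw
    category lands in the bin containing the midpoint of its cumulative-count
    interval, with repair passes that guarantee the map is non-decreasing,
    never jumps by more than one between occupied categories, and hits every
    target bin.  Ties stay in the lower bin.
    """
    n = int(counts.sum())
    occupied = np.flatnonzero(counts)
    if len(occupied) < target_c:
        raise ValueError(
            f"only {len(occupied)} occupied raw categories for target of "
            f"{target_c}; histogram: {counts.tolist()}"
        )
    cum = np.cumsum(counts)
    mid = cum - counts / 2.0
    bins_occ = np.floor(mid[occupied] * target_c / n).astype(int)
    bins_occ = np.clip(bins_occ, 0, target_c - 1)
    bins_occ[0] = 0
    m = len(occupied)
    for j in range(1, m):  # monotone, adjacency between occupied categories
        bins_occ[j] = max(bins_occ[j - 1], min(bins_occ[j], bins_occ[j - 1] + 1))
    for j in range(m - 1, -1, -1):  # surjectivity: top bins must be reachable
        bins_occ[j] = max(bins_occ[j], target_c - (m - j))
    for j in range(1, m):
        bins_occ[j] = max(bins_occ[j], bins_occ[j - 1])
    full = np.zeros(len(counts), dtype=int)
    prev = 0
    k = 0
    for r in range(len(counts)):
        if k < m and occupied[k] == r:
            prev = bins_occ[k]
            k += 1
        full[r] = prev
    return full


def recode_categories(raw: ResponseMatrix, target_c: int) -> ResponseMatrix:
    """Collapse each CR item's raw score scale onto ``target_c`` categories.

    The map per item is surjective and non-decreasing, built by equal-count
    collapsing of the observed marginal distribution (deterministic; ties to
    the lower bin), so person ordering by CR score is preserved up to ties.
    MC columns are untouched.
    """
    if target_c < 2:
        raise ValueError("target_c must be at least 2")
    if raw.n_categories < target_c:
        raise ValueError(
            f"cannot expand {raw.n_categories} categories to {target_c}"
        )
    values = raw.values.copy()
    cr_cols = np.flatnonzero(raw.format_labels == "CR")
    for j in cr_cols:
        col = raw.values[:, j]
        counts = np.bincount(col, minlength=raw.n_categories)
        mapping = _collapse_map(counts, target_c)
        values[:, j] = mapping[col]
    return ResponseMatrix(values=values, format_labels=raw.format_labels.copy(),
                          n_categories=target_c, item_ids=raw.item_ids)


# ---------------------------------------------------------------------------
# Observed disattenuated correlation
# ---------------------------------------------------------------------------


def cronbach_alpha(scores: np.ndarray) -> float:
    """Coefficient alpha of a persons x items score block (sample variances)."""
    scores = np.asarray(scores, dtype=float)
    n_items = scores.shape[1]
    if n_items < 2:
        raise ValueError("coefficient alpha needs at least two items")
    item_var = scores.var(axis=0, ddof=1).sum()
    total_var = scores.sum(axis=1).var(ddof=1)
    if total_var < 1e-12:
        raise ValueError("zero-variance summed score")
    return n_items / (n_items - 1) * (1.0 - item_var / total_var)


def observed_disattenuated_correlation(responses: ResponseMatrix) -> float:
    """Observed MC-CR subscore correlation corrected for unreliability.

    r(X_MC, X_CR) / sqrt(alpha_MC * alpha_CR), with coefficient alpha as the
    reliability estimate.  In finite samples the result can exceed 1; it is
    returned uncorrected so callers see the raw index.
    """
    mc, cr = responses.mc_values, responses.cr_values
    if mc.shape[1] < 2 or cr.shape[1] < 2:
        raise ValueError("need at least two items per format")
    if responses.n_persons < 3:
        raise ValueError("need at least three persons")
    x, y = mc.sum(axis=1), cr.sum(axis=1)
    if x.std() < 1e-12 or y.std() < 1e-12:
        raise ValueError("zero-variance subscore")
    r = float(np.corrcoef(x, y)[0, 1])
    return r / np.sqrt(cronbach_alpha(mc) * cronbach_alpha(cr))


# ---------------------------------------------------------------------------
# Response-matrix CSV interchange
# ---------------------------------------------------------------------------


def write_response_csv(path, responses: ResponseMatrix) -> None:
    """Write a response matrix: header row of item ids, one row per person.

    Item format is carried by the id prefix ('MC' / 'CR')."""
    pd.DataFrame(responses.values, columns=list(responses.item_ids)).to_csv(
        path, index=False
    )


def read_response_csv(path, n_categories: int | None = None) -> ResponseMatrix:
    """Read a response matrix written by :func:`write_response_csv`."""
    df = pd.read_csv(path)
    labels = []
    for col in df.columns:
        if col.startswith("MC"):
            labels.append("MC")
        elif col.startswith("CR"):
            labels.append("CR")
        else:
            raise ValueError(f"item id {col!r} must start with 'MC' or 'CR'")
    labels = np.array(labels)
    values = df.to_numpy()
    if n_categories is None:
        cr = values[:, labels == "CR"]
        n_categories = int(cr.max()) + 1 if cr.size else 2
    return ResponseMatrix(values=values, format_labels=labels,
                          n_categories=n_categories, item_ids=tuple(df.columns))
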