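"""Item response models for mixed-format (MC + CR) tests.

Two model families are implemented:

* **Bi-factor (multidimensional normal ogive)** — every item loads on a
  general ability ``theta_g`` plus exactly one format-specific ability
  (``theta_mc`` for multiple-choice items, ``theta_cr`` for constructed
  response items); all three abilities are mutually orthogonal.  MC items
  follow a multidimensional 3-parameter normal ogive model (M3PNOM), CR
  items a multidimensional graded response model (MGRM) built from
  normal-ogive boundary curves.

* **Unidimensional (logistic)** — the conventional single-ability analysis:
  the 3-parameter logistic model (3PL) for MC items and Samejima's graded
  response model (GRM) for CR items.  No ``D = 1.7`` scaling constant is
  applied anywhere; each family is used on its native metric, and all
  downstream comparisons are rank-based and therefore metric-invariant.

Scalar operations take a single item and a single ability point; the
``*_probs_*`` array helpers evaluate whole item blocks at many ability
points at once and are the workhorses for calibration, scoring and
simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr

__all__ = [
    "Z_CLAMP",
    "BifactorMCItem",
    "BifactorCRItem",
    "UnidimMCItem",
    "UnidimCRItem",
    "ThetaTriple",
    "prob_mc_bifactor",
    "prob_cr_bifactor",
    "prob_mc_unidim",
    "prob_cr_unidim",
    "mc_probs_bifactor",
    "cr_probs_bifactor",
    "mc_probs_unidim",
    "cr_probs_unidim",
    "mc_bifactor_arrays",
    "cr_bifactor_arrays",
    "mc_unidim_arrays",
    "cr_unidim_arrays",
    "write_item_csv",
    "read_item_csv",
]

# Linear predictors are clamped at |z| = Z_CLAMP before CDF evaluation: far
# enough out that Phi underflows to exactly 0/1 in double precision, so
# category probabilities still telescope to 1 within 1e-12, while avoiding
# overflow in exp() for the logistic family.
Z_CLAMP = 38.0


def _phi(z):
    """Standard-normal CDF with tail clamping."""
    return ndtr(np.clip(z, -Z_CLAMP, Z_CLAMP))


def _sigma(z):
    """Logistic CDF with tail clamping."""
    return expit(np.clip(z, -Z_CLAMP, Z_CLAMP))


def _require_finite(name: str, *values: float) -> None:
    for v in values:
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v!r}")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ThetaTriple:
    """Orthogonal bi-factor abilities (general, MC-specific, CR-specific)."""

    theta_g: float
    theta_mc: float
    theta_cr: float

    def __post_init__(self) -> None:
        _require_finite("theta", self.theta_g, self.theta_mc, self.theta_cr)

    def as_array(self) -> np.ndarray:
        return np.array([self.theta_g, self.theta_mc, self.theta_cr])


@dataclass(frozen=True)
class BifactorMCItem:
    """MC item under the bi-factor normal-ogive model.

    P(y=1 | theta) = g + (1 - g) * Phi(a_g*theta_g + a_mc*theta_mc - d).
    """

    a_g: float
    a_mc: float
    d: float
    g: float

    def __post_init__(self) -> None:
        _require_finite("item parameter", self.a_g, self.a_mc, self.d, self.g)
        if not (0.0 <= self.g < 1.0):
            raise ValueError(f"lower asymptote g must lie in [0, 1), got {self.g}")


@dataclass(frozen=True)
class BifactorCRItem:
    """CR item under the bi-factor graded normal-ogive model.

    Category boundaries are d + o_c with o_1 = 0 by convention, so
    ``offsets`` holds (o_2, ..., o_{C-1}): strictly increasing positives.
    """

    a_g: float
    a_cr: float
    d: float
    offsets: tuple[float, ...]

    def __post_init__(self) -> None:
        _require_finite("item parameter", self.a_g, self.a_cr, self.d, *self.offsets)
        object.__setattr__(self, "offsets", tuple(float(o) for o in self.offsets))
        full = (0.0,) + self.offsets
        if any(b <= a for a, b in zip(full, full[1:])):
            raise ValueError(
                f"category offsets must be strictly increasing and > 0, got {self.offsets}"
            )

    @property
    def n_categories(self) -> int:
        return len(self.offsets) + 2

    @property
    def boundaries(self) -> np.ndarray:
        """Finite boundaries (d + o_c for c = 1..C-1), ascending."""
        return self.d + np.concatenate([[0.0], self.offsets])


@dataclass(frozen=True)
class UnidimMCItem:
    """MC item under the 3-parameter logistic model."""

    a: float
    b: float
    g: float

    def __post_init__(self) -> None:
        _require_finite("item parameter", self.a, self.b, self.g)
        if not (0.0 <= self.g < 1.0):
            raise ValueError(f"lower asymptote g must lie in [0, 1), got {self.g}")


@dataclass(frozen=True)
class UnidimCRItem:
    """CR item under the logistic graded response model (thresholds b_1..b_{C-1})."""

    a: float
    thresholds: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        _require_finite("item parameter", self.a, *self.thresholds)
        object.__setattr__(self, "thresholds", tuple(float(b) for b in self.thresholds))
        if len(self.thresholds) < 1:
            raise ValueError("a graded item needs at least one threshold")
        if any(y <= x for x, y in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError(f"thresholds must be strictly increasing, got {self.thresholds}")

    @property
    def n_categories(self) -> int:
        return len(self.thresholds) + 1


# ---------------------------------------------------------------------------
# Scalar probability operations
# ---------------------------------------------------------------------------


def prob_mc_bifactor(item: BifactorMCItem, theta: ThetaTriple) -> float:
    """P(correct) for an MC item under the bi-factor normal-ogive model."""
    z = item.a_g * theta.theta_g + item.a_mc * theta.theta_mc - item.d
    return float(item.g + (1.0 - item.g) * _phi(z))


def prob_cr_bifactor(item: BifactorCRItem, theta: ThetaTriple, category: int) -> float:
    """P(y = category) for a CR item under the bi-factor graded model.

    With z = a_g*theta_g + a_cr*theta_cr and boundaries
    t = (-inf, d, d+o_2, ..., d+o_{C-1}, +inf), returns
    Phi(z - t_c) - Phi(z - t_{c+1}).
    """
    C = item.n_categories
    if not (0 <= category < C):
        raise ValueError(f"category must lie in 0..{C - 1}, got {category}")
    z = item.a_g * theta.theta_g + item.a_cr * theta.theta_cr
    upper = _phi(z - item.boundaries)  # P(y >= c) for c = 1..C-1
    ge = np.concatenate([[1.0], upper, [0.0]])  # P(y >= c) for c = 0..C
    return float(ge[category] - ge[category + 1])


def prob_mc_unidim(item: UnidimMCItem, theta: float) -> float:
    """P(correct) for an MC item under the 3PL."""
    _require_finite("theta", theta)
    z = item.a * (theta - item.b)
    return float(item.g + (1.0 - item.g) * _sigma(z))


def prob_cr_unidim(item: UnidimCRItem, theta: float, category: int) -> float:
    """P(y = category) for a CR item under the logistic GRM."""
    _require_finite("theta", theta)
    C = item.n_categories
    if not (0 <= category < C):
        raise ValueError(f"category must lie in 0..{C - 1}, got {category}")
    upper = _sigma(item.a * (theta - np.asarray(item.thresholds)))
    ge = np.concatenate([[1.0], upper, [0.0]])
    return float(ge[category] - ge[category + 1])


# ---------------------------------------------------------------------------
# Vectorised evaluation over item blocks
# ---------------------------------------------------------------------------


def mc_bifactor_arrays(items) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stack bi-factor MC item parameters into (a_g, a_mc, d, g) arrays."""
    a_g = np.array([it.a_g for it in items], dtype=float)
    a_mc = np.array([it.a_mc for it in items], dtype=float)
    d = np.array([it.d for it in items], dtype=float)
    g = np.array([it.g for it in items], dtype=float)
    return a_g, a_mc, d, g


def cr_bifactor_arrays(items) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack bi-factor CR parameters into (a_g, a_cr, boundaries[J, C-1])."""
    a_g = np.array([it.a_g for it in items], dtype=float)
    a_cr = np.array([it.a_cr for it in items], dtype=float)
    bounds = np.stack([it.boundaries for it in items])
    return a_g, a_cr, bounds


def mc_unidim_arrays(items) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    a = np.array([it.a for it in items], dtype=float)
    b = np.array([it.b for it in items], dtype=float)
    g = np.array([it.g for it in items], dtype=float)
    return a, b, g


def cr_unidim_arrays(items) -> tuple[np.ndarray, np.ndarray]:
    a = np.array([it.a for it in items], dtype=float)
    thr = np.stack([np.asarray(it.thresholds) for it in items])
    return a, thr


def _is_array_tuple(items) -> bool:
    """True when ``items`` is already a tuple of stacked parameter arrays
    (as produced by the ``*_arrays`` helpers) rather than a sequence of
    item objects."""
    return (isinstance(items, tuple) and len(items) > 0
            and isinstance(items[0], np.ndarray))


def _graded_from_upper(ge_inner: np.ndarray) -> np.ndarray:
    """Turn inner cumulative curves P(y>=c), c=1..C-1 (last axis) into
    category probabilities P(y=c), c=0..C-1."""
    pad_shape = ge_inner.shape[:-1] + (1,)
    ge = np.concatenate(
        [np.ones(pad_shape), ge_inner, np.zeros(pad_shape)], axis=-1
    )
    return ge[..., :-1] - ge[..., 1:]


def mc_probs_bifactor(items, thetas: np.ndarray) -> np.ndarray:
    """P(correct) matrix, persons x items, bi-factor MC block.

    ``thetas`` is (n, 3) columns (theta_g, theta_mc, theta_cr).
    """
    a_g, a_mc, d, g = items if _is_array_tuple(items) else mc_bifactor_arrays(items)
    thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
    z = thetas[:, [0]] * a_g + thetas[:, [1]] * a_mc - d
    return g + (1.0 - g) * _phi(z)


def cr_probs_bifactor(items, thetas: np.ndarray) -> np.ndarray:
    """Category-probability tensor, persons x items x categories (bi-factor CR)."""
    a_g, a_cr, bounds = items if _is_array_tuple(items) else cr_bifactor_arrays(items)
    thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
    z = thetas[:, [0]] * a_g + thetas[:, [2]] * a_cr  # (n, J)
    ge_inner = _phi(z[:, :, None] - bounds[None, :, :])
    return _graded_from_upper(ge_inner)


def mc_probs_unidim(items, theta: np.ndarray) -> np.ndarray:
    """P(correct) matrix, persons x items, unidimensional 3PL block."""
    a, b, g = items if _is_array_tuple(items) else mc_unidim_arrays(items)
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    z = a * (theta[:, None] - b)
    return g + (1.0 - g) * _sigma(z)


def cr_probs_unidim(items, theta: np.ndarray) -> np.ndarray:
    """Category-probability tensor, persons x items x categories (logistic GRM)."""
    a, thr = items if _is_array_tuple(items) else cr_unidim_arrays(items)
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    ge_inner = _sigma(a[None, :, None] * (theta[:, None, None] - thr[None, :, :]))
    return _graded_from_upper(ge_inner)


# ---------------------------------------------------------------------------
# Item-parameter CSV interchange
# ---------------------------------------------------------------------------

_BASE_COLUMNS = ["item_id", "format", "model", "a_g", "a_spec", "d", "g"]


def _offset_columns(n_categories: int) -> list[str]:
    return [f"o{c}" for c in range(2, n_categories)]


def write_item_csv(path, mc_items, cr_items, model: str, n_categories: int = 5,
                   item_ids=None) -> None:
    """Write an item-parameter table.

    One row per item with columns item_id, format, model, a_g, a_spec, d, g,
    o2..o{C-1}; cells that do not apply to an item are left blank (a blank is
    "not applicable", never zero).  Column use by row type:

    * bifactor MC:  a_g, a_spec = a_mc, d, g
    * bifactor CR:  a_g, a_spec = a_cr, d, o2.. = category offsets
    * unidim MC:    a_g = a, d = b, g
    * unidim CR:    a_g = a, d = b_1, o2.. = b_2..b_{C-1} (absolute thresholds)

    Values are written with 12 significant digits, so a write/read round trip
    is lossless at that precision.
    """
    if model not in ("bifactor", "unidim"):
        raise ValueError(f"model must be 'bifactor' or 'unidim', got {model!r}")
    ocols = _offset_columns(n_categories)
    if item_ids is None:
        item_ids = [f"MC{k + 1:03d}" for k in range(len(mc_items))] + [
            f"CR{k + 1:03d}" for k in range(len(cr_items))
        ]
    rows = []
    for iid, it in zip(item_ids, list(mc_items) + list(cr_items)):
        row = dict.fromkeys(_BASE_COLUMNS + ocols, "")
        row["item_id"] = iid
        row["model"] = model
        if isinstance(it, BifactorMCItem):
            row.update(format="MC", a_g=it.a_g, a_spec=it.a_mc, d=it.d, g=it.g)
        elif isinstance(it, BifactorCRItem):
            row.update(format="CR", a_g=it.a_g, a_spec=it.a_cr, d=it.d)
            for col, o in zip(ocols, it.offsets):
                row[col] = o
        elif isinstance(it, UnidimMCItem):
            row.update(format="MC", a_g=it.a, d=it.b, g=it.g)
        elif isinstance(it, UnidimCRItem):
            row.update(format="CR", a_g=it.a, d=it.thresholds[0])
            for col, b in zip(ocols, it.thresholds[1:]):
                row[col] = b
        else:  # pragma: no cover - defensive
            raise TypeError(f"unsupported item type {type(it)!r}")
        rows.append(row)
    df = pd.DataFrame(rows, columns=_BASE_COLUMNS + ocols)
    num_cols = df.columns[3:]
    df[num_cols] = df[num_cols].map(
        lambda v: "" if v == "" else f"{float(v):.12g}"
    )
    df.to_csv(path, index=False)


def read_item_csv(path):
    """Read an item-parameter table written by :func:`write_item_csv`.

    Returns ``(mc_items, cr_items, model, item_ids)``.  The schema is
    validated strictly: unknown or missing columns, unknown format/model
    labels, and blanks in required cells all raise ``ValueError``.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = list(df.columns)
    if cols[: len(_BASE_COLUMNS)] != _BASE_COLUMNS:
        raise ValueError(
            f"item CSV must start with columns {_BASE_COLUMNS}, got {cols}"
        )
    ocols = cols[len(_BASE_COLUMNS):]
    if ocols != _offset_columns(len(ocols) + 2):
        raise ValueError(f"offset columns must be o2, o3, ... in order, got {ocols}")
    models = set(df["model"])
    if len(models) != 1 or models - {"bifactor", "unidim"}:
        raise ValueError(f"item CSV must hold a single model family, got {models}")
    model = models.pop()

    def cell(row, col, *, required: bool):
        raw = row[col].strip()
        if raw == "":
            if required:
                raise ValueError(f"item {row['item_id']!r}: column {col!r} is required")
            return None
        return float(raw)

    mc_items, cr_items, item_ids = [], [], []
    for _, row in df.iterrows():
        item_ids.append(row["item_id"])
        fmt = row["format"]
        if fmt == "MC":
            blanks = [c for c in ocols if row[c].strip() != ""]
            if blanks:
                raise ValueError(f"MC item {row['item_id']!r} has offset cells {blanks}")
            if model == "bifactor":
                mc_items.append(
                    BifactorMCItem(
                        a_g=cell(row, "a_g", required=True),
                        a_mc=cell(row, "a_spec", required=True),
                        d=cell(row, "d", required=True),
                        g=cell(row, "g", required=True),
                    )
                )
            else:
                if row["a_spec"].strip():
                    raise ValueError(
                        f"unidim MC item {row['item_id']!r} must leave a_spec blank"
                    )
                mc_items.append(
                    UnidimMCItem(
                        a=cell(row, "a_g", required=True),
                        b=cell(row, "d", required=True),
                        g=cell(row, "g", required=True),
                    )
                )
        elif fmt == "CR":
            if row["g"].strip():
                raise ValueError(f"CR item {row['item_id']!r} must leave g blank")
            ovals = [cell(row, c, required=True) for c in ocols]
            if model == "bifactor":
                cr_items.append(
                    BifactorCRItem(
                        a_g=cell(row, "a_g", required=True),
                        a_cr=cell(row, "a_spec", required=True),
                        d=cell(row, "d", required=True),
                        offsets=tuple(ovals),
                    )
                )
            else:
                if row["a_spec"].strip():
                    raise ValueError(
                        f"unidim CR item {row['item_id']!r} must leave a_spec blank"
                    )
                cr_items.append(
                    UnidimCRItem(
                        a=cell(row, "a_g", required=True),
                        thresholds=(cell(row, "d", required=True), *ovals),
                    )
                )
        else:
            raise ValueError(f"unknown format {fmt!r} for item {row['item_id']!r}")
    return mc_items, cr_items, model, item_ids
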