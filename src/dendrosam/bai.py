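"""Basal area increment (BAI) from dated ring-width series.

A tree's annual radial increments are converted to annual cross-sectional
area increments at coring height by anchoring on the bark-free stem
diameter measured in the final field year and reconstructing radii
outside-in: the radius before year *t* is the radius after year *t* minus
that year's ring width.  BAI for year *t* is then the area of the annulus,
``pi * (r_t**2 - r_{t-1}**2)`` in mm² yr⁻¹.

A power transform ``x ** b`` stabilizes the strong mean–variance coupling
of BAI before regression modeling; the exponent is estimated from a pooled
spread-versus-level regression (Cook–Peters style) over adjacent-year
pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "RingWidthSeries",
    "TreeMeta",
    "BaiSeries",
    "PowerTransform",
    "AffineTaperBarkModel",
    "bark_free_diameter_at_core_height",
    "bai_series",
    "estimate_power_exponent",
    "apply_power_transform",
]


@dataclass(frozen=True)
class RingWidthSeries:
    """Dated annual ring widths for one increment core, inner to outer.

    Parameters
    ----------
    tree_id : str
        Sample / tree identifier.
    years : array-like of int
        Strictly consecutive calendar years, ascending.
    widths_mm : array-like of float
        Ring width per year in millimetres; finite and non-negative.
    """

    tree_id: str
    years: np.ndarray
    widths_mm: np.ndarray

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=int)
        widths = np.asarray(self.widths_mm, dtype=float)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "widths_mm", widths)
        if years.size == 0:
            raise ValueError(f"{self.tree_id}: empty ring-width series")
        if years.size != widths.size:
            raise ValueError(f"{self.tree_id}: years/widths length mismatch")
        if years.size > 1 and not np.all(np.diff(years) == 1):
            raise ValueError(f"{self.tree_id}: years must be consecutive")
        if not np.all(np.isfinite(widths)) or np.any(widths < 0):
            raise ValueError(f"{self.tree_id}: widths must be finite and >= 0")

    @property
    def first_year(self) -> int:
        return int(self.years[0])

    @property
    def last_year(self) -> int:
        return int(self.years[-1])


@dataclass(frozen=True)
class TreeMeta:
    """Field metadata for one cored tree.

    ``unit_status`` records whether the tree stands in a treated or an
    untreated experimental unit; individual *rings* of treated-unit trees
    are still untreated until the year after thinning (see
    :func:`dendrosam.covariates.treatment_status`).
    """

    tree_id: str
    plot_id: str
    block_id: str
    site_id: str
    unit_status: str  # "treated-unit" | "untreated-unit"
    dbh_2019_cm: float
    thin_year: int | None = None
    burn_years: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.unit_status not in ("treated-unit", "untreated-unit"):
            raise ValueError(f"{self.tree_id}: bad unit_status {self.unit_status!r}")
        if not (self.dbh_2019_cm > 0):
            raise ValueError(f"{self.tree_id}: dbh_2019_cm must be > 0")
        if self.unit_status == "untreated-unit" and self.thin_year is not None:
            raise ValueError(f"{self.tree_id}: untreated-unit tree cannot have a thin_year")
        object.__setattr__(self, "burn_years", tuple(int(y) for y in self.burn_years))


@dataclass(frozen=True)
class BaiSeries:
    """Annual basal area increment (mm² yr⁻¹) for one tree."""

    tree_id: str
    years: np.ndarray
    bai_mm2: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "years", np.asarray(self.years, dtype=int))
        object.__setattr__(self, "bai_mm2", np.asarray(self.bai_mm2, dtype=float))


@dataclass(frozen=True)
class PowerTransform:
    """Monotone power transform ``x -> x**b`` with ``b`` in (0, 1].

    ``n_pairs`` and ``slope`` record the spread-vs-level regression the
    exponent came from (when estimated rather than fixed).
    """

    exponent_b: float
    n_pairs: int | None = None
    slope: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.exponent_b) or not (0 < self.exponent_b <= 1):
            raise ValueError(f"exponent_b must be in (0, 1], got {self.exponent_b}")

    def __call__(self, x):
        return apply_power_transform(x, self)

    def inverse(self, y):
        y = np.asarray(y, dtype=float)
        if np.any(y < 0):
            raise ValueError("inverse power transform requires y >= 0")
        return y ** (1.0 / self.exponent_b)


@dataclass(frozen=True)
class AffineTaperBarkModel:
    """Affine map from outside-bark dbh (1.37 m) to inside-bark diameter at
    coring height (40 cm): ``inside = a + b * dbh``.

    The species-specific taper and bark equations used for the original
    field data are published elsewhere and not bundled here; this default
    stands in for them and is fully configurable.
    """

    a: float = 0.0
    b: float = 0.9

    def __call__(self, dbh_cm: float) -> float:
        return self.a + self.b * dbh_cm


def bark_free_diameter_at_core_height(
    dbh_2019_cm: float,
    taper_bark_model: Callable[[float], float] | None = None,
) -> float:
    """Predict bark-free diameter (cm) at coring height from outside-bark dbh.

    ``taper_bark_model`` is any callable mapping outside-bark dbh at breast
    height (cm) to inside-bark diameter at 40 cm height (cm); the default
    is :class:`AffineTaperBarkModel`.
    """
    if not (dbh_2019_cm > 0):
        raise ValueError("dbh_2019_cm must be > 0")
    model = taper_bark_model if taper_bark_model is not None else AffineTaperBarkModel()
    out = float(model(dbh_2019_cm))
    if not (out > 0):
        raise ValueError(f"taper/bark model returned non-positive diameter {out}")
    return out


def bai_series(ring: RingWidthSeries, final_bark_free_radius_mm: float) -> BaiSeries:
    """Annual BAI (mm² yr⁻¹) by outside-in radius reconstruction.

    The radius after the last measured ring equals
    ``final_bark_free_radius_mm``; earlier radii are obtained by
    successively subtracting ring widths.  Requires the final radius to be
    at least the sum of widths, else the pith-side radius would go
    negative.
    """
    widths = ring.widths_mm
    r_final = float(final_bark_free_radius_mm)
    # radii after each year, outermost last
    r_after = r_final - np.concatenate([np.cumsum(widths[::-1])[::-1][1:], [0.0]])
    r_before = r_after - widths
    neg = np.nonzero(r_before < -1e-9)[0]
    if neg.size:
        yr = int(ring.years[neg[0]])
        raise ValueError(
            f"{ring.tree_id}: reconstructed radius negative before year {yr} "
            f"(final radius {r_final} mm < total ring width {widths.sum()} mm)"
        )
    r_before = np.clip(r_before, 0.0, None)
    bai = math.pi * (r_after**2 - r_before**2)
    return BaiSeries(ring.tree_id, ring.years.copy(), bai)


def estimate_power_exponent(
    bai_collection: Sequence[BaiSeries] | Sequence[np.ndarray],
) -> PowerTransform:
    """Estimate the variance-stabilizing exponent from pooled spread vs level.

    For adjacent years within each series, level ``M = (x_t + x_{t-1})/2``
    and spread ``S = |x_t - x_{t-1}|``; ``log S`` is regressed on ``log M``
    pooled over all series (pairs with zero spread or zero level dropped),
    and ``b = 1 - slope``, clamped to [0.05, 1].  A slope of 1 (spread
    proportional to level) gives the log-like limit b = 0.05; slope 0
    (spread independent of level) gives b = 1 (no transform needed).
    """
    levels: list[np.ndarray] = []
    spreads: list[np.ndarray] = []
    for s in bai_collection:
        x = np.asarray(s.bai_mm2 if isinstance(s, BaiSeries) else s, dtype=float)
        if x.size < 2:
            continue
        m = 0.5 * (x[1:] + x[:-1])
        sp = np.abs(np.diff(x))
        keep = (sp > 0) & (m > 0)
        levels.append(m[keep])
        spreads.append(sp[keep])
    if not levels:
        raise ValueError("cannot estimate exponent: need >= 2 values in some series")
    m = np.concatenate(levels)
    sp = np.concatenate(spreads)
    if m.size == 0:
        raise ValueError("cannot estimate exponent: all spreads zero (constant series)")
    slope, _ = np.polyfit(np.log(m), np.log(sp), 1)
    b = float(np.clip(1.0 - slope, 0.05, 1.0))
    return PowerTransform(exponent_b=b, n_pairs=int(m.size), slope=float(slope))


def apply_power_transform(bai_mm2, transform: PowerTransform):
    """Elementwise ``x**b``; strictly monotone on [0, inf) for b > 0."""
    x = np.asarray(bai_mm2, dtype=float)
    if np.any(x < 0):
        raise ValueError("power transform requires non-negative input")
    out = x**transform.exponent_b
    return float(out) if np.isscalar(bai_mm2) else out
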