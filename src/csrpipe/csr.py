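"""Trait-to-CSR ordination and ternary strategy classification.

The ordination maps each species' three leaf traits onto Grime's C
(competitor), S (stress-tolerator) and R (ruderal) axes: LA drives C,
LDMC drives S, SLA drives R. Per axis the trait is transformed (square
root of its proportion of a global maximum for LA, logit for LDMC,
natural log for SLA), min–max rescaled against calibration bounds,
clamped to [0, 1], and the three clamped values are normalised to
percentages summing to 100.

The calibration bounds are supplied as a versioned table, not hard-coded:
the engine is the transform/rescale/clamp/normalise skeleton. The package
ships a default table calibrated to the synthetic generator's trait
ranges; analyses of real floras should substitute bounds calibrated on a
reference species set (e.g. the published global StrateFy calibration).

Each CSR point is then labelled with one of Grime's 19 ternary strategy
classes by Euclidean nearest centroid in the simplex.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AXIS_TRAIT = {"C": "LA", "S": "LDMC", "R": "SLA"}
TRAIT_COLUMN = {"LA": "la_mm2", "LDMC": "ldmc_pct", "SLA": "sla_mm2_mg"}
TRANSFORMS = ("sqrt_of_proportion_of_max", "logit_of_percent", "natural_log", "identity")


@dataclass(frozen=True)
class CSRScore:
    """A point in the ternary simplex: C, S, R percentages summing to 100."""

    c: float
    s: float
    r: float

    def __post_init__(self):
        for v in (self.c, self.s, self.r):
            if not (-1e-9 <= v <= 100 + 1e-9):
                raise ValueError(f"CSR component {v} outside [0, 100]")
        if abs(self.c + self.s + self.r - 100.0) > 1e-9:
            raise ValueError(f"CSR components sum to {self.c + self.s + self.r}, not 100")

    def as_array(self) -> np.ndarray:
        return np.array([self.c, self.s, self.r])


@dataclass(frozen=True)
class AxisCalibration:
    trait: str
    transform: str
    params: dict
    calib_min: float
    calib_max: float


@dataclass(frozen=True)
class CalibrationTable:
    """Per-axis transform and min/max bounds on the transformed scale."""

    version: str
    axes: dict[str, AxisCalibration]

    def __post_init__(self):
        if set(self.axes) != {"C", "S", "R"}:
            raise ValueError("calibration must define exactly the C, S and R axes")
        for axis, cal in self.axes.items():
            if cal.transform not in TRANSFORMS:
                raise ValueError(f"axis {axis}: unknown transform {cal.transform!r}")
            if cal.transform != "identity" and cal.trait != AXIS_TRAIT[axis]:
                raise ValueError(
                    f"axis {axis} must be driven by {AXIS_TRAIT[axis]}, got {cal.trait}")
            if not cal.calib_min < cal.calib_max:
                raise ValueError(f"axis {axis}: calib_min must be below calib_max")

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationTable":
        obj = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls._from_obj(obj)

    @classmethod
    def _from_obj(cls, obj: dict) -> "CalibrationTable":
        axes = {axis: AxisCalibration(d["trait"], d["transform"], d.get("params", {}),
                                      float(d["calib_min"]), float(d["calib_max"]))
                for axis, d in obj["axes"].items()}
        return cls(version=obj.get("version", "unversioned"), axes=axes)

    @classmethod
    def default(cls) -> "CalibrationTable":
        """The shipped synthetic-scale calibration (version tag names it)."""
        ref = resources.files("csrpipe.data").joinpath("calibration_synthetic.json")
        return cls._from_obj(json.loads(ref.read_text(encoding="utf-8")))


def identity_calibration() -> CalibrationTable:
    """Pass-through calibration on [0, 1]: raw scores equal clamped traits.

    Intended for tests and for feeding pre-scaled axis values directly.
    """
    axes = {a: AxisCalibration(AXIS_TRAIT[a], "identity", {}, 0.0, 1.0) for a in "CSR"}
    return CalibrationTable(version="identity", axes=axes)


def _apply_transform(value: float, cal: AxisCalibration) -> float:
    if cal.transform == "sqrt_of_proportion_of_max":
        m = cal.params["max_value"]
        return math.sqrt(min(value, m) / m) if value > 0 else 0.0
    if cal.transform == "logit_of_percent":
        p = value / 100.0
        if p <= 0.0:
            return -math.inf
        if p >= 1.0:
            return math.inf
        return math.log(p / (1.0 - p))
    if cal.transform == "natural_log":
        return math.log(value) if value > 0 else -math.inf
    return value  # identity


def traits_to_csr(profile, calibration: CalibrationTable | None = None) -> CSRScore:
    """Ordinate one species' (LA, LDMC, SLA) onto the CSR simplex.

    ``profile`` is anything with attributes la_mm2, ldmc_pct, sla_mm2_mg
    (a SpeciesTraitProfile or a DataFrame row). Trait values outside a
    transform's domain (e.g. LDMC = 100 under the logit) map to the clamp
    boundary with a logged warning rather than raising.
    """
    calibration = calibration or CalibrationTable.default()
    trait_value = {"LA": profile.la_mm2, "LDMC": profile.ldmc_pct, "SLA": profile.sla_mm2_mg}
    raw = []
    for axis in ("C", "S", "R"):
        cal = calibration.axes[axis]
        t = _apply_transform(trait_value[cal.trait], cal)
        if not math.isfinite(t):
            logger.warning("axis %s: trait %s=%s outside transform domain; clamped",
                           axis, cal.trait, trait_value[cal.trait])
        scaled = (t - cal.calib_min) / (cal.calib_max - cal.calib_min)
        raw.append(min(1.0, max(0.0, scaled)))
    total = sum(raw)
    if total == 0.0:
        return CSRScore(100 / 3, 100 / 3, 100 / 3)
    return CSRScore(*(100.0 * v / total for v in raw))


def _midpoint(a, b):
    return tuple((x + y) / 2 for x, y in zip(a, b))


def _strategy_centroids() -> dict[str, tuple[float, float, float]]:
    third = 100.0 / 3.0
    prim = {"C": (100.0, 0.0, 0.0), "S": (0.0, 100.0, 0.0), "R": (0.0, 0.0, 100.0)}
    sec = {"CS": (50.0, 50.0, 0.0), "CR": (50.0, 0.0, 50.0), "SR": (0.0, 50.0, 50.0)}
    cent = {"CSR": (third, third, third)}
    base = {**prim, **sec, **cent}
    trans = {}
    for p in prim:
        for q in sec:
            if p in q:
                trans[f"{p}/{q}"] = _midpoint(prim[p], sec[q])
        trans[f"{p}/CSR"] = _midpoint(prim[p], cent["CSR"])
    for q in sec:
        trans[f"{q}/CSR"] = _midpoint(sec[q], cent["CSR"])
    return {**base, **trans}


STRATEGY_CENTROIDS: dict[str, tuple[float, float, float]] = _strategy_centroids()
_LABELS = sorted(STRATEGY_CENTROIDS)  # lexicographic order is the tie-break
_CENTROID_MATRIX = np.array([STRATEGY_CENTROIDS[k] for k in _LABELS])


@dataclass(frozen=True)
class StrategyClass:
    label: str
    centroid: CSRScore


def classify_strategy(score: CSRScore) -> StrategyClass:
    """Assign the Grime ternary class whose centroid is nearest (Euclidean).

    Ties are broken by lexicographic label order.
    """
    return classify_triplet(score.c, score.s, score.r)


def classify_triplet(c: float, s: float, r: float) -> StrategyClass:
    """Classify a raw (c, s, r) triplet by nearest centroid.

    Accepts coordinates rounded to whole percent (published tables), whose
    sum may miss 100 by a point or two; exact simplex closure is not
    required here, only for ordination output.
    """
    point = np.array([c, s, r], dtype=float)
    if point.min() < 0 or point.max() > 100 or abs(point.sum() - 100.0) > 2.0:
        raise ValueError(f"({c}, {s}, {r}) is not a CSR triplet")
    d2 = ((_CENTROID_MATRIX - point) ** 2).sum(axis=1)
    label = _LABELS[int(np.argmin(d2))]
    return StrategyClass(label, CSRScore(*STRATEGY_CENTROIDS[label]))


_SQRT3_2 = math.sqrt(3.0) / 2.0
# triangle corners: S at origin, R at (1, 0), C at the apex
_CORNERS = {"C": (0.5, _SQRT3_2), "S": (0.0, 0.0), "R": (1.0, 0.0)}


def ternary_to_cartesian(score: CSRScore) -> tuple[float, float]:
    """Barycentric map of (c, s, r) onto an equilateral triangle."""
    c, s, r = score.c / 100, score.s / 100, score.r / 100
    x = c * _CORNERS["C"][0] + s * _CORNERS["S"][0] + r * _CORNERS["R"][0]
    y = c * _CORNERS["C"][1]
    return (x, y)


def cartesian_to_ternary(x: float, y: float) -> CSRScore:
    """Inverse of :func:`ternary_to_cartesian` on the simplex."""
    c = y / _SQRT3_2
    r = x - 0.5 * c
    s = 1.0 - c - r
    return CSRScore(100 * c, 100 * s, 100 * r)


def score_table(profiles: pd.DataFrame,
                calibration: CalibrationTable | None = None) -> pd.DataFrame:
    """Ordinate and classify every species in a profile table.

    Returns columns species_id, c, s, r, strategy_class.
    """
    calibration = calibration or CalibrationTable.default()
    rows = []
    for p in profiles.itertuples(index=False):
        score = traits_to_csr(p, calibration)
        rows.append((p.species_id, score.c, score.s, score.r,
                     classify_strategy(score).label))
    return pd.DataFrame(rows, columns=["species_id", "c", "s", "r", "strategy_class"])


def classify_table(scores: pd.DataFrame) -> pd.DataFrame:
    """Classification-only mode: label an existing table of c, s, r columns."""
    labels = [classify_triplet(row.c, row.s, row.r).label
              for row in scores.itertuples(index=False)]
    out = scores.copy()
    out["strategy_class"] = labels
    return out
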