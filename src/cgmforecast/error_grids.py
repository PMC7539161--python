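"""Clarke and Parkes (Consensus) error-grid analysis.

Both grids partition the (reference, predicted) glucose plane into clinical
consequence zones A (accurate) through E (erroneous reading that would
prompt dangerous treatment).  The Clarke grid is defined by closed-form
boundary inequalities; the Parkes grid by the published vertex tables of the
consensus zone boundaries, implemented here as point-in-polygon tests (type
1 diabetes variant — matching a type-1 cohort; the type 2 grid is a stub).

Boundary policy: zone regions for C/D/E are taken as open sets (strict
inequalities / polygon interiors), so a point exactly on a zone boundary
falls to the better (earlier-letter) neighbouring zone.  Inputs are clamped
to 550 mg/dL, the upper edge of both published grids.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

ZONES = ("A", "B", "C", "D", "E")
GRID_MAX = 550.0


class DomainError(ValueError):
    """Raised for glucose values outside the grid domain (must be positive)."""


# ---------------------------------------------------------------------------
# Clarke error grid (1987): closed-form region inequalities.
# x = reference, y = predicted, both mg/dL.


def clarke_zones(reference: np.ndarray, predicted: np.ndarray) -> np.ndarray:
    """Vectorised Clarke zoning.  Returns an array of 'A'..'E' labels."""
    x = np.asarray(reference, dtype=float)
    y = np.asarray(predicted, dtype=float)
    if np.any(x <= 0) or np.any(y <= 0):
        raise DomainError("glucose values must be positive")
    x = np.minimum(x, GRID_MAX)
    y = np.minimum(y, GRID_MAX)

    zone_a = ((x <= 70) & (y <= 70)) | ((y >= 0.8 * x) & (y <= 1.2 * x))
    # open regions: boundaries fall through to the better letter
    zone_e = ((x < 70) & (y > 180)) | ((x > 180) & (y < 70))
    zone_c = ((x > 70) & (x < 290) & (y > x + 110)) | (
        (x > 130) & (x < 180) & (y < 1.4 * x - 182)
    )
    zone_d = ((x < 70) & (y > 70) & (y < 180) & (y > 1.2 * x)) | (
        (x > 240) & (y > 70) & (y < 180)
    )

    out = np.full(x.shape, "B", dtype="U1")
    out[zone_e] = "E"
    out[zone_d] = "D"
    out[zone_c] = "C"  # C beats D/E where open regions touch (better letter)
    out[zone_a] = "A"
    return out


def clarke_zone(reference: float, predicted: float) -> str:
    """Clarke zone letter for a single (reference, predicted) pair."""
    return str(clarke_zones(np.array([reference]), np.array([predicted]))[0])


# ---------------------------------------------------------------------------
# Parkes (Consensus) error grid, type 1 diabetes variant.
#
# The published boundary polylines (x = reference, y = predicted, mg/dL).
# "Upper" polylines bound zones above the identity diagonal, "lower" below.

PARKES_T1_BOUNDS = {
    "E_upper": [(0, 150), (35, 155), (50, 550)],
    "D_upper": [(0, 100), (25, 100), (50, 125), (80, 215), (125, 550)],
    "D_lower": [(250, 0), (250, 40), (550, 150)],
    "C_upper": [(0, 60), (30, 60), (50, 80), (70, 110), (260, 550)],
    "C_lower": [(120, 0), (120, 30), (260, 130), (550, 250)],
    "B_upper": [(0, 50), (30, 50), (140, 170), (280, 380), (430, 550)],
    "B_lower": [(50, 0), (50, 30), (170, 145), (385, 300), (550, 450)],
}


# polygons close slightly beyond the grid edge so that values clamped to
# exactly 550 lie in a region's interior, not on its boundary
_PAD = GRID_MAX + 10.0


def _upper_polygon(polyline: list[tuple[float, float]]) -> Polygon:
    """Region above an upper boundary polyline, closed along the top-left."""
    return Polygon(polyline + [(polyline[-1][0], _PAD), (0, _PAD)])


def _lower_polygon(polyline: list[tuple[float, float]]) -> Polygon:
    """Region below a lower boundary polyline, closed along the bottom-right."""
    return Polygon(polyline + [(_PAD, polyline[-1][1]), (_PAD, 0)])


def _build_parkes_t1():
    polys = {
        "E_upper": _upper_polygon(PARKES_T1_BOUNDS["E_upper"]),
        "D_upper": _upper_polygon(PARKES_T1_BOUNDS["D_upper"]),
        "D_lower": _lower_polygon(PARKES_T1_BOUNDS["D_lower"]),
        "C_upper": _upper_polygon(PARKES_T1_BOUNDS["C_upper"]),
        "C_lower": _lower_polygon(PARKES_T1_BOUNDS["C_lower"]),
        "B_upper": _upper_polygon(PARKES_T1_BOUNDS["B_upper"]),
        "B_lower": _lower_polygon(PARKES_T1_BOUNDS["B_lower"]),
    }
    # worst-to-best check order; nested regions mean the first hit wins
    order = ["E_upper", "D_upper", "D_lower", "C_upper", "C_lower", "B_upper", "B_lower"]
    letters = [name[0] for name in order]
    return [polys[name] for name in order], letters


_PARKES_T1_POLYS, _PARKES_T1_LETTERS = _build_parkes_t1()


def parkes_zones(reference: np.ndarray, predicted: np.ndarray, diabetes_type: int = 1) -> np.ndarray:
    """Vectorised Parkes consensus zoning (type 1 grid)."""
    if diabetes_type != 1:
        raise NotImplementedError("only the type 1 diabetes Parkes grid is implemented")
    x = np.asarray(reference, dtype=float)
    y = np.asarray(predicted, dtype=float)
    if np.any(x <= 0) or np.any(y <= 0):
        raise DomainError("glucose values must be positive")
    x = np.minimum(x, GRID_MAX)
    y = np.minimum(y, GRID_MAX)

    out = np.full(x.shape, "A", dtype="U1")
    undecided = np.ones(x.shape, dtype=bool)
    for poly, letter in zip(_PARKES_T1_POLYS, _PARKES_T1_LETTERS):
        if not undecided.any():
            break
        idx = np.nonzero(undecided)[0]
        # strict interior: boundary points fall through to the better zone
        inside = shapely.contains_xy(poly, x[idx], y[idx])
        out[idx[inside]] = letter
        undecided[idx[inside]] = False
    return out


def parkes_zone(reference: float, predicted: float, diabetes_type: int = 1) -> str:
    """Parkes consensus zone letter for a single pair (type 1 grid)."""
    return str(parkes_zones(np.array([reference]), np.array([predicted]), diabetes_type)[0])


# ---------------------------------------------------------------------------
# zone-distribution reporting


@dataclass
class ZoneReport:
    """Per-zone counts and fractions for one grid over a set of pairs."""

    kind: str                       # "clarke" | "parkes"
    counts: dict[str, int]
    n: int

    @property
    def fractions(self) -> dict[str, float]:
        return {z: self.counts[z] / self.n for z in ZONES}

    @property
    def clinically_acceptable(self) -> float:
        """A+B fraction — the share of predictions that would not harm."""
        return (self.counts["A"] + self.counts["B"]) / self.n

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "zone": list(ZONES),
                "count": [self.counts[z] for z in ZONES],
                "percent": [100.0 * self.fractions[z] for z in ZONES],
            }
        )


def zone_distribution(
    pairs: Iterable[tuple[float, float]] | np.ndarray, kind: str = "parkes"
) -> ZoneReport:
    """Tally zones over (reference, predicted) pairs."""
    arr = np.asarray(list(pairs) if not isinstance(pairs, np.ndarray) else pairs, dtype=float)
    if arr.size == 0:
        raise ValueError("zone_distribution requires at least one pair")
    ref, pred = arr[:, 0], arr[:, 1]
    if kind == "clarke":
        zones = clarke_zones(ref, pred)
    elif kind == "parkes":
        zones = parkes_zones(ref, pred)
    else:
        raise ValueError(f"unknown grid kind {kind!r}; expected 'clarke' or 'parkes'")
    counts = Counter(zones.tolist())
    return ZoneReport(kind=kind, counts={z: counts.get(z, 0) for z in ZONES}, n=len(ref))
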