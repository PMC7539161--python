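"""Independent error-grid oracles used to cross-check the implementation.

These deliberately use different mechanisms from the package: the Clarke
oracle classifies via matplotlib Path polygons built from the corner points
of the published regions, and the Parkes oracle interpolates the published
boundary polylines directly (pure Python, no shapely).  Both clamp to the
550 mg/dL grid edge.  Boundary points may legitimately disagree with the
implementation; random float test points never hit boundaries.
"""

from __future__ import annotations

from matplotlib.path import Path

GRID_MAX = 550.0

# Clarke region corner polygons (x = reference, y = predicted).
_CLARKE_POLYS = [
    ("E", Path([(0, 180), (70, 180), (70, 550), (0, 550)])),        # upper-left
    ("E", Path([(180, 0), (550, 0), (550, 70), (180, 70)])),        # lower-right
    ("C", Path([(70, 180), (290, 400), (290, 550), (70, 550)])),    # upper
    ("C", Path([(130, 0), (180, 0), (180, 70)])),                   # lower triangle
    ("D", Path([(0, 70), (175 / 3, 70), (70, 84), (70, 180), (0, 180)])),  # upper-left
    ("D", Path([(240, 70), (550, 70), (550, 180), (240, 180)])),    # right band
]


def clarke_oracle(reference: float, predicted: float) -> str:
    x = min(reference, GRID_MAX)
    y = min(predicted, GRID_MAX)
    if (x <= 70 and y <= 70) or (0.8 * x <= y <= 1.2 * x):
        return "A"
    for letter, poly in _CLARKE_POLYS:
        if poly.contains_point((x, y)):
            return letter
    return "B"


# Parkes type-1 boundary polylines (same published vertex tables the
# implementation embeds, but evaluated by direct segment interpolation).
_PARKES_UPPER = [
    ("E", [(0, 150), (35, 155), (50, 550)]),
    ("D", [(0, 100), (25, 100), (50, 125), (80, 215), (125, 550)]),
    ("C", [(0, 60), (30, 60), (50, 80), (70, 110), (260, 550)]),
    ("B", [(0, 50), (30, 50), (140, 170), (280, 380), (430, 550)]),
]
_PARKES_LOWER = [
    ("D", [(250, 0), (250, 40), (550, 150)]),
    ("C", [(120, 0), (120, 30), (260, 130), (550, 250)]),
    ("B", [(50, 0), (50, 30), (170, 145), (385, 300), (550, 450)]),
]


def _boundary_y(polyline, x):
    """Interpolated boundary y at abscissa x, or None outside the polyline span."""
    for (x0, y0), (x1, y1) in zip(polyline, polyline[1:]):
        if x0 <= x <= x1 and x1 > x0:
            return y0 + (y1 - y0) * (x - x0) / (x1 - x0)
        if x == x0 == x1:
            return max(y0, y1)
    return None


def parkes_oracle(reference: float, predicted: float) -> str:
    x = min(reference, GRID_MAX)
    y = min(predicted, GRID_MAX)
    worst = "A"
    rank = {"A": 0, "B": 1, "C": 2, "D": 3, "E": 4}
    for letter, polyline in _PARKES_UPPER:
        b = _boundary_y(polyline, x)
        if b is not None and y > b and rank[letter] > rank[worst]:
            worst = letter
    for letter, polyline in _PARKES_LOWER:
        b = _boundary_y(polyline, x)
        if b is not None and y < b and rank[letter] > rank[worst]:
            worst = letter
    return worst
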