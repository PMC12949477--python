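"""24-2 test-pattern geometry and field summary statistics.

The Humphrey Field Analyzer 24-2 pattern places 54 stimulus locations on a
6-degree grid covering 24 degrees of visual field in every direction plus a
nasal extension to 27 degrees.  Two locations straddle the physiological
blind spot (15 degrees temporal, +/-3 degrees vertical) and are excluded
from analysis, leaving the 52 locations indexed here.

Everything in this package uses right-eye orientation: positive x is the
temporal field (blind spot at x = +15), the nasal extension sits at
x = -27.  Left-eye data would be mirrored at I/O time.
"""

from __future__ import annotations

import numpy as np

#: Instrument dynamic range for measured thresholds (dB).
THRESHOLD_MIN = 0.0
THRESHOLD_MAX = 40.0

#: Blind-spot locations excluded from the 54-point pattern (right eye).
BLIND_SPOT = ((15, 3), (15, -3))


def _build_grid() -> list[tuple[int, int]]:
    # Row extents of the 24-2 pattern (y, degrees) -> x range.  Rows at
    # y=+/-3 extend one extra step nasally (x=-27 in right-eye orientation).
    rows = {
        21: (-9, 9),
        15: (-15, 15),
        9: (-21, 21),
        3: (-27, 21),
        -3: (-27, 21),
        -9: (-21, 21),
        -15: (-15, 15),
        -21: (-9, 9),
    }
    pts: list[tuple[int, int]] = []
    # Standard export order: superior row first, left to right within a row.
    for y in sorted(rows, reverse=True):
        lo, hi = rows[y]
        for x in range(lo, hi + 1, 6):
            if (x, y) in BLIND_SPOT:
                continue
            pts.append((x, y))
    return pts


#: The 52 analysed 24-2 locations in stable export order (vf.1 .. vf.52):
#: row-major, superior-left to inferior-right, blind spot excluded.
GRID: tuple[tuple[int, int], ...] = tuple(_build_grid())

_INDEX = {xy: i for i, xy in enumerate(GRID)}

N_LOCATIONS = len(GRID)  # 52


def grid_coordinates() -> list[tuple[int, int]]:
    """Return the 52 (x, y) grid coordinates in export order."""
    return list(GRID)


def location_index(x: int, y: int) -> int:
    """0-based index of grid coordinate (x, y); KeyError if not in pattern."""
    return _INDEX[(x, y)]


def _neighbor_sets() -> tuple[frozenset[int], ...]:
    out = []
    for (x, y) in GRID:
        nb = set()
        for dx in (-6, 0, 6):
            for dy in (-6, 0, 6):
                if dx == 0 and dy == 0:
                    continue
                j = _INDEX.get((x + dx, y + dy))
                if j is not None:
                    nb.add(j)
        out.append(frozenset(nb))
    return tuple(out)


#: 8-connected neighbours (Chebyshev distance one grid step) per location.
NEIGHBORS: tuple[frozenset[int], ...] = _neighbor_sets()


def neighbors(index: int) -> frozenset[int]:
    """8-connected grid neighbours of ``index`` within the 52-location set."""
    if not 0 <= index < N_LOCATIONS:
        raise IndexError(f"location index out of range: {index}")
    return NEIGHBORS[index]


def normative_thresholds() -> np.ndarray:
    """Age-normal threshold surface (dB) over the 52 locations.

    A smooth eccentricity-decreasing hill-of-vision surrogate: roughly
    34 dB near fixation falling to ~31 dB at the pattern edge.  The exact
    normative surface only sets the staircase operating point and the
    threshold <-> total-deviation offset; it is exposed so users can swap
    in their own table.
    """
    xy = np.asarray(GRID, dtype=float)
    ecc = np.hypot(xy[:, 0], xy[:, 1])
    return np.round(35.0 - 0.15 * ecc, 1)


def mean_deviation(td_values: np.ndarray) -> float:
    """Unweighted mean of the 52 total-deviation values (dB).

    Used as the mean-deviation surrogate throughout (the instrument's
    weighted MD is a non-goal).
    """
    td_values = np.asarray(td_values, dtype=float)
    if td_values.shape != (N_LOCATIONS,):
        raise ValueError(f"expected {N_LOCATIONS} total-deviation values")
    return float(td_values.mean())


def grid_table() -> "np.ndarray":
    """(index, x, y) rows documenting the export order; index is 1-based."""
    return np.array([(i + 1, x, y) for i, (x, y) in enumerate(GRID)], dtype=int)
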