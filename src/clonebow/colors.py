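"""Ternary RGB color model.

Cells labeled by multicolor (Brainbow-type) recombination are classified by
the relative intensities of the three recombined fluorophores.  Measured
channel means are normalized onto the RGB 2-simplex (a ternary plot), the
simplex is partitioned into 25 color-identity regions, region frequencies
are classed as frequent / rare / intermediate, and clones are classed as
red or non-red by their mean red fraction.

The 25-region partition is the triangular grid obtained by dividing each
simplex edge into ``N_SUBDIV = 5`` equal intervals: 15 upward and 10
downward unit triangles.  A point with normalized coordinates (r, g, b) is
located by the half-open floors ``i = floor(5r)``, ``j = floor(5g)``,
``k = floor(5b)``: ``i + j + k == 4`` identifies an upward triangle,
``i + j + k == 3`` a downward one, and lattice points (sum 5) are assigned
to an upward triangle by decrementing the largest coordinate's floor
(ties broken in r, g, b order) so that every simplex point maps to exactly
one region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

N_SUBDIV = 5
N_REGIONS = N_SUBDIV * N_SUBDIV

FREQUENT = "frequent"
RARE = "rare"
INTERMEDIATE = "intermediate"

RED = "red"
NONRED = "nonred"
EXCLUDED = "excluded"


class UnclassifiableColorError(ValueError):
    """Raised when a measurement carries no usable signal (all channels zero)."""


@dataclass(frozen=True)
class ColorThresholds:
    """Frequency- and red-classification cutoffs (fractions of 1).

    ``frequent_min``/``rare_max`` class color-identity regions by their share
    of all cells; ``red_min``/``nonred_max`` class clones by mean red
    fraction.  Defaults follow the standard multicolor-clone criteria:
    >10% frequent, <2.5% rare, >5% red, <1% non-red.
    """

    frequent_min: float = 0.10
    rare_max: float = 0.025
    red_min: float = 0.05
    nonred_max: float = 0.01

    def __post_init__(self) -> None:
        if not (0 <= self.rare_max < self.frequent_min <= 1):
            raise ValueError("need 0 <= rare_max < frequent_min <= 1")
        if not (0 <= self.nonred_max < self.red_min <= 1):
            raise ValueError("need 0 <= nonred_max < red_min <= 1")


def normalize_rgb(r: float, g: float, b: float) -> tuple[float, float, float]:
    """Project nonnegative channel means onto the ternary simplex.

    Raises :class:`UnclassifiableColorError` when all channels are zero.
    """
    total = r + g + b
    if total <= 0:
        raise UnclassifiableColorError("all-zero color measurement")
    return (r / total, g / total, b / total)


def assign_color_identity(r: float, g: float, b: float) -> int:
    """Map a ternary coordinate to its region index in ``[0, 24]``.

    Upward triangles are indexed 0-14, downward 15-24, each in
    lexicographic (i, j) order of their floor coordinates.
    """
    s = r + g + b
    if not math.isclose(s, 1.0, abs_tol=1e-9):
        raise ValueError(f"not a simplex point: sum={s!r}")
    n = N_SUBDIV
    # snap tolerance: values within ~1e-9 below a grid line count as on it,
    # so classification is stable under round-off (e.g. after rescaling)
    eps = 1e-9
    i = min(int(math.floor(n * r + eps)), n)
    j = min(int(math.floor(n * g + eps)), n)
    k = min(int(math.floor(n * b + eps)), n)
    tot = i + j + k
    if tot == n:  # lattice point: push into an upward triangle
        coords = [i, j, k]
        vals = [r, g, b]
        largest = max(range(3), key=lambda a: (vals[a], -a))
        coords[largest] -= 1
        i, j, k = coords
        tot = n - 1
    if tot == n - 1:  # upward triangle
        return i * n - i * (i - 1) // 2 + j
    if tot == n - 2:  # downward triangle
        n_up = n * (n + 1) // 2
        return n_up + i * (n - 1) - i * (i - 1) // 2 + j
    raise ValueError(f"floor sum {tot} outside expected range for ({r},{g},{b})")


def assign_color_identities(rgb: np.ndarray) -> np.ndarray:
    """Vectorized :func:`assign_color_identity` over an (n, 3) array of
    channel means (normalization applied row-wise)."""
    rgb = np.asarray(rgb, dtype=float)
    totals = rgb.sum(axis=1)
    if np.any(totals <= 0):
        raise UnclassifiableColorError("row with all-zero channels")
    frac = rgb / totals[:, None]
    return np.array(
        [assign_color_identity(*row) for row in frac], dtype=int
    )


def region_triangle(region_index: int) -> np.ndarray:
    """Vertices of a region as a (3, 3) array of simplex points.

    Used by the plotting export and by the brute-force geometric oracle in
    the test suite.
    """
    n = N_SUBDIV
    n_up = n * (n + 1) // 2
    if not 0 <= region_index < N_REGIONS:
        raise ValueError("region index out of range")
    if region_index < n_up:  # upward
        idx = region_index
        i = 0
        while idx >= n - i:
            idx -= n - i
            i += 1
        j = idx
        k = (n - 1) - i - j
        verts = [(i + 1, j, k), (i, j + 1, k), (i, j, k + 1)]
    else:  # downward
        idx = region_index - n_up
        i = 0
        while idx >= n - 1 - i:
            idx -= n - 1 - i
            i += 1
        j = idx
        k = (n - 2) - i - j
        verts = [(i + 1, j + 1, k), (i + 1, j, k + 1), (i, j + 1, k + 1)]
    return np.array(verts, dtype=float) / n


def classify_frequency(
    counts_per_region: Mapping[int, int],
    thresholds: ColorThresholds = ColorThresholds(),
) -> dict[int, str]:
    """Class each observed region as frequent / rare / intermediate by its
    share of the total cell count."""
    total = sum(counts_per_region.values())
    if total <= 0:
        raise ValueError("empty region counts")
    out: dict[int, str] = {}
    for region, count in counts_per_region.items():
        frac = count / total
        if frac > thresholds.frequent_min:
            out[region] = FREQUENT
        elif frac < thresholds.rare_max:
            out[region] = RARE
        else:
            out[region] = INTERMEDIATE
    return out


def red_fraction(rgb: np.ndarray, normalized: bool = True) -> float:
    """Mean red content of a set of cells.

    ``normalized=True`` (default) averages per-cell R/(R+G+B), which is
    invariant to per-cell illumination; ``False`` uses the raw red-channel
    mean divided by the raw total, for comparison with intensity-based
    workflows.  Cells with zero total intensity are skipped.
    """
    rgb = np.asarray(rgb, dtype=float)
    totals = rgb.sum(axis=1)
    ok = totals > 0
    if not np.any(ok):
        raise UnclassifiableColorError("no classifiable cells in clone")
    if normalized:
        return float(np.mean(rgb[ok, 0] / totals[ok]))
    return float(rgb[ok, 0].sum() / totals[ok].sum())


def classify_red_condition(
    rgb: np.ndarray,
    thresholds: ColorThresholds = ColorThresholds(),
    normalized: bool = True,
) -> str:
    """Class a clone as ``red`` (> red_min mean red fraction), ``nonred``
    (< nonred_max) or ``excluded`` (in between)."""
    frac = red_fraction(rgb, normalized=normalized)
    if frac > thresholds.red_min:
        return RED
    if frac < thresholds.nonred_max:
        return NONRED
    return EXCLUDED


def region_frequency_table(region_indices: Iterable[int],
                           thresholds: ColorThresholds = ColorThresholds()):
    """Per-region count / fraction / frequency-class report as a DataFrame."""
    import pandas as pd

    idx = np.asarray(list(region_indices), dtype=int)
    if idx.size == 0:
        raise ValueError("no classified cells")
    counts = {int(r): int(c) for r, c in zip(*np.unique(idx, return_counts=True))}
    classes = classify_frequency(counts, thresholds)
    total = idx.size
    rows = [
        {
            "region_index": r,
            "count": counts.get(r, 0),
            "fraction": counts.get(r, 0) / total,
            "frequency_class": classes.get(r, RARE if 0 < thresholds.rare_max else INTERMEDIATE),
        }
        for r in range(N_REGIONS)
    ]
    # unobserved regions have fraction 0 -> rare by definition when rare_max > 0
    for row in rows:
        if row["count"] == 0:
            row["frequency_class"] = RARE if thresholds.rare_max > 0 else INTERMEDIATE
    return pd.DataFrame(rows)


def ternary_xy(rgb: Sequence[float] | np.ndarray) -> np.ndarray:
    """2-D ternary-plot coordinates for simplex points (R bottom-left,
    G bottom-right, B top)."""
    arr = np.atleast_2d(np.asarray(rgb, dtype=float))
    x = arr[:, 1] + 0.5 * arr[:, 2]
    y = (np.sqrt(3) / 2) * arr[:, 2]
    return np.column_stack([x, y])
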