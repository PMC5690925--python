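"""Primary fluence maps: aperture rasterization, composition, comparison.

A beam's integrated primary fluence at the isocenter plane is

    F(x, y) = sum_k  t_k * A_k(x, y)

where ``t_k`` is segment k's beam-on time in seconds and ``A_k`` its aperture
indicator (1 inside the MLC opening, 0 outside).  ``F`` is therefore the
open time of each point, in seconds.  Rasterization is area-weighted: a
pixel's value is the fraction of its area inside the aperture, so pixels
straddling a leaf tip or a leaf-row boundary get fractional coverage.  This
keeps the map's integral equal to sum_k t_k * open-area(k) and makes pass
rates insensitive to grid phase.

Plan and delivered maps are compared with an intensity-difference criterion:
pixels where the *planned* map exceeds ``low_cut`` (default 10%) of its
maximum are evaluated; an evaluated pixel passes when |delivered - planned|
is under ``pass_frac`` (default 2%) of that maximum.  The pass rate is the
percentage of evaluated pixels that pass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .datamodel import N_LEAF_PAIRS, FluenceMap, GridSpec, LeafPair, Segment

__all__ = [
    "FluenceStats",
    "rasterize_aperture",
    "compose_fluence",
    "fluence_compare",
    "aperture_open_area",
]


@dataclass(frozen=True)
class FluenceStats:
    """Difference statistics between a planned and a delivered fluence map.

    ``mean_diff``/``sd_diff`` are of the signed difference (delivered minus
    planned) over the evaluated pixels; ``max_diff`` is the largest absolute
    difference.  ``pass_rate`` is in percent, or ``None`` when no pixel was
    evaluated (degenerate all-closed plan beam).
    """

    mean_diff: float
    max_diff: float
    sd_diff: float
    pass_rate: Optional[float]
    n_evaluated: int

    def __post_init__(self) -> None:
        if self.n_evaluated < 0:
            raise ValueError("n_evaluated must be >= 0")
        if self.pass_rate is not None and not 0.0 <= self.pass_rate <= 100.0:
            raise ValueError("pass_rate must be in [0, 100]")


def _interval_overlap(edges: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Per-cell overlap fraction of interval [lo, hi] with the cells defined
    by ``edges`` (len n+1); returns an array of length n in [0, 1]."""
    left = edges[:-1]
    width = edges[1] - edges[0]
    overlap = np.minimum(edges[1:], hi) - np.maximum(left, lo)
    return np.clip(overlap / width, 0.0, 1.0)


def rasterize_aperture(
    leaf_pairs: Sequence[LeafPair], grid: GridSpec
) -> np.ndarray:
    """Area-weighted raster of an MLC aperture on the isocenter plane.

    Returns a (ny, nx) array of pixel coverage fractions in [0, 1]: 1 for a
    pixel fully inside the opening, 0 fully outside, fractional at leaf tips
    and leaf-row boundaries.  Row 0 is the pair-1 side (most negative y).

    Raises ``ValueError`` if the leaf pairs are not the full 30-pair stack or
    the grid does not cover the stack.
    """
    if len(leaf_pairs) != N_LEAF_PAIRS:
        raise ValueError(f"expected {N_LEAF_PAIRS} leaf pairs, got {len(leaf_pairs)}")
    stack_half = N_LEAF_PAIRS * grid.leaf_width / 2.0
    if grid.y_extent / 2.0 < stack_half - 1e-9:
        raise ValueError("grid does not cover the leaf stack in y")

    x_edges = grid.x_edges()
    y_edges = grid.y_edges()
    out = np.zeros((grid.ny, grid.nx))
    for pair in leaf_pairs:
        if pair.opening_cm <= 0.0:
            continue
        y_lo = -stack_half + (pair.pair_index - 1) * grid.leaf_width
        y_hi = y_lo + grid.leaf_width
        row_frac = _interval_overlap(y_edges, y_lo, y_hi)
        col_frac = _interval_overlap(x_edges, pair.left_x, pair.right_x)
        if not np.any(row_frac) or not np.any(col_frac):
            continue
        out += np.outer(row_frac, col_frac)
    # leaf rows are disjoint, but guard against float accumulation
    np.clip(out, 0.0, 1.0, out=out)
    return out


def aperture_open_area(leaf_pairs: Sequence[LeafPair], grid: GridSpec) -> float:
    """Analytic open area of an aperture (cm^2), clipped to the grid in x."""
    half_x = grid.x_extent / 2.0
    area = 0.0
    for pair in leaf_pairs:
        w = min(pair.right_x, half_x) - max(pair.left_x, -half_x)
        if w > 0:
            area += w * grid.leaf_width
    return area


def compose_fluence(segments: Sequence[Segment], grid: GridSpec) -> FluenceMap:
    """Compose a beam's integrated fluence map F = sum_k t_k * A_k, seconds."""
    if not segments:
        raise ValueError("cannot compose fluence from an empty segment list")
    values = np.zeros((grid.ny, grid.nx))
    for seg in segments:
        if seg.beam_on_time == 0.0:
            continue
        values += seg.beam_on_time * rasterize_aperture(seg.leaf_pairs, grid)
    return FluenceMap(values=values, grid=grid)


def fluence_compare(
    plan_map: FluenceMap,
    delivered_map: FluenceMap,
    low_cut: float = 0.10,
    pass_frac: float = 0.02,
) -> FluenceStats:
    """Compare a delivered fluence map against the planned one.

    Evaluated pixels are those where the planned map is strictly greater
    than ``low_cut`` times its maximum; an evaluated pixel passes when the
    absolute difference is strictly less than ``pass_frac`` times that
    maximum.  Statistics are of (delivered - planned) over the evaluated set.

    Raises ``ValueError`` on mismatched grids.  With an all-zero planned map
    nothing is evaluated and ``pass_rate`` is ``None``.
    """
    if plan_map.grid != delivered_map.grid:
        raise ValueError("fluence maps must share one grid")
    p = plan_map.values
    d = delivered_map.values
    peak = float(p.max(initial=0.0))
    evaluated = p > low_cut * peak if peak > 0 else np.zeros(p.shape, dtype=bool)
    n_eval = int(evaluated.sum())
    if n_eval == 0:
        return FluenceStats(0.0, 0.0, 0.0, None, 0)
    diff = (d - p)[evaluated]
    passed = int(np.count_nonzero(np.abs(diff) < pass_frac * peak))
    return FluenceStats(
        mean_diff=float(diff.mean()),
        max_diff=float(np.abs(diff).max()),
        sd_diff=float(diff.std()),
        pass_rate=100.0 * passed / n_eval,
        n_evaluated=n_eval,
    )
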