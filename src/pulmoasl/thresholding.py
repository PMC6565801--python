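"""Intensity thresholding of ASL voxel grids and optimal-threshold search.

Conduit arteries and veins passing through a slice carry blood destined
elsewhere; their voxels show the highest ASL intensities.  Removing voxels
whose total signal exceeds x% of the full-voxel reference suppresses that
contamination at some cost in genuine perfusion signal.  The cost function

    C(x) = [1 - Q_fraction(x)] + [1 - Q_remain(x)] + [1 - C_removed(x)]
           + dCOV(x) + dgrad(x)

balances five unitless terms: the perfusion fraction of the retained
signal, the fraction of perfusion signal retained, the fraction of conduit
signal removed, and the fractional mismatches of the coefficient of
variation and of the gravitational gradient between the thresholded ASL
image and the underlying (unfiltered) capillary perfusion.  The optimal
threshold is the argmin of C over a descending sweep 100%, 95%, ..., 5%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .asl import VoxelGrid

log = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = tuple(range(100, 0, -5))


@dataclass
class ThresholdSweepResult:
    """Per-threshold metric table plus the cost argmin."""

    table: pd.DataFrame
    optimal_x: float
    tie_break_note: str = ""


def apply_threshold(grid: VoxelGrid, x_pct: float) -> VoxelGrid:
    """Remove voxels whose TOTAL signal strictly exceeds (x/100) * S_full.

    All components of a removed voxel are dropped together; voxels exactly
    at the boundary are retained.  Returns a new grid whose ``retained``
    mask reflects the filter and whose component arrays are zeroed outside
    it; the input grid is untouched.
    """
    if not (0 < x_pct <= 100):
        raise ValueError("threshold percentage must lie in (0, 100]")
    out = grid.copy()
    cut = (x_pct / 100.0) * grid.s_full
    keep = out.retained & ~(out.total > cut)
    for name in ("capillary", "arterial", "venous", "volume"):
        arr = getattr(out, name)
        arr[~keep] = 0.0
    out.retained = keep
    return out


def perfusion_metrics(
    filtered: VoxelGrid,
    unfiltered: VoxelGrid,
    literal_c_removed: bool = False,
) -> tuple[float, float, float]:
    """(Q_fraction, Q_remain, C_removed) of a filtered grid.

    Q_fraction: capillary / total signal in the filtered grid.
    Q_remain:   capillary(filtered) / capillary(unfiltered).
    C_removed:  1 - conduit(filtered) / conduit(unfiltered), where conduit
                is arterial + venous.  With ``literal_c_removed`` the raw
                after/prior ratio is returned instead (the variable then
                measures conduit signal remaining).

    Zero-denominator conventions: no conduit signal at all means the filter
    vacuously removed everything (C_removed = 1); no perfusion signal means
    nothing could be lost (Q_remain = 1); an empty filtered grid has
    Q_fraction = 0.
    """
    if filtered.capillary.shape != unfiltered.capillary.shape:
        raise ValueError("filtered and unfiltered grids must share geometry")
    cap_f = float(filtered.capillary[filtered.retained].sum())
    tot_f = float(filtered.total[filtered.retained].sum())
    cap_u = float(unfiltered.capillary[unfiltered.retained].sum())
    con_f = float(
        (filtered.arterial + filtered.venous)[filtered.retained].sum()
    )
    con_u = float(
        (unfiltered.arterial + unfiltered.venous)[unfiltered.retained].sum()
    )
    q_fraction = cap_f / tot_f if tot_f != 0 else 0.0
    q_remain = cap_f / cap_u if cap_u != 0 else 1.0
    if con_u != 0:
        remaining = con_f / con_u
    else:
        log.warning("no conduit signal in the unfiltered grid; C_removed = 1")
        remaining = 0.0
    c_removed = remaining if literal_c_removed else 1.0 - remaining
    return q_fraction, q_remain, c_removed


def cov(grid: VoxelGrid, component: str = "total") -> float:
    """Coefficient of variation (population SD / mean) over retained voxels."""
    arr = grid.total if component == "total" else getattr(grid, component)
    vals = arr[grid.retained]
    if vals.size < 2:
        raise ValueError("COV needs at least 2 retained voxels")
    mean = float(vals.mean())
    if mean == 0:
        raise ValueError("COV undefined: mean of retained voxels is zero")
    return float(vals.std(ddof=0) / mean)


def gravitational_gradient(
    grid: VoxelGrid,
    up_sign: int = 1,
    component: str = "total",
    n_bins: int = 10,
) -> float:
    """OLS slope of binned mean voxel value against gravitational height.

    Retained voxels are binned into ``n_bins`` equal intervals of height
    over the slice's lung extent; height is the in-plane dorsoventral (y)
    coordinate in cm, oriented so it increases toward the non-dependent
    side (``up_sign=+1`` for supine, where up is ventral; ``-1`` for
    prone).  A negative gradient therefore means flow decreasing away from
    the dependent region.  Raises if fewer than 2 bins are non-empty.
    """
    arr = grid.total if component == "total" else getattr(grid, component)
    yc, _ = grid.voxel_centers()
    ny, nz = arr.shape
    heights = np.broadcast_to((up_sign * yc)[:, None] * 0.1, (ny, nz))  # mm->cm
    h = heights[grid.retained]
    v = arr[grid.retained]
    if h.size < 2 or np.ptp(h) == 0:
        raise ValueError("gradient undefined: fewer than 2 distinct heights")
    edges = np.linspace(h.min(), h.max(), n_bins + 1)
    idx = np.clip(np.digitize(h, edges) - 1, 0, n_bins - 1)
    centers, means = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            # abscissa is the members' mean height (not the nominal bin
            # center) so an exactly linear field is recovered exactly
            centers.append(h[sel].mean())
            means.append(v[sel].mean())
    if len(centers) < 2:
        raise ValueError("gradient undefined: fewer than 2 non-empty bins")
    slope = np.polyfit(np.asarray(centers), np.asarray(means), 1)[0]
    return float(slope)


def cost(
    q_fraction: float,
    q_remain: float,
    c_removed: float,
    cov_asl: float | None,
    cov_q: float | None,
    grad_asl: float | None,
    grad_q: float | None,
) -> tuple[float, float, float]:
    """Five-term cost C(x); returns (cost, dCOV, dgrad).

    dCOV = |COV_ASL - COV_Q| / COV_Q and dgrad = |grad_ASL - grad_Q| /
    |grad_Q| are fractional absolute differences so all five terms share a
    unitless scale.  A zero (or unavailable) reference drops the term with
    a logged warning.
    """
    d_cov = 0.0
    if cov_q is None or cov_q == 0 or cov_asl is None:
        log.warning("COV reference unavailable; dCOV term dropped")
    else:
        d_cov = abs(cov_asl - cov_q) / cov_q
    d_grad = 0.0
    if grad_q is None or grad_q == 0 or grad_asl is None:
        log.warning("gradient reference unavailable; dgrad term dropped")
    else:
        d_grad = abs(grad_asl - grad_q) / abs(grad_q)
    c = (1.0 - q_fraction) + (1.0 - q_remain) + (1.0 - c_removed) + d_cov + d_grad
    return c, d_cov, d_grad


def threshold_sweep(
    grid: VoxelGrid,
    thresholds=DEFAULT_THRESHOLDS,
    up_sign: int = 1,
    n_bins: int = 10,
    literal_c_removed: bool = False,
) -> ThresholdSweepResult:
    """Run the descending threshold sweep and locate the cost minimum.

    The reference statistics COV_Q and grad_Q are computed once from the
    UNFILTERED capillary component.  Ties in the cost argmin are broken
    toward the larger x (least filtering); the full per-x table is kept so
    flat minima can be diagnosed.
    """
    xs = list(thresholds)
    if any(x2 >= x1 for x1, x2 in zip(xs, xs[1:])):
        raise ValueError("thresholds must be strictly descending")
    if not all(5 <= x <= 100 for x in xs):
        raise ValueError("thresholds must lie in [5, 100]")

    try:
        cov_q = cov(grid, component="capillary")
    except ValueError:
        cov_q = None
    try:
        grad_q = gravitational_gradient(grid, up_sign, "capillary", n_bins)
    except ValueError:
        grad_q = None

    rows = []
    for x in xs:
        filt = apply_threshold(grid, x)
        q_frac, q_rem, c_rem = perfusion_metrics(filt, grid, literal_c_removed)
        try:
            cov_asl = cov(filt)
        except ValueError:
            cov_asl = None
        try:
            grad_asl = gravitational_gradient(filt, up_sign, "total", n_bins)
        except ValueError:
            grad_asl = None
        c, d_cov, d_grad = cost(q_frac, q_rem, c_rem, cov_asl, cov_q,
                                grad_asl, grad_q)
        rows.append(
            {
                "x_pct": x,
                "Q_fraction": q_frac,
                "Q_remain": q_rem,
                "C_removed": c_rem,
                "COV_ASL": cov_asl,
                "COV_Q": cov_q,
                "grad_ASL": grad_asl,
                "grad_Q": grad_q,
                "dCOV": d_cov,
                "dgrad": d_grad,
                "cost": c,
            }
        )
    table = pd.DataFrame(rows)
    costs = table["cost"].to_numpy()
    best = int(np.argmin(costs))  # first occurrence = largest x (descending)
    note = ""
    if int((costs == costs[best]).sum()) > 1:
        note = "tie broken toward larger x (least filtering)"
    return ThresholdSweepResult(table=table, optimal_x=float(xs[best]),
                                tie_break_note=note)


def optimal_threshold(sweep: ThresholdSweepResult | pd.DataFrame) -> float:
    """Argmin of the cost over the sweep grid, ties toward larger x."""
    table = sweep.table if isinstance(sweep, ThresholdSweepResult) else sweep
    if table.empty:
        raise ValueError("empty sweep")
    order = table.sort_values("x_pct", ascending=False)
    costs = order["cost"].to_numpy()
    return float(order["x_pct"].to_numpy()[int(np.argmin(costs))])
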