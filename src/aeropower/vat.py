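"""Ventilatory anaerobic threshold (VAT) detection by the V-slope method.

The V-slope method locates the breakpoint of the VCO2-vs-VO2 relation: below
the threshold CO2 output tracks O2 uptake with a shallow slope; above it,
buffering of lactic acid adds non-metabolic CO2 and the slope steepens.  The
breakpoint is found by an exhaustive two-segment least-squares search over
candidate split points of the VO2-sorted breath cloud.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError
from .recording import CpetRecording

__all__ = ["VatPoint", "detect_vat_vslope", "two_segment_fit"]

#: Minimum breaths per segment in the exhaustive breakpoint search.
MIN_SEGMENT = 5


@dataclass
class VatPoint:
    """Result of a V-slope fit on one recording.

    ``slope_below`` / ``slope_above`` are the OLS slopes of the lower and
    upper segments ("Slope A" / "Slope B").  ``reliable`` is False when the
    two-segment fit improves the single-line SSE by less than the configured
    fraction, when the upper slope is not steeper than the lower, or when the
    search is otherwise degenerate.
    """

    breath_index: int
    vo2_at_vat: float
    vco2_at_vat: float
    time_at_vat: float
    ve_at_vat: float
    rf_at_vat: float
    rr_at_vat: float
    slope_below: float
    slope_above: float
    sse: float
    sse_single: float
    reliable: bool


def _segment_stats(x: np.ndarray, y: np.ndarray):
    """Cumulative sufficient statistics for OLS of y on x over every prefix."""
    n = np.arange(1, len(x) + 1, dtype=float)
    sx = np.cumsum(x)
    sy = np.cumsum(y)
    sxx = np.cumsum(x * x)
    sxy = np.cumsum(x * y)
    syy = np.cumsum(y * y)
    return n, sx, sy, sxx, sxy, syy


def _sse_from_stats(n, sx, sy, sxx, sxy, syy):
    """SSE of per-segment simple OLS given raw-moment sums (vectorized)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        cxx = sxx - sx * sx / n
        cxy = sxy - sx * sy / n
        cyy = syy - sy * sy / n
        sse = cyy - np.where(cxx > 1e-12, cxy * cxy / np.where(cxx > 1e-12, cxx, 1.0), 0.0)
    return np.maximum(sse, 0.0)


def two_segment_fit(x: np.ndarray, y: np.ndarray, min_segment: int = MIN_SEGMENT):
    """Exhaustive two-segment least-squares breakpoint search.

    ``x`` must be sorted ascending.  The data are split into ``x[:s]`` and
    ``x[s:]`` for every admissible ``s`` (at least ``min_segment`` points per
    segment); each segment gets its own OLS line and the split minimizing the
    total SSE wins.  Ties go to the smallest split index.

    Returns
    -------
    (s, sse_two, sse_one, slope_lo, slope_hi)
        Split index (first point of the upper segment), two-segment SSE,
        single-line SSE, and the two segment slopes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 2 * min_segment:
        raise InsufficientDataError(
            f"need at least {2 * min_segment} points for a two-segment fit, got {n}"
        )
    # prefix stats (forward) and suffix stats (reverse)
    fn, fsx, fsy, fsxx, fsxy, fsyy = _segment_stats(x, y)
    rn, rsx, rsy, rsxx, rsxy, rsyy = _segment_stats(x[::-1], y[::-1])

    sse_one = float(_sse_from_stats(fn[-1], fsx[-1], fsy[-1], fsxx[-1], fsxy[-1], fsyy[-1]))

    # split s means lower = [0, s), upper = [s, n)
    splits = np.arange(min_segment, n - min_segment + 1)
    lo = _sse_from_stats(fn[splits - 1], fsx[splits - 1], fsy[splits - 1],
                         fsxx[splits - 1], fsxy[splits - 1], fsyy[splits - 1])
    up_idx = n - splits - 1  # index into reversed prefix stats
    hi = _sse_from_stats(rn[up_idx], rsx[up_idx], rsy[up_idx],
                         rsxx[up_idx], rsxy[up_idx], rsyy[up_idx])
    total = lo + hi
    best = int(np.argmin(total))
    s = int(splits[best])
    sse_two = float(total[best])

    def _slope(xs, ys):
        xc = xs - xs.mean()
        den = float(xc @ xc)
        if den <= 1e-12:
            return 0.0
        return float(xc @ (ys - ys.mean()) / den)

    slope_lo = _slope(x[:s], y[:s])
    slope_hi = _slope(x[s:], y[s:])
    return s, sse_two, sse_one, slope_lo, slope_hi


def detect_vat_vslope(
    recording: CpetRecording,
    *,
    min_breaths: int = 20,
    min_segment: int = MIN_SEGMENT,
    min_improvement: float = 0.05,
) -> VatPoint:
    """Locate the VAT of a recording via the V-slope breakpoint.

    Breaths of the incremental phase are sorted by VO2; VCO2 is regressed on
    VO2 with an exhaustive two-segment search.  The fit is flagged
    ``reliable=False`` when the two-segment SSE improves on the single-line
    SSE by less than ``min_improvement`` (relative), or when the upper slope
    is not at least as steep as the lower one.

    Raises
    ------
    InsufficientDataError
        Fewer than ``min_breaths`` incremental breaths, or a degenerate VO2
        span.
    """
    inc = recording.incremental()
    if len(inc) < min_breaths:
        raise InsufficientDataError(
            f"need at least {min_breaths} incremental breaths, got {len(inc)}"
        )
    vo2 = inc["vo2_ml_min"].to_numpy(dtype=float)
    if np.ptp(vo2) <= 1e-9:
        raise InsufficientDataError("VO2 span is degenerate; cannot fit V-slope")
    order = np.argsort(vo2, kind="stable")
    x = vo2[order]
    y = inc["vco2_ml_min"].to_numpy(dtype=float)[order]

    s, sse_two, sse_one, slope_lo, slope_hi = two_segment_fit(x, y, min_segment)

    if sse_one <= 1e-12:
        improvement = 0.0  # already a perfect single line: no breakpoint exists
    else:
        improvement = 1.0 - sse_two / sse_one
    reliable = improvement >= min_improvement and slope_hi >= slope_lo

    brk = order[s]  # position within incremental frame
    rr = recording.respiratory_rate()
    inc_rr = rr[recording.breaths["t_s"] >= recording.warmup_s].reset_index(drop=True)
    row = inc.iloc[brk]
    return VatPoint(
        breath_index=int(brk),
        vo2_at_vat=float(x[s]),
        vco2_at_vat=float(row["vco2_ml_min"]),
        time_at_vat=float(row["t_s"]),
        ve_at_vat=float(row["ve_l_min"]),
        rf_at_vat=float(row["rf_per_min"]),
        rr_at_vat=float(inc_rr.iloc[brk]),
        slope_below=float(slope_lo),
        slope_above=float(slope_hi),
        sse=sse_two,
        sse_single=sse_one,
        reliable=bool(reliable),
    )
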