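"""Independent brute-force oracles for exposure detection.

These implementations deliberately share no code with the package: they
enumerate every candidate window (vectorized with numpy for speed) and keep
exactly the windows that are fully qualifying, maximal, and long enough.
"""

from __future__ import annotations

import datetime as dt
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

ONE_DAY = dt.timedelta(days=1)


def _continuous_span(
    observations: Dict[dt.date, Optional[float]],
) -> Tuple[List[dt.date], np.ndarray]:
    days = sorted(observations)
    start, end = days[0], days[-1]
    n = (end - start).days + 1
    span = [start + dt.timedelta(days=i) for i in range(n)]
    values = np.full(n, np.nan)
    for day, value in observations.items():
        if value is not None:
            values[(day - start).days] = value
    return span, values


def _maximal_windows(qual: np.ndarray, min_len: int) -> List[Tuple[int, int]]:
    """All (i, j) index windows that are entirely qualifying, maximal in
    both directions, and of length >= min_len — checked exhaustively."""
    n = len(qual)
    if n == 0:
        return []
    cs = np.concatenate([[0], np.cumsum(qual)])
    i, j = np.triu_indices(n)
    length = j - i + 1
    full = (cs[j + 1] - cs[i]) == length
    left_ok = (i == 0) | ~qual[np.maximum(i - 1, 0)]
    right_ok = (j == n - 1) | ~qual[np.minimum(j + 1, n - 1)]
    keep = full & left_ok & right_ok & (length >= min_len)
    return sorted(zip(i[keep].tolist(), j[keep].tolist()))


def oracle_heat_events(
    observations: Dict[dt.date, Optional[float]],
    threshold: float = 95.0,
    min_run: int = 3,
    season: Tuple[Tuple[int, int], Tuple[int, int]] = ((5, 1), (9, 30)),
) -> List[Tuple[dt.date, dt.date, float]]:
    """Qualifying events as (start, end, peak) from an exhaustive window
    scan.  ``observations`` maps date -> tmax (None/absent = missing)."""
    if not observations:
        return []
    span, tmax = _continuous_span(observations)
    in_season = np.array(
        [season[0] <= (d.month, d.day) <= season[1] for d in span]
    )
    qual = np.where(np.isnan(tmax), False, tmax >= threshold) & in_season
    return [
        (span[a], span[b], float(np.nanmax(tmax[a : b + 1])))
        for a, b in _maximal_windows(qual, min_run)
    ]


def oracle_drought_spells(
    weeks: Sequence[Tuple[dt.date, int]], min_severity: int = 2
) -> List[Tuple[dt.date, dt.date, int]]:
    """Maximal week-runs at/above ``min_severity`` (categories as ints,
    NONE = -1) via an exhaustive scan over contiguous weekly grids."""
    if not weeks:
        return []
    starts = [w for w, _ in weeks]
    # split into contiguous 7-day blocks, scan each exhaustively
    blocks: List[List[Tuple[dt.date, int]]] = [[weeks[0]]]
    for prev, cur in zip(weeks, weeks[1:]):
        if cur[0] - prev[0] == dt.timedelta(days=7):
            blocks[-1].append(cur)
        else:
            blocks.append([cur])
    out: List[Tuple[dt.date, dt.date, int]] = []
    for block in blocks:
        cats = np.array([c for _, c in block])
        qual = cats >= min_severity
        for a, b in _maximal_windows(qual, 1):
            out.append((block[a][0], block[b][0], int(cats[a : b + 1].max())))
    return sorted(out)


def oracle_overlap_days(
    events: Sequence[Tuple[dt.date, dt.date]],
    period_days: set,
    policy: str = "full_containment",
) -> int:
    """Day-by-day overlap count."""
    covered = set()
    for start, end in events:
        days = {start + dt.timedelta(days=k) for k in range((end - start).days + 1)}
        if policy == "full_containment":
            if days <= period_days:
                covered |= days
        else:
            covered |= days & period_days
    return len(covered)


def oracle_heavy_precip_days(
    observations: Dict[dt.date, Optional[float]], threshold: float, year: int
) -> int:
    return sum(
        1
        for day, p in observations.items()
        if p is not None and day.year == year and p > threshold
    )
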