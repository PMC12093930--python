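"""Measurement suite: miss rates, workload capacity, behaviour metrics.

The quantities here summarise dyadic paddle-game performance:

miss rate
    ``1 - hits / (hits + misses)`` for a processing unit (a player, an
    agent, or a team) in one cell (condition x workload).

balls maintained at 40%
    the real-valued number of concurrent balls at which a unit's
    interpolated miss-rate-vs-workload curve crosses a 40% criterion —
    a workload-normalised performance index in the psychophysical
    threshold tradition.  The curve is the unique cubic interpolating
    the four (workload, miss rate) points.

workload capacity coefficient C(p)
    ``C(p) = p(A) * p(B) - p(AB)``, where p(A), p(B) are the members'
    solo miss rates from the separate condition and p(AB) the team miss
    rate in a collaborative or competitive condition at the same
    workload.  The product p(A)p(B) is the miss rate an
    unlimited-capacity independent parallel (UCIP) team would produce
    (both members process every ball independently; the team misses
    only when both do).  C < 0 is limited capacity (a cost of
    teamwork), C = 0 unlimited, C > 0 supercapacity.

behavioural patterns
    *momentary distance* — mean absolute horizontal paddle separation
    per frame; *highly correlated segments* (HCS) — the proportion of
    trial time inside any sliding window where the Pearson correlation
    of the two paddles' frame-to-frame movements exceeds a threshold
    (0.97).

An exclusion filter removes dyads whose human members failed the
secondary-task (DRT) accuracy or baseline miss-rate criteria.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class UndefinedCellError(ValueError):
    """A metric cell has an empty denominator (no terminated balls)."""


# ---------------------------------------------------------------------------
# miss rate and capacity coefficient
# ---------------------------------------------------------------------------

def miss_rate(hits: float, misses: float) -> float:
    """Complement of the hit rate, ``1 - hits / (hits + misses)``.

    Fractional hit counts are allowed (simultaneous hits are split).
    Raises :class:`UndefinedCellError` when the denominator is empty so
    callers can exclude (not zero-fill) the cell.
    """
    if hits < 0 or misses < 0:
        raise ValueError("hit and miss counts must be >= 0")
    total = hits + misses
    if total == 0:
        raise UndefinedCellError("no terminated balls in cell")
    return 1.0 - hits / total


CAPACITY_ZERO_BAND = 0.01  # |C| <= band reported as "unlimited"


@dataclass(frozen=True)
class CapacityResult:
    """C(p) for one dyad cell, with its inputs and classification."""

    pA: float
    pB: float
    pAB: float
    C: float
    classification: str  # limited | unlimited | super
    dyad_id: str | None = None
    condition: str | None = None
    workload: object = None


def capacity_coefficient(pA: float, pB: float, pAB: float,
                         zero_band: float = CAPACITY_ZERO_BAND,
                         **labels) -> CapacityResult:
    """Workload capacity coefficient ``C(p) = pA * pB - pAB``.

    ``pA``/``pB`` are individual miss rates from the separate condition
    and ``pAB`` the team miss rate in a team condition.  ``zero_band``
    only affects the categorical label ("unlimited" for |C| within the
    band); the signed value is returned exactly.
    """
    for name, p in (("pA", pA), ("pB", pB), ("pAB", pAB)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {p}")
    c = pA * pB - pAB
    if abs(c) <= zero_band:
        cls = "unlimited"
    else:
        cls = "limited" if c < 0 else "super"
    return CapacityResult(pA=pA, pB=pB, pAB=pAB, C=c, classification=cls,
                          **labels)


# ---------------------------------------------------------------------------
# balls maintained at the 40% criterion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BallsMaintained:
    """Workload (ball count) at which the miss-rate curve crosses 40%."""

    n_balls_at_criterion: float
    criterion: float
    fit_points: tuple
    crossing_valid: bool  # False -> linear-fit fallback was used
    unit_id: str | None = None
    condition: str | None = None


def balls_maintained(points, criterion: float = 0.40, **labels) -> BallsMaintained:
    """Interpolated workload at which a unit's miss rate reaches ``criterion``.

    ``points`` are four (ball_count, miss_rate) pairs, one per workload
    level.  The unique degree-3 polynomial through them is intersected
    with the criterion; the smallest root inside [min count, max count]
    is returned (the first attainment of the criterion as load rises).
    When no interior crossing exists the root of a least-squares linear
    fit is reported instead, flagged with ``crossing_valid=False``.
    """
    pts = sorted((float(w), float(r)) for w, r in points)
    if len(pts) != 4:
        raise ValueError("exactly four (workload, miss_rate) points required")
    w = np.array([p[0] for p in pts])
    r = np.array([p[1] for p in pts])
    if len(np.unique(w)) != 4:
        raise ValueError("workload counts must be distinct")
    if ((r < 0) | (r > 1)).any():
        raise ValueError("miss rates must lie in [0, 1]")
    # unique cubic interpolant through the four points
    coeffs = np.polynomial.polynomial.polyfit(w, r, 3)
    shifted = coeffs.copy()
    shifted[0] -= criterion
    if np.allclose(shifted, 0.0, atol=1e-12):
        # flat profile exactly at the criterion: first attainment is the
        # lowest workload measured
        return BallsMaintained(float(w[0]), criterion, tuple(pts), True,
                               **labels)
    roots = np.polynomial.polynomial.polyroots(shifted)
    # collinear inputs make the cubic degenerate: huge or slightly complex
    # spurious roots appear; keep roots that are real relative to their size
    real = np.sort(roots[np.abs(roots.imag)
                         <= 1e-8 * np.maximum(1.0, np.abs(roots.real))].real)
    eps = 1e-9
    interior = real[(real >= w[0] - eps) & (real <= w[-1] + eps)]
    if interior.size:
        x = float(np.clip(interior[0], w[0], w[-1]))
        return BallsMaintained(x, criterion, tuple(pts), True, **labels)
    slope, intercept = np.polyfit(w, r, 1)
    if slope == 0:
        raise UndefinedCellError("flat miss-rate profile never crosses criterion")
    x = float((criterion - intercept) / slope)
    return BallsMaintained(x, criterion, tuple(pts), False, **labels)


def ucip_balls_benchmark(nA: float, nB: float) -> float:
    """Predicted team balls-maintained with no efficiency loss: nA + nB."""
    if nA < 0 or nB < 0:
        raise ValueError("ball counts must be >= 0")
    return nA + nB


# ---------------------------------------------------------------------------
# behavioural patterns
# ---------------------------------------------------------------------------

def momentary_distance(xA, xB) -> float:
    """Mean absolute horizontal distance between paddles across frames."""
    a = np.asarray(xA, dtype=float)
    b = np.asarray(xB, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("position traces must be equal-length 1-D arrays")
    if a.size == 0:
        raise ValueError("position traces must be non-empty")
    return float(np.mean(np.abs(a - b)))


def hcs_proportion(xA, xB, window_s: float = 1.0, threshold: float = 0.97,
                   tick_rate: int = 60) -> float:
    """Proportion of trial time spent in highly correlated movement.

    A window of ``window_s`` slides over the two paddle traces with a
    one-frame stride; within each window the Pearson correlation of the
    *first-differenced* positions (movement, not position, so shared
    drift does not inflate the correlation) is computed at lag 0.  A
    frame counts as highly correlated if it lies in any window whose
    correlation exceeds ``threshold``; windows where either paddle does
    not move (zero variance) never qualify.  Returns highly correlated
    frames / total frames.
    """
    a = np.asarray(xA, dtype=float)
    b = np.asarray(xB, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("position traces must be equal-length 1-D arrays")
    n = a.size
    win = int(round(window_s * tick_rate))
    if win < 2 or n < win + 1:
        raise UndefinedCellError("trace shorter than one correlation window")
    da = np.diff(a)
    db = np.diff(b)
    m = win  # diffs per window; window i covers frames [i, i + win]
    n_win = da.size - m + 1
    # sliding Pearson correlation via cumulative sums
    c = np.concatenate
    csa, csb = c(([0.0], np.cumsum(da))), c(([0.0], np.cumsum(db)))
    csa2, csb2 = c(([0.0], np.cumsum(da * da))), c(([0.0], np.cumsum(db * db)))
    csab = c(([0.0], np.cumsum(da * db)))
    sa = csa[m:] - csa[:-m]
    sb = csb[m:] - csb[:-m]
    sa2 = csa2[m:] - csa2[:-m]
    sb2 = csb2[m:] - csb2[:-m]
    sab = csab[m:] - csab[:-m]
    var_a = sa2 - sa * sa / m
    var_b = sb2 - sb * sb / m
    cov = sab - sa * sb / m
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = cov / np.sqrt(var_a * var_b)
    good = (var_a > 1e-12) & (var_b > 1e-12) & (corr > threshold)
    covered = np.zeros(n + 1)
    idx = np.flatnonzero(good)
    np.add.at(covered, idx, 1.0)
    np.add.at(covered, np.minimum(idx + m + 1, n), -1.0)
    frames_hot = np.count_nonzero(np.cumsum(covered[:-1]) > 0)
    return frames_hot / n


@dataclass(frozen=True)
class BehaviorMetrics:
    trial_id: str
    momentary_distance: float
    hcs_proportion: float


def behavior_metrics(log, window_s: float = 1.0, threshold: float = 0.97,
                     tick_rate: int | None = None) -> BehaviorMetrics:
    """Momentary distance and HCS proportion of one dyadic trial log."""
    if log.xA is None or log.xB is None:
        raise ValueError("trial log lacks paddle traces for both players")
    tick = tick_rate if tick_rate is not None else int(round(log.n_frames / 45.0))
    return BehaviorMetrics(
        trial_id=log.trial_id,
        momentary_distance=momentary_distance(log.xA, log.xB),
        hcs_proportion=hcs_proportion(log.xA, log.xB, window_s, threshold, tick))


# ---------------------------------------------------------------------------
# exclusion filter
# ---------------------------------------------------------------------------

DRT_ACCURACY_MIN = 0.5   # excluded if accuracy < 0.5 (strictly less)
BASELINE_MISS_MAX = 0.5  # excluded if low-workload separate miss > 0.5


@dataclass
class ExclusionReport:
    retained: list
    excluded: dict = field(default_factory=dict)  # dyad_id -> list of reasons


def exclusion_filter(summaries) -> ExclusionReport:
    """Apply the participant-quality exclusion rules to dyad summaries.

    ``summaries`` is an iterable of dicts with keys ``dyad_id`` and
    ``humans`` — a mapping of human player ids to
    ``{"drt_accuracy": float, "low_separate_missrate": float}``
    (machine members are simply absent and never trigger exclusion).
    A dyad is retained iff every human member has DRT accuracy >= 0.5
    and a low-workload separate-condition miss rate <= 0.5; the
    inequalities are strict in the exclusion direction, so a member
    exactly at 0.5/0.5 is retained.  Dyads with missing cells are
    excluded with a distinct ``unevaluable`` code.
    """
    report = ExclusionReport(retained=[])
    for s in summaries:
        dyad = s["dyad_id"]
        reasons = []
        for player, cells in s.get("humans", {}).items():
            acc = cells.get("drt_accuracy")
            mr = cells.get("low_separate_missrate")
            if acc is None or mr is None:
                reasons.append(f"{player}: unevaluable (missing low-workload "
                               "separate cell or DRT accuracy)")
                continue
            if acc < DRT_ACCURACY_MIN:
                reasons.append(f"{player}: DRT accuracy {acc:.3f} < 0.5")
            if mr > BASELINE_MISS_MAX:
                reasons.append(f"{player}: low-workload separate miss rate "
                               f"{mr:.3f} > 0.5")
        if reasons:
            report.excluded[dyad] = reasons
        else:
            report.retained.append(dyad)
    return report


# ---------------------------------------------------------------------------
# per-dyad metric extraction from session records
# ---------------------------------------------------------------------------

def _pooled_rates(trials, unit: str):
    hits = sum(t.hits[unit] for t in trials)
    misses = sum(t.misses[unit] for t in trials)
    return miss_rate(hits, misses)


def dyad_miss_table(record) -> pd.DataFrame:
    """Tidy per-unit miss rates for one dyad session.

    One row per (unit, condition, workload): units are the individual
    players in the separate condition and the team in collaborative /
    competitive conditions, with hit/miss counts pooled over the three
    repeats of each workload.
    """
    rows = []
    for condition in set(t.condition for t in record.trials):
        workloads = sorted({t.workload for t in record.trials
                            if t.condition == condition},
                           key=lambda w: _workload_rank(w))
        for wl in workloads:
            cell = [t for t in record.trials
                    if t.condition == condition and t.workload == wl]
            units = ("A", "B") if condition == "separate" else ("team",)
            for unit in units:
                hits = sum(t.hits[unit] for t in cell)
                misses = sum(t.misses[unit] for t in cell)
                try:
                    rate = miss_rate(hits, misses)
                except UndefinedCellError:
                    rate = np.nan
                rows.append({"dyad_id": record.dyad_id,
                             "team_type": record.team_type,
                             "condition": condition, "workload": wl,
                             "unit": unit, "hits": hits, "misses": misses,
                             "miss_rate": rate})
    return pd.DataFrame(rows)


def _workload_rank(wl):
    from .simulator import WORKLOAD_NAMES
    return (WORKLOAD_NAMES.index(wl) if isinstance(wl, str)
            and wl in WORKLOAD_NAMES else float(wl))


def dyad_capacity_table(record, config=None) -> pd.DataFrame:
    """C(p) per (team condition, workload) for one dyad session.

    Solo miss rates p(A) and p(B) are pooled per workload across the
    separate-condition repeats; p(AB) is the pooled team miss rate in
    each team condition at the same workload.
    """
    miss = dyad_miss_table(record)
    sep = miss[miss.condition == "separate"].set_index(["unit", "workload"])
    rows = []
    for condition in ("collaborative", "competitive"):
        team = miss[(miss.condition == condition) & (miss.unit == "team")]
        for _, row in team.iterrows():
            wl = row.workload
            try:
                pA = float(sep.loc[("A", wl), "miss_rate"])
                pB = float(sep.loc[("B", wl), "miss_rate"])
            except KeyError:
                continue
            if np.isnan(pA) or np.isnan(pB) or np.isnan(row.miss_rate):
                continue
            res = capacity_coefficient(pA, pB, float(row.miss_rate))
            rows.append({"dyad_id": record.dyad_id,
                         "team_type": record.team_type,
                         "condition": condition, "workload": wl,
                         "pA": pA, "pB": pB, "pAB": res.pAB, "C": res.C,
                         "classification": res.classification})
    return pd.DataFrame(rows)
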