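"""Per-step propulsion peak and impulse, aggregation, and exclusion rules.

Within one stance phase the AP-GRF traces two lobes: a negative braking
lobe in early stance and a positive propulsive lobe in late stance.  The
propulsion *peak* is the maximum of the propulsive portion; the propulsion
window runs from the zero-crossing before the peak to the zero-crossing
after it, extended forward over any interior negative dip that separates
two positive lobes (the dip's area then *subtracts* from the impulse),
but never over a trailing negative lobe after the last positive lobe
(that is unrelated to propulsion and ignored).  The propulsion *impulse*
is the signed trapezoidal integral over the window.  Both metrics are
normalized by body mass (N/kg and N/kg.s).

Aggregation: metrics are averaged over all valid stance phases per
gait-speed condition per participant.  A condition needs at least 23
valid steps per leg to be reliable; a participant is excluded outright
when two or more conditions fail that rule, otherwise only the offending
conditions are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ParameterError

#: minimum number of valid steps per leg for a reliable condition estimate
MIN_STEPS_PER_LEG = 23
#: participant is excluded when this many conditions fail the step rule
MAX_FAILING_CONDITIONS = 2


@dataclass
class PropulsionWindow:
    """Half-open sample window ``[start_index, end_index)`` around the peak."""

    start_index: int
    end_index: int
    peak_index: int
    bridged_dips: int = 0

    def __post_init__(self) -> None:
        if not (self.start_index <= self.peak_index < self.end_index):
            raise ParameterError("window must satisfy start <= peak < end")


@dataclass
class StepMetrics:
    """Mass-normalized propulsion metrics of one stance phase."""

    peak: float  # N/kg
    impulse: float  # N/kg.s
    leg: str  # "paretic" | "non_paretic" | "left" | "right"
    condition_id: str = ""
    valid: bool = True
    reason: Optional[str] = None


@dataclass
class LegSummary:
    mean_peak: float
    mean_impulse: float
    n_steps: int


@dataclass
class ConditionMetrics:
    """Per-leg condition averages plus the 23-step inclusion decision."""

    condition_id: str
    speed: float
    is_cws: bool = False
    legs: Dict[str, LegSummary] = field(default_factory=dict)
    included: bool = True
    exclusion_reason: Optional[str] = None  # None | "too_few_steps"


def find_propulsion_peak(ap_grf: np.ndarray) -> Optional[Tuple[int, float]]:
    """Locate the propulsive maximum of one stance-phase AP-GRF segment.

    Returns ``(peak_index, peak_value)`` or ``None`` when the segment has
    no positive sample (no propulsion; the step is invalid, not an error).
    Ties are broken by the latest index, since propulsion occurs in late
    stance.
    """
    seg = np.asarray(ap_grf, dtype=float)
    if seg.size == 0 or not np.any(seg > 0):
        return None
    rev = seg[::-1]
    idx = seg.size - 1 - int(np.argmax(rev))  # latest of equal maxima
    return idx, float(seg[idx])


def delimit_propulsion_window(ap_grf: np.ndarray, peak_index: int) -> PropulsionWindow:
    """Bound the propulsion region by zero-crossings around the peak.

    Start is the last negative-to-positive crossing before the peak (or the
    stance start).  Scanning forward from the peak, interior negative dips
    followed by another positive lobe are bridged and counted; the window
    ends at the final positive-to-negative crossing after which no positive
    lobe remains, so trailing negative lobes are excluded.
    """
    seg = np.asarray(ap_grf, dtype=float)
    if not (0 <= peak_index < seg.size) or seg[peak_index] <= 0:
        raise ParameterError("peak_index must point at a positive sample")
    start = peak_index
    while start > 0 and seg[start - 1] > 0:
        start -= 1
    end = peak_index
    dips = 0
    while True:
        while end < seg.size and seg[end] > 0:
            end += 1
        later_pos = np.flatnonzero(seg[end:] > 0)
        if later_pos.size == 0:
            break
        gap = seg[end:end + later_pos[0]]
        if np.any(gap < 0):
            dips += 1
        end += int(later_pos[0])
    return PropulsionWindow(start_index=start, end_index=end,
                            peak_index=peak_index, bridged_dips=dips)


def compute_impulse(ap_grf: np.ndarray, window: PropulsionWindow, fs: float) -> float:
    """Signed trapezoidal integral (N.s) of the AP-GRF over the window.

    The bounding zero-crossing samples adjacent to the window are included
    in the integration support so the lobe area up to the sign change is
    captured; interior dips subtract.
    """
    if fs <= 0:
        raise ParameterError("fs must be positive")
    seg = np.asarray(ap_grf, dtype=float)
    lo = max(window.start_index - 1, 0)
    hi = min(window.end_index + 1, seg.size)
    return float(np.trapezoid(seg[lo:hi], dx=1.0 / fs))


def normalize_by_mass(value: float, body_mass_kg: float) -> float:
    """Convert N to N/kg (or N.s to N/kg.s) by dividing by body mass."""
    if body_mass_kg <= 0:
        raise ParameterError("body mass must be positive")
    return value / body_mass_kg


def score_step(ap_grf: np.ndarray, fs: float, body_mass_kg: float, leg: str,
               condition_id: str = "") -> StepMetrics:
    """Extract mass-normalized peak and impulse for one stance segment."""
    found = find_propulsion_peak(ap_grf)
    if found is None:
        return StepMetrics(peak=np.nan, impulse=np.nan, leg=leg,
                           condition_id=condition_id, valid=False, reason="no_propulsion")
    peak_idx, peak_val = found
    window = delimit_propulsion_window(ap_grf, peak_idx)
    impulse = compute_impulse(ap_grf, window, fs)
    return StepMetrics(peak=normalize_by_mass(peak_val, body_mass_kg),
                       impulse=normalize_by_mass(impulse, body_mass_kg),
                       leg=leg, condition_id=condition_id)


def summarize_condition(steps: Sequence[StepMetrics], condition_id: str, speed: float,
                        is_cws: bool = False,
                        min_steps: int = MIN_STEPS_PER_LEG) -> ConditionMetrics:
    """Average valid steps per leg; mark the condition excluded when any
    leg has fewer than ``min_steps`` valid steps (boundary inclusive:
    exactly 23 valid steps is enough)."""
    legs = sorted({s.leg for s in steps})
    out = ConditionMetrics(condition_id=condition_id, speed=speed, is_cws=is_cws)
    for leg in legs:
        vals = [(s.peak, s.impulse) for s in steps if s.leg == leg and s.valid]
        n = len(vals)
        if n:
            peaks, imps = zip(*vals)
            out.legs[leg] = LegSummary(float(np.mean(peaks)), float(np.mean(imps)), n)
        else:
            out.legs[leg] = LegSummary(np.nan, np.nan, 0)
        if n < min_steps:
            out.included = False
            out.exclusion_reason = "too_few_steps"
    if not legs:
        out.included = False
        out.exclusion_reason = "too_few_steps"
    return out


def apply_participant_exclusion(conditions: Sequence[ConditionMetrics],
                                max_failing: int = MAX_FAILING_CONDITIONS):
    """Apply the two-condition participant exclusion rule.

    Returns ``(participant_included, kept_conditions, report)`` where
    ``report`` lists each dropped condition with its reason.  A participant
    with ``max_failing`` or more failing conditions is excluded entirely;
    otherwise only the failing conditions are dropped.
    """
    failing = [c for c in conditions if not c.included]
    report = {
        "n_conditions": len(conditions),
        "n_failing": len(failing),
        "failing_conditions": [
            {"condition_id": c.condition_id, "speed": c.speed, "reason": c.exclusion_reason}
            for c in failing
        ],
        "participant_included": len(failing) < max_failing,
    }
    if len(failing) >= max_failing:
        return False, [], report
    return True, [c for c in conditions if c.included], report
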