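"""Stance-phase estimation from foot markers and step-validity flagging.

On a treadmill the foot markers oscillate back and forth relative to the
pelvis: the heel reaches its most anterior position at initial contact
(IC) and the toe its most posterior position at terminal contact (TC).
Detecting those pelvis-relative extrema per leg yields the stance interval
[IC, TC) without force thresholds, which keeps event detection independent
of the force channels whose propulsive content we are about to score.

Indices are 0-based sample indices at the (resampled) 100 Hz rate, and
stance intervals are half-open ``[ic, tc)``.

A step is invalid for propulsion analysis when

* ``crossover``: at any sample during the stance the contralateral foot's
  heel or toe ML coordinate lies on the ipsilateral side of the belt
  midline (both feet at least partially on one plate, so per-leg force
  attribution fails); a sample exactly on the midline counts, or
* ``edge``: the stance touches the boundary of the trimmed window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
from scipy.signal import find_peaks

from .errors import DetectionError, ParameterError
from .grf_io import MarkerSet

#: physiological guard on stance duration, seconds
MIN_STANCE_S = 0.2
MAX_STANCE_S = 2.5

#: nominal cadence model, steps/min as a function of belt speed (m/s);
#: used only to set the minimum peak separation of the detector
CADENCE_INTERCEPT = 60.0
CADENCE_SLOPE = 40.0


@dataclass
class StancePhase:
    """One leg's ground-contact interval ``[ic_index, tc_index)``."""

    leg: str  # "left" | "right"
    ic_index: int
    tc_index: int
    valid: bool = True
    exclusion_reason: Optional[str] = None  # None | "crossover" | "edge"

    def __post_init__(self) -> None:
        if not self.ic_index < self.tc_index:
            raise ParameterError("stance requires ic_index < tc_index")


def expected_stride_time(belt_speed: float,
                         cadence_intercept: float = CADENCE_INTERCEPT,
                         cadence_slope: float = CADENCE_SLOPE) -> float:
    """Nominal stride time (s) from the linear cadence-vs-speed model."""
    if belt_speed <= 0:
        raise ParameterError("belt speed must be positive")
    cadence = cadence_intercept + cadence_slope * belt_speed  # steps/min
    return 2.0 * 60.0 / cadence


def _leg_events(heel_rel: np.ndarray, toe_rel: np.ndarray, fs: float,
                min_sep: int) -> List[StancePhase]:
    if np.ptp(heel_rel) < 1e-9 or np.ptp(toe_rel) < 1e-9:
        raise DetectionError("flat marker trajectories: no forward/backward extrema")
    ics, _ = find_peaks(heel_rel, distance=min_sep)
    tcs, _ = find_peaks(-toe_rel, distance=min_sep)
    if ics.size == 0 or tcs.size == 0:
        raise DetectionError("no gait-cycle extrema found in marker trajectories")
    phases: List[StancePhase] = []
    n = heel_rel.size
    for k, ic in enumerate(ics):
        upper = ics[k + 1] if k + 1 < ics.size else n
        cands = tcs[(tcs > ic) & (tcs <= upper)]
        if cands.size == 0:
            continue  # partial cycle at the window edge
        if cands.size > 1:
            raise DetectionError(
                f"non-alternating IC/TC events near sample {ic}: "
                f"{cands.size} terminal contacts within one stride "
                f"(IC samples {ics.tolist()}, TC samples {tcs.tolist()})"
            )
        tc = int(cands[0])
        dur = (tc - ic) / fs
        if not (MIN_STANCE_S <= dur <= MAX_STANCE_S):
            continue  # physiologically impossible, treat as detection artifact
        phase = StancePhase(leg="", ic_index=int(ic), tc_index=tc)
        if ic <= 0 or tc >= n:
            phase.valid = False
            phase.exclusion_reason = "edge"
        phases.append(phase)
    return phases


def detect_stance_phases(markers: MarkerSet, belt_speed: float, fs: float = None,
                         min_sep_fraction: float = 0.4,
                         cadence_intercept: float = CADENCE_INTERCEPT,
                         cadence_slope: float = CADENCE_SLOPE) -> Dict[str, List[StancePhase]]:
    """Detect stance phases per leg from pelvis-relative foot-marker extrema.

    The minimum peak separation is ``min_sep_fraction`` x the expected
    stride time at the given belt speed.  First and last partial cycles are
    dropped.  Detection is translation invariant: the pelvis reference is
    subtracted before extrema are located.
    """
    fs = markers.fs_marker if fs is None else fs
    stride_t = expected_stride_time(belt_speed, cadence_intercept, cadence_slope)
    min_sep = max(int(round(min_sep_fraction * stride_t * fs)), 1)
    pelvis = markers.ap["pelvis"]
    out: Dict[str, List[StancePhase]] = {}
    for leg, heel, toe in (("left", "l_heel", "l_toe"), ("right", "r_heel", "r_toe")):
        phases = _leg_events(markers.ap[heel] - pelvis, markers.ap[toe] - pelvis, fs, min_sep)
        for p in phases:
            p.leg = leg
        out[leg] = phases
    return out


def flag_crossover_steps(phases: Dict[str, List[StancePhase]], markers: MarkerSet,
                         belt_midline: float = 0.0) -> Dict[str, List[StancePhase]]:
    """Flag stances during which the *other* foot strays onto this belt.

    Convention: the left belt occupies ML < ``belt_midline``, the right
    belt ML > ``belt_midline``.  A contralateral heel or toe sample exactly
    on the midline counts as partially placed.  Flags are updated in place
    and the mapping returned for convenience.
    """
    contra = {"left": ("r_heel", "r_toe"), "right": ("l_heel", "l_toe")}
    for leg, plist in phases.items():
        heel_ml = markers.ml[contra[leg][0]]
        toe_ml = markers.ml[contra[leg][1]]
        for p in plist:
            seg_h = heel_ml[p.ic_index:p.tc_index]
            seg_t = toe_ml[p.ic_index:p.tc_index]
            if leg == "left":
                crossed = bool(np.any(seg_h <= belt_midline) or np.any(seg_t <= belt_midline))
            else:
                crossed = bool(np.any(seg_h >= belt_midline) or np.any(seg_t >= belt_midline))
            if crossed:
                p.valid = False
                p.exclusion_reason = "crossover"
    return phases


def count_valid_steps(phases) -> int:
    """Number of stance phases still usable for propulsion analysis."""
    return sum(1 for p in phases if p.valid)
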