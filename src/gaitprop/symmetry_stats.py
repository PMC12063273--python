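"""Propulsion symmetry and assembly of the long-format observation table.

Propulsion symmetry is the relative contribution of the paretic leg to
total propulsion::

    symmetry = paretic / (paretic + non_paretic)

computed per gait-speed condition for both the propulsion peak and the
propulsion impulse.  A value of 0.5 (50 %) means both legs contribute
equally; values below 0.5 mean the paretic leg contributes less.  For
controls the numerator is the left leg.  Internally symmetry is always a
fraction in [0, 1]; reports render it x100 as a percentage.

Each participant also carries a ``symmetry_at_cws`` covariate: the
observed symmetry at their comfortable-walking-speed condition, constant
across that participant's rows.  Participants whose CWS condition was
excluded (too few steps) cannot provide it and are dropped from the
symmetry models, with the reason logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .grf_io import OBSERVATION_COLUMNS, ParticipantMeta
from .propulsion_metrics import ConditionMetrics

logger = logging.getLogger(__name__)


@dataclass
class ObservationRow:
    """One (participant, condition, leg) record feeding the mixed models.

    Symmetry fields are condition-level (identical across the two leg rows
    of a condition); ``*_symmetry_at_cws`` is participant-level.  Missing
    symmetry (dropped CWS condition, or both legs zero) is NaN.
    """

    participant_id: str
    group: str
    condition_id: str
    speed: float
    is_cws: bool
    leg: str
    peak: float
    impulse: float
    n_steps: int
    peak_symmetry: float
    impulse_symmetry: float
    peak_symmetry_at_cws: float
    impulse_symmetry_at_cws: float


def compute_symmetry(paretic_value: float, nonparetic_value: float) -> float:
    """Fractional contribution of the paretic (or left) leg to the total.

    Both inputs must be non-negative and not both zero.
    """
    if paretic_value < 0 or nonparetic_value < 0:
        raise ParameterError("propulsion values must be non-negative")
    total = paretic_value + nonparetic_value
    if total == 0:
        raise ParameterError("symmetry undefined: both legs contributed zero propulsion")
    return paretic_value / total


def _leg_roles(meta: ParticipantMeta) -> Dict[str, str]:
    """Map physical legs to analysis roles for one participant."""
    if meta.group == "control":
        return {"left": "left", "right": "right"}
    if meta.paretic_side == "left":
        return {"left": "paretic", "right": "non_paretic"}
    if meta.paretic_side == "right":
        return {"left": "non_paretic", "right": "paretic"}
    raise ParameterError(f"{meta.participant_id}: stroke participant needs a paretic side")


def _numerator_leg(meta: ParticipantMeta) -> str:
    """Physical leg whose propulsion forms the symmetry numerator."""
    return "left" if meta.group == "control" else meta.paretic_side


def _condition_symmetry(cond: ConditionMetrics, meta: ParticipantMeta):
    num = _numerator_leg(meta)
    den = "right" if num == "left" else "left"
    try:
        sp = compute_symmetry(cond.legs[num].mean_peak, cond.legs[den].mean_peak)
        si = compute_symmetry(cond.legs[num].mean_impulse, cond.legs[den].mean_impulse)
    except ParameterError as exc:
        logger.warning("%s %s: symmetry dropped (%s)", meta.participant_id,
                       cond.condition_id, exc)
        return np.nan, np.nan
    return sp, si


def build_observation_table(
    participants: Sequence,  # iterable of (ParticipantMeta, [ConditionMetrics])
) -> List[ObservationRow]:
    """Assemble the long-format table for the mixed models.

    ``participants`` yields pairs of metadata and *included* condition
    summaries (exclusion rules already applied).  Symmetry is computed per
    condition; the CWS condition's symmetry is broadcast to all of a
    participant's rows as the ``symmetry_at_cws`` covariate.
    """
    rows: List[ObservationRow] = []
    for meta, conditions in participants:
        roles = _leg_roles(meta)
        cws = [c for c in conditions if c.is_cws]
        if cws:
            sp_cws, si_cws = _condition_symmetry(cws[0], meta)
        else:
            sp_cws = si_cws = np.nan
            logger.warning(
                "%s: CWS condition missing or excluded; participant dropped "
                "from symmetry models", meta.participant_id)
        for cond in conditions:
            sp, si = _condition_symmetry(cond, meta)
            for phys_leg, role in roles.items():
                leg = cond.legs.get(phys_leg)
                if leg is None:
                    continue
                rows.append(ObservationRow(
                    participant_id=meta.participant_id, group=meta.group,
                    condition_id=cond.condition_id, speed=cond.speed,
                    is_cws=cond.is_cws, leg=role,
                    peak=leg.mean_peak, impulse=leg.mean_impulse,
                    n_steps=leg.n_steps,
                    peak_symmetry=sp, impulse_symmetry=si,
                    peak_symmetry_at_cws=sp_cws, impulse_symmetry_at_cws=si_cws,
                ))
    return rows


def observation_frame(rows: Sequence[ObservationRow]) -> pd.DataFrame:
    """Observation rows as a DataFrame in the canonical column order."""
    if not rows:
        raise ParameterError("no observation rows")
    return pd.DataFrame([vars(r) for r in rows])[OBSERVATION_COLUMNS]
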