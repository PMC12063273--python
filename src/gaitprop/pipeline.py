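"""End-to-end orchestration: signals or step metrics -> observation table -> fits.

Two input routes converge on the same long-format observation table:

* metrics mode: generated per-step metrics are aggregated directly
  (condition averaging + exclusion rules);
* waveform mode: AP-GRF and marker signals are conditioned (trim ->
  filter -> resample), stance phases detected from the foot markers,
  crossover steps flagged, and per-step metrics extracted from each leg's
  plate, before the same aggregation.

The model suite then fits the four primary symmetry models
(peak/impulse x stroke/control), the two per-leg speed x leg models, the
per-leg post-hoc models when the interaction is significant, and the
control propulsion models.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Optional, Tuple

import pandas as pd

from . import gait_events, propulsion_metrics, symmetry_stats
from .errors import GaitPropError
from .grf_io import GrfRecording, MarkerSet
from .lmm_models import (LmmFit, fit_control_propulsion_model, fit_leg_model,
                         fit_per_leg_posthoc, fit_symmetry_model, posthoc_required)
from .preprocess import FilterSpec, preprocess_condition
from .propulsion_metrics import (ConditionMetrics, StepMetrics,
                                 apply_participant_exclusion, score_step,
                                 summarize_condition)
from .synthetic_gait import CohortData, GeneratorParams, synthesize_waveforms

logger = logging.getLogger(__name__)


def process_waveform_condition(rec: GrfRecording, markers: MarkerSet,
                               belt_speed: float,
                               spec: FilterSpec = FilterSpec(),
                               belt_midline: float = 0.0,
                               head_s: float = 10.0, tail_s: float = 5.0,
                               ) -> List[StepMetrics]:
    """Signals of one condition -> per-step propulsion metrics.

    Applies the full conditioning chain, detects and flags stance phases,
    and scores each stance from its own leg's plate channel.  Invalid
    steps (crossover/edge) are returned flagged, never scored.
    """
    rec, markers = preprocess_condition(rec, markers, spec=spec,
                                        head_s=head_s, tail_s=tail_s)
    phases = gait_events.detect_stance_phases(markers, belt_speed)
    phases = gait_events.flag_crossover_steps(phases, markers, belt_midline)
    plate = {"left": rec.ap_left, "right": rec.ap_right}
    steps: List[StepMetrics] = []
    for leg, plist in phases.items():
        for p in plist:
            if not p.valid:
                steps.append(StepMetrics(peak=float("nan"), impulse=float("nan"),
                                         leg=leg, condition_id=rec.condition_id,
                                         valid=False, reason=p.exclusion_reason))
                continue
            seg = plate[leg][p.ic_index:p.tc_index]
            steps.append(score_step(seg, rec.fs_force, rec.body_mass_kg, leg,
                                    rec.condition_id))
    return steps


def _aggregate(meta, condition_steps) -> Tuple[Optional[tuple], dict]:
    """Summarize conditions, apply exclusion rules for one participant."""
    summaries: List[ConditionMetrics] = []
    for entry, steps in condition_steps:
        summaries.append(summarize_condition(steps, entry.condition_id,
                                             entry.belt_speed, entry.is_cws))
    included, kept, report = apply_participant_exclusion(summaries)
    report["participant_id"] = meta.participant_id
    if not included:
        return None, report
    return (meta, kept), report


def process_cohort(cohort: CohortData, params: GeneratorParams = None,
                   mode: str = "metrics",
                   spec: FilterSpec = FilterSpec()) -> Tuple[pd.DataFrame, dict]:
    """Cohort -> observation table + exclusion report.

    ``mode="metrics"`` aggregates the generated step metrics directly;
    ``mode="waveforms"`` first renders every condition as signals and runs
    the full signal pipeline (slower; requires ``params``).
    """
    participants = []
    reports = []
    for prec in cohort.participants:
        condition_steps = []
        for cond in prec.conditions:
            if mode == "metrics":
                steps = cond.steps["left"] + cond.steps["right"]
            elif mode == "waveforms":
                rec, markers, _ = synthesize_waveforms(prec.participant, cond, params)
                steps = process_waveform_condition(rec, markers,
                                                   cond.entry.belt_speed, spec=spec)
            else:
                raise ValueError(f"unknown mode {mode!r}")
            condition_steps.append((cond.entry, steps))
        kept, report = _aggregate(prec.participant.meta, condition_steps)
        reports.append(report)
        if kept is not None:
            participants.append(kept)
    rows = symmetry_stats.build_observation_table(participants)
    table = symmetry_stats.observation_frame(rows)
    report = {
        "n_participants": len(cohort.participants),
        "n_included": len(participants),
        "excluded_participants": [r["participant_id"] for r in reports
                                  if not r["participant_included"]],
        "per_participant": reports,
    }
    return table, report


def step_audit_frame(cohort: CohortData) -> pd.DataFrame:
    """Tidy per-step audit table (one row per generated step)."""
    rows = []
    for prec in cohort.participants:
        pid = prec.participant.meta.participant_id
        for cond in prec.conditions:
            for leg in ("left", "right"):
                for i, s in enumerate(cond.steps[leg]):
                    rows.append(dict(participant_id=pid,
                                     condition_id=cond.entry.condition_id,
                                     speed=cond.entry.belt_speed, leg=leg,
                                     step_index=i, peak=s.peak, impulse=s.impulse,
                                     valid=s.valid, reason=s.reason))
    return pd.DataFrame(rows)


def fit_model_suite(table: pd.DataFrame, df_method: str = "satterthwaite",
                    alpha: float = 0.05) -> Dict[str, LmmFit]:
    """Fit every model the analysis reports for whatever groups are present.

    Post-hoc per-leg fits are added only when the corresponding speed x leg
    interaction is significant at ``alpha``.  Non-convergence is surfaced
    on the fit objects; the suite always continues.
    """
    if table.empty:
        raise GaitPropError("observation table is empty")
    fits: Dict[str, LmmFit] = {}
    groups = set(table["group"])
    for metric in ("peak", "impulse"):
        if "stroke" in groups:
            fits[f"symmetry_{metric}_stroke"] = fit_symmetry_model(
                table, metric, "stroke", df_method)
            leg_fit = fit_leg_model(table, metric, df_method)
            fits[f"leg_{metric}_stroke"] = leg_fit
            if posthoc_required(leg_fit, alpha):
                for leg in ("non_paretic", "paretic"):
                    fits[f"posthoc_{metric}_{leg}"] = fit_per_leg_posthoc(
                        table, metric, leg, df_method)
        if "control" in groups:
            fits[f"symmetry_{metric}_control"] = fit_symmetry_model(
                table, metric, "control", df_method)
            fits[f"propulsion_{metric}_control"] = fit_control_propulsion_model(
                table, metric, df_method)
    return fits


def report_text(fits: Dict[str, LmmFit]) -> str:
    """Human-readable fit report in the field's beta/SE/t(df)/p style."""
    lines = []
    for name, fit in fits.items():
        status = "" if fit.converged else "  [NOT CONVERGED]"
        singular = "  [singular random effects]" if fit.singular else ""
        lines.append(f"== {name} (n_obs={fit.n_obs}, n_participants={fit.n_groups})"
                     f"{status}{singular}")
        for term, row in fit.params.iterrows():
            note = "  (not reported)" if term in fit.not_reported else ""
            lines.append(
                f"   {term:>12s}: beta = {row.estimate: .4g}, SE = {row.se:.3g}, "
                f"t = {row.t:.3g}({row.df:.1f}), p = {row.p:.3g}{note}")
        rand = ", ".join(f"{k} SD = {v:.3g}" for k, v in fit.random_sd.items())
        lines.append(f"   random: {rand}; residual SD = {fit.resid_sd:.3g}")
    return "\n".join(lines) + "\n"
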