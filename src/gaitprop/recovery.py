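"""Parameter-recovery harness.

With no raw study data available, validation is by simulation: cohorts are
generated from the shipped effect-size parameter file, pushed through the
aggregation pipeline and the mixed-model suite, and the fitted fixed
effects are compared with the generative values.  The harness returns the
per-replicate estimates of every reported quantity; callers summarize
(Monte-Carlo means) and compare at their own tolerances.

Quantities reported per stroke replicate (names match the analysis
reports):

* ``sym_impulse_speed`` / ``sym_impulse_interaction`` — gait-speed and
  speed x symmetry-at-CWS coefficients of the impulse-symmetry model
  (fraction per m/s).
* ``sym_peak_speed`` — speed coefficient of the peak-symmetry model.
* ``posthoc_peak_nonparetic`` / ``posthoc_peak_paretic`` — per-leg
  post-hoc speed slopes on the propulsion peak, N/kg per 0.1 m/s.
* ``legmodel_impulse_speed`` — speed slope of the speed x leg impulse model,
  N/kg.s per 0.1 m/s.
* ``legmodel_impulse_leg`` — magnitude of the paretic leg effect on the
  impulse, N/kg.s.

Per control replicate: ``control_peak_speed`` and
``control_impulse_speed`` (N/kg and N/kg.s per m/s) and
``control_peak_sym_intercept`` (fraction).
"""

from __future__ import annotations

import copy
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .lmm_models import (fit_control_propulsion_model, fit_leg_model,
                         fit_per_leg_posthoc, fit_symmetry_model)
from .pipeline import process_cohort
from .synthetic_gait import GeneratorParams, generate_cohort


def replicate_seeds(base_seed: int, n_rep: int) -> np.ndarray:
    """Deterministic per-replicate seeds derived from one base seed."""
    rng = np.random.default_rng(base_seed)
    return rng.integers(0, 2 ** 31 - 1, size=n_rep)


def stroke_replicate(params: GeneratorParams, seed: int,
                     df_method: str = "between_within") -> Dict[str, float]:
    """Generate one stroke cohort (metrics mode) and fit the stroke models."""
    cohort = generate_cohort(params, "stroke", int(seed))
    table, _ = process_cohort(cohort)
    out: Dict[str, float] = {}
    fit = fit_symmetry_model(table, "impulse", "stroke", df_method)
    out["sym_impulse_speed"] = fit.estimate("speed")
    out["sym_impulse_interaction"] = fit.estimate("speed:s0")
    fit = fit_symmetry_model(table, "peak", "stroke", df_method)
    out["sym_peak_speed"] = fit.estimate("speed")
    fit = fit_per_leg_posthoc(table, "peak", "non_paretic", df_method)
    out["posthoc_peak_nonparetic"] = fit.estimate("speed") / 10.0
    fit = fit_per_leg_posthoc(table, "peak", "paretic", df_method)
    out["posthoc_peak_paretic"] = fit.estimate("speed") / 10.0
    fit = fit_leg_model(table, "impulse", df_method)
    out["legmodel_impulse_speed"] = fit.estimate("speed") / 10.0
    out["legmodel_impulse_leg"] = abs(fit.estimate("leg_p"))
    return out


def control_replicate(params: GeneratorParams, seed: int,
                      df_method: str = "between_within") -> Dict[str, float]:
    """Generate one control cohort and fit the control models."""
    cohort = generate_cohort(params, "control", int(seed))
    table, _ = process_cohort(cohort)
    out: Dict[str, float] = {}
    out["control_peak_speed"] = fit_control_propulsion_model(
        table, "peak", df_method).estimate("speed")
    out["control_impulse_speed"] = fit_control_propulsion_model(
        table, "impulse", df_method).estimate("speed")
    out["control_peak_sym_intercept"] = fit_symmetry_model(
        table, "peak", "control", df_method).estimate("Intercept")
    return out


def run_recovery(params: GeneratorParams, base_seed: int, n_rep: int = 50,
                 group: str = "stroke") -> pd.DataFrame:
    """Monte-Carlo recovery: one row of fitted quantities per replicate."""
    fn = stroke_replicate if group == "stroke" else control_replicate
    rows = [fn(params, s) for s in replicate_seeds(base_seed, n_rep)]
    return pd.DataFrame(rows)


def null_leg_params(params: GeneratorParams) -> GeneratorParams:
    """Stroke parameters with exchangeable legs and no speed effect on the
    share: every leg, speed and interaction effect is generatively zero."""
    raw = copy.deepcopy({"stroke": params.stroke, "control": params.control,
                         "gait": params.gait, "waveform": params.waveform})
    for metric in ("peak", "impulse"):
        mp = raw["stroke"][metric]
        mp["sym_speed_beta"] = 0.0
        mp["sym_interaction_beta"] = 0.0
        mp["share_at_cws"] = dict(mp["share_at_cws"], mean=0.5, sd=0.03,
                                  min=0.3, max=0.7)
    return GeneratorParams.from_dict(raw)


def posthoc_trigger_rate(params: GeneratorParams, base_seed: int,
                         n_rep: int = 100, metric: str = "peak",
                         alpha: float = 0.05,
                         df_method: str = "satterthwaite") -> float:
    """Fraction of replicates whose speed x leg interaction is significant.

    With :func:`null_leg_params` this estimates the type-I rate of the
    post-hoc decision rule (nominal ``alpha``).
    """
    trig = 0
    for s in replicate_seeds(base_seed, n_rep):
        cohort = generate_cohort(params, "stroke", int(s))
        table, _ = process_cohort(cohort)
        fit = fit_leg_model(table, metric, df_method)
        if fit.pvalue("speed:leg_p") < alpha:
            trig += 1
    return trig / n_rep
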