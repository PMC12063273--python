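"""Synthetic hemiparetic-gait cohorts with recorded ground truth.

The study the pipeline reimplements deposited no raw data, so validation
rests on parameter recovery: cohorts are generated from the printed
mixed-model estimates and the pipeline must recover them.

The generative model works on (total propulsion, paretic share) per
metric.  The share of the paretic leg follows the symmetry mixed model
exactly — a participant's share is linear in belt speed, anchored at the
participant's share at comfortable walking speed (CWS), with the printed
fixed effects and random-slope SDs — while total propulsion (sum of both
legs) is linear in speed with slopes derived from the printed per-leg
slopes.  Per-leg condition means are then ``share x total`` and
``(1 - share) x total``, so the symmetry covariates the pipeline computes
always derive from generated per-leg values, and the printed per-leg
coefficients re-emerge when the per-leg mixed models are fitted (the
calibration is derived in docs/methods.md).

Two output modes:

* **metrics mode** — per-step peak/impulse values (condition mean plus
  multiplicative step noise); fast, used for the recovery simulations.
* **waveform mode** — full AP-GRF traces (1000 Hz) and foot/pelvis marker
  trajectories (100 Hz) rendering each stance as a negative braking
  half-sine followed by a positive propulsion half-sine whose amplitude
  and duration solve the step's target peak and impulse exactly
  (A = peak x mass, T = pi x impulse / (2 x peak)); exercises the whole
  signal pipeline.

Every observable has a recorded truth (latent effects, per-condition
means, per-step values, injected crossover steps), and all generation is
reproducible from a seed.
"""

from __future__ import annotations

import importlib.resources as resources
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .errors import ParameterError
from .grf_io import (ConditionEntry, ConditionSchedule, GrfRecording, MarkerSet,
                     ParticipantMeta)
from .propulsion_metrics import StepMetrics

DEFAULT_PARAMS_FILE = "params_paper.yaml"


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass
class GeneratorParams:
    """Nested generator configuration (see ``data/params_paper.yaml``)."""

    stroke: dict
    control: dict
    gait: dict
    waveform: dict

    @classmethod
    def from_dict(cls, raw: dict) -> "GeneratorParams":
        missing = {"stroke", "control", "gait", "waveform"} - set(raw)
        if missing:
            raise ParameterError(f"generator params missing sections {sorted(missing)}")
        p = cls(**{k: raw[k] for k in ("stroke", "control", "gait", "waveform")})
        for grp in ("stroke", "control"):
            for metric in ("peak", "impulse"):
                for k, v in p.group(grp)[metric].items():
                    if k.endswith("_sd") and v < 0:
                        raise ParameterError(f"{grp}.{metric}.{k} must be >= 0")
        for grp in ("stroke", "control"):
            c = p.group(grp)["cws"]
            if not c["min"] < c["max"]:
                raise ParameterError(f"{grp}: cws bounds inverted")
        return p

    def group(self, group: str) -> dict:
        if group not in ("stroke", "control"):
            raise ParameterError(f"unknown group {group!r}")
        return getattr(self, group)


def load_params(path=None) -> GeneratorParams:
    """Load generator parameters from YAML (packaged defaults when no path)."""
    if path is None:
        ref = resources.files("gaitprop").joinpath("data", DEFAULT_PARAMS_FILE)
        raw = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    return GeneratorParams.from_dict(raw)


# ---------------------------------------------------------------------------
# Cohort sampling
# ---------------------------------------------------------------------------

@dataclass
class MetricLatents:
    """Per-participant random effects for one propulsion metric."""

    share_anchor: float      # share at CWS (stroke) or intercept deviation (control)
    slope_dev: float         # deviation from the population share slope
    total_intercept_dev: float
    total_slope_dev: float


@dataclass
class SyntheticParticipant:
    meta: ParticipantMeta
    latents: Dict[str, MetricLatents]
    max_speed: float


@dataclass
class StepTruth:
    leg: str                 # physical leg, "left" | "right"
    peak: float
    impulse: float
    crossover: bool = False
    ic_time: Optional[float] = None
    tc_time: Optional[float] = None
    injected: bool = True    # False: padding stance rendered at the condition mean


@dataclass
class ConditionRecord:
    entry: ConditionEntry
    steps: Dict[str, List[StepMetrics]]        # physical leg -> steps
    truth_steps: Dict[str, List[StepTruth]]
    truth_means: Dict[str, Dict[str, float]]   # leg -> {"peak": .., "impulse": ..}
    n_truncated: int = 0


@dataclass
class ParticipantRecord:
    participant: SyntheticParticipant
    schedule: ConditionSchedule
    conditions: List[ConditionRecord] = field(default_factory=list)


@dataclass
class CohortData:
    group: str
    participants: List[ParticipantRecord]
    seed: int


def _trunc_normal(rng, mean, sd, lo, hi):
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def sample_cohort(params: GeneratorParams, group: str, seed) -> List[SyntheticParticipant]:
    """Draw a cohort's metadata and latent random effects.

    Latents are zero-mean Gaussians with the configured SDs (the share
    anchor is Gaussian around its configured mean, truncated to its
    bounds); identical seeds yield identical cohorts.
    """
    g = params.group(group)
    rng = np.random.default_rng(seed)
    out = []
    for i in range(int(g["n_participants"])):
        cws = _trunc_normal(rng, g["cws"]["mean"], g["cws"]["sd"],
                            g["cws"]["min"], g["cws"]["max"])
        grid = g.get("cws_grid", 0.05)
        cws = round(round(cws / grid) * grid, 3)
        mass = _trunc_normal(rng, g["body_mass"]["mean"], g["body_mass"]["sd"],
                             g["body_mass"]["min"], g["body_mass"]["max"])
        if group == "stroke":
            side = "left" if rng.random() < g["paretic_side_left_ratio"] else "right"
            max_speed = round(cws + g["max_speed_margin"], 3)
        else:
            side = "none"
            max_speed = max(g["speeds"])
        # peak and impulse latents share a participant-level factor: a leg
        # that is weak in peak is weak in impulse too.  The marginal SDs are
        # unchanged, so per-metric model recovery is unaffected; the
        # correlation keeps the per-step impulse/peak ratio physiological.
        rho = params.gait.get("cross_metric_correlation", 0.8)
        a, b = np.sqrt(rho), np.sqrt(1.0 - rho)
        shared = rng.normal(size=4)
        latents = {}
        for metric in ("peak", "impulse"):
            mp = g[metric]
            own = rng.normal(size=4)
            z = a * shared + b * own
            if group == "stroke":
                sa = mp["share_at_cws"]
                anchor = float(np.clip(sa["mean"] + sa["sd"] * z[0],
                                       sa["min"], sa["max"]))
            else:
                anchor = mp["sym_intercept_sd"] * z[0]
            latents[metric] = MetricLatents(
                share_anchor=anchor,
                slope_dev=mp["sym_slope_sd"] * z[1],
                total_intercept_dev=mp["total_intercept_sd"] * z[2],
                total_slope_dev=mp["total_slope_sd"] * z[3],
            )
        meta = ParticipantMeta(participant_id=f"{group[:2]}{i:03d}", group=group,
                               paretic_side=side, cws=cws, body_mass_kg=mass)
        out.append(SyntheticParticipant(meta=meta, latents=latents, max_speed=max_speed))
    return out


def build_schedule(participant: SyntheticParticipant, params: GeneratorParams,
                   rng=None) -> ConditionSchedule:
    """Build the speed schedule a participant walks.

    Stroke: 0.2 m/s up to and including CWS in 0.2 m/s increments,
    randomized, then CWS + 0.1, CWS + 0.2, ... up to the maximum speed.
    Controls: the fixed 0.4-1.6 m/s grid randomized, plus one condition at
    CWS.  Durations: 180 s at <= 0.4 m/s, 120 s above.  The randomized
    order is recorded for realism but never used by the analysis.
    """
    rng = np.random.default_rng() if rng is None else rng
    meta = participant.meta
    if meta.group == "stroke":
        if meta.cws < 0.2:
            raise ParameterError("comfortable walking speed below the 0.2 m/s floor")
        low = [round(v, 3) for v in np.arange(0.2, meta.cws - 1e-9, 0.2)]
        if not low or abs(low[-1] - meta.cws) > 1e-9:
            low.append(round(meta.cws, 3))
        order = rng.permutation(len(low))
        speeds = [(low[k], abs(low[k] - meta.cws) < 1e-9) for k in order]
        v = meta.cws + 0.1
        while v <= participant.max_speed + 1e-9:
            speeds.append((round(v, 3), False))
            v += 0.1
    else:
        grid = [(round(v, 3), False) for v in params.control["speeds"]]
        order = rng.permutation(len(grid))
        speeds = [grid[k] for k in order] + [(round(meta.cws, 3), True)]
    entries = []
    for j, (v, is_cws) in enumerate(speeds):
        entries.append(ConditionEntry(
            condition_id=f"C{j:02d}", belt_speed=v,
            duration_s=180.0 if v <= 0.4 else 120.0, is_cws=is_cws))
    return ConditionSchedule(meta=meta, entries=entries)


# ---------------------------------------------------------------------------
# Condition means and step metrics
# ---------------------------------------------------------------------------

def condition_means(participant: SyntheticParticipant, metric: str, speed: float,
                    params: GeneratorParams) -> Tuple[Dict[str, float], int]:
    """True per-leg condition mean for one metric, keyed by physical leg.

    Returns ``(means, n_truncated)`` where ``n_truncated`` counts floor
    truncations of the share or total (possible at very low speeds with
    extreme latents).
    """
    meta = participant.meta
    g = params.group(meta.group)
    mp = g[metric]
    lat = participant.latents[metric]
    gait = params.gait
    truncated = 0
    if meta.group == "stroke":
        slope = (mp["sym_speed_beta"] + mp["sym_interaction_beta"] * lat.share_anchor
                 + lat.slope_dev)
        share = lat.share_anchor + slope * (speed - meta.cws)
    else:
        share = (0.5 + lat.share_anchor
                 + (mp["sym_speed_beta"] + lat.slope_dev) * speed)
    floor = gait["share_floor"]
    if not (floor <= share <= 1.0 - floor):
        share = float(np.clip(share, floor, 1.0 - floor))
        truncated += 1
    total = (mp["total_intercept"] + lat.total_intercept_dev
             + (mp["total_speed_slope"] + lat.total_slope_dev) * speed)
    if total < gait["total_floor"]:
        total = gait["total_floor"]
        truncated += 1
    num = share * total
    den = (1.0 - share) * total
    if meta.group == "control" or meta.paretic_side == "left":
        means = {"left": num, "right": den}
    else:
        means = {"left": den, "right": num}
    return means, truncated


def steps_per_leg(speed: float, duration_s: float, params: GeneratorParams,
                  head_s: float = 10.0, tail_s: float = 5.0) -> int:
    """Expected analysable step count per leg from the cadence model."""
    gait = params.gait
    cadence = gait["cadence_intercept"] + gait["cadence_slope"] * speed  # steps/min
    usable = duration_s - head_s - tail_s
    return int(np.floor(usable * cadence / 60.0 / 2.0))


def synthesize_step_metrics(participant: SyntheticParticipant, entry: ConditionEntry,
                            params: GeneratorParams, rng) -> ConditionRecord:
    """Generate one condition's per-step metrics plus ground truth.

    Step values are the true condition mean times ``1 + N(0, cv)`` noise,
    independently per step and metric.  With zero noise and zero latents
    every step equals the fixed-effect line exactly.  Crossover steps are
    injected at the configured rate and marked invalid.
    """
    n = steps_per_leg(entry.belt_speed, entry.duration_s, params)
    rate = params.gait["crossover_rate"]
    truth_means: Dict[str, Dict[str, float]] = {"left": {}, "right": {}}
    n_trunc = 0
    means = {}
    for metric in ("peak", "impulse"):
        m, t = condition_means(participant, metric, entry.belt_speed, params)
        n_trunc += t
        means[metric] = m
        for leg in ("left", "right"):
            truth_means[leg][metric] = m[leg]
    cv = {m: params.group(participant.meta.group)[m]["step_noise_cv"]
          for m in ("peak", "impulse")}
    # step-to-step vigour moves peak and impulse together
    rho = params.gait.get("step_noise_correlation", 0.7)
    a, b = np.sqrt(rho), np.sqrt(1.0 - rho)
    steps: Dict[str, List[StepMetrics]] = {"left": [], "right": []}
    truth: Dict[str, List[StepTruth]] = {"left": [], "right": []}
    for leg in ("left", "right"):
        for _ in range(n):
            z = rng.normal(size=3)
            pk = means["peak"][leg] * (1.0 + cv["peak"] * (a * z[0] + b * z[1]))
            im = means["impulse"][leg] * (1.0 + cv["impulse"] * (a * z[0] + b * z[2]))
            pk = max(pk, 1e-6)
            im = max(im, 1e-6)
            crossed = bool(rng.random() < rate)
            steps[leg].append(StepMetrics(
                peak=pk, impulse=im, leg=leg, condition_id=entry.condition_id,
                valid=not crossed, reason="crossover" if crossed else None))
            truth[leg].append(StepTruth(leg=leg, peak=pk, impulse=im, crossover=crossed))
    return ConditionRecord(entry=entry, steps=steps, truth_steps=truth,
                           truth_means=truth_means, n_truncated=n_trunc)


def generate_cohort(params: GeneratorParams, group: str, seed) -> CohortData:
    """Full metrics-mode cohort: participants, schedules, per-step metrics."""
    ss = np.random.SeedSequence(seed)
    cohort_seed, sched_seed, steps_seed = ss.spawn(3)
    participants = sample_cohort(params, group, cohort_seed)
    sched_rng = np.random.default_rng(sched_seed)
    out = []
    for part, child in zip(participants, steps_seed.spawn(len(participants))):
        schedule = build_schedule(part, params, sched_rng)
        rng = np.random.default_rng(child)
        rec = ParticipantRecord(participant=part, schedule=schedule)
        for entry in schedule.entries:
            rec.conditions.append(synthesize_step_metrics(part, entry, params, rng))
        out.append(rec)
    return CohortData(group=group, participants=out, seed=seed)


# ---------------------------------------------------------------------------
# Waveform rendering
# ---------------------------------------------------------------------------

def _half_sine(n: int) -> np.ndarray:
    return np.sin(np.pi * (np.arange(n) + 0.5) / n)


def _propulsion_lobe(peak_per_kg: float, impulse_per_kg: float, max_dur: float,
                     fs: float):
    """Lobe samples (per kg) with exact target peak and area.

    A pure half-sine (duration ``pi x impulse / (2 x peak)``) when it fits
    within ``max_dur``; otherwise a flat-topped lobe (quarter-sine ramps
    around a plateau) of duration ``max_dur`` holding the same peak and
    area — the shape slow push-off takes when the impulse is large
    relative to the peak.  Raises when even a square lobe could not hold
    the area.
    """
    t_half = np.pi * impulse_per_kg / (2.0 * peak_per_kg)
    if t_half <= max_dur:
        n = max(int(round(t_half * fs)), 4)
        return peak_per_kg * _half_sine(n), t_half
    if impulse_per_kg / peak_per_kg > max_dur:
        raise ParameterError(
            f"impulse {impulse_per_kg:.3g} N/kg.s cannot fit a lobe of "
            f"{max_dur:.2f} s at peak {peak_per_kg:.3g} N/kg")
    T = max_dur
    w = (T - impulse_per_kg / peak_per_kg) / (2.0 * (1.0 - 2.0 / np.pi))
    n = max(int(round(T * fs)), 4)
    nw = min(max(int(round(w * fs)), 1), n // 2)
    lobe = np.full(n, peak_per_kg)
    ramp = np.sin(np.pi * (np.arange(nw) + 0.5) / (2 * nw))
    lobe[:nw] = peak_per_kg * ramp
    lobe[n - nw:] = peak_per_kg * ramp[::-1]
    return lobe, T


def synthesize_waveforms(participant: SyntheticParticipant, cond: ConditionRecord,
                         params: GeneratorParams, rng=None,
                         crossover_steps: Optional[Dict[str, Sequence[int]]] = None,
                         head_s: float = 10.0, tail_s: float = 5.0):
    """Render one condition's step metrics as force and marker signals.

    Each stance is a braking half-sine followed by a propulsion half-sine
    solving the step's target peak and impulse; steps inside the analysis
    window carry the injected metrics-mode values (in order), padding
    steps outside it carry the condition mean.  ``crossover_steps`` maps a
    physical leg to in-window step indices whose *contralateral* foot is
    made to stray over the belt midline during the stance.

    Returns ``(GrfRecording, MarkerSet, truth)`` where truth lists the
    rendered in-window steps per leg with their IC/TC times.
    """
    wf = params.waveform
    gait = params.gait
    entry = cond.entry
    meta = participant.meta
    fs_f, fs_m = wf["fs_force"], wf["fs_marker"]
    speed = entry.belt_speed
    dur = entry.duration_s
    cadence = gait["cadence_intercept"] + gait["cadence_slope"] * speed
    step_t = 60.0 / cadence
    stride_t = 2.0 * step_t
    stance_t = gait["stance_fraction"] * stride_t
    n_f = int(round(dur * fs_f))
    n_m = int(round(dur * fs_m))
    force = {"left": np.zeros(n_f), "right": np.zeros(n_f)}
    crossover_steps = crossover_steps or {}

    # global periodic marker model: heel forward extremum at every IC,
    # toe backward extremum at every TC, relative to a stationary pelvis
    stride_len = speed * stride_t
    t_m = np.arange(n_m) / fs_m
    ic0 = {"left": 0.25 * stride_t, "right": 0.25 * stride_t + step_t}
    ap = {"pelvis": np.zeros(n_m)}
    ml = {"pelvis": np.zeros(n_m)}
    off = wf["foot_ml_offset"]
    for leg, sign in (("left", -1.0), ("right", 1.0)):
        phase = 2.0 * np.pi * (t_m - ic0[leg]) / stride_t
        ap[f"{leg[0]}_heel"] = 0.5 * stride_len * np.cos(phase)
        phase_tc = 2.0 * np.pi * (t_m - (ic0[leg] + stance_t)) / stride_t
        ap[f"{leg[0]}_toe"] = 0.15 - 0.5 * stride_len * np.cos(phase_tc)
        ml[f"{leg[0]}_heel"] = np.full(n_m, sign * off)
        ml[f"{leg[0]}_toe"] = np.full(n_m, sign * off)

    truth: Dict[str, List[StepTruth]] = {"left": [], "right": []}
    mass = meta.body_mass_kg
    for leg in ("left", "right"):
        injected = [s for s in cond.steps[leg]]
        k_inj = 0
        n_strides = int(np.floor((dur - ic0[leg]) / stride_t))
        for k in range(n_strides):
            ic = ic0[leg] + k * stride_t
            tc = ic + stance_t
            if tc >= dur - 0.05:
                break
            in_window = (ic >= head_s + 0.1) and (tc <= dur - tail_s - 0.1)
            if in_window and k_inj < len(injected):
                pk, im = injected[k_inj].peak, injected[k_inj].impulse
                step_idx = k_inj
                k_inj += 1
            else:
                pk = cond.truth_means[leg]["peak"]
                im = cond.truth_means[leg]["impulse"]
                step_idx = None
            cap = gait.get("propulsion_max_fraction", 0.68) * stance_t
            try:
                lobe, t_prop = _propulsion_lobe(pk, im, cap, fs_f)
            except ParameterError as exc:
                raise ParameterError(
                    f"{meta.participant_id} {entry.condition_id} {leg} step {k}: {exc}"
                ) from exc
            # propulsion lobe ends just before terminal contact so that
            # event-detection jitter (+-2 samples at 100 Hz) cannot clip it
            p1 = int(round((tc - 0.04 * stance_t) * fs_f))
            p0 = p1 - lobe.size
            force[leg][p0:p1] += mass * lobe
            # braking lobe over early stance; the gap before propulsion keeps
            # the 15 Hz filter transition out of the propulsion window
            b0 = int(round(ic * fs_f))
            b1 = min(int(round((ic + gait["braking_fraction"] * stance_t) * fs_f)),
                     p0 - max(int(round(0.06 * stance_t * fs_f)), 2))
            if b1 > b0 + 4:
                force[leg][b0:b1] -= (gait["braking_amplitude_ratio"] * pk * mass
                                      * _half_sine(b1 - b0))
            crossed = (step_idx is not None
                       and step_idx in set(crossover_steps.get(leg, ())))
            truth[leg].append(StepTruth(leg=leg, peak=pk, impulse=im,
                                        crossover=crossed, ic_time=ic, tc_time=tc,
                                        injected=step_idx is not None))
            if crossed:
                contra = "right" if leg == "left" else "left"
                sign = -1.0 if leg == "left" else 1.0  # toward this leg's belt
                i0 = int(round(ic * fs_m))
                i1 = int(round(tc * fs_m))
                bump = 0.5 * (1 - np.cos(2 * np.pi * np.arange(i1 - i0)
                                         / max(i1 - i0 - 1, 1)))
                excursion = sign * (off + wf["crossover_ml"]) - (-sign * off)
                for mk in (f"{contra[0]}_heel", f"{contra[0]}_toe"):
                    ml[mk] = ml[mk].copy()
                    ml[mk][i0:i1] = -sign * off + bump * excursion

    rec = GrfRecording(ap_left=force["left"], ap_right=force["right"], fs_force=fs_f,
                       body_mass_kg=mass, condition_id=entry.condition_id)
    markers = MarkerSet(ap=ap, ml=ml, fs_marker=fs_m)
    return rec, markers, truth
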