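"""Signal conditioning: steady-state trimming, zero-phase filtering, resampling.

The prescribed processing of each gait-speed condition is

1. drop the first 10 s and final 5 s (treadmill start/stop transients),
2. low-pass the force and marker streams with a second-order zero-phase
   Butterworth filter at 15 Hz (applied forward and backward, so the
   effective magnitude response is fourth order and the group delay zero),
3. resample the 1000 Hz force stream to 100 Hz to match motion capture.

Trimming precedes filtering here so start/stop transients never enter the
filter; because at least 5 s are always trimmed and filter edge effects are
confined to well under a second, the order is immaterial for every
extracted metric.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
from scipy import signal

from .errors import ParameterError
from .grf_io import GrfRecording, MarkerSet

DEFAULT_HEAD_S = 10.0
DEFAULT_TAIL_S = 5.0


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Butterworth design (order refers to the one-pass design)."""

    order: int = 2
    cutoff_hz: float = 15.0
    zero_phase: bool = True


def filter_zero_phase(x: np.ndarray, fs: float, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Apply the configured Butterworth low-pass forward and backward.

    Output has the same length as the input and zero phase shift.  Requires
    ``fs > 2 * cutoff`` and enough samples to cover the filtfilt warm-up
    padding.
    """
    x = np.asarray(x, dtype=float)
    if not fs > 2.0 * spec.cutoff_hz:
        raise ParameterError(
            f"sampling rate {fs} Hz must exceed twice the {spec.cutoff_hz} Hz cutoff"
        )
    b, a = signal.butter(spec.order, spec.cutoff_hz, btype="low", fs=fs)
    padlen = 3 * max(len(a), len(b))
    if x.size <= padlen:
        raise ParameterError(f"signal of {x.size} samples too short for filtering (need > {padlen})")
    if not spec.zero_phase:
        return signal.lfilter(b, a, x)
    return signal.filtfilt(b, a, x)


def resample_series(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Polyphase-decimate ``x`` from ``fs_in`` to ``fs_out`` Hz.

    Intended to run after the 15 Hz low-pass, which already acts as the
    anti-alias filter; band-limited content below the cutoff is preserved
    within 1 % amplitude.  Upsampling is not supported.
    """
    x = np.asarray(x, dtype=float)
    if fs_in < fs_out:
        raise ParameterError(f"fs_in {fs_in} < fs_out {fs_out}: upsampling unsupported")
    ratio = Fraction(fs_out / fs_in).limit_denominator(10000)
    if ratio == 1:
        return x.copy()
    return signal.resample_poly(x, ratio.numerator, ratio.denominator)


def _trim(x: np.ndarray, fs: float, head_s: float, tail_s: float) -> np.ndarray:
    i0 = int(round(head_s * fs))
    i1 = x.size - int(round(tail_s * fs))
    return x[i0:i1]


def trim_condition(rec: GrfRecording, markers: MarkerSet = None,
                   head_s: float = DEFAULT_HEAD_S, tail_s: float = DEFAULT_TAIL_S):
    """Cut the start/stop transients off force and marker streams.

    Both streams are trimmed to the same wall-clock window; the condition
    duration shrinks by exactly ``head_s + tail_s`` seconds.  A condition
    shorter than that is unusable and raises.
    """
    if rec.duration_s <= head_s + tail_s:
        raise ParameterError(
            f"condition of {rec.duration_s:.1f} s cannot lose {head_s + tail_s:.0f} s of transients"
        )
    out_rec = replace(
        rec,
        ap_left=_trim(rec.ap_left, rec.fs_force, head_s, tail_s),
        ap_right=_trim(rec.ap_right, rec.fs_force, head_s, tail_s),
        v_left=None if rec.v_left is None else _trim(rec.v_left, rec.fs_force, head_s, tail_s),
        v_right=None if rec.v_right is None else _trim(rec.v_right, rec.fs_force, head_s, tail_s),
    )
    out_markers = None
    if markers is not None:
        out_markers = MarkerSet(
            ap={k: _trim(v, markers.fs_marker, head_s, tail_s) for k, v in markers.ap.items()},
            ml={k: _trim(v, markers.fs_marker, head_s, tail_s) for k, v in markers.ml.items()},
            fs_marker=markers.fs_marker,
        )
    return out_rec, out_markers


def preprocess_condition(rec: GrfRecording, markers: MarkerSet,
                         spec: FilterSpec = FilterSpec(), target_fs: float = 100.0,
                         head_s: float = DEFAULT_HEAD_S, tail_s: float = DEFAULT_TAIL_S):
    """Full conditioning chain: trim -> filter -> resample force to ``target_fs``.

    Markers are filtered with the same 15 Hz spec (one filter for both
    streams) and are expected to already be at ``target_fs``.
    """
    rec, markers = trim_condition(rec, markers, head_s, tail_s)
    ap_l = filter_zero_phase(rec.ap_left, rec.fs_force, spec)
    ap_r = filter_zero_phase(rec.ap_right, rec.fs_force, spec)
    ap_l = resample_series(ap_l, rec.fs_force, target_fs)
    ap_r = resample_series(ap_r, rec.fs_force, target_fs)
    rec = replace(rec, ap_left=ap_l, ap_right=ap_r, v_left=None, v_right=None,
                  fs_force=target_fs)
    if markers is not None:
        markers = MarkerSet(
            ap={k: filter_zero_phase(v, markers.fs_marker, spec) for k, v in markers.ap.items()},
            ml={k: filter_zero_phase(v, markers.fs_marker, spec) for k, v in markers.ml.items()},
            fs_marker=markers.fs_marker,
        )
    return rec, markers
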