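"""Per-trace response quantities.

Peak ΔF/F within a stimulation window, time to 50% of peak, half-decay
time after the peak, the adaptation index 1 − F_offset/F_peak, capped
pixel maps for display, and two-stage (within-fly, then across-fly)
vibration tuning curves.

Half-crossing times are linearly interpolated between frames so they
are not quantized to the 0.4 s (2.5 fps) or 0.125 s (8.01 Hz) frame
grids; F_offset uses nearest-frame sampling because it is pinned to a
single time point (19 s after stimulus onset by default, where the
stimulus offset typically falls for sustained-stimulation protocols).
Kinetics are defined only for excitatory responses: operations refuse
traces with non-positive peak rather than silently dividing by it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import (
    InvalidParameterError,
    MissingDataError,
    TraceTooShortError,
    UndefinedKineticsError,
)
from .preprocessing import DffTrace

__all__ = [
    "ResponseKinetics",
    "peak_response",
    "rise_decay_times",
    "adaptation_index",
    "compute_kinetics",
    "cap_pixel_map",
    "TuningCurve",
    "vibration_tuning",
]


@dataclass(frozen=True)
class ResponseKinetics:
    """Kinetics of one ΔF/F trace around one stimulation window.

    ``t50_rise`` is measured from stimulus onset; ``t50_decay`` from the
    peak time, and is ``None`` when the trace never falls to half-peak
    before the end of the trial (e.g. a sustained plateau).
    """

    f_peak: float
    t_peak: float  # absolute time of the peak, s
    stim_onset: float
    t50_rise: float | None = None
    t50_decay: float | None = None
    f_offset: float | None = None
    adaptation_index: float | None = None

    def as_dict(self) -> dict:
        return {
            "f_peak": self.f_peak,
            "t_peak": self.t_peak,
            "stim_onset": self.stim_onset,
            "t50_rise": self.t50_rise,
            "t50_decay": self.t50_decay,
            "f_offset": self.f_offset,
            "adaptation_index": self.adaptation_index,
        }


def _window_slice(trace: DffTrace, t_lo: float, t_hi: float) -> np.ndarray:
    sel = np.nonzero((trace.times >= t_lo) & (trace.times <= t_hi))[0]
    if len(sel) == 0:
        raise TraceTooShortError(
            f"no frames in the window [{t_lo}, {t_hi}] s "
            f"(trace spans [{trace.times[0]}, {trace.times[-1]}] s)"
        )
    return sel


def peak_response(
    trace: DffTrace, stim_onset: float, stim_duration: float
) -> ResponseKinetics:
    """Maximum ΔF/F over frames within the stimulation window.

    Ties go to the earliest frame.
    """
    if not stim_duration > 0:
        raise InvalidParameterError("stim_duration must be > 0")
    sel = _window_slice(trace, stim_onset, stim_onset + stim_duration)
    vals = trace.values[sel]
    k = int(np.argmax(vals))  # argmax returns the first maximum
    return ResponseKinetics(
        f_peak=float(vals[k]),
        t_peak=float(trace.times[sel[k]]),
        stim_onset=float(stim_onset),
    )


def _interp_time(t0: float, t1: float, v0: float, v1: float, level: float) -> float:
    if v1 == v0:
        return float(t1)
    return float(t0 + (level - v0) * (t1 - t0) / (v1 - v0))


def rise_decay_times(
    trace: DffTrace, stim_onset: float, kinetics: ResponseKinetics
) -> ResponseKinetics:
    """Fill ``t50_rise`` and ``t50_decay`` on a partially built kinetics record.

    ``t50_rise``: first upward crossing of 0.5·f_peak at or after the
    stimulus onset, relative to onset. ``t50_decay``: first downward
    crossing of 0.5·f_peak after the peak, relative to the peak time;
    ``None`` when the trace never decays that far before it ends.
    """
    if not kinetics.f_peak > 0:
        raise UndefinedKineticsError(
            f"t50 metrics are undefined for f_peak = {kinetics.f_peak}"
        )
    half = 0.5 * kinetics.f_peak
    times, values = trace.times, trace.values

    # --- rise: scan frames from onset up to the peak
    t50_rise: float | None = None
    peak_idx = int(np.argmin(np.abs(times - kinetics.t_peak)))
    prev_idx: int | None = None
    for k in range(peak_idx + 1):
        if times[k] < stim_onset:
            prev_idx = k
            continue
        if values[k] >= half:
            if prev_idx is None or values[prev_idx] >= half:
                t_cross = float(times[k])
            else:
                t_cross = _interp_time(
                    times[prev_idx], times[k], values[prev_idx], values[k], half
                )
            t50_rise = max(t_cross, stim_onset) - stim_onset
            break
        prev_idx = k

    # --- decay: scan frames after the peak
    t50_decay: float | None = None
    for k in range(peak_idx + 1, len(values)):
        if values[k] <= half:
            t_cross = _interp_time(
                times[k - 1], times[k], values[k - 1], values[k], half
            )
            t50_decay = t_cross - kinetics.t_peak
            break

    return replace(
        kinetics, stim_onset=float(stim_onset), t50_rise=t50_rise, t50_decay=t50_decay
    )


def adaptation_index(
    trace: DffTrace,
    stim_onset: float,
    offset_lag: float = 19.0,
    kinetics: ResponseKinetics | None = None,
) -> ResponseKinetics:
    """Adaptation index 1 − F_offset/F_peak.

    ``F_peak`` is the peak ΔF/F in the window from stimulus onset to
    onset + ``offset_lag`` (or is taken from a supplied ``kinetics``
    record); ``F_offset`` is the ΔF/F at the frame nearest
    onset + ``offset_lag``. An index of 1 means complete decay to
    baseline by the offset time, 0 means no adaptation, and negative
    values mean the signal grew over time.
    """
    if not offset_lag > 0:
        raise InvalidParameterError("offset_lag must be > 0")
    t_offset = stim_onset + offset_lag
    if trace.times[-1] < t_offset:
        raise TraceTooShortError(
            f"trace ends at {trace.times[-1]:.3f} s, before the offset sample "
            f"at {t_offset:.3f} s"
        )
    if kinetics is None:
        kinetics = peak_response(trace, stim_onset, offset_lag)
    if not kinetics.f_peak > 0:
        raise UndefinedKineticsError(
            f"adaptation index is undefined for f_peak = {kinetics.f_peak}"
        )
    nearest = int(np.argmin(np.abs(trace.times - t_offset)))
    f_offset = float(trace.values[nearest])
    index = 1.0 - f_offset / kinetics.f_peak
    return replace(kinetics, f_offset=f_offset, adaptation_index=index)


def compute_kinetics(
    trace: DffTrace,
    stim_onset: float,
    stim_duration: float,
    offset_lag: float | None = None,
) -> ResponseKinetics:
    """Peak, half-rise/half-decay, and (optionally) the adaptation index."""
    kin = peak_response(trace, stim_onset, stim_duration)
    if not kin.f_peak > 0:
        raise UndefinedKineticsError(
            f"kinetics are undefined for f_peak = {kin.f_peak}"
        )
    kin = rise_decay_times(trace, stim_onset, kin)
    if offset_lag is not None:
        full = adaptation_index(trace, stim_onset, offset_lag, kinetics=kin)
        kin = replace(kin, f_offset=full.f_offset, adaptation_index=full.adaptation_index)
    return kin


def kinetics_to_frame(records: Iterable[tuple[dict, ResponseKinetics]]) -> pd.DataFrame:
    """One row per trace: identifying labels followed by the kinetics."""
    rows = []
    for labels, kin in records:
        row = dict(labels)
        row.update(kin.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def cap_pixel_map(
    pixel_map: np.ndarray, cap: float = 3.0
) -> tuple[np.ndarray, np.ndarray]:
    """Flag display outliers in a per-pixel peak-ΔF/F map.

    Pixels with values strictly above ``cap`` (default 3.0, i.e. 300%
    ΔF/F) are flagged for white rendering; values at or below the cap
    pass through untouched. Returns ``(display_map, capped_mask)`` where
    the display map holds NaN at capped pixels (NaN renders as the
    colormap's "bad"/white color).
    """
    pm = np.asarray(pixel_map, dtype=float)
    if not np.all(np.isfinite(pm)):
        raise InvalidParameterError("pixel map must be finite")
    mask = pm > cap
    display = pm.copy()
    display[mask] = np.nan
    return display, mask


@dataclass(frozen=True)
class TuningCurve:
    """Frequency tuning: within-fly means, then the across-fly mean."""

    frequencies: np.ndarray  # Hz, strictly increasing
    mean_response: np.ndarray  # ΔF/F per frequency
    per_fly: pd.DataFrame  # index = fly_id, columns = frequency
    n_flies: int

    def to_frame(self) -> pd.DataFrame:
        out = self.per_fly.T.copy()
        out.insert(0, "mean", self.mean_response)
        out.index.name = "frequency_hz"
        return out


def vibration_tuning(responses: pd.DataFrame) -> TuningCurve:
    """Two-stage tuning curve from per-repetition response summaries.

    ``responses`` must have columns ``fly_id``, ``frequency_hz``,
    ``response`` (one row per repetition; a ``rep`` column is allowed
    and ignored). Responses are averaged within each fly before
    averaging across flies, so flies with unequal repetition counts
    contribute equally. Every fly must have at least one repetition at
    every frequency.
    """
    required = {"fly_id", "frequency_hz", "response"}
    if not required.issubset(responses.columns):
        raise InvalidParameterError(
            f"responses must have columns {sorted(required)}"
        )
    if len(responses) == 0:
        raise MissingDataError("responses table is empty")
    flies = sorted(responses["fly_id"].unique())
    freqs = np.sort(responses["frequency_hz"].unique())
    per_fly = responses.groupby(["fly_id", "frequency_hz"])["response"].mean().unstack()
    for fly in flies:
        for f in freqs:
            if fly not in per_fly.index or pd.isna(per_fly.loc[fly, f]):
                raise MissingDataError(
                    f"fly {fly!r} has no response at {f} Hz"
                )
    per_fly = per_fly.loc[flies, freqs]
    mean = per_fly.mean(axis=0).to_numpy()
    return TuningCurve(
        frequencies=np.asarray(freqs, dtype=float),
        mean_response=mean,
        per_fly=per_fly,
        n_flies=len(flies),
    )
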