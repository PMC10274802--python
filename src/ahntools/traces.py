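"""Background-subtracted ΔF/F and per-group calcium-trace aggregation.

Each recording carries a focal ROI intensity series (a soma or dendritic
region) and a background ROI drawn in empty neuropil nearby.  Background
is subtracted frame-by-frame, the baseline F0 is the mean corrected
fluorescence over the 5 s before stimulus onset, and ΔF/F is
(F_corr − F0) / F0.  Group means preserve the individual traces for the
per-animal overlay plots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import ConfigError, ValidationError


@dataclass
class TraceRecording:
    """One ROI's fluorescence time series with its background ROI."""

    rate_hz: float
    focal: np.ndarray
    background: np.ndarray
    stim_time_s: float
    soma_id: str = ""
    fly_id: str = ""
    trial_id: str = ""

    def __post_init__(self) -> None:
        self.focal = np.asarray(self.focal, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.rate_hz <= 0:
            raise ConfigError(f"frame rate must be positive, got {self.rate_hz}")
        if self.focal.shape != self.background.shape or self.focal.ndim != 1:
            raise ValidationError("focal and background series must be equal-length 1D")
        dur = len(self.focal) / self.rate_hz
        if not (0 <= self.stim_time_s <= dur):
            raise ValidationError(
                f"stimulus time {self.stim_time_s}s outside recording of {dur:.3g}s")

    @property
    def stim_frame(self) -> int:
        return int(round(self.stim_time_s * self.rate_hz))

    def times(self) -> np.ndarray:
        return np.arange(len(self.focal)) / self.rate_hz


def dff(rec: TraceRecording, baseline_window_s: float = 5.0,
        baseline_on_corrected: bool = True) -> np.ndarray:
    """ΔF/F with frame-wise background subtraction and pre-stimulus baseline.

    F_corr(t) = F(t) − B(t); F0 = mean of F_corr over
    [stim − window, stim); output (F_corr − F0) / F0.  With
    ``baseline_on_corrected=False`` F0 is taken on the raw focal trace
    instead (the subtraction still applies to the numerator).
    """
    n_base = int(round(baseline_window_s * rec.rate_hz))
    stim = rec.stim_frame
    if stim - n_base < 0:
        raise ConfigError(
            f"need {baseline_window_s}s of pre-stimulus recording, have "
            f"{stim / rec.rate_hz:.3g}s")
    corr = rec.focal - rec.background
    base = corr if baseline_on_corrected else rec.focal
    f0 = float(base[stim - n_base:stim].mean())
    if f0 <= 0:
        raise ValidationError(
            f"baseline F0 = {f0:.4g} <= 0 (focal ROI darker than background)")
    return (corr - f0) / f0


def aggregate_traces(
    series: list[np.ndarray],
    rates_hz: list[float] | float | None = None,
    resample: bool = False,
    target_rate_hz: float | None = None,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Pointwise mean across stimulus-aligned ΔF/F traces.

    Traces must share a frame rate unless ``resample`` is set, in which
    case they are linearly interpolated onto the slowest (or
    ``target_rate_hz``) clock over the common duration.  Returns
    (mean series, individual series) — individuals are preserved for
    per-animal overlay export.
    """
    if not series:
        raise ConfigError("no traces to aggregate")
    series = [np.asarray(s, dtype=float) for s in series]
    if rates_hz is not None and not np.isscalar(rates_hz):
        rates = list(rates_hz)
        if len(set(rates)) > 1:
            if not resample:
                raise ConfigError("mixed frame rates; enable resample=True")
            rate = target_rate_hz or min(rates)
            dur = min(len(s) / r for s, r in zip(series, rates))
            t_out = np.arange(0, dur, 1.0 / rate)
            series = [np.interp(t_out, np.arange(len(s)) / r, s)
                      for s, r in zip(series, rates)]
    n = min(len(s) for s in series)
    if any(len(s) != n for s in series):
        series = [s[:n] for s in series]
    stack = np.vstack(series)
    return stack.mean(axis=0), [np.asarray(s) for s in stack]
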