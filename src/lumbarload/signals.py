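"""EMG amplitude estimation and stream synchronization.

EMG amplitude is estimated by full-wave rectification followed by zero-phase
low-pass smoothing, then interpolated onto the common 50 Hz session grid.
sEMG and IMMU clocks are aligned from the tap markers (short high-amplitude
pulses created by tapping the electrodes/sensor before the measurement): the
per-stream marker times give the EMG-minus-IMMU clock offset, and all EMG
streams are shifted onto the sacrum-IMMU master clock.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .types import DT, SAMPLE_RATE, EmgStream, Session, ValidationError


class SyncError(RuntimeError):
    """Tap-marker detection or synchronization failed."""


@dataclass(frozen=True)
class EnvelopeParams:
    """Parameters of the EMG amplitude estimator.

    smoothing_cutoff is the low-pass corner in Hz (must stay below the 25 Hz
    Nyquist limit of the 50 Hz target grid); 3 Hz is a conventional envelope
    bandwidth for trunk-load estimation.
    """

    smoothing_cutoff: float = 3.0
    rectification: str = "full_wave"
    target_rate: float = SAMPLE_RATE

    def __post_init__(self):
        if not 0.0 < self.smoothing_cutoff < 25.0:
            raise ValidationError(
                f"smoothing_cutoff {self.smoothing_cutoff} Hz outside (0, 25)"
            )
        if self.rectification != "full_wave":
            raise ValidationError("only full-wave rectification is supported")


@dataclass
class SyncResult:
    """Offset of one EMG stream's clock relative to the IMMU master clock."""

    offset: float  # s, EMG clock minus IMMU clock
    marker_times: dict[str, float] = field(default_factory=dict)
    confidence: float = float("inf")


def lowpass_filtfilt(x: np.ndarray, cutoff: float, fs: float, order: int = 2) -> np.ndarray:
    """Zero-phase Butterworth low-pass along axis 0."""
    sos = sps.butter(order, cutoff, btype="low", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x, axis=0)


def emg_amplitude(
    stream: EmgStream,
    params: EnvelopeParams = EnvelopeParams(),
    grid_t: np.ndarray | None = None,
) -> EmgStream:
    """Estimate the amplitude envelope of a raw sEMG channel.

    Full-wave rectification, zero-phase low-pass at ``smoothing_cutoff``,
    then linear interpolation onto the 50 Hz grid (the envelope is band
    limited far below the grid Nyquist, so linear interpolation is exact to
    first order). Returns a new stream carrying the envelope.
    """
    fs = stream.raw_rate
    if fs < 4.0 * params.smoothing_cutoff:
        raise ValidationError(
            f"{stream.channel}: raw rate {fs:.0f} Hz < 4 x cutoff "
            f"{params.smoothing_cutoff} Hz"
        )
    rectified = np.abs(stream.raw)
    smoothed = lowpass_filtfilt(rectified, params.smoothing_cutoff, fs)
    # filtfilt can undershoot below zero near sharp transients
    smoothed = np.maximum(smoothed, 0.0)
    if grid_t is None:
        t0 = np.ceil(stream.t_raw[0] / DT) * DT
        grid_t = t0 + DT * np.arange(int((stream.t_raw[-1] - t0) / DT) + 1)
    env = np.interp(grid_t, stream.t_raw, smoothed)
    return EmgStream(stream.channel, stream.t_raw, stream.raw, grid_t, env)


def detect_tap_marker(
    t: np.ndarray, x: np.ndarray, window: float = 5.0
) -> tuple[float, float]:
    """Locate the tap marker in the pre-trial window of one channel.

    Returns ``(marker_time, confidence)`` where confidence is the prominence
    ratio of the selected transient to the next candidate (``inf`` when it is
    the only one). Raises :class:`SyncError` when no transient stands out.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    mask = t <= t[0] + window
    seg = np.abs(x[mask] - np.median(x[mask]))
    if seg.size < 3 or np.ptp(seg) == 0:
        raise SyncError("no tap marker: flat pre-trial window")
    peaks, props = sps.find_peaks(seg, prominence=1e-12)
    if peaks.size == 0:
        raise SyncError("no tap marker: no transient found in pre-trial window")
    prom = props["prominences"]
    order = np.argsort(prom)[::-1]
    best = peaks[order[0]]
    confidence = float(prom[order[0]] / prom[order[1]]) if peaks.size > 1 else float("inf")
    if confidence <= 1.0:
        raise SyncError(
            f"ambiguous tap marker: prominence ratio {confidence:.2f} <= 1"
        )
    return float(t[mask][best]), confidence


def synchronize(
    session: Session,
    params: EnvelopeParams = EnvelopeParams(),
    window: float = 5.0,
) -> dict[str, SyncResult]:
    """Align all EMG streams of a session onto the sacrum-IMMU clock.

    Per trial, the tap marker is located in the sacrum accelerometer and in
    every raw EMG channel; the offset (EMG clock minus IMMU clock) is the
    median EMG marker time minus the IMMU marker time. EMG raw time axes are
    shifted by the offset and envelopes recomputed on the IMMU 50 Hz grid.
    Mutates the session (streams and ``sync_offsets``) and returns the
    per-trial results.
    """
    results: dict[str, SyncResult] = {}
    for trial in session.trials:
        if "sacrum" not in trial.immu or not trial.emg:
            continue
        sacrum = trial.immu["sacrum"]
        acc_mag = np.linalg.norm(sacrum.linacc, axis=1)
        t_immu, conf_immu = detect_tap_marker(sacrum.t, acc_mag, window)
        emg_markers: dict[str, float] = {}
        confs = [conf_immu]
        for name, ch in trial.emg.items():
            t_m, conf = detect_tap_marker(ch.t_raw, ch.raw, window)
            emg_markers[name] = t_m
            confs.append(conf)
        offset = float(np.median(list(emg_markers.values())) - t_immu)
        grid = sacrum.t
        for name, ch in trial.emg.items():
            shifted = EmgStream(ch.channel, ch.t_raw - offset, ch.raw)
            trial.emg[name] = emg_amplitude(shifted, params, grid_t=grid)
        marker_times = dict(emg_markers)
        marker_times["sacrum"] = t_immu
        results[trial.id] = SyncResult(
            offset=offset, marker_times=marker_times, confidence=float(min(confs))
        )
        session.sync_offsets[trial.id] = offset
    if not results:
        raise SyncError("session contains no trial with both sacrum IMMU and EMG")
    return results


__all__ = [
    "EnvelopeParams",
    "SyncResult",
    "SyncError",
    "lowpass_filtfilt",
    "emg_amplitude",
    "detect_tap_marker",
    "synchronize",
]
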