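"""Signal conditioning: band-pass filtering, down-sampling, average reference.

The conditioning chain mirrors standard resting-state microstate practice:
a zero-phase 1-40 Hz band-pass, integer-ratio decimation to 125 Hz with an
explicit anti-aliasing low-pass, and re-referencing to the common average.
All operations are linear and preserve channel count and labels.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .recording import EEGRecording

__all__ = [
    "bandpass_filter",
    "downsample",
    "average_reference",
    "DEFAULT_EDGE_EXCLUDE_S",
]

#: Seconds excluded at each end of a filtered recording before GFP-peak
#: extraction; forward-backward filtering contaminates the edges.
DEFAULT_EDGE_EXCLUDE_S = 1.0


def bandpass_filter(
    rec: EEGRecording, low_hz: float = 1.0, high_hz: float = 40.0, order: int = 4
) -> EEGRecording:
    """Zero-phase Butterworth band-pass, applied independently per channel.

    A 4th-order Butterworth is run forward and backward (``sosfiltfilt``),
    which doubles the effective order and cancels phase distortion so that
    instantaneous topographies are not delayed relative to each other.

    Raises
    ------
    ValueError
        If the band edges do not satisfy ``0 < low_hz < high_hz < fs/2``.
    """
    nyq = rec.fs / 2.0
    if not low_hz > 0:
        raise ValueError(f"low edge must be positive, got low_hz={low_hz}")
    if not low_hz < high_hz:
        raise ValueError(f"low edge {low_hz} Hz must be below high edge {high_hz} Hz")
    if not high_hz < nyq:
        raise ValueError(f"high edge {high_hz} Hz must be below Nyquist ({nyq} Hz)")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=rec.fs, output="sos")
    out = signal.sosfiltfilt(sos, rec.data, axis=1)
    return rec.with_data(out)


def bandpass_response(
    fs: float, low_hz: float, high_hz: float, freqs: np.ndarray, order: int = 4
) -> np.ndarray:
    """Magnitude response of :func:`bandpass_filter` at ``freqs`` (Hz).

    Because the filter is applied forward and backward, the effective
    magnitude is the squared single-pass magnitude.
    """
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    _, h = signal.sosfreqz(sos, worN=2 * np.pi * np.asarray(freqs) / fs)
    return np.abs(h) ** 2


def downsample(rec: EEGRecording, target_fs: float, aa_order: int = 8) -> EEGRecording:
    """Integer-ratio decimation with a zero-phase anti-aliasing low-pass.

    The decimation factor ``fs / target_fs`` must be an integer (e.g. the
    8:1 step from 1 kHz to 125 Hz); non-integer ratios are refused rather
    than silently resampled.  Before decimation the data are low-passed at
    ``0.4 * target_fs`` with a zero-phase Butterworth.  With ratio 1 the
    operation is a no-op.
    """
    if target_fs > rec.fs:
        raise ValueError(f"target_fs={target_fs} exceeds recording fs={rec.fs}")
    ratio = rec.fs / target_fs
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9:
        raise ValueError(
            f"fs={rec.fs} is not an integer multiple of target_fs={target_fs} "
            f"(ratio {ratio:.6g}); refusing non-integer decimation"
        )
    if q == 1:
        return rec.with_data(rec.data.copy())
    sos = signal.butter(aa_order, 0.4 * target_fs, btype="lowpass", fs=rec.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.data, axis=1)
    n_out = rec.n_samples // q
    out = filtered[:, ::q][:, :n_out]
    return rec.with_data(out, fs=float(target_fs))


def average_reference(rec: EEGRecording) -> EEGRecording:
    """Subtract the instantaneous mean across channels from every channel.

    After average referencing the per-sample channel mean is zero, which the
    spatial-correlation machinery downstream assumes.  Idempotent; leaves the
    global field power of every sample unchanged.
    """
    out = rec.data - rec.data.mean(axis=0, keepdims=True)
    return rec.with_data(out)
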