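"""Conditioning of raw monopolar sEMG.

The chain applied before any map analysis: zero-phase 20-450 Hz band-pass,
power-line removal by spectral interpolation (50 Hz and four higher
harmonics), detection of channels with bad electrode-skin contact, and
envelope extraction (rectification followed by a zero-phase 1 Hz low-pass).
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .recording import EmgRecording, EnvelopeMatrix

__all__ = [
    "bandpass",
    "remove_powerline",
    "envelope",
    "detect_bad_channels",
    "preprocess_emg",
]


def bandpass(rec: EmgRecording, low: float = 20.0, high: float = 450.0) -> EmgRecording:
    """Zero-phase 4th-order Butterworth band-pass (20-450 Hz).

    Applied forward-backward (``sosfiltfilt``), which doubles the effective
    order and cancels phase distortion -- envelope timing therefore stays
    aligned with the kinematics.
    """
    if rec.fs <= 2 * high:
        raise ValueError(
            f"sampling rate {rec.fs} too low: Nyquist must exceed {high} Hz"
        )
    sos = sps.butter(4, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    return rec.with_data(sps.sosfiltfilt(sos, rec.data, axis=-1))


def remove_powerline(
    rec: EmgRecording,
    f0: float = 50.0,
    n_harmonics: int = 5,
    half_width_hz: float = 1.0,
) -> EmgRecording:
    """Remove power-line interference by spectral interpolation.

    For each harmonic ``k*f0`` (k = 1..n_harmonics) the magnitude spectrum
    inside a narrow band (+- ``half_width_hz``) is replaced by linear
    interpolation between the mean magnitudes of the two flanking bands of
    equal width; phases are retained, so the inverse transform stays real
    and the broadband signal is untouched outside the notches.
    """
    if f0 * n_harmonics >= rec.fs / 2:
        raise ValueError("highest harmonic exceeds the Nyquist frequency")
    n = rec.n_samples
    spec = np.fft.rfft(rec.data, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / rec.fs)
    mag = np.abs(spec)
    phase = np.angle(spec)
    for k in range(1, n_harmonics + 1):
        fc = k * f0
        band = (freqs >= fc - half_width_hz) & (freqs <= fc + half_width_hz)
        if not band.any():
            continue
        left = (freqs >= fc - 2 * half_width_hz) & (freqs < fc - half_width_hz)
        right = (freqs > fc + half_width_hz) & (freqs <= fc + 2 * half_width_hz)
        if not left.any() or not right.any():
            continue
        m_left = mag[:, left].mean(axis=1)
        m_right = mag[:, right].mean(axis=1)
        f_left = freqs[left].mean()
        f_right = freqs[right].mean()
        frac = (freqs[band] - f_left) / (f_right - f_left)
        mag[:, band] = m_left[:, None] + frac[None, :] * (m_right - m_left)[:, None]
    cleaned = np.fft.irfft(mag * np.exp(1j * phase), n=n, axis=-1)
    out = rec.with_data(cleaned)
    out.meta = {**rec.meta, "powerline": {"f0": f0, "n_harmonics": n_harmonics,
                                          "half_width_hz": half_width_hz}}
    return out


def envelope(rec: EmgRecording, cutoff_hz: float = 1.0) -> EnvelopeMatrix:
    """Envelope: rectify, then zero-phase 4th-order Butterworth low-pass (1 Hz).

    Filter ringing can push the smoothed rectified signal slightly below
    zero; those values are clipped to 0 (the factorization downstream
    requires nonnegative input).
    """
    sos = sps.butter(4, cutoff_hz, btype="lowpass", fs=rec.fs, output="sos")
    env = sps.sosfiltfilt(sos, np.abs(rec.data), axis=-1)
    return EnvelopeMatrix(
        env=np.clip(env, 0.0, None),
        fs=rec.fs,
        grid=rec.grid,
        bad_mask=rec.bad_mask.copy(),
        provenance={"envelope_cutoff_hz": cutoff_hz, "order": 4,
                    "zero_phase": True, **rec.meta},
    )


def detect_bad_channels(
    env: EnvelopeMatrix,
    z_thresh: float = 3.5,
    corr_floor: float = 0.2,
    corr_rescue: float = 0.5,
    scale_floor_decades: float = 0.1,
    decimate: int = 32,
    max_bad_fraction: float = 0.5,
) -> np.ndarray:
    """Flag channels with bad electrode-skin contact from their envelopes.

    A channel is flagged when its envelope is inconsistent with a working
    contact on a grid where neighbouring electrodes see shared activity:

    * robust z-score of log10 envelope RMS (median / scaled MAD, scale
      floored at ``scale_floor_decades`` so a homogeneous noise floor does
      not inflate scores) below ``-z_thresh`` -- dead or attenuated contact;
    * z-score above ``+z_thresh`` *and* maximum absolute correlation with
      its 4-connected neighbours below ``corr_rescue`` -- an isolated
      high-amplitude artifact (genuine activity is spatially shared);
    * neighbour correlation below ``corr_floor`` with a below-median
      amplitude (z < -1) -- low-level uncorrelated contact noise.

    Raises if more than ``max_bad_fraction`` of the grid is flagged
    (systemic acquisition failure).
    """
    if env.n_channels < 8:
        raise ValueError("bad-channel detection needs at least 8 channels")
    e = env.env[:, ::decimate]
    rms = np.sqrt(np.mean(env.env**2, axis=1))
    log_rms = np.log10(np.maximum(rms, 1e-300))
    med = np.median(log_rms)
    mad = np.median(np.abs(log_rms - med))
    scale = max(1.4826 * mad, scale_floor_decades)
    z = (log_rms - med) / scale

    e_c = e - e.mean(axis=1, keepdims=True)
    sd = e_c.std(axis=1)
    max_corr = np.zeros(env.n_channels)
    for i in range(env.n_channels):
        best = 0.0
        for j in env.grid.neighbors(i):
            if sd[i] > 0 and sd[j] > 0:
                r = float(e_c[i] @ e_c[j] / (e.shape[1] * sd[i] * sd[j]))
                best = max(best, abs(r))
        max_corr[i] = best

    flagged = (
        (z < -z_thresh)
        | ((z > z_thresh) & (max_corr < corr_rescue))
        | ((max_corr < corr_floor) & (z < -1.0))
    )
    if flagged.sum() > max_bad_fraction * env.n_channels:
        raise ValueError(
            f"{flagged.sum()} of {env.n_channels} channels flagged: "
            "systemic acquisition failure"
        )
    return flagged


def preprocess_emg(
    rec: EmgRecording,
    f0: float = 50.0,
    n_harmonics: int = 5,
) -> EnvelopeMatrix:
    """Full conditioning chain: band-pass, power-line removal, envelope,
    bad-channel detection.  Returns the envelope matrix with ``bad_mask``
    set (union of any mask already on the recording and the detected one).
    """
    clean = remove_powerline(bandpass(rec), f0=f0, n_harmonics=n_harmonics)
    env = envelope(clean)
    detected = detect_bad_channels(env)
    env.bad_mask = env.bad_mask | detected
    return env
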