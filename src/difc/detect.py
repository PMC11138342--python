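"""Per-channel background removal, noise estimation and peak finding.

The detector is intentionally simple and threshold-based, mirroring how
transient cell-transit spikes are picked out of a slowly drifting
autofluorescence background:

1. subtract the median of a moving 5 s window (background),
2. estimate the noise as the standard deviation of the background-subtracted
   signal in a moving 1 min window,
3. keep transient local maxima whose amplitude is at least ``k = 5`` times
   the local noise, i.e. a minimum peak SNR of ``20*log10(5) = 13.9`` dB.

All windows are centered on the sample and truncated at the trace edges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .io import ChannelId

__all__ = [
    "NoiseProfile",
    "PeakCandidate",
    "DetectionParams",
    "subtract_background",
    "estimate_noise",
    "find_candidates",
    "snr_db",
    "detect_channel",
    "candidates_to_frame",
    "frame_to_candidates",
]

#: Minimum local noise (mV) used when normalizing amplitudes, so that
#: synthetic noiseless traces do not divide by zero.
SIGMA_FLOOR_MV = 1e-6


@dataclass(frozen=True)
class NoiseProfile:
    """Moving-window noise level of a background-subtracted channel."""

    sigma: np.ndarray  # mV per sample, same length as the signal
    window_s: float


@dataclass(frozen=True)
class PeakCandidate:
    """A transient maximum on one channel that passed the k-sigma threshold."""

    channel: ChannelId
    time_s: float
    index: int
    amplitude_mV: float
    amplitude_sigma: float
    width_s: float  # full width at half maximum
    snr_db: float
    #: raw (pre-background-subtraction) signal at the peak sample; lets the
    #: saturation check see peaks clipped at the detector rail, whose
    #: background-subtracted amplitude understates the true intensity
    raw_mV: float = float("nan")


@dataclass(frozen=True)
class DetectionParams:
    bg_window_s: float = 5.0
    noise_window_s: float = 60.0
    k: float = 5.0
    #: iteratively re-estimate noise with candidate peaks masked out; at
    #: high event rates the pulses themselves otherwise inflate the
    #: moving-window sigma and raise the threshold against dim events
    mask_peaks_for_noise: bool = False


def _window_samples(window_s: float, sampling_rate: float) -> int:
    """Centered-window length in samples; forced odd for symmetry."""
    n = int(round(window_s * sampling_rate))
    if n % 2 == 0:
        n += 1
    return max(n, 1)


def subtract_background(
    signal: np.ndarray, sampling_rate: float, window_s: float = 5.0
) -> np.ndarray:
    """Remove the moving-median background from a raw channel.

    ``out[i] = signal[i] - median(signal[i-h : i+h])`` with the window
    truncated at the edges.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.size == 0:
        raise ValueError("empty signal")
    w = _window_samples(window_s, sampling_rate)
    if w < 3:
        raise ValueError(
            f"background window of {window_s} s is under 3 samples at "
            f"{sampling_rate} Hz"
        )
    med = pd.Series(signal).rolling(w, center=True, min_periods=1).median()
    return signal - med.to_numpy()


def estimate_noise(
    bg_subtracted: np.ndarray, sampling_rate: float, window_s: float = 60.0
) -> NoiseProfile:
    """Moving-window standard deviation of the background-subtracted signal.

    Uses the population standard deviation (ddof=0).  Input is assumed to be
    already background-subtracted.
    """
    x = np.asarray(bg_subtracted, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    w = _window_samples(window_s, sampling_rate)
    if w < 2:
        raise ValueError(
            f"noise window of {window_s} s is under 2 samples at "
            f"{sampling_rate} Hz"
        )
    sd = pd.Series(x).rolling(w, center=True, min_periods=1).std(ddof=0)
    return NoiseProfile(sigma=sd.to_numpy(), window_s=window_s)


def snr_db(amplitude: float, sigma: float) -> float:
    """Peak signal-to-noise ratio ``20*log10(amplitude/sigma)`` in dB."""
    if not (amplitude > 0 and sigma > 0):
        raise ValueError("amplitude and sigma must be positive")
    return 20.0 * math.log10(amplitude / sigma)


def _fwhm(x: np.ndarray, peak: int, sampling_rate: float) -> float:
    """Full width at half maximum around ``peak`` by linear interpolation."""
    half = x[peak] / 2.0
    # left crossing
    j = peak
    while j > 0 and x[j - 1] > half:
        j -= 1
    if j == 0:
        left = 0.0
    else:
        lo, hi = x[j - 1], x[j]
        left = (j - 1) + (half - lo) / (hi - lo) if hi != lo else float(j)
    j = peak
    n = x.size
    while j < n - 1 and x[j + 1] > half:
        j += 1
    if j == n - 1:
        right = float(n - 1)
    else:
        hi, lo = x[j], x[j + 1]
        right = j + (hi - half) / (hi - lo) if hi != lo else float(j)
    width = (right - left) / sampling_rate
    # a one-sample spike still has finite width: floor at one sample period
    return max(width, 1.0 / sampling_rate)


def _merge_nearby(cands: list[PeakCandidate]) -> list[PeakCandidate]:
    """Merge candidates closer than half a peak width, keeping the taller.

    One cell transiting the sensing region produces one continuous peak;
    noise riding on its flanks must not be double counted.
    """
    if len(cands) < 2:
        return cands
    cands = sorted(cands, key=lambda c: c.time_s)
    merged: list[PeakCandidate] = [cands[0]]
    for c in cands[1:]:
        prev = merged[-1]
        if c.time_s - prev.time_s < 0.5 * max(c.width_s, prev.width_s):
            if c.amplitude_mV > prev.amplitude_mV:
                merged[-1] = c
        else:
            merged.append(c)
    return merged


def find_candidates(
    bg_subtracted: np.ndarray,
    noise: NoiseProfile,
    sampling_rate: float,
    channel: ChannelId,
    k: float = 5.0,
) -> list[PeakCandidate]:
    """Transient maxima with amplitude >= ``k`` x the local noise.

    A candidate is a strict local maximum (plateaus contribute their
    midpoint) of the background-subtracted trace.  Amplitude is expressed
    both in mV and in local-noise-sigma units; width is the FWHM measured by
    linear interpolation between samples.
    """
    if not k > 0:
        raise ValueError("k must be > 0")
    x = np.asarray(bg_subtracted, dtype=float)
    sigma = np.asarray(noise.sigma, dtype=float)
    if sigma.shape != x.shape:
        raise ValueError("noise profile not aligned with signal")
    peaks, _ = find_peaks(x)
    out: list[PeakCandidate] = []
    for p in peaks:
        sig = max(sigma[p], SIGMA_FLOOR_MV)
        amp = x[p]
        if amp < k * sig:
            continue
        out.append(
            PeakCandidate(
                channel=channel,
                time_s=p / sampling_rate,
                index=int(p),
                amplitude_mV=float(amp),
                amplitude_sigma=float(amp / sig),
                width_s=_fwhm(x, p, sampling_rate),
                snr_db=snr_db(amp, sig),
            )
        )
    return _merge_nearby(out)


def detect_channel(
    signal: np.ndarray,
    sampling_rate: float,
    channel: ChannelId,
    params: DetectionParams = DetectionParams(),
) -> tuple[list[PeakCandidate], np.ndarray, NoiseProfile]:
    """Run background subtraction, noise estimation and peak finding.

    Returns ``(candidates, bg_subtracted, noise)``.  With
    ``mask_peaks_for_noise`` the noise is re-estimated after masking two
    widths either side of each candidate, and detection repeated against
    the refined profile until the candidate set is stable (newly revealed
    dim peaks are masked in turn); at most 5 passes.
    """
    raw = np.asarray(signal, dtype=float)
    bg = subtract_background(raw, sampling_rate, params.bg_window_s)
    noise = estimate_noise(bg, sampling_rate, params.noise_window_s)
    cands = find_candidates(bg, noise, sampling_rate, channel, params.k)
    if params.mask_peaks_for_noise:
        w = _window_samples(params.noise_window_s, sampling_rate)
        for _ in range(5):
            if not cands:
                break
            masked = pd.Series(bg.copy())
            for c in cands:
                half = max(int(round(2 * c.width_s * sampling_rate)), 1)
                masked.iloc[max(c.index - half, 0) : c.index + half + 1] = np.nan
            sd = masked.rolling(w, center=True, min_periods=2).std(ddof=0)
            sd = sd.ffill().bfill().fillna(0.0)
            refined = NoiseProfile(sigma=sd.to_numpy(), window_s=params.noise_window_s)
            new = find_candidates(bg, refined, sampling_rate, channel, params.k)
            noise = refined
            if len(new) == len(cands) and all(
                a.index == b.index for a, b in zip(new, cands)
            ):
                cands = new
                break
            cands = new
    cands = [replace(c, raw_mV=float(raw[c.index])) for c in cands]
    return cands, bg, noise


# ---------------------------------------------------------------------------
# candidate tables (CLI plumbing)

_LABELS = {"P1-G": (1, "green"), "P1-O": (1, "orange"),
           "P2-G": (2, "green"), "P2-O": (2, "orange")}


def candidates_to_frame(candidates) -> pd.DataFrame:
    """Candidate list as a DataFrame for columnar-text export."""
    return pd.DataFrame(
        [
            {
                "channel": c.channel.label,
                "time_s": c.time_s,
                "index": c.index,
                "amplitude_mV": c.amplitude_mV,
                "amplitude_sigma": c.amplitude_sigma,
                "width_s": c.width_s,
                "snr_db": c.snr_db,
                "raw_mV": c.raw_mV,
            }
            for c in candidates
        ],
        columns=["channel", "time_s", "index", "amplitude_mV",
                 "amplitude_sigma", "width_s", "snr_db", "raw_mV"],
    )


def frame_to_candidates(df: pd.DataFrame) -> list[PeakCandidate]:
    out = []
    for row in df.itertuples(index=False):
        probe, color = _LABELS[str(row.channel)]
        out.append(
            PeakCandidate(
                channel=ChannelId(probe, color),
                time_s=float(row.time_s),
                index=int(row.index),
                amplitude_mV=float(row.amplitude_mV),
                amplitude_sigma=float(row.amplitude_sigma),
                width_s=float(row.width_s),
                snr_db=float(row.snr_db),
                raw_mV=float(getattr(row, "raw_mV", float("nan"))),
            )
        )
    return out
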