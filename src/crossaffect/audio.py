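"""Audio containers, WAV loading and frame slicing.

All downstream descriptor extraction operates on mono clips resampled to a
canonical 16 kHz rate, so that the 26 auditory bands cover 0-8 kHz exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile
from scipy.signal import get_window, resample_poly

CANONICAL_RATE = 16_000

DOMAINS = ("sound", "music", "speech_spont", "speech_enacted", "synthetic")


@dataclass
class AudioClip:
    """A mono audio clip with samples in [-1, 1].

    Parameters
    ----------
    samples : ndarray
        Amplitude sequence, peak-normalized to at most 1 in magnitude.
    rate : int
        Sampling rate in Hz.
    clip_id : str
        Identifier used in output tables and logs.
    domain : str
        Domain tag (``sound``, ``music``, ``speech_spont``,
        ``speech_enacted`` or ``synthetic``).
    """

    samples: np.ndarray
    rate: int
    clip_id: str = ""
    domain: str = "synthetic"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64).ravel()
        if self.samples.size == 0:
            raise ValueError(f"clip {self.clip_id!r}: empty sample array")
        if self.rate <= 0:
            raise ValueError(f"clip {self.clip_id!r}: rate must be > 0")
        peak = np.max(np.abs(self.samples))
        if peak > 1.0:
            self.samples = self.samples / peak

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate

    def resampled(self, rate: int = CANONICAL_RATE) -> "AudioClip":
        if self.rate == rate:
            return self
        g = np.gcd(int(self.rate), int(rate))
        out = resample_poly(self.samples, rate // g, self.rate // g)
        return AudioClip(np.clip(out, -1.0, 1.0), rate, self.clip_id, self.domain)


def load_wav(path, clip_id: str | None = None, domain: str = "synthetic",
             rate: int = CANONICAL_RATE) -> AudioClip:
    """Load a WAV file (PCM 16/24/32-bit or float), downmix and resample."""
    sr, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim > 1:  # downmix channels
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(np.float64)
    if clip_id is None:
        clip_id = str(path)
    clip = AudioClip(data, sr, clip_id=clip_id, domain=domain)
    return clip.resampled(rate)


def save_wav(path, clip: AudioClip) -> None:
    """Write a clip as 16-bit PCM WAV."""
    pcm = np.clip(clip.samples, -1.0, 1.0)
    wavfile.write(path, clip.rate, (pcm * 32767.0).astype(np.int16))


def frame_signal(samples: np.ndarray, rate: int, win_len: float, hop: float,
                 window: str = "hamming") -> tuple[np.ndarray, np.ndarray]:
    """Slice a signal into tapered frames.

    Returns ``(frames, raw_frames)`` where ``frames`` is tapered by the
    requested window and ``raw_frames`` holds the untapered samples (needed
    for the zero-crossing rate).  Frame count is
    ``floor((n - win) / hop) + 1``.
    """
    if hop <= 0 or win_len < hop:
        raise ValueError("require win_len >= hop > 0")
    samples = np.asarray(samples, dtype=np.float64)
    win = int(round(win_len * rate))
    hop_n = int(round(hop * rate))
    n = samples.size
    if n < win:
        raise ValueError(
            f"clip of {n} samples shorter than one {win}-sample window")
    n_frames = (n - win) // hop_n + 1
    idx = np.arange(win)[None, :] + hop_n * np.arange(n_frames)[:, None]
    raw = samples[idx]
    taper = get_window(window, win, fftbins=True)
    return raw * taper, raw


def frame_times(n_frames: int, win_len: float, hop: float) -> np.ndarray:
    """Frame center times in seconds."""
    return hop * np.arange(n_frames) + win_len / 2.0


def frames_centered(samples: np.ndarray, rate: int, centers: np.ndarray,
                    win_len: float) -> np.ndarray:
    """Untapered frames of length ``win_len`` centered on given times.

    The signal is zero-padded at both edges so every requested center is
    valid; used to place long pitch/voice-quality analysis windows on the
    same 10 ms frame grid as the short spectral windows.
    """
    win = int(round(win_len * rate))
    half = win // 2
    padded = np.pad(np.asarray(samples, dtype=np.float64), (half, win))
    starts = np.round(np.asarray(centers) * rate).astype(int)  # + half - half
    idx = np.arange(win)[None, :] + starts[:, None]
    return padded[idx]
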