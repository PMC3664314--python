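"""Frame-level low-level descriptor (LLD) extraction.

Produces, per 10 ms frame, the 64 canonical descriptors used throughout the
pipeline: energy-related contours (auditory loudness, RASTA-filtered
loudness, RMS energy, zero-crossing rate), spectral/cepstral contours
(26 RASTA-filtered auditory bands, MFCC 1-14, sub-band energies, roll-off
points, flux, centroid, entropy, slope, psychoacoustic sharpness,
harmonicity, spectral moments) and voicing-related contours (F0 via
subharmonic summation with Viterbi smoothing, log HNR, jitter, shimmer).
The voicing *probability* contour is kept as an auxiliary array that defines
the voiced mask.

All spectral analysis runs at a canonical 16 kHz so the 26 auditory bands
span 0-8 kHz.  Short 25 ms Hamming windows on a 10 ms hop are used for
spectral/cepstral/energy contours; longer 60 ms windows, centered on the
same 10 ms grid, for F0 and voice quality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import dct, irfft, rfft
from scipy.signal import find_peaks, get_window, lfilter

from .audio import (
    CANONICAL_RATE,
    AudioClip,
    frame_signal,
    frame_times,
    frames_centered,
)

# ---------------------------------------------------------------------------
# canonical descriptor inventory

ENERGY_LLDS = ["loudness", "rasta_loudness", "rms_energy", "zcr"]
BAND_LLDS = [f"aud_band_{b}" for b in range(1, 27)]
MFCC_LLDS = [f"mfcc_{i}" for i in range(1, 15)]
SPECTRAL_LLDS = (
    BAND_LLDS
    + MFCC_LLDS
    + [
        "energy_250_650",
        "energy_1000_4000",
        "rolloff_25",
        "rolloff_50",
        "rolloff_75",
        "rolloff_90",
        "spectral_flux",
        "spectral_centroid",
        "spectral_entropy",
        "spectral_slope",
        "sharpness",
        "harmonicity",
        "spectral_variance",
        "spectral_skewness",
        "spectral_kurtosis",
    ]
)
VOICING_LLDS = ["f0", "log_hnr", "jitter_local", "jitter_delta", "shimmer_local"]

LLD_NAMES: list[str] = ENERGY_LLDS + SPECTRAL_LLDS + VOICING_LLDS
assert len(LLD_NAMES) == 64

# Figure-style group labels (cepstral / prosodic / spectral / sound quality)
LLD_GROUPS: dict[str, str] = {}
for _n in ENERGY_LLDS:
    LLD_GROUPS[_n] = "prosodic"
for _n in SPECTRAL_LLDS:
    LLD_GROUPS[_n] = "cepstral" if _n.startswith("mfcc_") else "spectral"
LLD_GROUPS["f0"] = "prosodic"
for _n in ("log_hnr", "jitter_local", "jitter_delta", "shimmer_local"):
    LLD_GROUPS[_n] = "sound_quality"

# coarse category (energy / spectral / voicing) used by the feature manifest
LLD_CATEGORY: dict[str, str] = {}
for _n in ENERGY_LLDS:
    LLD_CATEGORY[_n] = "energy"
for _n in SPECTRAL_LLDS:
    LLD_CATEGORY[_n] = "spectral"
for _n in VOICING_LLDS:
    LLD_CATEGORY[_n] = "voicing"


@dataclass
class LLDConfig:
    """All pinned extraction constants (the ``lld:`` config block)."""

    rate: int = CANONICAL_RATE
    win_len: float = 0.025
    hop: float = 0.010
    window: str = "hamming"
    n_fft: int = 512
    n_bands: int = 26
    fmin: float = 0.0
    fmax: float = 8000.0
    compression: float = 0.33          # Stevens-style loudness exponent
    rasta_pole: float = 0.94           # band-pass on log band trajectories
    rasta_numer: tuple = (0.2, 0.1, 0.0, -0.1, -0.2)
    n_mfcc: int = 14
    f0_win_len: float = 0.060
    f0_n_fft: int = 1024
    f0_min: float = 55.0
    f0_max: float = 600.0
    f0_cands_per_octave: int = 24
    shs_harmonics: int = 10
    shs_decay: float = 0.84
    shs_fmax: float = 5000.0
    voicing_threshold: float = 0.45
    voicing_scale: float = 6.0         # p = R / (R + scale)
    viterbi_cost: float = 10.0         # octave-jump penalty weight
    energy_gate: float = 1e-4          # frame RMS below this -> unvoiced
    eps: float = 1e-10
    hnr_min_db: float = -20.0
    hnr_max_db: float = 60.0


@dataclass
class LLDMatrix:
    """Per-frame values of the 64 descriptors for one clip."""

    frame_times: np.ndarray
    values: np.ndarray                  # frames x 64
    names: list[str]
    groups: dict[str, str]
    voiced_mask: np.ndarray
    voicing_prob: np.ndarray
    clip_id: str = ""

    def __post_init__(self) -> None:
        if self.values.shape[1] != 64:
            raise ValueError("LLDMatrix must have exactly 64 columns")

    def contour(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.values, columns=self.names)
        df.insert(0, "frame_time", self.frame_times)
        return df


# ---------------------------------------------------------------------------
# auditory frequency scale

def hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(n_bands: int, n_fft: int, rate: int, fmin: float,
                   fmax: float) -> tuple[np.ndarray, np.ndarray]:
    """Triangular Mel-spaced filters; returns (filters, band center freqs)."""
    edges_hz = mel_to_hz(np.linspace(hz_to_mel(fmin), hz_to_mel(fmax),
                                     n_bands + 2))
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / rate)
    fb = np.zeros((n_bands, freqs.size))
    for b in range(n_bands):
        lo, mid, hi = edges_hz[b], edges_hz[b + 1], edges_hz[b + 2]
        up = (freqs - lo) / max(mid - lo, 1e-9)
        down = (hi - freqs) / max(hi - mid, 1e-9)
        fb[b] = np.clip(np.minimum(up, down), 0.0, None)
    return fb, edges_hz[1:-1]


def equal_loudness_weight(f):
    """Equal-loudness-style spectral weighting (RASTA-PLP form)."""
    f = np.asarray(f, dtype=float)
    fsq = f ** 2
    w = ((fsq / (fsq + 1.6e5)) ** 2) * ((fsq + 1.44e6) / (fsq + 9.61e6))
    return np.maximum(w, 1e-4)


def bark_scale(f):
    f = np.asarray(f, dtype=float)
    return 13.0 * np.arctan(0.00076 * f) + 3.5 * np.arctan((f / 7500.0) ** 2)


def sharpness_weight(z):
    """High-frequency emphasis for psychoacoustic sharpness."""
    z = np.asarray(z, dtype=float)
    return np.where(z <= 14.0, 1.0, np.exp(0.38 * (z - 14.0)))


# ---------------------------------------------------------------------------
# sub-operations (exposed for testing)

def auditory_spectrum(power_spectra: np.ndarray, cfg: LLDConfig,
                      fb: np.ndarray | None = None) -> np.ndarray:
    """26 non-negative auditory band values per frame."""
    if fb is None:
        fb, _ = mel_filterbank(cfg.n_bands, cfg.n_fft, cfg.rate, cfg.fmin,
                               cfg.fmax)
    return power_spectra @ fb.T


def rasta_filter(log_bands: np.ndarray, cfg: LLDConfig) -> np.ndarray:
    """Band-pass filtering of log band trajectories over time.

    A strictly constant trajectory settles to 0 (the filter has no DC gain).
    """
    b = np.asarray(cfg.rasta_numer)
    a = np.array([1.0, -cfg.rasta_pole])
    return lfilter(b, a, log_bands, axis=0)


def loudness_from_bands(bands: np.ndarray, weights: np.ndarray,
                        cfg: LLDConfig) -> np.ndarray:
    """Perceptually weighted, compressed sum of auditory bands (>= 0)."""
    specific = np.maximum(bands * weights, 0.0) ** cfg.compression
    return specific.sum(axis=-1)


def rms_energy_zcr(raw_frames: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    rms = np.sqrt(np.mean(raw_frames ** 2, axis=1))
    signs = np.sign(raw_frames)
    # treat exact zeros as carrying the previous sign: no spurious crossings
    for i in range(1, signs.shape[1]):
        z = signs[:, i] == 0
        signs[z, i] = signs[z, i - 1]
    crossings = np.sum(np.abs(np.diff(signs, axis=1)) > 1, axis=1)
    return rms, crossings / raw_frames.shape[1]


def mfcc_from_bands(bands: np.ndarray, cfg: LLDConfig) -> np.ndarray:
    logb = np.log(np.maximum(bands, cfg.eps))
    cep = dct(logb, type=2, norm="ortho", axis=1)
    return cep[:, 1:cfg.n_mfcc + 1]


def spectral_descriptors(mag: np.ndarray, freqs: np.ndarray,
                         cfg: LLDConfig) -> dict[str, np.ndarray]:
    """Frame-wise spectral statistics from magnitude spectra."""
    eps = cfg.eps
    power = mag ** 2
    total = power.sum(axis=1)
    ok = total > eps
    # normalized power spectrum: for a pure tone this is a point mass at the
    # tone bin, so centroid/entropy behave like distribution statistics
    p = np.where(ok[:, None], power / np.maximum(total, eps)[:, None], 0.0)

    out: dict[str, np.ndarray] = {}
    # flux: normalized frame-to-frame spectral difference, 0 for first frame
    flux = np.zeros(mag.shape[0])
    if mag.shape[0] > 1:
        flux[1:] = np.sqrt(((p[1:] - p[:-1]) ** 2).sum(axis=1))
    out["spectral_flux"] = flux

    centroid = (p * freqs).sum(axis=1)
    out["spectral_centroid"] = np.where(ok, centroid, 0.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -(p * np.log(np.maximum(p, eps))).sum(axis=1)
    out["spectral_entropy"] = np.where(ok, np.maximum(ent, 0.0), 0.0)

    fc = freqs - freqs.mean()
    slope = (mag * fc).sum(axis=1) / (fc ** 2).sum()
    out["spectral_slope"] = np.where(ok, slope, 0.0)

    dev = freqs[None, :] - centroid[:, None]
    var = (p * dev ** 2).sum(axis=1)
    sd = np.sqrt(np.maximum(var, eps))
    out["spectral_variance"] = np.where(ok, var, 0.0)
    out["spectral_skewness"] = np.where(ok, (p * dev ** 3).sum(axis=1) / sd ** 3, 0.0)
    out["spectral_kurtosis"] = np.where(ok, (p * dev ** 4).sum(axis=1) / sd ** 4, 0.0)

    cum = np.cumsum(power, axis=1)
    ptotal = cum[:, -1]
    pok = ptotal > eps
    for q in (0.25, 0.50, 0.75, 0.90):
        idx = (cum < q * ptotal[:, None]).sum(axis=1)
        idx = np.minimum(idx, freqs.size - 1)
        out[f"rolloff_{int(q * 100)}"] = np.where(pok, freqs[idx], 0.0)

    for name, lo, hi in (("energy_250_650", 250.0, 650.0),
                         ("energy_1000_4000", 1000.0, 4000.0)):
        sel = (freqs >= lo) & (freqs <= hi)
        out[name] = power[:, sel].sum(axis=1)
    return out


def harmonicity_cepstral(mag: np.ndarray, cfg: LLDConfig) -> np.ndarray:
    """Cepstral-peak harmonicity: peak of the real cepstrum in the plausible
    pitch quefrency range.  Gain-invariant (gain only shifts quefrency 0)."""
    logmag = np.log(np.maximum(mag, cfg.eps))
    cep = irfft(logmag, axis=1)
    qmin = max(int(cfg.rate / cfg.f0_max), 2)
    qmax = min(int(cfg.rate / cfg.f0_min) + 1, cep.shape[1] // 2)
    return cep[:, qmin:qmax].max(axis=1)


def shs_candidates(cfg: LLDConfig) -> np.ndarray:
    n_oct = np.log2(cfg.f0_max / cfg.f0_min)
    n = int(np.ceil(n_oct * cfg.f0_cands_per_octave)) + 1
    return cfg.f0_min * 2.0 ** (np.linspace(0.0, n_oct, n))


def shs_matrix(cfg: LLDConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Linear-interpolation matrix mapping a magnitude spectrum to SHS
    candidate scores: scores = mag @ M.T.  Returns (M, candidates, W) where
    W[c] is the total harmonic weight available to candidate c."""
    cands = shs_candidates(cfg)
    freqs = np.fft.rfftfreq(cfg.f0_n_fft, d=1.0 / cfg.rate)
    df = freqs[1] - freqs[0]
    M = np.zeros((cands.size, freqs.size))
    W = np.zeros(cands.size)
    for ci, c in enumerate(cands):
        for h in range(1, cfg.shs_harmonics + 1):
            fh = h * c
            if fh > cfg.shs_fmax:
                break
            w = cfg.shs_decay ** (h - 1)
            pos = fh / df
            i0 = int(pos)
            frac = pos - i0
            if i0 + 1 < freqs.size:
                M[ci, i0] += w * (1.0 - frac)
                M[ci, i0 + 1] += w * frac
                W[ci] += w
    return M, cands, W


def viterbi_path(emissions: np.ndarray, cands: np.ndarray,
                 cfg: LLDConfig) -> np.ndarray:
    """Smooth pitch-candidate path: emission log-scores minus a quadratic
    octave-jump penalty between consecutive frames."""
    n_frames, n_cands = emissions.shape
    dlog = np.log2(cands[None, :] / cands[:, None])
    trans = -cfg.viterbi_cost * dlog ** 2
    score = emissions[0].copy()
    back = np.zeros((n_frames, n_cands), dtype=np.int32)
    for t in range(1, n_frames):
        tot = score[:, None] + trans
        back[t] = np.argmax(tot, axis=0)
        score = tot[back[t], np.arange(n_cands)] + emissions[t]
    path = np.zeros(n_frames, dtype=np.int32)
    path[-1] = int(np.argmax(score))
    for t in range(n_frames - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def f0_voicing(clip: AudioClip, cfg: LLDConfig | None = None,
               centers: np.ndarray | None = None,
               frames: np.ndarray | None = None
               ) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame F0 (Hz, 0 when unvoiced) and voicing probability."""
    cfg = cfg or LLDConfig()
    clip = clip.resampled(cfg.rate)
    if centers is None:
        tapered, _ = frame_signal(clip.samples, cfg.rate, cfg.win_len,
                                  cfg.hop, cfg.window)
        centers = frame_times(tapered.shape[0], cfg.win_len, cfg.hop)
    if frames is None:
        frames = frames_centered(clip.samples, cfg.rate, centers,
                                 cfg.f0_win_len)
    taper = get_window("hann", frames.shape[1], fftbins=True)
    mag = np.abs(rfft(frames * taper, n=cfg.f0_n_fft, axis=1))
    M, cands, W = shs_matrix(cfg)
    scores = mag @ M.T                                  # frames x candidates
    mean_mag = mag.mean(axis=1)
    flat = np.maximum(W[None, :] * mean_mag[:, None], cfg.eps)
    ratio = scores / flat                               # >> 1 when harmonic
    best_ratio = ratio.max(axis=1)
    prob = best_ratio / (best_ratio + cfg.voicing_scale)
    rms = np.sqrt(np.mean(frames ** 2, axis=1))
    prob = np.where(rms < cfg.energy_gate, 0.0, prob)
    emissions = np.log(np.maximum(ratio, cfg.eps))
    path = viterbi_path(emissions, cands, cfg)
    f0 = cands[path]
    voiced = prob >= cfg.voicing_threshold
    return np.where(voiced, f0, 0.0), prob


def _refine_peaks(x: np.ndarray, peaks: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Parabolic sub-sample refinement of peak positions and heights."""
    peaks = peaks[(peaks > 0) & (peaks < x.size - 1)]
    ym, y0, yp = x[peaks - 1], x[peaks], x[peaks + 1]
    denom = ym - 2.0 * y0 + yp
    delta = np.where(np.abs(denom) > 1e-12,
                     0.5 * (ym - yp) / np.where(denom == 0, 1.0, denom), 0.0)
    delta = np.clip(delta, -0.5, 0.5)
    return peaks + delta, y0 - 0.25 * (ym - yp) * delta


def voice_quality(clip: AudioClip, f0: np.ndarray,
                  cfg: LLDConfig | None = None,
                  centers: np.ndarray | None = None,
                  frames: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """Per-frame log HNR (dB), local/delta jitter and local shimmer.

    Cycle peaks are located once over the whole clip (sub-sample refined by
    parabolic interpolation) and assigned to each 60 ms analysis window.
    Jitter is the mean absolute consecutive period difference over the mean
    period; delta jitter the same statistic on period differences; shimmer
    the analog on cycle peak amplitudes.  All are 0 on unvoiced frames and
    on frames with fewer than 3 detected periods.
    """
    cfg = cfg or LLDConfig()
    clip = clip.resampled(cfg.rate)
    n = f0.size
    if centers is None:
        centers = frame_times(n, cfg.win_len, cfg.hop)
    out = {k: np.zeros(n) for k in
           ("log_hnr", "jitter_local", "jitter_delta", "shimmer_local")}
    voiced = np.flatnonzero(f0 > 0)
    if voiced.size == 0:
        return out
    if frames is None:
        frames = frames_centered(clip.samples, cfg.rate, centers,
                                 cfg.f0_win_len)
    half_win = frames.shape[1] / 2.0

    # HNR from the unbiased normalized autocorrelation at the pitch lag
    vf = frames[voiced]
    win_n = frames.shape[1]
    nfft = 2 * win_n
    acf = irfft(np.abs(rfft(vf, n=nfft, axis=1)) ** 2, axis=1)[:, :win_n]
    unbias = win_n / np.maximum(win_n - np.arange(win_n), 1)
    acf = acf * unbias
    acf0 = np.maximum(acf[:, 0], cfg.eps)
    lags = np.round(cfg.rate / f0[voiced]).astype(int)
    lo = np.maximum((lags * 0.85).astype(int), 1)
    hi = np.minimum((lags * 1.15).astype(int) + 1, win_n - 1)
    r = np.empty(voiced.size)
    for i in range(voiced.size):
        r[i] = acf[i, lo[i]:hi[i]].max() / acf0[i]
    r = np.clip(r, 1e-6, 1.0 - 1e-6)
    out["log_hnr"][voiced] = np.clip(10.0 * np.log10(r / (1.0 - r)),
                                     cfg.hnr_min_db, cfg.hnr_max_db)

    # one global peak pass, constrained by the highest voiced pitch
    samples = clip.samples
    min_dist = max(int(0.7 * cfg.rate / f0[voiced].max()), 1)
    peaks, _ = find_peaks(samples, distance=min_dist,
                          height=0.05 * np.max(np.abs(samples)) + cfg.eps)
    if peaks.size < 4:
        return out
    pos, amp = _refine_peaks(samples, peaks)
    periods = np.diff(pos)
    mid = 0.5 * (pos[:-1] + pos[1:])           # sample position of each cycle

    centers_n = np.asarray(centers) * cfg.rate
    a = np.searchsorted(mid, centers_n[voiced] - half_win)
    b = np.searchsorted(mid, centers_n[voiced] + half_win)
    c = b - a
    ok = c >= 3

    def _csum(v):
        return np.concatenate(([0.0], np.cumsum(v)))

    cs_t = _csum(periods)
    cs_dt = _csum(np.abs(np.diff(periods)))
    cs_ddt = _csum(np.abs(np.diff(periods, n=2)))
    cs_a = _csum(amp)
    cs_da = _csum(np.abs(np.diff(amp)))
    def _at(cs, idx):
        # results where the clamp bites are masked out by `good` below
        return cs[np.clip(idx, 0, cs.size - 1)]

    with np.errstate(divide="ignore", invalid="ignore"):
        mean_t = np.where(ok, (cs_t[b] - cs_t[a]) / np.maximum(c, 1), 1.0)
        good = ok & (mean_t > 0)
        jit = (_at(cs_dt, np.maximum(b - 1, a)) - _at(cs_dt, a)) \
            / np.maximum(c - 1, 1)
        jit_d = (_at(cs_ddt, np.maximum(b - 2, a)) - _at(cs_ddt, a)) \
            / np.maximum(c - 2, 1)
        mean_a = (_at(cs_a, b + 1) - _at(cs_a, a)) / np.maximum(c + 1, 1)
        shim = (_at(cs_da, b) - _at(cs_da, a)) / np.maximum(c, 1)
    out["jitter_local"][voiced] = np.where(good, jit / mean_t, 0.0)
    out["jitter_delta"][voiced] = np.where(good, jit_d / mean_t, 0.0)
    out["shimmer_local"][voiced] = np.where(good & (mean_a > cfg.eps),
                                            shim / np.maximum(mean_a, cfg.eps),
                                            0.0)
    return out


# ---------------------------------------------------------------------------
# assembly

class LLDExtractor:
    """Caches filterbanks/SHS matrices for a fixed config."""

    def __init__(self, cfg: LLDConfig | None = None):
        self.cfg = cfg or LLDConfig()
        cfg = self.cfg
        self.fb, self.band_centers = mel_filterbank(
            cfg.n_bands, cfg.n_fft, cfg.rate, cfg.fmin, cfg.fmax)
        self.band_weights = equal_loudness_weight(self.band_centers)
        self.sharp_w = sharpness_weight(bark_scale(self.band_centers))
        self.bark_z = bark_scale(self.band_centers)
        self.freqs = np.fft.rfftfreq(cfg.n_fft, d=1.0 / cfg.rate)

    def __call__(self, clip: AudioClip) -> LLDMatrix:
        return self.extract(clip)

    def extract(self, clip: AudioClip) -> LLDMatrix:
        cfg = self.cfg
        clip = clip.resampled(cfg.rate)
        tapered, raw = frame_signal(clip.samples, cfg.rate, cfg.win_len,
                                    cfg.hop, cfg.window)
        n_frames = tapered.shape[0]
        times = frame_times(n_frames, cfg.win_len, cfg.hop)
        mag = np.abs(rfft(tapered, n=cfg.n_fft, axis=1))
        power = mag ** 2

        bands = np.maximum(power @ self.fb.T, 0.0)
        floored = np.maximum(bands - cfg.eps, 0.0)
        loud = loudness_from_bands(floored, self.band_weights, cfg)
        log_bands = np.log(np.maximum(bands, cfg.eps))
        rasta_log = rasta_filter(log_bands, cfg)
        rasta_bands = np.exp(np.clip(rasta_log, -60.0, 60.0)) - 1.0
        rasta_loud = loudness_from_bands(np.maximum(rasta_bands, 0.0),
                                         self.band_weights, cfg)

        rms, zcr = rms_energy_zcr(raw)
        mfcc = mfcc_from_bands(bands, cfg)
        spec = spectral_descriptors(mag, self.freqs, cfg)
        harm = harmonicity_cepstral(mag, cfg)

        specific = np.maximum(floored * self.band_weights, 0.0) ** cfg.compression
        denom = np.maximum(specific.sum(axis=1), cfg.eps)
        sharp = 0.11 * (specific * self.sharp_w * self.bark_z).sum(axis=1) / denom
        sharp = np.where(loud > 0, sharp, 0.0)

        long_frames = frames_centered(clip.samples, cfg.rate, times,
                                      cfg.f0_win_len)
        f0, vprob = f0_voicing(clip, cfg, centers=times, frames=long_frames)
        vq = voice_quality(clip, f0, cfg, centers=times, frames=long_frames)

        cols = {
            "loudness": loud,
            "rasta_loudness": rasta_loud,
            "rms_energy": rms,
            "zcr": zcr,
            **{f"aud_band_{b + 1}": rasta_log[:, b] for b in range(cfg.n_bands)},
            **{f"mfcc_{i + 1}": mfcc[:, i] for i in range(cfg.n_mfcc)},
            **spec,
            "sharpness": sharp,
            "harmonicity": harm,
            "f0": f0,
            **vq,
        }
        values = np.column_stack([cols[name] for name in LLD_NAMES])
        values = np.nan_to_num(values, nan=0.0, posinf=0.0, neginf=0.0)
        return LLDMatrix(
            frame_times=times,
            values=values,
            names=list(LLD_NAMES),
            groups=dict(LLD_GROUPS),
            voiced_mask=f0 > 0,
            voicing_prob=vprob,
            clip_id=clip.clip_id,
        )


def extract_lld(clip: AudioClip, cfg: LLDConfig | None = None) -> LLDMatrix:
    """Extract the 64-descriptor contour matrix for one clip."""
    return LLDExtractor(cfg).extract(clip)
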