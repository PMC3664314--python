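"""Synthetic multi-domain corpora with controlled acoustic drivers.

The restricted speech/music/sound corpora this analysis targets cannot be
redistributed, so the generator produces audio whose *drivers* — loudness
level, loudness-contour shape (flat / ramp / parabola), amplitude-modulation
rate ("tempo"), fundamental frequency and spectral noisiness — are sampled
per instance, with latent arousal/valence defined as linear combinations of
the standardized drivers plus Gaussian noise.  K simulated raters of
heterogeneous reliability then produce a rating matrix, optionally
discretized to the five-point scale.  The latent truth is stored separately
from the ratings and is only ever used by evaluation harnesses.

A feature-level generator is also provided: it skips audio entirely and
plants a block of features sharing a latent factor with the target across
domains, which gives fast, analytically controllable inputs for the
relevance and regression stages.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .audio import AudioClip
from .gold import CONTINUOUS, FIVE_POINT, RatingMatrix

DRIVER_NAMES = ("loudness_db", "tempo", "f0", "noisiness")
CONTOUR_SHAPES = ("flat", "ramp", "parabola")

FIVE_POINT_THRESHOLDS = (-0.6, -0.2, 0.2, 0.6)


@dataclass
class DomainSpec:
    name: str
    n: int = 200
    duration: tuple[float, float] = (2.0, 4.0)
    loudness_db: tuple[float, float] = (-30.0, -6.0)
    tempo: tuple[float, float] = (0.5, 6.0)
    f0: tuple[float, float] = (90.0, 400.0)
    noisiness: tuple[float, float] = (0.0, 0.8)
    shapes: tuple[str, ...] = CONTOUR_SHAPES
    valence_sign_flip: bool = False   # inverts driver->valence weights

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValueError("need n >= 4 per domain")


@dataclass
class AffectModel:
    """Latent affect as linear functions of standardized drivers + noise."""

    arousal_weights: dict = field(default_factory=lambda: {
        "loudness_db": 0.55, "tempo": 0.45, "f0": 0.25, "noisiness": 0.0})
    valence_weights: dict = field(default_factory=lambda: {
        "loudness_db": -0.45, "tempo": 0.0, "f0": 0.0, "noisiness": -0.35})
    noise_sd: float = 0.25
    scale: float = 0.35               # target SD of the latent on [-1, 1]


@dataclass
class RaterModel:
    noise_sds: tuple[float, ...] = (0.10, 0.15, 0.20, 0.30, 0.40, 0.50)
    scale: str = CONTINUOUS


@dataclass
class SynthConfig:
    domains: list[DomainSpec] = field(default_factory=lambda: [
        DomainSpec("sound", duration=(2.0, 4.0)),
        DomainSpec("music", duration=(20.0, 30.0), valence_sign_flip=True),
        DomainSpec("speech", duration=(2.0, 4.0)),
    ])
    affect: AffectModel = field(default_factory=AffectModel)
    raters: RaterModel = field(default_factory=RaterModel)
    rate: int = 16_000
    seed: int = 0

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SynthCorpus:
    domain: str
    clips: list[AudioClip]
    latent_arousal: np.ndarray
    latent_valence: np.ndarray
    ratings: dict[str, RatingMatrix]
    drivers: dict[str, np.ndarray]
    config_hash: str = ""


def gen_clip(drivers: dict, duration: float, rate: int = 16_000,
             seed: int = 0, clip_id: str = "", domain: str = "synthetic"
             ) -> AudioClip:
    """One clip: harmonic complex at ``f0`` mixed with noise at the set
    noisiness, amplitude-modulated at the tempo rate, scaled to the
    loudness level and shaped by the chosen contour."""
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    harm = np.zeros(n)
    for h in range(1, 9):
        harm += np.sin(2.0 * np.pi * h * drivers["f0"] * t
                       + rng.uniform(0, 2 * np.pi)) / h
    harm /= np.sqrt(np.mean(harm ** 2))
    noise = rng.standard_normal(n)
    noise /= np.sqrt(np.mean(noise ** 2))
    nu = float(np.clip(drivers["noisiness"], 0.0, 1.0))
    x = np.sqrt(1.0 - nu) * harm + np.sqrt(nu) * noise

    depth = 0.8
    env = 1.0 - 0.5 * depth * (1.0 + np.cos(2.0 * np.pi * drivers["tempo"] * t))
    shape_name = drivers.get("shape", "flat")
    u = t / t[-1]
    if shape_name == "ramp":
        shape = 0.3 + 0.7 * u
    elif shape_name == "parabola":
        shape = 0.25 + 0.75 * (1.0 - (2.0 * u - 1.0) ** 2)
    else:
        shape = np.ones(n)
    x = x * env * shape
    x /= np.max(np.abs(x)) + 1e-12
    gain = 10.0 ** (drivers["loudness_db"] / 20.0)
    return AudioClip(0.95 * gain * x, rate, clip_id=clip_id, domain=domain)


def _latent(z: dict[str, np.ndarray], weights: dict, noise_sd: float,
            scale: float, rng: np.random.Generator) -> np.ndarray:
    raw = sum(w * z[d] for d, w in weights.items() if w != 0.0)
    raw = np.asarray(raw, dtype=float) + noise_sd * rng.standard_normal(
        len(next(iter(z.values()))))
    sd = raw.std()
    if sd > 0:
        raw = raw * (scale / sd)
    return np.clip(raw, -1.0, 1.0)


def _rate(latent: np.ndarray, model: RaterModel, rng: np.random.Generator,
          dimension: str) -> RatingMatrix:
    cols = []
    for sd in model.noise_sds:
        col = np.clip(latent + sd * rng.standard_normal(latent.size),
                      -1.0, 1.0)
        if model.scale == FIVE_POINT:
            col = np.digitize(col, FIVE_POINT_THRESHOLDS) - 2.0
        cols.append(col)
    scale = FIVE_POINT if model.scale == FIVE_POINT else CONTINUOUS
    return RatingMatrix(np.column_stack(cols), scale, dimension=dimension)


def gen_corpus(config: SynthConfig) -> list[SynthCorpus]:
    """Per-domain corpora; the master seed fully determines the output."""
    out = []
    chash = config.hash()
    for di, dom in enumerate(config.domains):
        rng = np.random.default_rng(np.random.SeedSequence(
            [config.seed, 1000 + di]))
        n = dom.n
        drivers = {
            "loudness_db": rng.uniform(*dom.loudness_db, n),
            "tempo": rng.uniform(*dom.tempo, n),
            "f0": rng.uniform(*dom.f0, n),
            "noisiness": rng.uniform(*dom.noisiness, n),
        }
        shapes = rng.choice(list(dom.shapes), size=n)
        z = {d: (v - v.mean()) / (v.std() + 1e-12)
             for d, v in drivers.items()}
        aro = _latent(z, config.affect.arousal_weights,
                      config.affect.noise_sd, config.affect.scale, rng)
        vw = dict(config.affect.valence_weights)
        if dom.valence_sign_flip:
            vw = {k: -w for k, w in vw.items()}
        val = _latent(z, vw, config.affect.noise_sd, config.affect.scale, rng)
        ratings = {
            "arousal": _rate(aro, config.raters, rng, "arousal"),
            "valence": _rate(val, config.raters, rng, "valence"),
        }
        clips = []
        seeds = rng.integers(0, 2 ** 31 - 1, size=n)
        durs = rng.uniform(*dom.duration, n)
        for i in range(n):
            d = {k: float(v[i]) for k, v in drivers.items()}
            d["shape"] = str(shapes[i])
            clips.append(gen_clip(d, float(durs[i]), config.rate,
                                  seed=int(seeds[i]),
                                  clip_id=f"{dom.name}_{i:04d}",
                                  domain=dom.name))
        out.append(SynthCorpus(dom.name, clips, aro, val, ratings, drivers,
                               chash))
    return out


# ---------------------------------------------------------------------------
# feature-level generator (no audio)

@dataclass
class FeatureLevelConfig:
    domains: tuple[str, ...] = ("sound", "music", "speech")
    n: int = 200
    d: int = 500
    s: int = 20                     # planted (target-linked) features
    driver_noise_sd: float = 0.5    # feature-side noise on planted dims
    target_noise_sd: float = 0.5
    flip_domain: str | None = None  # planted signs inverted in this domain
    seed: int = 0

    @property
    def planted_population_r(self) -> float:
        """corr(x_planted, y) implied by the generative formula."""
        return 1.0 / np.sqrt((1.0 + self.driver_noise_sd ** 2)
                             * (1.0 + self.target_noise_sd ** 2))


def gen_feature_level(config: FeatureLevelConfig):
    """DomainDataset list with a planted correlated feature block.

    In every domain, features 0..s-1 share a latent factor with the target
    (arousal); the remaining d-s features are independent noise.  Valence
    uses the same construction with the planted signs inverted in
    ``flip_domain`` (the cross-domain sign-inversion phenomenon).
    """
    from .relevance import DomainDataset

    out = []
    for di, name in enumerate(config.domains):
        rng = np.random.default_rng(np.random.SeedSequence(
            [config.seed, 2000 + di]))
        g = rng.standard_normal(config.n)
        y = g + config.target_noise_sd * rng.standard_normal(config.n)
        X = rng.standard_normal((config.n, config.d))
        sign = -1.0 if name == config.flip_domain else 1.0
        for j in range(config.s):
            X[:, j] = g + config.driver_noise_sd * rng.standard_normal(config.n)
        arousal = y / max(np.abs(y).max(), 1.0)
        valence = sign * arousal
        out.append(DomainDataset(name, X, arousal, valence))
    return out
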