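"""Synthetic snore-related-sound (SRS) generator.

Clinical overnight recordings of snore/breathing/silence are not publicly
deposited, so this module synthesises labelled 16 kHz segments whose
3200-sample parts reproduce the *feature-space structure* the downstream
analysis consumes — the class-conditional clusters in (entropy, LLE)
space — rather than waveform realism:

* ``snore``: a harmonic stack on a 100-150 Hz fundamental whose period is
  chaotically jittered (logistic map, r = 3.99) under a slow amplitude
  envelope, plus a weak band-limited breathy noise floor.  Parts land at
  high entropy (~2-4.5 bits) and low LLE.
* ``breathing``: band-pass-filtered (300-800 Hz) Gaussian noise gated by a
  slowly varying turbulent gust envelope.  Intermediate entropy,
  intermediate LLE.
* ``silence``: a low-amplitude band-limited noise floor punctuated by rare
  large clicks from the recording chain; after min-max normalization the
  floor collapses into one or two amplitude bins, giving near-zero entropy
  and the fastest neighbour divergence (highest LLE) of the three classes.

All randomness flows from explicit integer seeds through per-segment
substreams keyed by (dataset seed, subject, class, segment index), so a
dataset is bit-reproducible regardless of generation order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .core import (
    CLASS_TO_CODE,
    PART_LENGTH,
    SAMPLE_RATE_HZ,
    AudioSegment,
    SegmentSpec,
    check_label,
)

__all__ = ["SynthesisConfig", "DatasetDesign", "generate_segment", "generate_dataset"]

MIN_DURATION_S = PART_LENGTH / SAMPLE_RATE_HZ  # 0.2 s: one extractable part

_SUBJECT_STREAM = 0x5EF  # substream tag separating subject-effect draws


@dataclass(frozen=True)
class SynthesisConfig:
    """Waveform parameters of the three class synthesisers.

    Defaults were calibrated once so that the default feature extraction
    (m=5, tau=8, 32 bins) places each class in its target cluster.
    """

    # snore
    snore_f0_range_hz: tuple[float, float] = (100.0, 150.0)
    snore_n_harmonics: int = 10
    snore_jitter_depth: float = 0.02  # fractional period modulation
    snore_jitter_r: float = 3.99  # logistic-map rate driving the jitter
    snore_noise_level: float = 0.05  # breathy floor relative to unit carrier
    snore_noise_cut_hz: float = 800.0
    snore_env_rate_range_hz: tuple[float, float] = (2.0, 5.0)
    snore_env_floor: float = 0.08
    snore_env_exponent: float = 1.5  # >1 deepens the inter-burst dips
    # breathing
    breathing_band_hz: tuple[float, float] = (300.0, 800.0)
    breathing_gust_cut_hz: float = 6.0
    breathing_env_floor: float = 0.05
    breathing_gust_exponent: float = 4.0  # peakiness of the gust gain
    # silence
    silence_floor_cut_hz: float = 1000.0
    silence_click_rate_hz: float = 8.0
    silence_click_amp_range: tuple[float, float] = (400.0, 1000.0)
    #: False -> the dominant near-zero-entropy silence cluster; True -> the
    #: secondary higher-entropy silence regime (milder clicks).
    silence_second_cluster: bool = False
    silence_second_click_amp_range: tuple[float, float] = (10.0, 40.0)
    #: scale of the per-subject random effects (0 disables them).  Subjects
    #: differ in fundamental frequency, breathiness, breathing band and
    #: ambient floor, which is what makes the subject-disjoint experiment
    #: genuinely harder than the shared-subject one.
    subject_variability: float = 1.0


def _segment_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed))


def _substream_seeds(dataset_seed: int, subject_id: str, label: str, index: int) -> tuple[int, int]:
    """Stable per-segment seeds: a counter-keyed substream of the dataset seed.

    Returns (duration_seed, waveform_seed) so the duration draw does not
    consume from the waveform stream.
    """
    key = (
        int(dataset_seed),
        zlib.crc32(subject_id.encode()),
        CLASS_TO_CODE[label],
        int(index),
    )
    state = np.random.SeedSequence(key).generate_state(2)
    return int(state[0]), int(state[1])


def subject_config(
    base: SynthesisConfig, dataset_seed: int, subject_id: str
) -> SynthesisConfig:
    """Perturb the synthesis parameters with per-subject random effects.

    Each subject gets its own fundamental-frequency range, breathiness,
    breathing band and ambient-noise character, drawn from a substream
    keyed by (dataset seed, subject).  Deterministic; identity when
    ``subject_variability`` is 0.
    """
    v = base.subject_variability
    if v == 0:
        return base
    key = (int(dataset_seed), zlib.crc32(subject_id.encode()), _SUBJECT_STREAM)
    rng = np.random.default_rng(np.random.SeedSequence(key))
    f0_centre = rng.uniform(110.0, 140.0)
    lognorm = lambda s: float(np.exp(rng.normal(0.0, s * v)))  # noqa: E731
    band_lo, band_hi = base.breathing_band_hz
    band_factor = lognorm(0.2)
    return SynthesisConfig(
        snore_f0_range_hz=(f0_centre - 8.0, f0_centre + 8.0),
        snore_n_harmonics=base.snore_n_harmonics,
        snore_jitter_depth=base.snore_jitter_depth * lognorm(0.3),
        snore_jitter_r=base.snore_jitter_r,
        snore_noise_level=base.snore_noise_level * lognorm(0.35),
        snore_noise_cut_hz=base.snore_noise_cut_hz,
        snore_env_rate_range_hz=base.snore_env_rate_range_hz,
        snore_env_floor=float(np.clip(base.snore_env_floor * lognorm(0.3), 0.02, 0.4)),
        snore_env_exponent=base.snore_env_exponent,
        breathing_band_hz=(band_lo * band_factor, band_hi * band_factor),
        breathing_gust_cut_hz=base.breathing_gust_cut_hz * lognorm(0.2),
        breathing_env_floor=float(np.clip(base.breathing_env_floor * lognorm(0.3), 0.02, 0.4)),
        breathing_gust_exponent=base.breathing_gust_exponent,
        silence_floor_cut_hz=base.silence_floor_cut_hz * lognorm(0.25),
        silence_click_rate_hz=base.silence_click_rate_hz * lognorm(0.4),
        silence_click_amp_range=base.silence_click_amp_range,
        silence_second_cluster=base.silence_second_cluster,
        silence_second_click_amp_range=base.silence_second_click_amp_range,
        subject_variability=v,
    )


def _lowpass_noise(rng: np.random.Generator, n: int, cut_hz: float, order: int = 4) -> np.ndarray:
    sos = signal.butter(order, cut_hz, "lowpass", fs=SAMPLE_RATE_HZ, output="sos")
    pad = 1000
    x = signal.sosfiltfilt(sos, rng.standard_normal(n + 2 * pad))[pad : pad + n]
    sd = x.std()
    return x / sd if sd > 0 else x


def _snore(rng: np.random.Generator, n: int, cfg: SynthesisConfig) -> np.ndarray:
    f0 = rng.uniform(*cfg.snore_f0_range_hz)
    # chaotic period jitter: one logistic-map step per fundamental period
    u = rng.uniform(0.2, 0.8)
    freqs = []
    total = 0
    while total < n:
        f = f0 * (1.0 + cfg.snore_jitter_depth * (2.0 * u - 1.0))
        period = max(2, int(round(SAMPLE_RATE_HZ / f)))
        freqs.append(np.full(min(period, n - total), f))
        total += period
        u = cfg.snore_jitter_r * u * (1.0 - u)
    inst_f = np.concatenate(freqs)[:n]
    phase = 2.0 * np.pi * np.cumsum(inst_f) / SAMPLE_RATE_HZ
    amps = 1.0 / np.arange(1, cfg.snore_n_harmonics + 1)
    phis = rng.uniform(0, 2 * np.pi, cfg.snore_n_harmonics)
    x = np.zeros(n)
    for k, (a, p) in enumerate(zip(amps, phis), start=1):
        x += a * np.sin(k * phase + p)
    t = np.arange(n) / SAMPLE_RATE_HZ
    env_rate = rng.uniform(*cfg.snore_env_rate_range_hz)
    s = 0.5 + 0.5 * np.sin(2 * np.pi * env_rate * t + rng.uniform(0, 2 * np.pi))
    env = cfg.snore_env_floor + (1.0 - cfg.snore_env_floor) * s**cfg.snore_env_exponent
    noise = _lowpass_noise(rng, n, cfg.snore_noise_cut_hz, order=2)
    return env * x + cfg.snore_noise_level * noise


def _breathing(rng: np.random.Generator, n: int, cfg: SynthesisConfig) -> np.ndarray:
    sos = signal.butter(4, cfg.breathing_band_hz, "bandpass", fs=SAMPLE_RATE_HZ, output="sos")
    pad = 1000
    x = signal.sosfiltfilt(sos, rng.standard_normal(n + 2 * pad))[pad : pad + n]
    # slowly varying turbulent gust gain
    g = _lowpass_noise(rng, n, cfg.breathing_gust_cut_hz, order=2)
    rng_g = g.max() - g.min()
    g = (g - g.min()) / rng_g if rng_g > 0 else np.zeros(n)
    env = cfg.breathing_env_floor + (1.0 - cfg.breathing_env_floor) * g**cfg.breathing_gust_exponent
    return env * x


def _silence(rng: np.random.Generator, n: int, cfg: SynthesisConfig) -> np.ndarray:
    x = _lowpass_noise(rng, n, cfg.silence_floor_cut_hz, order=4)
    amp_range = (
        cfg.silence_second_click_amp_range
        if cfg.silence_second_cluster
        else cfg.silence_click_amp_range
    )
    n_clicks = max(2, rng.poisson(cfg.silence_click_rate_hz * n / SAMPLE_RATE_HZ))
    pos = rng.integers(0, n, n_clicks)
    x[pos] += rng.uniform(*amp_range, n_clicks) * rng.choice([-1.0, 1.0], n_clicks)
    return x


_SYNTH = {"snore": _snore, "breathing": _breathing, "silence": _silence}


def generate_segment(spec: SegmentSpec, config: SynthesisConfig | None = None) -> AudioSegment:
    """Synthesise one labelled segment; bit-deterministic given ``spec.seed``."""
    cfg = config or SynthesisConfig()
    n = spec.n_samples
    if n < PART_LENGTH:
        raise ValueError(
            f"duration {spec.duration_s} s gives {n} samples; at least "
            f"{PART_LENGTH} samples ({MIN_DURATION_S} s) are needed for one part"
        )
    rng = _segment_rng(spec.seed)
    samples = _SYNTH[spec.label](rng, n, cfg)
    return AudioSegment(samples=samples, label=spec.label, subject_id=spec.subject_id)


@dataclass
class DatasetDesign:
    """Per-(subject, class) segment counts, in a fixed row order."""

    rows: list[tuple[str, str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for subject, label, count in self.rows:
            check_label(label)
            if count < 0:
                raise ValueError(f"negative segment count for ({subject}, {label})")

    @property
    def total_segments(self) -> int:
        return sum(c for _, _, c in self.rows)

    @property
    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for subject, _, _ in self.rows:
            seen.setdefault(subject, None)
        return list(seen)

    def count(self, subject: str, label: str) -> int:
        return sum(c for s, l, c in self.rows if s == subject and l == label)


def generate_dataset(
    design: DatasetDesign,
    seed: int,
    duration_range_s: tuple[float, float] = (0.5, 2.0),
    config: SynthesisConfig | None = None,
) -> list[AudioSegment]:
    """Generate exactly the per-(subject, class) segment counts of ``design``.

    Segment durations are drawn uniformly from ``duration_range_s``.  Each
    segment uses its own seed substream, so the output is reproducible and
    independent of row order.
    """
    lo, hi = duration_range_s
    if lo < MIN_DURATION_S:
        raise ValueError(f"duration_range_s lower bound must be >= {MIN_DURATION_S} s")
    base = config or SynthesisConfig()
    segments: list[AudioSegment] = []
    subject_cfgs: dict[str, SynthesisConfig] = {}
    for subject, label, count in design.rows:
        if subject not in subject_cfgs:
            subject_cfgs[subject] = subject_config(base, seed, subject)
        for idx in range(count):
            dur_seed, wav_seed = _substream_seeds(seed, subject, label, idx)
            duration = float(_segment_rng(dur_seed).uniform(lo, hi))
            spec = SegmentSpec(
                label=label, duration_s=duration, subject_id=subject, seed=wav_seed
            )
            segments.append(generate_segment(spec, subject_cfgs[subject]))
    return segments
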