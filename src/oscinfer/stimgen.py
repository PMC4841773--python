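"""Rule-governed pitch sequences and harmonic-complex audio synthesis.

The stimulus is a chain of fixed-duration segments, each carrying one
fundamental frequency (f).  A hidden Gaussian *population* with mean
``mu_pop`` (Hz) and standard deviation ``sigma_pop`` (octaves) governs the
f values.  At every segment after the first the population is replaced,
with probability ``p_change``, by a fresh (mu_pop, sigma_pop) pair drawn
from uniform ranges; otherwise the f value is drawn from the population
currently in effect.  Because sigma_pop is specified in octaves, the
population lives in log-frequency space::

    log2(f) ~ Normal(log2(mu_pop), sigma_pop**2)

Audio renders the sequence as a phase-continuous harmonic complex: the
instantaneous fundamental is defined sample-wise, each harmonic h is
``sin(2*pi*r_h + 2*pi*h*(1/s)*cumsum(f))`` with one fixed random phase
offset r_h per harmonic, harmonics are summed up to the generation
Nyquist, a zero-phase high-pass keeps only unresolved harmonics, and the
waveform is generated at double rate then polyphase-resampled 2:1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.io import wavfile

from ._errors import ConfigurationError

DEFAULT_MU_RANGE = (120.0, 140.0)        # Hz
DEFAULT_SIGMA_RANGE = (1.0 / 128.0, 1.0 / 16.0)  # octaves
DEFAULT_P_CHANGE = 1.0 / 8.0
DEFAULT_SEGMENT_DURATION = 0.3           # seconds

__all__ = [
    "PopulationParams",
    "StimulusSequence",
    "AudioSynthConfig",
    "sample_population",
    "generate_sequence",
    "synthesize_audio",
    "write_wav",
    "write_sequence_log",
    "read_sequence_log",
]


@dataclass(frozen=True)
class PopulationParams:
    """Hidden population: mean fundamental (Hz) and spread (octaves)."""

    mu_pop: float
    sigma_pop: float


@dataclass
class StimulusSequence:
    """Ordered segment f values with ground-truth population bookkeeping."""

    f: np.ndarray
    change: np.ndarray
    populations: list[PopulationParams]
    segment_duration: float = DEFAULT_SEGMENT_DURATION
    seed: int | None = None

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        self.change = np.asarray(self.change, dtype=bool)
        if not (len(self.f) == len(self.change) == len(self.populations)):
            raise ConfigurationError("f, change and populations must have equal length")
        if len(self.f) == 0:
            raise ConfigurationError("empty stimulus sequence")
        if np.any(self.f <= 0):
            raise ConfigurationError("all f values must be positive")
        if not self.change[0]:
            raise ConfigurationError("change[0] is true by convention")

    def __len__(self) -> int:
        return len(self.f)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "segment_index": np.arange(len(self.f)),
                "f_hz": self.f,
                "change_flag": self.change.astype(int),
                "mu_pop": [p.mu_pop for p in self.populations],
                "sigma_pop": [p.sigma_pop for p in self.populations],
            }
        )


def _check_range(name: str, rng: tuple[float, float]) -> None:
    lo, hi = rng
    if not (0 < lo <= hi):
        raise ConfigurationError(f"{name} must be a non-empty positive interval, got {rng}")


def sample_population(
    rng: np.random.Generator,
    mu_range: tuple[float, float] = DEFAULT_MU_RANGE,
    sigma_range: tuple[float, float] = DEFAULT_SIGMA_RANGE,
) -> PopulationParams:
    """Draw a fresh population: mu ~ U(mu_range) Hz, sigma ~ U(sigma_range) oct."""
    _check_range("mu_range", mu_range)
    _check_range("sigma_range", sigma_range)
    return PopulationParams(
        mu_pop=float(rng.uniform(*mu_range)),
        sigma_pop=float(rng.uniform(*sigma_range)),
    )


def generate_sequence(
    n_segments: int,
    p_change: float = DEFAULT_P_CHANGE,
    rng: np.random.Generator | int | None = None,
    mu_range: tuple[float, float] = DEFAULT_MU_RANGE,
    sigma_range: tuple[float, float] = DEFAULT_SIGMA_RANGE,
    segment_duration: float = DEFAULT_SEGMENT_DURATION,
) -> StimulusSequence:
    """Generate the rule-governed pitch sequence.

    Segment 1 always starts a fresh population (change[0] is True).  Every
    later segment replaces the population with probability ``p_change``
    before its f value is drawn.
    """
    if n_segments < 1:
        raise ConfigurationError("n_segments must be >= 1")
    if not 0.0 <= p_change <= 1.0:
        raise ConfigurationError("p_change must lie in [0, 1]")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    gen = np.random.default_rng(rng)

    f = np.empty(n_segments)
    change = np.zeros(n_segments, dtype=bool)
    populations: list[PopulationParams] = []
    pop = sample_population(gen, mu_range, sigma_range)
    change[0] = True
    for t in range(n_segments):
        if t > 0 and gen.random() < p_change:
            pop = sample_population(gen, mu_range, sigma_range)
            change[t] = True
        populations.append(pop)
        f[t] = 2.0 ** gen.normal(math.log2(pop.mu_pop), pop.sigma_pop)
    return StimulusSequence(
        f=f,
        change=change,
        populations=populations,
        segment_duration=segment_duration,
        seed=seed,
    )


@dataclass
class AudioSynthConfig:
    """Harmonic-complex synthesis parameters.

    ``phase_offsets`` (radians, one per harmonic) are drawn once from
    ``phase_seed`` and held fixed for the whole waveform.  ``harmonics``
    defaults to every integer h with h * min(f) below the generation
    Nyquist; the high-pass then keeps only unresolved harmonics.
    """

    sample_rate_gen: int = 88200
    sample_rate_out: int = 44100
    highpass_hz: float = 1800.0
    harmonics: np.ndarray | None = None
    phase_offsets: np.ndarray | None = None
    phase_seed: int = 0
    apply_highpass: bool = True
    downsample: bool = True
    stopband_db: float = 70.0        # FIR high-pass stopband attenuation
    transition_hz: float = 200.0     # FIR transition width
    amplitude: float = 0.99

    def __post_init__(self) -> None:
        if self.sample_rate_gen <= 0 or self.sample_rate_out <= 0:
            raise ConfigurationError("sample rates must be positive")
        if self.downsample and self.sample_rate_gen != 2 * self.sample_rate_out:
            raise ConfigurationError(
                "generation rate must be exactly twice the output rate "
                f"(got {self.sample_rate_gen} vs {self.sample_rate_out})"
            )


def synthesize_audio(
    seq: StimulusSequence,
    cfg: AudioSynthConfig | None = None,
) -> tuple[np.ndarray, int]:
    """Render a sequence to a phase-continuous harmonic-complex waveform.

    Returns ``(waveform, sample_rate)`` with the waveform normalised to
    ``cfg.amplitude`` peak.  Phase continuity at segment boundaries is
    guaranteed by accumulating instantaneous frequency.
    """
    cfg = cfg or AudioSynthConfig()
    fs = cfg.sample_rate_gen
    n_per_seg = fs * seq.segment_duration
    if abs(n_per_seg - round(n_per_seg)) > 1e-9:
        raise ConfigurationError("segment_duration must be an integer number of samples")
    n_per_seg = int(round(n_per_seg))

    inst_f = np.repeat(seq.f, n_per_seg)
    base_phase = 2.0 * np.pi * np.cumsum(inst_f) / fs

    if cfg.harmonics is None:
        h_max = int(np.floor((fs / 2.0) / seq.f.min()))
        harmonics = np.arange(1, max(h_max, 1) + 1)
    else:
        harmonics = np.asarray(cfg.harmonics, dtype=int)
    if cfg.phase_offsets is None:
        offsets = np.random.default_rng(cfg.phase_seed).uniform(
            0.0, 2.0 * np.pi, size=len(harmonics)
        )
    else:
        offsets = np.asarray(cfg.phase_offsets, dtype=float)
        if len(offsets) != len(harmonics):
            raise ConfigurationError("need one phase offset per harmonic")

    wave = np.zeros_like(base_phase)
    chunk = max(1, int(8_000_000 // max(len(base_phase), 1)))
    for i in range(0, len(harmonics), chunk):
        h = harmonics[i : i + chunk, None].astype(float)
        r = offsets[i : i + chunk, None]
        wave += np.sin(r + h * base_phase[None, :]).sum(axis=0)

    if cfg.apply_highpass:
        # linear-phase FIR applied centred => zero phase; a sharp edge is
        # needed because the highest sub-cutoff harmonic sits close to it
        numtaps, beta = sps.kaiserord(cfg.stopband_db, cfg.transition_hz / (fs / 2))
        numtaps |= 1
        taps = sps.firwin(
            numtaps, cfg.highpass_hz, window=("kaiser", beta), pass_zero=False, fs=fs
        )
        wave = sps.oaconvolve(wave, taps, mode="same")
    rate = fs
    if cfg.downsample:
        wave = sps.resample_poly(wave, 1, 2)
        rate = cfg.sample_rate_out
    peak = np.max(np.abs(wave))
    if peak > 0:
        wave = wave * (cfg.amplitude / peak)
    return wave, rate


def write_wav(path: str | Path, wave: np.ndarray, sample_rate: int) -> None:
    """Write a [-1, 1] waveform as 16-bit PCM WAV."""
    data = np.clip(wave, -1.0, 1.0)
    wavfile.write(str(path), int(sample_rate), (data * 32767).astype(np.int16))


def write_sequence_log(seq: StimulusSequence, path: str | Path) -> None:
    """Ground-truth CSV: segment_index, f_hz, change_flag, mu_pop, sigma_pop."""
    seq.to_frame().to_csv(path, index=False)


def read_sequence_log(
    path: str | Path, segment_duration: float = DEFAULT_SEGMENT_DURATION
) -> StimulusSequence:
    df = pd.read_csv(path)
    pops = [
        PopulationParams(mu_pop=m, sigma_pop=s)
        for m, s in zip(df["mu_pop"], df["sigma_pop"])
    ]
    return StimulusSequence(
        f=df["f_hz"].to_numpy(),
        change=df["change_flag"].to_numpy().astype(bool),
        populations=pops,
        segment_duration=segment_duration,
    )
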