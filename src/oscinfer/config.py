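"""Run configuration: YAML round-trip, presets, and seed fan-out."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from ._errors import ConfigurationError
from .synthlfp import EffectSpec, default_effects

PRESET_NAMES = ("main", "df-only-partial", "no-precision")


@dataclass
class StimulusConfig:
    n_segments: int = 2000
    p_change: float = 1.0 / 8.0
    mu_range: tuple[float, float] = (120.0, 140.0)
    sigma_range: tuple[float, float] = (1.0 / 128.0, 1.0 / 16.0)
    segment_duration: float = 0.3
    audio: bool = False


@dataclass
class GridConfig:
    n_mu: int = 41
    n_sigma: int = 29
    n_f: int = 513
    pad_sigmas: float = 4.0


@dataclass
class LfpConfig:
    n_channels: int = 5
    sample_rate: float = 1000.0
    noise_exponent: float = 1.0
    noise_scale: float = 1.0
    pad_seconds: float = 1.0
    gain: float = 0.6                      # used when effects is None
    effects: list[EffectSpec] | None = None


@dataclass
class AnalysisConfig:
    n_perm: int = 100
    alpha: float = 0.05
    reject_percentile: float = 99.5
    channel_alpha: float = 0.05
    roi_band: tuple[float, float] = (30.0, 100.0)
    compare_window_ms: tuple[float, float] = (90.0, 500.0)
    lag_span: int = 2


@dataclass
class RunConfig:
    """Everything needed for a reproducible end-to-end run."""

    stimulus: StimulusConfig = field(default_factory=StimulusConfig)
    grid: GridConfig = field(default_factory=GridConfig)
    lfp: LfpConfig = field(default_factory=LfpConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    preset: str = "main"
    seed: int = 0

    def validate(self) -> "RunConfig":
        if self.preset not in PRESET_NAMES:
            raise ConfigurationError(
                f"unknown preset {self.preset!r}; expected one of {PRESET_NAMES}"
            )
        if not 0 < self.stimulus.p_change < 1:
            raise ConfigurationError("p_change must lie strictly in (0, 1)")
        if self.analysis.alpha < 1.0 / self.analysis.n_perm:
            raise ConfigurationError("alpha unresolvable with n_perm permutations")
        for eff in self.resolved_effects():
            if eff.band[1] > self.lfp.sample_rate / 2:
                raise ConfigurationError(
                    f"effect band {eff.band} exceeds Nyquist "
                    f"({self.lfp.sample_rate / 2} Hz)"
                )
        return self

    def resolved_effects(self) -> list[EffectSpec]:
        if self.lfp.effects is not None:
            return self.lfp.effects
        return default_effects(self.lfp.gain)

    def stage_rngs(self) -> dict[str, np.random.Generator]:
        """Deterministic per-stage generators fanned out from the master seed."""
        names = ("stimulus", "inversion", "lfp", "analysis", "report")
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return {n: np.random.default_rng(ss) for n, ss in zip(names, children)}

    # --- YAML round trip -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        if self.lfp.effects is not None:
            d["lfp"]["effects"] = [asdict(e) for e in self.lfp.effects]
        return _tuples_to_lists(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        stim = StimulusConfig(**_listify(d.get("stimulus", {}), ("mu_range", "sigma_range")))
        grid = GridConfig(**d.get("grid", {}))
        lfp_d = dict(d.get("lfp", {}))
        effects = lfp_d.pop("effects", None)
        if effects is not None:
            effects = [
                EffectSpec(**_listify(e, ("band", "window_ms"))) for e in effects
            ]
        lfp = LfpConfig(effects=effects, **lfp_d)
        ana = AnalysisConfig(
            **_listify(d.get("analysis", {}), ("roi_band", "compare_window_ms"))
        )
        return cls(
            stimulus=stim,
            grid=grid,
            lfp=lfp,
            analysis=ana,
            preset=d.get("preset", "main"),
            seed=int(d.get("seed", 0)),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _tuples_to_lists(obj):
    if isinstance(obj, dict):
        return {k: _tuples_to_lists(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_tuples_to_lists(v) for v in obj]
    return obj


def _listify(d: dict, tuple_keys: tuple[str, ...]) -> dict:
    out = dict(d)
    for k in tuple_keys:
        if k in out and out[k] is not None:
            out[k] = tuple(out[k])
    return out
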