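"""End-to-end orchestration: stimulus -> inversion -> partialisation ->
synthetic LFP -> time-frequency regression, with artifacts written to a
run directory and a machine-readable summary."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from . import inversion, regressors, stimgen, synthlfp, tfreg
from .config import RunConfig

log = logging.getLogger(__name__)

STAGES = ("simulate", "invert", "synth", "analyze", "report")


@dataclass
class PipelineState:
    """In-memory artifacts carried between stages."""

    cfg: RunConfig
    outdir: Path
    rngs: dict = field(default_factory=dict)
    seq: stimgen.StimulusSequence | None = None
    regs: inversion.RegressorSet | None = None
    partial: regressors.PartialisedRegressors | None = None
    recording: synthlfp.SyntheticRecording | None = None
    tf: tfreg.TFDecomposition | None = None
    maps: dict = field(default_factory=dict)
    summary: dict = field(default_factory=dict)


def _preset_design(cfg: RunConfig):
    return regressors.PRESETS[cfg.preset](
        regressors.REGRESSOR_COLUMNS, cfg.analysis.lag_span
    )


def stage_simulate(state: PipelineState) -> None:
    cfg = state.cfg
    state.seq = stimgen.generate_sequence(
        cfg.stimulus.n_segments,
        cfg.stimulus.p_change,
        rng=state.rngs["stimulus"],
        mu_range=cfg.stimulus.mu_range,
        sigma_range=cfg.stimulus.sigma_range,
        segment_duration=cfg.stimulus.segment_duration,
    )
    stimgen.write_sequence_log(state.seq, state.outdir / "stimulus.csv")
    if cfg.stimulus.audio:
        wave, rate = stimgen.synthesize_audio(state.seq)
        stimgen.write_wav(state.outdir / "stimulus.wav", wave, rate)


def stage_invert(state: PipelineState) -> None:
    cfg = state.cfg
    if state.seq is None:
        state.seq = stimgen.read_sequence_log(state.outdir / "stimulus.csv")
    space = inversion.build_model_space(
        mu_range=cfg.stimulus.mu_range,
        sigma_range=cfg.stimulus.sigma_range,
        n_mu=cfg.grid.n_mu,
        n_sigma=cfg.grid.n_sigma,
        n_f=cfg.grid.n_f,
        pad_sigmas=cfg.grid.pad_sigmas,
    )
    state.regs = inversion.compute_regressors(
        state.seq, space, p_change=cfg.stimulus.p_change
    )
    state.regs.to_csv(state.outdir / "regressors.csv")
    state.partial = regressors.partialise(
        state.regs, lag_span=cfg.analysis.lag_span, design=_preset_design(cfg)
    )
    state.partial.to_csv(state.outdir / "partialised.csv")
    lagcorr = regressors.lagged_correlation_matrix(state.regs)
    lagcorr.to_csv(state.outdir / "lagged_correlations.csv")

    frame = state.regs.frame
    r_s_xi = float(np.corrcoef(frame["surprise"], frame["pe"])[0, 1])
    truth = frame["change_true"].to_numpy()
    inferred = frame["change_inferred"].to_numpy()
    state.summary["r_surprise_pe"] = r_s_xi
    state.summary["change_hit_rate"] = float(inferred[truth].mean())
    state.summary["change_false_alarm_rate"] = float(inferred[~truth].mean())


def stage_synth(state: PipelineState) -> None:
    cfg = state.cfg
    state.recording = synthlfp.generate_recording(
        state.regs,
        effects=cfg.resolved_effects(),
        n_channels=cfg.lfp.n_channels,
        sample_rate=cfg.lfp.sample_rate,
        noise_exponent=cfg.lfp.noise_exponent,
        noise_scale=cfg.lfp.noise_scale,
        pad_seconds=cfg.lfp.pad_seconds,
        segment_duration=cfg.stimulus.segment_duration,
        rng=state.rngs["lfp"],
    )
    synthlfp.write_recording(state.recording, state.outdir / "recording.h5")


def stage_analyze(state: PipelineState) -> None:
    cfg = state.cfg
    rng = state.rngs["analysis"]
    if state.recording is None:
        state.recording = synthlfp.read_recording(state.outdir / "recording.h5")
    state.tf = tfreg.morlet_decompose(state.recording)

    mask = tfreg.reject_artifacts(
        state.tf,
        mean_percentile=cfg.analysis.reject_percentile,
        max_percentile=cfg.analysis.reject_percentile,
    )
    keep = mask.keep_all_channels
    selected, observed, _null = tfreg.select_channels(
        state.tf,
        n_perm=cfg.analysis.n_perm,
        alpha=cfg.analysis.channel_alpha,
        rng=rng,
        keep_segments=np.nonzero(keep)[0],
    )
    state.summary["n_segments_kept"] = int(keep.sum())
    state.summary["channels_selected"] = selected.tolist()

    # align partialised regressors with kept TF segments
    part = state.partial
    seg_kept = state.tf.segments[keep]
    common = np.intersect1d(part.segments, seg_kept)
    part_rows = {
        c: part.frame.loc[common, c].to_numpy() for c in part.frame.columns
    }
    tf_index = {s: i for i, s in enumerate(state.tf.segments)}
    keep_idx = np.array([tf_index[s] for s in common])

    effects = cfg.resolved_effects()
    for name, series in part_rows.items():
        state.maps[name] = tfreg.regress_with_permutations(
            state.tf,
            series,
            n_perm=cfg.analysis.n_perm,
            alpha=cfg.analysis.alpha,
            rng=rng,
            keep_segments=keep_idx,
        )
    recovery = tfreg.summarize_recovery(state.maps, effects)
    for name, maps in state.maps.items():
        recovery[name]["induced_threshold"] = maps.threshold("induced")
        recovery[name]["evoked_threshold"] = maps.threshold("evoked")
    state.summary["recovery"] = recovery
    _write_maps(state)


def _write_maps(state: PipelineState) -> None:
    with h5py.File(state.outdir / "maps.h5", "w") as h5:
        h5.create_dataset("times_ms", data=state.tf.times_ms)
        h5.create_dataset("freqs_hz", data=state.tf.freqs_hz)
        for name, maps in state.maps.items():
            g = h5.create_group(name)
            g.create_dataset("evoked_r", data=maps.evoked_r)
            g.create_dataset("induced_r", data=maps.induced_r)
            g.create_dataset("evoked_z", data=maps.evoked_z)
            g.create_dataset("induced_z", data=maps.induced_z)
            g.create_dataset("induced_mask", data=maps.mask("induced"))
            g.create_dataset("evoked_mask", data=maps.mask("evoked"))
            g.attrs["induced_threshold"] = maps.threshold("induced")
            g.attrs["evoked_threshold"] = maps.threshold("evoked")


def stage_report(state: PipelineState) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not state.maps:
        log.warning("report: no maps in state; run analyze first")
        return
    names = list(state.maps)
    fig, axes = plt.subplots(
        len(names), 2, figsize=(9, 2.6 * len(names)), squeeze=False
    )
    for row, name in enumerate(names):
        maps = state.maps[name]
        for col, kind in enumerate(("induced", "evoked")):
            ax = axes[row][col]
            z = getattr(maps, f"{kind}_z")
            vmax = np.abs(z).max() or 1.0
            ax.pcolormesh(
                maps.times_ms,
                maps.freqs_hz,
                z.T,
                cmap="RdBu_r",
                vmin=-vmax,
                vmax=vmax,
            )
            ax.set_title(f"{name} ({kind})", fontsize=9)
            ax.set_xlabel("time (ms)")
            ax.set_ylabel("freq (Hz)")
    fig.tight_layout()
    fig.savefig(state.outdir / "maps.png", dpi=120)
    plt.close(fig)


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "invert": stage_invert,
    "synth": stage_synth,
    "analyze": stage_analyze,
    "report": stage_report,
}


def run_pipeline(
    cfg: RunConfig,
    outdir: str | Path,
    stages: tuple[str, ...] = STAGES,
) -> PipelineState:
    """Execute the requested stages in order, writing all artifacts.

    The resolved config and a summary JSON (with per-stage timings) are
    always written next to the outputs; on a stage failure, partial
    outputs are preserved and the failing stage is recorded.
    """
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "resolved_config.yaml")

    state = PipelineState(cfg=cfg, outdir=outdir, rngs=cfg.stage_rngs())
    timings = {}
    state.summary["seed"] = cfg.seed
    state.summary["preset"] = cfg.preset
    try:
        for stage in STAGES:
            if stage not in stages:
                continue
            t0 = time.perf_counter()
            log.info("stage %s ...", stage)
            _STAGE_FUNCS[stage](state)
            timings[stage] = round(time.perf_counter() - t0, 3)
    except Exception as exc:
        state.summary["failed_stage"] = stage
        state.summary["error"] = repr(exc)
        raise
    finally:
        state.summary["timings_s"] = timings
        (outdir / "summary.json").write_text(
            json.dumps(state.summary, indent=2, default=str)
        )
    return state
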