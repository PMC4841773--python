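"""Morlet decomposition and two-stage evoked/induced regression.

Analysis chain, applied to a segment-locked multichannel recording:

1. Complex Morlet wavelet convolution on a fixed grid (-300..600 ms in
   10 ms steps relative to segment onset, 2..100 Hz in 2 Hz steps, cycle
   count rising linearly from 1 at 2 Hz to 10 at 100 Hz).
2. Artifact rejection from per-frequency z-scored amplitudes: trials
   whose mean or maximum normalised amplitude exceeds an automated
   percentile threshold are dropped.
3. Channel selection: a channel is kept when its largest mean-across-
   segments response in a 300 ms window beats a permutation null built by
   jittering each segment's window by up to +/-300 ms.
4. Two-stage regression at every (channel, time, frequency) point: the
   real and imaginary parts are each regressed on the (partialised)
   regressor; the modulus of the two correlation coefficients is the
   *evoked* response.  The complex residuals are converted to amplitude
   and regressed again, yielding the signed *induced* correlation.
5. Fisher-Z transformation, channel averaging, and max-statistic
   permutation correction (regressor shuffled across segments, full maps
   recomputed, largest |Z| in the correction domain per permutation).

Also provided: a gamma-band region-of-interest test, the paired
surprise-vs-prediction-error window comparison, total variance explained
by the four regressors of interest, and pattern-similarity scores across
channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from ._errors import ConfigurationError
from .synthlfp import SyntheticRecording

DEFAULT_TIMES_MS = np.arange(-300, 601, 10)
DEFAULT_FREQS_HZ = np.arange(2, 101, 2)
GAMMA_BAND = (30.0, 100.0)
# canonical bands; membership is half-open (lo, hi] so bins at band
# boundaries are counted once
BANDS = {
    "delta": (0.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 100.0),
}

__all__ = [
    "TFDecomposition",
    "ArtifactMask",
    "RegressorMaps",
    "wavelet_cycles",
    "morlet_decompose",
    "reject_artifacts",
    "select_channels",
    "evoked_induced_regress",
    "fisher_z",
    "regress_with_permutations",
    "permutation_threshold",
    "gamma_roi_test",
    "compare_regressor_windows",
    "variance_explained",
    "pattern_similarity",
]


def wavelet_cycles(freqs_hz: np.ndarray) -> np.ndarray:
    """Cycles per wavelet, linear from 1 at 2 Hz to 10 at 100 Hz."""
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    return 1.0 + 9.0 * (freqs_hz - 2.0) / 98.0


@dataclass
class TFDecomposition:
    """Complex coefficients indexed (channel, segment, time, frequency)."""

    coeffs: np.ndarray
    times_ms: np.ndarray
    freqs_hz: np.ndarray
    segments: np.ndarray          # indices of segments kept (edge-safe)
    sample_rate: float

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[0]

    @property
    def n_segments(self) -> int:
        return self.coeffs.shape[1]

    def amplitude(self) -> np.ndarray:
        return np.abs(self.coeffs)


def _make_wavelet(f: float, cycles: float, fs: float, n_sigma: float = 3.5) -> np.ndarray:
    sigma_t = cycles / (2.0 * np.pi * f)
    half = int(np.ceil(n_sigma * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    envelope = np.exp(-(t**2) / (2.0 * sigma_t**2))
    wavelet = envelope * np.exp(2j * np.pi * f * t)
    # unit response to a unit-amplitude sinusoid at the centre frequency
    return wavelet / (0.5 * envelope.sum())


def morlet_decompose(
    recording: SyntheticRecording | np.ndarray,
    onsets: np.ndarray | None = None,
    sample_rate: float | None = None,
    times_ms: np.ndarray = DEFAULT_TIMES_MS,
    freqs_hz: np.ndarray = DEFAULT_FREQS_HZ,
) -> TFDecomposition:
    """Convolve with complex Morlet wavelets and sample the epoch grid.

    Segments whose sampling window (padded by the longest wavelet
    half-length) would run past the recording edge are dropped.
    """
    if isinstance(recording, SyntheticRecording):
        signal = recording.signal
        onsets = recording.onsets if onsets is None else np.asarray(onsets)
        fs = recording.sample_rate if sample_rate is None else sample_rate
    else:
        signal = np.atleast_2d(np.asarray(recording, dtype=float))
        if onsets is None or sample_rate is None:
            raise ConfigurationError("raw-array input needs onsets and sample_rate")
        onsets = np.asarray(onsets)
        fs = sample_rate

    times_ms = np.asarray(times_ms)
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    cycles = wavelet_cycles(freqs_hz)
    offsets = np.round(times_ms * fs / 1000.0).astype(int)

    max_half = int(np.ceil(3.5 * (cycles / (2 * np.pi * freqs_hz)).max() * fs))
    n = signal.shape[1]
    ok = (onsets + offsets.min() - max_half >= 0) & (onsets + offsets.max() + max_half < n)
    kept = np.nonzero(ok)[0]
    if len(kept) < len(onsets):
        dropped = len(onsets) - len(kept)
        import logging

        logging.getLogger(__name__).info(
            "morlet_decompose: dropped %d edge segment(s)", dropped
        )
    onsets_kept = onsets[kept]

    nch = signal.shape[0]
    out = np.empty(
        (nch, len(onsets_kept), len(offsets), len(freqs_hz)), dtype=np.complex64
    )
    idx = onsets_kept[:, None] + offsets[None, :]
    for j, (f, c) in enumerate(zip(freqs_hz, cycles)):
        w = _make_wavelet(f, c, fs)
        for ch in range(nch):
            conv = sps.oaconvolve(signal[ch], w, mode="same")
            out[ch, :, :, j] = conv[idx]
    return TFDecomposition(
        coeffs=out,
        times_ms=times_ms,
        freqs_hz=freqs_hz,
        segments=kept,
        sample_rate=fs,
    )


@dataclass
class ArtifactMask:
    """Per-(channel, segment) keep flags, a pure function of the stored
    per-trial statistics and thresholds."""

    keep: np.ndarray          # (n_channels, n_segments) bool
    trial_mean: np.ndarray    # mean normalised amplitude per trial
    trial_max: np.ndarray     # max normalised amplitude per trial
    mean_threshold: np.ndarray
    max_threshold: np.ndarray

    @property
    def keep_all_channels(self) -> np.ndarray:
        return self.keep.all(axis=0)


def reject_artifacts(
    tf: TFDecomposition,
    mean_percentile: float = 99.5,
    max_percentile: float = 99.5,
    mean_threshold: float | None = None,
    max_threshold: float | None = None,
) -> ArtifactMask:
    """Flag outlier trials from per-frequency normalised amplitudes.

    Amplitudes are z-scored per (channel, frequency) across segments and
    times; each trial's mean and maximum normalised amplitude is compared
    against a percentile-derived (or explicit) threshold.
    """
    amp = tf.amplitude().astype(np.float32)
    mean = amp.mean(axis=(1, 2), keepdims=True)
    sd = amp.std(axis=(1, 2), keepdims=True)
    sd[sd == 0] = 1.0
    z = (amp - mean) / sd
    trial_mean = z.mean(axis=(2, 3))
    trial_max = z.max(axis=(2, 3))
    if mean_threshold is None:
        thr_mean = np.percentile(trial_mean, mean_percentile, axis=1)
    else:
        thr_mean = np.full(tf.n_channels, mean_threshold)
    if max_threshold is None:
        thr_max = np.percentile(trial_max, max_percentile, axis=1)
    else:
        thr_max = np.full(tf.n_channels, max_threshold)
    keep = (trial_mean <= thr_mean[:, None]) & (trial_max <= thr_max[:, None])
    return ArtifactMask(
        keep=keep,
        trial_mean=trial_mean,
        trial_max=trial_max,
        mean_threshold=thr_mean,
        max_threshold=thr_max,
    )


def select_channels(
    tf: TFDecomposition,
    n_perm: int = 100,
    alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
    window_ms: tuple[float, float] = (0.0, 300.0),
    jitter_ms: float = 300.0,
    keep_segments: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Keep channels with a significant stimulus-locked response.

    The observed statistic is the largest mean-across-segments amplitude
    anywhere in the analysis window; the null re-averages with each
    segment's window independently jittered by up to +/-jitter_ms.
    Returns ``(selected_channel_indices, observed, null)``.
    """
    gen = np.random.default_rng(rng)
    amp = tf.amplitude().astype(np.float32)
    if keep_segments is not None:
        amp = amp[:, keep_segments]
    nch, nseg, ntime, nfreq = amp.shape
    dt = float(np.median(np.diff(tf.times_ms)))
    wi = np.nonzero((tf.times_ms >= window_ms[0]) & (tf.times_ms <= window_ms[1]))[0]
    jmax = int(round(jitter_ms / dt))
    jmax = min(jmax, int(wi.min()), int(ntime - 1 - wi.max()))

    observed = amp.mean(axis=1)[:, wi, :].max(axis=(1, 2))
    null = np.empty((nch, n_perm), dtype=np.float32)
    rows = np.arange(nseg)[:, None]
    for p in range(n_perm):
        js = gen.integers(-jmax, jmax + 1, size=nseg) if jmax > 0 else np.zeros(nseg, int)
        idx = wi[None, :] + js[:, None]
        for ch in range(nch):
            shifted = amp[ch][rows, idx, :]
            null[ch, p] = shifted.mean(axis=0).max()
    thresholds = np.quantile(null, 1.0 - alpha, axis=1)
    selected = np.nonzero(observed > thresholds)[0]
    if len(selected) == 0:
        import warnings

        warnings.warn(
            "no channel exceeded the stimulus-response threshold",
            RuntimeWarning,
            stacklevel=2,
        )
    return selected, observed, null


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher Z transform, z = atanh(r); |r| must be < 1."""
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) >= 1.0):
        raise ValueError("|r| must be < 1 for the Fisher Z transform")
    out = np.arctanh(arr)
    return float(out) if np.isscalar(r) or out.ndim == 0 else out


class _TwoStageWorkspace:
    """Pre-centred flat views of the complex coefficients.

    Centring per (channel, time, frequency) point and the per-point SDs do
    not depend on the regressor, so they are computed once and reused for
    every permutation.  Segments run along axis 0; points are flattened in
    (channel, time, frequency) order.
    """

    def __init__(self, coeffs: np.ndarray, keep_segments: np.ndarray | None):
        if keep_segments is not None:
            coeffs = coeffs[:, keep_segments]
        self.nch, self.nseg, self.ntime, self.nfreq = coeffs.shape
        if self.nseg < 3:
            raise ConfigurationError("need at least 3 segments for regression")
        flat = coeffs.transpose(1, 0, 2, 3).reshape(self.nseg, -1)
        self.yr = np.ascontiguousarray(flat.real, dtype=np.float32)
        self.yi = np.ascontiguousarray(flat.imag, dtype=np.float32)
        self.yr -= self.yr.mean(axis=0)
        self.yi -= self.yi.mean(axis=0)
        self.sd_r = self.yr.std(axis=0)
        self.sd_i = self.yi.std(axis=0)
        self.sd_r[self.sd_r == 0] = np.inf
        self.sd_i[self.sd_i == 0] = np.inf

    def _shape(self, arr: np.ndarray) -> np.ndarray:
        return arr.reshape(self.nch, self.ntime, self.nfreq)

    def maps(self, x: np.ndarray) -> dict[str, np.ndarray]:
        n = self.nseg
        x = np.asarray(x, dtype=np.float64)
        if len(x) != n:
            raise ConfigurationError("regressor must align with kept segments")
        sx = x.std()
        if sx == 0:
            raise ConfigurationError("zero-variance regressor: correlation undefined")
        xc = ((x - x.mean()) / sx).astype(np.float32)   # unit variance

        cov_r = (xc @ self.yr) / n                       # = sx-scaled covariance
        cov_i = (xc @ self.yi) / n
        r_re = cov_r / self.sd_r
        r_im = cov_i / self.sd_i
        evoked = np.hypot(r_re, r_im)

        # joint residualisation of both parts (beta in units of xc)
        resid_r = self.yr - xc[:, None] * cov_r[None, :]
        resid_i = self.yi - xc[:, None] * cov_i[None, :]
        s2 = resid_r
        np.square(resid_r, out=s2)
        np.square(resid_i, out=resid_i)
        s2 += resid_i
        amp = np.sqrt(s2)
        mean_amp = amp.mean(axis=0)
        var_amp = s2.mean(axis=0) - mean_amp**2
        sd_amp = np.sqrt(np.maximum(var_amp, 0.0))
        sd_amp[sd_amp == 0] = np.inf
        induced = ((xc @ amp) / n - 0.0) / sd_amp        # xc zero-mean, unit SD
        return {"evoked": self._shape(evoked), "induced": self._shape(induced)}


def evoked_induced_regress(
    tf: TFDecomposition | np.ndarray,
    regressor: np.ndarray,
    keep_segments: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Two-stage regression at every (channel, time, frequency) point.

    Stage 1 regresses the real and imaginary parts separately on the
    regressor; the modulus of the two r values is the evoked map.  The
    complex residuals (both parts residualised jointly, intercept
    included) are converted to amplitude and regressed again, giving the
    signed induced map.  Returns ``{"evoked": ..., "induced": ...}`` of
    shape (n_channels, n_times, n_freqs).
    """
    coeffs = tf.coeffs if isinstance(tf, TFDecomposition) else np.asarray(tf)
    return _TwoStageWorkspace(coeffs, keep_segments).maps(regressor)


@dataclass
class RegressorMaps:
    """Observed and permutation-null maps for one regressor.

    ``evoked_z``/``induced_z`` are channel-averaged Fisher-Z maps of shape
    (n_times, n_freqs); the null arrays hold one channel-averaged map per
    permutation, so corrected thresholds can be recomputed over any
    correction domain (e.g. a gamma ROI) without re-running permutations.
    """

    times_ms: np.ndarray
    freqs_hz: np.ndarray
    evoked_r: np.ndarray           # (n_channels, T, F)
    induced_r: np.ndarray
    evoked_z: np.ndarray           # (T, F)
    induced_z: np.ndarray
    evoked_null: np.ndarray        # (n_perm, T, F)
    induced_null: np.ndarray
    alpha: float

    def threshold(self, kind: str = "induced", domain: np.ndarray | None = None) -> float:
        null = getattr(self, f"{kind}_null")
        if domain is not None:
            null = null[:, domain]
            if null.shape[1] == 0:
                raise ConfigurationError("empty correction domain")
            maxima = np.abs(null).max(axis=1)
        else:
            maxima = np.abs(null).max(axis=(1, 2))
        return float(np.quantile(maxima, 1.0 - self.alpha))

    def mask(self, kind: str = "induced", domain: np.ndarray | None = None) -> np.ndarray:
        z = getattr(self, f"{kind}_z")
        thr = self.threshold(kind, domain)
        out = np.abs(z) > thr
        if domain is not None:
            out = out & domain
        return out


def _avg_fisher_z(r_maps: np.ndarray) -> np.ndarray:
    """Average per-channel maps in Fisher-Z space."""
    return np.arctanh(np.clip(r_maps, -1 + 1e-7, 1 - 1e-7)).mean(axis=0)


def regress_with_permutations(
    tf: TFDecomposition,
    regressor: np.ndarray,
    n_perm: int = 100,
    alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
    keep_segments: np.ndarray | None = None,
) -> RegressorMaps:
    """Observed maps plus a max-statistic permutation null.

    Each permutation shuffles the regressor across segments and recomputes
    the full two-stage regression; channel-averaged Fisher-Z maps are
    stored per permutation.
    """
    if alpha < 1.0 / n_perm:
        raise ConfigurationError(
            f"alpha={alpha} unresolvable with n_perm={n_perm} permutations"
        )
    gen = np.random.default_rng(rng)
    ws = _TwoStageWorkspace(tf.coeffs, keep_segments)
    obs = ws.maps(regressor)
    x = np.asarray(regressor, dtype=float)
    T, F = len(tf.times_ms), len(tf.freqs_hz)
    evoked_null = np.empty((n_perm, T, F), dtype=np.float32)
    induced_null = np.empty((n_perm, T, F), dtype=np.float32)
    for p in range(n_perm):
        xp = gen.permutation(x)
        maps = ws.maps(xp)
        evoked_null[p] = _avg_fisher_z(maps["evoked"])
        induced_null[p] = _avg_fisher_z(maps["induced"])
    return RegressorMaps(
        times_ms=tf.times_ms,
        freqs_hz=tf.freqs_hz,
        evoked_r=obs["evoked"],
        induced_r=obs["induced"],
        evoked_z=_avg_fisher_z(obs["evoked"]),
        induced_z=_avg_fisher_z(obs["induced"]),
        evoked_null=evoked_null,
        induced_null=induced_null,
        alpha=alpha,
    )


def permutation_threshold(
    null_maps: np.ndarray, alpha: float, domain: np.ndarray | None = None
) -> float:
    """Corrected threshold: (1-alpha) quantile of per-permutation maxima."""
    if domain is not None:
        null_maps = null_maps[:, domain]
        maxima = np.abs(null_maps).max(axis=1)
    else:
        maxima = np.abs(null_maps).max(axis=tuple(range(1, null_maps.ndim)))
    return float(np.quantile(maxima, 1.0 - alpha))


def band_domain(
    freqs_hz: np.ndarray, times_ms: np.ndarray, band: tuple[float, float],
    window_ms: tuple[float, float] | None = None,
) -> np.ndarray:
    """(T, F) boolean mask selecting a frequency band (and time window).

    Band membership is half-open, lo < f <= hi, so adjacent canonical
    bands never share a frequency bin.
    """
    fmask = (freqs_hz > band[0]) & (freqs_hz <= band[1])
    if not fmask.any():
        raise ConfigurationError(f"band {band} lies outside the frequency grid")
    tmask = np.ones(len(times_ms), dtype=bool)
    if window_ms is not None:
        tmask = (times_ms >= window_ms[0]) & (times_ms <= window_ms[1])
    return tmask[:, None] & fmask[None, :]


def wavelet_sigma_f(freqs_hz: np.ndarray) -> np.ndarray:
    """Spectral SD (Hz) of the analysis wavelet at each frequency.

    sigma_f = f / cycles; with 1-3 cycles below 30 Hz the wavelets are
    spectrally broad, so a narrowband effect is necessarily visible in
    neighbouring bins.
    """
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    return freqs_hz / wavelet_cycles(freqs_hz)


def spectral_reach(carrier_hz: float, freqs_hz: np.ndarray, n_sigma: float = 3.0) -> np.ndarray:
    """Which frequency bins can see a carrier through their wavelet passband."""
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    return np.abs(freqs_hz - carrier_hz) <= n_sigma * wavelet_sigma_f(freqs_hz)


def summarize_recovery(
    maps: dict[str, "RegressorMaps"],
    effects: list | None = None,
) -> dict:
    """Per (regressor, band) significance table with ground-truth checks.

    For each regressor: which canonical bands contain significant points
    (evoked and induced), the band holding the peak significant |Z|, and —
    when ground-truth effects are supplied — whether the embedded
    (band, window) is recovered and whether any significance appears at
    bins spectrally remote from the embedded carrier (beyond 3 wavelet
    sigma_f), i.e. contamination not attributable to wavelet bandwidth.
    """
    effect_lookup = {e.regressor: e for e in (effects or [])}
    out: dict = {}
    for name, m in maps.items():
        entry: dict = {"significant": {}, "peak_band": {}, "embedded": None}
        for kind in ("evoked", "induced"):
            mask = m.mask(kind)
            z = np.abs(getattr(m, f"{kind}_z"))
            sig_bands = []
            for band_name, band in BANDS.items():
                dom = band_domain(m.freqs_hz, m.times_ms, band)
                if (mask & dom).any():
                    sig_bands.append(band_name)
            entry["significant"][kind] = sig_bands
            if mask.any():
                zz = np.where(mask, z, 0.0)
                fpk = m.freqs_hz[np.unravel_index(zz.argmax(), zz.shape)[1]]
                entry["peak_band"][kind] = next(
                    b for b, (lo, hi) in BANDS.items() if lo < fpk <= hi
                )
            else:
                entry["peak_band"][kind] = None
        eff = effect_lookup.get(name)
        if eff is not None:
            kind = eff.mode
            mask = m.mask(kind)
            dom = band_domain(m.freqs_hz, m.times_ms, eff.band, eff.window_ms)
            reach = spectral_reach(eff.center_hz, m.freqs_hz)
            remote = mask & ~reach[None, :]
            entry["embedded"] = {
                "band": list(eff.band),
                "window_ms": list(eff.window_ms),
                "mode": eff.mode,
                "recovered": bool((mask & dom).any()),
                "remote_contamination": bool(remote.any()),
            }
        out[name] = entry
    return out


def gamma_roi_test(
    maps: RegressorMaps, band: tuple[float, float] = GAMMA_BAND, kind: str = "induced"
) -> np.ndarray:
    """Max-statistic correction restricted to a frequency band ROI."""
    domain = band_domain(maps.freqs_hz, maps.times_ms, band)
    return maps.mask(kind, domain)


@dataclass
class WindowComparison:
    """Paired comparison of two regressors' mean windowed induced correlation."""

    mean_z: dict[str, float]            # stage-2 channel-mean windowed Z
    mean_z_stage1: dict[str, float]
    per_channel_diff: np.ndarray
    diff: float
    p_value: float
    n_perm: int


def compare_regressor_windows(
    tf: TFDecomposition,
    residual_a: np.ndarray,
    residual_b: np.ndarray,
    names: tuple[str, str] = ("surprise", "pe"),
    stage1: tuple[np.ndarray, np.ndarray] | None = None,
    window_ms: tuple[float, float] = (90.0, 500.0),
    band: tuple[float, float] = GAMMA_BAND,
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
    keep_segments: np.ndarray | None = None,
) -> WindowComparison:
    """Which of two mutually-partialised regressors better explains the
    windowed induced response?

    ``residual_a``/``residual_b`` are the stage-2 residuals (each
    additionally partialised on the other); ``stage1`` optionally carries
    the residuals without mutual partialisation, reported for reference.
    The difference of channel-mean windowed Fisher-Z values is tested by a
    sign-flip (label-swap) permutation across channels.
    """
    domain = band_domain(tf.freqs_hz, tf.times_ms, band, window_ms)
    gen = np.random.default_rng(rng)

    def windowed_channel_means(x: np.ndarray) -> np.ndarray:
        maps = evoked_induced_regress(tf, x, keep_segments)["induced"]
        z = np.arctanh(np.clip(maps, -1 + 1e-7, 1 - 1e-7))
        return z[:, domain].mean(axis=1)

    za = windowed_channel_means(residual_a)
    zb = windowed_channel_means(residual_b)
    d = za - zb
    diff = float(d.mean())
    flips = gen.integers(0, 2, size=(n_perm, len(d))) * 2 - 1
    null = (flips * d[None, :]).mean(axis=1)
    p = float((np.sum(np.abs(null) >= abs(diff)) + 1) / (n_perm + 1))

    stage1_means = {}
    if stage1 is not None:
        stage1_means = {
            names[0]: float(windowed_channel_means(stage1[0]).mean()),
            names[1]: float(windowed_channel_means(stage1[1]).mean()),
        }
    return WindowComparison(
        mean_z={names[0]: float(za.mean()), names[1]: float(zb.mean())},
        mean_z_stage1=stage1_means,
        per_channel_diff=d,
        diff=diff,
        p_value=p,
        n_perm=n_perm,
    )


def variance_explained(
    tf: TFDecomposition,
    regressors: np.ndarray,
    window_ms: tuple[float, float] = (0.0, 300.0),
    keep_segments: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """R^2 of induced amplitude on the raw regressors, channel-averaged.

    ``regressors`` is (n_segments, k).  Returns ``(r2_map, times_ms)``
    with r2_map of shape (n_window_times, n_freqs).
    """
    coeffs = tf.coeffs if keep_segments is None else tf.coeffs[:, keep_segments]
    X = np.asarray(regressors, dtype=float)
    nch, nseg, ntime, nfreq = coeffs.shape
    if X.shape[0] != nseg:
        raise ConfigurationError("regressor matrix must align with kept segments")
    tmask = (tf.times_ms >= window_ms[0]) & (tf.times_ms <= window_ms[1])
    amp = np.abs(coeffs[:, :, tmask, :]).astype(np.float64)
    amp = amp.reshape(nch, nseg, -1)

    Xd = np.column_stack([np.ones(nseg), (X - X.mean(axis=0)) / X.std(axis=0)])
    pinv = np.linalg.pinv(Xd)
    r2 = np.empty((nch, amp.shape[2]))
    for ch in range(nch):
        y = amp[ch]
        beta = pinv @ y
        resid = y - Xd @ beta
        sst = ((y - y.mean(axis=0)) ** 2).sum(axis=0)
        sst[sst == 0] = np.inf
        r2[ch] = 1.0 - (resid**2).sum(axis=0) / sst
    return r2.mean(axis=0).reshape(tmask.sum(), nfreq), tf.times_ms[tmask]


def pattern_similarity(channel_maps: np.ndarray) -> np.ndarray:
    """Per-channel similarity to the mean correlation pattern, in [-1, 1].

    The channel-averaged map acts as a filter: each channel's score is the
    mean elementwise product of its map with the filter, scaled by the
    largest absolute score.
    """
    maps = np.asarray(channel_maps, dtype=float)
    if maps.ndim < 2 or maps.shape[0] < 1:
        raise ConfigurationError("need at least one channel map")
    filt = maps.mean(axis=0)
    scores = (maps * filt[None]).reshape(maps.shape[0], -1).mean(axis=1)
    peak = np.abs(scores).max()
    return scores / peak if peak > 0 else scores
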