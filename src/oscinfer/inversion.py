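"""Bayes-optimal inversion of the pitch-sequence generative process.

The observer knows the generative rules exactly: segment fundamentals are
drawn from a hidden Gaussian population in log-frequency space, and the
population is replaced with probability ``p_change`` at every segment.
Inference runs on a discretised three-dimensional model space over
(population mean mu, population SD sigma, fundamental f):

* each *column* of the cube, P(f | mu, sigma), is the forward model;
* each *plane*, P(mu, sigma | f) up to normalisation, is the inverse model.

The sequential loop maintains a posterior plane over (mu, sigma) as the
normalised product of the inverse planes of all observations since the
most recently inferred population change.  The prior prediction for the
next f value is a mixture of

* the *no-change* predictive: the posterior-weighted average of forward
  columns, and
* the *change* predictive: the unweighted (uniform-parameter) average,

weighted ``(1 - p_change)`` and ``p_change`` respectively.  Per segment
the regressors are

* surprise  ``S_t  = -log p(f_t)`` (prior bin mass, probability floor
  guards zero-mass tail bins),
* prediction error ``xi_t = |log2 f_t - mu_t|`` (octaves),
* prediction change ``dmu_t = |mu_{t+1} - mu_t|`` (octaves),
* precision ``Pi_t = 1 / var_t`` (octaves^-2),
* pitch change ``df_t = |log2(f_t / f_{t-1})|`` (octaves; undefined for
  the first segment).

Population changes are inferred with Bayes' rule on the present f value,
``P(c|f) = 1 / (1 + ((1-p)/p) * P(f|~c) / P(f|c))``, evaluated for
candidate change times t, t-1, t-2, t-3.  For the candidate at lag k the
change likelihood uses a predictive rooted at the uniform parameter plane
and updated with the observations after k (at lag 0 this is exactly the
uniform-average change predictive); the no-change likelihood always uses
the predictive from all observations since the last accepted change.  A
change is declared at the candidate with the largest P(c|f), ties broken
toward the most recent candidate, iff that value exceeds 0.5.
Retrospective changes never alter priors that have already been emitted.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtr

from ._errors import ConfigurationError, DegeneratePosteriorError, UndefinedEvidenceError
from .stimgen import (
    DEFAULT_MU_RANGE,
    DEFAULT_P_CHANGE,
    DEFAULT_SIGMA_RANGE,
    StimulusSequence,
)

DEFAULT_N_MU = 41
DEFAULT_N_SIGMA = 29
DEFAULT_N_F = 513
DEFAULT_PAD_SIGMAS = 4.0
SURPRISE_FLOOR = 1e-12
CHANGE_THRESHOLD = 0.5
MAX_CANDIDATES = 4

__all__ = [
    "ModelSpace",
    "ParameterPosterior",
    "PredictiveDistribution",
    "ChangeInference",
    "RegressorSet",
    "build_model_space",
    "update_posterior",
    "predict",
    "change_posterior",
    "infer_change",
    "IdealObserver",
    "compute_regressors",
]


@dataclass
class ModelSpace:
    """Discretised cube P(f | mu, sigma); f bins uniform in octaves."""

    mu_grid: np.ndarray          # Hz
    sigma_grid: np.ndarray       # octaves
    f_centers_oct: np.ndarray    # log2 Hz
    f_edges_oct: np.ndarray
    cube: np.ndarray             # (n_f, n_mu, n_sigma), every column sums to 1

    @property
    def n_f(self) -> int:
        return len(self.f_centers_oct)

    @property
    def flat(self) -> np.ndarray:
        """(n_f, n_mu * n_sigma) view of the cube."""
        return self.cube.reshape(self.n_f, -1)

    def f_to_bin(self, f_hz: float | np.ndarray) -> np.ndarray | int:
        """Index of the f bin containing log2(f_hz), clipped to the grid."""
        idx = np.searchsorted(self.f_edges_oct, np.log2(f_hz), side="right") - 1
        return np.clip(idx, 0, self.n_f - 1)


def build_model_space(
    mu_range: tuple[float, float] = DEFAULT_MU_RANGE,
    sigma_range: tuple[float, float] = DEFAULT_SIGMA_RANGE,
    n_mu: int = DEFAULT_N_MU,
    n_sigma: int = DEFAULT_N_SIGMA,
    n_f: int = DEFAULT_N_F,
    pad_sigmas: float = DEFAULT_PAD_SIGMAS,
    f_range_oct: tuple[float, float] | None = None,
) -> ModelSpace:
    """Build the discretised model space.

    The f grid spans the mu range padded by ``pad_sigmas * max(sigma)``
    octaves on each side, so that unclipped generator draws stay on-grid
    out to the 4-sigma tails.  Column mass at each bin is the Gaussian
    probability between the bin edges, renormalised to sum to one.
    """
    if min(n_mu, n_sigma, n_f) < 2:
        raise ConfigurationError("need at least 2 grid points per dimension")
    mu_lo, mu_hi = mu_range
    sg_lo, sg_hi = sigma_range
    if not (0 < mu_lo <= mu_hi and 0 < sg_lo <= sg_hi):
        raise ConfigurationError("mu_range and sigma_range must be positive intervals")

    lo_needed = math.log2(mu_lo) - pad_sigmas * sg_hi
    hi_needed = math.log2(mu_hi) + pad_sigmas * sg_hi
    if f_range_oct is None:
        f_lo, f_hi = lo_needed, hi_needed
    else:
        f_lo, f_hi = f_range_oct
        if f_lo > lo_needed + 1e-12 or f_hi < hi_needed - 1e-12:
            raise ConfigurationError(
                "f grid too narrow: must cover the mu range padded by "
                f"{pad_sigmas} * max(sigma) octaves ([{lo_needed}, {hi_needed}])"
            )

    mu_grid = np.linspace(mu_lo, mu_hi, n_mu)
    sigma_grid = np.linspace(sg_lo, sg_hi, n_sigma)
    edges = np.linspace(f_lo, f_hi, n_f + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    z = (edges[:, None, None] - np.log2(mu_grid)[None, :, None]) / sigma_grid[None, None, :]
    cdf = ndtr(z)
    cube = np.diff(cdf, axis=0)
    cube /= cube.sum(axis=0, keepdims=True)
    return ModelSpace(
        mu_grid=mu_grid,
        sigma_grid=sigma_grid,
        f_centers_oct=centers,
        f_edges_oct=edges,
        cube=cube,
    )


@dataclass
class ParameterPosterior:
    """Posterior over (mu, sigma), normalised to a sum of 1."""

    plane: np.ndarray            # (n_mu, n_sigma)
    segments_used: np.ndarray    # observation indices since the last change

    def __post_init__(self) -> None:
        self.segments_used = np.asarray(self.segments_used, dtype=int)


def _plane_from_log(log_plane: np.ndarray, context: str) -> np.ndarray:
    m = log_plane.max()
    if not np.isfinite(m):
        raise DegeneratePosteriorError(
            f"all-zero parameter posterior ({context}); observations fall "
            "outside the support of every forward column — widen the f grid"
        )
    w = np.exp(log_plane - m)
    return w / w.sum()


def update_posterior(
    space: ModelSpace,
    f_values: np.ndarray,
    segments_used: np.ndarray | None = None,
) -> ParameterPosterior:
    """Posterior plane ∝ product of the inverse planes of the observations."""
    f_values = np.atleast_1d(np.asarray(f_values, dtype=float))
    if len(f_values) == 0:
        raise ConfigurationError("update_posterior needs at least one observation")
    x = np.log2(f_values)
    margin = 0.1  # octaves of tolerated overshoot before declaring degeneracy
    lo, hi = space.f_edges_oct[0] - margin, space.f_edges_oct[-1] + margin
    if np.any(x < lo) or np.any(x > hi):
        bad = f_values[(x < lo) | (x > hi)]
        raise DegeneratePosteriorError(
            f"observation(s) {bad} fall far outside the f grid "
            f"[{2**space.f_edges_oct[0]:.1f}, {2**space.f_edges_oct[-1]:.1f}] Hz"
        )
    bins = space.f_to_bin(f_values)
    with np.errstate(divide="ignore"):
        log_flat = np.log(space.flat[bins, :])
    log_plane = log_flat.sum(axis=0)
    plane = _plane_from_log(log_plane, f"{len(f_values)} observations")
    if segments_used is None:
        segments_used = np.arange(len(f_values))
    return ParameterPosterior(
        plane=plane.reshape(len(space.mu_grid), len(space.sigma_grid)),
        segments_used=segments_used,
    )


@dataclass
class PredictiveDistribution:
    """Prior over f with octave-space summary statistics."""

    p: np.ndarray        # mass over f bins, sums to 1
    mu_t: float          # octaves (log2 Hz)
    var_t: float         # octaves^2
    pi_t: float          # octaves^-2, exactly 1 / var_t

    @classmethod
    def from_mass(cls, p: np.ndarray, x_oct: np.ndarray) -> "PredictiveDistribution":
        p = p / p.sum()
        mu = float(p @ x_oct)
        var = float(p @ (x_oct - mu) ** 2)
        # quantisation floor: mass confined to one bin still has the
        # within-bin variance of a uniform density, width**2 / 12
        width = float(np.median(np.diff(x_oct)))
        var = max(var, width**2 / 12.0)
        return cls(p=p, mu_t=mu, var_t=var, pi_t=1.0 / var)


def predict(
    space: ModelSpace,
    posterior: ParameterPosterior,
    p_change: float = DEFAULT_P_CHANGE,
) -> PredictiveDistribution:
    """Mixture prior: (1-p)·posterior-weighted columns + p·uniform average."""
    p_nc = space.flat @ posterior.plane.ravel()
    p_c = space.flat.mean(axis=1)
    prior = (1.0 - p_change) * p_nc + p_change * p_c
    return PredictiveDistribution.from_mass(prior, space.f_centers_oct)


def change_posterior(
    p_f_change: float,
    p_f_nochange: float,
    p_change: float = DEFAULT_P_CHANGE,
) -> float:
    """P(c|f) = 1 / (1 + ((1-p)/p) * P(f|~c) / P(f|c)).

    With equal likelihoods this returns the prior ``p_change`` (1/8 under
    defaults); the 0.5 decision boundary sits at likelihood ratio
    ``P(f|~c)/P(f|c) = p/(1-p)`` (1/7 under defaults).
    """
    if p_f_change < 0 or p_f_nochange < 0:
        raise UndefinedEvidenceError("likelihoods must be non-negative")
    if p_f_change == 0 and p_f_nochange == 0:
        raise UndefinedEvidenceError("both likelihoods are zero")
    if not 0 < p_change < 1:
        if p_change == 0:
            return 0.0
        if p_change == 1:
            return 1.0
        raise ConfigurationError("p_change must lie in [0, 1]")
    if p_f_change == 0:
        return 0.0
    ratio = p_f_nochange / p_f_change
    return 1.0 / (1.0 + (1.0 - p_change) / p_change * ratio)


@dataclass
class ChangeInference:
    """Change probabilities per candidate change time for one segment."""

    p_change_given_f: dict[int, float]   # candidate segment index -> P(c|f)
    inferred_lag: int | None             # chosen change time, None if no change
    threshold: float = CHANGE_THRESHOLD


@dataclass
class RegressorSet:
    """Per-segment regressors emitted by the sequential inversion."""

    frame: pd.DataFrame
    p_change: float
    priors: np.ndarray | None = None       # optional (n+1, n_f) prior masses
    f_centers_oct: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.frame)

    def __getitem__(self, col: str) -> np.ndarray:
        return self.frame[col].to_numpy()

    def to_csv(self, path: str | Path) -> None:
        cols = [
            "segment_index",
            "f_hz",
            "df",
            "surprise",
            "pe",
            "dmu",
            "precision",
            "mu_prior",
            "var_prior",
            "change_inferred",
        ]
        self.frame[cols].to_csv(path, index=False)

    def write_priors_hdf5(self, path: str | Path) -> None:
        """Dump per-segment prior distributions for visualisation."""
        import h5py

        if self.priors is None:
            raise ValueError("observer was run without store_priors=True")
        with h5py.File(path, "w") as h5:
            h5.create_dataset("priors", data=self.priors, compression="gzip")
            h5.create_dataset("f_centers_oct", data=self.f_centers_oct)
            h5.attrs["p_change"] = self.p_change


class IdealObserver:
    """Sequential Bayes-optimal observer over a discretised model space.

    ``step(f_t)`` consumes one segment: it evaluates the current prior at
    f_t, emits the regressors, runs lagged change inference and updates
    the parameter posterior.  The posterior product is accumulated in log
    space; the inverse-plane rows of the last few observations are kept so
    that lagged change candidates can root a fresh posterior at any of the
    last ``max_candidates`` segments.
    """

    def __init__(
        self,
        space: ModelSpace,
        p_change: float = DEFAULT_P_CHANGE,
        max_candidates: int = MAX_CANDIDATES,
        threshold: float = CHANGE_THRESHOLD,
        surprise_floor: float = SURPRISE_FLOOR,
        store_priors: bool = False,
    ) -> None:
        if not 0 < p_change < 1:
            raise ConfigurationError("p_change must lie strictly in (0, 1)")
        self.space = space
        self.p_change = p_change
        self.max_candidates = max_candidates
        self.threshold = threshold
        self.surprise_floor = surprise_floor
        self.store_priors = store_priors

        self._flat = space.flat
        with np.errstate(divide="ignore"):
            self._log_flat = np.log(self._flat)
        self._n_params = self._flat.shape[1]
        self._p_c = self._flat.mean(axis=1)          # change predictive
        self._x = space.f_centers_oct

        self.t = 0
        self.last_change = 0
        self._acc = np.zeros(self._n_params)          # sum of log inverse planes
        self._recent: deque[tuple[int, np.ndarray]] = deque(maxlen=max_candidates)
        self.priors: list[np.ndarray] = []
        self.change_events: list[tuple[int, int, float]] = []  # (t, change_at, P)

    def current_prior(self) -> PredictiveDistribution:
        """Mixture prior prediction for the upcoming segment."""
        plane = _plane_from_log(self._acc, f"segment {self.t}")
        p_nc = self._flat @ plane
        prior = (1.0 - self.p_change) * p_nc + self.p_change * self._p_c
        pred = PredictiveDistribution.from_mass(prior, self._x)
        self._last_p_nc = p_nc
        return pred

    def _candidate_likelihood(self, k: int, bin_t: int) -> float:
        """P(f_t | change at k): uniform-rooted posterior over obs k..t-1."""
        if k == self.t:
            return float(self._p_c[bin_t])
        rows = [row for (i, row) in self._recent if i >= k]
        plane = _plane_from_log(np.sum(rows, axis=0), f"candidate change at {k}")
        return float(self._flat[bin_t] @ plane)

    def step(self, f_t: float) -> dict:
        t = self.t
        bin_t = int(self.space.f_to_bin(f_t))
        x_t = math.log2(f_t)

        pred = self.current_prior()
        if self.store_priors:
            self.priors.append(pred.p.copy())
        surprise = -math.log(max(float(pred.p[bin_t]), self.surprise_floor))
        pe = abs(x_t - pred.mu_t)

        # --- lagged change inference (skipped at t=0: change by fiat) ---
        inference = None
        if t == 0:
            self.change_events.append((0, 0, 1.0))
            change_at = 0
        else:
            l_stay = float(self._last_p_nc[bin_t])
            cands: dict[int, float] = {}
            k_lo = max(self.last_change + 1, t - (self.max_candidates - 1), 1)
            for k in range(k_lo, t + 1):
                l_ck = self._candidate_likelihood(k, bin_t)
                try:
                    cands[k] = change_posterior(l_ck, l_stay, self.p_change)
                except UndefinedEvidenceError:
                    continue
            change_at = None
            if cands:
                best_p = max(cands.values())
                if best_p > self.threshold:
                    # ties broken toward the most recent candidate
                    change_at = max(k for k, v in cands.items() if v >= best_p)
                    self.change_events.append((t, change_at, best_p))
            inference = ChangeInference(
                p_change_given_f=cands, inferred_lag=change_at, threshold=self.threshold
            )

        # --- posterior bookkeeping (never rewrites emitted priors) ---
        log_row = self._log_flat[bin_t]
        self._recent.append((t, log_row))
        if change_at is not None and change_at > self.last_change:
            self.last_change = change_at
            rows = [row for (i, row) in self._recent if i >= change_at]
            self._acc = np.sum(rows, axis=0)
        else:
            self._acc = self._acc + log_row

        self.t = t + 1
        return {
            "segment_index": t,
            "f_hz": f_t,
            "x_oct": x_t,
            "surprise": surprise,
            "pe": pe,
            "mu_prior": pred.mu_t,
            "var_prior": pred.var_t,
            "precision": pred.pi_t,
            "prior_mass": float(pred.p[bin_t]),
            "change_at": change_at,
            "inference": inference,
        }


def infer_change(
    space: ModelSpace,
    history: np.ndarray,
    f_t: float,
    p_change: float = DEFAULT_P_CHANGE,
    max_candidates: int = MAX_CANDIDATES,
) -> ChangeInference:
    """One-shot lagged change inference given the observations since the
    last accepted change (``history``) followed by the present value ``f_t``.
    """
    obs = IdealObserver(space, p_change=p_change, max_candidates=max_candidates)
    for f in np.atleast_1d(history):
        rec = obs.step(float(f))
    rec = obs.step(float(f_t))
    return rec["inference"]


def compute_regressors(
    seq: StimulusSequence,
    space: ModelSpace | None = None,
    p_change: float | None = None,
    store_priors: bool = False,
    **observer_kwargs,
) -> RegressorSet:
    """Run the full sequential inversion over a stimulus sequence.

    Emits one row per segment with df, surprise, pe, dmu, precision plus
    prior summaries and change bookkeeping.  ``df`` for the first segment
    is undefined and emitted as NaN.
    """
    if len(seq) < 2:
        raise ConfigurationError("need at least 2 segments")
    if space is None:
        space = build_model_space()
    if p_change is None:
        p_change = DEFAULT_P_CHANGE
    obs = IdealObserver(
        space, p_change=p_change, store_priors=store_priors, **observer_kwargs
    )
    records = [obs.step(float(f)) for f in seq.f]
    final_pred = obs.current_prior()      # prior for segment n+1, for dmu_n
    if store_priors:
        obs.priors.append(final_pred.p.copy())

    n = len(records)
    mu = np.array([r["mu_prior"] for r in records] + [final_pred.mu_t])
    frame = pd.DataFrame(
        {
            "segment_index": np.arange(n),
            "f_hz": seq.f,
            "x_oct": [r["x_oct"] for r in records],
            "df": np.concatenate([[np.nan], np.abs(np.diff(np.log2(seq.f)))]),
            "surprise": [r["surprise"] for r in records],
            "pe": [r["pe"] for r in records],
            "dmu": np.abs(np.diff(mu)),
            "precision": [r["precision"] for r in records],
            "mu_prior": mu[:-1],
            "var_prior": [r["var_prior"] for r in records],
            "prior_mass": [r["prior_mass"] for r in records],
            "change_true": seq.change,
        }
    )
    inferred = np.zeros(n, dtype=bool)
    detect_time = np.full(n, -1)
    for (t, k, _p) in obs.change_events:
        inferred[k] = True
        detect_time[k] = t
    frame["change_inferred"] = inferred
    frame["change_detect_time"] = detect_time
    priors = np.asarray(obs.priors) if store_priors else None
    return RegressorSet(
        frame=frame,
        p_change=p_change,
        priors=priors,
        f_centers_oct=space.f_centers_oct if store_priors else None,
    )
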