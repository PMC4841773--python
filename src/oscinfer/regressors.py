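"""Partialisation and lagged cross-correlation of the inference regressors.

The five per-segment series (df, surprise, pe, dmu, precision) are highly
mutually correlated, both instantaneously and across neighbouring
segments.  To isolate the unique explanatory contribution of each, every
regressor is replaced by its residual after least-squares projection onto
the other regressors at lags -2..+2 and its own values at lags +/-1, +/-2
(never lag 0), plus an intercept.  All series are z-scored beforehand so
correlation and regression coefficients coincide.  Segments lacking the
full lag window (and the first segment, whose df is undefined) are
dropped symmetrically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import ConfigurationError
from .inversion import RegressorSet

REGRESSOR_COLUMNS = ("df", "surprise", "pe", "dmu", "precision")
DEFAULT_LAG_SPAN = 2

__all__ = [
    "REGRESSOR_COLUMNS",
    "PartialisedRegressors",
    "design_main",
    "design_df_only",
    "design_no_precision",
    "PRESETS",
    "partialise",
    "lagged_correlation_matrix",
]


def _frame(regs) -> pd.DataFrame:
    return regs.frame if isinstance(regs, RegressorSet) else pd.DataFrame(regs)


def zscore(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    sd = a.std()
    if sd == 0:
        return a - a.mean()
    return (a - a.mean()) / sd


Design = dict[str, list[tuple[str, int]]]


def design_main(
    columns: tuple[str, ...] = REGRESSOR_COLUMNS, lag_span: int = DEFAULT_LAG_SPAN
) -> Design:
    """Full design: every other regressor at lags -span..+span, own lags
    +/-1..+/-span (never 0)."""
    design: Design = {}
    lags = range(-lag_span, lag_span + 1)
    for target in columns:
        cols: list[tuple[str, int]] = []
        for other in columns:
            for lag in lags:
                if other == target and lag == 0:
                    continue
                cols.append((other, lag))
        design[target] = cols
    return design


def design_df_only(
    columns: tuple[str, ...] = REGRESSOR_COLUMNS, lag_span: int = DEFAULT_LAG_SPAN
) -> Design:
    """Perceptual regressors conditioned only on contemporaneous pitch
    change; df itself left unpartialised (centred only)."""
    design: Design = {"df": []}
    for target in columns:
        if target == "df":
            continue
        design[target] = [("df", 0)]
    return design


def design_no_precision(
    columns: tuple[str, ...] = REGRESSOR_COLUMNS, lag_span: int = DEFAULT_LAG_SPAN
) -> Design:
    """Full design with precision omitted entirely (as target and regressor)."""
    kept = tuple(c for c in columns if c != "precision")
    return design_main(kept, lag_span)


PRESETS = {
    "main": design_main,
    "df-only-partial": design_df_only,
    "no-precision": design_no_precision,
}


@dataclass
class PartialisedRegressors:
    """Residual series plus the conditioning design that produced them."""

    frame: pd.DataFrame          # indexed by segment_index of the kept rows
    design: Design
    lag_span: int

    def __getitem__(self, col: str) -> np.ndarray:
        return self.frame[col].to_numpy()

    @property
    def segments(self) -> np.ndarray:
        return self.frame.index.to_numpy()

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index_label="segment_index")


def partialise(
    regs,
    lag_span: int = DEFAULT_LAG_SPAN,
    design: Design | str = "main",
    columns: tuple[str, ...] = REGRESSOR_COLUMNS,
) -> PartialisedRegressors:
    """Project out lagged nuisance regressors from each series.

    ``design`` may be a preset name or an explicit mapping
    ``target -> [(column, lag), ...]``.  Rows with NaN in any used series
    (the first segment's df) and rows lacking the full lag window are
    dropped before projection.
    """
    frame = _frame(regs)
    if isinstance(design, str):
        try:
            design = PRESETS[design](columns, lag_span)
        except KeyError:
            raise ConfigurationError(f"unknown partialisation preset {design!r}")
    used = sorted({c for cols in design.values() for c, _ in cols} | set(design))

    raw = {c: frame[c].to_numpy(dtype=float) for c in used}
    valid = np.ones(len(frame), dtype=bool)
    for c in used:
        valid &= np.isfinite(raw[c])
    if not valid.any():
        raise ConfigurationError("no finite rows in regressor series")
    start = int(np.argmax(valid))          # leading invalid rows (first segment)
    stop = len(frame) - int(np.argmax(valid[::-1]))
    if not valid[start:stop].all():
        raise ConfigurationError("internal NaNs in regressor series")
    z = {c: zscore(raw[c][start:stop]) for c in used}
    n = stop - start
    if n < (2 * lag_span + 1) * max(len(design), 1):
        raise ConfigurationError("too few segments for the requested lag design")

    sl = slice(lag_span, n - lag_span)
    idx = np.arange(n)[sl]

    def at_lag(series: np.ndarray, lag: int) -> np.ndarray:
        return series[idx + lag]

    out = {}
    for target, cols in design.items():
        y = z[target][sl]
        X = np.column_stack(
            [np.ones(len(y))] + [at_lag(z[c], lag) for (c, lag) in cols]
        )
        if np.linalg.matrix_rank(X) < X.shape[1]:
            warnings.warn(
                f"rank-deficient conditioning design for {target!r}; "
                "using pseudo-inverse projection",
                RuntimeWarning,
                stacklevel=2,
            )
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        out[target] = y - X @ beta

    segs = frame["segment_index"].to_numpy()[start:stop][sl] if "segment_index" in frame \
        else np.arange(start, stop)[sl]
    result = pd.DataFrame(out, index=pd.Index(segs, name="segment_index"))
    return PartialisedRegressors(frame=result, design=design, lag_span=lag_span)


def lagged_correlation_matrix(
    regs,
    max_lag: int = 2,
    columns: tuple[str, ...] = REGRESSOR_COLUMNS,
) -> pd.DataFrame:
    """Pearson r between every pair of regressors at every lag.

    Entry (a, (b, L)) is the correlation of a_t with b_{t+L}.  Rows with
    NaN in either series (after lagging) are dropped pairwise.
    """
    frame = _frame(regs)
    series = {c: frame[c].to_numpy(dtype=float) for c in columns}
    n = len(frame)
    if n <= 2 * max_lag + 2:
        raise ConfigurationError("series too short for the requested max_lag")
    lags = range(-max_lag, max_lag + 1)
    data = {}
    for b in columns:
        for lag in lags:
            col = []
            for a in columns:
                x = series[a][max_lag : n - max_lag]
                y = series[b][max_lag + lag : n - max_lag + lag]
                ok = np.isfinite(x) & np.isfinite(y)
                col.append(float(np.corrcoef(x[ok], y[ok])[0, 1]))
            data[(b, lag)] = col
    out = pd.DataFrame(data, index=pd.Index(columns, name="regressor"))
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["with", "lag"])
    return out
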