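"""Raw intensity -> normalized log2 abundance.

The default pipeline is log2 transform followed by cyclic loess, the
standard pairwise normalization for multiplexed proteomics channels:
for every unordered channel pair a locally weighted regression of the
log-ratio M = x_i - x_j on the average log-intensity A = (x_i + x_j)/2
is fit over complete cases, and half the fitted trend is subtracted from
one channel and added to the other.  Iterating over all pairs for a few
cycles removes per-channel scale and intensity-dependent biases without
ever touching the missingness pattern.

Per-protein scaling to the t = 0 abundance (:func:`scale_to_initial`)
is presentation-only: decay fitting works on unscaled log2 values since
the linear model's free intercept absorbs the initial abundance.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .containers import AbundanceMatrix, NormalizedMatrix
from .errors import ConfigError, InputError


def log2_transform(m: AbundanceMatrix, zero_policy: str = "missing") -> NormalizedMatrix:
    """log2 of every finite intensity; zeros handled per ``zero_policy``.

    ``zero_policy="missing"`` (default) turns zeros into missing values;
    ``"error"`` rejects them.  Negative intensities are always an error.
    """
    vals = m.data.to_numpy(dtype=float)
    if np.nanmin(vals, initial=0.0) < 0:
        raise InputError("negative intensities cannot be log-transformed")
    zero = vals == 0
    if zero.any():
        if zero_policy == "missing":
            vals = np.where(zero, np.nan, vals)
        elif zero_policy == "error":
            raise InputError("zero intensities present and zero_policy='error'")
        else:
            raise ConfigError(f"unknown zero_policy: {zero_policy!r}")
    with np.errstate(invalid="ignore"):
        out = np.log2(vals)
    data = pd.DataFrame(out, index=m.data.index, columns=m.data.columns)
    return NormalizedMatrix(
        data=data, design=m.design,
        provenance={"steps": [{"op": "log2_transform", "zero_policy": zero_policy}]})


def cyclic_loess_normalize(m: NormalizedMatrix, span: float = 0.7,
                           cycles: int = 3, iterations: int = 3
                           ) -> NormalizedMatrix:
    """Pairwise MA-trend removal over all channel pairs, iterated.

    Parameters
    ----------
    span:
        loess smoothing fraction (local window as a share of complete
        cases per pair).
    cycles:
        Full sweeps over all unordered channel pairs.
    iterations:
        Robustifying reweighting iterations inside each loess fit.
    """
    if not 0 < span <= 1:
        raise ConfigError("span must lie in (0, 1]")
    if cycles < 1:
        raise ConfigError("cycles must be >= 1")
    vals = m.data.to_numpy(dtype=float).copy()
    n_chan = vals.shape[1]
    if n_chan < 2:
        raise InputError("cyclic loess requires >= 2 channels")
    cols = list(m.data.columns)

    # precondition: every pair needs enough complete proteins
    finite = np.isfinite(vals)
    for i, j in itertools.combinations(range(n_chan), 2):
        n_complete = int((finite[:, i] & finite[:, j]).sum())
        if n_complete < 10:
            raise InputError(
                f"channel pair ({cols[i]}, {cols[j]}) has only {n_complete} "
                "complete proteins; need >= 10")

    for _ in range(cycles):
        for i, j in itertools.combinations(range(n_chan), 2):
            ok = np.isfinite(vals[:, i]) & np.isfinite(vals[:, j])
            mm = vals[ok, i] - vals[ok, j]
            aa = 0.5 * (vals[ok, i] + vals[ok, j])
            fitted = lowess(mm, aa, frac=span, it=iterations,
                            return_sorted=False)
            vals[ok, i] -= fitted / 2.0
            vals[ok, j] += fitted / 2.0

    data = pd.DataFrame(vals, index=m.data.index, columns=m.data.columns)
    return m.copy_with(data, {"op": "cyclic_loess", "span": span,
                              "cycles": cycles, "iterations": iterations})


def scale_to_initial(m: NormalizedMatrix) -> tuple[NormalizedMatrix, int]:
    """Subtract each protein's mean t = 0 log2 abundance from its trace.

    Proteins with no finite t = 0 value are dropped; the count of dropped
    proteins is returned alongside the scaled matrix.
    """
    times = m.times().to_numpy(dtype=float)
    t0_cols = times == 0.0
    if not t0_cols.any():
        raise InputError("no t = 0 channel in design")
    vals = m.data.to_numpy(dtype=float)
    t0_vals = vals[:, t0_cols]
    n_t0 = np.isfinite(t0_vals).sum(axis=1)
    t0_sum = np.nansum(np.where(np.isfinite(t0_vals), t0_vals, 0.0), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t0_mean = np.where(n_t0 > 0, t0_sum / np.maximum(n_t0, 1), np.nan)
    keep = np.isfinite(t0_mean)
    dropped = int((~keep).sum())
    scaled = vals[keep] - t0_mean[keep][:, None]
    data = pd.DataFrame(scaled, index=m.data.index[keep], columns=m.data.columns)
    out = m.copy_with(data, {"op": "scale_to_initial", "dropped": dropped})
    return out, dropped


def normalize_pipeline(m: AbundanceMatrix, span: float = 0.7, cycles: int = 3,
                       zero_policy: str = "missing") -> NormalizedMatrix:
    """log2 transform then cyclic loess — the default preprocessing."""
    return cyclic_loess_normalize(log2_transform(m, zero_policy), span=span,
                                  cycles=cycles)
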