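"""Per-protein exponential decay inference with moderated statistics.

Model
-----
Each protein's chase trace is assumed to follow first-order decay,
``A(t) = A0 * exp(-k t)``.  On the log2 scale this is a straight line,
``log2 A(t) = beta0 + beta1 * t`` with ``beta1 = -k / ln 2``, so the
rate constant and half-life come from an ordinary least-squares fit of
log2 abundance on time: ``k = -beta1 * ln 2`` and
``t_half = 1 / (-beta1)`` hours whenever the slope is negative.

Because a five-point trace leaves few residual degrees of freedom, the
slope test borrows strength across proteins: the residual variances are
modeled as scaled chi-square draws around a prior ``s0^2`` with ``d0``
prior degrees of freedom, estimated by moment matching of the
log-variances against a scaled F distribution.  Each protein's variance
is then squeezed toward the prior,

    s_tilde^2 = (d0 * s0^2 + df * s^2) / (d0 + df),

and the moderated t statistic ``beta1 / (u * s_tilde)`` (with ``u`` the
slope's unscaled standard-error factor) is referred to a t distribution
with ``df + d0`` degrees of freedom.  Benjamini–Hochberg adjustment
controls the FDR across proteins.

Call tiers
----------
``screen_hit``      : t_half below the observation window, q < alpha,
                      and a negative slope.
``high_confidence`` : screen_hit and R^2 above the cutoff.
Everything else is ``stable``.  The half-life cutoff defaults to the
window length — the rate that gives a twofold drop over the experiment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .containers import NormalizedMatrix
from .errors import ConfigError, InputError

LN2 = np.log(2.0)


@dataclass
class DecayModelConfig:
    """Thresholds for instability calling."""

    fdr_alpha: float = 0.05
    halflife_cutoff_h: float | None = None   # default: the window length
    r2_cutoff: float = 0.5
    log2fc_cutoff: float = -0.5
    min_obs: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.fdr_alpha < 1:
            raise ConfigError("fdr_alpha must lie in (0, 1)")
        if self.halflife_cutoff_h is not None and self.halflife_cutoff_h <= 0:
            raise ConfigError("halflife_cutoff_h must be > 0")
        if self.min_obs < 3:
            raise ConfigError("min_obs must be >= 3 (slope + intercept + 1 df)")


@dataclass
class ShrinkagePrior:
    """Empirical-Bayes variance prior: d0 prior df (may be inf), s0^2 scale."""

    d0: float
    s0_2: float

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise ConfigError("d0 must be >= 0")
        if not (self.s0_2 > 0):
            raise ConfigError("s0_2 must be > 0")


# --------------------------------------------------------------------------
# per-protein OLS
# --------------------------------------------------------------------------

def fit_protein_decay(times, values, min_obs: int = 4):
    """OLS of log2 value on time for a single trace.

    Returns ``(beta0, beta1, s2, df_resid, r2, se_unscaled)`` or ``None``
    when fewer than ``min_obs`` finite observations (or fewer than two
    distinct times) remain.  ``se_unscaled`` is ``1/sqrt(Sxx)``, the
    factor multiplying the residual SD to give the slope's standard error.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    ok = np.isfinite(t) & np.isfinite(y)
    t, y = t[ok], y[ok]
    if t.size < min_obs or np.unique(t).size < 2:
        return None
    tbar, ybar = t.mean(), y.mean()
    sxx = float(np.sum((t - tbar) ** 2))
    sxy = float(np.sum((t - tbar) * (y - ybar)))
    beta1 = sxy / sxx
    beta0 = ybar - beta1 * tbar
    resid = y - (beta0 + beta1 * t)
    sse = float(np.sum(resid ** 2))
    sst = float(np.sum((y - ybar) ** 2))
    df_resid = t.size - 2
    s2 = sse / df_resid if df_resid > 0 else np.nan
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    return beta0, beta1, s2, df_resid, r2, 1.0 / np.sqrt(sxx)


def fit_decay_matrix(m: NormalizedMatrix, min_obs: int = 4) -> tuple[pd.DataFrame, int]:
    """Fit every protein in a normalized matrix.

    Returns the per-protein fit table and the count of proteins skipped
    for having fewer than ``min_obs`` observations.
    """
    times = m.times().to_numpy(dtype=float)
    rows, skipped = [], 0
    for pid, trace in m.data.iterrows():
        fit = fit_protein_decay(times, trace.to_numpy(dtype=float), min_obs)
        if fit is None:
            skipped += 1
            continue
        beta0, beta1, s2, df_resid, r2, u = fit
        rows.append({"protein_id": pid, "beta0": beta0, "beta1": beta1,
                     "s2": s2, "df_resid": df_resid, "r2": r2, "se_unscaled": u})
    return pd.DataFrame(rows), skipped


# --------------------------------------------------------------------------
# empirical-Bayes variance shrinkage
# --------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(s2_list, df_list) -> ShrinkagePrior:
    """Moment-match log sample variances to a scaled F distribution.

    Under the hierarchical model ``s^2 | sigma^2 ~ sigma^2 chi^2_df / df``
    with ``sigma^2`` drawn from a scaled inverse chi-square prior
    ``(d0, s0^2)``, the marginal of ``s^2/s0^2`` is F(df, d0).  Matching
    the mean and excess variance of
    ``e = log s^2 - digamma(df/2) + log(df/2)`` yields closed-form
    estimates: the excess dispersion of ``e`` beyond ``trigamma(df/2)``
    determines ``d0`` through the inverse trigamma, and ``s0^2`` follows
    from the mean.  When the observed dispersion does not exceed the
    theoretical minimum the prior is degenerate: ``d0 = inf`` and
    ``s0^2 = mean(s^2)``.
    """
    s2 = np.asarray(s2_list, dtype=float)
    df = np.asarray(df_list, dtype=float)
    if s2.shape != df.shape:
        raise InputError("s2_list and df_list must have equal length")
    ok = np.isfinite(s2) & np.isfinite(df) & (df >= 1)
    s2, df = s2[ok], df[ok]
    if s2.size < 10:
        raise InputError("need >= 10 proteins with df_resid >= 1")
    if np.all(s2 <= 0):
        raise InputError("all residual variances are zero; cannot estimate prior")
    med = np.median(s2)
    if med == 0:
        raise InputError("more than half of residual variances are zero")
    s2 = np.maximum(s2, 1e-5 * med)   # guard exact zeros off the log scale

    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(np.sum((e - emean) ** 2) / (e.size - 1))
    evar -= float(np.mean(special.polygamma(1, df / 2.0)))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_2 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_2 = float(s2.mean())
    return ShrinkagePrior(d0=d0, s0_2=s0_2)


def moderate_and_test(fits: pd.DataFrame, prior: ShrinkagePrior) -> pd.DataFrame:
    """Add squeezed variances, moderated t statistics and two-sided p values.

    ``s_tilde^2 = (d0 s0^2 + df s^2)/(d0 + df)`` (equal to ``s0^2`` when
    ``d0 = inf`` and to ``s^2`` when ``d0 = 0``); the t statistic has
    ``df + d0`` degrees of freedom.
    """
    out = fits.copy()
    df = out["df_resid"].to_numpy(dtype=float)
    s2 = out["s2"].to_numpy(dtype=float)
    if np.isinf(prior.d0):
        s2_tilde = np.full_like(s2, prior.s0_2)
        df_total = np.full_like(s2, np.inf)
    else:
        s2_tilde = (prior.d0 * prior.s0_2 + df * s2) / (prior.d0 + df)
        df_total = df + prior.d0
    se = out["se_unscaled"].to_numpy(dtype=float) * np.sqrt(s2_tilde)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = out["beta1"].to_numpy(dtype=float) / se
    p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    out["s2_tilde"] = s2_tilde
    out["t_mod"] = t_mod
    out["p"] = p
    return out


def bh_adjust(p_list) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p values (q values)."""
    p = np.asarray(p_list, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InputError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# --------------------------------------------------------------------------
# calling & labeling
# --------------------------------------------------------------------------

def call_tiers(fits: pd.DataFrame, config: DecayModelConfig,
               window_h: float) -> pd.DataFrame:
    """Derive kinetic quantities and assign stability tiers.

    Adds ``k`` (1/h), ``halflife_h``, ``log2fc_window`` (fitted slope x
    window length), ``q`` and ``tier`` columns.
    """
    if window_h <= 0:
        raise ConfigError("window_h must be > 0")
    out = fits.copy()
    beta1 = out["beta1"].to_numpy(dtype=float)
    decaying = beta1 < 0
    halflife = np.where(decaying, -1.0 / np.where(decaying, beta1, -1.0), np.inf)
    out["halflife_h"] = halflife
    out["k"] = np.where(decaying, -beta1 * LN2, 0.0)
    out["log2fc_window"] = beta1 * window_h
    out["q"] = bh_adjust(out["p"].to_numpy(dtype=float))

    cutoff = config.halflife_cutoff_h if config.halflife_cutoff_h is not None \
        else window_h
    screen = decaying & (halflife < cutoff) & (out["q"].to_numpy() < config.fdr_alpha)
    high = screen & (out["r2"].to_numpy(dtype=float) > config.r2_cutoff)
    tier = np.where(high, "high_confidence", np.where(screen, "screen_hit", "stable"))
    out["tier"] = tier
    return out


def ml_label(results: list[pd.DataFrame], fdr_alpha: float = 0.05,
             log2fc_cutoff: float = -0.5) -> pd.Series:
    """Binary instability labels for classifier training.

    A protein is positive iff, in at least one results table, it shows
    ``q < fdr_alpha`` AND ``log2fc_window < log2fc_cutoff``.  All other
    quantified proteins are negative.  Each table must carry unique
    protein ids.
    """
    if not results:
        raise InputError("need at least one results table")
    all_ids: list[str] = []
    positive: set[str] = set()
    seen: set[str] = set()
    for res in results:
        if res["protein_id"].duplicated().any():
            dup = res.loc[res["protein_id"].duplicated(), "protein_id"].tolist()
            raise InputError(f"duplicate protein ids within one results table: {dup[:5]}")
        pos = res.loc[(res["q"] < fdr_alpha) &
                      (res["log2fc_window"] < log2fc_cutoff), "protein_id"]
        positive.update(pos)
        for pid in res["protein_id"]:
            if pid not in seen:
                seen.add(pid)
                all_ids.append(pid)
    labels = pd.Series([1 if pid in positive else 0 for pid in all_ids],
                       index=pd.Index(all_ids, name="protein_id"),
                       name="is_unstable")
    return labels


def analyze_matrix(m: NormalizedMatrix, config: DecayModelConfig | None = None,
                   window_h: float | None = None) -> tuple[pd.DataFrame, dict]:
    """Full inference on a normalized matrix: fit, shrink, test, call.

    Returns the results table and a run summary (tier counts, prior,
    skipped proteins).
    """
    config = config or DecayModelConfig()
    times = m.times().to_numpy(dtype=float)
    if window_h is None:
        window_h = float(np.nanmax(times) - np.nanmin(times))
    fits, skipped = fit_decay_matrix(m, min_obs=config.min_obs)
    if fits.empty:
        raise InputError("no protein had enough observations to fit")
    prior = estimate_prior(fits["s2"], fits["df_resid"])
    fits = moderate_and_test(fits, prior)
    results = call_tiers(fits, config, window_h)
    summary = {
        "n_fit": int(len(results)),
        "n_skipped": int(skipped),
        "window_h": window_h,
        "prior_d0": float(prior.d0),
        "prior_s0_2": float(prior.s0_2),
        "tiers": results["tier"].value_counts().to_dict(),
    }
    return results, summary
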