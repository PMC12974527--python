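"""Exact and rank-based statistics linking decay calls, annotations and scores.

* :func:`fisher_enrichment` — is the substrate-annotation catalog
  over-represented among instability hits?  Two-sided Fisher exact p
  (probability-mass ordering over the hypergeometric outcomes) with a
  cross-product odds ratio, Haldane +0.5 corrected only when a cell is
  zero.
* :func:`mann_whitney` — do predicted instability probabilities differ
  between annotated and unannotated proteins?  Exact enumeration for
  tiny tie-free samples, normal approximation with tie and continuity
  corrections otherwise.
* :func:`compare_rates` — Pearson correlation of decay rate constants
  across two screens, optionally restricted to cataloged substrates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .mining import AnnotationCatalog

TIER_RANK = {"stable": 0, "screen_hit": 1, "high_confidence": 2}


@dataclass
class ContingencyResult:
    table: np.ndarray            # [[hit&annot, hit&unannot], [nonhit&annot, nonhit&unannot]]
    odds_ratio: float
    p_two_sided: float
    haldane_corrected: bool

    def caption(self) -> str:
        a, b = self.table[0]
        return (f"{a} annotated substrates and {b} unannotated substrates "
                f"exceeding these thresholds (odds ratio = {self.odds_ratio:.1f}, "
                f"P-value = {self.p_two_sided:.1e})")


@dataclass
class RankTestResult:
    U: float
    p_two_sided: float
    n1: int
    n2: int
    method: str
    median_a: float | None = None
    median_b: float | None = None


@dataclass
class RateComparison:
    shared_ids: list
    pearson_r: float
    n: int


def contingency_from_table(table) -> ContingencyResult:
    """Fisher exact test and cross-product odds ratio for a 2x2 table."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise InputError("table must be 2x2 nonnegative integer counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise InputError("contingency table has an empty margin")
    a, b, c, d = t.ravel()
    corrected = bool((t == 0).any())
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds_ratio = (a * d) / (b * c)
    p = float(stats.fisher_exact(np.round(np.asarray(table)).astype(int),
                                 alternative="two-sided")[1])
    return ContingencyResult(table=np.round(np.asarray(table)).astype(int),
                             odds_ratio=float(odds_ratio), p_two_sided=p,
                             haldane_corrected=corrected)


def fisher_enrichment(results: pd.DataFrame, catalog: AnnotationCatalog,
                      hit_tier: str = "screen_hit") -> ContingencyResult:
    """Enrichment of cataloged substrates among instability hits.

    ``hit_tier`` sets the minimum tier counting as a hit
    (``screen_hit`` counts both screen hits and high-confidence hits).
    """
    if hit_tier not in TIER_RANK or hit_tier == "stable":
        raise InputError(f"hit_tier must be screen_hit or high_confidence, got {hit_tier!r}")
    annotated = catalog.annotated_ids()
    rank = results["tier"].map(TIER_RANK)
    if rank.isna().any():
        bad = results.loc[rank.isna(), "tier"].unique().tolist()
        raise InputError(f"unknown tiers in results: {bad}")
    hit = (rank >= TIER_RANK[hit_tier]).to_numpy()
    annot = results["protein_id"].isin(annotated).to_numpy()
    table = [[int((hit & annot).sum()), int((hit & ~annot).sum())],
             [int((~hit & annot).sum()), int((~hit & ~annot).sum())]]
    return contingency_from_table(table)


def mann_whitney(scores_a, scores_b, mode: str = "auto") -> RankTestResult:
    """Two-sided Mann–Whitney U test on two score groups.

    ``mode="auto"`` uses exact enumeration when n1 + n2 <= 12 with no
    ties, else the tie-corrected normal approximation with continuity
    correction; ``"exact"``/``"asymptotic"`` force a path.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputError("both score groups must be nonempty")
    combined = np.concatenate([a, b])
    if np.unique(combined).size == 1:
        warnings.warn("all scores identical across both groups; p = 1")
        return RankTestResult(U=a.size * b.size / 2.0, p_two_sided=1.0,
                              n1=a.size, n2=b.size, method="degenerate",
                              median_a=float(np.median(a)),
                              median_b=float(np.median(b)))
    has_ties = np.unique(combined).size < combined.size
    if mode == "auto":
        method = "exact" if (a.size + b.size <= 12 and not has_ties) else "asymptotic"
    elif mode in {"exact", "asymptotic"}:
        method = mode
    else:
        raise InputError(f"unknown mode: {mode!r}")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return RankTestResult(U=float(res.statistic), p_two_sided=float(res.pvalue),
                          n1=a.size, n2=b.size, method=method,
                          median_a=float(np.median(a)), median_b=float(np.median(b)))


def compare_rates(results_a: pd.DataFrame, results_b: pd.DataFrame,
                  subset: set | None = None) -> RateComparison:
    """Pearson correlation of rate constants over shared proteins.

    ``subset`` (e.g. catalog annotated ids) restricts the intersection.
    Rate constants are the signed slope-derived values ``-beta1 * ln 2``
    so that stable proteins contribute near-zero rates.
    """
    ka = results_a.set_index("protein_id")["beta1"] * -np.log(2.0)
    kb = results_b.set_index("protein_id")["beta1"] * -np.log(2.0)
    shared = ka.index.intersection(kb.index)
    if subset is not None:
        shared = shared.intersection(pd.Index(list(subset)))
    pair = pd.DataFrame({"a": ka.reindex(shared), "b": kb.reindex(shared)}).dropna()
    if len(pair) < 3:
        raise InputError(f"only {len(pair)} shared proteins after filtering; need >= 3")
    r = float(stats.pearsonr(pair["a"], pair["b"])[0])
    return RateComparison(shared_ids=list(pair.index), pearson_r=r, n=len(pair))
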