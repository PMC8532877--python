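"""Small-sample group statistics, ΔΔCT fold changes and term enrichment.

The meat-quality trait comparisons come as per-group mean ± SEM summaries
(n = 4 animals per muscle); a pooled two-sample t statistic is rebuilt
directly from those summaries.  qPCR fold changes follow the 2^-ΔΔCT
convention against a reference gene and calibrator sample.  Term
enrichment is a hypergeometric upper-tail test per term with
Benjamini–Hochberg FDR control across terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .quant import bh_adjust


@dataclass
class GroupSummary:
    """One trait's per-group summary statistics (mean ± SEM, n)."""

    trait: str
    mean1: float
    sem1: float
    n1: int
    mean2: float
    sem2: float
    n2: int

    def __post_init__(self) -> None:
        if self.sem1 < 0 or self.sem2 < 0:
            raise ValueError("SEM must be non-negative")
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("need n >= 2 per group to test")


def pooled_t_from_summary(summary: GroupSummary) -> tuple[float, int, float]:
    """Two-sample t test rebuilt from per-group mean ± SEM.

    t = (m1 - m2) / sqrt(SEM1² + SEM2²) with df = n1 + n2 - 2 (the
    pooled, equal-variance convention; with equal group sizes the pooled
    standard error equals the root sum of squared SEMs).  Returns
    (t, df, two-sided p).  Two degenerate cases: identical means with
    zero SEMs give p = 1; distinct means with zero SEMs give p = 0.
    """
    s = summary
    df = s.n1 + s.n2 - 2
    se = float(np.hypot(s.sem1, s.sem2))
    diff = s.mean1 - s.mean2
    if se == 0.0:
        return (0.0, df, 1.0) if diff == 0 else (np.inf if diff > 0 else -np.inf,
                                                 df, 0.0)
    t = diff / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return t, df, p


def welch_t_from_summary(summary: GroupSummary) -> tuple[float, float, float]:
    """Welch's unequal-variance alternative (Welch–Satterthwaite df)."""
    s = summary
    se = float(np.hypot(s.sem1, s.sem2))
    if se == 0.0:
        return (0.0, float(s.n1 + s.n2 - 2), 1.0) if s.mean1 == s.mean2 \
            else (np.inf, float(s.n1 + s.n2 - 2), 0.0)
    num = (s.sem1 ** 2 + s.sem2 ** 2) ** 2
    den = s.sem1 ** 4 / (s.n1 - 1) + s.sem2 ** 4 / (s.n2 - 1)
    df = num / den if den > 0 else float(s.n1 + s.n2 - 2)
    t = (s.mean1 - s.mean2) / se
    return t, df, 2.0 * sps.t.sf(abs(t), df)


def trait_table_tests(table: pd.DataFrame, method: str = "pooled") -> pd.DataFrame:
    """Run the summary t test over a trait table.

    Expects columns trait, mean1, sem1, n1, mean2, sem2, n2; adds t, df
    and p (rounded to 2 decimals in ``p_2dp`` for comparison against
    printed values).
    """
    fn = pooled_t_from_summary if method == "pooled" else welch_t_from_summary
    rows = []
    for _, r in table.iterrows():
        t, df, p = fn(GroupSummary(r["trait"], r["mean1"], r["sem1"], int(r["n1"]),
                                   r["mean2"], r["sem2"], int(r["n2"])))
        rows.append({"trait": r["trait"], "t": t, "df": df, "p": p,
                     "p_2dp": round(p, 2)})
    return pd.DataFrame(rows)


def ddct_fold_change(ct_target_sample: float, ct_ref_sample: float,
                     ct_target_calibrator: float, ct_ref_calibrator: float
                     ) -> float:
    """Relative expression by the 2^-ΔΔCT method.

    ΔΔCT = (CT_target - CT_ref)_sample - (CT_target - CT_ref)_calibrator;
    the fold change is 2 raised to its negative.
    """
    ddct = (ct_target_sample - ct_ref_sample) \
        - (ct_target_calibrator - ct_ref_calibrator)
    return float(2.0 ** (-ddct))


@dataclass
class EnrichmentResult:
    term: str
    population_size: int   # N
    annotated: int         # K: population features carrying the term
    study_size: int        # n
    hits: int              # k: study features carrying the term
    p_value: float
    fdr: float | None = None
    significant: bool | None = None


def hypergeom_enrich(study: set, population: set,
                     term_map: dict[str, set],
                     fdr_threshold: float = 0.05) -> list[EnrichmentResult]:
    """Hypergeometric over-representation test per term.

    For each term with K annotated features in a population of N, and k
    hits in a study set of n, p = P(X >= k) under Hypergeometric(N, K, n)
    (p = 1 when k = 0).  FDR is Benjamini–Hochberg across the tested
    terms; a term is significant at FDR <= ``fdr_threshold``.
    """
    if not study <= population:
        raise ValueError("study set must be a subset of the population")
    N, n = len(population), len(study)
    results = []
    for term in sorted(term_map):
        members = term_map[term] & population
        K = len(members)
        if K == 0:
            continue
        k = len(members & study)
        p = float(sps.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        results.append(EnrichmentResult(term, N, K, n, k, min(p, 1.0)))
    fdr = bh_adjust([r.p_value for r in results])
    for r, q in zip(results, fdr):
        r.fdr = float(q)
        r.significant = bool(q <= fdr_threshold)
    return results


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "term": r.term, "N": r.population_size, "K": r.annotated,
        "n": r.study_size, "k": r.hits, "p_value": r.p_value,
        "fdr": r.fdr, "significant": r.significant} for r in results])
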