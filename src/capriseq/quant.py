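"""Expression normalization, sample correlation and differential calling.

Counts normalize to FPKM (count / kilobase of feature / million fragments
in the sample).  Differential expression between the two muscle groups
(BF vs LD) uses a negative-binomial Wald test on median-of-ratios
normalized counts with a moment dispersion estimate; features are called
differential under the study thresholds — adjusted p < 0.05, |log2 fold
change| > 1 and nonzero FPKM.  Fold changes are oriented BF/LD; a flip
switch is provided because published tables sometimes print the opposite
orientation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DISPERSION_FLOOR = 1e-8


@dataclass
class CountMatrix:
    """Feature × sample integer counts with lengths and group labels."""

    counts: pd.DataFrame                 # features × samples
    lengths: pd.Series                   # feature effective lengths, bases
    groups: pd.Series                    # sample -> 'LD' | 'BF'

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.lengths = self.lengths.reindex(self.counts.index)
        if (self.lengths <= 0).any() or self.lengths.isna().any():
            raise ValueError("feature lengths must be positive for all features")
        self.groups = self.groups.reindex(self.counts.columns)
        if self.groups.isna().any():
            raise ValueError("every sample needs a group label")

    def samples_in(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])


def compute_fpkm(cm: CountMatrix) -> pd.DataFrame:
    """FPKM = count / (length/1e3) / (sample total/1e6).

    Scale-invariant per sample: doubling every count in a sample leaves
    its FPKM column unchanged.
    """
    totals = cm.counts.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero library size in samples {bad}")
    kb = cm.lengths / 1e3
    return cm.counts.div(kb, axis=0).div(totals / 1e6, axis=1)


def correlation_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Sample × sample Pearson r on expression values.

    Symmetric with unit diagonal; constant columns yield NaN rows/columns
    and a warning, since r is undefined there.
    """
    if expr.shape[1] < 2:
        raise ValueError("need at least two samples")
    constant = [c for c in expr.columns if expr[c].nunique() <= 1]
    if constant:
        warnings.warn(f"constant expression column(s) {constant}: r undefined",
                      RuntimeWarning, stacklevel=2)
    r = expr.corr(method="pearson")
    np.fill_diagonal(r.values, 1.0)
    for c in constant:
        r.loc[c, :] = np.nan
        r.loc[:, c] = np.nan
    return r


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors.

    Each sample's factor is the median, over features nonzero in every
    sample, of the count over the feature's geometric mean.  Columns of
    identical counts all get factor 1.  Without any all-nonzero feature
    the factors fall back to library-size ratios (with a warning).
    """
    arr = counts.to_numpy(dtype=float)
    usable = (arr > 0).all(axis=1)
    if not usable.any():
        warnings.warn("no feature nonzero in all samples; "
                      "falling back to library-size factors", RuntimeWarning,
                      stacklevel=2)
        totals = arr.sum(axis=0)
        return pd.Series(totals / np.exp(np.mean(np.log(totals))),
                         index=counts.columns, name="size_factor")
    sub = arr[usable]
    log_geo = np.mean(np.log(sub), axis=1, keepdims=True)
    factors = np.exp(np.median(np.log(sub) - log_geo, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1).

    NaN inputs stay NaN and do not count toward the number of tests.
    """
    p = np.asarray(pvalues, dtype=float)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    q = p[ok]
    m = q.size
    if m:
        order = np.argsort(q, kind="stable")
        ranked = q[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        res = np.empty(m)
        res[order] = np.minimum(adj, 1.0)
        out[ok] = res
    return out


def nb_wald_test(cm: CountMatrix, factors: pd.Series | None = None,
                 pseudocount: float = 0.5,
                 flip_orientation: bool = False) -> pd.DataFrame:
    """Per-feature negative-binomial Wald test, unpaired two-group design.

    Counts are scaled by the size factors; group means and a pooled
    within-group moment estimate of the NB dispersion (floored at 1e-8)
    feed a Wald statistic on the log2 fold change (BF/LD, plus the
    pseudocount for stability) via the delta method, referred to a t
    distribution with n1+n2-2 degrees of freedom.  Features where one
    group has an all-zero total are skipped (p = NaN, ``skipped`` set).
    """
    ld, bf = cm.samples_in("LD"), cm.samples_in("BF")
    if len(ld) < 2 or len(bf) < 2:
        raise ValueError("need at least two samples per group")
    if factors is None:
        factors = size_factors(cm.counts)
    q = cm.counts / factors

    q_ld, q_bf = q[ld].to_numpy(), q[bf].to_numpy()
    n1, n2 = q_ld.shape[1], q_bf.shape[1]
    mu1, mu2 = q_ld.mean(axis=1), q_bf.mean(axis=1)
    v1 = q_ld.var(axis=1, ddof=1)
    v2 = q_bf.var(axis=1, ddof=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        a1 = np.where(mu1 > 0, (v1 - mu1) / mu1 ** 2, 0.0)
        a2 = np.where(mu2 > 0, (v2 - mu2) / mu2 ** 2, 0.0)
    alpha = np.maximum((a1 + a2) / 2.0, DISPERSION_FLOOR)

    lfc = np.log2(mu2 + pseudocount) - np.log2(mu1 + pseudocount)
    if flip_orientation:
        lfc = -lfc
    var_mean1 = (mu1 + alpha * mu1 ** 2) / n1
    var_mean2 = (mu2 + alpha * mu2 ** 2) / n2
    ln2sq = np.log(2.0) ** 2
    se2 = (var_mean1 / (mu1 + pseudocount) ** 2
           + var_mean2 / (mu2 + pseudocount) ** 2) / ln2sq
    skipped = (mu1 == 0) | (mu2 == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = lfc / np.sqrt(se2)
    pval = 2.0 * stats.t.sf(np.abs(wald), df=n1 + n2 - 2)
    pval[skipped] = np.nan

    res = pd.DataFrame({
        "baseMean_LD": mu1, "baseMean_BF": mu2,
        "dispersion": alpha, "log2_fold_change": lfc,
        "wald_stat": wald, "p_value": pval,
        "skipped": skipped}, index=cm.counts.index)
    res["padj"] = bh_adjust(res["p_value"].to_numpy())
    return res


def call_de(results: pd.DataFrame, fpkm: pd.DataFrame,
            padj_threshold: float = 0.05, lfc_threshold: float = 1.0,
            fpkm_mode: str = "any") -> pd.DataFrame:
    """Apply the differential-expression thresholds.

    DE requires padj < ``padj_threshold``, |log2FC| > ``lfc_threshold``
    and FPKM > 0 in at least one sample (``fpkm_mode='any'``; 'all'
    demands every sample).  Adds ``is_de`` and a ``direction`` column
    ('up' for log2FC > threshold, 'down' for < -threshold); up + down
    counts partition the DE set.
    """
    if not results.index.equals(fpkm.index):
        fpkm = fpkm.reindex(results.index)
    expressed = (fpkm > 0).any(axis=1) if fpkm_mode == "any" \
        else (fpkm > 0).all(axis=1)
    out = results.copy()
    out["expressed"] = expressed
    out["is_de"] = (out["padj"].lt(padj_threshold).fillna(False)
                    & (out["log2_fold_change"].abs() > lfc_threshold)
                    & expressed)
    out["direction"] = np.select(
        [out["is_de"] & (out["log2_fold_change"] > lfc_threshold),
         out["is_de"] & (out["log2_fold_change"] < -lfc_threshold)],
        ["up", "down"], default="")
    return out


def set_overlap(sets: dict[str, set]) -> pd.DataFrame:
    """Shared / exclusive tallies across named feature sets.

    Rows: each set's size and exclusive count, every pairwise
    intersection, the n-way intersection and the union.  For two sets,
    union = exclusive_A + exclusive_B + shared.
    """
    names = list(sets)
    rows = []
    union = set().union(*sets.values()) if sets else set()
    for name in names:
        others = set().union(*(sets[o] for o in names if o != name)) \
            if len(names) > 1 else set()
        rows.append({"set": name, "size": len(sets[name]),
                     "exclusive": len(sets[name] - others)})
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            rows.append({"set": f"{a}&{b}", "size": len(sets[a] & sets[b]),
                         "exclusive": np.nan})
    if len(names) > 2:  # n-way row would duplicate the pairwise one for n=2
        shared_all = set.intersection(*(sets[n] for n in names))
        rows.append({"set": "&".join(names), "size": len(shared_all),
                     "exclusive": np.nan})
    rows.append({"set": "union", "size": len(union), "exclusive": np.nan})
    return pd.DataFrame(rows)
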