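"""Experimental-variability analyses.

Replicate chronic-toxicity studies of the same compound disagree, and the
spread of those replicates is the natural benchmark for any in-silico
prediction: a model cannot be expected to predict more precisely than the
experiments reproduce.  This module quantifies that spread within a single
database (mean per-compound standard deviation of -log10 LOAELs), between
two databases (correlation of per-compound medians), and compares two
databases' variability (t-test on SD lists) and size composition
(chi-square on small-compound counts).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import ToxDataset, sig_repr
from .validate import correlation_stats


@dataclass
class CompoundVariability:
    canonical_smiles: str
    measurements: tuple[float, ...]  # -log10 scale
    sd: float  # sample SD (n-1 denominator)


@dataclass
class VariabilityReport:
    """Intra-database variability of compounds with replicate measurements."""

    dataset: str
    n_multi: int
    mean_sd_log: float  # mean over compounds of the per-compound sample SD
    per_compound: list[CompoundVariability]

    def sds(self) -> list[float]:
        return [c.sd for c in self.per_compound]


@dataclass
class InterDbCorrelation:
    r_squared: float
    rmse: float
    n_structures: int
    p_value: float
    empty: bool = False


@dataclass
class SdComparison:
    """Two-sample t-test on per-compound SD lists; Welch variant."""

    p_value: float
    statistic: float
    n_a: int
    n_b: int
    sufficient: bool


@dataclass
class SmallCompoundComparison:
    """Counts of structures below a heavy-atom cutoff and the chi-square test."""

    cutoff: int
    n_small_a: int
    n_total_a: int
    n_small_b: int
    n_total_b: int
    p_value: float
    p_value_corrected: float  # with Yates continuity correction


def intra_db_variability(db: ToxDataset) -> VariabilityReport:
    """Per-compound sample SDs of -log10 LOAELs and their unweighted mean.

    Only structures with at least two measurements enter; each compound
    counts once regardless of its replicate count.  A database without
    multi-measured compounds yields an empty report (mean NaN), not an
    error.
    """
    per_compound = []
    for smi in sorted(db.index):
        values = db.measurements(smi)
        if len(values) >= 2:
            per_compound.append(
                CompoundVariability(
                    canonical_smiles=smi,
                    measurements=tuple(values),
                    sd=float(np.std(values, ddof=1)),
                )
            )
    mean_sd = float(np.mean([c.sd for c in per_compound])) if per_compound else float("nan")
    return VariabilityReport(
        dataset=db.name,
        n_multi=len(per_compound),
        mean_sd_log=mean_sd,
        per_compound=per_compound,
    )


def inter_db_correlation(a: ToxDataset, b: ToxDataset) -> InterDbCorrelation:
    """Correlation of per-compound median -log10 LOAELs across two databases.

    Value pairs identical at five significant digits in both databases are
    dropped from both sides first (they likely report the same experiment);
    a compound whose values are all shared this way is excluded entirely.
    Medians of the remaining values are correlated.
    """
    def drop_shared(records, shared: Counter) -> list[float]:
        budget = Counter(shared)
        kept = []
        for rec in records:
            key = sig_repr(rec.loael_mmol)
            if budget[key] > 0:
                budget[key] -= 1
            else:
                kept.append(rec.loael_neg_log10)
        return kept

    pairs_a, pairs_b = [], []
    for smi in sorted(a.structure_set() & b.structure_set()):
        va = a.index[smi]
        vb = b.index[smi]
        shared = Counter(sig_repr(r.loael_mmol) for r in va) & Counter(
            sig_repr(r.loael_mmol) for r in vb
        )
        keep_a = drop_shared(va, shared)
        keep_b = drop_shared(vb, shared)
        if keep_a and keep_b:
            pairs_a.append(float(np.median(keep_a)))
            pairs_b.append(float(np.median(keep_b)))
    if len(pairs_a) < 3:
        return InterDbCorrelation(float("nan"), float("nan"), len(pairs_a), float("nan"), empty=True)
    r2, rmse, p = correlation_stats(pairs_a, pairs_b)
    return InterDbCorrelation(r2, rmse, len(pairs_a), p)


def compare_sd_distributions(a: VariabilityReport, b: VariabilityReport) -> SdComparison:
    """Welch two-sample t-test on the per-compound SD lists of two databases."""
    sds_a, sds_b = a.sds(), b.sds()
    if len(sds_a) < 2 or len(sds_b) < 2:
        return SdComparison(float("nan"), float("nan"), len(sds_a), len(sds_b), sufficient=False)
    t, p = stats.ttest_ind(sds_a, sds_b, equal_var=False)
    return SdComparison(float(p), float(t), len(sds_a), len(sds_b), sufficient=True)


def small_compound_comparison(
    a: ToxDataset, b: ToxDataset, cutoff: int = 11
) -> SmallCompoundComparison:
    """Chi-square test on the 2x2 table of small vs non-small structures.

    "Small" means fewer than ``cutoff`` heavy atoms (default 11).  p-values
    with and without Yates continuity correction are both reported; the
    uncorrected one is the headline number.
    """
    def counts(db: ToxDataset) -> tuple[int, int]:
        small = sum(1 for s in db.structures.values() if s.heavy_atoms < cutoff)
        return small, db.n_structures

    small_a, total_a = counts(a)
    small_b, total_b = counts(b)
    table = np.array(
        [[small_a, total_a - small_a], [small_b, total_b - small_b]]
    )
    if table.sum() == 0 or (table.sum(axis=0) == 0).any():
        p_plain = p_corr = float("nan")
    else:
        p_plain = float(stats.chi2_contingency(table, correction=False)[1])
        p_corr = float(stats.chi2_contingency(table, correction=True)[1])
    return SmallCompoundComparison(
        cutoff=cutoff,
        n_small_a=small_a,
        n_total_a=total_a,
        n_small_b=small_b,
        n_total_b=total_b,
        p_value=p_plain,
        p_value_corrected=p_corr,
    )
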