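"""Germination time-course statistics, amplicon-length haplotype calling
and the expression-GWAS Bonferroni threshold.

Germination assays score the cumulative number of seeds completing
germination per replicate dish at fixed times after imbibition; curves are
summarized as mean ± SE percent and compared per timepoint with Welch's
t-test (the unequal-variance form of Student's t; an equal-variance option
exists behind a flag).  Promoter haplotypes are called from diagnostic PCR
amplicon lengths: a short product marks the insertion-free promoter, a
~2.3 kb longer product the insertion-bearing one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import dunnett_pvalues

__all__ = [
    "GerminationTrial",
    "HaplotypeCall",
    "germination_percent",
    "timepoint_tests",
    "dunnett_vs_control",
    "call_haplotype",
    "haplotype_frequencies",
    "bonferroni_threshold",
    "significance_stars",
]

HAP_SHORT = "Hap_C7-2"
HAP_LONG = "Hap_Z58"
HAP_OTHER = "other"


@dataclass
class GerminationTrial:
    """One replicate's cumulative germination counts over time."""

    genotype: str
    treatment: str
    replicate: int
    time_h: np.ndarray
    n_germinated: np.ndarray  # cumulative
    n_total: int

    def __post_init__(self):
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.n_germinated = np.asarray(self.n_germinated, dtype=int)
        if self.time_h.shape != self.n_germinated.shape:
            raise ValueError("time_h and n_germinated must align")
        if np.any(np.diff(self.time_h) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if np.any(self.n_germinated < 0) or np.any(self.n_germinated > self.n_total):
            raise ValueError("counts must lie in [0, n_total]")
        if np.any(np.diff(self.n_germinated) < 0):
            raise ValueError("cumulative counts must be non-decreasing")


@dataclass
class HaplotypeCall:
    line_id: str
    amplicon_bp: int
    haplotype: str


def germination_percent(
    trials: list[GerminationTrial], genotype: str, treatment: str
) -> pd.DataFrame:
    """Mean ± SE germination percent per timepoint for one condition.

    Timepoints missing from some replicates are reported with the reduced
    replicate count and a warning.
    """
    sel = [t for t in trials if t.genotype == genotype and t.treatment == treatment]
    if len(sel) < 2:
        raise ValueError("need >= 2 replicates")
    per_time: dict[float, list[float]] = {}
    for t in sel:
        for tt, n in zip(t.time_h, t.n_germinated):
            per_time.setdefault(float(tt), []).append(100.0 * n / t.n_total)
    rows = []
    for tt in sorted(per_time):
        vals = np.asarray(per_time[tt])
        if vals.size < len(sel):
            warnings.warn(f"timepoint {tt} h present in only {vals.size}/{len(sel)} replicates")
        se = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else np.nan
        rows.append(dict(time_h=tt, mean_pct=vals.mean(), se_pct=se, n=vals.size))
    return pd.DataFrame(rows)


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _replicate_percent_table(trials, genotype, treatment):
    out: dict[float, list[float]] = {}
    for t in trials:
        if t.genotype == genotype and t.treatment == treatment:
            for tt, n in zip(t.time_h, t.n_germinated):
                out.setdefault(float(tt), []).append(100.0 * n / t.n_total)
    return out


def timepoint_tests(
    trials: list[GerminationTrial],
    genotype_a: str,
    genotype_b: str,
    treatment: str,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-timepoint two-sided t-tests between two genotypes.

    Welch's form by default; ``equal_var=True`` gives the pooled-variance
    Student form.  Identical replicate sets (zero variance, equal means)
    report p = 1.
    """
    ta = _replicate_percent_table(trials, genotype_a, treatment)
    tb = _replicate_percent_table(trials, genotype_b, treatment)
    rows = []
    for tt in sorted(set(ta) & set(tb)):
        va, vb = np.asarray(ta[tt]), np.asarray(tb[tt])
        if va.size < 2 or vb.size < 2:
            raise ValueError(f"timepoint {tt}: need >= 2 replicates per genotype")
        if va.var(ddof=1) == 0 and vb.var(ddof=1) == 0:
            p = 1.0 if va.mean() == vb.mean() else 0.0
        else:
            p = float(sps.ttest_ind(va, vb, equal_var=equal_var).pvalue)
        rows.append(
            dict(time_h=tt, mean_a=va.mean(), mean_b=vb.mean(), p=p, stars=significance_stars(p))
        )
    return pd.DataFrame(rows)


def dunnett_vs_control(
    final_percents: dict[str, np.ndarray], control: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Dunnett many-to-one comparison of final germination percentages."""
    pvals = dunnett_pvalues(final_percents, control=control)
    rows = [
        dict(genotype=g, p_adj=p, significant=p < alpha, stars=significance_stars(p))
        for g, p in pvals.items()
    ]
    return pd.DataFrame(rows)


def call_haplotype(
    amplicon_bp: int,
    short_ref: int = 365,
    long_ref: int = 2682,
    tol: int = 50,
) -> str:
    """Call the promoter haplotype from a diagnostic amplicon length.

    Within ``tol`` bp of the short reference product -> insertion-free
    haplotype; within ``tol`` of the long product -> insertion haplotype;
    anything else -> 'other' (additional polymorphisms segregate in wide
    panels).
    """
    if amplicon_bp <= 0:
        raise ValueError("amplicon length must be positive")
    if abs(amplicon_bp - short_ref) <= tol:
        return HAP_SHORT
    if abs(amplicon_bp - long_ref) <= tol:
        return HAP_LONG
    return HAP_OTHER


def haplotype_frequencies(calls: list[HaplotypeCall] | list[str]) -> pd.DataFrame:
    """Counts and integer-rounded percentages per haplotype."""
    labels = [c.haplotype if isinstance(c, HaplotypeCall) else c for c in calls]
    if not labels:
        raise ValueError("no calls")
    ser = pd.Series(labels).value_counts().sort_index()
    pct = (100.0 * ser / ser.sum()).round().astype(int)
    if pct.sum() != 100:
        warnings.warn(f"rounded percentages sum to {pct.sum()} (rounding)")
    return pd.DataFrame({"haplotype": ser.index, "n": ser.to_numpy(), "percent": pct.to_numpy()})


def bonferroni_threshold(n_tests: int, familywise_alpha: float = 1.0) -> float:
    """Bonferroni genome-wide p threshold, alpha / m.

    The alpha = 1 convention (1/m) is the documented default used for
    expression-GWAS thresholds in the maize association literature; pass
    0.05 for the textbook familywise level.
    """
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return familywise_alpha / n_tests
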