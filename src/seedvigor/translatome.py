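"""Paired RNA-seq / RNC-seq differential analysis and five-way gene
classification.

Translation efficiency (TE) of a gene is the ratio of its ribosome-
nascent-chain-associated (RNC) abundance to its total mRNA (RNA)
abundance.  With paired RNA and RNC libraries in two groups (mutant vs
control), each gene is modelled with a negative-binomial log-linear model
with library-size offsets:

    log mu = log(libsize) + b0 + b_group*group + b_assay*assay
             + b_int*(group x assay)

The RNA effect is the group coefficient estimated within RNA samples; the
TE effect is the group x assay interaction (proportional RNA/RNC shifts
cancel).  P-values come from likelihood-ratio tests at a common
method-of-moments dispersion, and Benjamini-Hochberg adjustment is applied
separately within the RNA family and the TE family (the two volcano
plots).  Categories:

    Transcription   q_rna < fdr, q_te >= fdr
    Translation     q_te < fdr, q_rna >= fdr
    Homodirection   both < fdr, fold changes same sign
    Opposite        both < fdr, fold changes opposite sign
    Unchanged       otherwise
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "GenePairCounts",
    "TEResult",
    "CATEGORIES",
    "te_test",
    "classify_genes",
    "category_counts",
    "estimate_dispersion",
]

CATEGORIES = ("Transcription", "Translation", "Homodirection", "Opposite", "Unchanged")


@dataclass
class GenePairCounts:
    """Gene x sample count matrix with paired RNA/RNC sample metadata.

    ``sample_meta`` is a DataFrame indexed like the count columns with
    columns assay ('RNA'|'RNC'), group, replicate.  RNA and RNC samples
    must pair one-to-one by (group, replicate).
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self):
        if not self.counts.columns.equals(self.sample_meta.index):
            raise ValueError("count columns and sample_meta index must align")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        bad_assay = set(self.sample_meta["assay"]) - {"RNA", "RNC"}
        if bad_assay:
            raise ValueError(f"unknown assays: {sorted(bad_assay)}")
        for (assay, group), sub in self.sample_meta.groupby(["assay", "group"]):
            if len(sub) < 2:
                raise ValueError(f"cell ({assay}, {group}) has < 2 replicates")
        rna = self.sample_meta[self.sample_meta.assay == "RNA"]
        rnc = self.sample_meta[self.sample_meta.assay == "RNC"]
        k_rna = set(zip(rna.group, rna.replicate))
        k_rnc = set(zip(rnc.group, rnc.replicate))
        if k_rna != k_rnc:
            odd = k_rna ^ k_rnc
            raise ValueError(f"unpaired replicates: {sorted(odd)}")

    @property
    def gene_ids(self):
        return self.counts.index


@dataclass
class TEResult:
    gene_id: str
    log2fc_rna: float
    log2fc_te: float
    p_rna: float
    p_te: float
    q_rna: float = np.nan
    q_te: float = np.nan
    category: str = ""


def _nb_loglike(y, mu, alpha):
    """Negative-binomial log-likelihood (mean/dispersion parameterization)."""
    if alpha <= 0:
        return float((-mu + y * np.log(mu) - special.gammaln(y + 1)).sum())
    size = 1.0 / alpha
    return float(
        (
            special.gammaln(y + size)
            - special.gammaln(size)
            - special.gammaln(y + 1)
            + size * np.log(size / (size + mu))
            + y * np.log(mu / (size + mu))
        ).sum()
    )


def _nb_irls(y, X, offset, alpha, maxiter=50, tol=1e-8):
    """Fisher-scoring fit of an NB log-linear model with fixed dispersion.

    Returns (beta, loglike).  Small and self-contained because it is run
    tens of thousands of times per dataset; matches statsmodels GLM
    NegativeBinomial estimates to ~1e-8.
    """
    n, p = X.shape
    # start from the null-ish fit
    mean0 = max(np.mean(y / np.exp(offset)), 1e-8)
    beta = np.zeros(p)
    beta[0] = np.log(mean0)
    eta = offset + X @ beta
    mu = np.exp(eta)
    ll = _nb_loglike(y, mu, alpha)
    for _ in range(maxiter):
        w = mu / (1.0 + alpha * mu)  # Fisher weights for log link
        z = eta - offset + (y - mu) / mu
        WX = X * w[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ WX, WX.T @ z)
        except np.linalg.LinAlgError:
            break
        step = 1.0
        for _ in range(20):  # step-halving for stability
            eta_new = offset + X @ (beta + step * (beta_new - beta))
            eta_new = np.clip(eta_new, -30, 30)
            mu_new = np.exp(eta_new)
            ll_new = _nb_loglike(y, mu_new, alpha)
            if ll_new >= ll - 1e-12:
                break
            step /= 2.0
        beta = beta + step * (beta_new - beta)
        eta, mu = eta_new, mu_new
        if abs(ll_new - ll) < tol * (abs(ll) + 1):
            ll = ll_new
            break
        ll = ll_new
    return beta, ll


def estimate_dispersion(counts: np.ndarray, lib_sizes: np.ndarray, cells: list[np.ndarray]) -> float:
    """Common NB dispersion by method of moments.

    Counts are normalized by library size; within each design cell the
    moment estimate alpha = (var - mean)/mean^2 is formed per gene, and
    the median of positive estimates across genes/cells is returned
    (floored at 1e-4; overdispersion below that is indistinguishable from
    Poisson at these depths).
    """
    s = lib_sizes / lib_sizes.mean()
    norm = counts / s
    ests = []
    for idx in cells:
        sub = norm[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            a = (v - m) / m**2
        ests.append(a[np.isfinite(a) & (m > 0)])
    pooled = np.concatenate(ests) if ests else np.array([])
    pos = pooled[pooled > 0]
    if pos.size == 0:
        return 1e-4
    return float(max(np.median(pos), 1e-4))


def te_test(gp: GenePairCounts, fdr: float = 0.05, dispersion: float | None = None) -> list[TEResult]:
    """Per-gene RNA and TE differential tests with BH adjustment.

    Genes with all-zero counts are excluded (logged).  ``dispersion`` may
    be supplied; by default a common method-of-moments estimate is used.
    """
    meta = gp.sample_meta
    counts = gp.counts.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("library sizes must be positive")
    nonzero = counts.sum(axis=1) > 0
    n_drop = int((~nonzero).sum())
    if n_drop:
        logger.info("te_test: excluding %d all-zero genes", n_drop)
    genes = gp.counts.index[nonzero]
    counts = counts[nonzero]

    groups = sorted(meta["group"].unique())
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    ref_group, alt_group = groups[0], groups[1]
    g = (meta["group"] == alt_group).to_numpy(dtype=float)
    a = (meta["assay"] == "RNC").to_numpy(dtype=float)
    offset = np.log(lib)

    cells = [
        np.flatnonzero((meta["assay"] == assay).to_numpy() & (meta["group"] == grp).to_numpy())
        for assay in ("RNA", "RNC")
        for grp in groups
    ]
    alpha = estimate_dispersion(counts, lib, cells) if dispersion is None else float(dispersion)

    X_full = np.column_stack([np.ones_like(g), g, a, g * a])
    X_noint = X_full[:, :3]
    rna_idx = np.flatnonzero(a == 0)
    Xr_full = np.column_stack([np.ones(rna_idx.size), g[rna_idx]])
    Xr_null = Xr_full[:, :1]

    results = []
    ln2 = np.log(2.0)
    for gi, gene in enumerate(genes):
        y = counts[gi]
        beta_f, ll_f = _nb_irls(y, X_full, offset, alpha)
        _, ll_ni = _nb_irls(y, X_noint, offset, alpha)
        yr = y[rna_idx]
        beta_r, ll_r = _nb_irls(yr, Xr_full, offset[rna_idx], alpha)
        _, ll_r0 = _nb_irls(yr, Xr_null, offset[rna_idx], alpha)
        lrt_te = max(2.0 * (ll_f - ll_ni), 0.0)
        lrt_rna = max(2.0 * (ll_r - ll_r0), 0.0)
        results.append(
            TEResult(
                gene_id=str(gene),
                log2fc_rna=float(beta_r[1] / ln2),
                log2fc_te=float(beta_f[3] / ln2),
                p_rna=float(chi2.sf(lrt_rna, 1)),
                p_te=float(chi2.sf(lrt_te, 1)),
            )
        )
    # BH within each of the two families
    if results:
        q_rna = multipletests([r.p_rna for r in results], method="fdr_bh")[1]
        q_te = multipletests([r.p_te for r in results], method="fdr_bh")[1]
        for r, qr, qt in zip(results, q_rna, q_te):
            r.q_rna = float(qr)
            r.q_te = float(qt)
    return classify_genes(results, fdr=fdr)


def classify_genes(results: list[TEResult], fdr: float = 0.05) -> list[TEResult]:
    """Assign each gene to exactly one of the five categories."""
    for r in results:
        if np.isnan(r.q_rna) or np.isnan(r.q_te):
            r.category = "Unclassifiable"
            continue
        sig_rna = r.q_rna < fdr
        sig_te = r.q_te < fdr
        if sig_rna and not sig_te:
            r.category = "Transcription"
        elif sig_te and not sig_rna:
            r.category = "Translation"
        elif sig_rna and sig_te:
            same = np.sign(r.log2fc_rna) == np.sign(r.log2fc_te)
            r.category = "Homodirection" if same else "Opposite"
        else:
            r.category = "Unchanged"
    return results


def category_counts(results: list[TEResult]) -> pd.DataFrame:
    """Per-category (and per-direction) gene counts.

    Direction is the sign of the relevant fold change: RNA for
    Transcription, TE for Translation, either (they agree) for
    Homodirection; Opposite and Unchanged get direction '.'.
    """
    rows = []
    for r in results:
        if r.category == "Unclassifiable":
            continue
        if r.category == "Transcription":
            direction = "up" if r.log2fc_rna > 0 else "down"
        elif r.category == "Translation":
            direction = "up" if r.log2fc_te > 0 else "down"
        elif r.category == "Homodirection":
            direction = "up" if r.log2fc_rna > 0 else "down"
        else:
            direction = "."
        rows.append((r.category, direction))
    df = pd.DataFrame(rows, columns=["category", "direction"])
    out = (
        df.groupby(["category", "direction"]).size().rename("n_genes").reset_index()
    )
    totals = df.groupby("category").size()
    out["category_total"] = out["category"].map(totals)
    return out
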