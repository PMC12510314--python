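"""Synthetic-data generators with the statistical structure each analysis
stage assumes, so the whole pipeline can run and be tested end to end
without any external download.

Every generator takes one integer seed and derives per-replicate
substreams by fixed offsets (``numpy`` SeedSequence spawning via
``default_rng([seed, k])``), so replicates are individually reproducible
and byte-identical across runs.  Coalescent genotype simulation lives in
:mod:`seedvigor.popgen` (``simulate_coalescent_window``); it is re-exported
here for convenience.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .binding import BindingSeries, DilutionPlan, fraction_bound
from .methylation import BisulfiteLocus
from .phenotype import GerminationTrial
from .popgen import (  # noqa: F401  (re-exported generators)
    DemographicModel,
    simulate_coalescent_window,
    simulate_coalescent_windows,
)
from .translatome import CATEGORIES, GenePairCounts

__all__ = [
    "gen_binding_plate",
    "gen_rna_rnc_counts",
    "gen_bisulfite_clones",
    "gen_germination",
    "simulate_coalescent_window",
    "simulate_coalescent_windows",
    "DemographicModel",
]


def _rng(seed: int, *offsets: int) -> np.random.Generator:
    if seed < 0:
        raise ValueError("seed must be >= 0")
    return np.random.default_rng([int(seed), *map(int, offsets)])


def gen_binding_plate(
    true_kd: float,
    bound_level: float,
    unbound_level: float,
    noise_sd: float,
    plan: DilutionPlan,
    target_conc: float = 0.089,
    n_reps: int = 3,
    seed: int = 0,
    ligand: str = "ligand",
    **series_kwargs,
) -> list[BindingSeries]:
    """Simulate replicate dose-response ladders on a dilution plan.

    Each well's expected fluorescence sits exactly on the depletion
    isotherm, unbound + (bound - unbound) * FB(L; T, KD); replicates
    differ only by their i.i.d. Gaussian noise draws.  ``true_kd`` and
    ``target_conc`` in µM; ``noise_sd`` in fluorescence units.
    """
    if true_kd <= 0 or target_conc <= 0:
        raise ValueError("true_kd and target_conc must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if plan.n_wells < 4:
        raise ValueError("plan needs >= 4 wells")
    L = plan.ladder(ligand)
    fb = fraction_bound(L, target_conc, true_kd)
    mean = unbound_level + (bound_level - unbound_level) * fb
    out = []
    for rep in range(1, n_reps + 1):
        rng = _rng(seed, rep)
        fnorm = mean + rng.normal(0.0, noise_sd, size=L.size) if noise_sd > 0 else mean.copy()
        out.append(
            BindingSeries(
                ligand_conc=L,
                fnorm=fnorm,
                target_conc=target_conc,
                replicate=rep,
                **series_kwargs,
            )
        )
    return out


_CATEGORY_RULES = {
    # category -> (rna_lfc nonzero?, te_lfc nonzero?, sign constraint)
    "Unchanged": (False, False, None),
    "Transcription": (True, False, None),
    "Translation": (False, True, None),
    "Homodirection": (True, True, "same"),
    "Opposite": (True, True, "opposite"),
}


def _check_planted(planted: pd.DataFrame) -> None:
    for gene, row in planted.iterrows():
        cat = row["category"]
        if cat not in CATEGORIES:
            raise ValueError(f"gene {gene}: unknown category {cat!r}")
        rna_nz, te_nz, sign = _CATEGORY_RULES[cat]
        if (row["rna_log2fc"] != 0) != rna_nz or (row["te_log2fc"] != 0) != te_nz:
            raise ValueError(f"gene {gene}: fold changes inconsistent with category {cat}")
        if sign == "same" and np.sign(row["rna_log2fc"]) != np.sign(row["te_log2fc"]):
            raise ValueError(f"gene {gene}: Homodirection requires same-sign fold changes")
        if sign == "opposite" and np.sign(row["rna_log2fc"]) == np.sign(row["te_log2fc"]):
            raise ValueError(f"gene {gene}: Opposite requires opposite-sign fold changes")


def gen_rna_rnc_counts(
    n_genes: int,
    n_reps_per_group: int = 4,
    planted: pd.DataFrame | None = None,
    dispersion: float = 0.1,
    lib_sizes: np.ndarray | float | None = None,
    seed: int = 0,
    base_mean_log2: tuple[float, float] = (5.0, 2.0),
) -> tuple[GenePairCounts, pd.DataFrame]:
    """Negative-binomial RNA/RNC count tables with planted effects.

    ``planted`` maps gene index -> (category, rna_log2fc, te_log2fc);
    unlisted genes are Unchanged.  RNA means shift by rna_log2fc between
    groups; RNC means by rna_log2fc + te_log2fc (so TE-only effects leave
    RNA untouched and proportional shifts cancel in TE).  Counts are NB
    with one common dispersion (Poisson when ``dispersion`` ~ 0), scaled
    to the requested library sizes.  ``lib_sizes`` defaults to 500 reads
    per gene on average (the per-gene coverage of a typical 20-40M-read
    embryo library over ~40k genes, carried over to smaller simulated
    gene panels).

    Returns the count container and a per-gene truth table.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    genes = [f"g{i:05d}" for i in range(n_genes)]
    truth = pd.DataFrame(
        {"category": "Unchanged", "rna_log2fc": 0.0, "te_log2fc": 0.0},
        index=pd.Index(genes, name="gene"),
    )
    if planted is not None:
        planted = planted.copy()
        if not planted.index.isin(truth.index).all():
            planted.index = [genes[i] for i in planted.index]
        _check_planted(planted)
        truth.loc[planted.index, ["category", "rna_log2fc", "te_log2fc"]] = planted[
            ["category", "rna_log2fc", "te_log2fc"]
        ]

    samples = []
    for assay in ("RNA", "RNC"):
        for group in ("control", "mutant"):
            for rep in range(1, n_reps_per_group + 1):
                samples.append((f"{assay}_{group}_{rep}", assay, group, rep))
    meta = pd.DataFrame(
        [(a, g, r) for _, a, g, r in samples],
        index=pd.Index([s[0] for s in samples], name="sample"),
        columns=["assay", "group", "replicate"],
    )
    n_samples = len(samples)
    if lib_sizes is None:
        lib_sizes = 500.0 * n_genes
    lib = np.broadcast_to(np.asarray(lib_sizes, dtype=float), (n_samples,)).copy()

    rng0 = _rng(seed, 0)
    base = 2.0 ** rng0.normal(base_mean_log2[0], base_mean_log2[1], size=n_genes)
    rel = base / base.sum()

    rna_lfc = truth["rna_log2fc"].to_numpy()
    te_lfc = truth["te_log2fc"].to_numpy()
    counts = np.empty((n_genes, n_samples), dtype=np.int64)
    for k, (name, assay, group, rep) in enumerate(samples):
        lfc = np.zeros(n_genes)
        if group == "mutant":
            lfc = rna_lfc + (te_lfc if assay == "RNC" else 0.0)
        mu_rel = rel * 2.0**lfc
        mu = lib[k] * mu_rel / mu_rel.sum()  # renormalize: library size is fixed by design
        rng = _rng(seed, 1, k)
        if dispersion < 1e-8:
            counts[:, k] = rng.poisson(mu)
        else:
            size = 1.0 / dispersion
            p = size / (size + mu)
            counts[:, k] = rng.negative_binomial(size, p)
    cdf = pd.DataFrame(counts, index=truth.index, columns=meta.index)
    return GenePairCounts(cdf, meta), truth


def gen_bisulfite_clones(
    ref_seq: str,
    p_meth: dict[str, float],
    n_clones: int = 8,
    conversion_failure: float = 0.0,
    seed: int = 0,
    region_id: str = "region",
) -> BisulfiteLocus:
    """Simulate bisulfite-converted clone sequences of one amplicon.

    Every cytosine is retained as C (read methylated) with probability
    p_meth[context] + (1 - p_meth[context]) * conversion_failure — i.e.
    incomplete conversion biases the summary upward, as in real data —
    and otherwise converted to T.  Non-cytosine bases copy verbatim.
    """
    from .methylation import call_contexts

    ref = ref_seq.upper()
    if set(ref) - set("ACGT"):
        raise ValueError("reference must contain only ACGT")
    for ctx, p in p_meth.items():
        if not 0 <= p <= 1:
            raise ValueError(f"p_meth[{ctx}] outside [0, 1]")
    if not 0 <= conversion_failure <= 1:
        raise ValueError("conversion_failure outside [0, 1]")
    contexts = dict(call_contexts(ref))
    clones = []
    for k in range(n_clones):
        rng = _rng(seed, k)
        chars = list(ref)
        for i, base in enumerate(ref):
            if base != "C":
                continue
            ctx = contexts.get(i, "indeterminate")
            p = p_meth.get(ctx, 0.0)
            keep = p + (1.0 - p) * conversion_failure
            if rng.random() >= keep:
                chars[i] = "T"
        clones.append("".join(chars))
    return BisulfiteLocus(region_id=region_id, ref_seq=ref, clones=clones)


def gen_germination(
    genotypes: list[str],
    timepoints: np.ndarray,
    n_reps: int = 3,
    seeds_per_rep: int = 50,
    logistic_params: dict[str, tuple[float, float, float]] | None = None,
    seed: int = 0,
    treatment: str = "NAA",
) -> list[GerminationTrial]:
    """Simulate cumulative germination counts along logistic time-courses.

    ``logistic_params`` maps genotype -> (t50 hours, slope per hour,
    max_pct); the fraction germinated by time t is

        F(t) = (max_pct / 100) / (1 + exp(-slope * (t - t50))).

    Each seed draws one uniform variate and counts as germinated at every
    timepoint where F(t) exceeds it, which makes counts binomial around
    the curve at each time *and* exactly monotone within a replicate.  An
    infinite slope yields a step at t50.
    """
    t = np.asarray(timepoints, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("timepoints must be strictly increasing")
    if seeds_per_rep <= 0:
        raise ValueError("seeds_per_rep must be positive")
    if logistic_params is None:
        logistic_params = {g: (60.0, 0.15, 95.0) for g in genotypes}
    out = []
    for gi, geno in enumerate(genotypes):
        t50, slope, max_pct = logistic_params[geno]
        if not 0 <= max_pct <= 100:
            raise ValueError("max_pct outside [0, 100]")
        with np.errstate(over="ignore"):
            if np.isinf(slope):
                curve = np.where(t > t50, max_pct / 100.0, 0.0)
            else:
                curve = (max_pct / 100.0) / (1.0 + np.exp(-slope * (t - t50)))
        for rep in range(1, n_reps + 1):
            rng = _rng(seed, gi, rep)
            u = rng.random(seeds_per_rep)
            counts = (u[None, :] < curve[:, None]).sum(axis=1)
            out.append(
                GerminationTrial(
                    genotype=geno,
                    treatment=treatment,
                    replicate=rep,
                    time_h=t,
                    n_germinated=counts,
                    n_total=seeds_per_rep,
                )
            )
    return out
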