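"""Windowed FST / nucleotide-diversity selection scan between two
populations, with null thresholds from label permutation and from a
neutral domestication-bottleneck coalescent model.

Data model: haploid biallelic calls (0/1, -1 missing) at strictly
increasing physical positions, each haplotype labelled with its source
population (e.g. teosinte vs maize).  Window statistics are a 3000-bp
sliding window with a 100-bp step by default.

FST uses the Weir & Cockerham (1984) variance-component estimator
specialized to haploid calls: with two populations of (pairwise-complete)
sample sizes n1, n2 and allele frequencies p1, p2,

    MSP = n1 (p1 - pbar)^2 + n2 (p2 - pbar)^2
    MSG = (n1 p1 q1 + n2 p2 q2) / (n1 + n2 - 2)
    n_c = (n1 + n2) - (n1^2 + n2^2) / (n1 + n2)
    a   = (MSP - MSG) / n_c          (between-population component)
    b   = MSG                        (within-population component)

and window FST is the ratio of sums sum(a) / sum(a + b) over polymorphic
sites.  Negative per-site components are retained (standard practice);
window FST slightly below zero is reported as computed.  A Hudson-style
estimator is available behind a flag for sensitivity analysis.

Nucleotide diversity is theta_pi = sum_sites 2 p q n/(n-1) / L with L the
window span in bp, i.e. per-site diversity including invariant positions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "HaplotypeMatrix",
    "DemographicModel",
    "WindowStat",
    "site_fst",
    "site_components",
    "pi",
    "window_scan",
    "simulate_coalescent_window",
    "simulate_coalescent_windows",
    "permutation_threshold",
    "bottleneck_threshold",
]

MISSING = -1


@dataclass
class HaplotypeMatrix:
    """Haploid 0/1 allele matrix (haplotypes x sites) with positions and
    per-haplotype population labels."""

    alleles: np.ndarray
    positions: np.ndarray
    pop_labels: np.ndarray
    contig: str = "1"

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.pop_labels = np.asarray(self.pop_labels)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be 2-D (haplotypes x sites)")
        if self.positions.size != self.alleles.shape[1]:
            raise ValueError("positions must match number of sites")
        if self.pop_labels.size != self.alleles.shape[0]:
            raise ValueError("pop_labels must match number of haplotypes")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        bad = ~np.isin(self.alleles, (0, 1, MISSING))
        if bad.any():
            raise ValueError("alleles must be 0, 1 or -1 (missing)")

    @property
    def populations(self) -> list:
        seen = {}
        for x in self.pop_labels:
            seen.setdefault(x, None)
        return list(seen)

    def subset_population(self, label) -> np.ndarray:
        return self.alleles[self.pop_labels == label]

    def sort_sites(self) -> "HaplotypeMatrix":
        order = np.argsort(self.positions, kind="stable")
        return HaplotypeMatrix(
            self.alleles[:, order], self.positions[order], self.pop_labels, self.contig
        )


@dataclass
class DemographicModel:
    """Two-population domestication-bottleneck history.

    All sizes are diploid effective sizes; times in generations before
    present.  The crop (maize) lineage has size ``N_maize_now`` from the
    present back to ``t_bottleneck_end``, then ``N_maize_bottleneck`` back
    to the split at ``t_split``, at which point both lineages merge into an
    ancestor of size ``N_anc`` (the wild lineage keeps ``N_teosinte``
    throughout).  Defaults are literature-typical maize-domestication
    values and are configuration, not fitted quantities.
    """

    N_anc: float = 150_000.0
    N_maize_bottleneck: float = 7_500.0
    N_maize_now: float = 150_000.0
    N_teosinte: float = 150_000.0
    t_split: float = 10_000.0
    t_bottleneck_end: float = 9_000.0
    mu: float = 3e-8
    r: float = 0.0

    def __post_init__(self):
        for name in ("N_anc", "N_maize_bottleneck", "N_maize_now", "N_teosinte",
                     "t_split", "t_bottleneck_end", "mu"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.r < 0:
            raise ValueError("recombination rate must be >= 0")
        if not self.t_bottleneck_end < self.t_split:
            raise ValueError("t_bottleneck_end must precede t_split (backwards in time)")


@dataclass
class WindowStat:
    contig: str
    start: int  # 1-based inclusive
    end: int  # exclusive
    n_sites: int
    fst: float
    pi_pop1: float
    pi_pop2: float

    @property
    def pi_ratio(self) -> float:
        if self.pi_pop2 > 0:
            return self.pi_pop1 / self.pi_pop2
        return np.nan


def _freqs_and_sizes(alleles: np.ndarray):
    """Per-site non-missing sample size and alt-allele frequency."""
    present = alleles != MISSING
    n = present.sum(axis=0).astype(float)
    alt = np.where(present, alleles, 0).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / n, np.nan)
    return n, p


def site_components(alleles1: np.ndarray, alleles2: np.ndarray, estimator: str = "wc"):
    """Vectorized per-site FST variance components for two populations.

    Returns (a, d) arrays where site FST = a/d when d > 0; for the
    Weir-Cockerham estimator a is the between-population component and
    d = a + b.  Sites monomorphic across both populations, or with < 2
    non-missing alleles in either population, get (0, 0).
    """
    n1, p1 = _freqs_and_sizes(np.asarray(alleles1))
    n2, p2 = _freqs_and_sizes(np.asarray(alleles2))
    valid = (n1 >= 2) & (n2 >= 2)
    n1 = np.where(valid, n1, 2.0)
    n2 = np.where(valid, n2, 2.0)
    p1 = np.where(valid, p1, 0.0)
    p2 = np.where(valid, p2, 0.0)
    q1, q2 = 1 - p1, 1 - p2
    ntot = n1 + n2
    pbar = (n1 * p1 + n2 * p2) / ntot
    poly = valid & ~((pbar == 0) | (pbar == 1))
    if estimator == "wc":
        msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2
        msg = (n1 * p1 * q1 + n2 * p2 * q2) / (ntot - 2)
        nc = ntot - (n1**2 + n2**2) / ntot
        a = (msp - msg) / nc
        d = a + msg
    elif estimator == "hudson":
        # within heterozygosity (sample-size corrected) and between
        hw = 0.5 * (p1 * q1 * n1 / (n1 - 1) + p2 * q2 * n2 / (n2 - 1))
        hb = p1 * q2 + p2 * q1
        a = hb - hw
        d = hb
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    a = np.where(poly, a, 0.0)
    d = np.where(poly, d, 0.0)
    return a, d


def site_fst(n1_counts, n2_counts, estimator: str = "wc"):
    """Single-site FST components from (ref, alt) allele counts per population.

    Returns (a, a_plus_b) for the Weir-Cockerham haploid estimator; site
    FST = a / (a + b) when the denominator is positive.
    """
    r1, a1 = n1_counts
    r2, a2 = n2_counts
    if r1 + a1 < 2 or r2 + a2 < 2:
        raise ValueError("each population needs >= 2 non-missing alleles")
    col1 = np.array([[0]] * r1 + [[1]] * a1, dtype=np.int8)
    col2 = np.array([[0]] * r2 + [[1]] * a2, dtype=np.int8)
    a, d = site_components(col1, col2, estimator=estimator)
    return float(a[0]), float(d[0])


def pi(alleles: np.ndarray, span_bp: float) -> float:
    """Per-site nucleotide diversity of one population over a window.

    theta_pi = sum_sites 2 p q n / (n - 1) divided by the window span in
    bp, with pairwise-complete n per site.  Sites with < 2 non-missing
    calls contribute 0 (warned if the whole window is missing).
    """
    alleles = np.asarray(alleles)
    if alleles.shape[0] < 2:
        raise ValueError("pi needs >= 2 haplotypes")
    if span_bp <= 0:
        raise ValueError("span must be positive")
    if alleles.shape[1] == 0:
        return 0.0
    n, p = _freqs_and_sizes(alleles)
    ok = n >= 2
    if not ok.any():
        warnings.warn("window has no sites with >= 2 calls; pi = 0")
        return 0.0
    contrib = 2.0 * p[ok] * (1 - p[ok]) * n[ok] / (n[ok] - 1)
    return float(contrib.sum() / span_bp)


def _window_starts(first: int, last: int, window_bp: int, step_bp: int):
    span = last - first + 1
    if span < window_bp:
        warnings.warn("region shorter than one window; single truncated window")
        return np.array([first]), True
    n_win = (span - window_bp) // step_bp + 1
    return first + step_bp * np.arange(n_win), False


def window_scan(
    hm: HaplotypeMatrix,
    window_bp: int = 3000,
    step_bp: int = 100,
    min_sites: int = 3,
    estimator: str = "wc",
    pops: tuple | None = None,
) -> list[WindowStat]:
    """Sliding-window FST and per-population diversity along the region.

    Windows are anchored at the first variant position, [start,
    start + window_bp) half-open, advancing by ``step_bp``.  Window FST is
    ratio-of-sums over the window's polymorphic sites; windows with fewer
    than ``min_sites`` usable sites (or a zero denominator) carry NaN FST
    so that window coordinates stay stable.
    """
    if window_bp < step_bp:
        raise ValueError("window_bp must be >= step_bp")
    if hm.alleles.shape[1] == 0:
        raise ValueError("empty haplotype matrix")
    if pops is None:
        pops = tuple(hm.populations)
    if len(pops) != 2:
        raise ValueError("exactly two populations required")
    a1 = hm.subset_population(pops[0])
    a2 = hm.subset_population(pops[1])
    comp_a, comp_d = site_components(a1, a2, estimator=estimator)
    seg = comp_d != 0  # polymorphic, usable sites

    # per-site pi contributions for each population
    def _site_pi(alleles):
        n, p = _freqs_and_sizes(alleles)
        ok = n >= 2
        c = np.zeros_like(p)
        c[ok] = 2.0 * p[ok] * (1 - p[ok]) * n[ok] / (n[ok] - 1)
        return c

    pi1 = _site_pi(a1)
    pi2 = _site_pi(a2)

    pos = hm.positions
    first, last = int(pos[0]), int(pos[-1])
    starts, truncated = _window_starts(first, last, window_bp, step_bp)
    out = []
    # prefix sums over sites (site-sorted by construction)
    ca = np.concatenate([[0.0], np.cumsum(comp_a)])
    cd = np.concatenate([[0.0], np.cumsum(comp_d)])
    cs = np.concatenate([[0], np.cumsum(seg)])
    c1 = np.concatenate([[0.0], np.cumsum(pi1)])
    c2 = np.concatenate([[0.0], np.cumsum(pi2)])
    for s in starts:
        e = s + window_bp if not truncated else last + 1
        lo = np.searchsorted(pos, s, side="left")
        hi = np.searchsorted(pos, e, side="left")
        n_seg = int(cs[hi] - cs[lo])
        span = e - s
        sum_a = ca[hi] - ca[lo]
        sum_d = cd[hi] - cd[lo]
        if n_seg >= min_sites and sum_d > 0:
            fst = sum_a / sum_d
        else:
            fst = np.nan
        out.append(
            WindowStat(
                contig=hm.contig,
                start=int(s),
                end=int(e),
                n_sites=n_seg,
                fst=float(fst),
                pi_pop1=float((c1[hi] - c1[lo]) / span),
                pi_pop2=float((c2[hi] - c2[lo]) / span),
            )
        )
    return out


def _demography(model: DemographicModel):
    import msprime

    # msprime ploidy-1 samples: coalescence rate 1/N_e; pass 2N so that
    # E[pairwise TMRCA] = 2N generations and E[pi] = 4 N mu (diploid-N
    # convention of the model fields).
    dem = msprime.Demography()
    dem.add_population(name="teosinte", initial_size=2 * model.N_teosinte)
    dem.add_population(name="maize", initial_size=2 * model.N_maize_now)
    dem.add_population(name="anc", initial_size=2 * model.N_anc)
    dem.add_population_parameters_change(
        time=model.t_bottleneck_end, population="maize",
        initial_size=2 * model.N_maize_bottleneck,
    )
    dem.add_population_split(
        time=model.t_split, derived=["teosinte", "maize"], ancestral="anc"
    )
    return dem


def _ts_to_matrix(ts, n1: int, n2: int, L: int, contig: str) -> HaplotypeMatrix:
    gm = ts.genotype_matrix()  # sites x samples
    pos = np.array([int(s.position) + 1 for s in ts.sites()], dtype=np.int64)
    # discrete-genome sites are unique integers; clip any biallelic recoding
    alleles = np.minimum(gm.T.astype(np.int8), 1)
    labels = np.array(["teosinte"] * n1 + ["maize"] * n2)
    keep = (alleles.sum(axis=0) > 0) & (alleles.sum(axis=0) < alleles.shape[0])
    return HaplotypeMatrix(alleles[:, keep], pos[keep], labels, contig=contig)


def simulate_coalescent_windows(
    model: DemographicModel,
    L: int,
    n1: int,
    n2: int,
    seed: int,
    n_reps: int = 1,
):
    """Yield ``n_reps`` independent neutral windows under the model.

    Haplotypes are drawn from the standard two-population coalescent with
    the bottleneck history and (near-)infinite-sites 0/1 mutations at rate
    ``model.mu`` per bp per generation.
    """
    import msprime

    if L <= 0:
        raise ValueError("window length must be positive")
    if n1 + n2 < 2:
        raise ValueError("need at least 2 sampled haplotypes")
    if seed < 0:
        raise ValueError("seed must be >= 0")
    rng = np.random.default_rng(seed)
    anc_seed, mut_seed = rng.integers(1, 2**31 - 1, size=2)
    samples = {}
    if n1:
        samples["teosinte"] = n1
    if n2:
        samples["maize"] = n2
    reps = msprime.sim_ancestry(
        samples=samples,
        demography=_demography(model),
        sequence_length=L,
        recombination_rate=model.r,
        ploidy=1,
        random_seed=int(anc_seed),
        num_replicates=n_reps,
    )
    for i, ts in enumerate(reps):
        mts = msprime.sim_mutations(
            ts,
            rate=model.mu,
            model=msprime.BinaryMutationModel(),
            random_seed=int(mut_seed) + i,
        )
        yield _ts_to_matrix(mts, n1, n2, L, contig=f"sim{i}")


def simulate_coalescent_window(
    model: DemographicModel, L: int, n1: int, n2: int, seed: int
) -> HaplotypeMatrix:
    """Single neutral window (see :func:`simulate_coalescent_windows`)."""
    return next(simulate_coalescent_windows(model, L, n1, n2, seed, n_reps=1))


def permutation_threshold(
    hm: HaplotypeMatrix,
    window_bp: int = 3000,
    step_bp: int = 100,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    min_sites: int = 3,
    estimator: str = "wc",
) -> float:
    """Scan-wide FST significance threshold by population-label permutation.

    Labels are shuffled ``n_perm`` times; each shuffle records the maximum
    window FST over the rescan; the threshold is the empirical
    (1 - alpha) quantile (linear interpolation) of those maxima, i.e. a
    familywise bound on the no-differentiation null.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if hm.alleles.shape[0] < 4:
        raise ValueError("need >= 4 haplotypes to permute meaningfully")
    pops = hm.populations
    if len(pops) != 2:
        raise ValueError("exactly two populations required")
    rng = np.random.default_rng(seed)
    labels = hm.pop_labels.copy()
    maxima = np.empty(n_perm)
    for b in range(n_perm):
        rng.shuffle(labels)
        hperm = HaplotypeMatrix(hm.alleles, hm.positions, labels, hm.contig)
        stats = window_scan(hperm, window_bp, step_bp, min_sites, estimator, pops=tuple(pops))
        fsts = np.array([w.fst for w in stats])
        maxima[b] = np.nanmax(fsts) if np.any(~np.isnan(fsts)) else -np.inf
    finite = maxima[np.isfinite(maxima)]
    if finite.size == 0:
        raise ValueError("no permutation produced a defined window FST")
    return float(np.quantile(finite, 1 - alpha))


def bottleneck_threshold(
    model: DemographicModel,
    window_bp: int = 3000,
    n_sim: int = 1000,
    n1: int = 18,
    n2: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, float]:
    """Neutral-model thresholds for window FST and pi_teosinte/pi_maize.

    Simulates ``n_sim`` independent neutral windows under the bottleneck
    model and returns the empirical (1 - alpha) quantiles (linear
    interpolation) of window FST and of the diversity ratio; windows where
    the maize diversity is 0 are excluded from the ratio distribution with
    a logged count.
    """
    if n_sim < 200:
        raise ValueError("n_sim must be >= 200")
    fsts, ratios = [], []
    n_zero = 0
    for hm in simulate_coalescent_windows(model, window_bp, n1, n2, seed, n_reps=n_sim):
        a1 = hm.subset_population("teosinte")
        a2 = hm.subset_population("maize")
        comp_a, comp_d = site_components(a1, a2)
        if comp_d.sum() > 0:
            fsts.append(float(comp_a.sum() / comp_d.sum()))
        pi_teo = pi(a1, window_bp) if a1.shape[1] else 0.0
        pi_mz = pi(a2, window_bp) if a2.shape[1] else 0.0
        if pi_mz > 0:
            ratios.append(pi_teo / pi_mz)
        else:
            n_zero += 1
    if n_zero:
        logger.info("bottleneck_threshold: %d/%d windows had zero maize diversity", n_zero, n_sim)
    q = 1 - alpha
    return float(np.quantile(fsts, q)), float(np.quantile(ratios, q))
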