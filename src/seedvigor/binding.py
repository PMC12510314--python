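"""Serial-dilution planning, ligand-depletion binding isotherm, KD fitting
and the replicate/multiple-comparison statistics for dose-response plates.

The assay layout modelled here: a reaction containing the ligand (the
RNA-binding protein) at a known stock concentration is serially diluted
2-fold along a 12-well row, then an equal volume of labelled target mRNA is
added to every well, halving all concentrations.  Final ligand
concentration in well k is therefore

    stock * mix_fraction / fold**(k-1)        (mix_fraction = 0.5).

Because the fluorescent target is present at a fixed concentration (tens of
nM) that is not always negligible against the dissociation constant, the
fraction of target bound follows the single-site *depletion* isotherm
(solution of the mass-action quadratic) rather than the hyperbolic
L/(L+KD); the latter is recovered in the T -> 0 limit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "DilutionPlan",
    "BindingSeries",
    "KdEstimate",
    "plan_serial_dilution",
    "fraction_bound",
    "fit_kd",
    "fit_kd_replicates",
    "qc_series",
    "resample_kd_se",
    "compare_treatments",
]


@dataclass
class DilutionPlan:
    """A k-well, fold-wise serial dilution with equal-volume target addition.

    ``stock_conc`` maps reagent name -> stock concentration in µM for every
    co-diluted reagent (ligand plus any chaperone/cofactor premixed in the
    reaction).  ``mix_fraction`` is the fraction of the final well volume
    contributed by the dilution series once the target is added (0.5 for
    equal volumes).
    """

    n_wells: int = 12
    fold: float = 2.0
    stock_conc: dict[str, float] = field(default_factory=dict)
    mix_fraction: float = 0.5

    def __post_init__(self):
        if self.n_wells < 2:
            raise ValueError("a dilution series needs at least 2 wells")
        if self.fold <= 1:
            raise ValueError("dilution fold must exceed 1")
        if not 0 < self.mix_fraction <= 1:
            raise ValueError("mix_fraction must be in (0, 1]")
        for name, c in self.stock_conc.items():
            if c <= 0:
                raise ValueError(f"stock concentration of {name!r} must be positive")

    def ladder(self, reagent: str) -> np.ndarray:
        """Final concentrations (µM) of ``reagent`` in wells 1..n."""
        stock = self.stock_conc[reagent]
        k = np.arange(self.n_wells)
        return stock * self.mix_fraction / self.fold**k

    def well_conc(self, reagent: str, well: int) -> float:
        """Final concentration (µM) in 1-based ``well``."""
        if not 1 <= well <= self.n_wells:
            raise ValueError(f"well {well} outside 1..{self.n_wells}")
        return float(self.ladder(reagent)[well - 1])


def plan_serial_dilution(
    stocks: dict[str, float] | float,
    n_wells: int = 12,
    fold: float = 2.0,
    mix_fraction: float = 0.5,
) -> DilutionPlan:
    """Build the plate's dilution plan from reaction stock concentrations (µM)."""
    if not isinstance(stocks, dict):
        stocks = {"ligand": float(stocks)}
    return DilutionPlan(n_wells=n_wells, fold=fold, stock_conc=dict(stocks), mix_fraction=mix_fraction)


# well_flags bit meanings
FLAG_OUTLIER = "outlier"
FLAG_INHOMOGENEOUS = "inhomogeneous"


@dataclass
class BindingSeries:
    """One replicate's dose-response ladder."""

    ligand_conc: np.ndarray  # µM, strictly decreasing
    fnorm: np.ndarray  # normalized fluorescence per well
    target_conc: float = 0.089  # µM (constant across wells)
    treatment: str = "alone"
    aging: str = "unaged"
    incubation_h: float = 1.0
    replicate: int = 1
    initial_fluorescence: np.ndarray | None = None
    well_flags: list[set] = None  # type: ignore[assignment]
    unusable: bool = False

    def __post_init__(self):
        self.ligand_conc = np.asarray(self.ligand_conc, dtype=float)
        self.fnorm = np.asarray(self.fnorm, dtype=float)
        if self.ligand_conc.shape != self.fnorm.shape:
            raise ValueError("ligand_conc and fnorm must align")
        if np.any(np.diff(self.ligand_conc) >= 0):
            raise ValueError("ligand_conc must be strictly decreasing")
        if self.well_flags is None:
            self.well_flags = [set() for _ in self.ligand_conc]

    @property
    def unflagged(self) -> np.ndarray:
        return np.array([len(f) == 0 for f in self.well_flags])


@dataclass
class KdEstimate:
    kd: float  # µM
    se: float  # µM
    bound_level: float
    unbound_level: float
    n_wells_used: int
    legitimate: bool
    reason: str = ""
    residual_sd: float = np.nan

    def __post_init__(self):
        if self.legitimate and not self.kd > 0:
            raise ValueError("legitimate estimate requires kd > 0")
        if self.se < 0:
            raise ValueError("se must be >= 0")


def fraction_bound(L_tot, T_tot, kd):
    """Fraction of target bound under single-site binding with depletion.

    Solves T_bound from  T_bound = L_free*T_free/KD  with mass balance,
    using the cancellation-free root form

        FB = 2*L / (L + T + KD + sqrt((L + T + KD)^2 - 4*L*T)),

    which is continuous at T -> 0 (limit L/(L+KD)) and monotone increasing
    in L, decreasing in KD.  Concentrations in consistent units.
    """
    L = np.asarray(L_tot, dtype=float)
    T = np.asarray(T_tot, dtype=float)
    if np.any(L < 0) or np.any(T < 0):
        raise ValueError("concentrations must be non-negative")
    if not np.all(np.asarray(kd) > 0):
        raise ValueError("kd must be positive")
    s = L + T + kd
    disc = np.maximum(s * s - 4.0 * L * T, 0.0)
    fb = 2.0 * L / (s + np.sqrt(disc))
    return fb if fb.shape else float(fb)


def _profiled_ssr(log_kd: float, L: np.ndarray, T: float, y: np.ndarray):
    """SSR at a given kd, profiling out the linear (unbound, bound) levels."""
    fb = fraction_bound(L, T, np.exp(log_kd))
    X = np.column_stack([1.0 - fb, fb])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid), coef


def _fit_kd_point(L: np.ndarray, T: float, y: np.ndarray, n_starts: int = 7):
    """Multi-start profiled least squares; returns (kd, unbound, bound, ssr)."""
    lo, hi = np.log(L.min() / 10.0), np.log(L.max() * 10.0)
    starts = np.linspace(lo, hi, n_starts)
    # bracket each start between its neighbours for a bounded local search
    edges = np.concatenate([[lo], (starts[1:] + starts[:-1]) / 2, [hi]])
    best = None
    for i in range(n_starts):
        res = minimize_scalar(
            lambda lk: _profiled_ssr(lk, L, T, y)[0],
            bounds=(edges[i], edges[i + 1]),
            method="bounded",
            options={"xatol": 1e-10},
        )
        ssr, coef = _profiled_ssr(res.x, L, T, y)
        cand = (ssr, np.exp(res.x), coef)
        # tie-break: lowest residual, then lowest kd
        if best is None or cand[0] < best[0] - 1e-30 or (
            abs(cand[0] - best[0]) <= 1e-30 and cand[1] < best[1]
        ):
            best = cand
    ssr, kd, (unbound, bound) = best
    return kd, unbound, bound, ssr


def fit_kd(series: BindingSeries, min_wells: int = 5, min_decades: float = 2.0) -> KdEstimate:
    """Fit the dissociation constant of one dose-response series.

    Least squares of fnorm = unbound + (bound - unbound) * FB(L; T, KD) over
    (KD, bound, unbound).  The two levels enter linearly and are profiled
    out, leaving a 1-D search over log KD started from a 7-point log-spaced
    grid spanning [min ladder / 10, max ladder * 10].

    Legitimacy (the analogue of a dash in a published KD table): the fit
    must converge, the amplitude |bound - unbound| must exceed 3x the
    residual SD, and KD must fall inside the searched range.  The standard
    error here comes from the curvature of the SSR profile; replicate-based
    SEs are provided by :func:`fit_kd_replicates`.
    """
    use = series.unflagged
    L = series.ligand_conc[use]
    y = series.fnorm[use]
    if series.unusable or L.size < min_wells:
        return KdEstimate(np.nan, 0.0, np.nan, np.nan, int(L.size), False, "too_few_wells")
    if np.log10(L.max() / L.min()) < min_decades:
        return KdEstimate(np.nan, 0.0, np.nan, np.nan, int(L.size), False, "narrow_ladder")
    T = series.target_conc
    try:
        kd, unbound, bound, ssr = _fit_kd_point(L, T, y)
    except (np.linalg.LinAlgError, ValueError):
        return KdEstimate(np.nan, 0.0, np.nan, np.nan, int(L.size), False, "no_convergence")
    dof = max(L.size - 3, 1)
    resid_sd = np.sqrt(ssr / dof)
    amplitude = abs(bound - unbound)
    # curvature-based SE on kd: Var(kd) ~ 2 sigma^2 / d2SSR/dkd2
    h = kd * 1e-4
    ssr_p = _profiled_ssr(np.log(kd + h), L, T, y)[0]
    ssr_m = _profiled_ssr(np.log(max(kd - h, 1e-12)), L, T, y)[0]
    d2 = (ssr_p - 2 * ssr + ssr_m) / h**2
    se = float(np.sqrt(2 * resid_sd**2 / d2)) if d2 > 0 else 0.0

    legitimate, reason = True, ""
    if amplitude < 3.0 * resid_sd:
        legitimate, reason = False, "low_amplitude"
    elif not (L.min() / 10.0 * 1.001 <= kd <= L.max() * 10.0 / 1.001):
        legitimate, reason = False, "kd_outside_ladder"
    return KdEstimate(
        kd=float(kd),
        se=se,
        bound_level=float(bound),
        unbound_level=float(unbound),
        n_wells_used=int(L.size),
        legitimate=legitimate,
        reason=reason,
        residual_sd=float(resid_sd),
    )


def fit_kd_replicates(series_list: list[BindingSeries]) -> KdEstimate:
    """Fit each replicate separately; KD = replicate mean, SE = sd/sqrt(n).

    With fewer than 3 legitimate replicate fits, falls back to the best
    single fit's curvature SE.  Legitimate only if a majority of replicates
    produced legitimate fits.
    """
    fits = [fit_kd(s) for s in series_list]
    ok = [f for f in fits if f.legitimate]
    if len(ok) >= 3:
        kds = np.array([f.kd for f in ok])
        return KdEstimate(
            kd=float(kds.mean()),
            se=float(kds.std(ddof=1) / np.sqrt(kds.size)),
            bound_level=float(np.mean([f.bound_level for f in ok])),
            unbound_level=float(np.mean([f.unbound_level for f in ok])),
            n_wells_used=int(sum(f.n_wells_used for f in ok)),
            legitimate=True,
            residual_sd=float(np.mean([f.residual_sd for f in ok])),
        )
    if ok:
        best = min(ok, key=lambda f: f.residual_sd)
        legit = len(ok) * 2 > len(fits)
        if not legit:
            return KdEstimate(best.kd, best.se, best.bound_level, best.unbound_level,
                              best.n_wells_used, False, "majority_illegitimate", best.residual_sd)
        return best
    reasons = sorted({f.reason for f in fits})
    return KdEstimate(np.nan, 0.0, np.nan, np.nan, 0, False, ";".join(reasons))


def qc_series(
    series: BindingSeries,
    homogeneity_tol: float = 0.2,
    outlier_z: float = 4.0,
) -> BindingSeries:
    """Flag anomalous wells before fitting.

    Outliers: studentized *deleted* residuals — each candidate well is
    predicted from a provisional fit to the other clean wells, and
    flagged when its deleted residual exceeds ``outlier_z`` robust SDs
    (MAD-scaled across the ladder's deleted residuals).  Deleting the
    well before predicting keeps high-leverage wells (the top of the
    ladder, which anchors the bound plateau) from masking themselves.
    Only the single worst well is flagged per pass — while any gross
    outlier remains it also corrupts the other wells' leave-one-out
    predictions — and the pass repeats until no well exceeds the
    threshold.  The default z of 4
    is deliberately conservative for 12-well ladders, where the MAD
    scale estimate is itself noisy.  Inhomogeneity: wells whose initial
    fluorescence deviates from the ladder median by more than
    ``homogeneity_tol`` (fractional).  If more than half the wells end up
    flagged the series is marked unusable, mirroring how anomalous scans
    get a whole series excluded.
    """
    flags = [set(f) for f in series.well_flags]
    if series.initial_fluorescence is not None:
        init = np.asarray(series.initial_fluorescence, dtype=float)
        med = np.median(init)
        bad = np.abs(init - med) > homogeneity_tol * abs(med)
        for i in np.flatnonzero(bad):
            flags[i].add(FLAG_INHOMOGENEOUS)
    T = series.target_conc
    for _ in range(len(flags)):  # one well flagged per pass at most
        kept = [i for i, f in enumerate(flags) if not f]
        if len(kept) < 6:
            break
        deleted = np.full(len(flags), np.nan)
        try:
            for i in kept:
                rest = [j for j in kept if j != i]
                L, y = series.ligand_conc[rest], series.fnorm[rest]
                kd, unbound, bound, _ = _fit_kd_point(L, T, y)
                fb_i = fraction_bound(series.ligand_conc[i], T, kd)
                deleted[i] = series.fnorm[i] - (unbound + (bound - unbound) * fb_i)
        except (np.linalg.LinAlgError, ValueError):
            break
        dk = deleted[kept]
        mad = np.median(np.abs(dk - np.median(dk)))
        scale = 1.4826 * mad if mad > 0 else np.std(dk, ddof=1)
        if scale <= 0:
            break
        worst = max(kept, key=lambda i: abs(deleted[i]))
        if abs(deleted[worst]) <= outlier_z * scale:
            break
        flags[worst].add(FLAG_OUTLIER)
    out = BindingSeries(
        ligand_conc=series.ligand_conc,
        fnorm=series.fnorm,
        target_conc=series.target_conc,
        treatment=series.treatment,
        aging=series.aging,
        incubation_h=series.incubation_h,
        replicate=series.replicate,
        initial_fluorescence=series.initial_fluorescence,
        well_flags=flags,
    )
    n_flagged = sum(len(f) > 0 for f in flags)
    if n_flagged * 2 > len(flags):
        out.unusable = True
        warnings.warn(
            f"series replicate={series.replicate}: {n_flagged}/{len(flags)} wells flagged; marked unusable"
        )
    return out


def resample_kd_se(replicate_kds) -> dict[tuple[int, int], float]:
    """Pairwise (leave-one-out) standard errors from exactly 3 replicate KDs.

    For each pair {i, j} the SE of the 2-value mean is sd/sqrt(2) = |x-y|/2.
    These pairwise SEs are the inputs to the variability ANOVA used when
    replicate scatter itself is the quantity under comparison.
    """
    vals = np.asarray(replicate_kds, dtype=float)
    if vals.size != 3:
        raise ValueError("resampling is defined for exactly 3 replicates")
    pairs = [(1, 2), (2, 3), (1, 3)]
    return {
        (i, j): float(abs(vals[i - 1] - vals[j - 1]) / 2.0) for i, j in pairs
    }


def compare_treatments(
    kd_table,
    control: str = "alone",
    alpha: float = 0.05,
):
    """Treatment statistics on a replicate-level KD table.

    ``kd_table`` is a DataFrame with columns treatment, aging,
    incubation_h, replicate, kd.  Within each (aging, treatment) stratum a
    one-way ANOVA across incubation durations is run and Scheffé letters
    assigned; within each (aging, incubation_h) stratum each enzyme
    treatment is compared against ``control`` with Dunnett's test.

    Returns dict with keys 'anova' (DataFrame), 'scheffe' (DataFrame of
    letters), 'dunnett' (DataFrame of adjusted p).
    """
    import pandas as pd

    from .stats import dunnett_pvalues, one_way_anova, scheffe_letters

    df = kd_table.copy()
    anova_rows, scheffe_rows, dunnett_rows = [], [], []
    for (aging, treatment), sub in df.groupby(["aging", "treatment"]):
        groups = {}
        for dur, g in sub.groupby("incubation_h"):
            v = g["kd"].dropna().to_numpy()
            if v.size < 2:
                if v.size == 1 and v.var() == 0:
                    warnings.warn(
                        f"({aging},{treatment}) duration {dur}: single replicate excluded"
                    )
                continue
            groups[dur] = v
        if len(groups) >= 2:
            res = one_way_anova(groups)
            anova_rows.append(
                dict(aging=aging, treatment=treatment, f=res.f, p=res.p,
                     df_between=res.df_between, df_within=res.df_within)
            )
            letters = scheffe_letters(groups, alpha=alpha)
            for dur, letter in letters.items():
                scheffe_rows.append(
                    dict(aging=aging, treatment=treatment, incubation_h=dur,
                         mean_kd=res.group_means[dur], letters=letter)
                )
    for (aging, dur), sub in df.groupby(["aging", "incubation_h"]):
        groups = {
            t: g["kd"].dropna().to_numpy()
            for t, g in sub.groupby("treatment")
            if g["kd"].dropna().size >= 2
        }
        if control in groups and len(groups) >= 2:
            pvals = dunnett_pvalues(groups, control=control)
            for t, p in pvals.items():
                dunnett_rows.append(
                    dict(aging=aging, incubation_h=dur, treatment=t,
                         control=control, p_adj=p, significant=p < alpha)
                )
    return {
        "anova": pd.DataFrame(anova_rows),
        "scheffe": pd.DataFrame(scheffe_rows),
        "dunnett": pd.DataFrame(dunnett_rows),
    }
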