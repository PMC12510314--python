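"""Locus-specific DNA methylation quantification.

Two complementary assays are modelled:

* McrBC-qPCR: McrBC cuts methylated DNA, so amplifiable template remaining
  after digestion reports (un)methylation.  The remaining fraction is
  2^(-ddCt), where ddCt subtracts the digestion shift of unmethylated
  reference genes from the digestion shift of the region of interest, and
  the methylation score is 1 minus that fraction.

* Locus-specific bisulfite sequencing: unmethylated cytosines convert to
  uracil (read as T); methylated cytosines stay C.  Clones of the PCR
  amplicon are compared with the reference to call per-cytosine
  methylation, aggregated by sequence context — CG, CHG, CHH with
  H in {A, C, T} — the three contexts plant methyltransferases maintain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BisulfiteLocus",
    "MethylationSummary",
    "CONTEXTS",
    "mcrbc_relative_methylation",
    "call_contexts",
    "bisulfite_summary",
    "reverse_complement",
]

CONTEXTS = ("CG", "CHG", "CHH")
_H = set("ACT")
_ACGT = set("ACGT")

_COMP = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class BisulfiteLocus:
    """A reference amplicon plus its bisulfite-converted clone sequences.

    Clones are assumed gap-free and pre-aligned to the reference (Sanger
    sequencing of a fixed amplicon).  ``strand='bottom'`` reverse-
    complements the reference before context calling, since locus-specific
    bisulfite PCR interrogates a single strand.
    """

    region_id: str
    ref_seq: str
    clones: list[str]
    strand: str = "top"

    def __post_init__(self):
        self.ref_seq = self.ref_seq.upper()
        self.clones = [c.upper() for c in self.clones]
        if not self.clones:
            raise ValueError("at least one clone required")
        for i, c in enumerate(self.clones):
            if len(c) != len(self.ref_seq):
                raise ValueError(f"clone {i} length differs from reference")
        if self.strand not in ("top", "bottom"):
            raise ValueError("strand must be 'top' or 'bottom'")


@dataclass
class MethylationSummary:
    region_id: str
    per_context: dict = field(default_factory=dict)  # context -> dict(n_sites, n_calls, n_methylated, percent)
    n_flagged_calls: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(region_id=self.region_id, context=ctx, **self.per_context[ctx])
            for ctx in CONTEXTS
        ]
        return pd.DataFrame(rows)


def call_contexts(ref_seq: str) -> list[tuple[int, str]]:
    """Classify every cytosine of ``ref_seq`` by its downstream context.

    Returns (0-based position, context) with context one of CG / CHG /
    CHH / 'indeterminate' (trailing cytosines lacking the 1-2 downstream
    bases, or any non-ACGT base in the triplet).
    """
    seq = ref_seq.upper()
    out = []
    n = len(seq)
    for i, base in enumerate(seq):
        if base != "C":
            if base not in _ACGT:
                out.append((i, "indeterminate"))
            continue
        if i + 1 >= n:
            out.append((i, "indeterminate"))
            continue
        b1 = seq[i + 1]
        if b1 == "G":
            out.append((i, "CG"))
            continue
        if b1 not in _H:
            out.append((i, "indeterminate"))
            continue
        if i + 2 >= n:
            out.append((i, "indeterminate"))
            continue
        b2 = seq[i + 2]
        if b2 == "G":
            out.append((i, "CHG"))
        elif b2 in _H:
            out.append((i, "CHH"))
        else:
            out.append((i, "indeterminate"))
    return out


def bisulfite_summary(locus: BisulfiteLocus) -> MethylationSummary:
    """Per-context methylation percentages across a locus's clones.

    For every cytosine position of the (strand-oriented) reference and
    every clone: C = methylated, T = unmethylated (converted); anything
    else is flagged and excluded from the denominator.
    """
    ref = locus.ref_seq if locus.strand == "top" else reverse_complement(locus.ref_seq)
    clones = (
        locus.clones
        if locus.strand == "top"
        else [reverse_complement(c) for c in locus.clones]
    )
    ctx_positions = {ctx: [] for ctx in CONTEXTS}
    for pos, ctx in call_contexts(ref):
        if ctx in ctx_positions:
            ctx_positions[ctx].append(pos)
    summary = {}
    n_flagged = 0
    for ctx in CONTEXTS:
        positions = ctx_positions[ctx]
        n_meth = n_calls = 0
        for clone in clones:
            for p in positions:
                b = clone[p]
                if b == "C":
                    n_meth += 1
                    n_calls += 1
                elif b == "T":
                    n_calls += 1
                else:
                    n_flagged += 1
        percent = 100.0 * n_meth / n_calls if n_calls else np.nan
        summary[ctx] = dict(
            n_sites=len(positions),
            n_calls=n_calls,
            n_methylated=n_meth,
            percent=percent,
        )
    if n_flagged:
        logger.info("bisulfite_summary %s: %d non-C/T calls excluded", locus.region_id, n_flagged)
    return MethylationSummary(locus.region_id, summary, n_flagged)


def mcrbc_relative_methylation(
    ct: pd.DataFrame,
    region: str,
    genotype: str,
    reference_regions: tuple[str, ...] = ("Ubi-2", "Actin1"),
) -> tuple[float, float]:
    """McrBC-qPCR methylation score (0..1) with replicate SE.

    ``ct`` columns: region, genotype, digested (bool), replicate, ct.
    Per replicate: dCt = Ct(digested) - Ct(undigested) for the region and
    (averaged over the reference genes) for the references; ddCt is their
    difference; remaining template = 2^(-ddCt); score = 1 - remaining,
    clamped to [0, 1] after averaging.  SE is the replicate SD / sqrt(n)
    of the unclamped scores.
    """

    def _dct(reg: str) -> dict:
        sub = ct[(ct.region == reg) & (ct.genotype == genotype)]
        dig = sub[sub.digested].set_index("replicate")["ct"]
        und = sub[~sub.digested].set_index("replicate")["ct"]
        if dig.empty or und.empty:
            raise ValueError(f"missing digested/undigested Ct for region {reg!r}")
        common = dig.index.intersection(und.index)
        if common.empty:
            raise ValueError(f"no paired replicates for region {reg!r}")
        return {r: float(dig[r] - und[r]) for r in common}

    d_region = _dct(region)
    d_refs = [_dct(r) for r in reference_regions]
    reps = set(d_region)
    for d in d_refs:
        reps &= set(d)
    if len(reps) < 2:
        raise ValueError("need >= 2 complete replicates across region and references")
    scores = []
    for r in sorted(reps):
        ref_mean = float(np.mean([d[r] for d in d_refs]))
        ddct = d_region[r] - ref_mean
        scores.append(1.0 - 2.0 ** (-ddct))
    scores = np.asarray(scores)
    mean = float(scores.mean())
    se = float(scores.std(ddof=1) / np.sqrt(scores.size))
    if mean < 0:
        logger.info(
            "mcrbc %s/%s: negative score %.3f before clamping (unmethylated with noise)",
            region, genotype, mean,
        )
    return float(np.clip(mean, 0.0, 1.0)), se
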