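"""Readers and writers for the plain-text formats the pipeline exchanges.

Genotypes travel as VCF (haploid GT, or diploid GT split into two
haplotypes) plus a two-column population map, or as a plain TSV matrix;
binding plates as CSV; RNA/RNC counts as TSV with a two-row header
(assay, group_replicate); bisulfite loci as FASTA (first record the
reference, the rest clones); germination and qPCR Ct tables as CSV.
"""

from __future__ import annotations

import csv

import numpy as np
import pandas as pd

from .binding import BindingSeries
from .methylation import BisulfiteLocus
from .phenotype import GerminationTrial
from .popgen import MISSING, HaplotypeMatrix, WindowStat
from .translatome import GenePairCounts

__all__ = [
    "read_popmap",
    "read_vcf",
    "write_vcf",
    "read_haplotype_tsv",
    "write_haplotype_tsv",
    "write_window_stats",
    "read_plate_csv",
    "write_plate_csv",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_bisulfite_fasta",
    "write_bisulfite_fasta",
    "read_germination_csv",
    "write_germination_csv",
    "read_ct_csv",
    "read_protein_fasta",
]


def read_popmap(path) -> dict[str, str]:
    """Two-column (sample, label) whitespace/tab-delimited population map."""
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sample, label = line.split()[:2]
            out[sample] = label
    return out


def read_vcf(path, popmap: dict[str, str]) -> HaplotypeMatrix:
    """Load a biallelic VCF into a haplotype matrix.

    Diploid GTs contribute two haplotypes per sample (phase is taken at
    face value, as in haplotype-level diversity scans); haploid GTs one.
    Samples absent from ``popmap`` are dropped; multiallelic records are
    rejected.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = vcf.samples
    keep = [i for i, s in enumerate(samples) if s in popmap]
    if not keep:
        raise ValueError("no VCF samples present in the population map")
    rows_per_sample = None
    alleles_cols, positions = [], []
    contig = None
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(f"multiallelic record at {var.CHROM}:{var.POS}")
        contig = contig or var.CHROM
        gts = var.genotype.array()  # samples x (alleles..., phased)
        ploidy = gts.shape[1] - 1
        if rows_per_sample is None:
            rows_per_sample = ploidy
        col = []
        for i in keep:
            for a in gts[i, :ploidy]:
                col.append(MISSING if a < 0 else int(a))
        alleles_cols.append(col)
        positions.append(var.POS)
    if not alleles_cols:
        raise ValueError("empty VCF")
    alleles = np.array(alleles_cols, dtype=np.int8).T
    labels = []
    for i in keep:
        labels.extend([popmap[samples[i]]] * rows_per_sample)
    return HaplotypeMatrix(alleles, np.array(positions), np.array(labels), contig=contig)


def write_vcf(hm: HaplotypeMatrix, path, sample_prefix: str = "hap") -> None:
    """Write a haplotype matrix as a minimal haploid-GT VCF."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={hm.contig}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        names = [f"{sample_prefix}{i}_{lab}" for i, lab in enumerate(hm.pop_labels)]
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(names) + "\n")
        for j, pos in enumerate(hm.positions):
            gts = ["." if a == MISSING else str(int(a)) for a in hm.alleles[:, j]]
            fh.write(f"{hm.contig}\t{pos}\t.\tA\tT\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")


def write_haplotype_tsv(hm: HaplotypeMatrix, path) -> None:
    """Plain-matrix TSV: header row of positions, then label + alleles per haplotype."""
    with open(path, "w") as fh:
        fh.write("#contig\t" + hm.contig + "\n")
        fh.write("label\t" + "\t".join(map(str, hm.positions)) + "\n")
        for lab, row in zip(hm.pop_labels, hm.alleles):
            fh.write(str(lab) + "\t" + "\t".join("." if a == MISSING else str(int(a)) for a in row) + "\n")


def read_haplotype_tsv(path) -> HaplotypeMatrix:
    with open(path) as fh:
        contig_line = fh.readline().strip().split("\t")
        contig = contig_line[1] if len(contig_line) > 1 else "1"
        header = fh.readline().strip().split("\t")
        positions = np.array([int(x) for x in header[1:]])
        labels, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            labels.append(parts[0])
            rows.append([MISSING if a == "." else int(a) for a in parts[1:]])
    return HaplotypeMatrix(np.array(rows, dtype=np.int8), positions, np.array(labels), contig=contig)


def write_window_stats(stats: list[WindowStat], path) -> None:
    """BED-like TSV of window statistics."""
    with open(path, "w") as fh:
        fh.write("contig\tstart\tend\tn_sites\tfst\tpi_pop1\tpi_pop2\tpi_ratio\n")
        for w in stats:
            ratio = w.pi_ratio
            fh.write(
                f"{w.contig}\t{w.start}\t{w.end}\t{w.n_sites}\t"
                f"{w.fst:.6g}\t{w.pi_pop1:.6g}\t{w.pi_pop2:.6g}\t"
                f"{'NA' if np.isnan(ratio) else f'{ratio:.6g}'}\n"
            )


_PLATE_COLS = ["well", "ligand_conc_uM", "fnorm", "replicate", "treatment", "aging", "incubation_h", "target_conc_uM"]


def write_plate_csv(series_list: list[BindingSeries], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_PLATE_COLS)
        for s in series_list:
            for k, (conc, f) in enumerate(zip(s.ligand_conc, s.fnorm), start=1):
                w.writerow([k, f"{conc:.8g}", f"{f:.8g}", s.replicate, s.treatment, s.aging, s.incubation_h, s.target_conc])


def read_plate_csv(path) -> list[BindingSeries]:
    df = pd.read_csv(path)
    out = []
    keys = ["treatment", "aging", "incubation_h", "replicate"]
    for vals, sub in df.groupby(keys, sort=True):
        sub = sub.sort_values("well")
        kw = dict(zip(keys, vals))
        out.append(
            BindingSeries(
                ligand_conc=sub["ligand_conc_uM"].to_numpy(),
                fnorm=sub["fnorm"].to_numpy(),
                target_conc=float(sub["target_conc_uM"].iloc[0]) if "target_conc_uM" in sub else 0.089,
                **kw,
            )
        )
    return out


def write_counts_tsv(gp: GenePairCounts, path) -> None:
    """Two-row header: assay line, then sample (group_replicate) line."""
    meta = gp.sample_meta
    with open(path, "w") as fh:
        fh.write("assay\t" + "\t".join(meta["assay"]) + "\n")
        fh.write("gene\t" + "\t".join(f"{g}_{r}" for g, r in zip(meta["group"], meta["replicate"])) + "\n")
        for gene, row in gp.counts.iterrows():
            fh.write(str(gene) + "\t" + "\t".join(map(str, row.to_numpy())) + "\n")


def read_counts_tsv(path) -> GenePairCounts:
    with open(path) as fh:
        assay_row = fh.readline().rstrip("\n").split("\t")[1:]
        sample_row = fh.readline().rstrip("\n").split("\t")[1:]
        genes, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            genes.append(parts[0])
            rows.append([int(x) for x in parts[1:]])
    groups, reps = [], []
    for s in sample_row:
        g, r = s.rsplit("_", 1)
        groups.append(g)
        reps.append(int(r))
    names = [f"{a}_{s}" for a, s in zip(assay_row, sample_row)]
    meta = pd.DataFrame(
        {"assay": assay_row, "group": groups, "replicate": reps},
        index=pd.Index(names, name="sample"),
    )
    counts = pd.DataFrame(rows, index=pd.Index(genes, name="gene"), columns=meta.index)
    return GenePairCounts(counts, meta)


def write_bisulfite_fasta(locus: BisulfiteLocus, path) -> None:
    """FASTA with the reference first, clones after."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seq_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(locus.ref_seq), id=f"{locus.region_id}_ref", description="")]
    records += [
        SeqRecord(Seq(c), id=f"{locus.region_id}_clone{i + 1}", description="")
        for i, c in enumerate(locus.clones)
    ]
    seq_write(records, str(path), "fasta")


def read_bisulfite_fasta(path, region_id: str | None = None, strand: str = "top") -> BisulfiteLocus:
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 2:
        raise ValueError("need a reference record plus >= 1 clone")
    rid = region_id or records[0].id.removesuffix("_ref")
    return BisulfiteLocus(
        region_id=rid,
        ref_seq=str(records[0].seq),
        clones=[str(r.seq) for r in records[1:]],
        strand=strand,
    )


def read_protein_fasta(path):
    from Bio import SeqIO

    from .phylogeny import ProteinAlignment

    records = list(SeqIO.parse(str(path), "fasta"))
    return ProteinAlignment([r.id for r in records], [str(r.seq) for r in records])


_GERM_COLS = ["genotype", "treatment", "replicate", "time_h", "n_germinated", "n_total"]


def write_germination_csv(trials: list[GerminationTrial], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_GERM_COLS)
        for t in trials:
            for tt, n in zip(t.time_h, t.n_germinated):
                w.writerow([t.genotype, t.treatment, t.replicate, tt, int(n), t.n_total])


def read_germination_csv(path) -> list[GerminationTrial]:
    df = pd.read_csv(path)
    out = []
    for (geno, treat, rep), sub in df.groupby(["genotype", "treatment", "replicate"], sort=True):
        sub = sub.sort_values("time_h")
        out.append(
            GerminationTrial(
                genotype=str(geno),
                treatment=str(treat),
                replicate=int(rep),
                time_h=sub["time_h"].to_numpy(),
                n_germinated=sub["n_germinated"].to_numpy(),
                n_total=int(sub["n_total"].iloc[0]),
            )
        )
    return out


def read_ct_csv(path) -> pd.DataFrame:
    """qPCR Ct table: region, genotype, digested (0/1 or bool), replicate, ct."""
    df = pd.read_csv(path)
    df["digested"] = df["digested"].astype(bool)
    return df
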