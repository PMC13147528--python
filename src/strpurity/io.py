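"""Readers and writers for the pipeline's tabular formats.

TSV tables are handled with pandas; BED tracks use the standard 0-based
half-open convention; genotype and SNV files can be read from VCF (via
cyvcf2, allele sequences in REF/ALT, diploid GT per sample) with a TSV
fallback for callers that export flat tables.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .annotate import GenomicInterval, SNVRecord, SistrScore, normalize_chrom
from .filters import LocusGenotypes

__all__ = [
    "read_tsv",
    "write_tsv",
    "read_bed",
    "write_bed",
    "read_genotypes_tsv",
    "write_genotypes_tsv",
    "read_genotypes_vcf",
    "write_genotypes_vcf",
    "read_snvs_vcf",
    "write_snvs_vcf",
    "read_sistr_scores",
]


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_bed(path: str | Path, chrom_style: str = "chr") -> list[GenomicInterval]:
    ivs = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            payload = fields[3] if len(fields) > 3 else None
            ivs.append(GenomicInterval(normalize_chrom(chrom, chrom_style), start, end, payload))
    return ivs


def write_bed(intervals: list[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            name = "" if iv.payload is None else f"\t{iv.payload}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}{name}\n")


# --- genotype tables -----------------------------------------------------

_GT_COLUMNS = ["locus_id", "chrom", "start", "end", "motif", "sample", "allele1", "allele2"]


def read_genotypes_tsv(path: str | Path) -> list[LocusGenotypes]:
    """Long-format TSV: one row per (locus, sample); '.' marks a missing call."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    loci: list[LocusGenotypes] = []
    for (locus_id, chrom, start, end, motif), grp in df.groupby(
        ["locus_id", "chrom", "start", "end", "motif"], sort=False
    ):
        calls: list[tuple[str, str] | None] = []
        for a1, a2 in zip(grp["allele1"], grp["allele2"]):
            if a1 == "." or a2 == "." or pd.isna(a1) or pd.isna(a2):
                calls.append(None)
            else:
                calls.append((a1, a2))
        loci.append(LocusGenotypes(locus_id, motif, calls, chrom, int(start), int(end)))
    return loci


def write_genotypes_tsv(loci: list[LocusGenotypes], path: str | Path,
                        samples: list[str] | None = None) -> None:
    rows = []
    for locus in loci:
        names = samples or [f"S{i}" for i in range(locus.n_samples)]
        for name, call in zip(names, locus.calls):
            a1, a2 = call if call is not None else (".", ".")
            rows.append((locus.locus_id, locus.chrom, locus.start, locus.end,
                         locus.motif, name, a1, a2))
    pd.DataFrame(rows, columns=_GT_COLUMNS).to_csv(path, sep="\t", index=False)


def write_genotypes_vcf(loci: list[LocusGenotypes], path: str | Path,
                        samples: list[str] | None = None) -> None:
    """Minimal VCF with full allele sequences in REF/ALT and GT per sample."""
    n = loci[0].n_samples if loci else 0
    names = samples or [f"S{i}" for i in range(n)]
    chroms = sorted({locus.chrom for locus in loci})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##INFO=<ID=MOTIF,Number=1,Type=String,Description="Repeat motif">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(names) + "\n")
        for locus in sorted(loci, key=lambda x: (x.chrom, x.start)):
            alleles: list[str] = []
            for call in locus.calls:
                if call is not None:
                    for a in call:
                        if a not in alleles:
                            alleles.append(a)
            if not alleles:
                continue
            ref, alts = alleles[0], alleles[1:]
            idx = {a: i for i, a in enumerate(alleles)}
            gts = []
            for call in locus.calls:
                if call is None:
                    gts.append("./.")
                else:
                    gts.append(f"{idx[call[0]]}/{idx[call[1]]}")
            alt_field = ",".join(alts) if alts else "."
            fh.write(f"{locus.chrom}\t{locus.start + 1}\t{locus.locus_id}\t{ref}\t"
                     f"{alt_field}\t.\tPASS\tMOTIF={locus.motif}\tGT\t" + "\t".join(gts) + "\n")


def read_genotypes_vcf(path: str | Path) -> list[LocusGenotypes]:
    import cyvcf2

    loci: list[LocusGenotypes] = []
    vcf = cyvcf2.VCF(str(path))
    for var in vcf:
        alleles = [var.REF, *var.ALT]
        calls: list[tuple[str, str] | None] = []
        for gt in var.genotypes:
            a1, a2 = gt[0], gt[1]
            if a1 < 0 or a2 < 0:
                calls.append(None)
            else:
                calls.append((alleles[a1], alleles[a2]))
        motif = var.INFO.get("MOTIF") or ""
        end = var.start + len(var.REF)
        loci.append(LocusGenotypes(var.ID or f"{var.CHROM}:{var.start}",
                                   motif, calls, var.CHROM, var.start, end))
    vcf.close()
    return loci


# --- SNVs ----------------------------------------------------------------

def write_snvs_vcf(snvs: list[SNVRecord], path: str | Path) -> None:
    chroms = sorted({v.chrom for v in snvs})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AC,Number=A,Type=Integer,Description="Allele count">\n')
        fh.write('##FILTER=<ID=lowq,Description="Failed quality filters">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(snvs, key=lambda x: (x.chrom, x.pos)):
            filt = "PASS" if v.filter_pass else "lowq"
            fh.write(f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\t{filt}\tAC={v.allele_count}\n")


def read_snvs_vcf(path: str | Path) -> list[SNVRecord]:
    import cyvcf2

    out: list[SNVRecord] = []
    vcf = cyvcf2.VCF(str(path))
    for var in vcf:
        ac = var.INFO.get("AC")
        if isinstance(ac, tuple):
            ac = ac[0]
        out.append(SNVRecord(
            chrom=var.CHROM,
            pos=var.start,
            ref=var.REF,
            alt=var.ALT[0] if var.ALT else ".",
            allele_count=int(ac) if ac is not None else 1,
            filter_pass=var.FILTER is None,  # cyvcf2 reports PASS as None
        ))
    vcf.close()
    return out


def read_sample_names(path: str | Path) -> list[str]:
    """Sample names, in call order, from a genotype VCF or long TSV."""
    if str(path).endswith(".vcf"):
        import cyvcf2

        vcf = cyvcf2.VCF(str(path))
        names = list(vcf.samples)
        vcf.close()
        return names
    return list(pd.read_csv(path, sep="\t", dtype=str)["sample"].unique())


def read_sistr_scores(path: str | Path) -> dict[str, SistrScore]:
    df = pd.read_csv(path, sep="\t")
    return {
        row["locus_id"]: SistrScore(row["locus_id"], float(row["s_median"]),
                                    float(row["ci_width"]))
        for _, row in df.iterrows()
    }
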