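"""Reading and writing the file formats the pipeline stages exchange.

Pooled allele depths travel as VCF 4.2 (FORMAT ``AD`` for the two parental
alleles, FORMAT ``BC`` for the four base depths A,C,G,T) or as a flat TSV
with one row per SNP.  VCF is read through pysam; the writer emits plain
text since pooled records are flat and fixed-width.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pysam

POOL_COLUMNS = ["chrom", "pos", "ref", "alt"] + [
    f"{pool}_{x}" for pool in ("high", "low") for x in ("A", "C", "G", "T", "M", "P")
]

_VCF_HEADER_LINES = [
    "##fileformat=VCFv4.2",
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Depths of the maternal (ref) and paternal (alt) alleles">',
    '##FORMAT=<ID=BC,Number=4,Type=Integer,Description="Read depth of bases A,C,G,T">',
]


def write_pool_vcf(counts: pd.DataFrame, path: str | Path) -> None:
    """Write a pooled-bulk VCF: parents JF914/JF173 plus HIGH and LOW pools.

    The maternal allele is the REF column; parents are written as the fixed
    homozygotes 0/0 and 1/1.
    """
    counts = counts.reset_index(drop=True)
    with open(path, "w") as fh:
        for line in _VCF_HEADER_LINES:
            fh.write(line + "\n")
        for chrom, sub in counts.groupby("chrom", sort=False):
            length = int(sub["pos"].max()) if len(sub) else 1
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            "JF914\tJF173\tHIGH\tLOW\n"
        )
        for row in counts.itertuples(index=False):
            high_bc = ",".join(
                str(getattr(row, f"high_{b}")) for b in ("A", "C", "G", "T")
            )
            low_bc = ",".join(
                str(getattr(row, f"low_{b}")) for b in ("A", "C", "G", "T")
            )
            fields = [
                row.chrom,
                str(row.pos),
                ".",
                row.ref,
                row.alt,
                ".",
                "PASS",
                ".",
                "GT:AD:BC",
                "0/0:.:.",
                "1/1:.:.",
                f"./.:{row.high_M},{row.high_P}:{high_bc}",
                f"./.:{row.low_M},{row.low_P}:{low_bc}",
            ]
            fh.write("\t".join(fields) + "\n")


def read_pool_vcf(path: str | Path) -> pd.DataFrame:
    """Read a pooled-bulk VCF back into a pool-allele-counts table."""
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            row = {
                "chrom": rec.chrom,
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": rec.alts[0] if rec.alts else ".",
            }
            for pool, sample in (("high", "HIGH"), ("low", "LOW")):
                ad = rec.samples[sample].get("AD")
                bc = rec.samples[sample].get("BC")
                for i, base in enumerate(("A", "C", "G", "T")):
                    row[f"{pool}_{base}"] = int(bc[i])
                row[f"{pool}_M"] = int(ad[0])
                row[f"{pool}_P"] = int(ad[1])
            rows.append(row)
    return pd.DataFrame(rows, columns=POOL_COLUMNS).astype(
        {c: np.int64 for c in POOL_COLUMNS if c not in ("chrom", "ref", "alt")}
    )


def write_pool_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts[POOL_COLUMNS].to_csv(path, sep="\t", index=False)


def read_pool_counts_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def read_phenotypes_tsv(path: str | Path) -> pd.DataFrame:
    """Phenotype table with at least plant_id and NFFB columns."""
    df = pd.read_csv(path, sep="\t")
    missing = {"plant_id", "NFFB"} - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    return df


def read_qtl_intervals(path: str | Path) -> pd.DataFrame:
    """BED-like TSV of QTL intervals: chrom, start, end (1-based inclusive), name."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "name"],
    )
    return df
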