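"""Plain-text interchange formats: VCF v4.2, GTF, TSV tables.

Coordinates are 0-based half-open in memory and 1-based in VCF/GTF on disk.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    '##FORMAT=<ID=AD,Number=2,Type=Integer,Description="Ref,alt read depth">\n'
    '##FORMAT=<ID=PAC,Number=2,Type=Integer,Description="Phasable alt reads on hap1,hap2">\n'
    '##FORMAT=<ID=PRC,Number=2,Type=Integer,Description="Phasable ref reads on hap1,hap2">\n'
    '##INFO=<ID=HAP,Number=1,Type=Integer,Description="Truth haplotype (1/2)">\n'
    '##INFO=<ID=COPY,Number=1,Type=Integer,Description="Truth origin copy (1/2)">\n'
    '##INFO=<ID=CTX,Number=1,Type=String,Description="Trinucleotide class">\n'
)


def write_germline_vcf(hets: pd.DataFrame, path, sample: str = "donor") -> None:
    """Phased germline hets: GT 1|0 when the alt rides haplotype 1."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for r in hets.itertuples(index=False):
            gt = "1|0" if r.hap == 0 else "0|1"
            fh.write(f"{r.chrom}\t{r.pos + 1}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t.\tGT\t{gt}\n")


def write_truth_vcf(somatic: pd.DataFrame, path, sample: str = "cell") -> None:
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for r in somatic.itertuples(index=False):
            info = f"HAP={r.hap + 1};COPY={r.origin + 1};CTX={r.context}"
            fh.write(f"{r.chrom}\t{r.pos + 1}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t{info}\tGT\t0/1\n")


def write_calls_vcf(calls: pd.DataFrame, path, sample: str = "cell") -> None:
    """Somatic calls with phasable read counts in FORMAT."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for r in calls.itertuples(index=False):
            fmt = (
                f"0/1:{r.ref_reads},{r.alt_reads}:"
                f"{r.c_alt_h1},{r.c_alt_h2}:{r.c_ref_h1},{r.c_ref_h2}"
            )
            fh.write(
                f"{r.chrom}\t{r.pos + 1}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t.\t"
                f"GT:AD:PAC:PRC\t{fmt}\n"
            )


def read_vcf(path) -> pd.DataFrame:
    """Read a (plain-text) VCF into a DataFrame with 0-based positions."""
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            row = {
                "chrom": rec.chrom,
                "pos": rec.pos - 1,
                "ref": rec.ref,
                "alt": rec.alts[0] if rec.alts else ".",
            }
            for k in ("HAP", "COPY", "CTX"):
                if k in rec.info:
                    row[k.lower()] = rec.info[k]
            for name in rec.samples:
                gt = rec.samples[name].get("GT")
                if gt is not None and rec.samples[name].phased:
                    row["hap"] = 0 if gt[0] == 1 else 1
            rows.append(row)
    return pd.DataFrame(rows)


def write_evidence_tsv(evidence: pd.DataFrame, path) -> None:
    evidence.to_csv(path, sep="\t", index=False)


def read_evidence_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_gtf(genes: pd.DataFrame, cds: pd.DataFrame, path, source: str = "cardiosnv") -> None:
    """One transcript per gene: gene/transcript/exon(CDS) features."""
    with open(path, "w") as fh:
        for g in genes.itertuples(index=False):
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{g.chrom}\t{source}\ttranscript\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            sub = cds[cds["gene_id"] == g.gene_id].sort_values("start")
            total = 0
            for c in sub.itertuples(index=False):
                frame = (3 - total % 3) % 3 if g.strand == "-" else total % 3
                fh.write(
                    f"{g.chrom}\t{source}\tCDS\t{c.start + 1}\t{c.end}\t.\t{g.strand}\t{frame}\t{attrs}\n"
                )
                total += c.end - c.start


def read_gtf(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a GTF into (genes, cds) frames with 0-based half-open coordinates."""
    import pyranges

    df = pyranges.read_gtf(str(path)).df
    genes = (
        df[df["Feature"] == "gene"]
        .rename(columns={"Chromosome": "chrom", "Start": "start", "End": "end", "Strand": "strand"})
        [["gene_id", "chrom", "strand", "start", "end"]]
        .reset_index(drop=True)
    )
    cds = (
        df[df["Feature"] == "CDS"]
        .rename(columns={"Start": "start", "End": "end"})
        [["gene_id", "start", "end"]]
        .reset_index(drop=True)
    )
    return genes, cds
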