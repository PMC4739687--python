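"""Readers and writers for the pipeline's file formats.

Internal coordinates are 1-based inclusive everywhere; exporters
convert to each format's native convention (BED is 0-based half-open,
GFF3 and VCF are 1-based). All outputs are plain text.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .sim import Gene, ReferenceGenome
from .variants import VariantCall

PathLike = Union[str, Path]

__all__ = [
    "write_fasta", "read_fasta",
    "write_gff3", "read_gff3",
    "write_bed", "read_bed",
    "write_vcf", "read_vcf",
    "write_tsv", "read_tsv",
    "write_genome",
]


def write_fasta(path: PathLike, sequences: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(path: PathLike, genes: Iterable[Gene]) -> None:
    """Write gene models as GFF3 (gene + CDS features, 1-based)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.scaffold}\tsuperbsa\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            phase = 0
            for s, e in sorted(g.cds):
                fh.write(
                    f"{g.scaffold}\tsuperbsa\tCDS\t{s}\t{e}\t.\t{g.strand}\t{phase}\t"
                    f"Parent={g.gene_id}\n"
                )
                phase = (3 - ((e - s + 1 - phase) % 3)) % 3


def read_gff3(path: PathLike) -> list[Gene]:
    """Read gene models written by :func:`write_gff3` (gene + CDS features)."""
    genes: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            sc, _src, ftype, start, end, _score, strand, _phase, attrs = line.rstrip("\n").split("\t")
            fields = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if ftype == "gene":
                gid = fields["ID"]
                genes[gid] = {
                    "scaffold": sc, "start": int(start), "end": int(end),
                    "strand": strand, "cds": [],
                }
                order.append(gid)
            elif ftype == "CDS":
                genes[fields["Parent"]]["cds"].append((int(start), int(end)))
    return [
        Gene(gene_id=gid, scaffold=d["scaffold"], start=d["start"], end=d["end"],
             strand=d["strand"], cds=tuple(sorted(d["cds"])))
        for gid, d in ((g, genes[g]) for g in order)
    ]


def write_bed(path: PathLike, intervals: dict[str, list[tuple[int, int]]]) -> None:
    """Write 1-based inclusive intervals as 0-based half-open BED."""
    with open(path, "w") as fh:
        for sc in sorted(intervals):
            for s, e in sorted(intervals[sc]):
                fh.write(f"{sc}\t{s - 1}\t{e}\n")


def read_bed(path: PathLike) -> dict[str, list[tuple[int, int]]]:
    """Read BED into 1-based inclusive intervals per scaffold."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            sc, s, e = line.split()[:3]
            out.setdefault(sc, []).append((int(s) + 1, int(e)))
    return out


def write_vcf(path: PathLike, calls: Iterable[VariantCall],
              samples: tuple[str, str] = ("sweet", "sour")) -> None:
    """Write truth variants as a two-sample VCF.

    The carrier parent gets GT 1/1 (parents are homozygous), the other
    0/0; DP carries the call depth and the SVTYPE/END info fields mark
    structural calls.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="SV end">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for v in sorted(calls, key=lambda c: (c.scaffold, c.position)):
            info = "."
            if v.kind != "SNP":
                info = f"SVTYPE={v.kind}"
                if v.end is not None:
                    info += f";END={v.end}"
            gts = []
            for s in samples:
                zyg = "0/1" if v.zygosity == "het" else "1/1"
                gts.append(f"{zyg if s == v.sample else '0/0'}:{v.depth}")
            fh.write(
                f"{v.scaffold}\t{v.position}\t.\t{v.ref}\t{v.alt}\t{v.quality:g}\t"
                f"PASS\t{info}\tGT:DP\t" + "\t".join(gts) + "\n"
            )


def read_vcf(path: PathLike) -> list[VariantCall]:
    """Read a VCF into per-sample calls (one VariantCall per carrier sample).

    Depth comes from the sample DP field, quality from QUAL, zygosity
    from GT; samples with genotype 0/0 or ./. contribute no call.
    """
    calls: list[VariantCall] = []
    samples: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                samples = line.rstrip("\n").split("\t")[9:]
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, pos, _id, ref, alt, qual, _filt, info = parts[:8]
            fmt = parts[8].split(":")
            kind = "SNP"
            end = None
            for kv in info.split(";"):
                if kv.startswith("SVTYPE="):
                    kind = kv.split("=", 1)[1]
                elif kv.startswith("END="):
                    end = int(kv.split("=", 1)[1])
            for sample, cell in zip(samples, parts[9:]):
                vals = dict(zip(fmt, cell.split(":")))
                gt = vals.get("GT", "./.")
                if gt in ("0/0", "0|0", "./."):
                    continue
                zyg = "hom" if gt in ("1/1", "1|1") else "het"
                calls.append(
                    VariantCall(
                        sample=sample, scaffold=chrom, position=int(pos), kind=kind,
                        ref=ref, alt=alt, depth=int(vals.get("DP", 0)),
                        quality=float(qual) if qual != "." else 0.0,
                        zygosity=zyg, end=end,
                    )
                )
    return calls


def write_tsv(path: PathLike, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_tsv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_genome(outdir: PathLike, genome: ReferenceGenome) -> None:
    """Export a reference as FASTA + GFF3 + repeat BED into a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(outdir / "reference.fasta", genome.scaffolds)
    write_gff3(outdir / "genes.gff3", genome.genes)
    write_bed(outdir / "repeats.bed", genome.repeats)
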