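"""Readers and writers for the plain-text formats the toolkit exchanges:
FASTA, phased VCF (PS-tagged), BED, BEDPE, PAF segment maps, Hi-C pairs text
and TSV tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .assembly import SegmentMap
from .phasing import PhaseBlock
from .simulate import ToyGenome
from .sv import LEFT, RIGHT, Breakend, SvCall


def write_fasta(path, records: dict[str, str]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(s), id=name, description="") for name, s in records.items()),
        str(path),
        "fasta",
    )


def read_fasta(path) -> dict[str, str]:
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# phased VCF
# ---------------------------------------------------------------------------

_VCF_HEADER = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE
"""


def write_phased_vcf(path, genome: ToyGenome) -> None:
    """Phased het SNPs, one phase set (PS) per phase block.

    REF is the hap1 allele; GT is ``0|1`` when hap1 carries allele A of its
    block and ``1|0`` otherwise, so allele A is always the first GT field.
    """
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for rec in genome.chromosomes:
            ori = dict(zip(rec.phase_blocks["block_id"], rec.phase_blocks["hap1_is_A"]))
            ps_of = dict(zip(rec.phase_blocks["block_id"], rec.phase_blocks["start"]))
            for s in rec.snps.itertuples(index=False):
                gt = "0|1" if ori[s.block_id] else "1|0"
                fh.write(
                    f"{rec.name}\t{s.pos + 1}\t.\t{s.allele_hap1}\t{s.allele_hap2}"
                    f"\t.\tPASS\t.\tGT:PS\t{gt}:{ps_of[s.block_id]}\n"
                )


def read_phased_vcf(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            chrom, pos, _, ref, alt, _, _, _, fmt, sample = line.rstrip("\n").split("\t")
            fields = dict(zip(fmt.split(":"), sample.split(":")))
            rows.append(
                (chrom, int(pos) - 1, ref, alt, fields["GT"], int(fields["PS"]))
            )
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "gt", "ps"])


def phase_blocks_from_vcf(
    vcf: pd.DataFrame, observations: pd.DataFrame | None = None
) -> list[PhaseBlock]:
    """Rebuild PhaseBlocks (with optional read pileups) from a phased VCF table."""
    blocks = []
    for (chrom, ps), grp in vcf.groupby(["chrom", "ps"]):
        grp = grp.sort_values("pos")
        rows = []
        for s in grp.itertuples(index=False):
            a_allele = s.ref if s.gt == "0|1" else s.alt
            b_allele = s.alt if s.gt == "0|1" else s.ref
            depth, vaf = 0, np.nan
            if observations is not None:
                at = observations[
                    (observations["chrom"] == chrom) & (observations["pos"] == s.pos)
                ]
                depth = len(at)
                if depth:
                    vaf = float((at["allele"] == a_allele).mean())
            rows.append((s.pos, a_allele, b_allele, vaf, depth))
        snps = pd.DataFrame(rows, columns=["pos", "allele_A", "allele_B", "vaf_A", "depth"])
        blocks.append(
            PhaseBlock(f"{chrom}_ps{ps}", chrom, int(grp["pos"].min()),
                       int(grp["pos"].max()) + 1, snps)
        )
    return blocks


# ---------------------------------------------------------------------------
# BED / BEDPE / pairs / PAF
# ---------------------------------------------------------------------------

_STRAND_OF_SIDE = {LEFT: "+", RIGHT: "-"}
_SIDE_OF_STRAND = {"+": LEFT, "-": RIGHT}


def write_bed(path, intervals, chrom: str | None = None) -> None:
    """Intervals as BED3(+1): accepts (start, end[, extra]) or (chrom, start, end[, extra])."""
    with open(path, "w") as fh:
        for iv in intervals:
            if chrom is not None:
                fh.write("\t".join(str(x) for x in (chrom, *iv)) + "\n")
            else:
                fh.write("\t".join(str(x) for x in iv) + "\n")


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(str(path), sep="\t", header=None)
    cols = ["chrom", "start", "end", "name", "score"][: df.shape[1]]
    df.columns = cols + list(df.columns[len(cols):])
    return df


def write_bedpe(path, svs: list[SvCall]) -> None:
    with open(path, "w") as fh:
        for i, c in enumerate(svs):
            b1, b2 = c.breakend1, c.breakend2
            fh.write(
                f"{b1.chrom}\t{b1.pos}\t{b1.pos + 1}\t{b2.chrom}\t{b2.pos}"
                f"\t{b2.pos + 1}\t{c.sv_class.replace(' ', '_')}_{i}\t{c.support}"
                f"\t{_STRAND_OF_SIDE[b1.side]}\t{_STRAND_OF_SIDE[b2.side]}"
                f"\t{c.status}\t{c.haplotype or '.'}\n"
            )


def read_bedpe(path) -> list[SvCall]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            b1 = Breakend(f[0], int(f[1]), _SIDE_OF_STRAND[f[8]])
            b2 = Breakend(f[3], int(f[4]), _SIDE_OF_STRAND[f[9]])
            status = f[10] if len(f) > 10 else "candidate"
            hap = None if len(f) <= 11 or f[11] == "." else f[11]
            out.append(
                SvCall(b1, b2, support=int(f[7]), status=status, haplotype=hap)
            )
    return out


def write_pairs(path, pairs: pd.DataFrame) -> None:
    """Hi-C pairs as 4-column text: chrom1 pos1 chrom2 pos2."""
    pairs[["source1", "pos1", "source2", "pos2"]].to_csv(
        str(path), sep="\t", header=False, index=False
    )


def read_pairs(path) -> pd.DataFrame:
    return pd.read_csv(
        str(path), sep="\t", header=None,
        names=["source1", "pos1", "source2", "pos2"],
    )


def write_paf(path, smap: SegmentMap, ref_length: int | None = None) -> None:
    """A segment map as PAF records (one line per segment)."""
    with open(path, "w") as fh:
        for s in smap.segments:
            alen = s.contig_len
            fh.write(
                f"{smap.contig}\t{smap.contig_length}\t{s.contig_start}"
                f"\t{s.contig_end}\t{s.strand}\t{s.chrom}\t{ref_length or 0}"
                f"\t{s.ref_start}\t{s.ref_end}\t{alen}\t{alen}\t60\n"
            )


def read_paf(path) -> pd.DataFrame:
    df = pd.read_csv(str(path), sep="\t", header=None, usecols=range(12))
    df.columns = [
        "qname", "qlen", "qstart", "qend", "strand", "tname", "tlen",
        "tstart", "tend", "nmatch", "alnlen", "mapq",
    ]
    return df


def write_tsv(path, df: pd.DataFrame) -> None:
    df.to_csv(str(path), sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(str(path), sep="\t")
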