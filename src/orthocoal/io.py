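"""Readers and writers for the pipeline's file formats.

FASTA via Biopython, VCF via pysam, cluster files in the OrthoMCL groups
dialect (``clusterID: taxon|contig taxon|contig ...``), block tables and
paralog-pair lists as TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .coalcore import SiteClassCounts
from .haploblocks import Block, VcfVariant
from .models import CLASSES
from .orthofilter import ClusterSet, VERDICT_PARALOG, VERDICT_SUBGENE

BLOCK_COLUMNS = ["orthogroup", "n_sites", *CLASSES, "four_gamete_pass"]


# -- FASTA ------------------------------------------------------------------

def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: dict) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# -- OrthoMCL-style groups --------------------------------------------------

def read_groups(path, inflation: float) -> ClusterSet:
    clusters = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cluster_id, _, rest = line.partition(":")
        members = []
        for token in rest.split():
            taxon, _, contig = token.partition("|")
            members.append((taxon, contig))
        clusters[cluster_id.strip()] = tuple(members)
    return ClusterSet(inflation=inflation, clusters=clusters)


def write_groups(path, cluster_set: ClusterSet) -> None:
    with open(path, "w") as fh:
        for cluster_id, members in cluster_set.clusters.items():
            tokens = " ".join(f"{taxon}|{contig}" for taxon, contig in members)
            fh.write(f"{cluster_id}: {tokens}\n")


# -- paralog pairs ----------------------------------------------------------

def read_paralog_pairs(path) -> set:
    """Unordered within-taxon contig pairs with a paralog verdict."""
    df = pd.read_csv(path, sep="\t")
    pairs = set()
    for row in df.itertuples(index=False):
        if row.verdict in (VERDICT_PARALOG, VERDICT_SUBGENE):
            pairs.add(
                frozenset({(row.taxon, row.contig_a), (row.taxon, row.contig_b)})
            )
    return pairs


def write_paralog_pairs(path, rows) -> None:
    """``rows``: iterables of (taxon, contig_a, contig_b, verdict)."""
    pd.DataFrame(rows, columns=["taxon", "contig_a", "contig_b", "verdict"]).to_csv(
        path, sep="\t", index=False
    )


# -- VCF --------------------------------------------------------------------

def read_vcf(path) -> dict:
    """Per-contig lists of :class:`VcfVariant` from a VCF 4.x file."""
    import pysam

    out: dict[str, list[VcfVariant]] = {}
    with pysam.VariantFile(str(path)) as vcf:
        sample = next(iter(vcf.header.samples))
        for rec in vcf:
            gt = rec.samples[sample]["GT"]
            passed = (not rec.filter.keys()) or ("PASS" in rec.filter.keys())
            out.setdefault(rec.chrom, []).append(
                VcfVariant(
                    contig=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alts=tuple(rec.alts or ()),
                    genotype=tuple(g for g in gt if g is not None),
                    passed=passed,
                )
            )
    return out


def write_vcf(path, contig_lengths: dict, variants) -> None:
    """Write a minimal single-sample VCF 4.2 text file."""
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c},length={l}>" for c, l in contig_lengths.items()]
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample1")
    for v in sorted(variants, key=lambda v: (v.contig, v.pos)):
        gt = "/".join(str(g) for g in v.genotype)
        lines.append(
            f"{v.contig}\t{v.pos}\t.\t{v.ref}\t{','.join(v.alts)}\t99\t"
            f"{'PASS' if v.passed else 'FAIL'}\t.\tGT\t{gt}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# -- block tables -----------------------------------------------------------

def blocks_to_frame(blocks) -> pd.DataFrame:
    rows = [
        {
            "orthogroup": b.orthogroup_id,
            "n_sites": b.n_sites,
            **{c: b.counts[c] for c in CLASSES},
            "four_gamete_pass": b.four_gamete_pass,
        }
        for b in blocks
    ]
    return pd.DataFrame(rows, columns=BLOCK_COLUMNS)


def frame_to_blocks(df: pd.DataFrame) -> list:
    return [
        Block(
            orthogroup_id=str(row.orthogroup),
            counts=SiteClassCounts(*(int(getattr(row, c)) for c in CLASSES)),
            n_sites=int(row.n_sites),
            four_gamete_pass=bool(row.four_gamete_pass),
        )
        for row in df.itertuples(index=False)
    ]


def write_block_table(path, blocks) -> None:
    df = blocks if isinstance(blocks, pd.DataFrame) else blocks_to_frame(blocks)
    df.to_csv(path, sep="\t", index=False)


def read_block_table(path) -> list:
    return frame_to_blocks(pd.read_csv(path, sep="\t"))


def write_json(path, payload) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
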