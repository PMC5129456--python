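"""From reference CDS + VCF to blocks of classified fourfold-degenerate sites.

For each taxon one diploid individual is represented by its reference CDS and
an alternate haplotype obtained by applying heterozygous biallelic SNPs from
the taxon's VCF.  Indel records and genotypes lacking the reference allele
(alternate homozygotes, typically assembly errors when reads and reference
come from the same individual) are counted and dropped.

Cross-taxon peptide alignments are back-translated into four-row codon
alignments (ref and alt haplotype per taxon).  A column is a usable fourfold
degenerate site when it is a third codon position, its codon is gap-free in
every row, the first two codon positions agree across all rows and the codon
family is fourfold degenerate.  Each such site is classified by the folded
pattern of the four bases, and runs of 150 consecutive fourfold sites become
blocks ``k = {kA, kB, kAB, kAABB}`` with a four-gamete compatibility flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .coalcore import SiteClassCounts
from .models import CLASSES, K_A, K_AB, K_AABB, K_B

log = logging.getLogger(__name__)

INVARIANT = "invariant"
EXCLUDED = "excluded_multiallelic"

_BASES = frozenset("ACGT")

#: codon prefixes whose four completions encode the same amino acid
FOURFOLD_PREFIXES = frozenset(
    prefix
    for prefix in {c[:2] for c in standard_dna_table.forward_table}
    if len(
        {
            standard_dna_table.forward_table.get(prefix + b)
            for b in "ACGT"
            if prefix + b not in standard_dna_table.stop_codons
        }
    )
    == 1
    and all(prefix + b not in standard_dna_table.stop_codons for b in "ACGT")
)


@dataclass(frozen=True)
class VcfVariant:
    """The slice of a VCF record this pipeline consumes."""

    contig: str
    pos: int  # 1-based, per VCF convention
    ref: str
    alts: tuple[str, ...]
    genotype: tuple[int, ...]
    passed: bool = True


@dataclass(frozen=True)
class HaplotypePair:
    taxon: str
    ref_seq: str
    alt_seq: str
    n_het_applied: int = 0
    n_indels_dropped: int = 0
    n_alt_homozygotes_dropped: int = 0

    def __post_init__(self) -> None:
        if len(self.ref_seq) != len(self.alt_seq):
            raise ValueError("ref and alt haplotypes differ in length")


@dataclass(frozen=True)
class CodonAlignment:
    """Four aligned coding rows: (A ref, A alt, B ref, B alt)."""

    orthogroup_id: str
    a_ref: str
    a_alt: str
    b_ref: str
    b_alt: str

    def __post_init__(self) -> None:
        n = len(self.a_ref)
        if any(len(r) != n for r in (self.a_alt, self.b_ref, self.b_alt)):
            raise ValueError("alignment rows differ in length")
        if n % 3:
            raise ValueError("alignment length not a codon multiple")

    @property
    def rows(self) -> tuple[str, str, str, str]:
        return (self.a_ref, self.a_alt, self.b_ref, self.b_alt)

    def __len__(self) -> int:
        return len(self.a_ref)


@dataclass(frozen=True)
class SiteClassification:
    column: int
    klass: str


@dataclass(frozen=True)
class Block:
    orthogroup_id: str
    counts: SiteClassCounts
    n_sites: int = 150
    four_gamete_pass: bool = True

    def __post_init__(self) -> None:
        if self.counts.total > self.n_sites:
            raise ValueError("more classified mutations than sites in block")


# ---------------------------------------------------------------------------
# haplotypes
# ---------------------------------------------------------------------------

def apply_vcf_haplotype(
    reference_cds: str, variants, taxon: str = "", contig: str = ""
) -> HaplotypePair:
    """Construct the alternate haplotype for one contig from VCF records.

    Heterozygous biallelic SNPs (genotype 0/1) are substituted into the
    alternate sequence; indels and alternate-homozygote genotypes are counted
    and skipped.
    """
    ref = reference_cds.upper()
    alt = list(ref)
    n_het = n_indel = n_althom = 0
    for v in variants:
        if not v.passed:
            continue
        if v.pos < 1 or v.pos > len(ref):
            raise ValueError(
                f"VCF position {v.pos} outside contig {contig or v.contig} "
                f"of length {len(ref)}"
            )
        if len(v.ref) != 1 or any(len(a) != 1 for a in v.alts):
            n_indel += 1
            continue
        if 0 not in v.genotype:
            n_althom += 1
            continue
        if set(v.genotype) == {0}:
            continue
        alleles = (v.ref,) + v.alts
        alt_allele = next(alleles[g] for g in v.genotype if g != 0)
        base = ref[v.pos - 1]
        if base not in _BASES or alt_allele not in _BASES:
            log.warning(
                "skipping variant with non-ACGT base at %s:%d", contig or v.contig, v.pos
            )
            continue
        if v.ref != base:
            log.warning(
                "VCF REF %s disagrees with reference %s at %s:%d; record skipped",
                v.ref, base, contig or v.contig, v.pos,
            )
            continue
        alt[v.pos - 1] = alt_allele
        n_het += 1
    return HaplotypePair(
        taxon=taxon,
        ref_seq=ref,
        alt_seq="".join(alt),
        n_het_applied=n_het,
        n_indels_dropped=n_indel,
        n_alt_homozygotes_dropped=n_althom,
    )


# ---------------------------------------------------------------------------
# codon alignment
# ---------------------------------------------------------------------------

def _backtranslate(peptide_row: str, cds: str, orthogroup_id: str) -> str:
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    expected = peptide_row.replace("-", "")
    if len(codons) != len(expected):
        raise ValueError(
            f"{orthogroup_id}: CDS has {len(codons)} codons but peptide row "
            f"has {len(expected)} residues"
        )
    out = []
    it = iter(enumerate(codons))
    for aa in peptide_row:
        if aa == "-":
            out.append("---")
            continue
        idx, codon = next(it)
        translated = str(Seq(codon).translate())
        if translated != aa:
            raise ValueError(
                f"{orthogroup_id}: codon {idx} ({codon}) translates to "
                f"{translated}, peptide says {aa}"
            )
        out.append(codon)
    return "".join(out)


def build_codon_alignment(
    peptide_alignment: tuple[str, str],
    cds_a: str,
    cds_b: str,
    hap_a: HaplotypePair,
    hap_b: HaplotypePair,
    orthogroup_id: str = "",
) -> CodonAlignment:
    """Back-translate a two-row peptide alignment into a four-row codon
    alignment (ref and alt haplotype per taxon share the taxon's gaps)."""
    row_a, row_b = (r.upper() for r in peptide_alignment)
    if len(row_a) != len(row_b):
        raise ValueError("peptide rows differ in length")
    for name, cds, hap in (("A", cds_a, hap_a), ("B", cds_b, hap_b)):
        if hap.ref_seq != cds.upper():
            raise ValueError(
                f"{orthogroup_id}: haplotype pair for taxon {name} does not "
                "match its CDS"
            )
    a_ref = _backtranslate(row_a, cds_a.upper(), orthogroup_id)
    b_ref = _backtranslate(row_b, cds_b.upper(), orthogroup_id)
    a_alt = _apply_gap_structure(a_ref, hap_a.alt_seq)
    b_alt = _apply_gap_structure(b_ref, hap_b.alt_seq)
    return CodonAlignment(orthogroup_id, a_ref, a_alt, b_ref, b_alt)


def _apply_gap_structure(gapped_ref: str, alt_seq: str) -> str:
    out = []
    i = 0
    for ch in gapped_ref:
        if ch == "-":
            out.append("-")
        else:
            out.append(alt_seq[i])
            i += 1
    return "".join(out)


def fourfold_sites(alignment: CodonAlignment) -> list[int]:
    """Alignment columns that are usable fourfold-degenerate third positions."""
    rows = alignment.rows
    out = []
    for start in range(0, len(alignment), 3):
        codons = [r[start : start + 3] for r in rows]
        if any("-" in c for c in codons):
            continue
        prefixes = {c[:2] for c in codons}
        if len(prefixes) != 1:
            continue
        if next(iter(prefixes)) in FOURFOLD_PREFIXES:
            out.append(start + 2)
    return out


def classify_site(bases: tuple[str, str, str, str]) -> str:
    """Folded class of one column given (a_ref, a_alt, b_ref, b_alt)."""
    bases = tuple(b.upper() for b in bases)
    if any(b not in _BASES for b in bases):
        log.info("excluding column with gap/ambiguity %s", bases)
        return EXCLUDED
    a_ref, a_alt, b_ref, b_alt = bases
    alleles = set(bases)
    if len(alleles) == 1:
        return INVARIANT
    if len(alleles) > 2:
        return EXCLUDED
    het_a = a_ref != a_alt
    het_b = b_ref != b_alt
    if het_a and het_b:
        return K_AB
    if het_a:
        return K_A
    if het_b:
        return K_B
    return K_AABB


def classify_alignment(alignment: CodonAlignment) -> list[SiteClassification]:
    """Classify every usable fourfold site of the alignment, in order."""
    rows = alignment.rows
    return [
        SiteClassification(col, classify_site(tuple(r[col] for r in rows)))
        for col in fourfold_sites(alignment)
    ]


# ---------------------------------------------------------------------------
# blocks
# ---------------------------------------------------------------------------

def four_gamete_pass(counts: SiteClassCounts) -> bool:
    """Without phase, the only detectable four-gamete violation is the joint
    presence of a shared-heterozygous site and a fixed difference."""
    return not (counts.kAB > 0 and counts.kAABB > 0)


def make_blocks(
    classified,
    orthogroup_id: str,
    block_size: int = 150,
    policy: str = "first_block_per_orthogroup",
) -> list[Block]:
    """Assemble blocks of ``block_size`` consecutive fourfold sites.

    'Consecutive' refers to the ordered sequence of qualifying fourfold
    sites; excluded multiallelic columns still occupy a slot in the block
    span but contribute to no mutation class.
    """
    if policy not in ("first_block_per_orthogroup", "all_blocks"):
        raise ValueError(f"unknown block policy {policy!r}")
    sites = list(classified)
    blocks = []
    for start in range(0, len(sites) - block_size + 1, block_size):
        chunk = sites[start : start + block_size]
        tally = dict.fromkeys(CLASSES, 0)
        for site in chunk:
            if site.klass in tally:
                tally[site.klass] += 1
        counts = SiteClassCounts(**tally)
        blocks.append(
            Block(
                orthogroup_id=orthogroup_id,
                counts=counts,
                n_sites=block_size,
                four_gamete_pass=four_gamete_pass(counts),
            )
        )
        if policy == "first_block_per_orthogroup":
            break
    return blocks


def summarize_sfs(
    blocks,
    mode: str = "all_sites",
    seed: int | None = None,
) -> dict:
    """Average per-site frequencies of the four classes across blocks.

    ``all_sites``: frequency_c = sum k_c / (n_blocks * n_sites).
    ``one_variable_site_per_block``: one variable site drawn uniformly per
    block that has any; reported as per-class counts plus the invariant
    complement (blocks without variable sites).
    """
    blocks = list(blocks)
    if not blocks:
        raise ValueError("no blocks to summarize")
    if mode == "all_sites":
        total_sites = sum(b.n_sites for b in blocks)
        freqs = {
            c: sum(b.counts[c] for b in blocks) / total_sites for c in CLASSES
        }
        return {"mode": mode, "n_blocks": len(blocks), "frequencies": freqs}
    if mode == "one_variable_site_per_block":
        rng = np.random.default_rng(seed)
        counts = dict.fromkeys(CLASSES, 0)
        n_invariant = 0
        for b in blocks:
            k = np.array([b.counts[c] for c in CLASSES], dtype=float)
            if k.sum() == 0:
                n_invariant += 1
                continue
            drawn = rng.choice(len(CLASSES), p=k / k.sum())
            counts[CLASSES[drawn]] += 1
        return {
            "mode": mode,
            "n_blocks": len(blocks),
            "counts": counts,
            "invariant_blocks": n_invariant,
            "seed": seed,
        }
    raise ValueError(f"unknown mode {mode!r}")
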