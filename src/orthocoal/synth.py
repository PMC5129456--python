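"""Synthetic data with the statistical structure the pipeline assumes.

Two levels are provided.  :func:`simulate_block_table` draws blockwise
mutation configurations directly from the structured-coalescent simulator —
the input the inference stage consumes.  :func:`simulate_fixture` goes
further back and fabricates the upstream files (CDS and peptide FASTA per
taxon, per-taxon VCFs, cluster files over an inflation grid, contig
metadata), planting paralog pairs, splice isoforms, droppable VCF records
and per-block mutation configurations whose ground truth is emitted
alongside, so the whole chain orthofilter -> haploblocks -> infer can be
exercised end to end without any external data.

Defaults emulate the study conditions of the focal toad comparison: a
per-site ancestral theta of about 0.0015, an old split (T ~ 20 in 2 N_anc
generations) with weak unidirectional gene flow, about 1,500 blocks of 150
fourfold-degenerate sites, coding sequences of ~1,500 bp with roughly 30%
of codons fourfold degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from . import io as ocio
from .coalcore import simulate_block
from .haploblocks import FOURFOLD_PREFIXES, VcfVariant, four_gamete_pass
from .models import CLASSES, DemographicModel
from .orthofilter import ClusterSet, ContigRecord

#: study-like default history: old split, weak B->A gene flow, mild size change
DEFAULT_MODEL = DemographicModel(
    "IM2", theta=0.00154, T=19.8, M=0.015, direction="B->A",
    size_factor=1.36, size_target="A",
)

_FOURFOLD_CODONS = sorted(p + b for p in FOURFOLD_PREFIXES for b in "ACGT")
_OTHER_CODONS = sorted(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if (a + b) not in FOURFOLD_PREFIXES
    and (a + b + c) not in ("TAA", "TAG", "TGA")
)


@dataclass(frozen=True)
class SyntheticScenario:
    """Generator settings; defaults are the emulated study conditions."""

    model: DemographicModel = DEFAULT_MODEL
    n_blocks: int = 1479
    n_sites: int = 150
    seed: int = 0
    # fixture geometry
    taxa: tuple = ("tA", "tB", "tC", "tD")
    backbone_taxon: str = "out"
    backbone_limit: int = 3
    n_orthogroups: int = 10
    n_codons: int = 520
    n_fourfold_codons: int = 160
    n_paralog_components: int = 2
    n_subgene_components: int = 1
    n_isoform_components: int = 2
    n_missing_taxon_clusters: int = 1
    n_excess_backbone_clusters: int = 1
    n_nonrobust_clusters: int = 1
    n_indel_records: int = 2
    n_althom_records: int = 2
    inflations: tuple = (0.5, 1.0, 1.5, 2.0, 3.0, 5.0)

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.n_fourfold_codons < self.n_sites:
            raise ValueError("need at least n_sites fourfold codons")
        planted = (
            self.n_paralog_components
            + self.n_subgene_components
            + self.n_missing_taxon_clusters
            + self.n_excess_backbone_clusters
            + self.n_nonrobust_clusters
        )
        if self.n_orthogroups < planted + 1:
            raise ValueError("n_orthogroups too small for the planted defects")


# ---------------------------------------------------------------------------
# block tables
# ---------------------------------------------------------------------------

def simulate_block_table(scenario: SyntheticScenario) -> pd.DataFrame:
    """Independent blockwise draws ``k`` under the scenario's model."""
    rng = np.random.default_rng(np.random.SeedSequence(scenario.seed))
    rows = []
    for i in range(scenario.n_blocks):
        k = simulate_block(scenario.model, scenario.n_sites, rng)
        rows.append(
            {
                "orthogroup": f"og{i}",
                "n_sites": scenario.n_sites,
                **{c: k[c] for c in CLASSES},
                "four_gamete_pass": four_gamete_pass(k),
            }
        )
    return pd.DataFrame(rows, columns=ocio.BLOCK_COLUMNS)


# ---------------------------------------------------------------------------
# full upstream fixture
# ---------------------------------------------------------------------------

def _mutate_fourfold(codon: str, rng) -> str:
    """A different third base within the same fourfold family."""
    alternatives = [b for b in "ACGT" if b != codon[2]]
    return codon[:2] + alternatives[rng.integers(0, 3)]


def _ancestor_codons(scenario: SyntheticScenario, rng) -> list[str]:
    n4 = scenario.n_fourfold_codons
    codons = [
        _FOURFOLD_CODONS[rng.integers(0, len(_FOURFOLD_CODONS))] for _ in range(n4)
    ] + [
        _OTHER_CODONS[rng.integers(0, len(_OTHER_CODONS))]
        for _ in range(scenario.n_codons - n4)
    ]
    rng.shuffle(codons)
    return codons


def _divergent_copy(codons: list[str], rate: float, rng) -> list[str]:
    """Copy with random substitutions (any position) at roughly `rate`."""
    seq = list("".join(codons))
    n_mut = int(round(rate * len(seq)))
    for pos in rng.choice(len(seq), size=n_mut, replace=False):
        choices = [b for b in "ACGT" if b != seq[pos]]
        seq[pos] = choices[rng.integers(0, 3)]
    out = "".join(seq)
    return [out[i : i + 3] for i in range(0, len(out), 3)]


def simulate_fixture(scenario: SyntheticScenario, outdir) -> dict:
    """Write a complete synthetic input set and its ground truth.

    Returns a manifest mapping logical names to file paths plus the truth
    tables as DataFrames.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seq_rng, block_rng = (
        np.random.default_rng(s)
        for s in np.random.SeedSequence(scenario.seed).spawn(2)
    )
    tax_a, tax_b, tax_c, tax_d = scenario.taxa

    # assign one planted defect per orthogroup, clean ones last
    fates = (
        ["paralog_pair"] * scenario.n_paralog_components
        + ["subgene_pair"] * scenario.n_subgene_components
        + ["missing_taxon"] * scenario.n_missing_taxon_clusters
        + ["excess_backbone"] * scenario.n_excess_backbone_clusters
        + ["not_robust"] * scenario.n_nonrobust_clusters
    )
    fates += ["clean"] * (scenario.n_orthogroups - len(fates))

    cds: dict[str, dict[str, str]] = {t: {} for t in scenario.taxa}
    peptides: dict[str, dict[str, str]] = {t: {} for t in scenario.taxa}
    variants: dict[str, list[VcfVariant]] = {tax_a: [], tax_b: []}
    contigs: list[ContigRecord] = []
    paralog_truth = []
    block_truth = []
    cluster_truth = []
    clusters = {}
    nonrobust_ids = []

    drop_host = next(i for i, f in enumerate(fates) if f == "clean")

    for i, fate in enumerate(fates):
        og = f"og{i}"
        anc = _ancestor_codons(scenario, seq_rng)
        n_nt = 3 * len(anc)
        fourfold_idx = [
            j for j, c in enumerate(anc) if c[:2] in FOURFOLD_PREFIXES
        ][: scenario.n_sites]

        k = simulate_block(scenario.model, scenario.n_sites, block_rng)
        positions = seq_rng.choice(
            len(fourfold_idx), size=k.total, replace=False
        )
        slots = iter(sorted(int(p) for p in positions))

        a_codons = list(anc)
        b_codons = list(anc)
        for klass in CLASSES:
            for _ in range(k[klass]):
                codon_i = fourfold_idx[next(slots)]
                pos1 = 3 * codon_i + 3  # 1-based third position
                ref_base = anc[codon_i][2]
                alt_codon = _mutate_fourfold(anc[codon_i], seq_rng)
                alt_base = alt_codon[2]
                if klass == "kAABB":
                    b_codons[codon_i] = alt_codon
                    continue
                record = lambda taxon: variants[taxon].append(
                    VcfVariant(
                        contig=f"{taxon}_{og}", pos=pos1, ref=ref_base,
                        alts=(alt_base,), genotype=(0, 1),
                    )
                )
                if klass in ("kA", "kAB"):
                    record(tax_a)
                if klass in ("kB", "kAB"):
                    record(tax_b)

        named = {
            tax_a: "".join(a_codons),
            tax_b: "".join(b_codons),
            tax_c: "".join(anc),
            tax_d: "".join(anc),
        }
        for taxon, seq in named.items():
            cid = f"{taxon}_{og}"
            cds[taxon][cid] = seq
            peptides[taxon][cid] = str(Seq(seq).translate())
            contigs.append(
                ContigRecord(cid, taxon, n_nt, 0, n_nt, component_id=f"{taxon}_cmp{i}")
            )

        # planted companion contigs in taxon A's component
        rep = f"{tax_a}_{og}"
        if fate in ("paralog_pair", "subgene_pair"):
            pid = f"{rep}p"
            if fate == "paralog_pair":
                par = _divergent_copy(a_codons, 0.05, seq_rng)
            else:
                par = list(a_codons)
                start = len(a_codons) // 2  # internal tract, clear of termini
                par[start : start + 40] = _divergent_copy(
                    a_codons[start : start + 40], 0.45, seq_rng
                )
            seq = "".join(par)
            cds[tax_a][pid] = seq
            peptides[tax_a][pid] = str(Seq(seq).translate())
            contigs.append(
                ContigRecord(pid, tax_a, n_nt, 0, n_nt - 3, component_id=f"{tax_a}_cmp{i}")
            )
            verdict = "paralog" if fate == "paralog_pair" else "paralog_subgene"
            paralog_truth.append((tax_a, rep, pid, verdict))
        if i < scenario.n_isoform_components:
            iid = f"{rep}i"
            short = "".join(a_codons[: len(a_codons) - 30])
            cds[tax_a][iid] = short
            contigs.append(
                ContigRecord(
                    iid, tax_a, len(short), 0, len(short), component_id=f"{tax_a}_cmp{i}"
                )
            )
            paralog_truth.append((tax_a, rep, iid, "compatible"))

        # cluster membership
        members = [(t, f"{t}_{og}") for t in scenario.taxa]
        reasons = set()
        if fate in ("paralog_pair", "subgene_pair"):
            members.insert(1, (tax_a, f"{rep}p"))
            reasons.add("has_paralog_pair")
        if fate == "missing_taxon":
            members = [m for m in members if m[0] != tax_d]
            reasons.add("missing_taxon")
        n_backbone = (
            scenario.backbone_limit + 1 if fate == "excess_backbone" else 1
        )
        for bnum in range(n_backbone):
            bid = f"out_{og}_{bnum}"
            members.append((scenario.backbone_taxon, bid))
            peptides.setdefault(scenario.backbone_taxon, {})[bid] = "M" + "".join(
                "ACDEFGHIKLMNPQRSTVWY"[seq_rng.integers(0, 20)] for _ in range(60)
            )
        if fate == "excess_backbone":
            reasons.add("excess_backbone")
        if fate == "not_robust":
            reasons.add("not_robust")
            nonrobust_ids.append(og)
        clusters[og] = tuple(members)
        cluster_truth.append(
            {
                "cluster_id": og,
                "fate": fate,
                "expected_retained": not reasons,
                "expected_reasons": ",".join(sorted(reasons)),
            }
        )
        block_truth.append(
            {
                "orthogroup": og,
                "n_sites": scenario.n_sites,
                **{c: k[c] for c in CLASSES},
                "four_gamete_pass": four_gamete_pass(k),
                "expected_retained": not reasons,
            }
        )

    # droppable VCF records, planted in one clean orthogroup
    host = f"og{drop_host}"
    for taxon in (tax_a, tax_b):
        contig = f"{taxon}_{host}"
        seq = cds[taxon][contig]
        bad_pos = [
            3 * j + 1
            for j, c in enumerate(
                seq[i : i + 3] for i in range(0, len(seq), 3)
            )
            if c[:2] not in FOURFOLD_PREFIXES
        ]
        cursor = iter(bad_pos)
        for _ in range(scenario.n_indel_records):
            pos = next(cursor)
            base = seq[pos - 1]
            variants[taxon].append(
                VcfVariant(contig=contig, pos=pos, ref=base, alts=(base + "A",),
                           genotype=(0, 1))
            )
        for _ in range(scenario.n_althom_records):
            pos = next(cursor)
            base = seq[pos - 1]
            alt = "A" if base != "A" else "G"
            variants[taxon].append(
                VcfVariant(contig=contig, pos=pos, ref=base, alts=(alt,),
                           genotype=(1, 1))
            )

    # cluster files over the inflation grid
    manifest: dict = {"outdir": str(outdir)}
    cluster_paths = {}
    for inflation in scenario.inflations:
        cl = dict(clusters)
        if inflation == max(scenario.inflations):
            for og in nonrobust_ids:
                members = cl.pop(og)
                half = len(members) // 2
                cl[f"{og}_a"] = tuple(members[:half])
                cl[f"{og}_b"] = tuple(members[half:])
        path = outdir / f"clusters_I{inflation}.txt"
        ocio.write_groups(path, ClusterSet(inflation=inflation, clusters=cl))
        cluster_paths[inflation] = str(path)
    manifest["clusters"] = cluster_paths

    for taxon in scenario.taxa:
        p = outdir / f"{taxon}_cds.fasta"
        ocio.write_fasta(p, cds[taxon])
        manifest[f"cds_{taxon}"] = str(p)
    for taxon, peps in peptides.items():
        p = outdir / f"{taxon}_pep.fasta"
        ocio.write_fasta(p, peps)
        manifest[f"pep_{taxon}"] = str(p)
    for taxon in (tax_a, tax_b):
        p = outdir / f"{taxon}.vcf"
        lengths = {cid: len(seq) for cid, seq in cds[taxon].items()}
        ocio.write_vcf(p, lengths, variants[taxon])
        manifest[f"vcf_{taxon}"] = str(p)

    pair_path = outdir / "paralog_pairs.tsv"
    ocio.write_paralog_pairs(
        pair_path, [r for r in paralog_truth if r[3] != "compatible"]
    )
    manifest["paralog_pairs"] = str(pair_path)

    contig_df = pd.DataFrame(
        [
            {
                "contig_id": c.contig_id,
                "taxon": c.taxon,
                "sequence_length": c.sequence_length,
                "orf_start": c.orf_start,
                "orf_end": c.orf_end,
                "component_id": c.component_id,
            }
            for c in contigs
        ]
    )
    truth = {
        "blocks": pd.DataFrame(block_truth),
        "clusters": pd.DataFrame(cluster_truth),
        "paralogs": pd.DataFrame(
            paralog_truth, columns=["taxon", "contig_a", "contig_b", "verdict"]
        ),
        "contigs": contig_df,
        "vcf_counts": pd.DataFrame(
            [
                {
                    "taxon": t,
                    "n_records": len(variants[t]),
                    "n_indels": scenario.n_indel_records,
                    "n_althoms": scenario.n_althom_records,
                }
                for t in (tax_a, tax_b)
            ]
        ),
    }
    for name, df in truth.items():
        path = outdir / f"truth_{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        manifest[f"truth_{name}"] = str(path)
    manifest["truth"] = truth
    manifest["scenario"] = scenario
    return manifest
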