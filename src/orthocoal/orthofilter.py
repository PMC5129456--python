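"""Paralog screening and reduction of peptide clusterings to robust orthogroups.

De novo transcriptome assemblies mix alleles, splice isoforms and recent
paralogs within one assembly component.  Down-stream coalescent inference
needs exactly one sequence per gene per taxon, so contig pairs within a
component are classified from their pairwise alignment:

* overall identity below a threshold (default 0.98) -> ``paralog``;
* a long internal low-identity tract (alternate use of duplicated exons,
  i.e. paralogy below the level of the gene) -> ``paralog_subgene`` even
  when the mean identity is high;
* low-identity tracts touching an alignment terminus are treated as
  structural variation and excluded from the mean-identity computation.

Cross-taxon Markov clusterings (one per inflation value) are then filtered:
a cluster is kept only if it contains no within-taxon paralog pair, at least
one contig from every required taxon, at most ``backbone_limit`` contigs of
the outgroup backbone proteome, and if its non-backbone membership is
reproduced exactly at every alternate inflation value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)

VERDICT_COMPATIBLE = "compatible"
VERDICT_PARALOG = "paralog"
VERDICT_SUBGENE = "paralog_subgene"

REASON_PARALOG = "has_paralog_pair"
REASON_MISSING_TAXON = "missing_taxon"
REASON_BACKBONE = "excess_backbone"
REASON_NOT_ROBUST = "not_robust"


@dataclass(frozen=True)
class ContigRecord:
    """An assembled contig with its predicted ORF (0-based, half-open)."""

    contig_id: str
    taxon: str
    sequence_length: int
    orf_start: int
    orf_end: int
    component_id: str

    def __post_init__(self) -> None:
        if not (0 <= self.orf_start < self.orf_end <= self.sequence_length):
            raise ValueError(f"invalid ORF coordinates on {self.contig_id}")
        if (self.orf_end - self.orf_start) % 3:
            raise ValueError(f"ORF length not a codon multiple on {self.contig_id}")

    @property
    def orf_length(self) -> int:
        return self.orf_end - self.orf_start


@dataclass(frozen=True)
class PairwiseAlignment:
    contig_a: str
    contig_b: str
    columns: tuple  # of (base_a | '-', base_b | '-')

    def __post_init__(self) -> None:
        if not any(a != "-" or b != "-" for a, b in self.columns):
            raise ValueError("alignment has no non-gap columns")

    @classmethod
    def from_strings(cls, contig_a: str, contig_b: str, row_a: str, row_b: str):
        if len(row_a) != len(row_b):
            raise ValueError("aligned rows differ in length")
        return cls(contig_a, contig_b, tuple(zip(row_a.upper(), row_b.upper())))


@dataclass(frozen=True)
class ParalogCall:
    pair: tuple[str, str]
    verdict: str
    mean_identity: float
    excluded_terminal_columns: int
    flagged_internal_tracts: tuple


@dataclass(frozen=True)
class ClusterSet:
    """One clustering of (taxon, contig) members, at a given inflation."""

    inflation: float
    clusters: dict  # cluster_id -> tuple of (taxon, contig_id)

    def __post_init__(self) -> None:
        seen: set = set()
        for cid, members in self.clusters.items():
            for member in members:
                if member in seen:
                    raise ValueError(
                        f"contig {member} appears in more than one cluster"
                    )
                seen.add(member)


@dataclass(frozen=True)
class OrthogroupDecision:
    cluster_id: str
    retained: bool
    exclusion_reasons: frozenset

    def __post_init__(self) -> None:
        if self.retained != (not self.exclusion_reasons):
            raise ValueError("retained flag inconsistent with exclusion reasons")


# ---------------------------------------------------------------------------


def select_component_representative(contigs) -> str:
    """Representative contig of one assembly component: longest ORF, ties
    broken by contig length, then lexicographically smallest id."""
    contigs = list(contigs)
    if not contigs:
        raise ValueError("empty component")
    components = {c.component_id for c in contigs}
    if len(components) > 1:
        raise ValueError(f"contigs from multiple components: {components}")
    best = min(contigs, key=lambda c: (-c.orf_length, -c.sequence_length, c.contig_id))
    return best.contig_id


def classify_pair(
    alignment: PairwiseAlignment,
    identity_threshold: float = 0.98,
    terminal_window: int = 100,
    low_identity_cutoff: float = 0.85,
    min_internal_tract: int = 60,
) -> ParalogCall:
    """Classify a contig pair as compatible, paralog, or sub-gene paralog.

    A sliding window (``terminal_window`` comparable columns, step 1) finds
    low-identity tracts; tracts touching either terminus are excluded from
    the mean identity, internal tracts of at least ``min_internal_tract``
    columns flag sub-gene paralogy outright.
    """
    match = np.array(
        [a == b for a, b in alignment.columns if a != "-" and b != "-"], dtype=float
    )
    n = match.size
    if n == 0:
        raise ValueError(
            f"no comparable columns between {alignment.contig_a} and {alignment.contig_b}"
        )

    window = min(terminal_window, n)
    # identity of every length-`window` run of comparable columns
    cums = np.concatenate([[0.0], np.cumsum(match)])
    win_identity = (cums[window:] - cums[:-window]) / window
    low = win_identity < low_identity_cutoff

    tracts = []  # (start, end) in comparable-column coordinates
    i = 0
    while i < low.size:
        if low[i]:
            j = i
            while j + 1 < low.size and low[j + 1]:
                j += 1
            tracts.append((i, j + window))  # window smear included
            i = j + 1
        else:
            i += 1

    excluded = np.zeros(n, dtype=bool)
    internal: list[tuple[int, int]] = []
    for start, end in tracts:
        if start == 0 or end >= n:
            excluded[start:end] = True
        elif end - start >= min_internal_tract:
            internal.append((start, end))

    kept = ~excluded
    mean_identity = float(match[kept].mean()) if kept.any() else float(match.mean())

    if internal:
        verdict = VERDICT_SUBGENE
    elif mean_identity < identity_threshold:
        verdict = VERDICT_PARALOG
    else:
        verdict = VERDICT_COMPATIBLE
    return ParalogCall(
        pair=(alignment.contig_a, alignment.contig_b),
        verdict=verdict,
        mean_identity=mean_identity,
        excluded_terminal_columns=int(excluded.sum()),
        flagged_internal_tracts=tuple(internal),
    )


def filter_clusters(
    primary: ClusterSet,
    paralog_pairs: set,
    required_taxa: set,
    backbone_taxon: str,
    backbone_limit: int = 3,
) -> list[OrthogroupDecision]:
    """Annotate every cluster with all violated criteria (not short-circuited).

    ``paralog_pairs`` holds unordered pairs ``frozenset({(taxon, contig_a),
    (taxon, contig_b)})``; a cluster containing both members of any pair is
    excluded, as are clusters missing a required taxon or exceeding the
    backbone-contig limit.
    """
    if not required_taxa:
        raise ValueError("required_taxa must be non-empty")
    if backbone_limit < 0:
        raise ValueError("backbone_limit must be >= 0")
    decisions = []
    tallies: dict[str, int] = {}
    for cluster_id, members in primary.clusters.items():
        reasons = set()
        member_set = set(members)
        for pair in paralog_pairs:
            if pair <= member_set:
                reasons.add(REASON_PARALOG)
                break
        taxa_present = {taxon for taxon, _ in members}
        if not required_taxa <= taxa_present:
            reasons.add(REASON_MISSING_TAXON)
        n_backbone = sum(1 for taxon, _ in members if taxon == backbone_taxon)
        if n_backbone > backbone_limit:
            reasons.add(REASON_BACKBONE)
        for r in reasons:
            tallies[r] = tallies.get(r, 0) + 1
        decisions.append(
            OrthogroupDecision(cluster_id, not reasons, frozenset(reasons))
        )
    for reason, count in sorted(tallies.items()):
        log.info("clusters failing %s: %d", reason, count)
    return decisions


def robust_orthogroups(
    survivors,
    primary: ClusterSet,
    alternates,
    backbone_taxon: str | None = None,
) -> set:
    """Surviving clusters whose non-backbone membership is reproduced exactly
    as a cluster at every alternate inflation value.

    Backbone (outgroup proteome) contigs are ignored in the comparison; their
    attachment is volatile under inflation changes.  A contig absent from an
    alternate clustering counts as a membership change.
    """
    alternates = list(alternates)
    if not alternates:
        raise ValueError("at least one alternate clustering is required")

    def core(members):
        return frozenset(m for m in members if m[0] != backbone_taxon)

    robust = set()
    for cluster_id in survivors:
        target = core(primary.clusters[cluster_id])
        ok = True
        for alt in alternates:
            if not any(core(m) == target for m in alt.clusters.values()):
                log.info(
                    "cluster %s not reproduced at inflation %s",
                    cluster_id,
                    alt.inflation,
                )
                ok = False
                break
        if ok:
            robust.add(cluster_id)
    return robust


def decide_orthogroups(
    primary: ClusterSet,
    alternates,
    paralog_pairs: set,
    required_taxa: set,
    backbone_taxon: str,
    backbone_limit: int = 3,
) -> list[OrthogroupDecision]:
    """Full filtering pipeline: criterion screen plus inflation robustness."""
    screened = filter_clusters(
        primary, paralog_pairs, required_taxa, backbone_taxon, backbone_limit
    )
    survivors = [d.cluster_id for d in screened if d.retained]
    robust = robust_orthogroups(survivors, primary, alternates, backbone_taxon)
    final = []
    for d in screened:
        reasons = set(d.exclusion_reasons)
        if d.retained and d.cluster_id not in robust:
            reasons.add(REASON_NOT_ROBUST)
        final.append(
            OrthogroupDecision(d.cluster_id, not reasons, frozenset(reasons))
        )
    return final
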