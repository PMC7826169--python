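"""Best-hit ortholog families: one member per genome, paralogs kept aside.

Each pivot gene seeds one family.  Per (pivot gene, genome) the top-ranked
hit becomes the family member; lower-ranked hits of the same genome are
recorded as within-paralogs/xenologs.  A subject gene can be the member of
at most one family: conflicts are resolved greedily in descending identity
order (ties broken by longer pivot gene, then smaller pivot gene id), and a
family losing its best hit falls back to that genome's next-best unclaimed
hit, or none.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

from .genome_io import Dataset
from .homology import Hit

ACTIVE = "active"
STRINGENT_EXCLUDED = "stringent_excluded"


@dataclasses.dataclass(frozen=True)
class Member:
    genome_id: str
    gene_id: str
    identity: float


@dataclasses.dataclass(frozen=True)
class WithinParalog:
    genome_id: str
    gene_id: str
    identity: float


@dataclasses.dataclass(frozen=True)
class Removal:
    genome_id: str
    gene_id: str
    reason: str  # partial_hidden | double_outlier
    identity: float


@dataclasses.dataclass
class OrthologFamily:
    """One pivot gene with at most one member per genome."""

    pivot_gene_id: str
    members: dict[str, Member] = dataclasses.field(default_factory=dict)
    within_paralogs: list[WithinParalog] = dataclasses.field(default_factory=list)
    removals: list[Removal] = dataclasses.field(default_factory=list)
    status: str = ACTIVE

    def member_identities(self) -> list[float]:
        return [m.identity for m in self.members.values()]

    def frequency(self, n_genomes: int) -> float:
        return family_frequency(self, n_genomes)

    def remove_member(self, genome_id: str, reason: str) -> None:
        member = self.members.pop(genome_id)
        self.removals.append(
            Removal(member.genome_id, member.gene_id, reason, member.identity)
        )


def family_frequency(family: OrthologFamily, n_genomes: int) -> float:
    """Fraction of genomes contributing a member (the pivot's own included)."""
    if n_genomes < 1:
        raise ValueError("n_genomes must be >= 1")
    return len(family.members) / n_genomes


def build_families(
    dataset: Dataset, hits: list[Hit], config=None
) -> list[OrthologFamily]:
    """Turn threshold-filtered hits into one ortholog family per pivot gene.

    The pivot genome's member of each family is the pivot gene itself at
    identity 100 (its self-hit).  Hits are then awarded greedily in
    descending identity order under the one-member-per-genome and
    one-family-per-subject-gene constraints.  Remaining hits of a genome
    with an assigned member become within-paralogs when they do not exceed
    the member's identity; hits that lost their subject gene to a stronger
    family stay unassigned.
    """
    pivot = dataset.pivot
    pivot_id = dataset.pivot_id
    for h in hits:
        try:
            dataset.gene(h.genome_id, h.target_gene_id)
        except KeyError:
            raise ValueError(
                f"hit references unknown gene {h.genome_id}|{h.target_gene_id}"
            ) from None
        if h.pivot_gene_id not in pivot:
            raise ValueError(f"hit references unknown pivot gene {h.pivot_gene_id!r}")

    families = {p.gene_id: OrthologFamily(pivot_gene_id=p.gene_id) for p in pivot.genes}
    claimed: set[tuple[str, str]] = set()
    for p in pivot.genes:
        families[p.gene_id].members[pivot_id] = Member(pivot_id, p.gene_id, 100.0)
        claimed.add((pivot_id, p.gene_id))

    def rank_key(h: Hit):
        return (
            -h.identity,
            -pivot.gene(h.pivot_gene_id).length,
            h.pivot_gene_id,
            -dataset.gene(h.genome_id, h.target_gene_id).length,
            h.target_gene_id,
            h.genome_id,
        )

    ordered = sorted(hits, key=rank_key)
    for h in ordered:
        family = families[h.pivot_gene_id]
        if h.genome_id in family.members:
            continue
        if (h.genome_id, h.target_gene_id) in claimed:
            continue
        family.members[h.genome_id] = Member(h.genome_id, h.target_gene_id, h.identity)
        claimed.add((h.genome_id, h.target_gene_id))

    for h in ordered:
        family = families[h.pivot_gene_id]
        member = family.members.get(h.genome_id)
        if member is None or member.gene_id == h.target_gene_id:
            continue
        if h.identity <= member.identity:
            family.within_paralogs.append(
                WithinParalog(h.genome_id, h.target_gene_id, h.identity)
            )

    return [families[p.gene_id] for p in pivot.genes]
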