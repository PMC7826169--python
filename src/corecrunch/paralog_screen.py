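"""Two-step hidden-paralog detection over identity-score distributions.

Step one (partially hidden copies) uses the within-paralog scores of a
family: every member scoring below the best within-paralog is removed,
because a genome that kept both copies reveals the identity level of the
paralogous lineage.

Step two (completely hidden copies) is the double outlier test.  For each
putative core family, Tukey's fences over the member identities
(distribution 1, the *vertical* test) flag candidate paralogs; a candidate
is confirmed only if its identity is also outside the fences of its own
genome's profile (distribution 2, the *horizontal* test), i.e. atypical
even for that genome's overall divergence from the pivot.  The horizontal
test is what keeps genuinely divergent strains in the core: their low
scores are low everywhere, not just in one family.

Fences are ``Q1 - 1.5*IQR`` and ``Q3 + 1.5*IQR`` with linearly
interpolated quartiles (quantile p at position ``p*(n-1)``); a value is an
outlier only when strictly below the lower or strictly above the upper
fence.  Families with fewer than four members skip the vertical test, whose
quartiles would be degenerate.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Optional

import numpy as np

from .families import OrthologFamily, STRINGENT_EXCLUDED, family_frequency

logger = logging.getLogger(__name__)

MIN_FAMILY_SIZE_FOR_DOUBLE_TEST = 4


def quartiles(values: Iterable[float]) -> tuple[float, float]:
    """(Q1, Q3) with linear interpolation at positions 0.25/0.75 * (n-1)."""
    arr = np.asarray(list(values), dtype=np.float64)
    if arr.size == 0:
        raise ValueError("quartiles of an empty collection")
    q1, q3 = np.quantile(arr, [0.25, 0.75])
    return float(q1), float(q3)


@dataclasses.dataclass(frozen=True)
class Fences:
    """Tukey's fences of one identity-score distribution."""

    q1: float
    q3: float
    lower: float
    upper: float
    n: int

    @classmethod
    def from_values(cls, values: Iterable[float]) -> "Fences":
        vals = list(values)
        q1, q3 = quartiles(vals)
        iqr = q3 - q1
        return cls(q1=q1, q3=q3, lower=q1 - 1.5 * iqr, upper=q3 + 1.5 * iqr, n=len(vals))

    def is_outlier(self, value: float) -> bool:
        return value < self.lower or value > self.upper


def tukey_fences(values: Iterable[float]) -> Fences:
    return Fences.from_values(values)


@dataclasses.dataclass
class GenomeProfile:
    """Distribution 2: one genome's member identities across putative core genes."""

    genome_id: str
    scores: list[float]
    median: Optional[float]
    fences: Optional[Fences]

    @property
    def usable(self) -> bool:
        return bool(self.scores)


def screen_partial_hidden(family: OrthologFamily, stringent: bool = False) -> OrthologFamily:
    """Remove members scoring below the family's best within-paralog.

    A no-op when the family has no recorded within-paralogs.  Under the
    stringent option a family that loses any member is excluded outright.
    """
    if not family.within_paralogs or family.status != "active":
        return family
    threshold = max(wp.identity for wp in family.within_paralogs)
    flagged = sorted(
        (gid for gid, m in family.members.items() if m.identity < threshold)
    )
    for genome_id in flagged:
        family.remove_member(genome_id, "partial_hidden")
    if stringent and flagged:
        family.status = STRINGENT_EXCLUDED
    return family


def build_genome_profiles(
    families: Iterable[OrthologFamily],
    n_genomes: int,
    frequency_threshold: float = 0.9,
    genome_ids: Optional[Iterable[str]] = None,
) -> dict[str, GenomeProfile]:
    """Per-genome identity distributions over the putative core families.

    Putative core = active families whose current frequency meets the
    threshold.  Profiles (and their fences) are computed once, in a single
    pass, and are not updated as the double-outlier screen removes members.
    """
    scores: dict[str, list[float]] = {gid: [] for gid in (genome_ids or [])}
    for family in families:
        if family.status != "active":
            continue
        if family_frequency(family, n_genomes) < frequency_threshold:
            continue
        for genome_id, member in family.members.items():
            scores.setdefault(genome_id, []).append(member.identity)
    profiles: dict[str, GenomeProfile] = {}
    for genome_id, vals in scores.items():
        if vals:
            profiles[genome_id] = GenomeProfile(
                genome_id=genome_id,
                scores=vals,
                median=float(np.median(vals)),
                fences=Fences.from_values(vals),
            )
        else:
            profiles[genome_id] = GenomeProfile(
                genome_id=genome_id, scores=[], median=None, fences=None
            )
    return profiles


def screen_double_outliers(
    family: OrthologFamily,
    profiles: dict[str, GenomeProfile],
    stringent: bool = False,
    min_members: int = MIN_FAMILY_SIZE_FOR_DOUBLE_TEST,
) -> OrthologFamily:
    """Remove members that are outliers in both distributions.

    Vertical: fences over this family's member identities (the tested
    member's own score included).  Horizontal: fences over the member
    genome's profile.  A candidate from a genome with an empty profile is
    kept and a warning logged.
    """
    if family.status != "active" or len(family.members) < min_members:
        return family
    fences1 = Fences.from_values(family.member_identities())
    confirmed: list[str] = []
    for genome_id in sorted(family.members):
        member = family.members[genome_id]
        if not fences1.is_outlier(member.identity):
            continue
        profile = profiles.get(genome_id)
        if profile is None or not profile.usable:
            logger.warning(
                "family %s: vertical outlier %s|%s has no usable genome profile; kept",
                family.pivot_gene_id, genome_id, member.gene_id,
            )
            continue
        if profile.fences.is_outlier(member.identity):
            confirmed.append(genome_id)
    for genome_id in confirmed:
        family.remove_member(genome_id, "double_outlier")
    if stringent and confirmed:
        family.status = STRINGENT_EXCLUDED
    return family
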