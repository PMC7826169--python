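"""Identity-scored homology search of pivot genes against every genome.

The identity of two sequences is defined on a single score-optimal global
alignment: ``100 * identical_pairs / alignment_columns`` where the
denominator counts every column, gap columns included.  Alignments are
computed with an affine-gap (Gotoh) dynamic program; a gap of length *k*
costs ``open + (k - 1) * extend``.  Protein alignments score substitutions
with BLOSUM62 (gap open 10, extend 1); nucleotide alignments use match +2,
mismatch -3 (gap open 5, extend 2).  These constants only shape the
alignment -- identity itself is the plain column count above, and ambiguity
symbols (``X``/``B``/``Z``/``J`` for proteins, IUPAC codes for nucleotides)
never count as identical pairs.

Ties between co-optimal alignments are broken deterministically during
traceback (diagonal, then gap-in-subject, then gap-in-query), and the pair
is put into a canonical order before aligning so that identity is exactly
symmetric.

A candidate pair may be skipped before the full dynamic program only when a
banded edit-distance bound proves it cannot reach the identity threshold;
see :func:`may_reach_identity`.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import edlib
import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

from .genome_io import Dataset, GeneRecord, Genome

logger = logging.getLogger(__name__)

PROTEIN_GAP_OPEN = 10
PROTEIN_GAP_EXTEND = 1
NUCLEOTIDE_GAP_OPEN = 5
NUCLEOTIDE_GAP_EXTEND = 2
NUCLEOTIDE_MATCH = 2
NUCLEOTIDE_MISMATCH = -3

_NEG = -(10 ** 15)  # effectively -infinity; int64 arithmetic stays exact

PROTEIN_AMBIGUOUS = "BJXZ"
NUCLEOTIDE_AMBIGUOUS = "RYSWKMBDHVN"


@dataclasses.dataclass(frozen=True)
class Hit:
    """One pivot-gene-to-genome-gene match passing both admission filters."""

    pivot_gene_id: str
    genome_id: str
    target_gene_id: str
    identity: float
    length_ratio: float


@dataclasses.dataclass
class ScoringConfig:
    """Admission thresholds and backend for the homology stage."""

    identity_threshold: float = 90.0
    length_ratio_threshold: float = 0.8
    alphabet: str = "protein"
    backend: str = "internal"

    def __post_init__(self) -> None:
        if not 0 < self.identity_threshold <= 100:
            raise ValueError("identity_threshold must be in (0, 100]")
        if not 0 < self.length_ratio_threshold <= 1:
            raise ValueError("length_ratio_threshold must be in (0, 1]")
        if self.alphabet not in ("protein", "nucleotide"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")


def _build_protein_matrix() -> np.ndarray:
    blosum = substitution_matrices.load("BLOSUM62")
    sub = np.full((26, 26), -4, dtype=np.int64)
    for x in blosum.alphabet:
        if x == "*":
            continue
        for y in blosum.alphabet:
            if y == "*":
                continue
            sub[ord(x) - 65, ord(y) - 65] = int(blosum[x, y])
    return sub


def _build_nucleotide_matrix() -> np.ndarray:
    sub = np.full((26, 26), NUCLEOTIDE_MISMATCH, dtype=np.int64)
    np.fill_diagonal(sub, NUCLEOTIDE_MATCH)
    return sub


def _ambiguity_mask(letters: str) -> np.ndarray:
    mask = np.zeros(26, dtype=np.bool_)
    for ch in letters:
        mask[ord(ch) - 65] = True
    return mask


_PROTEIN_SUB = _build_protein_matrix()
_NUCLEOTIDE_SUB = _build_nucleotide_matrix()
_PROTEIN_AMB = _ambiguity_mask(PROTEIN_AMBIGUOUS)
_NUCLEOTIDE_AMB = _ambiguity_mask(NUCLEOTIDE_AMBIGUOUS)


@njit(cache=True)
def _gotoh(a, b, sub, gap_open, gap_extend, amb):  # pragma: no cover - jitted
    """Affine-gap global alignment; returns (score, identical_pairs, columns).

    Three-state Gotoh DP over int64 scores (exact arithmetic), followed by a
    traceback with fixed tie priority: match state before gap-in-b before
    gap-in-a, and within gap states the gap-open predecessor before the
    gap-extend predecessor.
    """
    n = a.shape[0]
    m = b.shape[0]
    NEG = _NEG
    M = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    Ix = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # gap in b (consumes a)
    Iy = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # gap in a (consumes b)
    M[0, 0] = 0
    for i in range(1, n + 1):
        Ix[i, 0] = -(gap_open + (i - 1) * gap_extend)
    for j in range(1, m + 1):
        Iy[0, j] = -(gap_open + (j - 1) * gap_extend)
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = sub[ai, b[j - 1]]
            best = M[i - 1, j - 1]
            if Ix[i - 1, j - 1] > best:
                best = Ix[i - 1, j - 1]
            if Iy[i - 1, j - 1] > best:
                best = Iy[i - 1, j - 1]
            if best > NEG:
                M[i, j] = best + s
            x1 = M[i - 1, j] - gap_open
            x2 = Ix[i - 1, j] - gap_extend
            Ix[i, j] = x1 if x1 >= x2 else x2
            y1 = M[i, j - 1] - gap_open
            y2 = Iy[i, j - 1] - gap_extend
            Iy[i, j] = y1 if y1 >= y2 else y2

    score = M[n, m]
    state = 0
    if Ix[n, m] > score:
        score = Ix[n, m]
        state = 1
    if Iy[n, m] > score:
        score = Iy[n, m]
        state = 2

    i = n
    j = m
    matches = 0
    columns = 0
    while i > 0 or j > 0:
        if state == 0:
            columns += 1
            ai = a[i - 1]
            bj = b[j - 1]
            if ai == bj and not amb[ai]:
                matches += 1
            prev = M[i, j] - sub[ai, bj]
            if M[i - 1, j - 1] == prev:
                state = 0
            elif Ix[i - 1, j - 1] == prev:
                state = 1
            else:
                state = 2
            i -= 1
            j -= 1
        elif state == 1:
            columns += 1
            v = Ix[i, j]
            if M[i - 1, j] == v + gap_open:
                state = 0
            else:
                state = 1
            i -= 1
        else:
            columns += 1
            v = Iy[i, j]
            if M[i, j - 1] == v + gap_open:
                state = 0
            else:
                state = 2
            j -= 1
    return score, matches, columns


def _encode(seq: str) -> np.ndarray:
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).astype(np.int64) - 65
    if codes.min() < 0 or codes.max() > 25:
        raise ValueError("sequence contains characters outside A-Z")
    return codes


def _alignment_params(alphabet: str):
    if alphabet == "protein":
        return _PROTEIN_SUB, PROTEIN_GAP_OPEN, PROTEIN_GAP_EXTEND, _PROTEIN_AMB
    return _NUCLEOTIDE_SUB, NUCLEOTIDE_GAP_OPEN, NUCLEOTIDE_GAP_EXTEND, _NUCLEOTIDE_AMB


def align_stats(a: str, b: str, alphabet: str = "protein") -> tuple[int, int, int]:
    """(score, identical_pairs, columns) of the canonical global alignment.

    The pair is ordered lexicographically before aligning so the result is
    symmetric in its arguments.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    if b < a:
        a, b = b, a
    sub, go, ge, amb = _alignment_params(alphabet)
    score, matches, columns = _gotoh(_encode(a), _encode(b), sub, go, ge, amb)
    return int(score), int(matches), int(columns)


def pairwise_identity(a: str, b: str, alphabet: str = "protein") -> float:
    """Percent identity over all columns of the optimal global alignment."""
    _, matches, columns = align_stats(a, b, alphabet)
    return 100.0 * matches / columns


def length_ratio(a: GeneRecord, b: GeneRecord) -> float:
    """min/max of the two unaligned sequence lengths; symmetric."""
    la, lb = a.length, b.length
    if la < 1 or lb < 1:
        raise ValueError("length_ratio requires non-empty sequences")
    return min(la, lb) / max(la, lb)


def may_reach_identity(a: str, b: str, identity_threshold: float) -> bool:
    """Cheap, provably safe pre-filter on the pair's best possible identity.

    For any global alignment with ``m`` identical pairs over ``c`` columns,
    the non-identical columns form an edit script, so ``c - m >= d`` where
    ``d`` is the Levenshtein distance; with ``m <= L0 = min(|a|, |b|)`` this
    gives ``identity <= 100 * L0 / (L0 + d)``.  The pair can therefore be
    skipped whenever ``d > L0 * (100 - t) / t``.  The banded distance is
    computed with edlib.
    """
    L0 = min(len(a), len(b))
    kmax = int(L0 * (100.0 - identity_threshold) / identity_threshold)
    d = edlib.align(a, b, mode="NW", task="distance", k=kmax)["editDistance"]
    return d != -1


def search_genome(pivot: Genome, subject: Genome, config: ScoringConfig) -> list[Hit]:
    """All subject genes passing both admission filters, per pivot gene.

    Hits are grouped by pivot gene (pivot gene order preserved) and sorted
    within each group by descending identity, then descending length ratio,
    then ascending target gene id.
    """
    thr = config.identity_threshold
    lrt = config.length_ratio_threshold
    subj_lengths = np.array([g.length for g in subject.genes], dtype=np.float64)
    hits: list[Hit] = []
    for p in pivot.genes:
        ratios = np.minimum(subj_lengths, p.length) / np.maximum(subj_lengths, p.length)
        candidates = np.nonzero(ratios >= lrt)[0]
        group: list[Hit] = []
        for k in candidates:
            s = subject.genes[int(k)]
            if not may_reach_identity(p.sequence, s.sequence, thr):
                continue
            ident = pairwise_identity(p.sequence, s.sequence, config.alphabet)
            if ident >= thr:
                group.append(
                    Hit(
                        pivot_gene_id=p.gene_id,
                        genome_id=subject.genome_id,
                        target_gene_id=s.gene_id,
                        identity=ident,
                        length_ratio=float(ratios[int(k)]),
                    )
                )
        group.sort(key=lambda h: (-h.identity, -h.length_ratio, h.target_gene_id))
        hits.extend(group)
    return hits


def search_all(dataset: Dataset, config: ScoringConfig) -> list[Hit]:
    """Search the pivot against every genome (itself included)."""
    pivot = dataset.pivot
    hits: list[Hit] = []
    for genome_id in dataset.genome_ids:
        hits.extend(search_genome(pivot, dataset.genome(genome_id), config))
    return hits


def write_hits_table(hits: list[Hit], dataset: Dataset, path: Path | str) -> Path:
    """Write hits as 12-column blast-style tabular output.

    Query ids are pivot gene ids, subject ids are ``genome_id|gene_id`` and
    column 3 carries the identity at full float precision so that a
    re-parsed table reproduces the identical hit set.  Alignment length is
    approximated by the longer sequence and the remaining bookkeeping
    columns are nominal; only columns 1-3 are consumed on re-parse.
    """
    path = Path(path)
    pivot = dataset.pivot
    with open(path, "w") as fh:
        for h in hits:
            qlen = pivot.gene(h.pivot_gene_id).length
            slen = dataset.gene(h.genome_id, h.target_gene_id).length
            alen = max(qlen, slen)
            mism = alen - round(alen * h.identity / 100.0)
            fh.write(
                f"{h.pivot_gene_id}\t{h.genome_id}|{h.target_gene_id}\t"
                f"{h.identity:.17g}\t{alen}\t{mism}\t0\t1\t{qlen}\t1\t{slen}\t"
                f"0.0\t{2 * alen}\n"
            )
    return path


def parse_hits_table(path: Path | str, dataset: Dataset, config: ScoringConfig) -> list[Hit]:
    """Ingest 12-column blast-style tabular search output.

    Identity is taken from column 3; the length ratio is recomputed from the
    stored gene lengths, not from the reported alignment length.  Rows
    failing either admission threshold are dropped; malformed rows are
    counted and logged.  A subject id without the ``genome|gene`` separator
    is an error naming the offending line.
    """
    path = Path(path)
    pivot = dataset.pivot
    hits: list[Hit] = []
    malformed = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                malformed += 1
                continue
            query, subject = fields[0], fields[1]
            if "|" not in subject:
                raise ValueError(
                    f"{path}:{lineno}: subject id {subject!r} has no 'genome|gene' separator"
                )
            try:
                identity = float(fields[2])
            except ValueError:
                malformed += 1
                continue
            genome_id, gene_id = subject.split("|", 1)
            if query not in pivot:
                raise ValueError(f"{path}:{lineno}: query {query!r} is not a pivot gene")
            ratio = length_ratio(pivot.gene(query), dataset.gene(genome_id, gene_id))
            if identity < config.identity_threshold or ratio < config.length_ratio_threshold:
                continue
            hits.append(
                Hit(
                    pivot_gene_id=query,
                    genome_id=genome_id,
                    target_gene_id=gene_id,
                    identity=identity,
                    length_ratio=ratio,
                )
            )
    if malformed:
        logger.warning("%s: skipped %d malformed row(s)", path, malformed)
    return hits
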