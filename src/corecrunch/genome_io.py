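"""Reading per-genome FASTA files, pivot designation, and all on-disk outputs.

A dataset is a directory with one multi-FASTA file per genome (coding
sequences, protein by default).  The genome identifier is the file stem;
record identifiers (first whitespace-delimited token of the header) are the
gene identifiers, unique within a genome.
"""

from __future__ import annotations

import dataclasses
import json
import random
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO

FASTA_EXTENSIONS = {".fa", ".fasta", ".faa", ".fna", ".ffn"}

# Residues accepted per alphabet.  Ambiguity codes are tolerated on input but
# never count as identical positions during identity computation (see
# :mod:`corecrunch.homology`).
PROTEIN_LETTERS = set("ACDEFGHIKLMNPQRSTVWY") | set("BJXZUO")
NUCLEOTIDE_LETTERS = set("ACGTU") | set("RYSWKMBDHVN")


@dataclasses.dataclass(frozen=True)
class GeneRecord:
    """One coding sequence of one genome."""

    genome_id: str
    gene_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclasses.dataclass
class Genome:
    """An ordered collection of genes read from a single FASTA file."""

    genome_id: str
    genes: list[GeneRecord]
    source_path: Optional[Path] = None

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"genome {self.genome_id!r}: no sequences")
        self._by_id = {g.gene_id: g for g in self.genes}

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def gene(self, gene_id: str) -> GeneRecord:
        return self._by_id[gene_id]


@dataclasses.dataclass
class Dataset:
    """All genomes of one run plus the designated pivot genome."""

    genomes: list[Genome]
    pivot_id: str

    def __post_init__(self) -> None:
        self._by_id = {g.genome_id: g for g in self.genomes}
        if len(self._by_id) != len(self.genomes):
            raise ValueError("duplicate genome_id in dataset")
        if len(self.genomes) < 2:
            raise ValueError("a dataset needs at least 2 genomes")
        if self.pivot_id not in self._by_id:
            raise ValueError(
                f"pivot {self.pivot_id!r} not among genomes: "
                f"{sorted(self._by_id)}"
            )

    @property
    def n_genomes(self) -> int:
        return len(self.genomes)

    @property
    def pivot(self) -> Genome:
        return self._by_id[self.pivot_id]

    @property
    def genome_ids(self) -> list[str]:
        return sorted(self._by_id)

    def genome(self, genome_id: str) -> Genome:
        return self._by_id[genome_id]

    def gene(self, genome_id: str, gene_id: str) -> GeneRecord:
        return self._by_id[genome_id].gene(gene_id)


def _validate_sequence(seq: str, alphabet: str, genome_id: str, gene_id: str) -> None:
    allowed = PROTEIN_LETTERS if alphabet == "protein" else NUCLEOTIDE_LETTERS
    for pos, ch in enumerate(seq):
        if ch not in allowed:
            raise ValueError(
                f"genome {genome_id!r}, record {gene_id!r}: residue {ch!r} at "
                f"position {pos + 1} is outside the {alphabet} alphabet"
            )


def read_genome_fasta(path: Path | str, alphabet: str = "protein") -> Genome:
    """Read one per-genome multi-FASTA file.

    Sequences are upper-cased; a single terminal stop symbol ``*`` is
    stripped from protein sequences.  Duplicate record identifiers and
    residues outside the declared alphabet raise ``ValueError``.
    """
    path = Path(path)
    if alphabet not in ("protein", "nucleotide"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    genome_id = path.stem
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        gene_id = record.id
        if gene_id in seen:
            raise ValueError(f"genome {genome_id!r}: duplicate record ID {gene_id!r}")
        seen.add(gene_id)
        seq = str(record.seq).upper()
        if alphabet == "protein" and seq.endswith("*"):
            seq = seq[:-1]
        if not seq:
            raise ValueError(f"genome {genome_id!r}: record {gene_id!r} is empty")
        _validate_sequence(seq, alphabet, genome_id, gene_id)
        genes.append(GeneRecord(genome_id=genome_id, gene_id=gene_id, sequence=seq))
    if not genes:
        raise ValueError(f"{path}: no sequences")
    return Genome(genome_id=genome_id, genes=genes, source_path=path)


def choose_pivot(genome_ids: Iterable[str], seed: int) -> str:
    """Seeded uniform pivot draw; a pure function of (sorted ids, seed)."""
    ids = sorted(genome_ids)
    if not ids:
        raise ValueError("no genomes to choose a pivot from")
    return random.Random(seed).choice(ids)


def load_dataset(
    directory: Path | str,
    pivot: Optional[str] = None,
    seed: int = 0,
    alphabet: str = "protein",
) -> Dataset:
    """Load every FASTA file in *directory* as one genome and fix the pivot.

    If *pivot* is not given it is drawn uniformly from the sorted genome
    identifiers with ``random.Random(seed)``, so the same directory contents
    and seed always yield the same pivot.
    """
    directory = Path(directory)
    paths = sorted(
        p for p in directory.iterdir()
        if p.is_file() and p.suffix.lower() in FASTA_EXTENSIONS
    )
    if len(paths) < 2:
        raise ValueError(
            f"{directory}: found {len(paths)} FASTA file(s); at least 2 genomes required"
        )
    genomes = [read_genome_fasta(p, alphabet=alphabet) for p in paths]
    ids = sorted(g.genome_id for g in genomes)
    if pivot is None:
        pivot = choose_pivot(ids, seed)
    elif pivot not in ids:
        raise ValueError(f"pivot {pivot!r} not found; available genomes: {ids}")
    return Dataset(genomes=genomes, pivot_id=pivot)


def write_fasta(records: Iterable[tuple[str, str]], path: Path) -> None:
    """Write (header, sequence) pairs as single-line-sequence FASTA."""
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n{seq}\n")


def _family_filename(pivot_gene_id: str) -> str:
    safe = "".join(c if (c.isalnum() or c in "._-") else "_" for c in pivot_gene_id)
    return f"{safe}.fasta"


def write_outputs(core, dataset: Dataset, out_dir: Path | str, overwrite: bool = False) -> Path:
    """Write per-family FASTAs, the summary TSV, the run log and a JSON snapshot.

    Returns the path of the summary TSV.  Family FASTAs contain one record
    per retained member with ``genome_id|gene_id`` headers.  The summary has
    one row per family (core and excluded alike), sorted by family id.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fam_dir = out_dir / "families"
    fam_dir.mkdir(exist_ok=True)

    for family in core.families:
        path = fam_dir / _family_filename(family.pivot_gene_id)
        if path.exists() and path.stat().st_size > 0 and not overwrite:
            raise FileExistsError(f"refusing to overwrite non-empty {path}")
        members = sorted(family.members.values(), key=lambda m: m.genome_id)
        write_fasta(
            ((f"{m.genome_id}|{m.gene_id}", dataset.gene(m.genome_id, m.gene_id).sequence)
             for m in members),
            path,
        )

    rows = []
    for family in core.families:
        rows.append((family, "core"))
    for family, reason in core.excluded:
        rows.append((family, reason))
    rows.sort(key=lambda fr: fr[0].pivot_gene_id)

    summary_path = out_dir / "summary.tsv"
    with open(summary_path, "w") as fh:
        fh.write(
            "family_id\tn_members\tn_within_paralogs\t"
            "n_partial_hidden_removed\tn_double_outlier_removed\tstatus\n"
        )
        for family, status in rows:
            n_partial = sum(1 for r in family.removals if r.reason == "partial_hidden")
            n_double = sum(1 for r in family.removals if r.reason == "double_outlier")
            fh.write(
                f"{family.pivot_gene_id}\t{len(family.members)}\t"
                f"{len(family.within_paralogs)}\t{n_partial}\t{n_double}\t{status}\n"
            )

    log_path = out_dir / "run_log.txt"
    with open(log_path, "w") as fh:
        fh.write("corecrunch run parameters\n")
        params = core.parameters
        if params is not None:
            for field, value in sorted(dataclasses.asdict(params).items()):
                fh.write(f"{field}\t{value}\n")
        fh.write(f"resolved_pivot\t{core.pivot_id}\n")
        fh.write(f"n_genomes\t{core.n_genomes}\n")
        fh.write("identity_definition\tidentical_pairs / alignment_columns_incl_gaps\n")
        fh.write("quartile_convention\tlinear interpolation at p*(n-1)\n")
        fh.write("gap_model\tfirst gap residue costs 'open', each further residue 'extend'\n")
        fh.write("protein_gaps\topen=10 extend=1 (BLOSUM62)\n")
        fh.write("nucleotide_gaps\topen=5 extend=2 (match=2 mismatch=-3)\n")

    with open(out_dir / "core.json", "w") as fh:
        json.dump(core.to_dict(), fh, indent=1, sort_keys=True)

    return summary_path
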