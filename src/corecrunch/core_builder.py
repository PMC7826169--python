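"""Pipeline orchestration: frequency filter, core assembly, consensus, alignment.

The pipeline runs as: load genomes -> homology search (internal aligner or
a pre-computed blast-style table) -> best-hit family construction ->
partial-hidden screen -> frequency pre-selection -> genome profiles ->
double-outlier screen -> final frequency filter -> outputs.  All frequency
comparisons are inclusive (a family in exactly 90% of genomes passes the
default threshold).  The only stochastic choice, the pivot draw, flows from
one seed recorded in the run log, so a run is deterministic given its
inputs and seed.
"""

from __future__ import annotations

import dataclasses
import json
import shutil
import subprocess
import tempfile
from pathlib import Path
from typing import Optional

from . import genome_io
from .families import (
    ACTIVE,
    Member,
    OrthologFamily,
    Removal,
    STRINGENT_EXCLUDED,
    build_families,
    family_frequency,
)
from .genome_io import Dataset, load_dataset, write_outputs
from .homology import ScoringConfig, parse_hits_table, search_all
from .paralog_screen import (
    build_genome_profiles,
    screen_double_outliers,
    screen_partial_hidden,
)

BELOW_FREQUENCY = "below_frequency"
CONSENSUS_INCONSISTENT = "consensus_inconsistent"


@dataclasses.dataclass
class RunConfig:
    """Everything a run needs; defaults follow the recommended settings."""

    input_dir: str
    out_dir: str
    pivot: Optional[str] = None
    identity_threshold: float = 90.0
    frequency_threshold: float = 0.9
    length_ratio_threshold: float = 0.8
    stringent: bool = False
    alphabet: str = "protein"
    backend: str = "internal"  # or "tabular:<path>"
    aligner: str = "none"  # none | mafft | muscle | command template
    seed: int = 0
    screen_partial: bool = True
    screen_double: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.identity_threshold <= 100:
            raise ValueError("identity_threshold must be in (0, 100]")
        if not 0 < self.frequency_threshold <= 1:
            raise ValueError("frequency_threshold must be in (0, 1]")
        if not 0 < self.length_ratio_threshold <= 1:
            raise ValueError("length_ratio_threshold must be in (0, 1]")
        if Path(self.input_dir).resolve() == Path(self.out_dir).resolve():
            raise ValueError("out_dir must differ from input_dir")

    def scoring(self) -> ScoringConfig:
        backend = "tabular" if self.backend.startswith("tabular") else "internal"
        return ScoringConfig(
            identity_threshold=self.identity_threshold,
            length_ratio_threshold=self.length_ratio_threshold,
            alphabet=self.alphabet,
            backend=backend,
        )


@dataclasses.dataclass
class CoreGenome:
    """The families passing every screen plus a record of all exclusions."""

    families: list[OrthologFamily]
    excluded: list[tuple[OrthologFamily, str]]
    parameters: Optional[RunConfig]
    n_genomes: int
    pivot_id: str

    def family_ids(self) -> list[str]:
        return sorted(f.pivot_gene_id for f in self.families)

    def member_sets(self) -> dict[str, frozenset[tuple[str, str]]]:
        return {
            f.pivot_gene_id: frozenset(
                (m.genome_id, m.gene_id) for m in f.members.values()
            )
            for f in self.families
        }

    def to_dict(self) -> dict:
        def fam(f: OrthologFamily, status: str) -> dict:
            return {
                "pivot_gene_id": f.pivot_gene_id,
                "status": status,
                "members": [
                    dataclasses.asdict(f.members[g]) for g in sorted(f.members)
                ],
                "within_paralogs": [dataclasses.asdict(w) for w in f.within_paralogs],
                "removals": [dataclasses.asdict(r) for r in f.removals],
            }

        return {
            "parameters": dataclasses.asdict(self.parameters) if self.parameters else None,
            "n_genomes": self.n_genomes,
            "pivot_id": self.pivot_id,
            "families": [fam(f, "core") for f in self.families],
            "excluded": [fam(f, reason) for f, reason in self.excluded],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "CoreGenome":
        def fam(d: dict) -> OrthologFamily:
            f = OrthologFamily(pivot_gene_id=d["pivot_gene_id"])
            for m in d["members"]:
                f.members[m["genome_id"]] = Member(**m)
            from .families import WithinParalog

            f.within_paralogs = [WithinParalog(**w) for w in d["within_paralogs"]]
            f.removals = [Removal(**r) for r in d["removals"]]
            return f

        params = RunConfig(**data["parameters"]) if data["parameters"] else None
        return cls(
            families=[fam(d) for d in data["families"]],
            excluded=[(fam(d), d["status"]) for d in data["excluded"]],
            parameters=params,
            n_genomes=data["n_genomes"],
            pivot_id=data["pivot_id"],
        )

    @classmethod
    def from_run_dir(cls, run_dir: Path | str) -> "CoreGenome":
        with open(Path(run_dir) / "core.json") as fh:
            return cls.from_dict(json.load(fh))


def assemble_core(
    families: list[OrthologFamily],
    n_genomes: int,
    config: RunConfig,
    dataset: Optional[Dataset] = None,
) -> CoreGenome:
    """Apply the final frequency filter and collect exclusion reasons."""
    core: list[OrthologFamily] = []
    excluded: list[tuple[OrthologFamily, str]] = []
    for family in families:
        if family.status == STRINGENT_EXCLUDED:
            excluded.append((family, STRINGENT_EXCLUDED))
        elif family_frequency(family, n_genomes) >= config.frequency_threshold:
            core.append(family)
        else:
            excluded.append((family, BELOW_FREQUENCY))
    pivot_id = dataset.pivot_id if dataset is not None else (config.pivot or "")
    return CoreGenome(
        families=core,
        excluded=excluded,
        parameters=config,
        n_genomes=n_genomes,
        pivot_id=pivot_id,
    )


def run(config: RunConfig, write: bool = True) -> CoreGenome:
    """Execute the full pipeline; deterministic given (inputs, seed)."""
    dataset = load_dataset(
        config.input_dir, pivot=config.pivot, seed=config.seed, alphabet=config.alphabet
    )
    scoring = config.scoring()
    if config.backend.startswith("tabular:"):
        hits = parse_hits_table(config.backend.split(":", 1)[1], dataset, scoring)
    elif config.backend == "internal":
        hits = search_all(dataset, scoring)
    else:
        raise ValueError(f"unknown backend {config.backend!r}")

    families = build_families(dataset, hits, scoring)
    n = dataset.n_genomes
    if config.screen_partial:
        for family in families:
            screen_partial_hidden(family, stringent=config.stringent)
    putative = [
        f
        for f in families
        if f.status == ACTIVE and family_frequency(f, n) >= config.frequency_threshold
    ]
    profiles = build_genome_profiles(
        families, n, config.frequency_threshold, genome_ids=dataset.genome_ids
    )
    if config.screen_double:
        for family in putative:
            screen_double_outliers(family, profiles, stringent=config.stringent)
    core = assemble_core(families, n, config, dataset=dataset)
    if write:
        out_dir = Path(config.out_dir)
        try:
            write_outputs(core, dataset, out_dir)
            if config.aligner != "none" and core.families:
                align_and_concatenate(
                    core, dataset, config.aligner, out_dir / "core_alignment.fasta"
                )
        except Exception:
            shutil.rmtree(out_dir, ignore_errors=True)
            raise
    return core


def _check_consensus_parameters(a: Optional[RunConfig], b: Optional[RunConfig]) -> None:
    if a is None or b is None:
        return
    ignored = {"pivot", "out_dir"}
    da, db = dataclasses.asdict(a), dataclasses.asdict(b)
    differing = [k for k in da if k not in ignored and da[k] != db[k]]
    if differing:
        raise ValueError(
            "consensus requires identical parameters apart from the pivot; "
            f"differing fields: {sorted(differing)}"
        )


def consensus(core_a: CoreGenome, core_b: CoreGenome) -> CoreGenome:
    """Consensus of two runs that used different pivot genomes.

    Families are matched when their member gene sets overlap by more than
    half of the smaller set.  A matched pair is kept (once) when the member
    sets differ by at most the two pivot genes themselves; matched but
    inconsistent pairs are excluded.  A family found in only one run is kept
    only if it has no member from the other run's pivot genome, i.e. its
    pivot gene has no detected homolog there -- which is precisely the case
    a second pivot is meant to rescue.
    """
    _check_consensus_parameters(core_a.parameters, core_b.parameters)
    sets_a = core_a.member_sets()
    sets_b = core_b.member_sets()
    index_b: dict[tuple[str, str], str] = {}
    for fid, members in sets_b.items():
        for key in members:
            index_b[key] = fid

    pivots = {core_a.pivot_id, core_b.pivot_id}
    fams_a = {f.pivot_gene_id: f for f in core_a.families}
    fams_b = {f.pivot_gene_id: f for f in core_b.families}

    kept: list[OrthologFamily] = []
    excluded: list[tuple[OrthologFamily, str]] = []
    matched_b: set[str] = set()
    for fid_a in sorted(sets_a):
        members_a = sets_a[fid_a]
        overlap_counts: dict[str, int] = {}
        for key in members_a:
            fid_b = index_b.get(key)
            if fid_b is not None:
                overlap_counts[fid_b] = overlap_counts.get(fid_b, 0) + 1
        best = None
        for fid_b in sorted(overlap_counts):
            if overlap_counts[fid_b] > 0.5 * min(len(members_a), len(sets_b[fid_b])):
                if best is None or overlap_counts[fid_b] > overlap_counts[best]:
                    best = fid_b
        if best is None:
            if any(g == core_b.pivot_id for g, _ in members_a):
                excluded.append((fams_a[fid_a], CONSENSUS_INCONSISTENT))
            else:
                kept.append(fams_a[fid_a])
            continue
        matched_b.add(best)
        diff = members_a.symmetric_difference(sets_b[best])
        if len(diff) <= 2 and all(g in pivots for g, _ in diff):
            kept.append(fams_a[fid_a])
        else:
            excluded.append((fams_a[fid_a], CONSENSUS_INCONSISTENT))

    for fid_b in sorted(sets_b):
        if fid_b in matched_b:
            continue
        if any(g == core_a.pivot_id for g, _ in sets_b[fid_b]):
            excluded.append((fams_b[fid_b], CONSENSUS_INCONSISTENT))
        else:
            kept.append(fams_b[fid_b])

    kept.sort(key=lambda f: f.pivot_gene_id)
    return CoreGenome(
        families=kept,
        excluded=excluded,
        parameters=core_a.parameters,
        n_genomes=core_a.n_genomes,
        pivot_id=core_a.pivot_id,
    )


_ALIGNER_TEMPLATES = {
    "mafft": "mafft --quiet --retree 2 {input}",
    "muscle": "muscle -align {input} -output {output}",
}


def align_and_concatenate(
    core: CoreGenome,
    dataset: Dataset,
    aligner: str = "mafft",
    out_path: Path | str = "core_alignment.fasta",
) -> Path:
    """Align each core family externally and concatenate one row per genome.

    Families are processed in sorted pivot-gene-id order; a genome missing
    from a family contributes a gap run of that family's alignment length.
    The command template uses ``{input}``/``{output}`` placeholders; when
    ``{output}`` is absent the aligner's stdout is captured (mafft style).
    """
    if not core.families:
        raise ValueError("core genome is empty; nothing to align")
    template = _ALIGNER_TEMPLATES.get(aligner, aligner)
    exe = template.split()[0]
    if shutil.which(exe) is None:
        raise RuntimeError(f"dependency missing: aligner executable {exe!r} not found")

    out_path = Path(out_path)
    rows: dict[str, list[str]] = {gid: [] for gid in dataset.genome_ids}
    for family in sorted(core.families, key=lambda f: f.pivot_gene_id):
        with tempfile.TemporaryDirectory() as tmp:
            fam_in = Path(tmp) / "family.fasta"
            fam_out = Path(tmp) / "family_aligned.fasta"
            members = sorted(family.members.values(), key=lambda m: m.genome_id)
            genome_io.write_fasta(
                ((m.genome_id, dataset.gene(m.genome_id, m.gene_id).sequence)
                 for m in members),
                fam_in,
            )
            cmd = [
                part.format(input=str(fam_in), output=str(fam_out))
                for part in template.split()
            ]
            capture = "{output}" not in template
            result = subprocess.run(cmd, capture_output=True, text=True)
            if result.returncode != 0:
                raise RuntimeError(
                    f"aligner failed on family {family.pivot_gene_id}: "
                    f"{result.stderr.strip()[:500]}"
                )
            if capture:
                fam_out.write_text(result.stdout)
            aligned = {}
            from Bio import SeqIO

            for record in SeqIO.parse(str(fam_out), "fasta"):
                aligned[record.id] = str(record.seq).upper()
            lengths = {len(s) for s in aligned.values()}
            if len(lengths) != 1:
                raise RuntimeError(
                    f"aligner produced unequal row lengths for family "
                    f"{family.pivot_gene_id}"
                )
            width = lengths.pop()
            for gid in rows:
                rows[gid].append(aligned.get(gid, "-" * width))
    genome_io.write_fasta(
        ((gid, "".join(parts)) for gid, parts in sorted(rows.items())), out_path
    )
    return out_path
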