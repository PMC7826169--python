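"""Seeded genome simulator with ortholog/paralog truth labels.

The generator emulates exactly the structure the screening procedure
consumes: a shared ancestral gene set, per-genome divergence from a
complete pivot genome, per-gene loss, and paralog/xenolog placements in
four canonical configurations --

* ``A`` -- the ortholog is present everywhere, no extra copies;
* ``B`` -- within-paralogs: one or more genomes carry the ortholog plus a
  more divergent co-resident copy;
* ``C`` -- partially hidden: some genomes carry only the paralog (ortholog
  lost) while at least one other genome still carries both copies;
* ``D`` -- completely hidden: some genomes carry only the paralog and no
  genome retains a co-resident copy.

Mutation is substitution-only, so every planted identity to the pivot gene
is exact by Hamming count and independent of aligner gap parameters.
Genome 1 carries unmutated ancestral copies of every gene and is the
documented pivot for deterministic tests.  Hidden copies in scenario C are
planted strictly below the family's within-paralogs (the displaced copy is
the older, more divergent one), which is the configuration the
partial-hidden screen is designed to exploit; hidden copies in scenario C
are also planted in enough genomes that they are not vertical outliers of
their own family, leaving the partial-hidden screen as the only step that
can catch them.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .core_builder import CoreGenome
from .genome_io import write_fasta

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

ORTHOLOG = "ortholog"
WITHIN_PARALOG = "within_paralog"
HIDDEN_PARALOG = "hidden_paralog"
LOST = "lost"
PARALOG_LABELS = (WITHIN_PARALOG, HIDDEN_PARALOG)


@dataclasses.dataclass
class SimulationParams:
    """Study conditions of one simulated genome set."""

    n_genomes: int = 20
    n_genes: int = 100
    gene_length_range: tuple[int, int] = (150, 400)
    divergence_range: tuple[float, float] = (94.0, 98.0)
    loss_prob: float = 0.02
    scenario_counts: dict[str, int] = dataclasses.field(
        default_factory=lambda: {"A": 70, "B": 10, "C": 10, "D": 10}
    )
    paralog_identity_offset: float = 20.0
    # hidden copies in scenario C sit this many points below the family's
    # most conserved within-paralog
    hidden_extra_offset: float = 3.0
    n_within_hosts: int = 2
    # fraction of non-pivot genomes carrying the hidden copy in scenario C;
    # large enough that the copies shift Q1 of their own family and escape
    # the vertical outlier test
    c_hidden_fraction: float = 0.35
    d_max_hidden: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 2 or self.n_genes < 1:
            raise ValueError("need at least 2 genomes and 1 gene")
        if sum(self.scenario_counts.values()) > self.n_genes:
            raise ValueError("scenario counts exceed n_genes")
        if any(c < 0 for c in self.scenario_counts.values()):
            raise ValueError("scenario counts must be >= 0")
        if self.paralog_identity_offset <= 0 or self.hidden_extra_offset <= 0:
            raise ValueError("identity offsets must be > 0")
        lo, hi = self.divergence_range
        if not 0 < lo <= hi <= 100:
            raise ValueError("divergence_range must satisfy 0 < lo <= hi <= 100")
        n_nonpivot = self.n_genomes - 1
        if self.scenario_counts.get("C", 0) > 0:
            if self.n_genomes < 3:
                raise ValueError("scenario C requires at least 3 genomes")
            if self.n_hidden_hosts_c + 1 > n_nonpivot:
                raise ValueError("scenario C needs a within host besides the hidden hosts")
        if self.scenario_counts.get("D", 0) > 0 and self.n_genomes < 3:
            raise ValueError("scenario D requires at least 3 genomes")
        floor = lo - self.paralog_identity_offset - self.hidden_extra_offset
        if floor <= 5:
            raise ValueError("paralog offsets leave no signal above background identity")

    @property
    def n_hidden_hosts_c(self) -> int:
        return max(1, round(self.c_hidden_fraction * (self.n_genomes - 1)))


@dataclasses.dataclass(frozen=True)
class TruthRow:
    genome_id: str
    gene_id: str  # "-" for a lost placement
    family_id: str
    label: str
    scenario: str


class TruthTable:
    """Ground-truth labels for every simulated gene placement."""

    def __init__(self, rows: list[TruthRow]):
        self.rows = rows
        self.by_gene: dict[tuple[str, str], TruthRow] = {
            (r.genome_id, r.gene_id): r for r in rows if r.gene_id != "-"
        }
        self.scenario_of: dict[str, str] = {}
        self._fam_rows: dict[str, list[TruthRow]] = {}
        for r in rows:
            self.scenario_of[r.family_id] = r.scenario
            self._fam_rows.setdefault(r.family_id, []).append(r)

    @property
    def family_ids(self) -> list[str]:
        return sorted(self._fam_rows)

    def family_rows(self, family_id: str) -> list[TruthRow]:
        return self._fam_rows[family_id]

    def ortholog_count(self, family_id: str) -> int:
        return sum(1 for r in self._fam_rows[family_id] if r.label == ORTHOLOG)

    def write_tsv(self, path: Path | str) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("genome_id\tgene_id\tfamily_id\tlabel\tscenario\n")
            for r in self.rows:
                fh.write(f"{r.genome_id}\t{r.gene_id}\t{r.family_id}\t{r.label}\t{r.scenario}\n")
        return path

    @classmethod
    def read_tsv(cls, path: Path | str) -> "TruthTable":
        rows = []
        with open(path) as fh:
            next(fh)
            for line in fh:
                genome_id, gene_id, family_id, label, scenario = line.rstrip("\n").split("\t")
                rows.append(TruthRow(genome_id, gene_id, family_id, label, scenario))
        return cls(rows)


def mutate_to_identity(
    seq: str,
    target_identity: float,
    seed: Union[int, np.random.Generator],
) -> str:
    """Substitute positions so Hamming identity to *seq* is round-exact.

    Exactly ``round(L * (1 - t/100))`` positions, chosen uniformly without
    replacement, are replaced by a different residue; no indels, so the
    identity under any gapless comparison equals the planted value to within
    rounding at resolution ``100/L``.
    """
    if not 0 < target_identity <= 100:
        raise ValueError("target_identity must be in (0, 100]")
    L = len(seq)
    if target_identity < 100.0 / L:
        raise ValueError(
            f"target identity {target_identity} below the 1-residue resolution 100/{L}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_sub = round(L * (1.0 - target_identity / 100.0))
    if n_sub == 0:
        return seq
    positions = rng.choice(L, size=n_sub, replace=False)
    out = list(seq)
    for pos in positions:
        current = out[pos]
        choices = AMINO_ACIDS[AMINO_ACIDS != current]
        out[pos] = str(rng.choice(choices))
    return "".join(out)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS, size=length))


def simulate(
    params: SimulationParams, out_dir: Path | str
) -> tuple[Path, TruthTable]:
    """Write one FASTA per genome plus ``truth.tsv``; returns (dir, truth).

    Deterministic: the same parameters and seed yield a byte-identical file
    set.  Genome 1 (the first identifier in sorted order) is complete and
    holds exact ancestral sequences, making it the natural pivot.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(params.seed)

    genome_ids = [f"genome{i + 1:03d}" for i in range(params.n_genomes)]
    pivot_id = genome_ids[0]
    nonpivot = genome_ids[1:]
    divergence = {pivot_id: 100.0}
    lo, hi = params.divergence_range
    for gid in nonpivot:
        divergence[gid] = float(rng.uniform(lo, hi))

    scenarios: list[str] = []
    for tag in ("A", "B", "C", "D"):
        scenarios.extend([tag] * params.scenario_counts.get(tag, 0))
    scenarios.extend(["A"] * (params.n_genes - len(scenarios)))

    lmin, lmax = params.gene_length_range
    placements: dict[str, list[tuple[str, str, str, str]]] = {g: [] for g in genome_ids}
    truth_rows: list[TruthRow] = []

    for idx, scenario in enumerate(scenarios):
        family_id = f"fam{idx + 1:04d}"
        length = int(rng.integers(lmin, lmax + 1))
        ancestor = _random_sequence(rng, length)

        within_hosts: list[str] = []
        hidden_hosts: list[str] = []
        if scenario == "B":
            k = min(params.n_within_hosts, len(nonpivot))
            within_hosts = [nonpivot[i] for i in sorted(rng.choice(len(nonpivot), k, replace=False))]
        elif scenario == "C":
            n_hidden = params.n_hidden_hosts_c
            k = min(params.n_within_hosts, len(nonpivot) - n_hidden)
            order = rng.permutation(len(nonpivot))
            hidden_hosts = [nonpivot[i] for i in sorted(order[:n_hidden])]
            within_hosts = [nonpivot[i] for i in sorted(order[n_hidden:n_hidden + k])]
        elif scenario == "D":
            n_hidden = int(rng.integers(1, params.d_max_hidden + 1))
            hidden_hosts = [nonpivot[i] for i in sorted(rng.choice(len(nonpivot), n_hidden, replace=False))]

        protected = set(within_hosts) | set(hidden_hosts) | {pivot_id}
        within_targets = {
            g: divergence[g] - params.paralog_identity_offset for g in within_hosts
        }
        if scenario == "C":
            hidden_target = min(within_targets.values()) - params.hidden_extra_offset

        for gid in genome_ids:
            if gid in hidden_hosts:
                if scenario == "C":
                    target = hidden_target
                else:
                    target = divergence[gid] - params.paralog_identity_offset
                seq = mutate_to_identity(ancestor, target, rng)
                placements[gid].append((family_id, HIDDEN_PARALOG, scenario, seq))
                truth_rows.append(TruthRow(gid, "?", family_id, LOST, scenario))
                continue
            if gid not in protected and rng.random() < params.loss_prob:
                truth_rows.append(TruthRow(gid, "-", family_id, LOST, scenario))
                continue
            seq = (
                ancestor
                if gid == pivot_id
                else mutate_to_identity(ancestor, divergence[gid], rng)
            )
            placements[gid].append((family_id, ORTHOLOG, scenario, seq))
            if gid in within_hosts:
                wseq = mutate_to_identity(ancestor, within_targets[gid], rng)
                placements[gid].append((family_id, WITHIN_PARALOG, scenario, wseq))

    # "lost" rows created above for hidden hosts used a placeholder gene id;
    # drop them (the hidden copy itself is the record of that event).
    truth_rows = [r for r in truth_rows if r.gene_id != "?"]

    final_rows: list[TruthRow] = []
    for gid in genome_ids:
        entries = placements[gid]
        order = rng.permutation(len(entries))
        records = []
        for k, idx in enumerate(order):
            family_id, label, scenario, seq = entries[idx]
            gene_id = f"{gid}_g{k + 1:04d}"
            records.append((gene_id, seq))
            final_rows.append(TruthRow(gid, gene_id, family_id, label, scenario))
        write_fasta(records, out_dir / f"{gid}.fasta")

    final_rows.extend(truth_rows)
    truth = TruthTable(final_rows)
    truth.write_tsv(out_dir / "truth.tsv")
    return out_dir, truth


def evaluate(core: CoreGenome, truth: TruthTable) -> dict:
    """Score a core genome against the simulation's truth labels.

    Ortholog recall is reported both raw (over every planted ortholog) and
    normalised to *achievable* families: those whose surviving-ortholog
    frequency meets the run's threshold, i.e. families an oracle screener
    would itself keep.  Paralog-exclusion recall is the fraction of planted
    paralog placements kept out of the output.
    """
    if core.parameters is None:
        raise ValueError("core genome carries no parameter snapshot")
    thr = core.parameters.frequency_threshold
    n = core.n_genomes

    core_placements: dict[tuple[str, str], str] = {}
    fam_of_core: dict[str, str] = {}
    for family in core.families:
        pivot_key = (core.pivot_id, family.pivot_gene_id)
        if pivot_key not in truth.by_gene:
            raise ValueError(f"core pivot gene {pivot_key} absent from truth table")
        fam_of_core[family.pivot_gene_id] = truth.by_gene[pivot_key].family_id
        for member in family.members.values():
            key = (member.genome_id, member.gene_id)
            if key not in truth.by_gene:
                raise ValueError(f"core gene {key} absent from truth table (contamination)")
            core_placements[key] = truth.by_gene[key].label

    oracle_core = {
        fid: truth.ortholog_count(fid) / n >= thr for fid in truth.family_ids
    }
    in_core_truth_fams = set(fam_of_core.values())

    paralogs_planted = sum(1 for r in truth.rows if r.label in PARALOG_LABELS)
    paralogs_in_core = sum(1 for lbl in core_placements.values() if lbl in PARALOG_LABELS)

    orth_in_core = sum(1 for lbl in core_placements.values() if lbl == ORTHOLOG)
    orth_total = sum(1 for r in truth.rows if r.label == ORTHOLOG)
    orth_in_core_ach = sum(
        1
        for key, lbl in core_placements.items()
        if lbl == ORTHOLOG and oracle_core[truth.by_gene[key].family_id]
    )
    orth_total_ach = sum(
        truth.ortholog_count(fid) for fid in truth.family_ids if oracle_core[fid]
    )

    removal_labels = []
    for family in list(core.families) + [f for f, _ in core.excluded]:
        for removal in family.removals:
            row = truth.by_gene.get((removal.genome_id, removal.gene_id))
            if row is not None:
                removal_labels.append(row.label)
    removed_paralogs = sum(1 for lbl in removal_labels if lbl in PARALOG_LABELS)

    scenario_outcomes: dict[str, dict[str, int]] = {}
    scenario_misses: dict[str, int] = {}
    for fid in truth.family_ids:
        tag = truth.scenario_of[fid]
        out = scenario_outcomes.setdefault(
            tag,
            {"families": 0, "in_core": 0, "oracle_core": 0, "oracle_core_in_core": 0,
             "paralog_misses": 0},
        )
        out["families"] += 1
        in_core = fid in in_core_truth_fams
        if in_core:
            out["in_core"] += 1
        if oracle_core[fid]:
            out["oracle_core"] += 1
            if in_core:
                out["oracle_core_in_core"] += 1
    for key, lbl in core_placements.items():
        if lbl in PARALOG_LABELS:
            tag = truth.scenario_of[truth.by_gene[key].family_id]
            scenario_outcomes[tag]["paralog_misses"] += 1
            scenario_misses[tag] = scenario_misses.get(tag, 0) + 1

    return {
        "n_truth_rows": len(truth.rows),
        "n_core_families": len(core.families),
        "paralogs_planted": paralogs_planted,
        "paralogs_in_core": paralogs_in_core,
        "paralog_exclusion_recall": (
            1.0 if paralogs_planted == 0
            else (paralogs_planted - paralogs_in_core) / paralogs_planted
        ),
        "removal_precision": (
            1.0 if not removal_labels else removed_paralogs / len(removal_labels)
        ),
        "ortholog_recall_raw": 0.0 if orth_total == 0 else orth_in_core / orth_total,
        "ortholog_recall": (
            0.0 if orth_total_ach == 0 else orth_in_core_ach / orth_total_ach
        ),
        "scenario_outcomes": scenario_outcomes,
        "scenario_misses": scenario_misses,
    }
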