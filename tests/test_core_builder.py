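import dataclasses
import shutil

import pytest

from corecrunch import (
    CoreGenome,
    RunConfig,
    SimulationParams,
    align_and_concatenate,
    assemble_core,
    consensus,
    load_dataset,
    read_genome_fasta,
    run,
    simulate,
    write_outputs,
)
from corecrunch.families import Member, OrthologFamily

from conftest import make_genome_dir


def _family(pivot_gene, members):
    fam = OrthologFamily(pivot_gene_id=pivot_gene)
    for gid, gene, ident in members:
        fam.members[gid] = Member(gid, gene, ident)
    return fam


def _config(tmp_path, **kw):
    kwargs = dict(input_dir=str(tmp_path / "in"), out_dir=str(tmp_path / "out"))
    kwargs.update(kw)
    return RunConfig(**kwargs)


class TestAssembleCore:
    def _families(self, n_members_list):
        fams = []
        for k, n in enumerate(n_members_list):
            fams.append(
                _family(f"p{k}", [(f"g{i}", f"g{i}_x{k}", 95.0) for i in range(n)])
            )
        return fams

    def test_frequency_boundary_inclusive(self, tmp_path):
        config = _config(tmp_path, frequency_threshold=0.9)
        core = assemble_core(self._families([9, 8, 10]), n_genomes=10, config=config)
        assert [f.pivot_gene_id for f in core.families] == ["p0", "p2"]
        assert [(f.pivot_gene_id, r) for f, r in core.excluded] == [("p1", "below_frequency")]

    def test_threshold_one_requires_all_genomes(self, tmp_path):
        config = _config(tmp_path, frequency_threshold=1.0)
        core = assemble_core(self._families([9, 10]), n_genomes=10, config=config)
        assert [f.pivot_gene_id for f in core.families] == ["p1"]

    def test_stringent_families_never_core(self, tmp_path):
        fams = self._families([10, 10])
        fams[0].status = "stringent_excluded"
        config = _config(tmp_path, frequency_threshold=0.9)
        core = assemble_core(fams, n_genomes=10, config=config)
        assert [f.pivot_gene_id for f in core.families] == ["p1"]
        assert core.excluded[0][1] == "stringent_excluded"


class TestWriteOutputs:
    def test_empty_core_gives_header_only_summary(self, tmp_path):
        directory = make_genome_dir(
            tmp_path / "in", {"P": {"p1": "MKVLLE"}, "B": {"b1": "MKVLLD"}}
        )
        dataset = load_dataset(directory, pivot="P")
        core = CoreGenome(families=[], excluded=[], parameters=None,
                          n_genomes=2, pivot_id="P")
        summary = write_outputs(core, dataset, tmp_path / "out")
        lines = summary.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("family_id")
        assert list((tmp_path / "out" / "families").iterdir()) == []

    def test_family_fastas_and_summary_counts_agree(self, tmp_path):
        directory = make_genome_dir(
            tmp_path / "in",
            {
                "P": {"p1": "MKVLLE", "p2": "WWYYHH"},
                "B": {"b1": "MKVLLD", "b2": "WWYYHE"},
                "C": {"c1": "MKVLLN", "c2": "WWYYHD"},
            },
        )
        dataset = load_dataset(directory, pivot="P")
        fams = [
            _family("p1", [("P", "p1", 100.0), ("B", "b1", 95.0), ("C", "c1", 95.0)]),
            _family("p2", [("P", "p2", 100.0), ("B", "b2", 95.0), ("C", "c2", 95.0)]),
        ]
        core = CoreGenome(families=fams, excluded=[], parameters=None,
                          n_genomes=3, pivot_id="P")
        summary = write_outputs(core, dataset, tmp_path / "out")
        rows = [line.split("\t") for line in summary.read_text().splitlines()[1:]]
        assert len(rows) == 2
        for row in rows:
            fasta = tmp_path / "out" / "families" / f"{row[0]}.fasta"
            genome = read_genome_fasta(fasta)
            assert len(genome.genes) == int(row[1]) == 3
            # headers are genome|gene and sequences match the dataset
            for record in genome.genes:
                genome_id, gene_id = record.gene_id.split("|")
                assert dataset.gene(genome_id, gene_id).sequence == record.sequence

    def test_refuses_overwrite_without_flag(self, tmp_path):
        directory = make_genome_dir(
            tmp_path / "in", {"P": {"p1": "MKVLLE"}, "B": {"b1": "MKVLLD"}}
        )
        dataset = load_dataset(directory, pivot="P")
        fams = [_family("p1", [("P", "p1", 100.0), ("B", "b1", 95.0)])]
        core = CoreGenome(families=fams, excluded=[], parameters=None,
                          n_genomes=2, pivot_id="P")
        write_outputs(core, dataset, tmp_path / "out")
        with pytest.raises(FileExistsError):
            write_outputs(core, dataset, tmp_path / "out")
        write_outputs(core, dataset, tmp_path / "out", overwrite=True)


class TestRun:
    def test_no_paralogs_no_loss_recovers_every_family(self, tmp_path):
        params = SimulationParams(
            n_genomes=5, n_genes=10, scenario_counts={"A": 10}, loss_prob=0.0,
            gene_length_range=(100, 160), seed=3,
        )
        data_dir, _ = simulate(params, tmp_path / "data")
        core = run(RunConfig(input_dir=str(data_dir), out_dir=str(tmp_path / "out"),
                             pivot="genome001", identity_threshold=90.0, seed=3))
        assert len(core.families) == 10
        assert all(len(f.members) == 5 for f in core.families)

    def test_deleted_gene_drops_family_by_frequency(self, tmp_path):
        params = SimulationParams(
            n_genomes=5, n_genes=10, scenario_counts={"A": 10}, loss_prob=0.0,
            gene_length_range=(100, 160), seed=3,
        )
        data_dir, truth = simulate(params, tmp_path / "data")
        # delete one family's ortholog from two genomes
        victims = [r for r in truth.rows if r.family_id == "fam0002"
                   and r.genome_id in ("genome002", "genome003")]
        for row in victims:
            path = data_dir / f"{row.genome_id}.fasta"
            genome = read_genome_fasta(path)
            keep = [(g.gene_id, g.sequence) for g in genome.genes if g.gene_id != row.gene_id]
            path.write_text("".join(f">{gid}\n{seq}\n" for gid, seq in keep))
        core = run(RunConfig(input_dir=str(data_dir), out_dir=str(tmp_path / "out"),
                             pivot="genome001", identity_threshold=90.0, seed=3))
        assert len(core.families) == 9
        excluded = {f.pivot_gene_id: r for f, r in core.excluded}
        fam2_pivot_gene = next(r.gene_id for r in truth.rows
                               if r.family_id == "fam0002" and r.genome_id == "genome001")
        assert excluded == {fam2_pivot_gene: "below_frequency"}

    def test_same_seed_byte_identical_summary(self, tmp_path):
        params = SimulationParams(
            n_genomes=6, n_genes=8, scenario_counts={"A": 6, "B": 1, "D": 1},
            gene_length_range=(100, 160), seed=9,
        )
        data_dir, _ = simulate(params, tmp_path / "data")
        summaries = []
        for k in (1, 2):
            out = tmp_path / f"out{k}"
            run(RunConfig(input_dir=str(data_dir), out_dir=str(out),
                          identity_threshold=70.0, seed=5))
            summaries.append((out / "summary.tsv").read_bytes())
        assert summaries[0] == summaries[1]


class TestConsensus:
    @pytest.fixture
    def two_pivot_runs(self, tmp_path):
        params = SimulationParams(
            n_genomes=10, n_genes=20, scenario_counts={"A": 20}, loss_prob=0.0,
            gene_length_range=(100, 160), seed=21,
        )
        data_dir, truth = simulate(params, tmp_path / "data")
        # delete fam0005's ortholog from genome002 (the second pivot)
        victim = next(r for r in truth.rows
                      if r.family_id == "fam0005" and r.genome_id == "genome002")
        path = data_dir / "genome002.fasta"
        genome = read_genome_fasta(path)
        keep = [(g.gene_id, g.sequence) for g in genome.genes if g.gene_id != victim.gene_id]
        path.write_text("".join(f">{gid}\n{seq}\n" for gid, seq in keep))

        def _run(pivot, out):
            return run(RunConfig(input_dir=str(data_dir), out_dir=str(tmp_path / out),
                                 pivot=pivot, identity_threshold=70.0, seed=21))

        return _run("genome001", "runA"), _run("genome002", "runB"), truth

    def test_idempotent_on_identical_runs(self, two_pivot_runs):
        core_a, _, _ = two_pivot_runs
        merged = consensus(core_a, core_a)
        assert merged.family_ids() == core_a.family_ids()
        assert merged.member_sets() == core_a.member_sets()

    def test_family_missing_from_second_pivot_recovered(self, two_pivot_runs):
        core_a, core_b, truth = two_pivot_runs
        assert len(core_a.families) == 20
        assert len(core_b.families) == 19  # fam0005 invisible to pivot B
        merged = consensus(core_a, core_b)
        assert len(merged.families) == 20
        fam5_pivot_gene = next(r.gene_id for r in truth.rows
                               if r.family_id == "fam0005" and r.genome_id == "genome001")
        assert fam5_pivot_gene in merged.family_ids()
        assert not merged.excluded

    def test_inconsistent_membership_excluded(self, two_pivot_runs):
        core_a, core_b, _ = two_pivot_runs
        # corrupt one matched family in run B: disagree on 3 genomes
        fam_b = core_b.families[0]
        for k, gid in enumerate(sorted(fam_b.members)[:3]):
            fam_b.members[gid] = Member(gid, f"fake_gene_{k}", 95.0)
        merged = consensus(core_a, core_b)
        assert len(merged.families) == len(core_a.families) - 1
        assert [r for _, r in merged.excluded] == ["consensus_inconsistent"]

    def test_differing_parameters_rejected(self, two_pivot_runs):
        core_a, core_b, _ = two_pivot_runs
        core_b.parameters = dataclasses.replace(core_b.parameters, identity_threshold=90.0)
        with pytest.raises(ValueError, match="identity_threshold"):
            consensus(core_a, core_b)


@pytest.mark.skipif(shutil.which("mafft") is None, reason="mafft not on PATH")
class TestAlignAndConcatenate:
    @pytest.fixture
    def small_core(self, tmp_path):
        params = SimulationParams(
            n_genomes=4, n_genes=3, scenario_counts={"A": 3}, loss_prob=0.0,
            gene_length_range=(60, 90), seed=2,
        )
        data_dir, _ = simulate(params, tmp_path / "data")
        dataset = load_dataset(data_dir, pivot="genome001")
        core = run(RunConfig(input_dir=str(data_dir), out_dir=str(tmp_path / "out"),
                             pivot="genome001", identity_threshold=70.0, seed=2))
        return core, dataset

    @staticmethod
    def _read_alignment(path):
        from Bio import SeqIO

        return {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}

    def test_one_row_per_genome_lengths_additive(self, small_core, tmp_path):
        core, dataset = small_core
        out = align_and_concatenate(core, dataset, "mafft", tmp_path / "concat.fasta")
        rows = self._read_alignment(out)
        assert sorted(rows) == dataset.genome_ids
        assert len({len(s) for s in rows.values()}) == 1

    def test_missing_genome_gap_filled(self, small_core, tmp_path):
        core, dataset = small_core
        fam = core.families[0]
        fam.members.pop("genome003")
        out = align_and_concatenate(core, dataset, "mafft", tmp_path / "concat.fasta")
        rows = self._read_alignment(out)
        assert len(rows["genome003"]) == len(rows["genome001"])
        assert "-" in rows["genome003"]

    def test_missing_aligner_is_clear_error(self, small_core, tmp_path):
        core, dataset = small_core
        with pytest.raises(RuntimeError, match="dependency missing"):
            align_and_concatenate(core, dataset, "no_such_aligner_xyz {input}",
                                  tmp_path / "x.fasta")
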