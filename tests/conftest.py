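import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from corecrunch import RunConfig, SimulationParams, run, simulate

SCENARIO_SEEDS = (1, 2, 3, 4, 5)


def make_genome_dir(tmp: Path, genomes: dict[str, dict[str, str]]) -> Path:
    """Write {genome_id: {gene_id: sequence}} as one FASTA per genome."""
    tmp.mkdir(parents=True, exist_ok=True)
    for genome_id, genes in genomes.items():
        with open(tmp / f"{genome_id}.fasta", "w") as fh:
            for gene_id, seq in genes.items():
                fh.write(f">{gene_id}\n{seq}\n")
    return tmp


@pytest.fixture(scope="session")
def scenario_runs(tmp_path_factory):
    """Five seeded simulations at the study conditions (20 genomes, 100
    genes, scenarios A=70/B=10/C=10/D=10, divergence U[94,98], paralog
    offset 20, loss 0.02) run through the full pipeline and through each
    single-screen ablation, all at identity threshold 70 / frequency 0.9."""
    base = tmp_path_factory.mktemp("scenario")
    out = {}
    for seed in SCENARIO_SEEDS:
        data_dir, truth = simulate(SimulationParams(seed=seed), base / f"data{seed}")
        common = dict(
            input_dir=str(data_dir),
            pivot="genome001",
            identity_threshold=70.0,
            frequency_threshold=0.9,
            seed=seed,
        )
        full_dir = base / f"full{seed}"
        out[seed] = {
            "truth": truth,
            "data_dir": data_dir,
            "out_dir": full_dir,
            "full": run(RunConfig(out_dir=str(full_dir), **common)),
            "no_double": run(
                RunConfig(out_dir=str(base / f"nodouble{seed}"), screen_double=False, **common)
            ),
            "no_partial": run(
                RunConfig(out_dir=str(base / f"nopartial{seed}"), screen_partial=False, **common)
            ),
        }
    return out


def small_params(seed: int, **overrides) -> SimulationParams:
    """A scaled-down mixed-scenario dataset for cheap whole-pipeline tests."""
    kwargs = dict(
        n_genomes=10,
        n_genes=30,
        scenario_counts={"A": 18, "B": 4, "C": 4, "D": 4},
        gene_length_range=(120, 250),
        seed=seed,
    )
    kwargs.update(overrides)
    return SimulationParams(**kwargs)
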