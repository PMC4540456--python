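import pytest

from metastruct import synthfix


@pytest.fixture(scope="session")
def small_sim():
    """A small deterministic simulation shared across read-only tests."""
    cfg = synthfix.SimulationConfig(n_genomes=10, seed=42)
    pkg, genomes, truth = synthfix.simulate_package(cfg)
    return cfg, pkg, genomes, truth


@pytest.fixture()
def toy_genomes():
    """Three tiny hand-built genomes with distinct gene inventories."""
    from metastruct.refpkg import Gene, ReferenceGenome

    def genome(gid, fams, ssu):
        cds = [Gene(f, f"enzyme {f}", (f"1.1.1.{i + 1}",), "MKVLA" * 4) for i, f in enumerate(fams)]
        return ReferenceGenome(gid, f"taxon {gid}", ssu, cds)

    ssu = "ACGT" * 10
    return [
        genome("gA", ["famA", "famB", "famC"], ssu),
        genome("gB", ["famA", "famB"], "ACGG" * 10),
        genome("gC", ["famA", "famC"], "ACTT" * 10),
    ]
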