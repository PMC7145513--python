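import pytest

from paralogon import Gene, GenomeMap, SimConfig, WgdConfig, run_pipeline, simulate


def make_genome(species, chrom_gene_ids, biotypes=None):
    """Build a GenomeMap from {chromosome: [gene ids in order]}."""
    biotypes = biotypes or {}
    chroms = {
        c: [
            Gene(g, c, i, biotypes.get(g, "protein_coding"))
            for i, g in enumerate(ids)
        ]
        for c, ids in chrom_gene_ids.items()
    }
    return GenomeMap(species, chroms)


@pytest.fixture(scope="session")
def small_truth():
    """A compact 2R simulation reused across tests (2 outgroups, light SSD)."""
    cfg = SimConfig(
        n_genes=600,
        n_chromosomes=4,
        wgd_rounds=2,
        retention_prob=0.25,
        n_inversions=10,
        n_translocations=3,
        ssd_rate=0.02,
        n_outgroups=2,
        outgroup_loss_prob=0.15,
        seed=11,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def small_cfg():
    return WgdConfig(window_sizes=(50, 100), target_epochs={"WGD_1", "WGD_2"})


@pytest.fixture(scope="session")
def small_result(small_truth, small_cfg):
    return run_pipeline(
        small_truth.target,
        small_truth.outgroups,
        small_truth.orthologs,
        small_truth.paralogs,
        small_cfg,
    )
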