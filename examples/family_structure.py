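"""Ohnolog family sizes and the coupling between successive WGD rounds.

Two WGD rounds can produce at most four co-orthologous copies, so 2R
families should rarely exceed four members, and single-round (3R-like)
families should almost all have exactly two.  The example also doubles the
later-round retention odds for genes already in a retained earlier pair and
recovers that coupling as a gene-level odds ratio.
"""
from paralogon import (
    SimConfig,
    cross_wgd_enrichment,
    family_size_distribution,
    simulate,
)
from paralogon.calling import OhnologFamily

truth = simulate(SimConfig(n_genes=2000, n_chromosomes=8, wgd_rounds=2,
                           retention_prob=0.25, retention_odds_multiplier=2.0,
                           n_outgroups=0, seed=3))

for epoch in sorted(truth.true_families):
    fams = [OhnologFamily(f"{epoch}_{i}", "truth", m)
            for i, m in enumerate(truth.true_families[epoch])]
    dist = family_size_distribution(fams)
    print(f"{epoch}: {sum(dist.values())} families, size distribution {dict(sorted(dist.items()))}")

r = cross_wgd_enrichment(
    truth.true_families["WGD_1"], truth.true_families["WGD_2"],
    [g.gene_id for g in truth.target.genes()],
)
print()
print("2x2 table (rows: in a first-round pair yes/no; cols: retains a"
      " second-round partner yes/no):")
print(r.table.astype(int))
print(f"odds ratio = {r.odds_ratio:.3f} (simulated value 2), "
      f"chi-square = {r.chi_square:.1f}")
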