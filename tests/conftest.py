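import pandas as pd
import pytest

from ohnoscope.io import GeneCatalog, GeneModel, HomologyHitSet, HIT_COLUMNS
from ohnoscope.simulate import (ExprSimParams, GenomeSimParams,
                                simulate_expression, simulate_wgd_genome)


def make_catalog(scaffold_sizes: dict[str, int], genome_id="g",
                 gene_prefix="") -> GeneCatalog:
    """Catalog with ``n`` evenly spaced single-exon genes per scaffold.

    Gene ids are ``{prefix}{scaffold}_{i}`` with rank i.
    """
    genes = []
    for scaf, n in scaffold_sizes.items():
        for i in range(n):
            start = 1000 * i + 1
            genes.append(GeneModel(gene_id=f"{gene_prefix}{scaf}_{i}",
                                   scaffold_id=scaf, start=start,
                                   end=start + 500, strand="+"))
    return GeneCatalog(genome_id, genes)


def make_hits(pairs, filtered=True) -> HomologyHitSet:
    """Hit set from (query, subject) id pairs, reciprocal, passing filters."""
    rows = []
    for q, s in pairs:
        for a, b in ((q, s), (s, q)):
            rows.append((a, b, 90.0, 100, 0, 0, 1, 100, 1, 100, 1e-50,
                         200.0, 90.0, 90.0))
    return HomologyHitSet(pd.DataFrame(rows, columns=HIT_COLUMNS),
                          filtered=filtered)


@pytest.fixture(scope="session")
def sim_genome():
    """A small simulated post-WGD genome shared across tests."""
    params = GenomeSimParams(seed=42, n_ancestral_genes=120, n_scaffolds=3)
    return simulate_wgd_genome(params)


@pytest.fixture(scope="session")
def sim_experiment(sim_genome):
    catalog, hits, truth, seqs = sim_genome
    counts, samples, bin_counts, junctions, truth = simulate_expression(
        catalog, truth, ExprSimParams(seed=43))
    return dict(catalog=catalog, hits=hits, truth=truth, seqs=seqs,
                counts=counts, samples=samples, bin_counts=bin_counts,
                junctions=junctions)
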