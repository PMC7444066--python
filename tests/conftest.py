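import pytest

import tsrnakit as tk


@pytest.fixture(scope="session")
def toy_gene():
    return tk.make_trna_gene(seed=1, isotype="Thr", anticodon="TGT")


@pytest.fixture(scope="session")
def toy_ref(toy_gene):
    return tk.build_mature_reference(toy_gene)


@pytest.fixture(scope="session")
def gene_panel():
    return tk.make_gene_panel(seed=10, n_genes=4)


@pytest.fixture(scope="session")
def refs(gene_panel):
    return [tk.build_mature_reference(g) for g in gene_panel]


@pytest.fixture(scope="session")
def contaminants():
    mirna, rrna = tk.make_contaminants(seed=3)
    return mirna, rrna


@pytest.fixture(scope="session")
def small_simulation(refs, contaminants):
    """One-replicate day-0/day-7 simulation shared across tests."""
    mirna, rrna = contaminants
    profile = tk.SimulationProfile(n_reads_per_sample=1500, replicates=1,
                                   days=(0, 7), seed=11)
    reads, truth = tk.simulate_reads(refs, mirna, rrna, profile)
    return profile, reads, truth
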