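import numpy as np
import pandas as pd
import pytest

from ohnodiverge import phylo, simdata


@pytest.fixture(scope="session")
def base_config():
    return simdata.SimulationConfig(seed=7, n_orthogroups=40, p_loss_post_wgd=0.3)


@pytest.fixture(scope="session")
def trees_and_truth(base_config):
    return simdata.simulate_gene_trees(base_config)


@pytest.fixture(scope="session")
def taxon_groups(base_config):
    c = base_config
    return phylo.TaxonGroups(
        salmonids=set(c.salmonids), pike=c.pike, outgroups=set(c.outgroups), focal=c.focal
    )


@pytest.fixture(scope="session")
def synteny_map(base_config, trees_and_truth):
    _, truth = trees_and_truth
    blocks, windows = simdata.simulate_synteny(base_config, truth)
    return phylo.SyntenyMap(blocks=blocks, windows=windows)


@pytest.fixture()
def small_bundle():
    """Tiny deterministic expression bundle: 6 genes x 12 samples."""

    rng = np.random.default_rng(5)
    genes = [f"g{i}" for i in range(6)]
    samples = [f"s{j}" for j in range(12)]
    counts = pd.DataFrame(
        rng.poisson(50, size=(6, 12)), index=genes, columns=samples
    )
    meta = pd.DataFrame(
        {
            "tissue": ["gill"] * 6 + ["brain"] * 6,
            "condition": ["FW"] * 3 + ["SW"] * 3 + ["FW"] * 3 + ["SW"] * 3,
            "time": 0,
            "replicate": list(range(1, 4)) * 4,
        },
        index=pd.Index(samples, name="sample"),
    )
    return simdata.ExpressionBundle(counts=counts, meta=meta)


def random_gene_tree(rng, n_leaves, species_pool):
    """Random binary tree over random species; returns (newick, leaf list).

    Leaves are labelled gene{i}|species|chr:start-end with arbitrary loci.
    """

    labels = []
    for i in range(n_leaves):
        sp = species_pool[rng.integers(len(species_pool))]
        start = int(rng.integers(1, 10_000))
        labels.append(f"gene{i}|{sp}|{int(rng.integers(1, 9))}:{start}-{start + 99}")
    nodes = [f"'{lab}'" for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b})")
    return nodes[0] + ";", labels
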