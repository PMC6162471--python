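import numpy as np
import pytest
from hypothesis import settings

from mirnetmapper.io import InteractionTable

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")


def random_bipartite_edges(
    rng: np.random.Generator, n_mirnas: int, n_genes: int
) -> InteractionTable:
    """Random edge list where every miRNA targets a nonempty gene subset.

    Built directly from the RNG (independent of the package's fixture
    generator) so it can serve as neutral input for oracle comparisons.
    """
    edges = []
    for i in range(n_mirnas):
        k = int(rng.integers(1, max(2, n_genes // 2)))
        targets = rng.choice(n_genes, size=k, replace=False)
        edges.extend((f"m{i:02d}", f"g{j:03d}") for j in sorted(targets))
    return InteractionTable(edges=tuple(edges))


@pytest.fixture
def tiny_inputs(tmp_path):
    """A 5-edge interaction file plus a 4-gene DE list on disk."""
    edges = tmp_path / "edges.tsv"
    edges.write_text("m1\tgA\nm1\tgB\nm2\tgA\nm2\tgB\nm3\tgC\n")
    de = tmp_path / "de.txt"
    de.write_text("gA\ngB\ngC\ngD\n")
    return edges, de
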