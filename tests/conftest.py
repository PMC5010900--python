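import numpy as np
import pytest

from synbreak.formats import AlignmentAnchor, GenomicInterval
from synbreak.phylo import Phylogeny


@pytest.fixture
def quartet_tree() -> Phylogeny:
    """((A,B),(C,R)) with R as the reference leaf."""
    return Phylogeny.from_newick("((A,B),(C,R));")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20250919)


def make_anchor(ref_chrom, rs, re, tgt, ts, te, orientation="+", species="sp"):
    return AlignmentAnchor(
        ref=GenomicInterval(ref_chrom, rs, re),
        tgt=GenomicInterval(tgt, ts, te),
        orientation=orientation,
        species=species,
    )


def random_tree_newick(rng: np.random.Generator, n_leaves: int) -> str:
    """Random rooted binary topology by iterative joining."""
    nodes = [chr(ord("A") + i) for i in range(n_leaves - 1)] + ["R"]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b})")
    return nodes[0] + ";"
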