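import itertools

import numpy as np
import pytest

from cnsevo.intervals import GenomicInterval
from cnsevo.simulate import SimConfig, simulate_clade


def bitmap(intervals, length, chrom="chr1"):
    """Per-base boolean oracle for interval-algebra checks."""
    arr = np.zeros(length, dtype=bool)
    for iv in intervals:
        if iv.chrom == chrom:
            arr[iv.start:iv.end] = True
    return arr


def random_track(rng, n, length, chrom="chr1"):
    out = []
    for _ in range(n):
        s = int(rng.integers(0, length - 2))
        e = int(rng.integers(s + 1, min(length, s + 1 + rng.integers(1, 200)) + 1))
        out.append(GenomicInterval(chrom, s, min(e, length)))
    return out


def rooted_shapes(n):
    """All rooted binary tree shapes with n leaves, as '*' skeletons."""
    if n == 1:
        return ["*"]
    out = set()
    for k in range(1, n // 2 + 1):
        for a in rooted_shapes(k):
            for b in rooted_shapes(n - k):
                out.add("(" + ",".join(sorted([a, b])) + ")")
    return sorted(out)


def shape_to_newick(shape, prefix="L", lengths=None, rng=None):
    """Label a shape's leaves L1.. and optionally add branch lengths."""
    counter = itertools.count(1)
    chars = []
    for c in shape:
        if c == "*":
            chars.append(f"{prefix}{next(counter)}")
        else:
            chars.append(c)
    newick = "".join(chars) + ";"
    if rng is None:
        return newick
    # attach random positive lengths to every edge
    from skbio import TreeNode
    import io
    t = TreeNode.read(io.StringIO(newick), format="newick")
    for node in t.traverse(include_self=False):
        node.length = float(rng.uniform(0.05, 1.0))
    return str(t).strip()


@pytest.fixture(scope="session")
def small_clade():
    """One modest simulated clade shared by read-only tests."""
    cfg = SimConfig(
        tree="((A:0.05,(B:0.04,C:0.04)bc:0.02)ing:0.10,(O1:0.10,O2:0.12)out:0.06)root;",
        genome_length=150_000,
        n_genes=15,
        n_elements=50,
        variants_per_kb=3.0,
        seed=11,
    )
    return simulate_clade(cfg)
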