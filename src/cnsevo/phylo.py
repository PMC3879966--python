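"""Ancestral-CNS retention/loss bookkeeping and NJ tree reconstruction.

Loss mapping follows the Dollo premise: every ancestral CNS (a row of the
presence matrix, built on an outgroup-referenced union of pairwise hits)
originated once, so the observed absences are explained by losses only.
The minimal explanation places one loss on the stem branch of every
maximal clade whose leaves are all absent.

Tree building uses canonical neighbor joining (Q-criterion agglomeration,
via scikit-bio) on p-distances or Jukes–Cantor corrected distances from a
concatenated, gap-column-free CNS alignment, with bootstrap support from
column resampling.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj

from .intervals import GenomicInterval, coverage_fraction, merge_intervals

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Presence matrix and Dollo losses


@dataclass
class PresenceMatrix:
    """Union-row ancestral CNSs x species presence/absence."""

    rows: list[GenomicInterval]
    presence: pd.DataFrame  # bool; index = row ids, columns = species

    @property
    def species(self) -> list[str]:
        return list(self.presence.columns)


def build_presence_matrix(
    tracks: dict[str, list[GenomicInterval]],
    min_coverage: float = 0.5,
) -> PresenceMatrix:
    """Union of all per-species conserved tracks (outgroup coordinates),
    with a species present on a row when its track covers at least
    ``min_coverage`` of the row's bases."""
    all_ivs = [iv for track in tracks.values() for iv in track]
    if not all_ivs:
        return PresenceMatrix([], pd.DataFrame(columns=sorted(tracks)))
    rows = merge_intervals(all_ivs)
    data = {}
    for sp in sorted(tracks):
        track = merge_intervals(tracks[sp]) if tracks[sp] else []
        data[sp] = [coverage_fraction(row, track) >= min_coverage for row in rows]
    presence = pd.DataFrame(data, index=[f"row{i}" for i in range(len(rows))])
    return PresenceMatrix(rows, presence)


@dataclass
class LossAssignment:
    per_branch: dict[str, int]
    per_row: dict[str, list[str]] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.per_branch.values())


def _name_internals(tree: TreeNode) -> TreeNode:
    i = 0
    for node in tree.traverse(include_self=True):
        if not node.name:
            i += 1
            node.name = f"anc{i}"
    return tree


def dollo_losses(tree: TreeNode, absent: set[str]) -> list[str]:
    """Stem branches of the maximal all-absent clades of a rooted tree."""
    status: dict[int, bool] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            status[id(node)] = node.name in absent
        else:
            status[id(node)] = all(status[id(c)] for c in node.children)
    losses = []
    for node in tree.preorder(include_self=False):
        if status[id(node)] and not status[id(node.parent)]:
            losses.append(node.name)
    return losses


def assign_losses(matrix: PresenceMatrix, tree: TreeNode) -> LossAssignment:
    """Minimal-loss (Dollo) branch assignment for every presence-matrix row.

    Rows absent in every species cannot occur by construction of the union;
    a row present everywhere contributes no loss.
    """
    leaves = {t.name for t in tree.tips()}
    missing = set(matrix.species) - leaves
    if missing:
        raise ValueError(f"species not in tree: {sorted(missing)}")
    work = tree
    if leaves != set(matrix.species):
        work = tree.shear(matrix.species)
    work = _name_internals(work.copy())
    per_branch: dict[str, int] = {}
    per_row: dict[str, list[str]] = {}
    for row_id, row in matrix.presence.iterrows():
        absent = set(row.index[~row.values])
        if not absent:
            per_row[row_id] = []
            continue
        losses = dollo_losses(work, absent)
        per_row[row_id] = losses
        for br in losses:
            per_branch[br] = per_branch.get(br, 0) + 1
    return LossAssignment(per_branch=per_branch, per_row=per_row)


# ---------------------------------------------------------------------------
# Concatenated CNS alignment and NJ


def concat_alignment(
    per_cns_alignments: list[dict[str, str]],
    species: list[str] | None = None,
) -> dict[str, str]:
    """Concatenate reference-anchored per-CNS alignments, dropping every
    column that carries a gap or ambiguous base in any species.

    Each item maps species name to an equal-length aligned string (the
    reference species included as itself). CNSs missing a species are
    excluded (logged), not an error.
    """
    if species is None:
        species = sorted({sp for aln in per_cns_alignments for sp in aln})
    parts: dict[str, list[str]] = {sp: [] for sp in species}
    for i, aln in enumerate(per_cns_alignments):
        if not all(sp in aln for sp in species):
            logger.info("CNS %d lacks some species; excluded", i)
            continue
        lengths = {len(aln[sp]) for sp in species}
        if len(lengths) != 1:
            raise ValueError(f"CNS {i}: aligned strings differ in length")
        mats = np.array([list(aln[sp].upper()) for sp in species])
        good = np.all(np.isin(mats, list("ACGT")), axis=0)
        for j, sp in enumerate(species):
            parts[sp].append("".join(mats[j, good]))
    return {sp: "".join(chunks) for sp, chunks in parts.items()}


def distance_matrix(
    seqs: dict[str, str], model: str = "p-distance"
) -> DistanceMatrix:
    """Pairwise p-distance or JC-corrected distance over gap-free site pairs."""
    names = sorted(seqs)
    if len({len(s) for s in seqs.values()}) != 1:
        raise ValueError("sequences must have equal length")
    arrs = {n: np.frombuffer(seqs[n].upper().encode(), dtype=np.uint8)
            for n in names}
    valid = {n: np.isin(arrs[n], np.frombuffer(b"ACGT", dtype=np.uint8))
             for n in names}
    n = len(names)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[names[i]] & valid[names[j]]
            if not both.any():
                raise ValueError(
                    f"no comparable sites between {names[i]} and {names[j]}")
            p = float(np.mean(arrs[names[i]][both] != arrs[names[j]][both]))
            if model == "p-distance":
                d = p
            elif model in ("JC", "jc"):
                if p >= 0.75:
                    raise ValueError("JC distance undefined at p >= 0.75")
                d = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
            else:
                raise ValueError(f"unknown distance model {model!r}")
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat, ids=names)


def nj_from_distances(dm: DistanceMatrix) -> TreeNode:
    """Canonical NJ (Q-criterion) tree from a distance matrix."""
    if dm.shape[0] < 3:
        raise ValueError("NJ needs at least 3 taxa")
    return _skbio_nj(dm)


def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions of an unrooted tree, canonically encoded as
    the side not containing the lexicographically first taxon."""
    leaves = sorted(t.name for t in tree.tips())
    anchor = leaves[0]
    all_set = frozenset(leaves)
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if anchor in side:
            side = all_set - side
        if 1 < len(side) < len(all_set) - 1:
            out.add(side)
    return out


def same_topology(t1: TreeNode, t2: TreeNode) -> bool:
    return bipartitions(t1) == bipartitions(t2)


@dataclass
class NJResult:
    tree: TreeNode
    support: dict[frozenset, float]
    n_columns: int

    def newick(self) -> str:
        """Newick with bootstrap support (%) as internal node labels."""
        t = self.tree.copy()
        leaves = sorted(x.name for x in t.tips())
        anchor, all_set = leaves[0], frozenset(leaves)
        for node in t.non_tips(include_self=False):
            side = frozenset(x.name for x in node.tips())
            if anchor in side:
                side = all_set - side
            if side in self.support:
                node.name = f"{round(100 * self.support[side])}"
        buf = io.StringIO()
        t.write(buf, format="newick")
        return buf.getvalue().strip()


def nj_tree(
    seqs: dict[str, str],
    distance_model: str = "p-distance",
    bootstrap_reps: int = 100,
    seed: int = 0,
) -> NJResult:
    """NJ tree from an aligned (gap-free) sequence matrix with bootstrap
    support by column resampling; support = fraction of replicate trees
    containing each bipartition of the main tree."""
    names = sorted(seqs)
    if len(names) != len(set(names)):
        raise ValueError("duplicate taxon ids")
    length = {len(s) for s in seqs.values()}
    if len(length) != 1 or length == {0}:
        raise ValueError("need equal-length, nonempty sequences")
    n_cols = length.pop()
    if n_cols == 0:
        raise ValueError("zero alignment columns")
    main = nj_from_distances(distance_matrix(seqs, distance_model))
    splits = bipartitions(main)
    counts = {s: 0 for s in splits}
    rng = np.random.default_rng(seed)
    arrs = {n: np.array(list(seqs[n])) for n in names}
    for _ in range(bootstrap_reps):
        idx = rng.integers(0, n_cols, size=n_cols)
        boot = {n: "".join(arrs[n][idx]) for n in names}
        try:
            bt = nj_from_distances(distance_matrix(boot, distance_model))
        except ValueError:
            continue
        bsplits = bipartitions(bt)
        for s in splits:
            if s in bsplits:
                counts[s] += 1
    support = {s: c / bootstrap_reps for s, c in counts.items()} \
        if bootstrap_reps else {}
    return NJResult(tree=main, support=support, n_columns=n_cols)


def patristic_distances(tree: TreeNode) -> pd.DataFrame:
    """Leaf-to-leaf path lengths of a tree, as a symmetric DataFrame."""
    dm = tree.tip_tip_distances()
    return pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))
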