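"""Synthetic clade generator.

Evolves an ancestral genome along a rooted species tree under a
Jukes–Cantor substitution process with site-class rate multipliers:

* neutral background (intergenic, introns, UTRs) at the branch's nominal
  rate;
* planted noncoding elements at ``constrained_rate_factor`` times neutral,
  drawn at the root with GC content ``element_ancestral_gc`` (already below
  background) and substituting toward an AT-richer equilibrium
  (``gc_target_old_elements``), emulating the compositional decay of
  long-constrained elements and yielding a GC->AT substitution excess on
  every lineage;
* coding sites at codon-position-specific rates. ``codon_rate_profile``
  is normalised so the fastest position (the third, mostly synonymous)
  evolves at the neutral rate; first and second positions are then
  proportionally constrained, which places mean coding divergence below
  neutral divergence as required for coding-calibrated thresholds.

Element loss is modelled two ways, mirroring the two biological loss
processes: ``deletion`` excises the interval from every genome below the
loss branch; ``release`` lets the element evolve at the full neutral rate
from that branch onward, so it diverges past recognition when neutral
divergence exceeds the detection threshold.

Indels (geometric length, mean 3 bp) are sampled along the root-to-leaf
path length but applied in background regions at the leaves, keeping
feature coordinates exactly trackable through a per-leaf offset map.
Output genomes are soft-masked (lowercase) over gene exons and simulated
repeat runs.
"""

from __future__ import annotations

import io
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from skbio import TreeNode

from .intervals import GenomicInterval, merge_intervals
from .seqio import (
    GeneModel,
    write_bed,
    write_fasta,
    write_gff3,
    write_variants,
)

CHROM = "chr1"
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class LossEvent:
    element_id: int
    branch: str
    mode: str  # 'deletion' or 'release'

    def __post_init__(self) -> None:
        if self.mode not in ("deletion", "release"):
            raise ValueError(f"unknown loss mode {self.mode!r}")


@dataclass(frozen=True)
class RelocationEvent:
    """Move one element to the opposite genomic context in a single leaf."""

    element_id: int
    leaf: str


@dataclass
class SimConfig:
    """Parameters of one simulated clade. See module docstring for the model."""

    tree: str
    genome_length: int = 200_000
    n_genes: int = 30
    n_elements: int = 100
    element_length_range: tuple[int, int] = (150, 400)
    constrained_rate_factor: float = 0.1
    codon_rate_profile: tuple[float, float, float] = (0.5, 0.4, 3.0)
    indel_rate: float = 0.005
    loss_events: list[LossEvent] = field(default_factory=list)
    gene_deletions: list[tuple[str, str]] = field(default_factory=list)
    relocation_events: list[RelocationEvent] = field(default_factory=list)
    gc_background: float = 0.5
    element_ancestral_gc: float = 0.42
    gc_target_old_elements: float = 0.30
    mask_fraction: float = 0.15
    intron_element_fraction: float = 0.3
    variants_per_kb: float = 1.0
    variant_selection_gamma: float = 6.0
    outgroup_error_rate: float = 0.01
    reference: str | None = None
    seed: int = 0

    def validate(self, tree: TreeNode) -> None:
        if self.constrained_rate_factor < 0 or self.constrained_rate_factor >= 1:
            raise ValueError("constrained_rate_factor must be in [0, 1)")
        if any(r < 0 for r in self.codon_rate_profile) or \
                max(self.codon_rate_profile) == 0:
            raise ValueError("codon_rate_profile rates must be >= 0, not all zero")
        if self.indel_rate < 0 or self.variants_per_kb < 0:
            raise ValueError("rates must be >= 0")
        lo, hi = self.element_length_range
        if not (0 < lo <= hi):
            raise ValueError("invalid element_length_range")
        names = {n.name for n in tree.traverse() if n.name}
        for ev in self.loss_events:
            if ev.branch not in names:
                raise ValueError(f"loss-event branch {ev.branch!r} not in tree")
            if not 0 <= ev.element_id < self.n_elements:
                raise ValueError(f"loss-event element {ev.element_id} out of range")
        leaves = {t.name for t in tree.tips()}
        for ev in self.relocation_events:
            if ev.leaf not in leaves:
                raise ValueError(f"relocation leaf {ev.leaf!r} not in tree")
        for node in tree.traverse(include_self=False):
            if node.length is None or node.length < 0:
                raise ValueError("every branch needs a nonnegative length")
        if len(list(tree.tips())) < 2:
            raise ValueError("tree needs at least two leaves")


def prepare_tree(newick: str) -> TreeNode:
    """Parse newick and give deterministic names to unnamed internal nodes."""
    tree = TreeNode.read(io.StringIO(newick), format="newick")
    i = 0
    for node in tree.traverse(include_self=True):
        if not node.name:
            i += 1
            node.name = f"anc{i}"
    return tree


# ---------------------------------------------------------------------------
# Ancestral layout


class _Spacer:
    """Tracks free sub-intervals of background space for feature placement."""

    def __init__(self, intervals: Iterable[tuple[int, int]]):
        self.free = [(s, e) for s, e in intervals if e > s]

    def place(self, rng: np.random.Generator, length: int, margin: int) -> int | None:
        cand = [i for i, (s, e) in enumerate(self.free)
                if e - s >= length + 2 * margin]
        if not cand:
            return None
        i = cand[int(rng.integers(len(cand)))]
        s, e = self.free[i]
        off = int(rng.integers(s + margin, e - margin - length + 1))
        repl = [(s, off - margin), (off + length + margin, e)]
        self.free[i:i + 1] = [(a, b) for a, b in repl if b > a]
        return off


@dataclass
class _Element:
    element_id: int
    start: int
    end: int
    context: str  # 'intergenic' or 'intron'
    host_gene: str | None = None


def _build_gene(rng: np.random.Generator, start: int, gene_id: str) -> tuple[GeneModel, np.ndarray, int]:
    """Blueprint a 3-exon gene at ``start``; returns (model, cds codon-position
    map as (genomic_pos, codon_pos) array, genomic end)."""
    strand = "+" if rng.random() < 0.5 else "-"
    u5 = int(rng.integers(60, 201))
    cds_len = 3 * int(rng.integers(100, 301))
    u3 = int(rng.integers(100, 301))
    c1 = 3 * int(rng.integers(20, cds_len // 3 - 40))
    c2 = 3 * int(rng.integers(20, (cds_len - c1) // 3 - 19))
    c3 = cds_len - c1 - c2
    i1 = int(rng.integers(400, 1201))
    i2 = int(rng.integers(400, 1201))
    # genomic order of transcript parts
    if strand == "+":
        parts = [("utr5", u5), ("cds", c1), ("intron", i1), ("cds", c2),
                 ("intron", i2), ("cds", c3), ("utr3", u3)]
    else:
        parts = [("utr3", u3), ("cds", c3), ("intron", i2), ("cds", c2),
                 ("intron", i1), ("cds", c1), ("utr5", u5)]
    pos = start
    cds_ivs, utr5_ivs, utr3_ivs = [], [], []
    exon_bounds: list[list[int]] = []
    open_exon: list[int] | None = None
    for kind, length in parts:
        iv = (pos, pos + length)
        if kind == "intron":
            if open_exon:
                exon_bounds.append(open_exon)
            open_exon = None
        else:
            if open_exon is None:
                open_exon = [iv[0], iv[1]]
            else:
                open_exon[1] = iv[1]
            if kind == "cds":
                cds_ivs.append(iv)
            elif kind == "utr5":
                utr5_ivs.append(iv)
            else:
                utr3_ivs.append(iv)
        pos += length
    if open_exon:
        exon_bounds.append(open_exon)
    gene = GeneModel(
        gene_id=gene_id, transcript_id=f"{gene_id}.t1", chrom=CHROM,
        strand=strand,
        exons=[GenomicInterval(CHROM, s, e, strand) for s, e in exon_bounds],
        cds=[GenomicInterval(CHROM, s, e, strand) for s, e in cds_ivs],
        utr5=[GenomicInterval(CHROM, s, e, strand) for s, e in utr5_ivs],
        utr3=[GenomicInterval(CHROM, s, e, strand) for s, e in utr3_ivs],
    )
    # codon position per genomic CDS site, respecting strand and exon order
    genomic = np.concatenate([np.arange(s, e) for s, e in sorted(cds_ivs)])
    tr_order = genomic if strand == "+" else genomic[::-1]
    codon_pos = np.empty(len(tr_order), dtype=np.int64)
    codon_pos[:] = np.arange(len(tr_order)) % 3
    cp = dict(zip(tr_order.tolist(), codon_pos.tolist()))
    cds_map = np.array([[p, cp[p]] for p in genomic.tolist()], dtype=np.int64)
    return gene, cds_map, pos


def _shift_gene(g: GeneModel, offset: int) -> GeneModel:
    return GeneModel(
        gene_id=g.gene_id, transcript_id=g.transcript_id, chrom=g.chrom,
        strand=g.strand,
        exons=[iv.shifted(offset) for iv in g.exons],
        cds=[iv.shifted(offset) for iv in g.cds],
        utr5=[iv.shifted(offset) for iv in g.utr5],
        utr3=[iv.shifted(offset) for iv in g.utr3],
    )


def _random_codes(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p)


# ---------------------------------------------------------------------------
# Evolution


def _substitute(
    codes: np.ndarray,
    t: float,
    rates: np.ndarray,
    at_biased: np.ndarray,
    gc: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One branch of Jukes–Cantor evolution; biased sites draw replacements
    from an AT-rich stationary distribution."""
    p_change = 0.75 * (1.0 - np.exp(-4.0 * t * rates / 3.0))
    mut = rng.random(len(codes)) < p_change
    idx = np.nonzero(mut)[0]
    if len(idx) == 0:
        return codes
    out = codes.copy()
    plain = idx[~at_biased[idx]]
    if len(plain):
        out[plain] = (codes[plain] + rng.integers(1, 4, size=len(plain))) % 4
    biased = idx[at_biased[idx]]
    if len(biased):
        pi = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        new = rng.choice(4, size=len(biased), p=pi)
        clash = new == codes[biased]
        while clash.any():
            new[clash] = rng.choice(4, size=int(clash.sum()), p=pi)
            clash = new == codes[biased]
        out[biased] = new
    return out


@dataclass
class _LeafState:
    codes: np.ndarray  # ancestral-coordinate sequence at the leaf
    released: frozenset
    deleted: frozenset
    deleted_genes: frozenset
    path_length: float


@dataclass
class SimResult:
    """Everything one simulated clade produced."""

    config: SimConfig
    tree: TreeNode
    reference: str
    genomes: dict[str, str]
    genes: dict[str, list[GeneModel]]
    masks: dict[str, list[GenomicInterval]]
    truth: pd.DataFrame
    variants: pd.DataFrame
    leaf_codes: dict[str, np.ndarray]  # ancestral-coordinate codes per leaf
    anc_elements: list[_Element]

    def leaves(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    def element_intervals(self, leaf: str) -> list[GenomicInterval]:
        """Planted-element intervals present in ``leaf``, in leaf coordinates."""
        out = []
        for _, row in self.truth.iterrows():
            s, e = row[f"{leaf}_start"], row[f"{leaf}_end"]
            if s >= 0:
                out.append(GenomicInterval(CHROM, int(s), int(e), ".",
                                           f"elem{int(row.element_id)}"))
        return out

    def exclusion_track(self, leaf: str) -> list[GenomicInterval]:
        """Exonic plus repeat-masked bases: regions a CNS may not overlap."""
        ivs = [iv for g in self.genes[leaf] for iv in g.exons]
        return merge_intervals(ivs + list(self.masks[leaf]))

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for leaf in self.leaves():
            paths[f"genome_{leaf}"] = p = outdir / f"{leaf}.fa"
            write_fasta({CHROM: self.genomes[leaf]}, p)
            paths[f"genes_{leaf}"] = p = outdir / f"{leaf}.gff3"
            write_gff3(self.genes[leaf], p)
            paths[f"mask_{leaf}"] = p = outdir / f"{leaf}.mask.bed"
            write_bed(self.masks[leaf], p)
        paths["truth"] = p = outdir / "truth.tsv"
        self.truth.to_csv(p, sep="\t", index=False)
        paths["variants"] = p = outdir / "variants.tsv"
        write_variants(self.variants, p)
        paths["tree"] = p = outdir / "tree.nwk"
        self.tree.write(str(p), format="newick")
        return paths


def simulate_clade(config: SimConfig) -> SimResult:
    """Generate genomes, gene models, truth table and variants for a clade."""
    tree = prepare_tree(config.tree)
    config.validate(tree)
    rng = np.random.default_rng(config.seed)
    L = config.genome_length

    # --- ancestral layout ------------------------------------------------
    gap_min = 2500
    blueprints = [_build_gene(rng, 0, f"g{i:04d}") for i in range(config.n_genes)]
    span_total = sum(end for _, _, end in blueprints)
    budget = L - span_total - (config.n_genes + 1) * gap_min
    if budget < 0:
        raise ValueError("genome_length too small for requested gene count")
    extra = rng.multinomial(
        budget, np.full(config.n_genes + 1, 1.0 / (config.n_genes + 1)))
    genes: list[GeneModel] = []
    cds_maps: list[np.ndarray] = []
    gaps: list[tuple[int, int]] = []
    cursor = 0
    for i, (g, m, span) in enumerate(blueprints):
        gap = gap_min + int(extra[i])
        gaps.append((cursor, cursor + gap))
        cursor += gap
        genes.append(_shift_gene(g, cursor))
        m = m.copy()
        m[:, 0] += cursor
        cds_maps.append(m)
        cursor += span
    gaps.append((cursor, cursor + gap_min + int(extra[-1])))
    cursor = gaps[-1][1]
    L = cursor  # layout fills the genome exactly

    spacer = _Spacer(gaps)
    intron_spacer = _Spacer(
        [(iv.start, iv.end) for g in genes for iv in g.introns()]
    )
    elements: list[_Element] = []
    intron_by_pos = sorted(
        [(iv.start, iv.end, g.gene_id) for g in genes for iv in g.introns()]
    )

    n_intron = int(round(config.n_elements * config.intron_element_fraction))
    lo, hi = config.element_length_range
    for eid in range(config.n_elements):
        length = int(rng.integers(lo, hi + 1))
        use_intron = eid < n_intron
        sp = intron_spacer if use_intron else spacer
        off = sp.place(rng, length, margin=60 if use_intron else 150)
        if off is None and use_intron:
            use_intron, sp = False, spacer
            off = sp.place(rng, length, margin=150)
        if off is None:
            raise ValueError("could not place all elements; enlarge genome_length")
        host = None
        if use_intron:
            for s, e, gid in intron_by_pos:
                if s <= off and off + length <= e:
                    host = gid
                    break
        elements.append(_Element(eid, off, off + length,
                                 "intron" if use_intron else "intergenic", host))
    elements.sort(key=lambda e: e.start)
    # keep ids stable by re-sorting on id for truth table but positions sorted
    # for masking bookkeeping
    # --- masked repeat runs ----------------------------------------------
    masks: list[GenomicInterval] = []
    bg_total = sum(e - s for s, e in gaps)
    target = int(config.mask_fraction * bg_total)
    covered = 0
    attempts = 0
    while covered < target and attempts < 10_000:
        attempts += 1
        run = int(rng.integers(100, 601))
        off = spacer.place(rng, run, margin=50)
        if off is None:
            break
        masks.append(GenomicInterval(CHROM, off, off + run))
        covered += run
    masks = merge_intervals(masks) if masks else []

    # --- ancestral sequence and site classes ------------------------------
    codes = _random_codes(rng, L, config.gc_background)
    rates = np.ones(L)
    at_biased = np.zeros(L, dtype=bool)
    elem_of_site = np.full(L, -1, dtype=np.int64)
    for el in elements:
        codes[el.start:el.end] = _random_codes(
            rng, el.end - el.start, config.element_ancestral_gc)
        rates[el.start:el.end] = config.constrained_rate_factor
        at_biased[el.start:el.end] = True
        elem_of_site[el.start:el.end] = el.element_id
    profile = np.asarray(config.codon_rate_profile, dtype=float)
    factors = profile / profile.max()
    for m in cds_maps:
        rates[m[:, 0]] = factors[m[:, 1]]

    # --- evolve along the tree --------------------------------------------
    loss_by_branch: dict[str, list[LossEvent]] = {}
    for ev in config.loss_events:
        loss_by_branch.setdefault(ev.branch, []).append(ev)
    gene_del_by_branch: dict[str, list[str]] = {}
    for gid, branch in config.gene_deletions:
        gene_del_by_branch.setdefault(branch, []).append(gid)

    leaf_states: dict[str, _LeafState] = {}

    def recurse(node, codes_in, released, deleted, deleted_genes, rates_in, path):
        for child in node.children:
            rel, dele, gdel = set(released), set(deleted), set(deleted_genes)
            r = rates_in
            for ev in loss_by_branch.get(child.name, []):
                if ev.mode == "release":
                    rel.add(ev.element_id)
                else:
                    dele.add(ev.element_id)
            gdel.update(gene_del_by_branch.get(child.name, []))
            if rel != released:
                r = rates_in.copy()
                for eid in rel - released:
                    el = next(e for e in elements if e.element_id == eid)
                    r[el.start:el.end] = 1.0
                    # released elements also lose the AT bias
            bias = at_biased.copy()
            for eid in rel:
                el = next(e for e in elements if e.element_id == eid)
                bias[el.start:el.end] = False
            child_codes = _substitute(
                codes_in, child.length, r, bias,
                config.gc_target_old_elements, rng)
            if child.is_tip():
                leaf_states[child.name] = _LeafState(
                    child_codes, frozenset(rel), frozenset(dele),
                    frozenset(gdel), path + child.length)
            else:
                recurse(child, child_codes, rel, dele, gdel, r,
                        path + child.length)

    recurse(tree, codes, set(), set(), set(), rates, 0.0)

    leaves = [t.name for t in tree.tips()]
    reference = config.reference or leaves[0]
    if reference not in leaves:
        raise ValueError(f"reference {reference!r} is not a leaf")

    # --- realize leaves: deletions, relocations, indels --------------------
    reloc_by_leaf: dict[str, list[RelocationEvent]] = {}
    for ev in config.relocation_events:
        reloc_by_leaf.setdefault(ev.leaf, []).append(ev)

    exon_ivs = [(iv.start, iv.end) for g in genes for iv in g.exons]
    feature_ivs = sorted(exon_ivs + [(el.start, el.end) for el in elements]
                         + [(m.start, m.end) for m in masks])

    genomes: dict[str, str] = {}
    gene_models: dict[str, list[GeneModel]] = {}
    leaf_masks: dict[str, list[GenomicInterval]] = {}
    elem_coords: dict[str, dict[int, tuple[int, int] | None]] = {}

    def background_gaps() -> list[tuple[int, int]]:
        out, pos = [], 0
        for s, e in feature_ivs:
            if s > pos:
                out.append((pos, s))
            pos = max(pos, e)
        if pos < L:
            out.append((pos, L))
        return out

    bg_gaps = background_gaps()
    bg_lens = np.array([e - s for s, e in bg_gaps], dtype=float)
    bg_p = bg_lens / bg_lens.sum()
    # gaps outside every gene span (relocation targets for intron elements)
    gene_free: list[tuple[int, int]] = []
    occupied = sorted([(g.start, g.end) for g in genes]
                      + [(el.start, el.end) for el in elements]
                      + [(m.start, m.end) for m in masks])
    pos = 0
    for s, e in occupied:
        if s > pos:
            gene_free.append((pos, s))
        pos = max(pos, e)
    if pos < L:
        gene_free.append((pos, L))

    for leaf in leaves:
        st = leaf_states[leaf]
        rng_leaf = np.random.default_rng(
            np.random.SeedSequence([config.seed, 7, zlib.crc32(leaf.encode())]))
        edits: list[tuple[int, int, np.ndarray | None]] = []  # (pos, del_len, ins)
        # element deletions
        deleted_elems = set(st.deleted)
        for gid in st.deleted_genes:
            g = next(g for g in genes if g.gene_id == gid)
            edits.append((g.start, g.end - g.start, None))
            for el in elements:
                if g.start <= el.start and el.end <= g.end:
                    deleted_elems.add(el.element_id)
        for eid in st.deleted:
            el = next(e for e in elements if e.element_id == eid)
            edits.append((el.start, el.end - el.start, None))
        # relocations
        relocated: dict[int, tuple[int, int]] = {}  # eid -> (ins_anchor, length)
        for ev in reloc_by_leaf.get(leaf, []):
            el = next(e for e in elements if e.element_id == ev.element_id)
            if el.element_id in deleted_elems:
                continue
            if el.context == "intergenic":
                target_pool = [
                    (iv.start, iv.end) for g in genes for iv in g.introns()
                    if not any(el2.start < iv.end and el2.end > iv.start
                               for el2 in elements)
                    and iv.end - iv.start > (el.end - el.start) + 80
                ]
            else:
                target_pool = [(s, e) for s, e in gene_free
                               if e - s > (el.end - el.start) + 200]
            if not target_pool:
                continue
            s, e = target_pool[int(rng_leaf.integers(len(target_pool)))]
            anchor = int(rng_leaf.integers(s + 40, e - 40 - (el.end - el.start) + 1))
            edits.append((el.start, el.end - el.start, None))
            edits.append((anchor, 0, st.codes[el.start:el.end].copy()))
            relocated[el.element_id] = (anchor, el.end - el.start)
        # background indels
        n_indels = rng_leaf.poisson(config.indel_rate * st.path_length * L)
        for _ in range(n_indels):
            gi = int(rng_leaf.choice(len(bg_gaps), p=bg_p))
            s, e = bg_gaps[gi]
            length = min(int(rng_leaf.geometric(1 / 3.0)), max(1, (e - s) // 2))
            if rng_leaf.random() < 0.5:  # deletion inside the gap
                if e - s <= length + 2:
                    continue
                pos = int(rng_leaf.integers(s + 1, e - length))
                edits.append((pos, length, None))
            else:  # insertion
                pos = int(rng_leaf.integers(s + 1, e - 1))
                edits.append((pos, 0, rng_leaf.integers(0, 4, size=length)))

        edits.sort(key=lambda t: (t[0], t[1]))
        # drop overlapping deletions (keep first)
        cleaned: list[tuple[int, int, np.ndarray | None]] = []
        last_del_end = -1
        for pos, dlen, ins in edits:
            if pos < last_del_end:
                continue  # edit falls inside an earlier deletion
            if dlen > 0:
                last_del_end = pos + dlen
            cleaned.append((pos, dlen, ins))

        # build leaf sequence and ancestral->leaf coordinate map
        pieces: list[np.ndarray] = []
        cuts: list[tuple[int, int]] = []  # (anc_pos, new_pos_at_that_anc_pos)
        cur_anc, cur_new = 0, 0
        for pos, dlen, ins in cleaned:
            seg = st.codes[cur_anc:pos]
            pieces.append(seg)
            cur_new += len(seg)
            cur_anc = pos
            if dlen > 0:
                cur_anc += dlen
            if ins is not None:
                pieces.append(ins)
                cur_new += len(ins)
            cuts.append((cur_anc, cur_new))
        pieces.append(st.codes[cur_anc:])
        leaf_codes_final = np.concatenate(pieces) if pieces else st.codes
        cut_anc = np.array([c[0] for c in cuts], dtype=np.int64)
        cut_new = np.array([c[1] for c in cuts], dtype=np.int64)

        def amap(p: int) -> int:
            i = np.searchsorted(cut_anc, p, side="right") - 1
            if i < 0:
                return int(p)
            return int(cut_new[i] + (p - cut_anc[i]))

        def map_iv(iv: GenomicInterval) -> GenomicInterval | None:
            s, e = amap(iv.start), amap(iv.end)
            if e <= s:
                return None
            return GenomicInterval(iv.chrom, s, e, iv.strand, iv.name)

        # gene models in leaf coordinates
        leaf_genes = []
        for g in genes:
            if g.gene_id in st.deleted_genes:
                continue
            leaf_genes.append(GeneModel(
                gene_id=g.gene_id, transcript_id=g.transcript_id, chrom=CHROM,
                strand=g.strand,
                exons=[map_iv(iv) for iv in g.exons],
                cds=[map_iv(iv) for iv in g.cds],
                utr5=[map_iv(iv) for iv in g.utr5],
                utr3=[map_iv(iv) for iv in g.utr3],
            ))
        gene_models[leaf] = leaf_genes
        leaf_masks[leaf] = [m2 for m in masks if (m2 := map_iv(m))]

        coords: dict[int, tuple[int, int] | None] = {}
        for el in elements:
            if el.element_id in deleted_elems:
                coords[el.element_id] = None
            elif el.element_id in relocated:
                anchor, ln = relocated[el.element_id]
                s = amap(anchor) - ln  # insertion lands just before the anchor map
                # insertion occurred at anchor: mapped position of anchor is
                # after the inserted bases, so the element spans [s, s+ln)
                coords[el.element_id] = (s, s + ln)
            else:
                coords[el.element_id] = (amap(el.start), amap(el.end))
        elem_coords[leaf] = coords

        # sequence string with soft masking over exons and repeat runs
        seq_arr = _BASES[leaf_codes_final].copy()
        for g in leaf_genes:
            for iv in g.exons:
                seq_arr[iv.start:iv.end] = np.char.lower(seq_arr[iv.start:iv.end])
        for m in leaf_masks[leaf]:
            seq_arr[m.start:m.end] = np.char.lower(seq_arr[m.start:m.end])
        genomes[leaf] = "".join(seq_arr)

    # --- truth table -------------------------------------------------------
    ref_codes = leaf_states[reference].codes
    loss_info = {ev.element_id: ev for ev in config.loss_events}
    rows = []
    for el in sorted(elements, key=lambda e: e.element_id):
        row = {
            "element_id": el.element_id,
            "anc_start": el.start, "anc_end": el.end,
            "context": el.context,
            "loss_branch": loss_info[el.element_id].branch
            if el.element_id in loss_info else "",
            "loss_mode": loss_info[el.element_id].mode
            if el.element_id in loss_info else "",
        }
        for leaf in leaves:
            c = elem_coords[leaf][el.element_id]
            row[f"{leaf}_start"] = c[0] if c else -1
            row[f"{leaf}_end"] = c[1] if c else -1
            if c is None:
                row[f"{leaf}_divergence"] = np.nan
            else:
                a = leaf_states[leaf].codes[el.start:el.end]
                b = ref_codes[el.start:el.end]
                row[f"{leaf}_divergence"] = 100.0 * float(np.mean(a != b))
        rows.append(row)
    truth = pd.DataFrame(rows)

    # --- variants on the reference leaf ------------------------------------
    variants = _simulate_variants(config, truth, reference, genomes[reference],
                                  np.random.default_rng(
                                      np.random.SeedSequence([config.seed, 13])))

    return SimResult(
        config=config, tree=tree, reference=reference, genomes=genomes,
        genes=gene_models, masks=leaf_masks, truth=truth, variants=variants,
        leaf_codes={lf: leaf_states[lf].codes for lf in leaves},
        anc_elements=elements,
    )


def _sample_daf(rng, n, constrained, gamma, grid=50):
    i = np.arange(1, grid)
    w = 1.0 / i
    if constrained:
        w = w * np.exp(-gamma * i / grid)
    w = w / w.sum()
    return rng.choice(i, size=n, p=w) / grid


def _simulate_variants(config, truth, reference, ref_genome, rng):
    """Biallelic sites with population frequencies and an outgroup column.

    Derived-allele frequencies follow a 1/i spectrum, damped by
    exp(-gamma * f) at constrained (element) sites to emulate purifying
    selection. With probability f the reference assembly carries the derived
    allele, so the ref/alt columns require outgroup polarization downstream.
    """
    L = len(ref_genome)
    elem_track = np.zeros(L, dtype=bool)
    for _, row in truth.iterrows():
        s, e = int(row[f"{reference}_start"]), int(row[f"{reference}_end"])
        if s >= 0:
            elem_track[s:e] = True
    seq = np.frombuffer(ref_genome.upper().encode(), dtype=np.uint8)
    code = np.full(256, -1, dtype=np.int64)
    for i, b in enumerate("ACGT"):
        code[ord(b)] = i
    codes = code[seq]
    eligible = codes >= 0
    masked = np.frombuffer(ref_genome.encode(), dtype=np.uint8)
    is_lower = (masked >= ord("a"))
    eligible &= ~is_lower  # skip soft-masked (exonic/repeat) bases

    n_total = int(round(config.variants_per_kb * L / 1000.0))
    pool_elem = np.nonzero(eligible & elem_track)[0]
    pool_bg = np.nonzero(eligible & ~elem_track)[0]
    n_elem = int(round(n_total * len(pool_elem) / max(1, len(pool_elem) + len(pool_bg))))
    n_bg = n_total - n_elem
    n_elem = min(n_elem, len(pool_elem))
    n_bg = min(n_bg, len(pool_bg))
    sites = np.concatenate([
        rng.choice(pool_elem, size=n_elem, replace=False),
        rng.choice(pool_bg, size=n_bg, replace=False),
    ])
    constrained = np.concatenate([
        np.ones(n_elem, dtype=bool), np.zeros(n_bg, dtype=bool)])
    order = np.argsort(sites)
    sites, constrained = sites[order], constrained[order]
    daf = np.empty(len(sites))
    daf[constrained] = _sample_daf(rng, int(constrained.sum()), True,
                                   config.variant_selection_gamma)
    daf[~constrained] = _sample_daf(rng, int((~constrained).sum()), False,
                                    config.variant_selection_gamma)
    rows = []
    for pos, f, is_con in zip(sites, daf, constrained):
        anc = int(codes[pos])
        der = (anc + int(rng.integers(1, 4))) % 4
        if rng.random() < f:
            ref_a, alt_a, alt_freq = der, anc, 1.0 - f
        else:
            ref_a, alt_a, alt_freq = anc, der, f
        out_allele = anc
        if rng.random() < config.outgroup_error_rate:
            others = [b for b in range(4) if b not in (ref_a, alt_a)]
            out_allele = others[int(rng.integers(len(others)))]
        rows.append({
            "chrom": CHROM, "pos": int(pos) + 1,
            "ref": "ACGT"[ref_a], "alt": "ACGT"[alt_a],
            "alt_freq": round(float(alt_freq), 4),
            "outgroup_allele": "ACGT"[out_allele],
            "constrained": bool(is_con),
            "derived_freq_true": round(float(f), 4),
        })
    df = pd.DataFrame(rows, columns=[
        "chrom", "pos", "ref", "alt", "alt_freq", "outgroup_allele",
        "constrained", "derived_freq_true"])
    df["pos0"] = df["pos"] - 1
    return df


def emit_ortholog_cds(
    result: SimResult, leaves: tuple[str, str]
) -> list[tuple[str, str, str]]:
    """In-frame one-to-one ortholog CDS pairs for two leaves.

    Genes deleted in either leaf are excluded. Sequences are spliced CDS in
    transcript orientation; simulator guarantees positional homology (no
    indels inside genes), so pairs are codon-aligned.
    """
    l1, l2 = leaves
    for lf in leaves:
        if lf not in result.genomes:
            raise ValueError(f"unknown leaf {lf!r}")
    by_id = {lf: {g.gene_id: g for g in result.genes[lf]} for lf in leaves}
    out = []
    for gid, g1 in sorted(by_id[l1].items()):
        if gid not in by_id[l2]:
            continue
        seqs = []
        for lf, g in ((l1, g1), (l2, by_id[l2][gid])):
            s = "".join(result.genomes[lf][iv.start:iv.end].upper()
                        for iv in g.cds)
            if g.strand == "-":
                from .seqio import revcomp
                s = revcomp(s)
            seqs.append(s)
        if len(seqs[0]) % 3 or len(seqs[1]) % 3:
            continue
        out.append((gid, seqs[0], seqs[1]))
    return out
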