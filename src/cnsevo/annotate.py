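"""Genomic-context analyses of CNS sets.

Location classification uses fixed priority UTR > promoter > intron >
intergenic (any-base overlap; promoter = 1,000 bp upstream of a
transcript's TSS on its strand). Target genes are assigned by the smallest
average CNS-gene distance across the two species of a pairwise comparison,
within a 1-Mbp window in both. Enrichment uses the exact binomial tail on
term frequencies among target genes versus a background gene set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, intersect_coverage, merge_intervals
from .seqio import GeneModel

logger = logging.getLogger(__name__)

LOCATION_CLASSES = ("utr5", "utr3", "promoter", "intron", "intergenic")


@dataclass
class LocationCall:
    cns_id: str
    location: str
    gene_id: str | None = None


@dataclass
class TargetGeneCall:
    cns_id: str
    gene_id: str
    average_distance: float
    distance_1: float
    distance_2: float


def classify_location(
    cns: GenomicInterval,
    genes: Sequence[GeneModel],
    promoter_bp: int = 1000,
    cns_id: str = "",
) -> LocationCall:
    """Single location class per CNS: UTR beats promoter beats intron beats
    intergenic, regardless of overlap size; ties across genes break by
    larger overlap, then lexicographic gene id."""
    best: tuple[int, int, str, str] | None = None  # (prio, -overlap, gid, class)
    prio = {"utr5": 0, "utr3": 0, "promoter": 1, "intron": 2}
    for g in genes:
        if g.chrom != cns.chrom:
            continue
        regions = {
            "utr5": g.utr5,
            "utr3": g.utr3,
            "promoter": [p] if (p := g.promoter(promoter_bp)) else [],
            "intron": g.introns(),
        }
        for cls, ivs in regions.items():
            ov = sum(cns.overlap_length(iv) for iv in ivs)
            if ov > 0:
                key = (prio[cls], -ov, g.gene_id, cls)
                if best is None or key < best:
                    best = key
    if best is None:
        return LocationCall(cns_id or cns.name, "intergenic", None)
    return LocationCall(cns_id or cns.name, best[3], best[2])


def relocation_matrix(
    calls_by_species: dict[str, dict[str, LocationCall]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise same/different-location counts for single-copy orthologous
    CNSs (multi-copy CNSs must be excluded upstream).

    Returns (counts of differently located CNSs with percentages encoded as
    a separate frame): ``diff_counts`` upper matrix of CNSs in different
    classes, ``diff_pct`` percentage over the pair's comparable CNSs.
    CNSs lacking a call in a species are excluded pairwise (logged).
    """
    species = sorted(calls_by_species)
    diff_counts = pd.DataFrame(np.nan, index=species, columns=species)
    diff_pct = pd.DataFrame(np.nan, index=species, columns=species)
    for i, s1 in enumerate(species):
        for s2 in species[i + 1:]:
            shared = set(calls_by_species[s1]) & set(calls_by_species[s2])
            skipped = set(calls_by_species[s1]) ^ set(calls_by_species[s2])
            if skipped:
                logger.info("%d CNSs lack a call in %s/%s", len(skipped), s1, s2)
            if not shared:
                continue
            diff = sum(
                calls_by_species[s1][c].location != calls_by_species[s2][c].location
                for c in shared
            )
            for a, b in ((s1, s2), (s2, s1)):
                diff_counts.loc[a, b] = diff
                diff_pct.loc[a, b] = 100.0 * diff / len(shared)
    return diff_counts, diff_pct


def _gene_distance(cns: GenomicInterval, gene_span: GenomicInterval) -> float:
    """Edge-to-edge distance; 0 when the CNS overlaps the gene body."""
    if cns.overlaps(gene_span):
        return 0.0
    if gene_span.start >= cns.end:
        return float(gene_span.start - cns.end)
    return float(cns.start - gene_span.end)


def assign_target_gene(
    cns_id: str,
    cns_sp1: GenomicInterval,
    cns_sp2: GenomicInterval,
    genes_sp1: dict[str, GeneModel],
    genes_sp2: dict[str, GeneModel],
    ortholog_map: dict[str, str],
    window: int = 1_000_000,
) -> TargetGeneCall | None:
    """Likely target gene of a CNS with a homolog in a second species.

    Candidates are one-to-one ortholog pairs lying within ``window`` of the
    CNS in *both* species; the winner minimizes the average of the two
    CNS-gene distances. Ties break by smaller species-1 distance, then gene
    id. Returns None when no candidate is in the window."""
    best: tuple[float, float, str] | None = None
    for gid1, gid2 in sorted(ortholog_map.items()):
        if gid1 not in genes_sp1 or gid2 not in genes_sp2:
            continue
        d1 = _gene_distance(cns_sp1, genes_sp1[gid1].span)
        d2 = _gene_distance(cns_sp2, genes_sp2[gid2].span)
        if d1 > window or d2 > window:
            continue
        key = ((d1 + d2) / 2.0, d1, gid1)
        if best is None or key < best:
            best = key
    if best is None:
        return None
    avg, d1, gid1 = best
    return TargetGeneCall(cns_id, gid1, avg, d1, 2 * avg - d1)


def density_correlation(
    cns_track: Sequence[GenomicInterval],
    gene_spans: Sequence[GenomicInterval],
    chrom_sizes: dict[str, int],
    window: int = 1_000_000,
    step: int = 100_000,
) -> tuple[float, float, int]:
    """Pearson correlation of CNS and gene counts in sliding windows.

    Membership is by feature midpoint; only windows containing at least one
    CNS and one gene enter the correlation (empty windows, e.g. around
    centromeres, are excluded).
    """
    cns_mid = {}
    gene_mid = {}
    for chrom in chrom_sizes:
        cns_mid[chrom] = np.sort([
            (iv.start + iv.end) // 2 for iv in cns_track if iv.chrom == chrom])
        gene_mid[chrom] = np.sort([
            (iv.start + iv.end) // 2 for iv in gene_spans if iv.chrom == chrom])
    cns_counts, gene_counts = [], []
    for chrom, size in chrom_sizes.items():
        starts = np.arange(0, max(1, size - window + step), step)
        for s in starts:
            e = min(s + window, size)
            c = np.searchsorted(cns_mid[chrom], e) - np.searchsorted(cns_mid[chrom], s)
            g = np.searchsorted(gene_mid[chrom], e) - np.searchsorted(gene_mid[chrom], s)
            if c >= 1 and g >= 1:
                cns_counts.append(c)
                gene_counts.append(g)
    if len(cns_counts) < 3:
        raise ValueError("fewer than 3 windows with both a CNS and a gene")
    if np.std(cns_counts) == 0 or np.std(gene_counts) == 0:
        raise ValueError("degenerate counts: correlation undefined")
    r, p = stats.pearsonr(cns_counts, gene_counts)
    return float(r), float(p), len(cns_counts)


def enrichment_binomial(
    target_genes: Sequence[str],
    term_map: dict[str, set[str]],
    background_genes: Sequence[str],
) -> pd.DataFrame:
    """Per-term enrichment ratio and exact binomial tail p-values.

    For each term with background fraction p0, x of the n target genes
    carrying the term gives enrichment x / (n * p0), an overrepresentation
    p-value P(X >= x) and a depletion p-value P(X <= x) under
    Binomial(n, p0).
    """
    background = set(background_genes)
    targets = [g for g in target_genes]
    n = len(targets)
    rows = []
    for term in sorted(term_map):
        members = term_map[term] & background
        p0 = len(members) / len(background)
        x = sum(g in term_map[term] for g in targets)
        if p0 == 0:
            if x > 0:
                raise ValueError(
                    f"term {term!r} absent from background but present in targets")
            continue
        expected = n * p0
        rows.append({
            "term": term,
            "n_target": x,
            "expected": expected,
            "enrichment": x / expected if expected > 0 else np.nan,
            "p_over": float(stats.binom.sf(x - 1, n, p0)),
            "p_under": float(stats.binom.cdf(x, n, p0)),
        })
    return pd.DataFrame(rows)


def signature_overlap(
    cns: Sequence[GenomicInterval],
    signature: Sequence[GenomicInterval],
) -> tuple[pd.Series, int, float]:
    """Any-base overlap of each CNS with a signature track (e.g. ChIP peaks).

    Returns (per-CNS boolean series indexed by CNS name/position, count,
    fraction overlapping)."""
    sig = merge_intervals(list(signature)) if signature else []
    flags = {}
    for iv in cns:
        key = iv.name or f"{iv.chrom}:{iv.start}-{iv.end}"
        flags[key] = bool(intersect_coverage([iv], sig))
    series = pd.Series(flags, dtype=bool)
    count = int(series.sum())
    return series, count, count / len(series) if len(series) else 0.0
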